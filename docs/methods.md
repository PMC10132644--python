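# Methods

## The measurement problem

A phage population under CRISPR-Cas pressure is a mixture of target-region
haplotypes whose composition shifts as escape mutants are selected. The
observable quantities are (i) deep-sequenced amplicons of the
protospacer+PAM window, (ii) long reads over a larger PCR amplicon in which
large deletions can be seen directly, and (iii) in vitro plasmid-cleavage
time courses that calibrate how deleterious a given crRNA–target mismatch
combination is. This package turns each of those observables into a defined
statistic and provides a generator that produces all three data types with
known ground truth.

## Target geometry and position labels

A target window is PAM + protospacer (default 4 + 20 = 24 nt). Positions are
labelled relative to the PAM: PAM bases are negative (−1 adjacent to the
protospacer), protospacer bases 1..N counted from the PAM-proximal end. For
a 5′-PAM effector (Cas12a-like) the numbering runs left-to-right on the
amplicon plus strand; for a 3′-PAM effector (Cas9-like) it runs
right-to-left. Region boundaries are configuration, defaulting to seed =
1–6, mid = 7–12, PAM-distal = 13–N; these match common usage (a position-3
mismatch is "seed", position 8 "mid", 15/19 "PAM-distal") but are not
universal constants, hence the override.

All internal coordinates are 0-based half-open on the amplicon plus strand;
PAM-relative labels exist only at the reporting layer. R2 is
reverse-complemented before any comparison.

## Read-pair handling

The sequencing design guarantees both mates span the whole window, so the
window is located in each read by its two flank anchors (exact match first,
then at most one substitution per anchor, no indels; ambiguous or
out-of-order anchors fail). Anchored location is deterministic and cheap; it
is not a general-purpose aligner and is not meant to be one.

Concordance rule: if both mates cover the window their copies must be
identical, otherwise the pair is `rejected_discordant`; if only R1 covers it
R1's copy is used; if R1 does not reach the window the pair is
`rejected_unalignable`. The filter exists because a base-call or PCR error
on one strand almost never replicates on the other, so requiring agreement
suppresses the error floor. It can be disabled
(`require_concordance=False`), in which case R1's copy wins. A pair whose R1
fails but whose R2 covers the window is rejected rather than rescued — the
fallback convention names R1 only, and accepting R2-only pairs would make
the accepted set depend on which mate failed.

## Variant classes and the deletion-label convention

Accepted windows are compared positionwise to the reference: 0 differences =
wildtype, 1 = single substitution, ≥2 = multiple substitution. A window one
base short is a single-nucleotide deletion; anything else is complex
(multi-nt deletions are reported but excluded from per-position
substitution tabulation). Deleting any base of a homopolymer run yields the
same sequence, so single deletions are resolved leftmost within the run and
labelled canonically at the position adjacent to the run's 3′ side (clamped
to the last window position when the run touches the window edge). The
alternative "first mismatch" label (= the run's last position) is stored on
every call and can be selected at tabulation time; both conventions appear
in practice and carrying both keeps outputs comparable either way.

## Enrichment Z-scores

For per-position proportions of mutated reads, Z(p) = (x̄(p) − μ̄(p)) / σ:
x̄ and μ̄ are cross-replicate means in targeted and non-targeted samples and
σ is one scalar standard deviation pooled over the proportions at all
positions in all supplied samples (targeted and control together). The
pooling is deliberately literal; note its consequence that strongly enriched
positions inflate σ and therefore deflate their own Z — the statistic is a
ranking device, not a calibrated test. The denominator (sample, ddof=1, vs
population) is an option because the definition does not fix it; the default
is ddof=1. σ = 0 (all proportions identical) raises a degenerate-input
error instead of producing NaN.

## Nucleotide diversity

Diversity = (1/L) Σ_{i=2..n} Σ_{j<i} 2 x_i x_j π_ij with π_ij the Hamming
distance between window haplotypes and L the window length (24 by default).
The printed index form is implemented exactly; no small-sample (n/(n−1))
correction is applied. Haplotypes with a single deletion are re-expanded to
window length with a gap character at the canonical deletion position, so a
gap–base mismatch contributes 1 to π; deletion haplotypes can instead be
excluded (`deletions="exclude"`). Complex reads are always excluded — they
have no positionwise alignment.

## Long-read deletion calling and microhomology

Each read is matched piecewise to the wild-type amplicon. With
δ = len(reference) − len(read) > 0, every candidate breakpoint L splits the
read into a prefix aligned to `reference[:L]` and a suffix aligned to
`reference[L+δ:]`; cumulative mismatch arrays make the scan O(n). The split
minimising total substitutions is accepted as a single contiguous deletion
when (a) the total stays within a per-read budget of max(2, 2% of the read
length) and (b) the `min_anchor` (default 20) bases flanking the junction
each match with at most one substitution. Reads failing these checks are
"unresolved" — counted and reported, never silently dropped. This
minimum-mismatch formulation was chosen over a greedy longest-prefix /
longest-suffix scan because a greedy scan aborts on locally clustered
errors: at 0.5% substitution error on multi-kilobase reads it recovered only
about half the planted events, while the split search recovers ≥98% (both
measured by this package's own recovery study).

Identical flanking sequence at the two junctions makes the breakpoint
placement ambiguous: homology is measured as the maximal identical stretch
ending at both junctions plus the maximal stretch starting at both, and the
ambiguity interval of equivalent left breakpoints has exactly that width.
Events are normalised to the leftmost placement (standard variant
normalisation; deterministic), aggregated by canonical breakpoints with
support summed, and translated to genome coordinates by the amplicon's
offset.

## Kinetics

fraction cleaved = (nicked + linear) / (nicked + linear + supercoiled);
nicked and linear are pooled as "cleaved" and no two-step nick→linear model
is fitted. The time course is fit to f(t) = A(1 − e^(−kt)) by bounded least
squares (k ≥ 0, A ∈ [0,1]) restarted from the fixed grid
k₀ ∈ {10⁻⁴, 10⁻³, 10⁻², 10⁻¹, 1} s⁻¹, lowest RSS wins — no random
initialisation, so fits are deterministic. A is fitted freely by default
(several real gels plateau below 1); `fix_plateau` pins it. Degenerate
all-zero traces return k = 0 with a flag. Because the first quench point is
7 s, any k fast enough to reach ≥99% of plateau by then is only bounded from
below; such fits carry `k_is_lower_bound` rather than pretending precision.
Replicates are summarised as mean and sample SD of k_obs over converged
fits; conditions are compared with the classical pooled-variance unpaired
two-tailed t test (Welch optional). Default quench times: 7, 15, 30, 60,
300, 900, 1,800 s.

## Synthetic-data generator

`simulate_population` is a discrete-generation Wright–Fisher-style model:
each generation draws pop_size individuals multinomially with probability ∝
frequency × survival weight, then applies per-base substitution noise
(sites per mutated individual drawn from a Binomial(L, e) truncated at ≥1,
so small error rates cost no rejection sampling). Survival weights are an
explicit stand-in for relative escape from cleavage — weight ratios can be
set from relative cleavage rates. PCR and sequencing errors are collapsed
into one per-base substitution rate since the two are indistinguishable
downstream. Each generator call owns a single numpy RNG seeded explicitly;
identical inputs and seed give byte-identical output, and zero-noise
settings invert the downstream estimators exactly (a round-trip property the
tests rely on).

`emit_amplicon_reads` builds each genotype's full amplicon, takes R1 from
one end and reverse-complemented R2 from the other (both must span window
plus anchors), applies independent per-read errors, and can plant
deliberately discordant pairs flagged in the read identifier so filter
audits are exact. `emit_long_reads` plants deletions by excision and
realises requested junction microhomology by copying the 5′-flank h-mer
onto the 3′ junction of the reference fixture. `emit_timecourse` inverts
the kinetics model with clipped Gaussian noise.

What the generator does **not** emulate: realistic Illumina error profiles
and quality scores (qualities are constant), indel sequencing errors in
long reads, recombination between genotypes, and phage life-cycle dynamics
(burst size, adsorption, MOI structure). Passing tests therefore
demonstrate correctness of the statistics and callers under controlled
substitution noise and known mixtures — not robustness to platform-specific
artefacts.

## Demo escape scenario (defaults)

One synthetic 104-nt amplicon with a TTTA-PAM 24-nt window (8-nt anchors,
75-nt reads — mates overlap the full window as in the assumed sequencing
design). Population: wild type at 0.998 with survival weight 0.02, plus a
PAM −2 mutant and a seed position-2 mutant at 0.001 each with weight 1.0 —
a ~50× propagation advantage, consistent in magnitude with the 15–90×
cleavage-rate reductions such mutations cause in vitro. Six generations at
population size 20,000; two replicates; 2,000 read pairs per sample at
per-base error 10⁻³; per-generation per-base mutation rate 10⁻⁵;
non-targeted control = the same starting population propagated with equal
weights. These sizes make the full experiment (simulation → FASTQ →
classification → Z-scores → report) run in seconds while keeping multinomial
sampling error well below the effects being measured.

## Numerical choices and edge cases

* Frequencies must sum to 1 within 1e-9; empty samples, all-zero gel lanes,
  zero total survival weight, σ = 0 and zero-denominator ratios raise typed
  errors rather than returning NaN.
* Oracle-equivalence tests (diversity, Z-scores, tabulation, deletion
  placements) compare against naive reimplementations at 1e-12.
* Anchored window extraction tolerates one substitution per anchor — enough
  for the synthetic error floor; anchor indels are out of scope.
* Aggregation of deletion events is idempotent by construction (leftmost
  canonical keys).

## Known limitations

* The Z-score is not variance-stabilised; comparisons across samples with
  very different read depths inherit that noise.
* The deletion caller handles one contiguous deletion per read; nested or
  multiple deletions, insertions and inversions are out of scope and land in
  "unresolved".
* The population model has no recombination, which real phage use to
  propagate preexisting mutations; selection coefficients are per-generation
  abstractions, not mechanistic cleavage kinetics.
* Competition ratios are plain read-count ratios; no sampling-error interval
  is attached.
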