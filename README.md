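# phagescape

Quantifying how bacteriophage populations escape CRISPR-Cas targeting.

When bacteria expressing a Cas effector (Cas12a- or Cas9-style) are
challenged with phage, escape mutants carrying substitutions or deletions in
the protospacer/PAM target region are rapidly selected. `phagescape`
implements the computational side of that kind of experiment as a tested,
reusable pipeline:

* **Amplicon variant classification** — paired MiSeq-style reads spanning the
  whole PAM+protospacer window are merged under a strict R1/R2 concordance
  rule (pairs whose window copies disagree are removed; R1 is used when R2
  does not reach the window), and each accepted read is classified as
  wildtype, single/multiple substitution, single-nucleotide deletion, or
  complex, with positions labelled relative to the PAM (PAM = −4…−1,
  protospacer = 1…20 from the PAM-proximal end; e.g. `T-2C`, `A2T`, `G17T`).
* **Positional enrichment Z-scores** — for per-position mutated-read
  proportions x̄ (targeted samples) and μ̄ (non-targeted control),

      Z(p) = (x̄(p) − μ̄(p)) / σ

  with a single σ pooled over the proportions at all positions in all
  samples.
* **Nucleotide diversity** — from haplotype frequencies x_i over the 24-nt
  target window,

      Diversity = (1/L) Σ_{i=2..n} Σ_{j<i} 2 x_i x_j π_ij ,  L = 24,

  where π_ij is the pairwise nucleotide difference count.
* **Long-read deletion calling** — each long amplicon read is matched
  piecewise to the wild-type reference; single contiguous deletions are
  called, leftmost-normalised, annotated with junction microhomology
  (length, sequence, and the full breakpoint-ambiguity window), aggregated,
  and translated to genome coordinates.
* **Cleavage kinetics** — fraction cleaved = (nicked + linear)/total from gel
  densitometry, fit to the first-order model f(t) = A·(1 − e^(−k_obs·t)) by
  deterministic multi-start bounded least squares; replicate averaging and
  unpaired two-tailed t tests between conditions.
* **Synthetic data** — a seeded generator (Wright–Fisher-style multinomial
  selection, paired amplicon reads with planted discordance, long reads with
  planted deletions and microhomology, noisy kinetics time courses) so the
  whole pipeline is testable without external sequencing data.

## Worked example

```python
from phagescape import (
    classify_window, nucleotide_diversity, HaplotypeTable, fit_first_order,
)
from phagescape.pipeline import make_demo_target
from phagescape.synthetic import emit_timecourse

spec = make_demo_target()          # synthetic Cas12a-style target, TTTA PAM
print(spec.reference_window)       # TTTAAGAGACGAAAATCCAACGTG

win = spec.reference_window
mut = win[:5] + "T" + win[6:]      # substitution at protospacer position 2
call = classify_window(mut, spec)
print(call.variant_class, call.variants[0].label, call.variants[0].position.region)
# single_substitution G2T seed

table = HaplotypeTable({win: 0.5, mut: 0.5})
print(round(nucleotide_diversity(table), 6))
# 0.020833  (= 2·0.5·0.5·1/24, i.e. 1/48)

tc = emit_timecourse(k_obs=0.02, plateau=1.0, noise_sd=0.01, seed=7)
fit = fit_first_order(tc)
print(f"k_obs = {fit.k_obs:.4f} /s, plateau = {fit.plateau:.3f}")
# k_obs = 0.0199 /s, plateau = 0.995
```

The mutant read is a `G2T` seed substitution (position 2 counted from the
PAM); the 50/50 mixture of the two haplotypes has diversity 1/48 per site;
and the fitted rate constant recovers the simulated 0.02 s⁻¹ within the 1%
noise level.

## Command line

```bash
phagescape simulate --out demo --seed 1          # synthetic escape experiment
phagescape classify --config demo/analysis_config.yaml --out demo_results
phagescape report   --config demo/analysis_config.yaml --out demo_results
phagescape deletions --reads reads.fastq --reference amplicon.fasta \
    --out dels --genome-offset 19000
phagescape kinetics --table timecourses.tsv --out kin
```

`classify` writes per-read classification tables, per-position mutation
proportions, Z-scores vs the control samples, per-sample nucleotide
diversity, the fraction-mutated time course, and a run manifest with exact
read-count accounting (accepted + rejected pairs always equal the input).
`report` adds a Z-score heat map and a time-course plot.

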