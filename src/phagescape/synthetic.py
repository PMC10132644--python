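"""Seeded synthetic data: phage populations under selection, amplicon read
pairs, long reads with planted deletions, and cleavage time courses.

The population generator is a discrete-generation Wright–Fisher-style
model: each generation is a multinomial draw with probabilities
proportional to frequency × survival weight, followed by per-base
substitution noise.  Survival weights are a stand-in for relative escape
from CRISPR cleavage (a fully cleaved genotype has weight 0; an escape
mutant propagates at weight ~1), so weight ratios can be set from relative
cleavage rates.  PCR and sequencing substitution errors are collapsed into
a single per-base rate, since the two are not distinguishable downstream.

All generators take an explicit integer seed and use one private
numpy RNG stream per call; identical inputs and seed give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom as _binom

from .kinetics import DEFAULT_TIMEPOINTS, TimeCourse, first_order
from .targets import TargetSpec

_BASES = "ACGT"
_BASE_SET = frozenset(_BASES)
#: fixed Phred+33 quality character for synthetic reads (Q40)
QUALITY_CHAR = "I"


class ExtinctionError(RuntimeError):
    """Total propagation weight is zero: the phage population is extinct."""


class ConfigurationError(ValueError):
    """Rejected generator configuration (coverage, overlap, bounds)."""


@dataclass(frozen=True)
class GenotypeSpec:
    """One phage genotype in the simulated population.

    ``haplotype`` is the target-window sequence (it may be one base shorter
    than wild type to represent a single-nucleotide deletion edit).
    ``survival_weight`` is the per-generation relative propagation weight
    under CRISPR pressure.
    """

    haplotype: str
    initial_frequency: float
    survival_weight: float
    name: str = ""

    def __post_init__(self) -> None:
        if not set(self.haplotype) <= _BASE_SET:
            raise ConfigurationError("haplotype alphabet must be within ACGT")
        if not 0.0 <= self.initial_frequency <= 1.0:
            raise ConfigurationError("initial_frequency must lie in [0, 1]")
        if self.survival_weight < 0:
            raise ConfigurationError("survival_weight must be >= 0")


@dataclass
class PopulationTimeSeries:
    """Genotype frequencies sampled over generations."""

    timepoints: list[int]
    frequencies: list[dict[str, float]]  # one mapping per timepoint
    sample_sizes: list[int]

    def __post_init__(self) -> None:
        if sorted(self.timepoints) != self.timepoints or len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoints must be strictly increasing")
        for freqs in self.frequencies:
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies must sum to 1 (got {total})")

    def final_frequencies(self) -> dict[str, float]:
        return self.frequencies[-1]


@dataclass(frozen=True)
class FastqRecord:
    """Minimal 4-line FASTQ record with fixed synthetic quality."""

    read_id: str
    sequence: str

    def to_fastq(self) -> str:
        return f"@{self.read_id}\n{self.sequence}\n+\n{QUALITY_CHAR * len(self.sequence)}\n"


def write_fastq(records: Sequence[FastqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_fastq())


def read_fastq(path) -> list[FastqRecord]:
    from Bio import SeqIO

    return [
        FastqRecord(read_id=rec.description, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


# ---------------------------------------------------------------------------
# population simulation


def _validate_genotypes(genotypes: Sequence[GenotypeSpec]) -> None:
    if not genotypes:
        raise ConfigurationError("need at least one genotype")
    total = sum(g.initial_frequency for g in genotypes)
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"initial frequencies must sum to 1 (got {total})")
    haps = [g.haplotype for g in genotypes]
    if len(set(haps)) != len(haps):
        raise ConfigurationError("genotype haplotypes must be unique")


def _mutate_counts(
    counts: dict[str, int],
    error_rate: float,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Apply per-base substitution noise to a count vector of haplotypes.

    Novel haplotypes created by mutation inherit survival weight 0 unless a
    weight is already registered for them (new mutants are assumed cleaved
    unless the scenario says otherwise).
    """
    if error_rate == 0.0:
        return counts
    out: dict[str, int] = {}
    for hap, count in counts.items():
        if count == 0:
            continue
        L = len(hap)
        p_any = 1.0 - (1.0 - error_rate) ** L
        n_mut = rng.binomial(count, p_any)
        out[hap] = out.get(hap, 0) + (count - n_mut)
        if n_mut == 0:
            continue
        # number of mutated sites per mutated individual: Binomial(L, e) | >=1
        ms = np.arange(1, L + 1)
        pmf = _binom.pmf(ms, L, error_rate)
        pmf = pmf / pmf.sum()
        n_sites = rng.choice(ms, size=n_mut, p=pmf)
        for k in n_sites:
            positions = rng.choice(L, size=int(k), replace=False)
            hap_list = list(hap)
            for pos in positions:
                choices = [b for b in _BASES if b != hap_list[pos]]
                hap_list[pos] = choices[rng.integers(3)]
            new_hap = "".join(hap_list)
            out[new_hap] = out.get(new_hap, 0) + 1
    return out


def simulate_population(
    genotypes: Sequence[GenotypeSpec],
    n_generations: int,
    pop_size: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> PopulationTimeSeries:
    """Discrete-generation selection with multinomial resampling.

    Generation 0 records the exact initial frequencies.  Each subsequent
    generation draws ``pop_size`` individuals multinomially with
    probability proportional to frequency × survival weight, then applies
    per-base substitution noise at ``error_rate``.  Raises
    :class:`ExtinctionError` when the total propagation weight reaches
    zero (every remaining genotype is fully cleaved).
    """
    _validate_genotypes(genotypes)
    if pop_size < 1:
        raise ConfigurationError("pop_size must be >= 1")
    if n_generations < 0:
        raise ConfigurationError("n_generations must be >= 0")
    if not 0.0 <= error_rate < 1.0:
        raise ConfigurationError("error_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    weights = {g.haplotype: g.survival_weight for g in genotypes}
    freqs = {g.haplotype: g.initial_frequency for g in genotypes}

    # frequencies stay keyed by haplotype string so downstream read
    # emission can consume them directly
    def record(fr: dict[str, float]) -> dict[str, float]:
        return {h: f for h, f in fr.items() if f > 0}

    timepoints = [0]
    freq_series = [record(freqs)]
    sizes = [pop_size]
    current = dict(freqs)
    for gen in range(1, n_generations + 1):
        haps = sorted(current)
        raw = np.array([current[h] * weights.get(h, 0.0) for h in haps])
        total = raw.sum()
        if total <= 0.0:
            raise ExtinctionError(f"population extinct at generation {gen}")
        probs = raw / total
        draws = rng.multinomial(pop_size, probs)
        counts = {h: int(c) for h, c in zip(haps, draws) if c > 0}
        counts = _mutate_counts(counts, error_rate, rng)
        current = {h: c / pop_size for h, c in counts.items()}
        timepoints.append(gen)
        freq_series.append(record(current))
        sizes.append(pop_size)
    return PopulationTimeSeries(timepoints=timepoints, frequencies=freq_series, sample_sizes=sizes)


def sample_population(
    frequencies: dict[str, float],
    n_reads: int,
    seed: int = 0,
) -> dict[str, int]:
    """Multinomial read sample (genotype -> count) from a frequency mapping."""
    rng = np.random.default_rng(seed)
    haps = sorted(frequencies)
    probs = np.array([frequencies[h] for h in haps])
    probs = probs / probs.sum()
    draws = rng.multinomial(n_reads, probs)
    return {h: int(c) for h, c in zip(haps, draws) if c > 0}


# ---------------------------------------------------------------------------
# amplicon read pairs


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    chars = list(seq)
    for pos in np.flatnonzero(mask):
        choices = [b for b in _BASES if b != chars[pos]]
        chars[pos] = choices[rng.integers(3)]
    return "".join(chars)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def emit_amplicon_reads(
    population_sample: dict[str, int],
    target_spec: TargetSpec,
    read_length: int = 75,
    seq_error_rate: float = 0.0,
    discordance_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[FastqRecord], list[FastqRecord], pd.DataFrame]:
    """Paired amplicon reads from a genotype count sample.

    ``population_sample`` maps target-window haplotypes to read counts.
    R1 is the first ``read_length`` bases of each genotype's amplicon, R2
    the reverse complement of the last; both must span the whole target
    window.  Independent per-base substitution errors are applied to each
    read; a ``discordance_rate`` fraction of pairs get one deliberately
    conflicting base planted in R1's window copy, flagged in the read
    identifier (``discordant=1``) so filters can be audited exactly.

    Returns (R1 records, R2 records, truth table).
    """
    spec = target_spec
    ref = spec.amplicon_reference
    if not 0.0 <= discordance_rate <= 1.0:
        raise ConfigurationError("discordance_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    r1_records: list[FastqRecord] = []
    r2_records: list[FastqRecord] = []
    truth_rows = []
    idx = 0
    for hap in sorted(population_sample):
        count = population_sample[hap]
        amplicon = ref[: spec.window_start] + hap + ref[spec.window_end :]
        # each read must span the window plus both flank anchors from its
        # own primer end, or extraction downstream cannot locate the window
        win_end_on_amplicon = spec.window_start + len(hap)
        need_r1 = win_end_on_amplicon + len(spec.flank_anchor_right)
        need_r2 = len(amplicon) - (spec.window_start - len(spec.flank_anchor_left))
        if read_length < need_r1 or read_length < need_r2:
            raise ConfigurationError(
                f"read_length {read_length} does not cover the target window "
                f"and anchors from both ends of a {len(amplicon)} nt amplicon"
            )
        r1_template = amplicon[:read_length]
        r2_template = _revcomp(amplicon[-read_length:])
        for _ in range(count):
            r1 = _apply_errors(r1_template, seq_error_rate, rng)
            r2 = _apply_errors(r2_template, seq_error_rate, rng)
            discordant = rng.random() < discordance_rate
            if discordant:
                off = spec.window_start + int(rng.integers(len(hap)))
                choices = [b for b in _BASES if b != r1[off]]
                r1 = r1[:off] + choices[rng.integers(3)] + r1[off + 1 :]
            read_id = f"read{idx}|hap={hap}|discordant={int(discordant)}"
            r1_records.append(FastqRecord(read_id=read_id, sequence=r1))
            r2_records.append(FastqRecord(read_id=read_id, sequence=r2))
            truth_rows.append({"read_id": read_id, "haplotype": hap, "discordant": int(discordant)})
            idx += 1
    truth = pd.DataFrame(truth_rows, columns=["read_id", "haplotype", "discordant"])
    return r1_records, r2_records, truth


# ---------------------------------------------------------------------------
# long reads with planted deletions


def plant_microhomology(
    reference: str,
    deletions: Sequence[tuple[int, int]],
    microhomology_lengths: Sequence[int],
) -> str:
    """Copy each deletion's 5'-flank end onto its 3'-junction end.

    For a deletion [left, right) and requested homology h, the reference is
    edited so that ``ref[right-h:right] == ref[left-h:left]``: the h-mer
    ending at the left junction also ends at the right junction, making the
    breakpoint placement ambiguous over a window of width >= h.
    """
    if len(deletions) != len(microhomology_lengths):
        raise ConfigurationError("one microhomology length per deletion")
    ref = list(reference)
    for (left, right), h in zip(deletions, microhomology_lengths):
        if h < 0:
            raise ConfigurationError("microhomology length must be >= 0")
        if h > 0:
            if left - h < 0 or right - h <= left:
                raise ConfigurationError("deletion too small for requested homology")
            ref[right - h : right] = ref[left - h : left]
    return "".join(ref)


def emit_long_reads(
    reference: str,
    deletions: Sequence[tuple[int, int, float]],
    n_reads: int,
    microhomology_lengths: Optional[Sequence[int]] = None,
    seq_error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[str, list[FastqRecord], pd.DataFrame]:
    """Long reads over an amplicon, a fraction carrying planted deletions.

    ``deletions`` is a list of ``(left, right, frequency)``; the wild-type
    frequency is 1 minus the sum.  When ``microhomology_lengths`` is given
    the reference fixture is first edited so each junction carries the
    requested homology (see :func:`plant_microhomology`); the possibly
    edited reference is returned and should be used downstream.  Each read
    carries at most one deletion; overlapping planted deletions are a
    rejected configuration.

    Returns (reference_used, records, truth table).
    """
    if not set(reference) <= _BASE_SET:
        raise ConfigurationError("reference must be ACGT")
    intervals = [(l, r) for l, r, _ in deletions]
    for l, r in intervals:
        if not 0 <= l < r <= len(reference):
            raise ConfigurationError(f"deletion [{l},{r}) out of reference bounds")
    for a, b in zip(sorted(intervals), sorted(intervals)[1:]):
        if a[1] > b[0]:
            raise ConfigurationError("overlapping planted deletions are not allowed")
    freqs = [f for _, _, f in deletions]
    wt_freq = 1.0 - sum(freqs)
    if wt_freq < -1e-9 or any(f < 0 for f in freqs):
        raise ConfigurationError("deletion frequencies + wild type must sum to 1")
    if microhomology_lengths is not None:
        reference = plant_microhomology(reference, intervals, microhomology_lengths)
    rng = np.random.default_rng(seed)
    probs = np.array([max(wt_freq, 0.0)] + freqs)
    probs = probs / probs.sum()
    counts = rng.multinomial(n_reads, probs)
    records: list[FastqRecord] = []
    truth_rows = []
    idx = 0
    for kind, count in enumerate(counts):
        if kind == 0:
            template, left, right = reference, -1, -1
            label = "wildtype"
        else:
            left, right = intervals[kind - 1]
            template = reference[:left] + reference[right:]
            label = f"del_{left}_{right}"
        for _ in range(count):
            seq = _apply_errors(template, seq_error_rate, rng)
            read_id = f"longread{idx}|{label}"
            records.append(FastqRecord(read_id=read_id, sequence=seq))
            truth_rows.append({"read_id": read_id, "kind": label, "left": left, "right": right})
            idx += 1
    truth = pd.DataFrame(truth_rows, columns=["read_id", "kind", "left", "right"])
    return reference, records, truth


# ---------------------------------------------------------------------------
# kinetics time courses


def emit_timecourse(
    k_obs: float,
    plateau: float = 1.0,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicate_id: str = "rep1",
) -> TimeCourse:
    """First-order cleavage time course with optional Gaussian noise.

    fraction(t) = plateau · (1 − e^{−k_obs t}) + N(0, noise_sd²), clipped
    to [0, 1].
    """
    if k_obs < 0:
        raise ConfigurationError("k_obs must be >= 0")
    if not 0.0 <= plateau <= 1.0:
        raise ConfigurationError("plateau must lie in [0, 1]")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    t = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)
    y = first_order(t, k_obs, plateau)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    y = np.clip(y, 0.0, 1.0)
    return TimeCourse(timepoints=t, fraction_cleaved=y, replicate_id=replicate_id)
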