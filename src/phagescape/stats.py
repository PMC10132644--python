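"""Summary statistics for escape-mutant enrichment.

Three quantities summarise how a phage population responds to CRISPR
pressure:

* the positional enrichment Z-score, standardising the per-position
  mutated-read proportion in targeted samples against a non-targeted
  control:  Z(p) = (x̄(p) − μ̄(p)) / σ, where x̄ and μ̄ are cross-replicate
  means at position p and σ is a single pooled standard deviation of the
  proportions at all positions in all samples (experimental and control
  together);

* nucleotide diversity of the target window from haplotype frequencies,
  Diversity = (1/L) Σ_{i=2..n} Σ_{j<i} 2 x_i x_j π_ij with π_ij the number
  of nucleotide differences between haplotypes i and j and L the window
  length (24 nt for a 4-nt PAM plus 20-nt protospacer);

* the competition read ratio of a seed mutant to a PAM-distal mutant in a
  co-infection, seed reads / PAM-distal reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .amplicon import (
    SINGLE_DELETION,
    WILDTYPE,
    ClassifiedRead,
    EmptySampleError,
    PositionMutationMatrix,
    fraction_mutated,
)
from .targets import TargetSpec

GAP = "-"


class DegenerateInputError(ValueError):
    """All proportions identical: the pooled standard deviation is zero."""


class UndefinedRatioError(ZeroDivisionError):
    """Competition ratio with zero reads for the denominator mutant."""


@dataclass
class ZScoreMatrix:
    """Per-position enrichment Z-scores plus the inputs that produced them."""

    z: pd.Series  # index: signed PAM-relative position
    experimental_ids: list[str]
    control_ids: list[str]
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DegenerateInputError("sigma must be positive")
        if not np.all(np.isfinite(self.z.to_numpy())):
            raise ValueError("Z must be finite at every reported position")


def zscores(
    experimental: Sequence[PositionMutationMatrix],
    control: Sequence[PositionMutationMatrix],
    ddof: int = 1,
) -> ZScoreMatrix:
    """Positional enrichment Z-scores of experimental vs control samples.

    ``ddof=1`` uses the sample standard deviation for the pooled σ
    (``ddof=0`` for the population form).  Raises
    :class:`DegenerateInputError` when every proportion in every sample is
    identical (σ = 0), rather than returning NaN.
    """
    if not experimental or not control:
        raise ValueError("need at least one experimental and one control sample")
    positions = experimental[0].proportions.index
    for m in list(experimental) + list(control):
        if not m.proportions.index.equals(positions):
            raise ValueError("all samples must share one position set")
    exp = np.vstack([m.proportions.to_numpy() for m in experimental])
    ctl = np.vstack([m.proportions.to_numpy() for m in control])
    pooled = np.concatenate([exp.ravel(), ctl.ravel()])
    sigma = float(np.std(pooled, ddof=ddof))
    if sigma == 0.0:
        raise DegenerateInputError("all proportions identical across samples")
    z = (exp.mean(axis=0) - ctl.mean(axis=0)) / sigma
    return ZScoreMatrix(
        z=pd.Series(z, index=positions, name="Z"),
        experimental_ids=[m.sample_id for m in experimental],
        control_ids=[m.sample_id for m in control],
        sigma=sigma,
    )


# ---------------------------------------------------------------------------
# nucleotide diversity


@dataclass
class HaplotypeTable:
    """Target-window haplotypes and their frequencies in one sample.

    Haplotypes are equal-length strings over ACGT plus ``-`` (a gap
    placeholder standing for a single-nucleotide deletion at its canonical
    position, so deletion haplotypes stay comparable by Hamming distance).
    """

    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        if not self.frequencies:
            raise ValueError("need at least one haplotype")
        lengths = {len(h) for h in self.frequencies}
        if len(lengths) != 1:
            raise ValueError("haplotypes must share one length (gap-pad deletions)")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies must sum to 1 (got {total})")
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError("frequencies must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.frequencies)

    @property
    def window_length(self) -> int:
        return len(next(iter(self.frequencies)))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def nucleotide_diversity(table: HaplotypeTable, length: Optional[int] = None) -> float:
    """Frequency-weighted mean pairwise difference per site.

    Diversity = (1/L) Σ_{i=2..n} Σ_{j<i} 2 x_i x_j π_ij, with π_ij the
    Hamming distance between haplotypes i and j (a gap position counts as
    one difference against a base).  ``length`` defaults to the haplotype
    length; pass it explicitly if the normalising window differs.
    """
    L = length if length is not None else table.window_length
    if L <= 0:
        raise ValueError("window length must be positive")
    haps = list(table.frequencies)
    freqs = [table.frequencies[h] for h in haps]
    total = 0.0
    for i in range(1, len(haps)):
        for j in range(i):
            total += 2.0 * freqs[i] * freqs[j] * hamming(haps[i], haps[j])
    return total / L


def haplotypes_from_calls(
    calls: Sequence[ClassifiedRead],
    spec: TargetSpec,
    deletions: str = "gap",
) -> HaplotypeTable:
    """Build a haplotype frequency table from classified reads.

    Equal-length windows are used verbatim.  Single-deletion windows are
    re-expanded to window length with a ``-`` at the canonical deletion
    position (``deletions="gap"``) or dropped (``deletions="exclude"``).
    Complex reads are always excluded: their window has no positionwise
    alignment to the reference.
    """
    if deletions not in ("gap", "exclude"):
        raise ValueError(f"unknown deletion policy: {deletions!r}")
    L = spec.window_length
    counts: dict[str, int] = {}
    for c in calls:
        if c.status != "accepted" or c.variant_class == "complex":
            continue
        if c.variant_class == SINGLE_DELETION:
            if deletions == "exclude":
                continue
            off = spec.offset_of(c.variants[0].position.index)
            hap = spec.reference_window[:off] + GAP + spec.reference_window[off + 1 :]
        else:
            hap = c.window_sequence
        counts[hap] = counts.get(hap, 0) + 1
    if not counts:
        raise EmptySampleError("no usable reads for the haplotype table")
    n = sum(counts.values())
    return HaplotypeTable({h: c / n for h, c in counts.items()})


# ---------------------------------------------------------------------------
# competition & time course


def competition_ratio(seed_mutant_reads: int, pam_distal_mutant_reads: int) -> float:
    """Seed-mutant to PAM-distal-mutant read ratio in a competition sample."""
    if seed_mutant_reads < 0 or pam_distal_mutant_reads < 0:
        raise ValueError("read counts must be nonnegative")
    if pam_distal_mutant_reads == 0:
        raise UndefinedRatioError("zero PAM-distal mutant reads: ratio undefined")
    return seed_mutant_reads / pam_distal_mutant_reads


def timecourse_table(
    samples: Sequence[tuple[float, Sequence[Sequence[ClassifiedRead]]]],
) -> pd.DataFrame:
    """Fraction-mutated mean ± SD across replicates at each timepoint.

    ``samples`` is an ordered list of ``(time, replicate_call_sets)``.  The
    SD is the sample standard deviation; it is NaN for single replicates.
    """
    rows = []
    for time, replicates in samples:
        if not replicates:
            raise ValueError(f"timepoint {time}: need at least one replicate")
        fracs = [fraction_mutated(calls) for calls in replicates]
        rows.append(
            {
                "time": time,
                "mean_fraction_mutated": float(np.mean(fracs)),
                "sd_fraction_mutated": float(np.std(fracs, ddof=1)) if len(fracs) > 1 else float("nan"),
                "n_replicates": len(fracs),
            }
        )
    return pd.DataFrame(rows)
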