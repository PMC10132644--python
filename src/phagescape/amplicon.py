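"""Paired-read target-window extraction and variant classification.

Workflow for MiSeq-style amplicon data: the sequencing primers are designed
so that R1 and R2 each span the whole protospacer+PAM window.  For every
read pair the window is located by its flank anchors, the two copies are
required to agree (pairs whose target-region sequences disagree are removed
from analysis; if only R1 reaches the window its copy is used), and the
accepted window sequence is classified against the wild-type target into
mutually exclusive classes: wildtype, single substitution, multiple
substitutions, single-nucleotide deletion, or complex.

Single-nucleotide deletions inside a homopolymer run have several
equivalent placements.  Two labelling conventions are supported: the
canonical label reports the deletion at the position adjacent to the 3'
side of the run, and the alternative reports it at the first position where
the read mismatches the reference (both are carried on every call).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .targets import (
    PositionLabel,
    TargetSpec,
    deletion_label,
    substitution_label,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# read statuses
ACCEPTED = "accepted"
REJECTED_DISCORDANT = "rejected_discordant"
REJECTED_UNALIGNABLE = "rejected_unalignable"

# variant classes
WILDTYPE = "wildtype"
SINGLE_SUBSTITUTION = "single_substitution"
MULTIPLE_SUBSTITUTION = "multiple_substitution"
SINGLE_DELETION = "single_deletion"
COMPLEX = "complex"

DELETION_TYPE = "Δ"


class EmptySampleError(ValueError):
    """Raised when a statistic is requested over zero accepted reads."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Variant:
    """One mutated position: substitution (alt base) or deletion (alt '-')."""

    position: PositionLabel
    ref_base: str
    alt_base: str  # "-" for a deletion

    @property
    def is_deletion(self) -> bool:
        return self.alt_base == "-"

    @property
    def label(self) -> str:
        if self.is_deletion:
            return deletion_label(self.ref_base, self.position.index)
        return substitution_label(self.ref_base, self.position.index, self.alt_base)

    @property
    def mutation_type(self) -> str:
        """Per-type key, e.g. ``A>C`` or ``Δ``."""
        return DELETION_TYPE if self.is_deletion else f"{self.ref_base}>{self.alt_base}"


@dataclass
class ClassifiedRead:
    """Classification of one read pair's target window."""

    read_id: str
    status: str
    window_sequence: Optional[str] = None
    variant_class: Optional[str] = None
    variants: list[Variant] = field(default_factory=list)
    #: for single deletions, the first-mismatch alternative to the canonical
    #: 3'-adjacent variant (same event, other labelling convention)
    alt_deletion_variant: Optional[Variant] = None

    def __post_init__(self) -> None:
        if self.status != ACCEPTED and self.variant_class is not None:
            raise ValueError("rejected reads carry no variant class")

    @property
    def is_mutant(self) -> bool:
        return self.status == ACCEPTED and self.variant_class != WILDTYPE


@dataclass
class PositionMutationMatrix:
    """Per-position mutated-read proportions for one sample.

    ``proportions`` is indexed by signed PAM-relative position; its value at
    position p is the fraction of accepted reads carrying any variant at p.
    ``by_type`` breaks each position's total into mutation types (``A>C``,
    ``Δ``, ...); the row sums equal ``proportions`` when every read carries
    at most one variant per position (always true here).
    """

    sample_id: str
    n_accepted: int
    proportions: pd.Series
    by_type: pd.DataFrame

    def __post_init__(self) -> None:
        if self.n_accepted < 0:
            raise ValueError("n_accepted must be >= 0")
        bad = (self.proportions < 0) | (self.proportions > 1)
        if bool(bad.any()):
            raise ValueError("proportions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# window location


def _find_anchor(read: str, anchor: str, max_mismatch: int = 1) -> Optional[int]:
    """Locate ``anchor`` in ``read``; exact match first, then <=1 mismatch.

    Returns the start offset, or None when absent or ambiguous.  Indels in
    the anchor are not tolerated, which keeps location deterministic.
    """
    # exact
    first = read.find(anchor)
    if first != -1:
        if read.find(anchor, first + 1) != -1:
            return None  # ambiguous
        return first
    if max_mismatch <= 0:
        return None
    k = len(anchor)
    hits = []
    for i in range(len(read) - k + 1):
        mm = 0
        window = read[i : i + k]
        for a, b in zip(window, anchor):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            hits.append(i)
    if len(hits) != 1:
        return None
    return hits[0]


def extract_window(read_sequence: str, spec: TargetSpec) -> Optional[str]:
    """Extract the target window from a read oriented to the amplicon.

    Both flank anchors are located (exact match, falling back to a single
    mismatch per anchor); the enclosed subsequence is returned.  Its length
    can differ from the reference window when the read carries an indel.
    Returns None when either anchor is missing, ambiguous, or the anchors
    are out of order.
    """
    left = _find_anchor(read_sequence, spec.flank_anchor_left)
    right = _find_anchor(read_sequence, spec.flank_anchor_right)
    if left is None or right is None:
        return None
    start = left + len(spec.flank_anchor_left)
    if right < start:
        return None
    return read_sequence[start:right]


# ---------------------------------------------------------------------------
# pairing


def merge_pair(
    r1: str,
    r2: str,
    spec: TargetSpec,
    read_id: str = "",
    require_concordance: bool = True,
) -> ClassifiedRead:
    """Resolve one read pair to a single target-window sequence.

    R2 is reverse-complemented onto the amplicon plus strand before
    comparison.  If both reads cover the window their copies must be
    identical, otherwise the pair is rejected as discordant (set
    ``require_concordance=False`` to fall back to R1's copy instead).  If
    only R1 covers the window, R1's copy is used.  Pairs in which R1 does
    not reach the window are unalignable.

    The returned read has status and window only; pass it through
    :func:`classify_window` (or use :func:`classify_pairs`) for the variant
    class.
    """
    w1 = extract_window(r1, spec)
    w2 = extract_window(reverse_complement(r2), spec)
    if w1 is None:
        return ClassifiedRead(read_id=read_id, status=REJECTED_UNALIGNABLE)
    if w2 is not None and w1 != w2:
        if require_concordance:
            return ClassifiedRead(read_id=read_id, status=REJECTED_DISCORDANT)
    return ClassifiedRead(read_id=read_id, status=ACCEPTED, window_sequence=w1)


# ---------------------------------------------------------------------------
# classification


def _single_deletion_placements(ref: str, obs: str) -> list[int]:
    """All offsets i such that deleting ref[i] yields obs (len(obs)=len(ref)-1)."""
    return [i for i in range(len(ref)) if ref[:i] + ref[i + 1 :] == obs]


def classify_window(
    window: str,
    spec: TargetSpec,
    read_id: str = "",
) -> ClassifiedRead:
    """Classify an extracted window sequence against the wild-type target.

    Equal length: positionwise comparison — 0 differences is wildtype, 1 is
    a single substitution, >=2 multiple substitutions.  One base shorter: a
    single-nucleotide deletion, resolved leftmost within any homopolymer
    run and labelled canonically at the position 3'-adjacent to the run
    (the first-mismatch label is stored alongside).  Any other length, or a
    length L-1 sequence not explainable by one deletion, is complex.
    Non-ACGT characters reject the read as unalignable.
    """
    ref = spec.reference_window
    if not set(window) <= set("ACGT"):
        return ClassifiedRead(read_id=read_id, status=REJECTED_UNALIGNABLE)
    L = len(ref)
    if len(window) == L:
        variants = []
        for off, (rb, ob) in enumerate(zip(ref, window)):
            if rb != ob:
                variants.append(Variant(spec.label_at(off), rb, ob))
        if not variants:
            cls = WILDTYPE
        elif len(variants) == 1:
            cls = SINGLE_SUBSTITUTION
        else:
            cls = MULTIPLE_SUBSTITUTION
        return ClassifiedRead(
            read_id=read_id,
            status=ACCEPTED,
            window_sequence=window,
            variant_class=cls,
            variants=variants,
        )
    if len(window) == L - 1:
        placements = _single_deletion_placements(ref, window)
        if placements:
            leftmost = placements[0]
            rightmost = placements[-1]
            # canonical: adjacent position 3' of the (homopolymer) run;
            # clamped to the window when the run touches its 3' edge
            canon = min(rightmost + 1, L - 1)
            first_mm = min(rightmost, L - 1)
            canonical = Variant(spec.label_at(canon), ref[leftmost], "-")
            alternative = Variant(spec.label_at(first_mm), ref[leftmost], "-")
            return ClassifiedRead(
                read_id=read_id,
                status=ACCEPTED,
                window_sequence=window,
                variant_class=SINGLE_DELETION,
                variants=[canonical],
                alt_deletion_variant=alternative,
            )
    return ClassifiedRead(
        read_id=read_id,
        status=ACCEPTED,
        window_sequence=window,
        variant_class=COMPLEX,
        variants=[],
    )


def classify_pairs(
    pairs: Iterable[tuple[str, str, str]],
    spec: TargetSpec,
    require_concordance: bool = True,
) -> list[ClassifiedRead]:
    """Merge and classify an iterable of ``(read_id, r1, r2)`` pairs."""
    calls = []
    for read_id, r1, r2 in pairs:
        merged = merge_pair(r1, r2, spec, read_id=read_id, require_concordance=require_concordance)
        if merged.status == ACCEPTED:
            calls.append(classify_window(merged.window_sequence, spec, read_id=read_id))
        else:
            calls.append(merged)
    return calls


# ---------------------------------------------------------------------------
# tabulation


def _accepted(calls: Sequence[ClassifiedRead]) -> list[ClassifiedRead]:
    return [c for c in calls if c.status == ACCEPTED]


def tabulate(
    calls: Sequence[ClassifiedRead],
    spec: TargetSpec,
    sample_id: str = "sample",
    deletion_convention: str = "3prime_adjacent",
) -> PositionMutationMatrix:
    """Per-position mutated-read proportions over the accepted reads.

    Every variant of every accepted read increments its position, so a
    multiple-substitution read contributes to each of its mutated
    positions.  Deletions are counted at the canonical 3'-adjacent label by
    default (``deletion_convention="first_mismatch"`` switches to the
    first-mismatch label).  Complex reads count toward ``n_accepted`` but
    contribute no per-position variants.
    """
    if deletion_convention not in ("3prime_adjacent", "first_mismatch"):
        raise ValueError(f"unknown deletion convention: {deletion_convention!r}")
    accepted = _accepted(calls)
    if not accepted:
        raise EmptySampleError(f"sample {sample_id!r} has zero accepted reads")
    positions = spec.positions_by_index()
    pos_counts = {p: 0 for p in positions}
    type_counts: dict[tuple[int, str], int] = {}
    for call in accepted:
        variants = call.variants
        if (
            call.variant_class == SINGLE_DELETION
            and deletion_convention == "first_mismatch"
        ):
            variants = [call.alt_deletion_variant]
        for v in variants:
            pos_counts[v.position.index] += 1
            key = (v.position.index, v.mutation_type)
            type_counts[key] = type_counts.get(key, 0) + 1
    n = len(accepted)
    proportions = pd.Series(
        [pos_counts[p] / n for p in positions], index=positions, name=sample_id, dtype=float
    )
    types = sorted({t for _, t in type_counts})
    by_type = pd.DataFrame(0.0, index=positions, columns=types)
    for (p, t), c in type_counts.items():
        by_type.loc[p, t] = c / n
    return PositionMutationMatrix(
        sample_id=sample_id, n_accepted=n, proportions=proportions, by_type=by_type
    )


def fraction_mutated(calls: Sequence[ClassifiedRead]) -> float:
    """Fraction of accepted reads whose target window is not wild type."""
    accepted = _accepted(calls)
    if not accepted:
        raise EmptySampleError("zero accepted reads")
    return sum(c.variant_class != WILDTYPE for c in accepted) / len(accepted)


def status_counts(calls: Sequence[ClassifiedRead]) -> dict[str, int]:
    """Read-count accounting: every call lands in exactly one status bin."""
    counts = {ACCEPTED: 0, REJECTED_DISCORDANT: 0, REJECTED_UNALIGNABLE: 0}
    for c in calls:
        counts[c.status] += 1
    return counts


def calls_to_frame(calls: Sequence[ClassifiedRead]) -> pd.DataFrame:
    """Per-read classification table (one row per pair, no silent drops)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "read_id": c.read_id,
                "status": c.status,
                "variant_class": c.variant_class if c.status == ACCEPTED else "",
                "variants": ",".join(v.label for v in c.variants),
            }
        )
    return pd.DataFrame(rows, columns=["read_id", "status", "variant_class", "variants"])
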