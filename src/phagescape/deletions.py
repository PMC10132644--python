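"""Large-deletion detection in long amplicon reads.

Each long read is matched piecewise to the wild-type sequence of the PCR
amplicon: the longest matching prefix and suffix are found, and when they
jointly cover the read and the read is shorter than the reference, the gap
between them is a single contiguous deletion.  Breakpoints flanked by
microhomology — identical sequence ending (or starting) at both junctions —
admit several equivalent placements; events are normalised to the leftmost
placement and the homology length/sequence and full ambiguity window are
reported, since microhomology at deletion junctions is the signature of
recombination-mediated repair.

Matching tolerates scattered single-base substitutions (a small per-read
budget, and near-exact anchors flanking the junction); reads whose
discrepancies are inconsistent with one clean deletion are reported as
unresolved rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

# call statuses
DELETION = "deletion"
NO_DELETION = "no_deletion"
UNRESOLVED = "unresolved"

#: substitution budget: scattered errors up to this fraction of the read
_MAX_MISMATCH_RATE = 0.02


@dataclass
class DeletionEvent:
    """One deletion on the amplicon reference, leftmost-normalised.

    ``[left, right)`` is the deleted interval in 0-based half-open amplicon
    coordinates.  ``ambiguity`` is the closed interval of equivalent left
    breakpoints; its width equals ``homology_length``.  Genome coordinates
    are the amplicon coordinates shifted by the amplicon's genomic offset.
    """

    left: int
    right: int
    homology_length: int
    homology_sequence: str
    ambiguity: tuple[int, int]
    genome_left: Optional[int] = None
    genome_right: Optional[int] = None
    support: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.left < self.right:
            raise ValueError("require 0 <= left < right")
        if self.ambiguity[1] - self.ambiguity[0] != self.homology_length:
            raise ValueError("ambiguity width must equal homology_length")
        if len(self.homology_sequence) != self.homology_length:
            raise ValueError("homology sequence length must equal homology_length")

    @property
    def length(self) -> int:
        return self.right - self.left


@dataclass
class LongReadCall:
    """Per-read outcome: a deletion, no deletion, or unresolved."""

    read_id: str
    status: str
    event: Optional[DeletionEvent] = None


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def microhomology(reference: str, left: int, right: int) -> tuple[int, str, tuple[int, int]]:
    """Junction microhomology for the deletion ``[left, right)``.

    Returns ``(homology_length, homology_sequence, ambiguity)`` where the
    ambiguity interval ``[leftmost, rightmost]`` contains every left
    breakpoint producing the same deleted sequence.  The homology is the
    maximal identical stretch ending at both junctions plus the maximal
    identical stretch starting at both junctions; its length equals the
    width of the ambiguity window.
    """
    if not (0 <= left < right <= len(reference)):
        raise ValueError("invalid breakpoints")
    h_left = 0
    while left - h_left - 1 >= 0 and reference[left - h_left - 1] == reference[right - h_left - 1]:
        h_left += 1
    h_right = 0
    while right + h_right < len(reference) and reference[left + h_right] == reference[right + h_right]:
        h_right += 1
    homology_length = h_left + h_right
    homology_sequence = reference[left - h_left : left - h_left + homology_length]
    return homology_length, homology_sequence, (left - h_left, left + h_right)


def normalize_event(reference: str, left: int, right: int, support: int = 1,
                    genome_offset: Optional[int] = None) -> DeletionEvent:
    """Leftmost-normalise breakpoints and attach microhomology annotation."""
    while left > 0 and reference[left - 1] == reference[right - 1]:
        left -= 1
        right -= 1
    h, seq, amb = microhomology(reference, left, right)
    ev = DeletionEvent(
        left=left, right=right, homology_length=h, homology_sequence=seq,
        ambiguity=amb, support=support,
    )
    if genome_offset is not None:
        ev.genome_left = left + genome_offset
        ev.genome_right = right + genome_offset
    return ev


def find_deletion(
    read: str,
    reference: str,
    min_anchor: int = 20,
    read_id: str = "",
) -> LongReadCall:
    """Call a single contiguous deletion in one long read.

    The read is split at every candidate breakpoint L into a prefix aligned
    to ``reference[:L]`` and a suffix aligned to ``reference[L+delta:]``
    (``delta`` = length difference).  The split with the fewest total
    substitutions wins; the call is a deletion when that count stays within
    a small per-read budget and the ``min_anchor`` bases flanking the
    junction each match the reference with at most one substitution.  The
    event is reported at its leftmost placement.  Reads the same length as
    the reference are ``no_deletion``; reads whose discrepancies cannot be
    explained by one clean deletion are ``unresolved``.
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    if len(read) > len(reference):
        return LongReadCall(read_id=read_id, status=UNRESOLVED)
    delta = len(reference) - len(read)
    if delta == 0:
        return LongReadCall(read_id=read_id, status=NO_DELETION)
    n = len(read)
    if n < 2 * min_anchor:
        return LongReadCall(read_id=read_id, status=UNRESOLVED)
    r = _as_bytes(read)
    ref = _as_bytes(reference)
    # cumulative mismatches of read[:L] vs reference[:L] ...
    pre = np.concatenate([[0], np.cumsum(r != ref[:n])])
    # ... and of read[L:] vs reference[L+delta:]
    suf_mm = r != ref[delta:]
    suf = np.concatenate([np.cumsum(suf_mm[::-1])[::-1], [0]])
    total = pre + suf
    lo, hi = min_anchor, n - min_anchor
    split = int(lo + np.argmin(total[lo : hi + 1]))
    budget = max(2, int(np.ceil(_MAX_MISMATCH_RATE * n)))
    if total[split] > budget:
        return LongReadCall(read_id=read_id, status=UNRESOLVED)
    # junction anchors must be near-exact to pin the breakpoint
    left_anchor_mm = pre[split] - pre[split - min_anchor]
    right_anchor_mm = suf[split] - suf[split + min_anchor]
    if left_anchor_mm > 1 or right_anchor_mm > 1:
        return LongReadCall(read_id=read_id, status=UNRESOLVED)
    event = normalize_event(reference, split, split + delta)
    return LongReadCall(read_id=read_id, status=DELETION, event=event)


def call_reads(
    reads: Iterable[tuple[str, str]],
    reference: str,
    min_anchor: int = 20,
) -> list[LongReadCall]:
    """Run :func:`find_deletion` over ``(read_id, sequence)`` pairs."""
    return [find_deletion(seq, reference, min_anchor=min_anchor, read_id=rid)
            for rid, seq in reads]


def aggregate(
    events: Sequence[DeletionEvent],
    reference: str,
    genome_offset: int = 0,
) -> pd.DataFrame:
    """Merge equivalent deletion events under canonical leftmost breakpoints.

    Events of the same length whose placement (ambiguity) sets overlap
    describe the same deletion up to microhomology sliding; they share one
    leftmost-normalised key.  Support is summed and amplicon coordinates
    are translated to the genome by ``genome_offset``.  Aggregation is
    idempotent: aggregating an already-aggregated table changes nothing.
    """
    merged: dict[tuple[int, int], DeletionEvent] = {}
    for ev in events:
        canon = normalize_event(reference, ev.left, ev.right, support=ev.support)
        key = (canon.left, canon.right)
        if key in merged:
            merged[key].support += canon.support
        else:
            merged[key] = canon
    rows = []
    for (left, right), ev in sorted(merged.items()):
        rows.append(
            {
                "canonical_left": left,
                "canonical_right": right,
                "genome_left": left + genome_offset,
                "genome_right": right + genome_offset,
                "length": right - left,
                "homology_length": ev.homology_length,
                "homology_seq": ev.homology_sequence,
                "support": ev.support,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "canonical_left", "canonical_right", "genome_left", "genome_right",
            "length", "homology_length", "homology_seq", "support",
        ],
    )


def aggregate_to_bed(table: pd.DataFrame, chrom: str = "lambda") -> str:
    """Render an aggregated deletion table as BED lines (genome coordinates)."""
    lines = []
    for _, row in table.iterrows():
        lines.append(
            f"{chrom}\t{row.genome_left}\t{row.genome_right}\t"
            f"del_{row.length}nt_mh{row.homology_length}\t{row.support}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
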