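"""Target-region geometry: protospacer + PAM windows and PAM-relative position labels.

A CRISPR target window on an amplicon consists of the PAM and the
protospacer.  Positions are labelled relative to the PAM: PAM bases get
negative indices (-1 adjacent to protospacer position 1) and protospacer
bases are numbered 1..N starting at the PAM-proximal end.  For a 5'-PAM
effector (Cas12a-like, TTTV-class PAM) the PAM sits to the left of the
protospacer on the plus strand of the amplicon; for a 3'-PAM effector
(Cas9-like, NGG-class) it sits to the right, so protospacer numbering runs
right-to-left on the amplicon.

All internal coordinates are 0-based half-open on the amplicon plus strand;
PAM-relative labels exist only at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_VALID_BASES = frozenset("ACGT")

#: region names in PAM-relative order
REGION_PAM = "PAM"
REGION_SEED = "seed"
REGION_MID = "mid"
REGION_DISTAL = "PAM-distal"


class TargetSpecError(ValueError):
    """Invalid target-window specification."""


@dataclass(frozen=True, order=True)
class PositionLabel:
    """A PAM-relative position.

    ``index`` is a signed integer: PAM positions are negative (-1 adjacent
    to the protospacer), protospacer positions are 1..N counted from the
    PAM-proximal end.  There is no position 0.  ``region`` is one of
    ``PAM``, ``seed``, ``mid`` or ``PAM-distal``.
    """

    index: int
    region: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.index == 0:
            raise TargetSpecError("PAM-relative positions have no index 0")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return str(self.index)


@dataclass(frozen=True)
class TargetSpec:
    """Geometry of one protospacer+PAM target window on an amplicon.

    Parameters
    ----------
    amplicon_reference
        Wild-type amplicon sequence (plus strand), uppercase ACGT.
    window_start, window_end
        0-based half-open coordinates of the PAM+protospacer window on the
        amplicon.  ``window_end - window_start`` must equal
        ``pam_length + protospacer_length`` (24 for a 4-nt PAM and a 20-nt
        protospacer, the default window size used throughout).
    pam_side
        ``"5prime"`` if the PAM lies 5' of the protospacer on the amplicon
        plus strand (Cas12a-like), ``"3prime"`` if 3' (Cas9-like).
    pam_length, protospacer_length
        PAM and protospacer lengths in nt.
    flank_anchor_left, flank_anchor_right
        Sequences immediately outside the window used to locate it in
        reads.  Each must occur exactly once in the amplicon reference.
    seed_end, mid_end
        Protospacer region boundaries: seed = 1..seed_end,
        mid = seed_end+1..mid_end, PAM-distal = mid_end+1..N.
    genome_offset
        Offset added to amplicon coordinates to express them on the phage
        genome.
    """

    amplicon_reference: str
    window_start: int
    window_end: int
    pam_side: str  # "5prime" | "3prime"
    pam_length: int
    protospacer_length: int
    flank_anchor_left: str
    flank_anchor_right: str
    seed_end: int = 6
    mid_end: int = 12
    genome_offset: int = 0

    def __post_init__(self) -> None:
        ref = self.amplicon_reference
        if not set(ref) <= _VALID_BASES:
            raise TargetSpecError("amplicon reference must be uppercase ACGT")
        if self.pam_side not in ("5prime", "3prime"):
            raise TargetSpecError("pam_side must be '5prime' or '3prime'")
        if not (0 <= self.window_start < self.window_end <= len(ref)):
            raise TargetSpecError("window coordinates out of range")
        if self.window_end - self.window_start != self.pam_length + self.protospacer_length:
            raise TargetSpecError(
                "window length must equal pam_length + protospacer_length"
            )
        if not (1 <= self.seed_end < self.mid_end <= self.protospacer_length):
            raise TargetSpecError("require 1 <= seed_end < mid_end <= protospacer_length")
        for name, anchor in (
            ("flank_anchor_left", self.flank_anchor_left),
            ("flank_anchor_right", self.flank_anchor_right),
        ):
            if not anchor or not set(anchor) <= _VALID_BASES:
                raise TargetSpecError(f"{name} must be a non-empty ACGT string")
            if ref.count(anchor) != 1:
                raise TargetSpecError(f"{name} must occur exactly once in the amplicon")
        if ref.index(self.flank_anchor_left) + len(self.flank_anchor_left) != self.window_start:
            raise TargetSpecError("flank_anchor_left must end at window_start")
        if ref.index(self.flank_anchor_right) != self.window_end:
            raise TargetSpecError("flank_anchor_right must start at window_end")

    # -- derived geometry ------------------------------------------------

    @property
    def window_length(self) -> int:
        return self.window_end - self.window_start

    @property
    def reference_window(self) -> str:
        return self.amplicon_reference[self.window_start : self.window_end]

    @classmethod
    def from_window(
        cls,
        amplicon_reference: str,
        window_start: int,
        pam_side: str,
        pam_length: int = 4,
        protospacer_length: int = 20,
        anchor_length: int = 12,
        **kwargs,
    ) -> "TargetSpec":
        """Build a spec deriving the flank anchors from the reference itself."""
        window_end = window_start + pam_length + protospacer_length
        if window_start < anchor_length or window_end + anchor_length > len(amplicon_reference):
            raise TargetSpecError("amplicon too short for the requested anchors")
        return cls(
            amplicon_reference=amplicon_reference,
            window_start=window_start,
            window_end=window_end,
            pam_side=pam_side,
            pam_length=pam_length,
            protospacer_length=protospacer_length,
            flank_anchor_left=amplicon_reference[window_start - anchor_length : window_start],
            flank_anchor_right=amplicon_reference[window_end : window_end + anchor_length],
            **kwargs,
        )

    # -- position labelling ----------------------------------------------

    def region_of(self, index: int) -> str:
        if index < 0:
            return REGION_PAM
        if index <= self.seed_end:
            return REGION_SEED
        if index <= self.mid_end:
            return REGION_MID
        return REGION_DISTAL

    def label_at(self, offset: int) -> PositionLabel:
        """PAM-relative label for a 0-based offset within the window."""
        if not 0 <= offset < self.window_length:
            raise TargetSpecError(f"offset {offset} outside window")
        if self.pam_side == "5prime":
            # [PAM][protospacer]: offsets 0..pam-1 are PAM -pam..-1
            if offset < self.pam_length:
                index = offset - self.pam_length
            else:
                index = offset - self.pam_length + 1
        else:
            # [protospacer][PAM]: protospacer numbered from the PAM-proximal
            # (right) end, so offset 0 is position N
            if offset < self.protospacer_length:
                index = self.protospacer_length - offset
            else:
                index = -(offset - self.protospacer_length + 1)
        return PositionLabel(index=index, region=self.region_of(index))

    def offset_of(self, index: int) -> int:
        """Inverse of :meth:`label_at`: window offset of a signed position."""
        if index == 0 or not (-self.pam_length <= index <= self.protospacer_length):
            raise TargetSpecError(f"position {index} outside the target window")
        if self.pam_side == "5prime":
            return index + self.pam_length if index < 0 else index + self.pam_length - 1
        return self.protospacer_length - index if index > 0 else self.protospacer_length - index - 1

    def all_positions(self) -> list[PositionLabel]:
        """All labels in window (left-to-right amplicon) order."""
        return [self.label_at(o) for o in range(self.window_length)]

    def positions_by_index(self) -> list[int]:
        """Signed indices sorted PAM-first: -pam_length..-1, 1..N."""
        return list(range(-self.pam_length, 0)) + list(
            range(1, self.protospacer_length + 1)
        )


def substitution_label(ref_base: str, index: int, alt_base: str) -> str:
    """Field-standard variant name, e.g. ``T-2C`` for PAM -2 T>C, ``A2T`` for seed."""
    return f"{ref_base}{index}{alt_base}"


def deletion_label(ref_base: str, index: int) -> str:
    return f"{ref_base}{index}Δ"
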