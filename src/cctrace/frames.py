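"""Coordinate frames and core data containers.

Positions flanking an intron insertion point are expressed as *signed exon
positions*: +k is the k-th exon base 3' (downstream) of the insertion point,
-k the k-th base 5' of it; there is no position 0.  This is the coordinate
convention used throughout the mobile-intron literature ("the C-to-U editing
site at position +20").  Signed positions count exon bases on a designated
ungapped reference row, so gap columns in the reference have no signed
position and the signed-position <-> alignment-column map is a bijection over
the reference's non-gap columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_BASES = frozenset("ACGTN-")
GAP = "-"


class FrameError(ValueError):
    """A signed position cannot be mapped into the alignment."""


class LocusError(ValueError):
    """Malformed alignment or inconsistent per-taxon metadata."""


@dataclass(frozen=True)
class CoordinateFrame:
    """Signed-position coordinate frame around an intron insertion point.

    Parameters
    ----------
    insertion_column
        0-based alignment column immediately 5' of the insertion point
        (i.e. the column of exon position -1 when the reference is ungapped
        up to there).
    reference_row
        Aligned sequence on which exon positions are counted.  ``None``
        means every column is treated as a real exon base (no gaps).
    """

    insertion_column: int
    reference_row: str | None = None

    def __post_init__(self) -> None:
        if self.insertion_column < 0:
            raise FrameError("insertion_column must be >= 0")
        if self.reference_row is not None and not (
            0 <= self.insertion_column < len(self.reference_row)
        ):
            raise FrameError("insertion_column outside reference row")

    def _length(self) -> int | None:
        return None if self.reference_row is None else len(self.reference_row)

    def signed_to_column(self, signed_pos: int) -> int:
        """Map a signed exon position to a 0-based alignment column.

        Gap columns in the reference row are skipped when counting exon
        bases.  Raises :class:`FrameError` for position 0 or positions that
        run off the alignment.
        """
        if signed_pos == 0:
            raise FrameError("signed position 0 does not exist")
        ref = self.reference_row
        if ref is None:
            col = (
                self.insertion_column + signed_pos
                if signed_pos > 0
                else self.insertion_column + signed_pos + 1
            )
            if col < 0:
                raise FrameError(f"position {signed_pos} is 5' of the alignment")
            return col
        if signed_pos > 0:
            count = 0
            for col in range(self.insertion_column + 1, len(ref)):
                if ref[col] != GAP:
                    count += 1
                    if count == signed_pos:
                        return col
            raise FrameError(f"position +{signed_pos} beyond alignment end")
        count = 0
        for col in range(self.insertion_column, -1, -1):
            if ref[col] != GAP:
                count += 1
                if count == -signed_pos:
                    return col
        raise FrameError(f"position {signed_pos} is 5' of the alignment")

    def column_to_signed(self, column: int) -> int | None:
        """Inverse of :meth:`signed_to_column`; ``None`` for reference gaps."""
        ref = self.reference_row
        if ref is None:
            if column > self.insertion_column:
                return column - self.insertion_column
            return column - self.insertion_column - 1
        if not 0 <= column < len(ref):
            raise FrameError(f"column {column} out of range")
        if ref[column] == GAP:
            return None
        if column > self.insertion_column:
            return sum(1 for c in range(self.insertion_column + 1, column + 1) if ref[c] != GAP)
        return -sum(1 for c in range(column, self.insertion_column + 1) if ref[c] != GAP)


def normalize_seq(seq: str) -> str:
    """Uppercase, map U->T; reject characters outside {A,C,G,T,N,-,IUPAC}."""
    s = seq.upper().replace("U", "T")
    return s


@dataclass
class AlignedLocus:
    """An exon alignment around one intron insertion point.

    The intron sequence itself is *not* part of the alignment; taxa are
    annotated with an intron presence call instead (True/False/None for
    unknown).
    """

    taxa: list[str]
    rows: list[str]
    frame: CoordinateFrame
    intron_present: dict[str, bool | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise LocusError("taxa and rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise LocusError(f"duplicate taxon labels: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise LocusError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.rows = [normalize_seq(r) for r in self.rows]
        for taxon in self.taxa:
            self.intron_present.setdefault(taxon, None)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise LocusError(f"unknown taxon {taxon!r}") from None

    def base_at(self, taxon: str, signed_pos: int) -> str:
        return self.row(taxon)[self.frame.signed_to_column(signed_pos)]

    def intron_lacking_taxa(self) -> list[str]:
        return [t for t in self.taxa if self.intron_present.get(t) is False]

    def intron_bearing_taxa(self) -> list[str]:
        return [t for t in self.taxa if self.intron_present.get(t) is True]

    def with_frame(self, frame: CoordinateFrame) -> "AlignedLocus":
        return AlignedLocus(list(self.taxa), list(self.rows), frame, dict(self.intron_present))


@dataclass(frozen=True)
class EditSiteList:
    """Signed exon positions predicted to undergo C-to-U mRNA editing."""

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if 0 in self.positions:
            raise LocusError("edit-site position 0 does not exist")
        if len(set(self.positions)) != len(self.positions):
            raise LocusError("duplicate edit-site positions")

    @classmethod
    def from_iterable(cls, positions: Iterable[int]) -> "EditSiteList":
        return cls(tuple(int(p) for p in positions))

    def downstream(self, window: int | None = None) -> list[int]:
        """Positive positions, optionally limited to (0, window]."""
        out = [p for p in self.positions if p > 0]
        if window is not None:
            out = [p for p in out if p <= window]
        return sorted(out)


def check_taxa_consistency(locus_taxa: Sequence[str], tree_taxa: Sequence[str]) -> None:
    """Every locus taxon must resolve to exactly one tree tip."""
    missing = sorted(set(locus_taxa) - set(tree_taxa))
    if missing:
        raise LocusError(f"taxa absent from tree: {missing}")
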