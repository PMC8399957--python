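"""Multiple-sequence-alignment handling and residue⇄column position maps.

Alignments are consumed, not computed: any aligner's output in aligned
FASTA or Clustal format is accepted (parsed with :mod:`Bio.AlignIO`).
The central object is the :class:`PositionMap`, the strictly increasing
bidirectional correspondence between a sequence's 1-based residue indices
and 1-based alignment columns, which is what lets a variant observed in one
family member be placed onto the equivalent position of another.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import AlignIO

from .variants import AMINO_ACIDS, ProteinVariant

__all__ = [
    "GAP",
    "AlignmentSet",
    "PositionMap",
    "AlignmentFormatError",
    "read_alignment",
    "build_position_map",
    "map_paralogue_variant",
]

GAP = "-"
_LEGAL = AMINO_ACIDS | {GAP}


class AlignmentFormatError(ValueError):
    """Raised for ragged, duplicated or otherwise malformed alignments."""


@dataclass(frozen=True)
class PositionMap:
    """Residue index (1-based) ⇄ alignment column (1-based) for one sequence."""

    seq_id: str
    res_to_col: tuple[int, ...]  # res_to_col[i-1] = column of residue i

    @property
    def n_residues(self) -> int:
        return len(self.res_to_col)

    def column_of(self, residue_index: int) -> int:
        if not 1 <= residue_index <= self.n_residues:
            raise IndexError(
                f"{self.seq_id}: residue index {residue_index} outside "
                f"1..{self.n_residues}")
        return self.res_to_col[residue_index - 1]

    def residue_at(self, column: int) -> int | None:
        """Residue index occupying *column*, or ``None`` for a gap."""
        from bisect import bisect_left
        i = bisect_left(self.res_to_col, column)
        if i < len(self.res_to_col) and self.res_to_col[i] == column:
            return i + 1
        return None


@dataclass
class AlignmentSet:
    """Gapped sequences of equal length with unique identifiers."""

    records: list[tuple[str, str]]
    ncol: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentFormatError("alignment needs at least 2 records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            ragged = [(sid, len(seq)) for sid, seq in self.records]
            raise AlignmentFormatError(f"records of unequal length: {ragged}")
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate sequence id(s): {dup}")
        for sid, seq in self.records:
            bad = set(seq) - _LEGAL
            if bad:
                raise AlignmentFormatError(
                    f"record {sid!r}: illegal character(s) {sorted(bad)}")
        self.ncol = lengths.pop()

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def gapped(self, seq_id: str) -> str:
        for sid, seq in self.records:
            if sid == seq_id:
                return seq
        raise KeyError(f"unknown sequence id {seq_id!r}")

    def ungapped(self, seq_id: str) -> str:
        return self.gapped(seq_id).replace(GAP, "")

    def column(self, col: int) -> str:
        """Characters of 1-based column *col*, in record order."""
        if not 1 <= col <= self.ncol:
            raise IndexError(f"column {col} outside 1..{self.ncol}")
        return "".join(seq[col - 1] for _, seq in self.records)

    def columns(self) -> Iterable[str]:
        for col in range(1, self.ncol + 1):
            yield self.column(col)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.records:
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")


def read_alignment(source: str | Path | io.TextIOBase) -> AlignmentSet:
    """Read an aligned FASTA or Clustal file; the format is auto-detected.

    Gap characters ``.`` are normalized to ``-``; sequences are upper-cased.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
        name = "<stream>"
    else:
        text = Path(source).read_text()
        name = str(source)
    stripped = text.lstrip()
    if not stripped:
        raise AlignmentFormatError(f"{name}: empty alignment file")
    fmt = "fasta" if stripped.startswith(">") else "clustal"
    try:
        aln = AlignIO.read(io.StringIO(text), fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"{name}: cannot parse as {fmt}: {exc}") from exc
    records = [(rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in aln]
    return AlignmentSet(records=records)


def build_position_map(aln: AlignmentSet, seq_id: str) -> PositionMap:
    """Map the *k*-th non-gap character of *seq_id* to its alignment column."""
    gapped = aln.gapped(seq_id)  # KeyError for unknown id
    cols = tuple(i + 1 for i, ch in enumerate(gapped) if ch != GAP)
    return PositionMap(seq_id=seq_id, res_to_col=cols)


def map_paralogue_variant(
    aln: AlignmentSet,
    paralogue_id: str,
    variant: ProteinVariant,
    target_id: str,
    *,
    maps: dict[str, PositionMap] | None = None,
) -> int | None:
    """Target residue index sharing *variant*'s alignment column, or ``None``.

    The transfer is positional: the target wild-type residue at the mapped
    position may differ from the paralogue's. The variant's stated wild-type
    residue is validated against the paralogue's ungapped sequence, guarding
    against stale coordinates; ``None`` is returned when the target carries
    a gap in the variant's column.
    """
    maps = maps if maps is not None else {}
    pmap = maps.get(paralogue_id) or build_position_map(aln, paralogue_id)
    tmap = maps.get(target_id) or build_position_map(aln, target_id)
    maps.setdefault(paralogue_id, pmap)
    maps.setdefault(target_id, tmap)

    seq = aln.ungapped(paralogue_id)
    if variant.position > len(seq):
        raise ValueError(
            f"{paralogue_id}: variant position {variant.position} beyond "
            f"sequence length {len(seq)}")
    observed = seq[variant.position - 1]
    if observed != variant.wt:
        raise ValueError(
            f"{paralogue_id} {variant.change}: alignment has {observed!r} at "
            f"position {variant.position}, not {variant.wt!r}")
    col = pmap.column_of(variant.position)
    return tmap.residue_at(col)
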