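"""Set-valued physicochemical conservation scoring of alignment columns.

Each standard residue is described by ten binary property classes
(hydrophobic, polar, small, tiny, aliphatic, aromatic, positive, negative,
charged, proline) following the Livingstone–Barton rendering of the Taylor
classification. A column's conservation score

    Cs = (number of properties whose presence/absence state is identical
          across all counted residues) / 10

lies in [0, 1]; a column of identical residues scores exactly 1 and a
property that is absent from every counted residue counts as conserved
(agreement on absence). The packaged 20x10 table is user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .msa import GAP, AlignmentSet, build_position_map
from .variants import AMINO_ACIDS

__all__ = [
    "PROPERTY_NAMES",
    "load_property_table",
    "residue_properties",
    "column_conservation",
    "ConservationUndefinedError",
    "ConservationProfile",
    "conservation_profile",
]

#: The ten physicochemical property classes, in table column order.
PROPERTY_NAMES = (
    "hydrophobic", "polar", "small", "tiny", "aliphatic",
    "aromatic", "positive", "negative", "charged", "proline",
)


class ConservationUndefinedError(ValueError):
    """Raised when a conservation score is requested for an all-gap column."""


def load_property_table(source: str | Path | None = None) -> pd.DataFrame:
    """Load the 20x10 residue-property table (index: amino acid, bool cells)."""
    if source is None:
        ref = resources.files("paravar.data").joinpath("aa_properties.tsv")
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", comment="#", index_col="aa")
    else:
        df = pd.read_csv(source, sep="\t", comment="#", index_col="aa")
    if list(df.columns) != list(PROPERTY_NAMES):
        raise ValueError(
            f"property table columns {list(df.columns)} != {list(PROPERTY_NAMES)}")
    if set(df.index) != set(AMINO_ACIDS):
        raise ValueError("property table must cover exactly the 20 standard "
                         "amino acids")
    return df.astype(bool)

_DEFAULT_TABLE: pd.DataFrame | None = None
_DEFAULT_MATRIX: dict[str, np.ndarray] | None = None


def _default_matrix() -> dict[str, np.ndarray]:
    global _DEFAULT_TABLE, _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_TABLE = load_property_table()
        _DEFAULT_MATRIX = {aa: row.to_numpy()
                           for aa, row in _DEFAULT_TABLE.iterrows()}
    return _DEFAULT_MATRIX


def residue_properties(aa: str,
                       table: pd.DataFrame | None = None) -> dict[str, bool]:
    """Property presence/absence vector for one residue, as a name→bool dict."""
    aa = aa.upper()
    if aa not in AMINO_ACIDS:
        raise ValueError(f"nonstandard amino acid {aa!r}")
    if table is None:
        return dict(zip(PROPERTY_NAMES, (bool(b) for b in _default_matrix()[aa])))
    return {name: bool(table.loc[aa, name]) for name in PROPERTY_NAMES}


def column_conservation(column: Iterable[str],
                        gap_policy: str = "nongap",
                        table: pd.DataFrame | None = None) -> float:
    """Conservation score Cs of one alignment column.

    Parameters
    ----------
    column
        Residue characters of the column (gaps allowed).
    gap_policy
        ``"nongap"`` (default) scores the non-gap residues only; ``"strict"``
        treats any gap as breaking the conservation of every property
        (a gapped column scores 0.0).
    """
    chars = [c.upper() for c in column]
    residues = [c for c in chars if c != GAP]
    if not residues:
        raise ConservationUndefinedError("all-gap column has no defined Cs")
    bad = set(residues) - AMINO_ACIDS
    if bad:
        raise ValueError(f"nonstandard residue(s) in column: {sorted(bad)}")
    if gap_policy not in ("nongap", "strict"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    if gap_policy == "strict" and len(residues) < len(chars):
        return 0.0
    if table is None:
        matrix = _default_matrix()
        states = np.array([matrix[aa] for aa in set(residues)])
    else:
        states = np.array([[bool(table.loc[aa, p]) for p in PROPERTY_NAMES]
                           for aa in set(residues)])
    conserved = np.all(states == states[0], axis=0)
    return float(conserved.sum()) / len(PROPERTY_NAMES)


@dataclass
class ConservationProfile:
    """Per-column (and per target-position) conservation of an alignment."""

    cs_by_column: np.ndarray        # 1-based column c at index c-1; NaN = all-gap
    n_residues_by_column: np.ndarray
    target_id: str | None = None
    cs_by_position: dict[int, float] | None = None  # target residue index -> Cs

    def cs_at_column(self, col: int) -> float:
        value = self.cs_by_column[col - 1]
        if np.isnan(value):
            raise ConservationUndefinedError(f"column {col} is all-gap")
        return float(value)

    def cs_at_position(self, position: int) -> float:
        if self.cs_by_position is None:
            raise ValueError("profile was built without a target sequence")
        return self.cs_by_position[position]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "column": np.arange(1, len(self.cs_by_column) + 1),
            "cs": self.cs_by_column,
            "n_residues": self.n_residues_by_column,
        })
        return df


def conservation_profile(aln: AlignmentSet,
                         target_id: str | None = None,
                         gap_policy: str = "nongap",
                         table: pd.DataFrame | None = None) -> ConservationProfile:
    """Score every column of an alignment; optionally index by target position."""
    ncol = aln.ncol
    cs = np.full(ncol, np.nan)
    nres = np.zeros(ncol, dtype=int)
    for col in range(1, ncol + 1):
        chars = aln.column(col)
        residues = [c for c in chars if c != GAP]
        nres[col - 1] = len(residues)
        if residues:
            cs[col - 1] = column_conservation(chars, gap_policy=gap_policy,
                                              table=table)
    by_position = None
    if target_id is not None:
        pmap = build_position_map(aln, target_id)
        by_position = {res: float(cs[pmap.column_of(res) - 1])
                       for res in range(1, pmap.n_residues + 1)}
    return ConservationProfile(cs_by_column=cs, n_residues_by_column=nres,
                               target_id=target_id, cs_by_position=by_position)
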