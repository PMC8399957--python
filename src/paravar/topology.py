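"""Channel topology: assign variant positions to transmembrane regions.

A voltage-gated channel alpha subunit folds into four homologous repeat
domains (DI–DIV), each with six transmembrane segments (S1–S6) and a
membrane-reentering P-loop between S5 and S6; intracellular linkers join
consecutive domains and the chain starts/ends in cytoplasmic N/C termini.
Regions are simple 1-based inclusive residue intervals; a packaged,
reconstructed region table for the human Cav1.2 subunit ships with the
package and can be overridden by any user table of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .variants import BroadDataset, Category

__all__ = [
    "RegionClass",
    "RegionDefinition",
    "RegionDistribution",
    "load_regions",
    "default_cav12_regions",
    "assign_region",
    "region_distribution",
    "UNASSIGNED",
]

#: Bucket name for positions outside every defined region.
UNASSIGNED = "unassigned"


class RegionClass(str, Enum):
    TM_SEGMENT = "tm_segment"
    P_LOOP = "p_loop"
    LINKER = "linker"
    TERMINUS = "terminus"
    OTHER = "other"


@dataclass(frozen=True)
class RegionDefinition:
    """One named region: 1-based inclusive residue interval."""

    name: str
    start: int
    end: int
    klass: RegionClass = RegionClass.OTHER

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"region {self.name!r}: start {self.start} < 1")
        if self.start > self.end:
            raise ValueError(
                f"region {self.name!r}: start {self.start} > end {self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


def _validate(regions: Sequence[RegionDefinition]) -> tuple[RegionDefinition, ...]:
    ordered = tuple(sorted(regions, key=lambda r: r.start))
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"regions {a.name!r} [{a.start},{a.end}] and "
                f"{b.name!r} [{b.start},{b.end}] overlap")
    return ordered


def load_regions(source: str | Path | pd.DataFrame) -> tuple[RegionDefinition, ...]:
    """Load and validate a region table (columns: name, start, end, class).

    Returns the regions sorted by start coordinate; overlapping regions or
    inverted intervals raise ``ValueError`` naming the offenders.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", comment="#")
    required = {"name", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns {sorted(missing)}")
    class_col = "class" if "class" in df.columns else (
        "klass" if "klass" in df.columns else None)
    regions = []
    for _, row in df.iterrows():
        klass = (RegionClass(str(row[class_col]).lower())
                 if class_col is not None else RegionClass.OTHER)
        regions.append(RegionDefinition(
            name=str(row["name"]), start=int(row["start"]), end=int(row["end"]),
            klass=klass))
    return _validate(regions)


def default_cav12_regions() -> tuple[RegionDefinition, ...]:
    """The packaged (reconstructed) hCav1.2 region table."""
    ref = resources.files("paravar.data").joinpath("cav12_regions.tsv")
    with resources.as_file(ref) as path:
        return load_regions(path)


def assign_region(regions: Sequence[RegionDefinition], position: int) -> str:
    """Name of the unique region containing *position*, else ``"unassigned"``."""
    if position < 1:
        raise ValueError(f"position {position} must be >= 1")
    for region in regions:
        if position in region:
            return region.name
    return UNASSIGNED


@dataclass
class RegionDistribution:
    """Per-region, per-category variant counts and fractions for one gene."""

    counts: pd.DataFrame     # index: region name (+ unassigned); columns: categories
    fractions: pd.DataFrame  # same shape; each non-empty category column sums to 1

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.add_suffix("_n").join(self.fractions.add_suffix("_frac"))
        out.index.name = "region"
        return out.reset_index()


def region_distribution(ds: BroadDataset,
                        regions: Sequence[RegionDefinition],
                        gene: str | None = None) -> RegionDistribution:
    """Count variants per region per category for a single gene.

    ``ds`` must contain a single gene, or *gene* must name the one to use.
    Positions outside all regions fall into the ``unassigned`` bucket so
    that per-category counts over regions always sum to category totals.
    """
    if gene is not None:
        ds = ds.subset(gene=gene)
    if len({v.gene for v in ds.variants}) > 1:
        raise ValueError("region_distribution expects variants of a single gene; "
                         "pass gene=... to select one")
    ordered = _validate(regions)
    region_names = [r.name for r in ordered] + [UNASSIGNED]
    cats = [c.value for c in Category]
    counts = pd.DataFrame(0, index=region_names, columns=cats, dtype=int)
    for v in ds.variants:
        counts.loc[assign_region(ordered, v.position), v.category.value] += 1
    totals = counts.sum(axis=0)
    fractions = counts / totals.where(totals > 0, other=pd.NA)
    fractions = fractions.fillna(0.0).astype(float)
    return RegionDistribution(counts=counts, fractions=fractions)
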