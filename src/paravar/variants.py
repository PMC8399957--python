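"""Missense variant curation: parsing, merging and labelling.

Variants from heterogeneous source exports (ClinVar-, Humsavar-, Ensembl-
and gnomAD-style tables) are merged into one broad dataset in which each
distinct protein change carries exactly one clinical category:

* ``PLP``    — pathogenic / likely pathogenic, backed by a curated clinical
  assertion ('pathogenic' or 'likely pathogenic' with a named condition in
  ClinVar-style sources, 'disease' in Humsavar/Ensembl-style sources);
* ``BENIGN`` — population allele frequency strictly above a cut-off
  (default 1e-4), with no P/LP assertion;
* ``VUS``    — everything else (variant of uncertain significance).

A curated P/LP assertion takes precedence over the frequency heuristic;
the two rules never mix silently — precedence conflicts are logged.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "Category",
    "ProteinVariant",
    "BroadDataset",
    "DatasetSummary",
    "SubstitutionStats",
    "VariantParseError",
    "parse_protein_change",
    "format_protein_change",
    "is_benign_by_frequency",
    "read_source_table",
    "assemble_dataset",
    "summarize_counts",
    "substitution_stats",
    "DEFAULT_AF_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, one-letter codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Allele frequency above which an otherwise unlabelled variant is benign.
DEFAULT_AF_THRESHOLD = 1e-4

#: Recognized variant-source names and the clinical labels that qualify a
#: row as pathogenic/likely pathogenic in each source's dialect.
PLP_LABELS: dict[str, frozenset[str]] = {
    "clinvar": frozenset({"pathogenic", "likely pathogenic",
                          "pathogenic/likely pathogenic"}),
    "humsavar": frozenset({"disease"}),
    "ensembl": frozenset({"disease"}),
    "gnomad": frozenset(),
}

KNOWN_SOURCES = frozenset(PLP_LABELS)

_CHANGE_RE = re.compile(r"^([A-Za-z])([0-9]+)([A-Za-z])$")


class Category(str, Enum):
    """Clinical category of a missense variant."""

    PLP = "PLP"
    BENIGN = "BENIGN"
    VUS = "VUS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class VariantParseError(ValueError):
    """Raised when a protein-change string cannot be decomposed."""


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Decompose a short protein change like ``"A180T"``.

    Returns ``(wt, position, mut)`` where *position* is the 1-based residue
    index. Raises :class:`VariantParseError` for malformed strings,
    nonstandard residue letters, or synonymous (wt == mut) changes.
    """
    m = _CHANGE_RE.match(text.strip())
    if m is None:
        raise VariantParseError(f"malformed protein change {text!r}")
    wt, pos_s, mut = m.group(1).upper(), m.group(2), m.group(3).upper()
    for aa in (wt, mut):
        if aa not in AMINO_ACIDS:
            raise VariantParseError(
                f"nonstandard amino acid {aa!r} in protein change {text!r}")
    position = int(pos_s)
    if position < 1:
        raise VariantParseError(f"position must be >= 1 in {text!r}")
    if wt == mut:
        raise VariantParseError(
            f"wild-type and mutant residues are identical in {text!r}")
    return wt, position, mut


def format_protein_change(wt: str, position: int, mut: str) -> str:
    """Inverse of :func:`parse_protein_change` (``('A', 180, 'T')`` → ``"A180T"``)."""
    return f"{wt}{position}{mut}"


def is_benign_by_frequency(af: float,
                           threshold: float = DEFAULT_AF_THRESHOLD) -> bool:
    """Frequency-based benign rule: true iff ``af`` strictly exceeds *threshold*.

    ``af`` must be a frequency in [0, 1]; the boundary value itself is *not*
    benign (strict inequality).
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency {af!r} outside [0, 1]")
    return af > threshold


@dataclass(frozen=True)
class ProteinVariant:
    """One missense change on one gene.

    ``position`` is the 1-based residue index in the protein;
    ``af`` is a population allele frequency or ``None`` when unobserved.
    """

    gene: str
    position: int
    wt: str
    mut: str
    af: float | None = None
    category: Category = Category.VUS
    sources: frozenset[str] = frozenset()
    conditions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.wt not in AMINO_ACIDS or self.mut not in AMINO_ACIDS:
            raise ValueError(
                f"nonstandard residue in {self.gene} "
                f"{self.wt}{self.position}{self.mut}")
        if self.wt == self.mut:
            raise ValueError(f"synonymous change {self.wt}{self.position}{self.mut}")
        if self.position < 1:
            raise ValueError(f"position {self.position} must be >= 1")
        if self.af is not None and not 0.0 <= self.af <= 1.0:
            raise ValueError(f"allele frequency {self.af} outside [0, 1]")

    @property
    def change(self) -> str:
        """Short protein-change notation, e.g. ``"A180T"``."""
        return format_protein_change(self.wt, self.position, self.mut)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the change: ``(gene, position, wt, mut)``."""
        return (self.gene, self.position, self.wt, self.mut)

    @classmethod
    def from_change(cls, gene: str, change: str, **kwargs) -> "ProteinVariant":
        wt, pos, mut = parse_protein_change(change)
        return cls(gene=gene, position=pos, wt=wt, mut=mut, **kwargs)


@dataclass
class BroadDataset:
    """Merged, categorized missense variants across a gene family."""

    variants: list[ProteinVariant]
    genes: list[str]
    #: variants dropped because sources disagreed on the wild-type residue
    excluded: list[ProteinVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            dup = [k for k, c in Counter(keys).items() if c > 1][:3]
            raise ValueError(f"duplicate variants in dataset: {dup}")
        missing = {v.gene for v in self.variants} - set(self.genes)
        if missing:
            raise ValueError(f"variants reference genes not listed: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def subset(self, gene: str | None = None,
               category: Category | str | None = None) -> "BroadDataset":
        """Restrict to one gene and/or one category."""
        vs = self.variants
        if gene is not None:
            vs = [v for v in vs if v.gene == gene]
        if category is not None:
            cat = Category(category)
            vs = [v for v in vs if v.category is cat]
        genes = [gene] if gene is not None else list(self.genes)
        return BroadDataset(variants=vs, genes=genes)

    def category_counts(self) -> Counter:
        return Counter(v.category for v in self.variants)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": v.gene,
                "change": v.change,
                "position": v.position,
                "wt": v.wt,
                "mut": v.mut,
                "af": v.af,
                "category": v.category.value,
                "sources": ";".join(sorted(v.sources)),
                "conditions": ";".join(sorted(v.conditions)),
            }
            for v in self.variants
        ]
        return pd.DataFrame(
            rows,
            columns=["gene", "change", "position", "wt", "mut", "af",
                     "category", "sources", "conditions"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BroadDataset":
        variants = []
        for row in df.itertuples(index=False):
            af = getattr(row, "af", None)
            if af is not None and pd.isna(af):
                af = None
            sources = getattr(row, "sources", "") or ""
            conditions = getattr(row, "conditions", "") or ""
            if pd.isna(sources):
                sources = ""
            if pd.isna(conditions):
                conditions = ""
            variants.append(
                ProteinVariant.from_change(
                    gene=row.gene,
                    change=row.change,
                    af=af,
                    category=Category(row.category),
                    sources=frozenset(s for s in str(sources).split(";") if s),
                    conditions=frozenset(c for c in str(conditions).split(";") if c),
                )
            )
        genes = sorted({v.gene for v in variants})
        return cls(variants=variants, genes=genes)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BroadDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#",
                                    float_precision="round_trip"))


def read_source_table(path: str | Path) -> pd.DataFrame:
    """Read one per-source variant TSV (columns: gene, change, label, af, condition)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str, "change": str},
                     float_precision="round_trip")
    required = {"gene", "change"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("label", "condition"):
        if col not in df.columns:
            df[col] = ""
    if "af" not in df.columns:
        df["af"] = float("nan")
    return df


def _row_is_plp(source: str, label: str, condition: str) -> bool:
    label = (label or "").strip().lower()
    if label not in PLP_LABELS.get(source, frozenset()):
        return False
    if source == "clinvar" and not (condition or "").strip():
        # a ClinVar-style assertion must name a clinical condition
        return False
    return True


def assemble_dataset(
    source_tables: Mapping[str, pd.DataFrame],
    af_threshold: float = DEFAULT_AF_THRESHOLD,
) -> BroadDataset:
    """Merge per-source variant tables into one categorized broad dataset.

    Parameters
    ----------
    source_tables
        Mapping of source name (``clinvar``, ``humsavar``, ``ensembl``,
        ``gnomad``) to a DataFrame with columns ``gene``, ``change`` and
        optionally ``label``, ``af``, ``condition``.
    af_threshold
        Frequency above which (strictly) an unasserted variant is benign.

    Duplicates across sources are merged on ``(gene, position, wt, mut)``
    with sources and conditions unioned and the maximum reported allele
    frequency retained. The category is assigned by precedence: curated
    P/LP assertion, else frequency rule, else VUS. Variants at a
    (gene, position) where sources disagree on the wild-type residue are
    excluded with a warning and returned on ``BroadDataset.excluded``.
    """
    unknown = set(source_tables) - KNOWN_SOURCES
    if unknown:
        raise ValueError(f"unknown source name(s): {sorted(unknown)}; "
                         f"expected one of {sorted(KNOWN_SOURCES)}")

    merged: dict[tuple[str, int, str, str], dict] = {}
    # iterate sources in a fixed order so assembly is input-order independent
    for source in sorted(source_tables):
        df = source_tables[source]
        for row in df.itertuples(index=False):
            wt, pos, mut = parse_protein_change(str(row.change))
            key = (str(row.gene), pos, wt, mut)
            rec = merged.setdefault(
                key, {"af": None, "plp": False, "sources": set(), "conditions": set()})
            rec["sources"].add(source)
            condition = getattr(row, "condition", "")
            if not isinstance(condition, str):
                condition = "" if condition is None or pd.isna(condition) \
                    else str(condition)
            if condition.strip():
                rec["conditions"].add(condition.strip())
            af = getattr(row, "af", None)
            if af is not None and not pd.isna(af):
                af = float(af)
                if not 0.0 <= af <= 1.0:
                    raise ValueError(
                        f"{source}: allele frequency {af} outside [0, 1] "
                        f"for {key[0]} {wt}{pos}{mut}")
                rec["af"] = af if rec["af"] is None else max(rec["af"], af)
            label = getattr(row, "label", "")
            if isinstance(label, str) and _row_is_plp(source, label, str(condition or "")):
                rec["plp"] = True

    # wild-type consistency: one residue per (gene, position)
    wt_by_pos: dict[tuple[str, int], set[str]] = defaultdict(set)
    for gene, pos, wt, _ in merged:
        wt_by_pos[(gene, pos)].add(wt)
    conflicted = {gp for gp, wts in wt_by_pos.items() if len(wts) > 1}
    if conflicted:
        logger.warning(
            "excluding variants at %d position(s) with conflicting wild-type "
            "residues across sources: %s",
            len(conflicted), sorted(conflicted)[:5])

    variants: list[ProteinVariant] = []
    excluded: list[ProteinVariant] = []
    for key in sorted(merged):
        gene, pos, wt, mut = key
        rec = merged[key]
        if rec["plp"]:
            category = Category.PLP
            if rec["af"] is not None and rec["af"] > af_threshold:
                logger.info(
                    "%s %s%d%s: curated P/LP assertion outranks AF %.2g > %.2g",
                    gene, wt, pos, mut, rec["af"], af_threshold)
        elif rec["af"] is not None and is_benign_by_frequency(rec["af"], af_threshold):
            category = Category.BENIGN
        else:
            category = Category.VUS
        variant = ProteinVariant(
            gene=gene, position=pos, wt=wt, mut=mut, af=rec["af"],
            category=category,
            sources=frozenset(rec["sources"]),
            conditions=frozenset(rec["conditions"]),
        )
        if (gene, pos) in conflicted:
            excluded.append(variant)
        else:
            variants.append(variant)

    genes = sorted({v.gene for v in variants} | {v.gene for v in excluded})
    return BroadDataset(variants=variants, genes=genes, excluded=excluded)


def assemble_from_dir(directory: str | Path,
                      af_threshold: float = DEFAULT_AF_THRESHOLD) -> BroadDataset:
    """Assemble from a directory holding ``<source>.tsv`` files."""
    directory = Path(directory)
    tables = {}
    for path in sorted(directory.glob("*.tsv")):
        source = path.stem.lower()
        if source in KNOWN_SOURCES:
            tables[source] = read_source_table(path)
    if not tables:
        raise FileNotFoundError(
            f"no recognized source tables (*.tsv named after "
            f"{sorted(KNOWN_SOURCES)}) in {directory}")
    return assemble_dataset(tables, af_threshold=af_threshold)


@dataclass
class DatasetSummary:
    """Per-gene and total counts per clinical category."""

    per_gene: pd.DataFrame  # index: gene; columns: benign, plp, vus
    channel_names: Mapping[str, str] | None = None

    @property
    def totals(self) -> pd.Series:
        return self.per_gene.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.per_gene.to_numpy().sum())

    def to_frame(self) -> pd.DataFrame:
        """Summary table: gene, channel, benign, plp, vus."""
        df = self.per_gene.reset_index().rename(columns={"index": "gene"})
        names = self.channel_names or {}
        df.insert(1, "channel", [names.get(g, "") for g in df["gene"]])
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def summarize_counts(ds: BroadDataset,
                     channel_names: Mapping[str, str] | None = None) -> DatasetSummary:
    """Count BENIGN / PLP / VUS variants per gene and overall."""
    counts = {g: {"benign": 0, "plp": 0, "vus": 0} for g in ds.genes}
    for v in ds.variants:
        counts[v.gene][v.category.value.lower()] += 1
    per_gene = pd.DataFrame.from_dict(counts, orient="index",
                                      columns=["benign", "plp", "vus"])
    per_gene.index.name = "gene"
    per_gene = per_gene.sort_index()
    return DatasetSummary(per_gene=per_gene, channel_names=channel_names)


@dataclass
class SubstitutionStats:
    """Ranked residue and substitution frequencies for one category."""

    category: str
    n: int
    wt_ranking: list[tuple[str, int]]
    mut_ranking: list[tuple[str, int]]
    pair_ranking: list[tuple[str, int]]  # labels like "L > P"

    def to_frame(self) -> pd.DataFrame:
        k = max(len(self.wt_ranking), len(self.mut_ranking), len(self.pair_ranking))

        def pad(ranking):
            items = [f"{label} ({count})" for label, count in ranking]
            return items + [""] * (k - len(items))

        return pd.DataFrame({
            "wt_residue": pad(self.wt_ranking),
            "mut_residue": pad(self.mut_ranking),
            "substitution": pad(self.pair_ranking),
        })


def substitution_stats(ds: BroadDataset,
                       category: Category | str = "ALL",
                       k: int = 5) -> SubstitutionStats:
    """Top-*k* wild-type residues, mutant residues and wt→mut pairs by count.

    ``category`` is ``PLP``, ``BENIGN`` or ``"ALL"`` (PLP + BENIGN combined,
    i.e. the clinically characterized subset).
    """
    if isinstance(category, Category):
        cats = {category}
        label = category.value
    elif str(category).upper() == "ALL":
        cats = {Category.PLP, Category.BENIGN}
        label = "ALL"
    else:
        cats = {Category(category)}
        label = Category(category).value

    subset = [v for v in ds.variants if v.category in cats]
    wt_counts = Counter(v.wt for v in subset)
    mut_counts = Counter(v.mut for v in subset)
    pair_counts = Counter(f"{v.wt} > {v.mut}" for v in subset)

    def top(counter: Counter) -> list[tuple[str, int]]:
        # descending count, alphabetical tie-break for determinism
        items = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        return items[:k]

    return SubstitutionStats(
        category=label, n=len(subset),
        wt_ranking=top(wt_counts),
        mut_ranking=top(mut_counts),
        pair_ranking=top(pair_counts),
    )
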