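"""Paralogue annotation transfer.

A pathogenic/likely pathogenic (P/LP) variant observed in one member of a
protein family is evidence that the alignment-equivalent position of
another member is intolerant to substitution. The transfer is positional:
each paralogue P/LP variant is placed, through the family alignment, onto
the target residue sharing its column (the wild-type residues need not
match), and a target position is *supported* when at least one paralogue
P/LP variant maps there and the column's physicochemical conservation
score is strictly above a cut-off (default Cs > 0.3).

The :class:`ParalogueAnnotation` model bundles the alignment, the target
identifier and the paralogue variant set; :meth:`ParalogueAnnotation.fit`
returns a :class:`ParalogueAnnotationResults` with the per-position support
table, the mapped-variant/mapped-position bookkeeping and, when the target's
existing variant categories are supplied, the cross-tabulation of mapped
positions against them.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .conservation import ConservationProfile, conservation_profile
from .msa import AlignmentSet, map_paralogue_variant
from .variants import Category, ProteinVariant

__all__ = [
    "DEFAULT_CS_THRESHOLD",
    "ParalogueSupport",
    "TransferReport",
    "transfer_annotations",
    "ParalogueAnnotation",
    "ParalogueAnnotationResults",
]

DEFAULT_CS_THRESHOLD = 0.3


@dataclass(frozen=True)
class ParalogueSupport:
    """One target position hit by mapped paralogue P/LP variants."""

    position: int
    wt: str
    cs: float
    supported: bool
    supports: tuple[tuple[str, str], ...]  # (paralogue gene, change) pairs

    @property
    def tokens(self) -> tuple[str, ...]:
        """Supporting variants as ``GENE-Change`` tokens."""
        return tuple(f"{gene}-{change}" for gene, change in self.supports)


@dataclass
class TransferReport:
    """Support entries plus mapping bookkeeping."""

    target_id: str
    cs_threshold: float
    entries: list[ParalogueSupport]
    mapped_variant_count: int      # paralogue variants landing on a target residue
    mapped_position_count: int     # distinct target positions hit
    unmapped: list[tuple[str, str]]  # variants facing a target gap
    category_crosstab: dict[str, int] = field(default_factory=dict)

    @property
    def supported(self) -> list[ParalogueSupport]:
        return [e for e in self.entries if e.supported]

    @property
    def supported_positions(self) -> set[int]:
        return {e.position for e in self.supported}

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "position": e.position,
            "wt": e.wt,
            "cs": e.cs,
            "supported": e.supported,
            "supports": ";".join(e.tokens),
        } for e in self.entries]
        return pd.DataFrame(rows, columns=["position", "wt", "cs", "supported",
                                           "supports"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def transfer_annotations(
    aln: AlignmentSet,
    target_id: str,
    paralogue_variants: Iterable[tuple[str, ProteinVariant]],
    cs_threshold: float = DEFAULT_CS_THRESHOLD,
    gap_policy: str = "nongap",
    target_categories: Mapping[int, Category] | None = None,
    profile: ConservationProfile | None = None,
) -> TransferReport:
    """Map paralogue P/LP variants onto the target and flag supported positions.

    Parameters
    ----------
    paralogue_variants
        Iterable of ``(paralogue sequence id, variant)``; each variant's
        coordinates are validated against the alignment.
    target_categories
        Optional existing category per target position (a position's
        category is taken from its known variants); when given, the report
        cross-tabulates mapped positions against {PLP, BENIGN, VUS}.
    """
    if profile is None:
        profile = conservation_profile(aln, target_id=target_id,
                                       gap_policy=gap_policy)
    target_seq = aln.ungapped(target_id)
    maps: dict = {}
    hits: dict[int, set[tuple[str, str]]] = defaultdict(set)
    unmapped: list[tuple[str, str]] = []
    mapped_variants = 0
    for paralogue_id, variant in paralogue_variants:
        pos = map_paralogue_variant(aln, paralogue_id, variant, target_id,
                                    maps=maps)
        if pos is None:
            unmapped.append((paralogue_id, variant.change))
            continue
        mapped_variants += 1
        hits[pos].add((paralogue_id, variant.change))

    entries = []
    for pos in sorted(hits):
        cs = profile.cs_at_position(pos)
        supports = tuple(sorted(hits[pos]))
        entries.append(ParalogueSupport(
            position=pos,
            wt=target_seq[pos - 1],
            cs=cs,
            supported=cs > cs_threshold,
            supports=supports,
        ))

    crosstab: dict[str, int] = {}
    if target_categories is not None:
        counter: Counter = Counter()
        for pos in hits:
            cat = target_categories.get(pos)
            counter[cat.value if cat is not None else "UNKNOWN"] += 1
        crosstab = {k: counter.get(k, 0)
                    for k in ("PLP", "BENIGN", "VUS", "UNKNOWN")}

    return TransferReport(
        target_id=target_id,
        cs_threshold=cs_threshold,
        entries=entries,
        mapped_variant_count=mapped_variants,
        mapped_position_count=len(hits),
        unmapped=sorted(unmapped),
        category_crosstab=crosstab,
    )


class ParalogueAnnotation:
    """Annotation-transfer model for one target sequence in a family alignment.

    Parameters
    ----------
    alignment
        Family alignment containing the target and its paralogues.
    target_id
        Sequence identifier of the target (e.g. ``"CACNA1C"``).
    paralogue_variants
        ``(paralogue id, ProteinVariant)`` pairs — the P/LP variants to
        transfer.
    cs_threshold
        Strict lower bound on the column conservation score for a mapped
        position to count as supported.
    gap_policy
        Gap handling for the conservation score (``"nongap"`` or ``"strict"``).
    """

    def __init__(self, alignment: AlignmentSet, target_id: str,
                 paralogue_variants: Sequence[tuple[str, ProteinVariant]],
                 cs_threshold: float = DEFAULT_CS_THRESHOLD,
                 gap_policy: str = "nongap"):
        if target_id not in alignment.ids:
            raise KeyError(f"target {target_id!r} not in alignment")
        self.alignment = alignment
        self.target_id = target_id
        self.paralogue_variants = list(paralogue_variants)
        self.cs_threshold = cs_threshold
        self.gap_policy = gap_policy

    def fit(self, target_categories: Mapping[int, Category] | None = None
            ) -> "ParalogueAnnotationResults":
        profile = conservation_profile(self.alignment, target_id=self.target_id,
                                       gap_policy=self.gap_policy)
        report = transfer_annotations(
            self.alignment, self.target_id, self.paralogue_variants,
            cs_threshold=self.cs_threshold, gap_policy=self.gap_policy,
            target_categories=target_categories, profile=profile)
        return ParalogueAnnotationResults(model=self, profile=profile,
                                          report=report)


@dataclass
class ParalogueAnnotationResults:
    """Fitted annotation transfer: conservation profile + support table."""

    model: ParalogueAnnotation
    profile: ConservationProfile
    report: TransferReport

    @property
    def supports(self) -> list[ParalogueSupport]:
        return self.report.entries

    @property
    def supported_positions(self) -> set[int]:
        return self.report.supported_positions

    def summary(self) -> str:
        r = self.report
        lines = [
            "Paralogue annotation transfer",
            "=" * 34,
            f"target:                  {r.target_id}",
            f"paralogue P/LP variants: {len(self.model.paralogue_variants)}",
            f"mapped variants:         {r.mapped_variant_count}",
            f"mapped target positions: {r.mapped_position_count}",
            f"unmapped (target gap):   {len(r.unmapped)}",
            f"supported (Cs > {r.cs_threshold:g}):    {len(r.supported)}",
        ]
        if r.category_crosstab:
            lines.append("mapped positions by existing target category:")
            for cat, n in r.category_crosstab.items():
                lines.append(f"  {cat:<8} {n}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.report.to_frame()
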