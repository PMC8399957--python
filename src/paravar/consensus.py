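"""Consensus reclassification of VUS.

A variant of uncertain significance is promoted to *putative P/LP* exactly
when two independent lines of evidence agree: the best-performing
pathogenicity predictor calls it pathogenic (oriented score strictly above
the tool threshold) and its position carries paralogue-annotation support
(≥1 mapped paralogue P/LP variant at conservation Cs strictly above the
cut-off). Variants with only one line of evidence stay VUS but are tagged
with which line fired; unscored variants can never be promoted.
Only VUS are eligible — existing P/LP and benign classifications are never
touched.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import ParalogueSupport, TransferReport
from .topology import RegionDefinition, assign_region
from .variants import BroadDataset, Category, ProteinVariant

__all__ = [
    "ConsensusStatus",
    "ConsensusCall",
    "ConsensusResults",
    "reclassify",
    "export_table",
    "ConsensusReclassification",
]


class ConsensusStatus(str, Enum):
    PUTATIVE_PLP = "PUTATIVE_PLP"
    VUS_TOOL_ONLY = "VUS_TOOL_ONLY"
    VUS_PARALOGUE_ONLY = "VUS_PARALOGUE_ONLY"
    VUS = "VUS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ConsensusCall:
    variant: ProteinVariant
    score: float | None
    tool_positive: bool
    paralogue_supported: bool
    cs: float | None
    status: ConsensusStatus
    missing_score: bool = False
    supports: tuple[str, ...] = ()  # GENE-Change tokens


def _support_index(supports: Iterable[ParalogueSupport] | TransferReport
                   ) -> dict[int, ParalogueSupport]:
    entries = supports.entries if isinstance(supports, TransferReport) else supports
    return {s.position: s for s in entries}


def reclassify(
    vus: Sequence[ProteinVariant],
    scores: Mapping[tuple[str, str], float] | Mapping[str, float],
    tool_threshold: float,
    supports: Iterable[ParalogueSupport] | TransferReport,
) -> tuple[list[ConsensusCall], Counter]:
    """Apply the consensus rule to a VUS list.

    Parameters
    ----------
    vus
        The candidate variants (all of one target gene); non-VUS entries
        are rejected.
    scores
        Oriented tool score per variant, keyed by ``(gene, change)`` or by
        ``change``; absent or NaN means unscored.
    tool_threshold
        Strict lower bound on the oriented score for a pathogenic call.
    supports
        Paralogue-support entries (or the whole transfer report); only
        entries with ``supported=True`` (Cs strictly above the conservation
        cut-off) confer support.

    Returns the per-variant calls (ordered by position, then mutant
    residue) and a Counter of final statuses.
    """
    index = _support_index(supports)
    calls: list[ConsensusCall] = []
    for v in sorted(vus, key=lambda v: (v.gene, v.position, v.wt, v.mut)):
        if v.category is not Category.VUS:
            raise ValueError(
                f"{v.gene} {v.change} is {v.category}; only VUS are eligible")
        raw = scores.get((v.gene, v.change))
        if raw is None:
            raw = scores.get(v.change)
        score = None if raw is None or (isinstance(raw, float) and math.isnan(raw)) \
            else float(raw)
        entry = index.get(v.position)
        supported = bool(entry is not None and entry.supported)
        cs = entry.cs if entry is not None else None
        tokens = entry.tokens if (entry is not None and supported) else ()
        if score is None:
            status = ConsensusStatus.VUS
            calls.append(ConsensusCall(
                variant=v, score=None, tool_positive=False,
                paralogue_supported=supported, cs=cs, status=status,
                missing_score=True, supports=tokens))
            continue
        positive = score > tool_threshold
        if positive and supported:
            status = ConsensusStatus.PUTATIVE_PLP
        elif positive:
            status = ConsensusStatus.VUS_TOOL_ONLY
        elif supported:
            status = ConsensusStatus.VUS_PARALOGUE_ONLY
        else:
            status = ConsensusStatus.VUS
        calls.append(ConsensusCall(
            variant=v, score=score, tool_positive=positive,
            paralogue_supported=supported, cs=cs, status=status,
            supports=tokens))
    summary = Counter(c.status for c in calls)
    return calls, summary


def export_table(calls: Sequence[ConsensusCall],
                 regions: Sequence[RegionDefinition] | None = None
                 ) -> pd.DataFrame:
    """Reclassification table: numbered putative-P/LP rows sorted by position.

    Columns: ``#``, ``variant``, ``location`` (from the region table when
    given) and ``paralogues`` (comma-joined ``GENE-Change`` tokens).
    """
    rows = []
    promoted = [c for c in calls if c.status is ConsensusStatus.PUTATIVE_PLP]
    promoted.sort(key=lambda c: (c.variant.position, c.variant.mut))
    for i, call in enumerate(promoted, start=1):
        location = (assign_region(regions, call.variant.position)
                    if regions is not None else "")
        rows.append({
            "#": i,
            "variant": call.variant.change,
            "location": location,
            "paralogues": ",".join(call.supports),
        })
    return pd.DataFrame(rows, columns=["#", "variant", "location", "paralogues"])


class ConsensusReclassification:
    """Consensus model over one gene's VUS.

    Parameters
    ----------
    dataset
        Broad dataset (the VUS of *gene* are the candidates).
    gene
        Target gene symbol.
    scores
        Oriented tool score per variant (``(gene, change)`` or ``change``
        keys), e.g. the best benchmark tool's column.
    tool_threshold
        Strict oriented-score threshold for a pathogenic tool call.
    supports
        Paralogue support entries or a transfer report for the target.
    """

    def __init__(self, dataset: BroadDataset, gene: str,
                 scores: Mapping, tool_threshold: float,
                 supports: Iterable[ParalogueSupport] | TransferReport,
                 tool_name: str = "tool"):
        self.dataset = dataset
        self.gene = gene
        self.scores = scores
        self.tool_threshold = tool_threshold
        self.supports = supports
        self.tool_name = tool_name

    def fit(self) -> "ConsensusResults":
        vus = self.dataset.subset(gene=self.gene,
                                  category=Category.VUS).variants
        calls, summary = reclassify(vus, self.scores, self.tool_threshold,
                                    self.supports)
        return ConsensusResults(model=self, calls=calls, counts=summary)


@dataclass
class ConsensusResults:
    """Fitted consensus: per-VUS calls and status counts."""

    model: ConsensusReclassification
    calls: list[ConsensusCall]
    counts: Counter

    @property
    def putative_plp(self) -> list[ConsensusCall]:
        return [c for c in self.calls
                if c.status is ConsensusStatus.PUTATIVE_PLP]

    def to_table(self, regions: Sequence[RegionDefinition] | None = None
                 ) -> pd.DataFrame:
        return export_table(self.calls, regions=regions)

    def summary(self) -> str:
        n = len(self.calls)
        n_missing = sum(1 for c in self.calls if c.missing_score)
        lines = [
            f"Consensus reclassification of {n} {self.model.gene} VUS",
            "=" * 46,
            f"tool ({self.model.tool_name}) threshold (oriented): "
            f"> {self.model.tool_threshold:g}",
            f"tool-positive:            "
            f"{sum(1 for c in self.calls if c.tool_positive)}",
            f"paralogue-supported:      "
            f"{sum(1 for c in self.calls if c.paralogue_supported)}",
        ]
        for status in ConsensusStatus:
            lines.append(f"{status.value:<22}{self.counts.get(status, 0)}")
        if n_missing:
            lines.append(f"unscored (kept as VUS):   {n_missing}")
        return "\n".join(lines)
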