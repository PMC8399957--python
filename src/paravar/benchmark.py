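"""Benchmarking pathogenicity-predictor score panels.

The positive class is the curated P/LP variants, the negative class the
frequency-defined benign variants; VUS never enter the benchmark. Scores
come in dbNSFP-style panels (one row per variant, one column per tool,
missing values allowed) and are first oriented so that larger always means
more pathogenic. Per tool, the package computes

* the ROC curve over midpoint threshold candidates and its AUC in the
  rank (Mann–Whitney) form — the fraction of (positive, negative) pairs
  the tool orders correctly, ties counted half, which equals the
  trapezoidal area under the full ROC curve;
* an optimal threshold maximizing Youden's J = sensitivity + specificity − 1
  (a closest-to-top-left criterion is available), or a user-supplied
  published threshold;
* sensitivity, specificity and (unweighted) accuracy at that threshold.

Tools missing scores for too many labelled variants (default: 30% or more)
are dropped; the remaining tools are each evaluated on their own
complete cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .variants import BroadDataset, Category

__all__ = [
    "Direction",
    "ToolSpec",
    "ToolPanel",
    "ConfusionCounts",
    "Metrics",
    "RocResult",
    "DegenerateLabelsError",
    "default_tool_specs",
    "orient_scores",
    "missingness_filter",
    "auc",
    "roc_points",
    "best_threshold",
    "confusion_at",
    "metrics",
    "evaluate_panel",
    "PredictorBenchmark",
    "BenchmarkResults",
    "DEFAULT_MAX_MISSING",
]

DEFAULT_MAX_MISSING = 0.30


class Direction(str, Enum):
    HIGHER_PATHOGENIC = "higher"
    LOWER_PATHOGENIC = "lower"


class DegenerateLabelsError(ValueError):
    """Raised when an evaluation lacks positives or negatives."""


@dataclass(frozen=True)
class ToolSpec:
    """Name, score orientation and optional published threshold of one tool.

    The threshold is on the raw scale and read in the tool's own sense:
    pathogenic iff score > threshold for ``higher`` tools and
    score < threshold for ``lower`` tools (strict either way).
    """

    name: str
    direction: Direction = Direction.HIGHER_PATHOGENIC
    threshold: float | None = None

    def oriented_threshold(self) -> float | None:
        if self.threshold is None:
            return None
        if self.direction is Direction.LOWER_PATHOGENIC:
            return -self.threshold
        return self.threshold


def default_tool_specs() -> dict[str, ToolSpec]:
    """The packaged 16-tool panel specification."""
    ref = resources.files("paravar.data").joinpath("tool_specs.tsv")
    with resources.as_file(ref) as path:
        return read_tool_specs(path)


def read_tool_specs(source: str | Path) -> dict[str, ToolSpec]:
    df = pd.read_csv(source, sep="\t", comment="#")
    specs = {}
    for row in df.itertuples(index=False):
        thr = getattr(row, "threshold", None)
        thr = None if thr is None or pd.isna(thr) else float(thr)
        specs[str(row.name)] = ToolSpec(
            name=str(row.name),
            direction=Direction(str(row.direction).lower()),
            threshold=thr,
        )
    return specs


@dataclass
class ToolPanel:
    """Per-variant, per-tool raw scores (dbNSFP-like sparse table)."""

    scores: pd.DataFrame  # index: (gene, change); columns: tool names

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ToolPanel":
        if not {"gene", "change"} <= set(df.columns):
            raise ValueError("panel needs 'gene' and 'change' columns")
        scores = df.set_index(["gene", "change"])
        scores = scores.apply(pd.to_numeric, errors="coerce")
        if scores.index.has_duplicates:
            dup = scores.index[scores.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate variants in panel: {dup}")
        return cls(scores=scores)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ToolPanel":
        df = pd.read_csv(path, sep="\t", comment="#",
                         na_values=[".", ""], keep_default_na=True,
                         float_precision="round_trip")
        return cls.from_frame(df)

    def write_tsv(self, path: str | Path) -> None:
        self.scores.reset_index().to_csv(path, sep="\t", index=False,
                                         na_rep=".")

    @property
    def tools(self) -> list[str]:
        return list(self.scores.columns)

    def tool_scores(self, tool: str,
                    keys: Sequence[tuple[str, str]]) -> np.ndarray:
        """Raw scores of *tool* for the given (gene, change) keys (NaN = missing)."""
        s = self.scores[tool]
        return np.array([s.get(k, np.nan) for k in keys], dtype=float)


def orient_scores(spec: ToolSpec, scores: np.ndarray | Sequence[float]
                  ) -> np.ndarray:
    """Return scores on a scale where larger = more pathogenic."""
    arr = np.asarray(scores, dtype=float)
    if spec.direction is Direction.LOWER_PATHOGENIC:
        return -arr
    return arr.copy()


def missingness_filter(panel: ToolPanel,
                       keys: Sequence[tuple[str, str]],
                       max_missing: float = DEFAULT_MAX_MISSING
                       ) -> list[str]:
    """Tools whose missing fraction over *keys* is strictly below *max_missing*."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    retained = []
    for tool in panel.tools:
        values = panel.tool_scores(tool, keys)
        frac = float(np.isnan(values).mean()) if len(values) else 1.0
        if frac < max_missing:
            retained.append(tool)
    return retained


def _clean(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores have different lengths")
    keep = ~np.isnan(s)
    y, s = y[keep], s[keep]
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("labels must be 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateLabelsError(
            "need at least one positive and one negative with scores")
    return y, s


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-form AUC: P(score_pos > score_neg) with ties counted half.

    Missing (NaN) scores are excluded pairwise; a single-class input raises
    :class:`DegenerateLabelsError` rather than silently returning 0.5.
    """
    y, s = _clean(labels, scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    pos_rank_sum = ranks[y == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _threshold_candidates(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class Metrics:
    """Sensitivity/specificity/accuracy; undefined entries are NaN + flagged."""

    sensitivity: float
    specificity: float
    accuracy: float
    undefined: frozenset[str] = frozenset()


def metrics(cc: ConfusionCounts) -> Metrics:
    """Sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); accuracy = raw fraction correct."""
    undefined = set()
    if cc.positives:
        sens = cc.tp / cc.positives
    else:
        sens, undefined = math.nan, undefined | {"sensitivity"}
    if cc.negatives:
        spec = cc.tn / cc.negatives
    else:
        spec, undefined = math.nan, undefined | {"specificity"}
    total = cc.positives + cc.negatives
    if total:
        acc = (cc.tp + cc.tn) / total
    else:
        acc, undefined = math.nan, undefined | {"accuracy"}
    return Metrics(sensitivity=sens, specificity=spec, accuracy=acc,
                   undefined=frozenset(undefined))


def confusion_at(labels: Sequence[int], scores: Sequence[float],
                 threshold: float) -> ConfusionCounts:
    """Confusion counts predicting positive iff oriented score > threshold."""
    y, s = _clean(labels, scores)
    pred = s > threshold
    return ConfusionCounts(
        tp=int(((y == 1) & pred).sum()),
        fn=int(((y == 1) & ~pred).sum()),
        tn=int(((y == 0) & ~pred).sum()),
        fp=int(((y == 0) & pred).sum()),
    )


def roc_points(labels: Sequence[int], scores: Sequence[float]) -> pd.DataFrame:
    """ROC point per midpoint threshold candidate (plus ±inf sentinels)."""
    y, s = _clean(labels, scores)
    out = []
    for t in _threshold_candidates(s):
        cc = confusion_at(y, s, t)
        m = metrics(cc)
        out.append({"threshold": t, "sensitivity": m.sensitivity,
                    "specificity": m.specificity})
    return pd.DataFrame(out)


def best_threshold(labels: Sequence[int], scores: Sequence[float],
                   criterion: str = "youden"
                   ) -> tuple[float, ConfusionCounts]:
    """Optimal threshold over midpoint candidates.

    ``criterion="youden"`` maximizes J = sensitivity + specificity − 1;
    ``criterion="topleft"`` minimizes the squared distance to the ROC
    top-left corner. Ties are broken toward the smallest threshold.
    """
    if criterion not in ("youden", "topleft"):
        raise ValueError(f"unknown criterion {criterion!r}")
    y, s = _clean(labels, scores)
    best_t, best_cc, best_obj = None, None, -np.inf
    for t in _threshold_candidates(s):
        cc = confusion_at(y, s, t)
        m = metrics(cc)
        if criterion == "youden":
            obj = m.sensitivity + m.specificity - 1.0
        else:
            obj = -((1.0 - m.sensitivity) ** 2 + (1.0 - m.specificity) ** 2)
        if obj > best_obj:  # strict: first (= smallest) threshold wins ties
            best_t, best_cc, best_obj = t, cc, obj
    return float(best_t), best_cc


@dataclass
class RocResult:
    """Per-tool benchmark: AUC, ROC points and threshold metrics."""

    tool: str
    auc: float
    points: pd.DataFrame
    threshold: float            # oriented scale
    raw_threshold: float        # tool's own scale
    threshold_source: str       # "youden", "topleft" or "custom"
    confusion: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    n_evaluated: int
    missing_fraction: float


def _evaluate_tool(spec: ToolSpec, labels: np.ndarray, raw: np.ndarray,
                   criterion: str, use_custom: bool) -> RocResult:
    oriented = orient_scores(spec, raw)
    missing = float(np.isnan(oriented).mean()) if len(oriented) else 1.0
    a = auc(labels, oriented)
    pts = roc_points(labels, oriented)
    if use_custom and spec.threshold is not None:
        thr = spec.oriented_threshold()
        source = "custom"
        cc = confusion_at(labels, oriented, thr)
    else:
        thr, cc = best_threshold(labels, oriented, criterion=criterion)
        source = criterion
    m = metrics(cc)
    raw_thr = -thr if spec.direction is Direction.LOWER_PATHOGENIC else thr
    return RocResult(
        tool=spec.name, auc=a, points=pts, threshold=thr,
        raw_threshold=raw_thr, threshold_source=source, confusion=cc,
        sensitivity=m.sensitivity, specificity=m.specificity,
        accuracy=m.accuracy,
        n_evaluated=cc.positives + cc.negatives,
        missing_fraction=missing,
    )


class PredictorBenchmark:
    """Benchmark model: labelled variants + score panel + tool specs.

    Parameters
    ----------
    dataset
        Broad dataset; only PLP (positive) and BENIGN (negative) variants
        participate.
    panel
        Raw score panel; variants absent from the panel count as missing.
    specs
        Tool specifications; defaults to the packaged 16-tool panel for
        tools present in *panel*, with unknown panel columns treated as
        higher-is-pathogenic tools without custom thresholds.
    max_missing
        Strict upper bound on a tool's missing fraction over labelled
        variants (default 0.30); tools at or above it are dropped.
    criterion
        Threshold-selection criterion, ``"youden"`` (default) or ``"topleft"``.
    use_custom_thresholds
        Evaluate at each spec's published threshold instead of re-deriving one.
    """

    def __init__(self, dataset: BroadDataset, panel: ToolPanel,
                 specs: Mapping[str, ToolSpec] | None = None,
                 max_missing: float = DEFAULT_MAX_MISSING,
                 criterion: str = "youden",
                 use_custom_thresholds: bool = False):
        self.dataset = dataset
        self.panel = panel
        if specs is None:
            defaults = default_tool_specs()
            specs = {t: defaults.get(t, ToolSpec(name=t)) for t in panel.tools}
        self.specs = dict(specs)
        self.max_missing = max_missing
        self.criterion = criterion
        self.use_custom_thresholds = use_custom_thresholds

    def labelled(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        keys, labels = [], []
        for v in self.dataset.variants:
            if v.category is Category.PLP:
                keys.append((v.gene, v.change))
                labels.append(1)
            elif v.category is Category.BENIGN:
                keys.append((v.gene, v.change))
                labels.append(0)
        return keys, np.array(labels, dtype=int)

    def fit(self) -> "BenchmarkResults":
        keys, labels = self.labelled()
        if labels.sum() == 0 or labels.sum() == len(labels):
            raise DegenerateLabelsError(
                "benchmark needs both P/LP and benign variants")
        retained = missingness_filter(self.panel, keys, self.max_missing)
        dropped = [t for t in self.panel.tools if t not in retained]
        results = {}
        for tool in retained:
            spec = self.specs.get(tool, ToolSpec(name=tool))
            raw = self.panel.tool_scores(tool, keys)
            results[tool] = _evaluate_tool(spec, labels, raw,
                                           self.criterion,
                                           self.use_custom_thresholds)
        return BenchmarkResults(model=self, results=results, dropped=dropped,
                                n_positive=int(labels.sum()),
                                n_negative=int(len(labels) - labels.sum()))


def evaluate_panel(dataset: BroadDataset, panel: ToolPanel,
                   specs: Mapping[str, ToolSpec] | None = None,
                   **kwargs) -> "BenchmarkResults":
    """Functional wrapper around :class:`PredictorBenchmark`."""
    return PredictorBenchmark(dataset, panel, specs=specs, **kwargs).fit()


@dataclass
class BenchmarkResults:
    """Fitted benchmark: per-tool ROC results, sortable summary table."""

    model: PredictorBenchmark
    results: dict[str, RocResult]
    dropped: list[str]
    n_positive: int
    n_negative: int

    def table(self) -> pd.DataFrame:
        """One row per tool, sorted by accuracy then AUC (both descending)."""
        rows = []
        for r in self.results.values():
            spec = self.model.specs.get(r.tool, ToolSpec(name=r.tool))
            sense = "<" if spec.direction is Direction.LOWER_PATHOGENIC else ">"
            rows.append({
                "tool": r.tool,
                "threshold": f"{sense}{r.raw_threshold:g}",
                "auc": r.auc,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "accuracy": r.accuracy,
                "n": r.n_evaluated,
                "missing_fraction": r.missing_fraction,
            })
        df = pd.DataFrame(rows)
        if not df.empty:
            df = df.sort_values(["accuracy", "auc"], ascending=False,
                                kind="mergesort").reset_index(drop=True)
        return df

    def __getitem__(self, tool: str) -> RocResult:
        return self.results[tool]

    def summary(self) -> str:
        df = self.table()
        header = (f"Predictor benchmark: {self.n_positive} P/LP vs "
                  f"{self.n_negative} benign variants")
        body = df.to_string(
            index=False,
            formatters={c: (lambda v: f"{v:.3f}")
                        for c in ("auc", "sensitivity", "specificity",
                                  "accuracy", "missing_fraction")},
        ) if not df.empty else "(no tools retained)"
        lines = [header, "=" * len(header), body]
        if self.dropped:
            lines.append(f"dropped (missingness >= "
                         f"{self.model.max_missing:.0%}): "
                         + ", ".join(self.dropped))
        return "\n".join(lines)

    def write_tsv(self, path: str | Path) -> None:
        self.table().to_csv(path, sep="\t", index=False)

    def write_roc_points(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for tool, r in self.results.items():
            r.points.to_csv(directory / f"roc_{tool}.tsv", sep="\t",
                            index=False)

    def plot_roc(self, ax=None):
        """ROC curves for all retained tools (AUC in the legend)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        for tool in sorted(self.results,
                           key=lambda t: -self.results[t].auc):
            r = self.results[tool]
            pts = r.points.sort_values("specificity", ascending=False)
            ax.plot(1.0 - pts["specificity"], pts["sensitivity"],
                    label=f"{tool} ({r.auc:.2f})")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(fontsize=7, loc="lower right")
        return ax
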