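"""Synthetic inputs with known ground truth.

Every pipeline stage consumes files whose real counterparts (database
exports, family alignments, precomputed score panels) cannot be shipped,
so this module generates all of them with planted truth:

* :func:`simulate_family` — a paralogous family alignment whose columns are
  designed *invariant* (one residue family-wide), *property-conserved*
  (substitutions stay within one physicochemical group, e.g. {I,L,V}) or
  *free* (uniform substitution), with indels confined to designated loop
  stretches so the target's coordinate frame stays intact;
* :func:`simulate_variants` — per-source variant tables (ClinVar-,
  Humsavar-, Ensembl-, gnomAD-style dialects) with planted categories and
  planted paralogue support positions;
* :func:`simulate_scores` — class-conditional Gaussian tool scores with the
  closed-form AUC Φ(δ/√2) for a location shift δ at unit variance (a
  probit-squashed bounded family keeps the same AUC on a [0,1] scale).

Three independent pseudo-random streams (family, variants, scores) are
spawned from the master seed, so regenerating one artifact never perturbs
the others; a fixed seed makes the whole simulate → assemble → annotate →
evaluate → reclassify chain byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotation import ParalogueSupport
from .msa import GAP, AlignmentSet, build_position_map
from .variants import (AMINO_ACIDS, BroadDataset, Category, ProteinVariant,
                       parse_protein_change)

__all__ = [
    "ToolModel",
    "SimulationConfig",
    "FamilyTruth",
    "VariantTables",
    "simulate_family",
    "simulate_variants",
    "simulate_scores",
    "theoretical_auc",
    "variants_from_counts",
    "planted_transfer_scenario",
    "consensus_scenario",
    "PARALOGUE_GENES",
]

_AA = sorted(AMINO_ACIDS)

#: The 20 paralogues of the target channel (voltage-gated Na+/Ca2+ family
#: plus the NALCN leak channel), used as sequence/gene identifiers.
PARALOGUE_GENES = (
    "CACNA1A", "CACNA1B", "CACNA1D", "CACNA1E", "CACNA1F", "CACNA1G",
    "CACNA1H", "CACNA1I", "CACNA1S", "NALCN", "SCN1A", "SCN2A", "SCN3A",
    "SCN4A", "SCN5A", "SCN7A", "SCN8A", "SCN9A", "SCN10A", "SCN11A",
)

#: Physicochemical groups used for property-conserved columns; substitution
#: within a group leaves most of the ten property classes in agreement.
PROPERTY_GROUPS = (
    ("I", "L", "V"),     # aliphatic
    ("F", "W", "Y"),     # aromatic
    ("D", "E"),          # negative
    ("K", "R"),          # positive
    ("A", "G", "S"),     # tiny
    ("S", "T"),          # hydroxyl/small polar
)

_CONDITIONS = ("long QT syndrome", "Timothy syndrome", "Brugada syndrome",
               "epileptic encephalopathy", "cardiac arrhythmia")


@dataclass(frozen=True)
class ToolModel:
    """Class-conditional score model for one tool.

    Positives score ``delta`` higher than negatives on average (Gaussian
    noise, scale ``sigma``); theoretical AUC = Φ(delta / (sigma·√2)).
    ``family="bounded"`` squashes scores through the normal CDF onto [0,1]
    (a strictly increasing map, so the AUC is unchanged).
    """

    delta: float
    sigma: float = 1.0
    missing_rate: float = 0.0
    direction: str = "higher"
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.direction not in ("higher", "lower"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.family not in ("gaussian", "bounded"):
            raise ValueError(f"unknown score family {self.family!r}")


def theoretical_auc(delta: float, sigma: float = 1.0) -> float:
    """Closed-form AUC of the Gaussian location-shift model: Φ(δ/(σ√2))."""
    return float(norm.cdf(delta / (sigma * math.sqrt(2.0))))


def _default_tools() -> dict[str, ToolModel]:
    # deltas chosen so the theoretical AUCs span the strong-to-weak range
    # reported for real panels (≈0.97 down to ≈0.66)
    return {
        "ClinPred": ToolModel(delta=2.66, missing_rate=0.02),
        "REVEL": ToolModel(delta=2.09, missing_rate=0.05),
        "MCap": ToolModel(delta=1.90, missing_rate=0.10),
        "SIFT": ToolModel(delta=1.35, missing_rate=0.05, direction="lower"),
        "MutationTaster": ToolModel(delta=0.58, missing_rate=0.15),
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic pipeline; the seed fully determines outputs."""

    seed: int = 0
    # family / alignment
    n_paralogues: int = 20
    length: int = 600                 # target residues (core columns)
    frac_invariant: float = 0.30
    frac_property: float = 0.40       # remainder of core columns is free
    loop_fraction: float = 0.15       # core columns where indels may occur
    deletion_rate: float = 0.10       # per paralogue per loop column
    n_insert_columns: int = 10        # columns where the target is gapped
    target_gene: str = "CACNA1C"
    # variants (target gene)
    n_plp: int = 22
    n_benign: int = 21
    n_vus: int = 309
    n_planted_support_positions: int = 12
    max_support_per_position: int = 5
    benign_af_range: tuple[float, float] = (2e-4, 1e-2)
    rare_af_max: float = 9e-5
    af_threshold: float = 1e-4
    # scores
    tools: dict[str, ToolModel] = field(default_factory=_default_tools)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("n_paralogues", "length", "n_plp", "n_benign", "n_vus",
                     "n_planted_support_positions", "n_insert_columns"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.frac_invariant < 0 or self.frac_property < 0 or \
                self.frac_invariant + self.frac_property > 1.0:
            raise ValueError("conservation design fractions must be "
                             "non-negative and sum to <= 1")
        if not 0.0 < self.af_threshold < 1.0:
            raise ValueError("af_threshold must be in (0, 1)")
        lo, hi = self.benign_af_range
        if not self.af_threshold < lo <= hi <= 1.0:
            raise ValueError("benign_af_range must lie strictly above "
                             "af_threshold")
        if not 0.0 <= self.rare_af_max <= self.af_threshold:
            raise ValueError("rare_af_max must not exceed af_threshold")

    def streams(self) -> tuple[np.random.Generator, np.random.Generator,
                               np.random.Generator]:
        """Independent (family, variants, scores) random streams."""
        fam, var, sco = np.random.SeedSequence(self.seed).spawn(3)
        return (np.random.default_rng(fam), np.random.default_rng(var),
                np.random.default_rng(sco))

    def paralogue_ids(self) -> list[str]:
        base = list(PARALOGUE_GENES)
        if self.n_paralogues <= len(base):
            return base[: self.n_paralogues]
        extra = [f"PARA{i}" for i in range(len(base), self.n_paralogues)]
        return base + extra

    # flat key=value round trip for the CLI config file
    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        tools = raw.pop("tools", None)
        cfg = cls(**raw)
        if tools is not None:
            cfg.tools = {name: ToolModel(**spec) for name, spec in tools.items()}
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        data = asdict(self)
        data["tools"] = {name: asdict(tm) for name, tm in self.tools.items()}
        data["benign_af_range"] = list(self.benign_af_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class FamilyTruth:
    """Planted per-column design of a simulated family alignment."""

    column_design: list[str]          # per alignment column: invariant /
                                      # property / free / insert
    core_columns: list[int]           # alignment column of target residue i
                                      # (1-based, index i-1)
    property_group: dict[int, tuple[str, ...]]  # column -> allowed residues
    loop_columns: set[int]

    def design_of_position(self, position: int) -> str:
        return self.column_design[self.core_columns[position - 1] - 1]


def simulate_family(cfg: SimulationConfig) -> tuple[AlignmentSet, FamilyTruth]:
    """Generate the family alignment with planted conservation design."""
    rng, _, _ = cfg.streams()
    L = cfg.length
    n_par = cfg.n_paralogues

    # per-core-column design with exact fractions
    n_inv = int(round(cfg.frac_invariant * L))
    n_prop = int(round(cfg.frac_property * L))
    design = np.array(["invariant"] * n_inv + ["property"] * n_prop
                      + ["free"] * (L - n_inv - n_prop), dtype=object)
    rng.shuffle(design)

    # loop stretches: contiguous blocks holding all indels
    n_loop = int(round(cfg.loop_fraction * L))
    loop_core = set()
    if n_loop > 0:
        n_blocks = max(1, min(4, n_loop // 10 or 1))
        block_len = max(1, n_loop // n_blocks)
        starts = rng.choice(np.arange(1, max(2, L - block_len)),
                            size=n_blocks, replace=False)
        for s in np.sort(starts):
            loop_core.update(range(int(s), min(L, int(s) + block_len) + 1))

    root = np.empty(L, dtype=object)
    groups: dict[int, tuple[str, ...]] = {}
    for i in range(L):
        if design[i] == "property":
            grp = PROPERTY_GROUPS[rng.integers(len(PROPERTY_GROUPS))]
            groups[i + 1] = grp
            root[i] = grp[rng.integers(len(grp))]
        else:
            root[i] = _AA[rng.integers(20)]

    par_rows = np.empty((n_par, L), dtype=object)
    for p in range(n_par):
        for i in range(L):
            if design[i] == "invariant":
                par_rows[p, i] = root[i]
            elif design[i] == "property":
                grp = groups[i + 1]
                par_rows[p, i] = grp[rng.integers(len(grp))]
            else:
                par_rows[p, i] = _AA[rng.integers(20)]
            if (i + 1) in loop_core and rng.random() < cfg.deletion_rate:
                par_rows[p, i] = GAP

    # insertion columns: target gapped, paralogues partially occupied
    insert_after = sorted(
        rng.choice(sorted(loop_core) if loop_core else np.arange(1, L + 1),
                   size=min(cfg.n_insert_columns,
                            len(loop_core) or L),
                   replace=False).tolist()) if cfg.n_insert_columns else []

    target_cols: list[str] = []
    par_cols: list[list[str]] = [[] for _ in range(n_par)]
    col_design: list[str] = []
    core_columns: list[int] = []
    group_by_column: dict[int, tuple[str, ...]] = {}
    loop_columns: set[int] = set()
    col = 0
    insert_set = set(insert_after)
    for i in range(L):
        col += 1
        target_cols.append(str(root[i]))
        for p in range(n_par):
            par_cols[p].append(str(par_rows[p, i]))
        col_design.append(str(design[i]))
        core_columns.append(col)
        if design[i] == "property":
            group_by_column[col] = groups[i + 1]
        if (i + 1) in loop_core:
            loop_columns.add(col)
        if (i + 1) in insert_set:
            col += 1
            target_cols.append(GAP)
            keeper = int(rng.integers(n_par)) if n_par else 0
            for p in range(n_par):
                if p == keeper or rng.random() < 0.5:
                    par_cols[p].append(_AA[rng.integers(20)])
                else:
                    par_cols[p].append(GAP)
            col_design.append("insert")
            loop_columns.add(col)

    records = [(cfg.target_gene, "".join(target_cols))]
    for p, pid in enumerate(cfg.paralogue_ids()):
        records.append((pid, "".join(par_cols[p])))
    aln = AlignmentSet(records=records)
    truth = FamilyTruth(column_design=col_design, core_columns=core_columns,
                        property_group=group_by_column,
                        loop_columns=loop_columns)
    return aln, truth


@dataclass
class VariantTables:
    """Per-source variant tables plus the planted truth."""

    tables: dict[str, pd.DataFrame]
    target_truth: dict[tuple[str, int, str, str], Category]
    planted_support_positions: set[int]
    paralogue_plp: list[tuple[str, ProteinVariant]]

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for source, df in self.tables.items():
            df.to_csv(directory / f"{source}.tsv", sep="\t", index=False)


def _sample_changes(rng: np.random.Generator, seq: str, positions: np.ndarray
                    ) -> list[tuple[int, str, str]]:
    out = []
    for pos in positions:
        wt = seq[pos - 1]
        mut = wt
        while mut == wt:
            mut = _AA[rng.integers(20)]
        out.append((int(pos), wt, mut))
    return out


def simulate_variants(cfg: SimulationConfig,
                      family: tuple[AlignmentSet, FamilyTruth]
                      ) -> VariantTables:
    """Plant categorized target variants and supporting paralogue P/LP variants."""
    aln, truth = family
    _, rng, _ = cfg.streams()
    target_seq = aln.ungapped(cfg.target_gene)
    L = len(target_seq)
    n_total = cfg.n_plp + cfg.n_benign + cfg.n_vus
    if n_total > L:
        raise ValueError(f"cannot place {n_total} variants on {L} residues "
                         "with distinct positions")

    conserved = np.array([p for p in range(1, L + 1)
                          if truth.design_of_position(p) != "free"])
    all_pos = np.arange(1, L + 1)
    rng.shuffle(conserved)
    # P/LP variants sit at conserved positions; benign/VUS anywhere else
    plp_pos = conserved[: cfg.n_plp]
    remaining = np.setdiff1d(all_pos, plp_pos)
    rng.shuffle(remaining)
    benign_pos = remaining[: cfg.n_benign]
    vus_pos = np.sort(remaining[cfg.n_benign: cfg.n_benign + cfg.n_vus])

    rows: dict[str, list[dict]] = {"clinvar": [], "humsavar": [],
                                   "ensembl": [], "gnomad": []}
    truth_map: dict[tuple[str, int, str, str], Category] = {}

    def add(source: str, gene: str, pos: int, wt: str, mut: str,
            label: str = "", af: float | None = None, condition: str = ""):
        rows[source].append({
            "gene": gene, "change": f"{wt}{pos}{mut}", "label": label,
            "af": np.nan if af is None else af, "condition": condition,
        })

    g = cfg.target_gene
    for i, (pos, wt, mut) in enumerate(_sample_changes(rng, target_seq, plp_pos)):
        cond = _CONDITIONS[rng.integers(len(_CONDITIONS))]
        add("clinvar", g, pos, wt, mut, label="pathogenic", condition=cond)
        if i % 4 == 0:  # cross-source duplicate; P/LP precedence must hold
            add("gnomad", g, pos, wt, mut,
                af=float(rng.uniform(*cfg.benign_af_range)))
        truth_map[(g, pos, wt, mut)] = Category.PLP
    for pos, wt, mut in _sample_changes(rng, target_seq, benign_pos):
        add("gnomad", g, pos, wt, mut,
            af=float(rng.uniform(*cfg.benign_af_range)))
        truth_map[(g, pos, wt, mut)] = Category.BENIGN
    for i, (pos, wt, mut) in enumerate(_sample_changes(rng, target_seq, vus_pos)):
        if i % 2 == 0:
            add("clinvar", g, pos, wt, mut, label="uncertain significance")
        else:
            add("ensembl", g, pos, wt, mut)
        if i % 7 == 0:  # observed but too rare to be benign
            add("gnomad", g, pos, wt, mut,
                af=float(rng.uniform(0.0, cfg.rare_af_max)))
        truth_map[(g, pos, wt, mut)] = Category.VUS

    # planted paralogue support: VUS positions on conserved, gap-free columns
    planted: set[int] = set()
    paralogue_plp: list[tuple[str, ProteinVariant]] = []
    paralogue_ids = cfg.paralogue_ids()
    maps = {pid: build_position_map(aln, pid) for pid in paralogue_ids}
    candidates = [int(p) for p in vus_pos
                  if truth.design_of_position(int(p)) != "free"]
    rng.shuffle(candidates)
    for pos in candidates:
        if len(planted) >= cfg.n_planted_support_positions:
            break
        col = truth.core_columns[pos - 1]
        column = aln.column(col)
        occupied = [i for i, ch in enumerate(column[1:]) if ch != GAP]
        if not occupied:
            continue
        planted.add(pos)
        k = int(rng.integers(1, cfg.max_support_per_position + 1))
        chosen = rng.choice(occupied, size=min(k, len(occupied)), replace=False)
        for idx in np.atleast_1d(chosen):
            pid = paralogue_ids[int(idx)]
            res = maps[pid].residue_at(col)
            wt = aln.ungapped(pid)[res - 1]
            mut = wt
            while mut == wt:
                mut = _AA[rng.integers(20)]
            variant = ProteinVariant(gene=pid, position=res, wt=wt, mut=mut,
                                     category=Category.PLP)
            paralogue_plp.append((pid, variant))
            source = "humsavar" if rng.random() < 0.5 else "clinvar"
            label = "disease" if source == "humsavar" else "pathogenic"
            cond = _CONDITIONS[rng.integers(len(_CONDITIONS))]
            add(source, pid, res, wt, mut, label=label, condition=cond)

    tables = {s: pd.DataFrame(r, columns=["gene", "change", "label", "af",
                                          "condition"])
              for s, r in rows.items() if r}
    return VariantTables(tables=tables, target_truth=truth_map,
                         planted_support_positions=planted,
                         paralogue_plp=paralogue_plp)


def simulate_scores(cfg: SimulationConfig, dataset: BroadDataset,
                    pathogenic_keys: set | None = None) -> "pd.DataFrame":
    """Class-conditional tool scores for every variant of *dataset*.

    Variants whose key is in *pathogenic_keys* (default: the curated P/LP
    variants) draw from the shifted distribution; everything else from the
    baseline. Returns a panel DataFrame (columns gene, change, then one per
    tool) ready for :class:`paravar.benchmark.ToolPanel`.
    """
    _, _, rng = cfg.streams()
    if pathogenic_keys is None:
        pathogenic_keys = {v.key for v in dataset
                           if v.category is Category.PLP}
    variants = list(dataset)
    is_path = np.array([v.key in pathogenic_keys for v in variants])
    out = {"gene": [v.gene for v in variants],
           "change": [v.change for v in variants]}
    n = len(variants)
    for name in sorted(cfg.tools):
        tm = cfg.tools[name]
        raw = rng.normal(loc=np.where(is_path, tm.delta, 0.0), scale=tm.sigma,
                         size=n)
        if tm.family == "bounded":
            raw = norm.cdf(raw - tm.delta / 2.0)
        if tm.direction == "lower":
            raw = -raw
        if tm.missing_rate > 0:
            raw = np.where(rng.random(n) < tm.missing_rate, np.nan, raw)
        out[name] = raw
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# scenario builders for worked examples with published bookkeeping numbers
# ---------------------------------------------------------------------------

def variants_from_counts(counts: pd.DataFrame, seed: int = 0
                         ) -> dict[str, pd.DataFrame]:
    """Per-source tables realizing given per-gene (benign, plp, vus) counts.

    *counts* needs columns ``gene``, ``benign``, ``plp``, ``vus``. Assembling
    the returned tables reproduces the counts exactly; cross-source
    duplicates are included deliberately to exercise the merge rules.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows: dict[str, list[dict]] = {"clinvar": [], "humsavar": [],
                                   "ensembl": [], "gnomad": []}

    def add(source, gene, change, label="", af=None, condition=""):
        rows[source].append({"gene": gene, "change": change, "label": label,
                             "af": np.nan if af is None else af,
                             "condition": condition})

    for row in counts.itertuples(index=False):
        gene = str(row.gene)
        n_b, n_p, n_v = int(row.benign), int(row.plp), int(row.vus)
        positions = np.arange(1, n_b + n_p + n_v + 1)
        wts = [_AA[i] for i in rng.integers(0, 20, size=len(positions))]
        muts = []
        for wt in wts:
            mut = wt
            while mut == wt:
                mut = _AA[rng.integers(20)]
            muts.append(mut)
        changes = [f"{wt}{pos}{mut}"
                   for wt, pos, mut in zip(wts, positions, muts)]
        i = 0
        for _ in range(n_p):
            cond = _CONDITIONS[rng.integers(len(_CONDITIONS))]
            if i % 3 == 0:
                add("clinvar", gene, changes[i], label="likely pathogenic",
                    condition=cond)
            elif i % 3 == 1:
                add("humsavar", gene, changes[i], label="disease")
            else:
                add("ensembl", gene, changes[i], label="disease")
            if i % 5 == 0:  # duplicate benign-frequency row; P/LP must win
                add("gnomad", gene, changes[i], af=float(rng.uniform(2e-4, 1e-2)))
            i += 1
        for _ in range(n_b):
            add("gnomad", gene, changes[i], af=float(rng.uniform(2e-4, 1e-2)))
            i += 1
        for j in range(n_v):
            if j % 2 == 0:
                add("clinvar", gene, changes[i], label="uncertain significance")
            else:
                add("ensembl", gene, changes[i])
            if j % 9 == 0:  # seen in the population but too rare
                add("gnomad", gene, changes[i], af=float(rng.uniform(0, 9e-5)))
            i += 1
    return {s: pd.DataFrame(r, columns=["gene", "change", "label", "af",
                                        "condition"])
            for s, r in rows.items() if r}


def planted_transfer_scenario(
    n_variants: int = 146,
    category_split: tuple[int, int, int] = (11, 2, 76),
    n_paralogues: int = 6,
    length: int | None = None,
    seed: int = 0,
) -> tuple[AlignmentSet, list[tuple[str, ProteinVariant]],
           dict[int, Category]]:
    """Gap-free family alignment with a planted many-to-one mapping pattern.

    ``n_variants`` paralogue P/LP variants are planted so they map onto
    exactly ``sum(category_split)`` distinct target positions, of which the
    three split components carry existing PLP / BENIGN / VUS target
    categories. Returns (alignment, paralogue variants, target categories
    by position).
    """
    n_pos = sum(category_split)
    if n_variants < n_pos:
        raise ValueError("need at least one variant per mapped position")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    L = length or max(2 * n_pos, n_pos + 20)
    ids = ["TARGET"] + [f"PARA{i}" for i in range(1, n_paralogues + 1)]
    seqs = {sid: "".join(_AA[i] for i in rng.integers(0, 20, size=L))
            for sid in ids}
    aln = AlignmentSet(records=[(sid, seqs[sid]) for sid in ids])

    positions = rng.choice(np.arange(1, L + 1), size=n_pos, replace=False)
    positions = np.sort(positions)
    categories: dict[int, Category] = {}
    cat_seq = ([Category.PLP] * category_split[0]
               + [Category.BENIGN] * category_split[1]
               + [Category.VUS] * category_split[2])
    for pos, cat in zip(positions, cat_seq):
        categories[int(pos)] = cat

    # every position gets one variant; the surplus lands on random positions
    assignment = list(positions) + list(
        rng.choice(positions, size=n_variants - n_pos, replace=True))
    paralogue_variants: list[tuple[str, ProteinVariant]] = []
    used: set[tuple[str, int, str]] = set()
    for pos in assignment:
        pos = int(pos)
        for _ in range(100):
            pid = ids[1 + int(rng.integers(n_paralogues))]
            wt = seqs[pid][pos - 1]  # gap-free: column == residue index
            mut = wt
            while mut == wt:
                mut = _AA[rng.integers(20)]
            if (pid, pos, mut) not in used:
                used.add((pid, pos, mut))
                break
        paralogue_variants.append(
            (pid, ProteinVariant(gene=pid, position=pos, wt=wt, mut=mut,
                                 category=Category.PLP)))
    return aln, paralogue_variants, categories


def consensus_scenario(
    putative: pd.DataFrame,
    n_vus: int = 309,
    n_tool_positive: int = 188,
    tool_threshold: float = 0.66,
    target_gene: str = "CACNA1C",
    n_supported_negative: int = 5,
    seed: int = 0,
) -> tuple[list[ProteinVariant], dict[tuple[str, str], float],
           list[ParalogueSupport]]:
    """VUS set, tool scores and supports realizing a published consensus count.

    *putative* is a reference table (columns ``variant``, ``paralogues``)
    of the VUS that both evidence lines must promote: they receive scores
    strictly above *tool_threshold* and supported positions. Enough filler
    VUS are generated to reach ``n_vus`` total and ``n_tool_positive``
    tool-positive calls; ``n_supported_negative`` tool-negative fillers
    also get paralogue support, so support alone never promotes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    promoted: list[ProteinVariant] = []
    supports: list[ParalogueSupport] = []
    for row in putative.itertuples(index=False):
        wt, pos, mut = parse_protein_change(str(row.variant))
        promoted.append(ProteinVariant(gene=target_gene, position=pos, wt=wt,
                                       mut=mut, category=Category.VUS))
        tokens = tuple(str(row.paralogues).split(","))
        parsed = tuple(tuple(tok.split("-", 1)) for tok in tokens)
        supports.append(ParalogueSupport(
            position=pos, wt=wt, cs=float(rng.uniform(0.35, 0.9)),
            supported=True, supports=parsed))
    n_promoted = len(promoted)
    if n_tool_positive < n_promoted or n_vus < n_tool_positive:
        raise ValueError("need n_vus >= n_tool_positive >= promoted count")

    taken = {v.position for v in promoted}
    filler_positions = [p for p in range(1, 4 * n_vus) if p not in taken]
    rng.shuffle(filler_positions)
    fillers: list[ProteinVariant] = []
    for pos in filler_positions[: n_vus - n_promoted]:
        wt = _AA[rng.integers(20)]
        mut = wt
        while mut == wt:
            mut = _AA[rng.integers(20)]
        fillers.append(ProteinVariant(gene=target_gene, position=pos, wt=wt,
                                      mut=mut, category=Category.VUS))

    scores: dict[tuple[str, str], float] = {}
    for v in promoted:
        scores[(v.gene, v.change)] = float(rng.uniform(tool_threshold + 0.01,
                                                       1.0))
    n_pos_fillers = n_tool_positive - n_promoted
    for i, v in enumerate(fillers):
        if i < n_pos_fillers:
            scores[(v.gene, v.change)] = float(
                rng.uniform(tool_threshold + 0.01, 1.0))
        else:
            scores[(v.gene, v.change)] = float(rng.uniform(0.0, tool_threshold))
    # paralogue support on some tool-negative fillers: must stay VUS
    for v in fillers[n_pos_fillers: n_pos_fillers + n_supported_negative]:
        supports.append(ParalogueSupport(
            position=v.position, wt=v.wt, cs=float(rng.uniform(0.35, 0.9)),
            supported=True,
            supports=(("SCN1A", f"A{v.position}G"),)))
    return promoted + fillers, scores, supports
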