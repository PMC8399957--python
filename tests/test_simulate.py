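"""Synthetic-data generators: determinism, planted truth and closed forms."""

import numpy as np
import pytest
from scipy.stats import norm

from paravar.annotation import ParalogueAnnotation
from paravar.benchmark import PredictorBenchmark, ToolPanel, auc
from paravar.consensus import ConsensusReclassification, ConsensusStatus
from paravar.conservation import column_conservation
from paravar.msa import GAP
from paravar.simulate import (SimulationConfig, ToolModel, consensus_scenario,
                              planted_transfer_scenario, simulate_family,
                              simulate_scores, simulate_variants,
                              theoretical_auc, variants_from_counts)
from paravar.variants import Category, assemble_dataset


SMALL = dict(length=240, n_plp=12, n_benign=10, n_vus=60,
             n_planted_support_positions=8, n_paralogues=12)


@pytest.fixture(scope="module")
def small_run():
    cfg = SimulationConfig(seed=5, **SMALL)
    family = simulate_family(cfg)
    tables = simulate_variants(cfg, family)
    ds = assemble_dataset(tables.tables, af_threshold=cfg.af_threshold)
    return cfg, family, tables, ds


class TestFamily:
    def test_same_seed_byte_identical(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        a1, _ = simulate_family(cfg)
        a2, _ = simulate_family(SimulationConfig(seed=9, **SMALL))
        assert a1.records == a2.records

    def test_different_seed_differs(self):
        a1, _ = simulate_family(SimulationConfig(seed=1, **SMALL))
        a2, _ = simulate_family(SimulationConfig(seed=2, **SMALL))
        assert a1.records != a2.records

    def test_invariant_columns_score_one(self, small_run):
        _, (aln, truth), _, _ = small_run
        for col, design in enumerate(truth.column_design, start=1):
            if design == "invariant":
                column = aln.column(col)
                assert set(column) <= (set(column[0]) | {GAP})
                assert column_conservation(column) == 1.0

    def test_property_columns_beat_free_columns_on_average(self, small_run):
        _, (aln, truth), _, _ = small_run
        by_design = {"property": [], "free": []}
        for col, design in enumerate(truth.column_design, start=1):
            if design in by_design:
                column = aln.column(col)
                if set(column) != {GAP}:
                    by_design[design].append(column_conservation(column))
        assert np.mean(by_design["property"]) > np.mean(by_design["free"])

    def test_indels_confined_to_loop_columns(self, small_run):
        _, (aln, truth), _, _ = small_run
        for col in range(1, aln.ncol + 1):
            if GAP in aln.column(col):
                assert col in truth.loop_columns

    def test_gap_free_target_core(self, small_run):
        cfg, (aln, truth), _, _ = small_run
        assert len(aln.ungapped(cfg.target_gene)) == cfg.length


class TestVariants:
    def test_category_truth_respected_after_assembly(self, small_run):
        cfg, _, tables, ds = small_run
        target = {v.key: v.category for v in ds
                  if v.gene == cfg.target_gene}
        assert target == tables.target_truth

    def test_designed_af_yields_benign(self, small_run):
        cfg, _, _, ds = small_run
        benign = ds.subset(gene=cfg.target_gene, category=Category.BENIGN)
        assert len(benign) == cfg.n_benign
        assert all(v.af > cfg.af_threshold for v in benign)

    def test_planted_supports_recovered_exactly(self, small_run):
        cfg, (aln, _), tables, _ = small_run
        results = ParalogueAnnotation(aln, cfg.target_gene,
                                      tables.paralogue_plp).fit()
        assert results.supported_positions == tables.planted_support_positions

    def test_no_planted_plp_gives_empty_support(self):
        cfg = SimulationConfig(seed=5, **{**SMALL,
                                          "n_planted_support_positions": 0})
        family = simulate_family(cfg)
        tables = simulate_variants(cfg, family)
        assert tables.paralogue_plp == []
        results = ParalogueAnnotation(family[0], cfg.target_gene, []).fit()
        assert results.supported_positions == set()


class TestScores:
    def test_null_tool_auc_near_half(self):
        labels = np.r_[np.ones(2000, int), np.zeros(2000, int)]
        rng = np.random.default_rng(3)
        scores = rng.normal(0.0, 1.0, size=4000)  # delta = 0: no signal
        assert auc(labels, scores) == pytest.approx(0.5, abs=0.02)

    def test_empirical_auc_matches_closed_form(self):
        delta = 1.19
        rng = np.random.default_rng(17)
        labels = np.r_[np.ones(2000, int), np.zeros(2000, int)]
        scores = rng.normal(np.where(labels == 1, delta, 0.0), 1.0)
        assert theoretical_auc(delta) == pytest.approx(
            norm.cdf(delta / np.sqrt(2)))
        assert auc(labels, scores) == pytest.approx(theoretical_auc(delta),
                                                    abs=0.02)

    def test_auc_ordering_follows_deltas(self, small_run):
        cfg, _, _, ds = small_run
        panel = ToolPanel.from_frame(simulate_scores(cfg, ds))
        res = PredictorBenchmark(ds, panel).fit()
        deltas = {name: tm.delta for name, tm in cfg.tools.items()}
        aucs = {name: res[name].auc for name in res.results}
        strongest = max(deltas, key=deltas.get)
        weakest = min(deltas, key=deltas.get)
        assert aucs[strongest] > aucs[weakest]

    def test_bounded_family_stays_in_unit_interval(self, small_run):
        cfg, _, _, ds = small_run
        cfg2 = SimulationConfig(
            seed=cfg.seed, **SMALL,
            tools={"b": ToolModel(delta=2.0, family="bounded")})
        panel = simulate_scores(cfg2, ds)
        values = panel["b"].dropna()
        assert ((values >= 0) & (values <= 1)).all()

    def test_missingness_rate_applied(self, small_run):
        cfg, _, _, ds = small_run
        cfg2 = SimulationConfig(
            seed=cfg.seed, **SMALL,
            tools={"m": ToolModel(delta=1.0, missing_rate=0.4)})
        panel = simulate_scores(cfg2, ds)
        frac = panel["m"].isna().mean()
        assert frac == pytest.approx(0.4, abs=0.1)


class TestEndToEnd:
    def test_strong_signal_recovers_planted_set_exactly(self, tmp_path):
        cfg = SimulationConfig(
            seed=11, **SMALL,
            tools={"meta": ToolModel(delta=6.0, missing_rate=0.0)})
        family = simulate_family(cfg)
        tables = simulate_variants(cfg, family)
        # exercise the file dialects end to end
        tables.write(tmp_path / "src")
        family[0].write_fasta(tmp_path / "family.fasta")
        from paravar.msa import read_alignment
        from paravar.variants import assemble_from_dir

        ds = assemble_from_dir(tmp_path / "src", af_threshold=cfg.af_threshold)
        aln = read_alignment(tmp_path / "family.fasta")
        pathogenic = ({v.key for v in ds if v.category is Category.PLP}
                      | {v.key for v in ds
                         if v.gene == cfg.target_gene
                         and v.position in tables.planted_support_positions})
        panel = ToolPanel.from_frame(
            simulate_scores(cfg, ds, pathogenic_keys=pathogenic))
        ann = ParalogueAnnotation(aln, cfg.target_gene,
                                  tables.paralogue_plp).fit()
        scores = {k: float(v) for k, v in panel.scores["meta"].items()}
        res = ConsensusReclassification(
            ds, cfg.target_gene, scores, tool_threshold=3.0,
            supports=ann.report).fit()
        promoted = {c.variant.position for c in res.putative_plp}
        assert promoted == tables.planted_support_positions

    def test_no_signal_no_supports_returns_empty(self):
        cfg = SimulationConfig(
            seed=11, **{**SMALL, "n_planted_support_positions": 0},
            tools={"meta": ToolModel(delta=0.0)})
        family = simulate_family(cfg)
        tables = simulate_variants(cfg, family)
        ds = assemble_dataset(tables.tables, af_threshold=cfg.af_threshold)
        panel = ToolPanel.from_frame(simulate_scores(cfg, ds))
        ann = ParalogueAnnotation(family[0], cfg.target_gene,
                                  tables.paralogue_plp).fit()
        scores = {k: float(v) for k, v in panel.scores["meta"].items()}
        res = ConsensusReclassification(
            ds, cfg.target_gene, scores, tool_threshold=3.0,
            supports=ann.report).fit()
        assert res.putative_plp == []

    def test_chain_deterministic_under_fixed_seed(self):
        def run():
            cfg = SimulationConfig(seed=21, **SMALL)
            family = simulate_family(cfg)
            tables = simulate_variants(cfg, family)
            ds = assemble_dataset(tables.tables,
                                  af_threshold=cfg.af_threshold)
            panel = simulate_scores(cfg, ds)
            return ds.to_frame(), panel

        df1, p1 = run()
        df2, p2 = run()
        assert df1.equals(df2) and p1.equals(p2)


class TestScenarioBuilders:
    def test_counts_realized_exactly(self, channel_counts):
        sub = channel_counts.head(4)
        tables = variants_from_counts(sub, seed=2)
        ds = assemble_dataset(tables)
        from paravar.variants import summarize_counts

        summ = summarize_counts(ds)
        for row in sub.itertuples(index=False):
            got = summ.per_gene.loc[row.gene]
            assert (got["benign"], got["plp"], got["vus"]) == \
                (row.benign, row.plp, row.vus)

    def test_transfer_scenario_bookkeeping(self):
        from paravar.annotation import transfer_annotations

        aln, variants, cats = planted_transfer_scenario(
            n_variants=50, category_split=(4, 3, 13), seed=7)
        report = transfer_annotations(aln, "TARGET", variants,
                                      target_categories=cats)
        assert report.mapped_variant_count == 50
        assert report.mapped_position_count == 20
        assert report.category_crosstab == {"PLP": 4, "BENIGN": 3,
                                            "VUS": 13, "UNKNOWN": 0}

    def test_consensus_scenario_counts(self, putative_table):
        from paravar.consensus import reclassify

        vus, scores, supports = consensus_scenario(
            putative_table, n_vus=100, n_tool_positive=60, seed=4)
        assert len(vus) == 100
        calls, summary = reclassify(vus, scores, 0.66, supports)
        assert summary[ConsensusStatus.PUTATIVE_PLP] == len(putative_table)
        assert sum(1 for c in calls if c.tool_positive) == 60
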