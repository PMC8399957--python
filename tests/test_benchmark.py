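"""Score orientation, AUC, threshold optimization and panel evaluation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from paravar.benchmark import (ConfusionCounts, DegenerateLabelsError,
                               Direction, PredictorBenchmark, ToolPanel,
                               ToolSpec, auc, best_threshold, confusion_at,
                               default_tool_specs, evaluate_panel, metrics,
                               missingness_filter, orient_scores, roc_points)
from paravar.variants import BroadDataset, Category, ProteinVariant


def bruteforce_auc(labels, scores):
    """Exhaustive pairwise counting: wins + half-ties over all pos/neg pairs."""
    pos = [s for y, s in zip(labels, scores) if y == 1 and not np.isnan(s)]
    neg = [s for y, s in zip(labels, scores) if y == 0 and not np.isnan(s)]
    wins = sum((p > n) + 0.5 * (p == n) for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def exhaustive_best_j(labels, scores):
    """Scan every midpoint threshold and return the maximal Youden J."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    distinct = np.unique(s)
    candidates = np.concatenate(
        ([-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]))
    best = -np.inf
    for t in candidates:
        pred = s > t
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        best = max(best, sens + spec - 1)
    return best


class TestOrientation:
    def test_higher_tool_identity(self):
        spec = ToolSpec("t", Direction.HIGHER_PATHOGENIC, 0.5)
        np.testing.assert_array_equal(orient_scores(spec, [0.1, 0.9]),
                                      [0.1, 0.9])
        assert spec.oriented_threshold() == 0.5

    def test_lower_tool_negated_with_flipped_threshold(self):
        spec = ToolSpec("PROVEAN", Direction.LOWER_PATHOGENIC, -3.42)
        np.testing.assert_array_equal(orient_scores(spec, [-3.42, 1.0]),
                                      [3.42, -1.0])
        assert spec.oriented_threshold() == 3.42

    def test_double_orientation_is_identity(self):
        spec = ToolSpec("t", Direction.LOWER_PATHOGENIC)
        scores = np.array([0.3, -2.0, 5.5])
        np.testing.assert_array_equal(
            orient_scores(spec, orient_scores(spec, scores)), scores)


class TestMissingness:
    def _panel(self, missing_count, n=100):
        variants = [("G", f"A{i+1}T") for i in range(n)]
        values = [np.nan] * missing_count + [0.5] * (n - missing_count)
        import pandas as pd

        df = pd.DataFrame({"gene": [g for g, _ in variants],
                           "change": [c for _, c in variants],
                           "tool": values})
        return ToolPanel.from_frame(df), variants

    @pytest.mark.parametrize("missing,kept", [(10, True), (29, True),
                                              (30, False), (100, False)])
    def test_strictly_below_cutoff(self, missing, kept):
        panel, keys = self._panel(missing)
        retained = missingness_filter(panel, keys, max_missing=0.30)
        assert (retained == ["tool"]) is kept


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_all_ties(self):
        assert auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_half_pairs_won(self):
        assert auc([1, 0, 1, 0], [0.9, 0.4, 0.35, 0.8]) == 0.5

    def test_degenerate_single_class_signalled(self):
        with pytest.raises(DegenerateLabelsError):
            auc([1, 1], [0.2, 0.4])

    def test_missing_excluded_pairwise(self):
        assert auc([1, 1, 0], [0.9, np.nan, 0.1]) == 1.0

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 50))
            labels = np.zeros(n, int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            assert auc(labels, scores) == pytest.approx(
                bruteforce_auc(labels, scores), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        for _ in range(25):
            labels = rng.integers(0, 2, size=40)
            if labels.sum() in (0, 40):
                continue
            scores = rng.normal(size=40) + labels
            assert auc(labels, scores) == pytest.approx(
                roc_auc_score(labels, scores))

    @given(st.data())
    def test_increasing_transform_invariance_and_flip(self, data):
        n = data.draw(st.integers(4, 25))
        labels = data.draw(st.lists(st.sampled_from([0, 1]), min_size=n,
                                    max_size=n))
        if sum(labels) in (0, n):
            labels[0], labels[-1] = 0, 1
        # half-integer scores: ties survive the affine map exactly
        scores = [i * 0.5 for i in data.draw(
            st.lists(st.integers(-100, 100), min_size=n, max_size=n))]
        base = auc(labels, scores)
        transformed = [3 * s + 7 for s in scores]  # strictly increasing
        assert auc(labels, transformed) == pytest.approx(base)
        assert auc(labels, [-s for s in scores]) == pytest.approx(1 - base)

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(42)
        delta = 1.19
        pos = rng.normal(delta, 1, size=2000)
        neg = rng.normal(0, 1, size=2000)
        labels = np.r_[np.ones(2000, int), np.zeros(2000, int)]
        empirical = auc(labels, np.r_[pos, neg])
        assert empirical == pytest.approx(norm.cdf(delta / np.sqrt(2)),
                                          abs=0.02)


class TestBestThreshold:
    def test_separable_example(self):
        t, cc = best_threshold([1, 1, 0, 0], [0.9, 0.7, 0.6, 0.2])
        assert t == pytest.approx(0.65)
        m = metrics(cc)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_single_pair_midpoint(self):
        t, cc = best_threshold([1, 0], [0.8, 0.2])
        assert t == pytest.approx(0.5)
        m = metrics(cc)
        assert m.sensitivity + m.specificity - 1 == pytest.approx(1.0)

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            t, cc = best_threshold(labels, scores)
            m = metrics(cc)
            j = m.sensitivity + m.specificity - 1
            assert j == pytest.approx(exhaustive_best_j(labels, scores))

    def test_tie_breaks_to_smallest_threshold(self):
        # thresholds 0.35 and 0.55 give the same J; the smaller must win
        labels = [1, 1, 0, 0]
        scores = [0.9, 0.4, 0.5, 0.2]
        j_at = {}
        for t2 in [-np.inf, 0.3, 0.45, 0.7, np.inf]:
            m = metrics(confusion_at(labels, scores, t2))
            j_at[t2] = m.sensitivity + m.specificity - 1
        best_j = max(j_at.values())
        ties = sorted(k for k, v in j_at.items() if v == best_j)
        assert len(ties) > 1  # the instance really is tied
        t, _ = best_threshold(labels, scores)
        assert t == pytest.approx(ties[0])


class TestMetrics:
    def test_worked_arithmetic(self):
        m = metrics(ConfusionCounts(tp=95, fn=5, tn=94, fp=6))
        assert (m.sensitivity, m.specificity, m.accuracy) == (0.95, 0.94, 0.945)

    def test_zero_denominator_flagged(self):
        m = metrics(ConfusionCounts(tp=0, fn=0, tn=3, fp=1))
        assert "sensitivity" in m.undefined and np.isnan(m.sensitivity)
        assert m.specificity == 0.75

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_random_counts_match_formulas(self, tp, fn, tn, fp):
        m = metrics(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))
        if tp + fn:
            assert m.sensitivity == tp / (tp + fn)
        if tn + fp:
            assert m.specificity == tn / (tn + fp)
        if tp + fn + tn + fp:
            assert m.accuracy == (tp + tn) / (tp + fn + tn + fp)
            assert 0 <= m.accuracy <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fn=0, tn=0, fp=0)


def _labelled_dataset(n_pos=30, n_neg=30):
    variants = []
    for i in range(n_pos):
        variants.append(ProteinVariant("G", i + 1, "A", "T",
                                       category=Category.PLP))
    for i in range(n_neg):
        variants.append(ProteinVariant("G", n_pos + i + 1, "A", "T",
                                       af=0.001, category=Category.BENIGN))
    return BroadDataset(variants=variants, genes=["G"])


def _panel_for(ds, columns):
    import pandas as pd

    df = pd.DataFrame({"gene": [v.gene for v in ds],
                       "change": [v.change for v in ds]})
    for name, scores in columns.items():
        df[name] = scores
    return ToolPanel.from_frame(df)


class TestEvaluatePanel:
    def test_dominant_tool_has_higher_auc(self):
        rng = np.random.default_rng(3)
        ds = _labelled_dataset(50, 50)
        y = np.array([1] * 50 + [0] * 50)
        strong = rng.normal(3 * y, 1)
        weak = rng.normal(0.5 * y, 1)
        res = evaluate_panel(ds, _panel_for(ds, {"strong": strong,
                                                 "weak": weak}))
        assert res["strong"].auc >= res["weak"].auc
        table = res.table()
        assert table.iloc[0]["tool"] == "strong"  # sorted by accuracy/auc

    def test_perfect_separator(self):
        ds = _labelled_dataset(5, 5)
        scores = np.r_[np.full(5, 0.9), np.full(5, 0.1)]
        res = evaluate_panel(ds, _panel_for(ds, {"perfect": scores}))
        r = res["perfect"]
        assert r.auc == 1.0 and r.accuracy == 1.0

    def test_custom_threshold_strict(self):
        ds = _labelled_dataset(2, 2)
        # one positive sits exactly at the published threshold: not called
        scores = np.array([0.9, 0.66, 0.1, 0.2])
        spec = ToolSpec("ClinPred", Direction.HIGHER_PATHOGENIC, 0.66)
        res = evaluate_panel(ds, _panel_for(ds, {"ClinPred": scores}),
                             specs={"ClinPred": spec},
                             use_custom_thresholds=True)
        r = res["ClinPred"]
        assert r.threshold_source == "custom"
        assert r.confusion.tp == 1 and r.confusion.fn == 1
        assert r.sensitivity == 0.5 and r.specificity == 1.0

    def test_missingness_gate_drops_tool(self):
        ds = _labelled_dataset(10, 10)
        sparse = np.r_[np.full(10, np.nan), np.full(10, 0.5)]
        dense = np.linspace(0, 1, 20)[::-1]
        res = evaluate_panel(ds, _panel_for(ds, {"sparse": sparse,
                                                 "dense": dense}))
        assert res.dropped == ["sparse"]
        assert list(res.results) == ["dense"]

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(5)
        ds = _labelled_dataset(20, 20)
        scores = rng.normal(np.r_[np.ones(20), np.zeros(20)], 1)
        res = evaluate_panel(ds, _panel_for(ds, {"t": scores}))
        pts = res["t"].points.sort_values("threshold")
        assert (np.diff(pts["sensitivity"]) <= 1e-12).all()
        assert (np.diff(pts["specificity"]) >= -1e-12).all()

    def test_auc_equals_trapezoid_over_roc_points(self):
        rng = np.random.default_rng(9)
        labels = np.r_[np.ones(15, int), np.zeros(15, int)]
        scores = np.round(rng.normal(labels.astype(float), 1), 1)  # ties too
        pts = roc_points(labels, scores)
        x = 1 - pts["specificity"].to_numpy()
        y = pts["sensitivity"].to_numpy()
        order = np.lexsort((y, x))  # staircase vertices in curve order
        trapezoid = np.trapezoid(y[order], x[order])
        assert auc(labels, scores) == pytest.approx(trapezoid, abs=1e-12)

    def test_degenerate_dataset_signalled(self):
        ds = _labelled_dataset(3, 0)
        with pytest.raises(DegenerateLabelsError):
            evaluate_panel(ds, _panel_for(ds, {"t": [0.1, 0.2, 0.3]}))

    def test_default_specs_cover_published_panel(self):
        specs = default_tool_specs()
        assert len(specs) == 16
        assert specs["ClinPred"].threshold == 0.66
        assert specs["SIFT"].direction is Direction.LOWER_PATHOGENIC
        assert specs["PROVEAN"].threshold == -3.42
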