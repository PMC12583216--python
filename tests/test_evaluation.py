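"""Metric suite: accuracy, bootstrap, ICC, weighted kappa, severity report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aacscore.evaluation import (
    PairedScores,
    acceptable_proportion,
    bootstrap_ci,
    bootstrap_metrics,
    icc_2_1,
    regression_metrics,
    severity_report,
    weighted_kappa,
)
from aacscore.kauppila import Severity


# --- independent oracles ----------------------------------------------------

def icc_2_1_oracle(x: np.ndarray) -> float:
    """Brute-force two-way ANOVA decomposition via explicit loops."""
    n, k = x.shape
    grand = x.mean()
    row_means = [x[i].mean() for i in range(n)]
    col_means = [x[:, j].mean() for j in range(k)]
    ss_rows = sum(k * (rm - grand) ** 2 for rm in row_means)
    ss_cols = sum(n * (cm - grand) ** 2 for cm in col_means)
    ss_err = sum(
        (x[i, j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    msr, msc, mse = ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def weighted_kappa_oracle(a, b, scheme) -> float:
    """Cell-by-cell contingency computation over the full integer scale."""
    lo = min(min(a), min(b))
    hi = max(max(a), max(b))
    cats = list(range(lo, hi + 1))
    R = len(cats)
    n = len(a)
    num = den = 0.0
    for i, ci in enumerate(cats):
        for j, cj in enumerate(cats):
            o = sum(1 for x, y in zip(a, b) if x == ci and y == cj) / n
            pa = sum(1 for x in a if x == ci) / n
            pb = sum(1 for y in b if y == cj) / n
            w = abs(i - j) / (R - 1) if scheme == "linear" else ((i - j) / (R - 1)) ** 2
            num += w * o
            den += w * pa * pb
    return 1.0 - num / den


# --- regression metrics -----------------------------------------------------

class TestRegressionMetrics:
    def test_perfect_prediction(self):
        p = PairedScores(np.array([0, 10, 20]), np.array([0.0, 10.0, 20.0]))
        m = regression_metrics(p)
        assert (m.mae, m.mse) == (0.0, 0.0)
        assert m.spearman_rho == pytest.approx(1.0)
        assert m.r2 == pytest.approx(1.0)

    def test_hand_computed_example(self):
        p = PairedScores(np.array([0, 10, 20]), np.array([2.0, 10.0, 18.0]))
        m = regression_metrics(p)
        assert m.mae == pytest.approx(4 / 3)
        assert m.mse == pytest.approx(8 / 3)

    def test_rank_invariance_of_spearman(self):
        p = PairedScores(np.array([1, 2, 3, 4]), np.array([10.0, 20.0, 30.0, 40.0]))
        m = regression_metrics(p)
        assert m.spearman_rho == pytest.approx(1.0)
        assert m.r2 < 0  # wildly miscalibrated despite perfect ranks

    def test_constant_reference_flags_undefined(self):
        p = PairedScores(np.array([5, 5, 5]), np.array([4.0, 5.0, 6.0]))
        m = regression_metrics(p)
        assert np.isnan(m.spearman_rho) and np.isnan(m.r2)
        assert set(m.undefined) == {"spearman_rho", "r2"}

    @given(st.lists(st.tuples(st.integers(0, 24), st.floats(0, 24)), min_size=2, max_size=30))
    @settings(derandomize=True, max_examples=100)
    def test_mae_never_exceeds_rmse(self, pairs):
        ref = np.array([r for r, _ in pairs])
        pred = np.array([p for _, p in pairs])
        m = regression_metrics(PairedScores(ref, pred))
        assert m.mae <= np.sqrt(m.mse) + 1e-12


class TestAcceptableProportion:
    def test_strict_inequality_at_threshold(self):
        p = PairedScores(np.array([0, 0, 0]), np.array([0.0, 3.9, 4.0]))
        assert acceptable_proportion(p, 4.0) == pytest.approx(2 / 3)

    def test_all_exact(self):
        p = PairedScores(np.array([1, 2]), np.array([1.0, 2.0]))
        assert acceptable_proportion(p) == 1.0

    def test_zero_threshold_never_satisfied(self):
        p = PairedScores(np.array([1, 2]), np.array([1.0, 2.0]))
        assert acceptable_proportion(p, 0.0) == 0.0


class TestBootstrap:
    def test_constant_experiment_zero_width(self):
        ci = bootstrap_ci(lambda rng: {"m": 3.25}, B=50, seed=0)
        assert ci["m"] == (3.25, 3.25)

    def test_resample_interval_contains_point_estimate(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(0, 25, size=60)
        pred = ref + rng.normal(0, 2, size=60)
        p = PairedScores(ref, pred)
        ci = bootstrap_metrics(p, B=500, mode="resample", seed=1)
        m = regression_metrics(p)
        lo, hi = ci["mae"]
        assert lo <= m.mae <= hi
        assert lo < hi

    def test_retrain_mode_collects_distinct_replicates(self):
        calls = []

        def retrain(rng):
            ref = np.array([0, 5, 10, 15, 20])
            pred = ref + rng.normal(0, 1, size=5)
            calls.append(1)
            return PairedScores(ref, pred)

        ci = bootstrap_metrics(PairedScores(np.array([0, 1]), np.array([0.0, 1.0])),
                               B=5, mode="retrain", seed=2, retrain=retrain)
        assert len(calls) == 5
        assert ci["mae"][0] < ci["mae"][1]

    def test_failing_experiment_aborts(self):
        def bad(rng):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="bootstrap aborted"):
            bootstrap_ci(bad, B=100, seed=0)

    def test_endpoints_are_within_replicate_range(self):
        vals = []

        def exp(rng):
            v = float(rng.normal())
            vals.append(v)
            return {"m": v}

        ci = bootstrap_ci(exp, B=200, seed=3)
        assert min(vals) <= ci["m"][0] <= ci["m"][1] <= max(vals)


class TestIcc:
    def test_identical_columns_give_one(self):
        x = np.array([[1, 1], [5, 5], [9, 9], [3, 3]], dtype=float)
        assert icc_2_1(x) == pytest.approx(1.0)

    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 10))
            k = int(rng.integers(2, 5))
            x = rng.normal(size=(n, k)) * 5 + rng.normal(size=(n, 1)) * 3
            assert icc_2_1(x) == pytest.approx(icc_2_1_oracle(x), abs=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2
        df = pd.DataFrame(
            {"subject": np.repeat(np.arange(12), 3),
             "rater": np.tile(np.arange(3), 12),
             "score": x.ravel()}
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])  # two-way random, single, absolute
        icc21 = float(ref.loc[sel, "ICC"].iloc[0])
        assert icc_2_1(x) == pytest.approx(icc21, abs=1e-8)

    def test_constant_offset_between_raters_penalised(self):
        base = np.arange(10, dtype=float)
        x = np.column_stack([base, base + 20.0])
        val = icc_2_1(x)
        assert val == pytest.approx(icc_2_1_oracle(x), abs=1e-10)
        assert val < 0.5  # absolute agreement punishes systematic bias

    def test_subject_permutation_invariance(self, rng):
        x = rng.normal(size=(8, 3))
        perm = rng.permutation(8)
        assert icc_2_1(x[perm]) == pytest.approx(icc_2_1(x), abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc_2_1(np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="missing"):
            icc_2_1(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestWeightedKappa:
    def test_perfect_agreement(self):
        a = np.array([0, 1, 2, 1, 0])
        assert weighted_kappa(a, a) == pytest.approx(1.0)

    @pytest.mark.parametrize("scheme", ["linear", "quadratic"])
    def test_matches_oracles_on_random_tables(self, scheme, rng):
        for _ in range(25):
            n = int(rng.integers(10, 40))
            a = rng.integers(0, 4, size=n)
            b = np.clip(a + rng.integers(-1, 2, size=n), 0, 3)
            if len(np.unique(np.concatenate([a, b]))) < 2:
                continue
            ours = weighted_kappa(a, b, scheme)
            assert ours == pytest.approx(weighted_kappa_oracle(a.tolist(), b.tolist(), scheme), abs=1e-10)

    @pytest.mark.parametrize("scheme,sk_weights", [("linear", "linear"), ("quadratic", "quadratic")])
    def test_matches_sklearn_reference(self, scheme, sk_weights):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        a = rng.integers(0, 5, size=80)
        b = np.clip(a + rng.integers(-2, 3, size=80), 0, 4)
        ref = sk.cohen_kappa_score(a, b, weights=sk_weights, labels=np.arange(5))
        assert weighted_kappa(a, b, scheme) == pytest.approx(ref, abs=1e-10)

    def test_independent_uniform_ratings_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 4, size=5000)
        b = rng.integers(0, 4, size=5000)
        assert abs(weighted_kappa(a, b, "quadratic")) < 0.05

    def test_single_category_flagged_undefined(self):
        assert np.isnan(weighted_kappa(np.array([2, 2, 2]), np.array([2, 2, 2])))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_kappa(np.array([]), np.array([]))


class TestSeverityReport:
    def test_perfect_predictions_are_diagonal(self):
        ref = np.array([0, 2, 3, 8, 12, 15, 17, 20, 24])
        rep = severity_report(PairedScores(ref, ref.astype(float)))
        assert np.trace(rep.matrix) == len(ref)
        for cat in rep.per_category:
            assert rep.per_category[cat]["sensitivity"][0] == pytest.approx(100.0)
            assert rep.per_category[cat]["specificity"][0] == pytest.approx(100.0)

    def test_hand_built_matrix_metrics(self):
        # target confusion matrix rows (reference): (8,2,0 / 1,9,0 / 0,3,7)
        ref, pred = [], []
        def add(rcat, pcat, n):
            rs = {0: 2, 1: 10, 2: 20}
            ps = {0: 2.0, 1: 10.0, 2: 20.0}
            ref.extend([rs[rcat]] * n)
            pred.extend([ps[pcat]] * n)
        add(0, 0, 8); add(0, 1, 2)
        add(1, 0, 1); add(1, 1, 9)
        add(2, 1, 3); add(2, 2, 7)
        rep = severity_report(PairedScores(np.array(ref), np.array(pred)))
        assert rep.matrix.tolist() == [[8, 2, 0], [1, 9, 0], [0, 3, 7]]
        m = rep.per_category[Severity.no_mild]
        assert m["sensitivity"][0] == pytest.approx(100 * 8 / 10)
        assert m["specificity"][0] == pytest.approx(100 * 19 / 20)
        assert m["ppv"][0] == pytest.approx(100 * 8 / 9)
        assert m["npv"][0] == pytest.approx(100 * 19 / 21)
        assert m["accuracy"][0] == pytest.approx(100 * 27 / 30)
        sev = rep.per_category[Severity.severe]
        assert sev["sensitivity"][0] == pytest.approx(100 * 7 / 10)

    def test_marginals_reproduce_category_counts(self, rng):
        ref = rng.integers(0, 25, size=50)
        pred = np.clip(ref + rng.normal(0, 3, size=50), 0, 24)
        rep = severity_report(PairedScores(ref, pred))
        assert rep.matrix.sum() == 50
        from aacscore.kauppila import classify_severity

        ref_counts = np.bincount([("no_mild", "moderate", "severe").index(
            classify_severity(int(r)).value) for r in ref], minlength=3)
        assert rep.matrix.sum(axis=1).tolist() == ref_counts.tolist()

    def test_wilson_ci_brackets_point_estimate(self):
        ref = np.array([0, 0, 10, 10, 20, 20])
        pred = np.array([0.0, 12.0, 10.0, 9.0, 20.0, 3.0])
        rep = severity_report(PairedScores(ref, pred))
        for cat, metrics in rep.per_category.items():
            for name, (val, (lo, hi)) in metrics.items():
                if np.isfinite(val):
                    assert lo - 1e-9 <= val <= hi + 1e-9

    def test_absent_category_flagged(self):
        ref = np.array([1, 2, 3, 4])  # all no_mild
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        rep = severity_report(PairedScores(ref, pred))
        assert any("no_mild.specificity" in u for u in rep.undefined)
        assert any("moderate.sensitivity" in u for u in rep.undefined)
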