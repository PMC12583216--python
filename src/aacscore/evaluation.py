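"""Agreement and accuracy statistics for predicted vs. reference AAC scores.

Covers the full evaluation suite used for automated Kauppila scoring:
regression accuracy (MAE, MSE, Spearman's rho, R^2) with percentile
bootstrap confidence intervals, inter-rater agreement (two-way random-
effects single-measure absolute-agreement ICC(2,1) and weighted kappa), the
clinical-acceptability proportion (|error| < 4 by default), and severity-
stratified one-vs-rest classification metrics with Wilson score intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .kauppila import Severity, classify_severity

__all__ = [
    "PairedScores",
    "MetricsReport",
    "ConfusionSummary",
    "regression_metrics",
    "acceptable_proportion",
    "bootstrap_ci",
    "bootstrap_metrics",
    "icc_2_1",
    "weighted_kappa",
    "severity_report",
]


@dataclass(frozen=True)
class PairedScores:
    """Reference (manual-standard) totals paired with model predictions."""

    reference: np.ndarray
    predicted: np.ndarray
    ids: tuple = ()

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        pred = np.asarray(self.predicted, dtype=float)
        if ref.ndim != 1 or pred.shape != ref.shape:
            raise ValueError("reference and predicted must be equal-length 1-D sequences")
        if len(ref) < 2:
            raise ValueError("need at least 2 paired scores")
        if not np.all(ref == np.round(ref)) or ref.min() < 0 or ref.max() > 24:
            raise ValueError("reference scores must be integers in [0, 24]")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "predicted", pred)
        if self.ids and len(self.ids) != len(ref):
            raise ValueError("ids length mismatch")

    def __len__(self) -> int:
        return len(self.reference)

    def take(self, idx: np.ndarray) -> "PairedScores":
        ids = tuple(np.asarray(self.ids)[idx]) if self.ids else ()
        return PairedScores(self.reference[idx], self.predicted[idx], ids)


@dataclass(frozen=True)
class MetricsReport:
    """Point estimates (optionally with 95% CIs) of the regression metrics."""

    mae: float
    mse: float
    spearman_rho: float
    r2: float
    acceptable_proportion: float
    acceptability_threshold: float = 4.0
    ci: dict = field(default_factory=dict)
    undefined: tuple[str, ...] = ()


def regression_metrics(p: PairedScores, acceptability_threshold: float = 4.0) -> MetricsReport:
    """MAE, MSE, Spearman's rho (average ranks for ties), R^2, acceptability.

    With zero variance in the reference, Spearman's rho and R^2 are reported
    as NaN and listed in ``undefined`` rather than fabricated.
    """
    err = p.predicted - p.reference
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    undefined: list[str] = []
    if np.ptp(p.reference) == 0:
        rho, r2 = float("nan"), float("nan")
        undefined += ["spearman_rho", "r2"]
    else:
        rho = float(stats.spearmanr(p.reference, p.predicted).statistic)
        ss_res = float(np.sum(err**2))
        ss_tot = float(np.sum((p.reference - p.reference.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
    return MetricsReport(
        mae=mae, mse=mse, spearman_rho=rho, r2=r2,
        acceptable_proportion=acceptable_proportion(p, acceptability_threshold),
        acceptability_threshold=acceptability_threshold,
        undefined=tuple(undefined),
    )


def acceptable_proportion(p: PairedScores, threshold: float = 4.0) -> float:
    """Fraction of predictions with absolute error strictly below ``threshold``."""
    return float(np.mean(np.abs(p.predicted - p.reference) < threshold))


def bootstrap_ci(
    experiment: Callable[[np.random.Generator], Mapping[str, float]],
    B: int = 1000,
    seed: int = 0,
    max_failure_fraction: float = 0.01,
) -> dict[str, tuple[float, float]]:
    """Generic percentile bootstrap: 2.5th/97.5th percentiles over replicates.

    ``experiment`` is any re-runnable procedure mapping a replicate's RNG to
    a dict of metric values.  Failed replicates are recorded; the run aborts
    if more than ``max_failure_fraction`` of them fail.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    replicates: dict[str, list[float]] = {}
    failures = 0
    for _ in range(B):
        sub = np.random.default_rng(rng.integers(2**31 - 1))
        try:
            result = experiment(sub)
        except Exception:
            failures += 1
            if failures > max_failure_fraction * B:
                raise RuntimeError(f"bootstrap aborted: {failures}/{B} replicates failed")
            continue
        for k, v in result.items():
            replicates.setdefault(k, []).append(float(v))
    return {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in replicates.items()
    }


def _metric_dict(p: PairedScores, threshold: float) -> dict[str, float]:
    r = regression_metrics(p, threshold)
    return {"mae": r.mae, "mse": r.mse, "spearman_rho": r.spearman_rho, "r2": r.r2,
            "acceptable_proportion": r.acceptable_proportion}


def bootstrap_metrics(
    pairs: PairedScores,
    B: int = 1000,
    mode: str = "resample",
    seed: int = 0,
    retrain: Callable[[np.random.Generator], PairedScores] | None = None,
    acceptability_threshold: float = 4.0,
) -> dict[str, tuple[float, float]]:
    """95% bootstrap CIs for the regression metrics.

    ``mode='resample'`` bootstraps the test-set pairs without retraining (the
    fast variant).  ``mode='retrain'`` reproduces the full procedure —
    resample the training cases with replacement, retrain, predict on the
    fixed test set — via the caller-supplied ``retrain(rng) -> PairedScores``
    closure, run once per replicate.
    """
    if mode == "resample":
        n = len(pairs)

        def experiment(rng: np.random.Generator) -> dict[str, float]:
            idx = rng.integers(0, n, size=n)
            return _metric_dict(pairs.take(idx), acceptability_threshold)

    elif mode == "retrain":
        if retrain is None:
            raise ValueError("mode='retrain' requires a retrain(rng) -> PairedScores closure")

        def experiment(rng: np.random.Generator) -> dict[str, float]:
            return _metric_dict(retrain(rng), acceptability_threshold)

    else:
        raise ValueError(f"mode must be 'resample' or 'retrain', got {mode!r}")
    return bootstrap_ci(experiment, B=B, seed=seed)


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    ``ratings`` is an n x k matrix (n subjects, k raters, complete).  From
    the two-way ANOVA mean squares:

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    with MS_R the between-subjects, MS_C the between-raters and MS_E the
    residual mean square.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D n x k matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 subjects and k >= 2 raters, got {n} x {k}")
    if not np.isfinite(x).all():
        raise ValueError("ratings matrix contains missing or non-finite cells")
    grand = x.mean()
    ss_rows = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        return float("nan")
    return float((ms_r - ms_e) / denom)


def weighted_kappa(a: Sequence[int], b: Sequence[int], scheme: str = "quadratic") -> float:
    """Weighted Cohen's kappa for ordinal ratings on a shared integer scale.

    The scale spans every integer from the smallest to the largest observed
    rating.  Disagreement weights are ``|i-j|/(R-1)`` (linear) or
    ``((i-j)/(R-1))^2`` (quadratic); kappa = 1 - sum(wO)/sum(wE) with O the
    observed and E the chance-expected (outer product of marginals)
    proportions.  Returns NaN (undefined) when both raters use a single
    category, where chance disagreement is zero.
    """
    if scheme not in ("linear", "quadratic"):
        raise ValueError(f"scheme must be 'linear' or 'quadratic', got {scheme!r}")
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size == 0 or a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length non-empty 1-D integer vectors")
    if not (np.all(a == np.round(a)) and np.all(b == np.round(b))):
        raise ValueError("ratings must be integers")
    a = a.astype(int)
    b = b.astype(int)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    R = hi - lo + 1
    if R == 1:
        return float("nan")
    O = np.zeros((R, R))
    np.add.at(O, (a - lo, b - lo), 1.0)
    O /= O.sum()
    E = np.outer(O.sum(axis=1), O.sum(axis=0))
    d = np.abs(np.arange(R)[:, None] - np.arange(R)[None, :]) / (R - 1)
    w = d if scheme == "linear" else d**2
    return float(1.0 - (w * O).sum() / (w * E).sum())


_CATEGORIES = (Severity.no_mild, Severity.moderate, Severity.severe)


@dataclass(frozen=True)
class ConfusionSummary:
    """3x3 severity confusion matrix plus one-vs-rest metrics with 95% CIs.

    ``per_category`` maps each severity to a dict of metric name ->
    ``(value_percent, (ci_low_percent, ci_high_percent))``; metrics whose
    denominator is zero are NaN and listed in ``undefined``.
    """

    matrix: np.ndarray  # rows: reference, cols: predicted
    per_category: dict
    categories: tuple = _CATEGORIES
    undefined: tuple[str, ...] = ()


def _prediction_categories(predicted: np.ndarray) -> list[Severity]:
    return [classify_severity(int(np.round(np.clip(v, 0.0, 24.0)))) for v in predicted]


def severity_report(p: PairedScores) -> ConfusionSummary:
    """Severity-stratified classification report.

    Continuous predictions are clamped to [0, 24], rounded half-to-even and
    classified into tiers; per category (one-vs-rest) the report gives
    accuracy, sensitivity, specificity, NPV and PPV in percent with Wilson
    score 95% intervals.
    """
    ref_cat = [classify_severity(int(r)) for r in p.reference]
    pred_cat = _prediction_categories(p.predicted)
    idx = {c: i for i, c in enumerate(_CATEGORIES)}
    matrix = np.zeros((3, 3), dtype=int)
    for r, q in zip(ref_cat, pred_cat):
        matrix[idx[r], idx[q]] += 1

    n = matrix.sum()
    per_category: dict = {}
    undefined: list[str] = []
    for i, cat in enumerate(_CATEGORIES):
        tp = matrix[i, i]
        fn = matrix[i].sum() - tp
        fp = matrix[:, i].sum() - tp
        tn = n - tp - fn - fp
        counts = {
            "accuracy": (tp + tn, n),
            "sensitivity": (tp, tp + fn),
            "specificity": (tn, tn + fp),
            "npv": (tn, tn + fn),
            "ppv": (tp, tp + fp),
        }
        metrics = {}
        for name, (num, den) in counts.items():
            if den == 0:
                metrics[name] = (float("nan"), (float("nan"), float("nan")))
                undefined.append(f"{cat.value}.{name}")
            else:
                lo, hi = proportion_confint(num, den, alpha=0.05, method="wilson")
                metrics[name] = (100.0 * num / den, (100.0 * lo, 100.0 * hi))
        per_category[cat] = metrics
    return ConfusionSummary(matrix=matrix, per_category=per_category, undefined=tuple(undefined))
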