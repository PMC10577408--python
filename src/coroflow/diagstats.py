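"""Diagnostic-validation statistics for paired FFR / CT-FFR data.

Covers the full battery used to validate a noninvasive index against an
invasive reference standard: confusion-matrix metrics with exact
Clopper-Pearson intervals, prevalence-based predictive values, ROC/AUC with
the DeLong test for paired AUCs, the Youden-optimal threshold, McNemar's
test, Spearman correlation, Bland-Altman agreement, stratified performance
tables, and univariate logistic regression on discordant (false positive /
false negative) lesions.

The reference standard throughout is invasive FFR <= 0.80.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "DiagPerformance",
    "ROCCurve",
    "BlandAltmanResult",
    "LogisticFit",
    "confusion",
    "performance",
    "bayes_predictive",
    "roc",
    "delong_compare",
    "youden_threshold",
    "mcnemar",
    "mcnemar_from_counts",
    "spearman",
    "bland_altman",
    "stratified_performance",
    "agreement_by_stratum",
    "discordance_regression",
]


class DiagStatsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DiagStatsError("counts must be >= 0")
        if self.total == 0:
            raise DiagStatsError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total


@dataclass(frozen=True)
class MetricCI:
    """Proportion with a two-sided 95% CI; ``available`` is False when the
    denominator is zero (the estimate is then undefined, not zero)."""

    estimate: float | None
    lo: float | None
    hi: float | None
    available: bool = True


@dataclass(frozen=True)
class DiagPerformance:
    sensitivity: MetricCI
    specificity: MetricCI
    accuracy: MetricCI
    ppv: MetricCI
    npv: MetricCI


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_ci: tuple
    scores: np.ndarray
    truth: np.ndarray
    lower_is_positive: bool


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class LogisticFit:
    predictor: str
    coefficient: float | None
    odds_ratio: float | None
    std_err: float | None
    p_value: float | None
    separation: bool = False


# ---------------------------------------------------------------------------


def confusion(pred, truth) -> ConfusionMatrix:
    """Cross-tabulate binary predictions against binary truth."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape or pred.size == 0:
        raise DiagStatsError("pred and truth must be equal-length, non-empty")
    return ConfusionMatrix(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
    )


def _cp_interval(k: int, n: int, alpha: float = 0.05) -> MetricCI:
    """Clopper-Pearson exact two-sided interval for k successes out of n."""
    if n == 0:
        return MetricCI(None, None, None, available=False)
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return MetricCI(k / n, lo, hi)


def performance(cm: ConfusionMatrix) -> DiagPerformance:
    """Se/Sp/accuracy/PPV/NPV with exact Clopper-Pearson 95% CIs."""
    return DiagPerformance(
        sensitivity=_cp_interval(cm.tp, cm.tp + cm.fn),
        specificity=_cp_interval(cm.tn, cm.tn + cm.fp),
        accuracy=_cp_interval(cm.tp + cm.tn, cm.total),
        ppv=_cp_interval(cm.tp, cm.tp + cm.fp),
        npv=_cp_interval(cm.tn, cm.tn + cm.fn),
    )


def bayes_predictive(se: float, sp: float, prevalence: float) -> tuple:
    """(PPV, NPV, accuracy) from sensitivity, specificity and prevalence."""
    for name, val in (("se", se), ("sp", sp), ("prevalence", prevalence)):
        if not (0.0 < val < 1.0):
            raise DiagStatsError(f"{name} must lie in (0, 1), got {val}")
    ppv = se * prevalence / (se * prevalence + (1 - sp) * (1 - prevalence))
    npv = sp * (1 - prevalence) / ((1 - se) * prevalence + sp * (1 - prevalence))
    acc = se * prevalence + sp * (1 - prevalence)
    return ppv, npv, acc


# ---------------------------------------------------------------------------
# ROC / AUC


def _oriented_scores(scores: np.ndarray, lower_is_positive: bool) -> np.ndarray:
    return -scores if lower_is_positive else scores


def _auc_mann_whitney(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic (ties count 1/2), higher = positive."""
    ranks = stats.rankdata(scores)
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    r_pos = ranks[truth].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc(scores, truth, lower_is_positive: bool = True) -> ROCCurve:
    """ROC curve by threshold sweep plus the Mann-Whitney AUC.

    With ``lower_is_positive`` (the FFR convention: low values indicate
    ischemia) a case is called positive when score <= threshold.  The AUC CI
    is the DeLong variance-based normal interval.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise DiagStatsError("scores and truth must have equal length")
    if truth.all() or (~truth).all():
        raise DiagStatsError("both classes must be present")
    s = _oriented_scores(scores, lower_is_positive)
    auc = _auc_mann_whitney(s, truth)
    var = _delong_variance_single(s, truth)
    z = stats.norm.ppf(0.975)
    half = z * np.sqrt(max(var, 0.0))
    thresholds = np.unique(scores)
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    n_pos, n_neg = truth.sum(), (~truth).sum()
    for i, t in enumerate(thresholds):
        pred = scores <= t if lower_is_positive else scores >= t
        tpr[i] = (pred & truth).sum() / n_pos
        fpr[i] = (pred & ~truth).sum() / n_neg
    return ROCCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        auc_ci=(max(0.0, auc - half), min(1.0, auc + half)),
        scores=scores,
        truth=truth,
        lower_is_positive=lower_is_positive,
    )


def _delong_components(scores: np.ndarray, truth: np.ndarray) -> tuple:
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[truth]
    neg = scores[~truth]
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg) for p in pos])
    v01 = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / len(pos) for n in neg])
    return v10, v01


def _delong_variance_single(scores: np.ndarray, truth: np.ndarray) -> float:
    v10, v01 = _delong_components(scores, truth)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        return np.nan
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_compare(roc_a: ROCCurve, roc_b: ROCCurve) -> tuple:
    """Paired AUC comparison by DeLong's method: (delta_auc, z, p).

    Both curves must be computed on the same cases (identical truth).
    """
    if not np.array_equal(roc_a.truth, roc_b.truth):
        raise DiagStatsError("DeLong comparison requires the same truth vector")
    sa = _oriented_scores(roc_a.scores, roc_a.lower_is_positive)
    sb = _oriented_scores(roc_b.scores, roc_b.lower_is_positive)
    truth = roc_a.truth
    va10, va01 = _delong_components(sa, truth)
    vb10, vb01 = _delong_components(sb, truth)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    cov = s10 / m + s01 / n
    delta = roc_a.auc - roc_b.auc
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if delta == 0.0 and var <= 0:
        return 0.0, 0.0, 1.0
    if var <= 0:
        raise DiagStatsError("degenerate DeLong variance")
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(delta), float(z), float(p)


def youden_threshold(curve: ROCCurve, preferred: float = 0.80) -> tuple:
    """Threshold maximizing Youden's J = Se + Sp - 1.

    Returns ``(threshold, j, tied)``.  Exact ties in J are broken toward the
    threshold nearest ``preferred`` and flagged; perfect separation is also
    flagged, since every threshold in the separating gap attains J = 1.
    """
    j = curve.tpr - curve.fpr
    jmax = j.max()
    tied_idx = np.nonzero(np.isclose(j, jmax, atol=1e-12))[0]
    tie = len(tied_idx) > 1 or bool(np.isclose(jmax, 1.0))
    best = tied_idx[np.argmin(np.abs(curve.thresholds[tied_idx] - preferred))]
    return float(curve.thresholds[best]), float(jmax), tie


# ---------------------------------------------------------------------------
# Paired tests and agreement


def mcnemar(correct_a, correct_b) -> tuple:
    """McNemar test on paired correctness indicators: (statistic, p).

    Uses the exact binomial test when the discordant count is < 25,
    otherwise the continuity-corrected chi-square (|b-c|-1)^2 / (b+c).
    Degenerate case b + c = 0 returns (0.0, 1.0).
    """
    a = np.asarray(correct_a, dtype=bool)
    c_ = np.asarray(correct_b, dtype=bool)
    if a.shape != c_.shape:
        raise DiagStatsError("paired vectors must have equal length")
    b = int((a & ~c_).sum())
    c = int((~a & c_).sum())
    return mcnemar_from_counts(b, c)


def mcnemar_from_counts(b: int, c: int) -> tuple:
    """McNemar test from the two discordant counts directly."""
    if b + c == 0:
        return 0.0, 1.0
    statistic = (abs(b - c) - 1) ** 2 / (b + c)
    if b + c < 25:
        p = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
    else:
        p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def spearman(x, y) -> tuple:
    """Spearman rank correlation with average ranks for ties: (r, p)."""
    r = stats.spearmanr(x, y)
    return float(r.statistic), float(r.pvalue)


def bland_altman(ctffr, ffr) -> BlandAltmanResult:
    """Agreement between CT-FFR and invasive FFR (differences ct - invasive)."""
    d = np.asarray(ctffr, dtype=float) - np.asarray(ffr, dtype=float)
    if d.size < 2:
        raise DiagStatsError("need >= 2 paired observations")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


# ---------------------------------------------------------------------------
# Stratified evaluation


def stratified_performance(
    vessels: pd.DataFrame,
    strata: pd.Series | str,
    score_col: str = "ctffr",
    truth_col: str = "true_ffr",
    threshold: float = 0.80,
) -> pd.DataFrame:
    """performance() per stratum; rows indexed by stratum label.

    ``strata`` may be a column name or an aligned label series (e.g. an
    Agatston < 400 / >= 400 grouping or CT-FFR bins).
    """
    labels = vessels[strata] if isinstance(strata, str) else strata
    rows = []
    for label, grp in vessels.groupby(labels, observed=True):
        cm = confusion(grp[score_col] <= threshold, grp[truth_col] <= threshold)
        perf = performance(cm)
        rows.append(
            {
                "stratum": label,
                "n": cm.total,
                "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                **{
                    name: getattr(perf, name).estimate
                    for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv")
                },
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


def agreement_by_stratum(
    vessels: pd.DataFrame,
    score_col: str = "ctffr",
    truth_col: str = "true_ffr",
    threshold: float = 0.80,
) -> pd.DataFrame:
    """Classification agreement with the invasive standard per CT-FFR stratum.

    A vessel agrees when (CT-FFR <= 0.80) matches (FFR <= 0.80); reported per
    CT-FFR bin, reproducing the near-certainty of very high / very low values
    and the dip next to the cut point.
    """
    from .cohort import classify_ffr

    strata = classify_ffr(vessels[score_col].to_numpy(), kind="ct")["stratum"]
    agree = (vessels[score_col] <= threshold).to_numpy() == (
        vessels[truth_col] <= threshold
    ).to_numpy()
    df = pd.DataFrame({"stratum": strata, "agree": agree})
    out = df.groupby("stratum").agg(n=("agree", "size"), n_agree=("agree", "sum"))
    out["agreement"] = out["n_agree"] / out["n"]
    return out


def discordance_regression(
    vessels: pd.DataFrame,
    predictors: list,
    stratum_mask: pd.Series | None = None,
    score_col: str = "ctffr",
    truth_col: str = "true_ffr",
    threshold: float = 0.80,
) -> list:
    """Univariate logistic fits of lesion discordance on each predictor.

    The outcome is 1 when the CT-FFR call disagrees with the invasive
    standard (false positive or false negative) within the selected stratum.
    Complete separation is detected and flagged instead of silently
    diverging.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    df = vessels if stratum_mask is None else vessels[stratum_mask]
    y = (
        (df[score_col] <= threshold).to_numpy()
        != (df[truth_col] <= threshold).to_numpy()
    ).astype(float)
    fits: list[LogisticFit] = []
    for pred in predictors:
        x = df[pred].to_numpy(dtype=float)
        if y.sum() == 0 or y.sum() == len(y) or np.ptp(x) == 0:
            fits.append(LogisticFit(pred, None, None, None, None, separation=True))
            continue
        X = sm.add_constant(x)
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            coef = float(res.params[1])
            se = float(res.bse[1])
            if not np.isfinite(se) or se > 50:
                raise ValueError("separation")
            fits.append(
                LogisticFit(pred, coef, float(np.exp(coef)), se, float(res.pvalues[1]))
            )
        except Exception:
            fits.append(LogisticFit(pred, None, None, None, None, separation=True))
    return fits
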