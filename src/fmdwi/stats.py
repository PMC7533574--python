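"""ROI summaries and the group-discrimination statistical battery.

Covers the analysis stages that turn parameter maps into findings: ROI
means, two-sample t-tests (from raw values or from published mean/SD/n
summaries), ROC curves with AUC and Youden-index thresholds, multivariable
marker combination via logistic regression, Pearson partial correlation
(residual method) adjusting for covariates such as age, and
Benjamini–Hochberg FDR correction.  :func:`run_group_analysis` orchestrates
the full battery over a subjects table: AD-vs-controls and mild-vs-moderate
contrasts per ROI and parameter, ROC for α, ADC and their combinations, and
score correlations within the patient groups with FDR across that
correlation family.

Conventions: sample SD (n−1) throughout; pooled-variance t-test by default
(Welch by config); ROC orientation auto-chosen so AUC ≥ 0.5; Youden
candidate thresholds at midpoints between adjacent distinct scores plus
±∞, classifying disease-positive when the oriented score ≥ threshold, ties
resolved toward the smallest threshold.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "ROCSummary",
    "PartialCorrResult",
    "StatsConfig",
    "roi_mean",
    "two_sample_ttest",
    "ttest_from_summary",
    "pool_summaries",
    "roc_analysis",
    "youden_threshold",
    "combine_markers",
    "partial_correlation",
    "bh_fdr",
    "run_group_analysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    variant: str


@dataclass(frozen=True)
class ROCSummary:
    """Empirical ROC curve with Youden-optimal operating point.

    ``higher_is_positive`` records the orientation chosen so that AUC ≥ 0.5
    (True: large marker values indicate the positive class)."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    youden: float
    higher_is_positive: bool


@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    p: float
    n: int
    n_covariates: int


def roi_mean(map3d: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of a map over the finite voxels of a mask.

    Non-finite voxels (unfittable) are excluded and counted via debug
    logging; an all-non-finite ROI yields NaN.  An empty mask raises.
    """
    map3d = np.asarray(map3d, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if map3d.shape != mask.shape:
        raise ValueError(f"shape mismatch: map {map3d.shape} vs mask {mask.shape}")
    values = map3d[mask]
    if values.size == 0:
        raise ValueError("mask selects no voxels")
    finite = np.isfinite(values)
    n_excluded = int((~finite).sum())
    if n_excluded:
        logger.debug("roi_mean: excluded %d non-finite of %d voxels", n_excluded, values.size)
    if not finite.any():
        return math.nan
    return float(values[finite].mean())


def two_sample_ttest(x, y, variant: str = "pooled") -> TestResult:
    """Two-sided two-sample t-test; ``variant`` is "pooled" or "welch"."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        df = len(x) + len(y) - 2
        if x.mean() == y.mean():
            return TestResult(statistic=0.0, df=float(df), p=1.0, variant=variant)
        return TestResult(statistic=math.copysign(math.inf, x.mean() - y.mean()), df=float(df), p=0.0, variant=variant)
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TestResult(statistic=float(res.statistic), df=float(res.df), p=float(res.pvalue), variant=variant)


def ttest_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int, variant: str = "pooled"
) -> TestResult:
    """Two-sample t-test from sufficient statistics (mean, sample SD, n).

    Enables significance checks against published mean ± SD tables without
    subject-level data; formulas are identical to :func:`two_sample_ttest`.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    if sd1 == 0 and sd2 == 0:
        df = n1 + n2 - 2
        if m1 == m2:
            return TestResult(statistic=0.0, df=float(df), p=1.0, variant=variant)
        return TestResult(statistic=math.copysign(math.inf, m1 - m2), df=float(df), p=0.0, variant=variant)
    res = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(statistic=float(res.statistic), df=float(df), p=float(res.pvalue), variant=variant)


def pool_summaries(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, float, int]:
    """Exactly pool two subgroups' (mean, sample SD, n) into one group's.

    This is the identity that recovers the combined patient group's summary
    from its published mild/moderate subgroup rows: the pooled mean is the
    weighted mean and the pooled sum of squares adds within-group and
    between-group contributions.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("subgroup sizes must be >= 1")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    n = n1 + n2
    m = (n1 * m1 + n2 * m2) / n
    ss = (n1 - 1) * sd1**2 + (n2 - 1) * sd2**2 + n1 * (m1 - m) ** 2 + n2 * (m2 - m) ** 2
    sd = math.sqrt(ss / (n - 1))
    return m, sd, n


def _validate_binary(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D arrays")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return scores, labels


def youden_threshold(scores, labels, higher_is_positive: bool = True) -> tuple[float, float, float]:
    """Threshold maximising J = sensitivity + specificity − 1.

    Candidates are the midpoints between adjacent distinct scores plus ±∞;
    a subject is called positive when the oriented score is ≥ threshold.
    Ties in J are broken toward the smallest threshold.  Returns
    (threshold, sensitivity, specificity) in the marker's original units.
    """
    scores, labels = _validate_binary(scores, labels)
    s = scores if higher_is_positive else -scores
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate(([-np.inf], mids, [np.inf]))
    pos = labels == 1
    best = None
    for thr in candidates:
        pred = s >= thr
        sens = pred[pos].mean()
        spec = (~pred[~pos]).mean()
        J = sens + spec - 1.0
        if best is None or J > best[0] + 1e-12:
            best = (J, thr, sens, spec)
    _, thr, sens, spec = best
    if not higher_is_positive and np.isfinite(thr):
        thr = -thr
    return float(thr), float(sens), float(spec)


def roc_analysis(scores, labels) -> ROCSummary:
    """Empirical ROC with trapezoidal AUC and Youden operating point.

    Tied scores collapse into a single threshold step, making the AUC equal
    to the Mann–Whitney concordant-pair fraction with ½ credit for ties.
    Orientation is chosen automatically so AUC ≥ 0.5 and reported in
    ``higher_is_positive``.
    """
    scores, labels = _validate_binary(scores, labels)
    auc = float(roc_auc_score(labels, scores))
    higher = auc >= 0.5
    oriented = scores if higher else -scores
    auc = auc if higher else 1.0 - auc
    fpr, tpr, _ = roc_curve(labels, oriented)
    thr, sens, spec = youden_threshold(scores, labels, higher_is_positive=higher)
    return ROCSummary(
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        threshold=thr,
        sensitivity=sens,
        specificity=spec,
        youden=sens + spec - 1.0,
        higher_is_positive=higher,
    )


def combine_markers(features, labels) -> np.ndarray:
    """Combine continuous markers into one score per subject.

    Fits an unregularised maximum-likelihood logistic regression (intercept
    included, Newton iterations capped at 100, tolerance 1e-8) and returns
    its linear predictor.  Under perfect separation the ML optimum diverges,
    so the fit falls back to a ridge-stabilised logistic direction (penalty
    1e-6) with a warning; downstream ROC analysis only uses the ordering.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on subject count")
    if np.any(~np.isfinite(X)):
        raise ValueError("features must not contain missing values")
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError("need >= 2 subjects per class")
    # standardise for numerical stability; the linear predictor's ordering
    # (all ROC cares about) is unaffected
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            warnings.simplefilter("ignore", sm.tools.sm_exceptions.ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)  # overflow while diverging
            model = sm.Logit(y, sm.add_constant(Xs, has_constant="add"))
            fit = model.fit(disp=0, maxiter=100, tol=1e-8)
        if not fit.mle_retvals.get("converged", False) or not np.all(np.isfinite(fit.params)):
            raise RuntimeError("logistic fit did not converge")
        return np.asarray(fit.fittedvalues)  # linear predictor
    except Exception:
        logger.warning("perfect separation or non-convergence; using ridge-stabilised logistic direction")
        clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
        clf.fit(Xs, y)
        return Xs @ clf.coef_.ravel() + float(clf.intercept_[0])


def partial_correlation(x, y, covariates=None) -> PartialCorrResult:
    """Pearson partial correlation of x and y given covariates.

    Both variables are residualised on the covariates (with intercept) by
    least squares; r is the plain Pearson correlation of the residuals and
    p comes from t = r·√((n−2−k)/(1−r²)) on n−2−k degrees of freedom.
    With no covariates this reduces exactly to the ordinary Pearson test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    k = Z.shape[1]
    if len(y) != n or Z.shape[0] != n:
        raise ValueError("x, y and covariates disagree on length")
    if n <= 2 + k:
        raise ValueError(f"need n > 2 + {k} covariates, got n={n}")
    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        return PartialCorrResult(r=math.nan, p=math.nan, n=n, n_covariates=k)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrResult(r=r, p=p, n=n, n_covariates=k)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Orchestration over a subjects table
# ---------------------------------------------------------------------------

PARAMETERS = ("alpha", "hurst", "mu", "adc")
ROIS = ("left", "right")
SCALES = ("mmse", "moca")

_MARKER_SETS = {
    "alpha": ("alpha",),
    "adc": ("adc",),
    "alpha+adc": ("alpha", "adc"),
    "alpha+adc+hurst+mu": ("alpha", "adc", "hurst", "mu"),
}


@dataclass(frozen=True)
class StatsConfig:
    """Options of the orchestrated analysis."""

    ttest_variant: str = "pooled"
    covariates: tuple[str, ...] = ("age",)
    control_group: str = "controls"
    patient_groups: tuple[str, ...] = ("mild_AD", "moderate_AD")
    include_roc: bool = True
    include_correlations: bool = True


def _required_columns(config: StatsConfig) -> list[str]:
    cols = ["id", "group", "age", "sex", "mmse", "moca"]
    cols += [f"{p}_{r}" for p in PARAMETERS for r in ROIS]
    return cols


def run_group_analysis(subjects: pd.DataFrame, config: StatsConfig | None = None) -> dict:
    """Run the full statistical battery over a subjects table.

    Expects one row per subject with columns id, group, age, sex, mmse,
    moca and ``{parameter}_{roi}`` ROI means for parameter in
    (alpha, hurst, mu, adc) and roi in (left, right).  Produces a
    deterministic, order-invariant report dict with three sections:
    ``comparisons`` (t-tests per contrast × ROI × parameter), ``roc``
    (per contrast × ROI × marker set, combinations via logistic
    regression), and ``correlations`` (parameter vs cognitive score within
    the patient groups, partial on the configured covariates, with BH-FDR
    q-values across that family).
    """
    config = config or StatsConfig()
    missing = [c for c in _required_columns(config) if c not in subjects.columns]
    if missing:
        raise ValueError(f"subjects table is missing required columns: {missing}")
    df = subjects.sort_values("id").reset_index(drop=True)

    patients = df[df["group"].isin(config.patient_groups)]
    controls = df[df["group"] == config.control_group]
    if len(config.patient_groups) != 2:
        raise ValueError("expected exactly two patient groups (mild, moderate)")
    g_mild = df[df["group"] == config.patient_groups[0]]
    g_mod = df[df["group"] == config.patient_groups[1]]

    contrasts = {
        "AD_vs_controls": (patients, controls),
        "mild_vs_moderate": (g_mild, g_mod),
    }

    report: dict = {
        "n_subjects": int(len(df)),
        "groups": {g: int((df["group"] == g).sum()) for g in df["group"].unique()},
        "comparisons": [],
        "roc": [],
        "correlations": [],
    }

    for contrast, (ga, gb) in contrasts.items():
        for roi in ROIS:
            for param in PARAMETERS:
                col = f"{param}_{roi}"
                res = two_sample_ttest(ga[col], gb[col], variant=config.ttest_variant)
                report["comparisons"].append(
                    {
                        "contrast": contrast,
                        "roi": roi,
                        "parameter": param,
                        "statistic": res.statistic,
                        "df": res.df,
                        "p": res.p,
                        "variant": res.variant,
                    }
                )

    if config.include_roc:
        for contrast, (ga, gb) in contrasts.items():
            labels = np.concatenate([np.ones(len(ga), dtype=int), np.zeros(len(gb), dtype=int)])
            both = pd.concat([ga, gb], ignore_index=True)
            for roi in ROIS:
                for marker, params in _MARKER_SETS.items():
                    cols = [f"{p}_{roi}" for p in params]
                    X = both[cols].to_numpy()
                    scores = X[:, 0] if len(cols) == 1 else combine_markers(X, labels)
                    roc = roc_analysis(scores, labels)
                    report["roc"].append(
                        {
                            "contrast": contrast,
                            "roi": roi,
                            "marker": marker,
                            "auc": roc.auc,
                            "threshold": roc.threshold,
                            "sensitivity": roc.sensitivity,
                            "specificity": roc.specificity,
                            "youden": roc.youden,
                            "higher_is_positive": bool(roc.higher_is_positive),
                        }
                    )

    if config.include_correlations:
        rows = []
        for roi in ROIS:
            for param in PARAMETERS:
                for scale in SCALES:
                    sub = patients[[f"{param}_{roi}", scale, *config.covariates]].dropna()
                    res = partial_correlation(
                        sub[f"{param}_{roi}"], sub[scale], sub[list(config.covariates)]
                    )
                    rows.append(
                        {
                            "roi": roi,
                            "parameter": param,
                            "scale": scale,
                            "r": res.r,
                            "p": res.p,
                            "n": res.n,
                        }
                    )
        q = bh_fdr([row["p"] for row in rows])
        for row, qi in zip(rows, q):
            row["q"] = float(qi)
        report["correlations"] = rows

    return report
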