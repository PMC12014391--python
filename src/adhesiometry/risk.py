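"""Metastatic-risk classification from adhesion biomarkers.

Each animal (or sample) contributes a biomarker pair — the cancer
component's median detachment shear tau50 and the cancer fraction Pc —
and an outcome, the number of GFP+ lung nodules.  Risk is dichotomized at
a nodule-count threshold (default 2, i.e. high risk means >= 2 nodules);
the threshold itself can be chosen by scanning candidates for the most
significant biomarker difference between groups (Wilcoxon rank-sum).

The classifier is the logistic model with interaction

    logit(p) = a + b * tau50 + c * Pc + d * tau50 * Pc

fit by maximum likelihood on the predictors' natural scales, compared to
an intercept-only model with a likelihood-ratio (deviance) test, and
scored by ROC/AUC with the fitted probabilities as classifier scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RiskModel",
    "RocResult",
    "classify_risk",
    "threshold_scan",
    "fit_logistic",
    "deviance_test",
    "roc_analysis",
]

#: Default nodule-count threshold: >= 2 GFP+ nodules is high risk.
DEFAULT_NODULE_THRESHOLD = 2


def classify_risk(nodules: int, threshold: int = DEFAULT_NODULE_THRESHOLD) -> str:
    """'high' if the nodule count reaches the threshold, else 'low'."""
    n = int(nodules)
    if n < 0:
        raise ValueError(f"nodule count must be non-negative, got {nodules}")
    return "high" if n >= threshold else "low"


def risk_labels(nodules, threshold: int = DEFAULT_NODULE_THRESHOLD) -> np.ndarray:
    """Boolean high-risk labels for an array of nodule counts."""
    n = np.asarray(nodules)
    if np.any(n < 0):
        raise ValueError("nodule counts must be non-negative")
    return np.asarray(n >= threshold)


#: Combined group size up to which the rank-sum test is computed exactly
#: (mouse-cohort scale); larger samples use the normal approximation with
#: continuity and tie correction.
EXACT_RANKSUM_LIMIT = 20


def threshold_scan(
    cohort: pd.DataFrame,
    thresholds=range(1, 11),
    metric: str = "tau50",
    min_group: int = 2,
) -> tuple[pd.DataFrame, int]:
    """Scan nodule-count thresholds for the strongest group separation.

    For each candidate threshold the cohort is split into high/low risk
    and the chosen biomarker compared between groups with a two-sided
    Wilcoxon rank-sum test (exact for combined n <= 20 without ties,
    normal approximation with tie correction otherwise).  Thresholds
    leaving fewer than ``min_group`` samples in either group are skipped.

    Returns the ``(threshold, p_value, n_high, n_low)`` table and the best
    threshold (minimal p; ties broken toward the smaller threshold).
    """
    if metric not in cohort.columns:
        raise ValueError(f"metric column {metric!r} not in cohort")
    values = cohort[metric].to_numpy(dtype=float)
    nodules = cohort["nodules"].to_numpy()
    rows = []
    for thr in thresholds:
        hi = values[nodules >= thr]
        lo = values[nodules < thr]
        if len(hi) < min_group or len(lo) < min_group:
            continue
        n_total = len(hi) + len(lo)
        has_ties = len(np.unique(np.concatenate([hi, lo]))) < n_total
        method = "exact" if (n_total <= EXACT_RANKSUM_LIMIT and not has_ties) else "asymptotic"
        p = stats.mannwhitneyu(hi, lo, alternative="two-sided", method=method).pvalue
        rows.append(
            {"threshold": int(thr), "p_value": float(p), "n_high": len(hi), "n_low": len(lo)}
        )
    if not rows:
        raise ValueError(
            "threshold scan failed: no candidate threshold leaves "
            f">= {min_group} samples in both groups"
        )
    table = pd.DataFrame(rows)
    best = int(table.loc[table["p_value"].idxmin(), "threshold"])
    return table, best


@dataclass(frozen=True)
class RocResult:
    """ROC curve, AUC and the Youden-optimal operating point."""

    table: pd.DataFrame  # columns: threshold, tpr, fpr, sensitivity, specificity
    auc: float
    operating_threshold: float
    sensitivity: float
    specificity: float


def roc_analysis(scores, labels) -> RocResult:
    """ROC curve by sweeping every distinct score threshold.

    A sample is called positive when its score >= threshold.  AUC is the
    trapezoidal area, which equals the concordance probability with tied
    scores counted one half.  The reported operating point maximizes
    Youden's J = sensitivity + specificity - 1; among J-ties the more
    specific point is chosen.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # cumulative counts at each threshold (distinct scores only)
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    distinct = np.append(np.diff(s_sorted) != 0, True)
    thr = s_sorted[distinct]
    tpr = tps[distinct] / n_pos
    fpr = fps[distinct] / n_neg
    # prepend the (0, 0) corner at a threshold above every score
    thr = np.concatenate([[np.inf], thr])
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    auc = float(np.trapezoid(tpr, fpr))

    sens = tpr
    spec = 1.0 - fpr
    j = sens + spec - 1.0
    best = int(np.lexsort((-spec, -j))[0])
    table = pd.DataFrame(
        {"threshold": thr, "tpr": tpr, "fpr": fpr, "sensitivity": sens, "specificity": spec}
    )
    return RocResult(
        table=table,
        auc=auc,
        operating_threshold=float(thr[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
    )


@dataclass(frozen=True)
class RiskModel:
    """Fitted logistic risk model with its diagnostics.

    ``coefficients`` maps term names to estimates; ``a`` is the intercept,
    ``b``/``c``/``d`` the tau50, Pc and interaction coefficients when the
    full model is fit.  ``deviance_p`` comes from the likelihood-ratio
    test against the intercept-only model.
    """

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    probabilities: np.ndarray
    labels: np.ndarray
    llf: float
    deviance: float
    null_deviance: float
    deviance_statistic: float
    deviance_df: int
    deviance_p: float
    roc: RocResult
    separation_warning: bool
    nodule_threshold: int
    predictors: tuple[str, ...]


_TERMS = {
    "tau50": lambda d: d["tau50"].to_numpy(dtype=float),
    "pc": lambda d: d["pc"].to_numpy(dtype=float),
    "interaction": lambda d: d["tau50"].to_numpy(dtype=float)
    * d["pc"].to_numpy(dtype=float),
}

_COEF_NAMES = {"const": "a", "tau50": "b", "pc": "c", "interaction": "d"}


def fit_logistic(
    cohort: pd.DataFrame,
    threshold: int = DEFAULT_NODULE_THRESHOLD,
    predictors: tuple[str, ...] = ("tau50", "pc", "interaction"),
    average_replicates: bool = True,
) -> RiskModel:
    """Maximum-likelihood logistic regression of high-risk status.

    The default design matrix carries tau50, Pc and their product on
    natural scales.  When a sample appears in several rows (technical
    replicates) the biomarkers are averaged per sample first (disable with
    ``average_replicates=False`` to keep rows as independent entries).

    Complete separation is flagged rather than fatal: coefficients are
    reported with ``separation_warning=True``.
    """
    df = cohort.copy()
    if average_replicates and df["sample_id"].duplicated().any():
        df = (
            df.groupby("sample_id", as_index=False)
            .agg({"tau50": "mean", "pc": "mean", "nodules": "first"})
        )
    y = risk_labels(df["nodules"], threshold).astype(float)
    if y.min() == y.max():
        raise ValueError("cohort contains a single risk class; cannot fit")
    cols = [np.ones(len(df))]
    names = ["const"]
    for term in predictors:
        if term not in _TERMS:
            raise ValueError(f"unknown predictor {term!r}")
        cols.append(_TERMS[term](df))
        names.append(term)
    X = np.column_stack(cols)

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100, tol=1e-10)
        for w in caught:
            if "separat" in str(w.message).lower() or "converge" in str(w.message).lower():
                separation = True
    p = np.asarray(res.fittedvalues, dtype=float)
    # numerically saturated probabilities at every sample indicate separation
    if np.all((p < 1e-8) | (p > 1 - 1e-8)):
        separation = True

    llf = float(res.llf)
    deviance = float(res.deviance)
    null_deviance = float(res.null_deviance)
    stat = max(null_deviance - deviance, 0.0)
    df_test = X.shape[1] - 1
    p_dev = float(stats.chi2.sf(stat, df_test)) if df_test > 0 else 1.0
    roc = roc_analysis(p, y.astype(bool))

    coef = {_COEF_NAMES[n]: float(v) for n, v in zip(names, res.params)}
    ses = {_COEF_NAMES[n]: float(v) for n, v in zip(names, res.bse)}
    return RiskModel(
        coefficients=coef,
        standard_errors=ses,
        probabilities=p,
        labels=y.astype(bool),
        llf=llf,
        deviance=deviance,
        null_deviance=null_deviance,
        deviance_statistic=stat,
        deviance_df=df_test,
        deviance_p=p_dev,
        roc=roc,
        separation_warning=separation,
        nodule_threshold=threshold,
        predictors=tuple(predictors),
    )


def deviance_test(model: RiskModel) -> float:
    """Likelihood-ratio p-value of the fitted model vs the constant model.

    The statistic deviance(constant) - deviance(full) is referred to a
    chi-square with as many degrees of freedom as non-intercept terms.
    """
    return model.deviance_p
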