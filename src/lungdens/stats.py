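"""Diagnostic evaluation of lung density indices.

Group comparisons (Mann-Whitney / chi-square), Spearman correlations,
age- and sex-adjusted linear and logistic regressions, and ROC analysis
with Youden-optimal cutoffs. The AUC rank estimator, DeLong confidence
interval and cutoff scan are implemented here because they are the
quantities under evaluation; model fitting is delegated to statsmodels.

Conventions:

* Complete-case analysis per variable; the number of subjects actually
  used (``n_used``) is always reported.
* Two-sided tests at alpha = 0.05 throughout; no multiplicity correction
  by default (an option exists).
* ROC orientation is auto-selected so AUC >= 0.5 and recorded; "predict
  BO when the oriented score passes the cutoff" is inclusive on the BO
  side. Youden ties are broken toward the cutoff with higher specificity,
  then toward the more extreme cutoff on the BO side.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "RocResult",
    "DiagnosticMetrics",
    "Orientation",
    "SeparationError",
    "RankDeficiencyError",
    "compare_groups",
    "spearman_rho",
    "adjusted_linear_fit",
    "adjusted_logistic_or",
    "roc_analysis",
    "auc_mann_whitney",
    "delong_auc_ci",
    "diagnostic_metrics",
]

POSITIVE_GROUP = "BO"
NEGATIVE_GROUP = "control"


class SeparationError(RuntimeError):
    """Raised when a logistic fit is (quasi-)perfectly separated."""


class RankDeficiencyError(ValueError):
    """Raised when a regression design matrix is rank deficient."""


class Orientation(str, enum.Enum):
    HIGHER_INDICATES_BO = "higher_indicates_BO"
    LOWER_INDICATES_BO = "lower_indicates_BO"


# ---------------------------------------------------------------------------
# group comparison and correlation


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test: str  # "mann-whitney" | "chi-square"
    statistic: float
    p_value: float
    group_summaries: Dict[str, Dict[str, float]]


def _group_values(table: pd.DataFrame, variable: str, group: str) -> pd.Series:
    return table.loc[table["group"] == group, variable].dropna()


def compare_groups(table: pd.DataFrame, variable: str) -> GroupComparison:
    """Two-sided BO-vs-control comparison of one variable.

    Continuous variables use the Mann-Whitney U test (exact for small
    tie-free samples, normal approximation otherwise); categorical ones a
    chi-square test of the contingency table with Yates continuity
    correction for 2x2 tables. Per-group mean/SD and median/IQR are both
    reported.
    """
    col = table[variable]
    if pd.api.types.is_numeric_dtype(col):
        a = _group_values(table, variable, NEGATIVE_GROUP)
        b = _group_values(table, variable, POSITIVE_GROUP)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"variable {variable!r} needs >= 2 values per group")
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        summaries = {
            g: {
                "n": float(len(v)),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)),
                "median": float(v.median()),
                "iqr_low": float(v.quantile(0.25)),
                "iqr_high": float(v.quantile(0.75)),
            }
            for g, v in ((NEGATIVE_GROUP, a), (POSITIVE_GROUP, b))
        }
        return GroupComparison(variable, "mann-whitney", float(stat), float(p), summaries)
    sub = table[["group", variable]].dropna()
    if sub.empty:
        raise ValueError(f"variable {variable!r} is all-missing")
    contingency = pd.crosstab(sub["group"], sub[variable])
    if contingency.shape[0] < 2 or contingency.shape[1] < 2:
        raise ValueError(f"variable {variable!r} has no contrast across groups")
    stat, p, _, _ = sps.chi2_contingency(contingency.to_numpy(), correction=True)
    summaries = {
        g: {str(k): float(v) for k, v in row.items()}
        for g, row in contingency.iterrows()
    }
    return GroupComparison(variable, "chi-square", float(stat), float(p), summaries)


def spearman_rho(table: pd.DataFrame, var_x: str, var_y: str) -> Tuple[float, float, int]:
    """Spearman rank correlation (mid-rank ties, complete cases).

    Returns ``(rho, p_value, n_pairs)``.
    """
    sub = table[[var_x, var_y]].dropna()
    if len(sub) < 3:
        raise ValueError(f"need >= 3 complete pairs for ({var_x}, {var_y}), got {len(sub)}")
    rho, p = sps.spearmanr(sub[var_x], sub[var_y])
    return float(rho), float(p), len(sub)


# ---------------------------------------------------------------------------
# adjusted regressions


@dataclass(frozen=True)
class RegressionResult:
    """One estimated coefficient with its 95% CI on the reported scale."""

    outcome: str
    predictor: str
    scale: str  # "beta" | "odds_ratio"
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    covariates: Tuple[str, ...]
    n_used: int
    model_predictors: Tuple[str, ...] = ()


def _design(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Complete-case design frame with sex coded as a male indicator."""
    cols = list(dict.fromkeys(columns))
    sub = table[cols].dropna().copy()
    if "sex" in sub.columns:
        sub["sex"] = (sub["sex"] == "male").astype(float)
    return sub


def _check_rank(x: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(x)), x.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name the columns involved in an exact linear dependency
        offenders = []
        for j, name in enumerate(x.columns):
            others = np.delete(arr, j + 1, axis=1)
            resid = arr[:, j + 1] - others @ np.linalg.lstsq(others, arr[:, j + 1], rcond=None)[0]
            if np.allclose(resid, 0, atol=1e-8 * max(1.0, np.abs(arr[:, j + 1]).max())):
                offenders.append(name)
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear columns: {offenders or list(x.columns)}"
        )


def _ols_results(
    outcome: str,
    x: pd.DataFrame,
    y: pd.Series,
    report: Sequence[str],
    covariates: Tuple[str, ...],
) -> list[RegressionResult]:
    model = sm.OLS(y.to_numpy(dtype=float), sm.add_constant(x.to_numpy(dtype=float)))
    fit = model.fit()
    names = ["const"] + list(x.columns)
    out = []
    for name in report:
        j = names.index(name)
        est, se, p = fit.params[j], fit.bse[j], fit.pvalues[j]
        if se < 1e-12 or not np.isfinite(se):
            lo = hi = est  # exact fit: the CI collapses onto the estimate
            p = 0.0 if abs(est) > 1e-12 else 1.0
        else:
            ci = fit.conf_int(alpha=0.05)
            lo, hi = ci[j]
        out.append(
            RegressionResult(
                outcome=outcome,
                predictor=name,
                scale="beta",
                estimate=float(est),
                ci_low=float(lo),
                ci_high=float(hi),
                p_value=float(p),
                covariates=covariates,
                n_used=len(x),
                model_predictors=tuple(n for n in x.columns if n not in covariates),
            )
        )
    return out


def adjusted_linear_fit(
    table: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    selection: str = "univariate",
    stay_threshold: float = 0.05,
    covariates: Tuple[str, ...] = ("age_years", "sex"),
) -> list[RegressionResult]:
    """Age- and sex-adjusted OLS of one LDI outcome on PFT predictors.

    ``selection='univariate'`` fits one predictor at a time (always with
    the covariates); ``'backward'`` starts from all predictors and drops
    the largest-p one until every retained predictor has p below
    ``stay_threshold`` (covariates are never dropped); ``'all_subset'``
    fits every predictor subset and keeps the one with minimal AIC.
    Coefficients are unstandardized, per unit of the predictor.
    """
    predictors = list(predictors)
    if selection == "univariate":
        results = []
        for pred in predictors:
            sub = _design(table, [outcome, pred, *covariates])
            if len(sub) < 2 + len(covariates) + 2:
                raise ValueError(f"too few complete cases for predictor {pred!r}")
            x = sub[[pred, *covariates]]
            _check_rank(x)
            results.extend(_ols_results(outcome, x, sub[outcome], [pred], covariates))
        return results

    sub = _design(table, [outcome, *predictors, *covariates])
    if len(sub) < len(predictors) + len(covariates) + 3:
        raise ValueError("too few complete cases for multivariable selection")
    y = sub[outcome]

    if selection == "backward":
        current = list(predictors)
        while current:
            x = sub[[*current, *covariates]]
            _check_rank(x)
            fits = _ols_results(outcome, x, y, current, covariates)
            worst = max(fits, key=lambda r: r.p_value)
            if worst.p_value < stay_threshold:
                return fits
            current.remove(worst.predictor)
        return []
    if selection == "all_subset":
        if len(predictors) > 16:
            raise ValueError("all-subset selection limited to 16 predictors")
        best: Optional[Tuple[float, Tuple[str, ...]]] = None
        for mask in range(1 << len(predictors)):
            chosen = tuple(p for i, p in enumerate(predictors) if mask >> i & 1)
            x = sub[[*chosen, *covariates]]
            fit = sm.OLS(
                y.to_numpy(dtype=float), sm.add_constant(x.to_numpy(dtype=float))
            ).fit()
            if best is None or fit.aic < best[0]:
                best = (fit.aic, chosen)
        assert best is not None
        chosen = best[1]
        if not chosen:
            return []
        x = sub[[*chosen, *covariates]]
        _check_rank(x)
        return _ols_results(outcome, x, y, list(chosen), covariates)
    raise ValueError(f"unknown selection mode {selection!r}")


def adjusted_logistic_or(
    table: pd.DataFrame,
    predictor: str,
    covariates: Tuple[str, ...] = ("age_years", "sex"),
) -> RegressionResult:
    """Odds ratio of BO per unit of one predictor, adjusted for age and sex.

    Maximum-likelihood logistic fit with Wald 95% CI on the OR scale.
    Non-convergence and (quasi-)separation raise :class:`SeparationError`
    rather than returning divergent estimates.
    """
    sub = _design(table, ["group", predictor, *covariates])
    y = (sub["group"] == POSITIVE_GROUP).astype(float)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    if len(sub) < 10:
        raise ValueError(f"too few complete cases ({len(sub)}) for a logistic fit")
    x = sub[[predictor, *covariates]]
    _check_rank(x)
    # scale-aware divergence guard: |beta| * SD(predictor) bounds the
    # log-odds swing across the sample
    scales = x.to_numpy(dtype=float).std(axis=0, ddof=1)
    model = sm.Logit(y.to_numpy(), sm.add_constant(x.to_numpy(dtype=float)))
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = model.fit(disp=0, maxiter=200, method="newton")
    except (np.linalg.LinAlgError, PerfectSeparationError, PerfectSeparationWarning) as err:
        raise SeparationError(f"logistic fit for {predictor!r} failed: {err}") from err
    swings = np.abs(fit.params[1:]) * np.where(scales > 0, scales, 1.0)
    if not fit.mle_retvals.get("converged", False) or swings.max() > 30:
        raise SeparationError(
            f"logistic fit for {predictor!r} did not converge to finite odds "
            "(perfect or quasi-perfect separation)"
        )
    est = float(fit.params[1])
    se = float(fit.bse[1])
    z = sps.norm.ppf(0.975)
    return RegressionResult(
        outcome="group",
        predictor=predictor,
        scale="odds_ratio",
        estimate=float(np.exp(est)),
        ci_low=float(np.exp(est - z * se)),
        ci_high=float(np.exp(est + z * se)),
        p_value=float(fit.pvalues[1]),
        covariates=covariates,
        n_used=len(sub),
    )


# ---------------------------------------------------------------------------
# ROC analysis


def auc_mann_whitney(positive_scores: np.ndarray, negative_scores: np.ndarray) -> float:
    """Rank (pair-counting) AUC estimator; ties count one half.

    Equals P(score_BO > score_control) + 0.5 P(equal), and also the
    trapezoidal area under the empirical ROC curve.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x)


def delong_auc_ci(
    positive_scores: np.ndarray,
    negative_scores: np.ndarray,
    alpha: float = 0.05,
) -> Tuple[float, float, float]:
    """DeLong AUC variance and Wald CI, clipped to [0, 1].

    Returns ``(auc, ci_low, ci_high)``. Uses the structural-component
    formulation: V10 for positives, V01 for negatives.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    m, n = pos.size, neg.size
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # per-positive placement values
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per-negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Confusion-matrix metrics in percent; undefined ones flagged as None."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    undefined: Tuple[str, ...] = ()


def diagnostic_metrics(tp: int, fp: int, fn: int, tn: int) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV (in %) from confusion counts.

    A metric whose denominator margin is zero is flagged undefined and
    returned as None rather than as a number.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0 or v != int(v):
            raise ValueError(f"count {name} must be a non-negative integer, got {v}")
    metrics: Dict[str, Optional[float]] = {}
    undefined = []
    for name, num, den in (
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ):
        if den == 0:
            metrics[name] = None
            undefined.append(name)
        else:
            metrics[name] = 100.0 * num / den
    return DiagnosticMetrics(undefined=tuple(undefined), **metrics)  # type: ignore[arg-type]


@dataclass(frozen=True)
class RocResult:
    variable: str
    orientation: Orientation
    auc: float
    auc_ci: Tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    tp: int
    fp: int
    fn: int
    tn: int
    n_used: int

    @property
    def counts(self) -> Tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


def _youden_scan(
    pos: np.ndarray, neg: np.ndarray, orientation: Orientation
) -> Tuple[float, Tuple[int, int, int, int]]:
    """Exhaustive Youden scan over all observed values as candidate cutoffs.

    Prediction rule is inclusive on the BO side: BO iff score >= cutoff
    (higher orientation) or score <= cutoff (lower orientation). Ties on
    sensitivity+specificity prefer higher specificity, then the more
    extreme cutoff on the BO side.
    """
    sign = 1.0 if orientation is Orientation.HIGHER_INDICATES_BO else -1.0
    op, on = sign * pos, sign * neg
    best = None
    for c in np.unique(np.concatenate([op, on])):
        tp = int((op >= c).sum())
        fn = op.size - tp
        fp = int((on >= c).sum())
        tn = on.size - fp
        sens = tp / op.size
        spec = tn / on.size
        key = (sens + spec, spec, c)
        if best is None or key > best[0]:
            best = (key, float(sign * c), (tp, fp, fn, tn))
    assert best is not None
    return best[1], best[2]


def roc_analysis(
    table: pd.DataFrame,
    variable: str,
    ci_method: str = "delong",
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC evaluation of one variable for discriminating BO from control.

    Orientation is chosen so the oriented AUC is >= 0.5 and is recorded in
    the result; the optimal cutoff maximizes sensitivity + specificity
    over all observed values and is reported in the variable's original
    units.
    """
    sub = table[["group", variable]].dropna()
    pos = sub.loc[sub["group"] == POSITIVE_GROUP, variable].to_numpy(dtype=float)
    neg = sub.loc[sub["group"] == NEGATIVE_GROUP, variable].to_numpy(dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError(f"variable {variable!r} must be observed in both groups")
    if np.unique(np.concatenate([pos, neg])).size < 2:
        raise ValueError(f"variable {variable!r} has fewer than 2 distinct values")
    auc_raw = auc_mann_whitney(pos, neg)
    orientation = (
        Orientation.HIGHER_INDICATES_BO
        if auc_raw >= 0.5
        else Orientation.LOWER_INDICATES_BO
    )
    opos, oneg = (pos, neg) if auc_raw >= 0.5 else (-pos, -neg)
    if ci_method == "delong":
        auc, lo, hi = delong_auc_ci(opos, oneg)
    elif ci_method == "bootstrap":
        from .phantom import _substream

        rng = _substream(seed, f"roc-bootstrap:{variable}")
        auc = auc_mann_whitney(opos, oneg)
        draws = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            draws[b] = auc_mann_whitney(
                rng.choice(opos, opos.size, replace=True),
                rng.choice(oneg, oneg.size, replace=True),
            )
        lo, hi = (float(q) for q in np.quantile(draws, [0.025, 0.975]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    cutoff, (tp, fp, fn, tn) = _youden_scan(pos, neg, orientation)
    m = diagnostic_metrics(tp, fp, fn, tn)
    return RocResult(
        variable=variable,
        orientation=orientation,
        auc=auc,
        auc_ci=(lo, hi),
        cutoff=cutoff,
        sensitivity=m.sensitivity if m.sensitivity is not None else float("nan"),
        specificity=m.specificity if m.specificity is not None else float("nan"),
        ppv=m.ppv,
        npv=m.npv,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        n_used=int(pos.size + neg.size),
    )
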