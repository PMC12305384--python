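"""Propensity scores, inverse-probability-of-treatment weights, covariate
balance diagnostics, and weighted odds ratios.

The propensity score p(x) = P(exposed | x) is fit by maximum-likelihood
logistic regression (IRLS); weights are 1/p for the exposed and 1/(1-p) for
the comparison group, targeting the average treatment effect in the whole
population.  Balance is assessed by the standardized mean difference
(< 0.1 conventionally balanced).  The exposure-outcome association is
reported as an unweighted OR and an IP-weighted OR whose 95% CI uses a
heteroskedasticity-robust (sandwich) variance, the standard choice when the
outcome model is fit on a weighted pseudo-population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import config

__all__ = [
    "LogisticFit",
    "WeightedAnalysisResult",
    "AnalysisReport",
    "fit_logistic",
    "iptw_weights",
    "smd",
    "balance_table",
    "weighted_or",
    "build_design",
    "run_analysis",
]

_MAX_ABS_COEF = 30.0  # |logit| beyond this flags (quasi-)separation


class SeparationWarning(UserWarning):
    """Emitted when logistic coefficients diverge (perfect separation)."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression result."""

    params: pd.Series            # coefficients on the logit scale
    fitted: np.ndarray           # fitted probabilities, strictly in (0, 1)
    converged: bool
    iterations: int
    separation: bool
    cov_robust: np.ndarray       # sandwich covariance of the coefficients

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = np.asarray(X, float) @ self.params.to_numpy()
        return _sigmoid(eta)


@dataclass
class WeightedAnalysisResult:
    """Unweighted and IP-weighted odds ratios for one exposure contrast."""

    unweighted_or: float
    weighted_or: float
    ci_low: float
    ci_high: float
    se_log_or: float
    n_exposed: int
    n_comparison: int
    events_exposed: int
    events_comparison: int

    @property
    def rate_exposed(self) -> float:
        return self.events_exposed / self.n_exposed

    @property
    def rate_comparison(self) -> float:
        return self.events_comparison / self.n_comparison


@dataclass
class AnalysisReport:
    """Full output of one IPTW analysis: model, weights, balance, effect."""

    analysis: str
    subgroup: str
    propensity: LogisticFit
    weights: np.ndarray
    balance: pd.DataFrame
    result: WeightedAnalysisResult
    covariates: list[str] = field(default_factory=list)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-eta))
    return np.clip(p, 1e-12, 1 - 1e-12)


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of offending columns by greedy rank growth
        bad: list[str] = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            cand = X[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise np.linalg.LinAlgError(
            f"design matrix is singular; collinear columns: {bad}"
        )


def fit_logistic(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """(Weighted) maximum-likelihood logistic regression via IRLS.

    Convergence is declared when the largest absolute coefficient change
    falls below ``tol`` (default 1e-8) or after ``max_iter`` iterations.
    Diverging coefficients (|beta| > 30 without convergence) flag separation
    with a warning rather than an error.  A rank-deficient design raises,
    naming the collinear columns.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(float)
    else:
        Xm = np.asarray(X, float)
        names = [f"x{j}" for j in range(Xm.shape[1])]
    y = np.asarray(y, float)
    n, k = Xm.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    if (w <= 0).any():
        raise ValueError("sample weights must be positive")
    zero_cols = ~Xm.any(axis=0)
    if zero_cols.any():
        raise ValueError(f"constant-zero columns: {[names[j] for j in np.flatnonzero(zero_cols)]}")
    _check_design(Xm, names)

    beta = np.zeros(k)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        p = _sigmoid(Xm @ beta)
        r = p * (1 - p)
        W = w * r
        XtW = Xm.T * W
        H = XtW @ Xm
        grad = Xm.T @ (w * (y - p))
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > _MAX_ABS_COEF:
            separation = True
            warnings.warn(
                "logistic coefficients diverging; data may be separated",
                SeparationWarning,
                stacklevel=2,
            )
            break

    p = _sigmoid(Xm @ beta)
    # sandwich covariance A^-1 B A^-1 with weights treated as fixed
    r = p * (1 - p)
    A = (Xm.T * (w * r)) @ Xm
    score = Xm * (w * (y - p))[:, None]
    B = score.T @ score
    Ainv = np.linalg.pinv(A)
    cov = Ainv @ B @ Ainv
    return LogisticFit(
        params=pd.Series(beta, index=names),
        fitted=p,
        converged=converged,
        iterations=it,
        separation=separation,
        cov_robust=cov,
    )


def iptw_weights(
    propensity: np.ndarray,
    exposed: np.ndarray,
    truncate_percentiles: tuple[float, float] | None = None,
) -> np.ndarray:
    """ATE weights: 1/p for the exposed, 1/(1-p) for the comparison group.

    No stabilization or truncation by default; optional symmetric percentile
    truncation is available for sensitivity analyses.
    """
    p = np.asarray(propensity, float)
    e = np.asarray(exposed, bool)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("propensity scores must be strictly inside (0, 1)")
    w = np.where(e, 1.0 / p, 1.0 / (1.0 - p))
    if truncate_percentiles is not None:
        lo, hi = np.percentile(w, truncate_percentiles)
        w = np.clip(w, lo, hi)
    return w


def _wmean_var(x: np.ndarray, w: np.ndarray, binary: bool) -> tuple[float, float]:
    m = np.average(x, weights=w)
    if binary:
        v = m * (1 - m)
    else:
        v = np.average((x - m) ** 2, weights=w)
    return float(m), float(v)


def smd(
    values: np.ndarray,
    exposed: np.ndarray,
    weights: np.ndarray | None = None,
    binary: bool | None = None,
) -> float:
    """Standardized mean difference between exposure arms.

    |mean_e - mean_c| / sqrt((var_e + var_c) / 2), with weighted moments
    when weights are given.  Binary covariates (auto-detected unless stated)
    use the p(1-p) variance.  Zero pooled variance with unequal means
    returns +inf.
    """
    x = np.asarray(values, float)
    e = np.asarray(exposed, bool)
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    if binary is None:
        binary = bool(np.isin(np.unique(x), [0.0, 1.0]).all())
    m1, v1 = _wmean_var(x[e], w[e], binary)
    m0, v0 = _wmean_var(x[~e], w[~e], binary)
    pooled = (v1 + v0) / 2.0
    diff = abs(m1 - m0)
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return diff / np.sqrt(pooled)


def balance_table(
    data: pd.DataFrame,
    covariates: list[str],
    exposed: np.ndarray,
    weights: np.ndarray,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-covariate SMD before and after weighting, with balanced flags."""
    rows = []
    for c in covariates:
        x = data[c].to_numpy(float)
        before = smd(x, exposed)
        after = smd(x, exposed, weights)
        rows.append(
            {
                "covariate": c,
                "smd_unweighted": before,
                "smd_weighted": after,
                "balanced": after < threshold,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def weighted_or(
    outcome: np.ndarray,
    exposed: np.ndarray,
    weights: np.ndarray | None = None,
    alpha: float = 0.05,
) -> WeightedAnalysisResult:
    """Exposure-outcome odds ratio, unweighted and IP-weighted.

    The weighted OR is exp(slope) from a weighted logistic regression of the
    outcome on exposure; its CI uses the robust sandwich variance.  Requires
    events and non-events in both arms.
    """
    y = np.asarray(outcome, float)
    e = np.asarray(exposed, float)
    if weights is None:
        weights = np.ones_like(y)
    for arm in (0, 1):
        ys = y[e == arm]
        if len(ys) == 0 or ys.min() == ys.max():
            raise ValueError(
                f"arm {arm} lacks both events and non-events; "
                "continuity handling is out of scope"
            )
    X = np.column_stack([np.ones_like(e), e])
    fit_w = fit_logistic(X, y, sample_weight=weights)
    fit_u = fit_logistic(X, y)
    log_or = float(fit_w.params.iloc[1])
    se = float(np.sqrt(fit_w.cov_robust[1, 1]))
    z = stats.norm.ppf(1 - alpha / 2)
    return WeightedAnalysisResult(
        unweighted_or=float(np.exp(fit_u.params.iloc[1])),
        weighted_or=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        se_log_or=se,
        n_exposed=int((e == 1).sum()),
        n_comparison=int((e == 0).sum()),
        events_exposed=int(y[e == 1].sum()),
        events_comparison=int(y[e == 0].sum()),
    )


def build_design(
    cohort: pd.DataFrame, covariates: list[str] | None = None
) -> pd.DataFrame:
    """Propensity design matrix: intercept + the 24 baseline characteristics,
    with race expanded to Black/Other indicators (White reference)."""
    if covariates is None:
        covariates = config.COVARIATE_COLUMNS
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cohort))}
    for c in covariates:
        if c == "race":
            race = cohort["race"].astype(str)
            cols["race_black"] = (race == "Black").to_numpy(float)
            cols["race_other"] = (race == "Other").to_numpy(float)
        else:
            cols[c] = cohort[c].to_numpy(float)
    return pd.DataFrame(cols, index=cohort.index)


_ANALYSES = {
    "A": (None, "exposed_A"),
    "B": ("in_B", "exposed_B"),
    "C": ("in_C", "exposed_C"),
}


def run_analysis(
    cohort: pd.DataFrame,
    analysis: str = "A",
    subgroup: str = "all",
    covariates: list[str] | None = None,
    truncate_percentiles: tuple[float, float] | None = None,
) -> AnalysisReport:
    """Propensity model, IPTW, balance check, and ORs for one contrast.

    ``analysis`` is "A" (phenoconverted IM/PM vs NM/UM, everyone), "B"
    (inhibitor exposure among genotypic NMs) or "C" (genotype contrast among
    the inhibitor-free).  ``subgroup`` is "all", "HTC" (hydrocodone,
    tramadol, codeine) or "oxycodone".
    """
    if analysis not in _ANALYSES:
        raise ValueError(f"analysis must be one of {sorted(_ANALYSES)}")
    restrict, exposure_col = _ANALYSES[analysis]
    rows = cohort
    if restrict is not None:
        rows = rows.loc[rows[restrict] == 1]
    if subgroup != "all":
        rows = rows.loc[rows["drug_subgroup"] == subgroup]
    rows = rows.reset_index(drop=True)

    exposed = rows[exposure_col].to_numpy(int)
    X = build_design(rows, covariates)
    ps_fit = fit_logistic(X, exposed)
    w = iptw_weights(ps_fit.fitted, exposed, truncate_percentiles)
    design_covs = [c for c in X.columns if c != "intercept"]
    bal = balance_table(X, design_covs, exposed.astype(bool), w)
    res = weighted_or(rows["outcome"].to_numpy(int), exposed, w)
    return AnalysisReport(
        analysis=analysis,
        subgroup=subgroup,
        propensity=ps_fit,
        weights=w,
        balance=bal,
        result=res,
        covariates=design_covs,
    )
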