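"""Historical catch-trend reconstruction from recall surveys.

Catch per typical trip is modeled on the log scale with a random intercept
per fisher:

    log(catch_ij) = x_ij' beta + u_i + eps_ij,
    u_i ~ N(0, sigma_f^2),  eps_ij ~ N(0, sigma_e^2)

with candidate fixed effects year, gillnet length and fishing time (all
standardized).  Every subset of the candidate terms is fitted, models within
``delta_threshold`` AIC of the best are averaged with Akaike weights, and the
averaged year effect is back-transformed into a predicted catch trajectory.

AIC comparison across fixed-effect structures uses maximum-likelihood
refits by default (REML likelihoods are not comparable across different
fixed effects); reported coefficients come from REML.  A ``strict_reml_aic``
flag compares REML AICs literally instead.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "Standardizer", "ModelSpec", "FitResult", "AveragedModel",
    "TrendPrediction", "DiagnosticsReport", "CatchTrendRegressor",
    "standardize", "fit_lmm", "enumerate_models", "average_models",
    "predict_trend", "percent_decline", "diagnostics",
]

#: candidate fixed-effect terms and the survey columns they standardize
TERM_COLUMNS = {
    "year": "year_assigned",
    "gillnet_length": "gillnet_length_m",
    "fishing_time": "fishing_time_hr",
}

Z_CRIT = 1.959963984540054  # two-sided 95% normal quantile


class Standardizer:
    """Center/scale transform (sample SD, ddof=1) remembered for reuse."""

    def __init__(self) -> None:
        self.mean_: Optional[float] = None
        self.sd_: Optional[float] = None

    def fit(self, values: Sequence[float]) -> "Standardizer":
        v = np.asarray(values, dtype=float)
        if v.size < 2 or np.unique(v).size < 2:
            raise ValueError("standardize requires >= 2 distinct values")
        self.mean_ = float(v.mean())
        self.sd_ = float(v.std(ddof=1))
        return self

    def transform(self, values: Sequence[float]) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("Standardizer not fitted")
        return (np.asarray(values, dtype=float) - self.mean_) / self.sd_

    def fit_transform(self, values: Sequence[float]) -> np.ndarray:
        return self.fit(values).transform(values)


def standardize(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (R ``scale()`` convention)."""
    return Standardizer().fit_transform(values)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed-effect structure (random intercept implied)."""

    fixed_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.fixed_terms)) != len(self.fixed_terms):
            raise ValueError("duplicate fixed terms")
        for t in self.fixed_terms:
            parts = t.split(":")
            for p in parts:
                if p not in TERM_COLUMNS:
                    raise ValueError(f"unknown term {t!r}")

    @property
    def label(self) -> str:
        return " + ".join(self.fixed_terms) if self.fixed_terms else "1"


@dataclass
class FitResult:
    """A fitted random-intercept model for one candidate structure."""

    spec: ModelSpec
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    cov_fe: np.ndarray            # covariance of fixed effects (REML scale)
    var_fisher: float
    var_resid: float
    loglik: float                 # likelihood entering the AIC
    aic: float
    n_obs: int
    n_groups: int
    singular: bool = False
    fitted: Optional[np.ndarray] = None   # conditional fitted values
    resid: Optional[np.ndarray] = None

    @property
    def terms(self) -> tuple[str, ...]:
        return ("intercept",) + self.spec.fixed_terms


@dataclass
class AveragedModel:
    """Multimodel-averaged coefficients over the small-ΔAIC set."""

    member_fits: list[FitResult]
    akaike_weights: np.ndarray
    averaged_coefficients: dict[str, float]
    unconditional_se: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    term_importance: dict[str, float]
    delta_threshold: float


@dataclass
class TrendPrediction:
    """Back-transformed catch trajectory with a 95% band."""

    years: np.ndarray
    predicted_catch_kg: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


@dataclass
class DiagnosticsReport:
    """The four standard LMM residual checks.

    Linearity is summarized by the t statistic of a quadratic term in a
    residual-on-fitted regression; normality by the Shapiro-Wilk statistic;
    independence by the lag-1 autocorrelation of within-fisher residuals
    ordered by year; collinearity by per-term variance inflation factors.
    """

    curvature_t: float
    curvature_p: float
    shapiro_stat: float
    shapiro_p: float
    lag1_autocorrelation: float
    vif: dict[str, float]
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# design construction

def _design(data: pd.DataFrame, terms: tuple[str, ...],
            transforms: dict[str, Standardizer]) -> np.ndarray:
    cols = [np.ones(len(data))]
    for t in terms:
        parts = t.split(":")
        z = np.ones(len(data))
        for p in parts:
            z = z * transforms[p].transform(data[TERM_COLUMNS[p]].to_numpy())
        cols.append(z)
    return np.column_stack(cols)


def fit_transforms(data: pd.DataFrame,
                   candidates: Sequence[str]) -> dict[str, Standardizer]:
    return {t: Standardizer().fit(data[TERM_COLUMNS[t]].to_numpy())
            for t in candidates}


# ---------------------------------------------------------------------------
# fitting

def fit_lmm(spec: ModelSpec, data: pd.DataFrame, *,
            transforms: Optional[dict[str, Standardizer]] = None,
            reml: bool = True, strict_reml_aic: bool = False,
            precomputed_ml_llf: Optional[float] = None) -> FitResult:
    """Fit one random-intercept model of log catch.

    ``data`` needs columns ``catch_kg``, ``fisher_id`` and the covariates in
    :data:`TERM_COLUMNS`.  Coefficients are REML by default; the AIC comes
    from an ML refit unless ``strict_reml_aic``.  A boundary fit
    (``var_fisher`` ~ 0) is reported with ``singular=True``, not an error.
    """
    catch = data["catch_kg"].to_numpy(dtype=float)
    if np.any(catch <= 0):
        raise ValueError("catch_kg must be strictly positive before log transform")
    y = np.log(catch)
    groups = data["fisher_id"].to_numpy()
    if len(np.unique(groups)) < 2 or len(y) < 2:
        raise ValueError("need >= 2 fishers and >= 2 observations")
    base_terms = sorted({p for t in spec.fixed_terms for p in t.split(":")})
    if transforms is None:
        transforms = fit_transforms(data, base_terms)
    X = _design(data, spec.fixed_terms, transforms)
    names = ("intercept",) + spec.fixed_terms

    def _fit(use_reml: bool):
        last_err: Exception | None = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                return MixedLM(y, X, groups=groups).fit(reml=use_reml, method=method)
            except np.linalg.LinAlgError as e:  # optimizer walked into a singular region
                last_err = e
        raise last_err

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _fit(reml)
        if strict_reml_aic or not reml:
            llf = float(res.llf)
        elif precomputed_ml_llf is not None:
            llf = float(precomputed_ml_llf)
        else:
            llf = float(_fit(False).llf)

    k_params = X.shape[1] + 2  # fixed effects + fisher variance + residual variance
    fe = np.asarray(res.fe_params, dtype=float)
    se = np.sqrt(np.diag(np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]]))
    var_f = float(np.asarray(res.cov_re)[0, 0])
    try:
        fitted = np.asarray(res.fittedvalues, dtype=float)
    except (ValueError, np.linalg.LinAlgError):
        fitted = X @ fe  # singular RE covariance: marginal fit only
    return FitResult(
        spec=spec,
        coefficients=dict(zip(names, fe)),
        std_errors=dict(zip(names, se)),
        cov_fe=np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]],
        var_fisher=var_f,
        var_resid=float(res.scale),
        loglik=llf,
        aic=-2.0 * llf + 2.0 * k_params,
        n_obs=len(y),
        n_groups=len(np.unique(groups)),
        singular=var_f < 1e-8,
        fitted=fitted,
        resid=y - fitted,
    )


def enumerate_models(candidates: Sequence[str] = ("year", "gillnet_length", "fishing_time"),
                     interactions: str = "none") -> list[ModelSpec]:
    """All-subsets candidate structures, in deterministic order.

    ``interactions='with_year'`` additionally allows two-way interactions
    containing year, subject to marginality (both parents present).
    """
    if not candidates:
        raise ValueError("empty candidate set")
    if interactions not in ("none", "with_year"):
        raise ValueError(f"unknown interaction policy {interactions!r}")
    cands = list(candidates)
    specs: list[ModelSpec] = []
    for r in range(len(cands) + 1):
        for mains in itertools.combinations(cands, r):
            allowed = []
            if interactions == "with_year" and "year" in mains:
                allowed = [f"year:{m}" for m in mains if m != "year"]
            for q in range(len(allowed) + 1):
                for inters in itertools.combinations(allowed, q):
                    specs.append(ModelSpec(tuple(mains) + tuple(inters)))
    return specs


def average_models(fits: Sequence[FitResult], delta_threshold: float = 4.0) -> AveragedModel:
    """Full (zero-substituted) multimodel averaging over the ΔAIC set.

    Members are fits with AIC within ``delta_threshold`` of the minimum;
    weights are exp(-Δ/2), normalized.  A term absent from a member
    contributes estimate 0 with SE 0; the unconditional SE is
    sqrt(Σ w_i (se_i² + (b_i − b̄)²)).
    """
    if not fits:
        raise ValueError("no fits to average")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    members = [f for f, d in zip(fits, delta) if d < delta_threshold]
    d_m = np.array([f.aic for f in members]) - aics.min()
    w = np.exp(-d_m / 2.0)
    w = w / w.sum()

    terms: list[str] = []
    for f in members:
        for t in f.terms:
            if t not in terms:
                terms.append(t)
    avg: dict[str, float] = {}
    use: dict[str, float] = {}
    importance: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    for t in terms:
        est = np.array([f.coefficients.get(t, 0.0) for f in members])
        se = np.array([f.std_errors.get(t, 0.0) for f in members])
        b = float(np.sum(w * est))
        u = float(np.sqrt(np.sum(w * (se ** 2 + (est - b) ** 2))))
        avg[t] = b
        use[t] = u
        ci[t] = (b - Z_CRIT * u, b + Z_CRIT * u)
        importance[t] = float(np.sum(w[[t in f.terms for f in members]]))
    return AveragedModel(list(members), w, avg, use, ci, importance, delta_threshold)


def predict_trend(avg: AveragedModel, years: Sequence[float],
                  transforms: dict[str, Standardizer]) -> TrendPrediction:
    """Back-transformed predicted catch over a year grid.

    Covariates other than year are held at their standardized mean (0), so
    only the intercept and year columns of each member contribute.  The band
    propagates each member's fixed-effect covariance and the between-model
    spread, then exponentiates.
    """
    if "year" not in transforms:
        raise ValueError("missing 'year' transform")
    years = np.asarray(years, dtype=float)
    zy = transforms["year"].transform(years)

    means = np.zeros((len(avg.member_fits), len(years)))
    variances = np.zeros_like(means)
    for i, f in enumerate(avg.member_fits):
        names = f.terms
        x = np.zeros((len(years), len(names)))
        for j, t in enumerate(names):
            if t == "intercept":
                x[:, j] = 1.0
            elif t == "year":
                x[:, j] = zy
            # other mains and interactions involving them are 0 at the mean
        beta = np.array([f.coefficients[t] for t in names])
        means[i] = x @ beta
        variances[i] = np.einsum("ij,jk,ik->i", x, np.asarray(f.cov_fe), x)

    w = avg.akaike_weights[:, None]
    m = np.sum(w * means, axis=0)
    v = np.sum(w * (variances + (means - m) ** 2), axis=0)
    half = Z_CRIT * np.sqrt(v)
    return TrendPrediction(years, np.exp(m), np.exp(m - half), np.exp(m + half))


def percent_decline(catch_first: float, catch_last: float, *, rounded: bool = True) -> float:
    """Percent decline 100·(1 − last/first); rounded to the nearest integer
    (half up) for reporting by default."""
    if not catch_first > 0:
        raise ValueError("first-period catch must be > 0")
    pct = 100.0 * (1.0 - catch_last / catch_first)
    return float(math.floor(pct + 0.5)) if rounded else pct


def diagnostics(fit: FitResult, data: pd.DataFrame) -> DiagnosticsReport:
    """Residual diagnostics for one fitted model (see class docstring)."""
    if fit.resid is None or len(fit.resid) < 3:
        raise ValueError("need a fitted model with >= 3 residuals")
    resid, fitted = fit.resid, fit.fitted
    flags: list[str] = []

    # curvature: t statistic of fitted^2 in resid ~ fitted + fitted^2
    Xq = np.column_stack([np.ones_like(fitted), fitted, fitted ** 2])
    if np.linalg.matrix_rank(Xq) < 3:
        curv_t, curv_p = 0.0, 1.0
    else:
        beta, res_ss, *_ = np.linalg.lstsq(Xq, resid, rcond=None)
        dof = len(resid) - 3
        s2 = float(res_ss[0]) / dof if len(res_ss) and dof > 0 else np.var(resid - Xq @ beta)
        cov = s2 * np.linalg.inv(Xq.T @ Xq)
        curv_t = float(beta[2] / np.sqrt(cov[2, 2])) if cov[2, 2] > 0 else 0.0
        curv_p = float(2 * stats.t.sf(abs(curv_t), dof)) if dof > 0 else 1.0

    sh_stat, sh_p = (stats.shapiro(resid) if len(resid) >= 3 else (np.nan, np.nan))

    # lag-1 autocorrelation within fisher, ordered by year
    df = data.assign(_r=resid).sort_values(["fisher_id", "year_assigned"], kind="stable")
    pairs = []
    for _, g in df.groupby("fisher_id", sort=False):
        r = g["_r"].to_numpy()
        for a, b in zip(r[:-1], r[1:]):
            pairs.append((a, b))
    if len(pairs) >= 2:
        arr = np.asarray(pairs)
        with np.errstate(invalid="ignore"):
            lag1 = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
        if not np.isfinite(lag1):
            lag1 = 0.0
    else:
        lag1 = 0.0
    if abs(lag1) > 0.5:
        flags.append("autocorrelation")

    base_terms = sorted({p for t in fit.spec.fixed_terms for p in t.split(":")})
    vif: dict[str, float] = {}
    if len(fit.spec.fixed_terms) == 1:
        vif[fit.spec.fixed_terms[0]] = 1.0
    elif fit.spec.fixed_terms:
        transforms = fit_transforms(data, base_terms)
        X = _design(data, fit.spec.fixed_terms, transforms)
        for j, t in enumerate(fit.spec.fixed_terms, start=1):
            with np.errstate(divide="ignore", invalid="ignore"):
                v = float(variance_inflation_factor(X, j))
            if not np.isfinite(v) or v > 1e6:
                v = float("inf")
                flags.append(f"collinear:{t}")
            vif[t] = v
    return DiagnosticsReport(curv_t, curv_p, float(sh_stat), float(sh_p), lag1, vif, flags)


# ---------------------------------------------------------------------------
# estimator

class CatchTrendRegressor(BaseEstimator, RegressorMixin):
    """Multimodel-averaged random-intercept regression of log catch.

    Fits every subset of the candidate fixed effects as a random-intercept
    LMM, averages the ΔAIC < ``delta_threshold`` set with Akaike weights,
    and predicts back-transformed catch.

    Parameters
    ----------
    candidates : sequence of str
        Candidate fixed-effect terms among ``year``, ``gillnet_length``,
        ``fishing_time``.
    interactions : {"none", "with_year"}
        Whether to add two-way interactions containing year.
    delta_threshold : float
        ΔAIC cutoff for the averaging set.
    strict_reml_aic : bool
        Compare REML AICs literally instead of ML refits.

    Attributes
    ----------
    fits_ : list of FitResult
        One fit per candidate structure.
    averaged_ : AveragedModel
    coef_ : dict
        Averaged coefficients on the standardized log scale.
    transforms_ : dict of Standardizer
    diagnostics_ : DiagnosticsReport of the lowest-AIC member.
    """

    def __init__(self, candidates: Sequence[str] = ("year", "gillnet_length", "fishing_time"),
                 interactions: str = "none", delta_threshold: float = 4.0,
                 strict_reml_aic: bool = False):
        self.candidates = candidates
        self.interactions = interactions
        self.delta_threshold = delta_threshold
        self.strict_reml_aic = strict_reml_aic

    def fit(self, X: pd.DataFrame, y: Optional[Sequence[float]] = None,
            groups: Optional[Sequence] = None) -> "CatchTrendRegressor":
        """Fit on a periods table.

        ``X`` is a DataFrame with the covariate columns of
        :data:`TERM_COLUMNS` plus, when ``y``/``groups`` are omitted,
        ``catch_kg`` and ``fisher_id``.
        """
        data = X.copy()
        if y is not None:
            data["catch_kg"] = np.asarray(y, dtype=float)
        if groups is not None:
            data["fisher_id"] = np.asarray(groups)
        for col in ("catch_kg", "fisher_id"):
            if col not in data.columns:
                raise ValueError(f"missing {col!r}")
        self.transforms_ = fit_transforms(data, list(self.candidates))
        specs = enumerate_models(self.candidates, self.interactions)
        if self.strict_reml_aic:
            self.fits_ = [fit_lmm(s, data, transforms=self.transforms_,
                                  strict_reml_aic=True) for s in specs]
        else:
            # ML pass for the AIC surface; REML refit only for the averaging set
            ml = [fit_lmm(s, data, transforms=self.transforms_, reml=False)
                  for s in specs]
            min_aic = min(f.aic for f in ml)
            self.fits_ = [
                fit_lmm(f.spec, data, transforms=self.transforms_,
                        precomputed_ml_llf=f.loglik)
                if f.aic - min_aic < self.delta_threshold else f
                for f in ml
            ]
        self.averaged_ = average_models(self.fits_, self.delta_threshold)
        self.coef_ = dict(self.averaged_.averaged_coefficients)
        self.conf_int_ = dict(self.averaged_.conf_int)
        best = min(self.averaged_.member_fits, key=lambda f: f.aic)
        self.diagnostics_ = diagnostics(best, data)
        self.n_obs_ = len(data)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Population-level expected catch (kg) for new covariate rows."""
        if not hasattr(self, "averaged_"):
            raise ValueError("not fitted")
        log_pred = np.full(len(X), self.coef_.get("intercept", 0.0))
        for t, b in self.coef_.items():
            if t == "intercept":
                continue
            z = np.ones(len(X))
            for p in t.split(":"):
                z = z * self.transforms_[p].transform(X[TERM_COLUMNS[p]].to_numpy())
            log_pred = log_pred + b * z
        return np.exp(log_pred)

    def predict_trend(self, years: Sequence[float]) -> TrendPrediction:
        """Predicted catch trajectory over ``years`` (other covariates at mean)."""
        return predict_trend(self.averaged_, years, self.transforms_)
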