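"""Regression with subset-AR ARIMA errors: likelihood, fitting, diagnostics.

The transfer-function model for the weekly dependent count ``y_t`` is

    y_t = alpha + beta * x_t + omega * I_t + (outlier terms) + N_t
    phi(B) (1-B)^d N_t = theta(B) eps_t,      eps_t ~ N(0, sigma^2)

with ``x_t`` the contemporaneous control series, ``I_t`` a coded
intervention indicator, and a *subset* AR polynomial: only the configured
lags (by default 1 and 5) carry free coefficients, intermediate lags are
pinned at zero.  Estimation maximises the exact Gaussian likelihood via
the state-space innovations recursion (statsmodels' SARIMAX machinery);
standard errors come from the observed information at the optimum.  With
no ARMA terms and d = 0 the estimator collapses to ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.statespace.sarimax import SARIMAX
from statsmodels.tsa.stattools import acf as sm_acf
from statsmodels.tsa.stattools import pacf as sm_pacf

from .ingest import SeriesPair

logger = logging.getLogger("edseries")

Z_95 = 1.96  # two-tailed 95% multiplier used throughout


class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails; carries the best fit found."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class NoiseSpec:
    """ARIMA structure of the regression error term.

    ``ar_lags``/``ma_lags`` list the lags with free coefficients; all
    other lags up to the maximum are fixed at zero (a subset model).
    """

    ar_lags: tuple[int, ...] = (1, 5)
    ma_lags: tuple[int, ...] = ()
    d: int = 0

    def __post_init__(self) -> None:
        ar = tuple(sorted(set(int(l) for l in self.ar_lags)))
        ma = tuple(sorted(set(int(l) for l in self.ma_lags)))
        if any(l < 1 for l in ar + ma):
            raise ValueError("lags must be positive integers")
        if self.d not in (0, 1):
            raise ValueError("differencing order d must be 0 or 1")
        object.__setattr__(self, "ar_lags", ar)
        object.__setattr__(self, "ma_lags", ma)

    @property
    def max_lag(self) -> int:
        return max(self.ar_lags + self.ma_lags, default=0)

    def sarimax_order(self) -> tuple:
        ar = [1 if l in self.ar_lags else 0 for l in range(1, max(self.ar_lags, default=0) + 1)]
        ma = [1 if l in self.ma_lags else 0 for l in range(1, max(self.ma_lags, default=0) + 1)]
        return (ar or 0, self.d, ma or 0)


@dataclass(frozen=True)
class TransferModelSpec:
    """Structure of the transfer-function regression.

    ``intervention`` is the coded 0/1 indicator vector (or None for the
    identification-stage model without it).  ``burn_in_weeks`` residuals
    are dropped from reporting to discard start-up transients of the
    lagged noise model.
    """

    noise: NoiseSpec = NoiseSpec()
    include_control: bool = True
    intervention: tuple[float, ...] | None = None
    burn_in_weeks: int = 6

    def __post_init__(self) -> None:
        if self.intervention is not None:
            object.__setattr__(self, "intervention", tuple(float(v) for v in self.intervention))
        if self.burn_in_weeks < 0:
            raise ValueError("burn_in_weeks must be non-negative")

    def validate_against(self, pair: SeriesPair) -> None:
        if self.intervention is not None and len(self.intervention) != len(pair):
            raise ValueError("intervention indicator length must match the series")


@dataclass(frozen=True)
class ModelParams:
    """Explicit parameter point for likelihood evaluation."""

    alpha: float = 0.0
    beta_control: float | None = None
    omega: float | None = None
    phi: Mapping[int, float] = field(default_factory=dict)
    theta: Mapping[int, float] = field(default_factory=dict)
    sigma2: float = 1.0


@dataclass
class FitResult:
    """Estimates, uncertainty, and residuals from a transfer-model fit."""

    param_names: list[str]
    params: dict[str, float]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    pvalues: dict[str, float]
    loglik: float
    sigma2: float
    residuals: np.ndarray          # post burn-in, used for diagnostics
    residuals_full: np.ndarray     # one innovation per week
    nobs: int
    burn_in_weeks: int
    converged: bool
    spec: TransferModelSpec
    warnings: list[str] = field(default_factory=list)

    @property
    def beta_control(self) -> float | None:
        return self.params.get("control")

    @property
    def omega_intervention(self) -> float | None:
        return self.params.get("intervention")

    @property
    def phi(self) -> dict[int, float]:
        return {
            int(n.split(".L")[1]): v for n, v in self.params.items() if n.startswith("ar.L")
        }

    @property
    def theta(self) -> dict[int, float]:
        return {
            int(n.split(".L")[1]): v for n, v in self.params.items() if n.startswith("ma.L")
        }

    @property
    def outlier_names(self) -> list[str]:
        return [n for n in self.param_names if n.startswith(("AO_", "TC_", "LS_"))]

    def to_dict(self) -> dict:
        return {
            "parameters": [
                {
                    "name": name,
                    "label": display_label(name),
                    "estimate": self.params[name],
                    "se": self.se[name],
                    "ci95": list(self.ci95[name]),
                    "p_value": self.pvalues[name],
                }
                for name in self.param_names
            ],
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "nobs": self.nobs,
            "converged": self.converged,
            "warnings": list(self.warnings),
        }


def display_label(name: str) -> str:
    """Human-readable row label for a parameter, after the convention of
    intervention-analysis coefficient tables."""
    if name == "const":
        return "Intercept"
    if name == "control":
        return "Control series (Medi-Cal comparison)"
    if name == "intervention":
        return "Stay-at-home orders"
    if name.startswith("ar.L"):
        return f"AR({name.split('.L')[1]})"
    if name.startswith("ma.L"):
        return f"MA({name.split('.L')[1]})"
    if name == "sigma2":
        return "Innovation variance"
    for prefix, label in (("AO_w", "Additive outlier"), ("TC_w", "Temporary change"), ("LS_w", "Level shift")):
        if name.startswith(prefix):
            return f"{label} (week {name[len(prefix):]})"
    return name


# ---------------------------------------------------------------------------
# Model construction


def build_exog(
    pair: SeriesPair,
    spec: TransferModelSpec,
    extra_regressors: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"const": np.ones(len(pair))}
    if spec.include_control:
        cols["control"] = pair.control.values
    if spec.intervention is not None:
        cols["intervention"] = np.asarray(spec.intervention, dtype=float)
    for name, vec in (extra_regressors or {}).items():
        vec = np.asarray(vec, dtype=float)
        if len(vec) != len(pair):
            raise ValueError(f"regressor {name!r} length {len(vec)} != series length {len(pair)}")
        cols[name] = vec
    return pd.DataFrame(cols)


def _build_sarimax(
    pair: SeriesPair,
    spec: TransferModelSpec,
    extra_regressors: Mapping[str, np.ndarray] | None = None,
) -> SARIMAX:
    spec.validate_against(pair)
    exog = build_exog(pair, spec, extra_regressors)
    n_free = exog.shape[1] + len(spec.noise.ar_lags) + len(spec.noise.ma_lags) + 1
    if len(pair) <= spec.noise.max_lag + n_free:
        raise ValueError(
            f"series length {len(pair)} too short for max lag {spec.noise.max_lag} "
            f"plus {n_free} free parameters"
        )
    endog = pd.Series(pair.dependent.values, name="dependent")
    return SARIMAX(endog, exog=exog, order=spec.noise.sarimax_order(), trend="n")


def _assemble_param_vector(
    params: ModelParams, mod: SARIMAX, spec: TransferModelSpec
) -> np.ndarray:
    values: dict[str, float] = {"const": params.alpha, "sigma2": params.sigma2}
    if spec.include_control:
        if params.beta_control is None:
            raise ValueError("spec includes the control series but beta_control is None")
        values["control"] = params.beta_control
    if spec.intervention is not None:
        if params.omega is None:
            raise ValueError("spec includes an intervention but omega is None")
        values["intervention"] = params.omega
    for lag in spec.noise.ar_lags:
        values[f"ar.L{lag}"] = params.phi.get(lag, 0.0)
    for lag in spec.noise.ma_lags:
        values[f"ma.L{lag}"] = params.theta.get(lag, 0.0)
    extra_phi = set(params.phi) - set(spec.noise.ar_lags)
    extra_theta = set(params.theta) - set(spec.noise.ma_lags)
    if extra_phi or extra_theta:
        raise ValueError(f"parameters at lags outside the noise spec: {extra_phi | extra_theta}")
    try:
        vec = np.array([values[name] for name in mod.param_names])
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"parameter {exc} not specified") from exc
    return vec


def model_loglik(
    params: ModelParams,
    pair: SeriesPair,
    spec: TransferModelSpec,
    extra_regressors: Mapping[str, np.ndarray] | None = None,
) -> float:
    """Exact Gaussian log-likelihood of the transfer model at ``params``."""
    if params.sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    mod = _build_sarimax(pair, spec, extra_regressors)
    vec = _assemble_param_vector(params, mod, spec)
    if not np.all(np.isfinite(vec)):
        raise ValueError("parameters must be finite")
    return float(mod.loglike(vec))


def _ols_start(mod: SARIMAX, spec: TransferModelSpec) -> np.ndarray:
    """Start values: OLS regression coefficients, zero ARMA terms, OLS
    residual variance.  With no ARMA terms this is already the MLE."""
    y = np.asarray(mod.endog, dtype=float).ravel()
    x = np.asarray(mod.exog, dtype=float)
    if spec.noise.d == 1:
        y = np.diff(y)
        x = np.diff(x, axis=0)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sigma2 = max(float(resid @ resid) / len(y), 1e-8)
    n_arma = len(spec.noise.ar_lags) + len(spec.noise.ma_lags)
    return np.concatenate([beta, np.zeros(n_arma), [sigma2]])


def _check_ar_roots(params: dict[str, float]) -> bool:
    """True when the fitted AR polynomial has all roots outside the unit
    circle (a stationary noise process)."""
    lags = {int(n.split(".L")[1]): v for n, v in params.items() if n.startswith("ar.L")}
    if not lags:
        return True
    coeffs = np.zeros(max(lags) + 1)
    coeffs[0] = 1.0
    for lag, val in lags.items():
        coeffs[lag] = -val
    roots = np.polynomial.polynomial.polyroots(coeffs)
    return bool(np.all(np.abs(roots) > 1.0 + 1e-8))


def fit_transfer_model(
    pair: SeriesPair,
    spec: TransferModelSpec,
    extra_regressors: Mapping[str, np.ndarray] | None = None,
    start_params: Sequence[float] | None = None,
    maxiter: int = 500,
) -> FitResult:
    """Maximum-likelihood fit of the transfer-function model.

    Parameters start from the OLS solution with ARMA terms at zero unless
    ``start_params`` is given.  Non-convergence raises
    :class:`ConvergenceError` carrying the best point found; AR roots on
    or inside the unit circle only attach a warning flag.
    """
    mod = _build_sarimax(pair, spec, extra_regressors)
    start = np.asarray(start_params, float) if start_params is not None else _ols_start(mod, spec)

    def _valid(r) -> bool:
        # the Kalman filter degenerates (llf collapses to exactly 0) when
        # the optimizer escapes the stationary region, which the subset-AR
        # parameter transform does not fully enforce
        p = np.asarray(r.params, dtype=float)
        return (
            np.isfinite(r.llf)
            and r.llf != 0.0
            and np.all(np.isfinite(p))
            and p[-1] > 0
            and _check_ar_roots(dict(zip(mod.param_names, p)))
        )

    res = None
    for method in ("lbfgs", "nm", "bfgs"):
        try:
            attempt = mod.fit(
                start_params=start,
                disp=0,
                cov_type="oim",
                method=method,
                maxiter=5000 if method == "nm" else maxiter,
            )
        except Exception:  # an optimizer can fail outright in the bad region
            continue
        if _valid(attempt):
            if method != "lbfgs":
                polished = mod.fit(
                    start_params=attempt.params, disp=0, cov_type="oim", maxiter=maxiter
                )
                if _valid(polished) and polished.llf >= attempt.llf:
                    attempt = polished
            res = attempt
            break
    if res is None:
        raise ConvergenceError("optimizer left the admissible parameter region", best=None)
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged:
        # one more attempt with a derivative-free polish from the best point
        res2 = mod.fit(start_params=res.params, disp=0, cov_type="oim",
                       method="nm", maxiter=5000)
        if _valid(res2) and res2.llf >= res.llf:
            res = res2
        converged = bool(res.mle_retvals.get("converged", False))

    names = list(mod.param_names)
    params = {n: float(v) for n, v in zip(names, res.params)}
    bse = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(bse)):
        # observed information can be singular near the stationarity
        # boundary; fall back to the numerically differentiated Hessian
        with np.errstate(invalid="ignore"):
            bse_approx = np.sqrt(np.diag(res.cov_params_approx))
        bse = np.where(np.isfinite(bse), bse, bse_approx)
    se = {n: float(v) for n, v in zip(names, bse)}
    ci95 = {n: (params[n] - Z_95 * se[n], params[n] + Z_95 * se[n]) for n in names}
    z = {n: params[n] / se[n] if se[n] > 0 else np.inf for n in names}
    pvalues = {n: float(2 * stats.norm.sf(abs(z[n]))) for n in names}
    resid_full = np.asarray(res.resid, dtype=float)
    warnings: list[str] = []
    if not _check_ar_roots(params):
        warnings.append("ar_roots_on_or_inside_unit_circle")

    result = FitResult(
        param_names=names,
        params=params,
        se=se,
        ci95=ci95,
        pvalues=pvalues,
        loglik=float(res.llf),
        sigma2=float(params["sigma2"]),
        residuals=resid_full[spec.burn_in_weeks:],
        residuals_full=resid_full,
        nobs=len(pair),
        burn_in_weeks=spec.burn_in_weeks,
        converged=converged,
        spec=spec,
        warnings=warnings,
    )
    if not converged:
        raise ConvergenceError(
            f"optimizer failed to converge after {maxiter} iterations", best=result
        )
    return result


# ---------------------------------------------------------------------------
# Diagnostics


@dataclass
class DiagnosticsReport:
    """Sample ACF/PACF with a Bartlett reference band and, optionally, a
    portmanteau whiteness test."""

    acf: np.ndarray
    pacf: np.ndarray
    bartlett_band: float
    flagged_lags: tuple[int, ...]       # PACF exceedances, used for identification
    flagged_acf_lags: tuple[int, ...]
    nobs: int
    ljung_box_stat: float | None = None
    ljung_box_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "acf": self.acf.tolist(),
            "pacf": self.pacf.tolist(),
            "bartlett_band": self.bartlett_band,
            "flagged_lags": list(self.flagged_lags),
            "flagged_acf_lags": list(self.flagged_acf_lags),
            "nobs": self.nobs,
            "ljung_box_stat": self.ljung_box_stat,
            "ljung_box_p": self.ljung_box_p,
        }


def acf_pacf(x: Sequence[float], max_lag: int) -> DiagnosticsReport:
    """Sample autocorrelations and partial autocorrelations to ``max_lag``.

    The PACF uses the Durbin-Levinson (Levinson-Durbin) recursion; lags
    whose PACF (resp. ACF) exceed the +/-1.96/sqrt(T) Bartlett band are
    flagged.
    """
    x = np.asarray(x, dtype=float)
    t = len(x)
    if t <= max_lag + 1:
        raise ValueError(f"series length {t} must exceed max_lag + 1 = {max_lag + 1}")
    if np.ptp(x) == 0:
        raise ValueError("autocorrelation is undefined for a constant series")
    acf_vals = sm_acf(x, nlags=max_lag, fft=True)
    pacf_vals = sm_pacf(x, nlags=max_lag, method="ldb")
    band = Z_95 / np.sqrt(t)
    flagged = tuple(l for l in range(1, max_lag + 1) if abs(pacf_vals[l]) > band)
    flagged_acf = tuple(l for l in range(1, max_lag + 1) if abs(acf_vals[l]) > band)
    return DiagnosticsReport(
        acf=acf_vals,
        pacf=pacf_vals,
        bartlett_band=float(band),
        flagged_lags=flagged,
        flagged_acf_lags=flagged_acf,
        nobs=t,
    )


def ljung_box(residuals: Sequence[float], n_lags: int, n_fitted: int) -> tuple[float, float]:
    """Portmanteau test of residual whiteness over ``n_lags`` lags with
    ``n_lags - n_fitted`` degrees of freedom."""
    residuals = np.asarray(residuals, dtype=float)
    if n_lags <= n_fitted:
        raise ValueError(f"n_lags ({n_lags}) must exceed n_fitted ({n_fitted})")
    if len(residuals) <= n_lags:
        raise ValueError("series must be longer than n_lags")
    if np.ptp(residuals) == 0:
        raise ValueError("Ljung-Box is undefined for zero-variance residuals")
    table = acorr_ljungbox(residuals, lags=[n_lags], model_df=n_fitted)
    return float(table["lb_stat"].iloc[0]), float(table["lb_pvalue"].iloc[0])


def identify_noise(residuals: Sequence[float], max_lag: int = 10) -> NoiseSpec:
    """Suggest a subset-AR noise spec from the PACF of regression residuals.

    Lags whose partial autocorrelation exceeds the Bartlett band become
    free AR coefficients.  Advisory only: the pipeline adopts the
    suggestion only when it matches the configured spec.
    """
    report = acf_pacf(residuals, max_lag)
    return NoiseSpec(ar_lags=report.flagged_lags, ma_lags=(), d=0)
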