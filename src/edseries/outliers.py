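"""Iterative additive-outlier / temporary-change / level-shift detection.

Unusual single weeks (AO), geometrically decaying shocks (TC), and
permanent level changes (LS) inflate the innovation variance of a fitted
transfer model and widen intervention confidence intervals.  Following
the iterative detection-and-correction approach of Chen and Liu, each
pass scores every candidate (type, week) regressor by a fast
filtered-regression scan with the ARMA parameters held at their current
estimates, then confirms the leading candidates by full joint re-fits:
a candidate is accepted when its coefficient carries |t| above the
threshold in the re-estimated augmented model, and the loop repeats from
that model until nothing clears the threshold.

The scan statistic uses the standard reduction: with current AR
polynomial phi(B), differencing (1-B)^d and MA polynomial theta(B), both
the series and every regressor (current and candidate) are filtered by
pi(B) = phi(B)(1-B)^d / theta(B), after which each candidate's
coefficient is an added-variable regression

    t = (sum e~_t u_t / sum u_t^2) * sqrt(sum u_t^2) / sigma_hat

with u the filtered candidate projected off the filtered design.  Under
a pure white-noise model this collapses to the (studentized)
standardized residual for an AO candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .arima import ConvergenceError, FitResult, TransferModelSpec, build_exog, fit_transfer_model
from .ingest import SeriesPair

logger = logging.getLogger("edseries")

OUTLIER_TYPES = ("AO", "TC", "LS")
#: tie-break priority when |t| values are exactly equal (higher wins)
_TYPE_RANK = {"LS": 0, "TC": 1, "AO": 2}
#: scan |t| lead over the runner-up required to skip joint confirmation
#: of the alternatives
_DIRECT_MARGIN = 0.3


@dataclass(frozen=True)
class OutlierConfig:
    """Scan settings: detection threshold on |t|, enabled outlier types,
    TC decay rate, and a cap on accepted outliers.

    ``sigma_estimator`` sets the innovation-scale estimate that
    standardizes the scan statistics: ``"huber"`` (default) is a Huber
    proposal-2 scale of the filtered residuals, which resists inflation
    by the very outliers being hunted while staying nearly as efficient
    as the sample standard deviation on clean data; ``"mad"`` is the
    median-absolute-deviation alternative; ``"ml"`` uses the fitted
    model's maximum-likelihood sigma.

    The fast scan screens candidates; the decisive t value is the
    candidate coefficient's t statistic in the fully re-estimated
    augmented model.  Up to ``confirm_top`` candidates whose scan |t|
    exceeds ``screen_frac * t_threshold`` are re-fit jointly per
    iteration, and the best confirmed candidate above the threshold is
    accepted.  Screening below the final threshold matters because large
    unmodelled shifts bias the AR estimates toward a unit root, which
    deflates the filtered scan statistic; the joint re-fit removes that
    bias before the threshold is applied.
    """

    t_threshold: float = 3.5
    types_enabled: tuple[str, ...] = OUTLIER_TYPES
    tc_delta: float = 0.7
    max_outliers: int = 10
    sigma_estimator: str = "huber"
    confirm_top: int = 2
    screen_frac: float = 0.7

    def __post_init__(self) -> None:
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be positive")
        types = tuple(self.types_enabled)
        if not types or any(t not in OUTLIER_TYPES for t in types):
            raise ValueError(f"types_enabled must be a non-empty subset of {OUTLIER_TYPES}")
        if not 0.0 < self.tc_delta < 1.0:
            raise ValueError("tc_delta must lie strictly inside (0, 1)")
        if self.max_outliers < 1:
            raise ValueError("max_outliers must be positive")
        if self.sigma_estimator not in ("huber", "mad", "ml"):
            raise ValueError("sigma_estimator must be 'huber', 'mad' or 'ml'")
        if self.confirm_top < 1:
            raise ValueError("confirm_top must be positive")
        if not 0.0 < self.screen_frac <= 1.0:
            raise ValueError("screen_frac must lie in (0, 1]")
        object.__setattr__(self, "types_enabled", types)


@dataclass(frozen=True)
class OutlierRecord:
    """One accepted outlier: its type, 1-based week, the jointly
    re-estimated magnitude, the t statistic at detection, and the
    maximized log-likelihood after the joint re-fit that accepted it."""

    type: str
    week: int
    magnitude: float
    t_stat: float
    iteration: int
    loglik: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "type": self.type,
            "week_index": self.week,
            "magnitude": self.magnitude,
            "t_stat": self.t_stat,
            "loglik": self.loglik,
        }


def outlier_regressor(kind: str, week: int, series_length: int, delta: float = 0.7) -> np.ndarray:
    """Deterministic regressor encoding one outlier at a 1-based week.

    AO: unit pulse.  LS: unit step from the week onward.  TC: pulse that
    decays as delta**(t - week).
    """
    if not 1 <= week <= series_length:
        raise ValueError(f"week {week} outside 1..{series_length}")
    z = np.zeros(series_length)
    i = week - 1
    if kind == "AO":
        z[i] = 1.0
    elif kind == "LS":
        z[i:] = 1.0
    elif kind == "TC":
        z[i:] = delta ** np.arange(series_length - i)
    else:
        raise ValueError(f"unknown outlier type {kind!r}")
    return z


def _robust_scale(x: np.ndarray, estimator: str) -> float:
    """Scale estimate of filtered residuals for standardizing scan stats."""
    if estimator == "ml":
        return np.nan  # caller falls back to the model's ML sigma
    mad = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    if estimator == "mad" or mad <= 0:
        return mad
    try:
        from statsmodels.robust.scale import Huber

        _, scale = Huber()(x)
        return float(scale)
    except Exception:  # Huber iteration can fail on degenerate input
        return mad


def _pi_filter(spec: TransferModelSpec, phi: Mapping[int, float], theta: Mapping[int, float]):
    """Numerator/denominator of pi(B) = phi(B)(1-B)^d / theta(B)."""
    p = max(phi, default=0)
    num = np.zeros(p + 1)
    num[0] = 1.0
    for lag, val in phi.items():
        num[lag] = -val
    for _ in range(spec.noise.d):
        num = np.convolve(num, [1.0, -1.0])
    q = max(theta, default=0)
    den = np.zeros(q + 1)
    den[0] = 1.0
    for lag, val in theta.items():
        den[lag] = val
    return num, den


def scan_t_stats(
    fit: FitResult,
    pair: SeriesPair,
    spec: TransferModelSpec,
    config: OutlierConfig,
    extra_regressors: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """t statistic of every candidate (type, week) outlier regressor.

    Candidates already present in ``extra_regressors`` and degenerate
    designs (an LS at week 1 duplicates the intercept) are skipped.
    Returns a tidy frame with columns type, week, coef, t_stat,
    in_intervention, ordered as described by :func:`_order_candidates`.
    """
    t_len = len(pair)
    if not np.isfinite(fit.sigma2) or fit.sigma2 <= 0:
        raise ValueError("degenerate fit: innovation variance is not positive")

    exog = build_exog(pair, spec, extra_regressors)
    beta = np.array([fit.params[c] for c in exog.columns])
    resid_reg = pair.dependent.values - exog.to_numpy() @ beta
    if np.ptp(resid_reg) == 0 and np.allclose(resid_reg, 0):
        raise ValueError("degenerate fit: regression residuals are identically zero")

    # condition on the first max-lag observations: filtered rows before
    # that carry start-up transients, not innovations
    num, den = _pi_filter(spec, fit.phi, fit.theta)
    drop = max(fit.phi.keys(), default=0) + spec.noise.d
    y_f = lfilter(num, den, pair.dependent.values)[drop:]
    x_f = lfilter(num, den, exog.to_numpy(), axis=0)[drop:]

    # added-variable statistics: regression coefficients are re-estimated
    # jointly with each candidate (GLS given the current ARMA filter),
    # so a large unmodelled shift cannot hide inside a distorted
    # intervention or intercept estimate
    coef_x, *_ = np.linalg.lstsq(x_f, y_f, rcond=None)
    e_gls = y_f - x_f @ coef_x

    sigma = _robust_scale(e_gls, config.sigma_estimator)
    if not np.isfinite(sigma) or sigma <= 0:
        sigma = float(np.sqrt(fit.sigma2))
    # degrees-of-freedom correction: both scale estimates shrink with the
    # number of fitted mean-function parameters, which would inflate
    # every t statistic by the same factor
    n_rows, k = x_f.shape
    if n_rows > k:
        sigma *= np.sqrt(n_rows / (n_rows - k))

    accepted = {
        (name.split("_w")[0], int(name.split("_w")[1]))
        for name in (extra_regressors or {})
        if name.startswith(("AO_w", "TC_w", "LS_w"))
    }
    window_weeks = (
        set((np.flatnonzero(np.asarray(spec.intervention)) + 1).tolist())
        if spec.intervention is not None
        else set()
    )

    ss_floor = 1e-6
    rows = []
    for kind in config.types_enabled:
        # all candidate regressors of this type as columns of one matrix
        z = np.zeros((t_len, t_len))
        idx = np.arange(t_len)
        if kind == "AO":
            z[idx, idx] = 1.0
        elif kind == "LS":
            z[np.tril_indices(t_len)] = 1.0  # z[t, w] = 1 for t >= w
        else:  # TC
            rowi, colj = np.tril_indices(t_len)
            z[rowi, colj] = config.tc_delta ** (rowi - colj)
        w_f = lfilter(num, den, z, axis=0)[drop:]
        proj, *_ = np.linalg.lstsq(x_f, w_f, rcond=None)
        u = w_f - x_f @ proj
        ss = np.einsum("tw,tw->w", u, u)
        cross = e_gls @ u
        for week0 in range(t_len):
            week = week0 + 1
            if (kind, week) in accepted:
                continue
            if kind == "LS" and week == 1:
                continue  # collinear with the intercept
            if ss[week0] < ss_floor:
                logger.debug("skipping singular candidate %s week %d", kind, week)
                continue
            coef = cross[week0] / ss[week0]
            tstat = coef * np.sqrt(ss[week0]) / sigma
            rows.append((kind, week, coef, tstat, week in window_weeks))

    frame = pd.DataFrame(rows, columns=["type", "week", "coef", "t_stat", "in_intervention"])
    return _order_candidates(frame)


def _order_candidates(frame: pd.DataFrame, t_col: str = "t_stat") -> pd.DataFrame:
    """Deterministic candidate ordering: |t| descending (quantized to
    two decimals so collinear candidates tie exactly despite float and
    optimizer noise); quantized ties resolve to onsets outside the
    intervention window, then higher raw |t|, earlier week, LS > TC > AO.

    The window preference resolves a real degeneracy: with the pulse
    indicator in the model, a level shift starting at the window's first
    week spans the same column space as one starting the week after the
    window plus a change in the intervention coefficient, so their t
    values tie exactly; keeping the onset outside the window preserves
    the coded intervention's interpretation.
    """
    if not len(frame):
        return frame
    order = frame.assign(
        abs_t=frame[t_col].abs().round(2),
        abs_t_raw=frame[t_col].abs(),
        rank=frame["type"].map(_TYPE_RANK),
    ).sort_values(
        ["abs_t", "in_intervention", "abs_t_raw", "week", "rank"],
        ascending=[False, True, False, True, True],
    )
    return frame.loc[order.index].reset_index(drop=True)


def detect_and_adjust(
    pair: SeriesPair,
    spec: TransferModelSpec,
    config: OutlierConfig,
    initial_fit: FitResult | None = None,
    known_outliers: list[OutlierRecord] | None = None,
) -> tuple[FitResult, list[OutlierRecord]]:
    """Iterative outlier detection with joint re-estimation.

    Each iteration runs the fast scan, then confirms the top screened
    candidates by re-fitting the augmented model: the decisive t value
    is the candidate coefficient's t statistic with every parameter
    (regression, outlier, ARMA) re-estimated jointly.  The best
    confirmed candidate with joint |t| above the threshold is accepted
    and the loop repeats from the re-estimated model.  Accepted outliers
    are never removed.  Stops when no candidate clears the threshold or
    the cap is reached (the latter attaches a warning to the fit).
    """
    extra: dict[str, np.ndarray] = {}
    for rec in known_outliers or []:
        extra[f"{rec.type}_w{rec.week}"] = outlier_regressor(
            rec.type, rec.week, len(pair), config.tc_delta
        )
    if initial_fit is not None and set(initial_fit.outlier_names) == set(extra):
        fit = initial_fit
    else:
        fit = fit_transfer_model(pair, spec, extra or None)
    records: list[OutlierRecord] = []
    screen = config.screen_frac * config.t_threshold

    while True:
        scan = scan_t_stats(fit, pair, spec, config, extra)
        above_screen = scan[scan["t_stat"].abs() > screen]
        screened = above_screen.groupby("type", sort=False).head(config.confirm_top)
        # each type's best candidate is always worth confirming: a large
        # shift of another type can deflate every scan statistic at once
        top_per_type = scan.groupby("type", sort=False).head(1)
        screened = (
            pd.concat([screened, top_per_type])
            .drop_duplicates(subset=["type", "week"])
        )
        if screened.empty:
            break
        if len(records) >= config.max_outliers:
            if (scan["t_stat"].abs() > config.t_threshold).any():
                fit.warnings.append("max_outliers_reached_with_candidates_above_threshold")
                logger.warning("outlier cap %d reached with candidates above threshold",
                               config.max_outliers)
            break

        prev_llf = fit.loglik
        best = None
        top_scan = scan.iloc[0]
        runner_up = abs(scan.iloc[1]["t_stat"]) if len(scan) > 1 else -np.inf
        if (
            abs(top_scan["t_stat"]) > config.t_threshold
            and abs(top_scan["t_stat"]) - runner_up >= _DIRECT_MARGIN
        ):
            # clear scan winner: take it directly, but still require its
            # jointly re-estimated coefficient to clear the threshold;
            # close races instead go through likelihood-based
            # confirmation of all screened candidates below
            kind, week = str(top_scan["type"]), int(top_scan["week"])
            name = f"{kind}_w{week}"
            candidate = dict(extra)
            candidate[name] = outlier_regressor(kind, week, len(pair), config.tc_delta)
            new_fit = _refit_augmented(
                pair, spec, candidate, fit, float(top_scan["coef"]), prev_llf
            )
            if new_fit is not None:
                joint_t = _joint_t(new_fit, name, len(pair))
                if np.isfinite(joint_t) and abs(joint_t) > config.t_threshold:
                    best = {
                        "type": kind,
                        "week": week,
                        "t_stat": float(top_scan["t_stat"]),
                        "fit": new_fit,
                        "extra": candidate,
                        "name": name,
                    }
        if best is None:
            # weak-signal band: the scan statistic can be deflated by
            # shift-contaminated AR estimates, so confirm the screened
            # candidates with full joint re-fits and use the joint t
            confirmed = []
            for _, cand in screened.iterrows():
                kind, week = str(cand["type"]), int(cand["week"])
                name = f"{kind}_w{week}"
                candidate = dict(extra)
                candidate[name] = outlier_regressor(kind, week, len(pair), config.tc_delta)
                new_fit = _refit_augmented(
                    pair, spec, candidate, fit, float(cand["coef"]), prev_llf
                )
                if new_fit is None:
                    continue
                joint_t = _joint_t(new_fit, name, len(pair))
                if np.isfinite(joint_t) and abs(joint_t) > config.t_threshold:
                    confirmed.append(
                        {
                            "type": kind,
                            "week": week,
                            "t_stat": float(joint_t),
                            "in_intervention": bool(cand["in_intervention"]),
                            "fit": new_fit,
                            "extra": candidate,
                            "name": name,
                        }
                    )
            if not confirmed:
                break
            best = _select_confirmed(confirmed, spec, len(pair), config.tc_delta)
        if best["fit"].loglik <= prev_llf:
            fit.warnings.append(f"loglik_not_improved_by_{best['name']}")
            logger.warning("accepting %s did not improve the likelihood; stopping", best["name"])
            break
        extra = best["extra"]
        fit = best["fit"]
        records.append(
            OutlierRecord(
                type=best["type"],
                week=best["week"],
                magnitude=float(fit.params[best["name"]]),
                t_stat=float(best["t_stat"]),
                iteration=len(records) + 1,
                loglik=float(fit.loglik),
            )
        )
        logger.info(
            "accepted %s with |t|=%.2f (iteration %d)",
            best["name"], abs(best["t_stat"]), len(records),
        )

    return fit, records


#: log-likelihood differences below this are treated as statistical ties
#: (about two support units, the conventional indistinguishability band)
_LLF_TIE = 2.0


def _select_confirmed(
    confirmed: list[dict], spec: TransferModelSpec, t_len: int, delta: float
) -> dict:
    """Pick the confirmed candidate by greedy likelihood ascent.

    Candidates within ``_LLF_TIE`` of the best log-likelihood are
    statistically indistinguishable; among them, prefer the regressor
    least collinear with the coded intervention indicator (an outlier
    overlapping the intervention window competes with the intervention
    coefficient for the same variation), then the higher likelihood,
    then the earlier week, then LS > TC > AO.  Selecting on likelihood
    rather than the coefficient t matters for near-degenerate
    level-shift onsets around the intervention window, where every t is
    enormous but the fits differ markedly.
    """
    best_llf = max(c["fit"].loglik for c in confirmed)
    tied = [c for c in confirmed if c["fit"].loglik >= best_llf - _LLF_TIE]
    indicator = (
        np.asarray(spec.intervention, dtype=float)
        if spec.intervention is not None
        else np.zeros(t_len)
    )
    norm_i = np.linalg.norm(indicator)

    def overlap(c: dict) -> float:
        if norm_i == 0:
            return 0.0
        z = outlier_regressor(c["type"], c["week"], t_len, delta)
        return float(abs(z @ indicator) / (np.linalg.norm(z) * norm_i))

    return min(
        tied,
        key=lambda c: (
            round(overlap(c), 6),
            -c["fit"].loglik,
            c["week"],
            _TYPE_RANK[c["type"]],
        ),
    )


def _joint_t(fit: FitResult, name: str, t_len: int) -> float:
    """Candidate coefficient's t statistic in the jointly re-estimated
    model, with the same df correction applied to the scan scale."""
    se = fit.se.get(name, np.nan)
    if not np.isfinite(se) or se <= 0:
        return np.nan
    t = fit.params[name] / se
    n_par = len(fit.param_names)
    if t_len > n_par:
        t *= np.sqrt((t_len - n_par) / t_len)
    return float(t)


def _refit_augmented(
    pair: SeriesPair,
    spec: TransferModelSpec,
    candidate: dict[str, np.ndarray],
    fit: FitResult,
    scan_coef: float,
    prev_llf: float,
) -> FitResult | None:
    """Joint re-fit with the candidate regressor added.

    Both the default start (OLS regression, zero ARMA) and a warm start
    from the current estimates are tried and the higher likelihood kept:
    warm starts inherit the contaminated AR basin when a large shift is
    still unmodelled, while the default start escapes it.  The augmented
    model nests the current optimum (candidate coefficient 0), so that
    point serves as a fallback keeping the likelihood from decreasing.
    """
    best: FitResult | None = None
    for start in (
        None,
        _start_with_candidate(fit, scan_coef),
        _start_with_candidate(fit, 0.0),
    ):
        try:
            attempt = fit_transfer_model(pair, spec, candidate, start_params=start)
        except ConvergenceError as err:
            attempt = err.best
        if attempt is not None and (best is None or attempt.loglik > best.loglik):
            best = attempt
        if best is not None and best.loglik > prev_llf:
            break
    return best


def _start_with_candidate(fit: FitResult, coef: float) -> np.ndarray:
    """Parameter vector for the augmented model: previous estimates with
    the candidate's scan coefficient appended to the regression block."""
    names = fit.param_names
    n_exog = len(names) - len(fit.phi) - len(fit.theta) - 1
    exog_part = [fit.params[n] for n in names[:n_exog]]
    arma_part = [fit.params[n] for n in names[n_exog:-1]]
    return np.array(exog_part + [coef] + arma_part + [fit.params["sigma2"]])


def outliers_to_frame(records: list[OutlierRecord], anchor_date=None) -> pd.DataFrame:
    """Serialize accepted outliers, optionally resolving week start dates."""
    from datetime import timedelta

    rows = []
    for rec in records:
        row = rec.to_dict()
        if anchor_date is not None:
            row["week_start_date"] = (anchor_date + timedelta(days=7 * (rec.week - 1))).isoformat()
        rows.append(row)
    cols = ["iteration", "type", "week_index"]
    if anchor_date is not None:
        cols.append("week_start_date")
    cols += ["magnitude", "t_stat"]
    return pd.DataFrame(rows, columns=cols)
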