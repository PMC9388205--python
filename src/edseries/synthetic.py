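"""Synthetic weekly ED-count and encounter-level data with known truth.

Real ED encounter data are confidential hospital records, so every
experiment in this package runs on synthetic series built to carry the
same statistical structure the analysis assumes:

* a control series of weekly counts (iid Gaussian level noise around a
  stable mean) that falls by a sustained fractional drop from the
  pandemic onset week onward — the shared decline in all ED visits;
* a dependent series that tracks the control contemporaneously
  (coefficient ``beta_control``), drops a further ``omega`` counts per
  week during the coded intervention window, and carries subset-AR
  serially correlated noise at the configured lags;
* optional injected AO/TC/LS outliers of known type, week and size;
* optional encounter-level records (one row per visit, with demographics
  and decoys that the ingest filters must remove) whose weekly binning
  reproduces the count series exactly.

Every generated object is accompanied by a truth record holding the
realized parameters and events, so estimator-recovery experiments never
need the original data.  All randomness flows from a single integer seed
through named substreams; identical seed and config give byte-identical
output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
import numpy as np

from .ingest import EncounterRecord, SeriesPair, WeeklySeries, week_index_of
from .intervention import InterventionSpec, make_indicator
from .outliers import outlier_regressor

#: substream indices carved from the master seed
_STREAMS = {"control": 0, "noise": 1, "nonlatino": 2, "records": 3, "decoys": 4}

#: age-band sampling weights for generated adult encounters (bands
#: 18-34, 35-44, 45-54, 55-64, 65+), matching the cohort's age mix
AGE_BANDS = ((18, 34), (35, 44), (45, 54), (55, 64), (65, 89))
AGE_WEIGHTS = (0.2586, 0.2043, 0.2324, 0.1806, 0.1241)
SEX_LEVELS = ("female", "male", "unknown")
SEX_WEIGHTS = (0.552, 0.4476, 0.0004)

DECOY_KINDS = ("minor", "unknown_ethnicity", "other_payer", "inpatient")


def _default_intervention() -> InterventionSpec:
    return InterventionSpec(kind="pulse", start_date=date(2020, 3, 13), series_length=142, n_weeks=9)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate the study series.

    Means and SDs target the pre-pandemic segment; ``shared_covid_drop``
    is the sustained fractional fall in the control level from the
    intervention start week onward.  ``noise_sd`` is the innovation SD of
    the dependent series' subset-AR noise; the dependent series' SD is an
    emergent property, not enforced.
    """

    n_weeks: int = 142
    anchor_date: date = date(2018, 1, 5)
    control_mean: float = 571.08
    control_sd: float = 91.14
    dependent_mean_target: float = 544.25
    dependent_sd_target: float = 107.19
    beta_control: float = 0.97
    phi: dict[int, float] = field(default_factory=lambda: {1: 0.09, 5: 0.06})
    omega: float = -54.33
    intervention: InterventionSpec | None = field(default_factory=_default_intervention)
    shared_covid_drop: float = 0.35
    #: additional window-localized dip in the control series itself, in
    #: counts per week (used to build fixtures where the comparison group
    #: has its own intervention-window deficit); 0 for the primary setup
    control_pulse_effect: float = 0.0
    seasonal_amplitude: float = 0.0
    noise_sd: float = 60.0
    injected_outliers: tuple[tuple[str, int, float], ...] = ()
    tc_delta: float = 0.7
    # non-Latino Medi-Cal comparison series (alternate-pair sensitivity);
    # its smaller pandemic drop makes the Latino decline group-specific
    nonlatino_mean: float = 520.0
    nonlatino_sd: float = 85.0
    nonlatino_drop: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be positive")
        for name in ("control_sd", "noise_sd", "nonlatino_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("control_mean", "dependent_mean_target", "nonlatino_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.shared_covid_drop < 1.0 or not 0.0 <= self.nonlatino_drop < 1.0:
            raise ValueError("fractional drops must lie in [0, 1)")
        if not _stationary(self.phi):
            raise ValueError("phi does not define a stationary AR process")
        object.__setattr__(self, "phi", dict(self.phi))
        object.__setattr__(
            self,
            "injected_outliers",
            tuple((str(k), int(w), float(m)) for k, w, m in self.injected_outliers),
        )
        if self.intervention is not None and self.intervention.series_length != self.n_weeks:
            raise ValueError("intervention series_length must equal n_weeks")
        for kind, week, _ in self.injected_outliers:
            if kind not in ("AO", "TC", "LS"):
                raise ValueError(f"unknown injected outlier type {kind!r}")
            if not 1 <= week <= self.n_weeks:
                raise ValueError(f"injected outlier week {week} outside 1..{self.n_weeks}")

    @property
    def drop_start_week(self) -> int | None:
        if self.intervention is None:
            return None
        return week_index_of(self.intervention.start_date, self.anchor_date)

    def indicator(self) -> np.ndarray:
        if self.intervention is None:
            return np.zeros(self.n_weeks)
        return make_indicator(self.intervention, self.anchor_date)


def _stationary(phi: dict[int, float]) -> bool:
    if not phi:
        return True
    coeffs = np.zeros(max(phi) + 1)
    coeffs[0] = 1.0
    for lag, val in phi.items():
        coeffs[lag] = -val
    return bool(np.all(np.abs(np.polynomial.polynomial.polyroots(coeffs)) > 1.0))


@dataclass
class SyntheticTruth:
    """Everything needed to score an estimator against the generator."""

    alpha: float
    beta_control: float
    omega: float
    phi: dict[int, float]
    noise_sd: float
    indicator: np.ndarray
    expected_dependent: np.ndarray    # noise-free per-week expectation
    pre_round_dependent: np.ndarray
    dependent_counts: np.ndarray
    control_counts: np.ndarray
    injected_outliers: tuple[tuple[str, int, float], ...]
    seed: int
    nonlatino_counts: np.ndarray | None = None
    record_roles: list[str] | None = None   # aligned with emitted records

    def to_dict(self) -> dict:
        out = {
            "alpha": self.alpha,
            "beta_control": self.beta_control,
            "omega": self.omega,
            "phi": {str(k): v for k, v in self.phi.items()},
            "noise_sd": self.noise_sd,
            "indicator": self.indicator.tolist(),
            "expected_dependent": self.expected_dependent.tolist(),
            "pre_round_dependent": self.pre_round_dependent.tolist(),
            "dependent_counts": self.dependent_counts.tolist(),
            "control_counts": self.control_counts.tolist(),
            "injected_outliers": [list(o) for o in self.injected_outliers],
            "seed": self.seed,
        }
        if self.nonlatino_counts is not None:
            out["nonlatino_counts"] = self.nonlatino_counts.tolist()
        if self.record_roles is not None:
            out["record_roles"] = self.record_roles
        return out

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _substream(seed: int, name: str) -> np.random.Generator:
    child = np.random.SeedSequence(seed).spawn(len(_STREAMS))[_STREAMS[name]]
    return np.random.default_rng(child)


def simulate_subset_ar(
    phi: dict[int, float], sigma: float, n: int, rng: np.random.Generator, burn: int = 200
) -> np.ndarray:
    """Stationary subset-AR noise with innovation SD ``sigma``."""
    if not _stationary(phi):
        raise ValueError("phi does not define a stationary AR process")
    p = max(phi, default=0)
    total = n + burn
    eps = rng.normal(0.0, sigma, total)
    x = np.zeros(total)
    for t in range(total):
        acc = eps[t]
        for lag, val in phi.items():
            if t >= lag:
                acc += val * x[t - lag]
        x[t] = acc
    return x[burn:]


def _level_series(
    mean: float,
    sd: float,
    drop_frac: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    label: str,
    pulse_effect: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy level series with a sustained fractional drop from the
    pandemic onset week and an optional window-localized pulse dip;
    returns (counts, noise-free level)."""
    t = np.arange(config.n_weeks)
    level = np.full(config.n_weeks, mean)
    start = config.drop_start_week
    if start is not None and drop_frac > 0:
        level[start - 1 :] = mean * (1.0 - drop_frac)
    if pulse_effect:
        level = level + pulse_effect * config.indicator()
    seasonal = config.seasonal_amplitude * np.sin(2 * np.pi * t / 52.18)
    noise = rng.normal(0.0, sd, config.n_weeks)
    counts = np.maximum(0.0, np.rint(level + seasonal + noise))
    return counts.astype(int), level + seasonal


def gen_control_series(config: SyntheticConfig, seed: int | None = None) -> tuple[WeeklySeries, dict]:
    """Control weekly counts plus a truth dict with the noise-free level."""
    seed = config.seed if seed is None else seed
    rng = _substream(seed, "control")
    counts, level = _level_series(
        config.control_mean,
        config.control_sd,
        config.shared_covid_drop,
        config,
        rng,
        "control",
        pulse_effect=config.control_pulse_effect,
    )
    series = WeeklySeries(config.anchor_date, tuple(counts), "control")
    return series, {"level": level, "seed": seed}


def gen_pair(config: SyntheticConfig, seed: int | None = None) -> tuple[SeriesPair, SyntheticTruth]:
    """Aligned dependent/control pair drawn from the transfer model.

    The intercept alpha is chosen so the pre-intervention expected
    dependent mean equals ``dependent_mean_target``.
    """
    seed = config.seed if seed is None else seed
    control, _ = gen_control_series(config, seed)
    control_counts = np.asarray(control.counts, dtype=float)

    rng_noise = _substream(seed, "noise")
    noise = simulate_subset_ar(config.phi, config.noise_sd, config.n_weeks, rng_noise)

    indicator = config.indicator()
    alpha = config.dependent_mean_target - config.beta_control * config.control_mean

    outlier_effect = np.zeros(config.n_weeks)
    for kind, week, magnitude in config.injected_outliers:
        outlier_effect += magnitude * outlier_regressor(kind, week, config.n_weeks, config.tc_delta)

    expected = alpha + config.beta_control * control_counts + config.omega * indicator + outlier_effect
    pre_round = expected + noise
    counts = np.maximum(0.0, np.rint(pre_round)).astype(int)

    dependent = WeeklySeries(config.anchor_date, tuple(counts), "dependent")
    pair = SeriesPair(dependent=dependent, control=control)
    truth = SyntheticTruth(
        alpha=alpha,
        beta_control=config.beta_control,
        omega=config.omega,
        phi=dict(config.phi),
        noise_sd=config.noise_sd,
        indicator=indicator,
        expected_dependent=expected,
        pre_round_dependent=pre_round,
        dependent_counts=counts,
        control_counts=control_counts.astype(int),
        injected_outliers=config.injected_outliers,
        seed=seed,
    )
    return pair, truth


# ---------------------------------------------------------------------------
# Encounter-level emission


def _sample_adult_demographics(rng: np.random.Generator, n: int):
    bands = rng.choice(len(AGE_BANDS), size=n, p=AGE_WEIGHTS)
    ages = np.array([rng.integers(AGE_BANDS[b][0], AGE_BANDS[b][1] + 1) for b in bands])
    sexes = rng.choice(SEX_LEVELS, size=n, p=SEX_WEIGHTS)
    return ages, sexes


def _emit_week_records(
    rng: np.random.Generator,
    week_start: date,
    n: int,
    ethnicity: str,
    payer: str,
) -> list[EncounterRecord]:
    if n == 0:
        return []
    offsets = rng.integers(0, 7, size=n)
    ages, sexes = _sample_adult_demographics(rng, n)
    return [
        EncounterRecord(
            visit_date=week_start + timedelta(days=int(o)),
            ethnicity=ethnicity,
            age_years=int(a),
            sex=str(s),
            payer=payer,
            disposition="treat_release",
        )
        for o, a, s in zip(offsets, ages, sexes)
    ]


def _emit_decoy(rng: np.random.Generator, visit_date: date) -> tuple[EncounterRecord, str]:
    kind = DECOY_KINDS[rng.integers(0, len(DECOY_KINDS))]
    age = int(rng.integers(18, 90))
    sex = str(rng.choice(SEX_LEVELS, p=SEX_WEIGHTS))
    payer = ("restricted_medical", "full_medical")[rng.integers(0, 2)]
    ethnicity, disposition = "latino", "treat_release"
    if kind == "minor":
        age = int(rng.integers(0, 18))
    elif kind == "unknown_ethnicity":
        ethnicity = "unknown"
    elif kind == "other_payer":
        payer = "other"
    else:  # inpatient
        disposition = "inpatient"
    rec = EncounterRecord(
        visit_date=visit_date,
        ethnicity=ethnicity,
        age_years=age,
        sex=sex,
        payer=payer,
        disposition=disposition,
    )
    return rec, f"decoy:{kind}"


def gen_encounter_records(
    config: SyntheticConfig,
    seed: int | None = None,
    decoy_fraction: float = 0.0,
    include_nonlatino: bool = False,
) -> tuple[list[EncounterRecord], SyntheticTruth]:
    """One record per counted visit, plus labelled decoys the filters
    must remove.

    Dependent-series visits carry restricted-scope Medi-Cal, control
    visits full-scope Medi-Cal, all Latino adults with treat-and-release
    dispositions; visit dates are uniform within each week.  With
    ``include_nonlatino`` a third, non-Latino Medi-Cal series is emitted
    for the alternate-pair sensitivity.  ``truth.record_roles`` labels
    every returned record (aligned by position) as ``dependent``,
    ``control``, ``nonlatino`` or ``decoy:<kind>``; binning the
    non-decoy records reproduces the weekly truth exactly.
    """
    if not 0.0 <= decoy_fraction < 1.0:
        raise ValueError("decoy_fraction must lie in [0, 1)")
    seed = config.seed if seed is None else seed
    pair, truth = gen_pair(config, seed)
    rng = _substream(seed, "records")

    tagged: list[tuple[EncounterRecord, str]] = []
    nonlatino_counts = None
    if include_nonlatino:
        rng_nl = _substream(seed, "nonlatino")
        nonlatino_counts, _ = _level_series(
            config.nonlatino_mean, config.nonlatino_sd, config.nonlatino_drop, config, rng_nl, "nonlatino"
        )

    for w in range(1, config.n_weeks + 1):
        week_start = config.anchor_date + timedelta(days=7 * (w - 1))
        for rec in _emit_week_records(
            rng, week_start, int(truth.dependent_counts[w - 1]), "latino", "restricted_medical"
        ):
            tagged.append((rec, "dependent"))
        for rec in _emit_week_records(
            rng, week_start, int(truth.control_counts[w - 1]), "latino", "full_medical"
        ):
            tagged.append((rec, "control"))
        if nonlatino_counts is not None:
            for rec in _emit_week_records(
                rng, week_start, int(nonlatino_counts[w - 1]), "non_latino", "full_medical"
            ):
                tagged.append((rec, "nonlatino"))

    if decoy_fraction > 0:
        rng_d = _substream(seed, "decoys")
        n_decoys = int(round(decoy_fraction * len(tagged)))
        span_days = 7 * config.n_weeks
        for _ in range(n_decoys):
            visit = config.anchor_date + timedelta(days=int(rng_d.integers(0, span_days)))
            tagged.append(_emit_decoy(rng_d, visit))

    tagged.sort(key=lambda pair_: pair_[0].visit_date)  # stable: ties keep emission order
    truth.nonlatino_counts = (
        np.asarray(nonlatino_counts, dtype=int) if nonlatino_counts is not None else None
    )
    truth.record_roles = [role for _, role in tagged]
    return [rec for rec, _ in tagged], truth


def config_to_dict(config: SyntheticConfig) -> dict:
    out = dataclasses.asdict(config)
    out["anchor_date"] = config.anchor_date.isoformat()
    if config.intervention is not None:
        out["intervention"] = {
            "kind": config.intervention.kind,
            "start_date": config.intervention.start_date.isoformat(),
            "series_length": config.intervention.series_length,
            "n_weeks": config.intervention.n_weeks,
        }
    out["phi"] = {str(k): v for k, v in config.phi.items()}
    out["injected_outliers"] = [list(o) for o in config.injected_outliers]
    return out
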