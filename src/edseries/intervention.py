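"""Intervention regressors and effect translation.

The exposure of interest is a known calendar event (the first stay-at-home
orders).  It enters the transfer-function model as a coded indicator:
either a *pulse* (1 during a fixed window of weeks, 0 elsewhere) or a
*step* (1 from the event week through the end of the series).  The fitted
intervention coefficient omega is translated into reader-facing summaries:
visits statistically avoided over the window and the percent shortfall
relative to the weekly mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np

from .ingest import require_friday, week_index_of

INTERVENTION_KINDS = ("pulse", "step")


@dataclass(frozen=True)
class InterventionSpec:
    """Coded indicator for a calendar-anchored intervention.

    ``start_date`` must be a Friday so the event opens a week.  For a
    pulse, ``n_weeks`` consecutive weeks are coded 1; a step is coded 1
    from the start week through ``series_length``.
    """

    kind: str
    start_date: date
    series_length: int
    n_weeks: int = 0

    def __post_init__(self) -> None:
        if self.kind not in INTERVENTION_KINDS:
            raise ValueError(f"kind must be one of {INTERVENTION_KINDS}")
        require_friday(self.start_date)
        if self.series_length < 1:
            raise ValueError("series_length must be positive")
        if self.kind == "pulse" and self.n_weeks < 0:
            raise ValueError("n_weeks must be non-negative for a pulse")


def make_indicator(spec: InterventionSpec, anchor_date: date) -> np.ndarray:
    """Binary intervention vector of length ``spec.series_length``.

    Pulse: ones at week indices [start_week, start_week + n_weeks).
    Step: ones from start_week through the series end.
    """
    start_week = week_index_of(spec.start_date, anchor_date)
    t = spec.series_length
    if start_week > t:
        raise ValueError(f"intervention start week {start_week} exceeds series length {t}")
    vec = np.zeros(t)
    if spec.kind == "pulse":
        if spec.n_weeks == 0:
            return vec
        end_week = start_week + spec.n_weeks - 1
        if end_week > t:
            raise ValueError(
                f"pulse window weeks {start_week}..{end_week} exceeds series length {t}"
            )
        vec[start_week - 1 : end_week] = 1.0
    else:
        vec[start_week - 1 :] = 1.0
    return vec


@dataclass(frozen=True)
class EffectSummary:
    """Reader-facing translation of an intervention coefficient.

    ``avoided_visits`` is |omega| times the window duration in weeks;
    ``pct_below_expected`` expresses |omega| relative to the series'
    weekly mean.  Rounded display values accompany the raw ones.
    """

    omega: float
    duration_weeks: int
    weekly_mean: float
    avoided_visits: float
    pct_below_expected: float

    @property
    def avoided_visits_rounded(self) -> int:
        return int(round(self.avoided_visits))

    @property
    def pct_below_expected_rounded(self) -> float:
        return round(self.pct_below_expected, 2)

    def to_dict(self) -> dict:
        return {
            "omega": self.omega,
            "duration_weeks": self.duration_weeks,
            "weekly_mean": self.weekly_mean,
            "avoided_visits": self.avoided_visits,
            "avoided_visits_rounded": self.avoided_visits_rounded,
            "pct_below_expected": self.pct_below_expected,
            "pct_below_expected_rounded": self.pct_below_expected_rounded,
        }


def effect_summary(omega: float, duration_weeks: int, weekly_mean: float) -> EffectSummary:
    """Translate a fitted intervention coefficient into avoided visits and
    a percent shortfall below expected levels."""
    if weekly_mean <= 0:
        raise ValueError("weekly_mean must be positive")
    if duration_weeks < 0:
        raise ValueError("duration_weeks must be non-negative")
    return EffectSummary(
        omega=omega,
        duration_weeks=duration_weeks,
        weekly_mean=weekly_mean,
        avoided_visits=abs(omega) * duration_weeks,
        pct_below_expected=100.0 * abs(omega) / weekly_mean,
    )


def magnitude_change(initial_omega: float, adjusted_omega: float) -> float:
    """Percent change in coefficient magnitude between two model fits,
    e.g. before and after outlier adjustment."""
    if initial_omega == 0:
        raise ValueError("initial_omega must be non-zero")
    return 100.0 * (abs(adjusted_omega) - abs(initial_omega)) / abs(initial_omega)
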