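"""Encounter-level ingestion and Friday-anchored weekly binning.

Emergency-department encounter records arrive as one row per visit.  The
analysis operates on weekly counts, where a "week" is a 7-day period running
Friday through Thursday so that the Friday on which a policy shock lands
opens a fresh bin.  This module reads encounter CSVs, applies the cohort
inclusion filters (adult, self-reported Latino, Medi-Cal payer, treat-and-
release disposition), and aggregates to aligned weekly count series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("edseries")

ETHNICITIES = ("latino", "non_latino", "unknown")
SEXES = ("female", "male", "unknown")
PAYERS = ("restricted_medical", "full_medical", "other")
DISPOSITIONS = ("treat_release", "inpatient")

#: Friday in ``datetime.date.weekday()`` numbering (Monday == 0).
FRIDAY = 4

ENCOUNTER_COLUMNS = [
    "visit_date",
    "ethnicity",
    "age_years",
    "sex",
    "payer",
    "disposition",
]

WEEKLY_COLUMNS = [
    "week_index",
    "week_start_date",
    "count_dependent",
    "count_control",
]


@dataclass(frozen=True)
class EncounterRecord:
    """A single de-identified ED visit."""

    visit_date: date
    ethnicity: str
    age_years: int
    sex: str
    payer: str
    disposition: str

    def __post_init__(self) -> None:
        if not isinstance(self.visit_date, date):
            raise TypeError(f"visit_date must be a datetime.date, got {self.visit_date!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.payer not in PAYERS:
            raise ValueError(f"unknown payer {self.payer!r}")
        if self.disposition not in DISPOSITIONS:
            raise ValueError(f"unknown disposition {self.disposition!r}")


@dataclass(frozen=True)
class FilterSpec:
    """Cohort inclusion criteria applied before weekly aggregation.

    Defaults reproduce the primary analytic sample: adults (18+) of
    self-reported Latino ethnicity, insured by restricted-scope or
    full-scope Medi-Cal, with a treat-and-release ED disposition.  The
    inpatient sensitivity analysis widens ``dispositions_keep``.
    """

    min_age: int = 18
    ethnicity_keep: frozenset[str] = frozenset({"latino"})
    payer_keep: frozenset[str] = frozenset({"restricted_medical", "full_medical"})
    dispositions_keep: frozenset[str] = frozenset({"treat_release"})

    def __post_init__(self) -> None:
        for name in ("ethnicity_keep", "payer_keep", "dispositions_keep"):
            value = getattr(self, name)
            if not value:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, frozenset(value))

    def with_inpatient(self) -> "FilterSpec":
        """Variant that also keeps visits ending in a hospital stay."""
        return replace(self, dispositions_keep=frozenset({"treat_release", "inpatient"}))


@dataclass(frozen=True)
class WeeklySeries:
    """Friday-anchored weekly counts; week ``w`` covers days
    ``[anchor + 7(w-1), anchor + 7w)`` and indices are 1-based."""

    anchor_date: date
    counts: tuple[int, ...]
    group_label: str = ""

    def __post_init__(self) -> None:
        require_friday(self.anchor_date)
        counts = tuple(int(c) for c in self.counts)
        if len(counts) < 1:
            raise ValueError("series must contain at least one week")
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    def week_start(self, week_index: int) -> date:
        if not 1 <= week_index <= len(self):
            raise IndexError(f"week {week_index} outside 1..{len(self)}")
        return self.anchor_date + timedelta(days=7 * (week_index - 1))


@dataclass(frozen=True)
class SeriesPair:
    """Aligned dependent and control weekly series."""

    dependent: WeeklySeries
    control: WeeklySeries

    def __post_init__(self) -> None:
        if self.dependent.anchor_date != self.control.anchor_date:
            raise ValueError("dependent and control series must share an anchor date")
        if len(self.dependent) != len(self.control):
            raise ValueError("dependent and control series must have equal length")

    def __len__(self) -> int:
        return len(self.dependent)

    @property
    def anchor_date(self) -> date:
        return self.dependent.anchor_date


def require_friday(d: date) -> None:
    if d.weekday() != FRIDAY:
        raise ValueError(f"{d.isoformat()} is not a Friday")


def week_index_of(d: date, anchor_date: date) -> int:
    """1-based index of the Friday-to-Thursday week containing ``d``.

    Week 1 starts on ``anchor_date`` (which must be a Friday); a date
    ``k`` days after the anchor lands in week ``1 + k // 7``.
    """
    require_friday(anchor_date)
    if d < anchor_date:
        raise ValueError(f"{d.isoformat()} precedes the anchor {anchor_date.isoformat()}")
    return 1 + (d - anchor_date).days // 7


def span_weeks(start_date: date, end_date: date) -> int:
    """Number of whole Friday-to-Thursday weeks from ``start_date`` through
    ``end_date`` inclusive.  The span must divide evenly into weeks."""
    require_friday(start_date)
    if end_date <= start_date:
        raise ValueError("end_date must follow start_date")
    if end_date.weekday() != 3:  # Thursday
        raise ValueError(f"{end_date.isoformat()} is not a Thursday")
    days = (end_date - start_date).days + 1
    if days % 7:
        raise ValueError(f"span of {days} days is not a whole number of weeks")
    return days // 7


def filter_encounters(
    records: Sequence[EncounterRecord], spec: FilterSpec
) -> tuple[list[EncounterRecord], dict[str, int]]:
    """Apply the cohort filters, preserving order.

    Returns the surviving records and a tally of removals per criterion.
    A record failing several criteria is charged to the first failing one,
    in the order age, ethnicity, payer, disposition.
    """
    if not records:
        raise ValueError("records must be non-empty")
    kept: list[EncounterRecord] = []
    removed = {"age": 0, "ethnicity": 0, "payer": 0, "disposition": 0}
    for rec in records:
        if rec.age_years < spec.min_age:
            removed["age"] += 1
        elif rec.ethnicity not in spec.ethnicity_keep:
            removed["ethnicity"] += 1
        elif rec.payer not in spec.payer_keep:
            removed["payer"] += 1
        elif rec.disposition not in spec.dispositions_keep:
            removed["disposition"] += 1
        else:
            kept.append(rec)
    if not kept:
        logger.warning("filter_encounters removed every record (%s)", removed)
    return kept, removed


def bin_weekly(
    records: Iterable[EncounterRecord],
    anchor_date: date,
    n_weeks: int,
    group_label: str = "",
    zero_week_floor: int = 0,
) -> WeeklySeries:
    """Aggregate records into ``n_weeks`` Friday-anchored bins.

    Every record must fall inside ``[anchor, anchor + 7*n_weeks)``.  Weeks
    with no records get a zero count; an interior zero flanked by weeks above
    ``zero_week_floor`` is logged as a possible gap (real series have none).
    """
    require_friday(anchor_date)
    if n_weeks < 1:
        raise ValueError("n_weeks must be positive")
    end = anchor_date + timedelta(days=7 * n_weeks)
    counts = [0] * n_weeks
    for rec in records:
        if not anchor_date <= rec.visit_date < end:
            raise ValueError(
                f"record dated {rec.visit_date.isoformat()} outside the span "
                f"[{anchor_date.isoformat()}, {end.isoformat()})"
            )
        counts[week_index_of(rec.visit_date, anchor_date) - 1] += 1
    if zero_week_floor > 0:
        for w in range(1, n_weeks - 1):
            if counts[w] == 0 and min(counts[w - 1], counts[w + 1]) > zero_week_floor:
                logger.warning("week %d has zero count between busy neighbours", w + 1)
    return WeeklySeries(anchor_date=anchor_date, counts=tuple(counts), group_label=group_label)


# ---------------------------------------------------------------------------
# CSV dialects


def records_to_frame(records: Sequence[EncounterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "visit_date": [r.visit_date.isoformat() for r in records],
            "ethnicity": [r.ethnicity for r in records],
            "age_years": [r.age_years for r in records],
            "sex": [r.sex for r in records],
            "payer": [r.payer for r in records],
            "disposition": [r.disposition for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[EncounterRecord]:
    missing = [c for c in ENCOUNTER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"encounter table missing columns: {missing}")
    dates = pd.to_datetime(frame["visit_date"], format="ISO8601").dt.date
    return [
        EncounterRecord(
            visit_date=d,
            ethnicity=e,
            age_years=int(a),
            sex=s,
            payer=p,
            disposition=disp,
        )
        for d, e, a, s, p, disp in zip(
            dates,
            frame["ethnicity"],
            frame["age_years"],
            frame["sex"],
            frame["payer"],
            frame["disposition"],
        )
    ]


def read_encounters_csv(path) -> list[EncounterRecord]:
    return frame_to_records(pd.read_csv(path))


def write_encounters_csv(records: Sequence[EncounterRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def pair_to_frame(pair: SeriesPair) -> pd.DataFrame:
    t = len(pair)
    return pd.DataFrame(
        {
            "week_index": np.arange(1, t + 1),
            "week_start_date": [pair.dependent.week_start(w).isoformat() for w in range(1, t + 1)],
            "count_dependent": list(pair.dependent.counts),
            "count_control": list(pair.control.counts),
        }
    )


def frame_to_pair(
    frame: pd.DataFrame, dependent_label: str = "dependent", control_label: str = "control"
) -> SeriesPair:
    missing = [c for c in WEEKLY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"weekly table missing columns: {missing}")
    frame = frame.sort_values("week_index")
    idx = frame["week_index"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(frame) + 1)):
        raise ValueError("week_index must run 1..T without gaps")
    anchor = date.fromisoformat(str(frame["week_start_date"].iloc[0]))
    dep = WeeklySeries(anchor, tuple(frame["count_dependent"]), dependent_label)
    ctl = WeeklySeries(anchor, tuple(frame["count_control"]), control_label)
    return SeriesPair(dependent=dep, control=ctl)


def read_pair_csv(path) -> SeriesPair:
    return frame_to_pair(pd.read_csv(path))


def write_pair_csv(pair: SeriesPair, path) -> None:
    pair_to_frame(pair).to_csv(path, index=False)
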