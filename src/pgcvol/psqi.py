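"""Pittsburgh Sleep Quality Index (PSQI) component scoring.

The PSQI folds 19 self-rated items into seven component scores, each an
integer 0-3: subjective quality, latency, duration, habitual efficiency,
disturbances, use of sleep medication, and daytime dysfunction.  The total
is their sum (0-21, higher = worse); a total of 6 or more classifies the
respondent as a poor sleeper.

Banding rules implemented here are the instrument's standard ones:

* latency minutes: <=15 -> 0, 16-30 -> 1, 31-60 -> 2, >60 -> 3; added to
  the "could not fall asleep within 30 minutes" frequency and rebanded
  0 -> 0, 1-2 -> 1, 3-4 -> 2, 5-6 -> 3;
* duration (hours actually slept): >=7 -> 0, 6-<7 -> 1, 5-<6 -> 2, <5 -> 3;
* efficiency = hours slept / hours in bed x 100, with hours in bed taken
  from bed and rise times across midnight: >=85% -> 0, 75-84 -> 1,
  65-74 -> 2, <65 -> 3;
* disturbances: the nine frequency items (0-3 each) summed and banded
  0 -> 0, 1-9 -> 1, 10-18 -> 2, 19-27 -> 3;
* daytime dysfunction: the two ratings summed and banded 0 -> 0,
  1-2 -> 1, 3-4 -> 2, 5-6 -> 3.

Missing items are errors, not imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import pandas as pd

__all__ = [
    "PSQIResponses",
    "PSQIRecord",
    "POOR_SLEEP_CUTOFF",
    "COMPONENT_NAMES",
    "score_components",
    "total_and_class",
    "score_record",
    "score_table",
    "worst_case_responses",
    "best_case_responses",
]

POOR_SLEEP_CUTOFF = 6

COMPONENT_NAMES = (
    "quality",
    "latency",
    "duration",
    "efficiency",
    "disturbances",
    "medication",
    "daytime_dysfunction",
)

#: items scored on a 0-3 frequency/severity scale
_FREQ_ITEMS = (
    "trouble_falling_asleep",
    "wake_during_night",
    "bathroom",
    "cannot_breathe",
    "cough_snore",
    "too_cold",
    "too_hot",
    "bad_dreams",
    "pain",
    "other_disturbance",
    "subjective_quality",
    "sleep_medication",
    "trouble_staying_awake",
    "low_enthusiasm",
)

_DISTURBANCE_ITEMS = (
    "wake_during_night",
    "bathroom",
    "cannot_breathe",
    "cough_snore",
    "too_cold",
    "too_hot",
    "bad_dreams",
    "pain",
    "other_disturbance",
)


@dataclass
class PSQIResponses:
    """The 19 self-rated PSQI item responses for one participant.

    Clock times may be given as ``"HH:MM"`` strings or as hours since
    midnight (float in [0, 24)).  All frequency/severity items use the
    instrument's 0-3 scale (0 = not during the past month / very good,
    3 = three or more times a week / very bad).
    """

    bedtime: float | str
    sleep_latency_min: float
    waketime: float | str
    sleep_hours: float
    trouble_falling_asleep: int  # could not fall asleep within 30 min
    wake_during_night: int
    bathroom: int
    cannot_breathe: int
    cough_snore: int
    too_cold: int
    too_hot: int
    bad_dreams: int
    pain: int
    other_disturbance: int
    subjective_quality: int
    sleep_medication: int
    trouble_staying_awake: int
    low_enthusiasm: int


@dataclass
class PSQIRecord:
    """Scored PSQI: seven components, total, and the poor-sleep class."""

    components: tuple[int, ...]
    total: int
    poor: bool


def _parse_clock(value: float | str, item: str) -> float:
    """Clock time -> hours since midnight, in [0, 24)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"missing item: {item}")
    if isinstance(value, str):
        parts = value.strip().split(":")
        if len(parts) != 2:
            raise ValueError(f"item {item}: cannot parse clock time {value!r}")
        hours, minutes = int(parts[0]), int(parts[1])
        if not (0 <= hours < 24 and 0 <= minutes < 60):
            raise ValueError(f"item {item}: clock time {value!r} out of range")
        return hours + minutes / 60.0
    value = float(value)
    if not 0 <= value < 24:
        raise ValueError(f"item {item}: hours since midnight must be in [0, 24)")
    return value


def _check_freq(value, item: str) -> int:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"missing item: {item}")
    iv = int(value)
    if iv != value or iv not in (0, 1, 2, 3):
        raise ValueError(f"item {item}: expected a 0-3 rating, got {value!r}")
    return iv


def _check_nonneg(value, item: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"missing item: {item}")
    fv = float(value)
    if fv < 0:
        raise ValueError(f"item {item}: must be non-negative, got {value!r}")
    return fv


def _band(value: float, edges: tuple[float, ...]) -> int:
    """Score 0..3 by counting how many ascending band edges value exceeds."""
    score = 0
    for edge in edges:
        if value > edge:
            score += 1
    return score


def hours_in_bed(bedtime: float | str, waketime: float | str) -> float:
    """Time in bed in hours, wrapping across midnight; must be positive."""
    bed = _parse_clock(bedtime, "bedtime")
    wake = _parse_clock(waketime, "waketime")
    span = (wake - bed) % 24.0
    if span <= 0:
        raise ValueError("hours in bed must be positive (bed and rise times equal)")
    return span


def score_components(resp: PSQIResponses) -> tuple[int, ...]:
    """Score the seven PSQI components (each 0-3) from item responses.

    Order: quality, latency, duration, efficiency, disturbances,
    medication, daytime dysfunction.
    """
    freq = {item: _check_freq(getattr(resp, item), item) for item in _FREQ_ITEMS}
    latency_min = _check_nonneg(resp.sleep_latency_min, "sleep_latency_min")
    sleep_hours = _check_nonneg(resp.sleep_hours, "sleep_hours")

    quality = freq["subjective_quality"]

    latency_band = _band(latency_min, (15, 30, 60))
    latency_sum = latency_band + freq["trouble_falling_asleep"]
    latency = _band(latency_sum, (0, 2, 4))

    if sleep_hours >= 7:
        duration = 0
    elif sleep_hours >= 6:
        duration = 1
    elif sleep_hours >= 5:
        duration = 2
    else:
        duration = 3

    in_bed = hours_in_bed(resp.bedtime, resp.waketime)
    efficiency_pct = sleep_hours / in_bed * 100.0
    if efficiency_pct >= 85:
        efficiency = 0
    elif efficiency_pct >= 75:
        efficiency = 1
    elif efficiency_pct >= 65:
        efficiency = 2
    else:
        efficiency = 3

    dist_sum = sum(freq[item] for item in _DISTURBANCE_ITEMS)
    disturbances = _band(dist_sum, (0, 9, 18))

    medication = freq["sleep_medication"]

    day_sum = freq["trouble_staying_awake"] + freq["low_enthusiasm"]
    daytime = _band(day_sum, (0, 2, 4))

    return (quality, latency, duration, efficiency, disturbances, medication, daytime)


def total_and_class(components) -> tuple[int, bool]:
    """Sum the seven component scores and apply the >= 6 poor-sleep cutoff."""
    components = tuple(int(c) for c in components)
    if len(components) != 7:
        raise ValueError(f"expected 7 component scores, got {len(components)}")
    for i, c in enumerate(components):
        if c not in (0, 1, 2, 3):
            raise ValueError(f"component {COMPONENT_NAMES[i]} out of range: {c}")
    total = sum(components)
    return total, total >= POOR_SLEEP_CUTOFF


def score_record(resp: PSQIResponses) -> PSQIRecord:
    """Score one respondent end to end."""
    components = score_components(resp)
    total, poor = total_and_class(components)
    return PSQIRecord(components=components, total=total, poor=poor)


#: expected CSV column names, one per item
ITEM_COLUMNS = tuple(f.name for f in fields(PSQIResponses))


def score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Score a table with one row per participant.

    Requires the columns in :data:`ITEM_COLUMNS`; returns a copy with
    ``component_1`` .. ``component_7``, ``psqi_total`` and ``psqi_poor``
    appended.
    """
    missing = [c for c in ITEM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing item columns: {', '.join(missing)}")
    out = table.copy()
    scored = [
        score_record(PSQIResponses(**{c: row[c] for c in ITEM_COLUMNS}))
        for _, row in table.iterrows()
    ]
    for i in range(7):
        out[f"component_{i + 1}"] = [r.components[i] for r in scored]
    out["psqi_total"] = [r.total for r in scored]
    out["psqi_poor"] = [r.poor for r in scored]
    return out


def best_case_responses() -> PSQIResponses:
    """A respondent with perfect sleep: every component scores 0."""
    return PSQIResponses(
        bedtime="23:00", sleep_latency_min=5, waketime="07:00", sleep_hours=7.5,
        trouble_falling_asleep=0, wake_during_night=0, bathroom=0,
        cannot_breathe=0, cough_snore=0, too_cold=0, too_hot=0, bad_dreams=0,
        pain=0, other_disturbance=0, subjective_quality=0, sleep_medication=0,
        trouble_staying_awake=0, low_enthusiasm=0,
    )


def worst_case_responses() -> PSQIResponses:
    """A respondent at the instrument's ceiling: every component scores 3."""
    return PSQIResponses(
        bedtime="22:00", sleep_latency_min=120, waketime="08:00", sleep_hours=3.0,
        trouble_falling_asleep=3, wake_during_night=3, bathroom=3,
        cannot_breathe=3, cough_snore=3, too_cold=3, too_hot=3, bad_dreams=3,
        pain=3, other_disturbance=3, subjective_quality=3, sleep_medication=3,
        trouble_staying_awake=3, low_enthusiasm=3,
    )
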