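"""Tumor-volume response classification for PDX clinical trials (PCTs).

A PCT treats several mice per patient-derived model per arm and scores each
*case* (the averaged behaviour of the replicate treated mice) through up to two
rounds of drug exposure.  Round-1 percent volume change at the evaluation day
assigns a modified-RECIST category (mCR/mPR/mSD/mPD); relapse during a
monitoring window triggers a second round whose category separates acquired
resistance from the reversible drug-tolerant persister (DTP) phenotype.

Volumes follow the caliper formula TV = 0.5 * width^2 * length with the shorter
axis taken as width.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

__all__ = [
    "CATEGORIES",
    "OUTCOMES",
    "ResponseCutoffs",
    "VolumeMeasurement",
    "MouseSeries",
    "CaseRecord",
    "CaseCall",
    "RelapseCall",
    "CohortSummary",
    "Round2MissingError",
    "tumor_volume",
    "percent_change",
    "classify_round",
    "detect_relapse",
    "classify_case",
    "cohort_summary",
    "clamp_waterfall",
]

#: Ordered response categories, best to worst.
CATEGORIES = ("mCR", "mPR", "mSD", "mPD")

#: Case-level outcome labels.
OUTCOMES = (
    "sensitive",
    "intrinsic_resistance",
    "acquired_resistance",
    "dtp",
    "individual_differences",
    "unevaluable",
)


class Round2MissingError(ValueError):
    """A case relapsed but carries no second treatment round."""


@dataclass(frozen=True)
class ResponseCutoffs:
    """Thresholds governing category calls, relapse detection and waterfall caps.

    Percent-change cutoffs are the PCT convention: mCR at or below ``cr_max``,
    mPR at or below ``pr_max``, mSD strictly below ``sd_max``, mPD otherwise.
    Boundary ties resolve to the better (more responsive) category.
    """

    cr_max: float = -95.0
    pr_max: float = -50.0
    sd_max: float = 35.0
    evaluation_day: float = 21.0
    monitor_days: float = 90.0
    relapse_fraction: float = 0.73
    relapse_min_volume: float = 50.0
    waterfall_cap_hi: float = 200.0
    waterfall_cap_lo: float = -100.0
    day_tolerance: float = 3.5

    def __post_init__(self) -> None:
        if not (self.cr_max < self.pr_max < self.sd_max):
            raise ValueError("category cutoffs must satisfy cr_max < pr_max < sd_max")
        if not (self.waterfall_cap_lo < self.waterfall_cap_hi):
            raise ValueError("waterfall caps must be ordered")


def tumor_volume(width: float, length: float) -> float:
    """Caliper tumor volume in mm^3: 0.5 * width^2 * length.

    Axes are canonicalized so the shorter one is squared, making the formula
    symmetric in its arguments.
    """
    if width < 0 or length < 0:
        raise ValueError(f"caliper axes must be non-negative, got ({width}, {length})")
    w, l = sorted((width, length))
    return 0.5 * w * w * l


@dataclass(frozen=True)
class VolumeMeasurement:
    day: float
    width: float
    length: float

    @property
    def volume(self) -> float:
        return tumor_volume(self.width, self.length)


@dataclass
class MouseSeries:
    """One mouse's caliper series within a single arm and treatment round."""

    mouse_id: str
    arm: str  # "treatment" or "vehicle"
    round: int
    measurements: list[VolumeMeasurement] = field(default_factory=list)

    def days(self) -> list[float]:
        return [m.day for m in self.measurements]

    def volumes(self) -> list[float]:
        return [m.volume for m in self.measurements]


@dataclass
class CaseRecord:
    """All replicate series of one case plus flags."""

    case_id: str
    series: list[MouseSeries] = field(default_factory=list)
    early_termination: bool = False

    def treated(self, round: int) -> list[MouseSeries]:
        return [s for s in self.series if s.arm == "treatment" and s.round == round]


def _volume_at(days: Sequence[float], volumes: Sequence[float],
               at_day: float, tolerance: float) -> float:
    deltas = [abs(d - at_day) for d in days]
    best = min(range(len(days)), key=deltas.__getitem__)
    if deltas[best] > tolerance:
        raise ValueError(f"no measurement within {tolerance} days of day {at_day}")
    return volumes[best]


def percent_change(series: Sequence[VolumeMeasurement] | MouseSeries,
                   at_day: float, *, day_tolerance: float = 3.5) -> float:
    """Percent volume change at ``at_day`` relative to the day-0 baseline.

    Uses the measurement nearest the requested day (within a tolerance window);
    the result is uncapped.
    """
    if isinstance(series, MouseSeries):
        series = series.measurements
    if not series:
        raise ValueError("no evaluable baseline: empty series")
    days = [m.day for m in series]
    vols = [m.volume for m in series]
    v0 = _volume_at(days, vols, 0.0, day_tolerance)
    if v0 <= 0:
        raise ValueError("no evaluable baseline: baseline volume is zero")
    vt = _volume_at(days, vols, at_day, day_tolerance)
    return 100.0 * (vt - v0) / v0


def classify_round(pct: float, cutoffs: ResponseCutoffs = ResponseCutoffs()) -> str:
    """Map a percent volume change onto mCR/mPR/mSD/mPD."""
    if not math.isfinite(pct):
        raise ValueError(f"percent change must be finite, got {pct}")
    if pct <= cutoffs.cr_max:
        return "mCR"
    if pct <= cutoffs.pr_max:
        return "mPR"
    if pct < cutoffs.sd_max:
        return "mSD"
    return "mPD"


@dataclass(frozen=True)
class RelapseCall:
    relapse_day: Optional[float]
    nadir: Optional[float] = None
    nadir_day: Optional[float] = None
    insufficient_follow_up: bool = False

    def __bool__(self) -> bool:
        return self.relapse_day is not None


def detect_relapse(days: Sequence[float], volumes: Sequence[float],
                   cutoffs: ResponseCutoffs = ResponseCutoffs()) -> RelapseCall:
    """Find the first confirmed regrowth after the post-baseline nadir.

    Relapse at the first day where V >= nadir*(1+relapse_fraction) and
    V >= relapse_min_volume, confirmed by the next measurement also satisfying
    both conditions; only days up to ``monitor_days`` are considered.
    """
    pairs = sorted(zip(days, volumes))
    post = [(d, v) for d, v in pairs if d > 0]
    if len(post) < 2:
        return RelapseCall(None, insufficient_follow_up=True)
    nadir_day, nadir = min(post, key=lambda dv: dv[1])
    after = [(d, v) for d, v in post if d >= nadir_day]
    threshold = nadir * (1.0 + cutoffs.relapse_fraction)

    def hits(v: float) -> bool:
        return v >= threshold and v >= cutoffs.relapse_min_volume

    for idx, (d, v) in enumerate(after):
        if d > cutoffs.monitor_days:
            break
        if hits(v):
            if idx + 1 < len(after):
                if hits(after[idx + 1][1]):
                    return RelapseCall(d, nadir=nadir, nadir_day=nadir_day)
            else:
                # candidate on the final measurement: unconfirmed
                return RelapseCall(None, nadir=nadir, nadir_day=nadir_day,
                                   insufficient_follow_up=True)
    return RelapseCall(None, nadir=nadir, nadir_day=nadir_day)


def _mean_series(series_list: list[MouseSeries]) -> tuple[list[float], list[float]]:
    """Per-day mean volume across replicate mice (aligned by measurement day)."""
    acc: dict[float, list[float]] = {}
    for s in series_list:
        for m in s.measurements:
            acc.setdefault(m.day, []).append(m.volume)
    days = sorted(acc)
    return days, [sum(acc[d]) / len(acc[d]) for d in days]


@dataclass
class CaseCall:
    """Result of running one case through the two-round decision tree."""

    case_id: str
    outcome: str
    round1_pct: Optional[float] = None
    round1_category: Optional[str] = None
    per_mouse_round1: dict[str, float] = field(default_factory=dict)
    relapse_day: Optional[float] = None
    round2_pct: Optional[float] = None
    round2_category: Optional[str] = None
    flags: list[str] = field(default_factory=list)


def classify_case(case: CaseRecord,
                  cutoffs: ResponseCutoffs = ResponseCutoffs()) -> CaseCall:
    """Two-round decision tree assigning a case to its outcome group.

    Order of precedence: early termination -> unevaluable; replicate categories
    spanning non-adjacent classes -> individual_differences; round-1 mPD ->
    intrinsic_resistance; no relapse through the monitoring window -> sensitive;
    relapse -> round 2, where mPD -> acquired_resistance, mPR/mCR -> dtp and
    mSD is flagged indeterminate (the workflow does not define it).
    """
    call = CaseCall(case_id=case.case_id, outcome="unevaluable")
    if case.early_termination:
        call.flags.append("early_termination")
        return call

    r1 = case.treated(1)
    if not r1:
        raise ValueError(f"{case.case_id}: no round-1 treatment-arm series")
    per_mouse = {}
    for s in r1:
        per_mouse[s.mouse_id] = percent_change(
            s, cutoffs.evaluation_day, day_tolerance=cutoffs.day_tolerance)
    call.per_mouse_round1 = per_mouse
    call.round1_pct = sum(per_mouse.values()) / len(per_mouse)
    call.round1_category = classify_round(call.round1_pct, cutoffs)

    cat_idx = [CATEGORIES.index(classify_round(p, cutoffs)) for p in per_mouse.values()]
    if len(cat_idx) > 1 and max(cat_idx) - min(cat_idx) >= 2:
        call.outcome = "individual_differences"
        return call

    if call.round1_category == "mPD":
        call.outcome = "intrinsic_resistance"
        return call

    days, vols = _mean_series(r1)
    relapse = detect_relapse(days, vols, cutoffs)
    call.relapse_day = relapse.relapse_day
    if relapse.insufficient_follow_up:
        call.flags.append("insufficient_follow_up")
    if relapse.relapse_day is None:
        if max(days) < cutoffs.monitor_days:
            call.flags.append("follow_up_shorter_than_monitor_window")
        call.outcome = "sensitive"
        if call.round1_category in ("mPR", "mSD"):
            call.flags.append("non_relapsing_" + call.round1_category)
        return call

    r2 = case.treated(2)
    if not r2:
        raise Round2MissingError(
            f"{case.case_id}: relapse at day {relapse.relapse_day} but no round-2 data")
    pcts = [percent_change(s, cutoffs.evaluation_day,
                           day_tolerance=cutoffs.day_tolerance) for s in r2]
    call.round2_pct = sum(pcts) / len(pcts)
    call.round2_category = classify_round(call.round2_pct, cutoffs)
    if call.round2_category == "mPD":
        call.outcome = "acquired_resistance"
    elif call.round2_category in ("mPR", "mCR"):
        call.outcome = "dtp"
    else:
        call.outcome = "indeterminate"
        call.flags.append("round2_mSD_undefined")
    return call


def clamp_waterfall(pct: float, cutoffs: ResponseCutoffs = ResponseCutoffs()) -> float:
    """Clamp a percent change to the waterfall display caps."""
    return min(max(pct, cutoffs.waterfall_cap_lo), cutoffs.waterfall_cap_hi)


def _round_pct(x: float) -> float:
    return float(Decimal(x).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    n: int
    counts: dict[str, int]
    percentages: dict[str, float]
    waterfall: dict[str, float]


def cohort_summary(calls: Sequence[CaseCall],
                   cutoffs: ResponseCutoffs = ResponseCutoffs(),
                   counts: Optional[dict[str, int]] = None) -> CohortSummary:
    """Outcome counts, half-up 2-dp percentages and capped waterfall values.

    ``counts`` may be supplied directly (e.g. published tallies) in which case
    ``calls`` may be empty and the waterfall map is empty.
    """
    waterfall: dict[str, float] = {}
    if counts is None:
        if not calls:
            raise ValueError("empty cohort")
        counts = dict(Counter(c.outcome for c in calls))
        for c in calls:
            rep = c.round2_pct if c.round2_pct is not None else c.round1_pct
            if rep is not None:
                waterfall[c.case_id] = clamp_waterfall(rep, cutoffs)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty cohort")
    pct = {k: _round_pct(Decimal(100) * Decimal(v) / Decimal(n)) for k, v in counts.items()}
    return CohortSummary(n=n, counts=counts, percentages=pct, waterfall=waterfall)
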