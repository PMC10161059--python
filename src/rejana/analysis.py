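"""Event-based reject-rate computation.

The reject rate is defined per exposure-button press, not per image:
RR = N_rej / N_tot, where N_rej counts presses that produced no diagnostic
image and N_tot counts all presses.  Counting individual images instead
biases the rate whenever multi-acquisition exams (dual energy, image
pasting, tomosynthesis) are in the mix, because a single press then
contributes several images; :func:`compute_image_based_rate` implements the
image-count variant purely to demonstrate that bias.

Presses whose only rejections are practitioner-directed (category 8) or
non-patient/test exposures (category 9) are excluded from both numerator
and denominator by default, keeping RR interpretable as a measure of
technologist imaging performance.  Because the denominator treatment of
category 8 is a defensible policy choice, ``denominator_policy`` can
instead keep those presses in N_tot.

Rates are carried as exact rationals; rounding happens only at render time.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from .data_model import (AcquisitionRecord, AcquisitionType, EventStatus,
                         ExposureEvent, RecordPair, RejectInfo)
from .taxonomy import TaxonomyConfig, default_taxonomy, is_countable

#: Window for the fallback grouping of multi-acquisition records that lack
#: an irradiation-event UID (CR / digital-retrofit systems).
DEFAULT_GROUPING_WINDOW = _dt.timedelta(seconds=10)

STRATUM_KEYS = ("system", "operator", "protocol", "anatomy", "view",
                "acquisition_type", "reason_broad", "reason_detailed",
                "receptor_type", "month")


# ---------------------------------------------------------------------------
# Grouping acquisitions into exposure events

def group_into_events(pairs: Sequence[RecordPair],
                      window: _dt.timedelta = DEFAULT_GROUPING_WINDOW,
                      ) -> list[ExposureEvent]:
    """Group acquisition rows into exposure-button-press events.

    Rows sharing an irradiation-event UID form one event.  A single-exposure
    row without a UID becomes its own singleton event.  Multi-acquisition
    rows without a UID — typical of retrofit systems with no generator
    integration — are grouped heuristically: same system, same acquisition
    type, timestamps within ``window`` of the previous member; such events
    are flagged ``heuristic_grouping``.
    """
    events: dict[str, ExposureEvent] = {}
    order: list[str] = []
    anon_counter = 0
    # open heuristic groups keyed by (system, acquisition_type)
    open_groups: dict[tuple, ExposureEvent] = {}

    for record, reject in pairs:
        uid = record.irradiation_event_uid
        if uid is not None:
            ev = events.get(uid)
            if ev is None:
                ev = ExposureEvent(event_uid=uid)
                events[uid] = ev
                order.append(uid)
            ev.members.append((record, reject))
            continue

        if record.acquisition_type is None or \
                record.acquisition_type is AcquisitionType.SINGLE:
            anon_counter += 1
            uid = f"__singleton__{anon_counter}"
            events[uid] = ExposureEvent(event_uid=uid,
                                        members=[(record, reject)])
            order.append(uid)
            continue

        key = (record.system_identifier, record.acquisition_type)
        group = open_groups.get(key)
        if group is not None and _within_window(group, record, window):
            group.members.append((record, reject))
        else:
            anon_counter += 1
            uid = f"__heuristic__{anon_counter}"
            group = ExposureEvent(event_uid=uid, members=[(record, reject)],
                                  heuristic_grouping=True)
            events[uid] = group
            order.append(uid)
            open_groups[key] = group
    return [events[u] for u in order]


def _within_window(group: ExposureEvent, record: AcquisitionRecord,
                   window: _dt.timedelta) -> bool:
    last = group.members[-1][0].acquisition_datetime
    ts = record.acquisition_datetime
    if last is None or ts is None:
        return False
    if (last.tzinfo is None) != (ts.tzinfo is None):
        return False
    return abs(ts - last) <= window


# ---------------------------------------------------------------------------
# Event status

def event_reject_status(event: ExposureEvent,
                        taxonomy: Optional[TaxonomyConfig] = None,
                        ) -> EventStatus:
    """Status of one exposure event.

    DIAGNOSTIC if at least one member image survived review — the press
    produced a diagnostic image, however many siblings were discarded.
    Otherwise REJECTED if any member's reason is countable, else EXCLUDED
    (every rejection is practitioner-directed or a non-patient exposure).

    A rejected member with no broad reason cannot be statused and raises.
    """
    if not event.members:
        raise ValueError(f"event {event.event_uid} has no members")
    any_countable = False
    all_rejected = True
    for _, reject in event.members:
        if not reject.is_reject:
            all_rejected = False
            continue
        if reject.reason_broad is None:
            raise ValueError(
                f"rejected acquisition in event {event.event_uid} lacks a "
                "broad reject reason (required for analysis)")
        if is_countable(reject.reason_broad):
            any_countable = True
    if not all_rejected:
        return EventStatus.DIAGNOSTIC
    return EventStatus.REJECTED if any_countable else EventStatus.EXCLUDED


def assign_status(events: Iterable[ExposureEvent],
                  taxonomy: Optional[TaxonomyConfig] = None,
                  ) -> list[ExposureEvent]:
    """Set ``status`` on every event in place; returns the list."""
    out = list(events)
    for ev in out:
        ev.status = event_reject_status(ev, taxonomy)
    return out


# ---------------------------------------------------------------------------
# Reports

@dataclass(frozen=True)
class Thresholds:
    """Investigation thresholds on the reject rate, as percentages."""

    lower: Optional[float]
    target: float
    upper: float

    def __post_init__(self):
        if self.lower is not None and not self.lower < self.target:
            raise ValueError("thresholds must satisfy lower < target")
        if not self.target < self.upper:
            raise ValueError("thresholds must satisfy target < upper")


#: Community-recommended defaults: adult target 8% (investigate above 10%
#: or below 5%); pediatric target 5% (investigate above 7%, no lower bound).
ADULT_THRESHOLDS = Thresholds(lower=5.0, target=8.0, upper=10.0)
PEDIATRIC_THRESHOLDS = Thresholds(lower=None, target=5.0, upper=7.0)


class ThresholdFlag(str, Enum):
    BELOW_LOWER = "BELOW_LOWER"
    WITHIN = "WITHIN"
    ABOVE_UPPER = "ABOVE_UPPER"
    UNDEFINED = "UNDEFINED"


class Population(str, Enum):
    ADULT = "ADULT"
    PEDIATRIC = "PEDIATRIC"


DEFAULT_THRESHOLDS = {Population.ADULT: ADULT_THRESHOLDS,
                      Population.PEDIATRIC: PEDIATRIC_THRESHOLDS}


@dataclass
class RateRow:
    """Counts and the exact reject rate for one stratum (or overall)."""

    key: tuple[str, ...]
    n_total_events: int
    n_rejected_events: int
    n_excluded_events: int
    n_partially_rejected_events: int = 0
    threshold_flag: Optional[ThresholdFlag] = None

    @property
    def rate(self) -> Optional[Fraction]:
        if self.n_total_events == 0:
            return None
        return Fraction(self.n_rejected_events, self.n_total_events)


@dataclass
class RejectRateReport:
    strata_keys: tuple[str, ...]
    rows: list[RateRow]
    overall: RateRow
    population: Population = Population.ADULT
    thresholds: Thresholds = ADULT_THRESHOLDS
    denominator_policy: str = "exclude"
    n_heuristic_events: int = 0
    n_wrong_patient_rejects: int = 0


def flag_thresholds(rate: Optional[Fraction | float],
                    population: Population = Population.ADULT,
                    thresholds: Optional[Thresholds] = None) -> ThresholdFlag:
    """Flag a reject rate against investigation thresholds.

    ``rate`` is a fraction in [0, 1] (or None for undefined); thresholds are
    percentages.  Above the upper bound or below the lower bound both call
    for investigation — a too-low rate may mean rejects are being hidden.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS[population]
    if rate is None:
        return ThresholdFlag.UNDEFINED
    pct = Fraction(rate) * 100
    if pct > Fraction(thresholds.upper):
        return ThresholdFlag.ABOVE_UPPER
    if thresholds.lower is not None and pct < Fraction(thresholds.lower):
        return ThresholdFlag.BELOW_LOWER
    return ThresholdFlag.WITHIN


def _count(events: Iterable[ExposureEvent], key: tuple[str, ...] = (),
           denominator_policy: str = "exclude") -> RateRow:
    n_rej = n_diag = n_excl = n_partial = n_cat8 = 0
    for ev in events:
        if ev.status is None:
            raise ValueError("events must be statused before rate computation")
        if ev.status is EventStatus.REJECTED:
            n_rej += 1
        elif ev.status is EventStatus.DIAGNOSTIC:
            n_diag += 1
            if any(rj.is_reject for _, rj in ev.members):
                n_partial += 1
        else:
            n_excl += 1
            if any(rj.reason_broad == 8 for _, rj in ev.members):
                n_cat8 += 1
    n_tot = n_rej + n_diag
    if denominator_policy == "include-cat8":
        n_tot += n_cat8
        n_excl -= n_cat8
    elif denominator_policy != "exclude":
        raise ValueError(f"unknown denominator_policy {denominator_policy!r}")
    return RateRow(key=key, n_total_events=n_tot, n_rejected_events=n_rej,
                   n_excluded_events=n_excl,
                   n_partially_rejected_events=n_partial)


def compute_reject_rate(events: Sequence[ExposureEvent],
                        population: Population = Population.ADULT,
                        thresholds: Optional[Thresholds] = None,
                        denominator_policy: str = "exclude",
                        ) -> RejectRateReport:
    """Overall event-based reject rate: RR = N_rej / N_tot over
    exposure-button presses, excluded presses removed.

    With zero countable presses the rate is undefined (explicit None),
    never a division error.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS[population]
    overall = _count(events, (), denominator_policy)
    overall.threshold_flag = flag_thresholds(overall.rate, population,
                                             thresholds)
    return RejectRateReport(
        strata_keys=(), rows=[], overall=overall, population=population,
        thresholds=thresholds, denominator_policy=denominator_policy,
        n_heuristic_events=sum(1 for e in events if e.heuristic_grouping),
        n_wrong_patient_rejects=_count_wrong_patient(events),
    )


def _count_wrong_patient(events: Iterable[ExposureEvent]) -> int:
    # category-6 rejects are potential medical errors; surfaced separately
    return sum(1 for ev in events for _, rj in ev.members
               if rj.is_reject and rj.reason_broad == 6)


def compute_image_based_rate(events: Sequence[ExposureEvent],
                             ) -> Optional[Fraction]:
    """The *incorrect* image-count rate, for demonstrating its bias.

    Numerator: rejected member images of REJECTED events.  Denominator:
    all member images of non-EXCLUDED events.  Equals the event-based rate
    only when all non-excluded events share one multiplicity.
    """
    n_img_rej = 0
    n_img_tot = 0
    for ev in events:
        if ev.status is None:
            raise ValueError("events must be statused before rate computation")
        if ev.status is EventStatus.EXCLUDED:
            continue
        n_img_tot += ev.multiplicity
        if ev.status is EventStatus.REJECTED:
            n_img_rej += sum(1 for _, rj in ev.members if rj.is_reject)
    if n_img_tot == 0:
        return None
    return Fraction(n_img_rej, n_img_tot)


# ---------------------------------------------------------------------------
# Stratification

def _month_of(ev: ExposureEvent) -> Optional[str]:
    ts = ev.members[0][0].acquisition_datetime
    return None if ts is None else f"{ts.year:04d}-{ts.month:02d}"


def _event_reason(ev: ExposureEvent) -> tuple[Optional[int], Optional[str]]:
    """Reason attributed to a REJECTED event: that of the last-rejected
    member by reject time (the final rejection is why no diagnostic image
    resulted); ties break to the lexicographically smallest code."""
    best = None
    for _, rj in ev.members:
        if not rj.is_reject:
            continue
        ts = rj.reject_datetime or _dt.datetime.min.replace(
            tzinfo=_dt.timezone.utc)
        code = rj.reason_detailed or (str(rj.reason_broad)
                                      if rj.reason_broad else "")
        cand = (ts, code, rj.reason_broad, rj.reason_detailed)
        if best is None or cand[0] > best[0] or \
                (cand[0] == best[0] and cand[1] < best[1]):
            best = cand
    if best is None:
        return None, None
    return best[2], best[3]


def _stratum_value(ev: ExposureEvent, key: str) -> str:
    first = ev.members[0][0]
    if key == "system":
        v = first.system_identifier
    elif key == "operator":
        v = first.operator_id
    elif key == "protocol":
        v = first.protocol_id
    elif key == "anatomy":
        v = first.anatomy
    elif key == "view":
        v = first.view
    elif key == "acquisition_type":
        v = first.acquisition_type.value if first.acquisition_type else None
    elif key == "receptor_type":
        v = first.receptor_type.value if first.receptor_type else None
    elif key == "month":
        v = _month_of(ev)
    elif key == "reason_broad":
        v = None
        if ev.status is EventStatus.REJECTED:
            broad, _ = _event_reason(ev)
            v = str(broad) if broad is not None else None
    elif key == "reason_detailed":
        v = None
        if ev.status is EventStatus.REJECTED:
            _, det = _event_reason(ev)
            v = det
    else:
        raise KeyError(f"unknown stratification key {key!r}; "
                       f"valid keys: {', '.join(STRATUM_KEYS)}")
    return "" if v is None else v


def stratify(events: Sequence[ExposureEvent], by: Sequence[str],
             population: Population = Population.ADULT,
             thresholds: Optional[Thresholds] = None,
             denominator_policy: str = "exclude") -> RejectRateReport:
    """Reject rates broken down by one or more keys.

    Reason keys apply to REJECTED events only (a diagnostic press has no
    event-level reject reason); all other keys partition every event, so
    per-stratum counts add up to the overall counts.  Rows are ordered
    lexicographically by key for deterministic output.
    """
    by = tuple(by)
    for key in by:
        if key not in STRATUM_KEYS:
            raise KeyError(f"unknown stratification key {key!r}; "
                           f"valid keys: {', '.join(STRATUM_KEYS)}")
    report = compute_reject_rate(events, population, thresholds,
                                 denominator_policy)
    report.strata_keys = by
    if not by:
        return report

    reason_keys = {"reason_broad", "reason_detailed"}
    groups: dict[tuple[str, ...], list[ExposureEvent]] = {}
    for ev in events:
        if reason_keys & set(by) and ev.status is not EventStatus.REJECTED:
            continue
        key = tuple(_stratum_value(ev, k) for k in by)
        groups.setdefault(key, []).append(ev)
    for key in sorted(groups):
        row = _count(groups[key], key, denominator_policy)
        row.threshold_flag = flag_thresholds(row.rate, report.population,
                                             report.thresholds)
        report.rows.append(row)
    return report
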