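"""Rendering reject-rate reports and review worklists.

Output is deterministic — stable row ordering, RFC-4180 CSV with LF line
endings, fixed rounding — so two renders of the same report are
byte-identical and safe to diff across runs and sites.

Rates render as percentages with one decimal, except that a rate whose
exact value needs at most two decimals renders exactly (``8%``, ``11.25%``
rather than ``8.0%``, ``11.2%``).
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Optional, Sequence

from .data_model import EventStatus, ExposureEvent
from .analysis import RateRow, RejectRateReport

REPORT_SCHEMA = "rejana-report/1"
WORKLIST_SCHEMA = "rejana-worklist/1"


def format_percent(rate: Optional[Fraction]) -> str:
    """Render a rate in [0,1] as a percent string.

    Exact when the percentage has at most two decimals; otherwise rounded
    (half up) to one decimal.
    """
    if rate is None:
        return ""
    pct = Fraction(rate) * 100
    if 100 % pct.denominator == 0:
        # exact with <= 2 decimals; strip trailing zeros
        cents = pct * 100  # integral
        text = str(Decimal(int(cents)) / Decimal(100))
        if "." in text:
            text = text.rstrip("0").rstrip(".")
        return f"{text}%"
    d = (Decimal(pct.numerator) / Decimal(pct.denominator)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{d}%"


def _row_cells(row: RateRow) -> list[str]:
    return [str(row.n_total_events), str(row.n_rejected_events),
            str(row.n_excluded_events), format_percent(row.rate),
            row.threshold_flag.value if row.threshold_flag else ""]


def render_report(report: RejectRateReport, format: str = "csv",
                  redact: bool = False) -> str:
    """Render a report as a CSV or JSON document (deterministic)."""
    fmt = format.lower()
    if fmt == "csv":
        return _render_csv(report, redact)
    if fmt == "json":
        return _render_json(report, redact)
    raise ValueError(f"unknown report format {format!r}; use csv or json")


def _render_csv(report: RejectRateReport, redact: bool) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["# schema", REPORT_SCHEMA])
    w.writerow(["# population", report.population.value])
    th = report.thresholds
    w.writerow(["# thresholds_pct",
                "" if th.lower is None else f"{th.lower:g}",
                f"{th.target:g}", f"{th.upper:g}"])
    w.writerow(["# denominator_policy", report.denominator_policy])
    if redact:
        w.writerow(["# redacted", "true"])
    key_cols = list(report.strata_keys) or ["stratum"]
    w.writerow(key_cols + ["n_total_events", "n_rejected_events",
                           "n_excluded_events", "reject_rate",
                           "threshold_flag"])
    for row in report.rows:
        w.writerow(list(row.key) + _row_cells(row))
    overall_key = ["OVERALL"] + [""] * (len(key_cols) - 1)
    w.writerow(overall_key + _row_cells(report.overall))
    return buf.getvalue()


def _json_row(row: RateRow, keys: Sequence[str]) -> dict:
    rate = row.rate
    return {
        "key": dict(zip(keys, row.key)) if keys else {},
        "n_total_events": row.n_total_events,
        "n_rejected_events": row.n_rejected_events,
        "n_excluded_events": row.n_excluded_events,
        "n_partially_rejected_events": row.n_partially_rejected_events,
        "rate": None if rate is None else {
            "numerator": rate.numerator, "denominator": rate.denominator,
            "percent": format_percent(rate)},
        "threshold_flag": row.threshold_flag.value if row.threshold_flag
        else None,
    }


def _render_json(report: RejectRateReport, redact: bool) -> str:
    th = report.thresholds
    doc = {
        "schema": REPORT_SCHEMA,
        "population": report.population.value,
        "thresholds_pct": {"lower": th.lower, "target": th.target,
                           "upper": th.upper},
        "denominator_policy": report.denominator_policy,
        "redacted": redact,
        "strata_keys": list(report.strata_keys),
        "rows": [_json_row(r, report.strata_keys) for r in report.rows],
        "overall": _json_row(report.overall, report.strata_keys),
        "n_heuristic_events": report.n_heuristic_events,
        "n_wrong_patient_rejects": report.n_wrong_patient_rejects,
    }
    return json.dumps(doc, indent=2, sort_keys=False) + "\n"


# ---------------------------------------------------------------------------
# Review worklists

@dataclass(frozen=True)
class WorklistRow:
    event_uid: str
    accession_number: Optional[str]
    reason_broad: Optional[int]
    reason_detailed: Optional[str]
    rejected_image_refs: tuple[str, ...]
    operator_id: Optional[str]
    acquisition_datetime: Optional[_dt.datetime]
    reject_datetime: Optional[_dt.datetime]


@dataclass
class ReviewWorklist:
    rows: list[WorklistRow]

    def __len__(self):
        return len(self.rows)


def build_review_worklist(events: Sequence[ExposureEvent],
                          reason_broad: Optional[int] = None,
                          operator_id: Optional[str] = None,
                          start: Optional[_dt.datetime] = None,
                          end: Optional[_dt.datetime] = None,
                          include_excluded: bool = False) -> ReviewWorklist:
    """List rejected events for human review of their images and reasons.

    Filters are conjunctive; an omitted filter matches everything.  Rows are
    sorted by reject time (events without one sort first) then event UID.
    """
    from .analysis import _event_reason
    rows: list[WorklistRow] = []
    statuses = {EventStatus.REJECTED}
    if include_excluded:
        statuses.add(EventStatus.EXCLUDED)
    for ev in events:
        if ev.status not in statuses:
            continue
        broad, detailed = _event_reason(ev)
        rec = ev.members[0][0]
        reject_times = [rj.reject_datetime for _, rj in ev.members
                        if rj.is_reject and rj.reject_datetime is not None]
        last_reject = max(reject_times) if reject_times else None
        if reason_broad is not None and broad != reason_broad:
            continue
        if operator_id is not None and rec.operator_id != operator_id:
            continue
        if start is not None and (last_reject is None or last_reject < start):
            continue
        if end is not None and (last_reject is None or last_reject > end):
            continue
        refs = tuple(rj.rejected_image_ref for _, rj in ev.members
                     if rj.is_reject and rj.rejected_image_ref is not None)
        rows.append(WorklistRow(
            event_uid=ev.event_uid, accession_number=rec.accession_number,
            reason_broad=broad, reason_detailed=detailed,
            rejected_image_refs=refs, operator_id=rec.operator_id,
            acquisition_datetime=rec.acquisition_datetime,
            reject_datetime=last_reject))
    rows.sort(key=lambda r: (r.reject_datetime is not None,
                             r.reject_datetime or _dt.datetime.min,
                             r.event_uid))
    return ReviewWorklist(rows=rows)


def render_worklist(worklist: ReviewWorklist, redact: bool = False) -> str:
    """Render a worklist as deterministic CSV; ``redact`` drops the
    accession-number column (documented in the header)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["# schema", WORKLIST_SCHEMA])
    if redact:
        w.writerow(["# redacted", "true"])
    cols = ["event_uid", "reason_broad", "reason_detailed", "operator_id",
            "acquisition_datetime", "reject_datetime",
            "rejected_image_refs"]
    if not redact:
        cols.insert(1, "accession_number")
    w.writerow(cols)
    for r in worklist.rows:
        cells = [r.event_uid,
                 "" if r.reason_broad is None else str(r.reason_broad),
                 r.reason_detailed or "", r.operator_id or "",
                 r.acquisition_datetime.isoformat()
                 if r.acquisition_datetime else "",
                 r.reject_datetime.isoformat() if r.reject_datetime else "",
                 ";".join(r.rejected_image_refs)]
        if not redact:
            cells.insert(1, r.accession_number or "")
        w.writerow(cells)
    return buf.getvalue()
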