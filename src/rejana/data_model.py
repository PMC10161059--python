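"""Canonical record types for radiography reject analysis.

One :class:`AcquisitionRecord` describes a single raw x-ray image
acquisition (one detector readout); a :class:`RejectInfo` carries the
reject designation attached to it; an :class:`ExposureEvent` groups all
acquisitions produced by a single continuous actuation of the exposure
button — the unit in which reject rates are counted.

Validation never raises: :func:`validate_record` returns a report listing
errors (violated invariants) and warnings (missing lower-priority fields,
suspicious values) and leaves the record untouched.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, fields as _dc_fields
from enum import Enum
from typing import Any, Iterable, Mapping, Optional, Sequence


class AcquisitionType(str, Enum):
    """Whether an acquisition stands alone or is one of several raw images
    produced by a single exposure-button press."""

    SINGLE = "SINGLE"
    DUAL_ENERGY = "DUAL_ENERGY"
    IMAGE_PASTING = "IMAGE_PASTING"
    TOMOSYNTHESIS = "TOMOSYNTHESIS"
    OTHER_MULTI = "OTHER_MULTI"

    @property
    def is_multi(self) -> bool:
        return self is not AcquisitionType.SINGLE


class GridUse(str, Enum):
    IN = "IN"
    NONE = "NONE"
    UNKNOWN = "UNKNOWN"


class ReceptorType(str, Enum):
    WALL_STAND = "WALL_STAND"
    TABLE = "TABLE"
    FREE_DETECTOR = "FREE_DETECTOR"
    UNKNOWN = "UNKNOWN"


class EventStatus(str, Enum):
    """Reject status of an exposure event (see analysis.event_reject_status)."""

    DIAGNOSTIC = "DIAGNOSTIC"
    REJECTED = "REJECTED"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class Collimation:
    """Collimator shape plus edge/vertex coordinates.

    ``shape`` discriminates how ``coordinates`` are read (e.g. RECTANGULAR
    edges, POLYGONAL vertex pairs).  Shapes the toolkit does not recognise
    are preserved opaquely in ``opaque``.
    """

    shape: str = ""
    coordinates: tuple[float, ...] = ()
    opaque: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(
            {"shape": self.shape, "coordinates": list(self.coordinates),
             "opaque": self.opaque},
            separators=(",", ":"), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Collimation":
        d = json.loads(text)
        return cls(shape=d.get("shape", ""),
                   coordinates=tuple(float(c) for c in d.get("coordinates", [])),
                   opaque=d.get("opaque"))


@dataclass
class AcquisitionRecord:
    """One x-ray image acquisition with every element reject analysis needs.

    Only four elements are unconditionally required: the system identifier,
    the acquisition timestamp, the irradiation-event (exposure-button-press)
    UID and the acquisition type.  Everything else is optional at ingest and
    reported as a warning when absent, graded by analysis priority.

    Tube charge is stored exclusively in microampere-seconds (``micro_as``);
    mAs values lack the precision needed for technique review and are
    converted on ingest.
    """

    system_identifier: Optional[str] = None
    operator_id: Optional[str] = None
    acquisition_datetime: Optional[_dt.datetime] = None
    processing_datetime: Optional[_dt.datetime] = None
    patient_mrn: Optional[str] = None
    accession_number: Optional[str] = None
    anatomy: Optional[str] = None
    protocol_id: Optional[str] = None
    view: Optional[str] = None
    patient_size_selection: Optional[str] = None
    acquisition_type: Optional[AcquisitionType] = None
    irradiation_event_uid: Optional[str] = None
    kvp: Optional[float] = None
    micro_as: Optional[float] = None
    exposure_time: Optional[float] = None  # milliseconds
    ma: Optional[float] = None
    filter_material: Optional[str] = None
    filter_thickness_min: Optional[float] = None
    filter_thickness_max: Optional[float] = None
    filter_type: Optional[str] = None
    grid_use: Optional[GridUse] = None
    sid: Optional[float] = None  # millimeters
    receptor_type: Optional[ReceptorType] = None
    aec_status: Optional[str] = None
    aec_cells: Optional[str] = None
    aec_density: Optional[float] = None
    exposure_index: Optional[float] = None
    target_ei: Optional[float] = None
    deviation_index: Optional[float] = None
    detector_id: Optional[str] = None
    collimation: Optional[Collimation] = None
    dap: Optional[float] = None  # Gy·cm²
    processing_params: Optional[dict[str, str]] = None


@dataclass
class RejectInfo:
    """Reject designation for one acquisition.

    For a non-reject every other field must be absent.  For a reject the
    timestamp is required and the broad reason is required for analysis;
    the detailed code, when given, must belong to the broad category in
    the active taxonomy.
    """

    is_reject: bool = False
    reason_broad: Optional[int] = None
    reason_detailed: Optional[str] = None
    reject_datetime: Optional[_dt.datetime] = None
    rejected_image_ref: Optional[str] = None


#: (record, reject) pair — one exposure-log row.
RecordPair = tuple[AcquisitionRecord, RejectInfo]


@dataclass
class ExposureEvent:
    """All acquisitions produced by one exposure-button press."""

    event_uid: str
    members: list[RecordPair] = field(default_factory=list)
    status: Optional[EventStatus] = None
    #: True when the event was assembled by the timestamp-window fallback
    #: rather than a shared irradiation-event UID (retrofit/CR systems).
    heuristic_grouping: bool = False

    @property
    def multiplicity(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Field priorities (1 = needed for any reject rate, 2 = per-exam breakdowns,
# 3 = in-depth technique/EI analysis).

FIELD_PRIORITY: dict[str, int] = {
    "system_identifier": 1,
    "operator_id": 1,
    "acquisition_datetime": 1,
    "acquisition_type": 1,
    "irradiation_event_uid": 1,
    "patient_mrn": 2,
    "accession_number": 2,
    "anatomy": 2,
    "protocol_id": 2,
    "view": 2,
    "patient_size_selection": 2,
    "processing_datetime": 3,
    "kvp": 3,
    "micro_as": 3,
    "exposure_time": 3,
    "ma": 3,
    "filter_material": 3,
    "filter_thickness_min": 3,
    "filter_thickness_max": 3,
    "filter_type": 3,
    "grid_use": 3,
    "sid": 3,
    "receptor_type": 3,
    "aec_status": 3,
    "aec_cells": 3,
    "aec_density": 3,
    "exposure_index": 3,
    "target_ei": 3,
    "deviation_index": 3,
    "detector_id": 3,
    "collimation": 3,
    "dap": 3,
    "processing_params": 3,
}

#: Required for any rate computation; absence is an error, not a warning.
REQUIRED_FIELDS = ("system_identifier", "acquisition_datetime",
                   "irradiation_event_uid", "acquisition_type")

#: Agreement tolerance between a stored deviation index and the value
#: implied by EI/target EI; absorbs vendor rounding of EI to integers.
DI_TOLERANCE = 0.15


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def deviation_index(exposure_index: float, target_ei: float) -> float:
    """DI = 10·log10(EI / target EI): log-scaled deviation of detector
    exposure from its target."""
    return 10.0 * math.log10(exposure_index / target_ei)


def validate_record(record: AcquisitionRecord,
                    reject: Optional[RejectInfo] = None,
                    taxonomy: Optional[Any] = None) -> ValidationReport:
    """Check one acquisition (and its reject designation) against the
    data-element requirements.

    Returns a report; never raises and never modifies the inputs.
    ``taxonomy`` (a taxonomy.TaxonomyConfig) enables the detailed-code
    membership check; when omitted the default schema is used.
    """
    rep = ValidationReport()

    for name in REQUIRED_FIELDS:
        if getattr(record, name) is None:
            rep.errors.append(f"missing required (priority-1) field: {name}")
    if record.operator_id is None:
        rep.warnings.append(
            "operator_id absent (priority-1; resolvable later via accession)")

    for name, prio in FIELD_PRIORITY.items():
        if prio >= 2 and getattr(record, name) is None:
            rep.warnings.append(f"missing priority-{prio} field: {name}")

    if record.kvp is not None and not record.kvp > 0:
        rep.errors.append(f"kvp must be > 0, got {record.kvp}")
    if record.micro_as is not None and record.micro_as < 0:
        rep.errors.append(f"micro_as must be >= 0, got {record.micro_as}")
    if record.sid is not None and not record.sid > 0:
        rep.errors.append(f"sid must be > 0, got {record.sid}")

    for name in ("acquisition_datetime", "processing_datetime"):
        ts = getattr(record, name)
        if ts is not None and ts.tzinfo is None:
            rep.warnings.append(f"{name} is timezone-naive; assuming local time")

    if (record.exposure_index is not None and record.target_ei is not None
            and record.deviation_index is not None
            and record.exposure_index > 0 and record.target_ei > 0):
        implied = deviation_index(record.exposure_index, record.target_ei)
        if abs(implied - record.deviation_index) > DI_TOLERANCE:
            rep.warnings.append(
                f"deviation_index {record.deviation_index:g} inconsistent with "
                f"10*log10(EI/target EI) = {implied:.3f}")

    if reject is not None:
        _validate_reject(record, reject, taxonomy, rep)
    return rep


def _validate_reject(record: AcquisitionRecord, reject: RejectInfo,
                     taxonomy: Optional[Any], rep: ValidationReport) -> None:
    if not reject.is_reject:
        for name in ("reason_broad", "reason_detailed", "reject_datetime",
                     "rejected_image_ref"):
            if getattr(reject, name) is not None:
                rep.errors.append(f"non-reject carries reject field: {name}")
        return

    if reject.reject_datetime is None:
        rep.errors.append("reject missing required field: reject_datetime")
    elif (record.acquisition_datetime is not None
          and reject.reject_datetime.tzinfo is not None
          and record.acquisition_datetime.tzinfo is not None
          and reject.reject_datetime < record.acquisition_datetime):
        rep.errors.append("reject_datetime earlier than acquisition_datetime")
    elif (record.acquisition_datetime is not None
          and reject.reject_datetime.tzinfo is None
          and record.acquisition_datetime.tzinfo is None
          and reject.reject_datetime < record.acquisition_datetime):
        rep.errors.append("reject_datetime earlier than acquisition_datetime")

    if reject.reason_broad is None:
        rep.warnings.append(
            "reject lacks broad reason (priority-2; required for analysis)")
    elif not 1 <= reject.reason_broad <= 9:
        rep.errors.append(
            f"reason_broad must be 1..9, got {reject.reason_broad}")
    if reject.rejected_image_ref is None:
        rep.warnings.append("reject lacks rejected_image_ref (priority-2)")

    if reject.reason_detailed is not None and reject.reason_broad is not None:
        if taxonomy is None:
            from . import taxonomy as _tx
            taxonomy = _tx.default_taxonomy()
        code = taxonomy.find_detailed(reject.reason_detailed)
        if code is None:
            rep.errors.append(
                f"detailed reason {reject.reason_detailed!r} not in taxonomy")
        elif code.parent != reject.reason_broad:
            rep.errors.append(
                f"detailed reason {reject.reason_detailed!r} belongs to "
                f"category {code.parent}, not {reject.reason_broad}")


# ---------------------------------------------------------------------------
# Canonical single-file log (UTF-8 CSV, one row per acquisition).

CANONICAL_COLUMNS: tuple[str, ...] = tuple(
    f.name for f in _dc_fields(AcquisitionRecord)
) + ("is_reject", "reason_broad", "reason_detailed", "reject_datetime",
     "rejected_image_ref")

_ENUM_FIELDS = {"acquisition_type": AcquisitionType, "grid_use": GridUse,
                "receptor_type": ReceptorType}
_DT_FIELDS = {"acquisition_datetime", "processing_datetime", "reject_datetime"}
_FLOAT_FIELDS = {"kvp", "micro_as", "exposure_time", "ma",
                 "filter_thickness_min", "filter_thickness_max", "sid",
                 "aec_density", "exposure_index", "target_ei",
                 "deviation_index", "dap"}


def _cell(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, _dt.datetime):
        return value.isoformat()
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, Collimation):
        return value.to_json()
    if isinstance(value, dict):
        return json.dumps(value, separators=(",", ":"), sort_keys=True)
    return str(value)


def pair_to_row(record: AcquisitionRecord, reject: RejectInfo) -> dict[str, str]:
    """Serialize one (record, reject) pair to a canonical CSV row."""
    row = {f.name: _cell(getattr(record, f.name))
           for f in _dc_fields(AcquisitionRecord)}
    row["is_reject"] = "true" if reject.is_reject else "false"
    row["reason_broad"] = _cell(reject.reason_broad)
    row["reason_detailed"] = _cell(reject.reason_detailed)
    row["reject_datetime"] = _cell(reject.reject_datetime)
    row["rejected_image_ref"] = _cell(reject.rejected_image_ref)
    return row


def row_to_pair(row: Mapping[str, str]) -> RecordPair:
    """Parse one canonical CSV row back into a (record, reject) pair.

    Inverse of :func:`pair_to_row` on all present fields.
    """
    kwargs: dict[str, Any] = {}
    for f in _dc_fields(AcquisitionRecord):
        raw = row.get(f.name, "")
        if raw == "":
            continue
        name = f.name
        if name in _ENUM_FIELDS:
            kwargs[name] = _ENUM_FIELDS[name](raw)
        elif name in _DT_FIELDS:
            kwargs[name] = _dt.datetime.fromisoformat(raw)
        elif name in _FLOAT_FIELDS:
            kwargs[name] = float(raw)
        elif name == "collimation":
            kwargs[name] = Collimation.from_json(raw)
        elif name == "processing_params":
            kwargs[name] = json.loads(raw)
        else:
            kwargs[name] = raw
    record = AcquisitionRecord(**kwargs)

    reject = RejectInfo(is_reject=row.get("is_reject", "") == "true")
    if row.get("reason_broad"):
        reject.reason_broad = int(row["reason_broad"])
    if row.get("reason_detailed"):
        reject.reason_detailed = row["reason_detailed"]
    if row.get("reject_datetime"):
        reject.reject_datetime = _dt.datetime.fromisoformat(row["reject_datetime"])
    if row.get("rejected_image_ref"):
        reject.rejected_image_ref = row["rejected_image_ref"]
    return record, reject


def redact_pair(record: AcquisitionRecord, reject: RejectInfo) -> RecordPair:
    """Return a copy with patient MRN and accession number removed.

    For export only: redaction should happen after operator resolution,
    since the accession number is what links a study to its technologist.
    """
    import dataclasses
    rec = dataclasses.replace(record, patient_mrn=None, accession_number=None)
    return rec, reject


def write_canonical_log(pairs: Iterable[RecordPair], fh) -> None:
    """Write (record, reject) pairs as a canonical single-file CSV log."""
    import csv
    writer = csv.DictWriter(fh, fieldnames=list(CANONICAL_COLUMNS),
                            lineterminator="\n")
    writer.writeheader()
    for record, reject in pairs:
        writer.writerow(pair_to_row(record, reject))


def write_canonical_log_path(pairs: Sequence[RecordPair], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        write_canonical_log(pairs, fh)
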