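"""Reading vendor data into canonical records.

Three sources are supported: delimited exposure/reject logs (the canonical
single-file CSV, or any vendor dialect described by a
:class:`DialectConfig`), DICOM Part-10 headers, and rejection notes in the
Key Object Selection (KOS) style.  Legacy split exposure + reject reports
can be merged read-only; the canonical output is always a single file.

Operator identification supports the two reliable routes — the login name
recorded per acquisition (which wins) and an accession-number lookup against
RIS/HIS data.  Reading technologists' lead markers out of pixel data is
deliberately not implemented.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

from .data_model import (AcquisitionRecord, AcquisitionType, Collimation,
                         GridUse, ReceptorType, RecordPair, RejectInfo,
                         REQUIRED_FIELDS, CANONICAL_COLUMNS, row_to_pair,
                         _DT_FIELDS, _ENUM_FIELDS, _FLOAT_FIELDS)
from .taxonomy import TaxonomyConfig, classify_reason, default_taxonomy

Source = Union[str, os.PathLike, io.TextIOBase, Iterable[str]]


# ---------------------------------------------------------------------------
# Dialects

@dataclass
class DialectConfig:
    """How one vendor's log maps onto the canonical record.

    ``column_map`` maps source column names to canonical field names; the
    special target ``vendor_reason`` routes a free-text reason through the
    taxonomy's vendor patterns.  ``constants`` declares fields the log omits
    but that hold one value for the whole file (e.g. the station name of the
    unit the log was pulled from).  ``tube_charge_unit`` may be ``"mAs"``
    (converted x1000 to microampere-seconds) and ``sid_unit`` ``"cm"``
    (converted x10 to millimeters).
    """

    column_map: dict[str, str] = field(default_factory=dict)
    constants: dict[str, str] = field(default_factory=dict)
    datetime_formats: dict[str, str] = field(default_factory=dict)  # field->strptime
    reject_true_values: frozenset[str] = frozenset({"true", "1", "yes", "y",
                                                    "rejected", "reject"})
    tube_charge_unit: str = "uAs"
    sid_unit: str = "mm"
    delimiter: str = ","
    link_keys: tuple[str, ...] = ()

    def validate(self) -> None:
        targets = set(self.column_map.values()) | set(self.constants)
        missing = [f for f in REQUIRED_FIELDS if f not in targets]
        if missing:
            raise ValueError(
                "dialect lacks a source for required field(s): "
                + ", ".join(missing))


def canonical_dialect() -> DialectConfig:
    """Dialect of the canonical single-file log this package writes."""
    return DialectConfig(
        column_map={c: c for c in CANONICAL_COLUMNS},
        link_keys=("system_identifier", "acquisition_datetime"),
    )


def dialect_from_json(text: str) -> DialectConfig:
    import json
    doc = json.loads(text)
    cfg = DialectConfig(
        column_map=dict(doc.get("column_map", {})),
        constants=dict(doc.get("constants", {})),
        datetime_formats=dict(doc.get("datetime_formats", {})),
        tube_charge_unit=doc.get("tube_charge_unit", "uAs"),
        sid_unit=doc.get("sid_unit", "mm"),
        delimiter=doc.get("delimiter", ","),
        link_keys=tuple(doc.get("link_keys", ())),
    )
    if "reject_true_values" in doc:
        cfg.reject_true_values = frozenset(
            v.lower() for v in doc["reject_true_values"])
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Log parsing

@dataclass
class RowIssue:
    row_number: int  # 1-based data row index
    message: str


@dataclass
class ParseResult:
    pairs: list[RecordPair]
    failures: list[RowIssue] = field(default_factory=list)
    warnings: list[RowIssue] = field(default_factory=list)

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)


def _open_source(source: Source):
    if isinstance(source, (str, os.PathLike)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def parse_exposure_log(source: Source,
                       dialect: Optional[DialectConfig] = None,
                       taxonomy: Optional[TaxonomyConfig] = None,
                       ) -> ParseResult:
    """Parse a delimited exposure log into (record, reject) pairs.

    One pair per row, row order preserved.  Rows that fail to parse are
    collected in ``failures`` with their row number — a bad row never
    aborts the file.  Unit conversions declared by the dialect are applied.
    """
    if dialect is None:
        dialect = canonical_dialect()
    dialect.validate()
    if taxonomy is None:
        taxonomy = default_taxonomy()

    fh, close = _open_source(source)
    result = ParseResult(pairs=[])
    try:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        for i, row in enumerate(reader, start=1):
            try:
                pair = _parse_row(row, dialect, taxonomy, result, i)
            except Exception as exc:  # noqa: BLE001 — collected per contract
                result.failures.append(RowIssue(i, str(exc)))
                continue
            result.pairs.append(pair)
    finally:
        if close:
            fh.close()
    return result


def _parse_row(row: Mapping[str, str], dialect: DialectConfig,
               taxonomy: TaxonomyConfig, result: ParseResult,
               rownum: int) -> RecordPair:
    canon: dict[str, str] = {}
    vendor_reason = None
    for src, target in dialect.column_map.items():
        raw = row.get(src)
        if raw is None or raw == "":
            continue
        if target == "vendor_reason":
            vendor_reason = raw
        else:
            canon[target] = raw
    for target, value in dialect.constants.items():
        canon.setdefault(target, value)

    # normalize vendor datetime formats to ISO before canonical parsing
    for fld, fmt in dialect.datetime_formats.items():
        if fld in canon:
            canon[fld] = _dt.datetime.strptime(canon[fld], fmt).isoformat()

    # vendor unit declarations
    if dialect.tube_charge_unit.lower() == "mas" and "micro_as" in canon:
        canon["micro_as"] = repr(float(canon["micro_as"]) * 1000.0)
    if dialect.sid_unit.lower() == "cm" and "sid" in canon:
        canon["sid"] = repr(float(canon["sid"]) * 10.0)

    # vendor reject-flag encodings
    if "is_reject" in canon:
        canon["is_reject"] = (
            "true" if canon["is_reject"].strip().lower()
            in dialect.reject_true_values else "false")

    record, reject = row_to_pair(canon)

    if vendor_reason is not None and reject.is_reject:
        cls = classify_reason(vendor_reason, taxonomy)
        if cls.matched:
            if reject.reason_broad is None:
                reject.reason_broad = cls.broad
            if reject.reason_detailed is None:
                reject.reason_detailed = cls.detailed
            if cls.reprocessed_label:
                result.warnings.append(RowIssue(
                    rownum, f"vendor reason {vendor_reason!r} uses a "
                    "re-processed/non-clinical label; mapped to category 9"))
        else:
            result.warnings.append(RowIssue(
                rownum, f"vendor reason {vendor_reason!r} matched no pattern"))
    return record, reject


# ---------------------------------------------------------------------------
# Split exposure + reject reports (legacy, read-only)

@dataclass
class MergeResult:
    pairs: list[RecordPair]
    unlinked: list[tuple[int, str]] = field(default_factory=list)  # (row, why)
    ambiguous: list[tuple[int, str]] = field(default_factory=list)
    #: reject rows attached to an exposure row (two reject rows hitting the
    #: same exposure both count: linked + unlinked + ambiguous = reject rows)
    n_linked: int = 0


def merge_separate_reports(exposure_pairs: Sequence[RecordPair],
                           reject_pairs: Sequence[RecordPair],
                           link_keys: Sequence[str]) -> MergeResult:
    """Attach rows of a separate reject report to their exposure rows.

    Each reject row must match exactly one exposure row on ``link_keys``;
    rows matching none (e.g. because one file was anonymized and the key
    fields are blank) or more than one are reported, never silently dropped.
    """
    if not link_keys:
        raise ValueError("link_keys must be non-empty")
    link_keys = tuple(link_keys)

    def key_of(record: AcquisitionRecord):
        return tuple(getattr(record, k) for k in link_keys)

    index: dict[tuple, list[int]] = {}
    merged = [(rec, RejectInfo(is_reject=rj.is_reject, **{
        f: getattr(rj, f) for f in ("reason_broad", "reason_detailed",
                                    "reject_datetime", "rejected_image_ref")}))
              for rec, rj in exposure_pairs]
    for i, (rec, _) in enumerate(merged):
        index.setdefault(key_of(rec), []).append(i)

    result = MergeResult(pairs=merged)
    for n, (rec, rj) in enumerate(reject_pairs, start=1):
        key = key_of(rec)
        if all(v is None for v in key):
            result.unlinked.append(
                (n, "all link-key fields blank (anonymized reject report?)"))
            continue
        hits = index.get(key, [])
        if not hits:
            result.unlinked.append((n, f"no exposure row matches {key!r}"))
        elif len(hits) > 1:
            result.ambiguous.append(
                (n, f"{len(hits)} exposure rows match {key!r}"))
        else:
            result.n_linked += 1
            exp_rec, _ = result.pairs[hits[0]]
            result.pairs[hits[0]] = (exp_rec, RejectInfo(
                is_reject=True, reason_broad=rj.reason_broad,
                reason_detailed=rj.reason_detailed,
                reject_datetime=rj.reject_datetime,
                rejected_image_ref=rj.rejected_image_ref))
    return result


# ---------------------------------------------------------------------------
# DICOM header extraction

_GRID_MAP = {"IN": GridUse.IN, "NONE": GridUse.NONE}


def _combine_dt(ds, date_kw: str, time_kw: str,
                warn: Optional[list[str]]) -> Optional[_dt.datetime]:
    date = getattr(ds, date_kw, None)
    if not date:
        return None
    time = getattr(ds, time_kw, None)
    if not time:
        if warn is not None:
            warn.append(f"{time_kw} absent; defaulting to midnight")
        time = "000000"
    time = str(time)
    frac = 0
    if "." in time:
        time, fracs = time.split(".", 1)
        frac = int(float("0." + fracs) * 1e6)
    return _dt.datetime(int(date[0:4]), int(date[4:6]), int(date[6:8]),
                        int(time[0:2]), int(time[2:4] or 0),
                        int(time[4:6] or 0), frac)


def _flt(ds, kw: str) -> Optional[float]:
    v = getattr(ds, kw, None)
    return None if v in (None, "") else float(v)


def _txt(ds, kw: str) -> Optional[str]:
    v = getattr(ds, kw, None)
    return None if v in (None, "") else str(v)


def extract_from_dicom(source,
                       warn: Optional[list[str]] = None) -> AcquisitionRecord:
    """Populate an AcquisitionRecord from a DICOM header.

    ``source`` is a file path, file object or a pydicom Dataset; pixel data
    is never read.  Every field with a listed public tag is populated when
    the tag is present; absent tags leave the field absent.  Recognizable
    private elements are captured opaquely into ``processing_params``.

    Paired date+time attributes are combined into one timestamp; a missing
    time component defaults to midnight (noted in ``warn`` when given).
    """
    import pydicom
    from pydicom.dataset import Dataset
    if isinstance(source, Dataset):
        ds = source
    else:
        ds = pydicom.dcmread(source, stop_before_pixels=True, force=False)

    rec = AcquisitionRecord()
    rec.system_identifier = _txt(ds, "StationName") or _txt(
        ds, "DeviceSerialNumber")
    rec.operator_id = _txt(ds, "OperatorsName")
    rec.acquisition_datetime = _combine_dt(
        ds, "AcquisitionDate", "AcquisitionTime", warn)
    rec.processing_datetime = _combine_dt(
        ds, "ContentDate", "ContentTime", warn)
    rec.patient_mrn = _txt(ds, "PatientID")
    rec.accession_number = _txt(ds, "AccessionNumber")
    rec.anatomy = _txt(ds, "BodyPartExamined")
    if rec.anatomy is None:
        seq = getattr(ds, "AnatomicRegionSequence", None)
        if seq:
            rec.anatomy = _txt(seq[0], "CodeMeaning")
    rec.protocol_id = _txt(ds, "StudyDescription")
    seq = getattr(ds, "ProcedureCodeSequence", None)
    if seq:
        rec.protocol_id = _txt(seq[0], "CodeMeaning") or rec.protocol_id
    rec.view = _txt(ds, "ViewPosition")
    if rec.view is None:
        seq = getattr(ds, "ViewCodeSequence", None)
        if seq:
            rec.view = _txt(seq[0], "CodeMeaning")
    rec.irradiation_event_uid = _txt(ds, "IrradiationEventUID")
    rec.kvp = _flt(ds, "KVP")
    rec.micro_as = _flt(ds, "ExposureInuAs")
    rec.exposure_time = _flt(ds, "ExposureTime")
    rec.ma = _flt(ds, "XRayTubeCurrent")
    rec.filter_type = _txt(ds, "FilterType")
    rec.filter_material = _txt(ds, "FilterMaterial")
    rec.filter_thickness_min = _flt(ds, "FilterThicknessMinimum")
    rec.filter_thickness_max = _flt(ds, "FilterThicknessMaximum")
    grid = _txt(ds, "Grid")
    if grid is not None:
        rec.grid_use = _GRID_MAP.get(grid.upper(), GridUse.UNKNOWN)
    rec.sid = _flt(ds, "DistanceSourceToDetector")
    rec.aec_status = _txt(ds, "ExposureControlMode")
    rec.aec_cells = _txt(ds, "ExposureControlModeDescription")
    rec.exposure_index = _flt(ds, "ExposureIndex")
    rec.target_ei = _flt(ds, "TargetExposureIndex")
    rec.deviation_index = _flt(ds, "DeviationIndex")
    rec.detector_id = _txt(ds, "DetectorID")
    rec.collimation = _extract_collimation(ds)
    dap = _flt(ds, "ImageAndFluoroscopyAreaDoseProduct")
    if dap is not None:
        rec.dap = dap * 0.1  # header carries dGy*cm^2
    params = {}
    for elem in ds:
        if elem.tag.is_private and elem.VR not in ("SQ", "OB", "OW", "UN"):
            params[f"{elem.tag:08X}" if isinstance(elem.tag, int)
                   else str(elem.tag)] = str(elem.value)
    if params:
        rec.processing_params = params
    return rec


def _extract_collimation(ds) -> Optional[Collimation]:
    shape = _txt(ds, "CollimatorShape")
    if shape is None:
        return None
    if "RECTANGULAR" in shape:
        coords = [_flt(ds, kw) for kw in (
            "CollimatorLeftVerticalEdge", "CollimatorRightVerticalEdge",
            "CollimatorUpperHorizontalEdge", "CollimatorLowerHorizontalEdge")]
        return Collimation(shape=shape,
                           coordinates=tuple(c for c in coords
                                             if c is not None))
    if "POLYGONAL" in shape:
        verts = getattr(ds, "VerticesOfThePolygonalCollimator", None)
        if verts is not None:
            return Collimation(shape=shape,
                               coordinates=tuple(float(v) for v in verts))
        return Collimation(shape=shape)
    return Collimation(shape=shape, opaque=shape)


# ---------------------------------------------------------------------------
# KOS rejection notes

#: Fixed concept title marking instances rejected for quality reasons.
KOS_REJECTION_TITLE = "Rejected for Quality Reasons"


@dataclass(frozen=True)
class KosRejectionNote:
    """Information-level model of a Key Object Selection rejection note:
    a pointer document a PACS reads to sequester rejected instances from
    clinical worklists."""

    note_uid: str
    referenced_instance_uids: tuple[str, ...]
    reason_text: str = ""
    creation_datetime: Optional[_dt.datetime] = None
    title: str = KOS_REJECTION_TITLE


def build_kos_rejection_note(instance_uids: Sequence[str],
                             reason_text: str = "",
                             when: Optional[_dt.datetime] = None,
                             note_uid: Optional[str] = None,
                             ) -> KosRejectionNote:
    """Create a rejection note referencing the given SOP instances."""
    uids = tuple(instance_uids)
    if not uids:
        raise ValueError("a rejection note must reference at least one "
                         "instance")
    if note_uid is None:
        from pydicom.uid import generate_uid
        note_uid = str(generate_uid())
    return KosRejectionNote(note_uid=note_uid,
                            referenced_instance_uids=uids,
                            reason_text=reason_text,
                            creation_datetime=when)


def detect_rejected_instances(notes: Iterable[KosRejectionNote],
                              instance_uids: Sequence[str],
                              ) -> tuple[list[str], list[str]]:
    """Partition instances into (clinical, sequestered).

    Sequestered = referenced by at least one rejection note; clinical =
    the rest.  The partition is exact: disjoint and covering, input order
    preserved, duplicates in notes are harmless.
    """
    rejected = set()
    for note in notes:
        rejected.update(note.referenced_instance_uids)
    clinical = [u for u in instance_uids if u not in rejected]
    sequestered = [u for u in instance_uids if u in rejected]
    return clinical, sequestered


def kos_to_dicom_dataset(note: KosRejectionNote):
    """Optional adapter: render a note as a minimal pydicom KO dataset."""
    from pydicom.dataset import Dataset
    from pydicom.uid import KeyObjectSelectionDocumentStorage
    ds = Dataset()
    ds.SOPClassUID = KeyObjectSelectionDocumentStorage
    ds.SOPInstanceUID = note.note_uid
    ds.Modality = "KO"
    title = Dataset()
    title.CodeValue = "113001"
    title.CodingSchemeDesignator = "DCM"
    title.CodeMeaning = note.title
    ds.ConceptNameCodeSequence = [title]
    refs = []
    for uid in note.referenced_instance_uids:
        item = Dataset()
        item.ReferencedSOPInstanceUID = uid
        refs.append(item)
    ds.ReferencedSOPSequence = refs
    if note.creation_datetime is not None:
        ds.ContentDate = note.creation_datetime.strftime("%Y%m%d")
        ds.ContentTime = note.creation_datetime.strftime("%H%M%S")
    ds.TextValue = note.reason_text
    return ds


# ---------------------------------------------------------------------------
# Operator resolution

def resolve_operator(pairs: Sequence[RecordPair],
                     accession_to_operator: Mapping[str, str],
                     ) -> tuple[list[RecordPair], int]:
    """Fill missing operator ids from an accession-number lookup.

    A login-recorded operator already on the record always wins; records
    with neither a login nor a resolvable accession are counted unresolved.
    """
    unresolved = 0
    for record, _ in pairs:
        if record.operator_id is not None:
            continue
        op = (accession_to_operator.get(record.accession_number)
              if record.accession_number is not None else None)
        if op is not None:
            record.operator_id = op
        else:
            unresolved += 1
    return list(pairs), unresolved


def collect_logs(directory: Union[str, os.PathLike],
                 pattern: str = "*.csv",
                 dialect: Optional[DialectConfig] = None) -> ParseResult:
    """One-shot sweep of a drop directory: parse every matching log and
    concatenate the rows (sorted by filename for determinism)."""
    import fnmatch as _fn
    combined = ParseResult(pairs=[])
    for name in sorted(os.listdir(directory)):
        if not _fn.fnmatch(name, pattern):
            continue
        res = parse_exposure_log(os.path.join(directory, name), dialect)
        combined.pairs.extend(res.pairs)
        combined.failures.extend(res.failures)
        combined.warnings.extend(res.warnings)
    return combined
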