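"""Log parsing, split-report merging, DICOM extraction, KOS notes,
operator resolution."""

import datetime as dt
import io

import pytest

from rejana.data_model import (AcquisitionRecord, AcquisitionType, RejectInfo,
                               validate_record, write_canonical_log)
from rejana.ingest import (DialectConfig, build_kos_rejection_note,
                           canonical_dialect, detect_rejected_instances,
                           extract_from_dicom, kos_to_dicom_dataset,
                           merge_separate_reports, parse_exposure_log,
                           resolve_operator, collect_logs)

from conftest import BASE, UTC


def _vendor_log(rows, header):
    return io.StringIO("\n".join([header] + rows) + "\n")


VENDOR_DIALECT = DialectConfig(
    column_map={"Unit": "system_identifier", "When": "acquisition_datetime",
                "EventID": "irradiation_event_uid", "Type": "acquisition_type",
                "mAs": "micro_as", "SID_cm": "sid", "Status": "is_reject",
                "Reason": "vendor_reason"},
    datetime_formats={"acquisition_datetime": "%m/%d/%Y %H:%M:%S"},
    reject_true_values=frozenset({"x"}),
    tube_charge_unit="mAs", sid_unit="cm",
)


class TestParseExposureLog:
    def test_canonical_counts_and_order(self):
        pairs = [(AcquisitionRecord(system_identifier="S",
                                    acquisition_datetime=BASE,
                                    acquisition_type=AcquisitionType.SINGLE,
                                    irradiation_event_uid=f"u{i}"),
                  RejectInfo(is_reject=(i == 1), reason_broad=1 if i == 1 else None,
                             reject_datetime=BASE if i == 1 else None))
                 for i in range(3)]
        buf = io.StringIO()
        write_canonical_log(pairs, buf)
        buf.seek(0)
        res = parse_exposure_log(buf)
        assert len(res.pairs) == 3 and not res.failures
        assert [rj.is_reject for _, rj in res.pairs] == [False, True, False]
        assert [r.irradiation_event_uid for r, _ in res.pairs] == \
            ["u0", "u1", "u2"]

    def test_vendor_units_converted(self):
        src = _vendor_log(
            ['DR9,03/01/2023 08:00:00,e1,SINGLE,2.5,180,,'],
            "Unit,When,EventID,Type,mAs,SID_cm,Status,Reason")
        res = parse_exposure_log(src, VENDOR_DIALECT)
        rec, rj = res.pairs[0]
        assert rec.micro_as == 2500.0
        assert rec.sid == 1800.0
        assert not rj.is_reject
        assert rec.acquisition_datetime == dt.datetime(2023, 3, 1, 8)

    def test_vendor_reason_classified_via_taxonomy(self):
        from rejana.taxonomy import TaxonomyConfig, VendorPattern, \
            default_taxonomy
        tx = default_taxonomy()
        tx.vendor_map.insert(0, VendorPattern("*motion*", 2, "2.1"))
        src = _vendor_log(
            ['DR9,03/01/2023 08:00:00,e1,SINGLE,2.5,180,x,Patient Motion'],
            "Unit,When,EventID,Type,mAs,SID_cm,Status,Reason")
        res = parse_exposure_log(src, VENDOR_DIALECT, taxonomy=tx)
        _, rj = res.pairs[0]
        assert rj.is_reject and (rj.reason_broad, rj.reason_detailed) == (2, "2.1")

    def test_empty_file_with_header_is_empty_not_error(self):
        buf = io.StringIO(",".join(
            canonical_dialect().column_map) + "\n")
        res = parse_exposure_log(buf)
        assert res.pairs == [] and not res.failures

    def test_bad_row_collected_not_fatal(self):
        src = _vendor_log(
            ['DR9,03/01/2023 08:00:00,e1,SINGLE,2.5,180,,',
             'DR9,not-a-date,e2,SINGLE,2.5,180,,',
             'DR9,03/01/2023 08:05:00,e3,SINGLE,2.5,180,,'],
            "Unit,When,EventID,Type,mAs,SID_cm,Status,Reason")
        res = parse_exposure_log(src, VENDOR_DIALECT)
        assert len(res.pairs) == 2
        assert [f.row_number for f in res.failures] == [2]

    def test_dialect_missing_required_mapping_rejected(self):
        bad = DialectConfig(column_map={"Unit": "system_identifier"})
        with pytest.raises(ValueError, match="required"):
            parse_exposure_log(io.StringIO("Unit\nX\n"), bad)


def _exposures(n):
    return [(AcquisitionRecord(system_identifier="S", acquisition_datetime=BASE
                               + dt.timedelta(minutes=i),
                               acquisition_type=AcquisitionType.SINGLE,
                               irradiation_event_uid=f"u{i}"),
             RejectInfo()) for i in range(n)]


class TestMergeSeparateReports:
    LINK = ("system_identifier", "acquisition_datetime")

    def test_unique_link(self):
        rejects = [(AcquisitionRecord(system_identifier="S",
                                      acquisition_datetime=BASE
                                      + dt.timedelta(minutes=2)),
                    RejectInfo(is_reject=True, reason_broad=1,
                               reject_datetime=BASE))]
        res = merge_separate_reports(_exposures(5), rejects, self.LINK)
        assert len(res.pairs) == 5
        assert res.n_linked == 1 and not res.unlinked and not res.ambiguous
        assert res.pairs[2][1].is_reject and res.pairs[2][1].reason_broad == 1

    def test_ambiguous_reject_reported_not_linked(self):
        exposures = _exposures(2)
        # duplicate timestamps: both exposures share the link key
        exposures[1][0].acquisition_datetime = \
            exposures[0][0].acquisition_datetime
        rejects = [(AcquisitionRecord(
            system_identifier="S",
            acquisition_datetime=exposures[0][0].acquisition_datetime),
            RejectInfo(is_reject=True, reason_broad=1))]
        res = merge_separate_reports(exposures, rejects, self.LINK)
        assert res.n_linked == 0
        assert len(res.ambiguous) == 1 and not res.unlinked

    def test_anonymized_reject_log_all_unlinked_with_cause(self):
        rejects = [(AcquisitionRecord(), RejectInfo(is_reject=True))
                   for _ in range(3)]
        res = merge_separate_reports(_exposures(4), rejects, self.LINK)
        assert res.n_linked == 0 and len(res.unlinked) == 3
        assert all("anonymized" in why for _, why in res.unlinked)

    def test_accounting_invariant(self):
        import numpy as np
        rng = np.random.default_rng(3)
        exposures = _exposures(20)
        rejects = []
        for _ in range(8):
            if rng.random() < 0.5:
                i = int(rng.integers(20))
                rec = AcquisitionRecord(
                    system_identifier="S",
                    acquisition_datetime=exposures[i][0].acquisition_datetime)
            else:
                rec = AcquisitionRecord()  # unlinkable
            rejects.append((rec, RejectInfo(is_reject=True, reason_broad=1)))
        res = merge_separate_reports(exposures, rejects, self.LINK)
        assert res.n_linked + len(res.unlinked) + len(res.ambiguous) == 8
        assert res.n_linked <= 8

    def test_empty_link_keys_rejected(self):
        with pytest.raises(ValueError):
            merge_separate_reports(_exposures(1), [], ())


def _dicom_dataset(**tags):
    from pydicom.dataset import Dataset
    ds = Dataset()
    defaults = dict(StationName="DR-STAND-2", OperatorsName="tech1",
                    AcquisitionDate="20230301", AcquisitionTime="081530",
                    IrradiationEventUID="2.25.55.1", KVP="81",
                    ExposureInuAs="2500", DistanceSourceToDetector="1800")
    defaults.update(tags)
    for k, v in defaults.items():
        if v is not None:
            setattr(ds, k, v)
    return ds


class TestExtractFromDicom:
    def test_direct_tag_map(self):
        rec = extract_from_dicom(_dicom_dataset())
        assert rec.kvp == 81.0
        assert rec.system_identifier == "DR-STAND-2"
        assert rec.micro_as == 2500.0
        assert rec.acquisition_datetime == dt.datetime(2023, 3, 1, 8, 15, 30)

    def test_exposure_index_triplet_consistent(self):
        rec = extract_from_dicom(_dicom_dataset(
            ExposureIndex="358", TargetExposureIndex="400",
            DeviationIndex="-0.5"))
        assert (rec.exposure_index, rec.target_ei, rec.deviation_index) == \
            (358.0, 400.0, -0.5)
        rep = validate_record(rec)
        # 10*log10(358/400) = -0.482, within the 0.15 tolerance of -0.5
        assert not any("deviation_index" in w for w in rep.warnings)

    def test_absent_event_uid_caught_downstream(self):
        rec = extract_from_dicom(_dicom_dataset(IrradiationEventUID=None))
        assert rec.irradiation_event_uid is None
        rec.acquisition_type = AcquisitionType.SINGLE
        rep = validate_record(rec)
        assert any("irradiation_event_uid" in e for e in rep.errors)

    def test_missing_time_defaults_to_midnight_with_warning(self):
        warn = []
        rec = extract_from_dicom(_dicom_dataset(AcquisitionTime=None),
                                 warn=warn)
        assert rec.acquisition_datetime == dt.datetime(2023, 3, 1, 0, 0, 0)
        assert any("midnight" in w for w in warn)


class TestKosRejectionNotes:
    def test_single_reference(self):
        note = build_kos_rejection_note(["2.25.1"], "positioning", note_uid="n1")
        assert note.referenced_instance_uids == ("2.25.1",)
        assert note.title == "Rejected for Quality Reasons"

    def test_multi_image_reject_references_all(self):
        uids = [f"2.25.{i}" for i in range(4)]
        note = build_kos_rejection_note(uids, note_uid="n1")
        assert len(note.referenced_instance_uids) == 4

    def test_empty_reference_list_is_an_error(self):
        with pytest.raises(ValueError):
            build_kos_rejection_note([])

    def test_partition_examples(self):
        assert detect_rejected_instances([], ["A", "B"]) == (["A", "B"], [])
        note = build_kos_rejection_note(["A"], note_uid="n1")
        assert detect_rejected_instances([note], ["A", "B"]) == (["B"], ["A"])
        # two notes referencing A: sequestered once (idempotent)
        notes = [note, build_kos_rejection_note(["A"], note_uid="n2")]
        assert detect_rejected_instances(notes, ["A", "B"]) == (["B"], ["A"])

    def test_partition_is_exact_on_random_sets(self):
        import numpy as np
        rng = np.random.default_rng(11)
        for _ in range(50):
            uids = [f"2.25.{i}" for i in range(int(rng.integers(1, 30)))]
            notes = [build_kos_rejection_note(
                list(rng.choice(uids, size=int(rng.integers(1, 4)))),
                note_uid=f"n{j}") for j in range(int(rng.integers(0, 4)))]
            clinical, sequestered = detect_rejected_instances(notes, uids)
            assert len(clinical) + len(sequestered) == len(uids)
            assert not set(clinical) & set(sequestered)
            assert set(clinical) | set(sequestered) == set(uids)

    def test_dicom_adapter_carries_references(self):
        note = build_kos_rejection_note(["2.25.1", "2.25.2"], "motion",
                                        when=BASE, note_uid="2.25.99")
        ds = kos_to_dicom_dataset(note)
        assert ds.Modality == "KO"
        assert ds.ConceptNameCodeSequence[0].CodeValue == "113001"
        refs = [item.ReferencedSOPInstanceUID for item in ds.ReferencedSOPSequence]
        assert refs == ["2.25.1", "2.25.2"]


class TestResolveOperator:
    def _pair(self, operator=None, accession=None):
        return (AcquisitionRecord(system_identifier="S",
                                  operator_id=operator,
                                  accession_number=accession), RejectInfo())

    def test_login_wins_over_accession_lookup(self):
        pairs = [self._pair(operator="tech1", accession="A9")]
        _, unresolved = resolve_operator(pairs, {"A9": "tech2"})
        assert pairs[0][0].operator_id == "tech1" and unresolved == 0

    def test_accession_lookup_fills_missing(self):
        pairs = [self._pair(accession="A9")]
        _, unresolved = resolve_operator(pairs, {"A9": "tech2"})
        assert pairs[0][0].operator_id == "tech2" and unresolved == 0

    def test_neither_source_counts_unresolved(self):
        pairs = [self._pair()]
        _, unresolved = resolve_operator(pairs, {})
        assert pairs[0][0].operator_id is None and unresolved == 1


def test_collect_logs_sweeps_directory(tmp_path):
    from rejana.synthetic import scenario_image_pasting
    from rejana.data_model import write_canonical_log_path
    s = scenario_image_pasting()
    write_canonical_log_path(s.pairs[:100], tmp_path / "b.csv")
    write_canonical_log_path(s.pairs[100:200], tmp_path / "a.csv")
    (tmp_path / "ignore.txt").write_text("not a log\n")
    combined = collect_logs(tmp_path)
    assert len(combined.pairs) == 200
    # sorted by filename: a.csv rows first
    assert combined.pairs[0] == s.pairs[100]
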