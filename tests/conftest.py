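"""Shared fixtures and randomized-input generators.

The generators here are test inputs, not oracles: expected values in the
tests are computed by independent brute-force counters or frozen by hand.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from rejana.data_model import (AcquisitionRecord, AcquisitionType,
                               Collimation, ExposureEvent, GridUse,
                               ReceptorType, RejectInfo)
from rejana.analysis import assign_status

UTC = dt.timezone.utc
BASE = dt.datetime(2023, 6, 1, 9, 0, 0, tzinfo=UTC)

DETAILED_CODES = ("1.1", "1.2", "1.3", "2.1", "2.2", "3.1", "3.2", "3.3",
                  "4.1", "4.2", "4.3", "4.4", "5.1", "5.2", "6.1", "6.2",
                  "7.1", "8", "9")


def make_random_pair(rng: np.random.Generator, i: int):
    """One randomized (record, reject) pair with a mix of present/absent
    optional fields; values are chosen to be CSV-serializable."""
    when = BASE + dt.timedelta(seconds=int(rng.integers(0, 10**6)),
                               microseconds=int(rng.integers(0, 10**6)))
    rec = AcquisitionRecord(
        system_identifier=f"TEST-SYS-{int(rng.integers(1, 4))}",
        operator_id=(None if rng.random() < 0.2
                     else f"TEST-TECH-{int(rng.integers(1, 6))}"),
        acquisition_datetime=when,
        acquisition_type=AcquisitionType(
            rng.choice([t.value for t in AcquisitionType])),
        irradiation_event_uid=f"2.25.777.{i}",
        patient_mrn=None if rng.random() < 0.3 else f"TEST-MRN-{i:06d}",
        accession_number=None if rng.random() < 0.3 else f"TEST-ACC-{i:06d}",
        anatomy=str(rng.choice(["CHEST", "SPINE", "HAND", "PELVIS"])),
        view=str(rng.choice(["PA", "AP", "LAT"])),
        kvp=None if rng.random() < 0.3 else float(rng.uniform(40, 150)),
        micro_as=None if rng.random() < 0.3 else float(rng.uniform(0, 20000)),
        exposure_time=float(rng.uniform(1, 500)),
        sid=None if rng.random() < 0.5 else float(rng.uniform(900, 3000)),
        grid_use=GridUse(rng.choice([g.value for g in GridUse])),
        receptor_type=ReceptorType(
            rng.choice([r.value for r in ReceptorType])),
        exposure_index=float(rng.uniform(100, 900)),
        detector_id=f"TEST-DET-{int(rng.integers(1, 3))}",
        collimation=(None if rng.random() < 0.5 else Collimation(
            shape="RECTANGULAR",
            coordinates=tuple(float(x) for x in rng.integers(0, 3000, 4)))),
        dap=None if rng.random() < 0.5 else float(rng.uniform(0.01, 5.0)),
        processing_params=(None if rng.random() < 0.7
                           else {"LUT": str(int(rng.integers(1, 9)))}),
    )
    if rng.random() < 0.3:
        code = str(rng.choice(DETAILED_CODES))
        rj = RejectInfo(is_reject=True, reason_broad=int(code.split(".")[0]),
                        reason_detailed=code,
                        reject_datetime=when + dt.timedelta(
                            seconds=int(rng.integers(10, 600))),
                        rejected_image_ref=(None if rng.random() < 0.5
                                            else f"test:img/{i}"))
    else:
        rj = RejectInfo()
    return rec, rj


def make_random_events(rng: np.random.Generator, n_events: int,
                       max_multiplicity: int = 4) -> list[ExposureEvent]:
    """Randomized statused event set mixing multiplicities, partial
    rejections and excluded categories (8/9)."""
    pairs = []
    for i in range(n_events):
        mult = int(rng.integers(1, max_multiplicity + 1))
        acq_type = AcquisitionType.SINGLE if mult == 1 else AcquisitionType(
            rng.choice(["DUAL_ENERGY", "IMAGE_PASTING", "OTHER_MULTI"]))
        when = BASE + dt.timedelta(minutes=5 * i)
        uid = f"2.25.888.{i}"
        kind = rng.random()
        for m in range(mult):
            rec = AcquisitionRecord(
                system_identifier="TEST-SYS-1",
                operator_id=f"TEST-TECH-{int(rng.integers(1, 3))}",
                acquisition_datetime=when + dt.timedelta(seconds=m),
                acquisition_type=acq_type, irradiation_event_uid=uid,
                view=str(rng.choice(["PA", "LAT"])))
            if kind < 0.25:  # fully rejected, countable reasons
                code = str(rng.choice(DETAILED_CODES[:17]))
                rj = RejectInfo(is_reject=True,
                                reason_broad=int(code.split(".")[0]),
                                reason_detailed=code,
                                reject_datetime=when + dt.timedelta(minutes=1))
            elif kind < 0.35:  # fully rejected, categories 8/9 only
                broad = int(rng.choice([8, 9]))
                rj = RejectInfo(is_reject=True, reason_broad=broad,
                                reason_detailed=str(broad),
                                reject_datetime=when + dt.timedelta(minutes=1))
            elif kind < 0.5 and mult > 1 and m == 0:  # partial rejection
                code = str(rng.choice(DETAILED_CODES))
                rj = RejectInfo(is_reject=True,
                                reason_broad=int(code.split(".")[0]),
                                reason_detailed=code,
                                reject_datetime=when + dt.timedelta(minutes=1))
            else:
                rj = RejectInfo()
            pairs.append((rec, rj))
    from rejana.analysis import group_into_events
    return assign_status(group_into_events(pairs))


@pytest.fixture(scope="session")
def pasting_scenario():
    from rejana.synthetic import scenario_image_pasting
    return scenario_image_pasting()


@pytest.fixture(scope="session")
def dual_energy_scenario():
    from rejana.synthetic import scenario_dual_energy
    return scenario_dual_energy()
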