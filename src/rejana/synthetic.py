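"""Synthetic exposure logs with known ground truth.

Two kinds of output make every other module testable without touching real
patient data:

* fixed worked-scenario fixtures — a mixed single-exposure / image-pasting
  stream and a dual-energy / lateral chest stream whose counts are chosen so
  the event-based and image-based rates differ in a known way;
* a parameterized stochastic simulator with per-(operator, exam-class)
  reject probabilities, whose ground truth is returned alongside the log so
  estimators can be checked for parameter recovery.

All identifiers live in a reserved ``TEST-`` namespace so no synthetic row
can be mistaken for PHI; technique factors are plausible placeholders, not
dosimetry.  Fixtures are deterministic and byte-identical across runs.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .data_model import (AcquisitionRecord, AcquisitionType, ExposureEvent,
                         RecordPair, RejectInfo, ReceptorType)
from .analysis import assign_status, group_into_events

_BASE = _dt.datetime(2023, 3, 1, 8, 0, 0, tzinfo=_dt.timezone.utc)
_UID_ROOT = "2.25.4242"  # synthetic UID namespace

#: Detailed reject reasons cycled through by the scenario fixtures so
#: taxonomy stratification is exercised (countable categories 1-5).
_CYCLIC_REASONS = ("1.1", "2.1", "3.1", "4.2", "5.1")


def _spread(n_reject: int, n_total: int) -> list[bool]:
    """Evenly spread n_reject True flags over n_total slots (Bresenham)."""
    return [(i + 1) * n_reject // n_total > i * n_reject // n_total
            for i in range(n_total)]


def _record(system: str, operator: str, when: _dt.datetime,
            acq_type: AcquisitionType, uid: str, seq: int,
            **extra) -> AcquisitionRecord:
    return AcquisitionRecord(
        system_identifier=system, operator_id=operator,
        acquisition_datetime=when, acquisition_type=acq_type,
        irradiation_event_uid=uid,
        patient_mrn=f"TEST-MRN-{seq:05d}",
        accession_number=f"TEST-ACC-{seq:05d}",
        receptor_type=ReceptorType.WALL_STAND,
        kvp=extra.pop("kvp", 81.0), micro_as=extra.pop("micro_as", 2500.0),
        sid=extra.pop("sid", 1800.0), **extra)


def _reject(when: _dt.datetime, k: int) -> RejectInfo:
    code = _CYCLIC_REASONS[k % len(_CYCLIC_REASONS)]
    return RejectInfo(
        is_reject=True, reason_broad=int(code.split(".")[0]),
        reason_detailed=code,
        reject_datetime=when + _dt.timedelta(minutes=2),
        rejected_image_ref=f"test:rejects/TEST-IMG-{k:05d}")


@dataclass
class Scenario:
    pairs: list[RecordPair]
    events: list[ExposureEvent]


def scenario_image_pasting() -> Scenario:
    """Mixed workload: 500 button presses — 450 single-exposure (67
    rejected) and 50 image-pasting with four images each (4 fully
    rejected).  Event-based RR is 71/500; the image count gives 83/650,
    understating the true rate because pasting events carry extra images.
    """
    pairs: list[RecordPair] = []
    k_rej = 0
    single_flags = _spread(67, 450)
    paste_flags = _spread(4, 50)
    for i in range(450):
        when = _BASE + _dt.timedelta(minutes=2 * i)
        uid = f"{_UID_ROOT}.1.{i + 1}"
        rec = _record("TEST-DR-01", f"TEST-TECH-{i % 3 + 1}", when,
                      AcquisitionType.SINGLE, uid, i + 1,
                      anatomy="CHEST", view="PA", protocol_id="Chest PA")
        if single_flags[i]:
            pairs.append((rec, _reject(when, k_rej)))
            k_rej += 1
        else:
            pairs.append((rec, RejectInfo()))
    for j in range(50):
        when = _BASE + _dt.timedelta(minutes=900 + 5 * j)
        uid = f"{_UID_ROOT}.2.{j + 1}"
        rejected = paste_flags[j]
        for m in range(4):
            rec = _record("TEST-DR-01", f"TEST-TECH-{j % 3 + 1}",
                          when + _dt.timedelta(seconds=3 * m),
                          AcquisitionType.IMAGE_PASTING, uid, 451 + j,
                          anatomy="SPINE", view="AP",
                          protocol_id="Full Spine Pasting")
            if rejected:
                pairs.append((rec, _reject(when, k_rej)))
            else:
                pairs.append((rec, RejectInfo()))
        if rejected:
            k_rej += 1
    events = assign_status(group_into_events(pairs))
    return Scenario(pairs=pairs, events=events)


def scenario_dual_energy() -> Scenario:
    """Chest workload: 720 presses — 360 dual-energy PA (two exposures per
    press, 27 fully rejected) and 360 single-exposure LAT (54 rejected).
    Event-based RR is 81/720 = 11.25%; counting raw images gives 108/1080
    = 10% because each PA press contributes two images.
    """
    pairs: list[RecordPair] = []
    pa_flags = _spread(27, 360)
    lat_flags = _spread(54, 360)
    k_rej = 0
    for i in range(360):
        when = _BASE + _dt.timedelta(minutes=3 * i)
        uid = f"{_UID_ROOT}.3.{i + 1}"
        rejected = pa_flags[i]
        for m in range(2):
            rec = _record("TEST-DR-02", f"TEST-TECH-{i % 4 + 1}",
                          when + _dt.timedelta(seconds=2 * m),
                          AcquisitionType.DUAL_ENERGY, uid, 1000 + i,
                          anatomy="CHEST", view="PA",
                          protocol_id="Chest PA Dual Energy",
                          kvp=(60.0, 120.0)[m])
            if rejected:
                pairs.append((rec, _reject(when, k_rej)))
            else:
                pairs.append((rec, RejectInfo()))
        if rejected:
            k_rej += 1
        when_lat = when + _dt.timedelta(minutes=1)
        uid = f"{_UID_ROOT}.4.{i + 1}"
        rec = _record("TEST-DR-02", f"TEST-TECH-{i % 4 + 1}", when_lat,
                      AcquisitionType.SINGLE, uid, 1000 + i,
                      anatomy="CHEST", view="LAT", protocol_id="Chest LAT",
                      kvp=125.0)
        if lat_flags[i]:
            pairs.append((rec, _reject(when_lat, k_rej)))
            k_rej += 1
        else:
            pairs.append((rec, RejectInfo()))
    events = assign_status(group_into_events(pairs))
    return Scenario(pairs=pairs, events=events)


SCENARIOS = {"pasting": scenario_image_pasting,
             "dualenergy": scenario_dual_energy}


# ---------------------------------------------------------------------------
# Stochastic simulator

@dataclass(frozen=True)
class ExamClass:
    """One exam type in the simulated mix.

    ``multiplicity`` is the number of raw images per button press: a fixed
    integer, or an inclusive (lo, hi) range sampled per press.  Dual energy
    is 2; image pasting 3-5; tomosynthesis defaults to 24 (of order
    "dozens"; configure to taste).
    """

    name: str
    acquisition_type: AcquisitionType = AcquisitionType.SINGLE
    multiplicity: Union[int, tuple[int, int]] = 1
    view: Optional[str] = None
    anatomy: Optional[str] = None


DEFAULT_CLASSES = (
    ExamClass("single", AcquisitionType.SINGLE, 1),
    ExamClass("dual_energy", AcquisitionType.DUAL_ENERGY, 2),
    ExamClass("image_pasting", AcquisitionType.IMAGE_PASTING, (3, 5)),
    ExamClass("tomosynthesis", AcquisitionType.TOMOSYNTHESIS, 24),
)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated operations stream.

    ``reject_prob`` holds per-(operator, class) probabilities of a press
    being fully rejected, with ``default_reject_prob`` as fallback;
    ``excluded_rate`` is the probability a press is practitioner-directed
    or a non-patient/test exposure (categories 8/9, uncounted).
    ``reason_distribution`` weights detailed codes for countable rejects.
    """

    n_presses: int = 1000
    seed: int = 0
    system: str = "TEST-DR-SIM"
    operators: tuple[str, ...] = ("TEST-TECH-1", "TEST-TECH-2")
    exam_classes: tuple[ExamClass, ...] = (DEFAULT_CLASSES[0],)
    mix: Optional[tuple[float, ...]] = None  # defaults to uniform
    default_reject_prob: float = 0.08
    reject_prob: dict[tuple[str, str], float] = field(default_factory=dict)
    excluded_rate: float = 0.0
    reason_distribution: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in _CYCLIC_REASONS})

    def validate(self) -> None:
        if self.n_presses < 0:
            raise ValueError("n_presses must be >= 0")
        mix = self.mix or tuple(1 / len(self.exam_classes)
                                for _ in self.exam_classes)
        if len(mix) != len(self.exam_classes):
            raise ValueError("mix length must equal number of exam classes")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("mix proportions must sum to 1")
        probs = [self.default_reject_prob, self.excluded_rate,
                 *self.reject_prob.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not self.operators or not self.exam_classes:
            raise ValueError("need at least one operator and one exam class")

    def p_for(self, operator: str, cls: str) -> float:
        return self.reject_prob.get((operator, cls),
                                    self.default_reject_prob)


@dataclass
class StratumTruth:
    configured_p: float
    n_events: int = 0
    n_rejected: int = 0


@dataclass
class GroundTruth:
    """Realized per-stratum counts alongside the configured probabilities."""

    strata: dict[tuple[str, str], StratumTruth]
    n_presses: int
    n_rejected: int
    n_excluded: int


@dataclass
class SimulationResult:
    pairs: list[RecordPair]
    events: list[ExposureEvent]
    truth: GroundTruth


def simulate_operations(config: SimulationConfig) -> SimulationResult:
    """Simulate an operations stream press by press.

    Reproducible given the config seed (one private generator stream, no
    global state); the emitted log round-trips through ingest.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mix = np.asarray(config.mix or
                     [1 / len(config.exam_classes)] * len(config.exam_classes))
    reasons = sorted(config.reason_distribution)
    rweights = np.asarray([config.reason_distribution[r] for r in reasons],
                          dtype=float)
    rweights = rweights / rweights.sum() if len(rweights) else rweights

    strata = {(op, c.name): StratumTruth(configured_p=config.p_for(op, c.name))
              for op in config.operators for c in config.exam_classes}
    pairs: list[RecordPair] = []
    n_rej = n_excl = 0

    for i in range(config.n_presses):
        op = config.operators[int(rng.integers(len(config.operators)))]
        ci = int(rng.choice(len(config.exam_classes), p=mix))
        cls = config.exam_classes[ci]
        mult = cls.multiplicity
        if isinstance(mult, tuple):
            mult = int(rng.integers(mult[0], mult[1] + 1))
        when = _BASE + _dt.timedelta(seconds=90 * i)
        uid = f"{_UID_ROOT}.9.{config.seed}.{i + 1}"

        excluded = bool(rng.random() < config.excluded_rate)
        rejected = False
        if not excluded:
            st = strata[(op, cls.name)]
            st.n_events += 1
            rejected = bool(rng.random() < st.configured_p)
            if rejected:
                st.n_rejected += 1
                n_rej += 1
        else:
            n_excl += 1

        for m in range(mult):
            rec = _record(config.system, op,
                          when + _dt.timedelta(seconds=2 * m),
                          cls.acquisition_type, uid, i + 1,
                          anatomy=cls.anatomy, view=cls.view,
                          protocol_id=cls.name)
            if excluded:
                broad = 8 if rng.random() < 0.5 else 9
                rj = RejectInfo(is_reject=True, reason_broad=broad,
                                reason_detailed=str(broad),
                                reject_datetime=when + _dt.timedelta(minutes=1))
            elif rejected:
                code = reasons[int(rng.choice(len(reasons), p=rweights))] \
                    if reasons else "1.1"
                rj = RejectInfo(is_reject=True,
                                reason_broad=int(code.split(".")[0]),
                                reason_detailed=code,
                                reject_datetime=when + _dt.timedelta(minutes=1))
            else:
                rj = RejectInfo()
            pairs.append((rec, rj))

    events = assign_status(group_into_events(pairs))
    truth = GroundTruth(strata=strata, n_presses=config.n_presses,
                        n_rejected=n_rej, n_excluded=n_excl)
    return SimulationResult(pairs=pairs, events=events, truth=truth)


def config_from_json(text: str) -> SimulationConfig:
    import json
    doc = json.loads(text)
    classes = tuple(
        ExamClass(name=c["name"],
                  acquisition_type=AcquisitionType(
                      c.get("acquisition_type", "SINGLE")),
                  multiplicity=(tuple(c["multiplicity"])
                                if isinstance(c.get("multiplicity", 1), list)
                                else int(c.get("multiplicity", 1))),
                  view=c.get("view"), anatomy=c.get("anatomy"))
        for c in doc.get("exam_classes", [{"name": "single"}]))
    per = {}
    for key, p in doc.get("reject_prob", {}).items():
        op, _, cname = key.partition("|")
        per[(op, cname)] = float(p)
    cfg = SimulationConfig(
        n_presses=int(doc.get("n_presses", 1000)),
        seed=int(doc.get("seed", 0)),
        system=doc.get("system", "TEST-DR-SIM"),
        operators=tuple(doc.get("operators", ("TEST-TECH-1",))),
        exam_classes=classes,
        mix=tuple(doc["mix"]) if "mix" in doc else None,
        default_reject_prob=float(doc.get("default_reject_prob", 0.08)),
        reject_prob=per,
        excluded_rate=float(doc.get("excluded_rate", 0.0)),
        reason_distribution=dict(doc.get(
            "reason_distribution", {c: 1.0 for c in _CYCLIC_REASONS})),
    )
    cfg.validate()
    return cfg
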