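"""Standardized reject-reason schema.

Two levels: nine fixed broad categories shared by every institution, and a
customizable detailed level whose codes are dotted extensions of their broad
parent (``"1.2"`` under category 1).  Vendor free-text reasons are mapped
onto the schema through an ordered, case-insensitive glob pattern list so
tallies stay comparable across fleets of mixed manufacturers.

Categories 8 (practitioner-directed) and 9 (no patient exposure / test) are
excluded from reject-rate arithmetic: neither reflects technologist imaging
performance, and category 9 involves no patient dose at all.

There is deliberately no "re-processed / non-clinical" pseudo-category:
such a label invites misuse as an uncounted escape hatch.  Vendor strings
carrying it are mapped to category 9 by a default pattern (so the rows stay
visible but uncounted) and flagged via a warning counter.
"""

from __future__ import annotations

import fnmatch
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

#: The fixed broad level: ids are exactly 1..9 and immutable.
BROAD_CATEGORIES: tuple[tuple[int, str], ...] = (
    (1, "Patient positioning"),
    (2, "Patient motion"),
    (3, "Artifacts"),
    (4, "Image contrast or noise"),
    (5, "Incorrect selection (protocol, detector)"),
    (6, "Wrong body part or patient"),
    (7, "Equipment issue"),
    (8, "Practitioner-directed"),
    (9, "No patient exposure/test"),
)

#: Broad ids excluded from reject-rate numerator and denominator.
NON_COUNTABLE = frozenset({8, 9})

_DEFAULT_DETAILED: tuple[tuple[str, int, str], ...] = (
    ("1.1", 1, "Rotation/tilt"),
    ("1.2", 1, "Anatomy cut-off"),
    ("1.3", 1, "Patient orientation"),
    ("2.1", 2, "Voluntary motion"),
    ("2.2", 2, "Involuntary motion"),
    ("3.1", 3, "Known object"),
    ("3.2", 3, "Grid lines or similar artifact"),
    ("3.3", 3, "Nonuniformity or defect visible"),
    ("4.1", 4, "Inappropriate image contrast"),
    ("4.2", 4, "Unacceptable noise/underexposure"),
    ("4.3", 4, "Saturation/overexposure"),
    ("4.4", 4, "Grid use error"),
    ("5.1", 5, "Incorrect protocol selected"),
    ("5.2", 5, "Detector not correctly selected or initialized"),
    ("6.1", 6, "Body part imaged does not match order"),
    ("6.2", 6, "Patient imaged does not match order"),
    ("7.1", 7, "Equipment failed during exposure"),
    ("8", 8, "Practitioner-directed"),
    ("9", 9, "No patient exposure/test"),
)

#: Default vendor patterns routing "re-processed"/"non-clinical" labels to
#: category 9 so they are excluded from RR but never silently dropped.
_REPROCESSED_PATTERNS: tuple[tuple[str, int, Optional[str]], ...] = (
    ("*re-processed*", 9, "9"),
    ("*reprocessed*", 9, "9"),
    ("*non-clinical*", 9, "9"),
    ("*nonclinical*", 9, "9"),
)


@dataclass(frozen=True)
class DetailedCode:
    code: str
    parent: int
    label: str


@dataclass(frozen=True)
class VendorPattern:
    """Case-insensitive glob; first match in config order wins."""

    pattern: str
    broad: int
    detailed: Optional[str] = None


@dataclass
class TaxonomyConfig:
    detailed: list[DetailedCode] = field(default_factory=list)
    vendor_map: list[VendorPattern] = field(default_factory=list)

    @property
    def broad(self) -> tuple[tuple[int, str], ...]:
        return BROAD_CATEGORIES

    def find_detailed(self, code: str) -> Optional[DetailedCode]:
        for d in self.detailed:
            if d.code == code:
                return d
        return None


def default_taxonomy() -> TaxonomyConfig:
    """The standard schema with the suggested detailed defaults and the
    re-processed/non-clinical safety patterns."""
    return TaxonomyConfig(
        detailed=[DetailedCode(*t) for t in _DEFAULT_DETAILED],
        vendor_map=[VendorPattern(*p) for p in _REPROCESSED_PATTERNS],
    )


@dataclass(frozen=True)
class ClassifyResult:
    broad: Optional[int]
    detailed: Optional[str]
    matched: bool
    #: True when the input matched a re-processed/non-clinical fallback
    #: pattern — counted separately so misuse of such vendor labels surfaces.
    reprocessed_label: bool = False


def classify_reason(vendor_reason: str,
                    config: TaxonomyConfig) -> ClassifyResult:
    """Map a vendor free-text reject reason onto the schema.

    The first pattern (in config order) matching case-insensitively wins;
    an unmatched input is a data condition (``matched=False``), not an error.
    """
    text = vendor_reason.strip().lower()
    for pat in config.vendor_map:
        if fnmatch.fnmatchcase(text, pat.pattern.lower()):
            repro = any(pat.pattern == p[0] for p in _REPROCESSED_PATTERNS)
            return ClassifyResult(pat.broad, pat.detailed, True, repro)
    return ClassifyResult(None, None, False)


def is_countable(broad: int) -> bool:
    """Whether a broad category participates in reject-rate arithmetic.

    False for practitioner-directed (8) and non-patient/test (9) exposures.
    """
    if not 1 <= broad <= 9:
        raise ValueError(f"broad category must be in 1..9, got {broad}")
    return broad not in NON_COUNTABLE


def validate_taxonomy(config: TaxonomyConfig):
    """Check detailed codes and vendor patterns; returns a ValidationReport."""
    from .data_model import ValidationReport
    rep = ValidationReport()
    seen: set[str] = set()
    valid_broad = {bid for bid, _ in BROAD_CATEGORIES}
    for d in config.detailed:
        prefix = d.code.split(".", 1)[0]
        if not prefix.isdigit() or int(prefix) != d.parent:
            rep.errors.append(
                f"detailed code {d.code!r} prefix does not match parent "
                f"category {d.parent}")
        if d.parent not in valid_broad:
            rep.errors.append(f"detailed code {d.code!r} has unknown parent "
                              f"{d.parent}")
        if d.code in seen:
            rep.errors.append(f"duplicate detailed code {d.code!r}")
        seen.add(d.code)
    for pat in config.vendor_map:
        if pat.broad not in valid_broad:
            rep.errors.append(f"vendor pattern {pat.pattern!r} maps to "
                              f"unknown category {pat.broad}")
        elif pat.detailed is not None:
            d = config.find_detailed(pat.detailed)
            if d is None:
                rep.errors.append(f"vendor pattern {pat.pattern!r} maps to "
                                  f"unknown detailed code {pat.detailed!r}")
            elif d.parent != pat.broad:
                rep.errors.append(
                    f"vendor pattern {pat.pattern!r} detailed code "
                    f"{pat.detailed!r} not under category {pat.broad}")
    return rep


# ---------------------------------------------------------------------------
# JSON config document

def to_json(config: TaxonomyConfig) -> str:
    doc = {
        "schema": "rejana-taxonomy/1",
        "broad": [{"id": b, "name": n} for b, n in BROAD_CATEGORIES],
        "detailed": [{"code": d.code, "parent": d.parent, "label": d.label}
                     for d in config.detailed],
        "vendor_map": [{"pattern": p.pattern, "broad": p.broad,
                        "detailed": p.detailed} for p in config.vendor_map],
    }
    return json.dumps(doc, indent=2, sort_keys=False)


def from_json(text: str) -> TaxonomyConfig:
    """Load a taxonomy config document.

    The broad level in the document is informational only: broad ids and
    names are fixed and any attempt to alter them is rejected.
    """
    doc = json.loads(text)
    if "broad" in doc:
        got = [(int(b["id"]), b["name"]) for b in doc["broad"]]
        if got != list(BROAD_CATEGORIES):
            raise ValueError("broad categories are fixed and cannot be altered")
    cfg = TaxonomyConfig(
        detailed=[DetailedCode(d["code"], int(d["parent"]), d.get("label", ""))
                  for d in doc.get("detailed", [])],
        vendor_map=[VendorPattern(p["pattern"], int(p["broad"]),
                                  p.get("detailed"))
                    for p in doc.get("vendor_map", [])],
    )
    rep = validate_taxonomy(cfg)
    if rep.errors:
        raise ValueError("invalid taxonomy config: " + "; ".join(rep.errors))
    return cfg
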