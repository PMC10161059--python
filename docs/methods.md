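# Methods

## The counting model

The unit of analysis is the **exposure event**: all raw images produced by
one continuous actuation of the exposure button, identified by a shared
irradiation-event UID. An event's status is a pure function of its members:

- **DIAGNOSTIC** — at least one member image was not rejected. A press that
  yielded a usable image is a success, however many sibling images were
  discarded; partially-rejected events are tallied separately
  (`n_partially_rejected_events`) for transparency but never counted as
  rejects.
- **REJECTED** — every member was rejected and at least one rejection
  carries a countable reason (broad categories 1–7).
- **EXCLUDED** — every member was rejected and all reasons are
  practitioner-directed (8) or non-patient/test exposures (9).

The reject rate is `RR = |REJECTED| / (|REJECTED| + |DIAGNOSTIC|)`.
Excluded events leave both numerator and denominator: category 9 involves no
patient exposure at all, and category 8 repeats are procedure-driven, so
keeping either in the denominator would dilute a technologist-performance
measure. Because the denominator treatment of category 8 is genuinely
arguable, `denominator_policy="include-cat8"` keeps those presses in
`N_tot` (never in `N_rej`); the default remains full exclusion.

`compute_image_based_rate` implements the per-image count purely to
demonstrate its bias: with mixed multiplicities the image rate is a
multiplicity-weighted average of per-class rates rather than the per-press
rate. With zero countable events the rate is an explicit null, rendered as
`UNDEFINED`, never a division error.

Rates are exact `fractions.Fraction` values internally. Rendering uses
percent with one decimal, except that rates whose exact percentage needs at
most two decimals render exactly (`8%`, `7.5%`, `11.25%`); rounding is
half-up. This keeps reports deterministic and byte-identical across runs.

## Event grouping

Records sharing an irradiation-event UID form one event. Records without a
UID (common on CR and digital-retrofit units without generator integration):
single-exposure records become singleton events; multi-acquisition records
are grouped by same system + same acquisition type + timestamps within a
10-second window (configurable), and such events are flagged
`heuristic_grouping` so reports can state how much of the denominator rests
on the heuristic. Exposures that produce no image at all are invisible to
any log-based analysis; no imputation is attempted.

When a REJECTED event's members carry different reasons, strata by reason
use the **last-rejected** member's reason (by reject timestamp, ties to the
lexicographically smallest code): the final rejection is what left the press
without a diagnostic image.

## Taxonomy

Broad categories 1–9 are fixed; the detailed level is institution-
customizable, constrained only so that each code's numeric prefix matches
its parent. Vendor free-text reasons are mapped by an ordered list of
case-insensitive glob patterns; first match wins, which makes resolution
deterministic when vendor strings are ambiguous. There is deliberately no
"re-processed/non-clinical" category: the label invites misuse as an
uncounted escape hatch. Default patterns route such vendor strings to
category 9 (excluded but visible) and the classifier flags them so misuse
can be monitored. Category-6 rejects (wrong patient/body part) are potential
medical errors; reports carry a separate `n_wrong_patient_rejects` counter
but counting is not suppressed.

Taxonomy config JSON: `{"detailed": [{"code", "parent", "label"}],
"vendor_map": [{"pattern", "broad", "detailed"}]}`; an optional `broad`
block is verified against the fixed list and any alteration is rejected.

## Ingest

The canonical log is a UTF-8, RFC-4180 CSV with one row per acquisition and
fixed columns; reject columns are empty for non-rejects. Write→parse is the
identity on all present fields (floats via `repr`, timestamps via ISO-8601).
Vendor dialects declare column maps, per-field `strptime` formats, the value
set meaning "rejected", and units: tube charge is stored only as µAs (mAs
inputs lack precision and are converted ×1000), SID in mm (cm inputs ×10).
Per-row parse failures are collected with row numbers, never fatal.
Timestamps are stored timezone-aware; naive inputs are assumed local and
flagged with a warning.

Split exposure/reject reports are merged read-only by user-chosen link keys;
reject rows matching zero or multiple exposure rows are reported, never
dropped, and an all-blank key (an anonymized file) is called out as the
likely cause. PHI (MRN, accession) is retained by default — it is what links
a study to its technologist and its order — with redaction available only at
export, after operator resolution.

DICOM extraction reads header metadata only (pixel data is never touched).
Paired date+time attributes combine into one timestamp; a missing time
defaults to midnight with a warning. The dose-area-product attribute is
stored in Gy·cm² (the header carries dGy·cm², converted ×0.1). Private
elements are captured opaquely into `processing_params`. Acquisition type
and receptor type have no consistent public tag, so dialects or callers
must supply them. KOS rejection notes are modeled at the information level
(note UID, referenced instance UIDs, the fixed "Rejected for Quality
Reasons" concept, reason text); `kos_to_dicom_dataset` renders a minimal
pydicom KO dataset for interoperability experiments. Operator resolution
prefers the per-acquisition login and falls back to an accession→operator
map; lead-marker OCR is out of scope by design.

## Thresholds

Defaults follow the community recommendations: adult lower/target/upper =
5/8/10%, pediatric target/upper = 5/7% with no lower bound. Flags are
`ABOVE_UPPER` strictly above the upper bound, `BELOW_LOWER` strictly below
the lower (a too-low rate can mean rejects are being hidden or misfiled),
`WITHIN` otherwise, `UNDEFINED` for a null rate. Boundary values flag
`WITHIN`.

## Synthetic data

The two fixture scenarios reproduce canonical mixed-workload arithmetic:
(a) 450 single-exposure presses (67 rejected) + 50 four-image pasting
presses (4 fully rejected); (b) 360 dual-energy PA presses (27 rejected)
+ 360 single LAT presses (54 rejected). Reject flags are spread evenly over
each class (Bresenham spacing) and reasons cycle over detailed codes of
categories 1–5 so taxonomy stratification is exercised; the fixtures are
deterministic and byte-identical across runs. All identifiers use a reserved
`TEST-` prefix.

The stochastic simulator draws, per press, an operator (uniform), an exam
class (configured mix), whether the press is excluded (category 8/9, with
configured rate), and otherwise whether it is fully rejected with the
per-(operator, class) probability; rejected presses draw reasons from a
configurable distribution over detailed codes. Multiplicities: dual energy
2, image pasting 3–5 (sampled), tomosynthesis 24 by default ("dozens" is the
field's order of magnitude; configurable). One private `numpy` generator
stream per simulation, seeded explicitly. The ground-truth summary returns
configured probabilities and realized counts per stratum.

What the simulator does **not** emulate: partial rejections within a press
(real technologists sometimes reject one image of a pasting set and keep the
rest — the analysis handles this; randomized event-set tests cover it),
realistic technique factors or EI physics, order/RIS workflow, or
time-varying reject probabilities. Passing parameter-recovery tests
therefore shows the estimator is correct under binomial sampling, not that
any particular clinic meets its thresholds.

## Verification sizes and numerical choices

Randomized checks use 1000 event sets of ≤50 events for oracle equivalence
against a literal button-press counter, 1000 randomized records for log
roundtrips, and 10,000-press simulations for parameter recovery judged
against exact central 99% binomial intervals (scipy CDF inversion) — sizes
chosen so the whole suite runs in seconds while leaving the binomial bands
narrow (±0.7 percentage points at n = 10,000, p = 0.08). The deviation-index
consistency check uses a 0.15 tolerance to absorb vendors rounding the
exposure index to integers, and is a warning, not an error.

## Known limitations

- Grouping without UIDs is heuristic; the 10 s window can merge rapid-fire
  retrofit exposures from one detector or split slow pasting sequences.
- Exposures that never produce an image (retrofit units without generator
  integration) cannot appear in any log-based denominator.
- No statistical process control or confidence intervals on RR; the report
  carries exact counts so either can be layered on top.
- The KOS model is informational; the DICOM adapter emits a minimal dataset,
  not a fully conformant IOD.
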