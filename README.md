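# rejana — vendor-neutral reject analysis for digital radiography

A rejected radiograph is a patient exposure that never reaches the
radiologist: dose delivered with no diagnostic benefit. Tracking the reject
rate is a core quality-control activity in radiography departments, but
every vendor exports reject data in a different shape, with different reason
labels, and often counted the wrong way. `rejana` gives medical physicists
and QC technologists one canonical data model, a standardized reject-reason
taxonomy, and a correctly counted reject rate across a mixed-vendor fleet.

## The statistic

The reject rate is defined per **exposure-button press** (irradiation
event), not per image:

```
RR = N_rej / N_tot
```

where `N_rej` is the number of presses that produced no diagnostic image and
`N_tot` the total number of presses. Multi-acquisition exams — dual energy
(2 exposures per press), image pasting (3–5), tomosynthesis (dozens) — make
the distinction matter: counting images instead of presses weights
multi-image exams arbitrarily and biases the rate. Presses whose only
rejections are practitioner-directed (category 8) or non-patient/test
exposures (category 9) are excluded from numerator and denominator, since
neither reflects technologist imaging performance. Rates are kept as exact
rationals and rounded only at render time, and are flagged against
investigation thresholds (adult: target 8%, investigate above 10% or below
5%; pediatric: target 5%, investigate above 7%).

## What's in the box

- `rejana.data_model` — canonical acquisition/reject record types with
  validation and a canonical single-file CSV log format.
- `rejana.taxonomy` — nine fixed broad reject-reason categories, a
  customizable detailed level, and ordered glob mapping of vendor free-text
  reasons.
- `rejana.ingest` — vendor log dialects (column maps, datetime formats,
  unit conversions), legacy split exposure/reject report merging, DICOM
  header extraction (pydicom), KOS-style rejection notes, operator
  resolution via accession lookup.
- `rejana.analysis` — event grouping (by irradiation-event UID, with a
  flagged timestamp-window fallback for retrofit units), event status
  rules, event-based and image-based rates, stratification, thresholds.
- `rejana.reporting` — deterministic CSV/JSON reports and review worklists,
  with an explicit PHI-redaction switch.
- `rejana.synthetic` — worked-scenario fixtures and a seeded operations
  simulator with ground truth, so everything is testable without real data.

## Worked example

Generate the mixed single-exposure / image-pasting fixture (500 button
presses: 450 single with 67 rejects, 50 four-image pasting events with 4
fully rejected) and analyze it:

```
$ rejana fixtures --scenario pasting --out fixtures/
$ rejana report --in fixtures/pasting.csv --by acquisition_type
# schema,rejana-report/1
# population,ADULT
# thresholds_pct,5,8,10
# denominator_policy,exclude
acquisition_type,n_total_events,n_rejected_events,n_excluded_events,reject_rate,threshold_flag
IMAGE_PASTING,50,4,0,8%,WITHIN
SINGLE,450,67,0,14.9%,ABOVE_UPPER
OVERALL,500,71,0,14.2%,ABOVE_UPPER
```

Single-exposure exams run at 67/450 = 14.9%, image pasting at 4/50 = 8%,
and the combined event-based rate is 71/500 = 14.2% — above the adult upper
threshold, so the stream is flagged for investigation. Counting individual
images instead would report 83/650 = 12.8%, understating the problem
because each pasting press contributes four images:

```python
from rejana import scenario_image_pasting, compute_image_based_rate, format_percent
events = scenario_image_pasting().events
print(format_percent(compute_image_based_rate(events)))  # -> 12.8%
```

The same machinery ingests real vendor logs via a dialect JSON
(`rejana report --in vendor.csv --dialect dialect.json ...`); see
`docs/methods.md` for the dialect and taxonomy config schemas.

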