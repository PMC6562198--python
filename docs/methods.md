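# Methods

## The model

`ewsfusion` implements a combined early warning score for adult emergency
medical admissions on general wards. Two established aggregate scores are
fused:

* **NEWS** — the National Early Warning Score, an integer 0–20 computed from
  each set of seven vital-sign inputs (respiratory rate, SpO₂, supplemental
  oxygen, temperature, systolic blood pressure, heart rate, consciousness on
  the AVPU scale, with GCS values converted to AVPU first).
* **LDT-EWS** — a laboratory early warning score, an integer 0–15 computed
  from banded values of seven routine blood analytes (albumin, creatinine,
  haemoglobin, potassium, sodium, urea, white cell count), with sex-specific
  cut-offs where reference ranges differ by sex.

Because laboratory panels arrive roughly daily while vital signs arrive every
few hours, the two scores are asynchronous. At each vital-sign observation
the most recent value of each analyte is carried forward (up to a 120 h
horizon, after which it is treated as absent) and the combined index is

    risk = ω · LDTEWS/15 + (1 − ω) · NEWS/20,   ω = β · (1 − TimeSinceLabs/120)

where `TimeSinceLabs` is the age in hours of the *newest* linked laboratory
result, capped at 120. When every analyte has aged out, ω = 0 and the index
reduces exactly to NEWS/20. The laboratory share of the index therefore
ranges over [0, β] and the vitals share over [1 − β, 1]; with the reference
coefficient β = 0.26 these are 0–26% and 74–100%.

β is the only fitted quantity. It is estimated by grid search
(β = 0.01, 0.02, …, 0.99) with a 10-fold cross-validation-style average: the
data are partitioned at random at the *admission* level (all observations of
an admission share a fold, preventing within-admission leakage), the index is
evaluated on each fold at every candidate β, and the chosen β maximises the
mean across-fold AUROC against the primary outcome. Ties break to the
smallest β. A fold containing a single outcome class makes AUROC undefined
and raises an error rather than silently skipping the fold.

## Outcomes and cohort construction

The primary outcome of an observation is the *first* of in-hospital death or
unanticipated ICU admission within the following 24 h; the two events are
also labelled separately as secondary outcomes. The window is half-open,
`(obs_time, obs_time + 24 h]` — an event at exactly +24 h counts. This
boundary convention is our choice; the alternative changes labels only for
events falling on the exact minute boundary.

Inclusion: age ≥ 16, emergency admission method, qualifying specialty
(config data; synthetic cohorts use a single code), at least one complete
vital-sign set. Exclusions: (a) discharged alive before the first midnight
after admission; (b) no observations in the 24 h before the earliest of ICU
admission, discharge or death — a proxy for end-of-life pathways. The
reference point for (b) is the event time itself, not a midnight boundary.
Observations recorded at or after an admission's first event are dropped
from evaluation (the patient is no longer at risk on a ward). Audit counts
use first-failing-criterion attribution, so flow-diagram counts always sum
to the input count.

## Linkage conventions

* Ages are computed from the time a result was *received by the laboratory*
  (the recorded timestamp), as exact real-valued hours.
* A result received strictly after the observation time is never used;
  receipt exactly at the observation time counts with age 0. Exact ties in
  receipt time for the same analyte break to the higher value.
* Analytes older than the horizon are absent both for LDT-EWS scoring and
  for the `TimeSinceLabs` minimum — a single "aged-out ⇒ absent" rule.
* Labs belong to an admission if received between the calendar day before
  admission (covering overnight emergency-department workups) and the day
  of discharge.
* An analyte that is absent scores zero in LDT-EWS; an observation with no
  usable labs has LDT-EWS 0 and `TimeSinceLabs` 120.

## Scoring-table conventions

Band definitions live in a YAML config (`data/scoring_table.yaml`), not in
code. Every band is lower-inclusive/upper-exclusive; printed inclusive
cut-offs from score charts were converted once at transcription time, with
values exactly on a cut-off scoring in the higher-risk band (conservative
for a safety score). Temperature is scored at 0.1 °C resolution; other
inputs are not rounded. The shipped laboratory bands are this package's
default transcription: clinically conventional cut-offs, sex-specific for
creatinine and haemoglobin, per-analyte maxima summing to the declared
aggregate maximum of 15. The GCS→AVPU conversion (15→A, 13–14→V, 9–12→P,
3–8→U) is also config data. `validate_tables` checks that bands tile the
real line without gaps or overlaps and that attainable maxima equal the
declared 20 and 15.

## Evaluation

The c-statistic is the Mann–Whitney concordance probability computed from
midranks; confidence intervals use the DeLong structural-components variance
with a normal approximation, clipped to [0, 1] (an all-ties degenerate
variance returns the full interval with a warning). ROC curves come from
scikit-learn without threshold pruning, so the trapezoidal area equals the
c-statistic exactly. Calibration bins the index into equal-width bins
(default 0.05 — the index is continuous, so per-value observed risks are not
operational) and compares observed event rates with mean predicted score.
Threshold analysis flags `score ≥ threshold` and finds, for a reference
operating point (e.g. NEWS ≥ 5 or ≥ 7), the smallest threshold on another
score whose specificity is at least the reference's.

## Synthetic cohorts

No ward EHR data can ship with the package, so all tests run on synthetic
cohorts from a seeded generator that emulates the structure of such
extracts: median age ≈ 73 (16 + 84·Beta(5,2)), ≈ 49% male, right-skewed
length of stay (log-normal, median ≈ 3.7 days), vital-sign intervals
log-normal with median 6 h, laboratory panels drawn with probability 0.95
near admission (timestamped up to 8 h before the formal admission time)
and geometrically declining daily probability thereafter, 8% per-analyte
missingness and 4% of admissions with no labs at all. A reflected Gaussian
random walk per admission (latent "severity" on [0, 1]) drives both vitals
and analytes through monotone power transforms, so derangement is
correlated across channels; power transforms keep typical severities inside
zero-weight bands, giving the realistic right-skewed score distribution
(median NEWS 0–3). Laboratory severity adds an admission-level offset
(SD 0.25), so the blood picture carries signal not fully visible in the
vitals — without this, the relative weighting of the two scores would be
poorly identified.

Events are generated per inter-observation interval with probability
`expit(a + 10·risk) · Δt/24`, where `risk` is NEWS/20 in the default mode or
the combined index at a chosen planted β\* in planted mode (computed through
the package's own linkage/scoring/decay code). The intercepts
(−9.3 default, −8.8 planted — the two risk drivers have different upper
tails) were calibrated once so that ≈ 4.8% of admissions die in hospital and
≈ 1.1% have an unanticipated ICU admission, and frozen. 81% of events are
deaths. Death sets the discharge time; observations at or after the event
are removed. Each admission consumes its own pseudo-random substream spawned
from the cohort seed by admission index, so enlarging a cohort leaves
earlier admissions bit-identical.

What the generator does *not* model: laboratory turnaround lag, analyte
trends or baselines (chronic vs acute derangement), specialty case-mix
differences, DST or timezone effects, inter-observer measurement practices.
Passing tests therefore demonstrate the machinery's correctness and the
recoverability of the decay coefficient under the stated generative
assumptions, not clinical performance on real admissions.

## Problem sizes and numerical choices

Parameter-recovery experiments use cohorts of 2,000 admissions
(≈ 30,000 observations) and 20 seeded replicates; the recovery criterion is
that the *median* fitted β lies within ±0.05 (five grid steps) of the
planted 0.26 — individual replicates scatter more because the mean-AUROC
objective is flat near its optimum. Rate-calibration checks use 5,000
admissions; pipeline determinism 500. All index arithmetic is IEEE double
precision with no intermediate rounding; 3-decimal rounding is for display
only. Timestamps are naive local clock times at minute resolution and
elapsed hours are exact differences; "day" boundaries are local calendar
midnights.

## Known limitations

* A single decay horizon and a single linear decay are shared by all seven
  analytes; per-analyte phase-out is plausible future work.
* The shipped laboratory banding is a package default, not a canonical
  chart; supply your own YAML for a different instrument.
* The fitting objective is discrimination only; β is not tuned for
  calibration.
* The specialty list is configuration; the package does not attempt to
  classify specialties as higher-risk.
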