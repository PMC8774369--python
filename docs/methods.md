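# Methods

## The classification model

The MNCD state is the product of four axes: two sets of four binary
sub-axis flags (motor: fluctuations, dyskinesia, axial, tremor; non-motor:
neuropsychiatric, autonomic, sleep/fatigue, pain/sensory) and two ordinal
three-level axes (cognition C and dependency D). A sub-axis flag is 1 when
the symptom is present *and clinically relevant in the rater's judgment*;
that judgment is upstream of this package — no severity threshold is
computed here, the tool records the rater's 0/1 call. The M and N
subscripts are always derived as flag sums, never independently stored.

The state space has 2⁴ × 2⁴ × 3 × 3 = 2304 elements and is small enough
to enumerate, which the test suite and acceptance script exploit: every
staging property (totality, monotonicity in C and D, flag-insensitivity
once C or D is positive) is verified exhaustively rather than sampled.

## Staging policy

The published stage rules overlap (the stage-3 row admits D = 1 while
stage 4 requires D = 2) and do not literally cover dementia without
basic-ADL dependency (C = 2 with D ∈ {0, 1}): the stage-3 narrative reads
"cognitive impairment (no dementia)". Two design choices make `stage` a
total function:

1. **Severity-descending precedence.** Rules are matched top-down from
   stage 5; the first match wins. This resolves the stage-3/stage-4
   overlap deterministically and reproduces all five published worked
   examples.
2. **Uncovered states are staged, not rejected.** C = 2 with D ≤ 1 is
   assigned stage 3 (the least-severe stage consistent with cognitive
   impairment being present) and flagged `table3_conformant=False` with an
   explanatory note. Rejecting rater-entered data would lose information;
   the flag keeps the policy auditable. The same states draw a validation
   WARNING when D = 0, since dementia is defined by overt functional
   decline and full ADL independence is clinically incoherent with it —
   but it remains a warning, never an error.

Under this policy the stage counts over the 2304 states are
1 / 255 / 1280 / 512 / 256 for stages 1–5; the 1 and 255 follow directly
from the stage-1 and stage-2 predicates, and an independently coded
literal-predicate oracle in the tests confirms the full distribution.

## Notation codec

Formatters are conservative, parsers liberal. The canonical output is
pure ASCII (`M2N3C2D2 (1010/1110/2/2)-20`) because the typographic form
used in print (subscripts, en-dash) does not survive plain-text systems.
The parser additionally accepts underscored subscripts (`M_2_N_3_...`),
the en-dash/em-dash time separator, flexible whitespace, and a trailing
period. Parsing enforces the structural invariants — each subscript must
equal its block's digit-sum and the parenthesized C/D must match the
subscripted ones — and names the offending axis in the error. Time
suffixes print as bare integers when whole and with at most two decimals
otherwise (a 6-month history is `-0.5`); the suffix is optional because
the notation is meaningful without it. The stage is never embedded in the
string: it is derivable, and storing it would invite inconsistency.

## Cohort files

CSV (one column per sub-axis: `m_fluct … n_pain_sensory, cognition,
dependency`, plus `patient_id`, `years_from_onset`) and JSON (array of
objects, same keys), UTF-8, header mandatory. Times are decimal years
from symptom onset, not calendar dates — date handling is site-specific
and out of scope. Unknown columns round-trip untouched; derived columns
(`notation`, `M`, `N`, `stage`, `table3_conformant`) can be written for
convenience but are never read back as authoritative: on read they are
recomputed and mismatches are logged as warnings. (patient, time) pairs
must be unique.

## The progression simulator

The simulator is a discrete-time multistate model on the visit grid:
baseline at symptom onset in the all-zero state, then visits every
`visit_interval_years` up to `horizon_years`. Between visits separated by
`dt`, each 0-flag turns on with probability 1 − (1 − h)^dt (h its annual
onset hazard on the probability scale), each 1-flag reverts with the
analogous remission probability (default 0), and C and D each advance at
most one ordinal level with their own hazards. Discrete visit-step
dynamics rather than continuous-time hazards were chosen because the
classification only exists at evaluation moments; the 1 − (1 − h)^dt form
makes the annual onset fraction invariant to the visit interval. With
`couple_dementia_dependency` the C 1→2 transition is gated on the
dependency level *at the start of the step* (D ≥ 1), encoding that
dementia entails functional decline. One shared NumPy generator is seeded
once per cohort and patients are processed in fixed order, so identical
configs give bit-identical cohorts.

Three presets emulate qualitatively distinct published monitoring
scenarios; their parameter values are illustrative, tuned by the package
authors, not estimated from any cohort:

* `long_term_dementia` — annual flag hazards 0.05–0.10, C/D hazards 0.10
  with coupling, 25-year horizon: slow accrual, dementia late and only
  after instrumental dependency.
* `late_onset_rapid` — C/D hazards 0.40/0.45, 6-month visits over 8
  years: dementia with basic-ADL dependency (stage 5) within a few years.
* `tremor_benign` — tremor onset hazard 0.90 with remission 0.10, all
  other hazards ≈ 0: since the config deliberately has no initial-state
  field, "tremor present from the start" is modelled as near-certain
  onset by the first follow-up; remission models improvement after
  intervention. Over 500 patients the median final stage is 2.

What the simulator does *not* emulate: mortality and drop-out, treatment
effects beyond flag remission, correlation between sub-axes, rater noise,
and irregular visit schedules. Passing simulator-based tests therefore
shows the pipeline's internal consistency under a clean generative model,
not validity on real clinical data — that is exactly what the planned
observational phase of the classification project is for.

## Longitudinal summaries and agreement

The stage between visits is a right-continuous step function (held from a
visit until the next), so per-patient time-in-stage sums exactly to the
follow-up duration and the final visit contributes no dwell time.
Transition counts are visit-to-visit stage pairs on a 5 × 5 matrix;
regressions are transitions to a strictly lower stage.

Agreement over a raters × items table reports observed agreement, Cohen's
kappa, and weighted kappa with linear (1 − |i−j|/(k−1)) or quadratic
(1 − (i−j)²/(k−1)²) weights; kappa values are computed with
scikit-learn's `cohen_kappa_score`. With more than two raters all
statistics are averaged over rater pairs — a pairwise design matching
inter-/intra-observer comparisons; Fleiss' kappa for panel designs is a
possible extension, not implemented. When all ratings fall in one
category, chance agreement is 1 and kappa is undefined: it is reported as
NaN, with observed agreement still returned. The large-sample standard
error √(p₀(1−p₀)/(n(1−pₑ)²)) of the unweighted kappa is reported for
interval construction but gates nothing. Kappa was chosen as the field's
standard agreement metric; this is an assumption of the package, not a
prescription of the classification itself.

## Numerical choices and problem sizes

* Exhaustive checks run over all 2304 states (milliseconds).
* Stochastic checks use fixed seeds: hazard calibration at n = 10,000
  patients × 1 step against 1 − (1 − h)^dt within 3 binomial standard
  errors; chance-level kappa at n = 10,000 items within 3 standard
  errors of 0; preset comparisons at n = 500 patients.
* Mean time-to-stage-5 comparisons average over patients who reach stage
  5 within the horizon (NaN-mean); censored patients are excluded rather
  than imputed at the horizon.
* The visit count is `floor(horizon/interval)` with a 1e-9 relative guard
  against floating-point shortfall on exact multiples.

## Known limitations

* One published worked example describes a 6-month history but prints the
  time suffix `–5`; the example is internally inconsistent. The package
  stores whatever time it is given and does not attempt to reconcile.
* Whether the stage-3 clause "at least, C or D = 1" was meant to exclude
  C = 2 is ambiguous in the source; the nonconformance flag records the
  ambiguity instead of guessing.
* Flags carry no severity gradation below the 0/1 threshold, so the tool
  cannot distinguish "mild but relevant" from "severe" within a sub-axis.
* The time suffix's optionality is a package decision; the source does
  not state whether it is mandatory.
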