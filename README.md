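# mncd

Tools for the **MNCD classification** of Parkinson's disease (PD) — a
four-axis, five-stage clinical staging system designed to give a quick
visual summary of a patient's condition at every clinic visit, in the
spirit of oncology's TNM classification.

A patient-visit is summarized as

```
M<m> N<n> C<c> D<d>  (mmmm/nnnn/c/d)-t
```

* **M** — motor symptoms, four binary sub-axes: motor fluctuations,
  dyskinesia, axial symptoms, tremor; the subscript *m* is the number of
  sub-axes present and clinically relevant (0–4);
* **N** — non-motor symptoms, four binary sub-axes: neuropsychiatric,
  autonomic, sleep/fatigue, pain/sensory; subscript *n* likewise 0–4;
* **C** — cognition: 0 normal, 1 mild cognitive impairment, 2 dementia;
* **D** — dependency for activities of daily living (ADL): 0 independent,
  1 dependent for instrumental ADL, 2 dependent for basic ADL;
* **t** — years from symptom onset.

From the state a stage 1–5 is derived: 1 (no relevant symptoms) · 2 (at
least one motor or non-motor symptom, C = D = 0) · 3 (mild cognitive
impairment and/or instrumental-ADL dependency) · 4 (basic-ADL dependency
without dementia) · 5 (dementia with basic-ADL dependency). The full state
space has 2⁴ × 2⁴ × 3 × 3 = 2304 states; the staging function is total
over all of them, and states the published rules do not literally cover
(dementia without basic-ADL dependency) are staged by an explicit,
flagged policy (see `docs/methods.md`).

The package is aimed at movement-disorder clinicians and methodologists
preparing validation studies of the classification: it provides the
notation codec, the stage derivation, cohort file I/O, a longitudinal
progression simulator for power/design work, trajectory summaries, and
inter-rater agreement statistics (observed agreement, Cohen's kappa,
weighted kappa) for inter-/intra-observer variability studies.

## Worked example

Stage a notation string (this is the third published worked example — a
patient six years from onset with motor fluctuations, dyskinesia, freezing
of gait, depression, mild cognitive impairment and instrumental-ADL
dependency):

```console
$ mncd stage --notation "M3N1C1D1 (1110/1000/1/1)-6"
M3N1C1D1 (1110/1000/1/1)-6 -> stage 3
```

Simulate a small tremor-dominant benign cohort and summarize it:

```console
$ mncd simulate --preset tremor_benign --n-patients 5 --seed 7 \
      --out demo.csv --with-derived
$ head -3 demo.csv
patient_id,years_from_onset,m_fluct,m_dysk,m_axial,m_tremor,n_neuropsych,n_autonomic,n_sleep_fatigue,n_pain_sensory,cognition,dependency,notation,M,N,stage,table3_conformant
p0001,0.0,0,0,0,0,0,0,0,0,0,0,M0N0C0D0 (0000/0000/0/0)-0,0,0,1,True
p0001,1.0,0,0,0,1,0,0,0,0,0,0,M1N0C0D0 (0001/0000/0/0)-1,1,0,2,True
$ mncd summarize demo.csv
patient_id	n_visits	first_stage	last_stage	regressions	follow_up_years
p0001	16	1	2	1	15
p0002	16	1	2	0	15
```

Patient `p0001` starts symptom-free (stage 1), develops disabling tremor
within a year (`M1 (0001)`, stage 2) and — this being the benign,
intervention-responsive scenario — oscillates between stages 1 and 2 over
15 years (the one `regressions` count is a tremor remission), never
progressing on the cognition or dependency axes.

The same operations are available as library calls:

```python
from mncd import parse_notation, stage
record = parse_notation("M1N3C0D2 (0010/1011/0/2)-4")
stage(record).stage   # 4
```

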