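# abit

A scoring engine for the **Awake Bruxism Identification Tool (ABIT)** — a
screening instrument that places children aged 8–12 on an "AB Spectrum" for
awake bruxism (masticatory muscle activity during wakefulness: repetitive or
sustained tooth contact and/or bracing or thrusting of the mandible). The
package is for clinical researchers and pediatric dentistry groups who need
to score ABIT administrations reproducibly, run test–retest reliability
analyses, and simulate cohorts to plan studies.

The instrument combines six components:

* three 3-question Likert triplets — parents' report (R1), child self-report
  (SR), parents' report after a week of guided observation (R2) — each
  question scored 0–4 (never … always; "don't know" carries no score);
* an analog ecological momentary assessment (EMA) diary: 7 days × 6 emoji
  slots, one painted per perceived event, positive at ≥ 4 painted days;
* a clinical exam: intraoral (ICA: hyperkeratosis and indentation findings)
  and extraoral (ECA: masseter/temporal hypertrophy) point sums, positive
  only when both sides show at least one finding.

A triplet whose only nonzero answer is a single "almost never", or a diary
painted on fewer than 4 days, is *null* — treated as non-positive and
contributing no points. The spectrum total sums the positive components'
raw scores (clinical points always count); categories are `Not AB`,
`AB based on R/SR`, `AB based on R/SR and EMA`, `AB based on EMA` and
`AB based on CA`, which combine. The reliability module implements
Cronbach's α, single-measures ICC (consistency and agreement forms) and
Lin's concordance correlation coefficient with a Fisher-z confidence
interval. A seeded generator simulates paired test/retest cohorts from a
latent per-child event rate with known ground truth. See
[docs/methods.md](docs/methods.md) for the full model, including why the
attainable spectrum maximum is 86 although the published description says
96.

## Worked example

```python
>>> python examples/score_one_child.py
  R1: raw  3  status positive
  SR: raw  1  status null
  R2: raw  3  status positive
 ICA: raw  1  status positive
 ECA: raw  1  status positive
 EMA: raw  4  status positive

spectrum total: 12
categories:     AB based on R/SR and EMA + AB based on CA
```

The two parent reports (3 points each) and the 4-day diary (4 points) put
this child in the combined report+EMA category; the self-report's lone
"almost never" is null and contributes nothing; one intraoral plus one
extraoral finding add 2 points and the clinical category.

A reliability study on simulated paired cohorts
(`python examples/reliability_study.py`, 50 children, latent test–retest
correlation 0.9):

```
Cronbach's alpha (R1):  0.959
Cronbach's alpha (R2):  0.972
ICC consistency:        0.984
ICC agreement:          0.982
Lin's CCC:              0.982  (95% CI 0.969-0.990)
```

The other examples show cohort simulation with ground truth
(`examples/simulate_and_score.py`) and the perceived-event count table
(`examples/pilot_event_counts.py`). The same operations are available from
the shell via the `abit` command (`simulate`, `score`, `reliability`,
`report` subcommands), which reads and writes the documented CSV/JSON-lines
cohort formats.

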