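# Data dictionary — long panel CSV

One row per participant per assessment wave; missing score cells are empty.

## Design columns

| column | type | description |
|---|---|---|
| `participant_id` | string | opaque participant identifier, unique with `wave` |
| `cluster` | int 1..6 | recruitment cluster (health-centre group) |
| `sequence` | int 1..3 | randomized crossover sequence of the cluster |
| `wave` | int 1..5 | assessment wave (1 = baseline) |
| `time_weeks` | float | weeks since baseline, `(wave-1) * 8` by default |
| `treatment` | 0/1 | post-crossover exposure at this wave |

## Covariates (constant within participant)

| column | type | description |
|---|---|---|
| `gender` | `female`/`male` | reference level `female` |
| `age` | years | truncated 18–70 in generated data |
| `profession` | `physician`/`nurse`/`other` | reference `physician` |
| `contract` | `temporary`/`nontemporary` | reference `nontemporary` |
| `trainee` | 0/1 | in-training (resident) status |

## Mediator scores

| column | instrument | range |
|---|---|---|
| `cd_risc` | Connor-Davidson Resilience Scale (10-item) | 0–40 |
| `ffmq_observe` | FFMQ-15 observing facet (mean) | 1–5 |
| `ffmq_describe` | FFMQ-15 describing facet | 1–5 |
| `ffmq_act` | FFMQ-15 acting-with-awareness facet | 1–5 |
| `ffmq_nonjudge` | FFMQ-15 nonjudging facet | 1–5 |
| `ffmq_nonreact` | FFMQ-15 nonreacting facet | 1–5 |
| `socs_self` | Sussex-Oxford Compassion Scale, self | 20–100 |
| `socs_other` | Sussex-Oxford Compassion Scale, others | 20–100 |
| `aaq2` | Acceptance and Action Questionnaire-II (higher = more avoidance) | 7–49 |

## Outcome scores

| column | instrument | range |
|---|---|---|
| `pss` | Perceived Stress Scale (PSS-10), primary outcome | 0–40 |
| `phq9` | Patient Health Questionnaire-9 (depression) | 0–27 |
| `gad7` | Generalized Anxiety Disorder-7 | 0–21 |
| `bsi_gsi` | Brief Symptom Inventory-18 Global Severity Index | 0–72 |

## Derived columns (added by `attach_baseline`)

| column | type | description |
|---|---|---|
| `<outcome>_baseline` | float | the participant's wave-1 value of the outcome |
| `is_analysis` | bool | true for waves >= 2 (rows entering the models) |
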