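# telecare

Analysis toolkit for annotated nurse-telecare conversation corpora in
chronic-disease management (heart failure and related cardiometabolic
conditions). It is written for researchers who hold call transcripts
annotated with per-utterance topics, dialogue acts and symptom attributes,
linked to patient profiles and inpatient admission records, and who want to

1. detect **lifestyle-focused calls** — calls where the share of utterances
   on lifestyle management rises unusually high for that patient,
2. compare the **content and structure** of focused vs not-focused calls
   with patient-clustered regression,
3. tabulate **expert concern evaluations** of calls, and
4. associate the number of focused calls per patient with **inpatient
   utilization** (admission counts and average length of stay).

A first-class synthetic-cohort generator produces datasets with planted
focus events and known couplings, so every stage can be tested end to end
without access to clinical data.

## The detection rule

For patient *p* and call *i* (merged so that same-day calls count once,
ordered by date), the **utterance ratio** of a topic is

```
r_i = (utterances on topic in call i) / (total utterances in call i)
```

A median-regression (τ = 0.5 quantile regression) line `r̂(i) = a + b·i` is
fitted per patient over call order, minimising Σ|r_i − a − b·i|. Call *i*
is **lifestyle-focused** iff it has topic content, `r_i > r̂(i)`, and either

- **jump**: `r_i − r_{i−1} ≥ δ_jump` (default 0.05, with `r_{−1} = 0`), or
- **sustained**: call *i−1* is focused and `r_i ≥ r_{i−1} − δ_sustain`
  (default 0.02).

Calls with topic content that fail the rule are *content-not-focused*;
calls with zero topic content are *no-content*. The norm is the patient's
own trajectory — no cohort-wide ratio threshold exists.

Group comparisons use OLS on a group indicator with CR1 cluster-robust
standard errors (clusters = patients, small-sample factor
G/(G−1)·(N−1)/(N−K), t(G−1) inference), Holm–Bonferroni families for
multiple comparisons, Spearman rank correlations (midranks, t
approximation), pooled-SD Cohen *d*, and Fleiss κ for annotation
reliability.

## Worked example

```python
from telecare import SyntheticConfig, generate_cohort, partition_calls
from telecare import associate_focus_with_utilization, build_utilization_summaries

dataset, truth = generate_cohort(SyntheticConfig(seed=42))
partition = partition_calls(dataset)
print(partition.group_counts())

summaries = build_utilization_summaries(dataset, partition.focus_call_counts())
res = associate_focus_with_utilization(summaries)["avg_los"]
print(f"rho = {res.rho:+.3f}, P = {res.p_value:.3f}, P_adj = {res.p_adjusted:.3f}")
```

prints

```
{'lifestyle_focused': 127, 'content_not_focused': 377, 'no_content': 135}
rho = -0.241, P = 0.091, P_adj = 0.183
```

The partition shows how the cohort's 639 calls split into the three focus
groups; the Spearman ρ of −0.24 recovers (with sampling noise) the −0.3
rank coupling the generator plants between a patient's focus-call count and
their average length of stay — more lifestyle-focused coaching associates
with shorter stays, not fewer admissions. The `examples/` directory walks
through every capability: cohort generation, focus detection, the
content/structure comparison, concern tabulation, and the utilization
association, each printing and explaining its numbers.

A thin CLI wraps the pipeline for shell use:

```sh
telecare generate --out data/ --seed 7
telecare detect --calls data/synthetic_calls.jsonl --patients data/synthetic_patients.csv --out out/
telecare run-all --config run.yaml --out out/
```

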