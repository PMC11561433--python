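# Methods

## Data model

A cohort bundles four record streams. **Calls** are ordered utterance
lists; every utterance carries exactly one topic from a 13-value inventory
(the predominant subject of the unit), an optional list of dialogue acts
(18 acts in 7 reporting categories — multiple acts may attach to one
utterance), and optional symptom/lifestyle/vitals attributes. **Patients**
carry demographics, comorbidity flags and a patient-specific intervention
window. **Admissions** are dated stays with an elective flag and a cause
category. **Concern records** hold an expert reviewer's judgment on a call:
a possibly-empty set of concern areas and a follow-up level. Utterance text
is optional throughout: every analysis consumes labels and counts only.

Calls sharing a (patient, date) key are merged into one conversation before
analysis — a dropped connection or separate caregiver/patient calls on the
same day are one clinical contact. Merging concatenates utterances in file
order, reindexes them contiguously, and is idempotent.

## Focus-call detection

For one patient's merged, date-ordered calls, the utterance ratio of the
target topic (default `lifestyle_management`) is the call's topic utterance
count over its total utterance count. The patient's norm is the τ = 0.5
quantile-regression line of ratio on call order (statsmodels `QuantReg`);
call order, not calendar time, is the abscissa because gaps between calls
carry no information about conversational norms. Trajectories shorter than
`min_calls_for_fit` (default 4) use a constant line at the median ratio
instead: a 2–3-point median regression interpolates every point and no call
could ever sit above it. The L1 minimiser can be non-unique; any optimal
line is accepted and tests compare objective values, not coefficients.

A call is focused iff it has topic content, its ratio strictly exceeds the
trend at its order, and a jump (≥ `delta_jump` = 0.05 over the previous
call's ratio; the virtual predecessor of the first call has ratio 0) or a
sustained elevation (previous call focused and drop ≤ `delta_sustain` =
0.02) occurred. The thresholds quantify the qualitative notions
"substantially heightened" and "remained heightened": absolute ratio scales
are used because the baseline topic share is low (~2%) and relative changes
would be unstable near zero. Ties with the trend go to not-focused — a
deviation from the norm must exceed the norm. Calls above trend that fail
the jump/sustained criterion are written to a review queue, a deterministic
stand-in for manual adjudication of borderline calls.

## Group comparisons

Calls from the same patient are correlated, so two-group call-level
comparisons (focused vs content-not-focused) use OLS on an intercept plus
group indicator with CR1 cluster-robust standard errors: the cluster
sandwich scaled by G/(G−1)·(N−1)/(N−K), with p-values and 95% CIs from
t(G−1). This is one fixed convention among several in circulation; it
matches common defaults of econometrics cluster implementations and makes
results reproducible to the digit. The indicator coefficient equals the
difference of group means exactly. Eight dialogue-act outcomes (overall
plus seven categories) form one Holm–Bonferroni family; the utterance-count
comparison is reported unadjusted; symptom-attribute mention proportions
are purely descriptive (no test statistic is attached). Spearman
correlations use midranks with the t-approximation p-value
t = ρ√((n−2)/(1−ρ²)) at every n; Cohen *d* is the unpaired pooled-SD form
without small-sample (Hedges) correction. Fleiss κ validates dialogue-act
annotation reliability; a single-category table makes chance agreement 1
and κ undefined, which is raised as a degenerate-statistic error rather
than returned as NaN.

## Utilization indicators

"Six months" is fixed at 183 days. A patient's admission window is
[intervention start − 183 d, intervention end + 183 d], inclusive, keyed on
the admission date only; elective stays are excluded. Length of stay is
whole bed days (discharge − admission; same-day = 0), and average LOS is
cumulative bed days over the number of windowed admissions. Patients with
zero admissions enter count analyses with 0 but are excluded from LOS
analyses — imputing an average stay length for a patient who was never
admitted has no meaning. The two association tests (focus-call count vs
average LOS and vs admission count) form one Holm family; the group
contrast (patients with ≥ 1 focused call vs none) is descriptive Cohen *d*.

## Expert concern tabulation

Concern areas cross follow-up levels in an overlap-preserving table: a call
with areas {a, b} counts once in each area column but once in the flagged
total. Multiple ratings of one call (a pilot phase with shared patients)
are resolved by the union of areas and the most escalated follow-up level.
Unflagged calls carry no follow-up level — the level inventory applies to
flagged concerns. Union counts across areas use inclusion–exclusion with
explicitly supplied overlap counts; requesting a union over more than two
areas without the higher-order overlap terms is an error, since pairwise
information alone cannot determine it.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, with
defaults chosen as the study conditions:

| parameter | default | rationale |
|---|---|---|
| patients | 50 | cohort scale the analyses target |
| calls/patient | 11–15 (uniform) | scheduled-call range of the telesupport protocol |
| utterances/call | log-uniform 11–1289 | only min/median/max of real transcripts are known |
| baseline lifestyle share | 0.02 | low corpus-level topic share (~2%) |
| focus events/patient | 0–4 (uniform) | mean 2 focused calls per patient |
| event duration | 1–2 calls | short heightened episodes |
| ratio boost per event | +0.10 | lifts the share to ~0.12, well above baseline |
| dialogue acts/call | NB, mean 17.5 (focused) vs 10.1, SDs 12.4/7.7 | planted group difference 7.4 |
| admissions/patient | Poisson(3.4) | observed admission frequency |
| average LOS | mean 6.5, SD 2.4 days | observed stay lengths |
| focus–LOS rank coupling | −0.3 | target of the association analysis |
| concern flag rate | 0.242 | observed expert flag rate |

Topic counts per call are multinomial over the 13 topics with a
Dirichlet-perturbed patient-level mixture (concentration 300), so ratio
noise arises mechanically from call size rather than from modelled
semantics. Dialogue-act totals are gamma-Poisson (negative binomial) draws
matched to the group mean/SD and scattered over the call's lifestyle
utterances. The LOS coupling is a Gaussian copula: patients'
planted-focus-call counts are rank-transformed to normal scores (ties
broken at random), a correlated normal with
r = 2·sin(π·ρ_target/6) — the bivariate-normal inverse of Spearman's ρ —
sets each patient's LOS level, and individual stays are drawn around that
level with SD 1 day so that within-patient averaging attenuates the
coupling only mildly. Elective day procedures are occasionally added to
exercise the exclusion rule. Everything derives from a single integer seed
and regenerates byte-identically.

What the generator does **not** emulate: utterance text, within-call
discourse structure beyond act counts, seasonal or disease-progression
trends in topic shares, correlation between call size and focus status,
HF-specific admission causes, and rater disagreement on concerns. Passing
recovery tests therefore show that the pipeline's statistics recover
planted low-dimensional structure under realistic count noise — not that
the detection rule is clinically valid on real conversations.

## Detector performance under default conditions

Against planted events at default settings, the detector's pooled precision
is ~0.85 but pooled recall plateaus around 0.74 (and ~0.87 even when call
sizes are forced large). Three mechanisms bound it:

1. **Sustain tolerance vs count noise.** A boosted ratio of 0.12 on a
   median-sized call has binomial SD ≈ 0.024, so the second call of a
   two-call event drops by more than `delta_sustain` = 0.02 with
   probability ≈ 0.2–0.3 and loses its label.
2. **Strict trend inequality.** The L1 fit interpolates ~2 trajectory
   points exactly; a planted call lying on the line can never be "above
   trend".
3. **Chain cascades.** Adjacent events merge into 3–8-call elevated runs
   (up to 4 events × 2 calls on an 11–15-call trajectory); the sustained
   rule requires a *focused* predecessor, so one missed link orphans the
   rest of the run.

These are properties of the rule constants and the noise conditions, not
tunable defects; raising recall would require relaxing `delta_sustain`, a
non-strict trend comparison, or longer-memory chaining, all of which change
the stated rule.

## Numerical and degenerate-input conventions

Quantile regression falls back to the exact flat line when all ratios are
equal; non-finite fits (not observed in practice) fall back to the constant
median. Fewer than 2 clusters returns the OLS estimate with NaN inference
and a warning. Holm on an empty list returns an empty result. Spearman on a
constant vector and average LOS with zero admissions raise rather than
return NaN. Cohen *d* with zero pooled SD is 0 for equal means and signed
infinity otherwise. Probabilities print with 3 decimals and means/SDs with
1 in emitted reports; report files are byte-stable across runs of the same
configuration and seed.

## Problem sizes

Recovery experiments use 50 cohorts of 50 patients (~640 calls, ~170k
utterances each) for detector recall/precision, CI coverage of the planted
dialogue-act difference, and the mean recovered rank coupling; oracle
checks run on 6-point trajectories, 3-cluster toys and ≤ 8-call random
trajectories. At these sizes the full test suite and the acceptance script
each complete in a few minutes on one CPU.
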