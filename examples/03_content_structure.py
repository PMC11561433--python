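"""Compare content and structure of focused vs not-focused lifestyle calls.

Dialogue-act counts per call are compared by OLS with patient-clustered
standard errors; the eight dialogue-act comparisons form one
Holm-Bonferroni family, while the utterance-count comparison is reported
unadjusted.
"""

from telecare import SyntheticConfig, content_comparison, generate_cohort
from telecare.focus import partition_calls

dataset, _ = generate_cohort(SyntheticConfig(seed=42))
labels = partition_calls(dataset).label_map()
tables = content_comparison(dataset, labels)

acts = tables["content_comparison"]
cols = ["outcome", "mean_focused", "mean_not_focused", "estimate", "p_value", "p_adjusted"]
print(acts[cols].round(3).to_string(index=False))

utt = tables["utterance_comparison"].iloc[0]
print(f"\nutterances per call: focused {utt.mean_focused:.1f} vs "
      f"not focused {utt.mean_not_focused:.1f} (P = {utt.p_value:.3f}, unadjusted)")
print("\nThe overall-acts estimate is the adjusted mean difference in dialogue "
      "acts per call (focused minus not focused); the generator plants a "
      "difference of 7.4, which the clustered 95% CI should cover.")
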