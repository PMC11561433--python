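"""Tabulate expert concern evaluations over focus strata.

Reviewers mark concern areas (possibly several per call) and a follow-up
level; the table crosses areas with levels for all assessed calls and for
the lifestyle-focused stratum, preserving overlaps.
"""

from telecare import (
    SyntheticConfig,
    flagged_proportion,
    generate_cohort,
    generate_expert_evaluations,
    tabulate_concerns,
    union_concern_count,
)
from telecare.focus import partition_calls

config = SyntheticConfig(seed=42)
dataset, _ = generate_cohort(config)
labels = partition_calls(dataset).label_map()
records = generate_expert_evaluations(dataset, labels, config)

table = tabulate_concerns(records, labels)
print(f"assessed calls: {table.n_assessed['all']}, "
      f"flagged: {table.n_flagged['all']} ({flagged_proportion(table, 'all')}%)")
print(f"focused stratum: {table.n_assessed['lifestyle_focused']} assessed, "
      f"{flagged_proportion(table, 'lifestyle_focused')}% flagged")
print("\nconcern-area totals (all calls):")
for area, n in table.area_totals["all"].items():
    print(f"  {area:<28} {n}")
union = union_concern_count(table, ["hf_symptoms", "vitals"])
print(f"\ncalls concerning HF symptoms or vitals (no overlap supplied): {union}")
print("A call with two concern areas counts once per area, so area totals "
      "overlap; union counts resolve that by inclusion-exclusion.")
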