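"""End-to-end orchestration: load or generate a cohort, detect focus calls,
compare content and structure, tabulate expert concerns, and associate focus
calls with admissions.

Every stage is a pure function of (inputs, config, seed); reports are
emitted as deterministically formatted CSV files plus a JSON run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .corpus import CohortDataset, Vocabulary, merge_same_day_calls
from .expert import ConcernTable, flagged_proportion, tabulate_concerns
from .focus import CONTENT_NOT_FOCUSED, FOCUSED, FocusConfig, PartitionResult, partition_calls
from .io import CorpusPaths, load_corpus
from .stats import GroupComparisonResult, holm_bonferroni, ols_cluster_robust, proportion_with_attribute
from .synthetic import SyntheticConfig, generate_cohort, generate_expert_evaluations
from .utilization import (
    associate_focus_with_utilization,
    build_utilization_summaries,
    compare_focus_groups,
    summaries_to_frame,
)

logger = logging.getLogger("telecare")

ACT_CATEGORY_ORDER = (
    "exchanging_information",
    "understanding_information",
    "performing_action",
    "evaluation_of_health_condition",
    "social_emotional",
    "incomplete_dialogue_act",
    "others",
)


class RunConfig(BaseModel):
    """One full-analysis run: either interchange file inputs or synthetic mode."""

    calls: Optional[Path] = None
    patients: Optional[Path] = None
    admissions: Optional[Path] = None
    concerns: Optional[Path] = None
    vocabulary: Optional[Path] = None
    synthetic: bool = False
    synthetic_config: Optional[SyntheticConfig] = None
    focus: FocusConfig = Field(default_factory=FocusConfig)
    content_comparison: bool = True
    expert_eval: bool = True
    utilization_association: bool = True
    out_dir: Optional[Path] = None
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_input_mode(self):
        has_paths = self.calls is not None or self.patients is not None
        if self.synthetic and has_paths:
            raise ValueError("choose either synthetic mode or input paths, not both")
        if not self.synthetic and not has_paths:
            raise ValueError("either synthetic mode or input paths must be given")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = dict(data.get("inputs", {}))
        kwargs["synthetic"] = data.get("synthetic", False)
        if "synthetic_config" in data:
            kwargs["synthetic_config"] = SyntheticConfig(**data["synthetic_config"])
        if "focus_detection" in data:
            kwargs["focus"] = FocusConfig(**data["focus_detection"])
        for key in ("content_comparison", "expert_eval", "utilization_association"):
            if key in data.get("analyses", {}):
                kwargs[key] = data["analyses"][key]
        for key in ("out_dir", "seed", "log_level"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)


@dataclass
class ReportBundle:
    """All stage outputs of one run, as plain DataFrames keyed by report name."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    concern_table: Optional[ConcernTable] = None
    partition: Optional[PartitionResult] = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Content/structure comparison

def _per_call_outcomes(dataset: CohortDataset, labels, vocab: Vocabulary) -> pd.DataFrame:
    """One row per call with lifestyle content: group, act counts, utterances."""
    rows = []
    for call in dataset.calls:
        lab = labels.get(call.call_id)
        if lab is None or lab.group not in (FOCUSED, CONTENT_NOT_FOCUSED):
            continue
        counts = dict.fromkeys(ACT_CATEGORY_ORDER, 0)
        total = 0
        for utt in call.utterances:
            for act in utt.dialogue_acts:
                counts[vocab.act_category(act)] += 1
                total += 1
        rows.append(
            {
                "call_id": call.call_id,
                "patient_id": call.patient_id,
                "group": 1 if lab.group == FOCUSED else 0,
                "n_utterances": call.n_utterances,
                "overall_dialogue_acts": total,
                **counts,
            }
        )
    return pd.DataFrame(rows)


def _comparison_row(res: GroupComparisonResult, n_acts: tuple[int, int], medians, iqrs) -> dict:
    return {
        "outcome": res.outcome_name,
        "n_focused": res.n_per_group[1],
        "n_not_focused": res.n_per_group[0],
        "acts_focused": n_acts[1],
        "acts_not_focused": n_acts[0],
        "mean_focused": res.group_means[1],
        "sd_focused": res.group_sds[1],
        "median_focused": medians[1],
        "iqr_focused": iqrs[1],
        "mean_not_focused": res.group_means[0],
        "sd_not_focused": res.group_sds[0],
        "median_not_focused": medians[0],
        "iqr_not_focused": iqrs[0],
        "estimate": res.estimate,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p_value": res.p_value,
        "p_adjusted": res.p_adjusted,
    }


def content_comparison(
    dataset: CohortDataset, labels, vocab: Optional[Vocabulary] = None
) -> dict[str, pd.DataFrame]:
    """Compare focused vs content-not-focused calls on structure and content.

    Dialogue-act outcomes (overall plus the seven reporting categories) are
    compared by clustered OLS and Holm-adjusted as one family; the
    utterance-count comparison is reported unadjusted; symptom-attribute
    mention proportions are descriptive.
    """
    vocab = vocab or Vocabulary.default()
    frame = _per_call_outcomes(dataset, labels, vocab)
    if frame.empty or frame["group"].nunique() < 2:
        raise ValueError("content comparison needs calls in both groups")

    outcomes = ["overall_dialogue_acts", *ACT_CATEGORY_ORDER]
    results, rows = [], []
    for outcome in outcomes:
        res = ols_cluster_robust(
            frame[outcome], frame["group"], frame["patient_id"], outcome_name=outcome
        )
        results.append(res)
    adjusted = holm_bonferroni([r.p_value for r in results]).adjusted
    for res, p_adj in zip(results, adjusted):
        res = GroupComparisonResult(**{**res.__dict__, "p_adjusted": float(p_adj)})
        sub = frame[res.outcome_name]
        med = (
            float(sub[frame.group == 0].median()),
            float(sub[frame.group == 1].median()),
        )
        q = lambda g, lo, hi: (
            f"{sub[frame.group == g].quantile(lo):.1f}-{sub[frame.group == g].quantile(hi):.1f}"
        )
        iqr = (q(0, 0.25, 0.75), q(1, 0.25, 0.75))
        n_acts = (int(sub[frame.group == 0].sum()), int(sub[frame.group == 1].sum()))
        rows.append(_comparison_row(res, n_acts, med, iqr))
    acts_table = pd.DataFrame(rows)

    utt_res = ols_cluster_robust(
        frame["n_utterances"], frame["group"], frame["patient_id"], outcome_name="n_utterances"
    )
    utt_table = pd.DataFrame(
        [
            {
                "outcome": "n_utterances",
                "mean_focused": utt_res.group_means[1],
                "sd_focused": utt_res.group_sds[1],
                "mean_not_focused": utt_res.group_means[0],
                "sd_not_focused": utt_res.group_sds[0],
                "estimate": utt_res.estimate,
                "ci_low": utt_res.ci_low,
                "ci_high": utt_res.ci_high,
                "p_value": utt_res.p_value,
            }
        ]
    )

    focused_calls = [c for c in dataset.calls if labels.get(c.call_id) and labels[c.call_id].group == FOCUSED]
    content_calls = [
        c for c in dataset.calls if labels.get(c.call_id) and labels[c.call_id].group == CONTENT_NOT_FOCUSED
    ]
    symptom_attrs = set(vocab.attribute_groups.get("symptom_attributes", []))
    attr_rows = []
    for name, attrs in [("any_symptom_attribute", symptom_attrs)] + [
        (a, {a}) for a in sorted(symptom_attrs)
    ]:
        attr_rows.append(
            {
                "attribute": name,
                "prop_focused": proportion_with_attribute(focused_calls, attrs) if focused_calls else np.nan,
                "prop_not_focused": proportion_with_attribute(content_calls, attrs) if content_calls else np.nan,
            }
        )
    return {
        "content_comparison": acts_table,
        "utterance_comparison": utt_table,
        "attribute_proportions": pd.DataFrame(attr_rows),
    }


# ---------------------------------------------------------------------------
# Full run

def run_full_analysis(config: RunConfig) -> ReportBundle:
    logging.basicConfig(level=config.log_level)
    bundle = ReportBundle()
    vocab = Vocabulary.from_yaml(config.vocabulary) if config.vocabulary else Vocabulary.default()

    if config.synthetic:
        syn = config.synthetic_config or SyntheticConfig(seed=config.seed)
        if config.synthetic_config is None:
            syn = SyntheticConfig(seed=config.seed)
        dataset, truth = generate_cohort(syn)
        bundle.meta["synthetic_seed"] = syn.seed
        logger.info("generated synthetic cohort: %d patients, %d calls", len(dataset.patients), len(dataset.calls))
    else:
        paths = CorpusPaths(
            calls=config.calls,
            patients=config.patients,
            admissions=config.admissions,
            concerns=config.concerns,
            vocabulary=config.vocabulary,
        )
        dataset, truth, syn = load_corpus(paths, vocab), None, None
        logger.info("loaded cohort: %d patients, %d calls", len(dataset.patients), len(dataset.calls))

    dataset = CohortDataset(
        patients=dataset.patients,
        calls=merge_same_day_calls(dataset.calls),
        admissions=dataset.admissions,
        concerns=dataset.concerns,
    )

    partition = partition_calls(dataset, config.focus)
    bundle.partition = partition
    labels = partition.label_map()
    counts = partition.group_counts()
    logger.info("partition: %s", counts)
    bundle.tables["focus_labels"] = partition.to_frame()
    bundle.tables["review_queue"] = partition.review_queue
    bundle.tables["partition_counts"] = pd.DataFrame(
        [{"group": g, "n_calls": n} for g, n in counts.items()]
    )

    if config.content_comparison:
        try:
            bundle.tables.update(content_comparison(dataset, labels, vocab))
        except ValueError as exc:
            logger.warning("content comparison skipped: %s", exc)

    if config.expert_eval:
        concerns = dataset.concerns
        if concerns is None and config.synthetic:
            concerns = generate_expert_evaluations(dataset, labels, syn)
        if concerns:
            table = tabulate_concerns(concerns, labels)
            bundle.concern_table = table
            bundle.tables["concern_table"] = table.to_frame()
            bundle.tables["concern_summary"] = pd.DataFrame(
                [
                    {
                        "stratum": stratum,
                        "n_assessed": table.n_assessed[stratum],
                        "n_flagged": table.n_flagged[stratum],
                        "flagged_pct": flagged_proportion(table, stratum)
                        if table.n_assessed[stratum]
                        else np.nan,
                    }
                    for stratum in ("all", "lifestyle_focused")
                ]
            )
        else:
            logger.warning("expert evaluation skipped: no concern records supplied")

    if config.utilization_association:
        summaries = build_utilization_summaries(dataset, partition.focus_call_counts())
        bundle.tables["utilization_summary"] = summaries_to_frame(summaries)
        try:
            assoc = associate_focus_with_utilization(summaries)
            bundle.tables["association"] = pd.DataFrame(
                [
                    {"indicator": k, "rho": v.rho, "p_value": v.p_value, "p_adjusted": v.p_adjusted, "n": v.n}
                    for k, v in assoc.items()
                ]
            )
        except Exception as exc:
            logger.warning("association analysis skipped: %s", exc)
        try:
            comp = compare_focus_groups(summaries)
            bundle.tables["group_comparison"] = pd.DataFrame(
                [
                    {
                        "indicator": k,
                        "mean_with_focus": v.group_means[0],
                        "sd_with_focus": v.group_sds[0],
                        "mean_without_focus": v.group_means[1],
                        "sd_without_focus": v.group_sds[1],
                        "cohens_d": v.d,
                    }
                    for k, v in comp.items()
                ]
            )
        except Exception as exc:
            logger.warning("group comparison skipped: %s", exc)

    bundle.meta.update({"seed": config.seed, "version": __version__})
    if config.out_dir is not None:
        emit_reports(bundle, config.out_dir, config)
    return bundle


_ONE_DECIMAL = {
    "mean_focused", "sd_focused", "mean_not_focused", "sd_not_focused",
    "median_focused", "median_not_focused", "estimate", "ci_low", "ci_high",
    "mean_with_focus", "sd_with_focus", "mean_without_focus", "sd_without_focus",
    "flagged_pct", "avg_los",
}
_THREE_DECIMAL = {"p_value", "p_adjusted", "rho", "cohens_d", "ratio", "prop_focused", "prop_not_focused"}


def emit_reports(bundle: ReportBundle, out_dir, config: Optional[RunConfig] = None) -> list[Path]:
    """Write every report table as CSV with fixed float formatting.

    Means/SDs/estimates print with 1 decimal and probabilities with 3, the
    table style used throughout the reports; identical results yield
    byte-identical files.
    """
    out = Path(out_dir)
    if not bundle.tables:
        logger.warning("no results to emit; nothing written")
        return []
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(bundle.tables):
        frame = bundle.tables[name].copy()
        for col in frame.columns:
            if col in _ONE_DECIMAL:
                frame[col] = frame[col].map(lambda v: f"{v:.1f}" if pd.notna(v) else "")
            elif col in _THREE_DECIMAL:
                frame[col] = frame[col].map(lambda v: f"{v:.3f}" if pd.notna(v) else "")
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        written.append(path)
    log = {"meta": bundle.meta}
    if config is not None:
        # the output location is not part of the analysis configuration
        log["config"] = json.loads(config.model_dump_json(exclude={"out_dir"}))
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    written.append(out / "run_log.json")
    return written
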