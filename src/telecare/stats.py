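"""Statistical procedures used across the pipeline.

Thin, convention-fixing wrappers: Fleiss kappa (inter-rater agreement on the
dialogue-act annotation), OLS group comparison with CR1 patient-clustered
standard errors and t(G-1) inference, Holm-Bonferroni step-down adjustment,
Spearman rank correlation (midranks, t-approximation p), pooled-SD Cohen d,
and descriptive attribute-mention proportions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .corpus import AnnotatedCall


class DegenerateStatisticError(Exception):
    """The requested statistic is undefined on this input (e.g. zero variance)."""


@dataclass(frozen=True)
class ReliabilityResult:
    kappa: float
    n_items: int
    n_raters: int
    n_categories: int


@dataclass(frozen=True)
class GroupComparisonResult:
    outcome_name: str
    estimate: float
    se_clustered: float
    ci_low: float
    ci_high: float
    p_value: float
    p_adjusted: Optional[float]
    group_means: tuple[float, float]  # (reference group 0, comparison group 1)
    group_sds: tuple[float, float]
    n_per_group: tuple[int, int]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    p_adjusted: Optional[float]
    n: int


@dataclass(frozen=True)
class EffectSizeResult:
    d: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    group_ns: tuple[int, int]


@dataclass(frozen=True)
class AdjustedPValueSet:
    raw: tuple[float, ...]
    adjusted: tuple[float, ...]


# ---------------------------------------------------------------------------

def fleiss_kappa(ratings: np.ndarray, n_raters: int) -> ReliabilityResult:
    """Chance-corrected agreement for a fixed rater panel.

    ``ratings`` is an items x categories count matrix whose rows each sum to
    ``n_raters``.  kappa = (P_bar - P_e) / (1 - P_e) with per-item observed
    agreement and chance agreement from the marginal category proportions.
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("ratings must be an items x categories matrix with >=2 items and categories")
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    if not np.all(table.sum(axis=1) == n_raters):
        raise ValueError("each item's category counts must sum to n_raters")

    marginals = table.sum(axis=0) / table.sum()
    p_e = float(np.sum(marginals**2))
    if p_e >= 1.0:
        raise DegenerateStatisticError("all ratings fall in a single category; kappa undefined")

    from statsmodels.stats.inter_rater import fleiss_kappa as _fleiss

    kappa = float(_fleiss(table, method="fleiss"))
    return ReliabilityResult(
        kappa=kappa, n_items=table.shape[0], n_raters=n_raters, n_categories=table.shape[1]
    )


def ols_cluster_robust(
    outcome: Sequence[float],
    group: Sequence[int],
    cluster_ids: Sequence,
    outcome_name: str = "outcome",
) -> GroupComparisonResult:
    """Two-group comparison via OLS with cluster-robust (CR1) standard errors.

    Repeated calls from the same patient violate independence, so the
    variance uses the cluster sandwich estimator with the small-sample
    factor G/(G-1) x (N-1)/(N-K); p-values and 95% CIs come from the t
    distribution with G-1 degrees of freedom.  The coefficient on the group
    indicator equals the difference of group means (group 1 minus group 0).
    With fewer than 2 clusters the estimate is still returned but the
    inference fields are NaN (with a warning).
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group, dtype=int)
    clusters = np.asarray(cluster_ids)
    if not (len(y) == len(g) == len(clusters)):
        raise ValueError("outcome, group and cluster_ids must have equal length")
    if set(np.unique(g)) - {0, 1} or len(np.unique(g)) < 2:
        raise ValueError("group must be a binary indicator with both groups present")

    means = (float(y[g == 0].mean()), float(y[g == 1].mean()))
    sds = (float(y[g == 0].std(ddof=1)), float(y[g == 1].std(ddof=1)))
    ns = (int((g == 0).sum()), int((g == 1).sum()))

    n_clusters = len(np.unique(clusters))
    if n_clusters < 2:
        warnings.warn("fewer than 2 clusters: clustered inference undefined", stacklevel=2)
        return GroupComparisonResult(
            outcome_name, means[1] - means[0], math.nan, math.nan, math.nan, math.nan, None,
            means, sds, ns,
        )

    import statsmodels.api as sm

    X = sm.add_constant(g.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": clusters}, use_t=True)
    ci = res.conf_int(alpha=0.05)
    return GroupComparisonResult(
        outcome_name=outcome_name,
        estimate=float(res.params[1]),
        se_clustered=float(res.bse[1]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        p_value=float(res.pvalues[1]),
        p_adjusted=None,
        group_means=means,
        group_sds=sds,
        n_per_group=ns,
    )


def holm_bonferroni(p_values: Sequence[float]) -> AdjustedPValueSet:
    """Holm's step-down family-wise adjustment, order-preserving.

    Sorted ascending, p_(k) is multiplied by (m - k + 1), running maxima
    enforce monotonicity down the sorted list, values are capped at 1, and
    the result is returned in the input order.
    """
    raw = tuple(float(p) for p in p_values)
    if any(p < 0 or p > 1 for p in raw):
        raise ValueError("p-values must lie in [0, 1]")
    if not raw:
        return AdjustedPValueSet(raw=(), adjusted=())

    from statsmodels.stats.multitest import multipletests

    adjusted = multipletests(raw, method="holm")[1]
    return AdjustedPValueSet(raw=raw, adjusted=tuple(float(p) for p in adjusted))


def spearman_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with midranks for ties.

    The two-sided p-value uses the t approximation
    t = rho * sqrt((n - 2) / (1 - rho^2)) on n - 2 degrees of freedom.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateStatisticError("constant input: rank correlation undefined")

    from scipy.stats import spearmanr

    rho, p = spearmanr(xa, ya)
    return CorrelationResult(rho=float(rho), p_value=float(p), p_adjusted=None, n=len(xa))


def cohens_d(a: Sequence[float], b: Sequence[float]) -> EffectSizeResult:
    """Unpaired Cohen d with the pooled standard deviation (no bias correction).

    d = (mean_a - mean_b) / s_pooled,
    s_pooled^2 = ((n_a - 1) s_a^2 + (n_b - 1) s_b^2) / (n_a + n_b - 2).
    Equal-mean groups give d = 0 even when s_pooled = 0; unequal means with
    zero pooled SD give a signed infinity.
    """
    aa = np.asarray(a, dtype=float)
    ba = np.asarray(b, dtype=float)
    if len(aa) < 2 or len(ba) < 2:
        raise ValueError("both groups need at least 2 observations")
    mean_a, mean_b = float(aa.mean()), float(ba.mean())
    sd_a, sd_b = float(aa.std(ddof=1)), float(ba.std(ddof=1))
    na, nb = len(aa), len(ba)
    pooled = math.sqrt(((na - 1) * sd_a**2 + (nb - 1) * sd_b**2) / (na + nb - 2))
    diff = mean_a - mean_b
    if pooled == 0.0:
        d = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        d = diff / pooled
    return EffectSizeResult(d=d, group_means=(mean_a, mean_b), group_sds=(sd_a, sd_b), group_ns=(na, nb))


def proportion_with_attribute(calls: Sequence[AnnotatedCall], attribute_set: set[str]) -> float:
    """Fraction of calls with >=1 utterance carrying any of the listed attributes.

    Descriptive only; reported per attribute or pooled by varying
    ``attribute_set``.
    """
    if not calls:
        raise ValueError("proportion undefined on an empty call group")
    hits = sum(
        1
        for call in calls
        if any(set(u.attributes) & attribute_set for u in call.utterances)
    )
    return hits / len(calls)
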