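"""Harmonisation of raw group summaries into analysis-ready comparisons.

Four operations: pooling of groups that share a diversity level (or a control),
median dichotomisation of a continuous diversity gradient into equal-sized
high/low groups, conversion of survival-coded metrics to the mortality
direction, and the small additive offset that keeps log-based effect sizes
defined when means or SDs are zero.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence, Union

import numpy as np

from .datatypes import GroupSummary, ValidationError

logger = logging.getLogger(__name__)

#: Default log-safety offset added to means and SDs before effect sizes.
DEFAULT_OFFSET = 0.001


def pool_shared_groups(groups: Sequence[GroupSummary]) -> GroupSummary:
    """Pool several group summaries into one via the total-sum-of-squares rule.

    Pooled n is the total count, pooled mean the count-weighted mean, and the
    pooled variance combines within-group and between-group sums of squares so
    that it equals the variance of the concatenated sample:

        s_pooled^2 = [sum (n_i - 1) s_i^2 + sum n_i (m_i - m_bar)^2] / (N - 1)
    """
    groups = list(groups)
    if not groups:
        raise ValidationError("cannot pool an empty list of groups")
    metrics = {(g.metric, g.proportion, g.survival_direction) for g in groups}
    if len(metrics) > 1:
        raise ValidationError(f"cannot pool mixed metrics: {sorted(metrics)}")
    if len(groups) == 1:
        return groups[0]
    levels = {g.diversity_level for g in groups}
    level = levels.pop() if len(levels) == 1 else groups[0].diversity_level

    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    s = np.array([g.sd for g in groups], dtype=float)
    n_tot = n.sum()
    m_bar = float((n * m).sum() / n_tot)
    ss_within = float(((n - 1) * s**2).sum())
    ss_between = float((n * (m - m_bar) ** 2).sum())
    var = (ss_within + ss_between) / (n_tot - 1)
    g0 = groups[0]
    return GroupSummary(
        mean=m_bar,
        sd=math.sqrt(max(var, 0.0)),
        n=int(n_tot),
        metric=g0.metric,
        metric_label=g0.metric_label,
        diversity_level=level,
        proportion=g0.proportion,
        survival_direction=g0.survival_direction,
        direction_reversed=g0.direction_reversed,
    )


def _as_summary(obj: Union[GroupSummary, Iterable[float]], template: GroupSummary | None) -> GroupSummary:
    """Accept either a ready GroupSummary or raw replicate values."""
    if isinstance(obj, GroupSummary):
        return obj
    values = np.asarray(list(obj), dtype=float)
    if values.size < 2:
        raise ValidationError("replicate-level input needs >= 2 observations")
    kwargs = dict(metric="other")
    if template is not None:
        kwargs = dict(
            metric=template.metric,
            metric_label=template.metric_label,
            proportion=template.proportion,
            survival_direction=template.survival_direction,
        )
    return GroupSummary(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n=int(values.size),
        **kwargs,
    )


def dichotomise_continuous(
    populations: Sequence[tuple[float, Union[GroupSummary, Iterable[float]]]],
    template: GroupSummary | None = None,
) -> tuple[GroupSummary, GroupSummary]:
    """Split populations on a continuous diversity score into equal halves.

    Populations are sorted by score (ties broken by stable input order); the
    lower half becomes the low-diversity group and the upper half the
    high-diversity group, each pooled with :func:`pool_shared_groups`.  With an
    odd count the median population is dropped so the halves stay equal.
    """
    pops = list(populations)
    if len(pops) < 2:
        raise ValidationError("need >= 2 populations to dichotomise")
    scores = [float(s) for s, _ in pops]
    if any(not math.isfinite(s) for s in scores):
        raise ValidationError("diversity scores must be finite")
    if len(set(scores)) == 1:
        raise ValidationError("degenerate diversity gradient: all scores identical")

    order = sorted(range(len(pops)), key=lambda i: (scores[i], i))  # stable
    half = len(pops) // 2
    if len(pops) % 2 == 1:
        dropped = order[half]
        logger.info("odd population count: dropping median population (index %d)", dropped)
        low_idx, high_idx = order[:half], order[half + 1 :]
    else:
        low_idx, high_idx = order[:half], order[half:]

    low = pool_shared_groups([_as_summary(pops[i][1], template) for i in low_idx])
    high = pool_shared_groups([_as_summary(pops[i][1], template) for i in high_idx])
    return low.with_(diversity_level="low"), high.with_(diversity_level="high")


def survival_to_mortality(summary: GroupSummary) -> GroupSummary:
    """Reverse a survival-coded metric into the parasite-success direction.

    Proportions are complemented (mortality = 1 - survival; the SD of a
    complemented proportion is unchanged).  Non-proportion survival metrics
    (e.g. survival time) cannot be complemented on their own scale, so the
    record is flagged ``direction_reversed`` and the SMD sign is negated
    downstream; lnCVR is undefined under a mean shift and is not computed for
    such records.
    """
    if not summary.survival_direction:
        raise ValidationError("metric is not survival-direction coded")
    if summary.proportion:
        return summary.with_(mean=1.0 - summary.mean, survival_direction=False)
    return summary.with_(direction_reversed=True, survival_direction=False)


def apply_offset(summary: GroupSummary, offset: float = DEFAULT_OFFSET) -> GroupSummary:
    """Add a small positive constant to mean and SD (log-safety offset)."""
    if not offset > 0:
        raise ValidationError(f"offset must be positive, got {offset}")
    if summary.proportion and summary.mean + offset > 1.0:
        # keep the [0,1] invariant satisfiable: drop the proportion flag after
        # offsetting (the offset scale is no longer a strict proportion)
        return summary.with_(mean=summary.mean + offset, sd=summary.sd + offset, proportion=False)
    return summary.with_(mean=summary.mean + offset, sd=summary.sd + offset)
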