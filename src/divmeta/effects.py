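"""Effect sizes for mean (Hedges-corrected SMD) and relative variability (lnCVR).

Both effects compare a high- against a low-host-genetic-diversity group;
positive values mean greater parasite success (SMD) or greater relative
variability of parasite success (lnCVR) in the high-diversity group.  A
sampling variance-covariance matrix handles comparisons that reuse one
low-diversity control group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import ComparisonRecord, EffectSize, GroupSummary, ValidationError
from .harmonise import DEFAULT_OFFSET, apply_offset


def smd(
    low: GroupSummary,
    high: GroupSummary,
    hedges_correction: bool = True,
    variance_form: str = "large_sample",
) -> EffectSize:
    """Standardised mean difference (high minus low) with sampling variance.

    d = (m_H - m_L) / s_pool,  s_pool^2 = [(n_H-1) s_H^2 + (n_L-1) s_L^2] / (n_H+n_L-2)
    g = J d,  J = 1 - 3 / (4 (n_H+n_L-2) - 1)
    var(g) = (n_H+n_L)/(n_H n_L) + g^2 / (2 (n_H+n_L))

    ``variance_form="adjusted"`` replaces the second denominator with
    2 (n_H + n_L - 3.94), a small-sample variant kept for cross-checks.
    If both groups were flagged ``direction_reversed`` (survival-time metrics)
    the sign of g is negated, using d(-x) = -d(x).
    """
    n_l, n_h = low.n, high.n
    if n_l < 2 or n_h < 2:
        raise ValidationError("SMD needs n >= 2 in each group")
    df = n_l + n_h - 2
    s_pool2 = ((n_h - 1) * high.sd**2 + (n_l - 1) * low.sd**2) / df
    if s_pool2 <= 0:
        raise ValidationError("pooled SD is zero: SMD undefined")
    d = (high.mean - low.mean) / math.sqrt(s_pool2)
    j = 1.0 - 3.0 / (4.0 * df - 1.0) if hedges_correction else 1.0
    g = j * d
    if low.direction_reversed != high.direction_reversed:
        raise ValidationError("direction_reversed must apply to both groups or neither")
    if low.direction_reversed:
        g = -g
    n_tot = n_l + n_h
    denom = 2.0 * (n_tot - 3.94) if variance_form == "adjusted" else 2.0 * n_tot
    var = n_tot / (n_l * n_h) + g**2 / denom
    return EffectSize(kind="SMD", value=g, variance=var, n_low=n_l, n_high=n_h)


def lncvr(low: GroupSummary, high: GroupSummary) -> EffectSize:
    """Log coefficient-of-variation ratio (high vs low) with sampling variance.

    lnCVR = ln(s_H/m_H) - ln(s_L/m_L) + 1/(2(n_H-1)) - 1/(2(n_L-1))
    var   = s_L^2/(n_L m_L^2) + 1/(2(n_L-1)) + s_H^2/(n_H m_H^2) + 1/(2(n_H-1))

    The independence form is used: group summaries (not paired replicate
    series) are the input, so the mean-SD correlation term is set to zero.
    """
    n_l, n_h = low.n, high.n
    if n_l < 2 or n_h < 2:
        raise ValidationError("lnCVR needs n >= 2 in each group")
    if low.direction_reversed or high.direction_reversed:
        raise ValidationError("lnCVR undefined for direction-reversed (shifted-mean) metrics")
    for g in (low, high):
        if g.mean <= 0 or g.sd <= 0:
            raise ValidationError(
                "lnCVR needs positive means and SDs (apply the log-safety offset first)"
            )
    value = (
        math.log(high.sd / high.mean)
        - math.log(low.sd / low.mean)
        + 1.0 / (2.0 * (n_h - 1))
        - 1.0 / (2.0 * (n_l - 1))
    )
    var = (
        low.sd**2 / (n_l * low.mean**2)
        + 1.0 / (2.0 * (n_l - 1))
        + high.sd**2 / (n_h * high.mean**2)
        + 1.0 / (2.0 * (n_h - 1))
    )
    return EffectSize(kind="lnCVR", value=value, variance=var, n_low=n_l, n_high=n_h)


def effects_from_records(
    records: Sequence[ComparisonRecord],
    kind: str,
    offset: float = DEFAULT_OFFSET,
    offset_policy: str = "always",
    hedges_correction: bool = True,
) -> list[EffectSize]:
    """Compute one effect per comparison, applying the log-safety offset first.

    ``offset_policy``: "always" offsets every record (the default analysis
    path); "zeros_only" offsets only records with a zero mean or SD (kept as a
    sensitivity switch); "never" disables the offset.
    """
    if kind not in ("SMD", "lnCVR"):
        raise ValidationError(f"unknown effect kind {kind!r}")
    if offset_policy not in ("always", "zeros_only", "never"):
        raise ValidationError(f"unknown offset_policy {offset_policy!r}")
    out: list[EffectSize] = []
    for rec in records:
        low, high = rec.low, rec.high
        needs = any(g.mean <= 0 or g.sd <= 0 for g in (low, high))
        if offset_policy == "always" or (offset_policy == "zeros_only" and needs):
            low, high = apply_offset(low, offset), apply_offset(high, offset)
        if kind == "SMD":
            es = smd(low, high, hedges_correction=hedges_correction)
        else:
            if low.direction_reversed or high.direction_reversed:
                continue  # lnCVR undefined for shifted-mean survival metrics
            es = lncvr(low, high)
        es.comparison_id = rec.comparison_id
        es.study_id = rec.study_id
        es.experiment_id = rec.experiment_id
        es.host_genus = rec.host_genus
        es.shared_control_key = rec.shared_control_key
        es.moderators = dict(rec.moderators)
        out.append(es)
    return out


@dataclass
class SamplingCovariance:
    """Symmetric sampling VCV for a set of effects, with its row ordering."""

    matrix: np.ndarray
    ordering: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("VCV must be square")
        if not np.allclose(m, m.T):
            raise ValidationError("VCV must be symmetric")
        self.matrix = m

    def reorder(self, ordering: Sequence[str]) -> "SamplingCovariance":
        idx = [self.ordering.index(c) for c in ordering]
        return SamplingCovariance(self.matrix[np.ix_(idx, idx)], list(ordering))


def build_vcv(
    effects: Sequence[EffectSize],
    mode: str = "fixed_r",
    r: float = 0.5,
    control_n: Optional[dict[str, int]] = None,
) -> SamplingCovariance:
    """Assemble the sampling VCV with shared-control covariance blocks.

    Off-diagonals are nonzero only between effects sharing a
    ``shared_control_key``.  ``fixed_r`` sets cov_ij = r sqrt(v_i v_j)
    (0 < r < 1); ``exact_smd`` (SMD only) uses

        cov_ij = 1/n_C + g_i g_j / (2 N)

    with n_C the shared control group size and N the total size of the three
    groups involved.  The result is validated positive semidefinite; failure
    raises (no silent repair).
    """
    effects = list(effects)
    kinds = {e.kind for e in effects}
    if len(kinds) > 1:
        raise ValidationError(f"effects must share one kind, got {sorted(kinds)}")
    if mode not in ("fixed_r", "exact_smd"):
        raise ValidationError(f"unknown VCV mode {mode!r}")
    if mode == "fixed_r" and not (0.0 < r < 1.0):
        raise ValidationError(f"fixed_r correlation must lie in (0, 1), got {r}")
    if mode == "exact_smd" and kinds and kinds != {"SMD"}:
        raise ValidationError("exact_smd mode applies to SMD effects only")

    k = len(effects)
    v = np.array([e.variance for e in effects], dtype=float)
    mat = np.diag(v)
    blocks: dict[str, list[int]] = {}
    for i, e in enumerate(effects):
        if e.shared_control_key is not None:
            blocks.setdefault(str(e.shared_control_key), []).append(i)

    for key, idx in blocks.items():
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                if mode == "fixed_r":
                    cov = r * math.sqrt(v[i] * v[j])
                else:
                    ei, ej = effects[i], effects[j]
                    if control_n and key in control_n:
                        n_c = control_n[key]
                    else:
                        n_c = ei.n_low
                    if n_c is None or ei.n_high is None or ej.n_high is None:
                        raise ValidationError(
                            f"exact_smd needs group sizes for shared-control block {key!r}"
                        )
                    n_total = n_c + ei.n_high + ej.n_high
                    cov = 1.0 / n_c + ei.value * ej.value / (2.0 * n_total)
                mat[i, j] = mat[j, i] = cov

    ordering = [e.comparison_id for e in effects]
    vcv = SamplingCovariance(mat, ordering)
    if k:
        w = np.linalg.eigvalsh(mat)
        if w.min() < -1e-8 * max(1.0, w.max()):
            bad = ", ".join(sorted(blocks)) or "<none>"
            raise ValidationError(
                f"sampling VCV is not positive semidefinite (min eigenvalue "
                f"{w.min():.3g}); shared-control blocks: {bad}"
            )
    return vcv
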