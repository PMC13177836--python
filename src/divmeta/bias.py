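"""Publication-bias diagnostics and leave-one-out sensitivity analysis.

The bias check is the association between effect sizes and their standard
errors, reported as a Pearson correlation with a Fisher-z confidence interval
(a classical precision-weighted regression variant is available behind a
flag).  Sensitivity refits the overall model with one study, or one set of
independent comparisons (a shared-control group), omitted at a time, and
summarises the iterations by their arithmetic means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .datatypes import EffectSize, ValidationError
from .effects import build_vcv
from .model import MetaFit, ModelSpec, fit_reml


def egger_association(
    effects: Sequence[EffectSize], method: str = "correlation"
) -> tuple[float, tuple[float, float], float]:
    """Effect-size vs standard-error association (small-study-effect test).

    ``method="correlation"`` (default): Pearson r between effect values and
    SEs, with a Fisher-z 95% CI and two-sided p.  ``method="regression"``:
    classical Egger test, the intercept of a precision-weighted regression of
    effects on their SEs; returns (intercept, CI, p).
    """
    effects = list(effects)
    if len(effects) < 4:
        raise ValidationError("association test needs k >= 4 effects")
    y = np.array([e.value for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    if np.allclose(se, se[0]):
        raise ValidationError("association undefined: all standard errors equal")
    if method == "correlation":
        if np.allclose(y, y[0]):
            # constant effects: no association with SE by definition
            half = math.tanh(scipy.stats.norm.ppf(0.975) / math.sqrt(len(y) - 3))
            return 0.0, (-half, half), 1.0
        res = scipy.stats.pearsonr(y, se)
        ci = res.confidence_interval(confidence_level=0.95)
        return float(res.statistic), (float(ci.low), float(ci.high)), float(res.pvalue)
    if method == "regression":
        Xr = sm.add_constant(se)
        fit = sm.WLS(y, Xr, weights=1.0 / se**2).fit()
        lo, hi = fit.conf_int()[0]
        return float(fit.params[0]), (float(lo), float(hi)), float(fit.pvalues[0])
    raise ValidationError(f"unknown method {method!r}")


def funnel_table(effects: Sequence[EffectSize], fit: Optional[MetaFit] = None) -> pd.DataFrame:
    """Plot-ready funnel data: one row per effect (value, SE, precision),
    with the model mean and its CI attached as constant columns when a fitted
    overall model is supplied."""
    rows = [
        dict(
            comparison_id=e.comparison_id,
            study_id=e.study_id,
            value=e.value,
            se=e.se,
            precision=1.0 / e.se if e.se > 0 else np.inf,
        )
        for e in effects
    ]
    df = pd.DataFrame(rows, columns=["comparison_id", "study_id", "value", "se", "precision"])
    if not df.empty:
        df = df.sort_values("se", ascending=True, kind="stable").reset_index(drop=True)
    if fit is not None and len(fit.beta) >= 1:
        df["model_mean"] = fit.beta[0]
        df["model_ci_lb"] = fit.ci[0, 0]
        df["model_ci_ub"] = fit.ci[0, 1]
    return df


@dataclass
class LooResult:
    """Leave-one-out refits plus their unweighted model average."""

    method: str  # "leave1studyout" | "leave1setout"
    effect_kind: str
    iterations: pd.DataFrame  # omitted, estimate, se, z, p, ci.lb, ci.ub
    averaged: dict[str, float]
    averaged_weighted: dict[str, float] = field(default_factory=dict)
    failures: list[str] = field(default_factory=list)

    def averaged_frame(self) -> pd.DataFrame:
        """Summary row with the sensitivity-table column layout."""
        return pd.DataFrame(
            [
                dict(
                    Method=self.method.capitalize(),
                    ES=self.effect_kind,
                    Estimate=self.averaged["estimate"],
                    SE=self.averaged["se"],
                    z=self.averaged["z"],
                    p=self.averaged["p"],
                    **{"ci.lb": self.averaged["ci.lb"], "ci.ub": self.averaged["ci.ub"]},
                )
            ]
        )


def _unit_key(e: EffectSize, unit: str) -> str:
    if unit == "study":
        return e.study_id
    # comparison set: effects sharing a low-diversity control group form one
    # unit; unshared effects are their own unit
    return str(e.shared_control_key) if e.shared_control_key is not None else e.comparison_id


def leave_one_out(
    effects: Sequence[EffectSize],
    spec: Optional[ModelSpec] = None,
    unit: str = "study",
    **fit_kwargs,
) -> LooResult:
    """Refit the overall model once per omitted unit and average the results.

    ``unit="study"`` omits whole studies; ``unit="comparison_set"`` omits sets
    of comparisons that share a control group.  Averages are unweighted
    arithmetic means of the per-iteration estimate, SE, z, p and CI bounds; a
    precision-weighted (1/SE^2) average is provided alongside.
    """
    effects = list(effects)
    spec = spec or ModelSpec()
    if unit not in ("study", "comparison_set"):
        raise ValidationError(f"unknown unit {unit!r}")
    units = sorted({_unit_key(e, unit) for e in effects})
    if len(units) < 3:
        raise ValidationError("leave-one-out needs >= 3 omitted units")

    rows, failures = [], []
    for u in units:
        kept = [e for e in effects if _unit_key(e, unit) != u]
        try:
            vcv = build_vcv(kept, mode=spec.vcv_mode, r=spec.vcv_r)
            fit = fit_reml(kept, vcv=vcv, spec=spec, **fit_kwargs)
        except Exception as exc:  # refit failure: record, exclude from averages
            failures.append(f"{u}: {exc}")
            continue
        rows.append(
            dict(
                omitted=u,
                estimate=float(fit.beta[0]),
                se=float(fit.se[0]),
                z=float(fit.zval[0]),
                p=float(fit.pval[0]),
                **{"ci.lb": float(fit.ci[0, 0]), "ci.ub": float(fit.ci[0, 1])},
            )
        )
    iterations = pd.DataFrame(rows)
    if iterations.empty:
        raise ValidationError("all leave-one-out refits failed: " + "; ".join(failures))
    cols = ["estimate", "se", "z", "p", "ci.lb", "ci.ub"]
    averaged = {c: float(iterations[c].mean()) for c in cols}
    w = 1.0 / iterations["se"] ** 2
    averaged_weighted = {c: float((iterations[c] * w).sum() / w.sum()) for c in cols}
    return LooResult(
        method="leave1studyout" if unit == "study" else "leave1setout",
        effect_kind=spec.effect_kind,
        iterations=iterations,
        averaged=averaged,
        averaged_weighted=averaged_weighted,
        failures=failures,
    )
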