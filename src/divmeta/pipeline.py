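"""End-to-end pipeline: harmonised comparisons -> effects -> fits -> diagnostics.

Stages mirror the three research questions of the analysis: RQ1 the overall
mean (SMD) and variability (lnCVR) effect of host genetic diversity; RQ2 the
parasite-genetic-diversity x host-range interaction with directional
contrasts; RQ3 each contextual moderator singly with Holm-corrected pairwise
contrasts; plus publication-bias diagnostics and leave-one-out sensitivity.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bias import egger_association, funnel_table, leave_one_out
from .datatypes import ComparisonRecord, EffectSize, MODERATOR_LEVELS, ValidationError
from .effects import build_vcv, effects_from_records
from .io import (
    RunConfig,
    comparisons_to_frame,
    file_checksum,
    read_comparisons,
    write_effects,
    write_json,
    write_vcv,
)
from .model import (
    MetaFit,
    ModelSpec,
    collinearity_crosstab,
    contrast,
    fit_reml,
    holm_adjust,
    qm_test,
)
from .synth import diversity_uncertainty_preset, generate_dataset

logger = logging.getLogger(__name__)

ALL_STAGES = ("rq1", "rq2", "rq3", "bias", "loo")


def _fit_to_dict(fit: MetaFit) -> dict:
    return dict(
        coefficients={
            name: dict(
                estimate=float(b),
                se=float(s),
                z=float(z),
                p=float(p),
                ci=[float(lo), float(hi)],
                prediction_interval=[float(plo), float(phi)],
            )
            for name, b, s, z, p, (lo, hi), (plo, phi) in zip(
                fit.coef_names, fit.beta, fit.se, fit.zval, fit.pval, fit.ci,
                fit.prediction_intervals,
            )
        },
        tau2=fit.tau2,
        rho_experiment=fit.rho_exp,
        k=fit.k,
        loglik_reml=fit.loglik_reml,
        i2=fit.i2,
        i2_alternative=fit.i2_alternative,
        typical_sampling_variance=fit.typical_sampling_variance,
        converged=fit.converged,
    )


def _orchard_table(effects: Sequence[EffectSize], fit: MetaFit, by: Optional[str]) -> pd.DataFrame:
    """Plot-ready points (scaled by inverse SE) plus model means/CIs/PIs."""
    rows = []
    for e in effects:
        rows.append(
            dict(
                comparison_id=e.comparison_id,
                study_id=e.study_id,
                group=e.moderators.get(by, "") if by else "overall",
                value=e.value,
                se=e.se,
                size=1.0 / e.se if e.se > 0 else np.inf,
            )
        )
    pts = pd.DataFrame(rows)
    means = fit.summary_frame().reset_index(names="coefficient")
    means.insert(0, "row_type", "model_mean")
    pts.insert(0, "row_type", "point")
    return pd.concat([pts, means], ignore_index=True)


def _rq2_contrasts(fit: MetaFit) -> pd.DataFrame:
    """Directional contrast family on the 2x2 cell means, Holm-adjusted.

    (1) specialist minus generalist, averaged over parasite diversity;
    (2) within specialists, low minus high parasite diversity;
    (3) within generalists, low minus high parasite diversity.
    """
    idx = {name: i for i, name in enumerate(fit.coef_names)}

    def cell(pd_level: str, hr_level: str) -> Optional[int]:
        return idx.get(f"parasite_genetic_diversity={pd_level}:host_range={hr_level}")

    p = len(fit.beta)
    plan = []
    spec_cells = [cell(l, "specialist") for l in ("high", "low")]
    gen_cells = [cell(l, "generalist") for l in ("high", "low")]
    if all(i is not None for i in spec_cells + gen_cells):
        L = np.zeros(p)
        for i in spec_cells:
            L[i] += 0.5
        for i in gen_cells:
            L[i] -= 0.5
        plan.append(("specialist - generalist", L))
    for hr, cells in (("specialist", None), ("generalist", None)):
        lo, hi = cell("low", hr), cell("high", hr)
        if lo is not None and hi is not None:
            L = np.zeros(p)
            L[lo], L[hi] = 1.0, -1.0
            plan.append((f"{hr}: low - high parasite diversity", L))
        else:
            logger.warning("RQ2 contrast skipped for %s: empty cell", hr)
    if not plan:
        return pd.DataFrame()
    results = [contrast(fit, L, name=name) for name, L in plan]
    adj = holm_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_holm = a
    return pd.DataFrame(
        [
            dict(contrast=r.name, estimate=r.estimate, se=r.se, z=r.z, p=r.p, p_holm=r.p_holm)
            for r in results
        ]
    )


def _rq3_moderator(fit: MetaFit, moderator: str) -> tuple[pd.DataFrame, dict]:
    """All pairwise level contrasts (Holm within the moderator) plus the
    omnibus QM test of level equality."""
    names = fit.coef_names
    level_idx = {
        name.split("=", 1)[1]: i
        for i, name in enumerate(names)
        if name.startswith(moderator + "=")
    }
    levels = [l for l in MODERATOR_LEVELS[moderator] if l in level_idx]
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    results = []
    for a, b in pairs:
        L = np.zeros(len(fit.beta))
        L[level_idx[a]], L[level_idx[b]] = 1.0, -1.0
        results.append(contrast(fit, L, name=f"{a} - {b}"))
    if results:
        adj = holm_adjust([r.p for r in results])
        for r, a in zip(results, adj):
            r.p_holm = a
    table = pd.DataFrame(
        [
            dict(contrast=r.name, estimate=r.estimate, se=r.se, z=r.z, p=r.p, p_holm=r.p_holm)
            for r in results
        ]
    )
    omnibus: dict = {}
    if len(levels) >= 2:
        L = np.zeros((len(levels) - 1, len(fit.beta)))
        for r, lev in enumerate(levels[1:]):
            L[r, level_idx[levels[0]]] = 1.0
            L[r, level_idx[lev]] = -1.0
        qm, df, p = qm_test(fit, L=L)
        omnibus = dict(QM=qm, df=df, p=p)
    return table, omnibus


def load_input(config: RunConfig) -> tuple[list[ComparisonRecord], Optional[pd.DataFrame], dict]:
    """Resolve the configured input into comparison records (+ truth table)."""
    meta: dict = {}
    if config.input == "diversity_uncertainty":
        overrides = {"seed": config.seed}
        if config.n_studies is not None:
            overrides["n_studies"] = config.n_studies
        cfg = diversity_uncertainty_preset(**overrides)
        ds = generate_dataset(cfg)
        meta["input"] = "diversity_uncertainty preset"
        meta["n_clamped"] = ds.n_clamped
        return ds.comparisons, ds.truth, meta
    path = Path(config.input)
    records = read_comparisons(path)
    meta["input"] = str(path)
    meta["input_sha256"] = file_checksum(path)
    return records, None, meta


def run_pipeline(config: RunConfig, stages: Sequence[str] = ALL_STAGES) -> dict:
    """Execute the pipeline and persist JSON/CSV results plus a run manifest.

    Returns the in-memory result bundle (fits, contrast tables, diagnostics).
    Any stage failure raises with the stage name; outputs written so far are
    left in place.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records, truth, meta = load_input(config)
    comparisons_to_frame(records).to_csv(outdir / "comparisons.csv", index=False)
    if truth is not None:
        truth.to_csv(outdir / "truth.csv", index=False)

    bundle: dict = {"meta": meta, "config": config}
    stage = "effects"
    try:
        effects_by_kind: dict[str, list[EffectSize]] = {}
        vcv_by_kind = {}
        for kind in config.effect_kinds:
            eff = effects_from_records(
                records, kind, offset=config.offset, offset_policy=config.offset_policy
            )
            vcv = build_vcv(eff, mode=config.vcv_mode, r=config.vcv_r)
            effects_by_kind[kind] = eff
            vcv_by_kind[kind] = vcv
            write_effects(eff, outdir / f"effects_{kind}.csv")
            write_vcv(vcv, outdir / f"vcv_{kind}.csv")
        bundle["effects"] = effects_by_kind
        bundle["vcv"] = vcv_by_kind

        for kind in config.effect_kinds:
            eff, vcv = effects_by_kind[kind], vcv_by_kind[kind]
            kinds_meta = dict(effect_kind=kind, vcv_mode=config.vcv_mode, vcv_r=config.vcv_r,
                              offset=config.offset, offset_policy=config.offset_policy)

            if "rq1" in stages or "bias" in stages or "loo" in stages:
                stage = f"rq1[{kind}]"
                spec1 = ModelSpec(effect_kind=kind, fixed_terms=(),
                                  random_levels=config.random_levels,
                                  vcv_mode=config.vcv_mode, vcv_r=config.vcv_r)
                fit1 = fit_reml(eff, vcv=vcv, spec=spec1, n_starts=config.n_starts)
                bundle.setdefault("rq1", {})[kind] = fit1
                write_json({**kinds_meta, **_fit_to_dict(fit1)}, outdir / f"rq1_{kind}.json")
                _orchard_table(eff, fit1, by=None).to_csv(
                    outdir / f"orchard_rq1_{kind}.csv", index=False
                )

            if "rq2" in stages:
                stage = f"rq2[{kind}]"
                spec2 = ModelSpec(effect_kind=kind,
                                  fixed_terms=("parasite_genetic_diversity:host_range",),
                                  random_levels=config.random_levels,
                                  vcv_mode=config.vcv_mode, vcv_r=config.vcv_r)
                fit2 = fit_reml(eff, vcv=vcv, spec=spec2, n_starts=config.n_starts)
                ctr2 = _rq2_contrasts(fit2)
                bundle.setdefault("rq2", {})[kind] = (fit2, ctr2)
                write_json({**kinds_meta, **_fit_to_dict(fit2)}, outdir / f"rq2_{kind}.json")
                ctr2.to_csv(outdir / f"rq2_contrasts_{kind}.csv", index=False)
                _orchard_table(eff, fit2, by="host_range").to_csv(
                    outdir / f"orchard_rq2_{kind}.csv", index=False
                )

            if "rq3" in stages:
                for mod in config.rq3_moderators:
                    stage = f"rq3[{kind}:{mod}]"
                    observed = {e.moderators.get(mod) for e in eff}
                    observed.discard(None)
                    if len(observed) < 2:
                        logger.warning("rq3 %s skipped for %s: <2 observed levels", mod, kind)
                        continue
                    spec3 = ModelSpec(effect_kind=kind, fixed_terms=(mod,),
                                      random_levels=config.random_levels,
                                      vcv_mode=config.vcv_mode, vcv_r=config.vcv_r)
                    fit3 = fit_reml(eff, vcv=vcv, spec=spec3, n_starts=config.n_starts)
                    table, omnibus = _rq3_moderator(fit3, mod)
                    bundle.setdefault("rq3", {}).setdefault(kind, {})[mod] = (fit3, table, omnibus)
                    write_json(
                        {**kinds_meta, "moderator": mod, "omnibus": omnibus, **_fit_to_dict(fit3)},
                        outdir / f"rq3_{kind}_{mod}.json",
                    )
                    table.to_csv(outdir / f"rq3_contrasts_{kind}_{mod}.csv", index=False)

            if "bias" in stages:
                stage = f"bias[{kind}]"
                r, ci, p = egger_association(eff)
                bundle.setdefault("egger", {})[kind] = dict(r=r, ci=list(ci), p=p)
                write_json(
                    dict(effect_kind=kind, method="correlation", r=r, ci=list(ci), p=p),
                    outdir / f"egger_{kind}.json",
                )
                funnel = funnel_table(eff, fit=bundle["rq1"][kind])
                funnel.to_csv(outdir / f"funnel_{kind}.csv", index=False)

            if "loo" in stages:
                stage = f"loo[{kind}]"
                spec1 = ModelSpec(effect_kind=kind, fixed_terms=(),
                                  random_levels=config.random_levels,
                                  vcv_mode=config.vcv_mode, vcv_r=config.vcv_r)
                for unit in ("study", "comparison_set"):
                    loo = leave_one_out(eff, spec=spec1, unit=unit, n_starts=1)
                    bundle.setdefault("loo", {})[(kind, unit)] = loo
                    loo.iterations.to_csv(outdir / f"loo_{unit}_{kind}.csv", index=False)

        if "rq3" in stages or "rq2" in stages:
            stage = "collinearity"
            eff0 = effects_by_kind[config.effect_kinds[0]]
            ct = collinearity_crosstab(eff0, "parasite_genetic_diversity", "laboratory")
            bundle["collinearity"] = ct
            ct.counts.to_csv(outdir / "collinearity_counts.csv")
            ct.row_percent.to_csv(outdir / "collinearity_row_percent.csv")

        if "loo" in stages and "loo" in bundle:
            summary = pd.concat(
                [bundle["loo"][key].averaged_frame() for key in sorted(bundle["loo"])],
                ignore_index=True,
            )
            summary.to_csv(outdir / "loo_summary.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = dict(
        schema_version="1.0",
        package_version=__version__,
        seed=config.seed,
        stages=list(stages),
        config={
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        **{k: v for k, v in meta.items()},
        versions=dict(numpy=np.__version__, pandas=pd.__version__),
        n_comparisons=len(records),
        n_effects={k: len(v) for k, v in bundle.get("effects", {}).items()},
    )
    write_json(manifest, outdir / "manifest.json")
    return bundle
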