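import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from divmeta.datatypes import EffectSize, ValidationError
from divmeta.model import (
    ContrastResult,
    MetaFit,
    ModelSpec,
    MultilevelMetaRegression,
    collinearity_crosstab,
    contrast,
    fit_reml,
    holm_adjust,
    i2_decompose,
    prediction_interval,
    qm_test,
)
from divmeta.effects import effects_from_records
from divmeta.synth import diversity_uncertainty_preset, generate_dataset


def make_fit(beta, cov, tau2=None):
    """Hand-crafted MetaFit for inference-helper unit checks."""
    beta = np.asarray(beta, float)
    cov = np.asarray(cov, float)
    se = np.sqrt(np.diag(cov))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    import scipy.stats

    ci = np.column_stack([beta - 1.959963984540054 * se, beta + 1.959963984540054 * se])
    return MetaFit(
        beta=beta, se=se, cov_beta=cov, coef_names=[f"b{i}" for i in range(len(beta))],
        tau2=tau2 or {"study": 0.0}, rho_exp=0.0, k=len(beta) + 5, loglik_reml=0.0,
        ci=ci, prediction_intervals=ci.copy(), i2={}, i2_alternative={},
        typical_sampling_variance=0.1, converged=True, grad_norm=0.0,
        zval=z, pval=2 * scipy.stats.norm.sf(np.abs(z)),
    )


def effect(value, var, study="s1", exp=None, comp=None, genus="g1", **mods):
    return EffectSize(
        kind="SMD", value=value, variance=var, study_id=study,
        experiment_id=exp or study + "e", comparison_id=comp or f"{study}-{value}-{var}",
        host_genus=genus, moderators=mods,
    )


class TestFitClosedForms:
    def test_single_observation_gls(self):
        eff = [effect(0.5, 0.04, comp="c0")]
        fit = fit_reml(eff, spec=ModelSpec(random_levels=()))
        assert fit.beta[0] == pytest.approx(0.5)
        assert fit.se[0] == pytest.approx(0.2)

    def test_equal_variances_fixed_zero_tau2_is_plain_mean(self):
        vals = [0.1, 0.4, -0.2, 0.3, 0.9]
        eff = [effect(v, 0.16, study=f"s{i}", comp=f"c{i}") for i, v in enumerate(vals)]
        fit = fit_reml(
            eff, spec=ModelSpec(random_levels=("study",)),
            fix_tau2={"study": 0.0},
        )
        assert fit.beta[0] == pytest.approx(np.mean(vals), abs=1e-12)
        assert fit.se[0] == pytest.approx(math.sqrt(0.16 / 5), abs=1e-12)

    def test_unequal_variances_gls_weighting(self):
        vals = np.array([0.1, 0.7, -0.3, 0.2])
        v = np.array([0.05, 0.2, 0.1, 0.4])
        eff = [effect(y, vi, study=f"s{i}", comp=f"c{i}") for i, (y, vi) in enumerate(zip(vals, v))]
        fit = fit_reml(eff, spec=ModelSpec(random_levels=("study",)), fix_tau2={"study": 0.0})
        w = 1 / v
        assert fit.beta[0] == pytest.approx(float((w * vals).sum() / w.sum()), abs=1e-12)
        assert fit.se[0] == pytest.approx(float(1 / math.sqrt(w.sum())), abs=1e-12)


class TestAgainstIndependentMultilevelFitter:
    """Frozen reference values computed with the R package metafor (rma.mv,
    REML) on datasets regenerated deterministically from the generator."""

    def test_study_random_intercept(self):
        cfg = diversity_uncertainty_preset(
            seed=7, n_studies=12, shared_control_fraction=0.0,
            experiments_per_study=1, comparisons_per_experiment=2,
            tau2_genus=0.0, tau2_experiment=0.0, genus_duplication=0.0,
        )
        eff = effects_from_records(generate_dataset(cfg).comparisons, "SMD")
        fit = fit_reml(eff, spec=ModelSpec(random_levels=("study",)), n_starts=3)
        assert fit.beta[0] == pytest.approx(-0.396139, abs=5e-4)
        assert fit.se[0] == pytest.approx(0.186387, abs=5e-4)
        assert fit.tau2["study"] == pytest.approx(0.352628, abs=5e-4)

    def test_compound_symmetry_experiment_level(self):
        cfg = diversity_uncertainty_preset(
            seed=11, n_studies=15, shared_control_fraction=0.0,
            experiments_per_study=2, comparisons_per_experiment=(2, 3),
            tau2_genus=0.0, tau2_experiment=0.3, rho_experiment=0.6,
            genus_duplication=0.0,
        )
        eff = effects_from_records(generate_dataset(cfg).comparisons, "SMD")
        fit = fit_reml(eff, spec=ModelSpec(random_levels=("study", "experiment")), n_starts=3)
        assert fit.beta[0] == pytest.approx(-0.17647, abs=5e-4)
        assert fit.se[0] == pytest.approx(0.18633, abs=5e-4)
        assert fit.tau2["study"] == pytest.approx(0.37149, abs=1e-3)
        assert fit.tau2["experiment"] == pytest.approx(0.31209, abs=1e-3)
        assert fit.rho_exp == pytest.approx(0.5761, abs=2e-3)


class TestDesignMatrix:
    def test_rank_deficient_design_names_columns(self):
        # two moderators perfectly confounded -> aliased dummies
        eff = [
            effect(0.1 * i, 0.1, study=f"s{i}", comp=f"c{i}",
                   host_range="specialist" if i % 2 else "generalist",
                   laboratory="yes" if i % 2 else "no")
            for i in range(8)
        ]
        spec = ModelSpec(fixed_terms=("host_range", "laboratory"), random_levels=("study",))
        with pytest.raises(ValidationError, match="aliased"):
            fit_reml(eff, spec=spec)

    def test_unknown_moderator_rejected(self):
        with pytest.raises(ValidationError, match="unknown moderator"):
            ModelSpec(fixed_terms=("not_a_moderator",))

    def test_cell_means_parameterisation(self):
        eff = [
            effect(0.1 * i, 0.1, study=f"s{i}", comp=f"c{i}",
                   host_range="specialist" if i % 2 else "generalist")
            for i in range(10)
        ]
        fit = fit_reml(eff, spec=ModelSpec(fixed_terms=("host_range",), random_levels=("study",)),
                       fix_tau2={"study": 0.0})
        assert sorted(fit.coef_names) == ["host_range=generalist", "host_range=specialist"]
        gen = np.mean([e.value for e in eff if e.moderators["host_range"] == "generalist"])
        i = fit.coef_names.index("host_range=generalist")
        assert fit.beta[i] == pytest.approx(gen, abs=1e-10)


class TestQM:
    def test_zero_coefficient_gives_zero_qm(self):
        fit = make_fit([0.0], [[0.04]])
        qm, df, p = qm_test(fit, coefficients=[0])
        assert qm == pytest.approx(0.0)
        assert (df, p) == (1, pytest.approx(1.0))

    def test_wald_identity_single_coefficient(self):
        fit = make_fit([0.3], [[0.01]])
        qm, df, p = qm_test(fit, coefficients=[0])
        assert qm == pytest.approx((0.3 / 0.1) ** 2)
        assert df == 1

    def test_duplicated_contrast_row_rejected(self):
        fit = make_fit([0.3, -0.1], [[0.01, 0.0], [0.0, 0.02]])
        L = np.array([[1.0, -1.0], [1.0, -1.0]])
        with pytest.raises(ValidationError, match="rank"):
            qm_test(fit, L=L)


class TestContrast:
    def test_selection_reproduces_coefficient(self):
        fit = make_fit([0.3, -0.1], [[0.01, 0.0], [0.0, 0.02]])
        res = contrast(fit, [1.0, 0.0])
        assert res.estimate == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1)

    def test_difference_of_uncorrelated_coefficients(self):
        fit = make_fit([0.3, -0.1], [[0.01, 0.0], [0.0, 0.02]])
        res = contrast(fit, [1.0, -1.0])
        assert res.estimate == pytest.approx(0.4)
        assert res.se == pytest.approx(math.sqrt(0.03))

    def test_degenerate_contrasts_rejected(self):
        fit = make_fit([0.3, -0.1], [[0.01, 0.0], [0.0, 0.02]])
        with pytest.raises(ValidationError, match="zero-variance"):
            contrast(fit, [0.0, 0.0])
        with pytest.raises(ValidationError, match="length"):
            contrast(fit, [1.0])


class TestHolm:
    def test_step_down_example(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.3]) == pytest.approx([0.3])

    def test_ties_propagate_running_maximum(self):
        assert holm_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.6, 0.6, 0.6])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.1, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_dominates_input_and_idempotent_on_monotone(self, ps):
        adj = holm_adjust(ps)
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        assert all(a <= 1.0 for a in adj)
        # a second pass over an already-adjusted monotone sequence is inert
        again = holm_adjust(sorted(adj))
        assert np.all(np.asarray(again) >= np.asarray(sorted(adj)) - 1e-15)


class TestPredictionInterval:
    def test_equals_ci_without_heterogeneity(self):
        fit = make_fit([0.3], [[0.01]], tau2={"study": 0.0})
        lo, hi = prediction_interval(fit, 0)
        assert (lo, hi) == pytest.approx(tuple(fit.ci[0]))

    def test_half_width_formula(self):
        fit = make_fit([0.0], [[0.01]], tau2={"study": 0.02, "experiment": 0.01})
        lo, hi = prediction_interval(fit, 0)
        assert hi - lo == pytest.approx(2 * 1.959964 * math.sqrt(0.04), abs=1e-4)

    def test_width_monotone_in_tau2(self):
        widths = []
        for t in (0.0, 0.05, 0.2):
            fit = make_fit([0.1], [[0.01]], tau2={"study": t})
            lo, hi = prediction_interval(fit, 0)
            widths.append(hi - lo)
        assert widths == sorted(widths)


class TestI2:
    def test_zero_heterogeneity_zero_i2(self):
        fit = make_fit([0.1], [[0.01]], tau2={"study": 0.0, "genus": 0.0})
        out = i2_decompose(fit, [0.1] * 10)
        assert all(v == pytest.approx(0.0) for v in out.values())

    def test_equal_weights_identity(self):
        # equal v = 0.1 -> typical v equals 0.1; I2_study = .3/.4 = 75%
        fit = make_fit([0.1], [[0.01]], tau2={"study": 0.3})
        out = i2_decompose(fit, [0.1] * 20)
        assert out["study"] == pytest.approx(75.0)
        assert out["total"] == pytest.approx(75.0)

    def test_components_sum_to_total(self, small_smd_effects):
        fit = fit_reml(small_smd_effects, spec=ModelSpec(), n_starts=1)
        assert fit.i2["total"] == pytest.approx(
            sum(v for k, v in fit.i2.items() if k != "total")
        )

    def test_needs_two_effects(self):
        fit = make_fit([0.1], [[0.01]])
        with pytest.raises(ValidationError):
            i2_decompose(fit, [0.1])


class TestCollinearityCrosstab:
    def _records(self):
        rows = (
            [("high", "no")] * 3 + [("high", "yes")] * 1 + [("low", "yes")] * 4
        )
        return [
            effect(0.1, 0.1, comp=f"c{i}", parasite_genetic_diversity=a, laboratory=b)
            for i, (a, b) in enumerate(rows)
        ]

    def test_counts_and_row_percentages(self):
        ct = collinearity_crosstab(self._records(), "parasite_genetic_diversity", "laboratory")
        assert ct.counts.loc["high", "no"] == 3
        assert ct.row_percent.loc["high", "no"] == 75
        assert ct.row_percent.loc["high", "yes"] == 25
        assert ct.row_percent.loc["low", "yes"] == 100

    def test_unknown_moderator(self):
        with pytest.raises(ValidationError, match="unknown moderator"):
            collinearity_crosstab(self._records(), "nope", "laboratory")


class TestEstimatorConventions:
    def test_get_set_params_clone(self):
        est = MultilevelMetaRegression(fixed_terms=("host_range",), n_starts=2)
        params = est.get_params()
        assert params["fixed_terms"] == ("host_range",)
        est2 = clone(est)
        assert est2.get_params() == params
        est2.set_params(vcv_r=0.3)
        assert est2.vcv_r == 0.3

    def test_fitted_attributes_and_predict(self, small_smd_effects):
        est = MultilevelMetaRegression(
            fixed_terms=("host_range",), random_levels=("study",), n_starts=1
        )
        est.fit(small_smd_effects)
        assert hasattr(est, "beta_") and hasattr(est, "tau2_")
        pred = est.predict(pd.DataFrame({"host_range": ["specialist", "generalist"]}))
        for val, name in zip(pred, ("host_range=specialist", "host_range=generalist")):
            assert val == pytest.approx(est.beta_[est.coef_names_.index(name)])

    def test_too_few_effects_rejected(self):
        with pytest.raises(ValidationError, match="cannot identify"):
            fit_reml([effect(0.1, 0.1, comp="c0")], spec=ModelSpec(random_levels=("study",)))
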