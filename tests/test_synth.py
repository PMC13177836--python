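import numpy as np
import pytest

from divmeta.datatypes import ValidationError
from divmeta.effects import effects_from_records, smd
from divmeta.io import comparisons_to_frame
from divmeta.synth import (
    CELLS,
    ConfigError,
    SynthConfig,
    diversity_uncertainty_preset,
    generate_dataset,
    generate_replicates,
)


def flat_cells(smd_val=0.0, cvr_val=0.0):
    return {c: (smd_val, cvr_val) for c in CELLS}


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("tau2_study", -0.1),
            ("rho_experiment", 1.5),
            ("shared_control_fraction", 2.0),
            ("control_mean", -1.0),
            ("n_per_group", (1, 5)),
        ],
    )
    def test_errors_name_offending_field(self, field, value):
        cfg = SynthConfig()
        setattr(cfg, field, value)
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            cfg.validate()

    def test_cell_effects_must_cover_all_cells(self):
        cfg = SynthConfig(cell_effects={("low", "specialist"): (0.0, 0.0)})
        with pytest.raises(ConfigError, match="cell"):
            cfg.validate()

    def test_marginals_must_sum_to_one(self):
        cfg = SynthConfig()
        cfg.moderator_marginals = {"host_range": {"specialist": 0.6, "generalist": 0.6}}
        with pytest.raises(ConfigError, match="sum to 1"):
            cfg.validate()


class TestGenerateDataset:
    def test_deterministic_byte_identical_csv(self, tmp_path):
        cfg = diversity_uncertainty_preset(seed=5, n_studies=8)
        for name in ("a.csv", "b.csv"):
            ds = generate_dataset(cfg)
            comparisons_to_frame(ds.comparisons).to_csv(tmp_path / name, index=False)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_noise_free_limit_recovers_exact_smd(self):
        cfg = SynthConfig(
            n_studies=6, experiments_per_study=2, comparisons_per_experiment=2,
            cell_effects=flat_cells(smd_val=-0.5), sampling_noise=False, seed=1,
        )
        ds = generate_dataset(cfg)
        for rec in ds.comparisons:
            d = smd(rec.low, rec.high, hedges_correction=False)
            assert d.value == pytest.approx(-0.5, abs=1e-9)

    def test_lncvr_monte_carlo_consistency(self):
        # 1000 comparisons, one cell, true lnCVR = ln 2, n = 50 per group
        cfg = SynthConfig(
            n_studies=1000, experiments_per_study=1, comparisons_per_experiment=1,
            cell_effects=flat_cells(cvr_val=0.6931), n_per_group=50,
            shared_control_fraction=0.0, seed=17,
            moderator_marginals={
                "parasite_genetic_diversity": {"low": 1.0},
                "host_range": {"specialist": 1.0},
            },
        )
        ds = generate_dataset(cfg)
        eff = effects_from_records(ds.comparisons, "lnCVR")
        values = np.array([e.value for e in eff])
        mc_se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean() - 0.6931) < 3 * mc_se
        assert {r.moderators["host_range"] for r in ds.comparisons} == {"specialist"}

    def test_three_level_nesting_is_strict(self, small_dataset):
        study_of_exp = {}
        comp_ids = set()
        for rec in small_dataset.comparisons:
            assert rec.comparison_id not in comp_ids
            comp_ids.add(rec.comparison_id)
            assert study_of_exp.setdefault(rec.experiment_id, rec.study_id) == rec.study_id

    def test_truth_aligns_with_comparisons(self, small_dataset):
        assert len(small_dataset.truth) == len(small_dataset.comparisons)
        assert list(small_dataset.truth["comparison_id"]) == [
            r.comparison_id for r in small_dataset.comparisons
        ]

    def test_shared_controls_reuse_low_group(self):
        cfg = diversity_uncertainty_preset(seed=3, n_studies=10, shared_control_fraction=1.0)
        ds = generate_dataset(cfg)
        by_exp = {}
        for rec in ds.comparisons:
            by_exp.setdefault(rec.experiment_id, []).append(rec)
        multi = [recs for recs in by_exp.values() if len(recs) >= 2]
        assert multi, "expected multi-comparison experiments"
        for recs in multi:
            assert all(r.shared_control_key == recs[0].experiment_id for r in recs)
            lows = {(r.low.mean, r.low.sd, r.low.n) for r in recs}
            assert len(lows) == 1  # one control group reused

    def test_study_random_effect_scale(self):
        # tau2_study only, noise-free: per-study SMD deviations have the right SD
        cfg = SynthConfig(
            n_studies=400, experiments_per_study=1, comparisons_per_experiment=1,
            cell_effects=flat_cells(), tau2_study=0.25, sampling_noise=False, seed=8,
        )
        ds = generate_dataset(cfg)
        sd = ds.truth["true_smd"].std(ddof=1)
        assert sd == pytest.approx(0.5, rel=0.15)


class TestPreset:
    def test_sign_structure(self):
        cfg = diversity_uncertainty_preset()
        eff = cfg.cell_effects
        assert eff[("low", "specialist")][1] < 0  # variability drops: low parasite div
        assert eff[("high", "specialist")][1] > 0  # variability rises: high parasite div
        assert all(eff[c][0] <= 0 for c in CELLS)  # mean parasite success never rises
        for hr in ("generalist",):
            for pdiv in ("low", "high"):
                assert abs(eff[(pdiv, hr)][1]) <= min(
                    abs(eff[("low", "specialist")][1]), abs(eff[("high", "specialist")][1])
                )

    def test_overrides_and_unknown_field(self):
        cfg = diversity_uncertainty_preset(n_studies=5, seed=9)
        assert cfg.n_studies == 5 and cfg.seed == 9
        with pytest.raises(ConfigError, match="unknown"):
            diversity_uncertainty_preset(bogus=1)


class TestReplicates:
    def test_proportion_zero_probability_all_zero(self):
        cfg = SynthConfig(control_mean=0.0, seed=4)
        df = generate_replicates(cfg, "proportion", n_populations=3, n_replicates=20)
        assert (df["value"] == 0.0).all()

    def test_replicate_table_shape(self):
        df = generate_replicates(SynthConfig(control_mean=0.5, seed=4), "proportion",
                                 n_populations=4, n_replicates=6)
        assert set(df.columns) == {"population_id", "diversity_score", "replicate", "value"}
        assert len(df) == 24
        assert df["value"].between(0, 1).all()

    def test_poisson_variance_mean_identity(self):
        cfg = SynthConfig(control_mean=4.0, seed=21)
        df = generate_replicates(cfg, "count", n_populations=1, n_replicates=10000,
                                 diversity_slope=0.0)
        ratio = df["value"].var(ddof=1) / df["value"].mean()
        assert ratio == pytest.approx(1.0, abs=3 * np.sqrt(2.25 / 10000) + 0.01)

    def test_continuous_reproducible(self):
        cfg = SynthConfig(seed=13)
        a = generate_replicates(cfg, "continuous", n_populations=4, n_replicates=6)
        b = generate_replicates(cfg, "continuous", n_populations=4, n_replicates=6)
        assert a.equals(b)

    def test_unsupported_kind(self):
        with pytest.raises(ConfigError, match="metric_kind"):
            generate_replicates(SynthConfig(), "ordinal")
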