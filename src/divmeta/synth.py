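"""Synthetic comparison tables with the structure the analysis assumes.

The generator encodes a 2x2 scenario: host populations of high vs low genetic
diversity are compared for parasite success, and the true mean effect (SMD)
and true relative-variability effect (lnCVR) of extra host diversity depend on
the cell (parasite genetic diversity x parasite host range).  Around those
cell means sit study-, genus- and experiment-level random deviations
(experiment deviations compound-symmetric within an experiment), a 3-level
nesting of comparisons within experiments within studies, optional shared
low-diversity control groups, and exact finite-sample summary noise:

    sample mean ~ Normal(mu, sigma^2 / n)
    sample variance ~ sigma^2 * ChiSquare(n - 1) / (n - 1)

which makes the analytic SMD/lnCVR sampling-variance formulas exactly correct
and gives clean calibration targets for the model-fitting code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.optimize

from .datatypes import (
    ComparisonRecord,
    GroupSummary,
    MODERATOR_LEVELS,
    MODERATOR_NAMES,
    ValidationError,
)

CountOrRange = Union[int, tuple[int, int]]

#: the four scenario cells: (parasite_genetic_diversity, host_range)
CELLS = (
    ("low", "specialist"),
    ("high", "specialist"),
    ("low", "generalist"),
    ("high", "generalist"),
)


class ConfigError(ValidationError):
    """Invalid synthetic-data configuration (message names the field)."""


def _default_marginals() -> dict[str, dict[str, float]]:
    return {
        "metric_of_success": {"prevalence": 0.35, "load": 0.40, "virulence": 0.25},
        "host_type": {"invertebrate": 0.70, "vertebrate": 0.30},
        "parasite_type": {"microparasite": 0.75, "macroparasite": 0.25},
        "source_of_diversity": {"relatedness": 0.30, "genotypes": 0.40, "natural": 0.30},
        "scale_of_diversity": {"discrete": 0.60, "continuous": 0.40},
        "host_reproduction": {"sexual": 0.55, "asexual": 0.20, "mixed": 0.25},
        "host_mortality": {"yes": 0.60, "no": 0.40},
        "laboratory": {"yes": 0.55, "no": 0.45},
        "parasite_genetic_diversity": {"high": 0.55, "low": 0.45},
        "host_range": {"specialist": 0.50, "generalist": 0.50},
    }


@dataclass
class SynthConfig:
    """Full parameterisation of a synthetic comparison table."""

    n_studies: int = 48
    experiments_per_study: CountOrRange = (1, 3)
    comparisons_per_experiment: CountOrRange = (1, 3)
    cell_effects: dict[tuple[str, str], tuple[float, float]] = dc_field(
        default_factory=lambda: {c: (0.0, 0.0) for c in CELLS}
    )
    tau2_study: float = 0.0
    tau2_genus: float = 0.0
    tau2_experiment: float = 0.0
    rho_experiment: float = 0.5
    control_mean: float = 100.0
    control_cv: float = 0.2
    n_per_group: CountOrRange = (5, 30)
    shared_control_fraction: float = 0.25
    moderator_marginals: dict[str, dict[str, float]] = dc_field(default_factory=_default_marginals)
    genus_duplication: float = 0.10
    sampling_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("tau2_study", "tau2_genus", "tau2_experiment"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not -1.0 <= self.rho_experiment <= 1.0:
            raise ConfigError(f"rho_experiment must lie in [-1, 1], got {self.rho_experiment}")
        if not 0.0 <= self.shared_control_fraction <= 1.0:
            raise ConfigError(
                f"shared_control_fraction must lie in [0, 1], got {self.shared_control_fraction}"
            )
        if self.n_studies < 1:
            raise ConfigError(f"n_studies must be >= 1, got {self.n_studies}")
        if self.control_mean < 0:
            raise ConfigError(f"control_mean must be >= 0, got {self.control_mean}")
        if self.control_cv <= 0:
            raise ConfigError(f"control_cv must be > 0, got {self.control_cv}")
        if set(self.cell_effects) != set(CELLS):
            raise ConfigError(
                f"cell_effects must cover all four cells {CELLS}, got {sorted(self.cell_effects)}"
            )
        for name, rng in (
            ("experiments_per_study", self.experiments_per_study),
            ("comparisons_per_experiment", self.comparisons_per_experiment),
            ("n_per_group", self.n_per_group),
        ):
            lo, hi = (rng, rng) if isinstance(rng, int) else rng
            if lo > hi or lo < 1:
                raise ConfigError(f"{name} range invalid: {rng}")
            if name == "n_per_group" and lo < 2:
                raise ConfigError(f"n_per_group must be >= 2, got {rng}")
        for mod, probs in self.moderator_marginals.items():
            if mod not in MODERATOR_LEVELS:
                raise ConfigError(f"moderator_marginals: unknown moderator {mod!r}")
            unknown = set(probs) - set(MODERATOR_LEVELS[mod])
            if unknown:
                raise ConfigError(f"moderator_marginals[{mod!r}]: unknown levels {sorted(unknown)}")
            if abs(sum(probs.values()) - 1.0) > 1e-8:
                raise ConfigError(f"moderator_marginals[{mod!r}] must sum to 1")


@dataclass
class SyntheticDataset:
    """Generated comparisons plus the per-comparison truth used to make them."""

    comparisons: list[ComparisonRecord]
    truth: pd.DataFrame
    seed: int
    config: SynthConfig
    n_clamped: int = 0


def _draw_count(rng: np.random.Generator, spec: CountOrRange) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def _draw_level(rng: np.random.Generator, probs: dict[str, float]) -> str:
    levels = list(probs)
    p = np.array([probs[l] for l in levels], dtype=float)
    return levels[rng.choice(len(levels), p=p / p.sum())]


def _solve_mu_high(
    mu_l: float, sd_l: float, cv_h: float, theta: float, n_l: int, n_h: int
) -> tuple[float, bool]:
    """Population mean of the high group such that the standardized difference
    against the pooled SD equals theta, given CV_high.  Returns (mu_H, clamped).

    Solves mu_H = mu_L + theta * s_pool(mu_H) with
    s_pool^2 = [ (n_H-1)(cv_H mu_H)^2 + (n_L-1) sd_L^2 ] / (n_L + n_H - 2).
    """
    if theta == 0.0:
        return mu_l, False
    df = n_l + n_h - 2
    a = (n_h - 1) / df
    b = (n_l - 1) / df
    c2 = cv_h**2
    D = 1.0 - theta**2 * a * c2
    B = a * c2 * mu_l**2 + b * sd_l**2 * D
    if D > 1e-9 and B >= 0.0:
        mu_h = (mu_l + theta * math.sqrt(B)) / D
        if mu_h > 0:
            return mu_h, False

    def f(x: float) -> float:
        s_pool = math.sqrt((a * (cv_h * x) ** 2 + b * sd_l**2))
        return x - mu_l - theta * s_pool

    lo, hi = 1e-9 * mu_l, mu_l * (1.0 + abs(theta) * 10.0)
    try:
        if f(lo) * f(hi) < 0:
            return float(scipy.optimize.brentq(f, lo, hi)), False
    except ValueError:
        pass
    return 1e-3 * mu_l, True  # infeasibly negative effect on a positive scale


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate a comparison table plus its truth from a :class:`SynthConfig`.

    Deterministic given (config, seed); regeneration is bit-identical.
    """
    config.validate()
    if config.control_mean <= 0:
        raise ConfigError("control_mean must be > 0 for group-summary generation")
    rng = np.random.default_rng(config.seed)
    n_s = config.n_studies

    # genus map: one genus per study, a fraction duplicated across studies
    genus_of_study = [f"G{i + 1:03d}" for i in range(n_s)]
    n_dup = int(round(config.genus_duplication * n_s))
    if n_dup > 0 and n_s > 1:
        dup_targets = rng.choice(n_s, size=min(n_dup, n_s - 1), replace=False)
        for t in dup_targets:
            donor = int(rng.integers(0, n_s))
            while donor == t:
                donor = int(rng.integers(0, n_s))
            genus_of_study[t] = genus_of_study[donor]

    tau_s = math.sqrt(config.tau2_study)
    tau_g = math.sqrt(config.tau2_genus)
    tau_e = math.sqrt(config.tau2_experiment)
    rho = config.rho_experiment
    sr = math.sqrt(abs(rho))
    sr1 = math.sqrt(max(1.0 - abs(rho), 0.0))

    genus_effects: dict[str, np.ndarray] = {}
    records: list[ComparisonRecord] = []
    truth_rows: list[dict] = []
    n_clamped = 0

    marg = {**_default_marginals(), **config.moderator_marginals}

    for si in range(n_s):
        study_id = f"S{si + 1:03d}"
        genus = genus_of_study[si]
        if genus not in genus_effects:
            genus_effects[genus] = tau_g * rng.standard_normal(2)
        u_genus = genus_effects[genus]
        u_study = tau_s * rng.standard_normal(2)
        n_exp = _draw_count(rng, config.experiments_per_study)
        for ei in range(n_exp):
            exp_id = f"{study_id}-E{ei + 1}"
            cell = (
                _draw_level(rng, marg["parasite_genetic_diversity"]),
                _draw_level(rng, marg["host_range"]),
            )
            theta_cell = config.cell_effects[cell]
            m_comp = _draw_count(rng, config.comparisons_per_experiment)
            z0 = rng.standard_normal(2)
            shared = m_comp >= 2 and rng.random() < config.shared_control_fraction
            shared_key = exp_id if shared else None

            mu_l = config.control_mean
            sd_l = config.control_cv * mu_l
            if shared:
                n_l_shared = _draw_count(rng, config.n_per_group)
                low_shared = _sample_group(rng, mu_l, sd_l, n_l_shared, config.sampling_noise)

            for ci in range(m_comp):
                comp_id = f"{exp_id}-C{ci + 1}"
                zj = rng.standard_normal(2)
                u_exp = tau_e * (sr * z0 + sr1 * zj) if tau_e > 0 else np.zeros(2)
                theta_smd = theta_cell[0] + u_study[0] + u_genus[0] + u_exp[0]
                theta_cvr = theta_cell[1] + u_study[1] + u_genus[1] + u_exp[1]

                if shared:
                    n_l = n_l_shared
                    low_mean, low_sd = low_shared
                else:
                    n_l = _draw_count(rng, config.n_per_group)
                    low_mean, low_sd = _sample_group(rng, mu_l, sd_l, n_l, config.sampling_noise)
                n_h = _draw_count(rng, config.n_per_group)

                cv_h = config.control_cv * math.exp(theta_cvr)
                mu_h, clamped = _solve_mu_high(mu_l, sd_l, cv_h, theta_smd, n_l, n_h)
                n_clamped += clamped
                sd_h = cv_h * mu_h
                high_mean, high_sd = _sample_group(rng, mu_h, sd_h, n_h, config.sampling_noise)

                metric = _draw_level(rng, marg["metric_of_success"])
                moderators = {
                    "parasite_genetic_diversity": cell[0],
                    "host_range": cell[1],
                    "metric_of_success": metric,
                }
                for mod in MODERATOR_NAMES:
                    if mod not in moderators:
                        moderators[mod] = _draw_level(rng, marg[mod])

                records.append(
                    ComparisonRecord(
                        study_id=study_id,
                        experiment_id=exp_id,
                        comparison_id=comp_id,
                        host_genus=genus,
                        low=GroupSummary(
                            mean=low_mean, sd=low_sd, n=n_l,
                            metric=metric, diversity_level="low",
                        ),
                        high=GroupSummary(
                            mean=high_mean, sd=high_sd, n=n_h,
                            metric=metric, diversity_level="high",
                        ),
                        moderators=moderators,
                        shared_control_key=shared_key,
                    )
                )
                truth_rows.append(
                    dict(
                        comparison_id=comp_id,
                        study_id=study_id,
                        experiment_id=exp_id,
                        host_genus=genus,
                        parasite_genetic_diversity=cell[0],
                        host_range=cell[1],
                        true_smd=theta_smd,
                        true_lncvr=theta_cvr,
                        cell_smd=theta_cell[0],
                        cell_lncvr=theta_cell[1],
                        u_study_smd=u_study[0],
                        u_study_lncvr=u_study[1],
                        mu_low=mu_l,
                        mu_high=mu_h,
                        clamped=bool(clamped),
                    )
                )

    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(
        comparisons=records, truth=truth, seed=config.seed, config=config, n_clamped=n_clamped
    )


def _sample_group(
    rng: np.random.Generator, mu: float, sigma: float, n: int, noise: bool
) -> tuple[float, float]:
    if not noise:
        return mu, sigma
    mean = rng.normal(mu, sigma / math.sqrt(n))
    var = sigma**2 * rng.chisquare(n - 1) / (n - 1)
    return max(mean, 1e-6), math.sqrt(var)


def generate_replicates(
    config: SynthConfig,
    metric_kind: str,
    n_populations: int = 8,
    n_replicates: Optional[int] = None,
    diversity_slope: float = -0.5,
    n_trials: int = 20,
) -> pd.DataFrame:
    """Replicate-level observations per population with a continuous diversity
    score, for exercising the harmonisation (dichotomisation) stage.

    metric_kind: "continuous" (Normal), "proportion" (Binomial count / n_trials)
    or "count" (Poisson).  The population-level expectation declines linearly
    with the diversity score at rate ``diversity_slope`` (relative units).
    """
    config.validate()
    if metric_kind not in ("continuous", "proportion", "count"):
        raise ConfigError(f"unsupported metric_kind {metric_kind!r}")
    rng = np.random.default_rng(config.seed)
    n_rep = n_replicates if n_replicates is not None else _draw_count(rng, config.n_per_group)
    rows = []
    for pi in range(n_populations):
        score = float(rng.uniform()) if n_populations > 1 else 0.5
        scale = 1.0 + diversity_slope * (score - 0.5)
        if metric_kind == "continuous":
            mu = config.control_mean * scale
            values = rng.normal(mu, config.control_cv * config.control_mean, size=n_rep)
        elif metric_kind == "proportion":
            p0 = config.control_mean if config.control_mean <= 1.0 else 0.5
            p = float(np.clip(p0 * scale, 0.0, 1.0))
            values = rng.binomial(n_trials, p, size=n_rep) / n_trials
        else:
            lam = max(config.control_mean * scale, 0.0)
            values = rng.poisson(lam, size=n_rep).astype(float)
        for ri, v in enumerate(values):
            rows.append(
                dict(
                    population_id=f"P{pi + 1:03d}",
                    diversity_score=score,
                    replicate=ri + 1,
                    value=float(v),
                )
            )
    return pd.DataFrame(rows)


def diversity_uncertainty_preset(**overrides) -> SynthConfig:
    """Default scenario: extra host genetic diversity lowers mean parasite
    success in every cell (most strongly for specialist parasites), while its
    effect on variability flips sign with parasite genetic diversity for
    specialists (negative under low, positive under high parasite diversity)
    and is absent for generalists.  Cell magnitudes are illustrative and
    configurable."""
    cfg = SynthConfig(
        n_studies=48,
        experiments_per_study=(1, 3),
        comparisons_per_experiment=(1, 3),
        cell_effects={
            ("low", "specialist"): (-0.54, -0.54),
            ("high", "specialist"): (-0.76, 0.61),
            ("low", "generalist"): (-0.42, 0.0),
            ("high", "generalist"): (-0.23, 0.0),
        },
        tau2_study=0.45,
        tau2_genus=0.02,
        tau2_experiment=0.08,
        rho_experiment=0.5,
        control_mean=100.0,
        control_cv=0.2,
        n_per_group=(5, 30),
        shared_control_fraction=0.25,
        seed=0,
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown SynthConfig field {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg
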