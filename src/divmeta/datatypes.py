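"""Core record types shared across the pipeline.

The unit of analysis is one comparison of parasite success between a group of
high-genetic-diversity host populations and a group of low-genetic-diversity
host populations.  Each group is summarised by (mean, SD, n) of a parasite
success metric; comparisons nest within experiments, which nest within studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional


class ValidationError(ValueError):
    """Raised when a record or configuration violates its invariants."""


#: Closed moderator vocabularies (ten categorical moderators: the 2x2
#: parasite-diversity x host-range structure plus eight contextual factors).
MODERATOR_LEVELS: dict[str, tuple[str, ...]] = {
    "metric_of_success": ("prevalence", "load", "virulence"),
    "host_type": ("invertebrate", "vertebrate"),
    "parasite_type": ("microparasite", "macroparasite"),
    "source_of_diversity": ("relatedness", "genotypes", "natural"),
    "scale_of_diversity": ("discrete", "continuous"),
    "host_reproduction": ("sexual", "asexual", "mixed"),
    "host_mortality": ("yes", "no"),
    "laboratory": ("yes", "no"),
    "parasite_genetic_diversity": ("high", "low"),
    "host_range": ("specialist", "generalist"),
}

MODERATOR_NAMES: tuple[str, ...] = tuple(MODERATOR_LEVELS)

METRIC_KINDS = ("prevalence", "load", "virulence", "other")


@dataclass
class GroupSummary:
    """Summary of one diversity group: mean, SD and n of a success metric.

    ``proportion`` marks metrics bounded in [0, 1] (e.g. prevalence,
    survival/mortality rates); ``survival_direction`` marks metrics coded so
    that larger values mean parasite *failure* (host survival), which must be
    reversed before analysis; ``direction_reversed`` records that a
    non-proportion survival metric was handled by sign reversal downstream.
    """

    mean: float
    sd: float
    n: int
    metric: str = "other"
    metric_label: str = ""
    diversity_level: str = "low"
    proportion: bool = False
    survival_direction: bool = False
    direction_reversed: bool = False

    def __post_init__(self) -> None:
        if self.metric not in METRIC_KINDS:
            raise ValidationError(f"unknown metric {self.metric!r}")
        if self.diversity_level not in ("low", "high"):
            raise ValidationError(
                f"diversity_level must be 'low' or 'high', got {self.diversity_level!r}"
            )
        if not self.sd >= 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd}")
        if not self.n >= 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if self.proportion and not (0.0 <= self.mean <= 1.0):
            raise ValidationError(
                f"proportion metric mean must lie in [0, 1], got {self.mean}"
            )

    def with_(self, **kwargs) -> "GroupSummary":
        return replace(self, **kwargs)


@dataclass
class ComparisonRecord:
    """One harmonised high-vs-low diversity comparison with its moderators."""

    study_id: str
    experiment_id: str
    comparison_id: str
    host_genus: str
    low: GroupSummary
    high: GroupSummary
    moderators: dict[str, str] = field(default_factory=dict)
    shared_control_key: Optional[str] = None

    def __post_init__(self) -> None:
        if self.low.diversity_level != "low":
            raise ValidationError(
                f"{self.comparison_id}: 'low' group has diversity_level "
                f"{self.low.diversity_level!r}"
            )
        if self.high.diversity_level != "high":
            raise ValidationError(
                f"{self.comparison_id}: 'high' group has diversity_level "
                f"{self.high.diversity_level!r}"
            )
        for name, value in self.moderators.items():
            levels = MODERATOR_LEVELS.get(name)
            if levels is None:
                raise ValidationError(f"unknown moderator {name!r}")
            if value not in levels:
                raise ValidationError(
                    f"{self.comparison_id}: moderator {name}={value!r} not in {levels}"
                )


@dataclass
class EffectSize:
    """A typed effect (SMD or lnCVR) with its sampling variance."""

    kind: str  # "SMD" | "lnCVR"
    value: float
    variance: float
    comparison_id: str = ""
    study_id: str = ""
    experiment_id: str = ""
    host_genus: str = ""
    shared_control_key: Optional[str] = None
    n_low: Optional[int] = None
    n_high: Optional[int] = None
    moderators: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("SMD", "lnCVR"):
            raise ValidationError(f"kind must be 'SMD' or 'lnCVR', got {self.kind!r}")
        if not self.variance >= 0:
            raise ValidationError(f"variance must be >= 0, got {self.variance}")

    @property
    def se(self) -> float:
        return self.variance ** 0.5
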