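"""Canonical CSV schema, readers/writers and run configuration.

The comparison table has one row per high-vs-low diversity comparison:
identifiers, the two group summaries, the metric, and ten categorical
moderators.  Unknown extra columns are preserved as passthrough.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ComparisonRecord,
    EffectSize,
    GroupSummary,
    MODERATOR_NAMES,
    ValidationError,
)
from .effects import SamplingCovariance

SCHEMA_VERSION = "1.0"

#: required columns of the canonical comparison table
REQUIRED_COLUMNS: tuple[str, ...] = (
    "study_id",
    "experiment_id",
    "comparison_id",
    "host_genus",
    "low_mean",
    "low_sd",
    "low_n",
    "high_mean",
    "high_sd",
    "high_n",
    "metric",
) + MODERATOR_NAMES

OPTIONAL_COLUMNS: tuple[str, ...] = ("shared_control_key", "proportion", "survival_direction")


def read_comparisons(path: Union[str, Path]) -> list[ComparisonRecord]:
    """Read and validate a canonical comparison-table CSV.

    Row-level validation problems are collected and reported together with
    1-based file line numbers (header is line 1); nothing is silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing required columns {missing}")

    records: list[ComparisonRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            for col in ("low_mean", "low_sd", "high_mean", "high_sd"):
                if not np.isfinite(float(row[col])):
                    raise ValidationError(f"non-finite {col}")
            shared = row.get("shared_control_key")
            if pd.isna(shared):
                shared = None
            prop = bool(row.get("proportion", False)) if "proportion" in df else False
            surv = bool(row.get("survival_direction", False)) if "survival_direction" in df else False
            low = GroupSummary(
                mean=float(row["low_mean"]), sd=float(row["low_sd"]), n=int(row["low_n"]),
                metric=str(row["metric"]), diversity_level="low",
                proportion=prop, survival_direction=surv,
            )
            high = GroupSummary(
                mean=float(row["high_mean"]), sd=float(row["high_sd"]), n=int(row["high_n"]),
                metric=str(row["metric"]), diversity_level="high",
                proportion=prop, survival_direction=surv,
            )
            records.append(
                ComparisonRecord(
                    study_id=str(row["study_id"]),
                    experiment_id=str(row["experiment_id"]),
                    comparison_id=str(row["comparison_id"]),
                    host_genus=str(row["host_genus"]),
                    low=low,
                    high=high,
                    moderators={m: str(row[m]) for m in MODERATOR_NAMES},
                    shared_control_key=None if shared is None else str(shared),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError(f"{path.name}: {len(errors)} invalid rows:\n" + "\n".join(errors))
    return records


def comparisons_to_frame(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = dict(
            study_id=r.study_id,
            experiment_id=r.experiment_id,
            comparison_id=r.comparison_id,
            host_genus=r.host_genus,
            shared_control_key=r.shared_control_key,
            low_mean=r.low.mean,
            low_sd=r.low.sd,
            low_n=r.low.n,
            high_mean=r.high.mean,
            high_sd=r.high.sd,
            high_n=r.high.n,
            metric=r.low.metric,
            proportion=r.low.proportion,
            survival_direction=r.low.survival_direction,
        )
        row.update({m: r.moderators.get(m, "") for m in MODERATOR_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def write_comparisons(records: Sequence[ComparisonRecord], path: Union[str, Path]) -> None:
    comparisons_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def effects_to_frame(effects: Sequence[EffectSize]) -> pd.DataFrame:
    rows = []
    for e in effects:
        row = dict(
            kind=e.kind,
            value=e.value,
            variance=e.variance,
            comparison_id=e.comparison_id,
            study_id=e.study_id,
            experiment_id=e.experiment_id,
            host_genus=e.host_genus,
            shared_control_key=e.shared_control_key,
            n_low=e.n_low,
            n_high=e.n_high,
        )
        row.update({m: e.moderators.get(m, "") for m in MODERATOR_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def write_effects(effects: Sequence[EffectSize], path: Union[str, Path]) -> None:
    effects_to_frame(effects).to_csv(path, index=False, float_format="%.17g")


def read_effects(path: Union[str, Path]) -> list[EffectSize]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        shared = row.get("shared_control_key")
        mods = {m: str(row[m]) for m in MODERATOR_NAMES if m in df.columns and not pd.isna(row[m])}
        out.append(
            EffectSize(
                kind=str(row["kind"]),
                value=float(row["value"]),
                variance=float(row["variance"]),
                comparison_id=str(row["comparison_id"]),
                study_id=str(row["study_id"]),
                experiment_id=str(row["experiment_id"]),
                host_genus=str(row.get("host_genus", "")),
                shared_control_key=None if pd.isna(shared) else str(shared),
                n_low=None if pd.isna(row.get("n_low")) else int(row["n_low"]),
                n_high=None if pd.isna(row.get("n_high")) else int(row["n_high"]),
                moderators=mods,
            )
        )
    return out


def write_vcv(vcv: SamplingCovariance, path: Union[str, Path]) -> None:
    pd.DataFrame(vcv.matrix, index=vcv.ordering, columns=vcv.ordering).to_csv(
        path, float_format="%.17g"
    )


def read_vcv(path: Union[str, Path]) -> SamplingCovariance:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return SamplingCovariance(df.to_numpy(dtype=float), [str(c) for c in df.columns])


#: eight contextual moderators analysed one at a time (the 2x2 pair is RQ2)
RQ3_MODERATORS: tuple[str, ...] = tuple(
    m for m in MODERATOR_NAMES if m not in ("parasite_genetic_diversity", "host_range")
)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    input: str = "diversity_uncertainty"  # preset name or path to a comparison CSV
    effect_kinds: tuple[str, ...] = ("SMD", "lnCVR")
    vcv_mode: str = "fixed_r"
    vcv_r: float = 0.5
    offset: float = 0.001
    offset_policy: str = "always"
    random_levels: tuple[str, ...] = ("study", "genus", "experiment")
    rq3_moderators: tuple[str, ...] = RQ3_MODERATORS
    outdir: str = "divmeta_results"
    seed: int = 0
    n_studies: Optional[int] = None  # override for the preset
    n_starts: int = 2
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("effect_kinds", "random_levels", "rq3_moderators"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = asdict(self)
        for key in ("effect_kinds", "random_levels", "rq3_moderators"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def file_checksum(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: Union[str, Path]) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
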