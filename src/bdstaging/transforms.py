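"""Profiler normalisation: map the 12 raw clinical profilers onto [0, 1].

The staging model's severity formula operates on twelve unit-interval
"profilers" drawn from five life domains (clinical course of the bipolar
disorder, physical health, cognition, real-world functioning, and
health-related quality of life).  Raw inputs arrive on heterogeneous scales
— lifetime counts, binary flags, bounded psychometric totals, norm-based
z-scores — and each is sent into [0, 1] by a small family of transforms:

``capped_count``      min(count, cap) / cap
``binary``            identity on {0, 1}
``linear_rescale``    clip((x - lo) / (hi - lo), 0, 1)
``ordinal_map``       explicit monotone category -> value map
``categorical_bmi``   step map over BMI categories (normal / overweight / obese)
``z_linear_clip``     clip((z_best - z) / (z_best - z_worst), 0, 1), decreasing
                      in z because higher z means better health

Every transform is monotone in clinical severity and saturates at the
interval endpoints.  The registry of per-profiler transform specifications
is configurable; :func:`default_registry` ships the documented defaults.
"""

from __future__ import annotations

import math
from typing import Literal, Mapping

import pandas as pd
from pydantic import BaseModel, model_validator

__all__ = [
    "PROFILERS",
    "LIFE_DOMAINS",
    "SCIP_LEVELS",
    "TransformSpec",
    "transform_capped_count",
    "transform_binary",
    "transform_linear_rescale",
    "transform_ordinal",
    "transform_z_linear",
    "transform_bmi",
    "transform_value",
    "transform_patient",
    "transform_table",
    "default_registry",
    "registry_from_dict",
    "registry_to_dict",
]

#: Canonical profiler column names, in severity-formula order.
PROFILERS: tuple[str, ...] = (
    "hosp_n",
    "suic_att_n",
    "com_pd",
    "bmi",
    "mets",
    "illness_n",
    "scip_cat",
    "pd_x_bd",
    "fast_total",
    "fast_leisure",
    "sf_pf",
    "sf_mh",
)

#: Life-domain tag per profiler.
LIFE_DOMAINS: Mapping[str, str] = {
    "hosp_n": "bipolar_disorder",
    "suic_att_n": "bipolar_disorder",
    "com_pd": "bipolar_disorder",
    "bmi": "physical_health",
    "mets": "physical_health",
    "illness_n": "physical_health",
    "scip_cat": "cognition",
    "pd_x_bd": "functioning",
    "fast_total": "functioning",
    "fast_leisure": "functioning",
    "sf_pf": "qol",
    "sf_mh": "qol",
}

#: Ordered cognitive-impairment categories (screening instrument tertiles + none).
SCIP_LEVELS: tuple[str, ...] = ("none", "mild", "moderate", "severe")

TransformKind = Literal[
    "capped_count",
    "binary",
    "ordinal_map",
    "linear_rescale",
    "categorical_bmi",
    "z_linear_clip",
]


class TransformSpec(BaseModel):
    """One profiler's transform: its kind plus the kind's parameters.

    Parameters are validated at construction so a registry either fails
    loudly or is guaranteed to map each profiler's admissible domain
    into [0, 1].
    """

    name: str
    kind: TransformKind
    cap: int | None = None
    lo: float | None = None
    hi: float | None = None
    level_map: dict[str, float] | None = None
    z_best: float | None = None
    z_worst: float | None = None
    bmi_edges: tuple[float, float] | None = None
    bmi_values: tuple[float, float, float] | None = None

    @model_validator(mode="after")
    def _check_params(self) -> "TransformSpec":
        if self.kind == "capped_count":
            if self.cap is None or self.cap < 1:
                raise ValueError(f"{self.name}: capped_count requires cap >= 1")
        elif self.kind == "linear_rescale":
            if self.lo is None or self.hi is None or not self.lo < self.hi:
                raise ValueError(f"{self.name}: linear_rescale requires lo < hi")
        elif self.kind == "ordinal_map":
            if not self.level_map:
                raise ValueError(f"{self.name}: ordinal_map requires level_map")
            vals = list(self.level_map.values())
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"{self.name}: level_map values must lie in [0,1]")
            if vals != sorted(vals):
                raise ValueError(f"{self.name}: level_map must be monotone in category order")
        elif self.kind == "z_linear_clip":
            if self.z_best is None or self.z_worst is None or self.z_best == self.z_worst:
                raise ValueError(f"{self.name}: z_linear_clip requires z_best != z_worst")
        elif self.kind == "categorical_bmi":
            edges = self.bmi_edges or (25.0, 30.0)
            values = self.bmi_values or (0.0, 0.5, 1.0)
            if not edges[0] < edges[1]:
                raise ValueError(f"{self.name}: bmi_edges must be increasing")
            if list(values) != sorted(values) or not 0 <= values[0] or not values[-1] <= 1:
                raise ValueError(f"{self.name}: bmi_values must be non-decreasing in [0,1]")
            object.__setattr__(self, "bmi_edges", tuple(edges))
            object.__setattr__(self, "bmi_values", tuple(values))
        return self


def transform_capped_count(count: float, cap: int) -> float:
    """Saturating count transform ``min(count, cap) / cap``."""
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return min(count, cap) / cap


def transform_binary(flag: float) -> float:
    """Identity on {0, 1}; anything else is rejected."""
    if flag not in (0, 1):
        raise ValueError(f"binary profiler must be 0 or 1, got {flag!r}")
    return float(flag)


def transform_linear_rescale(score: float, lo: float, hi: float) -> float:
    """Linear rescale of a bounded instrument score, clipped to [0, 1]."""
    if lo >= hi:
        raise ValueError(f"lo must be < hi, got lo={lo}, hi={hi}")
    return min(max((score - lo) / (hi - lo), 0.0), 1.0)


def transform_ordinal(category: str, level_map: Mapping[str, float]) -> float:
    """Map an ordered category to its configured unit-interval value."""
    try:
        return float(level_map[category])
    except KeyError:
        raise ValueError(
            f"unknown category {category!r}; expected one of {sorted(level_map)}"
        ) from None


def transform_z_linear(z: float, z_best: float, z_worst: float) -> float:
    """Reverse-code a z-score (higher z = better health) onto [0, 1]."""
    if z_best == z_worst:
        raise ValueError("z_best and z_worst must differ")
    return min(max((z_best - z) / (z_best - z_worst), 0.0), 1.0)


def transform_bmi(
    bmi: float,
    edges: tuple[float, float] = (25.0, 30.0),
    values: tuple[float, float, float] = (0.0, 0.5, 1.0),
) -> float:
    """WHO-category step map: normal range -> values[0], overweight -> values[1],
    obese -> values[2]."""
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi < edges[0]:
        return values[0]
    if bmi < edges[1]:
        return values[1]
    return values[2]


def transform_value(raw, spec: TransformSpec) -> float:
    """Apply one TransformSpec to one raw value. NaN propagates as NaN."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return float("nan")
    if spec.kind == "capped_count":
        return transform_capped_count(raw, spec.cap)
    if spec.kind == "binary":
        return transform_binary(raw)
    if spec.kind == "linear_rescale":
        return transform_linear_rescale(raw, spec.lo, spec.hi)
    if spec.kind == "ordinal_map":
        return transform_ordinal(raw, spec.level_map)
    if spec.kind == "z_linear_clip":
        return transform_z_linear(raw, spec.z_best, spec.z_worst)
    if spec.kind == "categorical_bmi":
        return transform_bmi(raw, spec.bmi_edges, spec.bmi_values)
    raise ValueError(f"unknown transform kind {spec.kind!r}")  # pragma: no cover


def default_registry() -> dict[str, TransformSpec]:
    """The documented default transform per profiler.

    Counts saturate at caps chosen so that the tail beyond the cap is
    clinically equivalent "many" (6 hospitalisations, 6 suicide attempts,
    4 comorbid physical illnesses); the functioning totals rescale by their
    instrument ranges (0-72 and 0-6); cognition uses an equal-spaced
    four-level map; BMI uses the WHO category step map; the two SF-36
    z-scores reverse-code linearly over [-3, +3].
    """
    return {
        "hosp_n": TransformSpec(name="hosp_n", kind="capped_count", cap=6),
        "suic_att_n": TransformSpec(name="suic_att_n", kind="capped_count", cap=6),
        "com_pd": TransformSpec(name="com_pd", kind="binary"),
        "bmi": TransformSpec(
            name="bmi", kind="categorical_bmi", bmi_edges=(25.0, 30.0), bmi_values=(0.0, 0.5, 1.0)
        ),
        "mets": TransformSpec(name="mets", kind="binary"),
        "illness_n": TransformSpec(name="illness_n", kind="capped_count", cap=4),
        "scip_cat": TransformSpec(
            name="scip_cat",
            kind="ordinal_map",
            level_map={"none": 0.0, "mild": 1 / 3, "moderate": 2 / 3, "severe": 1.0},
        ),
        "pd_x_bd": TransformSpec(name="pd_x_bd", kind="binary"),
        "fast_total": TransformSpec(name="fast_total", kind="linear_rescale", lo=0.0, hi=72.0),
        "fast_leisure": TransformSpec(name="fast_leisure", kind="linear_rescale", lo=0.0, hi=6.0),
        "sf_pf": TransformSpec(name="sf_pf", kind="z_linear_clip", z_best=3.0, z_worst=-3.0),
        "sf_mh": TransformSpec(name="sf_mh", kind="z_linear_clip", z_best=3.0, z_worst=-3.0),
    }


def registry_from_dict(entries: list[dict] | dict[str, dict]) -> dict[str, TransformSpec]:
    """Build a registry from parsed YAML/JSON config entries."""
    if isinstance(entries, dict):
        entries = [{"name": k, **v} for k, v in entries.items()]
    registry = {}
    for entry in entries:
        spec = TransformSpec(**entry)
        if spec.name in registry:
            raise ValueError(f"duplicate transform for profiler {spec.name!r}")
        registry[spec.name] = spec
    _check_coverage(registry)
    return registry


def registry_to_dict(registry: Mapping[str, TransformSpec]) -> list[dict]:
    """Serialise a registry to plain dicts (YAML/JSON-ready)."""
    return [spec.model_dump(exclude_none=True) for spec in registry.values()]


def _check_coverage(registry: Mapping[str, TransformSpec]) -> None:
    missing = [p for p in PROFILERS if p not in registry]
    extra = [p for p in registry if p not in PROFILERS]
    if missing or extra:
        raise ValueError(
            f"transform registry must cover the 12 profilers exactly once; "
            f"missing={missing}, unknown={extra}"
        )


def transform_patient(raw: Mapping[str, object], registry: Mapping[str, TransformSpec] | None = None) -> dict[str, float]:
    """Transform one patient's raw profiler mapping to a unit-interval profile.

    Missing raw values propagate as NaN, never as silent zeros; downstream
    severity scoring refuses NaN explicitly.
    """
    registry = registry if registry is not None else default_registry()
    _check_coverage(registry)
    out: dict[str, float] = {}
    for name in PROFILERS:
        if name not in raw:
            out[name] = float("nan")
            continue
        try:
            out[name] = transform_value(raw[name], registry[name])
        except ValueError as exc:
            raise ValueError(f"profiler {name!r}: {exc}") from exc
    return out


def transform_table(
    frame: pd.DataFrame, registry: Mapping[str, TransformSpec] | None = None
) -> pd.DataFrame:
    """Transform a cohort table (one row per patient-timepoint).

    Returns a DataFrame with the 12 profiler columns on [0, 1], preserving
    the input index.  Rows whose raw values violate a transform's domain
    raise with the offending profiler named.
    """
    registry = registry if registry is not None else default_registry()
    _check_coverage(registry)
    cols = {}
    for name in PROFILERS:
        if name not in frame.columns:
            raise ValueError(f"input table lacks profiler column {name!r}")
        spec = registry[name]
        cols[name] = frame[name].map(lambda v, s=spec: transform_value(v, s))
    return pd.DataFrame(cols, index=frame.index)
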