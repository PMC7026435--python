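"""Global severity score, stage assignment, and the StagingModel/StagingResults pair.

The model is a fixed linear composite: with the twelve profilers mapped to
[0, 1] (see :mod:`bdstaging.transforms`),

    severity = (10 / 12) * sum(profilers)

so severity ranges over [0, 10] and equal weight attaches to each profiler.
Four interior cutoffs — by default the 5th/25th/50th/75th percentile scores
of the derivation cohort, 1.70 / 2.50 / 4.50 / 6.10 — partition [0, 10] into
five ordered clinical stages.  Stage 1 covers [0, 1.70]; each later stage s
covers the half-open interval (c_{s-1}, c_s], with stage 5 = (6.10, 10].

``StagingModel`` bundles a transform registry with cutoffs; ``fit`` scores a
raw cohort table and returns ``StagingResults``, which carries per-patient
severities and stages plus summary, construct-validity and transition
methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .transforms import (
    PROFILERS,
    TransformSpec,
    default_registry,
    transform_table,
)

__all__ = [
    "DEFAULT_CUTOFFS",
    "StageCutoffs",
    "severity_score",
    "assign_stage",
    "calibrate_cutoffs",
    "score_cohort",
    "StagingModel",
    "StagingResults",
]

SEVERITY_WEIGHT = 10.0 / 12.0


def _formula(total: float | np.ndarray | pd.Series):
    # 10 * s / 12 rather than (10/12) * s: exact at the endpoints (s = 0, 12)
    return 10.0 * total / 12.0


@dataclass(frozen=True)
class StageCutoffs:
    """Four strictly increasing interior boundaries on the severity axis.

    Stage s covers (c_{s-1}, c_s]; stage 1 is closed below at 0 and stage 5
    closed above at 10.
    """

    boundaries: tuple[float, float, float, float] = (1.70, 2.50, 4.50, 6.10)

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if len(b) != 4:
            raise ValueError("exactly four interior cutoffs are required")
        if not (0.0 < b[0] < b[1] < b[2] < b[3] < 10.0):
            raise ValueError(f"cutoffs must be strictly increasing inside (0, 10), got {b}")
        object.__setattr__(self, "boundaries", b)

    def __iter__(self):
        return iter(self.boundaries)


DEFAULT_CUTOFFS = StageCutoffs()


def severity_score(profile: Mapping[str, float] | Sequence[float]) -> float:
    """Evaluate the severity formula (10/12 times the profiler sum).

    ``profile`` is either a mapping with the 12 canonical profiler names or a
    sequence of 12 unit-interval values.  A missing or NaN profiler raises,
    naming the profiler: severity is never computed from silently imputed
    zeros.
    """
    if isinstance(profile, Mapping):
        values = []
        for name in PROFILERS:
            if name not in profile:
                raise ValueError(f"profiler {name!r} missing from profile")
            v = float(profile[name])
            if math.isnan(v):
                raise ValueError(f"profiler {name!r} is missing (NaN)")
            values.append(v)
    else:
        values = [float(v) for v in profile]
        if len(values) != len(PROFILERS):
            raise ValueError(f"expected {len(PROFILERS)} profiler values, got {len(values)}")
        if any(math.isnan(v) for v in values):
            raise ValueError("profile contains missing (NaN) values")
    if any(v < 0.0 or v > 1.0 for v in values):
        raise ValueError("transformed profiler values must lie in [0, 1]")
    return _formula(sum(values))


def assign_stage(severity: float, cutoffs: StageCutoffs = DEFAULT_CUTOFFS) -> int:
    """Assign the unique stage whose interval contains ``severity``."""
    if math.isnan(severity) or severity < 0.0 or severity > 10.0:
        raise ValueError(f"severity must lie in [0, 10], got {severity}")
    for s, c in enumerate(cutoffs.boundaries, start=1):
        if severity <= c:
            return s
    return 5


def assign_stages(severities: np.ndarray | Sequence[float], cutoffs: StageCutoffs = DEFAULT_CUTOFFS) -> np.ndarray:
    """Vectorised stage assignment with the same half-open convention."""
    sev = np.asarray(severities, dtype=float)
    if np.isnan(sev).any() or (sev < 0).any() or (sev > 10).any():
        raise ValueError("severities must lie in [0, 10] with no missing values")
    # searchsorted with side='left' puts x == c in the lower stage: (c', c] bins
    return np.searchsorted(np.asarray(cutoffs.boundaries), sev, side="left") + 1


def calibrate_cutoffs(
    severities: Sequence[float],
    percentiles: Sequence[float] = (5.0, 25.0, 50.0, 75.0),
) -> StageCutoffs:
    """Re-derive cutoffs as empirical percentiles of a severity sample.

    Uses the linear-interpolation percentile definition.  Requires at least
    20 values and four strictly increasing percentile levels in (0, 100);
    ties that collapse two boundaries raise, because the five intervals
    would no longer partition [0, 10].
    """
    sev = np.asarray(list(severities), dtype=float)
    if sev.size < 20:
        raise ValueError(f"need at least 20 severity values to calibrate, got {sev.size}")
    p = np.asarray(list(percentiles), dtype=float)
    if p.size != 4 or (np.diff(p) <= 0).any() or p[0] <= 0 or p[-1] >= 100:
        raise ValueError("percentiles must be 4 strictly increasing values in (0, 100)")
    cuts = np.percentile(sev, p, method="linear")
    if (np.diff(cuts) <= 0).any() or cuts[0] <= 0 or cuts[-1] >= 10:
        raise ValueError(
            f"calibration failed: percentile values {cuts.tolist()} do not "
            "define a strictly increasing partition of (0, 10)"
        )
    return StageCutoffs(tuple(cuts.tolist()))


def score_cohort(
    frame: pd.DataFrame,
    registry: Mapping[str, TransformSpec] | None = None,
    cutoffs: StageCutoffs = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Score a raw cohort table: transform, evaluate severity, assign stages.

    Returns a copy of ``frame`` with ``severity`` and ``stage`` columns
    appended.  Rows with any missing profiler get NaN severity and a
    missing stage (pandas NA), and are reported rather than fatal.
    """
    if frame.empty:
        raise ValueError("cohort table is empty")
    transformed = transform_table(frame, registry)
    sev = _formula(transformed.sum(axis=1, skipna=False))
    out = frame.copy()
    out["severity"] = sev
    ok = sev.notna()
    stage = pd.array([pd.NA] * len(out), dtype="Int64")
    if ok.any():
        stage[np.asarray(ok)] = assign_stages(sev[ok].to_numpy(), cutoffs)
    out["stage"] = stage
    return out


@dataclass
class StagingModel:
    """The staging model: a transform registry plus stage cutoffs.

    Parameters
    ----------
    registry
        Per-profiler transform specifications; defaults to the documented
        default registry.
    cutoffs
        Interior stage boundaries; defaults to 1.70 / 2.50 / 4.50 / 6.10.
    """

    registry: dict[str, TransformSpec] = field(default_factory=default_registry)
    cutoffs: StageCutoffs = DEFAULT_CUTOFFS

    @classmethod
    def from_config(cls, config: Mapping) -> "StagingModel":
        """Build from a parsed config mapping with optional ``transforms``
        (list of spec dicts) and ``cutoffs`` (4 floats) entries."""
        from .transforms import registry_from_dict

        registry = (
            registry_from_dict(config["transforms"])
            if "transforms" in config
            else default_registry()
        )
        cutoffs = (
            StageCutoffs(tuple(config["cutoffs"])) if "cutoffs" in config else DEFAULT_CUTOFFS
        )
        return cls(registry=registry, cutoffs=cutoffs)

    def severity(self, raw: Mapping[str, object]) -> float:
        """Severity of a single patient's raw profiler mapping."""
        from .transforms import transform_patient

        return severity_score(transform_patient(raw, self.registry))

    def stage(self, raw: Mapping[str, object]) -> int:
        """Stage of a single patient's raw profiler mapping."""
        return assign_stage(self.severity(raw), self.cutoffs)

    def fit(self, frame: pd.DataFrame) -> "StagingResults":
        """Score a raw cohort table and return results."""
        scored = score_cohort(frame, self.registry, self.cutoffs)
        return StagingResults(model=self, frame=scored)

    def calibrate(
        self,
        severities: Sequence[float],
        percentiles: Sequence[float] = (5.0, 25.0, 50.0, 75.0),
    ) -> "StagingModel":
        """Return a new model with cutoffs re-derived from a severity sample."""
        return StagingModel(registry=dict(self.registry), cutoffs=calibrate_cutoffs(severities, percentiles))


@dataclass
class StagingResults:
    """Per-patient severities and stages for a scored cohort.

    ``frame`` holds the input columns plus ``severity`` (full precision)
    and ``stage`` (nullable integer, 1-5).
    """

    model: StagingModel
    frame: pd.DataFrame

    @property
    def severities(self) -> pd.Series:
        return self.frame["severity"]

    @property
    def stages(self) -> pd.Series:
        return self.frame["stage"]

    def stage_counts(self) -> pd.Series:
        """Patients per stage 1-5 (stages with no patients included as 0)."""
        counts = self.stages.value_counts().reindex(range(1, 6), fill_value=0)
        counts.index.name = "stage"
        return counts.astype(int)

    def summary(self) -> str:
        """Human-readable cohort summary: severity moments and the stage table."""
        sev = self.severities.dropna()
        n_missing = int(self.severities.isna().sum())
        counts = self.stage_counts()
        pct = 100.0 * counts / counts.sum() if counts.sum() else counts * 0.0
        lines = [
            "Clinical staging model — cohort summary",
            "=" * 43,
            f"Patients scored: {len(sev)}" + (f" ({n_missing} with missing profilers)" if n_missing else ""),
            f"Severity mean (SD): {sev.mean():.2f} ({sev.std(ddof=1):.2f})"
            if len(sev) > 1
            else f"Severity mean: {sev.mean():.2f}",
            f"Severity min / max: {sev.min():.2f} / {sev.max():.2f}",
            f"Cutoffs: {', '.join(f'{c:.2f}' for c in self.model.cutoffs)}",
            "",
            "Stage   n      %",
        ]
        for s in range(1, 6):
            lines.append(f"  {s}    {counts[s]:3d}  {pct[s]:5.1f}")
        return "\n".join(lines)

    def validity_report(self, gaf: str | None = "gaf", drug_columns: Sequence[str] = ()):
        """Run the construct-validity battery on this scored cohort."""
        from .validity import build_validity_report

        return build_validity_report(
            self.frame, registry=self.model.registry, gaf=gaf, drug_columns=drug_columns
        )

    def transitions(self, followup: "StagingResults", id_column: str = "patient_id"):
        """Stage-transition summary from this (baseline) cohort to a follow-up."""
        from .longitudinal import pairs_from_results, transition_matrix

        return transition_matrix(pairs_from_results(self, followup, id_column=id_column))
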