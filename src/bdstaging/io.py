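"""Patient-table I/O, configuration, and the end-to-end pipeline.

Interchange formats: CSV (UTF-8, "." decimal) for patient tables, YAML for
configuration, JSON for machine-readable reports.  Column names are matched
case-insensitively on read and written in canonical case.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .longitudinal import (
    euthymic_subgroup_analysis,
    pairs_from_results,
    shift_expectations_check,
    transition_matrix,
)
from .model import StagingModel
from .transforms import PROFILERS, SCIP_LEVELS

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "read_patient_table",
    "write_patient_table",
    "load_config",
    "run_pipeline",
    "PipelineBundle",
]

logger = logging.getLogger("bdstaging")

REQUIRED_COLUMNS: tuple[str, ...] = ("patient_id", "timepoint", *PROFILERS)
OPTIONAL_COLUMNS: tuple[str, ...] = (
    "gaf",
    "n_drugs",
    "antipsychotic",
    "antidepressant",
    "benzodiazepine",
    "euthymic_throughout",
    "true_stage",
)

_BINARY = ("com_pd", "mets", "pd_x_bd")
_COUNTS = ("hosp_n", "suic_att_n", "illness_n")


def _validate_rows(frame: pd.DataFrame) -> list[str]:
    """Row-level validation; returns human-readable problems with line numbers
    (1-based, header = line 1)."""
    problems: list[str] = []
    for i, row in frame.iterrows():
        line = i + 2
        for col in _COUNTS:
            v = row[col]
            if pd.notna(v) and v < 0:
                problems.append(f"line {line}: {col} negative ({v})")
        for col in _BINARY:
            v = row[col]
            if pd.notna(v) and v not in (0, 1):
                problems.append(f"line {line}: {col} not binary ({v})")
        v = row["scip_cat"]
        if pd.notna(v) and v not in SCIP_LEVELS:
            problems.append(f"line {line}: scip_cat {v!r} not in {SCIP_LEVELS}")
        if pd.notna(row["fast_total"]) and not 0 <= row["fast_total"] <= 72:
            problems.append(f"line {line}: fast_total outside [0, 72] ({row['fast_total']})")
        if pd.notna(row["fast_leisure"]) and not 0 <= row["fast_leisure"] <= 6:
            problems.append(f"line {line}: fast_leisure outside [0, 6] ({row['fast_leisure']})")
        if pd.notna(row["bmi"]) and row["bmi"] <= 0:
            problems.append(f"line {line}: bmi not positive ({row['bmi']})")
        if row["timepoint"] not in ("baseline", "followup"):
            problems.append(f"line {line}: timepoint {row['timepoint']!r} invalid")
    return problems


def read_patient_table(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a patient table CSV.

    Column headers are matched case-insensitively against the canonical
    schema.  Missing required columns raise a schema error naming them; row
    validation problems are collected with line numbers and either raised
    (``strict``) or logged as warnings.
    """
    frame = pd.read_csv(path)
    rename = {}
    canonical = {c.lower(): c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS)}
    for col in frame.columns:
        key = col.strip().lower()
        if key in canonical:
            rename[col] = canonical[key]
    frame = frame.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    problems = _validate_rows(frame)
    if problems:
        msg = f"{path}: {len(problems)} row validation problems:\n" + "\n".join(problems)
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    return frame


def write_patient_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a patient table as canonical-case CSV without an index column."""
    frame.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Parse a YAML pipeline/model configuration file."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


@dataclass
class PipelineBundle:
    """Everything the end-to-end run produces."""

    baseline: "pd.DataFrame"
    followup: "pd.DataFrame"
    report: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_patient_table(self.baseline, out / "baseline_scored.csv")
        write_patient_table(self.followup, out / "followup_scored.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(self.report, fh, indent=2, default=_jsonable)
        with open(out / "report.txt", "w") as fh:
            fh.write(self.report["text"])


def _jsonable(obj):
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def run_pipeline(
    config: Mapping | None = None,
    seed: int = 0,
    baseline: pd.DataFrame | None = None,
    followup: pd.DataFrame | None = None,
) -> PipelineBundle:
    """Run the full pipeline: (simulate if no data given) -> transform ->
    score -> stage -> construct validity -> transitions.

    All randomness flows through one generator seeded by ``seed``; the
    report header echoes the seed, the cutoffs and the transform registry
    so a run is reproducible from its report alone.
    """
    from .cohort import attach_external_validators, default_config, evolve_cohort, generate_baseline
    from .transforms import registry_to_dict

    config = dict(config or {})
    model = StagingModel.from_config(config)
    rng = np.random.default_rng(seed)

    if baseline is None:
        cohort_cfg = default_config(int(config.get("n_baseline", 224)))
        logger.info("simulating baseline cohort (n=%d, seed=%d)", cohort_cfg.n_baseline, seed)
        baseline = generate_baseline(cohort_cfg, seed=rng)
        baseline = attach_external_validators(baseline, cohort_cfg, seed=rng)
        followup, _ = evolve_cohort(baseline, cohort_cfg, seed=rng)
        followup = attach_external_validators(followup, cohort_cfg, seed=rng)

    res_baseline = model.fit(baseline)
    logger.info("baseline scored: stage counts %s", res_baseline.stage_counts().to_dict())
    validity = res_baseline.validity_report(
        gaf="gaf" if "gaf" in baseline.columns else None,
        drug_columns=[c for c in ("n_drugs", "antipsychotic", "antidepressant", "benzodiazepine") if c in baseline.columns],
    )

    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": seed,
            "cutoffs": list(model.cutoffs),
            "transforms": registry_to_dict(model.registry),
        },
        "baseline_summary": {
            "n": int(res_baseline.severities.notna().sum()),
            "severity_mean": float(res_baseline.severities.mean()),
            "severity_sd": float(res_baseline.severities.std(ddof=1)),
            "stage_counts": {int(k): int(v) for k, v in res_baseline.stage_counts().items()},
        },
        "construct_validity": validity.to_frame().drop(columns="df").to_dict(orient="records"),
    }
    text_parts = [res_baseline.summary(), "", validity.to_text()]

    fu_frame = followup if followup is not None else pd.DataFrame()
    if not fu_frame.empty:
        res_followup = model.fit(fu_frame)
        pairs = pairs_from_results(res_baseline, res_followup)
        transitions = transition_matrix(pairs)
        passed, diag = shift_expectations_check(transitions)
        subgroup = euthymic_subgroup_analysis(pairs, baseline, fu_frame, model.registry)
        report["transitions"] = transitions.to_dict()
        report["big_shift_check"] = {"passed": passed, **diag}
        report["euthymic_subgroup"] = {
            "transitions": subgroup["transitions"].to_dict(),
            "paired_tests": subgroup["paired_tests"],
            "notes": subgroup["notes"],
        }
        text_parts += ["", transitions.to_text()]
    else:
        res_followup = None

    report["text"] = "\n".join(text_parts)
    return PipelineBundle(
        baseline=res_baseline.frame,
        followup=res_followup.frame if res_followup is not None else pd.DataFrame(),
        report=report,
    )
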