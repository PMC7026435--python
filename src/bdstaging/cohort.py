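"""Synthetic longitudinal cohorts with the staging model's stage structure.

No public patient-level dataset exists for this staging model, so every
pipeline stage is exercised on simulated cohorts.  The generator emulates
the published validation cohort of 129 adults with bipolar disorder
followed for three years: a five-stage baseline mix, per-stage profiler
distributions (means/SDs and prevalences by stage), a row-stochastic
5x5 stage-transition kernel for the three-year shift, a 32.2% rate of
sustained euthymia (with an euthymia-specific shift distribution biased
toward staying or regressing), and 57.6% retention at follow-up.

Distribution families are the simplest ones matching the published
mean/SD and support: negative binomial for overdispersed counts (Poisson
when the printed SD is at or below the mean), Bernoulli for flags,
truncated normals for bounded scales (BMI, FAST, GAF), plain normals for
the SF-36 z-scores, and categorical draws for cognitive category and the
prescribed-drug count.

Stage labels are guaranteed consistent with the scoring pipeline by
rejection sampling: a patient's profile is re-drawn until its computed
severity falls inside the intended stage's interval, so
``assign_stage(severity(transform(x)))`` recovers the generator's label
for every patient.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy import stats

from .longitudinal import StagePair
from .model import DEFAULT_CUTOFFS, StageCutoffs, _formula, assign_stages
from .transforms import PROFILERS, SCIP_LEVELS, default_registry, transform_table

__all__ = [
    "StageProfilerParams",
    "CohortConfig",
    "default_config",
    "generate_baseline",
    "evolve_cohort",
    "attach_external_validators",
]

# --- validation-cohort summary statistics used as generator defaults --------
# Per-stage (1..5) mean/SD pairs and prevalences for the 12 profilers.
_HOSP = [(0.7, 0.3), (0.3, 0.6), (0.8, 1.1), (2.0, 1.9), (5.8, 4.2)]
_SUIC = [(0.1, 0.3), (0.3, 0.6), (0.5, 0.9), (1.8, 1.6), (5.6, 4.8)]
_ILLNESS = [(0.3, 0.6), (0.8, 1.0), (1.9, 1.7), (2.5, 1.6), (2.4, 1.6)]
_BMI = [(21.2, 4.2), (21.6, 4.0), (25.3, 4.5), (26.0, 4.5), (28.5, 5.6)]
_FAST_T = [(8.3, 6.7), (15.6, 10.2), (26.5, 11.4), (38.0, 11.7), (55.9, 9.2)]
_FAST_L = [(0.4, 0.6), (1.2, 1.8), (2.2, 1.9), (3.3, 2.0), (5.5, 0.9)]
_SF_PF = [(0.3, 0.4), (0.2, 0.7), (-0.5, 1.0), (-0.8, 1.2), (-1.7, 1.1)]
_SF_MH = [(-0.7, 0.4), (-0.3, 0.6), (-0.6, 0.6), (-0.6, 0.7), (-0.5, 0.5)]
_COM_PD = [0.0, 0.0, 27 / 61, 8 / 25, 6 / 9]
_METS = [0.0, 0.05, 27 / 61, 17 / 25, 6 / 9]
_PD_X_BD = [0.0, 0.20, 30 / 61, 18 / 24, 1.0]
# Probability of "no cognitive impairment" per stage; the remaining mass is
# split across mild/moderate/severe in the cohort-level 19.4/20.9/20.2 mix.
_SCIP_NONE = [0.929, 0.55, 0.40, 0.08, 0.111]
_SCIP_REST = np.array([19.4, 20.9, 20.2])
_SCIP_REST = _SCIP_REST / _SCIP_REST.sum()

# External validators per stage: GAF mean/SD (bounded 1-100), prescribed-drug
# count distribution (1/2/3/4/5+ drugs) and drug-class prevalences.
_GAF = [(81.1, 11.9), (79.5, 9.2), (67.6, 11.4), (62.3, 10.8), (47.2, 12.0)]
_N_DRUGS = np.array(
    [
        [30.8, 26.3, 3.7, 4.5, 0.0],
        [38.5, 42.1, 25.9, 13.6, 0.0],
        [7.7, 21.1, 27.8, 31.8, 0.0],
        [15.4, 5.3, 22.2, 22.7, 55.6],
        [7.7, 5.3, 13.0, 18.2, 44.4],
    ]
)  # rows: 1..5+ drugs; columns: stages
_ANTIPSYCHOTIC = [7 / 14, 8 / 20, 37 / 61, 16 / 24, 8 / 10]
_ANTIDEPRESSANT = [3 / 14, 6 / 20, 31 / 60, 11 / 24, 9 / 10]
_BENZODIAZEPINE = [3 / 14, 6 / 19, 31 / 61, 16 / 24, 8 / 10]

# Three-year transition kernel (rows renormalised); the stage-3 one-step
# probabilities are 18.2% in each direction.
_KERNEL = np.array(
    [
        [1 / 3, 0.500, 0.167, 0.000, 0.000],
        [0.276, 0.311, 0.379, 0.034, 0.000],
        [0.000, 0.182, 0.633, 0.182, 0.000],
        [0.000, 0.000, 0.320, 0.417, 0.263],
        [0.000, 0.000, 0.111, 0.556, 1 / 3],
    ]
)
_KERNEL = _KERNEL / _KERNEL.sum(axis=1, keepdims=True)

# Shift distribution for the sustained-euthymia subgroup (biased to
# staying or regressing); clipped to valid stages and renormalised per row.
_EUTHYMIC_SHIFTS = {-2: 0.053, -1: 0.237, 0: 0.553, 1: 0.158}

_BASELINE_STAGE_PROBS = np.array([10.9, 15.5, 47.3, 18.6, 7.8])
_BASELINE_STAGE_PROBS = _BASELINE_STAGE_PROBS / _BASELINE_STAGE_PROBS.sum()


class StageProfilerParams(BaseModel):
    """Distribution parameters for one stage's profilers and validators."""

    hosp_n: tuple[float, float]
    suic_att_n: tuple[float, float]
    illness_n: tuple[float, float]
    bmi: tuple[float, float]
    fast_total: tuple[float, float]
    fast_leisure: tuple[float, float]
    sf_pf: tuple[float, float]
    sf_mh: tuple[float, float]
    com_pd: float = Field(ge=0, le=1)
    mets: float = Field(ge=0, le=1)
    pd_x_bd: float = Field(ge=0, le=1)
    scip_probs: tuple[float, float, float, float]
    gaf: tuple[float, float]
    n_drugs_probs: tuple[float, float, float, float, float]
    antipsychotic: float = Field(ge=0, le=1)
    antidepressant: float = Field(ge=0, le=1)
    benzodiazepine: float = Field(ge=0, le=1)

    @field_validator("scip_probs", "n_drugs_probs")
    @classmethod
    def _sums_to_one(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"probability vector must sum to 1, got sum={sum(v)}")
        return v


class CohortConfig(BaseModel):
    """Full generator configuration; defaults encode the validation cohort."""

    n_baseline: int = Field(default=224, ge=1)
    baseline_stage_probs: tuple[float, float, float, float, float]
    stages: tuple[
        StageProfilerParams,
        StageProfilerParams,
        StageProfilerParams,
        StageProfilerParams,
        StageProfilerParams,
    ]
    kernel: tuple[tuple[float, ...], ...]
    euthymic_shift_probs: dict[int, float]
    p_euthymic: float = Field(default=0.322, ge=0, le=1)
    p_retention: float = Field(default=0.576, ge=0, le=1)
    dropout_severity_slope: float = 0.0
    max_tries: int = Field(default=1000, ge=1)

    @field_validator("baseline_stage_probs")
    @classmethod
    def _stage_probs_ok(cls, v):
        if abs(sum(v) - 1.0) > 1e-9 or any(p < 0 for p in v):
            raise ValueError("baseline stage probabilities must be non-negative and sum to 1")
        return v

    @field_validator("kernel")
    @classmethod
    def _kernel_ok(cls, v):
        k = np.asarray(v, dtype=float)
        if k.shape != (5, 5):
            raise ValueError("transition kernel must be 5x5")
        if (k < 0).any() or np.abs(k.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("each kernel row must be a probability vector summing to 1")
        return v

    @field_validator("euthymic_shift_probs")
    @classmethod
    def _shifts_ok(cls, v):
        if any(not -4 <= s <= 4 for s in v) or any(p < 0 for p in v.values()):
            raise ValueError("euthymic shift probabilities must be non-negative with shifts in -4..4")
        return v


def _scip_probs(p_none: float) -> tuple[float, float, float, float]:
    rest = (1.0 - p_none) * _SCIP_REST
    probs = np.array([p_none, *rest])
    return tuple((probs / probs.sum()).tolist())


def default_config(n_baseline: int = 224) -> CohortConfig:
    """The default cohort configuration (the study conditions)."""
    stages = []
    for s in range(5):
        nd = _N_DRUGS[:, s] / _N_DRUGS[:, s].sum()
        stages.append(
            StageProfilerParams(
                hosp_n=_HOSP[s],
                suic_att_n=_SUIC[s],
                illness_n=_ILLNESS[s],
                bmi=_BMI[s],
                fast_total=_FAST_T[s],
                fast_leisure=_FAST_L[s],
                sf_pf=_SF_PF[s],
                sf_mh=_SF_MH[s],
                com_pd=_COM_PD[s],
                mets=_METS[s],
                pd_x_bd=_PD_X_BD[s],
                scip_probs=_scip_probs(_SCIP_NONE[s]),
                gaf=_GAF[s],
                n_drugs_probs=tuple(nd.tolist()),
                antipsychotic=_ANTIPSYCHOTIC[s],
                antidepressant=_ANTIDEPRESSANT[s],
                benzodiazepine=_BENZODIAZEPINE[s],
            )
        )
    shifts = np.array(list(_EUTHYMIC_SHIFTS.values()))
    shifts = shifts / shifts.sum()
    return CohortConfig(
        n_baseline=n_baseline,
        baseline_stage_probs=tuple(_BASELINE_STAGE_PROBS.tolist()),
        stages=tuple(stages),
        kernel=tuple(tuple(row) for row in _KERNEL),
        euthymic_shift_probs=dict(zip(_EUTHYMIC_SHIFTS, shifts.tolist())),
    )


def _sample_count(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Negative binomial matched to (mean, SD) when overdispersed, else Poisson."""
    var = sd * sd
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if var > mean:
        r = mean * mean / (var - mean)
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=size)
    return rng.poisson(mean, size=size)


def _sample_truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_profiles(rng: np.random.Generator, params: StageProfilerParams, size: int) -> pd.DataFrame:
    scip = rng.choice(len(SCIP_LEVELS), size=size, p=params.scip_probs)
    return pd.DataFrame(
        {
            "hosp_n": _sample_count(rng, *params.hosp_n, size),
            "suic_att_n": _sample_count(rng, *params.suic_att_n, size),
            "com_pd": rng.binomial(1, params.com_pd, size=size),
            "bmi": _sample_truncnorm(rng, *params.bmi, 12.0, 60.0, size),
            "mets": rng.binomial(1, params.mets, size=size),
            "illness_n": _sample_count(rng, *params.illness_n, size),
            "scip_cat": [SCIP_LEVELS[i] for i in scip],
            "pd_x_bd": rng.binomial(1, params.pd_x_bd, size=size),
            "fast_total": np.rint(_sample_truncnorm(rng, *params.fast_total, 0.0, 72.0, size)).astype(int),
            "fast_leisure": np.rint(_sample_truncnorm(rng, *params.fast_leisure, 0.0, 6.0, size)).astype(int),
            "sf_pf": rng.normal(*params.sf_pf, size=size),
            "sf_mh": rng.normal(*params.sf_mh, size=size),
        }
    )


def _severity_and_stage(frame: pd.DataFrame, cutoffs: StageCutoffs) -> tuple[np.ndarray, np.ndarray]:
    transformed = transform_table(frame, default_registry())
    sev = _formula(transformed.sum(axis=1, skipna=False).to_numpy())
    return sev, assign_stages(sev, cutoffs)


def _sample_stage_profiles(
    rng: np.random.Generator,
    params: StageProfilerParams,
    stage: int,
    size: int,
    cutoffs: StageCutoffs,
    max_tries: int,
    reject: bool = True,
) -> pd.DataFrame:
    """Draw ``size`` profiles from a stage's distributions.

    With rejection enabled, profiles whose computed severity lands outside
    the intended stage's interval are re-drawn (vectorised, up to
    ``max_tries`` rounds)."""
    out = _sample_profiles(rng, params, size)
    if not reject:
        return out
    pending = np.arange(size)
    for _ in range(max_tries):
        _, assigned = _severity_and_stage(out.iloc[pending], cutoffs)
        ok = assigned == stage
        pending = pending[~ok]
        if pending.size == 0:
            return out
        fresh = _sample_profiles(rng, params, pending.size)
        out.iloc[pending] = fresh.to_numpy(dtype=object)
    raise RuntimeError(
        f"rejection sampling for stage {stage} failed to converge within "
        f"{max_tries} rounds for {pending.size} patients"
    )


def generate_baseline(
    config: CohortConfig | None = None,
    seed: int | np.random.Generator = 0,
    cutoffs: StageCutoffs = DEFAULT_CUTOFFS,
    reject: bool = True,
) -> pd.DataFrame:
    """Generate a baseline cohort with true-stage labels.

    Each patient's stage is drawn from the baseline stage mix, then their
    profile from that stage's distributions (rejection-resampled by default
    until the computed severity lands in the stage's interval).  Fully
    reproducible from the seed.
    """
    config = config or default_config()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stages = rng.choice(np.arange(1, 6), size=config.n_baseline, p=config.baseline_stage_probs)
    blocks = []
    for s in range(1, 6):
        idx = np.flatnonzero(stages == s)
        if idx.size == 0:
            continue
        block = _sample_stage_profiles(
            rng, config.stages[s - 1], s, idx.size, cutoffs, config.max_tries, reject=reject
        )
        block.index = idx
        block["true_stage"] = s
        blocks.append(block)
    cohort = pd.concat(blocks).sort_index()
    cohort.insert(0, "patient_id", [f"P{i + 1:04d}" for i in range(config.n_baseline)])
    cohort.insert(1, "timepoint", "baseline")
    return cohort.reset_index(drop=True)


def _euthymic_kernel_row(stage: int, shift_probs: dict[int, float]) -> np.ndarray:
    row = np.zeros(5)
    for shift, p in shift_probs.items():
        target = stage + shift
        if 1 <= target <= 5:
            row[target - 1] += p
    return row / row.sum()


def evolve_cohort(
    baseline: pd.DataFrame,
    config: CohortConfig | None = None,
    seed: int | np.random.Generator = 0,
    cutoffs: StageCutoffs = DEFAULT_CUTOFFS,
    reject: bool = True,
) -> tuple[pd.DataFrame, list[StagePair]]:
    """Evolve a baseline cohort to follow-up.

    Sustained-euthymia flags are drawn first; euthymic patients move by the
    euthymia shift distribution (biased toward staying or regressing),
    everyone else by the cohort transition kernel.  Follow-up profiles are
    drawn from the target stage's distributions (with rejection), then
    retention filtering removes dropouts.  Returns the retained follow-up
    cohort and the StagePair list for retained patients.
    """
    config = config or default_config()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kernel = np.asarray(config.kernel, dtype=float)
    n = len(baseline)
    base_stage = baseline["true_stage"].to_numpy(dtype=int)
    euthymic = rng.binomial(1, config.p_euthymic, size=n).astype(bool)

    fu_stage = np.empty(n, dtype=int)
    for i in range(n):
        row = (
            _euthymic_kernel_row(base_stage[i], config.euthymic_shift_probs)
            if euthymic[i]
            else kernel[base_stage[i] - 1]
        )
        fu_stage[i] = rng.choice(5, p=row) + 1

    # retention; optional severity-dependent dropout via a logit shift
    if config.dropout_severity_slope != 0.0:
        sev, _ = _severity_and_stage(baseline[list(PROFILERS)], cutoffs)
        base_logit = np.log(config.p_retention / (1 - config.p_retention))
        logit = base_logit - config.dropout_severity_slope * (sev - sev.mean())
        p_keep = 1 / (1 + np.exp(-logit))
    else:
        p_keep = np.full(n, config.p_retention)
    retained = rng.binomial(1, p_keep).astype(bool)

    keep_idx = np.flatnonzero(retained)
    fu_blocks = []
    for s in range(1, 6):
        idx = keep_idx[fu_stage[keep_idx] == s]
        if idx.size == 0:
            continue
        block = _sample_stage_profiles(
            rng, config.stages[s - 1], s, idx.size, cutoffs, config.max_tries, reject=reject
        )
        block.index = idx
        block["true_stage"] = s
        fu_blocks.append(block)
    followup = pd.concat(fu_blocks).sort_index() if fu_blocks else pd.DataFrame()
    if not followup.empty:
        followup.insert(0, "patient_id", baseline["patient_id"].to_numpy()[followup.index])
        followup.insert(1, "timepoint", "followup")
        followup["euthymic_throughout"] = euthymic[followup.index].astype(int)
        followup = followup.reset_index(drop=True)

    pairs = [
        StagePair(
            patient_id=str(baseline["patient_id"].iloc[i]),
            baseline=int(base_stage[i]),
            followup=int(fu_stage[i]),
            euthymic_throughout=bool(euthymic[i]),
        )
        for i in keep_idx
    ]
    return followup, pairs


def attach_external_validators(
    cohort: pd.DataFrame,
    config: CohortConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Add GAF and drug-pattern columns sampled from per-stage distributions.

    GAF comes from stage-specific truncated normals bounded to 1-100; the
    prescribed-drug count (1..5, 5 meaning five or more) from stage-specific
    categorical distributions; and the three drug-class flags from
    stage-specific prevalences.
    """
    config = config or default_config()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if "true_stage" not in cohort.columns:
        raise ValueError("cohort needs a 'true_stage' column to attach validators")
    out = cohort.copy()
    n = len(out)
    gaf = np.empty(n)
    n_drugs = np.empty(n, dtype=int)
    classes = {"antipsychotic": np.empty(n, dtype=int), "antidepressant": np.empty(n, dtype=int), "benzodiazepine": np.empty(n, dtype=int)}
    stage_arr = out["true_stage"].to_numpy(dtype=int)
    for s in range(1, 6):
        idx = np.flatnonzero(stage_arr == s)
        if idx.size == 0:
            continue
        params = config.stages[s - 1]
        gaf[idx] = _sample_truncnorm(rng, *params.gaf, 1.0, 100.0, idx.size)
        n_drugs[idx] = rng.choice(np.arange(1, 6), size=idx.size, p=params.n_drugs_probs)
        for name in classes:
            classes[name][idx] = rng.binomial(1, getattr(params, name), size=idx.size)
    out["gaf"] = np.round(gaf).astype(int)
    out["n_drugs"] = n_drugs
    for name, vals in classes.items():
        out[name] = vals
    return out
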