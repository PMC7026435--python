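"""Longitudinal validity: stage shifts between baseline and follow-up.

A staging model for a chronic relapsing illness should be sticky over a
few years: most patients stay at their stage or move one step, and large
jumps (two or more stages) are rare.  This module summarises baseline ->
follow-up stage pairs as a 5x5 transition matrix with shift aggregates
(same / one-stage / two-plus-stage moves, progression vs regression), and
runs the sustained-euthymia subgroup analysis: patients who stayed free of
mood episodes throughout follow-up are expected to hold their stage or
regress, and those who did should show within-patient improvement on the
life-domain composites.

Life-domain composites are defined as the mean of each domain's
transformed (unit-interval, higher = worse) profilers, so a negative
paired difference (follow-up minus baseline) is an improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .transforms import LIFE_DOMAINS, TransformSpec, transform_table
from .validity import paired_t

if TYPE_CHECKING:  # pragma: no cover
    from .model import StagingResults

__all__ = [
    "StagePair",
    "TransitionSummary",
    "transition_matrix",
    "pairs_from_results",
    "domain_composites",
    "euthymic_subgroup_analysis",
    "shift_expectations_check",
]

STAGES = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class StagePair:
    """One patient's baseline and follow-up stage."""

    patient_id: str
    baseline: int
    followup: int
    euthymic_throughout: bool = False

    def __post_init__(self) -> None:
        if self.baseline not in STAGES or self.followup not in STAGES:
            raise ValueError(
                f"stages must be in 1..5, got ({self.baseline}, {self.followup})"
            )

    @property
    def shift(self) -> int:
        return self.followup - self.baseline


@dataclass
class TransitionSummary:
    """5x5 stage-transition counts with row-conditional frequencies and
    shift aggregates."""

    counts: pd.DataFrame  # index baseline stage, columns follow-up stage
    n: int
    row_frequencies: pd.DataFrame
    fraction_same: float
    fraction_one: float
    fraction_two_plus: float
    fraction_progressed: float
    fraction_regressed: float
    empty_rows: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "counts": self.counts.to_numpy().tolist(),
            "row_frequencies": self.row_frequencies.round(6).to_numpy().tolist(),
            "fraction_same": self.fraction_same,
            "fraction_one": self.fraction_one,
            "fraction_two_plus": self.fraction_two_plus,
            "fraction_progressed": self.fraction_progressed,
            "fraction_regressed": self.fraction_regressed,
            "empty_rows": list(self.empty_rows),
        }

    def to_text(self) -> str:
        lines = [
            f"Stage transitions (n = {self.n})",
            self.counts.to_string(),
            "",
            f"same stage:        {100 * self.fraction_same:.1f}%",
            f"one-stage shift:   {100 * self.fraction_one:.1f}%",
            f"two+ stage shift:  {100 * self.fraction_two_plus:.1f}%",
            f"progressed:        {100 * self.fraction_progressed:.1f}%",
            f"regressed:         {100 * self.fraction_regressed:.1f}%",
        ]
        return "\n".join(lines)


def transition_matrix(pairs: Sequence[StagePair] | Iterable[StagePair]) -> TransitionSummary:
    """Tabulate stage pairs into a TransitionSummary.

    counts[i, j] is the number of patients moving stage i -> stage j; the
    aggregates partition patients by |shift| and sum to 1 exactly.
    """
    pairs = list(pairs)
    counts = np.zeros((5, 5), dtype=int)
    for p in pairs:
        counts[p.baseline - 1, p.followup - 1] += 1
    n = counts.sum()
    idx = pd.Index(STAGES, name="baseline")
    cols = pd.Index(STAGES, name="followup")
    counts_df = pd.DataFrame(counts, index=idx, columns=cols)
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(row_sums[:, None] > 0, counts / np.maximum(row_sums[:, None], 1), np.nan)
    freq_df = pd.DataFrame(freq, index=idx, columns=cols)
    empty_rows = tuple(int(s) for s, rs in zip(STAGES, row_sums) if rs == 0)

    if n == 0:
        return TransitionSummary(counts_df, 0, freq_df, 0.0, 0.0, 0.0, 0.0, 0.0, empty_rows)

    shifts = np.abs(np.subtract.outer(np.arange(5), np.arange(5)))  # |i - j|
    same = counts[shifts == 0].sum()
    one = counts[shifts == 1].sum()
    two_plus = counts[shifts >= 2].sum()
    progressed = np.triu(counts, k=1).sum()
    regressed = np.tril(counts, k=-1).sum()
    return TransitionSummary(
        counts=counts_df,
        n=int(n),
        row_frequencies=freq_df,
        fraction_same=same / n,
        fraction_one=one / n,
        fraction_two_plus=two_plus / n,
        fraction_progressed=progressed / n,
        fraction_regressed=regressed / n,
        empty_rows=empty_rows,
    )


def pairs_from_results(
    baseline: "StagingResults",
    followup: "StagingResults",
    id_column: str = "patient_id",
    euthymic_column: str = "euthymic_throughout",
) -> list[StagePair]:
    """Join two scored cohorts on patient id into StagePair records.

    Patients present at only one timepoint, or with a missing stage at
    either, are dropped (attrition handling is the caller's concern).
    """
    b = baseline.frame[[id_column, "stage"]].rename(columns={"stage": "stage_baseline"})
    f = followup.frame[[id_column, "stage"]].rename(columns={"stage": "stage_followup"})
    euth_src = None
    for frame in (followup.frame, baseline.frame):
        if euthymic_column in frame.columns:
            euth_src = frame[[id_column, euthymic_column]]
            break
    merged = b.merge(f, on=id_column).dropna(subset=["stage_baseline", "stage_followup"])
    if euth_src is not None:
        merged = merged.merge(euth_src, on=id_column, how="left")
    else:
        merged[euthymic_column] = False
    return [
        StagePair(
            patient_id=str(r[id_column]),
            baseline=int(r["stage_baseline"]),
            followup=int(r["stage_followup"]),
            euthymic_throughout=bool(r[euthymic_column]),
        )
        for _, r in merged.iterrows()
    ]


def domain_composites(
    frame: pd.DataFrame, registry: Mapping[str, TransformSpec] | None = None
) -> pd.DataFrame:
    """Per-patient life-domain composites: mean of each domain's transformed
    profilers.  Returns one column per domain, indexed like ``frame``."""
    transformed = transform_table(frame, registry)
    out = {}
    for domain in dict.fromkeys(LIFE_DOMAINS.values()):
        cols = [p for p, d in LIFE_DOMAINS.items() if d == domain]
        out[domain] = transformed[cols].mean(axis=1, skipna=False)
    return pd.DataFrame(out, index=frame.index)


def euthymic_subgroup_analysis(
    pairs: Sequence[StagePair],
    baseline_frame: pd.DataFrame,
    followup_frame: pd.DataFrame,
    registry: Mapping[str, TransformSpec] | None = None,
    id_column: str = "patient_id",
) -> dict:
    """Transition summary and paired domain tests for the sustained-euthymia
    subgroup.

    Restricts to pairs with ``euthymic_throughout``; within that subgroup,
    paired t-tests compare each life-domain composite between baseline and
    follow-up separately for patients who remained at their stage and for
    those who regressed.  Subsets with fewer than 2 patients are skipped
    with a note.
    """
    euth = [p for p in pairs if p.euthymic_throughout]
    summary = transition_matrix(euth)
    result = {"transitions": summary, "paired_tests": {}, "notes": []}
    if not euth:
        result["notes"].append("euthymic subgroup empty; paired tests skipped")
        return result

    b_comp = domain_composites(baseline_frame, registry)
    b_comp[id_column] = baseline_frame[id_column].to_numpy()
    f_comp = domain_composites(followup_frame, registry)
    f_comp[id_column] = followup_frame[id_column].to_numpy()

    subsets = {
        "remained_same": [p.patient_id for p in euth if p.shift == 0],
        "regressed": [p.patient_id for p in euth if p.shift < 0],
    }
    domains = [c for c in b_comp.columns if c != id_column]
    for label, ids in subsets.items():
        if len(ids) < 2:
            result["notes"].append(f"{label} subset has n={len(ids)} < 2; tests skipped")
            continue
        b_sub = b_comp[b_comp[id_column].astype(str).isin(ids)].set_index(id_column)
        f_sub = f_comp[f_comp[id_column].astype(str).isin(ids)].set_index(id_column)
        common = b_sub.index.intersection(f_sub.index)
        tests = {}
        for domain in domains:
            before = b_sub.loc[common, domain].to_numpy(dtype=float)
            after = f_sub.loc[common, domain].to_numpy(dtype=float)
            ok = ~(np.isnan(before) | np.isnan(after))
            if ok.sum() < 2 or np.allclose(after[ok] - before[ok], (after[ok] - before[ok])[0]):
                diff = after[ok] - before[ok]
                if ok.sum() >= 2 and np.allclose(diff, 0):
                    tests[domain] = {"t": 0.0, "df": int(ok.sum() - 1), "p": 1.0, "n": int(ok.sum())}
                else:
                    result["notes"].append(f"{label}/{domain}: degenerate differences; test skipped")
                continue
            t, df, p = paired_t(before[ok], after[ok])
            tests[domain] = {"t": t, "df": df, "p": p, "n": int(ok.sum())}
        result["paired_tests"][label] = tests
    return result


def shift_expectations_check(
    summary: TransitionSummary, max_big_shift_fraction: float = 0.10
) -> tuple[bool, dict]:
    """Check that large shifts (|shift| >= 2 stages) are rare.

    Returns (passed, diagnostics); the default ceiling of 10% encodes the
    expectation that over a few years fewer than one patient in ten should
    jump two or more stages.
    """
    diagnostics = {
        "fraction_two_plus": summary.fraction_two_plus,
        "threshold": max_big_shift_fraction,
        "n": summary.n,
    }
    return summary.fraction_two_plus <= max_big_shift_fraction, diagnostics
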