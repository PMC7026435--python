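"""Construct-validity battery: stage-wise tests of profilers and external validators.

Construct validity for an ordered staging model means each profiler, and
each stage-external validator (global functioning, pharmacological
treatment pattern), worsens as the stage advances.  The battery mirrors
common clinical-staging practice: one-way ANOVA across the five stages for
continuous measures, Pearson chi-square (no continuity correction) for
categorical ones, Tukey HSD for post-hoc pairs, and paired t-tests for
within-patient longitudinal contrasts.  Raw p-values are reported without
multiplicity correction; the report header flags this.

In addition to the hypothesis tests, each profiler gets a descriptive
"monotone worsening" flag computed on its transformed (unit-interval,
higher = worse) stage means: the flag is set when the last stage is worse
than the first and no adjacent stage-to-stage improvement exceeds a
fraction (default 25%) of the range of the stage means.  The flag is a
trend descriptor and deliberately tolerant of small non-monotonicities at
noisy stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .transforms import LIFE_DOMAINS, PROFILERS, TransformSpec, default_registry, transform_table

__all__ = [
    "CONTINUOUS_PROFILERS",
    "CATEGORICAL_PROFILERS",
    "chi_square_independence",
    "oneway_anova",
    "tukey_hsd",
    "paired_t",
    "monotone_worsening",
    "build_validity_report",
    "ValidityRecord",
    "ValidityReport",
]

#: Profilers tested by one-way ANOVA on their raw (direct) scores.
CONTINUOUS_PROFILERS: tuple[str, ...] = (
    "hosp_n",
    "suic_att_n",
    "bmi",
    "illness_n",
    "fast_total",
    "fast_leisure",
    "sf_pf",
    "sf_mh",
)

#: Profilers tested by Pearson chi-square on stage-by-category tables.
CATEGORICAL_PROFILERS: tuple[str, ...] = ("com_pd", "mets", "scip_cat", "pd_x_bd")


def chi_square_independence(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Computes sum((O - E)^2 / E) with expected counts from the product of
    marginals, no continuity correction; df = (r - 1)(c - 1).  Rows or
    columns with a zero marginal are dropped with a warning before the
    computation; a warning is also issued when any expected count is
    below 5 (the asymptotic reference distribution is still used).
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (counts < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    row_ok = counts.sum(axis=1) > 0
    col_ok = counts.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn(
            "dropping zero-marginal rows/columns from contingency table", stacklevel=2
        )
        counts = counts[np.ix_(row_ok, col_ok)]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table needs >= 2 rows and >= 2 columns with positive marginals")
    stat, p, df, expected = stats.chi2_contingency(counts, correction=False)
    if (expected < 5).any():
        warnings.warn("expected count < 5 in contingency table; asymptotic p-value may be inaccurate", stacklevel=2)
    return float(stat), int(df), float(p)


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: returns (F, df_between, df_within, p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every ANOVA group needs at least 2 observations")
    k = len(arrays)
    n = sum(a.size for a in arrays)
    f, p = stats.f_oneway(*arrays)
    return float(f), k - 1, n - k, float(p)


def tukey_hsd(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise mean comparisons with studentized-range criticals.

    Returns a DataFrame with columns group1, group2, meandiff, p_adj,
    lower, upper, reject.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("Tukey HSD needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    values = np.concatenate(arrays)
    labels = np.concatenate([np.full(a.size, i + 1) for i, a in enumerate(arrays)])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    frame.columns = ["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"]
    return frame


def paired_t(before: Sequence[float], after: Sequence[float]) -> tuple[float, int, float]:
    """Paired t-test on (after - before); returns (t, df, p) with df = n - 1."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError(f"paired vectors differ in length: {b.size} vs {a.size}")
    if b.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        # degenerate: identical shifts; t is 0 (no change) or +/-inf (certain change)
        if np.allclose(d.mean(), 0.0):
            return 0.0, b.size - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), b.size - 1, 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), b.size - 1, float(p)


def monotone_worsening(stage_means: Sequence[float], rel_tol: float = 0.25) -> bool:
    """Trend flag on stage means of a transformed (higher = worse) profiler.

    True when the final stage is worse than the first and no adjacent
    improvement exceeds ``rel_tol`` times the range of the stage means.
    """
    m = np.asarray([x for x in stage_means if not np.isnan(x)], dtype=float)
    if m.size < 2:
        return False
    span = m.max() - m.min()
    if span <= 0:
        return False
    drops = np.maximum(0.0, -np.diff(m))
    return bool(m[-1] > m[0] and drops.max() <= rel_tol * span)


@dataclass
class ValidityRecord:
    """One tested measure: stage descriptives plus its between-stage test."""

    name: str
    domain: str
    test: str  # "anova" | "chi_square" | "skipped"
    per_stage: pd.DataFrame  # index stage; mean/sd or count/percent
    statistic: float | None
    df: tuple[int, ...] | None
    p_value: float | None
    monotone_worsening: bool | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class ValidityReport:
    """The full construct-validity battery output."""

    records: list[ValidityRecord]
    header: str = (
        "Construct-validity battery; raw p-values, no multiple-testing correction."
    )

    def __getitem__(self, name: str) -> ValidityRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "measure": rec.name,
                    "domain": rec.domain,
                    "test": rec.test,
                    "statistic": rec.statistic,
                    "df": rec.df,
                    "p_value": rec.p_value,
                    "monotone_worsening": rec.monotone_worsening,
                    "notes": "; ".join(rec.notes),
                }
            )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [self.header, "=" * len(self.header), ""]
        for rec in self.records:
            df_txt = "" if rec.df is None else f" ({', '.join(map(str, rec.df))})"
            stat_txt = "skipped" if rec.statistic is None else f"{rec.statistic:.3f}{df_txt}, p={rec.p_value:.3g}"
            flag = "" if rec.monotone_worsening is None else (
                "  [monotone worsening]" if rec.monotone_worsening else "  [not monotone]"
            )
            lines.append(f"{rec.name} [{rec.domain}] — {rec.test}: {stat_txt}{flag}")
            lines.append(rec.per_stage.round(3).to_string())
            for note in rec.notes:
                lines.append(f"  note: {note}")
            lines.append("")
        return "\n".join(lines)


def _anova_by_stage(frame: pd.DataFrame, column: str) -> tuple[ValidityRecord, list[str]]:
    notes: list[str] = []
    sub = frame[[column, "stage"]].dropna()
    groups, kept = [], []
    for s, g in sub.groupby("stage"):
        vals = g[column].to_numpy(dtype=float)
        if vals.size < 2:
            notes.append(f"stage {s} excluded from ANOVA (n={vals.size} < 2)")
            continue
        groups.append(vals)
        kept.append(s)
    per_stage = sub.groupby("stage")[column].agg(["count", "mean", "std"])
    if len(groups) < 2:
        return (
            ValidityRecord(column, LIFE_DOMAINS.get(column, "external"), "skipped", per_stage, None, None, None, notes=notes + ["fewer than 2 usable stages; ANOVA skipped"]),
            notes,
        )
    f, dfb, dfw, p = oneway_anova(groups)
    return (
        ValidityRecord(column, LIFE_DOMAINS.get(column, "external"), "anova", per_stage, f, (dfb, dfw), p, notes=notes),
        notes,
    )


def _chi_square_by_stage(frame: pd.DataFrame, column: str) -> ValidityRecord:
    notes: list[str] = []
    sub = frame[[column, "stage"]].dropna()
    table = pd.crosstab(sub[column], sub["stage"])
    per_stage = table.T
    per_stage_pct = 100 * per_stage.div(per_stage.sum(axis=1), axis=0)
    descr = pd.concat({"count": per_stage, "percent": per_stage_pct}, axis=1)
    if table.shape[0] < 2 or table.shape[1] < 2:
        return ValidityRecord(
            column, LIFE_DOMAINS.get(column, "external"), "skipped", descr, None, None, None,
            notes=["contingency table degenerate; chi-square skipped"],
        )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        stat, df, p = chi_square_independence(table.to_numpy())
    notes.extend(str(w.message) for w in caught)
    return ValidityRecord(
        column, LIFE_DOMAINS.get(column, "external"), "chi_square", descr, stat, (df,), p, notes=notes
    )


def build_validity_report(
    frame: pd.DataFrame,
    registry: Mapping[str, TransformSpec] | None = None,
    gaf: str | None = "gaf",
    drug_columns: Sequence[str] = (),
    rel_tol: float = 0.25,
) -> ValidityReport:
    """Run the full battery on a scored cohort (``stage`` column required).

    ANOVA is applied to continuous profilers on their raw scores and to the
    GAF external validator; chi-square to categorical profilers and to each
    drug-pattern column.  The monotone-worsening flag is evaluated on the
    transformed profiler values, so that "worse" points the same way for
    every profiler.
    """
    if "stage" not in frame.columns:
        raise ValueError("cohort must be scored first (missing 'stage' column)")
    registry = registry if registry is not None else default_registry()

    transformed = transform_table(frame, registry)
    transformed["stage"] = frame["stage"].to_numpy()
    stage_means = transformed.groupby("stage").mean()

    records: list[ValidityRecord] = []
    for name in PROFILERS:
        if name in CONTINUOUS_PROFILERS:
            rec, _ = _anova_by_stage(frame, name)
        else:
            rec = _chi_square_by_stage(frame, name)
        rec.monotone_worsening = monotone_worsening(
            stage_means[name].reindex(range(1, 6)).to_numpy(), rel_tol=rel_tol
        )
        records.append(rec)

    if gaf is not None and gaf in frame.columns:
        rec, _ = _anova_by_stage(frame, gaf)
        rec.domain = "external"
        # GAF decreases with severity; negate for the shared worse-is-up flag
        gaf_means = frame.groupby("stage")[gaf].mean().reindex(range(1, 6))
        rec.monotone_worsening = monotone_worsening((-gaf_means).to_numpy(), rel_tol=rel_tol)
        records.append(rec)

    for col in drug_columns:
        if col not in frame.columns:
            raise ValueError(f"drug column {col!r} not in cohort table")
        rec = _chi_square_by_stage(frame, col)
        rec.domain = "external"
        records.append(rec)

    return ValidityReport(records=records)
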