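"""Construct-validity battery against brute-force statistical oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bdstaging.validity import (
    build_validity_report,
    chi_square_independence,
    monotone_worsening,
    oneway_anova,
    paired_t,
    tukey_hsd,
)


def chi_square_oracle(table: np.ndarray) -> tuple[float, int]:
    """Explicit O/E double-loop Pearson statistic."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat, (table.shape[0] - 1) * (table.shape[1] - 1)


def anova_oracle(groups) -> tuple[float, int, int]:
    """Explicit between/within mean-square ratio."""
    all_vals = np.concatenate([np.asarray(g, float) for g in groups])
    grand = all_vals.mean()
    k, n = len(groups), all_vals.size
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k)), k - 1, n - k


def two_row_table(yes, n):
    yes, n = np.asarray(yes), np.asarray(n)
    return np.array([yes, n - yes])


class TestChiSquare:
    @pytest.mark.parametrize(
        "yes, n, published",
        [
            ((7, 8, 37, 16, 8), (14, 20, 61, 24, 10), 5.925),      # antipsychotics
            ((3, 6, 31, 11, 9), (14, 20, 60, 24, 10), 13.960),     # antidepressants
            ((3, 6, 31, 16, 8), (14, 19, 61, 24, 10), 13.430),     # benzodiazepines
            ((0, 1, 27, 17, 6), (14, 20, 61, 25, 9), 30.948),      # metabolic syndrome
        ],
    )
    def test_reproduces_published_drug_and_mets_statistics(self, yes, n, published):
        import warnings

        table = two_row_table(yes, n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # some expected counts fall below 5
            stat, df, p = chi_square_independence(table)
        oracle, odf = chi_square_oracle(table)
        assert stat == pytest.approx(oracle, abs=1e-9)
        assert df == odf == 4
        # published statistics recomputed from percentage-implied denominators
        assert stat == pytest.approx(published, abs=0.005)

    def test_proportional_rows_give_zero(self):
        stat, df, p = chi_square_independence(np.array([[10, 20, 30], [20, 40, 60]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariance_to_permutation(self):
        rng = np.random.default_rng(4)
        table = rng.integers(5, 40, size=(3, 5))
        stat, _, _ = chi_square_independence(table)
        perm = table[rng.permutation(3)][:, rng.permutation(5)]
        stat_p, _, _ = chi_square_independence(perm)
        assert stat_p == pytest.approx(stat)

    def test_zero_marginal_dropped_with_warning(self):
        table = np.array([[5, 0, 7], [9, 0, 3]])
        with pytest.warns(UserWarning, match="zero-marginal"):
            stat, df, _ = chi_square_independence(table)
        assert df == 1

    def test_matches_oracle_on_many_random_tables(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            r, c = rng.integers(2, 5, size=2)
            table = rng.integers(1, 30, size=(r, c))
            stat, df, _ = chi_square_independence(table)
            oracle, odf = chi_square_oracle(table)
            assert stat == pytest.approx(oracle, abs=1e-8)
            assert df == odf


class TestAnova:
    def test_two_groups_equal_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        f, dfb, dfw, p = oneway_anova([a, b])
        t, pt = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2)
        assert p == pytest.approx(pt)
        assert (dfb, dfw) == (1, 43)

    def test_identical_groups_give_zero_f(self):
        groups = [np.array([1.0, 2.0, 3.0])] * 4
        f, *_ = oneway_anova(groups)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_location_shift_invariance_and_scale(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(m, 1, 15) for m in (0, 0.5, 1.0)]
        f0, *_ = oneway_anova(groups)
        f_shift, *_ = oneway_anova([g + 100.0 for g in groups])
        f_scale, *_ = oneway_anova([g * 7.0 for g in groups])
        assert f_shift == pytest.approx(f0)
        assert f_scale == pytest.approx(f0)

    def test_matches_oracle_on_random_groups(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            groups = [rng.normal(rng.uniform(-1, 1), 1, rng.integers(3, 12)) for _ in range(rng.integers(2, 6))]
            f, dfb, dfw, _ = oneway_anova(groups)
            of, ob, ow = anova_oracle(groups)
            assert f == pytest.approx(of, rel=1e-9)
            assert (dfb, dfw) == (ob, ow)

    def test_stage_means_simulated_from_published_f_reference(self):
        """Five groups at the published functioning means/SDs and stage sizes
        produce F statistics of the published order of magnitude (~37)."""
        rng = np.random.default_rng(21)
        means = (8.3, 15.6, 26.5, 38.0, 55.9)
        sds = (6.7, 10.2, 11.4, 11.7, 9.2)
        sizes = (14, 20, 61, 24, 10)
        fs = []
        for _ in range(200):
            groups = [rng.normal(m, s, n) for m, s, n in zip(means, sds, sizes)]
            fs.append(oneway_anova(groups)[0])
        fs = np.array(fs)
        assert fs.min() > 15
        assert np.percentile(fs, 5) < 37.038 < np.percentile(fs, 95)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([[1.0], [2.0, 3.0]])


class TestTukey:
    def test_identical_groups_no_rejections(self):
        groups = [np.array([1.0, 2.0, 3.0, 2.5])] * 3
        frame = tukey_hsd(groups)
        assert not frame["reject"].astype(bool).any()

    def test_two_groups_agrees_with_t_test(self):
        rng = np.random.default_rng(17)
        for shift in (0.0, 2.5):
            a, b = rng.normal(0, 1, 15), rng.normal(shift, 1, 15)
            frame = tukey_hsd([a, b], alpha=0.05)
            _, p = stats.ttest_ind(a, b)
            assert bool(frame["reject"].iloc[0]) == (p < 0.05)

    def test_shifted_pair_flagged_null_pair_not(self):
        rng = np.random.default_rng(23)
        flags_shifted, flags_null = [], []
        for _ in range(100):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1, 20)
            c = rng.normal(2.0, 1, 20)
            frame = tukey_hsd([a, b, c]).set_index(["group1", "group2"])
            flags_null.append(bool(frame.loc[(1, 2), "reject"]))
            flags_shifted.append(bool(frame.loc[(1, 3), "reject"]))
        assert np.mean(flags_shifted) > 0.95
        assert np.mean(flags_null) < 0.10  # near nominal alpha


class TestPairedT:
    def test_no_change_gives_zero(self):
        before = np.array([1.0, 2.0, 3.0, 2.0])
        t, df, p = paired_t(before, before)
        assert t == 0.0 and p == 1.0 and df == 3

    def test_constant_shift_sign(self):
        rng = np.random.default_rng(2)
        before = rng.normal(0, 1, 30)
        t_up, _, _ = paired_t(before, before + 1.0 + rng.normal(0, 0.1, 30))
        t_down, _, _ = paired_t(before, before - 1.0 + rng.normal(0, 0.1, 30))
        assert t_up > 0 > t_down

    def test_equals_one_sample_t_on_differences(self):
        rng = np.random.default_rng(31)
        before, after = rng.normal(0, 1, 25), rng.normal(0.3, 1, 25)
        t, df, p = paired_t(before, after)
        d = after - before
        oracle_t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert t == pytest.approx(oracle_t, rel=1e-9)
        assert df == 24

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t([1, 2, 3], [1, 2])


class TestMonotoneFlag:
    def test_strictly_worsening(self):
        assert monotone_worsening([0.1, 0.2, 0.4, 0.6, 0.9])

    def test_overall_improvement_fails(self):
        assert not monotone_worsening([0.62, 0.55, 0.60, 0.60, 0.58])

    def test_small_dip_tolerated_when_trend_strong(self):
        assert monotone_worsening([0.12, 0.05, 0.13, 0.33, 0.97])

    def test_flat_profile_not_worsening(self):
        assert not monotone_worsening([0.4] * 5)


class TestValidityReport:
    def test_battery_on_synthetic_cohort(self, model, small_cohort):
        res = model.fit(small_cohort)
        report = res.validity_report(
            drug_columns=["n_drugs", "antipsychotic", "antidepressant", "benzodiazepine"]
        )
        frame = report.to_frame().set_index("measure")
        # test family matches measurement level
        for cat in ("com_pd", "mets", "scip_cat", "pd_x_bd"):
            assert frame.loc[cat, "test"] == "chi_square"
        for cont in ("hosp_n", "bmi", "fast_total", "sf_mh", "gaf"):
            assert frame.loc[cont, "test"] == "anova"
        assert "no multiple-testing correction" in report.header
        assert "gaf" in frame.index and frame.loc["gaf", "monotone_worsening"]

    def test_permuted_stages_control_false_positives(self, model, small_cohort):
        rng = np.random.default_rng(13)
        res = model.fit(small_cohort)
        frame = res.frame.copy()
        hits = []
        for _ in range(40):
            frame["stage"] = rng.permutation(frame["stage"].to_numpy())
            rep = build_validity_report(frame, registry=model.registry, gaf=None)
            ps = rep.to_frame()["p_value"].dropna()
            hits.append((ps < 0.05).mean())
        assert np.mean(hits) < 0.15  # near the nominal 5% rate

    def test_single_stage_cohort_skips_tests(self, model, small_cohort):
        frame = model.fit(small_cohort).frame.copy()
        frame = frame[frame["stage"] == 3]
        rep = build_validity_report(frame, registry=model.registry, gaf=None)
        assert all(r.test == "skipped" for r in rep.records)
        assert all(r.notes for r in rep.records)

    def test_missing_stage_column_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="stage"):
            build_validity_report(small_cohort)
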