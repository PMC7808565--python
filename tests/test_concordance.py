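"""Pair enumeration, correlation, regression residuals and pair flags."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cnafid import concordance as cc
from cnafid.core import SampleRecord
from cnafid.prep import AberrationSummary, GeneCopyProfile

from conftest import make_profile


def rec(sid, model="M1", patient="P1", cls="PT", passage=None, lineage=None,
        platform="SNP", tumor_type="CRC", center="C1"):
    return SampleRecord(sid, model, patient, tumor_type, center, cls,
                        passage=passage, lineage_id=lineage, platform=platform)


def gene_series(values, prefix="g"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


def gene_profile(sid, values):
    return GeneCopyProfile(sid, gene_series(np.asarray(values, dtype=float)))


class TestEnumeratePairs:
    def test_one_pt_two_pdx_combinatorics(self):
        records = [
            rec("PT1"), rec("X1", cls="PDX", passage=0, lineage="A"),
            rec("X2", cls="PDX", passage=1, lineage="A"),
        ]
        t = cc.enumerate_pairs(records)
        assert sorted(t["pair_type"]) == ["PDX_PDX", "PT_PDX", "PT_PDX"]
        pdx = t[t["pair_type"] == "PDX_PDX"].iloc[0]
        assert pdx["lineage_relation"] == "SAME_LINEAGE"
        assert pdx["sample_a"] == "X1"  # lower passage is the reference

    def test_lineage_split_classified_different(self):
        records = [
            rec("X1", cls="PDX", passage=2, lineage="A"),
            rec("X2", cls="PDX", passage=2, lineage="B"),
        ]
        t = cc.enumerate_pairs(records)
        assert t.iloc[0]["lineage_relation"] == "DIFFERENT_LINEAGE"

    def test_intrapatient_pt_pairs_across_models(self):
        records = [
            rec("PT1", model="M1"), rec("PT2", model="M2"),
        ]
        t = cc.enumerate_pairs(records)
        assert list(t["pair_type"]) == ["PT_PT_INTRAPATIENT"]

    def test_pdx_without_passage_excluded(self):
        records = [rec("PT1"), rec("X1", cls="PDX", passage=None)]
        assert len(cc.enumerate_pairs(records)) == 0

    def test_platform_mismatch_not_paired(self):
        records = [rec("PT1", platform="SNP"), rec("X1", cls="PDX", passage=0, platform="WES")]
        assert len(cc.enumerate_pairs(records)) == 0

    def test_cross_model_background_requires_type_and_center(self):
        records = [
            rec("A1", model="M1", patient="P1"),
            rec("B1", model="M2", patient="P2"),
            rec("C1", model="M3", patient="P3", center="C2"),
            rec("D1", model="M4", patient="P4", tumor_type="BRCA"),
        ]
        t = cc.enumerate_pairs(records, cross_model_background=True)
        cross = t[t["pair_type"] == "CROSS_MODEL"]
        assert len(cross) == 1
        assert {cross.iloc[0]["sample_a"], cross.iloc[0]["sample_b"]} == {"A1", "B1"}

    def test_pt_is_always_the_reference(self):
        records = [rec("X1", cls="PDX", passage=3), rec("PT1")]
        t = cc.enumerate_pairs(records)
        assert t.iloc[0]["sample_a"] == "PT1"


class TestCorrelateProfiles:
    def test_identical_profiles_r_one(self):
        rng = np.random.default_rng(0)
        a = gene_series(rng.normal(0, 1, 50))
        assert cc.correlate_profiles(a, a.copy()) == pytest.approx(1.0)

    def test_negated_profile_r_minus_one(self):
        rng = np.random.default_rng(0)
        a = gene_series(rng.normal(0, 1, 50))
        assert cc.correlate_profiles(a, -a) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 50)
        y = 0.5 * x + rng.normal(0, 0.5, 50)
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        got = cc.correlate_profiles(gene_series(x), gene_series(y))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = gene_series(rng.normal(0, 1, 40)), gene_series(rng.normal(0, 1, 40))
        assert cc.correlate_profiles(a, b) == pytest.approx(cc.correlate_profiles(b, a))

    def test_zero_variance_gives_nan(self):
        a = gene_series(np.zeros(40))
        b = gene_series(np.random.default_rng(0).normal(0, 1, 40))
        assert np.isnan(cc.correlate_profiles(a, b))

    def test_too_few_shared_features_rejected(self):
        a = gene_series(np.arange(10.0))
        with pytest.raises(ValueError, match="shared"):
            cc.correlate_profiles(a, a)


class TestStudentizedResiduals:
    def test_matches_brute_force_leave_one_out(self):
        """Externally studentized = residual scaled by the leave-one-out fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        for n in (8, 12, 20):
            x = rng.normal(0, 1, n)
            y = 1.3 * x - 0.2 + rng.normal(0, 0.4, n)
            res = sm.OLS(y, sm.add_constant(x)).fit()
            got = cc.externally_studentized(x, y, res.resid)
            for i in range(n):
                keep = np.arange(n) != i
                r = sm.OLS(y[keep], sm.add_constant(x[keep])).fit()
                pred = r.params[0] + r.params[1] * x[i]
                X = sm.add_constant(x[keep])
                xi = np.array([1.0, x[i]])
                var = r.mse_resid * (1 + xi @ np.linalg.inv(X.T @ X) @ xi)
                expected = (y[i] - pred) / np.sqrt(var)
                assert got[i] == pytest.approx(expected, abs=1e-9)


class TestAlteredGenes:
    def test_identical_profiles_no_altered_genes(self):
        rng = np.random.default_rng(0)
        a = gene_profile("A", rng.normal(0, 0.5, 300))
        res = cc.PairConcordanceModel(a, GeneCopyProfile("B", a.values.copy())).fit()
        assert res.altered_genes(0.1) == frozenset()

    def test_single_gene_perturbation_threshold_sensitivity(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.5, 300)
        a = gene_profile("A", vals)
        bvals = vals.copy()
        bvals[7] += 0.6
        b = gene_profile("B", bvals)
        res = cc.PairConcordanceModel(a, b).fit()
        assert res.altered_genes(0.5) == frozenset({"g7"})
        assert res.altered_genes(1.0) == frozenset()

    def test_thresholds_nest(self):
        rng = np.random.default_rng(4)
        a = gene_profile("A", rng.normal(0, 0.6, 400))
        b = gene_profile("B", a.values.to_numpy() + rng.normal(0, 0.5, 400))
        res = cc.PairConcordanceModel(a, b).fit()
        assert res.altered_genes(1.0) <= res.altered_genes(0.5)

    def test_regression_direction_is_asymmetric(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 0.6, 300)
        y = 0.5 * x + rng.normal(0, 0.3, 300)
        ab = cc.PairConcordanceModel(gene_profile("A", x), gene_profile("B", y)).fit()
        ba = cc.PairConcordanceModel(gene_profile("B", y), gene_profile("A", x)).fit()
        assert ab.improved_fit.slope != pytest.approx(1 / ba.improved_fit.slope, rel=1e-3)

    def test_values_floored_at_minus_three(self):
        vals = np.concatenate([[-8.0, -5.0], np.random.default_rng(0).normal(0, 0.5, 300)])
        m = cc.PairConcordanceModel(gene_profile("A", vals), gene_profile("B", vals))
        assert m.x.min() >= -3.0

    def test_both_deleted_genes_omitted_at_functional_threshold(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 0.4, 300)
        a, b = vals.copy(), vals.copy()
        a[0], b[0] = -7.0, -4.5  # both floored to −3: no dosage information
        a[1], b[1] = 0.0, 2.0  # genuine change
        res = cc.PairConcordanceModel(gene_profile("A", a), gene_profile("B", b)).fit()
        called = res.altered_genes(1.0, omit_both_deleted=True)
        assert "g1" in called and "g0" not in called
        assert "g0" not in res.altered_genes(1.0, omit_both_deleted=True)

    def test_outliers_excluded_from_improved_fit_exactly(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 0.6, 250)
        y = x + rng.normal(0, 0.05, 250)
        y[3] += 4.0  # gross outlier
        res = cc.PairConcordanceModel(gene_profile("A", x), gene_profile("B", y)).fit()
        student = res.initial_fit.studentized
        assert res.outliers == frozenset(student.index[student.abs() > 3])
        assert "g3" in res.outliers

    def test_degenerate_profile_flagged_invalid(self):
        a = gene_profile("A", np.zeros(300))
        b = gene_profile("B", np.random.default_rng(0).normal(0, 1, 300))
        res = cc.PairConcordanceModel(a, b).fit()
        assert not res.valid
        with pytest.raises(ValueError):
            res.altered_genes()


class TestCrossPlatform:
    def _profile(self, sid, vals):
        rows = [("1", 100_000 * i, 100_000 * (i + 1), float(v)) for i, v in enumerate(vals)]
        return make_profile(sid, rows)

    def test_exact_linear_relation_no_outliers(self):
        from cnafid.prep import bin_profile

        rng = np.random.default_rng(0)
        vals = rng.normal(0, 0.8, 150)
        a = self._profile("A", vals)
        b = self._profile("B", 0.8 * vals)
        res = cc.cross_platform_compare(bin_profile(a), bin_profile(b))
        assert len(res.fit.outlier_features) == 0
        assert res.discordant_genome_fraction == 0.0
        assert res.fit.slope == pytest.approx(0.8)

    def test_single_perturbed_window_flagged(self):
        from cnafid.prep import bin_profile

        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.8, 150)
        bvals = vals + rng.normal(0, 0.05, 150)
        bvals[42] += 5.0
        a, b = self._profile("A", vals), self._profile("B", bvals)
        res = cc.cross_platform_compare(bin_profile(a), bin_profile(b))
        assert res.fit.outlier_features == frozenset({("1", 4_200_000)})
        assert res.discordant_genome_fraction == pytest.approx(1 / 150)

    def test_focal_event_maps_back_to_source_segment(self):
        from cnafid.prep import bin_profile

        rng = np.random.default_rng(2)
        base = rng.normal(0, 0.5, 600)
        a_rows = [("1", 100_000 * i, 100_000 * (i + 1), float(v)) for i, v in enumerate(base)]
        # replace windows 50–64 with one 1.5-Mb deletion present only in a
        a_rows[50:65] = [("1", 5_000_000, 6_500_000, -2.5)]
        a = make_profile("A", a_rows)
        b = self._profile("B", base + rng.normal(0, 0.05, 600))
        ba, bb = bin_profile(a), bin_profile(b)
        res = cc.cross_platform_compare(ba, bb, profile_a=a, profile_b=b)
        flagged = {s for (_, s) in res.fit.outlier_features}
        event_windows = {100_000 * i for i in range(50, 65)}
        assert flagged <= event_windows  # nothing outside the event
        assert len(flagged) >= 0.9 * len(event_windows)
        assert res.discordant_genome_fraction == pytest.approx(len(flagged) / 600)
        assert list(res.outlier_segment_sizes_a) == [1_500_000]

    def test_too_few_windows_rejected(self):
        from cnafid.prep import bin_profile

        a = self._profile("A", np.arange(50.0))
        with pytest.raises(ValueError, match="windows"):
            cc.cross_platform_compare(bin_profile(a), bin_profile(a))


class TestPairFlags:
    def test_low_r_with_flat_sample_invalid(self):
        assert not cc.pair_is_valid(r=0.2, ipr_a=0.1, ipr_b=0.8)

    def test_flat_but_correlated_pair_valid(self):
        assert cc.pair_is_valid(r=0.95, ipr_a=0.1, ipr_b=0.8)

    def test_aberrant_low_r_pair_valid_but_discordant_candidate(self):
        assert cc.pair_is_valid(r=0.3, ipr_a=0.7, ipr_b=0.8)

    @pytest.mark.parametrize(
        "r,ia,ib,expected",
        [(0.5, 0.6, 0.7, True), (0.5, 0.6, 0.4, False), (0.6, 0.6, 0.7, False)],
    )
    def test_discordance_requires_both_aberrant_and_strict_low_r(self, r, ia, ib, expected):
        assert cc.flag_discordant(r, ia, ib) is expected

    def test_range_ratio_and_inversion(self):
        a = AberrationSummary(variance=0.1, ipr_5_95=0.4, n_windows=100)
        b = AberrationSummary(variance=0.1, ipr_5_95=0.8, n_windows=100)
        assert cc.range_ratio(a, b) == pytest.approx(0.5)
        assert cc.range_ratio(b, a) == pytest.approx(2.0)
        assert cc.range_ratio(a, a) == pytest.approx(1.0)

    def test_zero_denominator_range_ratio_undefined(self):
        a = AberrationSummary(variance=0.0, ipr_5_95=0.0, n_windows=100)
        b = AberrationSummary(variance=0.1, ipr_5_95=0.4, n_windows=100)
        with pytest.warns(UserWarning):
            assert np.isnan(cc.range_ratio(b, a))


class TestCompareGroups:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        p = cc.compare_groups(x, x.copy())
        assert p > 0.9

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        assert cc.compare_groups(a, b) < 1e-6

    def test_one_sided_wrong_direction(self):
        rng = np.random.default_rng(2)
        a = rng.normal(5, 1, 30)
        b = rng.normal(0, 1, 30)
        assert cc.compare_groups(a, b, alternative="less") > 0.5

    def test_rank_sum_matches_exhaustive_permutation(self):
        """Exact rank-sum p by enumerating all group assignments."""
        a = np.array([1.2, 3.4, 0.1, 2.2])
        b = np.array([4.5, 2.9, 5.1, 3.8])
        pooled = np.concatenate([a, b])
        ranks = pd.Series(pooled).rank().to_numpy()
        obs = ranks[: len(a)].sum()
        stats = [
            sum(ranks[list(idx)])
            for idx in itertools.combinations(range(8), 4)
        ]
        exact_p = np.mean([
            (s <= obs) or (s >= len(a) * 9 - obs) for s in stats
        ])
        got = cc.compare_groups(a, b, alternative="two-sided")
        assert got == pytest.approx(exact_p, abs=1e-9)

    def test_ks_variant_available(self):
        rng = np.random.default_rng(3)
        p = cc.compare_groups(rng.normal(0, 1, 50), rng.normal(0, 3, 50), test="ks")
        assert p < 0.05

    def test_all_tied_input_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="tied"):
            assert cc.compare_groups(np.ones(5), np.ones(5)) == 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            cc.compare_groups(np.ones(2), np.arange(5.0))


class TestMislabelDetection:
    def test_swap_candidate_reported(self):
        rng = np.random.default_rng(0)
        base1 = rng.normal(0, 0.8, 300)
        base2 = rng.normal(0, 0.8, 300)
        profiles = {
            "M1-PT": gene_profile("M1-PT", base1),
            # labelled M1 but actually matches model M2
            "M1-X": gene_profile("M1-X", base2 + rng.normal(0, 0.02, 300)),
            "M2-PT": gene_profile("M2-PT", base2),
        }
        records = [
            rec("M1-PT", model="M1"), rec("M1-X", model="M1", cls="PDX", passage=0),
            rec("M2-PT", model="M2", patient="P2"),
        ]
        pair_table = pd.DataFrame(
            [{"sample_a": "M1-PT", "sample_b": "M1-X",
              "pearson_r": cc.correlate_profiles(profiles["M1-PT"], profiles["M1-X"])}]
        )
        report = cc.detect_mislabeled(pair_table, profiles, records)
        assert "M1-X" in set(report["sample"])
        assert "M2-PT" in set(report["matches_sample"])
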