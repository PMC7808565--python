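"""Cohort G scores, PT-anchored rescaling, ΔG and preranked GSEA."""

import numpy as np
import pandas as pd
import pytest

from cnafid import gscore as gs
from cnafid.core import GeneSetCollection

from conftest import make_profile


def flat_cohort(n, value=0.0, length=10_000_000):
    return [make_profile(f"S{i}", [("1", 0, length, value)]) for i in range(n)]


def genes_on_chr1(n, spacing=100_000, size=20_000):
    return pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(n)], "symbol": [f"g{i}" for i in range(n)],
         "chrom": "1", "start": spacing * np.arange(n) + 1_000,
         "end": spacing * np.arange(n) + 1_000 + size, "biotype": "protein_coding"}
    )


class TestComputeGScores:
    def test_flat_cohort_all_zero(self):
        res = gs.compute_gscores(flat_cohort(6), genes_on_chr1(50), n_perm=5)
        assert (res.genes["g_amp"] == 0).all()
        assert (res.genes["g_del"] == 0).all()

    def test_shared_amplification_scores_amplitude_minus_threshold(self):
        profiles = [
            make_profile(f"S{i}", [("1", 0, 2_000_000, 1.0), ("1", 2_000_000, 10_000_000, 0.0)])
            for i in range(6)
        ]
        res = gs.compute_gscores(profiles, genes_on_chr1(50), n_perm=5)
        inside = res.genes.loc[[f"g{i}" for i in range(19)], "g_amp"]
        outside = res.genes.loc[[f"g{i}" for i in range(21, 50)], "g_amp"]
        assert np.allclose(inside, 0.9)  # mean of max(1 − 0.1, 0)
        assert np.allclose(outside, 0.0)

    def test_single_carrier_scales_with_frequency(self):
        profiles = flat_cohort(5)
        profiles[0] = make_profile(
            "S0", [("1", 0, 2_000_000, 1.0), ("1", 2_000_000, 10_000_000, 0.0)]
        )
        res = gs.compute_gscores(profiles, genes_on_chr1(50), n_perm=5)
        assert res.genes.loc["g0", "g_amp"] == pytest.approx(0.9 / 5)

    def test_deletions_scored_on_their_own_track(self):
        profiles = [
            make_profile(f"S{i}", [("1", 0, 2_000_000, -1.0), ("1", 2_000_000, 10_000_000, 0.0)])
            for i in range(5)
        ]
        res = gs.compute_gscores(profiles, genes_on_chr1(50), n_perm=5)
        assert res.genes.loc["g0", "g_del"] == pytest.approx(0.9)
        assert res.genes.loc["g0", "g_amp"] == 0.0

    def test_additive_under_cohort_mixing(self):
        rng = np.random.default_rng(0)

        def rand_cohort(k, seed):
            r = np.random.default_rng(seed)
            out = []
            for i in range(k):
                vals = r.normal(0, 0.4, 10)
                rows = [("1", 1_000_000 * j, 1_000_000 * (j + 1), float(v))
                        for j, v in enumerate(vals)]
                out.append(make_profile(f"C{seed}S{i}", rows))
            return out

        a, b = rand_cohort(5, 1), rand_cohort(7, 2)
        genes = genes_on_chr1(50, spacing=200_000)
        ga = gs.compute_gscores(a, genes, n_perm=5)
        gb = gs.compute_gscores(b, genes, n_perm=5)
        gab = gs.compute_gscores(a + b, genes, n_perm=5)
        expected = (5 * ga.genes["g_amp"] + 7 * gb.genes["g_amp"]) / 12
        assert np.allclose(gab.genes["g_amp"], expected, atol=1e-12)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="cohort"):
            gs.compute_gscores(flat_cohort(3), genes_on_chr1(50))

    def test_recurrent_event_is_significant_background_not(self):
        rng = np.random.default_rng(4)
        profiles = []
        for i in range(10):
            vals = rng.normal(0, 0.05, 100)
            vals[10:13] += 1.2  # recurrent amplicon in every sample
            rows = [("1", 100_000 * j, 100_000 * (j + 1), float(v))
                    for j, v in enumerate(vals)]
            profiles.append(make_profile(f"S{i}", rows))
        res = gs.compute_gscores(profiles, genes_on_chr1(100), n_perm=50, seed=3)
        sig = res.significant_genes("amp")
        assert {"g10", "g11", "g12"} <= sig
        assert len(sig) < 15  # the flat background stays out


class TestScaling:
    def _results(self, g_amp, g_del):
        genes = pd.DataFrame(
            {"g_amp": g_amp, "g_del": g_del,
             "p_amp": 0.5, "p_del": 0.5, "q_amp": 0.5, "q_del": 0.5},
            index=[f"g{i}" for i in range(len(g_amp))],
        )
        return gs.CohortGScoreResults(bins=pd.DataFrame(), genes=genes,
                                      n_samples=10, width=100_000, event_threshold=0.1)

    def test_exact_double_rescales_onto_reference(self):
        rng = np.random.default_rng(1)
        base = np.abs(rng.normal(0, 0.2, 200))
        pt = self._results(base, base * 0.5)
        pdx = self._results(2 * base, base)
        scaled, scaling = gs.scale_gscores(pdx, pt)
        assert scaling.slope_amp == pytest.approx(2.0)
        assert np.allclose(scaled.genes["g_amp"], base, atol=1e-9)

    def test_identity_scaling_for_identical_cohorts(self):
        rng = np.random.default_rng(2)
        base = np.abs(rng.normal(0, 0.2, 200))
        pt = self._results(base, base)
        scaled, scaling = gs.scale_gscores(self._results(base, base), pt)
        assert scaling.slope_amp == pytest.approx(1.0)
        assert scaling.intercept_amp == pytest.approx(0.0, abs=1e-12)

    def test_rescaling_is_idempotent(self):
        rng = np.random.default_rng(3)
        base = np.abs(rng.normal(0, 0.2, 500))
        pdx = self._results(1.7 * base + 0.01 + rng.normal(0, 0.01, 500), base)
        pt = self._results(base, base)
        scaled, _ = gs.scale_gscores(pdx, pt)
        _, again = gs.scale_gscores(scaled, pt)
        assert again.slope_amp == pytest.approx(1.0, abs=1e-6)
        assert again.intercept_amp == pytest.approx(0.0, abs=1e-6)

    def test_flat_pdx_track_rejected(self):
        rng = np.random.default_rng(4)
        base = np.abs(rng.normal(0, 0.2, 100))
        with pytest.raises(ValueError, match="slope"):
            gs.scale_gscores(self._results(np.zeros(100), base), self._results(base, base))

    def test_identical_cohorts_have_zero_delta(self):
        rng = np.random.default_rng(5)
        base = np.abs(rng.normal(0, 0.2, 100))
        r = self._results(base, base)
        d = gs.delta_g(r, r)
        assert np.allclose(d["dg_amp"], 0) and np.allclose(d["dg_del"], 0)


class TestGSEA:
    def _scores(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(np.abs(rng.normal(0, 0.05, n)),
                         index=[f"g{i:04d}" for i in range(n)])

    def test_streaming_es_matches_naive_recomputation(self):
        from cnafid.gscore import enrichment_score, enrichment_score_naive

        rng = np.random.default_rng(6)
        for _ in range(40):
            n = 400
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            k = int(rng.integers(3, 51))
            pos = np.sort(rng.choice(n, k, replace=False))
            mask = np.zeros(n, bool)
            mask[pos] = True
            es_fast, _ = enrichment_score(pos, scores[pos], n)
            es_naive = enrichment_score_naive(scores, mask)
            assert es_fast == pytest.approx(es_naive, abs=1e-9)

    def test_top_ranked_set_has_extreme_es(self):
        scores = self._scores()
        ranked = scores.sort_values(ascending=False)
        coll = GeneSetCollection({"TOP": frozenset(ranked.index[:10])}, {"TOP": "t"})
        res = gs.gsea_preranked(scores, coll, n_perm=100, seed=0)
        assert res.table.loc["TOP", "es"] > 0.95

    def test_es_bounded_by_one(self):
        scores = self._scores(seed=7)
        rng = np.random.default_rng(8)
        coll = GeneSetCollection(
            {f"S{i}": frozenset(rng.choice(scores.index, 30, replace=False))
             for i in range(10)},
            {},
        )
        res = gs.gsea_preranked(scores, coll, n_perm=50, seed=1)
        assert (res.table["es"].abs() <= 1.0).all()

    def test_random_sets_not_significant(self):
        scores = self._scores(seed=9)
        scores.iloc[100:140] += 0.5  # some real structure in the ranking
        rng = np.random.default_rng(10)
        coll = GeneSetCollection(
            {f"R{i}": frozenset(rng.choice(scores.index, 40, replace=False))
             for i in range(15)},
            {},
        )
        res = gs.gsea_preranked(scores, coll,
                                significant_genes=frozenset(scores.index[100:140]),
                                n_perm=200, seed=2)
        assert not res.table["significant"].any()

    def test_amplicon_set_blocked_by_leading_edge_rule(self):
        """A positionally clustered set rides an amplicon to a high NES but
        fails unless its leading-edge genes are individually significant."""
        scores = self._scores(seed=11)
        scores.iloc[200:240] += 0.5
        members = frozenset(scores.index[195:245])
        coll = GeneSetCollection({"AMP": members}, {"AMP": "t"})
        sig = frozenset(scores.index[200:240])
        with_sig = gs.gsea_preranked(scores, coll, significant_genes=sig,
                                     n_perm=300, seed=3)
        without = gs.gsea_preranked(scores, coll, significant_genes=frozenset(),
                                    n_perm=300, seed=3)
        assert with_sig.table.loc["AMP", "nes"] > 1.5
        assert bool(with_sig.table.loc["AMP", "significant"])
        assert not bool(without.table.loc["AMP", "significant"])
        assert without.table.loc["AMP", "leading_edge_sig_fraction"] == 0.0

    def test_short_ranked_list_rejected(self):
        scores = self._scores(n=100)
        coll = GeneSetCollection({"A": frozenset(scores.index[:10])}, {})
        with pytest.raises(ValueError, match="ranked"):
            gs.gsea_preranked(scores, coll)


class TestDeltaNES:
    def _res(self, names, nes, sig):
        table = pd.DataFrame(
            {"nes": nes, "significant": sig, "es": nes, "q": 0.01,
             "leading_edge_sig_fraction": 0.5},
            index=pd.Index(names, name="set_name"),
        )
        return gs.GSEAResult(table=table, leading_edges={})

    def test_identical_results_zero_delta(self):
        r = self._res(["A", "B"], [2.0, 1.8], [True, True])
        d = gs.delta_nes(r, r)
        assert np.allclose(d["delta_nes"], 0.0)

    def test_restriction_never_enlarges(self):
        r1 = self._res(["A", "B", "C"], [2.0, 1.0, 0.5], [True, False, False])
        r2 = self._res(["A", "B", "C"], [1.9, 1.2, 0.4], [False, False, False])
        d = gs.delta_nes(r1, r2)
        assert set(d.index) == {"A"}

    def test_no_significant_sets_warns_and_returns_empty(self):
        r1 = self._res(["A"], [1.0], [False])
        with pytest.warns(UserWarning):
            d = gs.delta_nes(r1, r1)
        assert d.empty

    def test_delta_correlation_of_permuted_results_near_zero(self):
        rng = np.random.default_rng(12)
        names = [f"S{i}" for i in range(60)]
        base = rng.normal(1.5, 0.5, 60)
        r1 = self._res(names, base, [True] * 60)
        r2 = self._res(names, base + rng.normal(0, 0.2, 60), [True] * 60)
        r3 = self._res(names, base + rng.normal(0, 0.2, 60), [True] * 60)
        d1, d2 = gs.delta_nes(r1, r2), gs.delta_nes(r2, r3)
        # deltas sharing the middle cohort are mechanically anticorrelated
        # through its noise; deltas with disjoint noise are uncorrelated
        d_ind = gs.delta_nes(r1, r3)
        assert abs(gs.delta_nes_correlation(d1, d_ind)) < 0.3
        assert gs.delta_nes_correlation(d1, d2) < -0.3
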