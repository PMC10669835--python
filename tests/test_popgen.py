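import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crocdiag as cd
from crocdiag.dart_io import MISSING
from crocdiag.popgen import _fst_from_freqs, _locus_stats

from conftest import build_matrix


class TestDiversity:
    def test_hand_computed_single_locus(self):
        m = build_matrix([[0, 1, 1, 2]], populations=["CSI"] * 4)
        div = cd.diversity_table(m)
        row = div.per_locus.loc[("CSI", "L001")]
        assert row["p"] == pytest.approx(0.5)
        assert row["He"] == pytest.approx(0.5)
        assert row["Ho"] == pytest.approx(0.5)
        assert row["F"] == pytest.approx(0.0)
        assert row["I"] == pytest.approx(np.log(2))
        assert row["Ne"] == pytest.approx(2.0)

    def test_fixed_population_degenerate_values(self):
        m = build_matrix(np.zeros((5, 4), dtype=np.int8), populations=["CSI"] * 4)
        div = cd.diversity_table(m)
        s = div.summary.loc[("CSI", "Mean")]
        assert s["He"] == 0 and s["Ho"] == 0 and s["Ne"] == 1 and s["Na"] == 1
        assert div.n_f_undefined["CSI"] == 5  # F undefined at every monomorphic locus

    def test_closed_forms_on_frequency_grid(self):
        # He = 2p(1−p) and Ne = 1/(p² + q²) for any biallelic frequency
        for p in np.linspace(0.05, 0.95, 19):
            n = 200
            n_alt = int(round(2 * n * p))
            calls = np.array([2] * (n_alt // 2) + [1] * (n_alt % 2)
                             + [0] * (n - n_alt // 2 - n_alt % 2), dtype=np.int8)
            st_ = _locus_stats(calls)
            ph = st_["p"]
            assert st_["He"] == pytest.approx(2 * ph * (1 - ph), abs=1e-12)
            assert st_["Ne"] == pytest.approx(1 / (ph**2 + (1 - ph) ** 2), abs=1e-12)

    def test_locus_inclusion_conventions_differ(self):
        calls = np.array([[0, 0, MISSING, MISSING],
                          [0, 1, 0, 1]], dtype=np.int8)
        m = build_matrix(calls, populations=["CSI", "CSI", "CPOTH", "CPOTH"])
        all_loci = cd.diversity_table(m, locus_inclusion="all")
        called = cd.diversity_table(m, locus_inclusion="called")
        # CPOTH has no calls at L001: the "all" convention averages in a
        # zero-allele row and deflates mean Na (how Na can print below 1)
        assert all_loci.summary.loc[("CPOTH", "Mean"), "Na"] == pytest.approx(1.0)
        assert called.summary.loc[("CPOTH", "Mean"), "Na"] == pytest.approx(2.0)

    def test_empty_population_rejected(self):
        m = build_matrix([[0, 1]], populations=["CSI", "CSI"])
        with pytest.raises(ValueError, match="empty"):
            cd.diversity_table(m, pops={"CSI": ["S01", "S02"], "X": []})


class TestFStatistics:
    def test_identical_frequencies_give_zero(self):
        calls = np.array([[0, 1, 0, 1], [1, 2, 1, 2]], dtype=np.int8)
        m = build_matrix(calls, populations=["CSI", "CSI", "CPOTH", "CPOTH"])
        fs = cd.f_statistics(m, n_permutations=0)
        assert fs.fst_overall == pytest.approx(0.0, abs=1e-12)

    def test_reciprocal_fixation_gives_one(self):
        calls = np.array([[0, 0, 2, 2], [2, 2, 0, 0]], dtype=np.int8)
        m = build_matrix(calls, populations=["CSI", "CSI", "CPOTH", "CPOTH"])
        fs = cd.f_statistics(m, n_permutations=0)
        assert fs.fst_overall == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        # spreadsheet-style arithmetic, independent of the implementation
        calls = np.array([[0, 1, 2, 2], [0, 0, 0, 2]], dtype=np.int8)
        m = build_matrix(calls, populations=["CSI", "CSI", "CPOTH", "CPOTH"])
        p = {"CSI": [0.25, 0.0], "CPOTH": [1.0, 0.5]}
        hs, ht = [], []
        for l in range(2):
            p1, p2 = p["CSI"][l], p["CPOTH"][l]
            hs.append((2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2)
            pbar = (p1 + p2) / 2
            ht.append(2 * pbar * (1 - pbar))
        expected = (sum(ht) - sum(hs)) / sum(ht)
        fs = cd.f_statistics(m, n_permutations=0)
        assert fs.fst_pairwise.loc["CSI", "CPOTH"] == pytest.approx(expected, abs=1e-12)
        assert fs.fst_overall == pytest.approx(expected, abs=1e-12)

    def test_globally_monomorphic_flagged(self):
        m = build_matrix(np.zeros((3, 4), dtype=np.int8),
                         populations=["CSI", "CSI", "CPOTH", "CPOTH"])
        fs = cd.f_statistics(m, n_permutations=0)
        assert np.isnan(fs.fst_overall)

    def test_fst_bounds_on_simulated_data(self, mixed_dataset):
        m, _, _ = mixed_dataset
        parents = m.take_samples((m.samples["population"] != "CANDIDATE").to_numpy())
        fs = cd.f_statistics(parents, n_permutations=0)
        pw = fs.fst_pairwise.to_numpy()
        vals = pw[~np.isnan(pw)]
        assert ((vals >= -1e-12) & (vals <= 1 + 1e-12)).all()
        assert 0 <= fs.fst_overall <= 1

    def test_permutation_p_detects_true_differentiation(self):
        calls = np.tile(np.array([[0] * 6 + [2] * 6], dtype=np.int8), (20, 1))
        m = build_matrix(calls, populations=["CSI"] * 6 + ["CPOTH"] * 6)
        fs = cd.f_statistics(m, n_permutations=99, seed=0)
        assert fs.p_pairwise.loc["CSI", "CPOTH"] <= 0.05

    def test_permutation_p_uniform_under_null(self):
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(60):
            calls = rng.binomial(2, 0.4, size=(20, 12)).astype(np.int8)
            m = build_matrix(calls, populations=["CSI"] * 6 + ["CPOTH"] * 6)
            fs = cd.f_statistics(m, n_permutations=299,
                                 seed=int(rng.integers(2**31)))
            pvals.append(fs.p_pairwise.loc["CSI", "CPOTH"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRelatedness:
    def test_identical_homozygous_dyad_scores_one(self):
        # identical homozygous dyads give num = den = 2 − 2p at every locus,
        # so the defining ratio is exactly 1 whatever the reference frequency
        calls = np.array([[2, 2, 0, 0, 1, 1],
                          [2, 2, 0, 0, 1, 1]], dtype=np.int8)
        m = build_matrix(calls)
        r, _ = cd.relatedness_qg(m)
        assert r.loc["S01", "S02"] == pytest.approx(1.0, abs=1e-12)

    def test_heterozygous_reference_contributes_nothing(self):
        # all-het dyad: every locus is 0/0 for the estimator → undefined pair
        calls = np.array([[1, 1, 0, 2], [1, 1, 2, 0]], dtype=np.int8)
        m = build_matrix(calls)
        r, _ = cd.relatedness_qg(m)
        assert np.isnan(r.loc["S01", "S02"])

    def test_clonal_dyads_outrank_background(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.5, size=(60, 1)).astype(np.int8)
        clones = np.repeat(base, 4, axis=1)
        others = rng.binomial(2, 0.5, size=(60, 4)).astype(np.int8)
        m = build_matrix(np.hstack([clones, others]))
        r, _ = cd.relatedness_qg(m)
        clone_ids = [f"S{j:02d}" for j in range(1, 5)]
        other_ids = [f"S{j:02d}" for j in range(5, 9)]
        clone_r = np.mean([r.loc[a, b] for i, a in enumerate(clone_ids)
                           for b in clone_ids[i + 1:]])
        other_r = np.mean([r.loc[a, b] for i, a in enumerate(other_ids)
                           for b in other_ids[i + 1:]])
        assert clone_r > 0.5 > other_r

    def test_random_mating_population_centers_near_zero(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.2, 0.8, size=400)
        calls = rng.binomial(2, p[:, None], size=(400, 150)).astype(np.int8)
        m = build_matrix(calls)
        _, mean_r = cd.relatedness_qg(m)
        assert abs(mean_r) < 0.02

    def test_too_few_individuals_rejected(self):
        m = build_matrix([[0, 1]])
        with pytest.raises(ValueError):
            cd.relatedness_qg(m)


class TestHWE:
    def test_exact_hw_proportions_give_zero(self):
        calls = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=np.int8)
        chi2, p = cd.hwe_test(calls)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_all_heterozygotes_closed_form(self):
        calls = np.ones(50, dtype=np.int8)
        chi2, _ = cd.hwe_test(calls)
        assert chi2 == pytest.approx(50.0, abs=1e-9)  # chi2 = n at p = 0.5, all het

    def test_matches_scipy_chisquare_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            calls = rng.integers(0, 3, size=40).astype(np.int8)
            if len(set(calls)) == 1:
                continue
            n = len(calls)
            p = calls.sum() / (2 * n)
            if p in (0, 1):
                continue
            obs = [(calls == k).sum() for k in (0, 1, 2)]
            exp = [n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2]
            chi2, pval = cd.hwe_test(calls)
            ref = stats.chisquare(obs, exp, ddof=1)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-9)
            assert pval == pytest.approx(ref.pvalue, abs=1e-9)

    def test_monomorphic_not_testable(self):
        with pytest.raises(ValueError, match="monomorphic"):
            cd.hwe_test(np.zeros(10, dtype=np.int8))


class TestWelch:
    def test_identical_samples_zero(self):
        res = cd.welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert res.t == pytest.approx(0.0)

    def test_both_constant_flagged_na(self):
        res = cd.welch_t([2.0, 2.0], [5.0, 5.0])
        assert res.undefined and np.isnan(res.t)

    def test_matches_scipy_and_longhand_df(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 4.0, 6.0, 8.0, 10.0]
        res = cd.welch_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        vx, vy = np.var(x, ddof=1) / 4, np.var(y, ddof=1) / 5
        df = (vx + vy) ** 2 / (vx**2 / 3 + vy**2 / 4)
        assert res.df == pytest.approx(df, abs=1e-12)


class TestAMOVA:
    @staticmethod
    def _dist(d):
        ids = pd.Index([f"S{i}" for i in range(len(d))], name="sample_id")
        return cd.DistanceMatrix(ids=ids, d=np.asarray(d, float),
                                 n_compared=np.ones((len(d), len(d)), dtype=int))

    def test_identical_individuals_all_within(self):
        d = self._dist(np.zeros((6, 6)))
        pops = {"P1": ["S0", "S1", "S2"], "P2": ["S3", "S4", "S5"]}
        res = cd.amova_two_level(d, pops, n_permutations=0)
        assert res.pct_within == pytest.approx(100.0)
        assert res.pct_among == pytest.approx(0.0)

    def test_saturated_divergence_mostly_among(self):
        d = np.zeros((6, 6))
        d[:3, 3:] = 1.0
        d[3:, :3] = 1.0
        res = cd.amova_two_level(
            self._dist(d), {"P1": ["S0", "S1", "S2"], "P2": ["S3", "S4", "S5"]},
            n_permutations=0)
        assert res.pct_among == pytest.approx(100.0)
        assert res.phi == pytest.approx(1.0)

    def test_hand_computed_ss_decomposition(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        pops = {"P1": ["S0", "S1", "S2"], "P2": ["S3", "S4", "S5"]}
        res = cd.amova_two_level(self._dist(d), pops, n_permutations=0)
        # independent double-loop SS arithmetic
        d2 = d**2
        ss_total = sum(d2[i, j] for i in range(6) for j in range(i + 1, 6)) / 6
        ss_w = (sum(d2[i, j] for i in range(3) for j in range(i + 1, 3)) / 3
                + sum(d2[i, j] for i in range(3, 6) for j in range(i + 1, 6)) / 3)
        assert res.ss_among == pytest.approx(ss_total - ss_w, abs=1e-9)
        assert res.ss_within == pytest.approx(ss_w, abs=1e-9)
        ms_w = ss_w / 4
        ms_a = (ss_total - ss_w) / 1
        n0 = (6 - (9 + 9) / 6) / 1
        var_a = max((ms_a - ms_w) / n0, 0.0)
        assert res.phi == pytest.approx(var_a / (var_a + ms_w), abs=1e-9)

    def test_permutation_p_significant_for_separated_groups(self):
        d = np.zeros((8, 8))
        d[:4, 4:] = 1.0
        d[4:, :4] = 1.0
        ids = [f"S{i}" for i in range(8)]
        res = cd.amova_two_level(
            self._dist(d), {"P1": ids[:4], "P2": ids[4:]},
            n_permutations=199, seed=1)
        assert res.p < 0.05

    def test_single_population_rejected(self):
        d = self._dist(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            cd.amova_two_level(d, {"P1": ["S0", "S1", "S2"]})
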