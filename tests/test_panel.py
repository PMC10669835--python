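import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import crocdiag as cd
from crocdiag.dart_io import MISSING

from conftest import build_matrix


def _two_species(calls_a, calls_b, marker_class="snp"):
    """Matrix with 1 locus: 3 A individuals then 3 B individuals."""
    calls = np.asarray([list(calls_a) + list(calls_b)], dtype=np.int8)
    pops = ["CSI"] * len(calls_a) + ["CPOTH"] * len(calls_b)
    return build_matrix(calls, marker_class=marker_class, populations=pops)


class TestFindDiagnosticLoci:
    def test_reciprocally_fixed_assigned_by_priority(self):
        m = _two_species([0, 0, 0], [2, 2, 2])
        panel = cd.find_diagnostic_loci(m, min_called_frac=0.0)
        e = panel.entries.iloc[0]
        assert (e["species"], e["state"], e["status"]) == ("A", 0, "fixed_opposite")
        panel_b = cd.find_diagnostic_loci(m, priority="B", min_called_frac=0.0)
        assert panel_b.entries.iloc[0]["species"] == "B"

    def test_identical_fixation_not_diagnostic(self):
        m = _two_species([0, 0, 0], [0, 0, 0])
        assert len(cd.find_diagnostic_loci(m, min_called_frac=0.0)) == 0

    def test_modes_disagree_when_allele_shared(self):
        # A fixed for 0; B polymorphic and still carrying allele 0
        m = _two_species([0, 0, 0], [0, 1, 2])
        fixed_nonfixed = cd.find_diagnostic_loci(m, mode="fixed_nonfixed",
                                                 min_called_frac=0.0)
        strict = cd.find_diagnostic_loci(m, mode="strict_absent",
                                         min_called_frac=0.0)
        assert list(fixed_nonfixed.loci("A")) == ["L001"]
        assert len(strict) == 0

    def test_heterozygote_blocks_fixation(self):
        m = _two_species([0, 1, 0], [2, 2, 2])
        panel = cd.find_diagnostic_loci(m, min_called_frac=0.0)
        assert list(panel.entries["species"]) == ["B"]  # only B side is fixed

    def test_pa_locus_strict_mode(self):
        m = _two_species([1, 1, 1], [0, 0, 0], marker_class="pa")
        panel = cd.find_diagnostic_loci(m, mode="strict_absent", min_called_frac=0.0)
        e = panel.entries.iloc[0]
        assert (e["species"], e["state"], e["status"]) == ("A", 1, "fixed_opposite")

    def test_insufficient_calls_skips_locus(self):
        m = _two_species([0, MISSING, MISSING], [2, 2, 2])
        assert len(cd.find_diagnostic_loci(m, min_called_frac=0.8)) == 0

    def test_panel_recovery_and_exclusivity(self, mixed_dataset):
        # no-missing variant of the mixed config for exact set recovery
        cfg = cd.SimConfig(n_loci=1500, frac_pa=0.3, missing_rate=0.0, seed=5)
        m, truth = cd.simulate_parentals(cfg)
        strict = cd.find_diagnostic_loci(m, mode="strict_absent")
        cat = truth.locus_category
        assert set(strict.loci()) == set(cat.index[cat == "reciprocal_fixed"])
        both = cd.find_diagnostic_loci(m, mode="fixed_nonfixed")
        expected = set(cat.index[cat.isin(
            ["reciprocal_fixed", "A_fixed_B_poly", "B_fixed_A_poly"])])
        assert set(both.loci()) == expected
        # exclusive assignment: the two species' panels partition the total
        assert len(both.loci("A")) + len(both.loci("B")) == len(both)
        # the A-skewed generator yields an asymmetric panel
        assert len(both.loci("A")) > len(both.loci("B"))

    def test_species_without_samples_is_an_error(self):
        m = build_matrix([[0, 0]], populations=["CSI", "CSI"])
        with pytest.raises(ValueError, match="species 'B'"):
            cd.find_diagnostic_loci(m)


class TestCATT:
    def test_complete_separation_tables_match_printed_maxima(self):
        chi2, p = cd.catt_from_table([[29, 0], [0, 30]])
        assert chi2 == pytest.approx(59.0, abs=1e-9)
        assert p < 0.001
        chi2, p = cd.catt_from_table([[58, 0], [0, 60]])
        assert chi2 == pytest.approx(118.0, abs=1e-9)
        assert p < 0.001

    def test_identical_distributions_give_zero(self):
        chi2, p = cd.catt_from_table([[10, 5, 5], [10, 5, 5]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_monomorphic_locus_flagged(self):
        calls = np.zeros(10, dtype=np.int8)
        labels = ["A"] * 5 + ["B"] * 5
        chi2, p = cd.catt_association(calls, labels)
        assert (chi2, p) == (0.0, 1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 12), min_size=6, max_size=6))
    def test_matches_correlation_identity_oracle(self, cells):
        # CATT (score test, N-denominator variance) equals N * corr(score, group)^2
        table = np.array(cells, dtype=float).reshape(2, 3)
        if table.sum(axis=1).min() == 0:
            return
        chi2, _ = cd.catt_from_table(table)
        scores, groups = [], []
        for r in range(2):
            for j in range(3):
                scores += [j] * int(table[r, j])
                groups += [r] * int(table[r, j])
        scores, groups = np.array(scores, float), np.array(groups, float)
        if scores.std() == 0 or groups.std() == 0:
            assert chi2 == 0.0
            return
        r = np.corrcoef(scores, groups)[0, 1]
        assert chi2 == pytest.approx(len(scores) * r**2, abs=1e-9)

    def test_scale_bounds_at_complete_separation(self):
        calls = np.array([0] * 14 + [2] * 15, dtype=np.int8)
        labels = ["A"] * 14 + ["B"] * 15
        chi2_g, _ = cd.catt_association(calls, labels, scale="genotype")
        chi2_a, _ = cd.catt_association(calls, labels, scale="allele")
        assert chi2_g == pytest.approx(29.0, abs=1e-9)   # = N
        assert chi2_a == pytest.approx(58.0, abs=1e-9)   # = 2N


class TestPIC:
    @pytest.mark.parametrize("freqs,expected", [
        ((1.0, 0.0), 0.0),
        ((0.5, 0.5), 0.5),
        ((0.8, 0.2), 0.32),
    ])
    def test_expected_heterozygosity_form(self, freqs, expected):
        assert cd.pic_index(freqs) == pytest.approx(expected, abs=1e-12)

    def test_botstein_form_peaks_lower(self):
        assert cd.pic_index((0.5, 0.5), botstein=True) == pytest.approx(0.375)

    def test_malformed_simplex_rejected(self):
        with pytest.raises(ValueError):
            cd.pic_index((0.5, 0.6))


class TestHamming:
    def test_identical_vectors_zero(self):
        m = build_matrix([[0, 0], [1, 1], [2, 2]])
        d = cd.hamming_matrix(m)
        assert d.d[0, 1] == 0.0

    def test_hand_counted_mixed_missing(self):
        m = build_matrix([[0, 0], [1, 2], [2, 2], [MISSING, 0]])
        d = cd.hamming_matrix(m)
        assert d.d[0, 1] == pytest.approx(1 / 3)
        assert d.n_compared[0, 1] == 3

    def test_between_species_distance_is_one_on_reciprocal_panel(self, reciprocal_cohort):
        _, _, parents, panel = reciprocal_cohort
        d = cd.hamming_matrix(parents, locus_subset=panel.loci())
        a = (parents.samples["population"] == "CSI").to_numpy()
        between = d.d[np.ix_(a, ~a)]
        assert np.all(between == 1.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(-1, 3, size=(10, 10)).astype(np.int8)
        m = build_matrix(calls)
        d = cd.hamming_matrix(m)
        for i in range(10):
            for j in range(10):
                num = den = 0
                for l in range(10):
                    if calls[l, i] != MISSING and calls[l, j] != MISSING:
                        den += 1
                        num += calls[l, i] != calls[l, j]
                if den:
                    assert d.d[i, j] == pytest.approx(num / den, abs=1e-12)
                    assert d.n_compared[i, j] == den or i == j
                elif i != j:
                    assert np.isnan(d.d[i, j])

    def test_disjoint_call_sets_flagged_undefined(self):
        m = build_matrix([[0, MISSING], [MISSING, 2]])
        d = cd.hamming_matrix(m)
        assert d.undefined_pairs[0, 1]


class TestConsensusIdentity:
    def test_identical_single_individual_groups(self):
        ma = build_matrix([[0], [1], [2]])
        mb = build_matrix([[0], [1], [2]])
        res = cd.consensus_identity(ma, mb)
        assert res["identical_sites_pct"] == 100.0
        assert res["pairwise_identity_pct"] == 100.0

    def test_completely_divergent_groups(self):
        ma = build_matrix(np.zeros((5, 2), dtype=np.int8))
        mb = build_matrix(np.full((5, 2), 2, dtype=np.int8))
        res = cd.consensus_identity(ma, mb)
        assert res["identical_sites_pct"] == 0.0

    def test_hand_counted_consensus_agreement(self):
        # 10 loci; consensus calls agree at exactly 4
        a_cons = [0, 0, 1, 1, 2, 2, 0, 1, 2, 0]
        b_cons = [0, 2, 1, 0, 2, 0, 1, 2, 2, 1]  # agree at loci 0,2,4,8
        ma = build_matrix(np.array([a_cons, a_cons]).T)
        mb = build_matrix(np.array([b_cons, b_cons]).T)
        res = cd.consensus_identity(ma, mb)
        assert res["identical_sites_pct"] == pytest.approx(40.0)

    def test_majority_with_tie_breaks_to_lowest_code(self):
        ma = build_matrix([[0, 0, 2]])        # majority 0
        mb = build_matrix([[0, 2, MISSING]])  # tie 0/2 → 0
        res = cd.consensus_identity(ma, mb)
        assert res["identical_sites_pct"] == 100.0

    def test_all_missing_locus_excluded_and_counted(self):
        ma = build_matrix([[0, 0], [MISSING, MISSING]])
        mb = build_matrix([[0, 0], [0, 0]])
        res = cd.consensus_identity(ma, mb)
        assert res["n_loci_excluded"] == 1
        assert res["identical_sites_pct"] == 100.0

    def test_within_identity_on_clonal_group(self):
        m = build_matrix(np.ones((4, 3), dtype=np.int8))
        res = cd.within_identity(m)
        assert res["identical_sites_pct"] == 100.0
        assert res["pairwise_identity_pct"] == 100.0
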