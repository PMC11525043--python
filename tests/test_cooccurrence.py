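from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mutualink import (PairCounts, bh_adjust, effect_size_standardized,
                       expected_cooccurrence, hypergeom_pmf, null_detection_rate,
                       prob_tails, rii, run_method, spearman_association)


def enumerate_placements(S, n1, n2):
    """Co-occurrence distribution by brute force over all uniform placements."""
    counts = {}
    total = 0
    for a in combinations(range(S), n1):
        sa = set(a)
        for b in combinations(range(S), n2):
            j = len(sa & set(b))
            counts[j] = counts.get(j, 0) + 1
            total += 1
    return {j: Fraction(c, total) for j, c in counts.items()}


class TestPairCounts:
    @pytest.mark.parametrize("kw", [
        dict(S=0, n1=0, n2=0, O=0),
        dict(S=5, n1=6, n2=1, O=1),
        dict(S=5, n1=3, n2=3, O=0),     # O below max(0, n1+n2-S)=1
        dict(S=5, n1=2, n2=3, O=3),     # O above min(n1, n2)
    ])
    def test_invalid_counts_rejected(self, kw):
        with pytest.raises(ValueError):
            PairCounts(**kw)


class TestPointStatistics:
    def test_expected_is_product_over_sites(self):
        assert expected_cooccurrence(PairCounts(S=40, n1=10, n2=20, O=5)) == 5.0
        assert expected_cooccurrence(PairCounts(S=10, n1=0, n2=5, O=0)) == 0.0
        assert expected_cooccurrence(PairCounts(S=4, n1=4, n2=4, O=4)) == 4.0

    def test_rii_value_symmetry_and_degenerate_zero(self):
        assert rii(PairCounts(S=20, n1=10, n2=10, O=8)) == pytest.approx(3 / 13)
        assert rii(PairCounts(S=20, n1=10, n2=10, O=5)) == 0.0     # O == E
        assert rii(PairCounts(S=6, n1=0, n2=3, O=0)) == 0.0        # O + E == 0
        assert -1 <= rii(PairCounts(S=10, n1=5, n2=5, O=0)) <= 1

    def test_effect_size_standardized(self):
        assert effect_size_standardized(PairCounts(S=20, n1=10, n2=10, O=8)) == \
            pytest.approx(3 / 20)
        assert effect_size_standardized(PairCounts(S=20, n1=10, n2=10, O=5)) == 0.0

    @given(st.integers(1, 12).flatmap(
        lambda S: st.tuples(st.just(S), st.integers(0, S), st.integers(0, S))))
    def test_rii_sign_matches_deviation_and_species_symmetry(self, snn):
        S, n1, n2 = snn
        lo, hi = max(0, n1 + n2 - S), min(n1, n2)
        for O in range(lo, hi + 1):
            pc = PairCounts(S=S, n1=n1, n2=n2, O=O)
            swapped = PairCounts(S=S, n1=n2, n2=n1, O=O)
            r = rii(pc)
            assert -1 <= r <= 1
            assert np.sign(r) == np.sign(O - expected_cooccurrence(pc))
            assert r == rii(swapped)
            assert effect_size_standardized(pc) == effect_size_standardized(swapped)
            assert prob_tails(pc, exact=True) == prob_tails(swapped, exact=True)


class TestHypergeometric:
    def test_two_site_coin_flip(self):
        pc = PairCounts(S=2, n1=1, n2=1, O=0)
        assert hypergeom_pmf(0, pc, exact=True) == Fraction(1, 2)
        assert hypergeom_pmf(1, pc, exact=True) == Fraction(1, 2)

    def test_example_against_enumeration(self):
        pc = PairCounts(S=5, n1=3, n2=2, O=2)
        assert hypergeom_pmf(2, pc, exact=True) == Fraction(3, 10)
        p_gt, p_lt, p_eq = prob_tails(pc, exact=True)
        assert p_gt == 0 and p_lt == Fraction(7, 10) and p_eq == Fraction(3, 10)

    @given(st.integers(1, 6).flatmap(
        lambda S: st.tuples(st.just(S), st.integers(0, S), st.integers(0, S))))
    def test_pmf_matches_enumeration_and_normalizes(self, snn):
        S, n1, n2 = snn
        dist = enumerate_placements(S, n1, n2)
        lo, hi = max(0, n1 + n2 - S), min(n1, n2)
        pc = PairCounts(S=S, n1=n1, n2=n2, O=lo)
        total = Fraction(0)
        for j in range(lo, hi + 1):
            p = hypergeom_pmf(j, pc, exact=True)
            assert p == dist.get(j, Fraction(0))
            total += p
        assert total == 1
        assert hypergeom_pmf(hi + 1, pc, exact=True) == 0
        assert hypergeom_pmf(lo - 1, pc, exact=True) == 0

    def test_matches_scipy_float_pmf(self):
        pc = PairCounts(S=30, n1=12, n2=9, O=5)
        for j in range(0, 10):
            assert hypergeom_pmf(j, pc) == pytest.approx(
                stats.hypergeom.pmf(j, 30, 12, 9), abs=1e-12)

    def test_tail_boundaries(self):
        pc = PairCounts(S=8, n1=5, n2=4, O=4)      # O at max
        p_gt, _, _ = prob_tails(pc)
        assert p_gt == 0.0
        pc = PairCounts(S=8, n1=5, n2=4, O=1)      # O at min
        _, p_lt, _ = prob_tails(pc)
        assert p_lt == 0.0

    def test_null_detection_rate_bounds_and_tail_ordering(self):
        pc = PairCounts(S=60, n1=20, n2=25, O=10)
        strict = null_detection_rate(pc, alpha=0.2, tail="strict")
        inclusive = null_detection_rate(pc, alpha=0.2, tail="inclusive")
        assert 0 <= inclusive <= strict <= 1
        # inclusive tail never rejects more often than alpha (valid test)
        assert inclusive <= 0.2 + 1e-12


class TestSpearman:
    def test_monotone_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman_association(x, x * 2 + 1)[0] == pytest.approx(1.0)
        assert spearman_association(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        rho, _ = spearman_association(np.array([1, 2, 3, 4.0]),
                                      np.array([2, 1, 4, 3.0]))
        assert rho == pytest.approx(0.6)

    def test_constant_vector_yields_nan_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            rho, p = spearman_association(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)
        assert "constant" in caplog.text

    def test_exact_permutation_p_agrees_with_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 4.0])
        rho_t, _ = spearman_association(x, y)
        rho_e, p_e = spearman_association(x, y, method="exact")
        assert rho_e == pytest.approx(rho_t)
        # oracle: proportion of the 120 permutations with |rho| >= observed
        assert 0 < p_e < 1
        count = 0
        from itertools import permutations as perms
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(stats.rankdata(x), ry)[0, 1])
        for pm in perms(range(5)):
            if abs(np.corrcoef(stats.rankdata(x), ry[list(pm)])[0, 1]) >= obs - 1e-12:
                count += 1
        assert p_e == pytest.approx(count / 120)


class TestBHAdjust:
    def test_step_up_examples(self):
        np.testing.assert_allclose(bh_adjust([0.07]), [0.07])
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_rejects_out_of_range_and_passes_nan(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # family size m=2 for the defined entries
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_dominate_raw_and_stay_in_unit_interval(self, ps):
        adj = bh_adjust(ps)
        assert ((adj >= np.asarray(ps) - 1e-12) & (adj <= 1 + 1e-12)).all()


class TestRunMethod:
    def test_cartesian_coverage_and_columns(self, small_community, fast_null_config):
        com = small_community
        for method in ("rii_null", "probabilistic", "spearman_plants"):
            table = run_method(com.plants, com.butterflies, method, 0.2,
                               null_config=fast_null_config)
            assert len(table) == com.plants.n_species * com.butterflies.n_species
            assert set(zip(table.plant, table.butterfly)) == {
                (p, b) for p in com.plants.species for b in com.butterflies.species}

    def test_probabilistic_max_overlap_pair_is_significant(self):
        from mutualink import OccurrenceData
        # plant and butterfly share all 4 occupied sites of 12: p_gt < alpha
        pres = np.zeros((12, 1))
        pres[:4] = 1.0
        plants = OccurrenceData(sites=[f"s{i}" for i in range(12)], species=["p"],
                                guild="plant", abundance=pres)
        bflies = OccurrenceData(sites=plants.sites, species=["b"],
                                guild="butterfly", abundance=pres.copy())
        table = run_method(plants, bflies, "probabilistic", 0.05)
        row = table.iloc[0]
        assert row.p_upper == 0.0 and row.significant

    def test_spearman_diagonal_of_identical_guilds(self, small_community):
        com = small_community
        from mutualink import OccurrenceData
        mirror = OccurrenceData(sites=com.plants.sites, species=com.plants.species,
                                guild="butterfly", abundance=com.plants.abundance)
        table = run_method(com.plants, mirror, "spearman_plants", 0.2)
        diag = table[table.plant == table.butterfly]
        varying = [sp for sp, col in zip(com.plants.species, com.plants.abundance.T)
                   if np.ptp(col) > 0]
        got = diag.set_index("plant").loc[varying, "statistic"]
        np.testing.assert_allclose(got, 1.0, atol=1e-12)

    def test_site_mismatch_rejected(self, small_community):
        com = small_community
        shifted = com.butterflies.subset(sites=list(reversed(com.butterflies.sites)))
        with pytest.raises(ValueError, match="site"):
            run_method(com.plants, shifted, "probabilistic", 0.2)
        with pytest.raises(ValueError, match="method"):
            run_method(com.plants, com.butterflies, "pearson", 0.2)

    def test_spearman_matches_scipy_per_pair(self, small_community):
        com = small_community
        table = run_method(com.plants, com.butterflies, "spearman_plants", 0.2)
        pa, ba = com.plants.abundance, com.butterflies.abundance
        for _, row in table.sample(8, random_state=0).iterrows():
            i = com.plants.species.index(row.plant)
            j = com.butterflies.species.index(row.butterfly)
            if np.ptp(pa[:, i]) == 0 or np.ptp(ba[:, j]) == 0:
                assert np.isnan(row.statistic)
                continue
            ref = stats.spearmanr(pa[:, i], ba[:, j])
            assert row.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert row.p_upper == pytest.approx(ref.pvalue, abs=1e-10)
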