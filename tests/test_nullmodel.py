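"""Segregation model, null simulation, exact oracle and P values."""

import itertools
import math

import numpy as np
import pytest

from polybsa.nullmodel import (
    NullModel,
    PvalueResult,
    SegregationModel,
    exact_bulk_index_pmf,
    gamete_dose_pmf,
    p_value,
    progeny_dose_pmf,
    simulate_bulk_index,
    simulate_null,
)


def brute_force_gamete_pmf(ploidy: int, parent_dose: int) -> np.ndarray:
    """Enumerate all homolog subsets of size ploidy/2 (independent oracle)."""
    marked = set(range(parent_dose))
    counts = np.zeros(parent_dose + 1)
    for combo in itertools.combinations(range(ploidy), ploidy // 2):
        counts[len(marked & set(combo))] += 1
    return counts / counts.sum()


class TestGameteDosePmf:
    @pytest.mark.parametrize("ploidy", [4, 6, 8])
    @pytest.mark.parametrize("dose", [0, 1, 2, 3])
    def test_matches_enumeration_oracle(self, ploidy, dose):
        np.testing.assert_allclose(
            gamete_dose_pmf(ploidy, dose),
            brute_force_gamete_pmf(ploidy, dose),
            atol=1e-12,
        )

    def test_hexaploid_simplex_segregates_1_to_1(self):
        # 10 of the C(6,3)=20 homolog triples contain the marked homolog
        np.testing.assert_allclose(gamete_dose_pmf(6, 1), [0.5, 0.5], atol=1e-12)

    def test_hexaploid_duplex(self):
        np.testing.assert_allclose(gamete_dose_pmf(6, 2), [0.2, 0.6, 0.2], atol=1e-12)

    def test_nulliplex_parent(self):
        np.testing.assert_allclose(gamete_dose_pmf(6, 0), [1.0], atol=1e-15)

    def test_odd_ploidy_rejected(self):
        with pytest.raises(ValueError):
            gamete_dose_pmf(5, 1)


class TestProgenyExpectations:
    @pytest.mark.parametrize(
        "plexity,freq", [(1, 1 / 12), (2, 1 / 6), (3, 1 / 4)]
    )
    def test_expected_allele_frequency(self, plexity, freq):
        m = SegregationModel(6, plexity)
        assert m.expected_allele_frequency == pytest.approx(freq, rel=1e-12)
        pmf = progeny_dose_pmf(6, plexity)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_simplex_expectations_match_printed_values(self):
        m = SegregationModel(6, 1)
        assert round(m.donor_parent_index, 3) == 0.167
        assert round(m.expected_allele_frequency, 3) == 0.083
        assert m.enriched_bulk_index() == pytest.approx(1 / 6)


class TestSimulateNull:
    def test_null_delta_centered_at_zero(self):
        m = SegregationModel(6, 1)
        nd = simulate_null(20, 20, 10**6, 10**6, m, replicates=20_000, seed=7)
        assert abs(nd.delta_samples.mean()) < 0.002

    def test_thresholds_nest(self):
        m = SegregationModel(6, 1)
        nd = simulate_null(10, 21, 80, 120, m, replicates=5000, seed=1)
        lo95, hi95 = nd.thresholds[0.95]
        lo99, hi99 = nd.thresholds[0.99]
        assert lo99 <= lo95 < hi95 <= hi99

    def test_thresholds_symmetric_for_matched_bulks(self):
        # with equal bulk sizes and depths, Δ and −Δ share one law, so the
        # bands must be near-mirror images (unequal designs are skewed: the
        # smaller bulk's right-skewed index dominates the lower tail)
        m = SegregationModel(6, 1)
        nd = simulate_null(15, 15, 100, 100, m, replicates=20_000, seed=1)
        for lo, hi in nd.thresholds.values():
            assert abs(lo + hi) < 0.05 * (hi - lo)

    def test_single_member_bulks_at_huge_depth(self):
        # each bulk is one progeny: dose 0 or 1 with p=1/2; at huge depth the
        # observed index is the true frequency, so Δ ∈ {-1/6, 0, +1/6} with
        # P(±1/6) = 1/4 each (exact enumeration of dose pairs)
        m = SegregationModel(6, 1)
        nd = simulate_null(1, 1, 10**6, 10**6, m, replicates=40_000, seed=5)
        rounded = np.round(nd.delta_samples * 6)
        values, counts = np.unique(rounded, return_counts=True)
        freq = dict(zip(values, counts / rounded.size))
        assert set(freq) == {-1.0, 0.0, 1.0}
        assert freq[1.0] == pytest.approx(0.25, abs=0.01)
        assert freq[-1.0] == pytest.approx(0.25, abs=0.01)

    def test_low_replicates_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            simulate_null(2, 2, 10, 10, SegregationModel(6, 1), replicates=999, seed=0)

    def test_bad_seed_type_rejected(self):
        with pytest.raises(TypeError):
            simulate_null(2, 2, 10, 10, SegregationModel(6, 1),
                          replicates=1000, seed="abc")

    def test_threshold_width_shrinks_with_depth(self):
        m = SegregationModel(6, 1)
        widths = []
        for depth in (20, 50, 200):
            nd = simulate_null(10, 21, depth, depth, m, replicates=50_000, seed=3)
            lo, hi = nd.thresholds[0.95]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


class TestExactOracle:
    def test_hand_enumerated_two_member_bulk(self):
        # n=2, depth=2, simplex: dose sum S ~ {0:1/4, 1:1/2, 2:1/4},
        # freq = S/12, index pmf computed by hand
        support, probs = exact_bulk_index_pmf(2, 2, SegregationModel(6, 1))
        np.testing.assert_allclose(support, [0.0, 0.5, 1.0])
        expected0 = 0.25 + 0.5 * (11 / 12) ** 2 + 0.25 * (10 / 12) ** 2
        expected2 = 0.5 * (1 / 12) ** 2 + 0.25 * (2 / 12) ** 2
        np.testing.assert_allclose(probs, [expected0, 1 - expected0 - expected2, expected2],
                                   atol=1e-12)

    def test_mean_equals_expected_bulk_frequency(self):
        support, probs = exact_bulk_index_pmf(2, 40, SegregationModel(6, 1))
        assert float(support @ probs) == pytest.approx(1 / 12, abs=1e-12)

    def test_plexity_zero_is_point_mass_at_zero(self):
        support, probs = exact_bulk_index_pmf(3, 10, SegregationModel(6, 0))
        assert probs[0] == pytest.approx(1.0, abs=1e-12)

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="simulate_null"):
            exact_bulk_index_pmf(1000, 100_000, SegregationModel(6, 3))

    def test_simulation_matches_oracle_cdf(self):
        # modest-size agreement check; the full-replicate version runs in the
        # acceptance suite
        m = SegregationModel(6, 1)
        support, probs = exact_bulk_index_pmf(2, 4, m)
        samples = simulate_bulk_index(2, 4, m, replicates=30_000, seed=9)
        ecdf = np.searchsorted(np.sort(samples), support, side="right") / samples.size
        ks = np.abs(ecdf - np.cumsum(probs)).max()
        assert ks < 0.02


@pytest.fixture(scope="module")
def nulldist():
    return simulate_null(10, 21, 100, 100, SegregationModel(6, 1),
                         replicates=10_000, seed=11)


class TestPvalues:

    def test_null_center_not_significant(self, nulldist):
        res = p_value(0.0, nulldist)
        assert res.p > 0.9
        assert not res.sig95 and not res.sig99

    def test_extreme_tail(self, nulldist):
        extreme = np.abs(nulldist.delta_samples).max() + 0.01
        res = p_value(extreme, nulldist)
        assert res.p == pytest.approx(1 / (nulldist.replicates + 1))
        assert res.sig99 and res.sig95

    def test_bit_reproducible_given_seed(self):
        m = SegregationModel(6, 1)
        a = simulate_null(10, 21, 90, 110, m, replicates=2000, seed=13)
        b = simulate_null(10, 21, 90, 110, m, replicates=2000, seed=13)
        assert a.p_value(0.08).p == b.p_value(0.08).p
        np.testing.assert_array_equal(a.delta_samples, b.delta_samples)

    def test_sig99_implies_sig95_enforced(self):
        with pytest.raises(ValueError):
            PvalueResult(p=0.001, sig95=False, sig99=True)

    def test_vectorised_matches_scalar(self, nulldist):
        deltas = np.array([-0.2, -0.05, 0.0, 0.08, 0.3])
        p, s95, s99 = nulldist.p_values(deltas)
        for i, d in enumerate(deltas):
            res = nulldist.p_value(d)
            assert p[i] == res.p
            assert s95[i] == res.sig95
            assert s99[i] == res.sig99


class TestNullModelCache:
    def test_score_is_order_independent_and_deterministic(self):
        m = SegregationModel(6, 1)
        nm1 = NullModel(m, 10, 21, replicates=2000, seed=17)
        nm2 = NullModel(m, 10, 21, replicates=2000, seed=17)
        delta = np.array([0.05, -0.12, 0.2, 0.0])
        dl = np.array([80, 100, 80, 120])
        dh = np.array([100, 100, 100, 90])
        p1, *_ = nm1.score(delta, dl, dh)
        # warm nm2's cache in a different order first
        nm2.get(120, 90)
        nm2.get(80, 100)
        p2, *_ = nm2.score(delta, dl, dh)
        np.testing.assert_array_equal(p1, p2)

    def test_get_matches_pairwise_simulation_stream(self):
        m = SegregationModel(6, 1)
        nm = NullModel(m, 10, 21, replicates=2000, seed=23)
        nd = nm.get(77, 103)
        assert (nd.depth_low, nd.depth_high) == (77, 103)
        assert nd.replicates == 2000
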