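"""Generator contracts: the closed-form trait correlation, the difficulty
grid layout, determinism, and the statistical signatures of TD and RD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

from raschld import (
    ResponseMatrix,
    SimulationCondition,
    difficulty_grid,
    rasch_probability,
    read_response_matrix,
    simulate,
    simulate_rd,
    simulate_td,
    trait_correlation,
    write_response_matrix,
)


class TestTraitCorrelation:
    @pytest.mark.parametrize("c,expected", [(0.0, 1.0), (1.0, 0.5), (2.0, 0.2)])
    def test_study_magnitudes(self, c, expected):
        assert trait_correlation(c) == pytest.approx(expected, abs=1e-12)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            trait_correlation(-0.5)

    @given(st.floats(min_value=0, max_value=50, allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_in_unit_interval_and_decreasing(self, c):
        rho = trait_correlation(c)
        assert 0 < rho <= 1
        assert trait_correlation(c + 0.5) < rho or c != c  # strictly decreasing


class TestRaschProbability:
    @pytest.mark.parametrize(
        "theta,b,expected",
        [(0.0, 0.0, 0.5), (2.0, 2.0, 0.5), (0.0, 1.0, 0.26894)],
    )
    def test_values(self, theta, b, expected):
        assert rasch_probability(theta, b) == pytest.approx(expected, abs=5e-6)

    @given(
        st.floats(-8, 8, allow_nan=False), st.floats(-8, 8, allow_nan=False)
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_and_bounded(self, theta, b):
        p = rasch_probability(theta, b)
        assert 0 < p < 1
        assert rasch_probability(theta + 1, b) > p
        assert rasch_probability(theta, b + 1) < p


class TestDifficultyGrid:
    @pytest.mark.parametrize("n_items,subset_size", [(30, 5), (60, 5), (60, 10)])
    def test_grid_is_equally_spaced_permutation(self, n_items, subset_size):
        b, subset, halo = difficulty_grid(n_items, subset_size)
        assert np.allclose(np.sort(b), np.linspace(-2, 2, n_items))
        assert b.min() == -2.0 and b.max() == 2.0
        assert abs(b.sum()) < 1e-12

    @pytest.mark.parametrize("n_items,subset_size", [(30, 5), (60, 10)])
    def test_halo_is_hardest_of_each_subset(self, n_items, subset_size):
        b, subset, halo = difficulty_grid(n_items, subset_size)
        assert halo.sum() == n_items // subset_size
        for s in range(n_items // subset_size):
            in_subset = subset == s
            assert halo[in_subset].sum() == 1
            halo_b = b[in_subset & halo][0]
            assert halo_b == b[in_subset].max()

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError):
            difficulty_grid(31, 5)


class TestConditionValidation:
    def test_bad_ld_type(self):
        with pytest.raises(ValueError):
            SimulationCondition(ld_type="bogus")

    def test_negative_magnitude(self):
        with pytest.raises(ValueError):
            SimulationCondition(ld_type="TD", magnitude=-1)

    def test_wrong_generator_for_type(self):
        with pytest.raises(ValueError):
            simulate_td(SimulationCondition(ld_type="RD", magnitude=1))
        with pytest.raises(ValueError):
            simulate_rd(SimulationCondition(ld_type="TD", magnitude=1))


class TestDeterminism:
    @pytest.mark.parametrize("ld,mag", [("TD", 1.0), ("RD", 2.0), ("none", 0.0)])
    def test_same_seed_same_matrix(self, ld, mag):
        cond = SimulationCondition(ld, mag, 30, 100, seed=99)
        a = simulate(cond)
        b = simulate(cond)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.truth.theta, b.truth.theta)

    def test_different_seeds_differ(self):
        a = simulate(SimulationCondition("TD", 1.0, 30, 100, seed=1))
        b = simulate(SimulationCondition("TD", 1.0, 30, 100, seed=2))
        assert not np.array_equal(a.data, b.data)


class TestTraitDependence:
    def test_null_model_item_proportions(self):
        """At c=0 the observed proportion correct per item matches the
        marginal E[logistic(theta - b)] over theta ~ N(0,1)."""
        cond = SimulationCondition("TD", 0.0, 30, 10000, seed=11)
        m = simulate(cond)
        b = m.truth.difficulties
        for i in np.argsort(b)[[0, 14, 29]]:  # easiest, middle, hardest
            expected = quad(
                lambda t, bi=b[i]: expit(t - bi) * norm.pdf(t), -9, 9
            )[0]
            se = np.sqrt(expected * (1 - expected) / cond.n_persons)
            assert abs(m.data[:, i].mean() - expected) < 3 * se

    def test_subset_score_correlation_attenuates_with_c(self):
        """Shared-trait correlation between subset sum scores drops as the
        subset-specific traits grow (rho = 1/(1+c^2))."""

        def subset_corr(c, seed):
            m = simulate(SimulationCondition("TD", c, 30, 5000, seed=seed))
            sub = m.truth.subset_of_item
            s0 = m.data[:, sub == 0].sum(axis=1)
            s1 = m.data[:, sub == 1].sum(axis=1)
            return np.corrcoef(s0, s1)[0, 1]

        r0 = np.mean([subset_corr(0.0, s) for s in (21, 22, 23)])
        r2 = np.mean([subset_corr(2.0, s) for s in (21, 22, 23)])
        assert r2 < r0 - 0.1


class TestResponseDependence:
    def test_d_zero_matches_null_rasch_margins(self):
        rd = simulate(SimulationCondition("RD", 0.0, 30, 10000, seed=31))
        td = simulate(SimulationCondition("TD", 0.0, 30, 10000, seed=32))
        p_rd, p_td = rd.data.mean(axis=0), td.data.mean(axis=0)
        se = np.sqrt(0.25 / 10000 * 2)
        assert np.abs(p_rd - p_td).max() < 5 * se + 0.01

    @pytest.mark.parametrize("d", [1.0, 2.0])
    def test_conditional_shift_on_halo(self, d):
        """Dependent items are easier after a correct halo response, and
        the conditional gap grows with d."""
        m = simulate(SimulationCondition("RD", d, 30, 8000, seed=41))
        sub, halo = m.truth.subset_of_item, m.truth.halo_flag
        gaps = []
        for s in range(6):
            halo_col = m.data[:, np.flatnonzero(halo & (sub == s))[0]]
            for j in np.flatnonzero(~halo & (sub == s)):
                p1 = m.data[halo_col == 1, j].mean()
                p0 = m.data[halo_col == 0, j].mean()
                assert p1 > p0
                gaps.append(p1 - p0)
        if d == 2.0:
            m1 = simulate(SimulationCondition("RD", 1.0, 30, 8000, seed=41))
            # same comparison at d=1 must give a smaller mean gap
            gaps1 = []
            for s in range(6):
                halo_col = m1.data[:, np.flatnonzero(halo & (sub == s))[0]]
                for j in np.flatnonzero(~halo & (sub == s)):
                    gaps1.append(
                        m1.data[halo_col == 1, j].mean()
                        - m1.data[halo_col == 0, j].mean()
                    )
            assert np.mean(gaps) > np.mean(gaps1)

    def test_within_subset_correlation_raised_between_unchanged(self):
        m2 = simulate(SimulationCondition("RD", 2.0, 30, 5000, seed=51))
        m0 = simulate(SimulationCondition("RD", 0.0, 30, 5000, seed=51))
        sub = m2.truth.subset_of_item

        def mean_corrs(m):
            r = np.corrcoef(m.data.T)
            iu = np.triu_indices(30, 1)
            same = sub[iu[0]] == sub[iu[1]]
            return r[iu][same].mean(), r[iu][~same].mean()

        w2, b2 = mean_corrs(m2)
        w0, b0 = mean_corrs(m0)
        assert w2 > w0 + 0.05
        assert abs(b2 - b0) < 0.08  # between-subset structure driven by theta only


class TestResponseMatrixContainer:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            ResponseMatrix(np.array([[0, 2], [1, 0]]))

    def test_csv_round_trip(self, tmp_path):
        m = simulate(SimulationCondition("TD", 1.0, 30, 50, seed=61))
        write_response_matrix(m, tmp_path / "rep")
        back = read_response_matrix(tmp_path / "rep")
        assert np.array_equal(back.data, m.data)
        assert back.condition == m.condition
        assert np.allclose(back.truth.theta, m.truth.theta)
        assert np.allclose(back.truth.difficulties, m.truth.difficulties)

    def test_every_item_has_both_categories(self):
        m = simulate(SimulationCondition("TD", 2.0, 30, 250, seed=71))
        col = m.data.sum(axis=0)
        assert (col > 0).all() and (col < m.n_persons).all()
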