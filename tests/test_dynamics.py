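import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from glvmap.dynamics import (
    IntegrationSettings,
    assess_viability,
    capped_derivative,
    glv_derivative,
    integrate_to_equilibrium,
    subset_equilibrium,
)
from glvmap.params import CommunityParameters

from conftest import random_community


def community(r, s, A, **kw):
    return CommunityParameters(r=np.asarray(r, float), s=np.asarray(s, float), A=np.asarray(A, float), **kw)


class TestDerivatives:
    def test_single_species_logistic(self):
        p = community([1.0], [1.0], [[0.0]])
        assert glv_derivative(np.array([0.5]), p) == pytest.approx([0.25])

    def test_extinct_species_has_zero_rate(self):
        p = community([1.0, -0.5], [1.0, 1.0], [[0.0, 0.3], [0.2, 0.0]])
        rates = glv_derivative(np.array([0.7, 0.0]), p)
        assert rates[1] == 0.0

    def test_direct_substitution_pair(self):
        A = [[0.0, 0.5], [0.0, 0.0]]
        p = community([1.0, 1.0], [1.0, 1.0], A)
        rates = glv_derivative(np.array([1.0, 1.0]), p)
        assert rates == pytest.approx([0.5, 0.0])

    def test_dimension_mismatch_raises(self):
        p = community([1.0], [1.0], [[0.0]])
        with pytest.raises(ValueError):
            glv_derivative(np.array([1.0, 2.0]), p)

    def test_feeding_enters_growth_term(self):
        p = community([-0.1], [1.0], [[0.0]], f=0.3)
        assert glv_derivative(np.array([0.1]), p) == pytest.approx([0.1 * (0.2 - 0.1)])


class TestCappedDerivative:
    def test_below_cap_matches_glv(self):
        p = community([1.0, 0.5], [1.0, 1.0], [[0.0, -0.1], [-0.2, 0.0]], K_T=100.0)
        x = np.array([2.0, 3.0])
        assert np.allclose(capped_derivative(x, p), glv_derivative(x, p))

    def test_symmetric_species_at_cap_static(self):
        p = community([1.0, 1.0], [1.0, 1.0], np.zeros((2, 2)), K_T=10.0)
        rates = capped_derivative(np.array([5.0, 5.0]), p)
        assert np.allclose(rates, 0.0)

    def test_weighted_mean_hand_computed(self):
        # r=(1, 0.5), negligible s, equal abundances at the cap: weighted
        # mean rate 0.75, so rates are +/- 5000 * 0.25.
        p = community([1.0, 0.5], [1e-12, 1e-12], np.zeros((2, 2)), K_T=10_000.0)
        rates = capped_derivative(np.array([5000.0, 5000.0]), p)
        assert rates == pytest.approx([1250.0, -1250.0], rel=1e-6)

    @hyp_settings(max_examples=200, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 6))
    def test_total_derivative_zero_at_cap(self, seed, S):
        rng = np.random.default_rng(seed)
        A = rng.normal(0, 0.2, size=(S, S))
        np.fill_diagonal(A, 0.0)
        p = community(rng.normal(0, 1, S), rng.uniform(0.1, 1, S), A, K_T=float(rng.uniform(10, 1e4)))
        x = rng.dirichlet(np.ones(S)) * p.K_T * rng.uniform(1.0, 1.2)
        rates = capped_derivative(x, p)
        assert abs(rates.sum()) <= 1e-10 * max(1.0, np.abs(rates).max())


class TestIntegration:
    def test_logistic_fixed_point(self):
        p = community([1.0], [0.01], [[0.0]], K_T=1e6)
        traj = integrate_to_equilibrium(p, np.array([1.0]))
        assert traj.converged
        assert traj.final.x == pytest.approx([100.0], rel=1e-6)

    def test_lone_obligate_mutualist_dies(self):
        A = [[0.0, 0.5], [0.5, 0.0]]
        p = community([-0.1, -0.1], [1.0, 1.0], A)
        traj = integrate_to_equilibrium(p, np.array([0.01, 0.0]))
        assert np.array_equal(traj.final.x, [0.0, 0.0])

    def test_cap_invariant_along_trajectory(self):
        # strong mutualists blow up to the cap but never beyond
        A = [[0.0, 1.5], [1.5, 0.0]]
        p = community([-0.1, -0.1], [1.0, 1.0], A, K_T=10_000.0)
        traj = integrate_to_equilibrium(p, np.array([1.0, 1.0]))
        assert traj.states.sum(axis=1).max() <= p.K_T * (1 + 1e-3)
        assert traj.final.x.sum() == pytest.approx(p.K_T, rel=1e-4)

    def test_capped_and_uncapped_agree_below_cap(self):
        p = community([1.0, 0.8], [1.0, 1.0], [[0.0, -0.2], [-0.3, 0.0]], K_T=10_000.0)
        capped = integrate_to_equilibrium(p, np.array([0.5, 0.5]))
        from dataclasses import replace

        uncapped = integrate_to_equilibrium(
            p, np.array([0.5, 0.5]), settings=replace(IntegrationSettings(), capped=False)
        )
        assert np.allclose(capped.final.x, uncapped.final.x, rtol=1e-6)

    def test_nonnegative_start_required(self):
        p = community([1.0], [1.0], [[0.0]])
        traj = integrate_to_equilibrium(p, np.array([0.0]))
        assert traj.final.x == pytest.approx([0.0])


class TestSubsetEquilibrium:
    def test_single_species_half(self):
        p = community([1.0], [2.0], [[0.0]])
        res = subset_equilibrium(p, [0])
        assert res.feasible and res.stable
        assert res.abundances == pytest.approx([0.5])

    def test_symmetric_competition_pair(self):
        A = [[0.0, -0.5], [-0.5, 0.0]]
        p = community([1.0, 1.0], [1.0, 1.0], A)
        res = subset_equilibrium(p, [0, 1])
        # oracle: solve the 2x2 linear system directly
        expected = np.linalg.solve(np.array([[1.0, 0.5], [0.5, 1.0]]), np.array([1.0, 1.0]))
        assert res.viable
        assert res.abundances == pytest.approx(expected)
        assert res.abundances == pytest.approx([2 / 3, 2 / 3])

    def test_negative_component_infeasible(self):
        A = [[0.0, 0.1], [0.1, 0.0]]
        p = community([1.0, -2.0], [1.0, 1.0], A)
        expected = np.linalg.solve(np.array([[1.0, -0.1], [-0.1, 1.0]]), np.array([1.0, -2.0]))
        assert expected.min() < 0  # confirms the constructed case
        res = subset_equilibrium(p, [0, 1])
        assert not res.feasible
        assert not res.viable

    def test_empty_subset_rejected(self):
        p = community([1.0], [1.0], [[0.0]])
        with pytest.raises(ValueError):
            subset_equilibrium(p, [])


class TestViability:
    def test_empty_set_viable_by_convention(self):
        p = community([1.0], [1.0], [[0.0]])
        assert assess_viability(p, []).viable

    @pytest.mark.parametrize("r,f,expected", [(0.3, 0.0, True), (-0.2, 0.0, False),
                                              (-0.2, 0.3, True), (0.0, 0.0, False)])
    def test_single_species_sign_rule(self, r, f, expected):
        p = community([r], [1.0], [[0.0]], f=f)
        assert assess_viability(p, [0]).viable is expected

    def test_interior_above_cap_viable_at_cap(self):
        # interior equilibrium (1e4 each) exceeds the cap; the pair persists
        # on the cap surface and returns after perturbation
        p = community([1.0, 1.0], [1e-4, 1e-4], np.zeros((2, 2)), K_T=10_000.0)
        res = assess_viability(p, [0, 1])
        assert res.viable and res.at_cap
        assert res.abundances.sum() == pytest.approx(p.K_T, rel=1e-4)

    def test_obligate_pair_viable_only_together(self, archetypes):
        p = archetypes["obligate_pair"]
        assert not assess_viability(p, [0]).viable
        assert not assess_viability(p, [1]).viable
        res = assess_viability(p, [0, 1])
        assert res.viable and res.at_cap

    def test_matches_multistart_oracle_small(self, fast):
        from oracle import subset_viable_oracle

        rng = np.random.default_rng(42)
        for seed in range(4):
            params = random_community(500 + seed, settings=fast)
            for mask in range(1, 8):
                subset = [i for i in range(3) if mask & (1 << i)]
                mine = assess_viability(params, subset, settings=fast).viable
                truth = subset_viable_oracle(params, subset, rng)
                assert mine == truth, f"seed {seed} subset {subset}: {mine} vs oracle {truth}"
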