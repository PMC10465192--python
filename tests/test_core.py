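"""Closed-form suppression-field terms: examples, limits and invariants."""

import numpy as np
import pytest

from supfield import (
    DensityError,
    Genotype,
    Population,
    SFMParams,
    assorted_suppression,
    effective_survival,
    initiator_term,
    mean_field_suppression,
)
from conftest import random_params, random_population

ATOL = 1e-9


class TestPopulation:
    def test_genotype_field_validation(self):
        with pytest.raises(ValueError, match="tolerance"):
            Genotype(tolerance=1.2, suppression=0.5)
        with pytest.raises(ValueError, match="suppression"):
            Genotype(tolerance=0.5, suppression=-0.1)

    def test_density_simplex_enforced_with_deviation_named(self):
        with pytest.raises(DensityError, match="deviation"):
            Population([0.5, 0.5], [0.5, 0.5], 0.8, [0.6, 0.6])

    def test_from_genotypes_round_trip(self):
        pop = Population.from_genotypes(
            [Genotype(0.3, 0.7, 0.8, 0.25), Genotype(0.6, 0.2, 0.9, 0.75)]
        )
        assert pop.k == 2
        assert pop.mean_tolerance == pytest.approx(0.3 * 0.25 + 0.6 * 0.75)

    @pytest.mark.parametrize("levels,expect", [(4, 16), (13, 169), (101, 10201)])
    def test_trait_grid_richness(self, levels, expect):
        pop = Population.trait_grid(levels)
        assert pop.k == expect
        assert pop.density.sum() == pytest.approx(1.0, abs=1e-12)
        assert pop.tolerance.min() == pytest.approx(0.2)
        assert pop.suppression.max() == pytest.approx(0.8)

    def test_trait_grid_crossed_with_survival_levels(self):
        p_levels = [0.5, 0.7, 0.9]
        pop = Population.trait_grid(4, max_survival=p_levels)
        assert pop.k == 16 * 3
        assert sorted(set(pop.max_survival)) == p_levels


class TestMeanField:
    def test_weighted_mean_example(self, two_type_pop):
        # D=(.5,.5), S=(.8,.2), alpha*rho=1 -> 0.5
        assert mean_field_suppression(two_type_pop, SFMParams()) == pytest.approx(0.5)

    def test_empty_community(self, two_type_pop):
        assert mean_field_suppression(two_type_pop, SFMParams(rho=0.0)) == 0.0

    def test_single_genotype_direct_evaluation(self):
        pop = Population([0.5], [0.37], 0.8, [1.0])
        params = SFMParams(alpha=0.6, rho=0.5)
        got = mean_field_suppression(pop, params)
        assert got == pytest.approx(0.111, abs=ATOL)
        # cross-check against the assorted form at phi = 1
        assert got == pytest.approx(
            assorted_suppression(pop, SFMParams(alpha=0.6, rho=0.5, phi=1.0), 0), abs=1e-12
        )


class TestAssortedSuppression:
    def test_mean_field_reduction_at_phi_one(self, rng):
        for _ in range(20):
            pop = random_population(rng)
            params = random_params(rng, phi=1.0)
            s = assorted_suppression(pop, params)
            assert np.all(np.abs(s - mean_field_suppression(pop, params)) < 1e-12)

    def test_complete_self_assortment_limit(self, two_type_pop):
        s = assorted_suppression(two_type_pop, SFMParams(phi=1e9))
        np.testing.assert_allclose(s, two_type_pop.suppression, atol=1e-8)

    def test_monotone_in_phi_for_strong_suppressor(self, two_type_pop):
        # genotype 0 has S=0.8 > S_bar: its felt field rises with phi
        vals = [
            assorted_suppression(two_type_pop, SFMParams(phi=p), 0)
            for p in [1.0, 2.0, 5.0, 10.0, 100.0, 1000.0]
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(0.5 < v < 0.8 for v in vals[1:])

    def test_single_genotype_identity_phi_cancels(self):
        pop = Population([0.5], [0.44], 0.8, [1.0])
        for phi in (0.5, 1.0, 10.0, 1e6):
            params = SFMParams(alpha=0.7, rho=0.9, phi=phi)
            got = assorted_suppression(pop, params, 0)
            assert got == pytest.approx(0.7 * 0.9 * 0.44, abs=1e-12)

    def test_phi_zero_with_full_density_is_domain_error(self):
        pop = Population([0.5], [0.5], 0.8, [1.0])
        with pytest.raises(ValueError, match="denominator"):
            assorted_suppression(pop, SFMParams(phi=0.0))

    def test_phi_zero_partial_density_well_defined(self, two_type_pop):
        # complete kin avoidance: the field comes entirely from others
        s0 = assorted_suppression(two_type_pop, SFMParams(phi=0.0), 0)
        assert s0 == pytest.approx((0.5 * 0.2) / 0.5, abs=1e-12)

    def test_matrix_form_agrees_at_phi_one_but_not_generally(self, rng):
        # the all-ones matrix reduces to the mean field exactly; a matrix
        # with phi on the diagonal and 1 elsewhere does NOT reproduce the
        # scalar (renormalized) form away from phi = 1 — the scalar form
        # is normative, the discrepancy is systematic and documented here
        pop = random_population(rng, k=6)
        ones = np.ones((6, 6))
        s_mat = assorted_suppression(pop, SFMParams(phi_matrix=ones))
        s_sca = assorted_suppression(pop, SFMParams(phi=1.0))
        np.testing.assert_allclose(s_mat, s_sca, atol=1e-12)
        m = np.ones((6, 6))
        np.fill_diagonal(m, 50.0)
        s_mat = assorted_suppression(pop, SFMParams(phi_matrix=m))
        s_sca = assorted_suppression(pop, SFMParams(phi=50.0))
        assert np.max(np.abs(s_mat - s_sca)) > 1e-3


class TestInitiatorTerm:
    def test_beta_one_collapses_to_unity(self, rng):
        for _ in range(10):
            pop = random_population(rng)
            B = initiator_term(pop, random_params(rng, beta=1.0))
            np.testing.assert_allclose(B, 1.0, atol=1e-12)

    def test_pairwise_no_replacement_example(self):
        # n=1, beta=0, P_bar=0.8, alpha*rho=1, S_i=0.5, T_bar=0.8 -> 0.72
        pop = Population([0.8], [0.5], 0.8, [1.0])
        B = initiator_term(pop, SFMParams(beta=0.0, n=1), genotype_index=0)
        assert B == pytest.approx(0.72, abs=ATOL)

    def test_large_neighbourhood_limit(self, two_type_pop):
        params = SFMParams(beta=0.3, n=10**6)
        s_hat = assorted_suppression(two_type_pop, params)
        B = initiator_term(two_type_pop, params)
        p_bar, t_bar = 0.8, two_type_pop.mean_tolerance
        limit = p_bar * 0.7 * (1.0 - s_hat * (1.0 - t_bar)) + 0.3
        np.testing.assert_allclose(B, limit, atol=1e-5)

    def test_stays_in_beta_one_band_for_in_range_inputs(self, rng):
        for _ in range(30):
            pop = random_population(rng)
            params = random_params(rng)
            B = np.atleast_1d(initiator_term(pop, params))
            assert np.all(B >= params.beta - 1e-12)
            assert np.all(B <= 1.0 + 1e-12)


class TestEffectiveSurvival:
    def test_complete_tolerance(self):
        pop = Population([1.0, 0.5], [0.6, 0.4], 0.8, [0.5, 0.5])
        p_hat, _ = effective_survival(pop, SFMParams(beta=0.2, phi=3.0))
        assert p_hat[0] == pytest.approx(0.8, abs=1e-12)

    @pytest.mark.parametrize("kw", [{"alpha": 0.0}, {"rho": 0.0}])
    def test_no_competition_when_field_vanishes(self, two_type_pop, kw):
        p_hat, terms = effective_survival(two_type_pop, SFMParams(**kw))
        np.testing.assert_allclose(p_hat, two_type_pop.max_survival, atol=1e-12)
        assert np.all(terms.felt_suppression == 0.0)

    def test_uniform_population_hand_value(self):
        # P=0.8, S=0.5, T=0.5, alpha*rho=1, beta=1 -> 0.8 - 0.8*0.5*1*0.5
        pop = Population([0.5], [0.5], 0.8, [1.0])
        p_hat, terms = effective_survival(pop, SFMParams(beta=1.0, phi=1.0), 0)
        assert p_hat == pytest.approx(0.6, abs=ATOL)
        assert terms.initiator[0] == pytest.approx(1.0)

    def test_beta_one_collapse_equals_bare_field_form(self, rng):
        # with beta = 1 the assembled model is P_i - P_i s_i (1 - T_i)
        for _ in range(10):
            pop = random_population(rng)
            params = random_params(rng, beta=1.0)
            p_hat, _ = effective_survival(pop, params)
            s = assorted_suppression(pop, params)
            bare = pop.max_survival - pop.max_survival * s * (1.0 - pop.tolerance)
            np.testing.assert_allclose(p_hat, bare, atol=1e-14)

    def test_never_exceeds_max_survival(self, rng):
        for _ in range(30):
            pop = random_population(rng)
            p_hat, terms = effective_survival(pop, random_params(rng))
            assert np.all(p_hat <= pop.max_survival + 1e-12)
            assert np.all(p_hat >= -1e-12)
            np.testing.assert_allclose(
                p_hat,
                pop.max_survival - terms.competition_cost,
                atol=1e-14,
            )

    def test_monotone_in_own_tolerance_on_canonical_domain(self, rng):
        # raising one genotype's T never lowers its survival for trait
        # draws on the canonical [0.2, 0.8] domain with moderate densities
        for _ in range(25):
            pop = random_population(rng)
            params = random_params(rng)
            i = int(rng.integers(pop.k))
            base, _ = effective_survival(pop, params, i)
            T = pop.tolerance.copy()
            T[i] = min(1.0, T[i] + 0.1)
            bumped = Population(T, pop.suppression, pop.max_survival, pop.density)
            up, _ = effective_survival(bumped, params, i)
            assert up >= base - 1e-12

    def test_monotone_decreasing_in_felt_suppression_at_fixed_initiator(self, rng):
        pop = random_population(rng)
        params = random_params(rng)
        s = assorted_suppression(pop, params)
        B = initiator_term(pop, params, felt_suppression=s)
        direct = pop.max_survival - pop.max_survival * s * B * (1.0 - pop.tolerance)
        worse = pop.max_survival - pop.max_survival * (s + 0.05) * B * (1.0 - pop.tolerance)
        assert np.all(worse <= direct + 1e-15)

    def test_kin_ratio_reported(self, two_type_pop):
        _, terms = effective_survival(two_type_pop, SFMParams(phi=10.0))
        expect = terms.felt_suppression / (1.0 * two_type_pop.mean_suppression)
        np.testing.assert_allclose(terms.kin_ratio, expect, atol=1e-12)
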