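"""Density iteration, selection gradients, thresholds, invasion and
strategy sweeps."""

import math

import numpy as np
import pytest

from supfield import (
    Population,
    PopulationCollapseError,
    SFMParams,
    ThresholdUndefinedError,
    effective_survival,
    equilibrate,
    ess_sweep,
    invasion_test,
    run_sfm,
    selection_gradient,
    step_sfm,
    threshold_density,
    tuned_params,
)
from supfield.dynamics import TUNED_PRESETS, _suppression_differential
from conftest import random_params, random_population


class TestStep:
    def test_identical_genotypes_leave_densities_unchanged(self):
        pop = Population([0.5] * 4, [0.5] * 4, 0.8, [0.25] * 4)
        out = step_sfm(pop, SFMParams(beta=0.3, phi=10.0))
        np.testing.assert_allclose(out.density, pop.density, atol=1e-15)

    def test_tolerance_always_beneficial(self):
        pop = Population([0.8, 0.2], [0.5, 0.5], 0.8, [0.5, 0.5])
        out = step_sfm(pop, SFMParams(phi=1.0, beta=0.5))
        assert out.density[0] > 0.5

    def test_suppression_neutral_without_assortment_or_initiator(self):
        pop = Population([0.5, 0.5], [0.8, 0.2], 0.8, [0.5, 0.5])
        out = step_sfm(pop, SFMParams(phi=1.0, beta=1.0))
        np.testing.assert_allclose(out.density, pop.density, atol=1e-15)

    def test_density_conservation(self, rng):
        for _ in range(20):
            pop = random_population(rng)
            out = step_sfm(pop, random_params(rng))
            assert abs(out.density.sum() - 1.0) < 1e-12

    def test_population_collapse_signalled(self):
        pop = Population([0.5], [0.5], 0.0, [1.0])
        with pytest.raises(PopulationCollapseError):
            step_sfm(pop, SFMParams())


class TestRun:
    def test_zero_steps_records_initial_state_only(self, grid_pop):
        traj = run_sfm(grid_pop, SFMParams(), steps=0)
        assert len(traj.frame) == 1
        assert traj.frame.loc[0, "mean_T"] == pytest.approx(0.5)

    def test_neutral_case_tolerance_rises_suppression_static(self, grid_pop):
        traj = run_sfm(grid_pop, SFMParams(phi=1.0, beta=1.0), steps=200)
        assert traj.final["mean_T"] > traj.initial["mean_T"]
        assert traj.final["mean_S"] == pytest.approx(traj.initial["mean_S"], abs=1e-9)

    def test_positive_assortment_selects_against_suppression(self, grid_pop):
        traj = run_sfm(grid_pop, tuned_params("tuned_age", phi=100.0), steps=200)
        assert traj.final["mean_S"] < traj.initial["mean_S"]

    def test_suppression_marginal_exactly_invariant_when_neutral(self, grid_pop):
        # phi=1, beta=1: survival depends on T only, so the marginal
        # density distribution over S levels never moves (exact)
        traj = run_sfm(grid_pop, SFMParams(phi=1.0, beta=1.0), steps=100)
        d0 = traj.densities[0].reshape(13, 13)
        d1 = traj.densities[-1].reshape(13, 13)
        np.testing.assert_allclose(d1.sum(axis=0), d0.sum(axis=0), atol=1e-12)

    def test_tolerance_mean_monotone_over_runs(self, rng):
        for _ in range(5):
            pop = Population.trait_grid(4)
            traj = run_sfm(pop, random_params(rng, phi=float(rng.choice([1.0, 10.0]))), steps=50)
            dT = np.diff(traj.frame.mean_T.values)
            assert np.all(dT >= -1e-12)

    def test_densities_conserved_every_step(self, grid_pop):
        traj = run_sfm(grid_pop, tuned_params("tuned_age_fig", phi=10.0), steps=100)
        np.testing.assert_allclose(traj.densities.sum(axis=1), 1.0, atol=1e-12)

    def test_equilibrate_stops_early_for_single_genotype(self):
        pop = Population([0.5], [0.5], 0.8, [1.0])
        _, steps = equilibrate(pop, SFMParams(), max_steps=50)
        assert steps == 1


class TestSelectionGradient:
    @pytest.mark.parametrize("n", [1, 8])
    @pytest.mark.parametrize("phi", [1.0, 5.0, 100.0])
    def test_matches_central_finite_differences(self, rng, n, phi):
        pop = random_population(rng, k=8)
        params = random_params(rng, n=n, phi=phi)
        gT, gS = selection_gradient(pop, params)
        h = 1e-6
        for i in (0, 3, 7):
            for trait, grad in (("tolerance", gT), ("suppression", gS)):
                arrs = {
                    "tolerance": pop.tolerance.copy(),
                    "suppression": pop.suppression.copy(),
                }
                up = {k: v.copy() for k, v in arrs.items()}
                dn = {k: v.copy() for k, v in arrs.items()}
                up[trait][i] += h
                dn[trait][i] -= h
                f = lambda a: effective_survival(
                    Population(a["tolerance"], a["suppression"], pop.max_survival, pop.density),
                    params,
                )[0][i]
                fd = (f(up) - f(dn)) / (2 * h)
                assert grad[i] == pytest.approx(fd, rel=1e-6, abs=1e-10)

    def test_rare_genotype_limits(self):
        # a vanishingly rare genotype cannot move the field: its
        # suppression gradient dies, its tolerance gradient is P*s*B
        eps = 1e-9
        pop = Population([0.5, 0.5], [0.3, 0.6], 0.8, [eps, 1.0 - eps])
        params = SFMParams(phi=1.0, beta=1.0)
        gT, gS = selection_gradient(pop, params)
        assert abs(gS[0]) < 1e-8
        s_hat = 1.0 * pop.mean_suppression
        assert gT[0] == pytest.approx(0.8 * s_hat, abs=1e-6)

    def test_pairwise_suppression_weaker_than_tolerance(self):
        # severe competition, no replacement, pairwise: |dP/dS| < |dP/dT|
        pop = Population.trait_grid(13)
        params = SFMParams(alpha=1.0, rho=1.0, beta=0.0, n=1, phi=1.0)
        gT, gS = selection_gradient(pop, params)
        assert np.all(np.abs(gS) < np.abs(gT))


class TestThreshold:
    FIG5 = dict(alpha=1.0, rho=0.9, beta=0.0, n=8, phi=100.0)

    def test_undefined_without_assortativity(self, two_type_pop):
        with pytest.raises(ThresholdUndefinedError):
            threshold_density(0, two_type_pop, SFMParams(phi=1.0))

    def test_weak_suppressor_threshold_and_sign_flip(self):
        # survival 0.9, tolerance 0.8, alpha*rho = 0.9, n = 8; the focal
        # genotype suppresses less than the community average
        pop = Population([0.8, 0.8], [0.3, 0.7], 0.9, [0.5, 0.5])
        params = SFMParams(**self.FIG5)
        res = threshold_density(0, pop, params, scan_points=4000)
        assert 0.0 < res.scan < 1.0
        assert 0.0 < res.formula < 1.0
        below = _suppression_differential(0, pop, params, res.scan * 0.5)
        above = _suppression_differential(0, pop, params, min(1 - 1e-9, res.scan * 2))
        assert below * above < 0

    def test_average_suppressor_has_degenerate_threshold(self):
        pop = Population([0.8, 0.8], [0.5, 0.5], 0.9, [0.5, 0.5])
        params = SFMParams(**self.FIG5)
        res = threshold_density(0, pop, params, scan_points=500)
        assert math.isnan(res.scan)
        for d in (0.01, 0.3, 0.9):
            assert abs(_suppression_differential(0, pop, params, d)) < 1e-12


class TestInvasion:
    PARAMS = SFMParams(alpha=1.0, rho=0.9, beta=0.0, n=8, phi=100.0)

    @pytest.fixture
    def resident(self):
        pop = Population([0.8], [0.8], 0.9, [1.0])
        res, _ = equilibrate(pop, self.PARAMS)
        return res

    def _cooperator_threshold(self):
        probe = Population([0.8, 0.8], [0.2, 0.8], 0.9, [1e-6, 1.0 - 1e-6])
        return threshold_density(0, probe, self.PARAMS, scan_points=4000).scan

    def test_identical_invader_is_neutral(self, resident):
        out = invasion_test(resident, self.PARAMS, 0.8, 0.8, 1e-3, steps=100)
        assert out.outcome == "neutral"

    def test_cooperator_repelled_below_threshold(self, resident):
        d = self._cooperator_threshold() * 0.3
        out = invasion_test(resident, self.PARAMS, 0.8, 0.2, d, steps=3000)
        assert out.outcome == "repelled"

    def test_cooperator_invades_above_threshold(self, resident):
        d = self._cooperator_threshold() * 3.0
        out = invasion_test(resident, self.PARAMS, 0.8, 0.2, d, steps=3000)
        assert out.outcome == "invades"
        # positive feedback: density rises monotonically near the end
        tail = out.invader_density[-5:]
        assert np.all(np.diff(tail) > 0)


class TestEssSweep:
    def test_instant_replacement_never_favours_suppression(self):
        df = ess_sweep(np.array([0.2, 0.5, 0.8]), np.array([1.0]), phi=10.0, steps=100)
        assert set(df.label) <= {"neutral", "cooperation"}

    def test_intense_competition_low_assortment_favours_defection(self):
        df = ess_sweep(np.array([0.1]), np.array([0.0]), phi=10.0, steps=200)
        assert df.label.iloc[0] == "defection"

    def test_high_assortment_favours_cooperation_across_replacement(self):
        df = ess_sweep(np.array([0.5, 0.8]), np.array([0.0, 0.5]), phi=100.0, steps=200)
        assert (df.label == "cooperation").all()


class TestPresets:
    def test_printed_tuned_values(self):
        assert TUNED_PRESETS["tuned_age"] == {"alpharho": 0.6, "beta": 0.85}
        assert TUNED_PRESETS["tuned_age_fig"] == {"alpharho": 0.96, "beta": 0.85}
        assert TUNED_PRESETS["tuned_noage"] == {"alpharho": 0.975, "beta": 0.755}

    def test_tuned_params_apply_product_through_rho(self):
        p = tuned_params("tuned_age", phi=10.0)
        assert p.alpharho == pytest.approx(0.6)
        assert p.beta == pytest.approx(0.85)
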