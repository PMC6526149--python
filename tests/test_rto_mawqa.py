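"""Modifier-adaptation RTO: profit arithmetic, the modified
optimization, surrogate gradients, and the full loop."""

import numpy as np
import pytest

from flownmr import rto_mawqa as rto
from flownmr.rto_mawqa import (
    MAWQAConfig,
    ModifierState,
    OperatingPoint,
    ProfitParams,
    estimate_gradient_quadratic,
    feed_molar_ratio,
    nominal_optimize,
    profit,
    run_mawqa,
)


class TestProfit:
    def test_zero_product_is_pure_feed_cost(self):
        u = np.array([3.68, 6.89, 5.60])
        assert np.isclose(profit(u, 0.0), -(10000 * 3.68 + 25000 * 6.89
                                            + 12000 * 5.60))

    def test_hand_evaluated_reference_point(self):
        # revenue 450000*0.2202*500/900*16.17 = 890158.5; cost 276250
        u = np.array([3.68, 6.89, 5.60])
        assert np.isclose(profit(u, 500.0), 890158.5 - 276250.0)

    def test_homogeneous_degree_one_in_flows(self):
        u = np.array([3.0, 6.5, 5.0])
        assert np.isclose(profit(2 * u, 400.0), 2 * profit(u, 400.0))

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            profit(np.array([-1.0, 6.0, 5.0]), 100.0)


class TestNominalOptimize:
    def test_zero_modifiers_match_grid_search_in_trust_region(self):
        model = rto.nominal_model()
        u_ref = np.array([5.0, 8.5, 7.0])
        radius = 0.8
        u = nominal_optimize(model, ModifierState(), u_ref,
                             trust_radius=radius)
        # grid oracle restricted to the same trust ball
        g = np.linspace(-radius, radius, 21)
        best = -np.inf
        pp = ProfitParams()
        for d1 in g:
            for d2 in g:
                for d3 in g:
                    cand = u_ref + np.array([d1, d2, d3])
                    if np.linalg.norm(cand - u_ref) > radius:
                        continue
                    if np.any(cand < 0.5) or np.any(cand > 9.0):
                        continue
                    if 1.10 * cand[1] < 2 * 0.96 * cand[0]:
                        continue
                    best = max(best, profit(cand, model(cand), pp))
        assert profit(u, model(u), pp) >= best - 1e-6 * abs(best)

    def test_gradient_matched_quadratics_have_common_fixed_point(self):
        """With lambda equal to the exact plant-model gradient gap, the
        modified problem is first-order stationary where the plant is."""
        u_star = np.array([4.0, 8.0, 6.0])  # interior plant optimum
        H = np.diag([-3000.0, -2000.0, -2500.0])

        def plant_profit(u):
            d = u - u_star
            return 5e4 + 0.5 * d @ H @ d

        u_model_star = u_star + np.array([0.5, -0.4, 0.3])

        def model_profit(u):
            d = u - u_model_star
            return 4e4 + 0.5 * d @ H @ d

        u_ref = u_star
        g_plant = H @ (u_ref - u_star)
        g_model = H @ (u_ref - u_model_star)
        lam = g_plant - g_model
        pp = ProfitParams()

        # express the quadratic pair through a fake concentration model
        def model(u):
            base = profit(u, 0.0, pp)
            c = (model_profit(u) - base) * pp.rho_mixture / (
                pp.w[3] * pp.M_LiNDPA * u.sum())
            return c

        mods = ModifierState(epsilon=plant_profit(u_ref) - model_profit(u_ref),
                             lam=lam)
        u_next = nominal_optimize(model, mods, u_ref, pp, trust_radius=1.5)
        assert np.linalg.norm(u_next - u_star) < 1e-4

    def test_ratio_constraint_projects_onto_boundary(self):
        """An unconstrained optimum below 2:1 stoichiometry is returned
        exactly on the constraint."""
        pp = ProfitParams()

        def model(u):  # rewards aniline, penalizes LiHMDS steeply
            return 200.0 + 50.0 * u[0] - 60.0 * u[1]

        u_ref = np.array([4.0, 8.0, 6.0])
        u = nominal_optimize(model, ModifierState(), u_ref, pp,
                             trust_radius=2.0)
        ratio = feed_molar_ratio(u, pp)
        assert ratio >= 2.0 - 1e-6
        assert ratio < 2.01  # pushed down onto the boundary


def _quad_history(coef, points, noise=0.0, rng=None):
    """Operating points sampled from a known quadratic profit."""

    def f(u):
        u1, u2, u3 = u
        z = np.array([1, u1, u2, u3, u1 * u1, u2 * u2, u3 * u3,
                      u1 * u2, u1 * u3, u2 * u3])
        val = float(z @ coef)
        if noise and rng is not None:
            val += rng.normal(0.0, noise)
        return val

    return [OperatingPoint(u=np.asarray(p, float), c_LiNDPA=0.0,
                           profit_plant=f(p), profit_model=0.0, iteration=i)
            for i, p in enumerate(points)]


class TestGradientEstimation:
    COEF = np.array([10.0, 3.0, -2.0, 1.0, -0.5, -0.8, -0.3, 0.2, 0.1, -0.4])

    def grad(self, u):
        u1, u2, u3 = u
        return np.array([
            3.0 + 2 * -0.5 * u1 + 0.2 * u2 + 0.1 * u3,
            -2.0 + 2 * -0.8 * u2 + 0.2 * u1 - 0.4 * u3,
            1.0 + 2 * -0.3 * u3 + 0.1 * u1 - 0.4 * u2,
        ])

    def test_exact_on_noiseless_quadratic(self, rng):
        u0 = np.array([3.0, 6.0, 5.0])
        pts = [u0 + rng.uniform(-0.5, 0.5, 3) for _ in range(14)]
        hist = _quad_history(self.COEF, pts)
        est = estimate_gradient_quadratic(hist, u0, regression_radius=2.0)
        assert est.ok
        np.testing.assert_allclose(est.gradient, self.grad(u0), atol=1e-8)

    def test_collinear_history_requests_probes(self):
        u0 = np.array([3.0, 6.0, 5.0])
        pts = [u0 + t * np.array([1.0, 0.5, 0.2]) for t in
               np.linspace(-0.5, 0.5, 15)]
        hist = _quad_history(self.COEF, pts)
        est = estimate_gradient_quadratic(hist, u0, regression_radius=2.0)
        assert not est.ok
        assert est.probes and len(est.probes) >= 6

    def test_too_few_points_requests_probes(self):
        u0 = np.array([3.0, 6.0, 5.0])
        hist = _quad_history(self.COEF, [u0 + e for e in np.eye(3) * 0.1])
        est = estimate_gradient_quadratic(hist, u0, regression_radius=1.0)
        assert not est.ok and est.probes

    def test_noise_error_shrinks_with_more_points(self):
        """Mean gradient error over 20 seeds decreases from 12 to 60
        regression points."""
        u0 = np.array([3.0, 6.0, 5.0])
        errs = {12: [], 60: []}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            for n in errs:
                pts = [u0 + rng.uniform(-0.5, 0.5, 3) for _ in range(n)]
                hist = _quad_history(self.COEF, pts, noise=0.05, rng=rng)
                est = estimate_gradient_quadratic(
                    hist, u0, regression_radius=2.0,
                    config=MAWQAConfig(max_history=100))
                errs[n].append(np.linalg.norm(est.gradient - self.grad(u0)))
        assert np.mean(errs[60]) < np.mean(errs[12])


class TestRunMAWQA:
    def test_fixed_point_when_plant_equals_model(self):
        """Starting at the model optimum with plant == model, the loop
        terminates quickly without leaving the point."""
        model = rto.nominal_model()
        u_opt, _ = rto.grid_optimum(lambda u: model(u), n=51)
        traj = run_mawqa(lambda u: model(u), model, u_opt,
                         config=MAWQAConfig(max_iter=6))
        iters = [p for p in traj if p.phase == "iterate"]
        pp = ProfitParams()
        p_start = profit(u_opt, model(u_opt), pp)
        assert iters[-1].profit_plant >= p_start - 1e-6 * abs(p_start)
        assert np.linalg.norm(iters[-1].u - u_opt) < 0.5

    def test_converges_to_true_plant_optimum_under_mismatch(self):
        plant = rto.simulated_plant()  # noiseless measurement mode
        model = rto.nominal_model()
        traj = run_mawqa(plant, model, np.array([3.58, 3.58, 3.58]))
        final = [p for p in traj if p.phase == "iterate"][-1]
        _, p_star = rto.grid_optimum(rto.simulated_plant(), n=51)
        assert final.profit_plant >= p_star * (1 - 0.01)
        assert feed_molar_ratio(final.u) >= 2.0 - 1e-6

    def test_reconverges_after_feed_batch_change(self):
        plant = rto.simulated_plant()
        model = rto.nominal_model()
        traj = run_mawqa(
            plant, model, np.array([3.58, 3.58, 3.58]),
            disturbance_iteration=15,
            on_disturbance=lambda: plant.set_feed_concs({"LiHMDS": 1.00}),
            config=MAWQAConfig(max_iter=45))
        final = [p for p in traj if p.phase == "iterate"][-1]
        _, p_star = rto.grid_optimum(
            rto.simulated_plant(feed_concs={"LiHMDS": 1.00}), n=51)
        assert final.profit_plant >= p_star * (1 - 0.01)

    def test_profit_never_ends_below_start(self):
        """Across noisy seeds the final measured profit beats the
        start-up point."""
        model = rto.nominal_model()
        for seed in range(5):
            plant = rto.simulated_plant(noise_sd=3.0, seed=seed)
            traj = run_mawqa(plant, model, np.array([3.58, 3.58, 3.58]),
                             config=MAWQAConfig(max_iter=20))
            iters = [p for p in traj if p.phase == "iterate"]
            assert iters[-1].profit_plant > iters[0].profit_plant

    def test_every_visited_point_respects_box_bounds(self):
        plant = rto.simulated_plant()
        model = rto.nominal_model()
        cfg = MAWQAConfig(max_iter=10)
        traj = run_mawqa(plant, model, np.array([3.58, 3.58, 3.58]),
                         config=cfg)
        for p in traj:
            assert np.all(p.u >= cfg.bounds[0] - 1e-9)
            assert np.all(p.u <= cfg.bounds[1] + 1e-9)
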