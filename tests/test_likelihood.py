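import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal

import jointlgm as jl
from jointlgm.likelihood import (IntervalGrid, MarginalEngine, SubjectRecord,
                                 conditional_joint_loglik, marginal_loglik,
                                 split_survival, survival_loglik_shared_re,
                                 survival_loglik_trajectory)
from jointlgm.parameters import (GrowthParameters, PiecewiseConstantHazard,
                                 SurvivalParameters)
from jointlgm.simulate import simulate_cohort, table4_asbi5_config
from jointlgm.trajectories import basis_row, get_spec

GRID = IntervalGrid.cycles()


class TestSplitSurvival:
    def test_event_mid_third_interval(self):
        sp = split_survival(1.5, 0, GRID)
        np.testing.assert_allclose(sp.lengths, [0.7, 0.7, 0.1])
        np.testing.assert_array_equal(sp.indicators, [1, 1, 0])
        assert sp.k_event == 2

    def test_short_censored_time(self):
        sp = split_survival(0.3, 1, GRID)
        np.testing.assert_allclose(sp.lengths, [0.3])
        np.testing.assert_array_equal(sp.indicators, [1])

    def test_boundary_assigned_to_lower_interval(self):
        sp = split_survival(1.4, 0, GRID)
        np.testing.assert_allclose(sp.lengths, [0.7, 0.7])
        np.testing.assert_array_equal(sp.indicators, [1, 0])

    def test_time_beyond_grid_uses_last_open_interval(self):
        sp = split_survival(6.0, 0, GRID)
        assert sp.k_event == 7
        assert sp.lengths[-1] == pytest.approx(6.0 - 4.9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            split_survival(0.0, 0, GRID)
        with pytest.raises(ValueError):
            split_survival(1.0, 2, GRID)

    def test_conservation_many_random_cases(self):
        # sum of non-missing interval lengths reproduces T exactly
        rng = np.random.default_rng(77)
        for _ in range(10_000):
            nb = rng.integers(1, 9)
            breaks = np.cumsum(rng.uniform(0.05, 1.5, nb))
            grid = IntervalGrid(breaks)
            T = float(rng.uniform(1e-3, breaks[-1] * 1.5))
            delta = int(rng.integers(0, 2))
            sp = split_survival(T, delta, grid)
            assert sp.lengths.sum() == pytest.approx(T, abs=1e-12, rel=0)
            assert (sp.indicators[:-1] == 1).all()
            assert sp.indicators[-1] == delta


BASE = PiecewiseConstantHazard([1.0], [0.1, 0.3])


class TestSharedREDensity:
    def test_hazard_reduces_to_baseline(self):
        p = SurvivalParameters([0.0], [0.0, 0.0], BASE)
        assert jl.hazard_shared_re(0.5, [5.0, 1.0], [0.0], p) == 0.1

    def test_log2_shift_doubles_hazard(self):
        p = SurvivalParameters([0.0], [np.log(2), 0.0], BASE)
        for t in (0.2, 0.9, 1.5, 3.0):
            assert jl.hazard_shared_re(t, [1.0, 0.0], [0.0], p) == \
                pytest.approx(2 * BASE.hazard(t))

    def test_hazard_log_identity(self, rng):
        p = SurvivalParameters([-0.4], [0.05, -0.2], BASE)
        for _ in range(100):
            t = rng.uniform(0, 4)
            b = rng.normal(0, 2, 2)
            z = rng.integers(0, 2)
            expected = np.exp(np.log(BASE.hazard(t)) - 0.4 * z
                              + 0.05 * b[0] - 0.2 * b[1])
            assert jl.hazard_shared_re(t, b, [z], p) == pytest.approx(expected)

    def test_unit_hazard_event_density(self):
        p = SurvivalParameters([0.0], [0.0],
                               PiecewiseConstantHazard([1.0], [1.0, 1.0]))
        assert survival_loglik_shared_re(0.5, 0, [0.0], [0.0], p) == \
            pytest.approx(-0.5)

    def test_censored_density_is_minus_cumhaz(self, rng):
        p = SurvivalParameters([0.3], [0.1], BASE)
        for _ in range(20):
            T = rng.uniform(0.1, 4)
            b = rng.normal(0, 3, 1)
            ll = survival_loglik_shared_re(T, 1, b, [1.0], p)
            assert ll <= 0
            assert ll == pytest.approx(
                -float(BASE.cumulative(np.array(T))) * np.exp(0.3 + 0.1 * b[0]))

    def test_piecewise_cumhaz_matches_quadrature(self):
        p = SurvivalParameters([np.log(2)], [0.0], BASE)
        ll = survival_loglik_shared_re(1.5, 0, [0.0], [1.0], p)
        H, _ = quad(lambda s: 2 * BASE.hazard(s), 0, 1.5, points=[1.0])
        assert ll == pytest.approx(np.log(2 * 0.3) - H, abs=1e-10)


class TestTrajectoryDensity:
    spec = get_spec("q_s")

    def test_coincides_with_shared_re_at_gamma_zero(self, rng):
        for _ in range(20):
            T = rng.uniform(0.1, 6)
            delta = int(rng.integers(0, 2))
            b = rng.normal(0, 5, 3)
            pt = SurvivalParameters([-0.2], [0.0], BASE)
            ps = SurvivalParameters([-0.2], [0.0, 0.0, 0.0], BASE)
            lt = survival_loglik_trajectory(split_survival(T, delta, GRID), b,
                                            [1.0], pt, self.spec, GRID)
            ls = survival_loglik_shared_re(T, delta, b, [1.0], ps)
            assert lt == pytest.approx(ls, abs=1e-12)

    def test_flat_trajectory_equals_shared_re_on_intercept(self, rng):
        gamma = 0.04
        c = 22.0
        pt = SurvivalParameters([0.1], [gamma], BASE)
        ps = SurvivalParameters([0.1], [gamma, 0.0, 0.0], BASE)
        for T, delta in [(0.5, 0), (2.3, 1), (5.5, 0)]:
            lt = survival_loglik_trajectory(split_survival(T, delta, GRID),
                                            [c, 0.0, 0.0], [1.0], pt,
                                            self.spec, GRID)
            ls = survival_loglik_shared_re(T, delta, [c, 0.0, 0.0], [1.0], ps)
            assert lt == pytest.approx(ls, abs=1e-12)

    def test_matches_interval_enumeration_oracle(self):
        # independent re-implementation: enumerate intervals, integrate the
        # baseline piecewise-analytically under the frozen multiplier
        b = np.array([28.8, 5.72, -1.12])
        gamma, alpha = 0.03, -0.4
        p = SurvivalParameters([alpha], [gamma], BASE)
        T = 2.0
        ll = survival_loglik_trajectory(split_survival(T, 0, GRID), b, [1.0],
                                        p, self.spec, GRID)
        edges = GRID.left_endpoints
        total = 0.0
        k = 0
        while edges[k + 1] < T:
            k += 1
        for j in range(k + 1):
            lo = edges[j]
            hi = min(T, edges[j + 1]) if j + 1 < len(edges) else T
            eta = float(basis_row(self.spec, lo) @ b)
            Hj = float(BASE.cumulative(np.array(hi)) -
                       BASE.cumulative(np.array(lo)))
            total -= np.exp(alpha + gamma * eta) * Hj
        eta_ev = float(basis_row(self.spec, edges[k]) @ b)
        total += np.log(BASE.hazard(T)) + alpha + gamma * eta_ev
        assert ll == pytest.approx(total, abs=1e-10)

    def test_grid_refinement_converges_to_continuous_link(self):
        # the stepwise predictor tends to gamma * eta(t) as the step shrinks
        b = np.array([25.0, 3.0, -0.6])
        gamma, alpha = 0.03, -0.1
        base = PiecewiseConstantHazard([1.3], [0.2, 0.35])
        p = SurvivalParameters([alpha], [gamma], base)
        T = 2.0

        def hazard(s):
            eta = float(basis_row(self.spec, s) @ b)
            return base.hazard(s) * np.exp(alpha + gamma * eta)

        H, _ = quad(hazard, 0, T, limit=400, points=[1.3])
        target = np.log(hazard(T)) - H
        errs = []
        for factor in (1, 10, 100):
            grid = IntervalGrid.cycles().refine(factor)
            ll = survival_loglik_trajectory(split_survival(T, 0, grid), b,
                                            [1.0], p, self.spec, grid)
            errs.append(abs(ll - target))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3


class TestConditionalJoint:
    spec = get_spec("q_s")
    growth = GrowthParameters([[25.0, 0.0], [2.0, -1.0], [-0.3, 0.0]],
                              np.diag([100.0, 1.0, 0.09]), 25.0)
    surv = SurvivalParameters([-0.4], [0.02, 0.1, 0.3], BASE)

    def test_no_observations_reduces_to_survival_plus_prior(self):
        sub = SubjectRecord(0, [1, 0], [0], [], [], T=1.2, delta=0)
        b = np.array([20.0, 1.0, -0.2])
        val = conditional_joint_loglik(sub, b, self.growth, self.surv,
                                       "shared_re", self.spec)
        expected = survival_loglik_shared_re(1.2, 0, b, [0], self.surv) + \
            multivariate_normal.logpdf(b, self.growth.beta @ [1, 0],
                                       self.growth.Sigma)
        assert val == pytest.approx(expected, abs=1e-12)

    def test_exact_observation_contributes_normalizing_constant(self):
        b = np.array([20.0, 1.0, -0.2])
        t = np.array([1.0])
        y = basis_row(self.spec, t) @ b
        sub = SubjectRecord(0, [1, 0], [0], t, y, T=1.2, delta=1)
        with_obs = conditional_joint_loglik(sub, b, self.growth, self.surv,
                                            "shared_re", self.spec)
        sub0 = SubjectRecord(0, [1, 0], [0], [], [], T=1.2, delta=1)
        without = conditional_joint_loglik(sub0, b, self.growth, self.surv,
                                           "shared_re", self.spec)
        assert with_obs - without == pytest.approx(
            -0.5 * np.log(2 * np.pi * self.growth.sigma2), abs=1e-12)

    def test_matches_naive_per_term_summation(self, rng):
        t = np.sort(rng.uniform(0.2, 4.0, 5))
        y = 25 + rng.normal(0, 6, 5)
        sub = SubjectRecord(0, [1, 1], [1], t, y, T=3.1, delta=0)
        b = rng.normal([25, 1, -0.3], 1.0)
        val = conditional_joint_loglik(sub, b, self.growth, self.surv,
                                       "shared_re", self.spec)
        naive = survival_loglik_shared_re(3.1, 0, b, [1], self.surv)
        for tj, yj in zip(t, y):
            mu = float(basis_row(self.spec, tj) @ b)
            naive += -0.5 * np.log(2 * np.pi * self.growth.sigma2) \
                - (yj - mu) ** 2 / (2 * self.growth.sigma2)
        naive += multivariate_normal.logpdf(b, self.growth.beta @ [1, 1],
                                            self.growth.Sigma)
        assert val == pytest.approx(naive, abs=1e-12)


class TestMarginal:
    def _subjects(self, n=8, seed=1, r=2):
        rng = np.random.default_rng(seed)
        subs = []
        for i in range(n):
            t = np.sort(rng.uniform(0.2, 4.0, rng.integers(1, 6)))
            y = 22 + rng.normal(0, 6, t.size)
            subs.append(SubjectRecord(i, [1, i % 2], [i % 2], t, y,
                                      T=float(rng.uniform(0.3, 5)),
                                      delta=int(rng.uniform() < 0.3)))
        return subs

    growth2 = GrowthParameters([[20.0, 0.0], [2.0, -1.0]],
                               [[25.0, 1.0], [1.0, 4.0]], 16.0)
    surv2 = SurvivalParameters([-0.3], [0.03, 0.2],
                               PiecewiseConstantHazard([1.0, 2.0],
                                                       [0.1, 0.2, 0.15]))

    def test_single_subject_matches_dense_grid(self):
        spec = get_spec("l_s")
        sub = SubjectRecord(0, [1, 1], [1], [0.3, 0.9, 1.6],
                            [24.0, 21.0, 26.0], T=2.3, delta=0)
        ll = marginal_loglik([sub], self.growth2, self.surv2, "shared_re",
                             spec, quad_nodes=15)
        b0 = np.linspace(-25, 65, 901)
        b1 = np.linspace(-20, 22, 901)
        B = np.stack(np.meshgrid(b0, b1, indexing="ij"), axis=-1)
        F = basis_row(spec, np.array(sub.t))
        Om = np.linalg.inv(self.growth2.Sigma)
        eta = np.einsum("jr,xyr->xyj", F, B)
        meas = -1.5 * np.log(2 * np.pi * 16.0) \
            - np.sum((np.array(sub.y) - eta) ** 2, -1) / 32.0
        d = B - self.growth2.beta @ [1, 1]
        prior = -np.log(2 * np.pi) \
            - 0.5 * np.log(np.linalg.det(self.growth2.Sigma)) \
            - 0.5 * np.einsum("xyr,rs,xys->xy", d, Om, d)
        u = -0.3 + B @ np.array([0.03, 0.2])
        H0T = float(self.surv2.baseline.cumulative(np.array(2.3)))
        surv = np.log(self.surv2.baseline.hazard(2.3)) + u - np.exp(u) * H0T
        val = np.trapezoid(np.trapezoid(np.exp(meas + prior + surv), b1,
                                        axis=1), b0)
        assert ll == pytest.approx(np.log(val), abs=1e-5)

    def test_quadrature_node_convergence(self):
        spec = get_spec("l_s")
        subs = self._subjects()
        vals = {}
        for nodes in (5, 9, 15):
            vals[nodes] = marginal_loglik(subs, self.growth2, self.surv2,
                                          "shared_re", spec, quad_nodes=nodes)
        assert abs(vals[9] - vals[15]) < abs(vals[5] - vals[9]) + 1e-12
        assert abs(vals[9] - vals[15]) < 1e-6

    def test_order_invariance_and_additivity(self):
        spec = get_spec("l_s")
        subs = self._subjects(n=10)
        total = marginal_loglik(subs, self.growth2, self.surv2, "shared_re",
                                spec)
        rev = marginal_loglik(subs[::-1], self.growth2, self.surv2,
                              "shared_re", spec)
        assert total == pytest.approx(rev, abs=1e-9)
        part = sum(marginal_loglik([s], self.growth2, self.surv2, "shared_re",
                                   spec) for s in subs)
        assert total == pytest.approx(part, abs=1e-8)

    def test_factorizes_at_gamma_zero(self):
        # joint marginal = Gaussian-marginal longitudinal + piecewise-
        # exponential survival, each by an independent closed form
        cfg = table4_asbi5_config(n_subjects=50, seed=3)
        cfg.survival.gamma = np.zeros(3)
        co = simulate_cohort(cfg)
        jm = jl.JointModel.from_cohort(co, spec="q_s", link="shared_re")
        g, s = cfg.growth, cfg.survival
        ll = jm.loglike(jm.packer.pack(g, s))
        closed = 0.0
        surv0 = SurvivalParameters(s.alpha, np.zeros(3), s.baseline)
        for sub in jm.subjects:
            if len(sub.t):
                F = basis_row(jm.spec, sub.t)
                closed += multivariate_normal.logpdf(
                    sub.y, F @ (g.beta @ sub.X),
                    F @ g.Sigma @ F.T + g.sigma2 * np.eye(len(sub.t)))
            closed += survival_loglik_shared_re(sub.T, sub.delta,
                                                np.zeros(3), sub.X_s, surv0)
        assert ll == pytest.approx(closed, abs=1e-6)

    def test_minimum_node_count_enforced(self):
        with pytest.raises(ValueError):
            MarginalEngine(self._subjects(2), get_spec("l_s"), "shared_re",
                           quad_nodes=2)

    def test_unknown_link_rejected(self):
        with pytest.raises(ValueError):
            MarginalEngine(self._subjects(2), get_spec("l_s"), "spline")
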