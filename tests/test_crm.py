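import numpy as np
import pytest

from envcomplexity.crm import (
    ByproductTensor,
    CommunityState,
    CRMParams,
    UptakeMatrix,
    crm_rhs,
    generate_byproduct_tensor,
    generate_uptake_matrix,
    initial_resources,
    integrate_batch,
    simulate_passaged,
    simulate_passaged_batch,
)
from envcomplexity.env_design import Environment


def single_species_system(c=5e-3, m=0.0):
    up = UptakeMatrix(np.array([[c]]), 1, 0, np.array([1.0]), 1e-2)
    byp = ByproductTensor(np.zeros((1, 0, 1)))
    params = CRMParams(m=m)
    return up, byp, params


class TestGenerators:
    def test_theta_zero_gives_empty_matrix(self, rng):
        up = generate_uptake_matrix(5, 8, 2, 0.0, rng=rng)
        assert np.all(up.C == 0)

    def test_theta_one_gives_full_matrix(self, rng):
        up = generate_uptake_matrix(5, 8, 2, 1.0, uptake_scale=2e-3, rng=rng)
        assert np.all(up.C > 0)
        assert np.all(up.C <= 2e-3)

    def test_nonzero_count_matches_binomial(self):
        # S=13, M=32+0, theta=0.5: mean 208, sd ~10.2 -> stay within 5 sd
        up = generate_uptake_matrix(13, 32, 0, 0.5, rng=np.random.default_rng(7))
        count = int((up.C > 0).sum())
        assert abs(count - 208) < 5 * 10.2

    def test_theta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_uptake_matrix(2, 4, 0, 1.5)

    def test_byproduct_probability_extremes(self, rng):
        empty = generate_byproduct_tensor(3, 4, 2, 0.0, rng)
        assert np.all(empty.D == 0)
        full = generate_byproduct_tensor(3, 5, 4, 1.0, rng)
        assert np.allclose(full.D, 0.25)

    def test_single_byproduct_columns_are_indicator(self, rng):
        t = generate_byproduct_tensor(4, 10, 1, 0.25, rng)
        assert set(np.unique(t.D)) <= {0.0, 1.0}

    def test_column_sums_mass_conserving(self, rng):
        t = generate_byproduct_tensor(6, 12, 5, 0.4, rng)
        sums = t.D.sum(axis=1)
        assert np.all(np.isclose(sums, 0.0) | np.isclose(sums, 1.0))

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            generate_byproduct_tensor(2, 3, 1, 1.2)


class TestRHS:
    def test_monod_half_velocity(self):
        # at R = k the uptake factor is exactly 1/2
        up, byp, params = single_species_system(c=1.0, m=0.0)
        state = CommunityState(np.array([1.0]), np.array([params.k]))
        dN, dR = crm_rhs(state, up, byp, params)
        w, l = params.w, params.l
        assert dN[0] == pytest.approx(w * (1 - l) * 0.5)
        assert dR[0] == pytest.approx(-0.5)

    def test_starvation_is_pure_decay(self):
        up, byp, _ = single_species_system()
        params = CRMParams(m=0.3)
        state = CommunityState(np.array([2.0]), np.array([0.0]))
        dN, dR = crm_rhs(state, up, byp, params)
        assert dN[0] == pytest.approx(-params.g * 0.3 * 2.0)
        assert dR[0] == 0.0

    def test_growth_consumption_ratio(self):
        # dN/dR = -g w (1-l) pointwise for one species, one resource, m=0
        up, byp, params = single_species_system(m=0.0)
        state = CommunityState(np.array([1e6]), np.array([0.7]))
        dN, dR = crm_rhs(state, up, byp, params)
        assert dN[0] / dR[0] == pytest.approx(-params.w * (1 - params.l))

    def test_dimension_mismatch_rejected(self):
        up, byp, params = single_species_system()
        state = CommunityState(np.array([1.0, 2.0]), np.array([0.5]))
        with pytest.raises(ValueError):
            crm_rhs(state, up, byp, params)


class TestIntegration:
    def test_zero_duration_returns_initial_state(self):
        up, byp, params = single_species_system()
        s0 = CommunityState(np.array([5.0]), np.array([1.5]))
        traj = integrate_batch(s0, 0.0, up, byp, params)
        assert traj[-1].t == 0.0
        assert np.array_equal(traj[-1].N, s0.N)

    def test_conservation_law(self):
        # Delta N = g w (1-l) Delta R for one species/resource, m=0
        up, byp, params = single_species_system(m=0.0)
        s0 = CommunityState(np.array([6e6]), np.array([1.5]))
        traj = integrate_batch(s0, 48.0, up, byp, params)
        end = traj[-1]
        dN = end.N[0] - s0.N[0]
        dR = s0.R[0] - end.R[0]
        expected = params.g * params.w * (1 - params.l) * dR
        assert dN == pytest.approx(expected, rel=1e-6)

    def test_no_uptake_is_static(self):
        up = UptakeMatrix(np.zeros((2, 3)), 3, 0, np.zeros(2), 1e-2)
        byp = ByproductTensor(np.zeros((2, 0, 3)))
        params = CRMParams(m=0.0)
        s0 = CommunityState(np.array([1e6, 2e6]), np.array([0.5, 0.5, 0.5]))
        end = integrate_batch(s0, 48.0, up, byp, params)[-1]
        assert np.array_equal(end.N, s0.N)
        assert np.array_equal(end.R, s0.R)

    def test_nonnegativity_and_monotone_growth(self, rng):
        up = generate_uptake_matrix(4, 6, 2, 0.7, rng=rng)
        byp = generate_byproduct_tensor(4, 6, 2, 0.25, rng=rng)
        params = CRMParams(m=0.0)
        s0 = CommunityState(np.full(4, 1e6), initial_resources(
            Environment("e", {i: 0.25 for i in range(6)}), 6, 2))
        traj = integrate_batch(s0, 24.0, up, byp, params, record_every=100)
        prev = s0.N
        for state in traj:
            assert np.all(state.N >= 0) and np.all(state.R >= 0)
            assert np.all(state.N >= prev - 1e-9)  # m=0: nondecreasing
            prev = state.N

    def test_step_halving_robustness(self, rng):
        up = generate_uptake_matrix(5, 8, 3, 0.5, rng=rng)
        byp = generate_byproduct_tensor(5, 8, 3, 0.25, rng=rng)
        env = Environment("e", {i: 1.5 / 8 for i in range(8)})
        ends = []
        for dt in (0.01, 0.005):
            r = simulate_passaged(env, up, byp, CRMParams(dt=dt, n_passages=2))
            ends.append(r.endpoint.N.sum())
        assert abs(ends[0] - ends[1]) / ends[1] < 1e-3


class TestPassaging:
    def test_single_batch_no_dilution_matches_integrate(self):
        up, byp, params = single_species_system(m=0.0)
        params = CRMParams(m=0.0, n_passages=1, dilution_factor=1.0)
        env = Environment("1-1", {0: 1.5})
        res = simulate_passaged(env, up, byp, params)
        s0 = CommunityState(np.array([params.N0]), np.array([1.5]))
        direct = integrate_batch(s0, params.passage_interval, up, byp, params)[-1]
        assert res.endpoint.N[0] == pytest.approx(direct.N[0], rel=1e-12)

    def test_washout_of_nonconsumer(self):
        # species that cannot eat anything decays below the dilution bound
        C = np.array([[5e-3], [0.0]])
        up = UptakeMatrix(C, 1, 0, np.array([1.0, 0.0]), 1e-2)
        byp = ByproductTensor(np.zeros((2, 0, 1)))
        params = CRMParams(m=0.1)
        env = Environment("1-1", {0: 1.5})
        res = simulate_passaged(env, up, byp, params)
        bound = params.N0 * params.dilution_factor ** (params.n_passages - 1)
        assert res.endpoint.N[1] < bound

    def test_energy_bound_on_batch_yield(self, rng):
        # biomass gain in a batch cannot exceed g * max(w) * total resource
        up = generate_uptake_matrix(6, 8, 3, 0.8, rng=rng)
        byp = generate_byproduct_tensor(6, 8, 3, 0.25, rng=rng)
        params = CRMParams(m=0.0, n_passages=1)
        env = Environment("e", {i: 1.5 / 8 for i in range(8)})
        res = simulate_passaged(env, up, byp, params)
        gain = res.endpoint.N.sum() - 6 * params.N0
        assert gain <= params.g * params.w * 1.5

    def test_batch_engine_matches_single_env_path(self, rng):
        up = generate_uptake_matrix(4, 6, 2, 0.6, rng=rng)
        byp = generate_byproduct_tensor(4, 6, 2, 0.25, rng=rng)
        params = CRMParams(n_passages=3)
        envs = [
            Environment("a", {0: 1.5}),
            Environment("b", {i: 0.25 for i in range(6)}),
        ]
        R0 = np.stack([initial_resources(e, 6, 0)[:6] for e in envs])
        N_end, yields = simulate_passaged_batch(R0, up, byp, params)
        for j, env in enumerate(envs):
            ref = simulate_passaged(env, up, byp, params)
            np.testing.assert_allclose(N_end[j], ref.endpoint.N, rtol=1e-10)
            assert yields[j] == pytest.approx(ref.yield_, rel=1e-10)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"l": 1.2},
            {"dt": 0.0},
            {"dilution_factor": 0.0},
            {"m": -0.1},
            {"N0": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CRMParams(**kwargs)
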