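import numpy as np
import pytest

from capdyn.control import (
    ControlTask,
    exit_enter_energies,
    normalize_adjacency,
    solve_optimal_control,
    transition_energy_matrix,
)
from capdyn.datatypes import ValidationError
from capdyn.synthetic import generate_connectome, generate_state_patterns

from _oracles import control_energy_oracle


class TestNormalizeAdjacency:
    def test_two_node_closed_form(self):
        w = 3.0
        a = np.array([[0.0, w], [w, 0.0]])
        system = normalize_adjacency(a, c=1.0)
        eigs = np.sort(np.linalg.eigvalsh(system.a_norm))
        np.testing.assert_allclose(
            eigs, [-w / (w + 1) - 1, w / (w + 1) - 1], atol=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_always_stable(self, seed):
        conn = generate_connectome(20, seed=seed)
        system = normalize_adjacency(conn)
        assert np.max(np.linalg.eigvalsh(system.a_norm)) < 0
        assert np.min(np.linalg.eigvalsh(system.a_norm)) >= -2.0

    def test_ratio_form_scale_identity(self):
        # rescaling the weights and the offset together leaves the
        # stabilized system unchanged (the normalization is a ratio)
        rng = np.random.default_rng(3)
        w = rng.random((6, 6))
        w = w + w.T
        np.fill_diagonal(w, 0.0)
        a1 = normalize_adjacency(w, c=1.0).a_norm
        a2 = normalize_adjacency(10.0 * w, c=10.0).a_norm
        np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            normalize_adjacency(np.zeros((4, 4)))


class TestOptimalControl:
    def test_zero_boundary_states_cost_nothing(self):
        system = normalize_adjacency(generate_connectome(10, seed=0))
        res = solve_optimal_control(
            system, ControlTask(x0=np.zeros(10), xf=np.zeros(10))
        )
        assert res.total_energy == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(res.trajectory, 0.0, atol=1e-12)

    def test_scalar_system_matches_oracle(self):
        a = np.array([[-1.0]])
        res = solve_optimal_control(
            a, ControlTask(x0=np.array([0.0]), xf=np.array([1.0]),
                           n_time_steps=2001)
        )
        oracle = control_energy_oracle(a, [0.0], [1.0], n_segments=2000)
        assert abs(res.total_energy - oracle) / oracle < 1e-3

    @pytest.mark.parametrize("seed", range(6))
    def test_three_node_systems_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.random((3, 3))
        w = w + w.T
        np.fill_diagonal(w, 0.0)
        system = normalize_adjacency(w)
        x0, xf = rng.normal(size=3), rng.normal(size=3)
        res = solve_optimal_control(
            system, ControlTask(x0=x0, xf=xf, n_time_steps=1001)
        )
        oracle = control_energy_oracle(system.a_norm, x0, xf, n_segments=800)
        assert abs(res.total_energy - oracle) / oracle < 0.005

    def test_total_equals_sum_of_nodal(self):
        system = normalize_adjacency(generate_connectome(12, seed=1))
        rng = np.random.default_rng(2)
        res = solve_optimal_control(
            system, ControlTask(x0=rng.normal(size=12), xf=rng.normal(size=12))
        )
        assert res.total_energy == pytest.approx(res.nodal_energy.sum(), rel=1e-12)
        assert np.all(res.nodal_energy >= 0)

    def test_energy_converged_in_time_steps(self):
        system = normalize_adjacency(generate_connectome(15, seed=3))
        rng = np.random.default_rng(4)
        x0, xf = rng.normal(size=15), rng.normal(size=15)
        e1 = solve_optimal_control(
            system, ControlTask(x0=x0, xf=xf, n_time_steps=1001)
        ).total_energy
        e2 = solve_optimal_control(
            system, ControlTask(x0=x0, xf=xf, n_time_steps=2001)
        ).total_energy
        assert abs(e1 - e2) / e2 < 1e-4

    def test_minimum_energy_control_invariant_to_rho(self):
        # with no state cost the optimum is the minimum-energy control,
        # whose energy does not depend on the control weight
        system = normalize_adjacency(generate_connectome(8, seed=5))
        rng = np.random.default_rng(6)
        x0, xf = rng.normal(size=8), rng.normal(size=8)
        s0 = np.zeros((8, 8))
        e1 = solve_optimal_control(
            system, ControlTask(x0=x0, xf=xf, rho=1.0, state_cost_S=s0)
        ).total_energy
        e2 = solve_optimal_control(
            system, ControlTask(x0=x0, xf=xf, rho=2.0, state_cost_S=s0)
        ).total_energy
        assert e1 == pytest.approx(e2, rel=1e-6)

    def test_invalid_tasks_rejected(self):
        with pytest.raises(ValidationError):
            ControlTask(x0=np.zeros(3), xf=np.zeros(3), rho=0.0)
        with pytest.raises(ValidationError):
            ControlTask(x0=np.zeros(3), xf=np.zeros(3), n_time_steps=1)
        with pytest.raises(ValidationError):
            ControlTask(x0=np.array([np.inf]), xf=np.zeros(1))
        system = normalize_adjacency(generate_connectome(5, seed=0))
        with pytest.raises(ValidationError, match="dimension"):
            solve_optimal_control(
                system, ControlTask(x0=np.zeros(4), xf=np.zeros(4))
            )


@pytest.fixture(scope="module")
def energies():
    conn = generate_connectome(30, seed=7)
    centroids = generate_state_patterns(4, 30, seed=8)
    totals, nodal = transition_energy_matrix(conn, centroids, n_time_steps=501)
    return totals, nodal


class TestTransitionEnergies:

    def test_self_maintenance_is_positive(self, energies):
        totals, _ = energies
        assert np.all(np.diag(totals) > 0)  # drift must be opposed

    def test_energy_matrix_is_asymmetric(self, energies):
        totals, _ = energies
        off = np.abs(totals - totals.T)[~np.eye(4, dtype=bool)]
        assert np.max(off) > 1e-6

    def test_nodal_consistency(self, energies):
        totals, nodal = energies
        np.testing.assert_allclose(nodal.sum(axis=2), totals, rtol=1e-9)

    def test_state_dimension_mismatch_rejected(self):
        conn = generate_connectome(10, seed=0)
        with pytest.raises(ValidationError):
            transition_energy_matrix(conn, np.zeros((2, 9)))


class TestEnergyLandscape:
    def test_two_state_classification(self):
        e = np.array([[np.nan, 10.0], [4.0, np.nan]])
        land = exit_enter_energies(e)
        assert land.exit_energy[0] == pytest.approx(10.0)
        assert land.enter_energy[0] == pytest.approx(4.0)
        assert land.classification[0] == "sink-like"
        assert land.classification[1] == "source-like"

    def test_symmetric_matrix_degenerate(self):
        e = np.array([
            [0.0, 5.0, 7.0],
            [5.0, 0.0, 6.0],
            [7.0, 6.0, 0.0],
        ])
        land = exit_enter_energies(e)
        assert land.degenerate
        np.testing.assert_allclose(land.exit_energy, land.enter_energy)

    def test_depth_rank_orders_by_mean_energy(self):
        e = np.array([
            [0.0, 1.0, 1.0],
            [9.0, 0.0, 9.0],
            [5.0, 5.0, 0.0],
        ])
        land = exit_enter_energies(e)
        mean_e = (land.exit_energy + land.enter_energy) / 2
        assert np.array_equal(np.argsort(land.depth_rank), np.argsort(mean_e))

    def test_missing_entries_flagged(self):
        e = np.array([[np.nan, np.nan, 3.0],
                      [2.0, np.nan, 4.0],
                      [1.0, 5.0, np.nan]])
        land = exit_enter_energies(e)
        assert land.has_missing
        assert land.exit_energy[0] == pytest.approx(3.0)
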