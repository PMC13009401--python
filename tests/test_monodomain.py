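"""FVM operators, PMJ exchange, and the operator-splitting time loop."""

import numpy as np
import pytest
import scipy.sparse as sp

from conftest import make_cable_config, make_wedge_config
from purkmyo.ionic import IonicModel, Rates
from purkmyo.mesh import (
    PMJMap,
    PurkinjeNetwork,
    build_cuboid_grid,
    build_purkinje_cable,
    build_purkinje_tree,
    map_pmjs,
)
from purkmyo.monodomain import (
    CoupledProblem,
    CoupledState,
    advance_step,
    assemble_myocardium,
    assemble_purkinje,
    compute_pmj_currents,
    run_simulation,
    setup_problem,
)

BETA, CM, DT = 1400.0, 1.0, 0.02


class NullReaction(IonicModel):
    """Pure-diffusion surrogate: I_ion = 0, single state."""

    name = "null"
    n_states = 1
    gating_indices = ()

    def rest_state(self):
        return np.array([-85.0])

    def rates(self, states):
        n = states.shape[0]
        return Rates(np.zeros(n), np.zeros_like(states),
                     np.zeros((n, 0)), np.zeros((n, 0)))


def seven_point_oracle(grid, beta, cm, dt):
    """Independent 7-point anisotropic Laplacian for axis-aligned fibres."""
    n = grid.n_volumes
    h = grid.h
    lookup = {tuple(ijk): r for r, ijk in enumerate(map(tuple, grid.indices))}
    K = np.zeros((n, n))
    for r, ijk in enumerate(grid.indices):
        for a in range(3):
            step = np.zeros(3, dtype=int)
            step[a] = 1
            nb = lookup.get(tuple(ijk + step))
            if nb is None:
                continue
            g = 0.5 * (grid.sigmas[r, a] + grid.sigmas[nb, a]) * h
            K[r, r] += g
            K[nb, nb] += g
            K[r, nb] -= g
            K[nb, r] -= g
    return K + np.diag(np.full(n, h ** 3 * beta * cm / dt))


class TestMyocardiumAssembly:
    def test_diffusion_annihilates_constants(self):
        grid = build_cuboid_grid((0.3, 0.2, 0.2), 0.05, (1.334, 0.176, 0.176),
                                 fiber_axis=(1.0, 1.0, 0.3))
        sys = assemble_myocardium(grid, BETA, CM, DT)
        assert np.abs(sys.K @ np.ones(grid.n_volumes)).max() < 1e-12

    def test_two_volume_cable_hand_assembly(self):
        # one shared face: off-diagonal -sigma*h, diagonal h^3 beta Cm/dt + sigma*h
        grid = build_cuboid_grid((0.2, 0.1, 0.1), 0.1, (1.0, 1.0, 1.0))
        sys = assemble_myocardium(grid, BETA, CM, DT)
        A = sys.A.toarray()
        mass = 0.1 ** 3 * BETA * CM / DT
        assert A[0, 1] == pytest.approx(-0.1, abs=1e-14)
        assert A[0, 0] == pytest.approx(mass + 0.1, rel=1e-14)

    def test_axis_aligned_fibres_match_seven_point_stencil(self):
        grid = build_cuboid_grid((0.3, 0.3, 0.15), 0.05, (1.334, 0.176, 0.176))
        sys = assemble_myocardium(grid, BETA, CM, DT)
        assert np.allclose(sys.A.toarray(), seven_point_oracle(grid, BETA, CM, DT),
                           atol=1e-12)
        assert sys.asymmetry == 0.0

    def test_oblique_fibres_keep_operator_spd(self):
        grid = build_cuboid_grid((0.2, 0.2, 0.2), 0.05, (1.334, 0.176, 0.176),
                                 fiber_axis=(1.0, 1.0, 0.5))
        sys = assemble_myocardium(grid, BETA, CM, DT)
        A = sys.A.toarray()
        assert np.allclose(A, A.T)
        assert np.linalg.eigvalsh(A).min() > 0
        assert np.abs(sys.K @ np.ones(grid.n_volumes)).max() < 1e-12

    def test_negative_conductivity_rejected(self):
        grid = build_cuboid_grid((0.2, 0.1, 0.1), 0.1, (1.0, 1.0, 1.0))
        grid.sigmas[0, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            assemble_myocardium(grid, BETA, CM, DT)


class TestPurkinjeAssembly:
    def test_straight_cable_is_tridiagonal_with_constant_kernel(self):
        net = build_purkinje_cable(0.25, 0.05, 2.0)
        sys = assemble_purkinje(net, BETA, CM, DT)
        K = sys.K.toarray()
        assert np.abs(K @ np.ones(net.n_volumes)).max() < 1e-14
        i, j = np.nonzero(K)
        assert np.abs(i - j).max() == 1

    def test_bifurcation_row_has_three_neighbours(self):
        net = build_purkinje_tree(1, 0.2, 0.025, 2.0)
        sys = assemble_purkinje(net, BETA, CM, DT)
        branching = [v for v, c in enumerate(net.children) if len(c) == 2][0]
        row = sys.K.toarray()[branching]
        assert np.count_nonzero(row) == 4  # parent + 2 children + diagonal

    def test_two_segment_cable_uses_harmonic_mean_face(self):
        s1, s2 = 3.0, 1.0
        nodes = np.array([[0.025, 0, 0], [0.075, 0, 0], [0.125, 0, 0]])
        net = PurkinjeNetwork(h=0.05, nodes=nodes, parent=np.array([-1, 0, 1]),
                              sigma=np.array([s1, s1, s2]))
        sys = assemble_purkinje(net, BETA, CM, DT)
        K = sys.K.toarray()
        assert K[0, 1] == pytest.approx(-s1 * 0.05, rel=1e-14)
        harm = 2 * s1 * s2 / (s1 + s2)
        assert K[1, 2] == pytest.approx(-harm * 0.05, rel=1e-14)

    def test_disconnected_network_rejected(self):
        nodes = np.array([[0.025, 0, 0], [0.075, 0, 0], [0.5, 0.5, 0.5]])
        with pytest.raises(ValueError, match="root"):
            PurkinjeNetwork(h=0.05, nodes=nodes, parent=np.array([-1, 0, -1]),
                            sigma=np.ones(3))


class TestPMJCurrents:
    def _single_map(self, grid):
        net = build_purkinje_cable(0.1, 0.025, 2.0, start=(0.0, 0.05, 0.05))
        return net, map_pmjs(net, grid, 1, 1000.0)

    def test_equal_potentials_give_zero_currents(self):
        grid = build_cuboid_grid((0.1, 0.1, 0.1), 0.05, (1, 1, 1))
        net, m = self._single_map(grid)
        cur = compute_pmj_currents(np.full(net.n_volumes, -85.0),
                                   np.full(grid.n_volumes, -85.0),
                                   m, m.rows(grid), net.h)
        assert np.all(cur.flux == 0.0)
        assert np.all(cur.terminal_current == 0.0)

    def test_hand_arithmetic_one_volume(self):
        # dV = 1 mV over 1000 kOhm -> 1e-3 uA; flux = 1e-3 / 0.025^2 = 1.6 uA/cm^2
        grid = build_cuboid_grid((0.1, 0.1, 0.1), 0.05, (1, 1, 1))
        net, m = self._single_map(grid)
        v_p = np.full(net.n_volumes, -84.0)
        v_m = np.full(grid.n_volumes, -85.0)
        cur = compute_pmj_currents(v_p, v_m, m, m.rows(grid), 0.025)
        assert cur.myo_currents[0][0] == pytest.approx(1e-3, rel=1e-12)
        assert cur.flux[0] == pytest.approx(1.6, rel=1e-12)
        assert cur.terminal_current[0] == pytest.approx(-1e-3, rel=1e-12)

    def test_retrograde_direction_gives_negative_myocardial_current(self):
        grid = build_cuboid_grid((0.1, 0.1, 0.1), 0.05, (1, 1, 1))
        net, m = self._single_map(grid)
        v_p = np.full(net.n_volumes, -85.0)
        v_m = np.full(grid.n_volumes, 20.0)  # myocardium depolarised first
        cur = compute_pmj_currents(v_p, v_m, m, m.rows(grid), net.h)
        assert cur.myo_currents[0][0] < 0
        assert cur.terminal_current[0] > 0

    def test_conservation_terminal_balances_myocardium(self, rng):
        grid = build_cuboid_grid((0.2, 0.2, 0.2), 0.05, (1, 1, 1))
        net = build_purkinje_tree(1, 0.1, 0.025, 2.0, start=(0.0, 0.1, 0.1))
        m = map_pmjs(net, grid, 6, 750.0)
        v_p = rng.uniform(-85, 20, net.n_volumes)
        v_m = rng.uniform(-85, 20, grid.n_volumes)
        cur = compute_pmj_currents(v_p, v_m, m, m.rows(grid), net.h)
        for t in range(len(m.terminals)):
            assert cur.terminal_current[t] + cur.myo_currents[t].sum() == pytest.approx(0.0, abs=1e-15)


def _null_problem(grid, **kw):
    model = NullReaction()
    sys_m = assemble_myocardium(grid, BETA, CM, DT)
    return CoupledProblem(grid=grid, model_m=model, sys_m=sys_m,
                          dt_ode=0.01, dt_pde=DT, **kw)


class TestAdvanceStep:
    def test_rest_state_is_equilibrium(self):
        cfg = make_wedge_config(stimuli=())
        problem = setup_problem(cfg)
        state = problem.initial_state()
        out, info = advance_step(problem, state, 0.0)
        assert np.abs(out.myo[:, 0] - state.myo[:, 0]).max() < 1e-9
        assert np.abs(out.purkinje[:, 0] - state.purkinje[:, 0]).max() < 1e-9
        assert not info.unstable

    def test_diffusion_conserves_total_charge(self, rng):
        grid = build_cuboid_grid((0.3, 0.2, 0.1), 0.05, (1.334, 0.176, 0.176))
        problem = _null_problem(grid)
        v0 = rng.uniform(-85.0, 20.0, grid.n_volumes)
        state = CoupledState(v0[:, None].copy())
        total0 = v0.sum() * grid.volume
        for k in range(10):
            state, info = advance_step(problem, state, k * DT)
        total = state.myo[:, 0].sum() * grid.volume
        assert total == pytest.approx(total0, rel=1e-8)

    def test_pmj_currents_globally_conserved_every_step(self):
        cfg = make_wedge_config(t_max=2.0)
        problem = setup_problem(cfg)
        state = problem.initial_state()
        for k in range(50):
            state, info = advance_step(problem, state, k * DT)
            applied = info.pmj.terminal_current.sum() + sum(
                c.sum() for c in info.pmj.myo_currents
            )
            assert applied == pytest.approx(0.0, abs=1e-12)

    def test_splitting_is_first_order_in_dt(self):
        def vfinal(dt):
            cfg = make_cable_config(1.0, length=0.3, t_max=20.0,
                                    dt_ode=dt / 2, dt_pde=dt)
            return run_simulation(cfg).snapshots_m[-1]

        ref = vfinal(0.0025)
        errs = [np.linalg.norm(vfinal(dt) - ref) for dt in (0.08, 0.04, 0.02)]
        for e_coarse, e_fine in zip(errs, errs[1:]):
            assert 1.5 <= e_coarse / e_fine <= 2.8  # halving dt halves the error

    def test_explicit_coupling_divergence_is_flagged_not_nan(self):
        cfg = make_wedge_config(r_pmj=1.0, dt_ode=0.25, dt_pde=0.5)
        result = run_simulation(cfg)
        assert result.unstable
        assert result.t_unstable is not None
        # guard fires before NaNs leak into recorded traces
        assert np.isfinite(result.terminal_trace).all() or result.unstable


class TestRunSimulation:
    def test_single_volume_without_stimulus_stays_at_rest(self):
        cfg = make_cable_config(1.0, h=0.05, length=0.05, t_max=10.0, stimuli=(),
                                output_every=100)
        res = run_simulation(cfg)
        assert res.lat_m[0] == -1.0
        for snap in res.snapshots_m:
            assert snap[0] == pytest.approx(-85.0, abs=1e-9)

    def test_benchmark_cuboid_geometry_and_stimulus(self):
        # printed protocol: 1 cm^3 at 250 um, corner 0.15 cm cube, 2 ms, 53 pA/pF
        cfg = make_cable_config(1.334)  # reuse template, then override
        cfg = cfg.replace(
            grid_extent=(1.0, 1.0, 1.0), grid_h=0.025,
            grid_sigma=(1.334, 0.176, 0.176),
            stimuli=(cfg.stimuli[0].__class__(
                "corner", ((0, 0, 0), (0.15, 0.15, 0.15)), 0.0, 2.0, 53.0, "myocardium"),),
            t_max=1.0,
        )
        problem = setup_problem(cfg)
        assert problem.grid.n_volumes == 64_000
        stim = problem.stimuli[0]
        assert stim.rows.size == 6 ** 3  # 0.15 / 0.025 per axis
        assert stim.amplitude == 53.0 and stim.duration == 2.0

    def test_wedge_myocardium_activates_only_after_terminal(self):
        cfg = make_wedge_config()
        problem = setup_problem(cfg)
        res = run_simulation(cfg, problem)
        term = problem.pmj_map.terminals[0]
        t_term = res.lat_p[term]
        activated = res.lat_m[res.lat_m >= 0]
        assert t_term > 0
        assert activated.size > 0
        assert activated.min() > t_term

    def test_dt_ratio_must_be_integer(self):
        with pytest.raises(ValueError, match="integer multiple"):
            make_cable_config(1.0, dt_ode=0.02, dt_pde=0.03)


class TestConductionVelocity:
    def test_cv_scales_with_sqrt_sigma(self):
        from purkmyo.calibrate import measure_cv

        cv1 = measure_cv(run_simulation(make_cable_config(0.3)))
        cv2 = measure_cv(run_simulation(make_cable_config(1.2)))
        assert cv2 / cv1 == pytest.approx(2.0, rel=0.05)
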