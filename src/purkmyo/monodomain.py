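"""Finite-volume assembly and the Godunov operator-splitting time loop.

Spatial discretisation: cubic control volumes (myocardium) and 1-D segment
volumes (Purkinje), both with node-centred unknowns. The implicit diffusion
solve of each domain uses the backward-Euler system

    (M + K) V^{n+1} = M V^{n+1/2} + I_src,        M_ii = h^3 beta C_m / dt,

where K is the stiffness (face-flux) part with zero row sums over no-flux
boundaries and I_src carries the explicit PMJ junction currents (uA). All
terms are expressed in uA (mV * mS = uA; mV / kOhm = uA), which makes the
mass/flux/junction bookkeeping dimensionally closed.

Each time step performs (1) dt_pde/dt_ode reaction sub-steps in both
domains, (2) evaluation of the resistive PMJ currents at the half step,
(3) two independent implicit diffusion solves with those currents as
sources. Computing the junction exchange at the half step decouples the
domains at the price of conditional stability: too small an R_PMJ for a
given dt makes the explicit exchange diverge, which the loop detects
(|V| > 500 mV or non-finite values) and reports instead of producing
silent NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix, diags

from . import linsolve
from .ionic import IonicModel, initial_states, step_forward_euler, step_rush_larsen
from .mesh import CartesianGrid, PMJMap, PurkinjeNetwork

__all__ = [
    "MonodomainSystem",
    "PMJCurrentSet",
    "CoupledState",
    "CoupledProblem",
    "SimulationResult",
    "Stimulus",
    "assemble_myocardium",
    "assemble_purkinje",
    "compute_pmj_currents",
    "advance_step",
    "setup_problem",
    "run_simulation",
]

INSTABILITY_THRESHOLD_MV = 500.0
SYMMETRY_TOL = 1e-8  # relative; above this the solver falls back to BiCG


@dataclass
class MonodomainSystem:
    """Backward-Euler diffusion system for one domain."""

    A: csr_matrix          # M + K, explicitly symmetrised
    K: csr_matrix          # stiffness part (uA per mV), zero row sums
    mass: np.ndarray       # M diagonal: h^3 beta C_m / dt per volume
    beta: float
    cm: float
    dt: float
    volume: float          # per-volume measure, cm^3
    asymmetry: float = 0.0 # max relative asymmetry before symmetrisation
    use_bicg: bool = False

    @property
    def n(self) -> int:
        return self.A.shape[0]


def _encode(indices: np.ndarray, dims) -> np.ndarray:
    return (indices[:, 0] * dims[1] + indices[:, 1]) * dims[2] + indices[:, 2]


class _Lookup:
    """Vectorised lattice-index -> storage-row lookup (missing -> -1)."""

    def __init__(self, indices: np.ndarray):
        self.dims = np.asarray([int(indices[:, a].max()) + 3 for a in range(3)])
        codes = _encode(indices, self.dims)
        self.order = np.argsort(codes)
        self.sorted_codes = codes[self.order]

    def rows(self, query: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(query)
        valid = np.all((q >= 0) & (q < self.dims), axis=1)
        codes = _encode(np.clip(q, 0, None), self.dims)
        pos = np.searchsorted(self.sorted_codes, codes)
        pos = np.clip(pos, 0, len(self.sorted_codes) - 1)
        hit = valid & (self.sorted_codes[pos] == codes)
        return np.where(hit, self.order[pos], -1)


def _finalize_system(
    rows, cols, vals, n: int, mass_value: float, beta: float, cm: float,
    dt: float, volume: float,
) -> MonodomainSystem:
    K = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    K.sum_duplicates()
    diff = (K - K.T).tocoo()
    scale = max(np.abs(K.data).max(), np.finfo(float).tiny) if K.nnz else 1.0
    asym = float(np.abs(diff.data).max() / scale) if diff.nnz else 0.0
    K = ((K + K.T) * 0.5).tocsr()
    mass = np.full(n, mass_value)
    A = (diags(mass) + K).tocsr()
    return MonodomainSystem(
        A=A, K=K, mass=mass, beta=beta, cm=cm, dt=dt, volume=volume,
        asymmetry=asym, use_bicg=asym > SYMMETRY_TOL,
    )


def assemble_myocardium(
    grid: CartesianGrid, beta: float = 1400.0, cm: float = 1.0, dt_pde: float = 0.02
) -> MonodomainSystem:
    """Assemble the 3-D anisotropic diffusion operator on the voxel grid.

    Face fluxes combine the normal-gradient term between the two
    face-adjacent volumes with centred transverse differences over the
    face's four lateral neighbour pairs (the cross-derivative part of the
    conductivity tensor), using the arithmetic average of the two adjacent
    tensors at the face. Missing neighbours impose zero flux. Assembly is
    explicitly symmetrised; the residual asymmetry is recorded and, above
    1e-8 relative, flips the solver to BiCG.
    """
    if dt_pde <= 0:
        raise ValueError("dt_pde must be positive")
    if grid.n_volumes == 0:
        raise ValueError("grid is empty")
    if np.any(grid.sigmas < 0):
        raise ValueError("negative conductivity")
    h = grid.h
    idx = grid.indices
    tensors = grid.conductivity_tensors()
    lut = _Lookup(idx)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r, c, v):
        rows.append(np.asarray(r))
        cols.append(np.asarray(c))
        vals.append(np.asarray(v, dtype=float))

    eye = np.eye(3, dtype=np.int64)
    for a in range(3):
        nb = lut.rows(idx + eye[a])
        have = nb >= 0
        i = np.flatnonzero(have)
        j = nb[have]
        if i.size == 0:
            continue
        tface = 0.5 * (tensors[i] + tensors[j])
        # normal term: flux into i over the shared face = sigma_aa (Vj - Vi) h
        g = tface[:, a, a] * h
        add(i, i, g)
        add(j, j, g)
        add(i, j, -g)
        add(j, i, -g)
        # transverse (cross-derivative) terms, centred over the face's
        # lateral neighbour pairs; a pair with a missing member is dropped
        # whole, preserving zero row sums
        for b in range(3):
            if b == a:
                continue
            coef = tface[:, a, b] * h / 4.0
            for base in (i, j):
                plus = lut.rows(idx[base] + eye[b])
                minus = lut.rows(idx[base] - eye[b])
                ok = (plus >= 0) & (minus >= 0) & (coef != 0.0)
                if not ok.any():
                    continue
                ii, jj = i[ok], j[ok]
                p, m, c = plus[ok], minus[ok], coef[ok]
                # flux into i gains coef*(V_plus - V_minus); j loses it
                add(ii, p, -c)
                add(ii, m, c)
                add(jj, p, c)
                add(jj, m, -c)

    n = grid.n_volumes
    r = np.concatenate(rows) if rows else np.zeros(0, dtype=int)
    c = np.concatenate(cols) if cols else np.zeros(0, dtype=int)
    v = np.concatenate(vals) if vals else np.zeros(0)
    return _finalize_system(
        r, c, v, n, h ** 3 * beta * cm / dt_pde, beta, cm, dt_pde, h ** 3
    )


def assemble_purkinje(
    network: PurkinjeNetwork, beta: float = 1400.0, cm: float = 1.0, dt_pde: float = 0.02
) -> MonodomainSystem:
    """Assemble the 1-D Purkinje operator.

    Each parent-child face carries the harmonic mean of the adjacent
    conductivities; branching volumes accumulate one flux per child plus
    the upstream one, terminal volumes only the upstream flux (the PMJ
    term enters as an explicit source at solve time).
    """
    if dt_pde <= 0:
        raise ValueError("dt_pde must be positive")
    network.validate()  # rejects disconnected/multi-root inputs
    h = network.h
    child = np.flatnonzero(network.parent >= 0)
    parent = network.parent[child]
    s1 = network.sigma[parent]
    s2 = network.sigma[child]
    g = 2.0 * s1 * s2 / (s1 + s2) * h  # harmonic-mean face conductivity * h
    n = network.n_volumes
    rows = np.concatenate([parent, child, parent, child])
    cols = np.concatenate([parent, child, child, parent])
    vals = np.concatenate([g, g, -g, -g])
    return _finalize_system(
        rows, cols, vals, n, h ** 3 * beta * cm / dt_pde, beta, cm, dt_pde, h ** 3
    )


# ---------------------------------------------------------------------------
# PMJ exchange
# ---------------------------------------------------------------------------

@dataclass
class PMJCurrentSet:
    """Half-step junction currents: conservative by construction.

    For each terminal, every coupled myocardial volume k receives
    (V_P - V_Mk) / R_PMJ uA; the terminal Purkinje volume carries the
    equal-and-opposite total. ``flux`` is J_PMJ = total / h_P^2 (uA/cm^2);
    its sign selects anterograde (positive, Purkinje -> myocardium) or
    retrograde propagation.
    """

    terminals: np.ndarray
    terminal_current: np.ndarray     # (n_t,) uA into the terminal volume
    myo_rows: list[np.ndarray]
    myo_currents: list[np.ndarray]   # uA into each coupled myocardial volume
    flux: np.ndarray                 # (n_t,) uA/cm^2


def compute_pmj_currents(
    v_p: np.ndarray,
    v_m: np.ndarray,
    pmj_map: PMJMap,
    myo_rows: list[np.ndarray],
    h_p: float,
) -> PMJCurrentSet:
    """Evaluate the resistive junction currents (pure evaluation, no state)."""
    term_cur = np.zeros(len(pmj_map.terminals))
    flux = np.zeros(len(pmj_map.terminals))
    myo_currents = []
    for t, (term, rows) in enumerate(zip(pmj_map.terminals, myo_rows)):
        cur = (v_p[term] - v_m[rows]) / pmj_map.r_pmj  # mV / kOhm = uA
        myo_currents.append(cur)
        total = float(cur.sum())
        term_cur[t] = -total
        flux[t] = total / h_p ** 2
    return PMJCurrentSet(
        terminals=pmj_map.terminals,
        terminal_current=term_cur,
        myo_rows=myo_rows,
        myo_currents=myo_currents,
        flux=flux,
    )


# ---------------------------------------------------------------------------
# Coupled problem and time stepping
# ---------------------------------------------------------------------------

@dataclass
class CoupledState:
    """States of both domains at one time level (V is column 0)."""

    myo: np.ndarray
    purkinje: np.ndarray | None = None

    def copy(self) -> "CoupledState":
        return CoupledState(
            self.myo.copy(), None if self.purkinje is None else self.purkinje.copy()
        )


@dataclass
class Stimulus:
    """Box stimulus: amplitude (pA/pF) applied to resolved rows during [start, start+duration)."""

    rows: np.ndarray
    start: float
    duration: float
    amplitude: float
    domain: str = "myocardium"


@dataclass
class CoupledProblem:
    grid: CartesianGrid
    model_m: IonicModel
    sys_m: MonodomainSystem
    network: PurkinjeNetwork | None = None
    model_p: IonicModel | None = None
    sys_p: MonodomainSystem | None = None
    pmj_map: PMJMap | None = None
    pmj_rows: list[np.ndarray] | None = None
    stimuli: list[Stimulus] = field(default_factory=list)
    dt_ode: float = 0.01
    dt_pde: float = 0.02
    ode_method: str = "rush_larsen"     # or "euler"
    solver_tol: float = linsolve.DEFAULT_TOL
    solver_maxit: int = linsolve.DEFAULT_MAXIT
    solver_preconditioner: str = "jacobi"
    solver_method: str = "auto"         # auto | cg | bicg

    def __post_init__(self) -> None:
        ratio = self.dt_pde / self.dt_ode
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"dt_pde = {self.dt_pde} must be an integer multiple of dt_ode = {self.dt_ode}"
            )
        self.n_substeps = int(round(ratio))
        if (self.network is None) != (self.sys_p is None):
            raise ValueError("network and Purkinje system must be provided together")

    def initial_state(self) -> CoupledState:
        purk = None
        if self.network is not None:
            purk = initial_states(self.model_p, self.network.n_volumes)
        return CoupledState(initial_states(self.model_m, self.grid.n_volumes), purk)

    def stim_current(self, t: float, domain: str, n: int) -> np.ndarray | float:
        out = None
        for s in self.stimuli:
            if s.domain != domain:
                continue
            if s.start - 1e-12 <= t < s.start + s.duration - 1e-12:
                if out is None:
                    out = np.zeros(n)
                out[s.rows] += s.amplitude
        return 0.0 if out is None else out


def _ode_step(problem, model, states, dt, i_stim):
    if problem.ode_method == "euler":
        return step_forward_euler(model, states, dt, i_stim)
    return step_rush_larsen(model, states, dt, i_stim)


def _diffusion_solve(problem, sys: MonodomainSystem, rhs, x0):
    if problem.solver_method == "bicg" or (
        problem.solver_method == "auto" and sys.use_bicg
    ):
        x, rep = linsolve.bicg_solve(
            sys.A, rhs, tol=problem.solver_tol, maxit=problem.solver_maxit, x0=x0
        )
    else:
        x, rep = linsolve.cg_solve(
            sys.A, rhs, tol=problem.solver_tol, maxit=problem.solver_maxit,
            preconditioner=problem.solver_preconditioner, x0=x0,
        )
    if not rep.converged:
        raise RuntimeError(
            f"diffusion solve failed: {rep.method} after {rep.iterations} iterations, "
            f"residual {rep.residual:.3e} ({rep.failure})"
        )
    return x, rep


@dataclass
class StepInfo:
    reports: list
    pmj: PMJCurrentSet | None
    unstable: bool = False


def advance_step(
    problem: CoupledProblem, state: CoupledState, t: float
) -> tuple[CoupledState, StepInfo]:
    """One Godunov-split step of length dt_pde starting at time t.

    Reaction sub-steps first (both domains), PMJ currents at the half step,
    then the two independent implicit diffusion solves with the junction
    currents as right-hand-side sources. Instability (|V| beyond the
    500 mV guard or non-finite values, the signature of the explicit
    PMJ-coupling blow-up) is flagged on the returned StepInfo, never
    silently propagated as NaN.
    """
    myo = state.myo
    purk = state.purkinje
    n_m = myo.shape[0]
    for k in range(problem.n_substeps):
        tk = t + k * problem.dt_ode
        myo = _ode_step(
            problem, problem.model_m, myo, problem.dt_ode,
            problem.stim_current(tk, "myocardium", n_m),
        )
        if purk is not None:
            purk = _ode_step(
                problem, problem.model_p, purk, problem.dt_ode,
                problem.stim_current(tk, "purkinje", purk.shape[0]),
            )

    pmj = None
    src_m = None
    if purk is not None and problem.pmj_map is not None:
        pmj = compute_pmj_currents(
            purk[:, 0], myo[:, 0], problem.pmj_map, problem.pmj_rows, problem.network.h
        )
        src_m = np.zeros(n_m)
        for rows, cur in zip(pmj.myo_rows, pmj.myo_currents):
            np.add.at(src_m, rows, cur)

    reports = []
    rhs_m = problem.sys_m.mass * myo[:, 0]
    if src_m is not None:
        rhs_m = rhs_m + src_m
    vm_new, rep = _diffusion_solve(problem, problem.sys_m, rhs_m, myo[:, 0])
    reports.append(rep)
    myo = myo.copy()
    myo[:, 0] = vm_new

    if purk is not None:
        rhs_p = (problem.sys_p.mass * purk[:, 0]).copy()
        if pmj is not None:
            rhs_p[pmj.terminals] += pmj.terminal_current
        vp_new, rep = _diffusion_solve(problem, problem.sys_p, rhs_p, purk[:, 0])
        reports.append(rep)
        purk = purk.copy()
        purk[:, 0] = vp_new

    vmax = np.abs(myo[:, 0]).max()
    if purk is not None:
        vmax = max(vmax, np.abs(purk[:, 0]).max())
    unstable = (not np.isfinite(vmax)) or vmax > INSTABILITY_THRESHOLD_MV
    return CoupledState(myo, purk), StepInfo(reports, pmj, unstable)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Everything a run produces, in memory.

    PMJ-site traces (terminal Purkinje volume and its nearest coupled
    myocardial volume) are sampled every PDE step, fixing the delay
    quantisation at dt_pde. Activation maps hold the first threshold
    crossing per volume (ms; -1 = never activated). Snapshots and ECG are
    sampled at the output cadence.
    """

    times: np.ndarray                       # PDE-step times (trace cadence)
    terminal_trace: np.ndarray | None
    nearest_myo_trace: np.ndarray | None
    lat_m: np.ndarray
    lat_p: np.ndarray | None
    snapshot_times: np.ndarray
    snapshots_m: list[np.ndarray]
    snapshots_p: list[np.ndarray]
    grid: CartesianGrid | None = None
    network: PurkinjeNetwork | None = None
    ecg_times: np.ndarray | None = None
    ecg: np.ndarray | None = None           # (n_leads, T)
    lead_labels: list[str] | None = None
    unstable: bool = False
    t_unstable: float | None = None
    max_solver_iterations: int = 0
    activation_threshold: float = -40.0


def setup_problem(config) -> CoupledProblem:
    """Build a CoupledProblem from a RunConfig (see io_formats)."""
    from .ionic import get_model
    from .mesh import map_pmjs

    grid = config.build_grid()
    network = config.build_network()
    model_m = get_model(config.myo_model)
    sys_m = assemble_myocardium(grid, config.beta, config.cm, config.dt_pde)
    model_p = sys_p = pmj_map = pmj_rows = None
    if network is not None:
        model_p = get_model(config.purkinje_model)
        sys_p = assemble_purkinje(network, config.beta, config.cm, config.dt_pde)
        pmj_map = map_pmjs(network, grid, config.n_pmj, config.r_pmj)
        pmj_rows = pmj_map.rows(grid)

    stimuli = []
    for sb in config.stimuli:
        lo, hi = np.asarray(sb.box[0], float), np.asarray(sb.box[1], float)
        if sb.domain == "myocardium":
            pts = grid.centers
        elif network is not None:
            pts = network.nodes
        else:
            raise ValueError("stimulus targets the Purkinje domain but no network is configured")
        rows = np.flatnonzero(np.all((pts >= lo) & (pts < hi), axis=1))
        if rows.size == 0:
            raise ValueError(f"stimulus box {sb.box} selects no volumes in {sb.domain}")
        stimuli.append(
            Stimulus(rows=rows, start=sb.start, duration=sb.duration,
                     amplitude=sb.amplitude, domain=sb.domain)
        )

    return CoupledProblem(
        grid=grid, model_m=model_m, sys_m=sys_m,
        network=network, model_p=model_p, sys_p=sys_p,
        pmj_map=pmj_map, pmj_rows=pmj_rows, stimuli=stimuli,
        dt_ode=config.dt_ode, dt_pde=config.dt_pde, ode_method=config.ode_method,
        solver_tol=config.solver_tol, solver_maxit=config.solver_maxit,
        solver_preconditioner=config.solver_preconditioner,
        solver_method=config.solver_method,
    )


def run_simulation(config, problem: CoupledProblem | None = None) -> SimulationResult:
    """Run a configured simulation to t_max; deterministic given the config."""
    from .ecg import compute_pseudo_ecg

    if problem is None:
        problem = setup_problem(config)
    state = problem.initial_state()
    n_steps = int(round(config.t_max / problem.dt_pde))
    if n_steps < 1 or abs(n_steps * problem.dt_pde - config.t_max) > 1e-9 * max(1.0, config.t_max):
        raise ValueError("t_max must be a positive integer multiple of dt_pde")
    thr = config.activation_threshold
    cadence = max(1, int(config.output_every))

    grid = problem.grid
    net = problem.network
    leads = config.build_leads(grid)

    n_t = len(problem.pmj_map.terminals) if problem.pmj_map is not None else 0
    nearest_rows = np.array([rows[0] for rows in problem.pmj_rows]) if n_t else None

    times = np.empty(n_steps)
    term_trace = np.empty((n_t, n_steps)) if n_t else None
    near_trace = np.empty((n_t, n_steps)) if n_t else None
    lat_m = np.full(grid.n_volumes, -1.0)
    lat_p = np.full(net.n_volumes, -1.0) if net is not None else None
    snap_times, snaps_m, snaps_p = [], [], []
    ecg_rows, ecg_times = [], []
    max_it = 0
    unstable = False
    t_unstable = None

    def record_lat(lat, v, t):
        hit = (lat < 0) & (v >= thr)
        lat[hit] = t

    # the initial state can already be above threshold (time 0 sample)
    state0 = problem.initial_state()
    record_lat(lat_m, state0.myo[:, 0], 0.0)
    if net is not None:
        record_lat(lat_p, state0.purkinje[:, 0], 0.0)

    used = 0
    for k in range(n_steps):
        t = k * problem.dt_pde
        state, info = advance_step(problem, state, t)
        t_next = (k + 1) * problem.dt_pde
        times[k] = t_next
        max_it = max([max_it] + [rep.iterations for rep in info.reports])
        vm = state.myo[:, 0]
        record_lat(lat_m, vm, t_next)
        if net is not None:
            vp = state.purkinje[:, 0]
            record_lat(lat_p, vp, t_next)
            if n_t:
                term_trace[:, k] = vp[problem.pmj_map.terminals]
                near_trace[:, k] = vm[nearest_rows]
        if (k + 1) % cadence == 0 or k == n_steps - 1:
            snap_times.append(t_next)
            snaps_m.append(vm.copy())
            if net is not None:
                snaps_p.append(vp.copy())
            if leads is not None:
                ecg_times.append(t_next)
                ecg_rows.append(compute_pseudo_ecg(problem.sys_m.K, vm, grid, leads))
        used = k + 1
        if info.unstable:
            unstable = True
            t_unstable = t_next
            break

    return SimulationResult(
        times=times[:used],
        terminal_trace=term_trace[:, :used] if n_t else None,
        nearest_myo_trace=near_trace[:, :used] if n_t else None,
        lat_m=lat_m,
        lat_p=lat_p,
        snapshot_times=np.asarray(snap_times),
        snapshots_m=snaps_m,
        snapshots_p=snaps_p,
        grid=grid,
        network=net,
        ecg_times=np.asarray(ecg_times) if leads is not None else None,
        ecg=np.asarray(ecg_rows).T if (leads is not None and ecg_rows) else None,
        lead_labels=list(leads.labels) if leads is not None else None,
        unstable=unstable,
        t_unstable=t_unstable,
        max_solver_iterations=max_it,
        activation_threshold=thr,
    )
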