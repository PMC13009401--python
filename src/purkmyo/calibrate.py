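"""PMJ-delay measurement, block/instability classification and batch sweeps.

The anterograde PMJ delay of a terminal is the difference between the
first time its nearest coupled myocardial volume and the terminal Purkinje
volume itself cross the activation threshold (-40 mV by default). A
terminal that activates while its nearest coupled volume never does marks
propagation block; a run that tripped the voltage guard marks instability.
Activation times are first-sample crossings without interpolation, so the
delay is quantised at the trace cadence (dt_pde for calibration runs).

Factorial sweeps are generated as the full Cartesian product over named
parameter axes (RunConfig field names) in lexicographic axis order, and
dispatched over a process pool; aggregated tables are sorted by run name
so they are identical for any worker count.
"""

from __future__ import annotations

import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import RunConfig, write_activation_map, write_config, write_delay_csv
from .mesh import PMJMap
from .monodomain import SimulationResult, run_simulation

__all__ = [
    "DelayRecord",
    "SweepSpec",
    "RunSpec",
    "measure_activation_time",
    "measure_pmj_delays",
    "measure_cv",
    "equispaced",
    "generate_sweep",
    "dispatch_batch",
    "delay_heatmap",
]

DELAY_THRESHOLD_MV = -40.0


@dataclass
class DelayRecord:
    """One terminal's anterograde junction delay (ms) and classification."""

    terminal: int
    terminal_lat: float | None
    myo_lat: float | None
    delay: float | None
    status: str  # ok | block | unstable

    def __post_init__(self) -> None:
        if self.status not in ("ok", "block", "unstable"):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.delay is not None) != (self.status == "ok"):
            raise ValueError("delay is defined exactly when status is ok")


def measure_activation_time(
    trace,
    threshold: float = DELAY_THRESHOLD_MV,
    times=None,
    dt: float | None = None,
    t0: float = 0.0,
) -> float | None:
    """Time of the first sample with V >= threshold; None if never crossed.

    The trace must be uniformly sampled; pass either its ``times`` axis or
    the sampling interval ``dt`` (plus the time ``t0`` of the first sample).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if times is None:
        if dt is None:
            raise ValueError("provide either times or dt")
        times = t0 + dt * np.arange(trace.size)
    times = np.asarray(times, dtype=float)
    if times.shape != trace.shape:
        raise ValueError("times and trace lengths differ")
    hit = np.flatnonzero(trace >= threshold)
    return float(times[hit[0]]) if hit.size else None


def measure_pmj_delays(
    result: SimulationResult,
    pmj_map: PMJMap | None = None,
    threshold: float = DELAY_THRESHOLD_MV,
) -> list[DelayRecord]:
    """One DelayRecord per terminal from a run's PMJ-site traces.

    ``pmj_map`` is only used to name terminals consistently; the traces
    stored on the result (terminal volume and its closest coupled
    myocardial volume, the first entry of the distance-sorted map) carry
    the measurement.
    """
    if result.terminal_trace is None or result.nearest_myo_trace is None:
        raise ValueError("result carries no PMJ traces (was the run coupled?)")
    terminals = (
        pmj_map.terminals if pmj_map is not None
        else np.arange(result.terminal_trace.shape[0])
    )
    if result.terminal_trace.shape[0] != len(terminals):
        raise ValueError("trace count does not match terminal count")
    records = []
    for row, term in enumerate(terminals):
        if result.terminal_trace.shape[1] == 0:
            raise ValueError(f"missing trace for terminal {term}")
        t_lat = measure_activation_time(
            result.terminal_trace[row], threshold, times=result.times
        )
        m_lat = measure_activation_time(
            result.nearest_myo_trace[row], threshold, times=result.times
        )
        if result.unstable:
            records.append(DelayRecord(int(term), t_lat, m_lat, None, "unstable"))
        elif t_lat is not None and m_lat is not None:
            records.append(DelayRecord(int(term), t_lat, m_lat, m_lat - t_lat, "ok"))
        else:
            records.append(DelayRecord(int(term), t_lat, m_lat, None, "block"))
    return records


def measure_cv(
    result: SimulationResult, axis: int = 0, frac: tuple[float, float] = (0.25, 0.75)
) -> float:
    """Planar-wave conduction velocity (cm/ms) from the activation map.

    Picks the two activated volumes closest to the given fractions of the
    domain extent along ``axis`` and divides distance by activation-time
    difference.
    """
    lat = result.lat_m
    act = lat >= 0
    if act.sum() < 2:
        raise ValueError("fewer than two activated volumes")
    x = result.grid.centers[:, axis]
    lo, hi = x.min(), x.max()
    cvs = []
    targets = [lo + f * (hi - lo) for f in frac]
    picks = []
    for tgt in targets:
        cand = np.flatnonzero(act)
        picks.append(cand[np.argmin(np.abs(x[cand] - tgt))])
    p0, p1 = picks
    if lat[p1] == lat[p0]:
        raise ValueError("degenerate activation times; enlarge the measurement window")
    return float((x[p1] - x[p0]) / (lat[p1] - lat[p0]))


# ---------------------------------------------------------------------------
# Factorial sweeps
# ---------------------------------------------------------------------------

def equispaced(lo: float, hi: float, count: int) -> tuple:
    """Equispaced sweep values, inclusive of both endpoints."""
    if count < 1:
        raise ValueError("count must be >= 1")
    return tuple(np.linspace(lo, hi, count))


def _fmt_value(v) -> str:
    if isinstance(v, float):
        return f"{v:g}"
    if isinstance(v, (str, Path)):
        return Path(str(v)).stem
    return str(v)


@dataclass
class SweepSpec:
    """Named parameter axes over a base configuration.

    Axis names are RunConfig field names (e.g. ``r_pmj``, ``n_pmj``,
    ``grid_file``, ``purkinje_h``, ``grid_h``); run count is the product of
    the axis lengths.
    """

    base: RunConfig
    axes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, values in self.axes.items():
            if len(values) == 0:
                raise ValueError(f"sweep axis {name!r} is empty")
            if not hasattr(self.base, name):
                raise ValueError(f"sweep axis {name!r} is not a RunConfig field")

    @property
    def run_count(self) -> int:
        n = 1
        for values in self.axes.values():
            n *= len(values)
        return n


@dataclass
class RunSpec:
    name: str
    config: RunConfig
    params: dict


def generate_sweep(spec: SweepSpec) -> list[RunSpec]:
    """Full Cartesian product, deterministic lexicographic axis order.

    Each run gets a unique directory-safe name encoding its parameter
    values, stable across platforms and runs.
    """
    names = sorted(spec.axes)
    runs: list[RunSpec] = []

    def recurse(i: int, chosen: dict) -> None:
        if i == len(names):
            label = "__".join(f"{k}={_fmt_value(v)}" for k, v in chosen.items())
            label = label or "base"
            runs.append(RunSpec(label, spec.base.replace(**chosen), dict(chosen)))
            return
        for v in spec.axes[names[i]]:
            recurse(i + 1, {**chosen, names[i]: v})

    recurse(0, {})
    return runs


def _execute_run(args) -> dict:
    """Worker body: run one configuration in its own directory; never raises."""
    run, out_dir = args
    run_dir = Path(out_dir) / run.name
    run_dir.mkdir(parents=True, exist_ok=True)
    try:
        write_config(run.config, run_dir / "config.ini")
        result = run_simulation(run.config)
        records = measure_pmj_delays(result) if result.terminal_trace is not None else []
        write_delay_csv(records, run_dir / "delays.csv")
        write_activation_map(result, run_dir / "activation_map.csv")
        (run_dir / "log.txt").write_text(
            f"status: {'unstable' if result.unstable else 'completed'}\n"
            f"steps: {len(result.times)}\n"
            f"max_solver_iterations: {result.max_solver_iterations}\n"
            + (f"t_unstable_ms: {result.t_unstable}\n" if result.unstable else "")
        )
        rows = [
            {
                "run": run.name, **run.params,
                "terminal": r.terminal,
                "terminal_lat_ms": r.terminal_lat,
                "myo_lat_ms": r.myo_lat,
                "delay_ms": r.delay,
                "status": r.status,
            }
            for r in records
        ]
        return {"run": run.name, "status": "unstable" if result.unstable else "ok",
                "rows": rows, "error": ""}
    except Exception as exc:  # failures are isolated, not propagated
        (run_dir / "log.txt").write_text(
            "status: failed\n" + "".join(traceback.format_exception(exc))
        )
        return {"run": run.name, "status": "failed", "rows": [], "error": str(exc)}


def dispatch_batch(runs: list[RunSpec], workers: int = 1, out_dir=".") -> pd.DataFrame:
    """Execute every run exactly once; aggregate results deterministically.

    Each run works in its own subdirectory of ``out_dir``. One diverging or
    failing run never aborts the batch; it is marked in the manifest.
    Returns the manifest; writes ``manifest.csv`` and the aggregated
    ``delays.csv`` (sorted by run name, then terminal — byte-identical for
    any worker count).
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    names = [r.name for r in runs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate run directory names in batch")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    args = [(r, str(out)) for r in runs]
    if workers == 1 or len(runs) <= 1:
        outcomes = [_execute_run(a) for a in args]
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            outcomes = list(pool.map(_execute_run, args))

    outcomes.sort(key=lambda o: o["run"])
    manifest = pd.DataFrame(
        [{"run": o["run"], "status": o["status"], "error": o["error"]} for o in outcomes],
        columns=["run", "status", "error"],
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    rows = [row for o in outcomes for row in o["rows"]]
    agg = pd.DataFrame(rows)
    if not agg.empty:
        agg = agg.sort_values(["run", "terminal"]).reset_index(drop=True)
    agg.to_csv(out / "delays.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Heatmaps
# ---------------------------------------------------------------------------

def delay_heatmap(records: pd.DataFrame, csv_path=None):
    """Mean anterograde delay over the (R_PMJ, N_PMJ) grid, plus masks.

    ``records`` needs columns r_pmj, n_pmj, delay_ms, status covering a
    full factorial grid for one geometry/discretisation. Returns
    (delay matrix, block mask, unstable mask, missing mask) as DataFrames
    indexed by R_PMJ (rows) and N_PMJ (columns). Missing cells are flagged,
    never silently filled.
    """
    required = {"r_pmj", "n_pmj", "delay_ms", "status"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    rs = np.sort(records["r_pmj"].unique())
    ns = np.sort(records["n_pmj"].unique())
    delay = pd.DataFrame(np.nan, index=rs, columns=ns)
    block = pd.DataFrame(False, index=rs, columns=ns)
    unstable = pd.DataFrame(False, index=rs, columns=ns)
    missing = pd.DataFrame(True, index=rs, columns=ns)
    for (r, n), group in records.groupby(["r_pmj", "n_pmj"]):
        missing.loc[r, n] = False
        status = set(group["status"])
        if "unstable" in status:
            unstable.loc[r, n] = True
        elif "block" in status:
            block.loc[r, n] = True
        else:
            delay.loc[r, n] = group["delay_ms"].astype(float).mean()
    if csv_path is not None:
        delay.to_csv(csv_path, index_label="r_pmj_kohm")
    return delay, block, unstable, missing
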