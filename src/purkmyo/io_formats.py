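"""Configuration parsing and result writers (EnSight Gold, VTK legacy, CSV).

Configuration is an INI dialect with sections [main], [grid], [purkinje],
[pmj], [ode], [linear_solver], [stim_*] and [ecg]. Units are fixed:
cm / ms / mV / mS / kOhm / pA-per-pF. Unknown keys are errors, not
warnings, so typos cannot silently fall back to defaults.

Output writers cover EnSight Gold binary (one .case index, one binary
geometry file with a hexa8 part per domain, one binary scalar file per
saved step; 80-character padded record headers and 32-bit reals as the
Gold binary layout requires), VTK legacy unstructured grids (ascii or
binary, cell data), and CSV writers for activation maps, ECG traces and
PMJ-delay tables.
"""

from __future__ import annotations

import configparser
import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import mesh
from .ecg import LeadSet

__all__ = [
    "StimulusBlock",
    "RunConfig",
    "parse_config",
    "write_config",
    "write_ensight_gold",
    "write_vtk_legacy",
    "write_activation_map",
    "write_ecg_csv",
    "write_delay_csv",
    "read_delay_csv",
]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusBlock:
    name: str
    box: tuple                 # ((x0,y0,z0), (x1,y1,z1)) cm, half-open
    start: float               # ms
    duration: float            # ms
    amplitude: float           # pA/pF
    domain: str = "myocardium"


@dataclass(frozen=True)
class RunConfig:
    """Full description of one simulation run (units cm/ms/mV/mS/kOhm)."""

    # [main]
    t_max: float
    beta: float = 1400.0
    cm: float = 1.0
    output_every: int = 100          # PDE steps between saved snapshots
    activation_threshold: float = -40.0
    # [grid] -- either a file or a cuboid description
    grid_file: str | None = None
    grid_extent: tuple | None = None
    grid_h: float | None = None
    grid_sigma: tuple | None = None
    grid_fiber_axis: tuple = (1.0, 0.0, 0.0)
    endo_box: tuple | None = None       # optional isotropic endocardial layer
    endo_sigma: tuple | None = None
    endo_tag: str = "endo"
    # [purkinje] -- file, cable or binary-tree fixture; all None = no Purkinje
    purkinje_file: str | None = None
    purkinje_depth: int | None = None
    purkinje_branch_length: float | None = None
    purkinje_h: float | None = None
    purkinje_sigma: float | None = None
    purkinje_start: tuple = (0.0, 0.0, 0.0)
    purkinje_direction: tuple = (1.0, 0.0, 0.0)
    # [pmj]
    r_pmj: float = 1000.0               # kOhm
    n_pmj: int = 5
    # [ode]
    dt_ode: float = 0.01
    dt_pde: float = 0.02
    myo_model: str = "mitchell_schaeffer"
    purkinje_model: str = "mitchell_schaeffer"
    ode_method: str = "rush_larsen"
    # [linear_solver]
    solver_tol: float = 1e-10
    solver_maxit: int = 5000
    solver_preconditioner: str = "jacobi"
    solver_method: str = "auto"
    # [stim_*]
    stimuli: tuple = ()
    # [ecg]
    sigma_b: float | None = None        # mS/cm; None = no ECG
    electrodes: tuple = ()              # ((label, (x, y, z)), ...)

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        ratio = self.dt_pde / self.dt_ode
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"dt_pde = {self.dt_pde} is not an integer multiple of dt_ode = {self.dt_ode}"
            )
        if self.r_pmj <= 0:
            raise ValueError("R_PMJ must be positive")
        if self.n_pmj < 1:
            raise ValueError("N_PMJ must be >= 1")
        for s in self.stimuli:
            if s.start >= self.t_max:
                warnings.warn(
                    f"stimulus {s.name!r} starts at {s.start} ms, outside the "
                    f"simulated window of {self.t_max} ms", stacklevel=2,
                )

    # -- factories ------------------------------------------------------
    def build_grid(self) -> mesh.CartesianGrid:
        if self.grid_file is not None:
            grid = mesh.read_grid(self.grid_file)
        else:
            if self.grid_extent is None or self.grid_h is None or self.grid_sigma is None:
                raise ValueError("[grid] needs either file= or extent/h/sigma")
            grid = mesh.build_cuboid_grid(
                self.grid_extent, self.grid_h, self.grid_sigma, self.grid_fiber_axis
            )
        if self.endo_box is not None:
            if self.endo_sigma is None:
                raise ValueError("[grid] endo_box requires endo_sigma")
            grid = mesh.tag_region(
                grid, (self.endo_box[:3], self.endo_box[3:]), self.endo_tag, self.endo_sigma
            )
        return grid

    def build_network(self) -> mesh.PurkinjeNetwork | None:
        if self.purkinje_file is not None:
            return mesh.read_network(self.purkinje_file)
        if self.purkinje_branch_length is None:
            return None
        if self.purkinje_h is None or self.purkinje_sigma is None:
            raise ValueError("[purkinje] needs h and sigma")
        depth = 0 if self.purkinje_depth is None else self.purkinje_depth
        return mesh.build_purkinje_tree(
            depth, self.purkinje_branch_length, self.purkinje_h, self.purkinje_sigma,
            start=self.purkinje_start, direction=self.purkinje_direction,
        )

    def build_leads(self, grid) -> LeadSet | None:
        if self.sigma_b is None or not self.electrodes:
            return None
        labels = [e[0] for e in self.electrodes]
        pos = np.asarray([e[1] for e in self.electrodes], dtype=float)
        return LeadSet(labels=labels, positions=pos, sigma_b=self.sigma_b)

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


_FLOAT_KEYS = {
    "main": {"t_max", "beta", "cm", "activation_threshold"},
    "grid": {"h"},
    "purkinje": {"branch_length", "h", "sigma"},
    "pmj": {"r_pmj"},
    "ode": {"dt_ode", "dt_pde"},
    "linear_solver": {"tol"},
    "ecg": {"sigma_b"},
}
_SECTION_KEYS = {
    "main": {"t_max", "beta", "cm", "output_every", "activation_threshold"},
    "grid": {"file", "extent", "h", "sigma", "fiber_axis", "endo_box", "endo_sigma", "endo_tag"},
    "purkinje": {"file", "depth", "branch_length", "h", "sigma", "start", "direction"},
    "pmj": {"r_pmj", "n_pmj"},
    "ode": {"dt_ode", "dt_pde", "myo_model", "purkinje_model", "method"},
    "linear_solver": {"tol", "maxit", "preconditioner", "method"},
    "ecg": {"sigma_b", "electrodes"},
}
_STIM_KEYS = {"box", "start", "duration", "amplitude", "domain"}


def _floats(text: str) -> tuple:
    return tuple(float(x) for x in text.replace(",", " ").split())


def _check_keys(section: str, items, allowed) -> None:
    for key in items:
        if key not in allowed:
            raise ValueError(f"unknown key {key!r} in section [{section}]")


def parse_config(path) -> RunConfig:
    """Parse an INI run configuration; unknown keys and sections are errors."""
    cp = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    with open(path) as fh:
        cp.read_file(fh)

    for sec in ("main", "grid"):
        if sec not in cp:
            raise ValueError(f"{path}: missing mandatory section [{sec}]")

    kw: dict = {}
    for sec in cp.sections():
        if sec.startswith("stim_"):
            _check_keys(sec, cp[sec], _STIM_KEYS)
            continue
        if sec not in _SECTION_KEYS:
            raise ValueError(f"{path}: unknown section [{sec}]")
        _check_keys(sec, cp[sec], _SECTION_KEYS[sec])

    main = cp["main"]
    kw["t_max"] = main.getfloat("t_max")
    if kw["t_max"] is None:
        raise ValueError(f"{path}: [main] requires t_max")
    for k in ("beta", "cm", "activation_threshold"):
        if k in main:
            kw[k] = main.getfloat(k)
    if "output_every" in main:
        kw["output_every"] = main.getint("output_every")

    g = cp["grid"]
    if "file" in g:
        kw["grid_file"] = g["file"]
    if "extent" in g:
        kw["grid_extent"] = _floats(g["extent"])
    if "h" in g:
        kw["grid_h"] = g.getfloat("h")
    if "sigma" in g:
        kw["grid_sigma"] = _floats(g["sigma"])
    if "fiber_axis" in g:
        kw["grid_fiber_axis"] = _floats(g["fiber_axis"])
    if "endo_box" in g:
        kw["endo_box"] = _floats(g["endo_box"])
    if "endo_sigma" in g:
        kw["endo_sigma"] = _floats(g["endo_sigma"])
    if "endo_tag" in g:
        kw["endo_tag"] = g["endo_tag"]

    if "purkinje" in cp:
        p = cp["purkinje"]
        if "file" in p:
            kw["purkinje_file"] = p["file"]
        if "depth" in p:
            kw["purkinje_depth"] = p.getint("depth")
        if "branch_length" in p:
            kw["purkinje_branch_length"] = p.getfloat("branch_length")
        if "h" in p:
            kw["purkinje_h"] = p.getfloat("h")
        if "sigma" in p:
            kw["purkinje_sigma"] = p.getfloat("sigma")
        if "start" in p:
            kw["purkinje_start"] = _floats(p["start"])
        if "direction" in p:
            kw["purkinje_direction"] = _floats(p["direction"])

    if "pmj" in cp:
        if "r_pmj" in cp["pmj"]:
            kw["r_pmj"] = cp["pmj"].getfloat("r_pmj")
        if "n_pmj" in cp["pmj"]:
            kw["n_pmj"] = cp["pmj"].getint("n_pmj")

    if "ode" in cp:
        o = cp["ode"]
        for k in ("dt_ode", "dt_pde"):
            if k in o:
                kw[k] = o.getfloat(k)
        if "myo_model" in o:
            kw["myo_model"] = o["myo_model"]
        if "purkinje_model" in o:
            kw["purkinje_model"] = o["purkinje_model"]
        if "method" in o:
            kw["ode_method"] = o["method"]

    if "linear_solver" in cp:
        ls = cp["linear_solver"]
        if "tol" in ls:
            kw["solver_tol"] = ls.getfloat("tol")
        if "maxit" in ls:
            kw["solver_maxit"] = ls.getint("maxit")
        if "preconditioner" in ls:
            kw["solver_preconditioner"] = ls["preconditioner"]
        if "method" in ls:
            kw["solver_method"] = ls["method"]

    stimuli = []
    for sec in cp.sections():
        if not sec.startswith("stim_"):
            continue
        s = cp[sec]
        box = _floats(s["box"])
        if len(box) != 6:
            raise ValueError(f"{path}: [{sec}] box needs 6 numbers (lo, hi corners)")
        stimuli.append(StimulusBlock(
            name=sec[len("stim_"):],
            box=(box[:3], box[3:]),
            start=s.getfloat("start"),
            duration=s.getfloat("duration"),
            amplitude=s.getfloat("amplitude"),
            domain=s.get("domain", "myocardium"),
        ))
    kw["stimuli"] = tuple(stimuli)

    if "ecg" in cp:
        e = cp["ecg"]
        if "sigma_b" in e:
            kw["sigma_b"] = e.getfloat("sigma_b")
        if "electrodes" in e:
            els = []
            for chunk in e["electrodes"].split(";"):
                chunk = chunk.strip()
                if not chunk:
                    continue
                tok = chunk.split()
                if len(tok) != 4:
                    raise ValueError(
                        f"{path}: [ecg] electrode entry {chunk!r} must be 'label x y z'"
                    )
                els.append((tok[0], tuple(float(x) for x in tok[1:])))
            kw["electrodes"] = tuple(els)

    return RunConfig(**kw)


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(float(v))
    if isinstance(v, (tuple, list)):
        return " ".join(_fmt(x) for x in v)
    return str(v)


def write_config(config: RunConfig, path) -> None:
    """Write a RunConfig so that parse(write(c)) == c field-for-field."""
    lines = ["[main]"]
    lines += [f"t_max = {_fmt(config.t_max)}", f"beta = {_fmt(config.beta)}",
              f"cm = {_fmt(config.cm)}", f"output_every = {config.output_every}",
              f"activation_threshold = {_fmt(config.activation_threshold)}", "", "[grid]"]
    if config.grid_file is not None:
        lines.append(f"file = {config.grid_file}")
    if config.grid_extent is not None:
        lines.append(f"extent = {_fmt(config.grid_extent)}")
    if config.grid_h is not None:
        lines.append(f"h = {_fmt(config.grid_h)}")
    if config.grid_sigma is not None:
        lines.append(f"sigma = {_fmt(config.grid_sigma)}")
    lines.append(f"fiber_axis = {_fmt(config.grid_fiber_axis)}")
    if config.endo_box is not None:
        lines.append(f"endo_box = {_fmt(config.endo_box)}")
        lines.append(f"endo_sigma = {_fmt(config.endo_sigma)}")
        lines.append(f"endo_tag = {config.endo_tag}")
    has_purk = config.purkinje_file is not None or config.purkinje_branch_length is not None
    if has_purk:
        lines += ["", "[purkinje]"]
        if config.purkinje_file is not None:
            lines.append(f"file = {config.purkinje_file}")
        else:
            if config.purkinje_depth is not None:
                lines.append(f"depth = {config.purkinje_depth}")
            lines.append(f"branch_length = {_fmt(config.purkinje_branch_length)}")
            lines.append(f"h = {_fmt(config.purkinje_h)}")
            lines.append(f"sigma = {_fmt(config.purkinje_sigma)}")
            lines.append(f"start = {_fmt(config.purkinje_start)}")
            lines.append(f"direction = {_fmt(config.purkinje_direction)}")
        lines += ["", "[pmj]", f"r_pmj = {_fmt(config.r_pmj)}", f"n_pmj = {config.n_pmj}"]
    lines += ["", "[ode]",
              f"dt_ode = {_fmt(config.dt_ode)}", f"dt_pde = {_fmt(config.dt_pde)}",
              f"myo_model = {config.myo_model}", f"purkinje_model = {config.purkinje_model}",
              f"method = {config.ode_method}"]
    lines += ["", "[linear_solver]",
              f"tol = {_fmt(config.solver_tol)}", f"maxit = {config.solver_maxit}",
              f"preconditioner = {config.solver_preconditioner}",
              f"method = {config.solver_method}"]
    for s in config.stimuli:
        lines += ["", f"[stim_{s.name}]",
                  f"box = {_fmt(s.box[0])} {_fmt(s.box[1])}",
                  f"start = {_fmt(s.start)}", f"duration = {_fmt(s.duration)}",
                  f"amplitude = {_fmt(s.amplitude)}", f"domain = {s.domain}"]
    if config.sigma_b is not None:
        entries = "; ".join(f"{lab} {_fmt(pos)}" for lab, pos in config.electrodes)
        lines += ["", "[ecg]", f"sigma_b = {_fmt(config.sigma_b)}",
                  f"electrodes = {entries}"]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# EnSight Gold binary
# ---------------------------------------------------------------------------

def _pad80(text: str) -> bytes:
    return text.encode("ascii")[:80].ljust(80, b"\x00")


def _hexa_nodes(centers: np.ndarray, h: float) -> np.ndarray:
    """(8n, 3) corner coordinates, 8 per volume, Gold hexa8 winding."""
    offs = np.array([
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ]) * (h / 2.0)
    return (centers[:, None, :] + offs[None, :, :]).reshape(-1, 3)


def _domain_parts(result):
    parts = [("myocardium", result.grid.centers, result.grid.h, result.snapshots_m)]
    if result.network is not None and result.snapshots_p:
        parts.append(("purkinje", result.network.nodes, result.network.h, result.snapshots_p))
    return parts


def write_ensight_gold(result, out_dir, basename: str = "sim") -> dict:
    """Write case + binary geometry + one binary scalar file per snapshot.

    Each domain becomes one unstructured hexa8 part (Purkinje volumes are
    drawn as cubes of side h_P); the transmembrane potential is a
    per-element scalar. Returns the written file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(result.snapshot_times) == 0:
        raise ValueError("result contains no snapshots")
    parts = _domain_parts(result)

    geo = out / f"{basename}.geo"
    with open(geo, "wb") as fh:
        fh.write(_pad80("C Binary"))
        fh.write(_pad80("purkmyo EnSight Gold geometry"))
        fh.write(_pad80("control volumes as hexa8"))
        fh.write(_pad80("node id off"))
        fh.write(_pad80("element id off"))
        for pid, (name, centers, h, _snaps) in enumerate(parts, start=1):
            nodes = _hexa_nodes(centers, h).astype("<f4")
            nn = nodes.shape[0]
            ne = centers.shape[0]
            fh.write(_pad80("part"))
            fh.write(struct.pack("<i", pid))
            fh.write(_pad80(name))
            fh.write(_pad80("coordinates"))
            fh.write(struct.pack("<i", nn))
            for axis in range(3):
                fh.write(nodes[:, axis].tobytes())
            fh.write(_pad80("hexa8"))
            fh.write(struct.pack("<i", ne))
            conn = (np.arange(8 * ne, dtype="<i4") + 1).reshape(ne, 8)
            fh.write(conn.tobytes())

    var_files = []
    for ti in range(len(result.snapshot_times)):
        vf = out / f"{basename}.Vm.{ti + 1:06d}"
        with open(vf, "wb") as fh:
            fh.write(_pad80(f"transmembrane potential step {ti + 1}"))
            for pid, (_name, _centers, _h, snaps) in enumerate(parts, start=1):
                fh.write(_pad80("part"))
                fh.write(struct.pack("<i", pid))
                fh.write(_pad80("hexa8"))
                fh.write(np.asarray(snaps[ti], dtype="<f4").tobytes())
        var_files.append(vf)

    case = out / f"{basename}.case"
    times = " ".join(f"{t:g}" for t in result.snapshot_times)
    case.write_text(
        "FORMAT\n"
        "type: ensight gold\n\n"
        "GEOMETRY\n"
        f"model: {geo.name}\n\n"
        "VARIABLE\n"
        f"scalar per element: Vm {basename}.Vm.******\n\n"
        "TIME\n"
        "time set: 1\n"
        f"number of steps: {len(result.snapshot_times)}\n"
        "filename start number: 1\n"
        "filename increment: 1\n"
        f"time values: {times}\n"
    )
    return {"case": case, "geometry": geo, "variables": var_files}


# ---------------------------------------------------------------------------
# VTK legacy
# ---------------------------------------------------------------------------

def write_vtk_legacy(result, out_dir, mode: str = "ascii", basename: str = "sim") -> list:
    """Per-snapshot legacy unstructured-grid files with V as cell data.

    ``mode`` selects ascii or binary payloads (binary is big-endian float32
    / int32 as the legacy format requires); both carry identical content at
    float32 precision.
    """
    if mode not in ("ascii", "binary"):
        raise ValueError(f"mode must be ascii or binary, got {mode!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(result.snapshot_times) == 0:
        raise ValueError("result contains no snapshots")
    parts = _domain_parts(result)
    all_nodes = np.concatenate([_hexa_nodes(c, h) for _n, c, h, _s in parts])
    n_cells = sum(c.shape[0] for _n, c, h, _s in parts)
    conn = np.arange(8 * n_cells).reshape(n_cells, 8)

    files = []
    for ti in range(len(result.snapshot_times)):
        values = np.concatenate([np.asarray(s[ti]) for _n, _c, _h, s in parts])
        path = out / f"{basename}_{ti:06d}.vtk"
        with open(path, "wb") as fh:
            fh.write(b"# vtk DataFile Version 3.0\n")
            fh.write(f"purkmyo snapshot t={result.snapshot_times[ti]:g} ms\n".encode())
            fh.write(b"ASCII\n" if mode == "ascii" else b"BINARY\n")
            fh.write(b"DATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {all_nodes.shape[0]} float\n".encode())
            if mode == "ascii":
                np.savetxt(fh, all_nodes, fmt="%.9g")
            else:
                fh.write(all_nodes.astype(">f4").tobytes())
                fh.write(b"\n")
            fh.write(f"CELLS {n_cells} {9 * n_cells}\n".encode())
            cells = np.column_stack([np.full(n_cells, 8), conn])
            if mode == "ascii":
                np.savetxt(fh, cells, fmt="%d")
            else:
                fh.write(cells.astype(">i4").tobytes())
                fh.write(b"\n")
            fh.write(f"CELL_TYPES {n_cells}\n".encode())
            types = np.full(n_cells, 12)
            if mode == "ascii":
                np.savetxt(fh, types[:, None], fmt="%d")
            else:
                fh.write(types.astype(">i4").tobytes())
                fh.write(b"\n")
            fh.write(f"CELL_DATA {n_cells}\n".encode())
            fh.write(b"SCALARS Vm float 1\nLOOKUP_TABLE default\n")
            if mode == "ascii":
                np.savetxt(fh, values.astype(np.float32)[:, None], fmt="%.9g")
            else:
                fh.write(values.astype(">f4").tobytes())
                fh.write(b"\n")
        files.append(path)
    return files


# ---------------------------------------------------------------------------
# CSV writers
# ---------------------------------------------------------------------------

def write_activation_map(result, path, domain: str = "myocardium") -> None:
    """Per-volume activation time (ms; -1 for never activated) as CSV."""
    import pandas as pd

    if domain == "myocardium":
        idx = result.grid.indices
        lat = result.lat_m
        df = pd.DataFrame({"i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2], "lat_ms": lat})
    elif domain == "purkinje":
        if result.lat_p is None:
            raise ValueError("result has no Purkinje domain")
        df = pd.DataFrame({"volume": np.arange(len(result.lat_p)), "lat_ms": result.lat_p})
    else:
        raise ValueError(f"unknown domain {domain!r}")
    df.to_csv(path, index=False)


def write_ecg_csv(result, path) -> None:
    """Time-by-lead CSV of the pseudo-ECG traces."""
    import pandas as pd

    if result.ecg is None:
        raise ValueError("result carries no ECG traces")
    if result.ecg.shape[1] != len(result.ecg_times):
        raise ValueError("ECG trace length does not match its time base")
    df = pd.DataFrame({"time_ms": result.ecg_times})
    for li, lab in enumerate(result.lead_labels):
        df[lab] = result.ecg[li]
    df.to_csv(path, index=False)


_DELAY_COLUMNS = ["terminal", "terminal_lat_ms", "myo_lat_ms", "delay_ms", "status"]


def write_delay_csv(records, path) -> None:
    """PMJ delay table: one row per DelayRecord."""
    import pandas as pd

    rows = [
        {
            "terminal": r.terminal,
            "terminal_lat_ms": "" if r.terminal_lat is None else repr(r.terminal_lat),
            "myo_lat_ms": "" if r.myo_lat is None else repr(r.myo_lat),
            "delay_ms": "" if r.delay is None else repr(r.delay),
            "status": r.status,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_DELAY_COLUMNS).to_csv(path, index=False)


def read_delay_csv(path) -> list:
    import pandas as pd

    from .calibrate import DelayRecord

    df = pd.read_csv(path, dtype={"status": str})
    out = []
    for _, row in df.iterrows():
        def opt(v):
            return None if pd.isna(v) else float(v)

        out.append(DelayRecord(
            terminal=int(row["terminal"]),
            terminal_lat=opt(row["terminal_lat_ms"]),
            myo_lat=opt(row["myo_lat_ms"]),
            delay=opt(row["delay_ms"]),
            status=row["status"],
        ))
    return out
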