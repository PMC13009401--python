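"""Geometry layer: voxel myocardium grids, 1-D Purkinje trees, PMJ maps.

The myocardium is a set of *active* cubic control volumes on a uniform
lattice (spacing ``h``, cm). Storing only active volumes makes wedges and
irregular shapes the same type as full cuboids; neighbour lookup goes
through a hash of the integer lattice index. Each volume carries a local
orthonormal fibre triad (f, s, n) and conductivities (sigma_f, sigma_t,
sigma_n) in mS/cm, which jointly define the anisotropic conductivity
tensor  sigma = f f^T sigma_f + s s^T sigma_t + n n^T sigma_n.

The Purkinje network is a rooted tree of 1-D control volumes with spacing
``h`` (cm); terminals (out-degree 0) are the junction sites coupled to the
myocardium through a fixed resistance R_PMJ, each to its N_PMJ nearest
myocardial volume centres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CartesianGrid",
    "PurkinjeNetwork",
    "PMJMap",
    "build_cuboid_grid",
    "tag_region",
    "build_purkinje_cable",
    "build_purkinje_tree",
    "map_pmjs",
    "read_grid",
    "write_grid",
    "read_network",
    "write_network",
]

_AXES = "xyz"


def _orthonormal_triad(fiber_axis: np.ndarray) -> np.ndarray:
    """Complete a unit fibre direction into an orthonormal (f, s, n) triad."""
    f = np.asarray(fiber_axis, dtype=float)
    nrm = np.linalg.norm(f)
    if nrm == 0:
        raise ValueError("fiber_axis must be a nonzero vector")
    f = f / nrm
    # pick the canonical axis least aligned with f to seed the sheet direction
    seed = np.eye(3)[np.argmin(np.abs(f))]
    s = seed - (seed @ f) * f
    s /= np.linalg.norm(s)
    n = np.cross(f, s)
    return np.stack([f, s, n])


@dataclass
class CartesianGrid:
    """Active cubic control volumes on a uniform lattice.

    Attributes
    ----------
    h : lattice spacing, cm.
    indices : (N, 3) int array of lattice indices (i, j, k); 0-based.
    tags : (N,) array of region labels (e.g. ``bulk``, ``dense-endo``).
    sigmas : (N, 3) conductivities (sigma_f, sigma_t, sigma_n), mS/cm.
    fibers : (N, 3, 3) per-volume triad; rows are f, s, n.
    """

    h: float
    indices: np.ndarray
    tags: np.ndarray
    sigmas: np.ndarray
    fibers: np.ndarray
    _lookup: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64).reshape(-1, 3)
        self.tags = np.asarray(self.tags, dtype=object)
        self.sigmas = np.asarray(self.sigmas, dtype=float).reshape(-1, 3)
        self.fibers = np.asarray(self.fibers, dtype=float).reshape(-1, 3, 3)
        self.validate()
        self._lookup = {tuple(ijk): r for r, ijk in enumerate(map(tuple, self.indices))}

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.h <= 0:
            raise ValueError("spacing h must be positive")
        if len({tuple(ijk) for ijk in self.indices}) != len(self.indices):
            raise ValueError("duplicate lattice indices in grid")
        if np.any(self.sigmas < 0):
            raise ValueError("conductivities must be non-negative")
        gram = np.einsum("vab,vcb->vac", self.fibers, self.fibers)
        if not np.allclose(gram, np.eye(3), atol=1e-10):
            raise ValueError("fibre triads must be orthonormal to 1e-10")

    # -- derived -------------------------------------------------------
    @property
    def n_volumes(self) -> int:
        return self.indices.shape[0]

    @property
    def centers(self) -> np.ndarray:
        """Volume centres, cm: ((i,j,k) + 1/2) h."""
        return (self.indices + 0.5) * self.h

    @property
    def volume(self) -> float:
        """Control-volume measure h^3, cm^3."""
        return self.h ** 3

    def row_of(self, ijk) -> int | None:
        return self._lookup.get(tuple(ijk))

    def conductivity_tensors(self) -> np.ndarray:
        """(N, 3, 3) full conductivity tensors from triads and sigmas."""
        return np.einsum("vd,vda,vdb->vab", self.sigmas, self.fibers, self.fibers)

    def replace(self, **kwargs) -> "CartesianGrid":
        data = dict(
            h=self.h,
            indices=self.indices.copy(),
            tags=self.tags.copy(),
            sigmas=self.sigmas.copy(),
            fibers=self.fibers.copy(),
        )
        data.update(kwargs)
        return CartesianGrid(**data)


def _axis_count(extent: float, h: float, axis: int) -> int:
    n = extent / h
    if abs(n - round(n)) > 1e-9 * max(1.0, abs(n)):
        raise ValueError(
            f"extent {extent} cm along axis {_AXES[axis]} is not an integer "
            f"multiple of h = {h} cm"
        )
    return int(round(n))


def build_cuboid_grid(
    extent,
    h: float,
    sigma,
    fiber_axis=(1.0, 0.0, 0.0),
    tag: str = "bulk",
) -> CartesianGrid:
    """Full cuboid of ``prod(round(extent_a / h))`` volumes.

    ``extent`` is the physical size per axis in cm and must be commensurate
    with ``h``; ``sigma`` is the uniform (sigma_f, sigma_t, sigma_n) triple;
    the uniform fibre triad is completed from ``fiber_axis`` (default x).
    """
    if h <= 0:
        raise ValueError("spacing h must be positive")
    counts = [_axis_count(e, h, a) for a, e in enumerate(extent)]
    if min(counts) < 1:
        raise ValueError("extent must contain at least one volume per axis")
    ii, jj, kk = np.meshgrid(*(np.arange(c) for c in counts), indexing="ij")
    indices = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    n = indices.shape[0]
    triad = _orthonormal_triad(np.asarray(fiber_axis, dtype=float))
    return CartesianGrid(
        h=h,
        indices=indices,
        tags=np.array([tag] * n, dtype=object),
        sigmas=np.tile(np.asarray(sigma, dtype=float), (n, 1)),
        fibers=np.tile(triad, (n, 1, 1)),
    )


def tag_region(grid: CartesianGrid, box, tag: str, sigma) -> CartesianGrid:
    """Retag volumes whose centres lie in the half-open box [lo, hi).

    ``box`` is ((x0, y0, z0), (x1, y1, z1)) in cm. Matching volumes get the
    new tag and conductivity triple; everything else is untouched. An empty
    intersection warns and returns the grid unchanged.
    """
    lo, hi = (np.asarray(b, dtype=float) for b in box)
    c = grid.centers
    inside = np.all((c >= lo) & (c < hi), axis=1)
    if not inside.any():
        warnings.warn(f"tag_region: box {box} contains no volume centres", stacklevel=2)
        return grid
    out = grid.replace()
    out.tags[inside] = tag
    out.sigmas[inside] = np.asarray(sigma, dtype=float)
    return out


# ---------------------------------------------------------------------------
# Purkinje networks
# ---------------------------------------------------------------------------

@dataclass
class PurkinjeNetwork:
    """Rooted tree of 1-D control volumes.

    ``nodes`` are the control-volume centres (cm); ``parent[v]`` is the
    upstream volume (-1 for the root, the His-bundle entry); ``sigma[v]``
    is the conductivity (mS/cm) of the segment joining v to its parent
    (for the root, of its first downstream segment). Faces between
    consecutive volumes take the harmonic mean of the adjacent values.
    """

    h: float
    nodes: np.ndarray
    parent: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.nodes.shape[0]
        if n == 0:
            raise ValueError("network must contain at least one volume")
        if self.h <= 0:
            raise ValueError("spacing h must be positive")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"network must have exactly one root, found {len(roots)}")
        if np.any(self.sigma <= 0):
            raise ValueError("Purkinje conductivity must be positive")
        # connectivity: walk up from every node and confirm it reaches the root
        root = roots[0]
        for v in range(n):
            seen, u = 0, v
            while self.parent[u] >= 0:
                u = int(self.parent[u])
                seen += 1
                if seen > n:
                    raise ValueError("cycle detected in network parents")
            if u != root:
                raise ValueError("network is not connected to the root")
        nonroot = np.flatnonzero(self.parent >= 0)
        if nonroot.size:
            d = np.linalg.norm(self.nodes[nonroot] - self.nodes[self.parent[nonroot]], axis=1)
            if np.any(np.abs(d - self.h) > 1e-8):
                bad = nonroot[np.argmax(np.abs(d - self.h))]
                raise ValueError(
                    f"consecutive volume distance {d.max():.6g} at volume {bad} "
                    f"differs from h = {self.h}"
                )

    @property
    def n_volumes(self) -> int:
        return self.nodes.shape[0]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_volumes)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                ch[int(p)].append(v)
        return ch

    @property
    def terminals(self) -> np.ndarray:
        """Volumes with no children (out-degree 0), in index order."""
        has_child = np.zeros(self.n_volumes, dtype=bool)
        has_child[self.parent[self.parent >= 0]] = True
        return np.flatnonzero(~has_child)

    @property
    def volume(self) -> float:
        """Per-volume measure: regular hexahedron of side h, cm^3."""
        return self.h ** 3


def build_purkinje_cable(
    length: float,
    h: float,
    sigma: float,
    start=(0.0, 0.0, 0.0),
    direction=(1.0, 0.0, 0.0),
) -> PurkinjeNetwork:
    """Straight unbranched cable of ``round(length / h)`` volumes."""
    n = _axis_count(length, h, 0)
    if n < 1:
        raise ValueError("cable must contain at least one volume")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    start = np.asarray(start, dtype=float)
    nodes = start + np.outer((np.arange(n) + 0.5) * h, d)
    parent = np.arange(-1, n - 1)
    return PurkinjeNetwork(h=h, nodes=nodes, parent=parent, sigma=np.full(n, float(sigma)))


def _rot_xy(direction: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = direction
    return np.array([c * x - s * y, s * x + c * y, z])


def build_purkinje_tree(
    depth: int,
    branch_length: float,
    h: float,
    sigma: float,
    start=(0.0, 0.0, 0.0),
    direction=(1.0, 0.0, 0.0),
) -> PurkinjeNetwork:
    """Symmetric binary tree fixture: 2^depth terminals.

    Depth 0 is a single straight cable. Each bifurcation splits at +-45
    degrees in the xy-plane; the geometry only matters for PMJ distances,
    the 1-D operator sees topology and spacing alone. Total volumes are
    (2^(depth+1) - 1) * (branch_length / h).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    per_branch = _axis_count(branch_length, h, 0)
    if per_branch < 1:
        raise ValueError("branch_length must contain at least one volume")
    nodes: list[np.ndarray] = []
    parent: list[int] = []

    def add_branch(first: np.ndarray, direction: np.ndarray, up: int, level: int) -> None:
        # first = centre of the branch's first volume, placed exactly h from
        # the upstream volume centre so spacing holds through bifurcations
        d = direction / np.linalg.norm(direction)
        prev = up
        for s_i in range(per_branch):
            nodes.append(first + s_i * h * d)
            parent.append(prev)
            prev = len(nodes) - 1
        if level < depth:
            tip = nodes[prev]
            for sign in (+1.0, -1.0):
                child_dir = _rot_xy(d, sign * np.pi / 4)
                add_branch(tip + h * child_dir, child_dir, prev, level + 1)

    d0 = np.asarray(direction, dtype=float)
    d0 = d0 / np.linalg.norm(d0)
    add_branch(np.asarray(start, dtype=float) + 0.5 * h * d0, d0, -1, 0)
    return PurkinjeNetwork(
        h=h,
        nodes=np.asarray(nodes),
        parent=np.asarray(parent, dtype=np.int64),
        sigma=np.full(len(nodes), float(sigma)),
    )


# ---------------------------------------------------------------------------
# PMJ map
# ---------------------------------------------------------------------------

@dataclass
class PMJMap:
    """Per-terminal coupling sets: the N_PMJ nearest myocardial volumes.

    ``coupled`` holds, per terminal, the (N_PMJ, 3) lattice indices of the
    coupled myocardial volumes sorted by ascending distance from the
    terminal centre (ties broken by lattice lexicographic order, so the map
    is independent of grid storage order). ``r_pmj`` is the junction
    resistance in kOhm.
    """

    terminals: np.ndarray          # Purkinje volume indices
    coupled: list[np.ndarray]      # per-terminal (N_PMJ, 3) lattice indices
    r_pmj: float
    n_pmj: int

    def __post_init__(self) -> None:
        if self.r_pmj <= 0:
            raise ValueError("R_PMJ must be positive")
        if self.n_pmj < 1:
            raise ValueError("N_PMJ must be >= 1")
        for t, lst in zip(self.terminals, self.coupled):
            if len({tuple(ijk) for ijk in lst}) != len(lst):
                raise ValueError(f"duplicate coupled volume for terminal {t}")

    def rows(self, grid: CartesianGrid) -> list[np.ndarray]:
        """Resolve lattice indices to grid storage rows."""
        out = []
        for lst in self.coupled:
            rows = [grid.row_of(ijk) for ijk in lst]
            if any(r is None for r in rows):
                raise ValueError("PMJ map references a volume absent from the grid")
            out.append(np.asarray(rows, dtype=np.int64))
        return out


def map_pmjs(
    network: PurkinjeNetwork, grid: CartesianGrid, n_pmj: int, r_pmj: float
) -> PMJMap:
    """Couple every terminal to its ``n_pmj`` nearest myocardial volumes.

    Distance is Euclidean from the terminal centre to the volume centres;
    exact ties are broken by ascending lattice (i, j, k) order so the result
    is deterministic and independent of grid storage order.
    """
    if n_pmj > grid.n_volumes:
        raise ValueError(
            f"N_PMJ = {n_pmj} exceeds the {grid.n_volumes} active myocardial volumes"
        )
    centers = grid.centers
    idx = grid.indices
    terminals = network.terminals
    coupled = []
    for t in terminals:
        d = np.linalg.norm(centers - network.nodes[t], axis=1)
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d))
        coupled.append(idx[order[:n_pmj]].copy())
    return PMJMap(terminals=terminals, coupled=coupled, r_pmj=float(r_pmj), n_pmj=int(n_pmj))


# ---------------------------------------------------------------------------
# Plain-text formats
# ---------------------------------------------------------------------------
# Grid:    header "h <cm>", then per volume
#          "i j k tag sf st sn fx fy fz sx sy sz nx ny nz"
# Network: header "h <cm>", then node lines "id x y z",
#          then edge lines "parent child sigma"

def write_grid(grid: CartesianGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"h {float(grid.h)!r}\n")
        for r in range(grid.n_volumes):
            i, j, k = (int(x) for x in grid.indices[r])
            nums = [*grid.sigmas[r], *grid.fibers[r].ravel()]
            fields = [str(i), str(j), str(k), str(grid.tags[r]),
                      *(repr(float(x)) for x in nums)]
            fh.write(" ".join(fields) + "\n")


def _fail_line(path, lineno: int, msg: str):
    raise ValueError(f"{path}: line {lineno}: {msg}")


def read_grid(path) -> CartesianGrid:
    indices, tags, sigmas, fibers = [], [], [], []
    h = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if h is None:
                if tok[0] != "h" or len(tok) != 2:
                    _fail_line(path, lineno, "expected header 'h <cm>'")
                h = float(tok[1])
                continue
            if len(tok) != 16:
                _fail_line(path, lineno, f"expected 16 fields, got {len(tok)}")
            try:
                indices.append([int(t) for t in tok[:3]])
                tags.append(tok[3])
                vals = [float(t) for t in tok[4:]]
            except ValueError:
                _fail_line(path, lineno, "malformed numeric field")
            sigmas.append(vals[:3])
            fibers.append(np.asarray(vals[3:]).reshape(3, 3))
    if h is None or not indices:
        raise ValueError(f"{path}: empty grid file")
    return CartesianGrid(
        h=h,
        indices=np.asarray(indices),
        tags=np.asarray(tags, dtype=object),
        sigmas=np.asarray(sigmas),
        fibers=np.asarray(fibers),
    )


def write_network(net: PurkinjeNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"h {float(net.h)!r}\n")
        for v in range(net.n_volumes):
            x, y, z = (float(c) for c in net.nodes[v])
            fh.write(f"{v} {x!r} {y!r} {z!r}\n")
        for v in range(net.n_volumes):
            p = int(net.parent[v])
            if p >= 0:
                fh.write(f"{p} {v} {float(net.sigma[v])!r}\n")


def read_network(path) -> PurkinjeNetwork:
    h = None
    nodes: dict[int, list[float]] = {}
    edges: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if h is None:
                if tok[0] != "h" or len(tok) != 2:
                    _fail_line(path, lineno, "expected header 'h <cm>'")
                h = float(tok[1])
                continue
            if len(tok) == 4:
                try:
                    nodes[int(tok[0])] = [float(t) for t in tok[1:]]
                except ValueError:
                    _fail_line(path, lineno, "malformed node line")
            elif len(tok) == 3:
                try:
                    edges.append((int(tok[0]), int(tok[1]), float(tok[2])))
                except ValueError:
                    _fail_line(path, lineno, "malformed edge line")
            else:
                _fail_line(path, lineno, f"expected node (4) or edge (3) fields, got {len(tok)}")
    if h is None or not nodes:
        raise ValueError(f"{path}: empty network file")
    n = len(nodes)
    if sorted(nodes) != list(range(n)):
        raise ValueError(f"{path}: node ids must be 0..{n - 1}")
    coords = np.asarray([nodes[v] for v in range(n)])
    parent = np.full(n, -1, dtype=np.int64)
    sigma = np.zeros(n)
    for p, c, s in edges:
        if not (0 <= p < n and 0 <= c < n):
            raise ValueError(f"{path}: edge ({p}, {c}) references unknown node")
        if parent[c] >= 0:
            raise ValueError(f"{path}: node {c} has two parents")
        parent[c] = p
        sigma[c] = s
    roots = np.flatnonzero(parent < 0)
    if len(roots) != 1:
        raise ValueError(f"{path}: network must have exactly one root, found {len(roots)}")
    root = int(roots[0])
    root_children = [c for c, _p in enumerate(parent) if _p == root]
    sigma[root] = sigma[root_children[0]] if root_children else 1.0
    return PurkinjeNetwork(h=h, nodes=coords, parent=parent, sigma=sigma)
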