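"""Pseudo-ECG in an unbounded homogeneous volume conductor.

The extracellular potential at an electrode is the 1/r-weighted sum of the
diffusion source term over the tissue,

    phi_e = 1/(4 pi sigma_b) * sum_i (div(sigma grad V))_i / ||r_i||,

where the per-volume source is exactly the stiffness-operator product
-(K V)_i already available from the PDE solve (volume-integrated, uA) and
r_i runs from each volume centre to the electrode. No torso geometry:
electrodes simply sit outside the tissue in the same conductor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import CartesianGrid

__all__ = ["LeadSet", "compute_pseudo_ecg", "correlate_ecg"]


@dataclass
class LeadSet:
    """Electrode labels and positions (cm) plus bath conductivity (mS/cm)."""

    labels: list[str]
    positions: np.ndarray
    sigma_b: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.labels) != self.positions.shape[0]:
            raise ValueError("one label per electrode required")
        if self.sigma_b <= 0:
            raise ValueError("bath conductivity must be positive")


def compute_pseudo_ecg(
    stiffness, v_m: np.ndarray, grid: CartesianGrid, leads: LeadSet
) -> np.ndarray:
    """Per-lead potentials for one snapshot of the transmembrane potential.

    ``stiffness`` is the diffusion-only flux operator K (not the full
    backward-Euler matrix); the source is -(K v) per volume. An electrode
    closer than h/2 to any volume centre sits inside the tissue and is
    rejected.
    """
    v_m = np.asarray(v_m, dtype=float)
    if v_m.shape[0] != grid.n_volumes:
        raise ValueError("potential vector does not match the grid")
    src = -(stiffness @ v_m)
    centers = grid.centers
    out = np.empty(len(leads.labels))
    for e, pos in enumerate(leads.positions):
        r = np.linalg.norm(centers - pos, axis=1)
        if np.any(r < grid.h / 2):
            raise ValueError(
                f"electrode {leads.labels[e]!r} lies inside the tissue "
                f"(distance {r.min():.4g} cm < h/2)"
            )
        out[e] = np.sum(src / r)
    return out / (4.0 * np.pi * leads.sigma_b)


def correlate_ecg(sim: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-lead Pearson correlation between two (n_leads, T) trace sets.

    Returns (per-lead r, unweighted mean over defined leads). A lead with
    zero variance in either trace yields NaN for that lead and is excluded
    from the mean.
    """
    sim = np.atleast_2d(np.asarray(sim, dtype=float))
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    if sim.shape != ref.shape:
        raise ValueError(f"trace shapes differ: {sim.shape} vs {ref.shape}")
    if sim.shape[1] < 2:
        raise ValueError("at least two samples per lead required")
    r = np.empty(sim.shape[0])
    for ld in range(sim.shape[0]):
        a = sim[ld] - sim[ld].mean()
        b = ref[ld] - ref[ld].mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        r[ld] = np.nan if (na == 0.0 or nb == 0.0) else float(a @ b / (na * nb))
    defined = ~np.isnan(r)
    mean = float(np.mean(r[defined])) if defined.any() else float("nan")
    return r, mean
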