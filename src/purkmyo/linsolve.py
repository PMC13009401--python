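"""Sparse iterative solvers with an explicit convergence contract.

The diffusion solves of the monodomain scheme are symmetric positive
definite, so the workhorse is a Jacobi-preconditioned conjugate gradient.
A biconjugate gradient fallback is provided for operators whose assembly
asymmetry exceeds the symmetrisation tolerance.

Both solvers report iterations, raw and preconditioned residual norms and
the failure cause on breakdown, rather than raising, so the time loop can
attach solver diagnostics to its run log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import issparse

DEFAULT_TOL = 1e-10
DEFAULT_MAXIT = 5000


@dataclass
class SolveReport:
    """Outcome of one iterative solve."""

    method: str
    iterations: int
    residual: float                 # ||b - Ax|| (raw)
    preconditioned_residual: float  # ||M^-1 (b - Ax)||, = residual when unpreconditioned
    converged: bool
    failure: str | None = None

    def __post_init__(self) -> None:
        if self.converged and self.failure is not None:
            raise ValueError("a converged solve cannot carry a failure cause")


def _check_system(A, b: np.ndarray) -> np.ndarray:
    if A.shape[0] != A.shape[1]:
        raise ValueError(f"operator must be square, got shape {A.shape}")
    b = np.asarray(b, dtype=float)
    if b.ndim != 1 or b.shape[0] != A.shape[0]:
        raise ValueError(
            f"right-hand side of length {b.shape} does not match operator of shape {A.shape}"
        )
    return b


def _jacobi_inverse(A) -> np.ndarray:
    d = A.diagonal() if issparse(A) else np.diagonal(A).copy()
    if np.any(d == 0.0):
        raise ValueError("Jacobi preconditioner undefined: zero on the diagonal")
    return 1.0 / d


def cg_solve(
    A,
    b: np.ndarray,
    tol: float = DEFAULT_TOL,
    maxit: int = DEFAULT_MAXIT,
    preconditioner: str = "jacobi",
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, SolveReport]:
    """Preconditioned conjugate gradient for symmetric positive definite systems.

    Parameters
    ----------
    A : sparse or dense square matrix, assumed symmetric.
    b : right-hand side vector.
    tol : relative tolerance on the preconditioned residual norm,
        measured against ``||b||`` (preconditioned).
    preconditioner : ``"none"`` or ``"jacobi"``.
    x0 : optional initial guess (warm start from the previous time level).

    Returns the solution vector and a :class:`SolveReport`. A breakdown
    (``p^T A p <= 0``, i.e. the operator is not positive definite along the
    search direction) is reported, not raised.
    """
    b = _check_system(A, b)
    n = b.shape[0]
    if preconditioner not in ("none", "jacobi"):
        raise ValueError(f"unknown preconditioner {preconditioner!r}")
    minv = _jacobi_inverse(A) if preconditioner == "jacobi" else None

    x = np.zeros(n) if x0 is None else np.array(x0, dtype=float)
    bnorm = float(np.linalg.norm(minv * b if minv is not None else b))
    if bnorm == 0.0 and x0 is None:
        return x, SolveReport("cg", 0, 0.0, 0.0, True)

    r = b - A @ x
    z = minv * r if minv is not None else r
    p = z.copy()
    rz = float(r @ z)
    target = tol * max(bnorm, np.finfo(float).tiny)
    pres0 = float(np.linalg.norm(z))
    if pres0 <= target:  # warm start already solves the system
        return x, SolveReport("cg", 0, float(np.linalg.norm(r)), pres0, True)

    for it in range(1, maxit + 1):
        pres = float(np.sqrt(max(rz, 0.0)))
        # note: rz = r^T M^-1 r, so sqrt(rz) is the M^-1/2-norm of the residual;
        # report the plain preconditioned norm instead for interpretability
        Ap = A @ p
        pAp = float(p @ Ap)
        if pAp <= 0.0:
            return x, SolveReport(
                "cg", it - 1, float(np.linalg.norm(b - A @ x)), pres, False,
                failure=f"breakdown: p^T A p = {pAp:.3e} <= 0 (operator not SPD)",
            )
        alpha = rz / pAp
        x += alpha * p
        r -= alpha * Ap
        z = minv * r if minv is not None else r
        rz_new = float(r @ z)
        pres = float(np.linalg.norm(z))
        if pres <= target:
            return x, SolveReport("cg", it, float(np.linalg.norm(r)), pres, True)
        beta = rz_new / rz if rz != 0.0 else 0.0
        rz = rz_new
        p = z + beta * p

    pres = float(np.linalg.norm(z))
    return x, SolveReport(
        "cg", maxit, float(np.linalg.norm(b - A @ x)), pres, False,
        failure=f"maxit {maxit} reached",
    )


def bicg_solve(
    A,
    b: np.ndarray,
    tol: float = DEFAULT_TOL,
    maxit: int = DEFAULT_MAXIT,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, SolveReport]:
    """Biconjugate gradient for general (possibly nonsymmetric) systems.

    Same convergence contract as :func:`cg_solve` but without the symmetry
    precondition; the shadow system uses ``A^T``. Unpreconditioned.
    """
    b = _check_system(A, b)
    n = b.shape[0]
    AT = A.T
    x = np.zeros(n) if x0 is None else np.array(x0, dtype=float)
    bnorm = float(np.linalg.norm(b))
    if bnorm == 0.0 and x0 is None:
        return x, SolveReport("bicg", 0, 0.0, 0.0, True)

    r = b - A @ x
    rt = r.copy()
    p = r.copy()
    pt = rt.copy()
    rho = float(rt @ r)
    target = tol * max(bnorm, np.finfo(float).tiny)
    res0 = float(np.linalg.norm(r))
    if res0 <= target:
        return x, SolveReport("bicg", 0, res0, res0, True)

    for it in range(1, maxit + 1):
        if rho == 0.0:
            res = float(np.linalg.norm(b - A @ x))
            if res <= target:
                return x, SolveReport("bicg", it - 1, res, res, True)
            return x, SolveReport(
                "bicg", it - 1, res, res, False,
                failure="breakdown: rho = 0 (shadow residual orthogonal)",
            )
        Ap = A @ p
        denom = float(pt @ Ap)
        if denom == 0.0:
            res = float(np.linalg.norm(b - A @ x))
            return x, SolveReport(
                "bicg", it - 1, res, res, False,
                failure="breakdown: pt^T A p = 0",
            )
        alpha = rho / denom
        x += alpha * p
        r -= alpha * Ap
        rt -= alpha * (AT @ pt)
        res = float(np.linalg.norm(r))
        if res <= target:
            return x, SolveReport("bicg", it, res, res, True)
        rho_new = float(rt @ r)
        beta = rho_new / rho
        rho = rho_new
        p = r + beta * p
        pt = rt + beta * pt

    res = float(np.linalg.norm(b - A @ x))
    return x, SolveReport("bicg", maxit, res, res, False, failure=f"maxit {maxit} reached")
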