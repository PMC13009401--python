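"""Ionic-model plugin layer with forward-Euler and Rush-Larsen integrators.

A model exposes its resting state, its state dimension, which state indices
are Hodgkin-Huxley gates (dy/dt = (y_inf(V) - y) / tau(V)), and a rate
evaluator. States live in a plain (n_volumes, n_states) float array with the
transmembrane potential V (mV) in column 0 by convention.

Currents use the per-capacitance convention: pA/pF is numerically mV/ms at
C_m = 1 uF/cm^2, matching how stimulus amplitudes are specified. The PDE
side carries C_m separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IonicModel",
    "Rates",
    "MitchellSchaeffer",
    "register_model",
    "get_model",
    "available_models",
    "initial_states",
    "step_forward_euler",
    "step_rush_larsen",
]


@dataclass
class Rates:
    """Evaluated dynamics at one time level.

    i_ion : (n,) total ionic current, pA/pF (dV/dt contribution is -i_ion).
    deta : (n, n_states) time derivatives; column 0 (V) is ignored by the
        integrators, which use -i_ion + i_stim instead. Gating columns are
        the forward-Euler form (y_inf - y)/tau, consistent with y_inf/tau.
    y_inf, tau : (n, n_gates) steady states and time constants for the
        model's gating indices, frozen at the current V (and any other
        instantaneous drivers).
    """

    i_ion: np.ndarray
    deta: np.ndarray
    y_inf: np.ndarray
    tau: np.ndarray


class IonicModel:
    """Base class; subclasses define name, n_states, gating_indices, rates()."""

    name: str = "abstract"
    n_states: int = 1
    gating_indices: tuple[int, ...] = ()

    def rest_state(self) -> np.ndarray:
        raise NotImplementedError

    def rates(self, states: np.ndarray) -> Rates:
        raise NotImplementedError


def initial_states(model: IonicModel, n_volumes: int) -> np.ndarray:
    """(n_volumes, n_states) block, every volume at the model's rest state."""
    return np.tile(model.rest_state(), (n_volumes, 1))


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr).all(axis=-1) if arr.ndim > 1
                                 else ~np.isfinite(arr))[0])
        raise FloatingPointError(f"non-finite {what} at volume {bad}")


def step_forward_euler(
    model: IonicModel, states: np.ndarray, dt: float, i_stim: np.ndarray | float = 0.0
) -> np.ndarray:
    """One explicit Euler step of the reaction system.

    V <- V + dt * (-I_ion + I_stim); eta <- eta + dt * f(V, eta).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    r = model.rates(states)
    _check_finite(r.i_ion, "ionic current")
    _check_finite(r.deta, "state derivative")
    out = states + dt * r.deta
    out[:, 0] = states[:, 0] + dt * (-r.i_ion + i_stim)
    return out


def step_rush_larsen(
    model: IonicModel, states: np.ndarray, dt: float, i_stim: np.ndarray | float = 0.0
) -> np.ndarray:
    """Rush-Larsen step: exponential update for gates, Euler elsewhere.

    Gates follow y <- y_inf + (y - y_inf) exp(-dt/tau) with y_inf, tau frozen
    at the current state; unconditionally stable for the gating subsystem.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    r = model.rates(states)
    _check_finite(r.i_ion, "ionic current")
    _check_finite(r.deta, "state derivative")
    out = states + dt * r.deta
    out[:, 0] = states[:, 0] + dt * (-r.i_ion + i_stim)
    if model.gating_indices:
        if np.any(r.tau <= 0):
            raise FloatingPointError("non-positive gating time constant")
        g = list(model.gating_indices)
        y = states[:, g]
        out[:, g] = r.y_inf + (y - r.y_inf) * np.exp(-dt / r.tau)
    return out


# ---------------------------------------------------------------------------
# Phenomenological two-variable model
# ---------------------------------------------------------------------------

@dataclass
class MitchellSchaeffer(IonicModel):
    """Two-variable excitable model rescaled to physiological voltages.

    The normalised Mitchell-Schaeffer formulation (activation variable
    u in [0, 1], recovery gate w) is mapped onto V = V_rest + V_amp * u so
    the model speaks mV and pA/pF like the biophysical models:

        du/dt = w u^2 (1 - u) / tau_in - u / tau_out
        dw/dt = (1 - w)/tau_open  if u < u_gate  else  -w / tau_close

    The gate is piecewise Hodgkin-Huxley (y_inf 1 or 0, tau tau_open or
    tau_close), so Rush-Larsen applies to it exactly. The rest state
    (V_rest, 1) is an exact fixed point. tau_in sets the upstroke speed;
    the default gives a maximum upstroke around 100 mV/ms, in the
    physiological range for working myocardium, and a plateau action
    potential of a few hundred ms -- adequate for conduction studies where
    only the depolarisation sequence matters.
    """

    tau_in: float = 0.15     # ms, inward (upstroke) time scale
    tau_out: float = 6.0     # ms, repolarisation time scale
    tau_open: float = 120.0  # ms, gate recovery
    tau_close: float = 150.0 # ms, gate closure (sets plateau duration)
    u_gate: float = 0.13     # dimensionless threshold
    v_rest: float = -85.0    # mV
    v_amp: float = 110.0     # mV, excursion to peak

    name: str = field(default="mitchell_schaeffer", repr=False)
    n_states: int = field(default=2, repr=False)
    gating_indices: tuple[int, ...] = field(default=(1,), repr=False)

    def rest_state(self) -> np.ndarray:
        return np.array([self.v_rest, 1.0])

    def rates(self, states: np.ndarray) -> Rates:
        v = states[:, 0]
        w = states[:, 1]
        u = (v - self.v_rest) / self.v_amp
        du = w * u * u * (1.0 - u) / self.tau_in - u / self.tau_out
        i_ion = -self.v_amp * du  # pA/pF so that dV/dt = -i_ion
        below = u < self.u_gate
        y_inf = np.where(below, 1.0, 0.0)
        tau = np.where(below, self.tau_open, self.tau_close)
        deta = np.zeros_like(states)
        deta[:, 1] = (y_inf - w) / tau
        return Rates(i_ion=i_ion, deta=deta, y_inf=y_inf[:, None], tau=tau[:, None])


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, type | object] = {}


def register_model(name: str, factory) -> None:
    _REGISTRY[name] = factory


def available_models() -> list[str]:
    return sorted(_REGISTRY)


def get_model(name: str, **kwargs) -> IonicModel:
    """Instantiate a registered model by name; unknown names list what exists."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown ionic model {name!r}; available: {', '.join(available_models())}"
        ) from None
    return factory(**kwargs)


register_model("mitchell_schaeffer", MitchellSchaeffer)


def _register_tentusscher() -> None:
    from .tentusscher import TenTusscher2006Epi

    register_model("tentusscher", TenTusscher2006Epi)


_register_tentusscher()
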