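"""ten Tusscher-Panfilov (2006) human ventricular model, epicardial variant.

Nineteen state variables: V plus twelve Hodgkin-Huxley gates (m, h, j, d,
f, f2, fCass, r, s, xs, xr1, xr2), the ryanodine-receptor availability
R_bar, and intracellular/subspace/SR calcium and Na+/K+ concentrations.
Currents are expressed per unit capacitance (pA/pF). The gate fCass is
driven by subspace calcium rather than voltage but retains the
(y_inf, tau) form, so Rush-Larsen applies to all twelve gates.

The shipped rest state is the model's quiescent (unpaced) equilibrium,
obtained by integrating the resting cell for 20 s of model time and then
polishing with a Newton solve; it is a fixed point of the dynamics to
machine precision. Note this differs from the paced steady state usually
quoted for the model: without stimulation the Na+/K+ pump slowly depletes
intracellular sodium until the fluxes balance exactly.
"""

from __future__ import annotations

import numpy as np

from .ionic import IonicModel, Rates

# physical constants
_R = 8314.472     # mJ / (mol K)
_T = 310.0        # K
_F = 96485.3415   # C / mol
_RTF = _R * _T / _F

# extracellular concentrations (mM)
_Ko = 5.4
_Nao = 140.0
_Cao = 2.0

# cell geometry / capacitance (as in the published formulation)
_Vc = 0.016404
_Vsr = 0.001094
_Vss = 0.00005468
_Cm = 0.185

# maximal conductances (epicardial)
_GNa = 14.838
_GK1 = 5.405
_Gto = 0.294
_GKr = 0.153
_GKs = 0.392
_GCaL = 3.98e-5
_GbNa = 2.9e-4
_GbCa = 5.92e-4
_GpCa = 0.1238
_GpK = 0.0146
_PNaK = 2.724
_kNaCa = 1000.0
_KpCa = 0.0005
_KmK = 1.0
_KmNa = 40.0
_KmNai = 87.5
_KmCa = 1.38
_ksat = 0.1
_gamma = 0.35
_alpha_naca = 2.5
_pKNa = 0.03

# calcium handling
_Vrel = 0.102
_k1p = 0.15
_k2p = 0.045
_k3 = 0.060
_k4 = 0.005
_EC = 1.5
_max_sr = 2.5
_min_sr = 1.0
_Vleak = 3.6e-4
_Vxfer = 0.0038
_Vmaxup = 6.375e-3
_Kup = 2.5e-4
_Bufc = 0.2
_Kbufc = 0.001
_Bufsr = 10.0
_Kbufsr = 0.3
_Bufss = 0.4
_Kbufss = 0.00025

# state layout
STATE_NAMES = (
    "V", "m", "h", "j", "d", "f", "f2", "fCass", "r", "s", "xs", "xr1", "xr2",
    "Rbar", "Cai", "CaSR", "Cass", "Nai", "Ki",
)
_GATES = tuple(range(1, 13))

# equilibrated quiescent state (see module docstring)
_REST = np.array([
    -8.605063924732e+01, 1.440668088343e-03, 7.667185863192e-01,
    7.667185863192e-01, 3.022678437285e-05, 9.999201918891e-01,
    9.995444960267e-01, 9.999984555247e-01, 2.107651262310e-08,
    9.999981680502e-01, 3.050692301695e-03, 1.880409483937e-04,
    4.797053150001e-01, 9.982157483726e-01, 2.619645289486e-05,
    1.923527550336e-01, 8.022051157066e-05, 3.357461957853e+00,
    1.387954923675e+02,
])


class TenTusscher2006Epi(IonicModel):
    """Epicardial ten Tusscher-Panfilov ventricular cell (19 states)."""

    name = "tentusscher"
    n_states = 19
    gating_indices = _GATES

    def rest_state(self) -> np.ndarray:
        return _REST.copy()

    def rates(self, states: np.ndarray) -> Rates:  # noqa: C901 - one big kinetic map
        V = states[:, 0]
        m, h, j = states[:, 1], states[:, 2], states[:, 3]
        d, f, f2, fCass = states[:, 4], states[:, 5], states[:, 6], states[:, 7]
        r, s = states[:, 8], states[:, 9]
        xs, xr1, xr2 = states[:, 10], states[:, 11], states[:, 12]
        Rbar = states[:, 13]
        Cai, CaSR, Cass = states[:, 14], states[:, 15], states[:, 16]
        Nai, Ki = states[:, 17], states[:, 18]

        EK = _RTF * np.log(_Ko / Ki)
        ENa = _RTF * np.log(_Nao / Nai)
        EKs = _RTF * np.log((_Ko + _pKNa * _Nao) / (Ki + _pKNa * Nai))
        ECa = 0.5 * _RTF * np.log(_Cao / Cai)

        # fast sodium
        INa = _GNa * m ** 3 * h * j * (V - ENa)

        # L-type calcium (GHK-like driving term about +15 mV); the removable
        # singularity at V = 15 mV is avoided by nudging vshift off zero,
        # which perturbs the current by < 1e-6 relative
        vshift = V - 15.0
        vshift = np.where(np.abs(vshift) < 1e-6, 1e-6, vshift)
        expv = np.exp(2.0 * vshift / _RTF)
        ICaL = (
            _GCaL * d * f * f2 * fCass * 4.0 * vshift * _F / _RTF
            * (0.25 * Cass * expv - _Cao) / (expv - 1.0)
        )

        # potassium currents
        Ito = _Gto * r * s * (V - EK)
        IKr = _GKr * np.sqrt(_Ko / 5.4) * xr1 * xr2 * (V - EK)
        IKs = _GKs * xs ** 2 * (V - EKs)
        aK1 = 0.1 / (1.0 + np.exp(0.06 * (V - EK - 200.0)))
        bK1 = (3.0 * np.exp(0.0002 * (V - EK + 100.0)) + np.exp(0.1 * (V - EK - 10.0))) / (
            1.0 + np.exp(-0.5 * (V - EK))
        )
        IK1 = _GK1 * np.sqrt(_Ko / 5.4) * aK1 / (aK1 + bK1) * (V - EK)
        IpK = _GpK * (V - EK) / (1.0 + np.exp((25.0 - V) / 5.98))

        # pumps and exchangers
        INaK = (
            _PNaK * _Ko * Nai
            / ((_Ko + _KmK) * (Nai + _KmNa))
            / (1.0 + 0.1245 * np.exp(-0.1 * V / _RTF) + 0.0353 * np.exp(-V / _RTF))
        )
        eg = np.exp(_gamma * V / _RTF)
        eg1 = np.exp((_gamma - 1.0) * V / _RTF)
        INaCa = (
            _kNaCa
            * (eg * Nai ** 3 * _Cao - eg1 * _Nao ** 3 * Cai * _alpha_naca)
            / ((_KmNai ** 3 + _Nao ** 3) * (_KmCa + _Cao) * (1.0 + _ksat * eg1))
        )
        IpCa = _GpCa * Cai / (Cai + _KpCa)
        IbNa = _GbNa * (V - ENa)
        IbCa = _GbCa * (V - ECa)

        i_ion = INa + ICaL + Ito + IKr + IKs + IK1 + IpK + INaK + INaCa + IpCa + IbNa + IbCa

        # gate kinetics ------------------------------------------------
        m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
        am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
        bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
        tau_m = am * bm

        h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
        low = V < -40.0
        ah = np.where(low, 0.057 * np.exp(-(V + 80.0) / 6.8), 0.0)
        bh = np.where(
            low,
            2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V),
            0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
        )
        tau_h = 1.0 / (ah + bh)

        j_inf = h_inf
        aj = np.where(
            low,
            (-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
            * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
            0.0,
        )
        bj = np.where(
            low,
            0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
            0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
        )
        tau_j = 1.0 / (aj + bj)

        d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
        ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
        bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
        gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
        tau_d = ad * bd + gd

        f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
        tau_f = (
            1102.5 * np.exp(-((V + 27.0) ** 2) / 225.0)
            + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
            + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0))
            + 20.0
        )
        f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
        tau_f2 = (
            562.0 * np.exp(-((V + 27.0) ** 2) / 240.0)
            + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
            + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0))
        )
        fCass_inf = 0.6 / (1.0 + (Cass / 0.05) ** 2) + 0.4
        tau_fCass = 80.0 / (1.0 + (Cass / 0.05) ** 2) + 2.0

        r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
        tau_r = 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
        s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau_s = (
            85.0 * np.exp(-((V + 45.0) ** 2) / 320.0)
            + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0))
            + 3.0
        )

        xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
        axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
        bxs = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
        tau_xs = axs * bxs + 80.0

        xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
        axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
        bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
        tau_xr1 = axr1 * bxr1
        xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
        axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
        bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
        tau_xr2 = axr2 * bxr2

        # calcium dynamics ---------------------------------------------
        kcasr = _max_sr - (_max_sr - _min_sr) / (1.0 + (_EC / CaSR) ** 2)
        k1 = _k1p / kcasr
        k2 = _k2p * kcasr
        O = k1 * Cass ** 2 * Rbar / (_k3 + k1 * Cass ** 2)
        dRbar = -k2 * Cass * Rbar + _k4 * (1.0 - Rbar)
        Irel = _Vrel * O * (CaSR - Cass)
        Ileak = _Vleak * (CaSR - Cai)
        Iup = _Vmaxup / (1.0 + (_Kup / Cai) ** 2)
        Ixfer = _Vxfer * (Cass - Cai)

        buf_c = 1.0 / (1.0 + _Bufc * _Kbufc / (Cai + _Kbufc) ** 2)
        buf_sr = 1.0 / (1.0 + _Bufsr * _Kbufsr / (CaSR + _Kbufsr) ** 2)
        buf_ss = 1.0 / (1.0 + _Bufss * _Kbufss / (Cass + _Kbufss) ** 2)

        dCai = buf_c * (
            (Ileak - Iup) * _Vsr / _Vc
            + Ixfer
            - (IbCa + IpCa - 2.0 * INaCa) * _Cm / (2.0 * _Vc * _F)
        )
        dCaSR = buf_sr * (Iup - Irel - Ileak)
        dCass = buf_ss * (
            -Ixfer * _Vc / _Vss
            + Irel * _Vsr / _Vss
            - ICaL * _Cm / (2.0 * _Vss * _F)
        )
        dNai = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * _Cm / (_Vc * _F)
        dKi = -(IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK) * _Cm / (_Vc * _F)

        y_inf = np.stack(
            [m_inf, h_inf, j_inf, d_inf, f_inf, f2_inf, fCass_inf,
             r_inf, s_inf, xs_inf, xr1_inf, xr2_inf], axis=1)
        tau = np.stack(
            [tau_m, tau_h, tau_j, tau_d, tau_f, tau_f2, tau_fCass,
             tau_r, tau_s, tau_xs, tau_xr1, tau_xr2], axis=1)

        deta = np.zeros_like(states)
        deta[:, 1:13] = (y_inf - states[:, 1:13]) / tau
        deta[:, 13] = dRbar
        deta[:, 14] = dCai
        deta[:, 15] = dCaSR
        deta[:, 16] = dCass
        deta[:, 17] = dNai
        deta[:, 18] = dKi
        return Rates(i_ion=i_ion, deta=deta, y_inf=y_inf, tau=tau)
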