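"""Membrane mechanism kinetics for the two-compartment TC neuron.

The mechanism roster is fixed (leak, fast Na+, delayed-rectifier K+,
persistent Na+, A-type K+, L-type Ca2+, low-threshold T-type Ca2+,
SK-type Ca-activated K+, HCN cation current, and first-order intracellular
Ca2+ dynamics).  The rate functions below are this package's sourced
re-specification of the canonical published kinetics for each mechanism:

* fast Na+/K+    -- Traub-style rate functions with tunable half-point
                    shifts (``vtraub`` for Na+, ``vtraub2`` for K+);
* T-type Ca2+    -- Destexhe-1998 low-threshold current in GHK
                    (permeability) form with a joint ``shift`` and an
                    activation-only ``actshift``;
* HCN            -- Budde-1997 style single activation gate;
* SK             -- Hill activation by [Ca2+]_i (K_d 0.43 uM, Hill 4.8)
                    with a tunable gate time constant;
* persistent Na+ -- single sigmoidal activation gate (half-point -52.6 mV,
                    slope 4.6 mV), fixed 2 ms time constant;
* A-type K+      -- Huguenard-style m^4 h transient K+ current;
* L-type Ca2+    -- m^2 GHK current with Reuveni-style alpha/beta rates;
* Ca2+ dynamics  -- influx into a 0.1 um shell scaled by the buffer
                    fraction ``gamma`` plus first-order removal ``taur``.

All steady states / time constants are evaluated on a voltage grid once
per (neuron, dt) and consumed as lookup tables by the integrator, so a
tunable shift simply translates the table.

Units: V in mV, t in ms, [Ca] in mM, rates in 1/ms.  Temperature is fixed
at 36 C; gate rate constants already include the corresponding Q10
factors.  A global ``rate_factor`` multiplies every intrinsic rate (i.e.
divides every time constant) to emulate temperature manipulation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "V_GRID",
    "NV",
    "V_MIN",
    "DV",
    "N_GATES",
    "GATE_NAMES",
    "build_gate_tables",
    "ghk_factors",
    "ghk_density",
    "sk_zinf",
    "FARADAY",
    "RGAS",
    "TEMP_K",
    "CA_RESTING_MM",
]

FARADAY = 96485.332  # C/mol
RGAS = 8.31446  # J/(mol K)
TEMP_K = 309.15  # 36 C
CA_RESTING_MM = 5e-5  # 50 nM resting free calcium

# lookup-table voltage grid
V_MIN, V_MAX, DV = -150.0, 100.0, 0.25
V_GRID = np.arange(V_MIN, V_MAX + DV / 2, DV)
NV = V_GRID.size

# gate ordering inside the tables
GATE_NAMES = (
    "na_m", "na_h", "kdr_n",          # somatic Traub Na/K
    "t_m", "t_h",                     # T-type Ca
    "ih",                             # HCN
    "nap_m",                          # persistent Na
    "a_m", "a_h",                     # A-type K
    "l_m",                            # L-type Ca
    "ax_m", "ax_h", "ax_n",           # axonal Traub Na/K
)
N_GATES = len(GATE_NAMES)

_T_PHI = 2.5 ** ((36.0 - 24.0) / 10.0)  # Q10 factor for the T current


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (exp(x/y) - 1) with the removable singularity handled."""
    out = np.empty_like(x)
    small = np.abs(x / y) < 1e-6
    out[small] = y * (1.0 - x[small] / y / 2.0)
    xs = x[~small]
    out[~small] = xs / (np.exp(xs / y) - 1.0)
    return out


def _traub_na(v: np.ndarray, vtraub: float):
    vm = v - vtraub
    a_m = 0.32 * _vtrap(13.0 - vm, 4.0)
    b_m = 0.28 * _vtrap(vm - 40.0, 5.0)
    a_h = 0.128 * np.exp((17.0 - vm) / 18.0)
    b_h = 4.0 / (1.0 + np.exp((40.0 - vm) / 5.0))
    return a_m, b_m, a_h, b_h


def _traub_k(v: np.ndarray, vtraub2: float):
    vk = v - vtraub2
    a_n = 0.032 * _vtrap(15.0 - vk, 5.0)
    b_n = 0.5 * np.exp((10.0 - vk) / 40.0)
    return a_n, b_n


def _t_current(v: np.ndarray, shift: float, actshift: float):
    vm_act = v + shift + actshift
    vm_inact = v + shift
    m_inf = 1.0 / (1.0 + np.exp(-(vm_act + 57.0) / 6.2))
    h_inf = 1.0 / (1.0 + np.exp((vm_inact + 81.0) / 4.0))
    tau_m = (
        0.612 + 1.0 / (np.exp(-(vm_act + 132.0) / 16.7) + np.exp((vm_act + 16.8) / 18.2))
    ) / _T_PHI
    tau_h = np.where(
        vm_inact < -80.0,
        np.exp((vm_inact + 467.0) / 66.6),
        28.0 + np.exp(-(vm_inact + 22.0) / 10.5),
    ) / _T_PHI
    return m_inf, tau_m, h_inf, tau_h


def _ih(v: np.ndarray):
    o_inf = 1.0 / (1.0 + np.exp((v + 83.9) / 6.7))
    tau = np.exp((v + 158.6) / 11.2) / (1.0 + np.exp((v + 75.0) / 5.5))
    return o_inf, np.maximum(tau, 1.0)


def _nap(v: np.ndarray):
    m_inf = 1.0 / (1.0 + np.exp(-(v + 52.6) / 4.6))
    tau = np.full_like(v, 2.0)
    return m_inf, tau


def _ia(v: np.ndarray):
    m_inf = 1.0 / (1.0 + np.exp(-(v + 60.0) / 8.5))
    tau_m = 0.27 / (np.exp((v + 35.8) / 19.7) + np.exp(-(v + 79.7) / 12.7)) + 0.1
    h_inf = 1.0 / (1.0 + np.exp((v + 78.0) / 6.0))
    tau_h = np.where(
        v < -63.0,
        0.27 / (np.exp((v + 46.0) / 5.0) + np.exp(-(v + 238.0) / 37.5)),
        19.0,
    )
    return m_inf, np.maximum(tau_m, 0.05), h_inf, np.maximum(tau_h, 0.5)


def _il(v: np.ndarray):
    a = 0.055 * _vtrap(-27.0 - v, 3.8)
    b = 0.94 * np.exp((-75.0 - v) / 17.0)
    tau = 1.0 / (a + b)
    return a * tau, np.maximum(tau, 0.05)


def sk_zinf(cai: float) -> float:
    """SK gate steady state as a Hill function of [Ca2+]_i (mM)."""
    return 1.0 / (1.0 + (0.00043 / max(cai, 1e-9)) ** 4.8)


def build_gate_tables(params, dt: float, rate_factor: float = 1.0):
    """Build per-gate lookup tables on the voltage grid.

    Returns ``(xinf, qexp)``, each of shape ``(N_GATES, NV)``; ``qexp`` is
    ``exp(-dt * rate_factor / tau)`` so a gate update is
    ``x <- xinf + (x - xinf) * qexp``.  ``rate_factor`` > 1 speeds up every
    intrinsic rate uniformly (temperature-style manipulation); 1 is the
    identity.
    """
    if rate_factor <= 0:
        raise ValueError("rate_factor must be > 0")
    v = V_GRID
    xinf = np.empty((N_GATES, NV))
    tau = np.empty((N_GATES, NV))

    a_m, b_m, a_h, b_h = _traub_na(v, params.vtraub)
    xinf[0], tau[0] = a_m / (a_m + b_m), 1.0 / (a_m + b_m)
    xinf[1], tau[1] = a_h / (a_h + b_h), 1.0 / (a_h + b_h)
    a_n, b_n = _traub_k(v, params.vtraub2)
    xinf[2], tau[2] = a_n / (a_n + b_n), 1.0 / (a_n + b_n)

    m_inf, tau_m, h_inf, tau_h = _t_current(v, params.t_shift, params.t_actshift)
    xinf[3], tau[3] = m_inf, tau_m
    xinf[4], tau[4] = h_inf, tau_h

    xinf[5], tau[5] = _ih(v)
    xinf[6], tau[6] = _nap(v)

    m_inf, tau_m, h_inf, tau_h = _ia(v)
    xinf[7], tau[7] = m_inf, tau_m
    xinf[8], tau[8] = h_inf, tau_h

    xinf[9], tau[9] = _il(v)

    a_m, b_m, a_h, b_h = _traub_na(v, params.axon_vtraub)
    xinf[10], tau[10] = a_m / (a_m + b_m), 1.0 / (a_m + b_m)
    xinf[11], tau[11] = a_h / (a_h + b_h), 1.0 / (a_h + b_h)
    a_n, b_n = _traub_k(v, params.axon_vtraub2)
    xinf[12], tau[12] = a_n / (a_n + b_n), 1.0 / (a_n + b_n)

    tau = np.maximum(tau, 0.01)
    qexp = np.exp(-dt * rate_factor / tau)
    return xinf, qexp


def ghk_factors():
    """Voltage-dependent factors of the divalent GHK current density.

    ``i(mA/cm^2) = P * (GA(V) * ca_i - GB(V) * ca_o)`` with P in cm/s and
    concentrations in mM.  Returned as two arrays on ``V_GRID``.
    """
    x = 2.0 * FARADAY * (V_GRID * 1e-3) / (RGAS * TEMP_K)
    # 2*F * 1e-6 mol/cm^3 per mM * 1e3 mA/A
    c = 2.0 * FARADAY * 1e-3
    ga = np.empty(NV)
    gb = np.empty(NV)
    small = np.abs(x) < 1e-6
    ga[small] = c * 1.0
    gb[small] = c * 1.0
    xs = x[~small]
    ga[~small] = c * xs / (1.0 - np.exp(-xs))
    gb[~small] = c * xs * np.exp(-xs) / (1.0 - np.exp(-xs))
    return ga, gb


def ghk_density(v: float, cai: float, cao: float) -> float:
    """Scalar GHK Ca2+ current density per unit permeability (mA/cm^2 per cm/s)."""
    x = 2.0 * FARADAY * (v * 1e-3) / (RGAS * TEMP_K)
    c = 2.0 * FARADAY * 1e-3
    if abs(x) < 1e-6:
        return c * (cai - cao)
    e = np.exp(-x)
    return c * x * (cai - cao * e) / (1.0 - e)
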