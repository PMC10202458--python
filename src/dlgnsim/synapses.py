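"""Synapse models: short-term depression, dual-exponential receptors, and
the NMDA/AMPA conductance-ratio arithmetic.

Each synapse is a two-stage process.  The presynaptic stage is a
simplified Tsodyks-Markram depression model: a single resource pool R
recovers exponentially (``tau_rec``) between events and a fraction
``u0 * R`` is released per spike.  The retinogeniculate ``u0`` is 0.3,
matching the measured paired-pulse ratio of 0.73; corticothalamic
synapses use ``u0 = 0.7``.  The postsynaptic stage is a peak-normalized
difference of exponentials per receptor: AMPA 1/2.2 ms, NMDA 1/150 ms
(adult variant 74 ms), GABA-A 5/50 ms with a -70 mV reversal (-90 mV
option).  Depression acts on the single presynaptic resource, i.e.
jointly on the NMDA and AMPA components of a glutamatergic synapse.

13% of the NMDA current is carried by Ca2+; that component is computed
with the GHK flux equation, with the permeability calibrated so the Ca2+
fraction equals 13% at a configurable calibration potential (-40 mV
default, an approximate depolarized operating point).

A standard sigmoidal Mg2+ block of the NMDA conductance is available but
OFF by default: the network model is specified without it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mechanisms import ghk_density, CA_RESTING_MM

__all__ = [
    "ReceptorKinetics",
    "AMPA_KINETICS",
    "NMDA_KINETICS",
    "NMDA_KINETICS_ADULT",
    "GABA_KINETICS",
    "DepressionState",
    "SynapseSpec",
    "conductance_ratio_from_current_ratio",
    "receptor_mix_fractions",
    "presynaptic_event",
    "receptor_conductance",
    "nmda_calcium_current",
    "nmda_ca_permeability",
    "mg_block",
    "paired_pulse_ratio",
    "calibrate_tau_rec",
    "U0_RETINAL",
    "U0_CORTICAL",
    "TAU_REC_DEFAULT_MS",
    "NMDA_CA_FRACTION",
    "NMDA_CA_CALIBRATION_MV",
]

U0_RETINAL = 0.3
U0_CORTICAL = 0.7
TAU_REC_DEFAULT_MS = 700.0
NMDA_CA_FRACTION = 0.13
NMDA_CA_CALIBRATION_MV = -40.0


@dataclass(frozen=True)
class ReceptorKinetics:
    """Dual-exponential receptor: rise/decay time constants (ms), reversal
    potential (mV), and the factor normalizing a unit-weight event to a
    peak conductance of exactly 1."""

    tau_rise: float
    tau_decay: float
    e_rev: float

    def __post_init__(self):
        if not (0.0 < self.tau_rise < self.tau_decay):
            raise ValueError("require 0 < tau_rise < tau_decay")

    @property
    def t_peak(self) -> float:
        """Time of the conductance peak after a single event (ms)."""
        tr, td = self.tau_rise, self.tau_decay
        return (td * tr / (td - tr)) * math.log(td / tr)

    @property
    def norm(self) -> float:
        tp = self.t_peak
        return 1.0 / (math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise))


AMPA_KINETICS = ReceptorKinetics(1.0, 2.2, 0.0)
NMDA_KINETICS = ReceptorKinetics(1.0, 150.0, 0.0)
NMDA_KINETICS_ADULT = ReceptorKinetics(1.0, 74.0, 0.0)
GABA_KINETICS = ReceptorKinetics(5.0, 50.0, -70.0)


@dataclass
class DepressionState:
    """Tsodyks-Markram single-resource depression state."""

    u0: float = U0_RETINAL
    tau_rec: float = TAU_REC_DEFAULT_MS
    r: float = 1.0
    t_last: float = -math.inf

    def __post_init__(self):
        if not (0.0 <= self.u0 <= 1.0):
            raise ValueError("u0 must be in [0, 1]")
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be > 0")


@dataclass
class SynapseSpec:
    """One synapse instance: source/target unit ids, peak conductance (uS),
    receptor-mix fractions (AMPA, NMDA, GABA; sum 1), delay (ms)."""

    source: int
    target: int
    g: float
    mix: tuple[float, float, float]
    delay: float
    depression: DepressionState = field(default_factory=DepressionState)

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("conductance must be >= 0")
        if self.delay <= 0:
            raise ValueError("delay must be > 0")


def conductance_ratio_from_current_ratio(
    beta: float, delta_nmda: float = 40.0, delta_ampa: float = 70.0
) -> float:
    """g_NMDA / g_AMPA from the peak-current ratio beta = I_AMPA / I_NMDA.

    In voltage clamp i = g * (E - V) with E = 0 for both receptors, so the
    conductance ratio is the current ratio corrected by the driving-force
    ratio: g_NMDA/g_AMPA = 1 / (beta * (delta_nmda / delta_ampa)), where
    the deltas are the holding-to-reversal potential differences (mV).
    beta = 0.78 with 40/70 mV gives the developmental value ~2.25.
    """
    if beta <= 0 or delta_nmda <= 0 or delta_ampa <= 0:
        raise ValueError("all inputs must be > 0")
    return 1.0 / (beta * (delta_nmda / delta_ampa))


def receptor_mix_fractions(g_nmda_over_g_ampa: float | None) -> tuple[float, float, float]:
    """(AMPA, NMDA, GABA) peak-conductance fractions for a glutamatergic
    synapse with the given g_NMDA/g_AMPA ratio; ``None`` or 0 -> AMPA only."""
    if not g_nmda_over_g_ampa:
        return (1.0, 0.0, 0.0)
    if g_nmda_over_g_ampa < 0:
        raise ValueError("conductance ratio must be >= 0")
    fn = g_nmda_over_g_ampa / (1.0 + g_nmda_over_g_ampa)
    return (1.0 - fn, fn, 0.0)


def presynaptic_event(state: DepressionState, t: float) -> float:
    """Process a presynaptic spike at time ``t`` (ms); returns the released
    fraction ``u0 * R`` and updates the state in place."""
    if t < state.t_last:
        raise ValueError("events must be processed in time order")
    elapsed = t - state.t_last
    r = 1.0 - (1.0 - state.r) * math.exp(-elapsed / state.tau_rec)
    release = state.u0 * r
    state.r = r * (1.0 - state.u0)
    state.t_last = t
    return release


def paired_pulse_ratio(u0: float, isi_ms: float, tau_rec: float = TAU_REC_DEFAULT_MS) -> float:
    """Second/first release ratio for a pulse pair from rest."""
    st = DepressionState(u0=u0, tau_rec=tau_rec)
    first = presynaptic_event(st, 0.0)
    second = presynaptic_event(st, isi_ms)
    return second / first if first > 0 else 1.0


def calibrate_tau_rec(
    target_ppr: float = 0.73, u0: float = U0_RETINAL, isi_ms: float = 50.0
) -> float:
    """Recovery time constant consistent with a target paired-pulse ratio
    at a given inter-pulse interval.

    PPR = 1 - (1 - u0) ... here PPR(isi) = 1 - u0 * exp(-isi/tau_rec), so
    tau_rec = -isi / log((1 - PPR) / u0).  With u0 = 0.3 the fast-ISI
    limit is 0.7; PPR 0.73 at 50 ms gives tau_rec ~ 485 ms.
    """
    if not (1.0 - u0 < target_ppr < 1.0):
        raise ValueError("target PPR unreachable for this u0")
    return -isi_ms / math.log((1.0 - target_ppr) / u0)


def receptor_conductance(
    kin: ReceptorKinetics, weight: float, event_times, t
) -> np.ndarray | float:
    """Conductance at time(s) ``t`` from a list of past event times, by
    direct summation of peak-normalized dual exponentials."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    g = np.zeros_like(t_arr)
    for te in event_times:
        d = t_arr - te
        m = d >= 0
        g[m] += weight * kin.norm * (
            np.exp(-d[m] / kin.tau_decay) - np.exp(-d[m] / kin.tau_rise)
        )
    return g if np.ndim(t) else float(g[0])


def mg_block(v: float | np.ndarray, mg_mm: float = 1.0):
    """Sigmoidal NMDA Mg2+ unblock factor (Jahr-Stevens form). Configurable
    option; OFF in the default network model."""
    return 1.0 / (1.0 + np.exp(-0.062 * np.asarray(v)) * mg_mm / 3.57)


def nmda_ca_permeability(
    g_nmda: float,
    cao: float,
    fraction: float = NMDA_CA_FRACTION,
    v_cal: float = NMDA_CA_CALIBRATION_MV,
    cai: float = CA_RESTING_MM,
) -> float:
    """Effective Ca2+ permeability such that at the calibration potential
    the GHK Ca2+ current equals ``fraction`` of the total (ohmic, E=0)
    NMDA current carried by conductance ``g_nmda`` (uS).  Returns the
    permeability*area product in units giving nA when multiplied by the
    GHK density factor."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    if cao <= 0 or cai <= 0:
        raise ValueError("concentrations must be > 0")
    if fraction == 0.0 or g_nmda == 0.0:
        return 0.0
    i_total = g_nmda * (v_cal - 0.0)  # nA, inward (negative) at -40 mV
    dens = ghk_density(v_cal, cai, cao)  # negative (inward) at -40 mV
    return fraction * i_total / dens


def nmda_calcium_current(
    g_nmda_open: float,
    v: float,
    ca_in: float,
    ca_out: float,
    fraction: float = NMDA_CA_FRACTION,
    v_cal: float = NMDA_CA_CALIBRATION_MV,
) -> float:
    """GHK-form Ca2+ component (nA) of an open NMDA conductance (uS).

    The permeability is calibrated once at resting [Ca2+]_i and the
    calibration potential, then evaluated at the actual (v, ca_in).
    """
    p = nmda_ca_permeability(g_nmda_open, ca_out, fraction, v_cal)
    return p * ghk_density(v, ca_in, ca_out)
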