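"""Single TC neuron: construction, current-clamp protocols, validation,
and the unitary synaptic conductance g0.

A neuron here is a one-neuron :class:`~dlgnsim.engine.CompiledNetwork`.
The axon is split into an odd number of segments no longer than 0.1 of
the AC length constant at 100 Hz.  Before any protocol the model settles
to its free steady state (1 s of model time by default); the settled
state is cached and reused across protocol sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (
    CompiledNetwork,
    SynapseTable,
    axon_segment_count,
    ac_length_constant_um,
)
from .params import NeuronParams
from .synapses import TAU_REC_DEFAULT_MS, U0_RETINAL, receptor_mix_fractions

__all__ = [
    "TCNeuron",
    "RateScaling",
    "build_neuron",
    "step_current_clamp",
    "validate_model",
    "estimate_unitary_conductance",
    "InexcitableModelError",
]

SETTLE_MS = 1000.0


class InexcitableModelError(RuntimeError):
    """No bracketing conductance fires the model."""


@dataclass(frozen=True)
class RateScaling:
    """Uniform multiplier on intrinsic gating rates (temperature-style
    manipulation) plus an optional NMDA decay override.  Factor 1 and
    ``nmda_tau_decay=None`` reproduce baseline dynamics bit-for-bit."""

    intrinsic: float = 1.0
    nmda_tau_decay: float | None = None

    def __post_init__(self):
        if self.intrinsic <= 0:
            raise ValueError("rate factor must be > 0")


class TCNeuron:
    """An integrable two-compartment TC neuron."""

    def __init__(
        self,
        params: NeuronParams,
        dt: float = 0.025,
        scaling: RateScaling = RateScaling(),
        receptor_ratio: float | None = 2.25,
        synapse_g: float = 0.0,
        probe_u0: float = U0_RETINAL,
    ):
        self.params = params
        self.dt = dt
        self.scaling = scaling
        self.receptor_ratio = receptor_ratio
        mix = receptor_mix_fractions(receptor_ratio)
        # One external source with one synapse onto the soma, for unitary
        # conductance probing; weight 0 leaves the neuron input-free.
        # The probe passes through the depression stage (first event from
        # rest releases u0), so g0 is the functional network unit.
        table = SynapseTable.from_records(
            1, 1,
            [(0, 0, synapse_g, 0, max(dt, 0.1), probe_u0, TAU_REC_DEFAULT_MS, 0)],
        )
        self.net = CompiledNetwork(
            [params],
            dt=dt,
            synapses=table,
            receptor_mixes=np.array([mix]),
            nmda_tau_decay=scaling.nmda_tau_decay,
            rate_factor=scaling.intrinsic,
        )
        self._rest = None

    @property
    def n_axon_segments(self) -> int:
        return int(self.net.nseg[0])

    def rest(self) -> dict:
        """Settle to free steady state (cached)."""
        if self._rest is None:
            self.net.reset_state()
            self.net.settle(SETTLE_MS)
            self._rest = self.net.snapshot()
        self.net.restore(self._rest)
        return self._rest

    @property
    def resting_potential(self) -> float:
        self.rest()
        return float(self.net.VS[0])


def build_neuron(
    params: NeuronParams,
    dt: float = 0.025,
    axon_segmentation_hz: float = 100.0,
    **kwargs,
) -> TCNeuron:
    """Build an integrable neuron from a validated parameter set.

    Raises ``ParameterError`` (from ``NeuronParams``) on bounds violations;
    the segment count satisfies the odd / 0.1-lambda rule by construction.
    """
    n = axon_segment_count(params, axon_segmentation_hz)
    assert n % 2 == 1, "internal error: segment count must be odd"
    neuron = TCNeuron(params, dt=dt, **kwargs)
    assert neuron.n_axon_segments == n
    return neuron


def step_current_clamp(
    neuron: TCNeuron,
    protocol: list[tuple[float, float]],
    dt: float | None = None,
    pre_ms: float = 100.0,
    post_ms: float = 100.0,
) -> list[dict]:
    """Run a step-current protocol; each step is (amplitude pA, duration ms).

    Each sweep starts from the cached resting state, records ``pre_ms`` of
    baseline, the step, and ``post_ms`` of recovery.  Returns one record
    per step with the somatic voltage trace sampled at dt and the spike
    times.  Deterministic given params, protocol and dt.
    """
    if not protocol:
        raise ValueError("protocol must be non-empty")
    if dt is not None and abs(dt - neuron.dt) > 1e-12:
        raise ValueError("rebuild the neuron to change dt")
    sweeps = []
    for step_idx, (amp_pa, dur_ms) in enumerate(protocol):
        if dur_ms <= 0:
            raise ValueError(f"step {step_idx}: duration must be > 0")
        neuron.rest()
        amp_na = amp_pa * 1e-3
        segs = []
        for phase_amp, phase_dur in (
            (0.0, pre_ms), (amp_na, dur_ms), (0.0, post_ms)
        ):
            if phase_dur <= 0:
                continue
            out = neuron.net.advance(phase_dur, i_inj_nA=phase_amp, record_every=1)
            segs.append(out)
        t = np.concatenate([s["t_rec_ms"] for s in segs])
        v = np.concatenate([s["v_soma"][:, 0] for s in segs])
        spikes = np.concatenate([s["spike_times_ms"] for s in segs])
        t0 = t[0]
        sweeps.append(
            {
                "amplitude_pA": amp_pa,
                "t_ms": t - t0,
                "v_mV": v,
                "spike_times_ms": spikes - t0,
                "stim_window_ms": (pre_ms, pre_ms + dur_ms),
                "n_spikes": int(
                    np.sum((spikes - t0 >= pre_ms) & (spikes - t0 < pre_ms + dur_ms))
                ),
            }
        )
    return sweeps


def validate_model(
    params: NeuronParams,
    neuron: TCNeuron | None = None,
    propagation_fraction: float = 0.9,
) -> dict:
    """The four biophysical-correctness checks.

    Structural: axon longer than wide, axon thinner than soma, Ca-buffer
    shell shallower than the soma radius.  Dynamic: a somatic spike must
    propagate without decrement -- the distal-axon peak above the 0 mV
    spike threshold must reach at least ``propagation_fraction`` of the
    somatic peak.  Failures are results, not errors.
    """
    checks = params.structural_checks()
    reasons = {
        "axon_longer_than_wide": "axon shorter than its diameter",
        "axon_thinner_than_soma": "axon thicker than soma",
        "ca_buffer_shallower_than_soma": "Ca buffer deeper than soma radius",
        "spike_propagation": "spike fails to propagate without decrement",
    }
    prop_ok = False
    if all(checks.values()):
        if neuron is None:
            neuron = build_neuron(params)
        neuron.rest()
        out = neuron.net.advance(
            30.0, i_inj_nA=0.5, record_every=1, record_axon=True
        )
        out2 = neuron.net.advance(20.0, record_every=1, record_axon=True)
        vs = np.concatenate([out["v_soma"][:, 0], out2["v_soma"][:, 0]])
        va = np.concatenate([out["v_axon_distal"], out2["v_axon_distal"]])
        soma_amp = float(vs.max())
        axon_amp = float(va.max())
        prop_ok = soma_amp > 0.0 and axon_amp >= propagation_fraction * soma_amp
    checks["spike_propagation"] = prop_ok
    return {
        "passed": all(checks.values()),
        "checks": checks,
        "reasons": [reasons[k] for k, ok in checks.items() if not ok],
    }


def estimate_unitary_conductance(
    neuron: TCNeuron,
    g_lo: float = 1e-5,
    g_hi: float = 1.0,
    rtol: float = 0.01,
    window_ms: float = 200.0,
) -> float:
    """Minimal peak synaptic conductance g0 (uS) that triggers a single
    spike from rest with one presynaptic event, for the neuron's receptor
    mix.  Bisection to relative tolerance ``rtol``.
    """
    tab = neuron.net.synapses

    def n_spikes(g: float) -> int:
        tab.g[0] = g
        neuron.rest()
        ev = (np.array([neuron.net.t_ms + 1.0]), np.array([0]))
        out = neuron.net.advance(window_ms, stimulus_events=ev)
        return out["spike_times_ms"].size

    try:
        hi = g_hi
        if n_spikes(hi) < 1:
            raise InexcitableModelError(
                f"no spike at upper bracket g={g_hi} uS"
            )
        lo = g_lo
        if n_spikes(lo) >= 1:
            return lo
        while hi / lo > 1.0 + rtol:
            mid = np.sqrt(lo * hi)
            if n_spikes(mid) >= 1:
                hi = mid
            else:
                lo = mid
        return float(hi)
    finally:
        tab.g[0] = 0.0


__all__ += ["ac_length_constant_um"]
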