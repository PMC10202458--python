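"""Whole-network simulation runs and the perturbation experiments.

``run`` advances a compiled network under a retinal stimulus and returns
the spike raster with diagnostics (bit-reproducible given seeds and
config).  ``silence_and_measure`` freezes homeostasis in a converged
model and compares matched epochs with a feedback loop enabled/disabled
(the F_disabled/F_control firing-rate ratio used to locate in-vivo-
consistent feedback strengths).  ``scale_kinetics`` derives a model
variant with uniformly scaled intrinsic gating rates and/or an
overridden NMDA decay time (the temperature-style manipulation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .engine import CompiledNetwork
from .network import NetworkModel
from .synth import SpikeTrainSet

__all__ = ["SimulationRun", "run", "silence_and_measure", "scale_kinetics"]


@dataclass
class SimulationRun:
    """Raster plus run metadata from one simulation epoch."""

    dt_ms: float
    duration_s: float
    spike_times_s: np.ndarray
    spike_units: np.ndarray
    n_neurons: int
    t_start_s: float = 0.0

    def trains(self) -> list[np.ndarray]:
        """Per-neuron sorted spike times (s, relative to epoch start)."""
        out = []
        rel = self.spike_times_s - self.t_start_s
        for i in range(self.n_neurons):
            ti = np.sort(rel[self.spike_units == i])
            out.append(ti)
        return out

    def rates_hz(self) -> np.ndarray:
        counts = np.bincount(self.spike_units, minlength=self.n_neurons)
        return counts / self.duration_s

    def to_spike_train_set(self, positions: np.ndarray) -> SpikeTrainSet:
        return SpikeTrainSet(
            unit_ids=np.arange(self.n_neurons),
            spike_times=self.trains(),
            positions=positions,
            duration_s=self.duration_s,
            provenance="synthetic",
        )


def run(
    net: CompiledNetwork,
    stimulus: SpikeTrainSet | tuple[np.ndarray, np.ndarray],
    duration_s: float,
    time_offset_s: float = 0.0,
) -> SimulationRun:
    """Advance ``duration_s`` of model time under the given stimulus.

    ``stimulus`` may be a :class:`SpikeTrainSet` (times relative to the
    global origin plus ``time_offset_s``) or pre-flattened event arrays in
    absolute ms.  Delays must be >= dt (enforced at compile time).
    """
    if isinstance(stimulus, SpikeTrainSet):
        ev_t, ev_s = stimulus.to_events_ms()
        ev_t = ev_t + time_offset_s * 1e3
    else:
        ev_t, ev_s = stimulus
    t0 = net.t_ms
    m = (ev_t >= t0) & (ev_t < t0 + duration_s * 1e3)
    out = net.advance(duration_s * 1e3, stimulus_events=(ev_t[m], ev_s[m]))
    return SimulationRun(
        dt_ms=net.dt,
        duration_s=duration_s,
        spike_times_s=out["spike_times_ms"] / 1e3,
        spike_units=out["spike_units"],
        n_neurons=net.n,
        t_start_s=t0 / 1e3,
    )


def silence_and_measure(
    net: CompiledNetwork,
    loop_to_disable: str,
    stimulus_events: tuple[np.ndarray, np.ndarray],
    epoch_s: float = 600.0,
) -> dict:
    """Firing-rate ratio F_disabled / F_control over matched epochs.

    The network must be at homeostatic steady state; weights are frozen
    (no updates run here).  The same starting state and stimulus drive a
    control epoch and an epoch with the named loop's conductances zeroed.
    """
    cls_id = {"trn": 1, "ctx": 2}.get(loop_to_disable)
    if cls_id is None:
        raise ValueError("loop must be 'trn' or 'ctx'")
    snap = net.snapshot()
    tab = net.synapses
    control = run(net, stimulus_events, epoch_s)
    f_control = control.rates_hz().mean()

    net.restore(snap)
    saved = tab.g.copy()
    tab.g[tab.cls == cls_id] = 0.0
    try:
        disabled = run(net, stimulus_events, epoch_s)
    finally:
        tab.g[:] = saved
        net.restore(snap)
    f_disabled = disabled.rates_hz().mean()
    if f_control <= 0:
        raise ZeroDivisionError("control epoch produced no spikes; ratio undefined")
    return {
        "ratio": f_disabled / f_control,
        "f_control_hz": f_control,
        "f_disabled_hz": f_disabled,
        "loop": loop_to_disable,
        "epoch_s": epoch_s,
    }


def scale_kinetics(
    model: NetworkModel,
    intrinsic_factor: float = 1.0,
    nmda_tau_decay_ms: float | None = None,
) -> NetworkModel:
    """Model variant with scaled intrinsic gating rates and/or an adult
    NMDA decay (e.g. 74 ms); factor 1 with ``None`` is the identity."""
    if intrinsic_factor <= 0:
        raise ValueError("intrinsic factor must be > 0")
    return dc_replace(
        model,
        rate_factor=model.rate_factor * intrinsic_factor,
        nmda_tau_decay=(
            nmda_tau_decay_ms if nmda_tau_decay_ms is not None else model.nmda_tau_decay
        ),
        synapse_records=model.synapse_records,
        feedback=model.feedback,
    )
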