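"""Synthetic inputs: retinal-wave spike trains and fitting targets.

The wave generator emulates multielectrode-array recordings of the
developing retina: slow waves nucleate at random sites (with a spatial
refractory rule approximating retinal-wave refractoriness), propagate as
expanding fronts, and each covered unit fires an *independent* Poisson
train at ~10 spikes/s while the front passes.  Nearby units are therefore
co-active on the wave timescale (hundreds of ms) but carry no pairwise
structure on the millisecond timescale, and the array sits silent between
waves -- the input statistics the network model needs, without any
biophysical retina model.

Also provided: synthetic "recorded" current-clamp traces from a known
parameter set (for fitting-recovery experiments) and heterogeneous,
validated neuron populations generated by jittering a canonical set so no
external database download is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import PARAM_TABLE, NeuronParams, ParameterError, canonical_params

__all__ = [
    "WaveGenConfig",
    "SpikeTrainSet",
    "generate_waves",
    "generate_target_neuron",
    "heterogeneous_population",
    "PopulationError",
]


class PopulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class WaveGenConfig:
    """Retinal-wave emulation preset.

    Distances are in electrode-grid units (pitch 1), times in seconds.
    The default 16x16 grid comfortably exceeds the >=30 adjacent active
    channels the recordings provide.
    """

    grid_shape: tuple[int, int] = (16, 16)
    wave_rate_per_min: float = 4.0
    speed: float = 2.0  # grid units / s
    extent: float = 8.0  # maximal front radius
    front_width: float = 5.0  # radial thickness: ~2.5 s local burst dwell,
    # matching the several-second bursts of the recordings emulated
    rate_in_wave: float = 10.0  # spikes/s while the front covers a unit
    baseline_rate: float = 0.02  # spikes/s between waves
    duration_s: float = 300.0
    refractory_s: float = 30.0  # no re-nucleation nearby for this long
    seed: int = 0

    def __post_init__(self):
        if self.grid_shape[0] * self.grid_shape[1] < 30:
            raise ValueError("paper-emulating presets need >= 30 channels")
        for name in ("wave_rate_per_min", "rate_in_wave", "baseline_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.speed <= 0 or self.extent <= 0 or self.front_width <= 0:
            raise ValueError("speed, extent and front width must be > 0")


@dataclass
class SpikeTrainSet:
    """Per-unit spike times (s) plus 2-D positions."""

    unit_ids: np.ndarray
    spike_times: list[np.ndarray]  # seconds, sorted
    positions: np.ndarray  # (n, 2)
    duration_s: float
    provenance: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.spike_times) != self.unit_ids.size:
            raise ValueError("one spike train per unit required")
        if self.positions.shape != (self.unit_ids.size, 2):
            raise ValueError("one 2-D position per unit required")

    @property
    def n_units(self) -> int:
        return self.unit_ids.size

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times))

    def mean_rate_hz(self) -> float:
        return self.total_spikes() / (self.n_units * self.duration_s)

    def to_events_ms(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened, time-sorted (times_ms, unit_index) event arrays."""
        times = np.concatenate([t for t in self.spike_times]) * 1e3
        srcs = np.concatenate(
            [np.full(t.size, i, dtype=np.int64) for i, t in enumerate(self.spike_times)]
        )
        order = np.argsort(times, kind="stable")
        return times[order], srcs[order]

    def window(self, t0_s: float, t1_s: float) -> "SpikeTrainSet":
        trains = [t[(t >= t0_s) & (t < t1_s)] - t0_s for t in self.spike_times]
        return SpikeTrainSet(
            self.unit_ids.copy(), trains, self.positions.copy(),
            t1_s - t0_s, self.provenance,
        )


def _poisson_times(rng, rate_hz: float, t0: float, t1: float) -> np.ndarray:
    if rate_hz <= 0 or t1 <= t0:
        return np.zeros(0)
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def generate_waves(cfg: WaveGenConfig) -> SpikeTrainSet:
    """Generate a seeded retinal-wave spike-train set on the MEA grid."""
    rng = np.random.default_rng(cfg.seed)
    nx, ny = cfg.grid_shape
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    n_units = pos.shape[0]

    # nucleation: Poisson in time, uniform in space, spatial refractory
    rate_s = cfg.wave_rate_per_min / 60.0
    nuclei: list[tuple[float, float, float]] = []  # (t, x, y)
    t = 0.0
    while True:
        if rate_s <= 0:
            break
        t += rng.exponential(1.0 / rate_s)
        if t >= cfg.duration_s:
            break
        for _ in range(20):
            x = rng.uniform(0, nx - 1)
            y = rng.uniform(0, ny - 1)
            ok = all(
                not (t - tn < cfg.refractory_s
                     and (x - xn) ** 2 + (y - yn) ** 2 < cfg.extent**2)
                for tn, xn, yn in nuclei
            )
            if ok:
                nuclei.append((t, x, y))
                break

    trains: list[np.ndarray] = []
    for u in range(n_units):
        parts = [_poisson_times(rng, cfg.baseline_rate, 0.0, cfg.duration_s)]
        ux, uy = pos[u]
        for tn, xn, yn in nuclei:
            d = np.hypot(ux - xn, uy - yn)
            if d > cfg.extent:
                continue
            # the annular front reaches the unit at d/speed and passes in
            # front_width/speed; clip to the wave's life span
            t_on = tn + d / cfg.speed
            t_off = min(
                tn + (d + cfg.front_width) / cfg.speed,
                tn + (cfg.extent + cfg.front_width) / cfg.speed,
            )
            parts.append(
                _poisson_times(rng, cfg.rate_in_wave, t_on, min(t_off, cfg.duration_s))
            )
        train = np.sort(np.concatenate(parts))
        trains.append(train[(train >= 0) & (train < cfg.duration_s)])

    return SpikeTrainSet(
        unit_ids=np.arange(n_units),
        spike_times=trains,
        positions=pos,
        duration_s=cfg.duration_s,
        provenance="synthetic",
        meta={"nuclei": nuclei, "config": cfg},
    )


def generate_target_neuron(
    params: NeuronParams,
    protocol: list[tuple[float, float]],
    noise_sd_mV: float = 0.5,
    seed: int = 0,
    dt: float = 0.025,
) -> dict:
    """Synthetic "recorded" traces: simulate the step protocol and add
    seeded Gaussian observation noise.  Ground truth is retained for
    recovery tests."""
    from .neuron import build_neuron, step_current_clamp

    rng = np.random.default_rng(seed)
    neuron = build_neuron(params, dt=dt)
    sweeps = step_current_clamp(neuron, protocol)
    traces = []
    for sw in sweeps:
        v = sw["v_mV"].copy()
        if noise_sd_mV > 0:
            v = v + rng.normal(0.0, noise_sd_mV, v.size)
        traces.append(
            {
                "amplitude_pA": sw["amplitude_pA"],
                "t_ms": sw["t_ms"],
                "v_mV": v,
                "n_spikes": sw["n_spikes"],
                "stim_window_ms": sw["stim_window_ms"],
            }
        )
    return {
        "traces": traces,
        "protocol": list(protocol),
        "noise_sd_mV": noise_sd_mV,
        "dt": dt,
        "ground_truth": params,
    }


# characteristic scale of linear-parameter jitter, as a fraction of the
# allowed range per unit of the jitter argument
_LIN_FRACTION = 0.1


def jitter_params(
    base: NeuronParams, rng: np.random.Generator, jitter: float
) -> NeuronParams:
    """One jittered draw around ``base``: log-normal on log-scale
    parameters, Gaussian (scaled to the bound range) on linear ones,
    clipped to the open-parameter bounds."""
    kwargs = {}
    for name, (_, scale, lo, hi) in PARAM_TABLE.items():
        v = getattr(base, name)
        if scale == "log":
            v = v * np.exp(rng.normal(0.0, jitter))
        else:
            v = v + rng.normal(0.0, jitter * _LIN_FRACTION * (hi - lo))
        kwargs[name] = float(np.clip(v, lo, hi))
    # keep the structural invariants satisfiable
    kwargs["axon_diam"] = min(kwargs["axon_diam"], 0.9 * kwargs["soma_L"])
    kwargs["axon_L"] = max(kwargs["axon_L"], 2.0 * kwargs["axon_diam"])
    return NeuronParams(**kwargs)


def heterogeneous_population(
    n: int,
    rng: np.random.Generator | int | None = 0,
    base: NeuronParams | None = None,
    jitter: float = 0.15,
    validate: bool = True,
    max_attempts_factor: int = 100,
) -> list[NeuronParams]:
    """Draw ``n`` validated parameter sets around a canonical base.

    ``jitter=0`` returns a homogeneous population (the single base set
    reused).  Every returned set passes the four validation checks; a
    rejection rate above 99% raises :class:`PopulationError`.
    """
    from .neuron import build_neuron, validate_model

    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if base is None:
        base = canonical_params()
    if jitter == 0:
        return [base] * n
    out: list[NeuronParams] = []
    attempts = 0
    max_attempts = max_attempts_factor * n
    while len(out) < n:
        if attempts >= max_attempts:
            raise PopulationError(
                f"rejection rate too high: {len(out)}/{attempts} accepted"
            )
        attempts += 1
        try:
            cand = jitter_params(base, rng, jitter)
        except ParameterError:
            continue
        if validate:
            try:
                if not validate_model(cand, build_neuron(cand, dt=0.05))["passed"]:
                    continue
            except Exception:
                continue
        out.append(cand)
    return out
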