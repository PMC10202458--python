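"""Construction of the heterogeneous dLGN network model.

TC neurons sit on a hexagonal lattice (default 7x16, 112 neurons, lattice
constant 1).  Retinal ganglion cell (rGC) sources -- an electrode array
from an ex vivo recording or its synthetic emulation -- are isotropically
scaled and centered onto the lattice.  Each (rGC, TC) pair connects with
probability exp(-d^2/sigma^2) and, when connected, carries peak
conductance g0 * exp(-d^2/sigma^2), where g0 is that neuron's unitary
conductance (minimal single-event conductance that fires it from rest)
and sigma is the convergence parameter (sigma=1 ~ adult 1-3 inputs,
sigma=4 ~ 10 inputs, sigma=9 ~ 20 inputs).

TRN inhibitory and cortical excitatory feedback are sketched as
non-specific all-to-all loops: every TC spike train re-enters onto every
TC neuron (including itself) with homogeneous conductance and delay,
optionally jittered +-20% per synapse.  In the full model the TRN delay
strictly exceeds the cortical delay (the disynaptic path through cortex
is the only route to TRN at this age).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .engine import CompiledNetwork, SynapseTable
from .params import NeuronParams
from .synapses import (
    TAU_REC_DEFAULT_MS,
    U0_CORTICAL,
    U0_RETINAL,
    receptor_mix_fractions,
)

__all__ = [
    "LatticeGeometry",
    "ConvergenceSpec",
    "FeedbackSpec",
    "NetworkModel",
    "build_lattice",
    "connect_retina",
    "calibrate_density",
    "add_feedback",
    "expected_convergence",
    "GeometryError",
    "CalibrationError",
]

RETINAL_DELAY_MS = 2.0

# receptor-mix matrix rows
MIX_RETINAL = 0
MIX_CORTICAL = 1
MIX_GABA = 2


class GeometryError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LatticeGeometry:
    """Hexagonal TC lattice plus source positions mapped onto it."""

    rows: int
    cols: int
    tc_positions: np.ndarray  # (n_tc, 2), lattice units
    source_positions: np.ndarray  # (n_src, 2), after scale-and-center

    @property
    def n_tc(self) -> int:
        return self.tc_positions.shape[0]

    @property
    def n_sources(self) -> int:
        return self.source_positions.shape[0]


@dataclass(frozen=True)
class ConvergenceSpec:
    sigma: float
    g0_uS: np.ndarray  # per target neuron

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class FeedbackSpec:
    """One all-to-all feedback loop re-entering the TC population."""

    kind: str  # "trn" | "ctx"
    relative_conductance: float  # in units of each target's g0
    delay_ms: float
    jitter_fraction: float = 0.0
    u0: float | None = None  # None -> kind default (TRN: no depression)

    def __post_init__(self):
        if self.kind not in ("trn", "ctx"):
            raise ValueError("loop kind must be 'trn' or 'ctx'")
        if self.delay_ms <= 0:
            raise ValueError("delay must be > 0")
        if not (0.0 <= self.jitter_fraction <= 0.2):
            raise ValueError("jitter fraction must be in [0, 0.2]")
        if self.relative_conductance < 0:
            raise ValueError("relative conductance must be >= 0")


def _hex_lattice(rows: int, cols: int) -> np.ndarray:
    xs, ys = [], []
    for r in range(rows):
        for c in range(cols):
            xs.append(c + 0.5 * (r % 2))
            ys.append(r * np.sqrt(3.0) / 2.0)
    return np.column_stack([xs, ys]).astype(float)


def build_lattice(
    rows: int, cols: int, electrode_positions: np.ndarray
) -> LatticeGeometry:
    """Place TC neurons on a hexagonal lattice and map the (usually square)
    electrode array onto it by isotropic scale and centering, so the scaled
    electrode hull covers the lattice hull."""
    if rows < 1 or cols < 1:
        raise GeometryError("rows and cols must be >= 1")
    el = np.asarray(electrode_positions, dtype=float)
    if el.ndim != 2 or el.shape[1] != 2 or el.shape[0] < 3:
        raise GeometryError("need at least 3 electrode positions in 2-D")
    if not np.all(np.isfinite(el)):
        raise GeometryError("electrode positions must be finite")
    tc = _hex_lattice(rows, cols)
    tc_c = tc.mean(axis=0)
    el_c = el.mean(axis=0)
    el0 = el - el_c
    tc0 = tc - tc_c
    # isotropic scale so the centered array covers the lattice hull on
    # every side of both axes (centroids need not sit at span centers)
    ratios = []
    for ax in range(2):
        if el0[:, ax].max() > 0 and tc0[:, ax].max() > 0:
            ratios.append(tc0[:, ax].max() / el0[:, ax].max())
        if el0[:, ax].min() < 0 and tc0[:, ax].min() < 0:
            ratios.append(tc0[:, ax].min() / el0[:, ax].min())
    scale = max(ratios) if ratios else 1.0
    if not np.isfinite(scale) or scale <= 0:
        scale = 1.0
    src = el0 * scale + tc_c
    return LatticeGeometry(rows, cols, tc, src)


def _pair_weights(geom: LatticeGeometry, sigma: float) -> np.ndarray:
    d2 = (
        (geom.source_positions[:, None, :] - geom.tc_positions[None, :, :]) ** 2
    ).sum(axis=2)
    return np.exp(-d2 / sigma**2)


def expected_convergence(geom: LatticeGeometry, sigma: float) -> float:
    """Mean number of connected rGC inputs per TC neuron, in expectation
    over the Bernoulli connectivity draw."""
    return float(_pair_weights(geom, sigma).sum(axis=0).mean())


def connect_retina(
    geom: LatticeGeometry,
    spec: ConvergenceSpec,
    rng: np.random.Generator,
    u0: float = U0_RETINAL,
    tau_rec: float = TAU_REC_DEFAULT_MS,
    delay_ms: float = RETINAL_DELAY_MS,
) -> list[tuple]:
    """Draw the retinogeniculate synapse records (seed-reproducible)."""
    g0 = np.asarray(spec.g0_uS, dtype=float)
    if g0.shape != (geom.n_tc,):
        raise ValueError("g0 must have one entry per TC neuron")
    w = _pair_weights(geom, spec.sigma)
    conn = rng.random(w.shape) < w
    records = []
    src_idx, tgt_idx = np.nonzero(conn)
    for s, t in zip(src_idx, tgt_idx):
        records.append(
            (int(s), int(t), g0[t] * w[s, t], MIX_RETINAL, delay_ms,
             u0, tau_rec, 0)
        )
    return records


def calibrate_density(
    geom: LatticeGeometry,
    sigma: float,
    target_convergence: float,
    tol: float = 0.10,
) -> LatticeGeometry:
    """Rescale the source array about the lattice center so the expected
    convergence at ``sigma`` matches the target within ``tol``.

    Shrinking the array raises source density over the lattice and with it
    the expected number of connected inputs per TC neuron.
    """
    if target_convergence < 1:
        raise CalibrationError("target convergence must be >= 1")
    center = geom.tc_positions.mean(axis=0)
    base = geom.source_positions - center

    def conv_at(scale: float) -> float:
        g = LatticeGeometry(
            geom.rows, geom.cols, geom.tc_positions, base * scale + center
        )
        return expected_convergence(g, sigma)

    lo, hi = 1e-3, 1e3
    f_lo, f_hi = conv_at(lo) - target_convergence, conv_at(hi) - target_convergence
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"target convergence {target_convergence} unreachable by rescaling"
        )
    scale = brentq(lambda s: conv_at(s) - target_convergence, lo, hi, xtol=1e-6)
    out = LatticeGeometry(
        geom.rows, geom.cols, geom.tc_positions, base * scale + center
    )
    achieved = expected_convergence(out, sigma)
    if abs(achieved - target_convergence) > tol * target_convergence:
        raise CalibrationError(
            f"calibration missed target: {achieved:.2f} vs {target_convergence}"
        )
    return out


def feedback_records(
    n_sources: int,
    n_tc: int,
    spec: FeedbackSpec,
    g0_uS: np.ndarray,
    rng: np.random.Generator | None = None,
) -> list[tuple]:
    """All-to-all loop records: every TC (source id ``n_sources + i``) onto
    every TC neuron, self-connections included."""
    if spec.jitter_fraction > 0 and rng is None:
        raise ValueError("jittered delays require a seeded rng")
    if spec.kind == "trn":
        mix, u0, tau_rec = MIX_GABA, 0.0, TAU_REC_DEFAULT_MS
    else:
        mix, u0, tau_rec = MIX_CORTICAL, U0_CORTICAL, TAU_REC_DEFAULT_MS
    if spec.u0 is not None:
        u0 = spec.u0
    cls = 1 if spec.kind == "trn" else 2
    records = []
    for i in range(n_tc):
        for j in range(n_tc):
            d = spec.delay_ms
            if spec.jitter_fraction > 0:
                d *= 1.0 + spec.jitter_fraction * (2.0 * rng.random() - 1.0)
            records.append(
                (n_sources + i, int(j), spec.relative_conductance * g0_uS[j],
                 mix, d, u0, tau_rec, cls)
            )
    return records


@dataclass
class NetworkModel:
    """The assembled dLGN model: geometry, neurons, synapse records, and
    receptor configuration.  ``compile()`` produces the integrable
    :class:`CompiledNetwork`."""

    geometry: LatticeGeometry
    neurons: list[NeuronParams]
    g0_uS: np.ndarray
    sigma: float
    receptor_ratio: float | None  # g_NMDA / g_AMPA; None => AMPA only
    synapse_records: list[tuple] = field(default_factory=list)
    feedback: list[FeedbackSpec] = field(default_factory=list)
    nmda_tau_decay: float | None = None
    gaba_e: float = -70.0
    rate_factor: float = 1.0

    def __post_init__(self):
        if len(self.neurons) != self.geometry.n_tc:
            raise ValueError("one parameter set per TC neuron required")
        if self.feedback:
            self._check_delay_order()

    def _check_delay_order(self):
        trn = [f.delay_ms for f in self.feedback if f.kind == "trn"]
        ctx = [f.delay_ms for f in self.feedback if f.kind == "ctx"]
        if trn and ctx and min(trn) <= max(ctx):
            raise ValueError(
                "TRN feedback delay must strictly exceed cortical delay"
            )

    def mix_matrix(self) -> np.ndarray:
        glut = receptor_mix_fractions(self.receptor_ratio)
        return np.array([glut, glut, (0.0, 0.0, 1.0)])

    def compile(self, dt: float = 0.1) -> CompiledNetwork:
        table = SynapseTable.from_records(
            self.geometry.n_sources, self.geometry.n_tc, self.synapse_records
        )
        return CompiledNetwork(
            self.neurons,
            dt=dt,
            synapses=table,
            receptor_mixes=self.mix_matrix(),
            nmda_tau_decay=self.nmda_tau_decay,
            gaba_e=self.gaba_e,
            rate_factor=self.rate_factor,
        )


def add_feedback(
    model: NetworkModel, spec: FeedbackSpec, rng: np.random.Generator | None = None
) -> NetworkModel:
    """Return a model extended with an all-to-all feedback loop (N^2 new
    synapses); validates the TRN-after-cortex delay ordering."""
    model.feedback.append(spec)
    try:
        model._check_delay_order()
    except ValueError:
        model.feedback.pop()
        raise
    model.synapse_records.extend(
        feedback_records(
            model.geometry.n_sources, model.geometry.n_tc, spec, model.g0_uS, rng
        )
    )
    return model
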