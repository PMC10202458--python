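"""Nonlinear firing-rate homeostasis.

Every ``update_interval`` seconds each neuron's afferent conductances are
multiplied by ``1 + tanh(alpha * (r0 - r_i))`` -- r_i being that neuron's
firing rate over the elapsed interval -- and clipped to [0, 10*g0].  In
heterosynaptic mode the same multiplier scales the retinal and cortical
synapses of a neuron jointly, preserving their conductance ratio.  The
loop stops once the population-mean rate over a trailing estimation
window is within the margin of the set-point (0.5 spikes/s without
cortical feedback, 1 spikes/s with it).

Full-scale constants (120 s interval, 27 min window) are the defaults;
``desk_scale()`` is the explicitly labeled reduced mode (20 s interval,
2 min window) used by the desk-size experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .engine import CompiledNetwork

__all__ = [
    "HomeostasisConfig",
    "HomeostasisHistory",
    "NonConvergenceError",
    "update_weights",
    "homeostatic_multiplier",
    "run_to_setpoint",
]


@dataclass(frozen=True)
class HomeostasisConfig:
    target_rate: float = 0.5  # spikes/s
    alpha: float = 0.05
    update_interval_s: float = 120.0
    window_s: float = 27.0 * 60.0
    margin: float = 0.10
    g_max_factor: float = 10.0  # g_max = factor * g0
    g_min: float = 0.0
    heterosynaptic: bool = False

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0.0 < self.margin < 1.0):
            raise ValueError("margin must be in (0, 1)")
        if not (0.0 <= self.g_min < self.g_max_factor):
            raise ValueError("need 0 <= g_min < g_max")

    @classmethod
    def desk_scale(cls, **over) -> "HomeostasisConfig":
        """Reduced constants for desk-size runs (explicitly labeled).

        The 240 s window preserves the full-scale window:interval
        smoothing ratio (27 min / 120 s ~ 13.5 intervals) so convergence
        is not declared while weights are still ramping.
        """
        cfg = cls(update_interval_s=20.0, window_s=240.0)
        return replace(cfg, **over)


@dataclass
class HomeostasisHistory:
    interval_rates: np.ndarray  # (n_intervals, n_neurons) spikes/s
    multipliers: np.ndarray  # (n_intervals, n_neurons)
    mean_rates: np.ndarray  # per interval population mean
    window_means: np.ndarray  # trailing-window population mean per interval
    converged: bool
    n_intervals: int


class NonConvergenceError(RuntimeError):
    def __init__(self, history: HomeostasisHistory):
        self.history = history
        super().__init__(
            f"homeostasis did not converge in {history.n_intervals} intervals"
        )


def homeostatic_multiplier(rate_i, cfg: HomeostasisConfig):
    """The tanh scaling factor 1 + tanh(alpha * (r0 - r))."""
    return 1.0 + np.tanh(cfg.alpha * (cfg.target_rate - np.asarray(rate_i)))


def update_weights(
    net: CompiledNetwork,
    rates: np.ndarray,
    cfg: HomeostasisConfig,
    g0_uS: np.ndarray,
) -> np.ndarray:
    """Apply one homeostatic update in place to the network's synapse
    table; returns the per-neuron multipliers.

    Retinal synapses always scale; cortical-loop synapses scale too in
    heterosynaptic mode (same per-target multiplier, ratio preserved).
    TRN synapses are never scaled.
    """
    tab = net.synapses
    mult = homeostatic_multiplier(rates, cfg)
    scaled_classes = (0, 2) if cfg.heterosynaptic else (0,)
    sel = np.isin(tab.cls, scaled_classes)
    tgt = tab.target[sel]
    tab.g[sel] = np.clip(
        tab.g[sel] * mult[tgt], cfg.g_min, cfg.g_max_factor * g0_uS[tgt]
    )
    return mult


def run_to_setpoint(
    net: CompiledNetwork,
    stimulus_events: tuple[np.ndarray, np.ndarray],
    cfg: HomeostasisConfig,
    g0_uS: np.ndarray,
    max_intervals: int = 40,
    min_intervals: int | None = None,
    raise_on_failure: bool = True,
) -> HomeostasisHistory:
    """Alternate simulation intervals and weight updates until the
    population-mean rate over the trailing window is within the margin of
    the set-point.

    ``stimulus_events`` are absolute (times_ms, source_id) arrays covering
    at least ``max_intervals`` update intervals from the network's current
    time.  On failure raises :class:`NonConvergenceError` carrying the
    full history (or returns it, flagged, if ``raise_on_failure`` False).
    """
    n = net.n
    dt_int_ms = cfg.update_interval_s * 1e3
    n_window = max(int(round(cfg.window_s / cfg.update_interval_s)), 1)
    if min_intervals is None:
        min_intervals = n_window
    ev_t, ev_s = stimulus_events

    rates_hist, mult_hist, mean_hist, win_hist = [], [], [], []
    converged = False
    for it in range(max_intervals):
        t0 = net.t_ms
        m = (ev_t >= t0) & (ev_t < t0 + dt_int_ms)
        out = net.advance(dt_int_ms, stimulus_events=(ev_t[m], ev_s[m]))
        counts = np.bincount(out["spike_units"], minlength=n)
        rates = counts / cfg.update_interval_s
        mult = update_weights(net, rates, cfg, g0_uS)
        rates_hist.append(rates)
        mult_hist.append(mult)
        mean_hist.append(rates.mean())
        w = np.mean(mean_hist[-n_window:])
        win_hist.append(w)
        if (
            it + 1 >= min_intervals
            and abs(w - cfg.target_rate) <= cfg.margin * cfg.target_rate
        ):
            converged = True
            break

    hist = HomeostasisHistory(
        interval_rates=np.array(rates_hist),
        multipliers=np.array(mult_hist),
        mean_rates=np.array(mean_hist),
        window_means=np.array(win_hist),
        converged=converged,
        n_intervals=len(rates_hist),
    )
    if not converged and raise_on_failure:
        raise NonConvergenceError(hist)
    return hist
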