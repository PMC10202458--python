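"""Spatial information carried by TC spiking.

For every neuron pair the intervals between their burst onsets are pooled
into the interval histogram of that pair's distance bin; the Shannon
mutual information

    I[r, dt] = sum_r p(r) sum_dt p(dt|r) log2( p(dt|r) / p(dt) )

then measures how well the distance r between two neurons can be
predicted from the intervals dt between their spikes -- the topographic
information content of the activity.  ``information_lost`` compares two
conditions: (mean_ref - mean_alt) / mean_ref, positive when the
alternative (e.g. AMPA-only) condition carries less spatial information.

Burst onsets are spikes preceded by at least 0.1 s of silence (the first
spike counts); raw interspike intervals are available behind the same
interface.  The estimator is the plain plug-in double sum, no bias
correction.  Pairing rule (an assumption, configurable): by default ALL
pairwise onset intervals |t_i - t_j| up to the 2 s maximum lag are
pooled (the full cross-interval distribution, as in inter-burst-interval
analyses of retinal waves); a nearest-onset-only variant is available
but note it discards the informative slow intervals whenever a fast one
exists.  Intervals are binned logarithmically (default 30 bins over
[1 ms, 2 s]) and pair distances into 8 quantile bins; p(r) is the
empirical pair-count prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MIResult",
    "MIBinning",
    "burst_onsets",
    "mutual_information",
    "mutual_information_from_joint",
    "information_lost",
    "BURST_ONSET_THRESHOLD_S",
]

BURST_ONSET_THRESHOLD_S = 0.1


def burst_onsets(spike_times_s: np.ndarray, threshold_s: float = BURST_ONSET_THRESHOLD_S) -> np.ndarray:
    """Onset spikes: the first spike, and every spike whose preceding ISI
    is >= threshold."""
    if threshold_s <= 0:
        raise ValueError("threshold must be > 0")
    st = np.asarray(spike_times_s, dtype=float)
    if st.size == 0:
        return st.copy()
    isi = np.diff(st)
    keep = np.concatenate([[True], isi >= threshold_s])
    return st[keep]


@dataclass(frozen=True)
class MIBinning:
    n_interval_bins: int = 30
    interval_min_s: float = 1e-3
    interval_max_s: float = 2.0
    n_distance_bins: int = 8
    max_lag_s: float = 2.0
    pairing: str = "all"  # "all" cross-intervals | "nearest" onset only

    def __post_init__(self):
        if self.pairing not in ("all", "nearest"):
            raise ValueError("pairing must be 'all' or 'nearest'")

    def interval_edges(self) -> np.ndarray:
        return np.geomspace(
            self.interval_min_s, self.interval_max_s, self.n_interval_bins + 1
        )


@dataclass
class MIResult:
    """Conditional interval distributions per distance bin and the scalar
    mutual information (bits)."""

    mi_bits: float
    p_r: np.ndarray
    p_dt_given_r: np.ndarray  # (n_r, n_dt)
    p_dt: np.ndarray
    distance_edges: np.ndarray
    interval_edges: np.ndarray
    n_samples: int
    binning: MIBinning


def mutual_information_from_joint(counts: np.ndarray) -> float:
    """Plug-in I[r, dt] in bits from a (n_r, n_dt) count table, using the
    pair-count prior p(r) = row mass."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty joint histogram")
    p_r = c.sum(axis=1) / total
    p_dt = c.sum(axis=0) / total
    mi = 0.0
    for ir in range(c.shape[0]):
        if p_r[ir] == 0:
            continue
        cond = c[ir] / c[ir].sum()
        nz = (cond > 0) & (p_dt > 0)
        mi += p_r[ir] * np.sum(cond[nz] * np.log2(cond[nz] / p_dt[nz]))
    return float(max(mi, 0.0))


def _pair_intervals(
    a: np.ndarray, b: np.ndarray, max_lag: float, pairing: str = "all"
) -> np.ndarray:
    """|dt| between onsets of two trains, capped at ``max_lag``.

    ``all``: every cross pair within the lag window (the cross-interval
    distribution).  ``nearest``: each onset contributes only its nearest
    partner in the other train.
    """
    if a.size == 0 or b.size == 0:
        return np.zeros(0)
    if pairing == "nearest":
        out = []
        for x, y in ((a, b), (b, a)):
            idx = np.searchsorted(y, x)
            left = np.clip(idx - 1, 0, y.size - 1)
            right = np.clip(idx, 0, y.size - 1)
            d = np.minimum(np.abs(x - y[left]), np.abs(x - y[right]))
            out.append(d)
        d = np.concatenate(out)
        return d[d <= max_lag]
    lo = np.searchsorted(b, a - max_lag, side="left")
    hi = np.searchsorted(b, a + max_lag, side="right")
    counts = hi - lo
    if counts.sum() == 0:
        return np.zeros(0)
    out = np.empty(int(counts.sum()))
    k = 0
    for i in range(a.size):
        if counts[i]:
            seg = np.abs(b[lo[i]:hi[i]] - a[i])
            out[k:k + counts[i]] = seg
            k += counts[i]
    return out


def mutual_information(
    trains_s: list[np.ndarray],
    positions: np.ndarray,
    binning: MIBinning = MIBinning(),
    use_burst_onsets: bool = True,
    onset_threshold_s: float = BURST_ONSET_THRESHOLD_S,
) -> MIResult:
    """I[r, dt] over all unit pairs of a raster with 2-D positions."""
    n = len(trains_s)
    if n < 2:
        raise ValueError("need at least 2 units")
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (n, 2):
        raise ValueError("one 2-D position per unit required")
    if use_burst_onsets:
        trains = [burst_onsets(t, onset_threshold_s) for t in trains_s]
    else:
        trains = [np.asarray(t, dtype=float) for t in trains_s]

    iu, ju = np.triu_indices(n, k=1)
    dists = np.hypot(
        positions[iu, 0] - positions[ju, 0], positions[iu, 1] - positions[ju, 1]
    )
    # distance bins: quantiles of the pair-distance distribution
    qs = np.linspace(0, 1, binning.n_distance_bins + 1)
    edges = np.quantile(dists, qs)
    edges = np.unique(edges)
    if edges.size < 3:
        raise ValueError("degenerate pair-distance distribution")
    r_bin = np.clip(np.searchsorted(edges, dists, side="right") - 1, 0, edges.size - 2)

    dt_edges = binning.interval_edges()
    counts = np.zeros((edges.size - 1, binning.n_interval_bins))
    for k in range(iu.size):
        d = _pair_intervals(
            trains[iu[k]], trains[ju[k]], binning.max_lag_s, binning.pairing
        )
        if d.size == 0:
            continue
        h, _ = np.histogram(d, bins=dt_edges)
        counts[r_bin[k]] += h

    total = counts.sum()
    if total <= 0:
        raise ValueError("empty joint histogram; no pooled intervals")
    mi = mutual_information_from_joint(counts)
    p_r = counts.sum(axis=1) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        p_cond = np.where(
            counts.sum(axis=1, keepdims=True) > 0,
            counts / counts.sum(axis=1, keepdims=True),
            0.0,
        )
    return MIResult(
        mi_bits=mi,
        p_r=p_r,
        p_dt_given_r=p_cond,
        p_dt=counts.sum(axis=0) / total,
        distance_edges=edges,
        interval_edges=dt_edges,
        n_samples=int(total),
        binning=binning,
    )


def information_lost(mi_ref, mi_alt) -> float:
    """(mean_ref - mean_alt) / mean_ref over trial MI values (bits).

    Positive = the alternative condition loses spatial information;
    negative = it gains.  Scalars or sequences of per-trial values.
    """
    ref = np.atleast_1d(np.asarray(
        [m.mi_bits if isinstance(m, MIResult) else m for m in np.atleast_1d(mi_ref)],
        dtype=float,
    ))
    alt = np.atleast_1d(np.asarray(
        [m.mi_bits if isinstance(m, MIResult) else m for m in np.atleast_1d(mi_alt)],
        dtype=float,
    ))
    mean_ref = ref.mean()
    if mean_ref <= 0:
        raise ZeroDivisionError("reference mean MI must be > 0")
    return float((mean_ref - alt.mean()) / mean_ref)
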