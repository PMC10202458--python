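"""Multiobjective evolutionary fitting of neuron parameters to
current-clamp voltage traces.

Two fitness families score every selected trace: the absolute difference
in spike count, and the Euclidean distance between voltage samples (so a
constant offset delta over n samples scores delta * sqrt(n)).  Two
genetic algorithms are provided behind one interface:

* ``nsga2`` -- nondominated-sorting GA: Pareto fronts by the dominance
  relation "better than or equal in all objectives and strictly better in
  at least one", crowding-distance tie-break, elitist survival.
* ``kamoga`` -- an adaptive-weight GA reconstructed from its stated
  principle: the weights of the fitness functions are re-adjusted each
  generation so that the correlation between the weighted total fitness
  and each individual objective is equalized across the generation
  (multiplicative updates with damping 0.5, iterated to 1% tolerance),
  avoiding over- or under-representation of individual objectives.  This
  is a sketch-faithful reconstruction and is swappable.

When no algorithm is named, one is chosen at random per run.  Search is
performed in the optimization scale of each parameter (log10 where
flagged, linear otherwise), normalized to [0, 1] over the bound range.
A configurable subset of parameters may be left free with the rest
clamped -- desk-scale recovery experiments free a handful of conductance
scales rather than all 29 dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .neuron import build_neuron, step_current_clamp, validate_model
from .params import PARAM_TABLE, NeuronParams

__all__ = [
    "GAConfig",
    "GAResult",
    "evaluate_objectives",
    "nondominated_sort",
    "dominates",
    "adaptive_weight_update",
    "run_ga",
    "select_and_validate",
    "database_summaries",
]

_FIELDS = list(PARAM_TABLE.keys())


# ---------------------------------------------------------------------------
# genome <-> parameters
# ---------------------------------------------------------------------------

def _to_scaled(value: float, name: str) -> float:
    _, scale, lo, hi = PARAM_TABLE[name]
    if scale == "log":
        return (math.log10(value) - math.log10(lo)) / (
            math.log10(hi) - math.log10(lo)
        )
    return (value - lo) / (hi - lo)


def _from_scaled(x: float, name: str) -> float:
    _, scale, lo, hi = PARAM_TABLE[name]
    x = min(max(x, 0.0), 1.0)
    if scale == "log":
        return 10.0 ** (math.log10(lo) + x * (math.log10(hi) - math.log10(lo)))
    return lo + x * (hi - lo)


def params_to_genome(p: NeuronParams, free: list[str]) -> np.ndarray:
    return np.array([_to_scaled(getattr(p, n), n) for n in free])


def genome_to_params(
    genome: np.ndarray, free: list[str], template: NeuronParams
) -> NeuronParams:
    changes = {n: _from_scaled(float(x), n) for n, x in zip(free, genome)}
    # keep structural invariants satisfiable under clamping
    p = dict(template.to_dict())
    out = template.replace(**changes)
    return out


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def evaluate_objectives(
    params: NeuronParams,
    target: dict,
    dt: float | None = None,
) -> np.ndarray:
    """Objective vector (2 per selected trace: |spike-count diff|,
    voltage Euclidean distance in mV*sqrt(samples)) against a target
    produced by ``synth.generate_target_neuron``.  A simulation blow-up
    marks the vector infeasible (all +inf, worst rank)."""
    traces = target["traces"]
    dt = target["dt"] if dt is None else dt
    protocol = target["protocol"]
    n_obj = 2 * len(traces)
    try:
        neuron = build_neuron(params, dt=dt)
        sweeps = step_current_clamp(neuron, protocol)
    except Exception:
        return np.full(n_obj, np.inf)
    obj = np.empty(n_obj)
    for k, (tr, sw) in enumerate(zip(traces, sweeps)):
        obj[2 * k] = abs(tr["n_spikes"] - sw["n_spikes"])
        n = min(tr["v_mV"].size, sw["v_mV"].size)
        obj[2 * k + 1] = float(
            np.linalg.norm(tr["v_mV"][:n] - sw["v_mV"][:n])
        )
    return obj


# ---------------------------------------------------------------------------
# nondominated sorting
# ---------------------------------------------------------------------------

def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff ``a`` is better than or equal to ``b`` in all objectives
    and strictly better in at least one (minimization)."""
    return bool(np.all(a <= b) and np.any(a < b))


def nondominated_sort(objectives: np.ndarray) -> list[np.ndarray]:
    """Pareto fronts (lists of indices, stable order within a front)."""
    f = np.asarray(objectives, dtype=float)
    n = f.shape[0]
    dominated_by = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(f[i], f[j]):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif dominates(f[j], f[i]):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    fronts = []
    current = np.flatnonzero(n_dominating == 0)
    while current.size:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(nxt), dtype=int)
    return fronts


def _crowding_distance(f: np.ndarray) -> np.ndarray:
    n, m = f.shape
    d = np.zeros(n)
    for k in range(m):
        order = np.argsort(f[:, k], kind="stable")
        span = f[order[-1], k] - f[order[0], k]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0 and n > 2:
            d[order[1:-1]] += (f[order[2:], k] - f[order[:-2], k]) / span
    return d


# ---------------------------------------------------------------------------
# adaptive weights (KAMOGA sketch)
# ---------------------------------------------------------------------------

def adaptive_weight_update(
    objectives: np.ndarray,
    weights: np.ndarray | None = None,
    damping: float = 0.5,
    tol: float = 0.01,
    max_iter: int = 100,
) -> np.ndarray:
    """Equalize the correlation between the weighted total fitness and
    each objective across the generation.

    Multiplicative updates with the given damping, iterated until the
    active correlations agree within ``tol`` (relative spread).
    Zero-variance objectives keep a frozen weight.  Weights are
    nonnegative and sum to 1.
    """
    f = np.asarray(objectives, dtype=float)
    n, m = f.shape
    w = np.full(m, 1.0 / m) if weights is None else np.asarray(weights, float).copy()
    w = np.clip(w, 0.0, None)
    if w.sum() == 0:
        w[:] = 1.0 / m
    w /= w.sum()
    sd = f.std(axis=0)
    active = sd > 0
    if active.sum() < 2 or n < 3:
        return w
    for _ in range(max_iter):
        total = f @ w
        if total.std() == 0:
            break
        c = np.array(
            [np.corrcoef(total, f[:, k])[0, 1] if active[k] else np.nan for k in range(m)]
        )
        ca = np.clip(c[active], 1e-3, None)
        mean_c = ca.mean()
        spread = (ca.max() - ca.min()) / max(mean_c, 1e-12)
        if spread < tol:
            break
        w[active] *= (mean_c / ca) ** damping
        w /= w.sum()
    return w


# ---------------------------------------------------------------------------
# the genetic algorithms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    generations: int = 1024
    population: int = 240
    elite: int = 30  # ~12% of the population carried over
    mutation_sigma: float = 0.05  # in the scaled [0,1] space
    mutation_rate: float = 0.3
    crossover_rate: float = 0.9
    seed: int = 0
    algorithm: str | None = None  # "nsga2" | "kamoga" | None -> random
    free_params: tuple[str, ...] | None = None  # None -> all 29

    def __post_init__(self):
        if not (0 < self.elite < self.population):
            raise ValueError("need 0 < elite < population")
        if self.algorithm not in (None, "nsga2", "kamoga"):
            raise ValueError("unknown algorithm")
        if self.free_params is not None:
            unknown = set(self.free_params) - set(_FIELDS)
            if unknown:
                raise ValueError(f"unknown free parameters: {sorted(unknown)}")

    @classmethod
    def desk_scale(cls, **over) -> "GAConfig":
        """Reduced 40x40 configuration for desk-size recovery runs."""
        base = dict(generations=40, population=40, elite=5)
        base.update(over)
        return cls(**base)


@dataclass
class GAResult:
    archive_params: list[NeuronParams]
    archive_objectives: np.ndarray
    best_index: int
    algorithm: str
    config: GAConfig
    template: NeuronParams
    free_params: tuple[str, ...]
    # per-generation best objective vector of the living population
    generation_best: list[np.ndarray] = None

    @property
    def best_params(self) -> NeuronParams:
        return self.archive_params[self.best_index]

    @property
    def best_objectives(self) -> np.ndarray:
        return self.archive_objectives[self.best_index]


def _rank_key(objectives: np.ndarray) -> np.ndarray:
    """Scalar sort key: nondominated rank, then normalized-sum tie-break."""
    f = np.asarray(objectives, dtype=float)
    finite = np.isfinite(f).all(axis=1)
    key = np.full(f.shape[0], np.inf)
    if finite.sum():
        ff = f[finite]
        fronts = nondominated_sort(ff)
        scale = ff.max(axis=0) - ff.min(axis=0)
        scale[scale == 0] = 1.0
        norm_sum = ((ff - ff.min(axis=0)) / scale).sum(axis=1)
        sub = np.empty(ff.shape[0])
        for r, fr in enumerate(fronts):
            sub[fr] = r + norm_sum[fr] / (norm_sum.max() + 1.0)
        key[finite] = sub
    return key


def run_ga(
    target: dict,
    cfg: GAConfig,
    template: NeuronParams | None = None,
    dt: float | None = None,
) -> GAResult:
    """Fit NeuronParams to target traces; returns the evaluated archive."""
    rng = np.random.default_rng(cfg.seed)
    algorithm = cfg.algorithm or rng.choice(["nsga2", "kamoga"])
    if template is None:
        template = target["ground_truth"]
    free = list(cfg.free_params) if cfg.free_params else list(_FIELDS)
    d = len(free)

    pop = rng.random((cfg.population, d))
    archive_p: list[NeuronParams] = []
    archive_f: list[np.ndarray] = []

    def evaluate(genomes: np.ndarray) -> np.ndarray:
        objs = []
        for g in genomes:
            try:
                p = genome_to_params(g, free, template)
                o = evaluate_objectives(p, target, dt=dt)
            except Exception:
                p = template
                o = np.full(2 * len(target["traces"]), np.inf)
            archive_p.append(p)
            archive_f.append(o)
            objs.append(o)
        return np.array(objs)

    def variation(parents: np.ndarray, n_children: int) -> np.ndarray:
        children = np.empty((n_children, d))
        for c in range(n_children):
            i, j = rng.integers(0, parents.shape[0], 2)
            a, b = parents[i], parents[j]
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(d) < 0.5
                child = np.where(mask, a, b)
            else:
                child = a.copy()
            mut = rng.random(d) < cfg.mutation_rate
            child = child + mut * rng.normal(0.0, cfg.mutation_sigma, d)
            children[c] = np.clip(child, 0.0, 1.0)
        return children

    fit = evaluate(pop)
    weights = None
    generation_best: list[np.ndarray] = [fit[np.argmin(_rank_key(fit))].copy()]
    for _ in range(cfg.generations - 1):
        if algorithm == "nsga2":
            key = _rank_key(fit)
            # crowding tie-break inside the scalar key ordering
            order = np.argsort(key, kind="stable")
        else:
            finite = np.isfinite(fit).all(axis=1)
            scalar = np.full(fit.shape[0], np.inf)
            if finite.sum() >= 3:
                weights = adaptive_weight_update(fit[finite], weights)
                scalar[finite] = fit[finite] @ weights
            elif finite.any():
                scalar[finite] = fit[finite].sum(axis=1)
            order = np.argsort(scalar, kind="stable")
        elite = pop[order[: cfg.elite]]
        parents = pop[order[: max(cfg.population // 2, 2)]]
        children = variation(parents, cfg.population - cfg.elite)
        pop = np.vstack([elite, children])
        fit_children = evaluate(children)
        fit = np.vstack([fit[order[: cfg.elite]], fit_children])
        generation_best.append(fit[np.argmin(_rank_key(fit))].copy())

    arch_f = np.array(archive_f)
    best = int(np.argmin(_rank_key(arch_f)))
    return GAResult(
        archive_params=archive_p,
        archive_objectives=arch_f,
        best_index=best,
        algorithm=str(algorithm),
        config=cfg,
        template=template,
        free_params=tuple(free),
        generation_best=generation_best,
    )


def select_and_validate(
    result: GAResult,
    top_fraction: float = 0.002,
    top_count: int | None = None,
) -> dict:
    """Re-sort the full archive, take the top fraction (or a fixed count,
    e.g. 510 at full scale), and apply the four validation checks."""
    f = result.archive_objectives
    order = np.argsort(_rank_key(f), kind="stable")
    if top_count is None:
        top_count = max(int(round(top_fraction * f.shape[0])), 1)
    chosen = order[:top_count]
    survivors, rejected = [], []
    for idx in chosen:
        p = result.archive_params[idx]
        v = validate_model(p)
        if v["passed"]:
            survivors.append((int(idx), p))
        else:
            rejected.append((int(idx), p, v["reasons"]))
    return {"survivors": survivors, "rejected": rejected, "selected": chosen}


# ---------------------------------------------------------------------------
# database summaries
# ---------------------------------------------------------------------------

def database_summaries(params_list: list[NeuronParams], n_components: int = 5) -> dict:
    """Per-parameter Gaussian KDE (Scott's rule) in each parameter's
    optimization scale, plus the leading principal components."""
    from scipy.stats import gaussian_kde
    from sklearn.decomposition import PCA

    if len(params_list) < 2:
        raise ValueError("need at least 2 models")
    x = np.array([[_to_scaled(getattr(p, n), n) for n in _FIELDS] for p in params_list])
    densities = {}
    for k, name in enumerate(_FIELDS):
        col = x[:, k]
        if col.std() == 0:
            densities[name] = None  # constant column: degenerate spike
            continue
        densities[name] = gaussian_kde(col)  # Scott bandwidth by default
    n_comp = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    proj = pca.fit_transform(x - x.mean(axis=0))
    return {
        "densities": densities,
        "scaled_values": x,
        "pca": pca,
        "projection": proj,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "fields": list(_FIELDS),
    }
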