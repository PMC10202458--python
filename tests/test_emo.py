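"""Evolutionary fitting machinery: dominance sorting vs brute force,
adaptive weights, objective arithmetic, database summaries."""

import numpy as np
import pytest

from dlgnsim.emo import (
    GAConfig,
    adaptive_weight_update,
    database_summaries,
    dominates,
    evaluate_objectives,
    genome_to_params,
    nondominated_sort,
    params_to_genome,
)
from dlgnsim.params import canonical_params
from dlgnsim.synth import generate_target_neuron, heterogeneous_population


def _brute_fronts(f):
    """O(n^2) reference: peel nondominated layers by exhaustive pairwise
    dominance."""
    f = np.asarray(f, dtype=float)
    remaining = list(range(f.shape[0]))
    fronts = []
    while remaining:
        front = [
            i for i in remaining
            if not any(dominates(f[j], f[i]) for j in remaining if j != i)
        ]
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


class TestNondominatedSort:
    def test_worked_three_point_example(self):
        f = np.array([[1.0, 1.0], [2.0, 2.0], [1.5, 0.5]])
        fronts = nondominated_sort(f)
        assert sorted(fronts[0].tolist()) == [0, 2]
        assert fronts[1].tolist() == [1]

    def test_identical_vectors_form_one_front(self):
        f = np.ones((5, 3))
        fronts = nondominated_sort(f)
        assert len(fronts) == 1 and fronts[0].tolist() == [0, 1, 2, 3, 4]

    def test_matches_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(3)
        for trial in range(50):
            n = rng.integers(5, 21)
            m = rng.integers(2, 5)
            f = rng.integers(0, 6, size=(n, m)).astype(float)
            got = [sorted(fr.tolist()) for fr in nondominated_sort(f)]
            assert got == _brute_fronts(f), f"trial {trial}"

    def test_dominance_relation_definition(self):
        assert dominates(np.array([1.0, 1.0]), np.array([1.0, 2.0]))
        assert not dominates(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert not dominates(np.array([0.0, 2.0]), np.array([1.0, 1.0]))


class TestAdaptiveWeights:
    def test_identically_distributed_objectives_get_equal_weights(self):
        rng = np.random.default_rng(4)
        base = rng.random(200)
        f = np.column_stack([base + 0.01 * rng.random(200) for _ in range(3)])
        w = adaptive_weight_update(f)
        assert np.allclose(w, 1 / 3, atol=0.05)

    def test_high_variance_objective_downweighted(self):
        rng = np.random.default_rng(5)
        f = np.column_stack([
            10.0 * rng.standard_normal(300),
            1.0 * rng.standard_normal(300),
        ])
        w = adaptive_weight_update(f)
        assert w[0] < 0.5 < w[1]
        # correlation-equalization oracle: after the update the weighted
        # total correlates about equally with both objectives
        total = f @ w
        c = [abs(np.corrcoef(total, f[:, k])[0, 1]) for k in range(2)]
        assert abs(c[0] - c[1]) < 0.1

    def test_weights_nonnegative_and_normalized(self):
        rng = np.random.default_rng(6)
        f = rng.random((50, 6)) * [1, 5, 10, 0.1, 2, 3]
        w = adaptive_weight_update(f)
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0)

    def test_zero_variance_objective_weight_frozen(self):
        rng = np.random.default_rng(7)
        f = np.column_stack([
            rng.random(100), np.full(100, 2.0), rng.random(100)
        ])
        w0 = np.array([0.2, 0.4, 0.4])
        w = adaptive_weight_update(f, w0)
        assert w.sum() == pytest.approx(1.0)


class TestGenomeMapping:
    def test_roundtrip_through_scaled_space(self):
        p = canonical_params()
        free = ["gna_max", "vtraub", "soma_L", "t_pcabar"]
        g = params_to_genome(p, free)
        assert np.all((g >= 0) & (g <= 1))
        back = genome_to_params(g, free, p)
        for name in free:
            assert getattr(back, name) == pytest.approx(getattr(p, name), rel=1e-9)

    def test_out_of_range_genome_clipped_to_bounds(self):
        p = canonical_params()
        back = genome_to_params(np.array([2.0, -1.0]), ["gna_max", "vtraub"], p)
        assert back.gna_max == pytest.approx(1e-1)
        assert back.vtraub == pytest.approx(-70.0)


@pytest.fixture(scope="module")
def target():
    return generate_target_neuron(
        canonical_params(), [(60.0, 150.0), (120.0, 150.0)],
        noise_sd_mV=0.0, seed=0, dt=0.05,
    )


class TestObjectives:

    def test_self_fit_scores_zero_spike_objectives(self, target):
        obj = evaluate_objectives(canonical_params(), target)
        assert obj[::2].tolist() == [0.0, 0.0]
        assert np.all(obj[1::2] < 1e-9)

    def test_constant_offset_gives_delta_sqrt_n(self, target):
        shifted = {
            **target,
            "traces": [
                {**tr, "v_mV": tr["v_mV"] + 3.0} for tr in target["traces"]
            ],
        }
        obj = evaluate_objectives(canonical_params(), shifted)
        for k, tr in enumerate(shifted["traces"]):
            n = tr["v_mV"].size
            assert obj[2 * k + 1] == pytest.approx(3.0 * np.sqrt(n), rel=1e-9)

    def test_spike_count_objective_is_absolute_difference(self, target):
        quiet = canonical_params().replace(gna_max=1e-7)
        obj = evaluate_objectives(quiet, target)
        expected = [tr["n_spikes"] for tr in target["traces"]]
        assert obj[::2].tolist() == [float(e) for e in expected]

    def test_invalid_parameters_marked_infeasible(self, target):
        class Broken:
            def __getattr__(self, name):
                raise RuntimeError("boom")

        obj = evaluate_objectives(Broken(), target)
        assert np.all(np.isinf(obj))


class TestDatabaseSummaries:
    def test_scott_bandwidth_and_unit_mass(self):
        pop = heterogeneous_population(40, 0, jitter=0.3, validate=False)
        s = database_summaries(pop)
        kde = s["densities"]["gna_max"]
        # Scott's factor for 1-D data: n^(-1/5)
        assert kde.factor == pytest.approx(40 ** (-1 / 5), rel=1e-6)
        grid = np.linspace(-0.5, 1.5, 2001)
        mass = np.trapezoid(kde(grid), grid)
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_pca_separates_constructed_clusters(self):
        a = heterogeneous_population(15, 1, jitter=0.05, validate=False)
        big = canonical_params().replace(
            gna_max=1e-3, gk_max=1e-3, soma_L=150.0, pas_g=5e-3
        )
        b = heterogeneous_population(15, 2, base=big, jitter=0.05, validate=False)
        s = database_summaries(a + b)
        proj = s["projection"][:, 0]
        assert (proj[:15].mean() - proj[15:].mean()) ** 2 > 4 * (
            proj[:15].var() + proj[15:].var()
        )
        assert len(s["explained_variance_ratio"]) == 5

    def test_requires_two_models(self):
        with pytest.raises(ValueError):
            database_summaries([canonical_params()])


def test_ga_config_validation():
    with pytest.raises(ValueError):
        GAConfig(population=10, elite=10)
    with pytest.raises(ValueError):
        GAConfig(algorithm="hillclimb")
    with pytest.raises(ValueError):
        GAConfig(free_params=("not_a_param",))
    desk = GAConfig.desk_scale()
    assert desk.generations == 40 and desk.population == 40
    full = GAConfig()
    assert (full.generations, full.population, full.elite) == (1024, 240, 30)
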