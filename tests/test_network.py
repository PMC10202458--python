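"""Lattice geometry, Gaussian connectivity, convergence calibration, and
feedback-loop construction."""

import numpy as np
import pytest

from dlgnsim.network import (
    CalibrationError,
    ConvergenceSpec,
    FeedbackSpec,
    GeometryError,
    NetworkModel,
    add_feedback,
    build_lattice,
    calibrate_density,
    connect_retina,
    expected_convergence,
    feedback_records,
)
from dlgnsim.params import canonical_params


def _square_grid(n_side, pitch=1.0):
    gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()]).astype(float) * pitch


class TestLattice:
    def test_default_7x16_lattice_has_112_neurons(self):
        geom = build_lattice(7, 16, _square_grid(12))
        assert geom.n_tc == 112

    def test_single_neuron_sits_at_electrode_centroid(self):
        el = _square_grid(4, pitch=3.0)
        geom = build_lattice(1, 1, el)
        assert geom.n_tc == 1
        assert np.allclose(geom.source_positions.mean(axis=0), geom.tc_positions[0])

    def test_interior_nearest_neighbor_distance_is_lattice_constant(self):
        geom = build_lattice(7, 16, _square_grid(12))
        pos = geom.tc_positions
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        hull_min, hull_max = pos.min(axis=0), pos.max(axis=0)
        interior = np.all(
            (pos > hull_min + 1.0) & (pos < hull_max - 1.0), axis=1
        )
        assert interior.sum() > 10
        assert np.allclose(d.min(axis=1)[interior], 1.0, atol=1e-9)

    def test_scaled_electrode_hull_covers_lattice_hull(self):
        geom = build_lattice(7, 16, _square_grid(8, pitch=0.1))
        for ax in range(2):
            assert geom.source_positions[:, ax].min() <= geom.tc_positions[:, ax].min() + 1e-9
            assert geom.source_positions[:, ax].max() >= geom.tc_positions[:, ax].max() - 1e-9

    def test_too_few_electrodes_rejected(self):
        with pytest.raises(GeometryError):
            build_lattice(7, 16, np.zeros((2, 2)))
        with pytest.raises(GeometryError):
            build_lattice(0, 16, _square_grid(4))


class TestConnectivity:
    def test_zero_distance_connects_with_probability_one_at_g0(self):
        geom = build_lattice(1, 1, _square_grid(3))
        # put one source exactly on the TC
        src = geom.source_positions.copy()
        src[0] = geom.tc_positions[0]
        geom = type(geom)(geom.rows, geom.cols, geom.tc_positions, src)
        g0 = np.array([0.01])
        rng = np.random.default_rng(0)
        recs = connect_retina(geom, ConvergenceSpec(2.0, g0), rng)
        on_top = [r for r in recs if r[0] == 0]
        assert len(on_top) == 1
        assert on_top[0][2] == pytest.approx(0.01)

    def test_empirical_connection_frequency_matches_gaussian(self):
        # Monte-Carlo oracle: frequency over seeded draws at fixed distance
        sigma, d = 2.0, 2.0
        geom_proto = build_lattice(1, 1, _square_grid(3))
        src = geom_proto.tc_positions[0] + np.array([[d, 0.0]])
        geom = type(geom_proto)(1, 1, geom_proto.tc_positions, src)
        p_expected = np.exp(-(d**2) / sigma**2)
        n_draws = 10_000
        hits = 0
        for s in range(n_draws):
            rng = np.random.default_rng(s)
            hits += len(connect_retina(geom, ConvergenceSpec(sigma, np.array([1.0])), rng))
        p_hat = hits / n_draws
        se = np.sqrt(p_expected * (1 - p_expected) / n_draws)
        assert abs(p_hat - p_expected) < 4 * se

    def test_connectivity_is_seed_reproducible(self):
        geom = build_lattice(3, 4, _square_grid(6))
        spec = ConvergenceSpec(2.0, np.full(12, 0.01))
        a = connect_retina(geom, spec, np.random.default_rng(42))
        b = connect_retina(geom, spec, np.random.default_rng(42))
        assert a == b

    def test_expected_convergence_monotone_in_sigma(self):
        geom = build_lattice(3, 4, _square_grid(8))
        convs = [expected_convergence(geom, s) for s in (1.0, 2.0, 4.0)]
        assert convs[0] < convs[1] < convs[2]

    def test_duplicating_sources_doubles_expected_convergence(self):
        geom = build_lattice(3, 4, _square_grid(8))
        doubled = type(geom)(
            geom.rows, geom.cols, geom.tc_positions,
            np.vstack([geom.source_positions, geom.source_positions]),
        )
        assert expected_convergence(doubled, 2.0) == pytest.approx(
            2 * expected_convergence(geom, 2.0)
        )


class TestCalibration:
    def test_sigma4_calibrates_to_ten_inputs(self):
        geom = build_lattice(7, 8, _square_grid(12))
        cal = calibrate_density(geom, 4.0, 10.0)
        assert expected_convergence(cal, 4.0) == pytest.approx(10.0, rel=0.01)

    def test_sigma9_calibrates_to_twenty_inputs(self):
        geom = build_lattice(7, 8, _square_grid(12))
        cal = calibrate_density(geom, 9.0, 20.0)
        assert expected_convergence(cal, 9.0) == pytest.approx(20.0, rel=0.01)

    def test_unreachable_target_raises(self):
        geom = build_lattice(7, 8, _square_grid(12))
        with pytest.raises(CalibrationError):
            calibrate_density(geom, 4.0, 0.5)


class TestFeedback:
    def _model(self, feedback=()):
        geom = build_lattice(2, 2, _square_grid(4))
        n = geom.n_tc
        return NetworkModel(
            geometry=geom,
            neurons=[canonical_params()] * n,
            g0_uS=np.full(n, 0.01),
            sigma=4.0,
            receptor_ratio=2.25,
            synapse_records=[],
            feedback=list(feedback),
        )

    def test_all_to_all_loop_has_n_squared_synapses(self):
        model = self._model()
        spec = FeedbackSpec("trn", 0.5, 50.0)
        add_feedback(model, spec)
        assert len(model.synapse_records) == model.geometry.n_tc ** 2
        # self-feedback included
        srcs = {r[0] - model.geometry.n_sources for r in model.synapse_records}
        tgts = {r[1] for r in model.synapse_records}
        assert srcs == tgts == set(range(model.geometry.n_tc))

    def test_jittered_delays_stay_within_20_percent(self):
        recs = feedback_records(
            0, 10, FeedbackSpec("trn", 1.0, 100.0, jitter_fraction=0.2),
            np.ones(10), np.random.default_rng(1),
        )
        delays = np.array([r[4] for r in recs])
        assert np.all(delays >= 80.0) and np.all(delays <= 120.0)
        assert delays.std() > 0

    def test_trn_delay_must_exceed_cortical_delay(self):
        model = self._model()
        add_feedback(model, FeedbackSpec("ctx", 0.5, 40.0))
        with pytest.raises(ValueError, match="strictly exceed"):
            add_feedback(model, FeedbackSpec("trn", 0.5, 30.0))
        # and the valid ordering is accepted
        add_feedback(model, FeedbackSpec("trn", 0.5, 90.0))

    def test_cortical_loop_uses_depressing_glutamatergic_synapses(self):
        recs = feedback_records(0, 3, FeedbackSpec("ctx", 1.0, 30.0), np.ones(3))
        u0s = {r[5] for r in recs}
        assert u0s == {0.7}
        assert {r[7] for r in recs} == {2}

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FeedbackSpec("trn", 1.0, 0.0)
        with pytest.raises(ValueError):
            FeedbackSpec("trn", 1.0, 10.0, jitter_fraction=0.5)
        with pytest.raises(ValueError):
            FeedbackSpec("cerebellum", 1.0, 10.0)
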