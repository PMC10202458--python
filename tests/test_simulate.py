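"""Whole-network engine contracts: determinism, event accounting,
silencing experiments, kinetic scaling."""

import numpy as np
import pytest

from dlgnsim.engine import CompiledNetwork, SynapseTable
from dlgnsim.network import (
    ConvergenceSpec,
    FeedbackSpec,
    NetworkModel,
    add_feedback,
    build_lattice,
)
from dlgnsim.params import canonical_params
from dlgnsim.simulate import run, scale_kinetics, silence_and_measure
from dlgnsim.synth import SpikeTrainSet


def _grid(n):
    gx, gy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()]).astype(float)


def _poisson_stimulus(rng, n_src, rate_hz, duration_s, positions):
    trains = [
        np.sort(rng.uniform(0, duration_s, rng.poisson(rate_hz * duration_s)))
        for _ in range(n_src)
    ]
    return SpikeTrainSet(
        unit_ids=np.arange(n_src), spike_times=trains,
        positions=positions, duration_s=duration_s,
    )


def _small_model(g_scale=1.0, feedback=(), seed=0, n_side=2):
    """2x2 TC lattice, 9 sources, dense hand-set connectivity."""
    geom = build_lattice(2, 2, _grid(3))
    n = geom.n_tc
    g0 = np.full(n, 0.01)
    rng = np.random.default_rng(seed)
    records = []
    for s in range(geom.n_sources):
        for t in range(n):
            d = np.linalg.norm(geom.source_positions[s] - geom.tc_positions[t])
            w = np.exp(-(d**2) / 4.0)
            if w > 0.3:
                records.append((s, t, g_scale * g0[t] * w, 0, 2.0, 0.3, 700.0, 0))
    model = NetworkModel(
        geometry=geom, neurons=[canonical_params()] * n, g0_uS=g0,
        sigma=2.0, receptor_ratio=2.25, synapse_records=records,
    )
    jr = np.random.default_rng(seed + 1)
    for fb in feedback:
        add_feedback(model, fb, jr)
    return model


class TestRun:
    def test_zero_conductance_afferents_keep_network_silent(self):
        model = _small_model(g_scale=0.0)
        net = model.compile(dt=0.1)
        rng = np.random.default_rng(2)
        stim = _poisson_stimulus(rng, 9, 5.0, 20.0, _grid(3))
        out = run(net, stim, 20.0)
        assert out.spike_times_s.size == 0

    def test_single_suprathreshold_event_fires_after_delay(self):
        # one synapse at 2x the unitary conductance (adjusted for the
        # depression stage releasing u0 of the resource)
        from dlgnsim.neuron import build_neuron, estimate_unitary_conductance

        p = canonical_params()
        g0 = estimate_unitary_conductance(build_neuron(p, dt=0.1))
        table = SynapseTable.from_records(
            1, 1, [(0, 0, 2.0 * g0, 0, 3.0, 0.3, 700.0, 0)]
        )
        net = CompiledNetwork(
            [p], dt=0.1, synapses=table,
            receptor_mixes=np.array([[1 / 3.25, 2.25 / 3.25, 0.0]]),
        )
        net.settle(1000.0)
        t_event = net.t_ms + 10.0
        out = net.advance(300.0, stimulus_events=(np.array([t_event]), np.array([0])))
        assert out["spike_times_ms"].size >= 1
        assert out["spike_times_ms"][0] > t_event + 3.0

    def test_identical_seeds_produce_identical_rasters(self):
        rng = np.random.default_rng(5)
        stim = _poisson_stimulus(rng, 9, 8.0, 30.0, _grid(3))
        rasters = []
        for _ in range(2):
            model = _small_model(seed=3)
            net = model.compile(dt=0.1)
            net.settle(500.0)
            out = run(net, (stim.to_events_ms()[0] + net.t_ms, stim.to_events_ms()[1]), 30.0)
            rasters.append((out.spike_times_s.copy(), out.spike_units.copy()))
        assert np.array_equal(rasters[0][0], rasters[1][0])
        assert np.array_equal(rasters[0][1], rasters[1][1])

    def test_scheduled_events_equal_spikes_times_out_degree(self):
        model = _small_model(seed=4)
        net = model.compile(dt=0.1)
        rng = np.random.default_rng(6)
        stim = _poisson_stimulus(rng, 9, 5.0, 20.0, _grid(3))
        out = run(net, stim, 25.0)
        tab = net.synapses
        outdeg = np.diff(tab.src_ptr)
        expected = sum(
            stim.spike_times[s].size * outdeg[s] for s in range(9)
        )
        expected += sum(
            (out.spike_units == i).sum() * outdeg[9 + i] for i in range(net.n)
        )
        assert net.n_events_scheduled == expected

    def test_neuron_relabeling_does_not_change_dynamics(self):
        # permute the construction order of an all-identical population;
        # the raster must be the permutation of the original
        rng = np.random.default_rng(7)
        stim = _poisson_stimulus(rng, 9, 8.0, 20.0, _grid(3))
        model = _small_model(seed=8)
        perm = np.array([2, 0, 3, 1])
        inv = np.argsort(perm)
        records_p = [
            (r[0], int(inv[r[1]]), *r[2:]) for r in model.synapse_records
        ]
        model_p = NetworkModel(
            geometry=model.geometry, neurons=model.neurons,
            g0_uS=model.g0_uS, sigma=model.sigma,
            receptor_ratio=model.receptor_ratio, synapse_records=records_p,
        )
        outs = []
        for m in (model, model_p):
            net = m.compile(dt=0.1)
            net.settle(300.0)
            ev = stim.to_events_ms()
            outs.append(run(net, (ev[0] + net.t_ms, ev[1]), 20.0))
        a, b = outs
        order_a = np.lexsort((a.spike_units, a.spike_times_s))
        mapped_units = inv[a.spike_units]
        order_b = np.lexsort((b.spike_units, b.spike_times_s))
        assert np.allclose(a.spike_times_s[order_a], b.spike_times_s[order_b])
        assert np.array_equal(
            np.sort(mapped_units), np.sort(b.spike_units)
        )


class TestSilencing:
    def _driven_net(self, feedback, seed=9, g_scale=2.0):
        model = _small_model(g_scale=g_scale, feedback=feedback, seed=seed)
        net = model.compile(dt=0.1)
        net.settle(500.0)
        rng = np.random.default_rng(seed)
        stim = _poisson_stimulus(rng, 9, 10.0, 120.0, _grid(3))
        ev = stim.to_events_ms()
        return net, (ev[0] + net.t_ms, ev[1])

    def test_zero_conductance_loop_ratio_is_one(self):
        net, ev = self._driven_net([FeedbackSpec("trn", 0.0, 50.0)])
        res = silence_and_measure(net, "trn", ev, epoch_s=60.0)
        assert res["ratio"] == pytest.approx(1.0)

    def test_disabling_inhibition_cannot_lower_rate(self):
        net, ev = self._driven_net([FeedbackSpec("trn", 2.0, 30.0)])
        res = silence_and_measure(net, "trn", ev, epoch_s=60.0)
        assert res["ratio"] >= 1.0

    def test_disabling_excitatory_loop_cannot_raise_rate(self):
        net, ev = self._driven_net([FeedbackSpec("ctx", 1.5, 20.0)])
        res = silence_and_measure(net, "ctx", ev, epoch_s=60.0)
        assert res["ratio"] <= 1.0

    def test_state_and_weights_restored_after_measurement(self):
        net, ev = self._driven_net([FeedbackSpec("trn", 1.0, 30.0)])
        g_before = net.synapses.g.copy()
        t_before = net.t_ms
        silence_and_measure(net, "trn", ev, epoch_s=30.0)
        assert np.array_equal(net.synapses.g, g_before)
        assert net.t_ms == t_before

    def test_unknown_loop_rejected(self):
        net, ev = self._driven_net([FeedbackSpec("trn", 1.0, 30.0)])
        with pytest.raises(ValueError):
            silence_and_measure(net, "l6", ev)


class TestScaleKinetics:
    def test_identity_variant_reproduces_raster(self):
        rng = np.random.default_rng(10)
        stim = _poisson_stimulus(rng, 9, 8.0, 20.0, _grid(3))
        model = _small_model(seed=11)
        variant = scale_kinetics(model, intrinsic_factor=1.0)
        rasters = []
        for m in (model, variant):
            net = m.compile(dt=0.1)
            net.settle(300.0)
            ev = stim.to_events_ms()
            out = run(net, (ev[0] + net.t_ms, ev[1]), 20.0)
            rasters.append(out.spike_times_s)
        assert np.array_equal(rasters[0], rasters[1])

    def test_nmda_decay_override_propagates(self):
        model = _small_model()
        variant = scale_kinetics(model, nmda_tau_decay_ms=74.0)
        net = variant.compile(dt=0.1)
        assert net.receptors.nmda.tau_decay == 74.0

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            scale_kinetics(_small_model(), intrinsic_factor=0.0)
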