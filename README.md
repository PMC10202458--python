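# dlgnsim

A desk-scale simulator and analysis suite for the developing mouse
retino-thalamic circuit (P7-P10), built for studying **parasitic
correlations**: the millisecond-precise spike correlations that the
broad, unrefined convergence of retinal ganglion cells (rGCs) onto
thalamocortical (TC) relay neurons would impose — correlations that
carry no topographic information and dilute the information conveyed by
retinal waves at slower timescales.  The package lets you ask, on a
workstation, how NMDA-receptor dominance at the retinogeniculate synapse
and the developmental delay of TRN/cortical feedback suppress them.

It is intended for computational neuroscientists who want the circuit
model, the input statistics and the spike-train metrics in one tested,
seedable package: conductance-based two-compartment TC neurons (29
tunable parameters), Tsodyks-Markram depressing NMDA/AMPA/GABA synapses,
a hexagonal dLGN lattice with Gaussian distance-dependent retinal
convergence (`p = exp(-d^2/sigma^2)`, conductance `g0 exp(-d^2/sigma^2)`),
nonlinear firing-rate homeostasis
(`g <- g (1 + tanh(alpha (r0 - r)))`, clipped to `[0, 10 g0]`),
all-to-all feedback loops, a synthetic retinal-wave generator emulating
multielectrode-array recordings, Mexican-hat (difference-of-Gaussians)
timescale-resolved pairwise spike correlation, the distance/interval
mutual information `I[r, dt]`, and two evolutionary multiobjective
fitting algorithms for the neuron model.

## Worked example

Build a pair of desk-scale networks (7x8 lattice, 56 neurons,
sigma = 4 so each TC receives ~10 retinal inputs) that share the same
synthetic waves and neuron draws and differ only in the receptor mix,
run homeostasis to the 0.5 spikes/s set-point, and compare fast-timescale
correlations:

```python
from dlgnsim.experiments import build_desk_network, run_homeostatic_condition
from dlgnsim.correlation import KERNEL_48MS, pairwise_correlation

for label, ratio in [("nmda+ampa", 2.25), ("ampa-only", None)]:
    desk = build_desk_network(sigma=4.0, receptor_ratio=ratio,
                              seed=1, duration_s=1300.0)
    cond = run_homeostatic_condition(desk, epoch_s=240.0, max_intervals=40)
    corr = pairwise_correlation(cond["sths"], KERNEL_48MS)
    print(label, round(cond["mean_rate_hz"], 3), round(corr.mean, 4))
```

Output from this exact configuration:

```
nmda+ampa 0.524 0.0717
ampa-only 0.368 0.159
```

Both networks converge to the neighborhood of the homeostatic set-point,
yet removing the slow NMDA component more than doubles the mean pairwise
correlation in the 48 ms window — the parasitic correlations that
convergent retinal input generates and that NMDA dominance suppresses.
The contrast grows toward faster windows (about sevenfold in the 24 ms
window: 0.108 vs 0.014) and vanishes above ~200 ms, where the
wave-timescale correlations that carry retinotopic information are
preserved by both mixes (`dlgnsim.correlation.timescale_sweep` returns
the full curves).

The same condition objects feed the other analyses:

```python
from dlgnsim.information import mutual_information, MIBinning
pos = desk.model.geometry.tc_positions
mi = mutual_information(cond["trains"], pos, MIBinning())
print(mi.mi_bits)        # spatial information in inter-onset intervals
```

A CLI wraps the recipes: `dlgnsim generate-waves`, `dlgnsim experiment
receptor-mix|spatial-info|trn-feedback|combined-feedback`, `dlgnsim analyze-corr`, `dlgnsim analyze-mi`,
`dlgnsim fit`.  See `docs/methods.md` for the model equations,
parameter meanings, desk-scale constants and known limitations.

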