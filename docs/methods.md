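# Methods

`dlgnsim` models the mouse retino-thalamic circuit during the first
postnatal week-and-a-half (P7-P10), when each thalamocortical (TC) relay
neuron of the dorsolateral geniculate nucleus (dLGN) still receives
convergent input from ~10-20 retinal ganglion cells (rGCs) through
NMDA-receptor-dominant synapses.  The package exists to exercise, at desk
scale, the phenomenon of *parasitic correlations*: millisecond-precise
spike correlations that broad, unrefined retinal convergence would impose
on TC neurons, which carry no topographic information and dilute the
information carried at slower (wave) timescales -- unless suppressed by
slow NMDA currents and by the developmental delay of TRN/cortical
feedback.

## Neuron model

Each TC neuron is a two-compartment "pen-and-ball" model: a
single-segment somatodendritic cylinder (length = diameter = `soma.L`)
and an unbranched axonal cable split into an odd number of segments no
longer than 0.1 of the AC length constant at 100 Hz.  The soma carries
nine mechanisms -- leak, transient Na+ and delayed-rectifier K+
(Traub-style rates with tunable half-point shifts `vtraub`/`vtraub2`),
persistent Na+, A-type K+, L-type Ca2+ (GHK form), low-threshold T-type
Ca2+ (Destexhe-1998 kinetics in GHK form, with a joint `shift` and an
activation-only `actshift`), SK-type Ca-activated K+ (Hill coefficient
4.8, K_d 0.43 uM, tunable gate time constant), and an HCN cation current
(Budde-1997-style) -- plus a submembrane Ca2+ pool (0.1 um shell, influx
fraction `gamma`, first-order removal `taur`, 50 nM floor).  The axon
carries leak and the fast Na+/K+ pair.  Membrane capacitance is fixed at
1 uF/cm^2; temperature at 36 C.  Exactly 29 quantities are tunable, each
addressed by a flat key string (e.g. `soma(0.5).TC_iT_Des98.pcabar`) and
bounded; conductance-like parameters are searched and jittered in log10
space.

The exact rate functions are this package's sourced re-specification of
each mechanism's canonical published kinetics (see `mechanisms.py`); the
mechanism roster and the free parameters are fixed, the rate functions
are documented and swappable.

### Integration

Gating variables advance by exponential Euler on per-neuron voltage
lookup tables (0.25 mV grid); compartment voltages by exponential Euler
with the conductances implicit, axon segments swept soma-outward with
the freshly updated upstream voltage (Gauss-Seidel).  GHK Ca2+ currents
enter the voltage equation as chord conductances toward the
instantaneous Ca2+ Nernst potential -- the same current, but implicit in
V, which keeps the step stable under heavy synaptic bombardment.  At
protocol-grade steps (dt <= 0.05 ms) one midpoint corrector pass
re-evaluates the rates, restoring near-second-order spike timing:
halving dt from the 0.025 ms default moves the first-spike latency of a
step response by < 0.5 ms and the mean tonic ISI by < 2%.  Network runs
use dt = 0.1 ms without the corrector, a resolution chosen for
desk-scale throughput; the population phenotype screen (below) runs
under the same settings, so single-cell behavior in the network matches
the screen.
Spikes are upward crossings of 0 mV at the soma with a 2 ms refractory
for counting.

### Validation and the unitary conductance g0

A parameter set is *valid* if the axon is longer than wide and thinner
than the soma, the Ca2+ buffer shell is shallower than the soma radius,
and an evoked somatic spike propagates to the distal axon without
decrement (distal peak above threshold >= 90% of the somatic peak --
the qualitative no-decrement requirement is fixed here at the 0.9
fraction).  Within the published bounds the two axon-geometry checks
cannot fail at construction; they are still enforced defensively.

`g0` is the minimal peak synaptic conductance that fires a neuron from
rest with a single presynaptic event, found by log-bisection to 1%.  The
probe event passes through the depression stage (a first event from rest
releases u0 = 0.3 of the resource), so g0 is the *functional* unit in
which network conductances, the homeostatic ceiling (10 g0) and feedback
strengths are expressed.

## Synapses

Each synapse is a two-stage process.  Presynaptic: simplified
Tsodyks-Markram depression -- one resource pool, recovery `tau_rec`
(default 700 ms; a calibration helper returns the (tau_rec, interval)
pairings consistent with the measured paired-pulse ratio 0.73 at
u0 = 0.3), release u0*R per spike, u0 = 0.3 retinogeniculate / 0.7
corticothalamic.  Depression acts on the single resource, i.e. jointly
on the NMDA and AMPA components (an assumption; whether the components depress
separately is left open by the measurements, so one shared pool is used).  Postsynaptic:
peak-normalized dual exponentials -- AMPA 1/2.2 ms, NMDA 1/150 ms (74 ms
"adult" option), GABA-A 5/50 ms at -70 mV (-90 mV option).  The NMDA:AMPA
peak-conductance ratio 2.25 derives from the measured peak-current ratio
0.78 via the driving-force correction 1/(beta * 40/70); 13% of the NMDA
current is carried by Ca2+, implemented as a GHK current whose
permeability is calibrated at -40 mV (a configurable approximate
operating point) and fed to the Ca2+ pool.  A sigmoidal Mg2+ block is
implemented but OFF by default: the network model is specified without
it, and all shipped analyses use the default.

## Network

56 (desk, 7x8) or 112 (default, 7x16) TC neurons sit on a hexagonal
lattice with unit constant.  Source (electrode) positions are
isotropically scaled and centered onto the lattice; `calibrate_density`
rescales the array so the expected convergence matches the target for
the chosen sigma (sigma=1 -> 2 inputs/TC, sigma=4 -> 10, sigma=9 -> 20,
interpolated on sigma^2 elsewhere).  Each (rGC, TC) pair connects with
probability exp(-d^2/sigma^2) and conductance g0 * exp(-d^2/sigma^2).
Feedback loops (TRN inhibitory, cortical excitatory) are non-specific
all-to-all projections of every TC spike train back onto every TC neuron
(self-connections included), homogeneous in conductance (quoted relative
to each target's g0) and delay, optionally jittered +-20% per synapse;
in the full model the TRN delay strictly exceeds the cortical delay.
TRN loop synapses do not depress (a modeling choice); cortical
loop synapses depress with u0 = 0.7.

### Heterogeneous populations

Populations are drawn by jittering a hand-tuned canonical P7 set:
log-normal (ln-sd 0.45) on log-scaled parameters, Gaussian (1.5% of the
bound range per unit jitter) on linear ones, clipped to bounds.  Draws
are kept only if they pass the four validation checks and a phenotype
screen, run under the network's own integration settings and with the
reference P7 receptor mix (so paired receptor modes share identical
draws): silent at rest, excitable (g0 above 1e-4 uS), and no
self-sustained firing after a 3 s wave-like synaptic barrage at 3 g0
(rebound spiking within ~2 s of offset is tolerated).  The assembled
network must additionally stay silent through a 20 s zero-input probe;
offenders are redrawn.  The screen matters: at this jitter level a few
percent of structurally valid draws are bistable or pacemake at the
network step and would otherwise pin the population firing rate far
above any homeostatic set-point.  The jitter level emulates the wide per-parameter
spread a database of independently fitted neuron models exhibits;
`jitter=0` gives the homogeneous-network control.

## Homeostasis

Every `update_interval` (120 s full scale; 20 s desk) each neuron's
afferent conductances are multiplied by `1 + tanh(alpha (r0 - r_i))`
with alpha = 0.05 and r_i the rate over the elapsed interval, clipped to
[0, 10 g0].  The run stops when the population-mean rate over a trailing
window (27 min full scale; 240 s desk -- chosen to preserve the
full-scale window:interval smoothing ratio, without which desk runs
declare convergence while weights are still ramping) is within 10% of
the set-point: 0.5 spikes/s without cortical feedback, 1 spikes/s with.
Heterosynaptic mode applies the same per-neuron multiplier to retinal
and cortical synapses, preserving their ratio; TRN synapses are never
scaled.  Non-convergence returns the full history; at adult convergence
(sigma=1) many neurons receive no retinal input and the population mean
may never reach the set-point -- analyses proceed over the final epoch
with the history flagged, which is the quantity of interest there
(a correlation bound, not a rate).

## Synthetic retinal waves

The generator emulates multielectrode-array recordings of the developing
retina, not retinal biophysics: waves nucleate as a Poisson process
(4/min) uniformly over a 16x16 (default; 12x12 desk) grid with a spatial
refractory rule (no re-nucleation within one wave extent for 30 s), and
propagate as an annular front (speed 2 grid units/s, extent 8, width 5,
i.e. ~2.5 s local burst dwell, matching the several-second local bursts
of such recordings).  Units inside the front fire independent Poisson
trains at 10 spikes/s; baseline 0.02 spikes/s otherwise.  Generated data
reproduce the input statistics that matter to the circuit: ~10 Hz
within-wave rates, long inter-wave silences, slow-timescale pairwise
correlation falling with electrode distance, and near-zero correlation
in sub-100 ms windows.  They do not reproduce wave-boundary shapes,
directional biases, ON/OFF types, or the non-Poisson fine structure of
real rGC bursts -- so passing tests demonstrate the circuit mechanisms
under the stated input statistics, not recording-level realism.

## Spike-correlation analysis

Spike trains are binned into 1 ms spike-time histograms, convolved with
a difference of two unit-area Gaussians (sigma_neg = 4 sigma_pos;
truncated at +-5 sigma_neg), and Pearson-correlated for all pairs
(whole-trace, silences included; zero-variance traces give r = 0 with a
logged warning).  The family spans sigma_pos 10..500 ms and is labeled
by the printed positive-window widths 24..886 ms; the labels are carried
verbatim because the analytic zero crossing of the unit-area
difference-of-Gaussians (|t| ~ 34 ms for 20/80 ms, a 69 ms window)
differs from the printed 48 ms -- the printed labels are treated as the
family's names, not recomputed quantities.

## Spatial information

Burst onsets are spikes preceded by >= 0.1 s of silence.  For every
neuron pair, all cross-train onset intervals |dt| <= 2 s are pooled into
the interval histogram (30 log bins over [1 ms, 2 s]) of that pair's
distance bin (8 quantile bins of the pair-distance distribution), and
the plug-in Shannon mutual information I[r, dt] is evaluated with the
pair-count prior p(r).  A nearest-onset-only pairing variant exists
behind a flag but is not the default: it discards the informative
100-500 ms intervals whenever a millisecond-scale interval is present,
which is exactly the regime under study.  No bias correction is applied
(plain plug-in); comparisons are therefore made between conditions with
matched spike counts and durations.  `I_lost = (<I_ref> - <I_alt>) /
<I_ref>` quantifies the spatial information lost by, e.g., an AMPA-only
variant relative to the NMDA+AMPA reference.

## Evolutionary fitting

Current-clamp targets are scored with two fitness families per trace:
|spike-count difference| and the Euclidean distance between voltage
samples.  Two GAs share one interface: a nondominated-sorting GA (Pareto
fronts under "no worse in all, better in at least one", crowding-distance
tie-break, elitist survival) and an adaptive-weight GA reconstructed
from its stated principle -- per generation, objective weights are
re-adjusted by damped multiplicative updates (damping 0.5, 1% tolerance)
until the correlation between the weighted total fitness and each
objective is equalized, preventing any objective from dominating.  The
adaptive-weight algorithm is a sketch-faithful reconstruction (its full
specification is not in the available text) and is swappable.  When no
algorithm is named one is drawn at random per run.  Full-scale defaults
are 1024 generations x 240 models with 30 elites; the desk-scale
recovery experiment runs 40 x 40 on a synthetic target from a known
parameter set, freeing a 6-parameter conductance subset
(gna/gk/pas/T/h/A) rather than all 29 dimensions -- a 1600-evaluation
budget cannot search the full space, and the recovery claim being tested
is that the machinery finds spike-count-exact, low-voltage-error models,
not that 29 parameters are identifiable from 6 traces.  Mutation is
Gaussian (sd 5% of the scaled range) in each parameter's optimization
scale; crossover uniform per parameter.  Post-hoc selection re-sorts the
full archive, takes a configured top fraction (0.2% at full scale, i.e.
510 of 245,760), and applies the validation checks.  Database summaries
provide per-parameter Gaussian KDEs (Scott's rule, in the optimization
scale) and the leading five principal components.

## Desk-scale experiment recipes

All randomness descends from one master seed through named substreams,
so paired conditions (NMDA+AMPA vs AMPA-only; feedback variants) share
waves, geometry and neuron draws exactly.  Desk constants, stamped into
every result: 7x8 lattice, 12x12 source grid, dt 0.1 ms, 20 s updates,
240 s window, capped at 25-45 update intervals, 180-240 s analysis epochs (homeostatic
updates keep running through the epoch, as at full scale), 1-3 replicas.
The 4-D feedback space (g_TRN, g_CTX, delay_TRN, delay_CTX) is sampled
by a seeded Latin hypercube with the TRN-delay-longer constraint, and
silencing experiments freeze the converged weights, then compare matched
epochs with a loop's conductances zeroed (F_disabled/F_control).

## Known limitations

* Desk-scale runs reproduce the direction and ordering of the published
  network effects, not their full magnitudes: with 56 neurons, minutes
  (not hours) of model time, and synthetic (not recorded) waves, the
  fast-correlation contrast between AMPA-only and NMDA+AMPA networks is
  a few-fold rather than ~20-fold, and information-loss estimates are
  small numbers with run-to-run variability.
* The plug-in MI estimator is biased upward at small sample sizes;
  only same-size comparisons are meaningful.
* No local dLGN interneurons, no explicit TRN/cortex cells (loops are
  sketches), no receptor desensitization, facilitation or stochastic
  release, no morphological detail.
* The exponential-Euler/Gauss-Seidel cable scheme is convergence-tested
  for this model family, not a general-purpose cable solver.
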