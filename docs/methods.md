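# Methods

## Scope and model summary

`laminet` simulates the primary current-dipole source of somatosensory
MEG/EEG evoked responses with a reduced laminar neocortical column. The
column contains a 10×10 grid of pyramidal-cell pairs in layers 2/3 and 5
(100 cells per layer) and 35 fast-spiking basket interneurons per layer.
The macroscale observable is the net intracellular current flowing along
the pyramidal apical dendrites: positive values denote current directed
from deep to superficial layers (up the dendrites), negative values the
reverse. Evoked responses are produced by sequences of exogenous
excitatory drives: *proximal* (feedforward, lemniscal-thalamic pattern)
drives contact the proximal apical compartments of both pyramidal
populations and both basket populations; *distal* (feedback,
non-lemniscal/cortico-cortical pattern) drives contact the distal apical
compartments and the L2/3 baskets only. On each trial one spike time per
drive is drawn from a Gaussian (mean, SD) and applied synchronously to
every targeted cell; trial-to-trial variability comes only from this
jitter.

## Cell model

Pyramidal cells are three compartments — soma, proximal apical, distal
apical — with Hodgkin–Huxley Na/K conductances at the soma, passive
dendrites, and strong soma→dendrite coupling so that somatic action
potentials measurably depolarize the apical compartments (spike
backpropagation, the model's source of fast upward current). The L5
distal compartment carries a small slow depolarizing calcium-like
conductance (sigmoidal activation, τ = 30 ms) standing in for dendritic
calcium dynamics. Basket cells are single-compartment fast spikers.

The soma and the proximal apical compartment sit at nearly the same
laminar depth, so the soma→prox dipole segment is short (0.05 length
units for L2/3, 0.1 for L5) while the prox→dist apical trunk is long
(0.9 and 1.8 units). This geometry fixes the sign conventions: proximal
excitation and backpropagating spikes push current up the trunk
(positive), distal excitation and somatic inhibition pull it down
(negative). L5 apical lengths are twice L2/3 lengths, so the aggregate
dipole is dominated by L5, with the layer traces exposed separately.

Integration is fixed-step (default dt = 0.025 ms): exponential Euler for
channel gating, forward Euler for the membrane equations, with every
population initialized at its numerically solved resting fixed point. A
divergence guard aborts if any |V| exceeds 150 mV, reporting time and
cell. Runs are bitwise reproducible given (configuration, events, seed).

## Synapses and connectivity

Synaptic conductances are peak-normalized dual exponentials. Defaults:
AMPA 0.5/5 ms, NMDA 1/20 ms with a sigmoidal magnesium-block voltage
dependence (1 mM Mg²⁺), GABA_A 0.5/5 ms onto pyramidal cells, GABA_B
1/20 ms (reversal −95 mV). Two deviations from these textbook pairs are
load-bearing:

- **Basket GABA_A decays in 25 ms.** The inhibitory-to-inhibitory decay
  constant sets the interneuron-gamma (ING) period of the basket
  subnetwork (~40 Hz).
- **Basket NMDA is slow (40/60 ms rise/decay).** Repeated distal drive
  then builds a smooth tonic excitation of the L2/3 baskets rather than
  a sequence of punctate kicks; see *Gamma mechanism* below.

Local connections follow a fixed population-level table (weights in µS:
pyramidal AMPA/NMDA 2e-4 … 1e-3 within and across layers; basket GABA_A/
GABA_B 2e-3 … 6e-2, including the strong basket↔basket GABA_A at 2e-2),
with realized pairwise weights `base · exp(−d/λ)` over grid distance.
The fall-off constant λ is per-projection: excitatory connections are
local (λ = 3 grid units), inhibitory output is broad (λ = 20), and
basket↔basket coupling is effectively all-to-all (λ = 100). The broad
inhibitory fall-off follows the convention of laminar column models in
this field and reflects the dense, space-spanning axonal arbors of
cortical PV interneurons; it is also functionally necessary here —
near-uniform mutual inhibition is what lets the 35-cell basket
populations fire as single synchronized volleys (with heterogeneous
coupling the volleys fragment and the gamma rhythm collapses).
Inhibition lands on pyramidal somata except the L2/3-basket → L5-
pyramidal projection, which contacts the distal apical dendrite (its
transient hyperpolarization produces *upward* current, visible during
the rebound phases).

Conduction delay is 1 ms for local connections and 0 within a drive.
Drive conductances are hand-tuned model defaults: the published figure
panels that contain the study's per-drive conductances are not
machine-readable, so the shipped values were chosen to reproduce the
deflection signs, ordering, and approximate latencies, and every value
is exposed in the experiment configuration files.

## Canned experiments

The registry (`laminet.get_experiment`) stores the published drive
timing statistics as canonical:

- `te_default` — tactile-evoked: proximal 19.6 ± 2.5, distal 65.7 ± 3.8,
  proximal 90.5 ± 10.4 ms; scaling 10.
- `mn_pre_ops` / `mn_post_ops` — median-nerve four-drive sequences
  (20.0/32.0/82.0/130.0 ± 3.0; 20.8 ± 4.1, 31.6 ± 2.7, 84.0 ± 4.5,
  134.4 ± 4.4 ms); scaling 40; 170 ms trials.
- `mn_no_early_distal` — ablation control without the ~30 ms distal
  drive.
- LE variants (300 ms trials, scaling 2500): single/burst distal and
  proximal drives (120…195 ± 8 ms at 25 ms spacing), `le_post_ops`
  (118.8 ± 10.0, 145.0 ± 10.0, 168.9 ± 9.2, 194.5 ± 11.5 plus late
  proximal 256.8 ± 12.2 ms), `le_post_ops_early_prox` (adds an early
  proximal drive; 50 trials by default as a five-plus-drive
  configuration), `le_aperiodic_burst` / `le_asynchronous_burst`
  controls, and `le_idi_variant(idi)` for parameterized inter-drive
  intervals.

Experiments default to 100 trials; the per-trial dipole is scaled
(10/40/2500 for TE/MN/LE) and smoothed with a unit-gain Hamming window
(5 ms during fitting and analysis, 20 ms for display) before averaging;
smoothing is applied per trial, then trials are averaged. The raw model
dipole is in arbitrary units (nA × length unit); the scaling factor maps
it to nAm-comparable magnitude. Absolute amplitudes are not calibrated
to empirical nAm — deflection timing, ordering, and spectral structure
are the quantities this model is used for.

## Gamma mechanism (LE N1)

The LE burst works as follows. The first distal drive carries a fast
AMPA punch that ignites a synchronized L2/3 basket volley. All four
drives deposit slow NMDA onto the baskets with decreasing per-drive
weights, which flattens the summed tonic-excitation envelope over the
burst window. After each volley, the mutual basket GABA_A (25 ms decay)
suppresses the population until the inhibition decays below the tonic
excitation, at which point the whole population fires again — a
self-paced rhythm at ~25 ms period that is robust to the ±10 ms jitter
of the individual drive times. Each volley delivers a synchronized
GABA_A/GABA_B volley to the pyramidal somata, producing the sharp
periodic downward deflections whose fundamental (~40 Hz) and second
harmonic (~80 Hz) appear in the trial-mean Morlet TFR. The deep N1
envelope itself is carved predominantly by this accumulating
volley-locked inhibition; the direct distal push on the pyramidal
dendrites is kept small and heaviest mid-burst, anchoring the trough
near 170 ms. Keeping the push small matters spectrally: a strong
push-carved trough varies trial to trial with the jittered drive times,
and the induced broadband background of that variability leaks into the
low end of the 30–60 Hz analysis band, where it can mask the 40 Hz volley
rhythm.

A consequence of this design is a known limitation: because the basket
rhythm is paced by tonic NMDA and the GABA_A release time, the
*accumulated* inhibition is nearly insensitive to the periodicity of the
drive times, and uniformly sampled drive times cluster (mean gap 16 ms
vs 25 ms), concentrating excitation. The aperiodic control (drive times
uniform over 120–200 ms) therefore produces a trial-mean N1 that is as
deep as or deeper than the periodic burst's, instead of the strongly
reduced depth reported for the reference simulations, where drive-phase
resonance gates the inhibition. Configurations that restored the
periodicity sensitivity (volleys gated by per-drive AMPA punches)
destroyed the 40/80 Hz spectral signature under the published 10 ms
drive jitter; the shipped defaults favor the spectral signature. The
corresponding test asserts the reduction faithfully and is expected to
fail with these defaults.

## Fitting and optimization

`rmse` scores a simulated trial mean against a target waveform after
linear interpolation onto the common time grid (full overlap by default,
optional sub-window). `optimize_drives` is a derivative-free staged
coordinate search: drives are visited in order of mean time; each free
parameter (drive means, per-target conductances) gets three shrinking
bracket passes of four candidates each, honoring the three-iterations-
per-parameter budget; conductances are searched on a log10 scale.
Candidate evaluations use a reduced trial count (default 25) with common
random numbers and 5 ms smoothing; the final RMSE can be re-evaluated at
full trial count. The running best is never worse than the initial
configuration, and failed candidate simulations are logged and skipped.
On self-generated targets with drive means displaced by +5 ms, the
search recovers the true means to well under 2 ms (bracket resolution
≈ 0.3 ms after three passes) and preserves drive ordering.

## Sensitivity analysis

One-at-a-time sweeps: 50 simulations per parameter by default, the
parameter drawn uniformly (conductances log10-uniform over 1e-5–1e-2 µS;
mean times uniform over ±4 ms for MN-length trials and ±10 ms for
LE-length trials), everything else fixed. All samples of a sweep share
trial seeds (common random numbers), so the per-time-point SD across
samples isolates parameter influence from jitter noise — the study does
not state whether seeds were shared; this choice gives strictly cleaner
attribution. Named sweep sets `mn_sensitivity` and `le_sensitivity`
mirror the parameter subsets analyzed in the reference study. Stacked
SDs are normalized by the pointwise total (rows sum to one wherever the
total is positive).

## Time-frequency analysis

Per-trial Morlet TFR, 3–100 Hz at 1 Hz steps: wavelet with m = f/3
cycles, Gaussian envelope σ = m/(2πf) = 1/(6π) s at every frequency,
amplitude A = (½Σ|w|²)^(−1/2), truncated at ±5σ; the trace is zero-padded
(default 300 ms per side), convolved per frequency (FFT convolution),
and |·|² is cropped to the original support aligned to the wavelet
center. Trials are averaged in the power domain, which retains
non-phase-locked activity. The dipole is heavily oversampled relative to
the 100 Hz analysis ceiling, so traces may be decimated (keep every n-th
sample; 1 kHz is the default in the pipeline scripts) with no loss in
band. `band_peak` reports the frequency of maximal window-averaged power
within a band, ties broken toward the lowest frequency for determinism.

## Surrogate waveforms

`laminet.surrogate` generates synthetic stand-ins for the empirical MN
and LE source waveforms as sums of Gaussian bumps plus optional white
noise: MN — small upward peak at 20 ms, dominant sharp trough at 37 ms,
shallow sustained negativity near 75 ms, partial rebound at 135 ms; LE —
single prolonged trough at 170 ms (σ = 32 ms) and a smaller rebound at
265 ms. Amplitudes are free parameters chosen only to respect the
relative-magnitude ordering of the deflections. These surrogates have
the deflection structure the fitting stages assume but none of the
spectral fine structure, noise color, or inter-subject variability of
recorded data: tests that pass on surrogates validate the pipeline
mechanics, not empirical fit quality. Users with access to the real
recordings can export them as two-column TSV (time_ms, nAm) and use them
directly.

## Problem sizes used in the shipped checks

The packaged tests and the acceptance script run the MN and LE
experiments at 25 trials (the reference protocol uses 100) and the
matched-pair ablation controls at 10 trials; these sizes give stable
trial means for every quantity asserted (latencies, band peaks, depth
ratios) while keeping the full suite fast on a single core. The
optimizer and sensitivity tests use a reduced 4×4-pyramid column with
shortened trials, where the same contracts (recovery within 2 ms,
zero-width sweeps, normalization identities) are exercised at a fraction
of the cost.

## Numerical and design choices

- Hamming kernels are normalized to unit DC gain; edges are handled by
  reflection padding, preserving baseline level.
- Trial seeds are `base_seed + trial_index`; each drive separates its
  stream with a `seed_offset`. Negative sampled drive times are clamped
  to zero with a warning.
- Degenerate inputs: zero-width sensitivity bounds give identically zero
  SD; point bounds in the optimizer produce a single evaluation per
  parameter and return the initial configuration; an all-zero waveform
  cannot be normalized (error); smoothing windows wider than the trace
  are an error.
- The experiment-duration validity check requires
  `duration ≥ mean + 2·SD` for every drive, which admits the published
  LE configuration (late proximal drive at 260 ± 12 ms in a 300 ms
  trial).
- Receptor kinetics accept an optional conductance ceiling
  (`g_max`, receptor-pool saturation); all defaults leave summation
  linear.

## Known limitations

- Cell morphology, channel densities, and absolute dipole scale are
  reduced-model choices, not reproductions of any multi-compartment
  model; agreement is expected at the level of mechanism and timing,
  not waveform-by-waveform amplitude.
- The aperiodic-burst depth contrast is not reproduced (see *Gamma
  mechanism*).
- No extracellular potentials (LFP/CSD), no plasticity, no rhythmic or
  Poisson background drive, no sensor-space projection.
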