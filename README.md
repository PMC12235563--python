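# laminet

A reduced laminar neocortical-column simulator for interpreting
source-localized MEG/EEG evoked responses in primary somatosensory
cortex (SI), with the full analysis pipeline around it: waveform
fitting, staged drive-parameter optimization, one-at-a-time sensitivity
analysis, and Morlet time-frequency decomposition.

## The problem

Electrical median-nerve (MN) stimulation and cutaneous laser (LE)
stimulation evoke stereotyped current-dipole responses in SI: the MN
response begins with upward current at ~20 ms (N1) followed by a
dominant downward deflection at 35–40 ms (P1), a prolonged depression,
and a rebound; the LE response is a single large downward deflection
near ~170 ms followed by a rebound, accompanied by ~40 Hz and ~80 Hz
gamma activity. Which laminar circuit events produce these deflections
cannot be read off the sensor data. `laminet` addresses this by
simulating the primary current source directly: a laminated cortical
column (L2/3 and L5 pyramidal cells plus basket interneurons) is driven
by sequences of exogenous proximal (feedforward) and distal (feedback)
synaptic drives, and the net intracellular current along the pyramidal
apical dendrites — the quantity source analysis estimates in nAm — is
read out, per layer and in aggregate. Positive dipole values mean
current flowing up the dendrites (deep → superficial).

The intended users are researchers modeling evoked M/EEG source
waveforms who want a desk-scale, fully scriptable column model whose
every parameter is inspectable, with deterministic seeding throughout.

## The model in brief

- 10×10 grid of L2/3+L5 pyramidal-cell pairs (three compartments,
  Hodgkin–Huxley soma, passive dendrites, spike backpropagation) and
  35 fast-spiking basket cells per layer.
- Local connectivity from a fixed population-level weight table (µS)
  with exponential spatial fall-off `w = base · exp(−d/λ)`.
- Evoked drives: per trial, one Gaussian-jittered spike time per drive,
  applied synchronously to all targeted cells; proximal drives contact
  proximal apical compartments and basket somata, distal drives contact
  distal apical compartments and L2/3 baskets. Drives are
  excitatory-only (AMPA/NMDA).
- Dipole readout: per-layer sum of axial currents × apical segment
  length, scaled (10/40/2500 for TE/MN/LE) and smoothed with a unit-gain
  Hamming window.
- Interneuron gamma (ING): basket↔basket GABA_A decays in ~25 ms, so
  under repetitive distal drive the basket population fires
  synchronized volleys self-paced at ~25 ms (~40 Hz), producing the
  gamma signature of the simulated LE response.

The canned experiment registry ships the published drive-timing
statistics for the tactile (TE), median-nerve (MN), and laser-evoked
(LE) simulation experiments, including ablation controls (MN without
the early distal drive; aperiodic and asynchronous LE bursts; IDI
variants). See `docs/methods.md` for the full model description and the
known limitations.

## Worked example

Run the post-optimization MN experiment at 25 trials and locate its
deflections:

```python
import numpy as np
from laminet import get_experiment, run_experiment

res = run_experiment(get_experiment("mn_post_ops"), n_trials=25)
t, d = res.mean.times, res.mean.aggregate

i30 = np.searchsorted(t, 30.0)
print(f"N1 peak   : {t[np.argmax(d[:i30])]:.2f} ms")
lo, hi = np.searchsorted(t, [20.0, 60.0])
print(f"P1 trough : {t[lo + np.argmin(d[lo:hi])]:.2f} ms")
lo, hi = np.searchsorted(t, [50.0, 120.0])
print(f"depression: max {d[lo:hi].max():.0f} (sub-baseline)")
```

prints

```
N1 peak   : 21.35 ms
P1 trough : 36.68 ms
depression: max -420 (sub-baseline)
```

i.e. the upward N1 near 20 ms, the dominant downward P1 before 40 ms,
and a sustained sub-baseline interval — the canonical MN deflection
sequence. (Dipole values are in scaled model units comparable to nAm;
timing and ordering, not absolute amplitude, are the calibrated
quantities.)

The same from the command line, plus the LE gamma analysis:

```bash
laminet simulate --experiment le_post_ops --trials 25 --seed 1 --out le_run
laminet tfr --in le_run --fmin 3 --fmax 100 --out le_tfr.tsv
laminet synth --kind mn --noise 1.0 --seed 2 --out mn_surrogate.tsv
laminet optimize --experiment mn_pre_ops --target mn_surrogate.tsv --out fit
```

Every run writes a manifest (config echo, seed, package version, output
digests) next to its outputs.

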