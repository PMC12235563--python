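"""One-at-a-time parameter sensitivity sweeps.

Around an optimized configuration, each parameter of interest is swept
alone: ``n_samples`` simulations with the parameter drawn uniformly over
its bounds (log10-uniform for conductances) while everything else stays
fixed.  The per-time-point standard deviation of the trial-mean dipole
across samples measures that parameter's contribution to waveform
variance; stacking the per-parameter SDs and normalizing by the pointwise
total shows the relative share over time.

All samples of one sweep reuse the same trial seeds (common random
numbers), so the SD reflects parameter variation rather than drive-time
jitter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .experiments import ExperimentConfig, run_experiment
from .fitting import get_drive_parameter, set_drive_parameter
from .network import build_network

__all__ = [
    "SensitivityResult",
    "sweep_parameter",
    "stack_and_normalize",
    "named_sweep_set",
]

CONDUCTANCE_BOUNDS = (1e-5, 1e-2)  # uS, swept on a log10 scale
TIME_HALFWIDTH_MN = 4.0  # ms
TIME_HALFWIDTH_LE = 10.0  # ms


@dataclass
class SensitivityResult:
    """Per-time-point dipole SD contributed by one swept parameter."""

    parameter: str
    drive: str  # grouping label
    times: np.ndarray
    sampled_values: np.ndarray
    sd: np.ndarray  # nAm, same grid as times

    def integrated_sd(self, window=None) -> float:
        mask = np.ones_like(self.times, bool)
        if window is not None:
            mask = (self.times >= window[0]) & (self.times <= window[1])
        return float(np.trapezoid(self.sd[mask], self.times[mask]))


def _default_bounds(config: ExperimentConfig, param: str):
    if param.endswith(".mean_time"):
        half = TIME_HALFWIDTH_LE if config.duration > 200 else TIME_HALFWIDTH_MN
        v = get_drive_parameter(config, param)
        return (max(0.0, v - half), v + half), False
    return CONDUCTANCE_BOUNDS, True


def sweep_parameter(
    config: ExperimentConfig,
    param: str,
    bounds=None,
    n_samples: int = 50,
    seed: int = 0,
    n_trials: int = 25,
) -> SensitivityResult:
    """Sweep one parameter, all others fixed.

    ``bounds=None`` selects the defaults: conductances log10-uniform over
    1e-5..1e-2 uS; mean times uniform over +/- 4 ms (short/MN-length
    trials) or +/- 10 ms (long/LE-length trials) around the configured
    value.  Zero-width bounds give an identically zero SD.
    """
    get_drive_parameter(config, param)  # raises for unknown parameter ids
    log10 = None
    if bounds is None:
        bounds, log10 = _default_bounds(config, param)
    if log10 is None:
        log10 = not param.endswith(".mean_time")
    lo, hi = bounds
    param_key = zlib.crc32(param.encode()) % (2 ** 31)
    rng = np.random.default_rng(np.random.SeedSequence((seed, param_key)))
    if log10:
        values = 10 ** rng.uniform(np.log10(lo), np.log10(hi), n_samples)
    else:
        values = rng.uniform(lo, hi, n_samples)

    network = build_network(config.network, seed=config.base_seed)
    means = []
    times = None
    for v in values:
        cfg = set_drive_parameter(config, param, float(v))
        res = run_experiment(cfg, n_trials=n_trials, network=network)
        means.append(res.mean.aggregate)
        times = res.mean.times
    sd = np.std(np.asarray(means), axis=0, ddof=0)
    return SensitivityResult(
        parameter=param,
        drive=param.split(".")[0],
        times=times,
        sampled_values=values,
        sd=sd,
    )


def stack_and_normalize(results) -> dict:
    """Stack per-parameter SD traces and normalize by the pointwise total.

    Returns ``{"times", "parameters", "raw", "normalized"}`` where raw and
    normalized are (n_parameters, n_times) arrays; normalized rows sum to
    one wherever the total SD is positive (and are zero elsewhere).
    """
    results = list(results)
    if not results:
        raise ValueError("no sensitivity results to stack")
    times = results[0].times
    for r in results[1:]:
        if len(r.times) != len(times) or not np.allclose(r.times, times):
            raise ValueError("sensitivity results are on different time grids")
    raw = np.vstack([r.sd for r in results])
    total = raw.sum(axis=0)
    normalized = np.divide(raw, total, out=np.zeros_like(raw),
                           where=total > 0)
    return {
        "times": times,
        "parameters": [r.parameter for r in results],
        "raw": raw,
        "normalized": normalized,
    }


#: Parameter subsets mirroring the study's sensitivity analyses.  Proximal
#: drives contribute their mean time and NMDA conductances; distal drives
#: their mean time plus AMPA and NMDA conductances.
_SWEEP_SETS = {
    "mn_sensitivity": [
        "evprox_1.mean_time",
        "evprox_1.L2_pyramidal.nmda",
        "evprox_1.L5_basket.nmda",
        "evprox_1.L5_pyramidal.nmda",
        "evdist_1.mean_time",
        "evdist_1.L2_basket.ampa",
        "evdist_1.L2_pyramidal.nmda",
        "evdist_1.L5_pyramidal.nmda",
        "evdist_2.mean_time",
        "evdist_2.L2_basket.ampa",
        "evdist_2.L2_pyramidal.nmda",
        "evdist_2.L5_pyramidal.nmda",
        "evprox_2.mean_time",
        "evprox_2.L2_pyramidal.nmda",
        "evprox_2.L5_basket.nmda",
        "evprox_2.L5_pyramidal.nmda",
    ],
    "le_sensitivity": [
        "evdist_1.mean_time",
        "evdist_1.L2_basket.ampa",
        "evdist_1.L2_pyramidal.ampa",
        "evdist_1.L2_basket.nmda",
        "evprox_1.mean_time",
        "evprox_1.L2_pyramidal.ampa",
        "evprox_1.L5_pyramidal.ampa",
        "evprox_1.L5_pyramidal.nmda",
    ],
}


def named_sweep_set(name: str) -> list:
    """Parameter list for a named sweep set (mn_sensitivity, le_sensitivity)."""
    if name not in _SWEEP_SETS:
        raise KeyError(
            f"unknown sweep set {name!r}; available: {sorted(_SWEEP_SETS)}"
        )
    return list(_SWEEP_SETS[name])
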