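"""Waveform scoring (RMSE) and staged drive-parameter optimization.

The optimizer mirrors the study workflow: starting from a hand-tuned drive
sequence, a derivative-free bounded search adjusts drive mean times and
per-target conductances to minimize the RMSE between the simulated
trial-mean dipole and an empirical (or surrogate) waveform.  Drives are
optimized in stages ordered by mean time; within a stage each free
parameter receives three shrinking bracket passes.  Candidate evaluations
run at a reduced trial count with common random numbers (fixed base seed),
and simulated dipoles are smoothed with the narrow 5 ms window during
optimization to prevent overfitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dipole import DipoleTimeSeries
from .drives import EvokedDrive, flatten_drives
from .experiments import ExperimentConfig, run_experiment
from .network import build_network

__all__ = [
    "FitResult",
    "ParameterBounds",
    "rmse",
    "optimize_drives",
    "drive_parameter_names",
    "get_drive_parameter",
    "set_drive_parameter",
]


def rmse(sim, target, window=None) -> float:
    """Root-mean-square error between two waveforms on a common grid.

    Both arguments are DipoleTimeSeries or (times, values) pairs.  The
    target is linearly interpolated onto the simulated time grid over the
    overlap of the two time ranges (optionally intersected with
    ``window``); non-overlapping ranges are an error.
    """
    ts, xs = _as_waveform(sim)
    tt, xt = _as_waveform(target)
    lo = max(ts[0], tt[0])
    hi = min(ts[-1], tt[-1])
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    if hi <= lo:
        raise ValueError("waveform time ranges do not overlap")
    mask = (ts >= lo) & (ts <= hi)
    xi = np.interp(ts[mask], tt, xt)
    return float(np.sqrt(np.mean((xs[mask] - xi) ** 2)))


def _as_waveform(w):
    if isinstance(w, DipoleTimeSeries):
        return np.asarray(w.times, float), np.asarray(w.aggregate, float)
    t, x = w
    return np.asarray(t, float), np.asarray(x, float)


# ---------------------------------------------------------------------------
# Drive-parameter addressing: "<drive>.mean_time" or
# "<drive>.<population>.<receptor>"
# ---------------------------------------------------------------------------

def drive_parameter_names(config: ExperimentConfig) -> list:
    """All free drive parameters of a configuration."""
    names = []
    for d in flatten_drives(config.drives):
        names.append(f"{d.name}.mean_time")
        for pop in sorted(d.weights):
            for rec in sorted(d.weights[pop]):
                names.append(f"{d.name}.{pop}.{rec}")
    return names


def _split(param: str):
    parts = param.split(".")
    if len(parts) == 2 and parts[1] == "mean_time":
        return parts[0], None, None
    if len(parts) == 3:
        return parts[0], parts[1], parts[2]
    raise KeyError(f"malformed drive parameter id {param!r}")


def get_drive_parameter(config: ExperimentConfig, param: str) -> float:
    name, pop, rec = _split(param)
    for d in flatten_drives(config.drives):
        if d.name == name:
            if pop is None:
                return d.mean_time
            try:
                return d.weights[pop][rec]
            except KeyError:
                raise KeyError(f"drive {name!r} has no weight {pop}/{rec}")
    raise KeyError(f"no drive named {name!r} in {config.name!r}")


def set_drive_parameter(config: ExperimentConfig, param: str,
                        value: float) -> ExperimentConfig:
    """Return a new configuration with one drive parameter replaced.

    Bursts are flattened first, so burst members are addressable
    individually.
    """
    name, pop, rec = _split(param)
    drives = []
    found = False
    for d in flatten_drives(config.drives):
        if d.name == name:
            found = True
            if pop is None:
                d = replace(d, mean_time=float(value))
            else:
                if pop not in d.weights or rec not in d.weights[pop]:
                    raise KeyError(f"drive {name!r} has no weight {pop}/{rec}")
                weights = {p: dict(r) for p, r in d.weights.items()}
                weights[pop][rec] = float(value)
                d = replace(d, weights=weights)
        drives.append(d)
    if not found:
        raise KeyError(f"no drive named {name!r} in {config.name!r}")
    return replace(config, drives=tuple(drives))


@dataclass(frozen=True)
class ParameterBounds:
    """Bounds for one free parameter (inclusive)."""

    lower: float
    upper: float
    log10: bool = False  # search on a log10 scale (conductances)

    def __post_init__(self):
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("bounds must be finite")
        if self.upper < self.lower:
            raise ValueError("upper bound below lower bound")


@dataclass
class FitResult:
    """Outcome of a staged optimization."""

    rmse: float
    initial_rmse: float
    config: ExperimentConfig
    initial_config: ExperimentConfig | None = None
    iteration_log: list = field(default_factory=list)  # (param, value, rmse)
    bounds: dict = field(default_factory=dict)

    @property
    def optimized_drives(self) -> tuple:
        return self.config.drives

    def order_preserved(self) -> bool:
        """Whether optimized drive mean times kept their initial ordering."""
        means = {d.name: d.mean_time
                 for d in flatten_drives(self.config.drives)}
        ref = self.initial_config or self.config
        init = {d.name: d.mean_time for d in flatten_drives(ref.drives)}
        by_init = sorted(init, key=init.__getitem__)
        by_opt = sorted(means, key=means.__getitem__)
        return by_init == by_opt


def default_bounds(config: ExperimentConfig, time_halfwidth: float = 10.0,
                   cond_range=(1e-5, 1e-1)) -> dict:
    """Bounds per free parameter: mean times +/- ``time_halfwidth`` ms,
    conductances log-uniform over ``cond_range`` (uS)."""
    bounds = {}
    for p in drive_parameter_names(config):
        v = get_drive_parameter(config, p)
        if p.endswith(".mean_time"):
            bounds[p] = ParameterBounds(max(0.0, v - time_halfwidth),
                                        v + time_halfwidth)
        else:
            bounds[p] = ParameterBounds(cond_range[0], cond_range[1],
                                        log10=True)
    return bounds


def optimize_drives(
    config: ExperimentConfig,
    target,
    bounds: dict | None = None,
    n_trials: int = 25,
    passes_per_parameter: int = 3,
    points_per_pass: int = 4,
    window=None,
    smoothing_window_ms: float = 5.0,
    final_n_trials: int | None = None,
    on_error: str = "skip",
) -> FitResult:
    """Staged bounded coordinate search over drive parameters.

    Stages are drives ordered by initial mean time.  Within a stage each
    free parameter is refined with ``passes_per_parameter`` bracket
    passes; each pass evaluates ``points_per_pass`` candidates across the
    current bracket and shrinks it around the best.  The running best
    configuration is never worse than the initial one.  Simulation
    failures during candidate evaluation are logged and the candidate is
    rejected (``on_error="raise"`` propagates instead).

    ``final_n_trials`` optionally re-evaluates the returned RMSE at a
    larger trial count.
    """
    work = replace(config, smoothing_window_ms=smoothing_window_ms)
    bounds = default_bounds(work) if bounds is None else dict(bounds)
    network = build_network(work.network, seed=work.base_seed)
    log = []

    def evaluate(cfg):
        res = run_experiment(cfg, n_trials=n_trials, network=network)
        return rmse(res.mean, target, window=window)

    best_cfg = work
    best_rmse = evaluate(work)
    initial_rmse = best_rmse
    log.append(("<initial>", float("nan"), best_rmse))

    stages = sorted(flatten_drives(work.drives), key=lambda d: d.mean_time)
    for drive in stages:
        params = [p for p in drive_parameter_names(best_cfg)
                  if p.split(".")[0] == drive.name and p in bounds]
        for param in params:
            b = bounds[param]
            lo, hi = b.lower, b.upper
            if b.log10:
                lo, hi = math.log10(max(lo, 1e-12)), math.log10(max(hi, 1e-12))
            center = get_drive_parameter(best_cfg, param)
            if b.log10:
                center = math.log10(max(center, 1e-12))
            center = min(max(center, lo), hi)
            half = (hi - lo) / 2.0
            for pass_idx in range(passes_per_parameter):
                if half <= 0:
                    if pass_idx > 0:
                        break  # degenerate bounds: a single evaluation
                    cand_vals = [center]
                else:
                    a = max(lo, center - half)
                    z = min(hi, center + half)
                    cand_vals = list(np.linspace(a, z, points_per_pass))
                for cv in cand_vals:
                    value = 10 ** cv if b.log10 else cv
                    cand = set_drive_parameter(best_cfg, param, value)
                    try:
                        score = evaluate(cand)
                    except Exception as exc:  # candidate failed to simulate
                        if on_error == "raise":
                            raise
                        log.append((param, value, float("inf")))
                        continue
                    log.append((param, value, score))
                    if score < best_rmse:
                        best_rmse = score
                        best_cfg = cand
                        center = cv
                half /= float(points_per_pass)

    final_rmse = best_rmse
    if final_n_trials is not None and final_n_trials != n_trials:
        res = run_experiment(best_cfg, n_trials=final_n_trials, network=network)
        final_rmse = rmse(res.mean, target, window=window)

    return FitResult(
        rmse=final_rmse,
        initial_rmse=initial_rmse,
        config=best_cfg,
        initial_config=work,
        iteration_log=log,
        bounds={k: v for k, v in bounds.items()},
    )
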