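"""Exogenous proximal/distal synaptic drives.

Evoked drives model layer-specific excitatory input from exogenous sources
(lemniscal thalamus for proximal/feedforward drive; non-lemniscal thalamus
or higher-order cortex for distal/feedback drive).  On each trial a single
spike time per drive is sampled from a Gaussian and applied synchronously
to every targeted cell; drives deliver AMPA/NMDA conductances only.

Proximal drives contact the proximal apical compartments of L2/3 and L5
pyramidal cells and the somata of L2/3 and L5 basket cells.  Distal drives
contact the distal apical compartments of L2/3 and L5 pyramidal cells and
the somata of L2/3 basket cells only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import SynapticEvent, ConfigurationError

__all__ = [
    "EvokedDrive",
    "DriveBurst",
    "AperiodicBurst",
    "PROXIMAL_TARGETS",
    "DISTAL_TARGETS",
    "sample_drive_times",
    "expand_burst",
    "sample_aperiodic_burst",
    "flatten_drives",
    "build_event_schedule",
    "trial_rng",
]

#: population -> compartment contacted, per drive pathway
PROXIMAL_TARGETS = {
    "L2_pyramidal": "prox",
    "L5_pyramidal": "prox",
    "L2_basket": "soma",
    "L5_basket": "soma",
}
DISTAL_TARGETS = {
    "L2_pyramidal": "dist",
    "L5_pyramidal": "dist",
    "L2_basket": "soma",
}

_DRIVE_RECEPTORS = ("ampa", "nmda")


def _validate_weights(location: str, weights: dict):
    allowed = PROXIMAL_TARGETS if location == "proximal" else DISTAL_TARGETS
    for pop, by_rec in weights.items():
        if pop not in allowed:
            raise ConfigurationError(
                f"{location} drive may not target {pop!r} "
                f"(allowed: {sorted(allowed)})"
            )
        for rec, w in by_rec.items():
            if rec not in _DRIVE_RECEPTORS:
                raise ConfigurationError(
                    f"drives are excitatory only (AMPA/NMDA), got {rec!r}"
                )
            if w < 0:
                raise ConfigurationError(f"negative drive weight for {pop}/{rec}")


@dataclass(frozen=True)
class EvokedDrive:
    """A single Gaussian-jittered synchronous evoked drive.

    ``weights`` maps target population -> {"ampa": uS, "nmda": uS}.
    ``seed_offset`` separates this drive's random stream from other drives
    sharing the same trial seed.
    """

    name: str
    location: str  # "proximal" | "distal"
    mean_time: float  # ms
    sd_time: float  # ms
    weights: dict
    seed_offset: int = 0

    def __post_init__(self):
        if self.location not in ("proximal", "distal"):
            raise ConfigurationError(f"unknown drive location {self.location!r}")
        if self.sd_time < 0:
            raise ConfigurationError("sd_time must be >= 0")
        _validate_weights(self.location, self.weights)

    @property
    def targets(self) -> dict:
        return PROXIMAL_TARGETS if self.location == "proximal" else DISTAL_TARGETS


@dataclass(frozen=True)
class DriveBurst:
    """A burst of ``count`` repetitive drives at a fixed inter-drive interval."""

    name: str
    location: str
    start_mean: float  # ms
    inter_drive_interval: float  # ms
    count: int
    sd_time: float
    weights: dict
    seed_offset: int = 0

    def __post_init__(self):
        if self.count < 1:
            raise ConfigurationError("burst count must be >= 1")
        if self.inter_drive_interval <= 0:
            raise ConfigurationError("inter_drive_interval must be positive")
        if self.location not in ("proximal", "distal"):
            raise ConfigurationError(f"unknown drive location {self.location!r}")
        _validate_weights(self.location, self.weights)


@dataclass(frozen=True)
class AperiodicBurst:
    """Control burst: ``count`` drive times sampled uniformly over a window.

    With ``synchronous=False`` an independent time is drawn for every
    targeted cell (the asynchronous control), otherwise one time per drive
    is shared by all cells.  ``weights`` is either one weight map shared by
    all events or a tuple of ``count`` maps assigned to the sampled times
    in temporal order (matching a periodic burst's per-drive weights).
    """

    name: str
    location: str
    window: tuple  # (start_ms, end_ms)
    count: int
    weights: object  # dict, or tuple of `count` dicts
    synchronous: bool = True
    seed_offset: int = 0

    def __post_init__(self):
        if self.count < 1:
            raise ConfigurationError("burst count must be >= 1")
        lo, hi = self.window
        if hi < lo:
            raise ConfigurationError("empty aperiodic burst window")
        if self.location not in ("proximal", "distal"):
            raise ConfigurationError(f"unknown drive location {self.location!r}")
        for w in self.weight_sequence():
            _validate_weights(self.location, w)

    def weight_sequence(self) -> tuple:
        """Per-event weight maps, in temporal order of the sampled times."""
        if isinstance(self.weights, dict):
            return (self.weights,) * self.count
        if len(self.weights) != self.count:
            raise ConfigurationError(
                "per-event weights must match the burst count"
            )
        return tuple(self.weights)

    @property
    def targets(self) -> dict:
        return PROXIMAL_TARGETS if self.location == "proximal" else DISTAL_TARGETS


def expand_burst(burst: DriveBurst) -> list:
    """Expand a periodic burst into its individual evoked drives."""
    drives = []
    for k in range(burst.count):
        drives.append(
            EvokedDrive(
                name=f"{burst.name}_{k + 1}",
                location=burst.location,
                mean_time=burst.start_mean + k * burst.inter_drive_interval,
                sd_time=burst.sd_time,
                weights=burst.weights,
                seed_offset=burst.seed_offset + k,
            )
        )
    return drives


def flatten_drives(drives) -> list:
    """Expand any DriveBurst entries, leaving other drives untouched."""
    out = []
    for d in drives:
        if isinstance(d, DriveBurst):
            out.extend(expand_burst(d))
        else:
            out.append(d)
    return out


def trial_rng(trial_seed: int, seed_offset: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((trial_seed, seed_offset)))


def sample_drive_times(drives, trial_seed: int) -> dict:
    """Sample one synchronous spike time per drive for one trial.

    Times are Gaussian(mean_time, sd_time); a negative sample is clamped to
    zero with a warning since events before t = 0 are undefined.  The
    result is deterministic per (drive list, trial_seed).
    """
    out = {}
    for d in drives:
        rng = trial_rng(trial_seed, d.seed_offset)
        t = float(rng.normal(d.mean_time, d.sd_time)) if d.sd_time > 0 else d.mean_time
        if t < 0:
            warnings.warn(
                f"drive {d.name!r} sampled a negative time ({t:.2f} ms); "
                "clamping to 0"
            )
            t = 0.0
        out[d.name] = t
    return out


def sample_aperiodic_burst(window, count: int, trial_seed: int,
                           synchronous: bool = True, n_cells: int | None = None,
                           seed_offset: int = 0) -> np.ndarray:
    """Sample drive times i.i.d. uniform over ``window`` for one trial.

    Returns shape (count,) when synchronous, else (count, n_cells) with an
    independent time per targeted cell.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("empty window")
    rng = trial_rng(trial_seed, seed_offset)
    if synchronous:
        return rng.uniform(lo, hi, size=count)
    if n_cells is None:
        raise ValueError("n_cells required for asynchronous sampling")
    return rng.uniform(lo, hi, size=(count, n_cells))


def build_event_schedule(drives, trial_seed: int, population_sizes: dict,
                         duration: float | None = None) -> list:
    """Expand drives into per-cell synaptic events for one trial.

    Returns a list of :class:`~laminet.network.SynapticEvent`.  Evoked
    drives and periodic bursts contribute one synchronous event per target;
    asynchronous aperiodic bursts contribute per-cell event times realized
    as one event per (drive, cell).
    """
    events = []

    def clip(t):
        if duration is not None:
            return min(max(t, 0.0), duration - 1e-9)
        return max(t, 0.0)

    aperiodic = [d for d in drives if isinstance(d, AperiodicBurst)]
    plain = flatten_drives([d for d in drives if not isinstance(d, AperiodicBurst)])
    times = sample_drive_times(plain, trial_seed)
    for d in plain:
        t = clip(times[d.name])
        for pop, comp in d.targets.items():
            for rec, w in d.weights.get(pop, {}).items():
                if w > 0:
                    events.append(SynapticEvent(t, pop, comp, rec, w))

    for d in aperiodic:
        wseq = d.weight_sequence()
        if d.synchronous:
            ts = np.sort(sample_aperiodic_burst(d.window, d.count, trial_seed,
                                                seed_offset=d.seed_offset))
            for t, wmap in zip(ts, wseq):
                t = clip(float(t))
                for pop, comp in d.targets.items():
                    for rec, w in wmap.get(pop, {}).items():
                        if w > 0:
                            events.append(SynapticEvent(t, pop, comp, rec, w))
        else:
            for pop, comp in d.targets.items():
                n = population_sizes[pop]
                ts = np.sort(sample_aperiodic_burst(
                    d.window, d.count, trial_seed, synchronous=False,
                    n_cells=n, seed_offset=d.seed_offset,
                ), axis=0)
                for k in range(d.count):
                    for rec, w in wseq[k].get(pop, {}).items():
                        if w <= 0:
                            continue
                        for cell in range(n):
                            wv = np.zeros(n)
                            wv[cell] = w
                            events.append(
                                SynapticEvent(clip(float(ts[k, cell])), pop,
                                              comp, rec, wv)
                            )
    return events
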