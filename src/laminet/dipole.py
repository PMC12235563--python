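"""Current-dipole readout from pyramidal intracellular axial currents.

The macroscale MEG/EEG source signal is the net intracellular current
flowing parallel to the pyramidal apical dendrites.  Per layer, the dipole
is the sum over that layer's pyramids of axial current times apical segment
length, signed positive for current flowing up the dendrite (deep to
superficial).  The aggregate is the sum of the two layer dipoles; because
the L5 apical length is twice that of L2/3, L5 dominates the aggregate.

Raw dipoles are in arbitrary model units (nA x length unit); a per-
experiment scaling factor maps them to empirical nAm, after which the trace
is smoothed by convolution with a unit-gain Hamming window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .network import StateTrace

__all__ = [
    "DipoleTimeSeries",
    "compute_dipole",
    "scale_and_smooth",
    "hamming_kernel",
    "write_dipole_tsv",
    "read_dipole_tsv",
]


@dataclass(frozen=True)
class DipoleTimeSeries:
    """Aggregate and per-layer current-dipole moment traces.

    ``aggregate == layer2 + layer5`` at every sample (exactly before
    smoothing, to float tolerance after, since all three traces are
    smoothed with the same kernel).  Positive values denote current flow up
    the apical dendrites.
    """

    times: np.ndarray  # ms
    aggregate: np.ndarray  # nAm after scaling
    layer2: np.ndarray
    layer5: np.ndarray
    scaling_factor: float = 1.0
    smoothing_window_ms: float = 0.0
    n_trials: int = 1

    def __post_init__(self):
        n = len(self.times)
        if not (len(self.aggregate) == len(self.layer2) == len(self.layer5) == n):
            raise ValueError("dipole trace lengths disagree")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def compute_dipole(trace: StateTrace, baseline_correct: bool = True) -> DipoleTimeSeries:
    """Unsmoothed, unscaled dipole from a state trace.

    Per-layer dipole: sum over pyramids of (axial current x segment length)
    for both apical segments, positive upward.  The resting membrane state
    carries a small standing apical voltage gradient, hence a constant
    dipole offset; ``baseline_correct`` (default) subtracts each layer's
    value at the first sample so that deflections are measured relative to
    the resting configuration.
    """
    if not trace.axial_currents:
        raise ValueError("state trace carries no axial currents")
    layers = {}
    for pop, key in (("L2_pyramidal", "layer2"), ("L5_pyramidal", "layer5")):
        if pop not in trace.axial_currents:
            raise ValueError(f"missing axial currents for {pop}")
        cur = trace.axial_currents[pop]  # (n_samples, n_cells, 2)
        l1, l2 = trace.apical_lengths[pop]
        layers[key] = (
            cur[:, :, 0].astype(np.float64).sum(axis=1) * l1
            + cur[:, :, 1].astype(np.float64).sum(axis=1) * l2
        )
        if baseline_correct:
            layers[key] = layers[key] - layers[key][0]
    return DipoleTimeSeries(
        times=trace.times.copy(),
        aggregate=layers["layer2"] + layers["layer5"],
        layer2=layers["layer2"],
        layer5=layers["layer5"],
    )


def hamming_kernel(window_ms: float, dt: float) -> np.ndarray:
    """Unit-gain (sum = 1) Hamming kernel of the stated width."""
    n = int(round(window_ms / dt))
    if n <= 1:
        return np.ones(1)
    k = np.hamming(n)
    return k / k.sum()


def _smooth(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    n = len(kernel)
    if n <= 1:
        return x.copy()
    if n > len(x):
        raise ValueError(
            f"smoothing window ({n} samples) wider than trace ({len(x)})"
        )
    # reflection padding preserves baseline level at the edges
    pad_l = n // 2
    pad_r = n - 1 - pad_l
    xp = np.concatenate([x[pad_l:0:-1], x, x[-2:-2 - pad_r:-1]])
    return np.convolve(xp, kernel, mode="valid")


def scale_and_smooth(dipole: DipoleTimeSeries, scaling_factor: float,
                     window_ms: float) -> DipoleTimeSeries:
    """Apply the dipole scaling factor and Hamming smoothing.

    ``window_ms = 0`` disables smoothing.  Layer traces and aggregate are
    smoothed with the same kernel, so additivity is preserved.
    """
    if window_ms < 0:
        raise ValueError("window_ms must be >= 0")
    kernel = hamming_kernel(window_ms, dipole.dt)
    return replace(
        dipole,
        aggregate=scaling_factor * _smooth(dipole.aggregate, kernel),
        layer2=scaling_factor * _smooth(dipole.layer2, kernel),
        layer5=scaling_factor * _smooth(dipole.layer5, kernel),
        scaling_factor=dipole.scaling_factor * scaling_factor,
        smoothing_window_ms=window_ms,
    )


_TSV_COLUMNS = ["time_ms", "agg_nAm", "L2_nAm", "L5_nAm"]


def write_dipole_tsv(dipole: DipoleTimeSeries, path) -> None:
    df = pd.DataFrame(
        {
            "time_ms": dipole.times,
            "agg_nAm": dipole.aggregate,
            "L2_nAm": dipole.layer2,
            "L5_nAm": dipole.layer5,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dipole_tsv(path) -> DipoleTimeSeries:
    """Read a dipole TSV, validating column layout and monotone time."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns)[: len(_TSV_COLUMNS)] != _TSV_COLUMNS:
        raise ValueError(
            f"unexpected dipole TSV columns {list(df.columns)!r}; "
            f"expected {_TSV_COLUMNS}"
        )
    t = df["time_ms"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    return DipoleTimeSeries(
        times=t,
        aggregate=df["agg_nAm"].to_numpy(float),
        layer2=df["L2_nAm"].to_numpy(float),
        layer5=df["L5_nAm"].to_numpy(float),
    )
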