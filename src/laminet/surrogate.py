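"""Surrogate empirical waveforms for fitting and testing.

Real median-nerve (MN) and laser-evoked (LE) source waveforms require
external recordings; these surrogates reproduce the deflection structure
those analyses assume, as a sum of Gaussian bumps plus white noise, so
fitting, optimization, and the full pipeline run with no data download.
They are synthetic stand-ins, not recorded data.

Default MN structure: small upward peak near 20 ms, dominant sharp
downward deflection at 35-40 ms, sustained shallow negativity through
50-100 ms, and a partial rebound toward baseline.  Default LE structure: a
single large, prolonged downward deflection centered near 170 ms (rising
between 100 and 200 ms) followed by a smaller upward rebound before
300 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Deflection",
    "SurrogateSpec",
    "mn_default_spec",
    "le_default_spec",
    "te_default_spec",
    "make_surrogate",
    "normalize_waveform",
    "write_waveform_tsv",
    "read_waveform_tsv",
]


@dataclass(frozen=True)
class Deflection:
    """One Gaussian bump: signed amplitude (nAm) at a latency (ms)."""

    latency_ms: float
    amplitude: float
    width_ms: float  # Gaussian SD

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ValueError("deflection width must be positive")


@dataclass(frozen=True)
class SurrogateSpec:
    kind: str  # "MN" | "LE" | "TE"
    deflections: tuple
    noise_sd: float = 0.0
    duration: float = 170.0
    dt: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")


def mn_default_spec(noise_sd: float = 0.0, seed: int = 0) -> SurrogateSpec:
    """MN surrogate: N1 (small, up, ~20 ms), P1 (dominant, down,
    35-40 ms), prolonged depression, rebound toward baseline."""
    return SurrogateSpec(
        kind="MN",
        deflections=(
            Deflection(20.0, 12.0, 3.5),
            Deflection(37.0, -30.0, 4.5),
            Deflection(75.0, -10.0, 22.0),
            Deflection(135.0, 8.0, 14.0),
        ),
        noise_sd=noise_sd, duration=170.0, seed=seed,
    )


def le_default_spec(noise_sd: float = 0.0, seed: int = 0) -> SurrogateSpec:
    """LE surrogate: one large prolonged downward N1 within 100-200 ms
    (lasting ~150 ms) and a smaller upward rebound before 300 ms."""
    return SurrogateSpec(
        kind="LE",
        deflections=(
            Deflection(170.0, -45.0, 32.0),
            Deflection(265.0, 14.0, 18.0),
        ),
        noise_sd=noise_sd, duration=300.0, seed=seed,
    )


def te_default_spec(noise_sd: float = 0.0, seed: int = 0) -> SurrogateSpec:
    """Tactile-evoked surrogate: like MN but with a small P1."""
    return SurrogateSpec(
        kind="TE",
        deflections=(
            Deflection(25.0, 8.0, 4.0),
            Deflection(45.0, -4.0, 6.0),
            Deflection(70.0, -15.0, 12.0),
            Deflection(100.0, 6.0, 12.0),
        ),
        noise_sd=noise_sd, duration=170.0, seed=seed,
    )


_DEFAULTS = {"mn": mn_default_spec, "le": le_default_spec, "te": te_default_spec}


def default_spec(kind: str, noise_sd: float = 0.0, seed: int = 0) -> SurrogateSpec:
    try:
        return _DEFAULTS[kind.lower()](noise_sd=noise_sd, seed=seed)
    except KeyError:
        raise KeyError(f"unknown surrogate kind {kind!r}; use mn, le, or te")


def make_surrogate(spec: SurrogateSpec):
    """Render a surrogate waveform: (times_ms, dipole_nAm).

    Deterministic per spec.seed; baseline zero outside the deflections.
    """
    times = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    x = np.zeros_like(times)
    for d in spec.deflections:
        x += d.amplitude * np.exp(-0.5 * ((times - d.latency_ms) / d.width_ms) ** 2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        x = x + rng.normal(0.0, spec.noise_sd, size=times.shape)
    return times, x


def normalize_waveform(waveform):
    """Scale a waveform so its most prominent deflection has magnitude 1.

    Scalar division by max |value|; an all-zero trace is an error.
    """
    t, x = waveform
    x = np.asarray(x, float)
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero waveform")
    return np.asarray(t, float), x / peak


def write_waveform_tsv(waveform, path) -> None:
    t, x = waveform
    pd.DataFrame({"time_ms": t, "agg_nAm": x}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_waveform_tsv(path):
    """Read a two-column (time_ms, value) waveform TSV.

    Accepts the full four-column dipole dialect as well, using the
    aggregate column.
    """
    df = pd.read_csv(path, sep="\t")
    if "time_ms" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"not a waveform TSV: columns {list(df.columns)!r}")
    t = df["time_ms"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    value_col = "agg_nAm" if "agg_nAm" in df.columns else df.columns[1]
    return t, df[value_col].to_numpy(float)
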