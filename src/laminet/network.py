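"""Reduced conductance-based laminar column model.

The network is a desk-scale stand-in for a laminated neocortical patch: a
10x10 grid of pyramidal-cell pairs in layers 2/3 and 5 plus 35 fast-spiking
basket interneurons per layer.  Pyramidal cells are three compartments
(soma, proximal apical, distal apical) with Hodgkin-Huxley-style Na/K
spiking conductances at the soma and passive apical compartments; the L5
distal compartment additionally carries a slow depolarizing calcium-like
conductance.  Basket cells are single-compartment fast spikers.  Local
connections follow a fixed population-level table with exponential synaptic
weight fall-off across the grid.

Units: conductances in uS, capacitance in nF, voltage in mV, time in ms,
current in nA (1 nF * 1 mV/ms = 1 uS * 1 mV = 1 nA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "POPULATIONS",
    "PYRAMIDAL",
    "BASKET",
    "RECEPTORS",
    "ReceptorKinetics",
    "CellParams",
    "ConnectionSpec",
    "NetworkConfig",
    "Network",
    "StateTrace",
    "ConfigurationError",
    "IntegrationError",
    "synaptic_weight",
    "build_network",
    "integrate",
    "default_connection_table",
    "default_cell_params",
]

POPULATIONS = ("L2_pyramidal", "L5_pyramidal", "L2_basket", "L5_basket")
PYRAMIDAL = ("L2_pyramidal", "L5_pyramidal")
BASKET = ("L2_basket", "L5_basket")
RECEPTORS = ("ampa", "nmda", "gabaa", "gabab")
EXCITATORY_RECEPTORS = ("ampa", "nmda")
INHIBITORY_RECEPTORS = ("gabaa", "gabab")

#: Compartment on the post-synaptic cell that each local population-level
#: projection contacts.  Inhibition lands on pyramidal somata except for the
#: L2/3 basket -> L5 pyramidal projection, which contacts the distal apical
#: dendrite; excitation between pyramidal populations contacts the apical
#: dendrites and basket cells are contacted at the soma.
LOCAL_TARGET_COMPARTMENT = {
    ("L2_pyramidal", "L2_pyramidal"): "prox",
    ("L2_pyramidal", "L5_pyramidal"): "dist",
    ("L2_pyramidal", "L2_basket"): "soma",
    ("L2_pyramidal", "L5_basket"): "soma",
    ("L5_pyramidal", "L5_pyramidal"): "prox",
    ("L5_pyramidal", "L5_basket"): "soma",
    ("L2_basket", "L2_pyramidal"): "soma",
    ("L2_basket", "L5_pyramidal"): "dist",
    ("L2_basket", "L2_basket"): "soma",
    ("L5_basket", "L5_pyramidal"): "soma",
    ("L5_basket", "L5_basket"): "soma",
}

#: Synaptic receptor sites realized on each (population, compartment).
SYNAPTIC_SITES = (
    ("L2_pyramidal", "soma", "gabaa"),
    ("L2_pyramidal", "soma", "gabab"),
    ("L2_pyramidal", "prox", "ampa"),
    ("L2_pyramidal", "prox", "nmda"),
    ("L2_pyramidal", "dist", "ampa"),
    ("L2_pyramidal", "dist", "nmda"),
    ("L5_pyramidal", "soma", "gabaa"),
    ("L5_pyramidal", "soma", "gabab"),
    ("L5_pyramidal", "prox", "ampa"),
    ("L5_pyramidal", "prox", "nmda"),
    ("L5_pyramidal", "dist", "ampa"),
    ("L5_pyramidal", "dist", "nmda"),
    ("L5_pyramidal", "dist", "gabaa"),
    ("L2_basket", "soma", "ampa"),
    ("L2_basket", "soma", "nmda"),
    ("L2_basket", "soma", "gabaa"),
    ("L5_basket", "soma", "ampa"),
    ("L5_basket", "soma", "nmda"),
    ("L5_basket", "soma", "gabaa"),
)

SPIKE_THRESHOLD_MV = 0.0
MIN_INTERSPIKE_MS = 2.0
DIVERGENCE_BOUND_MV = 150.0


class ConfigurationError(ValueError):
    """Raised for an invalid network or connection configuration."""


class IntegrationError(RuntimeError):
    """Raised when the membrane potential exceeds the divergence guard."""

    def __init__(self, time_ms: float, population: str, cell: int):
        self.time_ms = time_ms
        self.population = population
        self.cell = cell
        super().__init__(
            f"membrane potential diverged (|V| > {DIVERGENCE_BOUND_MV} mV) "
            f"at t = {time_ms:.3f} ms in {population} cell {cell}"
        )


@dataclass(frozen=True)
class ReceptorKinetics:
    """Dual-exponential synapse kinetics for one receptor type.

    ``g_max`` optionally bounds the summed open conductance (receptor-pool
    saturation, g -> g_max * tanh(g / g_max)); None leaves summation
    linear.
    """

    rise_ms: float
    decay_ms: float
    reversal_mv: float
    g_max: float | None = None

    def __post_init__(self):
        if not (self.decay_ms > self.rise_ms > 0):
            raise ConfigurationError(
                f"receptor kinetics require decay > rise > 0, got "
                f"rise={self.rise_ms}, decay={self.decay_ms}"
            )
        if self.g_max is not None and self.g_max <= 0:
            raise ConfigurationError("g_max must be positive when set")

    @property
    def peak_norm(self) -> float:
        """Factor scaling the dual-exponential so its peak equals the weight."""
        tr, td = self.rise_ms, self.decay_ms
        t_peak = tr * td / (td - tr) * math.log(td / tr)
        return 1.0 / (math.exp(-t_peak / td) - math.exp(-t_peak / tr))


@dataclass(frozen=True)
class CellParams:
    """Membrane and synaptic parameters of one cell population.

    Pyramidal cells carry three compartments (soma, prox, dist); baskets
    only the soma.  ``apical_lengths`` are the electrotonic segment lengths
    entering the dipole readout (soma->prox, prox->dist).
    """

    compartments: tuple = ("soma",)
    # capacitance per compartment (nF)
    c_soma: float = 0.05
    c_prox: float = 0.0
    c_dist: float = 0.0
    # passive leak (uS, mV)
    g_leak_soma: float = 0.025
    g_leak_prox: float = 0.0
    g_leak_dist: float = 0.0
    e_leak: float = -65.0
    # somatic spiking conductances (uS)
    g_na: float = 10.0
    g_k: float = 3.0
    e_na: float = 50.0
    e_k: float = -77.0
    # inter-compartment coupling (uS)
    g_couple_soma_prox: float = 0.0
    g_couple_prox_dist: float = 0.0
    # apical segment lengths (model length units)
    apical_lengths: tuple = (0.0, 0.0)
    # slow depolarizing calcium-like conductance at the distal compartment
    g_ca: float = 0.0
    e_ca: float = 80.0
    ca_tau_ms: float = 30.0
    ca_vhalf: float = -35.0
    ca_slope: float = 5.0
    # synaptic kinetics per receptor
    synapses: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in (
            "c_soma", "g_leak_soma", "g_na", "g_k",
            "g_couple_soma_prox", "g_couple_prox_dist", "g_ca",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def default_cell_params() -> dict:
    """Default parameters for the four populations.

    The kinetics pair fast (AMPA/GABA_A) with slow (NMDA/GABA_B) receptors;
    inhibitory-to-inhibitory GABA_A decays with a ~25 ms time constant,
    which sets the interneuron-gamma (ING) period of the basket subnetwork.
    """
    exc = {
        "ampa": ReceptorKinetics(0.5, 5.0, 0.0),
        "nmda": ReceptorKinetics(1.0, 20.0, 0.0),
    }
    pyr_syn = dict(exc)
    pyr_syn["gabaa"] = ReceptorKinetics(0.5, 5.0, -80.0)
    pyr_syn["gabab"] = ReceptorKinetics(1.0, 20.0, -95.0)
    # Basket NMDA is slow (40/60 ms rise/decay): repeated exogenous drive
    # builds a smooth tonic excitation on the interneurons, which the
    # 25 ms basket-basket GABA_A decay then paces into gamma (ING).
    basket_syn = {
        "ampa": ReceptorKinetics(0.5, 5.0, 0.0),
        "nmda": ReceptorKinetics(40.0, 60.0, 0.0),
        "gabaa": ReceptorKinetics(0.5, 25.0, -80.0),
    }

    # The soma and proximal apical compartment sit at nearly the same
    # laminar depth, so the soma->prox dipole segment is short; the long
    # prox->dist apical trunk spans the laminae and carries the dipole.
    l2_pyr = CellParams(
        compartments=("soma", "prox", "dist"),
        c_soma=0.08, c_prox=0.08, c_dist=0.08,
        g_leak_soma=0.015, g_leak_prox=0.006, g_leak_dist=0.006,
        g_na=12.0, g_k=3.0,
        g_couple_soma_prox=0.15, g_couple_prox_dist=0.04,
        apical_lengths=(0.05, 0.9),
        synapses=pyr_syn,
    )
    # L5 pyramids are larger: roughly double membrane area and apical
    # length, so the aggregate dipole is dominated by L5 activity.
    l5_pyr = CellParams(
        compartments=("soma", "prox", "dist"),
        c_soma=0.1, c_prox=0.1, c_dist=0.1,
        g_leak_soma=0.02, g_leak_prox=0.008, g_leak_dist=0.008,
        g_na=15.0, g_k=3.8,
        g_couple_soma_prox=0.2, g_couple_prox_dist=0.05,
        apical_lengths=(0.1, 1.8),
        g_ca=0.002,
        synapses=pyr_syn,
    )
    basket = CellParams(
        compartments=("soma",),
        c_soma=0.03, g_leak_soma=0.008,
        g_na=6.0, g_k=1.8,
        synapses=basket_syn,
    )
    return {
        "L2_pyramidal": l2_pyr,
        "L5_pyramidal": l5_pyr,
        "L2_basket": basket,
        "L5_basket": basket,
    }


@dataclass(frozen=True)
class ConnectionSpec:
    """One population-level local projection (pre -> post, one receptor).

    ``space_constant`` optionally overrides the network-level fall-off for
    this projection; inhibitory projections use a much broader fall-off
    than excitatory ones, making basket output near-uniform across the
    grid (a requirement for tight interneuron-gamma synchrony).
    """

    pre_population: str
    post_population: str
    receptor: str
    base_weight: float  # uS
    delay_ms: float = 1.0
    space_constant: float | None = None

    def __post_init__(self):
        if self.pre_population not in POPULATIONS:
            raise ConfigurationError(
                f"unknown pre-population {self.pre_population!r}"
            )
        if self.post_population not in POPULATIONS:
            raise ConfigurationError(
                f"unknown post-population {self.post_population!r}"
            )
        if self.receptor not in RECEPTORS:
            raise ConfigurationError(f"unknown receptor {self.receptor!r}")
        if self.pre_population in PYRAMIDAL and self.receptor not in EXCITATORY_RECEPTORS:
            raise ConfigurationError(
                f"pyramidal pre-population {self.pre_population} may only "
                f"carry AMPA/NMDA, got {self.receptor}"
            )
        if self.pre_population in BASKET and self.receptor not in INHIBITORY_RECEPTORS:
            raise ConfigurationError(
                f"basket pre-population {self.pre_population} may only "
                f"carry GABA_A/GABA_B, got {self.receptor}"
            )
        if self.base_weight < 0:
            raise ConfigurationError(
                f"negative base_weight for {self.pre_population}->"
                f"{self.post_population} {self.receptor}"
            )
        if (self.pre_population, self.post_population) not in LOCAL_TARGET_COMPARTMENT:
            raise ConfigurationError(
                f"no local pathway {self.pre_population} -> {self.post_population}"
            )


def default_connection_table() -> tuple:
    """Base local connection weights (uS) of the column.

    Pyramidal cells excite through AMPA/NMDA; basket cells inhibit through
    GABA_A/GABA_B.  Within-layer basket-to-basket GABA_A coupling supports
    gamma resonance of the inhibitory subnetwork.  Excitatory projections
    fall off over ~3 grid units; inhibitory output falls off over ~20 grid
    units, i.e. is nearly uniform across the 10x10 patch; basket-to-basket
    coupling is effectively all-to-all, reflecting the dense,
    space-spanning connectivity of cortical PV interneurons.
    """
    exc, inh, bb = 3.0, 20.0, 100.0
    t = [
        ("L2_pyramidal", "L2_pyramidal", "ampa", 2e-4, exc),
        ("L2_pyramidal", "L2_pyramidal", "nmda", 2e-4, exc),
        ("L2_pyramidal", "L5_pyramidal", "ampa", 2e-4, exc),
        ("L2_pyramidal", "L2_basket", "ampa", 5e-4, exc),
        ("L2_pyramidal", "L5_basket", "ampa", 2.5e-4, exc),
        ("L5_pyramidal", "L5_pyramidal", "ampa", 1e-3, exc),
        ("L5_pyramidal", "L5_pyramidal", "nmda", 5e-4, exc),
        ("L5_pyramidal", "L5_basket", "ampa", 5e-4, exc),
        ("L2_basket", "L2_pyramidal", "gabaa", 5e-2, inh),
        ("L2_basket", "L2_pyramidal", "gabab", 5e-2, inh),
        ("L2_basket", "L5_pyramidal", "gabaa", 2e-3, inh),
        ("L2_basket", "L2_basket", "gabaa", 2e-2, bb),
        ("L5_basket", "L5_pyramidal", "gabaa", 2e-2, inh),
        ("L5_basket", "L5_pyramidal", "gabab", 6e-2, inh),
        ("L5_basket", "L5_basket", "gabaa", 2e-2, bb),
    ]
    return tuple(
        ConnectionSpec(pre, post, rec, w, space_constant=sc)
        for (pre, post, rec, w, sc) in t
    )


@dataclass(frozen=True)
class NetworkConfig:
    """Structural configuration of the column."""

    n_pyr_per_layer: int = 100
    n_basket_per_layer: int = 35
    grid_spacing: float = 1.0
    space_constant: float = 3.0
    connection_table: tuple = field(default_factory=default_connection_table)
    cell_params: dict = field(default_factory=default_cell_params)

    def __post_init__(self):
        if self.n_pyr_per_layer <= 0 or self.n_basket_per_layer <= 0:
            raise ConfigurationError("cell counts must be positive")
        if self.space_constant <= 0:
            raise ConfigurationError("space_constant must be positive")
        seen = set()
        for c in self.connection_table:
            key = (c.pre_population, c.post_population, c.receptor)
            if key in seen:
                raise ConfigurationError(f"duplicate connection entry {key}")
            seen.add(key)

    def population_size(self, population: str) -> int:
        if population in PYRAMIDAL:
            return self.n_pyr_per_layer
        if population in BASKET:
            return self.n_basket_per_layer
        raise ConfigurationError(f"unknown population {population!r}")


def synaptic_weight(pre_pos, post_pos, base_weight: float, space_constant: float) -> float:
    """Realized synaptic weight with exponential fall-off over grid distance.

    ``base_weight * exp(-d / space_constant)`` with d the Euclidean distance
    between the two cells' grid positions.
    """
    if space_constant <= 0:
        raise ConfigurationError("space_constant must be positive")
    d = math.hypot(pre_pos[0] - post_pos[0], pre_pos[1] - post_pos[1])
    return base_weight * math.exp(-d / space_constant)


def _grid_positions(n: int, spacing: float, extent: float | None = None) -> np.ndarray:
    """Place n cells on a near-square lattice.

    If ``extent`` is given the lattice is rescaled to cover [0, extent]^2,
    which keeps the sparser basket lattice in register with the pyramidal
    grid.
    """
    side = math.ceil(math.sqrt(n))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    pos = np.stack([xs.ravel(), ys.ravel()], axis=1)[:n].astype(float)
    pos *= spacing
    if extent is not None and side > 1:
        pos *= extent / (spacing * (side - 1))
    return pos


@dataclass(frozen=True)
class RealizedConnection:
    pre_population: str
    post_population: str
    receptor: str
    target_compartment: str
    delay_ms: float
    weights: np.ndarray  # (n_pre, n_post), uS


@dataclass(frozen=True)
class Network:
    """A built column: cell positions plus realized pairwise weights."""

    config: NetworkConfig
    seed: int
    positions: dict  # population -> (n, 2) array
    connections: tuple  # of RealizedConnection

    @property
    def n_cells(self) -> int:
        return sum(p.shape[0] for p in self.positions.values())


def build_network(config: NetworkConfig, seed: int = 0) -> Network:
    """Build the column deterministically from its configuration.

    Every realized synapse's weight is base_weight * exp(-d/space_constant)
    over the pairwise grid distance; autapses are removed.
    """
    spacing = config.grid_spacing
    side = math.ceil(math.sqrt(config.n_pyr_per_layer))
    extent = spacing * max(side - 1, 1)
    positions = {
        "L2_pyramidal": _grid_positions(config.n_pyr_per_layer, spacing),
        "L5_pyramidal": _grid_positions(config.n_pyr_per_layer, spacing),
        "L2_basket": _grid_positions(config.n_basket_per_layer, spacing, extent=extent),
        "L5_basket": _grid_positions(config.n_basket_per_layer, spacing, extent=extent),
    }
    connections = []
    for spec in config.connection_table:
        pre = positions[spec.pre_population]
        post = positions[spec.post_population]
        diff = pre[:, None, :] - post[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        lam = spec.space_constant or config.space_constant
        if lam <= 0:
            raise ConfigurationError("space_constant must be positive")
        w = spec.base_weight * np.exp(-dist / lam)
        if spec.pre_population == spec.post_population:
            np.fill_diagonal(w, 0.0)  # no autapses
        connections.append(
            RealizedConnection(
                spec.pre_population,
                spec.post_population,
                spec.receptor,
                LOCAL_TARGET_COMPARTMENT[(spec.pre_population, spec.post_population)],
                spec.delay_ms,
                w,
            )
        )
    return Network(config=config, seed=seed, positions=positions,
                   connections=tuple(connections))


@dataclass(frozen=True)
class SynapticEvent:
    """One exogenous synaptic event on every cell of a population.

    ``weight`` may be a scalar (same conductance on all cells) or an array
    of per-cell conductances (uS).
    """

    time_ms: float
    population: str
    compartment: str
    receptor: str
    weight: object  # float or (n,) array


@dataclass
class StateTrace:
    """Full state trace of one integration run."""

    times: np.ndarray  # (n_samples,), ms
    dt: float
    spikes: dict  # population -> (cell_idx array, time array)
    axial_currents: dict  # pyramidal population -> (n_samples, n_cells, 2), nA
    apical_lengths: dict  # pyramidal population -> (l1, l2)
    v: dict | None = None  # optional population -> compartment -> (n_samples, n)

    def spike_count(self, population: str | None = None) -> int:
        pops = [population] if population else list(self.spikes)
        return sum(len(self.spikes[p][1]) for p in pops)


# Hodgkin-Huxley rate functions (resting potential near -65 mV).

def _vtrap(x, y):
    # x/(exp(x/y)-1) with the removable singularity handled
    out = np.where(np.abs(x / y) < 1e-6, y * (1 - x / y / 2.0), x / (np.expm1(x / y)))
    return out


def _hh_rates(v):
    am = 0.1 * _vtrap(-(v + 40.0), 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * _vtrap(-(v + 55.0), 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def _nmda_block(v):
    # Sigmoidal magnesium-block voltage dependence (1 mM Mg2+)
    return 1.0 / (1.0 + 0.28 * np.exp(-0.062 * v))


def _resting_state(cp: CellParams) -> dict:
    """Solve the drive-free steady state of one cell (all gates at inf)."""
    from scipy.optimize import fsolve

    multi = "prox" in cp.compartments

    def steady(vv):
        vs = vv[0]
        am, bm, ah, bh, an, bn = _hh_rates(np.asarray([vs]))
        m = (am / (am + bm))[0]
        h = (ah / (ah + bh))[0]
        nn = (an / (an + bn))[0]
        i_s = (
            cp.g_leak_soma * (vs - cp.e_leak)
            + cp.g_na * m ** 3 * h * (vs - cp.e_na)
            + cp.g_k * nn ** 4 * (vs - cp.e_k)
        )
        if not multi:
            return [i_s]
        vp, vd = vv[1], vv[2]
        i_s += cp.g_couple_soma_prox * (vs - vp)
        i_p = (
            cp.g_leak_prox * (vp - cp.e_leak)
            + cp.g_couple_soma_prox * (vp - vs)
            + cp.g_couple_prox_dist * (vp - vd)
        )
        i_d = (
            cp.g_leak_dist * (vd - cp.e_leak)
            + cp.g_couple_prox_dist * (vd - vp)
        )
        if cp.g_ca > 0:
            s_inf = 1.0 / (1.0 + math.exp(-(vd - cp.ca_vhalf) / cp.ca_slope))
            i_d += cp.g_ca * s_inf * (vd - cp.e_ca)
        return [i_s, i_p, i_d]

    x0 = [cp.e_leak] * (3 if multi else 1)
    sol = fsolve(steady, x0, full_output=False)
    if multi:
        return {"soma": sol[0], "prox": sol[1], "dist": sol[2]}
    return {"soma": sol[0]}


class _SiteState:
    """Dual-exponential conductance state for one (pop, comp, receptor)."""

    __slots__ = ("a", "b", "decay_f", "rise_f", "norm", "reversal",
                 "is_nmda", "g_max")

    def __init__(self, n, kin: ReceptorKinetics, dt, is_nmda):
        self.a = np.zeros(n)
        self.b = np.zeros(n)
        self.decay_f = math.exp(-dt / kin.decay_ms)
        self.rise_f = math.exp(-dt / kin.rise_ms)
        self.norm = kin.peak_norm
        self.reversal = kin.reversal_mv
        self.is_nmda = is_nmda
        self.g_max = kin.g_max

    def step(self):
        self.a *= self.decay_f
        self.b *= self.rise_f

    def add(self, w):
        self.a += w * self.norm
        self.b += w * self.norm

    def conductance(self, v):
        g = self.a - self.b
        if self.g_max is not None:
            g = self.g_max * np.tanh(g / self.g_max)
        if self.is_nmda:
            g = g * _nmda_block(v)
        return g

    def current(self, v):
        return self.conductance(v) * (v - self.reversal)


def integrate(
    network: Network,
    drive_events,
    duration: float,
    dt: float = 0.025,
    seed: int = 0,
    record_v: bool = False,
) -> StateTrace:
    """Integrate the column under a schedule of exogenous synaptic events.

    Fixed-step integration: exponential Euler for channel gating, forward
    Euler for the membrane equations.  The run is bitwise reproducible for
    identical (network, events, seed) and aborts with
    :class:`IntegrationError` if any membrane potential exceeds the
    divergence guard.

    Parameters
    ----------
    drive_events : iterable of SynapticEvent
        Exogenous events; all times must lie in [0, duration).
    duration, dt : float
        Simulation window and step, ms.
    record_v : bool
        If True, record every compartment's membrane potential.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    events = sorted(drive_events, key=lambda e: e.time_ms)
    for ev in events:
        if not (0 <= ev.time_ms < duration):
            raise ValueError(f"event time {ev.time_ms} outside [0, {duration})")
        if (ev.population, ev.compartment, ev.receptor) not in SYNAPTIC_SITES:
            raise ConfigurationError(
                f"no synaptic site ({ev.population}, {ev.compartment}, "
                f"{ev.receptor})"
            )

    cfg = network.config
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt

    params = {p: cfg.cell_params[p] for p in POPULATIONS}
    sizes = {p: cfg.population_size(p) for p in POPULATIONS}

    # --- state arrays, initialized at the resting fixed point ---
    v = {}
    gates = {}
    for p in POPULATIONS:
        cp = params[p]
        n = sizes[p]
        rest = _resting_state(cp)
        v[p] = {c: np.full(n, rest[c]) for c in cp.compartments}
        vs = v[p]["soma"]
        am, bm, ah, bh, an, bn = _hh_rates(vs)
        gates[p] = {
            "m": am / (am + bm),
            "h": ah / (ah + bh),
            "n": an / (an + bn),
        }
        if cp.g_ca > 0:
            gates[p]["s"] = 1.0 / (
                1.0 + np.exp(-(v[p]["dist"] - cp.ca_vhalf) / cp.ca_slope)
            )

    sites = {}
    sites_by_loc = {(p, c): [] for p in POPULATIONS for c in params[p].compartments}
    for (p, comp, rec) in SYNAPTIC_SITES:
        kin = params[p].synapses[rec]
        s = _SiteState(sizes[p], kin, dt, rec == "nmda")
        sites[(p, comp, rec)] = s
        sites_by_loc[(p, comp)].append(s)

    # --- pending-conductance ring buffers (delayed spike propagation) ---
    max_delay = max([c.delay_ms for c in network.connections], default=0.0)
    n_slots = int(round(max_delay / dt)) + 1
    rings = {k: np.zeros((n_slots, sizes[k[0]])) for k in sites}
    conns_by_pre = {p: [] for p in POPULATIONS}
    for c in network.connections:
        conns_by_pre[c.pre_population].append(
            (c, int(round(c.delay_ms / dt)) % n_slots,
             (c.post_population, c.target_compartment, c.receptor))
        )

    # exogenous events grouped by step (applied with zero extra delay)
    events_by_step = {}
    for ev in events:
        k = int(round(ev.time_ms / dt))
        events_by_step.setdefault(k, []).append(ev)

    # --- recording ---
    axial = {
        p: np.zeros((n_steps + 1, sizes[p], 2), dtype=np.float32)
        for p in PYRAMIDAL
    }
    v_rec = None
    if record_v:
        v_rec = {
            p: {c: np.zeros((n_steps + 1, sizes[p])) for c in params[p].compartments}
            for p in POPULATIONS
        }
    spike_cells = {p: [] for p in POPULATIONS}
    spike_times = {p: [] for p in POPULATIONS}
    last_spike = {p: np.full(sizes[p], -1e9) for p in POPULATIONS}
    prev_vs = {p: v[p]["soma"].copy() for p in POPULATIONS}

    def record(k):
        for p in PYRAMIDAL:
            cp = params[p]
            axial[p][k, :, 0] = cp.g_couple_soma_prox * (v[p]["soma"] - v[p]["prox"])
            axial[p][k, :, 1] = cp.g_couple_prox_dist * (v[p]["prox"] - v[p]["dist"])
        if v_rec is not None:
            for p in POPULATIONS:
                for c in params[p].compartments:
                    v_rec[p][c][k] = v[p][c]

    record(0)
    check_every = max(1, int(round(1.0 / dt)))

    for k in range(n_steps):
        slot = k % n_slots
        # deliver exogenous events scheduled for this step
        for ev in events_by_step.get(k, ()):
            rings[(ev.population, ev.compartment, ev.receptor)][slot] += ev.weight
        # transfer matured pending conductances into the synapse states
        for key, ring in rings.items():
            pend = ring[slot]
            if pend.any():
                sites[key].add(pend)
                pend[:] = 0.0
        for s in sites.values():
            s.step()

        # membrane update
        for p in POPULATIONS:
            cp = params[p]
            vs = v[p]["soma"]
            g = gates[p]
            am, bm, ah, bh, an, bn = _hh_rates(vs)
            for key, a, b in (("m", am, bm), ("h", ah, bh), ("n", an, bn)):
                tau = 1.0 / (a + b)
                inf = a * tau
                g[key] += (inf - g[key]) * (1.0 - np.exp(-dt / tau))
            i_na = cp.g_na * g["m"] ** 3 * g["h"] * (vs - cp.e_na)
            i_k = cp.g_k * g["n"] ** 4 * (vs - cp.e_k)
            i_soma = cp.g_leak_soma * (vs - cp.e_leak) + i_na + i_k
            for s in sites_by_loc[(p, "soma")]:
                i_soma = i_soma + s.current(vs)
            if "prox" in cp.compartments:
                vp, vd = v[p]["prox"], v[p]["dist"]
                i_soma = i_soma + cp.g_couple_soma_prox * (vs - vp)
                i_prox = (
                    cp.g_leak_prox * (vp - cp.e_leak)
                    + cp.g_couple_soma_prox * (vp - vs)
                    + cp.g_couple_prox_dist * (vp - vd)
                )
                i_dist = (
                    cp.g_leak_dist * (vd - cp.e_leak)
                    + cp.g_couple_prox_dist * (vd - vp)
                )
                for s in sites_by_loc[(p, "prox")]:
                    i_prox = i_prox + s.current(vp)
                for s in sites_by_loc[(p, "dist")]:
                    i_dist = i_dist + s.current(vd)
                if cp.g_ca > 0:
                    s_gate = gates[p]["s"]
                    s_inf = 1.0 / (1.0 + np.exp(-(vd - cp.ca_vhalf) / cp.ca_slope))
                    s_gate += (s_inf - s_gate) * (1.0 - math.exp(-dt / cp.ca_tau_ms))
                    i_dist = i_dist + cp.g_ca * s_gate * (vd - cp.e_ca)
                v[p]["prox"] = vp - dt / cp.c_prox * i_prox
                v[p]["dist"] = vd - dt / cp.c_dist * i_dist
            v[p]["soma"] = vs - dt / cp.c_soma * i_soma

        t_now = (k + 1) * dt
        # spike detection at the soma: upward threshold crossing
        for p in POPULATIONS:
            vs = v[p]["soma"]
            crossed = (prev_vs[p] < SPIKE_THRESHOLD_MV) & (vs >= SPIKE_THRESHOLD_MV)
            crossed &= (t_now - last_spike[p]) >= MIN_INTERSPIKE_MS
            if crossed.any():
                idx = np.nonzero(crossed)[0]
                last_spike[p][idx] = t_now
                spike_cells[p].extend(idx.tolist())
                spike_times[p].extend([t_now] * len(idx))
                for conn, delay_steps, site_key in conns_by_pre[p]:
                    w = conn.weights[idx].sum(axis=0)
                    rings[site_key][(k + 1 + delay_steps) % n_slots] += w
            prev_vs[p] = vs.copy()

        record(k + 1)

        if (k + 1) % check_every == 0:
            for p in POPULATIONS:
                for c in params[p].compartments:
                    # also trips on NaN/inf from numerical blow-up
                    bad = ~(np.abs(v[p][c]) <= DIVERGENCE_BOUND_MV)
                    if bad.any():
                        raise IntegrationError(t_now, p, int(np.nonzero(bad)[0][0]))

    spikes = {
        p: (np.asarray(spike_cells[p], dtype=int), np.asarray(spike_times[p]))
        for p in POPULATIONS
    }
    lengths = {p: tuple(params[p].apical_lengths) for p in PYRAMIDAL}
    return StateTrace(
        times=times, dt=dt, spikes=spikes, axial_currents=axial,
        apical_lengths=lengths, v=v_rec,
    )
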