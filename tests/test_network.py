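import math

import numpy as np
import pytest

from laminet.drives import EvokedDrive, build_event_schedule
from laminet.network import (
    POPULATIONS, PYRAMIDAL, CellParams, ConfigurationError, ConnectionSpec,
    IntegrationError, NetworkConfig, ReceptorKinetics, SynapticEvent,
    build_network, default_cell_params, integrate, synaptic_weight,
)


def test_default_network_has_published_cell_counts():
    """The canonical column: 10x10 pyramid pairs plus 35 baskets per layer."""
    net = build_network(NetworkConfig(), seed=0)
    assert net.positions["L2_pyramidal"].shape[0] == 100
    assert net.positions["L5_pyramidal"].shape[0] == 100
    assert net.positions["L2_basket"].shape[0] == 35
    assert net.positions["L5_basket"].shape[0] == 35
    assert net.n_cells == 270


@pytest.mark.parametrize(
    "d, expected_factor",
    [(0.0, 1.0), (1.0, math.exp(-1.0)), (300.0, math.exp(-100.0))],
)
def test_synaptic_weight_exponential_falloff(d, expected_factor):
    """w = base * exp(-d/lambda): identity at d=0, e-fold at d=lambda,
    vanishing at large distance (base weight from the L2/3 basket ->
    L2/3 pyramidal GABA_A entry)."""
    w = synaptic_weight((0.0, 0.0), (d, 0.0), 5e-2, 3.0)
    assert w == pytest.approx(5e-2 * math.exp(-d / 3.0), rel=1e-12)
    w1 = synaptic_weight((0.0, 0.0), (3.0, 0.0), 5e-2, 3.0)
    assert w1 == pytest.approx(5e-2 * math.exp(-1.0), rel=1e-12)


def test_synaptic_weight_rejects_nonpositive_space_constant():
    with pytest.raises(ConfigurationError):
        synaptic_weight((0, 0), (1, 0), 1e-3, 0.0)


def test_realized_weights_match_bruteforce_enumeration():
    """On a 3x3 grid with unit space constant, every realized pairwise
    weight equals the brute-force base*exp(-Euclidean distance)."""
    cfg = NetworkConfig(
        n_pyr_per_layer=9, n_basket_per_layer=4,
        connection_table=(
            ConnectionSpec("L2_pyramidal", "L2_pyramidal", "ampa", 2e-4,
                           space_constant=1.0),
        ),
    )
    net = build_network(cfg, seed=0)
    conn = net.connections[0]
    pos = net.positions["L2_pyramidal"]
    for i in range(9):
        for j in range(9):
            if i == j:
                expected = 0.0  # no autapses
            else:
                d = math.hypot(*(pos[i] - pos[j]))
                expected = 2e-4 * math.exp(-d / 1.0)
            assert conn.weights[i, j] == pytest.approx(expected, rel=1e-12)


def test_connection_table_rejects_wrong_transmitter():
    """Pyramidal cells are excitatory-only, baskets inhibitory-only."""
    with pytest.raises(ConfigurationError):
        ConnectionSpec("L2_pyramidal", "L2_basket", "gabaa", 1e-3)
    with pytest.raises(ConfigurationError):
        ConnectionSpec("L2_basket", "L2_pyramidal", "ampa", 1e-3)
    with pytest.raises(ConfigurationError):
        ConnectionSpec("L2_pyramidal", "L2_pyramidal", "ampa", -1e-3)
    with pytest.raises(ConfigurationError):
        ConnectionSpec("L6_pyramidal", "L2_pyramidal", "ampa", 1e-3)


def test_duplicate_connection_entries_rejected():
    dup = (
        ConnectionSpec("L2_pyramidal", "L2_pyramidal", "ampa", 1e-4),
        ConnectionSpec("L2_pyramidal", "L2_pyramidal", "ampa", 2e-4),
    )
    with pytest.raises(ConfigurationError):
        NetworkConfig(connection_table=dup)


def test_quiescence_without_drive(small_network):
    """No events from rest: potentials stay at rest, zero spikes."""
    trace = integrate(small_network, [], duration=50.0, record_v=True)
    assert trace.spike_count() == 0
    for pop in POPULATIONS:
        for comp, v in trace.v[pop].items():
            assert np.abs(v - v[0, 0]).max() < 0.05


def test_integration_is_bitwise_deterministic(small_network, small_config):
    sizes = {p: small_config.population_size(p) for p in POPULATIONS}
    drv = EvokedDrive(
        "p", "proximal", 10.0, 2.0,
        {"L2_pyramidal": {"ampa": 4e-2}, "L5_pyramidal": {"ampa": 4e-2},
         "L2_basket": {"ampa": 3e-3}, "L5_basket": {"ampa": 3e-3}},
    )
    events = build_event_schedule([drv], 7, sizes, duration=40.0)
    t1 = integrate(small_network, events, duration=40.0, seed=7)
    t2 = integrate(small_network, events, duration=40.0, seed=7)
    for pop in PYRAMIDAL:
        assert np.array_equal(t1.axial_currents[pop], t2.axial_currents[pop])
    for pop in POPULATIONS:
        assert np.array_equal(t1.spikes[pop][1], t2.spikes[pop][1])


def test_strong_proximal_drive_spikes_both_pyramidal_layers(small_network,
                                                            small_config):
    """Synchronous strong proximal input elicits somatic spikes in L2/3
    and L5 pyramids."""
    sizes = {p: small_config.population_size(p) for p in POPULATIONS}
    drv = EvokedDrive(
        "p", "proximal", 10.0, 0.0,
        {"L2_pyramidal": {"ampa": 5e-2, "nmda": 5e-3},
         "L5_pyramidal": {"ampa": 6e-2, "nmda": 5e-3},
         "L2_basket": {"ampa": 2.5e-3}, "L5_basket": {"ampa": 2.5e-3}},
    )
    events = build_event_schedule([drv], 0, sizes, duration=40.0)
    trace = integrate(small_network, events, duration=40.0)
    assert trace.spike_count("L2_pyramidal") > 0
    assert trace.spike_count("L5_pyramidal") > 0


def test_subthreshold_response_scales_linearly_with_conductance(
        uncoupled_network):
    """Peak membrane deflection of a single small synaptic event scales
    linearly with conductance within 5% (two-point ratio)."""
    def peak_deflection(g):
        ev = [SynapticEvent(5.0, "L2_pyramidal", "prox", "ampa", g)]
        trace = integrate(uncoupled_network, ev, duration=30.0, record_v=True)
        v = trace.v["L2_pyramidal"]["prox"][:, 0]
        return np.max(np.abs(v - v[0]))

    d1 = peak_deflection(1e-4)
    d2 = peak_deflection(2e-4)
    assert d2 / d1 == pytest.approx(2.0, rel=0.05)


def test_synaptic_conductance_matches_dual_exponential_oracle():
    """The discretized synapse state reproduces the closed-form
    normalized dual exponential at every step."""
    from laminet.network import _SiteState

    kin = ReceptorKinetics(0.5, 5.0, 0.0)
    dt = 0.025
    site = _SiteState(1, kin, dt, is_nmda=False)
    site.add(np.array([1e-3]))
    norm = kin.peak_norm
    sim = []
    for k in range(1, 801):
        site.step()
        sim.append(site.conductance(np.array([-65.0]))[0])
    t = np.arange(1, 801) * dt
    analytic = 1e-3 * norm * (np.exp(-t / 5.0) - np.exp(-t / 0.5))
    assert np.allclose(sim, analytic, rtol=1e-9, atol=1e-15)
    t_peak = 0.5 * 5.0 / 4.5 * math.log(10.0)
    assert max(sim) == pytest.approx(1e-3, rel=1e-3)
    assert abs(t[int(np.argmax(sim))] - t_peak) <= dt


def test_zero_weight_table_behaves_as_uncoupled(small_config,
                                                uncoupled_network):
    """All base weights zero: drive responses equal the uncoupled
    single-cell response."""
    zero_table = tuple(
        ConnectionSpec(c.pre_population, c.post_population, c.receptor, 0.0,
                       c.delay_ms, c.space_constant)
        for c in NetworkConfig().connection_table
    )
    cfg = NetworkConfig(n_pyr_per_layer=16, n_basket_per_layer=6,
                        connection_table=zero_table)
    net = build_network(cfg, seed=0)
    ev = [SynapticEvent(5.0, "L5_pyramidal", "prox", "ampa", 5e-3)]
    t_zero = integrate(net, ev, duration=30.0, record_v=True)
    t_unc = integrate(uncoupled_network, ev, duration=30.0, record_v=True)
    v0 = t_zero.v["L5_pyramidal"]["soma"]
    v1 = t_unc.v["L5_pyramidal"]["soma"]
    assert np.allclose(v0, v1, atol=1e-12)


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_divergence_guard_reports_time_and_cell(uncoupled_network):
    """A pathological event drives |V| past the bound -> IntegrationError
    naming the offending time and cell."""
    ev = [SynapticEvent(2.0, "L2_basket", "soma", "ampa", 1e3)]
    with pytest.raises(IntegrationError) as err:
        integrate(uncoupled_network, ev, duration=20.0)
    assert err.value.time_ms > 0
    assert err.value.population == "L2_basket"


def test_event_validation():
    net = build_network(NetworkConfig(n_pyr_per_layer=4, n_basket_per_layer=2))
    with pytest.raises(ValueError):
        integrate(net, [SynapticEvent(50.0, "L2_pyramidal", "prox", "ampa",
                                      1e-3)], duration=40.0)
    with pytest.raises(ConfigurationError):
        integrate(net, [SynapticEvent(5.0, "L5_basket", "soma", "gabab",
                                      1e-3)], duration=40.0)


def test_basket_gabaa_decay_is_gamma_period():
    """Inhibitory-to-inhibitory GABA_A decays with ~25 ms time constant."""
    params = default_cell_params()
    assert params["L2_basket"].synapses["gabaa"].decay_ms == pytest.approx(25.0)
    for pop, cp in params.items():
        for kin in cp.synapses.values():
            assert kin.decay_ms > kin.rise_ms > 0
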