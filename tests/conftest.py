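import dataclasses

import numpy as np
import pytest

from laminet.experiments import get_experiment, run_experiment
from laminet.network import NetworkConfig, build_network


@pytest.fixture(scope="session")
def small_config():
    """A reduced column (4x4 pyramids, 6 baskets/layer) for fast unit tests."""
    return NetworkConfig(n_pyr_per_layer=16, n_basket_per_layer=6)


@pytest.fixture(scope="session")
def small_network(small_config):
    return build_network(small_config, seed=0)


@pytest.fixture(scope="session")
def uncoupled_config():
    """Same size as small_config but with no local connections."""
    return NetworkConfig(n_pyr_per_layer=16, n_basket_per_layer=6,
                         connection_table=())


@pytest.fixture(scope="session")
def uncoupled_network(uncoupled_config):
    return build_network(uncoupled_config, seed=0)


# --- session-scoped ensembles shared by the acceptance tests -------------

@pytest.fixture(scope="session")
def mn_ensemble():
    """mn_post_ops at 25 trials (shared across tests)."""
    return run_experiment(get_experiment("mn_post_ops"), n_trials=25)


@pytest.fixture(scope="session")
def le_ensemble():
    """le_post_ops at 25 trials (shared across tests)."""
    return run_experiment(get_experiment("le_post_ops"), n_trials=25)


@pytest.fixture(scope="session")
def mn_ablation_pair():
    """mn_post_ops and its no-early-distal control at matched trials."""
    full = run_experiment(get_experiment("mn_post_ops"), n_trials=10)
    ablated = run_experiment(get_experiment("mn_no_early_distal"), n_trials=10)
    return full, ablated


@pytest.fixture(scope="session")
def le_burst_pair():
    """Periodic distal burst and its aperiodic control at matched trials."""
    periodic = run_experiment(get_experiment("le_distal_burst"), n_trials=10)
    aperiodic = run_experiment(get_experiment("le_aperiodic_burst"), n_trials=10)
    return periodic, aperiodic


def window_extremum(dipole, lo, hi, which="min"):
    """Value and time of the extremum of the aggregate within [lo, hi] ms."""
    t = dipole.times
    a = dipole.aggregate
    mask = (t >= lo) & (t <= hi)
    seg = a[mask]
    idx = np.argmin(seg) if which == "min" else np.argmax(seg)
    return seg[idx], t[mask][idx]
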