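import numpy as np
import pytest

from laminet.drives import (
    AperiodicBurst, DISTAL_TARGETS, DriveBurst, EvokedDrive,
    PROXIMAL_TARGETS, build_event_schedule, expand_burst,
    sample_aperiodic_burst, sample_drive_times,
)
from laminet.network import ConfigurationError

W_PROX = {"L2_pyramidal": {"ampa": 1e-3}, "L5_basket": {"ampa": 1e-3}}
W_DIST = {"L2_pyramidal": {"ampa": 1e-3}, "L2_basket": {"ampa": 1e-3}}
SIZES = {"L2_pyramidal": 4, "L5_pyramidal": 4, "L2_basket": 2, "L5_basket": 2}


def test_zero_jitter_returns_mean_exactly():
    d = EvokedDrive("a", "proximal", 20.8, 0.0, W_PROX)
    assert sample_drive_times([d], trial_seed=123)["a"] == 20.8


def test_gaussian_sampling_recovers_published_mean_and_sd():
    """Monte-Carlo over 10,000 trials recovers the post-optimization MN
    proximal drive statistics (20.8 +/- 4.1 ms) within standard error."""
    d = EvokedDrive("evprox_1", "proximal", 20.8, 4.1, W_PROX)
    samples = np.array(
        [sample_drive_times([d], trial_seed=k)["evprox_1"]
         for k in range(10_000)]
    )
    se_mean = 4.1 / np.sqrt(len(samples))
    assert samples.mean() == pytest.approx(20.8, abs=4 * se_mean)
    se_sd = 4.1 / np.sqrt(2 * (len(samples) - 1))
    assert samples.std(ddof=1) == pytest.approx(4.1, abs=4 * se_sd)


def test_distinct_seed_offsets_decorrelate_drives():
    d1 = EvokedDrive("a", "proximal", 50.0, 5.0, W_PROX, seed_offset=0)
    d2 = EvokedDrive("b", "proximal", 50.0, 5.0, W_PROX, seed_offset=1)
    t = sample_drive_times([d1, d2], trial_seed=9)
    assert t["a"] != t["b"]
    assert sample_drive_times([d1, d2], trial_seed=9) == t  # reproducible


def test_trials_with_distinct_seeds_are_uncorrelated():
    """Lag-1 autocorrelation across 10,000 per-trial samples is at noise
    level."""
    d = EvokedDrive("a", "distal", 100.0, 8.0, W_DIST)
    x = np.array([sample_drive_times([d], trial_seed=k)["a"]
                  for k in range(10_000)])
    x = x - x.mean()
    r1 = np.dot(x[:-1], x[1:]) / np.dot(x, x)
    assert abs(r1) < 4 / np.sqrt(len(x))


def test_expand_burst_published_le_means():
    """(start 120, IDI 25, count 4) -> means 120, 145, 170, 195 ms."""
    burst = DriveBurst("evdist", "distal", 120.0, 25.0, 4, 8.0, W_DIST)
    drives = expand_burst(burst)
    assert [d.mean_time for d in drives] == [120.0, 145.0, 170.0, 195.0]
    assert all(d.sd_time == 8.0 for d in drives)
    assert all(d.weights == W_DIST for d in drives)


@pytest.mark.parametrize(
    "start, idi, count, expected",
    [
        (120.0, 12.5, 7, [120.0 + 12.5 * k for k in range(7)]),
        (42.0, 10.0, 1, [42.0]),
    ],
)
def test_expand_burst_arithmetic_progression(start, idi, count, expected):
    burst = DriveBurst("b", "distal", start, idi, count, 2.0, W_DIST)
    assert [d.mean_time for d in expand_burst(burst)] == expected


def test_aperiodic_samples_stay_in_window():
    ts = sample_aperiodic_burst((120.0, 200.0), 4, trial_seed=1)
    assert ts.shape == (4,)
    assert np.all((ts >= 120.0) & (ts <= 200.0))
    assert np.all(sample_aperiodic_burst((150.0, 150.0), 5, 2) == 150.0)


def test_aperiodic_mean_approaches_window_midpoint():
    ts = np.concatenate(
        [sample_aperiodic_burst((120.0, 200.0), 4, k) for k in range(2000)]
    )
    se = (80.0 / np.sqrt(12.0)) / np.sqrt(len(ts))
    assert ts.mean() == pytest.approx(160.0, abs=4 * se)


def test_pathway_exclusivity_on_expanded_schedule():
    """Distal drives never contact L5 baskets or proximal compartments;
    proximal drives never contact distal compartments."""
    dist = EvokedDrive("d", "distal", 50.0, 2.0, {
        "L2_pyramidal": {"ampa": 1e-3}, "L5_pyramidal": {"ampa": 1e-3},
        "L2_basket": {"ampa": 1e-3},
    })
    prox = EvokedDrive("p", "proximal", 30.0, 2.0, {
        "L2_pyramidal": {"ampa": 1e-3}, "L5_pyramidal": {"ampa": 1e-3},
        "L2_basket": {"ampa": 1e-3}, "L5_basket": {"ampa": 1e-3},
    })
    events = build_event_schedule([dist, prox], 0, SIZES, duration=100.0)
    for ev in events:
        assert ev.receptor in ("ampa", "nmda")  # excitation only
    for ev in events:
        if ev.population == "L5_basket":
            # only the proximal drive may reach L5 baskets
            assert ev.time_ms == pytest.approx(
                sample_drive_times([prox], 0)["p"])
        if ev.compartment == "dist":
            assert ev.time_ms == pytest.approx(
                sample_drive_times([dist], 0)["d"])


def test_drive_target_validation():
    with pytest.raises(ConfigurationError):
        EvokedDrive("bad", "distal", 50.0, 1.0,
                    {"L5_basket": {"ampa": 1e-3}})
    with pytest.raises(ConfigurationError):
        EvokedDrive("bad", "proximal", 50.0, 1.0,
                    {"L2_pyramidal": {"gabaa": 1e-3}})
    with pytest.raises(ConfigurationError):
        EvokedDrive("bad", "proximal", 50.0, -1.0, W_PROX)
    with pytest.raises(ConfigurationError):
        DriveBurst("bad", "distal", 100.0, 0.0, 4, 8.0, W_DIST)


def test_negative_sampled_time_clamps_to_zero_with_warning():
    d = EvokedDrive("early", "proximal", 0.5, 50.0, W_PROX, seed_offset=0)
    hit = False
    for seed in range(200):
        import warnings

        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            t = sample_drive_times([d], trial_seed=seed)["early"]
        assert t >= 0.0
        if rec:
            hit = True
    assert hit, "no negative sample encountered in 200 trials"


def test_asynchronous_burst_draws_per_cell_times():
    ts = sample_aperiodic_burst((120.0, 200.0), 4, 3, synchronous=False,
                                n_cells=10)
    assert ts.shape == (4, 10)
    assert len(np.unique(ts)) > 30  # per-cell independence

    burst = AperiodicBurst("async", "distal", (120.0, 200.0), 2, W_DIST,
                           synchronous=False)
    events = build_event_schedule([burst], 0, SIZES, duration=300.0)
    # one event per (drive, cell) per targeted (pop, receptor)
    per_cell = [e for e in events if e.population == "L2_pyramidal"]
    assert len(per_cell) == 2 * SIZES["L2_pyramidal"]
    assert all(isinstance(e.weight, np.ndarray) for e in per_cell)
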