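import numpy as np
import pytest

from laminet.tfr import (
    MorletParams, TimeFrequencyMap, band_peak, morlet_tfr, morlet_wavelet,
    trial_mean_tfr,
)


def _tone(freq_hz, duration_ms=1000.0, dt=1.0, phase=0.0, amp=1.0):
    t = np.arange(0.0, duration_ms, dt)
    return t, amp * np.sin(2 * np.pi * freq_hz * t / 1000.0 + phase)


def test_envelope_sd_is_one_over_six_pi_seconds():
    """Under m = f/3 cycles, sigma = m/(2 pi f) = 1/(6 pi) s at every
    frequency."""
    params = MorletParams()
    expected = 1.0 / (6.0 * np.pi)
    for f in (3.0, 10.0, 40.0, 100.0):
        assert params.sigma_s(f) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.05305, abs=5e-5)


def test_wavelet_normalization_and_carrier():
    params = MorletParams()
    w = morlet_wavelet(40.0, 1.0, params)
    # A = (1/2 sum |w|^2)^(-1/2) makes the half-energy sum equal one
    assert 0.5 * np.sum(np.abs(w) ** 2) == pytest.approx(1.0, rel=1e-12)
    # the carrier oscillates at f: the analytic signal's phase advances
    # by 2 pi f dt per sample at the envelope center
    center = len(w) // 2
    dphi = np.angle(w[center + 1] / w[center])
    assert dphi == pytest.approx(2 * np.pi * 40.0 * 1e-3, rel=1e-6)


def test_pure_tone_power_localizes_at_tone_frequency():
    t, x = _tone(40.0)
    tfr = morlet_tfr(t, x)
    mean_power = tfr.power.mean(axis=1)
    assert tfr.freqs[np.argmax(mean_power)] == 40.0


def test_zero_trace_gives_zero_power():
    t = np.arange(0.0, 500.0, 1.0)
    tfr = morlet_tfr(t, np.zeros_like(t))
    assert np.all(tfr.power == 0.0)


def test_frequency_at_or_below_zero_rejected():
    with pytest.raises(ValueError):
        MorletParams(freqs=np.array([0.0, 10.0]))
    with pytest.raises(ValueError):
        morlet_wavelet(-5.0, 1.0, MorletParams())


def test_single_trial_mean_equals_single_tfr():
    t, x = _tone(20.0, duration_ms=600.0)
    single = morlet_tfr(t, x)
    mean = trial_mean_tfr([(t, x)])
    assert mean.n_trials == 1
    assert np.allclose(mean.power, single.power, rtol=1e-12)


def test_power_domain_average_retains_phase_cancelled_activity():
    """Two 40 Hz trials in antiphase cancel in the mean waveform but
    their trial-mean TFR keeps the 40 Hz ridge (non-phase-locked
    activity survives spectral-domain averaging)."""
    t, x1 = _tone(40.0, duration_ms=600.0)
    _, x2 = _tone(40.0, duration_ms=600.0, phase=np.pi)
    assert np.max(np.abs((x1 + x2) / 2)) < 1e-9  # waveform cancels
    tm = trial_mean_tfr([(t, x1), (t, x2)])
    profile = tm.power.mean(axis=1)
    ridge = tm.freqs[np.argmax(profile)]
    assert ridge == 40.0
    single = morlet_tfr(t, x1)
    assert np.allclose(tm.power, single.power, rtol=1e-6)


def test_crop_truncates_time_axis():
    t, x = _tone(10.0, duration_ms=600.0)
    tm = trial_mean_tfr([(t, x)], crop_ms=300.0)
    assert tm.times[-1] <= 300.0


def test_tone_dominates_far_frequencies_by_an_order_of_magnitude():
    """Time-averaged power at the tone exceeds power one octave away by
    at least 10x."""
    t, x = _tone(40.0)
    tfr = morlet_tfr(t, x)
    mid = (tfr.times > 200) & (tfr.times < 800)
    prof = tfr.power[:, mid].mean(axis=1)
    p40 = prof[np.argmin(np.abs(tfr.freqs - 40.0))]
    for f in (20.0, 80.0, 100.0):
        assert p40 / prof[np.argmin(np.abs(tfr.freqs - f))] >= 10.0


def test_power_is_additive_for_uncorrelated_tones():
    """Two-tone power at each tone matches the single-tone power within
    10%."""
    t, x1 = _tone(20.0)
    _, x2 = _tone(60.0)
    both = morlet_tfr(t, x1 + x2)
    alone1 = morlet_tfr(t, x1)
    alone2 = morlet_tfr(t, x2)
    mid = (t > 200) & (t < 800)
    for f, alone in ((20.0, alone1), (60.0, alone2)):
        i = np.argmin(np.abs(both.freqs - f))
        assert both.power[i, mid].mean() == pytest.approx(
            alone.power[i, mid].mean(), rel=0.10)


def test_band_peak_selection_and_tie_break():
    times = np.arange(5.0)
    freqs = np.arange(10.0, 15.0)
    flat = TimeFrequencyMap(times=times, freqs=freqs,
                            power=np.ones((5, 5)))
    # flat map: the tie-break returns the lowest in-band frequency
    assert band_peak(flat, (11.0, 14.0), (0.0, 4.0)) == 11.0
    power = np.ones((5, 5))
    power[3] = 7.0  # louder tone at 13 Hz
    two = TimeFrequencyMap(times=times, freqs=freqs, power=power)
    assert band_peak(two, (10.0, 14.0), (0.0, 4.0)) == 13.0
    with pytest.raises(ValueError):
        band_peak(flat, (99.0, 100.0), (0.0, 4.0))


def test_tfr_matches_independent_mne_implementation():
    """Cross-check against MNE's Morlet TFR on a two-tone signal: same
    peak frequency and matching power profile shape."""
    mne = pytest.importorskip("mne")

    t, x1 = _tone(25.0)
    _, x2 = _tone(70.0, amp=0.5)
    x = x1 + x2
    freqs = np.arange(5.0, 96.0, 1.0)
    params = MorletParams(freqs=freqs)
    ours = morlet_tfr(t, x, params)

    sfreq = 1000.0
    data = x[np.newaxis, np.newaxis, :]
    theirs = mne.time_frequency.tfr_array_morlet(
        data, sfreq=sfreq, freqs=freqs, n_cycles=freqs / 3.0,
        output="power", zero_mean=False,
    )[0, 0]
    mid = (t > 250) & (t < 750)
    ours_prof = ours.power[:, mid].mean(axis=1)
    theirs_prof = theirs[:, mid].mean(axis=1)
    assert freqs[np.argmax(ours_prof)] == freqs[np.argmax(theirs_prof)]
    # profiles agree up to a global scale
    scale = ours_prof.max() / theirs_prof.max()
    assert np.allclose(ours_prof, theirs_prof * scale,
                       atol=0.02 * ours_prof.max())
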