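"""Beat detection/scoring and the four heart-rate estimators."""

import numpy as np
import pytest

from neovitals.cardiac import (
    BeatSeries,
    detect_beats,
    estimate_hr_series,
    fit_ar,
    hr_ar_best_model,
    hr_ar_dominant_pole,
    hr_beat_counting,
    hr_fft,
    kalman_smooth_estimates,
    score_beats,
    window_sqi,
)
from neovitals.changepoint import ChangePointSet
from neovitals.filters import filter_cardiac
from neovitals.ppgi import ActivitySeries, PPGiSignal

FS = 20.0


def _cardiac_signal(hr_bpm=120.0, duration=40.0, harmonic=0.3, noise=0.0, seed=0):
    t = np.arange(0, duration, 1 / FS)
    f = hr_bpm / 60.0
    x = np.sin(2 * np.pi * f * t) + harmonic * np.sin(4 * np.pi * f * t)
    if noise:
        x = x + np.random.default_rng(seed).normal(0, noise, len(t))
    filt, ok = filter_cardiac(x, FS)
    return PPGiSignal(filt, FS, valid=ok)


def _periodic_beats(rate_bpm=120.0, duration=40.0):
    step = 60.0 / rate_bpm
    peaks = np.arange(step, duration, step)
    return BeatSeries(peaks, peaks - 0.2, np.ones(len(peaks)),
                      sqi=np.ones(len(peaks)))


# --- beat counting (interval convention) -----------------------------------

def test_counting_exact_on_periodic_train():
    beats = _periodic_beats(120.0)
    est = hr_beat_counting(beats, 20.0)
    assert est.valid
    assert est.value == pytest.approx(120.0, abs=1e-9)


def test_counting_uses_expanded_window():
    # 3 peaks 0.5 s apart ending exactly at the window edge: rate from the
    # 2 complete intervals over their 1.0 s span, not over the window length
    peaks = np.array([7.0, 7.5, 8.0])
    beats = BeatSeries(peaks, peaks - 0.2, np.ones(3), sqi=np.ones(3))
    est = hr_beat_counting(beats, 8.0)
    assert est.value == pytest.approx(120.0)


def test_counting_invalid_with_too_few_beats():
    peaks = np.array([7.0])
    beats = BeatSeries(peaks, peaks - 0.2, np.ones(1), sqi=np.ones(1))
    assert not hr_beat_counting(beats, 8.0).valid


def test_counting_ignores_zero_sqi_beats():
    peaks = np.arange(0.5, 8.0, 0.5)
    sqi = np.ones(len(peaks))
    sqi[:] = 0.0
    beats = BeatSeries(peaks, peaks - 0.2, np.ones(len(peaks)), sqi=sqi)
    assert not hr_beat_counting(beats, 8.0).valid


def test_counting_out_of_range_flagged_invalid():
    peaks = np.arange(1.0, 8.0, 1.0)        # 60 beats/min < 90
    beats = BeatSeries(peaks, peaks - 0.2, np.ones(len(peaks)),
                       sqi=np.ones(len(peaks)))
    est = hr_beat_counting(beats, 8.0)
    assert not est.valid


# --- FFT -------------------------------------------------------------------

def test_fft_recovers_tone_within_resolution():
    sig = _cardiac_signal(150.0)
    est = hr_fft(sig, 20.0)
    assert est.valid
    assert abs(est.value - 150.0) < 0.5


def test_fft_invalid_with_too_many_missing_samples():
    sig = _cardiac_signal(150.0)
    sig.valid[-120:] = False                  # 6 of last 8 s invalid
    assert not hr_fft(sig, len(sig) / FS).valid


# --- AR --------------------------------------------------------------------

def test_fit_ar_errors():
    with pytest.raises(ValueError):
        fit_ar(np.zeros(100), 8)              # constant
    with pytest.raises(ValueError):
        fit_ar(np.arange(10.0), 8)            # too short


def test_ar_pole_matches_tone():
    sig = _cardiac_signal(132.0, noise=0.05)
    est = hr_ar_dominant_pole(sig, 20.0)
    assert est.valid
    assert abs(est.value - 132.0) < 3.0
    assert 0.5 <= est.extra["pole_magnitude"] <= 1.1


def test_ar_pole_vs_periodogram_oracle():
    # independent oracle: zero-padded periodogram argmax on pure tones
    rng = np.random.default_rng(4)
    for f_hz in np.linspace(1.6, 4.4, 8):
        t = np.arange(0, 8, 1 / FS)
        x = np.sin(2 * np.pi * f_hz * t) + rng.normal(0, 0.05, len(t))
        model = fit_ar(x, 8, FS)
        pole = model.dominant_in_band_pole((1.5, 4.5))
        spec = np.abs(np.fft.rfft(x - x.mean(), 4096)) ** 2
        freqs = np.fft.rfftfreq(4096, 1 / FS)
        band = (freqs >= 1.5) & (freqs <= 4.5)
        f_fft = freqs[band][np.argmax(spec[band])]
        assert abs(60 * pole[0] - 60 * f_fft) < 3.0


def test_ar_frequency_response_peaks_at_pole():
    sig = _cardiac_signal(120.0, noise=0.05)
    x, _ = sig.samples[:160], sig.valid[:160]
    model = fit_ar(x, 8, FS)
    grid = np.linspace(1.5, 4.5, 1800)
    peak_hz = grid[np.argmax(model.frequency_response(grid))]
    pole_hz = model.dominant_in_band_pole((1.5, 4.5))[0]
    assert abs(peak_hz - pole_hz) * 60 < 2.0


def test_ar_best_model_valid_and_accurate():
    sig = _cardiac_signal(126.0, noise=0.05)
    est = hr_ar_best_model(sig, 20.0)
    assert est.valid
    assert abs(est.value - 126.0) < 3.0


def test_ar_best_model_fallback_flagged_on_noise():
    rng = np.random.default_rng(6)
    sig = PPGiSignal(rng.normal(size=400), FS)
    est = hr_ar_best_model(sig, 20.0)
    # whatever it returns on white noise must be flagged or in-range
    if est.valid and est.fallback:
        assert 90.0 <= est.value <= 270.0


def test_estimators_never_return_out_of_range_values():
    sig = _cardiac_signal(120.0, noise=0.2)
    beats = detect_beats(sig)
    beats = score_beats(beats, sig)
    for method in ("count", "fft", "ar8", "arbest"):
        for est in estimate_hr_series(sig, beats, method=method):
            if est.valid:
                assert 90.0 <= est.value <= 270.0


# --- beat SQI --------------------------------------------------------------

def test_clean_beats_score_high():
    sig = _cardiac_signal(120.0)
    beats = score_beats(detect_beats(sig), sig)
    core = (beats.peak_times > 8) & (beats.peak_times < 32)
    assert beats.sqi[core].mean() > 0.8
    assert beats.gates[core].all()


def test_activity_gate_zeroes_sqi():
    sig = _cardiac_signal(120.0)
    n_sec = int(len(sig) / FS)
    active = np.zeros(n_sec, bool)
    active[15:20] = True
    act = ActivitySeries(np.zeros(len(sig)), np.zeros(n_sec), active, 0.02, FS)
    beats = score_beats(detect_beats(sig), sig, activity=act)
    during = (beats.peak_times >= 15.5) & (beats.peak_times < 19.5)
    assert during.any()
    assert np.all(beats.sqi[during] == 0.0)
    assert np.all(~beats.gates[during, 0])


def test_changepoint_gate_zeroes_sqi():
    sig = _cardiac_signal(120.0)
    cps = ChangePointSet(indices=[int(20.0 * FS)], margin_s=1.0, sample_rate=FS)
    beats = score_beats(detect_beats(sig), sig, changes=cps)
    near = np.abs(beats.peak_times - 20.0) <= 0.8
    assert near.any()
    assert np.all(beats.sqi[near] == 0.0)


def test_amplitude_gate_rejects_outlier():
    sig = _cardiac_signal(120.0)
    beats = detect_beats(sig)
    amps = beats.amplitudes.copy()
    k = len(amps) // 2
    amps[k] *= 10.0                        # 10x the running median
    doctored = BeatSeries(beats.peak_times, beats.onset_times, amps,
                          sample_rate=beats.sample_rate)
    scored = score_beats(doctored, sig)
    assert not scored.gates[k, 4]
    assert scored.sqi[k] == 0.0


def test_window_sqi_mean_and_empty():
    beats = _periodic_beats(120.0)
    assert window_sqi(beats, 20.0) == pytest.approx(1.0)
    empty = BeatSeries(np.array([]), np.array([]), np.array([]),
                       sqi=np.array([]))
    assert window_sqi(empty, 20.0) == 0.0


# --- series + smoothing ----------------------------------------------------

def test_estimate_series_grid_and_stamps():
    sig = _cardiac_signal(120.0)
    beats = score_beats(detect_beats(sig), sig)
    ests = estimate_hr_series(sig, beats, method="count")
    assert ests[0].time == 8.0
    assert ests[-1].time == 40.0
    assert len(ests) == 33
    core = [e for e in ests if 12 <= e.time <= 36 and e.valid]
    err = [abs(e.value - 120.0) for e in core]
    assert np.mean(err) < 2.0


def test_kalman_smoothing_preserves_grid():
    sig = _cardiac_signal(120.0)
    beats = score_beats(detect_beats(sig), sig)
    raw = estimate_hr_series(sig, beats, method="count")
    smooth = kalman_smooth_estimates(raw)
    assert len(smooth) == len(raw)
    assert all(s.time == r.time for s, r in zip(smooth, raw))
    assert all(s.method.endswith("+kalman") for s in smooth)
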