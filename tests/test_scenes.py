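"""Scene generator: determinism, geometry, event-count consistency, waveforms."""

import numpy as np
import pytest

from neovitals import SceneConfig, generate_scene, generate_reference_waveforms
from neovitals.scenes import (
    BACKGROUND_RGB,
    SKIN_RGB,
    as_schedule,
    pulse_waveform,
)


def test_frames_deterministic_for_seed():
    cfg = SceneConfig(duration=2.0, seed=3)
    s1, _ = generate_scene(cfg)
    s2, _ = generate_scene(SceneConfig(duration=2.0, seed=3))
    for i in (0, 10, 39):
        np.testing.assert_array_equal(s1.frame(i), s2.frame(i))
        np.testing.assert_array_equal(s1.mask(i), s2.mask(i))


def test_different_seed_changes_frames():
    a, _ = generate_scene(SceneConfig(duration=1.0, seed=0))
    b, _ = generate_scene(SceneConfig(duration=1.0, seed=1))
    assert not np.array_equal(a.frame(0), b.frame(0))


def test_frame_shape_and_range():
    cfg = SceneConfig(duration=1.0, frame_size=(60, 80))
    scene, _ = generate_scene(cfg)
    f = scene.frame(0)
    assert f.shape == (60, 80, 3)
    assert f.min() >= 0.0 and f.max() <= 255.0
    assert scene.mask(0).shape == (60, 80)


def test_mask_is_skin_coloured_region():
    cfg = SceneConfig(duration=1.0, noise_sd=0.0, global_noise_sd=0.0)
    scene, _ = generate_scene(cfg)
    f = scene.frame(0)
    m = scene.mask(0)
    # interior of the mask is near the skin palette, outside near background
    interior = f[m].mean(axis=0)
    outside = f[~m].mean(axis=0)
    assert np.abs(interior - SKIN_RGB).max() < 15.0
    assert np.abs(outside - BACKGROUND_RGB).max() < 15.0


def test_beat_count_matches_schedule_integral():
    # beat count over the scene ~ integral of hr/60
    cfg = SceneConfig(duration=30.0, hr_schedule=[(0.0, 120.0), (15.0, 180.0)],
                      rr_schedule=40.0, seed=1)
    _, truth = generate_scene(cfg)
    expected = (15 * 120 + 15 * 180) / 60.0
    assert abs(len(truth.beat_times) - expected) <= 1


def test_breath_count_matches_schedule_integral():
    cfg = SceneConfig(duration=30.0, hr_schedule=150.0, rr_schedule=60.0, seed=1)
    _, truth = generate_scene(cfg)
    assert abs(len(truth.breath_times) - 30.0) <= 1


def test_ground_truth_series_follow_schedules():
    cfg = SceneConfig(duration=20.0, hr_schedule=[(0.0, 120.0), (10.0, 180.0)],
                      rr_schedule=50.0)
    _, truth = generate_scene(cfg)
    assert truth.hr_series[5] == 120.0
    assert truth.hr_series[15] == 180.0
    assert np.all(truth.rr_series == 50.0)


def test_dominant_green_frequency_is_heart_rate():
    cfg = SceneConfig(duration=20.0, hr_schedule=120.0, rr_schedule=40.0,
                      noise_sd=0.0, global_noise_sd=0.0, seed=2)
    scene, truth = generate_scene(cfg)
    sig = np.array([scene.frame(i)[..., 1][scene.mask(i)].mean()
                    for i in range(len(scene))])
    sig -= sig.mean()
    spec = np.abs(np.fft.rfft(sig, 8192))
    freqs = np.fft.rfftfreq(8192, 1.0 / cfg.frame_rate)
    band = (freqs > 1.0) & (freqs < 3.0)  # exclude DC/resp and the harmonic
    assert abs(freqs[band][np.argmax(spec[band])] - 2.0) < 0.05


def test_absence_interval_gives_empty_masks_and_presence_flags():
    cfg = SceneConfig(duration=10.0, absence_intervals=[(4.0, 6.0)])
    scene, truth = generate_scene(cfg)
    assert not scene.mask(int(5.0 * cfg.frame_rate)).any()
    assert scene.mask(0).any()
    assert not truth.presence[4] and not truth.presence[5]
    assert truth.presence[2] and truth.presence[8]


def test_lighting_step_scales_intensity():
    base = SceneConfig(duration=4.0, noise_sd=0.0, global_noise_sd=0.0)
    lit = SceneConfig(duration=4.0, noise_sd=0.0, global_noise_sd=0.0,
                      lighting_steps=[(2.0, 1.5)])
    s0, _ = generate_scene(base)
    s1, _ = generate_scene(lit)
    i_pre = int(1.0 * base.frame_rate)
    i_post = int(3.0 * base.frame_rate)
    np.testing.assert_allclose(s1.frame(i_pre), s0.frame(i_pre))
    unclipped = s0.frame(i_post) * 1.5 <= 255.0
    np.testing.assert_allclose(s1.frame(i_post)[unclipped],
                               (s0.frame(i_post) * 1.5)[unclipped], rtol=1e-6)


def test_motion_burst_moves_centroid():
    cfg = SceneConfig(duration=10.0, motion_bursts=[(4.0, 6.0, 5.0)], seed=3)
    scene, truth = generate_scene(cfg)
    quiet = scene.mask(0)
    moving = scene.mask(int(5.0 * cfg.frame_rate))
    cy0, cx0 = [c.mean() for c in np.nonzero(quiet)]
    cy1, cx1 = [c.mean() for c in np.nonzero(moving)]
    assert np.hypot(cx1 - cx0, cy1 - cy0) > 0.5
    assert truth.motion_seconds[4] and truth.motion_seconds[5]
    assert not truth.motion_seconds[1]


def test_config_rejects_out_of_range_schedules():
    with pytest.raises(ValueError):
        SceneConfig(hr_schedule=80.0)           # below 90 beats/min
    with pytest.raises(ValueError):
        SceneConfig(rr_schedule=10.0)           # below 18 breaths/min
    with pytest.raises(ValueError):
        SceneConfig(duration=-1.0)


def test_config_rejects_motion_during_absence():
    with pytest.raises(ValueError):
        SceneConfig(duration=10.0, motion_bursts=[(2.0, 4.0, 3.0)],
                    absence_intervals=[(3.0, 5.0)])


def test_schedule_coercion():
    s = as_schedule(100.0)
    assert np.all(s(np.array([0.0, 5.0])) == 100.0)
    s = as_schedule([(0.0, 100.0), (10.0, 140.0)])
    np.testing.assert_array_equal(s(np.array([0.0, 9.9, 10.0, 20.0])),
                                  [100.0, 100.0, 140.0, 140.0])
    s = as_schedule(lambda t: 100.0 + t)
    assert s(np.array([5.0]))[0] == 105.0
    with pytest.raises(ValueError):
        as_schedule([(5.0, 100.0)])  # must start at 0


def test_pulse_waveform_periodic_and_zero_mean():
    ph = np.linspace(0.0, 1.0, 1001)[:-1]
    w = pulse_waveform(ph)
    assert abs(w.mean()) < 1e-3
    np.testing.assert_allclose(pulse_waveform(np.array([0.25])),
                               pulse_waveform(np.array([1.25])), atol=1e-12)


# --- reference waveforms ---------------------------------------------------

def test_waveform_sampling_rates_and_lengths(ref_waveforms):
    wf = ref_waveforms
    assert len(wf.ecg) == 60 * 500
    assert len(wf.ppg) == 60 * 125
    assert len(wf.ip) == 60 * 64
    assert len(wf.hr_ecg) == len(wf.hr_ppg) == len(wf.rr_ip) == 60


def test_waveform_beat_count(ref_waveforms):
    # 150 beats/min for 60 s -> 150 beats (+-1 boundary effect)
    assert abs(len(ref_waveforms.beat_times) - 150) <= 1
    assert abs(len(ref_waveforms.breath_times) - 50) <= 1


def test_ip_dominant_frequency_is_respiration(ref_waveforms):
    ip = ref_waveforms.ip - ref_waveforms.ip.mean()
    spec = np.abs(np.fft.rfft(ip))
    freqs = np.fft.rfftfreq(len(ip), 1.0 / 64.0)
    sel = freqs > 0.1
    assert abs(freqs[sel][np.argmax(spec[sel])] - 50.0 / 60.0) < 0.05


def test_numerics_track_schedules(ref_waveforms):
    wf = ref_waveforms
    # after warm-up the monitor numerics sit on the schedule (RSA averages out)
    assert np.abs(wf.hr_ecg[20:] - 150.0).max() < 3.0
    assert np.abs(wf.hr_ppg[20:] - 150.0).max() < 3.0
    assert np.abs(wf.rr_ip[20:] - 50.0).max() < 3.0


def test_ecg_beat_intervals_carry_rsa(ref_waveforms):
    # instantaneous beat rate must oscillate at the breathing frequency
    beats = ref_waveforms.beat_times
    rate = 60.0 / np.diff(beats)
    t = beats[1:]
    grid = np.arange(1.0, 59.0, 0.25)
    r4 = np.interp(grid, t, rate)
    r4 -= r4.mean()
    spec = np.abs(np.fft.rfft(r4))
    freqs = np.fft.rfftfreq(len(r4), 0.25)
    sel = freqs > 0.1
    assert abs(freqs[sel][np.argmax(spec[sel])] - 50.0 / 60.0) < 0.08


def test_waveforms_deterministic():
    a = generate_reference_waveforms(120.0, 40.0, duration=10.0, seed=9)
    b = generate_reference_waveforms(120.0, 40.0, duration=10.0, seed=9)
    np.testing.assert_array_equal(a.ecg, b.ecg)
    np.testing.assert_array_equal(a.ppg, b.ppg)
    np.testing.assert_array_equal(a.ip, b.ip)


def test_waveforms_reject_out_of_range_schedules():
    with pytest.raises(ValueError):
        generate_reference_waveforms(80.0, 40.0, duration=10.0)
    with pytest.raises(ValueError):
        generate_reference_waveforms(150.0, 10.0, duration=10.0)
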