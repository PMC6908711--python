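"""Synthetic video scenes and matched monitor waveforms with known vital signs.

Every downstream stage of the pipeline (skin segmentation, PPGi extraction,
heart-rate and respiratory-rate estimation, reference-vital construction) is
exercised against scenes produced here, because clinical neonatal video
cannot be redistributed.  A scene is a skin-coloured filled ellipse on a
darker background whose green channel carries a cardiac-frequency pulse
waveform, whose minor axis and vertical centroid carry a respiratory-frequency
shape modulation, and which can be perturbed by motion bursts, lighting steps
and absence intervals.  Matched ECG / PPG / impedance-pneumography waveforms
are generated from the same beat and breath event times.

Frames are produced lazily (pure functions of the frame index) so that long
scenes do not need to be held in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "SceneConfig",
    "VideoFrame",
    "GroundTruth",
    "Scene",
    "ReferenceWaveforms",
    "generate_scene",
    "generate_reference_waveforms",
]

# Fixed palette: a light skin tone on a dark incubator-mattress background.
SKIN_RGB = np.array([210.0, 160.0, 135.0])
BACKGROUND_RGB = np.array([55.0, 58.0, 66.0])

HR_BOUNDS = (90.0, 270.0)
RR_BOUNDS = (18.0, 120.0)


Schedule = Callable[[np.ndarray], np.ndarray]


def as_schedule(spec) -> Schedule:
    """Coerce a schedule spec to a vectorised callable time -> value.

    Accepts a constant, a list of ``(start_time, value)`` steps (piecewise
    constant, first start time must be 0) or a callable.
    """
    if callable(spec):
        return lambda t: np.asarray(spec(np.asarray(t, dtype=float)), dtype=float)
    if np.isscalar(spec):
        v = float(spec)
        return lambda t: np.full_like(np.asarray(t, dtype=float), v)
    steps = sorted((float(s), float(v)) for s, v in spec)
    if steps[0][0] != 0.0:
        raise ValueError("step schedule must start at time 0")
    starts = np.array([s for s, _ in steps])
    values = np.array([v for _, v in steps])

    def sched(t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
        return values[idx]

    return sched


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene.

    ``hr_schedule`` / ``rr_schedule`` map time (s) to beats/min resp.
    breaths/min; constants, ``(start, value)`` step lists and callables are
    accepted.  ``ppgi_amplitude`` is the fractional green-channel modulation
    depth of the cardiac pulse; ``shape_amplitude`` the fractional modulation
    of the ellipse minor axis (and centroid) by breathing.
    """

    duration: float = 60.0
    frame_rate: float = 20.0
    frame_size: tuple[int, int] = (120, 160)  # rows, columns
    hr_schedule: object = 150.0
    rr_schedule: object = 60.0
    ppgi_amplitude: float = 0.03
    shape_amplitude: float = 0.04
    motion_bursts: Sequence[tuple[float, float, float]] = field(default_factory=list)
    lighting_steps: Sequence[tuple[float, float]] = field(default_factory=list)
    absence_intervals: Sequence[tuple[float, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    global_noise_sd: float = 0.3
    timestamp_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        t = np.arange(0.0, self.duration, 1.0)
        hr = as_schedule(self.hr_schedule)(t)
        rr = as_schedule(self.rr_schedule)(t)
        if np.any(hr < HR_BOUNDS[0]) or np.any(hr > HR_BOUNDS[1]):
            raise ValueError(f"hr_schedule values must lie in {HR_BOUNDS} beats/min")
        if np.any(rr < RR_BOUNDS[0]) or np.any(rr > RR_BOUNDS[1]):
            raise ValueError(f"rr_schedule values must lie in {RR_BOUNDS} breaths/min")
        for name, intervals in (
            ("motion_bursts", [(a, b) for a, b, _ in self.motion_bursts]),
            ("lighting_steps", [(a, a) for a, _ in self.lighting_steps]),
            ("absence_intervals", list(self.absence_intervals)),
        ):
            for a, b in intervals:
                if not (0.0 <= a <= self.duration and 0.0 <= b <= self.duration):
                    raise ValueError(f"{name} interval ({a}, {b}) outside [0, duration]")
                if b < a:
                    raise ValueError(f"{name} interval ({a}, {b}) reversed")
        for a0, b0, _ in self.motion_bursts:
            for a1, b1 in self.absence_intervals:
                if a0 < b1 and a1 < b0:
                    raise ValueError(
                        "motion burst (%g, %g) overlaps absence interval (%g, %g): "
                        "an absent subject cannot move" % (a0, b0, a1, b1)
                    )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class VideoFrame:
    """One RGB frame: ``pixels`` is rows x columns x 3, intensities in [0, 255]."""

    timestamp: float
    pixels: np.ndarray

    @property
    def green_plane(self) -> np.ndarray:
        return self.pixels[..., 1]


@dataclass
class GroundTruth:
    hr_series: np.ndarray          # 1 Hz, beats/min
    rr_series: np.ndarray          # 1 Hz, breaths/min
    skin_masks: "Sequence[np.ndarray]"
    presence: np.ndarray           # 1 Hz boolean
    beat_times: np.ndarray         # true beat instants, s
    breath_times: np.ndarray       # true breath instants, s
    motion_seconds: np.ndarray     # 1 Hz boolean: any motion burst overlaps


class _LazyMasks(Sequence):
    def __init__(self, scene: "Scene"):
        self._scene = scene

    def __len__(self) -> int:
        return self._scene.config.n_frames

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        if i < 0:
            i += len(self)
        return self._scene.mask(i)


def _event_times(schedule: Schedule, duration: float, dt: float = 0.01) -> np.ndarray:
    """Instants where the cumulative phase of a rate schedule crosses integers."""
    t = np.arange(0.0, duration + dt, dt)
    rate_hz = schedule(t) / 60.0
    phase = np.concatenate([[0.0], np.cumsum(0.5 * (rate_hz[1:] + rate_hz[:-1]) * dt)])
    n_events = int(np.floor(phase[-1]))
    targets = np.arange(1, n_events + 1, dtype=float)
    return np.interp(targets, phase, t)


def _phase(schedule: Schedule, times: np.ndarray, duration: float, dt: float = 0.01) -> np.ndarray:
    grid = np.arange(0.0, duration + dt, dt)
    rate_hz = schedule(grid) / 60.0
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (rate_hz[1:] + rate_hz[:-1]) * dt)])
    return np.interp(times, grid, cum)


def pulse_waveform(phase: np.ndarray) -> np.ndarray:
    """Non-sinusoidal cardiac pulse: fundamental plus one harmonic.

    The second harmonic steepens the upslope so the slope-sum beat detector
    has a realistic feature to lock onto.
    """
    return np.sin(2 * np.pi * phase) + 0.3 * np.sin(4 * np.pi * phase)


class Scene:
    """A generated scene: lazily evaluated frames plus exact ground truth.

    Iterating yields :class:`VideoFrame`; ``frame(i)`` / ``mask(i)`` give the
    pixel array (float32, [0, 255]) and boolean skin mask of frame ``i``.
    """

    def __init__(self, config: SceneConfig):
        self.config = config
        c = config
        rows, cols = c.frame_size
        self._rng_texture = np.random.default_rng([int(c.seed), 1])
        self._texture = self._rng_texture.normal(0.0, 4.0, size=(rows, cols, 3)).astype(np.float32)
        self._hr = as_schedule(c.hr_schedule)
        self._rr = as_schedule(c.rr_schedule)
        n = c.n_frames
        ideal = np.arange(n) / c.frame_rate
        if c.timestamp_jitter_sd > 0:
            jitter_rng = np.random.default_rng([int(c.seed), 2])
            self.timestamps = ideal + jitter_rng.normal(0.0, c.timestamp_jitter_sd, n)
        else:
            self.timestamps = ideal
        # cardiac / respiratory phase at each frame time
        self._cphase = _phase(self._hr, self.timestamps, c.duration)
        self._rphase = _phase(self._rr, self.timestamps, c.duration)
        # geometry: centre and semi-axes scale with the frame
        self._cx0 = cols / 2.0
        self._cy0 = rows / 2.0
        self._a0 = 0.30 * cols    # semi-major (x)
        self._b0 = 0.30 * rows    # semi-minor (y)
        self._tilt = 0.25         # fixed ellipse tilt, rad
        # smooth motion-burst trajectories, deterministic from the seed
        mrng = np.random.default_rng([int(c.seed), 3])
        self._burst_params = [
            (a, b, amp, mrng.uniform(0, 2 * np.pi, 2), mrng.uniform(1.0, 2.0, 2))
            for a, b, amp in c.motion_bursts
        ]
        self.ground_truth = self._make_ground_truth()

    # -- per-frame geometry ------------------------------------------------

    def _displacement(self, t: float) -> tuple[float, float]:
        dx = dy = 0.0
        for a, b, amp, phases, freqs in self._burst_params:
            if a <= t < b:
                # cosine taper avoids a step at the burst edges
                w = 0.5 * (1 - np.cos(2 * np.pi * min((t - a) / (b - a), 1.0)))
                taper = min(1.0, 5.0 * min(t - a, b - t) / (b - a))
                dx += amp * taper * np.sin(2 * np.pi * freqs[0] * t + phases[0])
                dy += amp * taper * np.sin(2 * np.pi * freqs[1] * t + phases[1])
                del w
        return dx, dy

    def _lighting(self, t: float) -> float:
        k = 1.0
        for ts, factor in self.config.lighting_steps:
            if t >= ts:
                k *= factor
        return k

    def _absent(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.config.absence_intervals)

    def _geometry(self, i: int):
        t = self.timestamps[i]
        breath = np.sin(2 * np.pi * self._rphase[i])
        b = self._b0 * (1 + self.config.shape_amplitude * breath)
        a = self._a0
        dx, dy = self._displacement(t)
        cx = self._cx0 + dx
        cy = self._cy0 + dy + self.config.shape_amplitude * self._b0 * breath
        tilt = self._tilt + 0.02 * breath
        return cx, cy, a, b, tilt

    def mask(self, i: int) -> np.ndarray:
        rows, cols = self.config.frame_size
        if self._absent(self.timestamps[i]):
            return np.zeros((rows, cols), dtype=bool)
        cx, cy, a, b, tilt = self._geometry(i)
        yy, xx = np.mgrid[0:rows, 0:cols]
        xr = (xx - cx) * np.cos(tilt) + (yy - cy) * np.sin(tilt)
        yr = -(xx - cx) * np.sin(tilt) + (yy - cy) * np.cos(tilt)
        return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    def frame(self, i: int) -> np.ndarray:
        c = self.config
        rows, cols = c.frame_size
        t = self.timestamps[i]
        img = np.empty((rows, cols, 3), dtype=np.float32)
        img[:] = BACKGROUND_RGB
        m = self.mask(i)
        if m.any():
            pulse = pulse_waveform(np.array([self._cphase[i]]))[0]
            breath = np.sin(2 * np.pi * self._rphase[i])
            skin = SKIN_RGB.copy()
            # green carries the cardiac pulse; all channels carry a weak
            # respiratory intensity component (blood-volume breathing signal)
            resp_mod = 1 + 0.4 * c.ppgi_amplitude * breath
            skin = skin * resp_mod
            skin[1] *= 1 + c.ppgi_amplitude * pulse
            img[m] = skin
        img += self._texture
        img *= self._lighting(t)
        if c.noise_sd > 0 or c.global_noise_sd > 0:
            rng = np.random.default_rng([int(c.seed), 4, int(i)])
            if c.noise_sd > 0:
                img += rng.normal(0.0, c.noise_sd, img.shape).astype(np.float32)
            if c.global_noise_sd > 0:
                # illumination flicker / camera gain: shared across pixels,
                # so it survives the spatial averaging that cancels pixel noise
                img += rng.normal(0.0, c.global_noise_sd, 3).astype(np.float32)
        return np.clip(img, 0.0, 255.0)

    def __len__(self) -> int:
        return self.config.n_frames

    def __iter__(self) -> Iterator[VideoFrame]:
        for i in range(len(self)):
            yield VideoFrame(self.timestamps[i], self.frame(i))

    # -- ground truth --------------------------------------------------------

    def _make_ground_truth(self) -> GroundTruth:
        c = self.config
        secs = np.arange(int(np.ceil(c.duration)))
        hr = self._hr(secs.astype(float))
        rr = self._rr(secs.astype(float))
        presence = np.array([not self._absent(float(s) + 0.5) for s in secs])
        motion = np.zeros(len(secs), dtype=bool)
        for a, b, _ in c.motion_bursts:
            motion |= (secs + 1 > a) & (secs < b)
        return GroundTruth(
            hr_series=hr,
            rr_series=rr,
            skin_masks=_LazyMasks(self),
            presence=presence,
            beat_times=_event_times(self._hr, c.duration),
            breath_times=_event_times(self._rr, c.duration),
            motion_seconds=motion,
        )


def generate_scene(config: SceneConfig) -> tuple[Scene, GroundTruth]:
    """Generate a synthetic scene; returns the (lazy) frame stream and truth."""
    scene = Scene(config)
    return scene, scene.ground_truth


# ---------------------------------------------------------------------------
# reference monitor waveforms
# ---------------------------------------------------------------------------

ECG_FS = 500.0
PPG_FS = 125.0
IP_FS = 64.0


@dataclass
class ReferenceWaveforms:
    """Monitor waveforms matched to a scene's vital-sign schedules.

    ECG at 500 Hz (QRS impulse train, R amplitude and baseline modulated by
    respiration so EDR / RSA / RPA are recoverable), PPG at 125 Hz (systolic
    peak plus dicrotic wave), impedance pneumography at 64 Hz, and 1 Hz
    monitor numerics derived from the event times.
    """

    ecg_time: np.ndarray
    ecg: np.ndarray
    ppg_time: np.ndarray
    ppg: np.ndarray
    ip_time: np.ndarray
    ip: np.ndarray
    numerics_time: np.ndarray
    hr_ecg: np.ndarray
    hr_ppg: np.ndarray
    rr_ip: np.ndarray
    spo2: np.ndarray
    beat_times: np.ndarray
    breath_times: np.ndarray


def _qrs_template(fs: float) -> np.ndarray:
    """Biphasic QRS-like spike, ~80 ms wide, unit R amplitude, plus a T hump."""
    t = np.arange(-0.04, 0.30, 1.0 / fs)
    qrs = np.exp(-0.5 * (t / 0.008) ** 2) - 0.25 * np.exp(-0.5 * ((t - 0.025) / 0.010) ** 2) \
        - 0.15 * np.exp(-0.5 * ((t + 0.022) / 0.010) ** 2)
    t_wave = 0.18 * np.exp(-0.5 * ((t - 0.16) / 0.035) ** 2)
    return (qrs + t_wave).astype(float)


def _rate_from_events(events: np.ndarray, duration: float, window: float) -> np.ndarray:
    """1 Hz rate numerics: mean rate over the trailing ``window`` seconds."""
    secs = np.arange(int(np.ceil(duration)), dtype=float) + 1.0
    out = np.full(len(secs), np.nan)
    for k, t1 in enumerate(secs):
        t0 = max(0.0, t1 - window)
        sel = events[(events >= t0) & (events <= t1)]
        if len(sel) >= 2:
            out[k] = 60.0 * (len(sel) - 1) / (sel[-1] - sel[0])
    # monitors hold the last value over dropouts
    for k in range(1, len(out)):
        if np.isnan(out[k]):
            out[k] = out[k - 1]
    first = np.flatnonzero(~np.isnan(out))
    if len(first):
        out[: first[0]] = out[first[0]]
    return out


def generate_reference_waveforms(hr_schedule, rr_schedule, duration: float,
                                 seed: int = 0, noise_sd: float = 0.01) -> ReferenceWaveforms:
    """Simulate patient-monitor waveforms for the given vital-sign schedules."""
    hr = as_schedule(hr_schedule)
    rr = as_schedule(rr_schedule)
    secs = np.arange(0.0, duration, 1.0)
    if np.any(hr(secs) < HR_BOUNDS[0]) or np.any(hr(secs) > HR_BOUNDS[1]):
        raise ValueError(f"hr_schedule values must lie in {HR_BOUNDS} beats/min")
    if np.any(rr(secs) < RR_BOUNDS[0]) or np.any(rr(secs) > RR_BOUNDS[1]):
        raise ValueError(f"rr_schedule values must lie in {RR_BOUNDS} breaths/min")
    rng = np.random.default_rng([int(seed), 11])
    # respiratory sinus arrhythmia: the instantaneous beat rate is modulated
    # a few percent at the breathing phase, so beat intervals carry the
    # respiratory frequency (recoverable as the RSA surrogate)
    dt = 0.01
    grid = np.arange(0.0, duration + dt, dt)
    rr_hz = rr(grid) / 60.0
    rphase_g = np.concatenate([[0.0], np.cumsum(0.5 * (rr_hz[1:] + rr_hz[:-1]) * dt)])
    beat_hz = hr(grid) / 60.0 * (1.0 + 0.04 * np.sin(2 * np.pi * rphase_g))
    bphase = np.concatenate([[0.0], np.cumsum(0.5 * (beat_hz[1:] + beat_hz[:-1]) * dt)])
    beats = np.interp(np.arange(1, int(np.floor(bphase[-1])) + 1, dtype=float), bphase, grid)
    breaths = _event_times(rr, duration)

    # --- ECG ---
    n_ecg = int(round(duration * ECG_FS))
    t_ecg = np.arange(n_ecg) / ECG_FS
    ecg = np.zeros(n_ecg)
    rphase = _phase(rr, beats, duration)
    template = _qrs_template(ECG_FS)
    off = int(round(0.04 * ECG_FS))  # R peak sits 40 ms into the template
    for bt, ph in zip(beats, rphase):
        amp = 1.0 + 0.30 * np.sin(2 * np.pi * ph)
        i0 = int(round(bt * ECG_FS)) - off
        j0, j1 = max(i0, 0), min(i0 + len(template), n_ecg)
        if j1 > j0:
            ecg[j0:j1] += amp * template[j0 - i0: j1 - i0]
    rphase_grid = _phase(rr, t_ecg, duration)
    ecg += 0.05 * np.sin(2 * np.pi * rphase_grid)  # respiratory baseline wander
    ecg += rng.normal(0.0, noise_sd, n_ecg)

    # --- PPG ---
    n_ppg = int(round(duration * PPG_FS))
    t_ppg = np.arange(n_ppg) / PPG_FS
    ppg = np.zeros(n_ppg)
    bounds = np.concatenate([[0.0], beats, [duration]])
    # beat phase on the PPG grid: fraction of the way through the current beat
    idx = np.searchsorted(beats, t_ppg, side="right")
    prev = bounds[idx]
    nxt = bounds[idx + 1]
    frac = np.clip((t_ppg - prev) / np.maximum(nxt - prev, 1e-6), 0.0, 1.0)
    ppg = 0.9 * np.exp(-0.5 * ((frac - 0.25) / 0.11) ** 2) \
        + 0.28 * np.exp(-0.5 * ((frac - 0.58) / 0.09) ** 2)
    ppg += rng.normal(0.0, noise_sd, n_ppg)

    # --- IP ---
    n_ip = int(round(duration * IP_FS))
    t_ip = np.arange(n_ip) / IP_FS
    ip = np.sin(2 * np.pi * _phase(rr, t_ip, duration)) + rng.normal(0.0, noise_sd, n_ip)

    numerics_t = np.arange(int(np.ceil(duration)), dtype=float) + 1.0
    hr_ecg = _rate_from_events(beats, duration, window=8.0)
    # the pulse-oximetry module averages over a longer horizon
    hr_ppg = _rate_from_events(beats, duration, window=12.0)
    rr_ip = _rate_from_events(breaths, duration, window=15.0)
    spo2 = np.full(len(numerics_t), 97.0)

    return ReferenceWaveforms(
        ecg_time=t_ecg, ecg=ecg, ppg_time=t_ppg, ppg=ppg, ip_time=t_ip, ip=ip,
        numerics_time=numerics_t, hr_ecg=hr_ecg, hr_ppg=hr_ppg, rr_ip=rr_ip,
        spo2=spo2, beat_times=beats, breath_times=breaths,
    )
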