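"""Beat detection, beat quality, and the four heart-rate estimators.

Heart rate is estimated from the cardiac-band PPGi signal over a running
8 s window with a 1 s step, by four algorithms: beat counting over the
expanded window, the dominant FFT frequency, the dominant in-band pole of a
fixed-order (p = 8) autoregressive model, and an AR best-model-order search
over p = 6..12.  Each detected beat carries a signal-quality index combining
hard gates (motion, step changes, physiological frequency bounds, clipping,
amplitude consistency) with a multi-scale DTW template-similarity score;
window SQI is the mean beat SQI and drives a quality-weighted Kalman filter.

All estimators report values inside 90-270 beats/min or flag the estimate
invalid; they never return out-of-range values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.regression.linear_model import burg

from .changepoint import ChangePointSet
from .detect import Events, slope_sum_detect
from .dtw import multiscale_dtw_score, resample_pulse
from .kalman import KalmanConfig, kalman_smooth
from .ppgi import ActivitySeries, PPGiSignal

__all__ = [
    "HR_RANGE", "BeatSeries", "ArModel", "VitalEstimate",
    "detect_beats", "score_beats", "hr_beat_counting", "hr_fft",
    "fit_ar", "ar_frequency_response", "hr_ar_dominant_pole",
    "hr_ar_best_model", "window_sqi", "kalman_smooth_estimates",
    "estimate_hr_series",
]

HR_RANGE = (90.0, 270.0)
WINDOW_S = 8.0
UPSLOPE_S = 0.150
REFRACTORY_S = 60.0 / HR_RANGE[1]
FFT_NPOINTS = 4096


@dataclass
class BeatSeries:
    """Detected beats with per-beat quality components.

    ``gates`` is an (n, 5) boolean array (activity, change-point, frequency
    bound, clipping, amplitude); combined SQI is zero whenever any gate
    fails, otherwise the DTW template-similarity score.
    """

    peak_times: np.ndarray
    onset_times: np.ndarray
    amplitudes: np.ndarray
    gates: np.ndarray = None
    dtw_scores: np.ndarray = None
    sqi: np.ndarray = None
    sample_rate: float = 20.0

    def __len__(self) -> int:
        return len(self.peak_times)

    @classmethod
    def from_events(cls, ev: Events) -> "BeatSeries":
        return cls(ev.peak_times, ev.onset_times, ev.amplitudes,
                   sample_rate=ev.sample_rate)


@dataclass
class VitalEstimate:
    """One per-second vital-sign estimate."""

    time: float
    value: float
    sqi: float = 0.0
    method: str = ""
    valid: bool = True
    fallback: bool = False
    extra: dict = field(default_factory=dict)


def _range_check(est: VitalEstimate, bounds=HR_RANGE) -> VitalEstimate:
    if est.valid and not (bounds[0] <= est.value <= bounds[1]):
        est.valid = False
    return est


# ---------------------------------------------------------------------------
# beat detection and quality
# ---------------------------------------------------------------------------

def detect_beats(filtered: PPGiSignal) -> BeatSeries:
    """Slope-sum beat detection on a cardiac-filtered PPGi signal.

    The upslope window is 150 ms (three samples at 20 frames/s) and the
    refractory period 222 ms, the beat period at 270 beats/min.
    """
    ev = slope_sum_detect(filtered.samples, filtered.sample_rate,
                          upslope_s=UPSLOPE_S, refractory_s=REFRACTORY_S,
                          valid=filtered.valid)
    return BeatSeries.from_events(ev)


def _clipped(segment: np.ndarray, min_run: int = 3) -> bool:
    """True if >= min_run consecutive samples sit at the segment extremum."""
    if len(segment) < min_run:
        return False
    for extremum in (segment.max(), segment.min()):
        at = np.abs(segment - extremum) < 1e-9 * max(1.0, abs(extremum))
        run = 0
        for flag in at:
            run = run + 1 if flag else 0
            if run >= min_run:
                return True
    return False


def score_beats(beats: BeatSeries, filtered: PPGiSignal,
                activity: ActivitySeries | None = None,
                changes: ChangePointSet | None = None,
                amplitude_band: tuple[float, float] = (0.25, 4.0),
                template_alpha: float = 0.1,
                template_reset_s: float = 10.0) -> BeatSeries:
    """Attach the five quality gates and the DTW similarity to each beat.

    Gates: (a) beat overlaps an active (high-motion) second; (b) beat within
    the exclusion margin of a detected step change; (c) instantaneous rate
    from the preceding inter-beat interval outside 90-270 beats/min;
    (d) clipping (three samples at the extremum within the beat);
    (e) amplitude outside ``amplitude_band`` times the running median of the
    last 15 accepted amplitudes.  Combined SQI = all-gates-pass x DTW score
    against an exponentially updated template of accepted beats.
    """
    n = len(beats)
    fs = filtered.sample_rate
    x = np.where(filtered.valid, filtered.samples, 0.0)
    gates = np.ones((n, 5), dtype=bool)
    dtw_scores = np.ones(n)
    accepted_amplitudes: list[float] = []
    template = None
    last_accept_time = -np.inf

    for k in range(n):
        peak_t = beats.peak_times[k]
        onset_t = beats.onset_times[k]
        # (a) activity
        if activity is not None:
            lo, hi = int(onset_t), int(peak_t) + 1
            gates[k, 0] = not any(activity.is_active_second(float(s))
                                  for s in range(lo, hi))
        # (b) step change
        if changes is not None:
            gates[k, 1] = not (changes.near(peak_t) or changes.near(onset_t))
        # (c) physiological frequency bound
        if k > 0:
            ibi = peak_t - beats.peak_times[k - 1]
            rate = 60.0 / ibi if ibi > 0 else np.inf
            gates[k, 2] = HR_RANGE[0] <= rate <= HR_RANGE[1]
        # beat segment: onset to next onset (or one median IBI)
        seg_end_t = beats.onset_times[k + 1] if k + 1 < n else peak_t + (peak_t - onset_t) + 0.2
        i0, i1 = int(round(onset_t * fs)), min(len(x), int(round(seg_end_t * fs)) + 1)
        segment = x[i0:i1]
        # (d) clipping
        if len(segment):
            gates[k, 3] = not _clipped(segment)
        # (e) amplitude consistency
        amp = beats.amplitudes[k]
        if len(accepted_amplitudes) >= 3:
            med = float(np.median(accepted_amplitudes[-15:]))
            gates[k, 4] = amplitude_band[0] * med <= amp <= amplitude_band[1] * med
        # DTW template similarity
        if len(segment) >= 4:
            pulse = resample_pulse(segment)
            if template is None or peak_t - last_accept_time > template_reset_s:
                template = pulse
                dtw_scores[k] = 1.0
            else:
                dtw_scores[k] = multiscale_dtw_score(pulse, template)
        if gates[k].all():
            accepted_amplitudes.append(float(amp))
            last_accept_time = peak_t
            if len(segment) >= 4:
                template = pulse if template is None \
                    else (1 - template_alpha) * template + template_alpha * pulse
    sqi = np.where(gates.all(axis=1), dtw_scores, 0.0)
    return BeatSeries(beats.peak_times, beats.onset_times, beats.amplitudes,
                      gates=gates, dtw_scores=dtw_scores, sqi=sqi,
                      sample_rate=beats.sample_rate)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _window_beats(beats: BeatSeries, t_end: float, window_s: float = WINDOW_S,
                  good_only: bool = True) -> np.ndarray:
    """Indices of beats whose peaks fall in the (nominal) window."""
    t0 = t_end - window_s
    sel = (beats.peak_times >= t0) & (beats.peak_times <= t_end)
    if good_only and beats.sqi is not None:
        sel &= beats.sqi > 0
    return np.flatnonzero(sel)


def hr_beat_counting(beats: BeatSeries, t_end: float,
                     window_s: float = WINDOW_S) -> VitalEstimate:
    """Beat-counting estimate over the window expanded to whole beats.

    The window is expanded to run exactly from the first to the last beat
    peak it contains; the rate is the number of complete inter-peak
    intervals (peaks - 1) over that expanded length.  Exact on periodic
    trains; invalid with fewer than two usable beats.
    """
    idx = _window_beats(beats, t_end, window_s)
    est = VitalEstimate(t_end, np.nan, method="count", valid=False)
    if len(idx) < 2:
        return est
    peaks = beats.peak_times[idx]
    l_exp = peaks[-1] - peaks[0]
    if l_exp <= 0:
        return est
    est.value = (len(peaks) - 1) * 60.0 / l_exp
    est.valid = True
    return _range_check(est)


def _window_samples(filtered: PPGiSignal, t_end: float,
                    window_s: float = WINDOW_S) -> tuple[np.ndarray, np.ndarray]:
    fs = filtered.sample_rate
    i1 = int(round(t_end * fs))
    i0 = max(0, i1 - int(round(window_s * fs)))
    return filtered.samples[i0:i1], filtered.valid[i0:i1]


def hr_fft(filtered: PPGiSignal, t_end: float, window_s: float = WINDOW_S,
           max_invalid_frac: float = 0.25) -> VitalEstimate:
    """Dominant-frequency estimate from a zero-padded FFT of the window."""
    x, valid = _window_samples(filtered, t_end, window_s)
    est = VitalEstimate(t_end, np.nan, method="fft", valid=False)
    if len(x) < window_s * filtered.sample_rate * 0.5:
        return est
    if (~valid).mean() > max_invalid_frac:
        return est
    xs = np.where(valid, x, 0.0)
    xs = xs - xs.mean()
    spec = np.abs(np.fft.rfft(xs, n=FFT_NPOINTS)) ** 2
    freqs = np.fft.rfftfreq(FFT_NPOINTS, d=1.0 / filtered.sample_rate)
    band = (freqs >= HR_RANGE[0] / 60.0) & (freqs <= HR_RANGE[1] / 60.0)
    if not band.any() or spec[band].max() <= 0:
        return est
    est.value = 60.0 * freqs[band][np.argmax(spec[band])]
    est.valid = True
    return _range_check(est)


@dataclass
class ArModel:
    """Autoregressive model fitted by Burg's method.

    ``coefficients`` are the polynomial a_0..a_p with a_0 = 1 such that the
    transfer function is ``1 / A(z)``; its roots are the poles.
    """

    order: int
    coefficients: np.ndarray
    noise_variance: float
    sample_rate: float

    @property
    def poles(self) -> np.ndarray:
        return np.roots(self.coefficients)

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Power spectrum S(f) = sigma_e^2 / |sum_k a_k e^{-i 2 pi f k}|^2."""
        f = np.asarray(freqs_hz, dtype=float) / self.sample_rate
        k = np.arange(self.order + 1)
        e = np.exp(-2j * np.pi * np.outer(f, k))
        denom = np.abs(e @ self.coefficients) ** 2
        return self.noise_variance / np.maximum(denom, 1e-300)

    def dominant_in_band_pole(self, band_hz: tuple[float, float]):
        """(frequency_hz, magnitude) of the largest-magnitude in-band pole."""
        lo = 2 * np.pi * band_hz[0] / self.sample_rate
        hi = 2 * np.pi * band_hz[1] / self.sample_rate
        angles = np.angle(self.poles)
        mags = np.abs(self.poles)
        sel = (angles >= lo) & (angles <= hi)
        if not sel.any():
            return None
        i = np.flatnonzero(sel)[np.argmax(mags[sel])]
        return angles[i] * self.sample_rate / (2 * np.pi), mags[i]


def fit_ar(samples: np.ndarray, order: int, sample_rate: float = 20.0) -> ArModel:
    """Fit an AR model by Burg's method to one window of samples."""
    x = np.asarray(samples, dtype=float)
    if len(x) <= 2 * order:
        raise ValueError(f"window of {len(x)} samples too short for AR order {order}")
    if np.ptp(x) == 0:
        raise ValueError("cannot fit an AR model to a constant signal")
    rho, sigma2 = burg(x, order=order, demean=True)
    coeff = np.concatenate([[1.0], -np.asarray(rho)])
    return ArModel(order, coeff, float(sigma2), sample_rate)


def ar_frequency_response(model: ArModel, freqs_hz: np.ndarray) -> np.ndarray:
    return model.frequency_response(freqs_hz)


_AR_BAND_GRID = None


def _band_grid(sample_rate: float) -> np.ndarray:
    # ~0.1 beats/min resolution over the cardiac band
    return np.linspace(HR_RANGE[0] / 60.0, HR_RANGE[1] / 60.0, 1800)


def hr_ar_dominant_pole(filtered: PPGiSignal, t_end: float,
                        window_s: float = WINDOW_S, order: int = 8,
                        min_pole_magnitude: float = 0.5,
                        max_invalid_frac: float = 0.25) -> VitalEstimate:
    """Rate from the dominant in-band pole of a fixed-order (8) AR model."""
    x, valid = _window_samples(filtered, t_end, window_s)
    est = VitalEstimate(t_end, np.nan, method="ar8", valid=False)
    if len(x) <= 2 * order or (~valid).mean() > max_invalid_frac:
        return est
    try:
        model = fit_ar(np.where(valid, x, 0.0), order, filtered.sample_rate)
    except ValueError:
        return est
    pole = model.dominant_in_band_pole((HR_RANGE[0] / 60.0, HR_RANGE[1] / 60.0))
    if pole is None or pole[1] < min_pole_magnitude:
        return est
    est.value = 60.0 * pole[0]
    est.valid = True
    est.extra["pole_magnitude"] = pole[1]
    return _range_check(est)


def hr_ar_best_model(filtered: PPGiSignal, t_end: float,
                     window_s: float = WINDOW_S,
                     orders: range = range(6, 13),
                     agreement_bpm: float = 1.0,
                     max_invalid_frac: float = 0.25) -> VitalEstimate:
    """AR best-model-order search over p = 6..12.

    For each order the dominant in-band pole frequency is compared with the
    argmax of the model's frequency response over the band; orders agreeing
    to within 1 beat/min are candidates and the candidate with the
    largest-magnitude dominant pole wins.  With no candidate the estimate
    falls back to the spectral peak of the order-8 model and is flagged.
    """
    x, valid = _window_samples(filtered, t_end, window_s)
    est = VitalEstimate(t_end, np.nan, method="arbest", valid=False)
    if len(x) <= 2 * max(orders) or (~valid).mean() > max_invalid_frac:
        return est
    xs = np.where(valid, x, 0.0)
    if np.ptp(xs) == 0:
        return est
    grid = _band_grid(filtered.sample_rate)
    band = (HR_RANGE[0] / 60.0, HR_RANGE[1] / 60.0)
    best = None  # (pole_magnitude, hr)
    fallback_model = None
    for p in orders:
        try:
            model = fit_ar(xs, p, filtered.sample_rate)
        except ValueError:
            continue
        if p == 8:
            fallback_model = model
        pole = model.dominant_in_band_pole(band)
        if pole is None:
            continue
        f_resp = grid[np.argmax(model.frequency_response(grid))]
        if abs(60.0 * pole[0] - 60.0 * f_resp) < agreement_bpm:
            if best is None or pole[1] > best[0]:
                best = (pole[1], 60.0 * pole[0])
    if best is not None:
        est.value = best[1]
        est.valid = True
        est.extra["pole_magnitude"] = best[0]
        return _range_check(est)
    if fallback_model is None:
        try:
            fallback_model = fit_ar(xs, 8, filtered.sample_rate)
        except ValueError:
            return est
    est.value = 60.0 * grid[np.argmax(fallback_model.frequency_response(grid))]
    est.valid = True
    est.fallback = True
    return _range_check(est)


def window_sqi(beats: BeatSeries, t_end: float, window_s: float = WINDOW_S) -> float:
    """Mean combined beat SQI over the window; 0 with no beats."""
    idx = _window_beats(beats, t_end, window_s, good_only=False)
    if len(idx) == 0 or beats.sqi is None:
        return 0.0
    return float(np.mean(beats.sqi[idx]))


def kalman_smooth_estimates(estimates: list[VitalEstimate],
                            config: KalmanConfig | None = None) -> list[VitalEstimate]:
    """Quality-weighted Kalman smoothing of a 1 Hz estimate series."""
    cfg = config or KalmanConfig(value_range=HR_RANGE)
    values = np.array([e.value if e.valid else np.nan for e in estimates])
    sqi = np.array([e.sqi for e in estimates])
    res = kalman_smooth(values, sqi, cfg)
    out = []
    for k, e in enumerate(estimates):
        out.append(VitalEstimate(e.time, res.values[k], res.sqi[k],
                                 method=e.method + "+kalman", valid=bool(res.valid[k]),
                                 extra={"variance": res.variances[k]}))
    return out


def estimate_hr_series(filtered: PPGiSignal, beats: BeatSeries,
                       method: str = "arbest", window_s: float = WINDOW_S,
                       smooth: bool = False) -> list[VitalEstimate]:
    """Heart rate on a 1 Hz grid (window end stamps, first after 8 s)."""
    duration = len(filtered) / filtered.sample_rate
    out = []
    for t_end in np.arange(window_s, np.floor(duration) + 1e-9, 1.0):
        if method == "count":
            est = hr_beat_counting(beats, t_end, window_s)
        elif method == "fft":
            est = hr_fft(filtered, t_end, window_s)
        elif method == "ar8":
            est = hr_ar_dominant_pole(filtered, t_end, window_s)
        elif method == "arbest":
            est = hr_ar_best_model(filtered, t_end, window_s)
        else:
            raise ValueError(f"unknown method {method!r}")
        est.sqi = window_sqi(beats, t_end, window_s)
        out.append(est)
    return kalman_smooth_estimates(out) if smooth else out
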