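"""Twelve-channel respiratory-rate estimation from frames and skin masks.

Breathing moves the chest and abdomen, which modulates both the colour of
the skin region (blood-volume effects in the PPGi channels) and its shape.
Twelve respiratory signals are extracted per frame in three groups:

* group 1: the raw PPGi means of the red, green and blue planes;
* group 2: area, perimeter, centroid-x, centroid-y of the whole skin label;
* group 3: major axis, minor axis, orientation, eccentricity and area of an
  ellipse fitted (by matching second central moments) to the largest
  connected skin region.

Each signal is band-limited to 0.3-2.0 Hz, breaths are detected twice
(mean-average-curve and boxed-slope-sum detectors), quality is scored per
10 s window (zero whenever the two detectors disagree on the breath count),
rate is estimated by counting over the expanded window, and the twelve
per-channel series are fused with quality-weighted Kalman filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .detect import Events, mac_detect, slope_sum_detect
from .dtw import multiscale_dtw_score, resample_pulse
from .filters import filter_respiratory
from .kalman import KalmanConfig, KalmanResult, fuse_channels
from .ppgi import ActivitySeries, PPGiSignal
from .cardiac import VitalEstimate

__all__ = [
    "RR_RANGE", "RESP_CHANNELS", "EllipseFit", "fit_ellipse",
    "extract_resp_signals", "detect_breaths_mac", "detect_breaths_bssf",
    "score_breaths", "resp_window_sqi", "rr_estimate",
    "estimate_rr_channel", "fuse_rr", "estimate_rr_series",
]

RR_RANGE = (18.0, 120.0)
RR_WINDOW_S = 10.0
BSSF_UPSLOPE_S = 0.300
BREATH_REFRACTORY_S = 0.5

RESP_CHANNELS = (
    "ppgi_red", "ppgi_green", "ppgi_blue",
    "skin_area", "skin_perimeter", "skin_centroid_x", "skin_centroid_y",
    "ellipse_major", "ellipse_minor", "ellipse_orientation",
    "ellipse_eccentricity", "ellipse_area",
)


@dataclass
class EllipseFit:
    """Ellipse with the same second central moments as a pixel region."""

    centre: tuple[float, float]     # (x, y) px
    major: float                    # full major axis length, px
    minor: float                    # full minor axis length, px
    orientation: float              # radians in (-pi/2, pi/2]
    eccentricity: float
    area: float                     # pi * (major/2) * (minor/2)
    valid: bool = True

    @classmethod
    def invalid(cls) -> "EllipseFit":
        return cls((np.nan, np.nan), np.nan, np.nan, np.nan, np.nan, np.nan, False)


def fit_ellipse(mask: np.ndarray, min_pixels: int = 5) -> EllipseFit:
    """Moment-matching ellipse fit to the largest connected skin region.

    Axis lengths are ``4 * sqrt(eigenvalue)`` of the central second-moment
    matrix (the full axes of the moment-equivalent ellipse); the orientation
    is the principal-axis angle measured from the +x (column) direction,
    wrapped to (-pi/2, pi/2].
    """
    mask = np.asarray(mask, dtype=bool)
    if np.count_nonzero(mask) < min_pixels:
        return EllipseFit.invalid()
    labels = measure.label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    ys, xs = np.nonzero(labels == largest)
    if len(xs) < min_pixels:
        return EllipseFit.invalid()
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    # + 1/12: each pixel is a unit square, not a point
    mxx = np.mean(dx * dx) + 1.0 / 12.0
    myy = np.mean(dy * dy) + 1.0 / 12.0
    mxy = np.mean(dx * dy)
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)
    minor = 4.0 * np.sqrt(max(evals[0], 0.0))
    major = 4.0 * np.sqrt(max(evals[1], 0.0))
    v = evecs[:, 1]  # principal eigenvector (x, y)
    orientation = np.arctan2(v[1], v[0])
    if orientation <= -np.pi / 2:
        orientation += np.pi
    elif orientation > np.pi / 2:
        orientation -= np.pi
    ecc = np.sqrt(max(0.0, 1.0 - (minor / major) ** 2)) if major > 0 else 0.0
    return EllipseFit((cx, cy), major, minor, orientation, ecc,
                      np.pi * (major / 2.0) * (minor / 2.0))


def extract_resp_signals(frames, masks, ppgi: dict[str, PPGiSignal] | None = None,
                         sample_rate: float | None = None) -> dict[str, PPGiSignal]:
    """All twelve respiratory channels; empty-mask frames are invalid in all.

    ``ppgi`` may carry pre-extracted per-channel PPGi signals (to avoid a
    second pass over the frames); otherwise they are computed here.
    """
    if sample_rate is None:
        sample_rate = getattr(getattr(frames, "config", None), "frame_rate", 20.0)
    shape_keys = RESP_CHANNELS[3:]
    series: dict[str, list[float]] = {k: [] for k in shape_keys}
    need_ppgi = ppgi is None
    if need_ppgi:
        ppgi_vals: dict[str, list[float]] = {k: [] for k in RESP_CHANNELS[:3]}
    for frame, mask in zip(frames, masks):
        mask = np.asarray(mask, dtype=bool)
        n_skin = int(np.count_nonzero(mask))
        if need_ppgi:
            pixels = getattr(frame, "pixels", frame)
            for name, ch in zip(RESP_CHANNELS[:3], range(3)):
                ppgi_vals[name].append(
                    np.nan if n_skin == 0 else float(pixels[..., ch][mask].sum() / n_skin))
        if n_skin == 0:
            for k in shape_keys:
                series[k].append(np.nan)
            continue
        ys, xs = np.nonzero(mask)
        series["skin_area"].append(float(n_skin))
        series["skin_perimeter"].append(float(measure.perimeter(mask)))
        series["skin_centroid_x"].append(float(xs.mean()))
        series["skin_centroid_y"].append(float(ys.mean()))
        ell = fit_ellipse(mask)
        series["ellipse_major"].append(ell.major)
        series["ellipse_minor"].append(ell.minor)
        series["ellipse_orientation"].append(ell.orientation)
        series["ellipse_eccentricity"].append(ell.eccentricity)
        series["ellipse_area"].append(ell.area)
    out: dict[str, PPGiSignal] = {}
    if need_ppgi:
        for name in RESP_CHANNELS[:3]:
            out[name] = PPGiSignal(np.array(ppgi_vals[name]), sample_rate, channel=name)
    else:
        for name in RESP_CHANNELS[:3]:
            out[name] = ppgi[name.replace("ppgi_", "")] if name.replace("ppgi_", "") in ppgi \
                else ppgi[name]
    for k in shape_keys:
        out[k] = PPGiSignal(np.array(series[k]), sample_rate, channel=k)
    # a frame invalid in one channel is invalid in all twelve
    common_valid = np.logical_and.reduce([out[k].valid for k in RESP_CHANNELS])
    for k in RESP_CHANNELS:
        out[k].valid = common_valid.copy()
    return out


# ---------------------------------------------------------------------------
# breath detection and quality
# ---------------------------------------------------------------------------

def detect_breaths_mac(signal: PPGiSignal, mac_window_s: float = 2.0) -> Events:
    """Mean-average-curve breath detector (2 s MAC, 500 ms refractory)."""
    return mac_detect(signal.samples, signal.sample_rate,
                      mac_window_s=mac_window_s,
                      refractory_s=BREATH_REFRACTORY_S, valid=signal.valid)


def detect_breaths_bssf(signal: PPGiSignal) -> Events:
    """Boxed slope-sum breath detector (300 ms upslope, 500 ms refractory)."""
    return slope_sum_detect(signal.samples, signal.sample_rate,
                            upslope_s=BSSF_UPSLOPE_S,
                            refractory_s=BREATH_REFRACTORY_S,
                            valid=signal.valid)


def score_breaths(events: Events, signal: PPGiSignal,
                  activity: ActivitySeries | None = None,
                  template_alpha: float = 0.1) -> np.ndarray:
    """Per-breath SQI: activity gate x range gate x DTW template similarity."""
    n = len(events)
    x = np.where(signal.valid, signal.samples, 0.0)
    fs = signal.sample_rate
    scores = np.zeros(n)
    template = None
    for k in range(n):
        peak_t = events.peak_times[k]
        onset_t = events.onset_times[k]
        if activity is not None and any(
                activity.is_active_second(float(s))
                for s in range(int(onset_t), int(peak_t) + 1)):
            continue
        if k > 0:
            interval = peak_t - events.peak_times[k - 1]
            rate = 60.0 / interval if interval > 0 else np.inf
            if not (RR_RANGE[0] <= rate <= RR_RANGE[1]):
                continue
        end_t = events.onset_times[k + 1] if k + 1 < n else peak_t + (peak_t - onset_t)
        i0, i1 = int(round(onset_t * fs)), min(len(x), int(round(end_t * fs)) + 1)
        segment = x[i0:i1]
        if len(segment) < 4:
            continue
        pulse = resample_pulse(segment)
        if template is None:
            template = pulse
            scores[k] = 1.0
        else:
            scores[k] = multiscale_dtw_score(pulse, template)
            template = (1 - template_alpha) * template + template_alpha * pulse
    return scores


def _count_in_window(events: Events, t0: float, t1: float) -> np.ndarray:
    return np.flatnonzero((events.peak_times >= t0) & (events.peak_times <= t1))


def resp_window_sqi(t_end: float, mac_events: Events, bssf_events: Events,
                    breath_scores: np.ndarray,
                    window_s: float = RR_WINDOW_S) -> float:
    """Window SQI; zero whenever the two detectors disagree on breath count."""
    t0 = t_end - window_s
    mac_idx = _count_in_window(mac_events, t0, t_end)
    bssf_idx = _count_in_window(bssf_events, t0, t_end)
    if len(mac_idx) != len(bssf_idx) or len(mac_idx) == 0:
        return 0.0
    return float(np.mean(breath_scores[mac_idx]))


def rr_estimate(events: Events, t_end: float, window_s: float = RR_WINDOW_S,
                sqi: float = 0.0, channel: str = "") -> VitalEstimate:
    """Counting estimate over the window expanded to whole breaths."""
    idx = _count_in_window(events, t_end - window_s, t_end)
    est = VitalEstimate(t_end, np.nan, sqi=sqi, method=f"count:{channel}", valid=False)
    if len(idx) < 2:
        return est
    peaks = events.peak_times[idx]
    span = peaks[-1] - peaks[0]
    if span <= 0:
        return est
    est.value = (len(peaks) - 1) * 60.0 / span
    est.valid = RR_RANGE[0] <= est.value <= RR_RANGE[1]
    return est


def estimate_rr_channel(signal: PPGiSignal, activity: ActivitySeries | None = None,
                        window_s: float = RR_WINDOW_S,
                        prefiltered: bool = False) -> list[VitalEstimate]:
    """Per-channel respiratory rate on a 1 Hz grid (first estimate at 10 s)."""
    if prefiltered:
        filt = signal
    else:
        samples, valid = filter_respiratory(signal.samples, signal.sample_rate,
                                            valid=signal.valid)
        filt = PPGiSignal(samples, signal.sample_rate, channel=signal.channel,
                          valid=valid)
    mac = detect_breaths_mac(filt)
    bssf = detect_breaths_bssf(filt)
    scores = score_breaths(mac, filt, activity)
    duration = len(filt) / filt.sample_rate
    out = []
    for t_end in np.arange(window_s, np.floor(duration) + 1e-9, 1.0):
        sqi = resp_window_sqi(t_end, mac, bssf, scores, window_s)
        est = rr_estimate(mac, t_end, window_s, sqi=sqi, channel=signal.channel)
        out.append(est)
    return out


def fuse_rr(channel_estimates: dict[str, list[VitalEstimate]],
            config: KalmanConfig | None = None) -> list[VitalEstimate]:
    """Fuse per-channel RR series with one Kalman filter per channel.

    Channel posteriors are combined with weights ``sqi / posterior_variance``
    over channels with positive SQI; a second with no positive-SQI channel is
    invalid.
    """
    cfg = config or KalmanConfig(value_range=RR_RANGE)
    names = list(channel_estimates)
    n = min(len(v) for v in channel_estimates.values())
    values = np.array([[channel_estimates[c][t].value
                        if channel_estimates[c][t].valid else np.nan
                        for t in range(n)] for c in names])
    sqis = np.array([[channel_estimates[c][t].sqi for t in range(n)] for c in names])
    fused: KalmanResult = fuse_channels(values, sqis, cfg)
    t0 = channel_estimates[names[0]][0].time
    out = []
    for t in range(n):
        out.append(VitalEstimate(t0 + t, fused.values[t], fused.sqi[t],
                                 method="fused", valid=bool(fused.valid[t]),
                                 extra={"variance": fused.variances[t]}))
    return out


def estimate_rr_series(signals: dict[str, PPGiSignal],
                       activity: ActivitySeries | None = None,
                       window_s: float = RR_WINDOW_S) -> tuple[list[VitalEstimate], dict]:
    """Full twelve-channel pipeline: filter, detect, score, count, fuse."""
    per_channel = {}
    for name in RESP_CHANNELS:
        if name not in signals:
            raise ValueError(f"missing respiratory channel {name!r}")
        try:
            per_channel[name] = estimate_rr_channel(signals[name], activity, window_s)
        except ValueError:
            # channel unusable end-to-end (e.g. all-constant orientation)
            duration = len(signals[name]) / signals[name].sample_rate
            per_channel[name] = [
                VitalEstimate(t, np.nan, 0.0, method=f"count:{name}", valid=False)
                for t in np.arange(window_s, np.floor(duration) + 1e-9, 1.0)]
    return fuse_rr(per_channel), per_channel
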