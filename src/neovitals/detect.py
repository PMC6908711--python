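"""Pulse peak/onset detectors shared by the cardiac and respiratory stages.

``slope_sum_detect`` implements the boxed slope-sum function (BSSF) detector:
the signal is transformed to a windowed sum of positive slopes which
emphasises pulse upslopes, and onsets are found by an adaptive threshold
with a refractory period.  For cardiac PPGi the upslope window is 150 ms
(three samples at 20 frames/s) with a 222 ms refractory (270 beats/min);
for respiratory signals the upslope window is 300 ms with a 500 ms
refractory.  ``mac_detect`` is the mean-average-curve detector: breath
onsets are upward crossings of the signal through its 2 s centred moving
average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Events", "slope_sum", "slope_sum_detect", "mac_detect"]


@dataclass
class Events:
    """Detected pulse events: paired onset and peak times (s) and amplitudes."""

    onset_times: np.ndarray
    peak_times: np.ndarray
    onset_values: np.ndarray
    peak_values: np.ndarray
    sample_rate: float

    def __len__(self) -> int:
        return len(self.peak_times)

    @property
    def amplitudes(self) -> np.ndarray:
        return self.peak_values - self.onset_values


def slope_sum(x: np.ndarray, window: int) -> np.ndarray:
    """Windowed sum of positive first differences (the BSSF transform)."""
    dx = np.diff(x, prepend=x[:1])
    up = np.maximum(dx, 0.0)
    c = np.cumsum(up)
    out = c.copy()
    out[window:] = c[window:] - c[:-window]
    return out


def slope_sum_detect(samples: np.ndarray, sample_rate: float,
                     upslope_s: float = 0.150, refractory_s: float = 60.0 / 270.0,
                     valid: np.ndarray | None = None,
                     init_s: float = 2.0) -> Events:
    """Onset/peak detection on a band-limited pulsatile signal.

    The adaptive threshold is initialised from the first ``init_s`` seconds
    of the slope-sum transform and updated with a decaying rule after each
    accepted pulse; between pulses it decays exponentially so the detector
    recovers after amplitude drops.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if valid is None:
        valid = np.isfinite(x)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(x)
    empty = Events(np.array([]), np.array([]), np.array([]), np.array([]), sample_rate)
    if n == 0 or not valid.any():
        return empty
    xs = np.where(valid, x, 0.0)
    w = int(np.ceil(upslope_s * sample_rate))
    ssf = slope_sum(xs, w)
    init = int(min(n, round(init_s * sample_rate)))
    base = ssf[:init][valid[:init]]
    if len(base) == 0 or base.max() <= 0:
        ref = ssf[valid].max() if ssf[valid].size else 0.0
    else:
        ref = np.percentile(base, 90)
    if ref <= 0:
        return empty
    threshold = 0.6 * ref
    floor = 1e-9 * max(ref, 1.0)
    refractory = int(round(refractory_s * sample_rate))
    decay = np.exp(-1.0 / (2.0 * sample_rate))  # 2 s time constant

    onsets, peaks = [], []
    i = 1
    last_onset = -10 ** 9
    armed = ssf[0] <= threshold  # re-arms whenever the slope sum dips below
    while i < n:
        if not valid[i]:
            i += 1
            continue
        if ssf[i] <= threshold:
            armed = True
        if ssf[i] > threshold and armed and i - last_onset >= refractory:
            onset = i
            # local slope-sum maximum after the crossing
            j = i
            search_end = min(n, i + 3 * w)
            while j + 1 < search_end and ssf[j + 1] >= ssf[j]:
                j += 1
            # signal peak: local maximum around the end of the upslope
            k_end = min(n, j + w + 2)
            seg = xs[onset:k_end]
            if len(seg) == 0:
                i += 1
                continue
            peak = onset + int(np.argmax(seg))
            # onset refined to the local signal minimum just before threshold crossing
            back = max(0, onset - w)
            onset_ref = back + int(np.argmin(xs[back:onset + 1]))
            onsets.append(onset_ref)
            peaks.append(peak)
            last_onset = onset
            threshold = 0.7 * threshold + 0.3 * (0.6 * ssf[j])
            armed = False
            i = max(i + 1, j)
        else:
            if i - last_onset > 2 * refractory:
                threshold = max(threshold * decay, floor)
            i += 1
    onsets = np.array(onsets, dtype=int)
    peaks = np.array(peaks, dtype=int)
    # enforce strictly increasing peak times
    if len(peaks) > 1:
        keep = np.concatenate([[True], np.diff(peaks) > 0])
        onsets, peaks = onsets[keep], peaks[keep]
    return Events(onsets / sample_rate, peaks / sample_rate,
                  xs[onsets] if len(onsets) else np.array([]),
                  xs[peaks] if len(peaks) else np.array([]), sample_rate)


def mac_detect(samples: np.ndarray, sample_rate: float,
               mac_window_s: float = 2.0, refractory_s: float = 0.5,
               valid: np.ndarray | None = None) -> Events:
    """Mean-average-curve breath detector.

    The MAC is a centred moving average of the signal; a breath onset is an
    upward crossing of the signal through the MAC and its peak the signal
    maximum before the next downward crossing.  Crossings closer than the
    refractory period to the previous onset are suppressed.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if valid is None:
        valid = np.isfinite(x)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(x)
    xs = np.where(valid, x, 0.0)
    w = max(3, int(round(mac_window_s * sample_rate)) | 1)  # odd length
    kernel = np.ones(w) / w
    mac = np.convolve(xs, kernel, mode="same")
    above = xs > mac
    refractory = int(round(refractory_s * sample_rate))
    onsets, peaks = [], []
    last_onset = -10 ** 9
    i = 1
    while i < n:
        if valid[i] and above[i] and not above[i - 1] and i - last_onset >= refractory:
            # downward crossing ends the breath plateau
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            peak = i + int(np.argmax(xs[i:j + 1]))
            # breath must rise measurably above the MAC to count
            if xs[peak] - mac[peak] > 1e-12:
                onsets.append(i)
                peaks.append(peak)
                last_onset = i
            i = j + 1
        else:
            i += 1
    onsets = np.array(onsets, dtype=int)
    peaks = np.array(peaks, dtype=int)
    return Events(onsets / sample_rate, peaks / sample_rate,
                  xs[onsets] if len(onsets) else np.array([]),
                  xs[peaks] if len(peaks) else np.array([]), sample_rate)
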