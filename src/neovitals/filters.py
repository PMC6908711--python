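"""FIR filtering cascades for the cardiac and respiratory bands.

The cardiac cascade is a 40th-order low-pass at 4.5 Hz followed by a
60th-order high-pass at 1.5 Hz (90-270 beats/min); the respiratory cascade a
100th-order high-pass at 0.3 Hz followed by an 80th-order low-pass at 2.0 Hz
(18-120 breaths/min).  Filters are windowed-sinc (Hamming) designs; the
output is shifted by the cascade group delay so it stays time-aligned with
the input.  Signals may carry invalid samples (e.g. frames where no skin was
visible): gaps up to ``max_bridge_s`` are bridged by linear interpolation,
longer gaps split the signal into independently filtered segments so filter
ringing cannot leak across an absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterCascade",
    "cardiac_cascade",
    "respiratory_cascade",
    "filter_cardiac",
    "filter_respiratory",
]

CARDIAC_BAND_HZ = (1.5, 4.5)
RESPIRATORY_BAND_HZ = (0.3, 2.0)


@dataclass
class FilterCascade:
    """Two FIR stages applied in series with group-delay compensation."""

    taps: list        # list of tap arrays
    sample_rate: float

    @property
    def group_delay_samples(self) -> int:
        return sum((len(t) - 1) // 2 for t in self.taps)

    @property
    def total_length(self) -> int:
        return sum(len(t) - 1 for t in self.taps) + 1

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex response of the cascade at the given frequencies."""
        w = 2 * np.pi * np.asarray(freqs_hz, dtype=float) / self.sample_rate
        h = np.ones_like(w, dtype=complex)
        for taps in self.taps:
            _, hi = sps.freqz(taps, worN=w)
            h *= hi
        return h

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Filter one contiguous segment (already detrended), delay-compensated."""
        y = np.asarray(x, dtype=float)
        for taps in self.taps:
            y = sps.lfilter(taps, 1.0, y)
        d = self.group_delay_samples
        out = np.empty_like(y)
        out[: len(y) - d] = y[d:]
        out[len(y) - d:] = y[-1] if len(y) else 0.0
        return out


def cardiac_cascade(sample_rate: float = 20.0) -> FilterCascade:
    """Low-pass order 40 at 4.5 Hz + high-pass order 60 at 1.5 Hz."""
    lp = sps.firwin(41, 4.5, fs=sample_rate)
    hp = sps.firwin(61, 1.5, fs=sample_rate, pass_zero=False)
    return FilterCascade([lp, hp], sample_rate)


def respiratory_cascade(sample_rate: float = 20.0) -> FilterCascade:
    """High-pass order 100 at 0.3 Hz + low-pass order 80 at 2.0 Hz."""
    hp = sps.firwin(101, 0.3, fs=sample_rate, pass_zero=False)
    lp = sps.firwin(81, 2.0, fs=sample_rate)
    return FilterCascade([hp, lp], sample_rate)


def valid_segments(valid: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of usable samples.

    Invalid runs of length <= ``max_gap`` are absorbed (to be bridged by
    interpolation); longer runs split the signal.
    """
    valid = np.asarray(valid, dtype=bool)
    n = len(valid)
    segments: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        start = i
        j = i
        while j < n:
            if valid[j]:
                j += 1
                continue
            k = j
            while k < n and not valid[k]:
                k += 1
            if k - j <= max_gap and k < n:
                j = k
                continue
            break
        segments.append((start, j))
        i = j
    return segments


def _bridge(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation over the (short) invalid samples of a segment."""
    if valid.all():
        return x.astype(float)
    idx = np.arange(len(x))
    out = x.astype(float).copy()
    out[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    return out


def _filter_with_gaps(samples: np.ndarray, valid: np.ndarray,
                      cascade: FilterCascade, max_bridge_s: float) -> tuple[np.ndarray, np.ndarray]:
    samples = np.asarray(samples, dtype=float)
    valid = np.ones(len(samples), dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    valid = valid & np.isfinite(samples)
    max_gap = int(round(max_bridge_s * cascade.sample_rate))
    out = np.zeros_like(samples, dtype=float)
    out_valid = np.zeros(len(samples), dtype=bool)
    any_segment = False
    for start, stop in valid_segments(valid, max_gap):
        seg = _bridge(samples[start:stop], valid[start:stop])
        if len(seg) < cascade.total_length:
            continue
        any_segment = True
        seg = sps.detrend(seg, type="linear")
        out[start:stop] = cascade.apply(seg)
        out_valid[start:stop] = valid[start:stop]
        # edge transients: the filter start-up occupies the first
        # total_length-1-delay samples after delay compensation, and the
        # last delay samples never receive filtered data
        d = cascade.group_delay_samples
        head = cascade.total_length - 1 - d
        out_valid[start: min(stop, start + head)] = False
        out_valid[max(start, stop - d): stop] = False
    if not any_segment and valid.any():
        raise ValueError(
            f"no contiguous run of at least {cascade.total_length} samples: "
            "signal too short for the filter cascade"
        )
    return out, out_valid


def filter_cardiac(samples: np.ndarray, sample_rate: float = 20.0,
                   valid: np.ndarray | None = None,
                   max_bridge_s: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Detrend + band-limit a PPGi signal to the cardiac band (1.5-4.5 Hz).

    Returns ``(filtered, valid)``; invalid input samples stay invalid.
    """
    return _filter_with_gaps(samples, valid, cardiac_cascade(sample_rate), max_bridge_s)


def filter_respiratory(samples: np.ndarray, sample_rate: float = 20.0,
                       valid: np.ndarray | None = None,
                       max_bridge_s: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Detrend + band-limit a respiratory signal to 0.3-2.0 Hz."""
    return _filter_with_gaps(samples, valid, respiratory_cascade(sample_rate), max_bridge_s)
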