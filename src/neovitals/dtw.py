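"""Small dynamic-time-warping distance for beat/breath template matching.

Pulses are resampled to a fixed short length (25 samples) before comparison,
so a dense O(n*m) dynamic programme is cheap.  The multi-scale score
averages the length-normalised distance over the full-resolution pair and a
half-resolution pair, then maps distance to a [0, 1] similarity via
``exp(-d / tau)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dtw_distance", "resample_pulse", "multiscale_dtw_score"]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Length-normalised DTW distance with absolute-difference local cost."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return np.inf
    prev = np.full(m + 1, np.inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = np.full(m + 1, np.inf)
        cost = np.abs(a[i - 1] - b)
        for j in range(1, m + 1):
            cur[j] = cost[j - 1] + min(prev[j], prev[j - 1], cur[j - 1])
        prev = cur
    return float(prev[m] / (n + m))


def resample_pulse(x: np.ndarray, length: int = 25) -> np.ndarray:
    """Resample to a fixed length and normalise amplitude (zero mean, unit sd)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return np.zeros(length)
    t = np.linspace(0.0, 1.0, len(x))
    ti = np.linspace(0.0, 1.0, length)
    y = np.interp(ti, t, x)
    sd = y.std()
    return (y - y.mean()) / sd if sd > 0 else y - y.mean()


def multiscale_dtw_score(pulse: np.ndarray, template: np.ndarray,
                         tau: float = 0.35) -> float:
    """Similarity in [0, 1] between a normalised pulse and the running template.

    Averages the normalised DTW distance at scales {1, 1/2} and maps it
    through ``exp(-d / tau)``; identical shapes score 1.
    """
    d_full = dtw_distance(pulse, template)
    d_half = dtw_distance(pulse[::2], template[::2])
    d = 0.5 * (d_full + d_half)
    return float(np.exp(-d / tau))
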