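"""Quality-weighted scalar Kalman filtering and multi-channel fusion.

Vital-sign estimates arrive on a 1 Hz grid with a signal-quality index (SQI)
in [0, 1].  Each series is smoothed by a random-walk Kalman filter whose
measurement variance is inflated as quality drops (``r / max(sqi, floor)^2``);
measurements below a quality threshold are treated as missing (prediction
only, growing variance).  Multi-channel fusion runs one filter per channel
and combines posteriors with SQI-and-precision weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KalmanConfig", "KalmanResult", "kalman_smooth", "fuse_channels"]


@dataclass
class KalmanConfig:
    process_var: float = 4.0       # (units/min)^2 per second random-walk drift
    measurement_var: float = 4.0
    sqi_floor: float = 0.05
    missing_below: float = 0.3     # SQI below this => prediction only
    value_range: tuple[float, float] = (90.0, 270.0)


@dataclass
class KalmanResult:
    values: np.ndarray
    variances: np.ndarray
    sqi: np.ndarray
    valid: np.ndarray


def kalman_smooth(values: np.ndarray, sqi: np.ndarray,
                  config: KalmanConfig | None = None) -> KalmanResult:
    """Random-walk Kalman filter over a 1 Hz estimate series.

    ``values`` may contain NaN (no estimate); those and low-SQI seconds are
    prediction-only steps.  Output values are clipped to the physiological
    range; a second is valid once at least one measurement has been absorbed.
    """
    cfg = config or KalmanConfig()
    z = np.asarray(values, dtype=float)
    s = np.clip(np.asarray(sqi, dtype=float), 0.0, 1.0)
    n = len(z)
    out = np.full(n, np.nan)
    var = np.full(n, np.nan)
    out_sqi = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    x = np.nan
    p = np.nan
    for t in range(n):
        have_meas = np.isfinite(z[t]) and s[t] >= cfg.missing_below
        if not np.isfinite(x):
            if have_meas:
                x = z[t]
                p = cfg.measurement_var / max(s[t], cfg.sqi_floor) ** 2
                out[t] = np.clip(x, *cfg.value_range)
                var[t], out_sqi[t], valid[t] = p, s[t], True
            continue
        p = p + cfg.process_var
        if have_meas:
            r = cfg.measurement_var / max(s[t], cfg.sqi_floor) ** 2
            k = p / (p + r)
            x = x + k * (z[t] - x)
            p = (1.0 - k) * p
            out_sqi[t] = s[t]
        out[t] = np.clip(x, *cfg.value_range)
        var[t] = p
        valid[t] = True
    return KalmanResult(out, var, out_sqi, valid)


def fuse_channels(values: np.ndarray, sqis: np.ndarray,
                  config: KalmanConfig | None = None) -> KalmanResult:
    """Fuse multiple 1 Hz estimate series into one.

    ``values`` and ``sqis`` are (n_channels, n_seconds).  Each channel is
    Kalman-filtered independently; the fused value per second is the
    SQI-and-precision weighted mean of channel posteriors, with weights
    ``w_i = sqi_i / posterior_variance_i`` over channels with positive SQI.
    Seconds where every channel has zero SQI are invalid.
    """
    cfg = config or KalmanConfig()
    values = np.atleast_2d(np.asarray(values, dtype=float))
    sqis = np.atleast_2d(np.asarray(sqis, dtype=float))
    n_ch, n = values.shape
    results = [kalman_smooth(values[i], sqis[i], cfg) for i in range(n_ch)]
    fused = np.full(n, np.nan)
    fused_var = np.full(n, np.nan)
    fused_sqi = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    for t in range(n):
        ws, xs, ss, vs = [], [], [], []
        for r in results:
            if r.valid[t] and r.sqi[t] > 0 and np.isfinite(r.values[t]):
                w = r.sqi[t] / max(r.variances[t], 1e-9)
                ws.append(w)
                xs.append(r.values[t])
                ss.append(r.sqi[t])
                vs.append(r.variances[t])
        if not ws:
            continue
        ws = np.array(ws)
        fused[t] = float(np.dot(ws, xs) / ws.sum())
        fused_var[t] = float(1.0 / np.sum(ws / np.array(vs)))
        fused_sqi[t] = float(np.dot(ws, ss) / ws.sum())
        valid[t] = True
    return KalmanResult(fused, fused_var, fused_sqi, valid)
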