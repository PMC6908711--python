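"""Gold-standard reference vitals from patient-monitor waveforms.

Monitor heart rates from ECG and pulse oximetry disagree during motion and
clinical events, so neither alone is a usable reference.  The reference
heart rate is the mean of the two 1 Hz numerics on seconds where they agree
to within 5 beats/min and both waveform SQIs exceed 0.5.  The reference
respiratory rate fuses four respiration signals (three ECG surrogates - EDR,
RSA, RPA - plus impedance pneumography) through two independent methods
(breath counting and AR dominant pole); it is valid when the two fused
method estimates differ by less than 5 breaths/min, and equals their mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate
from scipy import signal as sps

from .cardiac import fit_ar
from .detect import mac_detect, slope_sum_detect
from .kalman import KalmanConfig, fuse_channels
from .ppgi import PPGiSignal

__all__ = [
    "ReferenceVital", "detect_r_peaks", "ecg_sqi", "ppg_sqi",
    "reference_hr", "derive_resp_surrogates", "reference_rr",
    "sliding_sqi",
]

REF_RR_BAND_HZ = (0.3, 2.0)
SURROGATE_FS = 4.0
HR_AGREEMENT_BPM = 5.0     # "did not differ by more than 5"  (<=)
RR_AGREEMENT_BRPM = 5.0    # "less than 5"                    (<)
SQI_THRESHOLD = 0.5        # "greater than 0.5"               (>)


@dataclass
class ReferenceVital:
    """1 Hz reference series with constituent values retained."""

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    constituents: dict


# ---------------------------------------------------------------------------
# waveform SQIs
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float = 500.0) -> np.ndarray:
    """R-peak times (s) by the slope-sum detector tuned to QRS upslopes."""
    ev = slope_sum_detect(np.asarray(ecg, dtype=float), fs,
                          upslope_s=0.03, refractory_s=60.0 / 270.0)
    return ev.peak_times


def _derivative_qrs_detector(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Independent QRS detector: squared derivative, integration, peak picking."""
    x = np.asarray(ecg, dtype=float)
    d = np.gradient(x) * fs
    energy = d ** 2
    w = max(1, int(round(0.04 * fs)))
    integ = np.convolve(energy, np.ones(w) / w, mode="same")
    # QRS complexes concentrate derivative energy far above the baseline;
    # a robust noise-referenced threshold keeps this detector quiet on
    # broadband noise, where the energy envelope never leaves the bulk of
    # its own distribution
    med = np.median(integ)
    mad = np.median(np.abs(integ - med))
    height = med + 8.0 * mad
    peaks, _ = sps.find_peaks(integ, height=height,
                              distance=max(1, int(round(60.0 / 270.0 * fs))))
    # refine to the local signal maximum (the R peak itself)
    half = max(1, int(round(0.05 * fs)))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    return np.unique(refined) / fs


def _match_f1(a: np.ndarray, b: np.ndarray, tol_s: float = 0.150) -> float:
    """F1 score of greedy one-to-one event matching within a tolerance."""
    if len(a) == 0 and len(b) == 0:
        return 1.0
    if len(a) == 0 or len(b) == 0:
        return 0.0
    used = np.zeros(len(b), dtype=bool)
    tp = 0
    for t in a:
        i = np.searchsorted(b, t)
        best, best_d = -1, tol_s
        for j in (i - 1, i):
            if 0 <= j < len(b) and not used[j] and abs(b[j] - t) <= best_d:
                best, best_d = j, abs(b[j] - t)
        if best >= 0:
            used[best] = True
            tp += 1
    precision = tp / len(a)
    recall = tp / len(b)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def ecg_sqi(ecg_window: np.ndarray, fs: float = 500.0) -> float:
    """Agreement-based ECG quality: F1 between two independent QRS detectors."""
    a = detect_r_peaks(ecg_window, fs)
    b = _derivative_qrs_detector(ecg_window, fs)
    return _match_f1(a, b)


def ppg_sqi(ppg_window: np.ndarray, fs: float = 125.0) -> float:
    """Template-correlation PPG quality.

    Pulses are segmented peak-to-peak, resampled to a common length and
    correlated against their window average; the SQI is ``max(0, mean r)``,
    and 0 with fewer than two pulses (insufficient evidence).
    """
    x = np.asarray(ppg_window, dtype=float)
    ev = slope_sum_detect(x, fs, upslope_s=0.15, refractory_s=60.0 / 270.0)
    if len(ev) < 3:
        return 0.0
    idx = np.round(ev.peak_times * fs).astype(int)
    # fixed-duration windows centred on each peak: segmenting peak-to-peak
    # would imprint a common "starts high" shape even on noise
    med_ibi = int(round(np.median(np.diff(idx))))
    lo_off, hi_off = int(0.35 * med_ibi), int(0.65 * med_ibi)
    pulses = []
    for i in idx:
        i0, i1 = i - lo_off, i + hi_off
        if i0 >= 0 and i1 <= len(x) and i1 - i0 >= 4:
            seg = x[i0:i1]
            t = np.linspace(0, 1, len(seg))
            pulses.append(np.interp(np.linspace(0, 1, 40), t, seg))
    if len(pulses) < 2:
        return 0.0
    pulses = np.array(pulses)
    total = pulses.sum(axis=0)
    n_p = len(pulses)
    # correlate away from the anchor: the detected peak guarantees a local
    # maximum at the anchor position in every segment, which would correlate
    # with the template even on pure noise
    anchor = int(round(0.35 * pulses.shape[1]))
    keep = np.ones(pulses.shape[1], dtype=bool)
    keep[max(0, anchor - 3): anchor + 4] = False
    rs = []
    for p in pulses:
        # leave-one-out template: including the pulse itself would add a
        # spurious ~sqrt(1/N) correlation when few pulses are present
        template = ((total - p) / (n_p - 1))[keep]
        q = p[keep]
        if q.std() == 0 or template.std() == 0:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(q, template)[0, 1]))
    return float(max(0.0, np.mean(rs)))


def sliding_sqi(waveform: np.ndarray, fs: float, kind: str,
                duration_s: float, window_s: float = 10.0) -> np.ndarray:
    """1 Hz SQI series from a sliding window over the waveform."""
    fn = ecg_sqi if kind == "ecg" else ppg_sqi
    n_sec = int(np.floor(duration_s))
    out = np.zeros(n_sec)
    for s in range(n_sec):
        t1 = s + 1.0
        t0 = max(0.0, t1 - window_s)
        seg = waveform[int(t0 * fs): int(t1 * fs)]
        out[s] = fn(seg, fs) if len(seg) >= 2.0 * fs else 0.0
    return out


# ---------------------------------------------------------------------------
# reference heart rate
# ---------------------------------------------------------------------------

def reference_hr(hr_ecg: np.ndarray, hr_ppg: np.ndarray,
                 sqi_ecg: np.ndarray, sqi_ppg: np.ndarray) -> ReferenceVital:
    """Mean of the two monitor heart rates where they agree and quality holds.

    A second is valid iff ``|hr_ecg - hr_ppg| <= 5`` beats/min and both SQIs
    are strictly greater than 0.5.
    """
    hr_ecg = np.asarray(hr_ecg, dtype=float)
    hr_ppg = np.asarray(hr_ppg, dtype=float)
    sqi_ecg = np.asarray(sqi_ecg, dtype=float)
    sqi_ppg = np.asarray(sqi_ppg, dtype=float)
    n = len(hr_ecg)
    if not (len(hr_ppg) == len(sqi_ecg) == len(sqi_ppg) == n):
        raise ValueError("reference inputs must share the 1 Hz grid")
    finite = np.isfinite(hr_ecg) & np.isfinite(hr_ppg)
    valid = finite & (np.abs(hr_ecg - hr_ppg) <= HR_AGREEMENT_BPM) \
        & (sqi_ecg > SQI_THRESHOLD) & (sqi_ppg > SQI_THRESHOLD)
    values = np.where(valid, (hr_ecg + hr_ppg) / 2.0, np.nan)
    return ReferenceVital(np.arange(n, dtype=float) + 1.0, values, valid,
                          {"hr_ecg": hr_ecg, "hr_ppg": hr_ppg,
                           "sqi_ecg": sqi_ecg, "sqi_ppg": sqi_ppg})


# ---------------------------------------------------------------------------
# respiration surrogates and reference respiratory rate
# ---------------------------------------------------------------------------

def derive_resp_surrogates(ecg: np.ndarray, fs: float = 500.0,
                           r_peaks: np.ndarray | None = None,
                           duration_s: float | None = None) -> dict[str, PPGiSignal]:
    """EDR / RSA / RPA respiration surrogates on a uniform 4 Hz grid.

    RPA is the R-peak amplitude series, RSA the instantaneous beat rate
    (60 / inter-beat interval) at beat times, EDR the QRS area over +-50 ms
    around each R peak; each is cubic-interpolated to 4 Hz.  Fewer than four
    beats yield empty surrogates.
    """
    x = np.asarray(ecg, dtype=float)
    if duration_s is None:
        duration_s = len(x) / fs
    if r_peaks is None:
        r_peaks = detect_r_peaks(x, fs)
    empty = {k: PPGiSignal(np.array([]), SURROGATE_FS, channel=k)
             for k in ("edr", "rsa", "rpa")}
    if len(r_peaks) < 4:
        return empty
    idx = np.round(np.asarray(r_peaks) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < len(x))]
    if len(idx) < 4:
        return empty
    rpa = x[idx]
    rsa_t = r_peaks[1:]
    rsa = 60.0 / np.diff(r_peaks)
    half = int(round(0.05 * fs))
    edr = np.array([np.trapezoid(np.abs(x[max(0, i - half): i + half + 1])) / fs
                    for i in idx])
    grid = np.arange(0.0, duration_s, 1.0 / SURROGATE_FS)
    out = {}
    for name, (t, v) in (("edr", (r_peaks, edr)), ("rsa", (rsa_t, rsa)),
                         ("rpa", (r_peaks, rpa))):
        f = interpolate.interp1d(t, v, kind="cubic", bounds_error=False,
                                 fill_value=(v[0], v[-1]))
        out[name] = PPGiSignal(f(grid), SURROGATE_FS, channel=name)
    return out


def _resp_filter_4hz(samples: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Detrend + 0.3 Hz FIR high-pass adapted to the 4 Hz surrogate grid.

    At 4 Hz the Nyquist frequency is the 2.0 Hz band top, so no low-pass
    stage is needed.
    """
    taps = sps.firwin(41, REF_RR_BAND_HZ[0], fs=SURROGATE_FS, pass_zero=False)
    x = np.asarray(samples, dtype=float)
    ok = np.asarray(valid, dtype=bool) & np.isfinite(x)
    if ok.sum() < len(taps) + 4:
        raise ValueError("surrogate too short for the respiratory filter")
    xf = x.copy()
    if not ok.all():
        idx = np.arange(len(x))
        xf[~ok] = np.interp(idx[~ok], idx[ok], x[ok])
    xf = sps.detrend(xf, type="linear")
    y = sps.lfilter(taps, 1.0, xf)
    d = (len(taps) - 1) // 2
    out = np.empty_like(y)
    out[: len(y) - d] = y[d:]
    out[len(y) - d:] = y[-1]
    return out, ok


def _rr_count_series(sig: PPGiSignal, window_s: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """(values, sqi) 1 Hz series: counting RR with detector-agreement SQI."""
    mac = mac_detect(sig.samples, sig.sample_rate, mac_window_s=2.0,
                     refractory_s=0.5, valid=sig.valid)
    bssf = slope_sum_detect(sig.samples, sig.sample_rate, upslope_s=0.3,
                            refractory_s=0.5, valid=sig.valid)
    duration = len(sig) / sig.sample_rate
    n_sec = int(np.floor(duration))
    values = np.full(n_sec, np.nan)
    sqi = np.zeros(n_sec)
    for s in range(n_sec):
        t1 = s + 1.0
        if t1 < window_s:
            continue
        t0 = t1 - window_s
        m = mac.peak_times[(mac.peak_times >= t0) & (mac.peak_times <= t1)]
        b = bssf.peak_times[(bssf.peak_times >= t0) & (bssf.peak_times <= t1)]
        if len(m) < 2:
            continue
        span = m[-1] - m[0]
        if span <= 0:
            continue
        rr = (len(m) - 1) * 60.0 / span
        if not (18.0 <= rr <= 120.0):
            continue
        values[s] = rr
        sqi[s] = 1.0 if len(m) == len(b) else 0.3
    return values, sqi


def _rr_ar_series(sig: PPGiSignal, window_s: float = 10.0,
                  order: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """(values, sqi) 1 Hz series: AR dominant-pole RR in 0.3-2.0 Hz.

    Order 4 rather than the camera chain's order 8: a 10 s window at the
    4 Hz surrogate rate is only 40 samples, and the surrogates carry a
    single dominant respiratory component, so a low order is both better
    conditioned and sufficient.
    """
    duration = len(sig) / sig.sample_rate
    n_sec = int(np.floor(duration))
    values = np.full(n_sec, np.nan)
    sqi = np.zeros(n_sec)
    fs = sig.sample_rate
    for s in range(n_sec):
        t1 = s + 1.0
        if t1 < window_s:
            continue
        i1 = int(round(t1 * fs))
        i0 = max(0, i1 - int(round(window_s * fs)))
        seg = sig.samples[i0:i1]
        ok = sig.valid[i0:i1]
        if (~ok).mean() > 0.25 or len(seg) <= 2 * order:
            continue
        try:
            model = fit_ar(np.where(ok, seg, 0.0), order, fs)
        except ValueError:
            continue
        pole = model.dominant_in_band_pole(REF_RR_BAND_HZ)
        if pole is None:
            continue
        rr = 60.0 * pole[0]
        if not (18.0 <= rr <= 120.0):
            continue
        values[s] = rr
        sqi[s] = float(np.clip(pole[1], 0.0, 1.0))
    return values, sqi


def reference_rr(surrogates: dict[str, PPGiSignal], ip: np.ndarray,
                 ip_fs: float = 64.0, window_s: float = 10.0) -> ReferenceVital:
    """Two-method, four-signal fused reference respiratory rate.

    Per signal (EDR, RSA, RPA, resampled IP) a counting estimate and an AR
    dominant-pole estimate are computed per second; each method's four
    per-signal series are fused with quality-weighted Kalman filters.  A
    second is valid iff both fused estimates exist and differ by less than
    5 breaths/min; the value is their mean.
    """
    ip = np.asarray(ip, dtype=float)
    duration = len(ip) / ip_fs
    grid = np.arange(0.0, duration, 1.0 / SURROGATE_FS)
    ip4 = np.interp(grid, np.arange(len(ip)) / ip_fs, ip)
    signals = dict(surrogates)
    signals["ip"] = PPGiSignal(ip4, SURROGATE_FS, channel="ip")

    count_vals, count_sqis, ar_vals, ar_sqis = [], [], [], []
    n_sec = int(np.floor(duration))
    for name, sig in signals.items():
        if len(sig) == 0:
            count_vals.append(np.full(n_sec, np.nan)); count_sqis.append(np.zeros(n_sec))
            ar_vals.append(np.full(n_sec, np.nan)); ar_sqis.append(np.zeros(n_sec))
            continue
        try:
            filt, ok = _resp_filter_4hz(sig.samples, sig.valid)
        except ValueError:
            count_vals.append(np.full(n_sec, np.nan)); count_sqis.append(np.zeros(n_sec))
            ar_vals.append(np.full(n_sec, np.nan)); ar_sqis.append(np.zeros(n_sec))
            continue
        fsig = PPGiSignal(filt, SURROGATE_FS, channel=name, valid=ok)
        cv, cs = _rr_count_series(fsig, window_s)
        av, as_ = _rr_ar_series(fsig, window_s)
        count_vals.append(cv[:n_sec]); count_sqis.append(cs[:n_sec])
        ar_vals.append(av[:n_sec]); ar_sqis.append(as_[:n_sec])

    cfg = KalmanConfig(value_range=(18.0, 120.0))
    fused_count = fuse_channels(np.array(count_vals), np.array(count_sqis), cfg)
    fused_ar = fuse_channels(np.array(ar_vals), np.array(ar_sqis), cfg)
    valid = fused_count.valid & fused_ar.valid & \
        (np.abs(fused_count.values - fused_ar.values) < RR_AGREEMENT_BRPM)
    values = np.where(valid, (fused_count.values + fused_ar.values) / 2.0, np.nan)
    return ReferenceVital(np.arange(n_sec, dtype=float) + 1.0, values, valid,
                          {"rr_count": fused_count.values, "rr_ar": fused_ar.values,
                           "sqi_count": fused_count.sqi, "sqi_ar": fused_ar.sqi})
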