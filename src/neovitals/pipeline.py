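"""End-to-end orchestration: frames + masks -> HR / RR estimate series.

A single streaming pass over the frames collects everything the downstream
stages need (per-channel PPGi means, skin-shape respiratory channels and the
mask-change activity index), so long scenes never need to be materialised in
memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .cardiac import VitalEstimate, detect_beats, estimate_hr_series, score_beats
from .changepoint import detect_step_changes
from .filters import filter_cardiac
from .ppgi import ActivitySeries, PPGiSignal
from .respiratory import RESP_CHANNELS, estimate_rr_series, fit_ellipse

__all__ = ["FrameFeatures", "collect_frame_features", "run_pipeline"]


@dataclass
class FrameFeatures:
    """Per-frame features from one pass over the video."""

    sample_rate: float
    ppgi: dict                 # channel -> PPGiSignal (red/green/blue)
    resp: dict                 # all twelve respiratory channels
    activity: ActivitySeries
    n_frames: int


def collect_frame_features(frames, masks, sample_rate: float | None = None,
                           activity_threshold: float = 0.02) -> FrameFeatures:
    """One streaming pass: PPGi channels, shape channels, activity index."""
    if sample_rate is None:
        sample_rate = getattr(getattr(frames, "config", None), "frame_rate", 20.0)
    rgb = {"red": [], "green": [], "blue": []}
    shape: dict[str, list[float]] = {k: [] for k in RESP_CHANNELS[3:]}
    per_frame_activity = [0.0]
    prev_mask = None
    n = 0
    for frame, mask in zip(frames, masks):
        pixels = getattr(frame, "pixels", frame)
        mask = np.asarray(mask, dtype=bool)
        n_skin = int(np.count_nonzero(mask))
        for ch, name in enumerate(("red", "green", "blue")):
            rgb[name].append(np.nan if n_skin == 0
                             else float(pixels[..., ch][mask].sum() / n_skin))
        if prev_mask is not None:
            sym = int(np.count_nonzero(mask ^ prev_mask))
            denom = max(n_skin, int(np.count_nonzero(prev_mask)), 1)
            per_frame_activity.append(sym / denom)
        prev_mask = mask
        if n_skin == 0:
            for k in shape:
                shape[k].append(np.nan)
        else:
            ys, xs = np.nonzero(mask)
            shape["skin_area"].append(float(n_skin))
            shape["skin_perimeter"].append(float(measure.perimeter(mask)))
            shape["skin_centroid_x"].append(float(xs.mean()))
            shape["skin_centroid_y"].append(float(ys.mean()))
            ell = fit_ellipse(mask)
            shape["ellipse_major"].append(ell.major)
            shape["ellipse_minor"].append(ell.minor)
            shape["ellipse_orientation"].append(ell.orientation)
            shape["ellipse_eccentricity"].append(ell.eccentricity)
            shape["ellipse_area"].append(ell.area)
        n += 1

    per_frame_activity = np.array(per_frame_activity)
    n_sec = int(np.ceil(n / sample_rate))
    per_second = np.zeros(n_sec)
    for s in range(n_sec):
        lo = int(round(s * sample_rate))
        hi = min(int(round((s + 1) * sample_rate)), n)
        per_second[s] = per_frame_activity[lo:hi].mean() if hi > lo else 0.0
    activity = ActivitySeries(per_frame_activity, per_second,
                              per_second > activity_threshold,
                              activity_threshold, sample_rate)

    ppgi = {name: PPGiSignal(np.array(vals), sample_rate, channel=name)
            for name, vals in rgb.items()}
    resp = {f"ppgi_{name}": PPGiSignal(np.array(vals), sample_rate,
                                       channel=f"ppgi_{name}")
            for name, vals in rgb.items()}
    for k, vals in shape.items():
        resp[k] = PPGiSignal(np.array(vals), sample_rate, channel=k)
    common_valid = np.logical_and.reduce([resp[k].valid for k in RESP_CHANNELS])
    for k in RESP_CHANNELS:
        resp[k].valid = common_valid.copy()
    return FrameFeatures(sample_rate, ppgi, resp, activity, n)


def run_pipeline(frames, masks, hr_methods=("count", "fft", "ar8", "arbest"),
                 sample_rate: float | None = None, smooth_hr: bool = False):
    """Full camera pipeline.

    Returns a dict with the frame features, the filtered cardiac signal, the
    scored beats, per-method HR series, the fused RR series and the
    per-channel RR series.
    """
    feats = collect_frame_features(frames, masks, sample_rate)
    green = feats.ppgi["green"]
    filtered_samples, filtered_valid = filter_cardiac(
        green.samples, green.sample_rate, valid=green.valid)
    filtered = PPGiSignal(filtered_samples, green.sample_rate, channel="green",
                          valid=filtered_valid)
    changes = detect_step_changes(np.where(green.valid, green.samples,
                                           np.nanmean(green.samples[green.valid])
                                           if green.valid.any() else 0.0),
                                  green.sample_rate)
    beats = detect_beats(filtered)
    beats = score_beats(beats, filtered, feats.activity, changes)
    hr = {m: estimate_hr_series(filtered, beats, method=m, smooth=smooth_hr)
          for m in hr_methods}
    rr_fused, rr_channels = estimate_rr_series(feats.resp, feats.activity)
    return {
        "features": feats,
        "filtered": filtered,
        "changes": changes,
        "beats": beats,
        "hr": hr,
        "rr": rr_fused,
        "rr_channels": rr_channels,
    }
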