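"""Raw PPGi extraction from frames + skin masks, and the mask activity index.

The raw PPGi sample for a frame is the spatial mean of the chosen colour
plane over the skin pixels; its sampling rate equals the video frame rate.
Frames with an empty mask yield an invalid sample - no value is invented.
The activity index tracks frame-to-frame changes of the segmented skin area
(subject motion) as the symmetric-difference fraction of consecutive masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PPGiSignal", "ActivitySeries", "extract_ppgi", "extract_ppgi_rgb",
           "activity_index"]

CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass
class PPGiSignal:
    """Uniformly sampled scalar series with a per-sample validity flag."""

    samples: np.ndarray
    sample_rate: float
    channel: str = "green"
    valid: np.ndarray = field(default=None)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.samples)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.valid) != len(self.samples):
            raise ValueError("validity flag length must match sample count")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class ActivitySeries:
    """Per-frame activity plus its 1 Hz smoothing and active-second flags."""

    per_frame: np.ndarray
    per_second: np.ndarray
    active: np.ndarray
    threshold: float
    sample_rate: float

    def is_active_second(self, t: float) -> bool:
        i = int(t)
        if 0 <= i < len(self.active):
            return bool(self.active[i])
        return False


def _mean_over_mask(plane: np.ndarray, mask: np.ndarray) -> float:
    n = int(np.count_nonzero(mask))
    if n == 0:
        return np.nan
    return float(plane[mask].sum() / n)


def extract_ppgi(frames, masks, channel: str = "green",
                 sample_rate: float | None = None) -> PPGiSignal:
    """Spatially average one colour plane over the skin mask, per frame.

    ``frames`` is an iterable of RGB pixel arrays (or objects with a
    ``pixels`` attribute); ``masks`` the per-frame boolean skin labels.
    """
    if channel not in CHANNEL_INDEX:
        raise ValueError(f"unknown channel {channel!r}")
    ch = CHANNEL_INDEX[channel]
    frames = list(frames) if not hasattr(frames, "__len__") else frames
    if hasattr(frames, "__len__") and hasattr(masks, "__len__") \
            and len(frames) != len(masks):
        raise ValueError(f"{len(frames)} frames but {len(masks)} masks")
    if sample_rate is None:
        sample_rate = getattr(getattr(frames, "config", None), "frame_rate", 20.0)
    values = []
    for frame, mask in zip(frames, masks):
        pixels = getattr(frame, "pixels", frame)
        values.append(_mean_over_mask(pixels[..., ch], np.asarray(mask, dtype=bool)))
    return PPGiSignal(np.array(values), sample_rate, channel=channel)


def extract_ppgi_rgb(frames, masks, sample_rate: float | None = None) -> dict[str, PPGiSignal]:
    """All three channel means in a single pass over the frames."""
    frames_seq = frames
    if sample_rate is None:
        sample_rate = getattr(getattr(frames, "config", None), "frame_rate", 20.0)
    out = {name: [] for name in CHANNEL_INDEX}
    n_frames = 0
    for frame, mask in zip(frames_seq, masks):
        pixels = getattr(frame, "pixels", frame)
        mask = np.asarray(mask, dtype=bool)
        n = int(np.count_nonzero(mask))
        n_frames += 1
        for name, ch in CHANNEL_INDEX.items():
            out[name].append(np.nan if n == 0 else float(pixels[..., ch][mask].sum() / n))
    return {name: PPGiSignal(np.array(vals), sample_rate, channel=name)
            for name, vals in out.items()}


def activity_index(masks, sample_rate: float = 20.0,
                   threshold: float = 0.02) -> ActivitySeries:
    """Motion proxy from consecutive skin masks.

    Per frame pair the activity is the symmetric-difference fraction
    ``|S_t XOR S_{t-1}| / max(|S_t|, |S_{t-1}|, 1)``; the per-second value is
    its mean over the second and a second is flagged active when that mean
    exceeds ``threshold``.
    """
    per_frame = [0.0]
    prev = None
    n = 0
    for mask in masks:
        mask = np.asarray(mask, dtype=bool)
        if prev is not None:
            sym = int(np.count_nonzero(mask ^ prev))
            denom = max(int(np.count_nonzero(mask)), int(np.count_nonzero(prev)), 1)
            per_frame.append(sym / denom)
        prev = mask
        n += 1
    if n < 2:
        raise ValueError("activity index needs at least two masks")
    per_frame = np.array(per_frame)
    n_sec = int(np.ceil(n / sample_rate))
    per_second = np.zeros(n_sec)
    for s in range(n_sec):
        lo = int(round(s * sample_rate))
        hi = min(int(round((s + 1) * sample_rate)), n)
        per_second[s] = per_frame[lo:hi].mean() if hi > lo else 0.0
    return ActivitySeries(per_frame, per_second, per_second > threshold,
                          threshold, sample_rate)
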