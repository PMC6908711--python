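"""Colour-based skin segmentation baselines, augmentation and CNN-style objectives.

The segmentation objectives (cross-entropy detection loss, class-weighted
segmentation loss, their weighted sum) and the intersection-over-union metric
are pure functions; the trainable baselines are per-pixel colour classifiers
(histogram Naive Bayes and a Gaussian mixture per class) that produce a skin
probability map which is thresholded to a binary mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as _sk_rotate
from sklearn.mixture import GaussianMixture

EPS = 1e-12

__all__ = [
    "PixelColourModel",
    "train_colour_model",
    "classify_skin",
    "iou",
    "detection_loss",
    "segmentation_loss",
    "unified_loss",
    "augment_image",
    "rgb_to_hsl",
    "hsl_to_rgb",
]


# ---------------------------------------------------------------------------
# colour classifiers
# ---------------------------------------------------------------------------

@dataclass
class PixelColourModel:
    """Fitted per-pixel skin/non-skin colour model (raw RGB feature space)."""

    model_kind: str                      # "naive_bayes" | "gmm"
    log_priors: np.ndarray               # shape (2,)
    # naive_bayes: per-class per-channel histograms
    histograms: np.ndarray | None = None # shape (2, 3, n_bins), each row sums to 1
    n_bins: int = 32
    # gmm: one mixture per class
    gmms: tuple | None = None

    def log_likelihood(self, rgb: np.ndarray) -> np.ndarray:
        """Per-class log p(colour | class) for an (n, 3) float RGB array."""
        rgb = np.asarray(rgb, dtype=float).reshape(-1, 3)
        if self.model_kind == "naive_bayes":
            bins = np.clip((rgb / 256.0 * self.n_bins).astype(int), 0, self.n_bins - 1)
            out = np.zeros((len(rgb), 2))
            for c in range(2):
                for ch in range(3):
                    out[:, c] += np.log(self.histograms[c, ch][bins[:, ch]] + EPS)
            return out
        return np.stack([g.score_samples(rgb) for g in self.gmms], axis=1)

    def predict_proba(self, rgb: np.ndarray) -> np.ndarray:
        """Posterior (n, 2) over {non-skin, skin}; rows sum to 1."""
        ll = self.log_likelihood(rgb) + self.log_priors
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        return p / p.sum(axis=1, keepdims=True)

    # -- JSON round-trip (CLI model files) --
    def to_json(self) -> str:
        d = {"model_kind": self.model_kind, "log_priors": self.log_priors.tolist(),
             "n_bins": self.n_bins}
        if self.model_kind == "naive_bayes":
            d["histograms"] = self.histograms.tolist()
        else:
            d["gmms"] = [
                {"weights": g.weights_.tolist(), "means": g.means_.tolist(),
                 "covariances": g.covariances_.tolist()} for g in self.gmms
            ]
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "PixelColourModel":
        d = json.loads(text)
        m = cls(model_kind=d["model_kind"], log_priors=np.array(d["log_priors"]),
                n_bins=d.get("n_bins", 32))
        if m.model_kind == "naive_bayes":
            m.histograms = np.array(d["histograms"])
        else:
            gmms = []
            for gd in d["gmms"]:
                g = GaussianMixture(n_components=len(gd["weights"]), covariance_type="full")
                g.weights_ = np.array(gd["weights"])
                g.means_ = np.array(gd["means"])
                g.covariances_ = np.array(gd["covariances"])
                g.precisions_cholesky_ = np.linalg.cholesky(
                    np.linalg.inv(g.covariances_)).transpose(0, 2, 1)
                gmms.append(g)
            m.gmms = tuple(gmms)
        return m


def train_colour_model(pixels, labels=None, kind: str = "gmm", seed: int = 0,
                       n_components: int = 3, n_bins: int = 32) -> PixelColourModel:
    """Fit a skin/non-skin colour classifier.

    ``pixels`` is either an (n, 3) RGB array with a separate (n,) binary
    ``labels`` array, or an iterable of ``(rgb, label)`` pairs.
    """
    if labels is None:
        rgb = np.array([p for p, _ in pixels], dtype=float)
        labels = np.array([l for _, l in pixels], dtype=int)
    else:
        rgb = np.asarray(pixels, dtype=float).reshape(-1, 3)
        labels = np.asarray(labels, dtype=int)
    if kind not in ("naive_bayes", "gmm"):
        raise ValueError(f"unknown classifier kind {kind!r}")
    for c, name in ((0, "non-skin"), (1, "skin")):
        if not np.any(labels == c):
            raise ValueError(f"training data contains no {name} (class {c}) pixels")
    log_priors = np.log(np.bincount(labels, minlength=2) / len(labels))
    if kind == "naive_bayes":
        hists = np.empty((2, 3, n_bins))
        edges = np.linspace(0.0, 256.0, n_bins + 1)
        for c in range(2):
            for ch in range(3):
                h, _ = np.histogram(rgb[labels == c, ch], bins=edges)
                hists[c, ch] = (h + 0.5) / (h.sum() + 0.5 * n_bins)  # Jeffreys smoothing
        return PixelColourModel("naive_bayes", log_priors, histograms=hists, n_bins=n_bins)
    gmms = []
    for c in range(2):
        g = GaussianMixture(n_components=n_components, covariance_type="full",
                            random_state=seed, reg_covar=1e-4, n_init=1)
        g.fit(rgb[labels == c])
        gmms.append(g)
    return PixelColourModel("gmm", log_priors, gmms=tuple(gmms))


def classify_skin(frame: np.ndarray, model: PixelColourModel,
                  threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel skin probability map and thresholded mask for one RGB frame.

    Returns ``(prob_map, mask)`` where ``prob_map`` is rows x cols x 2
    (non-skin, skin posteriors summing to 1) and ``mask = prob_map[..., 1] >=
    threshold``.
    """
    pixels = getattr(frame, "pixels", frame)
    rows, cols = pixels.shape[:2]
    proba = model.predict_proba(pixels.reshape(-1, 3)).reshape(rows, cols, 2)
    return proba, proba[..., 1] >= threshold


# ---------------------------------------------------------------------------
# metrics and objectives
# ---------------------------------------------------------------------------

def iou(y_p: np.ndarray, y_g: np.ndarray) -> float:
    """Pixel-wise intersection-over-union of two binary masks.

    Defined as 1.0 when both masks are empty and 0.0 when exactly one is.
    """
    y_p = np.asarray(y_p, dtype=bool)
    y_g = np.asarray(y_g, dtype=bool)
    if y_p.shape != y_g.shape:
        raise ValueError(f"mask shapes differ: {y_p.shape} vs {y_g.shape}")
    union = np.logical_or(y_p, y_g).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(y_p, y_g).sum() / union)


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def detection_loss(d: np.ndarray, b: np.ndarray) -> float:
    """Two-class cross-entropy between softmax scores ``d`` and one-hot ``b``."""
    d = _clamp(np.asarray(d, dtype=float))
    b = np.asarray(b, dtype=float)
    return float(-(b[0] * np.log(d[0]) + b[1] * np.log(d[1])))


def class_weight(labels: np.ndarray) -> float:
    """Skin-class weight: ratio of non-skin to skin ground-truth pixels."""
    labels = np.asarray(labels)
    n_skin = int(np.count_nonzero(labels))
    n_non = labels.size - n_skin
    if n_skin == 0:
        raise ValueError("label has no skin pixels: class weight is undefined")
    return n_non / n_skin


def segmentation_loss(y_seg: np.ndarray, labels: np.ndarray,
                      lam: float | None = None) -> float:
    """Class-weighted pixel-wise cross-entropy over the whole image.

    ``y_seg`` is (..., 2) per-pixel softmax scores, ``labels`` the binary
    skin annotation.  The skin term is weighted by ``lam`` (defaults to the
    non-skin/skin pixel ratio of the annotation).
    """
    y_seg = np.asarray(y_seg, dtype=float)
    labels = np.asarray(labels)
    if y_seg.shape[:-1] != labels.shape:
        raise ValueError(f"shape mismatch: scores {y_seg.shape[:-1]} vs labels {labels.shape}")
    if lam is None:
        lam = class_weight(labels)
    s0 = _clamp(y_seg[..., 0]).ravel()
    s1 = _clamp(y_seg[..., 1]).ravel()
    l1 = labels.astype(float).ravel()
    l0 = 1.0 - l1
    return float(-(l0 * np.log(s0)).sum() - lam * (l1 * np.log(s1)).sum())


def unified_loss(det_loss: float, seg_loss: float,
                 alpha_det: float = 1.0, alpha_seg: float = 1.0) -> float:
    """Weighted sum of the detection and segmentation losses."""
    if alpha_det < 0 or alpha_seg < 0:
        raise ValueError("task weights must be non-negative")
    return alpha_det * det_loss + alpha_seg * seg_loss


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def rgb_to_hsl(rgb: np.ndarray) -> np.ndarray:
    """Vectorised RGB [0,255] -> HSL (h in [0,1), s, l in [0,1])."""
    rgb = np.asarray(rgb, dtype=float) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    l = (mx + mn) / 2.0
    d = mx - mn
    s = np.zeros_like(l)
    nz = d > 0
    denom = 1.0 - np.abs(2.0 * l - 1.0)
    s[nz] = d[nz] / np.maximum(denom[nz], 1e-12)
    h = np.zeros_like(l)
    rm, gm, bm = (mx == r) & nz, (mx == g) & nz & (mx != r), (mx == b) & nz & (mx != r) & (mx != g)
    h[rm] = ((g - b)[rm] / d[rm]) % 6.0
    h[gm] = (b - r)[gm] / d[gm] + 2.0
    h[bm] = (r - g)[bm] / d[bm] + 4.0
    return np.stack([h / 6.0, s, l], axis=-1)


def hsl_to_rgb(hsl: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsl`; returns RGB in [0, 255]."""
    h, s, l = hsl[..., 0] * 6.0, hsl[..., 1], hsl[..., 2]
    c = (1.0 - np.abs(2.0 * l - 1.0)) * s
    x = c * (1.0 - np.abs(h % 2.0 - 1.0))
    m = l - c / 2.0
    z = np.zeros_like(c)
    conds = [(0 <= h) & (h < 1), (1 <= h) & (h < 2), (2 <= h) & (h < 3),
             (3 <= h) & (h < 4), (4 <= h) & (h < 5), (5 <= h) & (h <= 6)]
    rs = [c, x, z, z, x, c]
    gs = [x, c, c, x, z, z]
    bs = [z, z, x, c, c, x]
    r = np.select(conds, rs, default=z)
    g = np.select(conds, gs, default=z)
    b = np.select(conds, bs, default=z)
    return np.clip(np.stack([r + m, g + m, b + m], axis=-1) * 255.0, 0.0, 255.0)


def augment_image(frame: np.ndarray, mode: str, parameter: float | None = None) -> np.ndarray:
    """Rotation (45-degree increments), mirroring, or HSL lightness scaling."""
    pixels = np.asarray(getattr(frame, "pixels", frame), dtype=float)
    if mode == "rotate":
        angle = float(parameter) % 360.0
        if angle % 45.0 != 0.0:
            raise ValueError("rotation angle must be a multiple of 45 degrees")
        if angle == 0.0:
            return pixels.copy()
        # bilinear, zero padding outside the original support
        return _sk_rotate(pixels, angle, resize=False, order=1, mode="constant",
                          cval=0.0, preserve_range=True)
    if mode == "mirror_x":
        return pixels[:, ::-1].copy()
    if mode == "mirror_y":
        return pixels[::-1].copy()
    if mode == "lighting":
        factor = float(parameter)
        if factor <= 0:
            raise ValueError("lighting factor must be positive")
        hsl = rgb_to_hsl(pixels)
        hsl[..., 2] = np.clip(hsl[..., 2] * factor, 0.0, 1.0)
        return hsl_to_rgb(hsl)
    raise ValueError(f"unknown augmentation mode {mode!r}")
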