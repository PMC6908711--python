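"""Validity masking, agreement statistics and gap analysis.

Camera estimates are judged only on "valid" seconds: the patient is present,
no clinical intervention is in progress, and the reference vitals are
mutually consistent.  The report carries the mean absolute error, the
bias-removed mean absolute deviation, Bland-Altman bias and 95% limits of
agreement, pooled Pearson correlation, the estimated-time percentage (valid
seconds with a camera estimate), and a gap analysis that re-computes the
estimated-time percentage when unestimated runs up to an allowance G are
tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidityMask", "EvaluationReport", "build_validity_mask",
    "evaluate", "gap_analysis", "permutation_pvalue",
]


@dataclass
class ValidityMask:
    patient_present: np.ndarray
    no_intervention: np.ndarray
    reference_valid: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return self.patient_present & self.no_intervention & self.reference_valid

    def summary_seconds(self) -> dict:
        return {
            "total": int(len(self.combined)),
            "absent": int(np.sum(~self.patient_present)),
            "intervention": int(np.sum(self.patient_present & ~self.no_intervention)),
            "reference_invalid": int(np.sum(self.patient_present & self.no_intervention
                                            & ~self.reference_valid)),
            "valid": int(np.sum(self.combined)),
        }


def build_validity_mask(presence, interventions, reference_valid) -> ValidityMask:
    """Combine 1 Hz presence, non-intervention and reference-validity flags.

    ``interventions`` may be a boolean series (True = intervention in
    progress) or a list of ``(start, end)`` second intervals.
    """
    presence = np.asarray(presence, dtype=bool)
    reference_valid = np.asarray(reference_valid, dtype=bool)
    n = len(presence)
    if not hasattr(interventions, "dtype") and interventions and \
            isinstance(interventions[0], (tuple, list)):
        flags = np.zeros(n, dtype=bool)
        for a, b in interventions:
            flags[int(np.floor(a)): int(np.ceil(b))] = True
        interventions = flags
    else:
        interventions = np.asarray(interventions, dtype=bool) \
            if len(np.atleast_1d(interventions)) else np.zeros(n, dtype=bool)
    if len(interventions) != n or len(reference_valid) != n:
        raise ValueError("validity-mask inputs must share the 1 Hz grid")
    return ValidityMask(presence, ~interventions, reference_valid)


@dataclass
class EvaluationReport:
    mae: float
    mad: float                    # bias-removed mean absolute deviation
    median_abs_diff: float
    bias: float                   # Bland-Altman mean difference
    loa: tuple[float, float]      # 95% limits of agreement
    correlation: float            # pooled Pearson; NaN if degenerate
    estimated_time_pct: float
    n_valid_seconds: int
    n_compared_seconds: int
    empty: bool = False
    gap_histogram: dict = field(default_factory=dict)


def evaluate(camera_values: np.ndarray, camera_valid: np.ndarray,
             reference_values: np.ndarray, reference_valid: np.ndarray,
             mask: np.ndarray | ValidityMask | None = None) -> EvaluationReport:
    """Agreement statistics over seconds valid in mask, camera and reference."""
    cam = np.asarray(camera_values, dtype=float)
    cam_ok = np.asarray(camera_valid, dtype=bool) & np.isfinite(cam)
    ref = np.asarray(reference_values, dtype=float)
    ref_ok = np.asarray(reference_valid, dtype=bool) & np.isfinite(ref)
    n = len(cam)
    if isinstance(mask, ValidityMask):
        mask = mask.combined
    mask = np.ones(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if not (len(ref) == len(mask) == n):
        raise ValueError("evaluation series must share the 1 Hz grid")
    valid = mask & ref_ok
    both = valid & cam_ok
    n_valid = int(valid.sum())
    n_both = int(both.sum())
    if n_both == 0:
        return EvaluationReport(np.nan, np.nan, np.nan, np.nan, (np.nan, np.nan),
                                np.nan, 0.0, n_valid, 0, empty=True)
    diff = cam[both] - ref[both]
    bias = float(diff.mean())
    mae = float(np.abs(diff).mean())
    mad = float(np.abs(diff - bias).mean())
    sd = float(diff.std(ddof=1)) if n_both > 1 else 0.0
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    if n_both > 1 and cam[both].std() > 0 and ref[both].std() > 0:
        corr = float(np.corrcoef(cam[both], ref[both])[0, 1])
    else:
        corr = np.nan
    pct = 100.0 * n_both / n_valid if n_valid else 0.0
    return EvaluationReport(mae, mad, float(np.median(np.abs(diff))), bias, loa,
                            corr, pct, n_valid, n_both)


def gap_analysis(camera_valid: np.ndarray, mask: np.ndarray,
                 allowance_s: float = 30.0) -> dict:
    """Histogram of unestimated gaps and the allowance-adjusted coverage.

    A gap is a maximal run of valid-but-unestimated seconds.  With allowance
    G, gaps of length <= G count as estimated; at G = 0 the adjusted
    percentage equals the raw estimated-time percentage.
    """
    cam_ok = np.asarray(camera_valid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n_valid = int(mask.sum())
    if n_valid == 0:
        return {"gaps": [], "histogram": {}, "raw_pct": 0.0, "adjusted_pct": 0.0,
                "allowance_s": allowance_s}
    gaps = []
    run = 0
    for ok, m in zip(cam_ok, mask):
        if not m:
            continue
        if ok:
            if run:
                gaps.append(run)
            run = 0
        else:
            run += 1
    if run:
        gaps.append(run)
    covered = int((mask & cam_ok).sum())
    bridged = covered + sum(g for g in gaps if g <= allowance_s)
    hist: dict[int, int] = {}
    for g in gaps:
        hist[g] = hist.get(g, 0) + 1
    return {
        "gaps": gaps,
        "histogram": dict(sorted(hist.items())),
        "raw_pct": 100.0 * covered / n_valid,
        "adjusted_pct": 100.0 * bridged / n_valid,
        "allowance_s": allowance_s,
    }


def permutation_pvalue(a: np.ndarray, b: np.ndarray, n_perm: int = 10000,
                       seed: int = 0) -> float:
    """One-sided permutation p-value for mean(a) < mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rng = np.random.default_rng(seed)
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n_a = len(a)
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if pooled[:n_a].mean() - pooled[n_a:].mean() <= observed:
            count += 1
    return (count + 1) / (n_perm + 1)
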