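"""Bayesian online change-point detection for step changes in PPGi signals.

Sudden lighting changes show up as step changes of the mean level of the
PPGi signal.  The detector is Bayesian online change-point detection with a
constant hazard and a Normal-Gamma observation model (Student-t predictive):
at each sample the posterior over the current run length is updated; a
collapse of the most probable run length back to (near) zero marks a change
point.  Samples within a margin of a change point are treated as invalid by
the beat- and breath-quality gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["ChangePointSet", "detect_step_changes"]


@dataclass
class ChangePointSet:
    indices: list[int] = field(default_factory=list)
    margin_s: float = 1.0
    sample_rate: float = 20.0

    def invalid_mask(self, n: int) -> np.ndarray:
        """Boolean mask of samples within ``margin_s`` of any change point."""
        m = int(round(self.margin_s * self.sample_rate))
        mask = np.zeros(n, dtype=bool)
        for i in self.indices:
            mask[max(0, i - m): min(n, i + m + 1)] = True
        return mask

    def near(self, time_s: float) -> bool:
        return any(abs(time_s - i / self.sample_rate) <= self.margin_s
                   for i in self.indices)


def detect_step_changes(samples: np.ndarray, sample_rate: float = 20.0,
                        hazard: float = 1.0 / 300.0, margin_s: float = 1.0,
                        max_run: int = 400) -> ChangePointSet:
    """Detect mean-level step changes by online Bayesian run-length tracking.

    ``hazard`` is the constant per-sample change probability prior; the run
    length posterior is truncated at ``max_run`` for speed.  Short signals
    (< 10 samples) return an empty set.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    result = ChangePointSet(margin_s=margin_s, sample_rate=sample_rate)
    if len(x) < 10:
        return result
    # noise scale from first differences: robust to the very level shifts
    # we are trying to detect (a global std would be inflated by them,
    # mis-specifying the observation prior)
    scale = np.std(np.diff(x)) / np.sqrt(2.0)
    if scale == 0:
        scale = np.std(x)
    if scale == 0:
        return result
    x = (x - np.mean(x)) / scale

    # Normal-Gamma prior on (mean, precision)
    mu0, kappa0, alpha0, beta0 = 0.0, 0.2, 1.0, 0.2

    n = len(x)
    # run-length posterior; index r = run length
    log_r = np.array([0.0])
    mu = np.array([mu0])
    kappa = np.array([kappa0])
    alpha = np.array([alpha0])
    beta = np.array([beta0])
    log_h = np.log(hazard)
    log_1mh = np.log1p(-hazard)
    min_sep = int(round(margin_s * sample_rate))
    map_hist = np.zeros(n, dtype=int)

    for t in range(n):
        # Student-t predictive for each run length hypothesis
        df = 2.0 * alpha
        scale_t = np.sqrt(beta * (kappa + 1.0) / (alpha * kappa))
        log_pred = stats.t.logpdf(x[t], df, loc=mu, scale=scale_t)

        log_growth = log_r + log_pred + log_1mh
        log_cp = np.logaddexp.reduce(log_r + log_pred + log_h)
        log_r_new = np.concatenate([[log_cp], log_growth])
        log_r_new -= np.logaddexp.reduce(log_r_new)

        # posterior parameter update (shifted by one run length)
        mu_new = np.concatenate([[mu0], (kappa * mu + x[t]) / (kappa + 1.0)])
        kappa_new = np.concatenate([[kappa0], kappa + 1.0])
        alpha_new = np.concatenate([[alpha0], alpha + 0.5])
        beta_new = np.concatenate(
            [[beta0], beta + 0.5 * kappa * (x[t] - mu) ** 2 / (kappa + 1.0)])

        if len(log_r_new) > max_run:
            # merge the two oldest runs into the cap bin: dropping the
            # longest-run hypothesis outright would delete the MAP for long
            # stationary stretches and fabricate a collapse.  The merged bin
            # keeps the parameters of whichever hypothesis carries more mass,
            # so a dominant run arriving at the cap is not corrupted by stale
            # parameters left over from before an earlier change point.
            if log_r_new[max_run] > log_r_new[max_run - 1]:
                mu_new[max_run - 1] = mu_new[max_run]
                kappa_new[max_run - 1] = kappa_new[max_run]
                alpha_new[max_run - 1] = alpha_new[max_run]
                beta_new[max_run - 1] = beta_new[max_run]
            log_r_new[max_run - 1] = np.logaddexp(log_r_new[max_run - 1],
                                                  log_r_new[max_run])
            log_r_new = log_r_new[:max_run]
            mu_new, kappa_new = mu_new[:max_run], kappa_new[:max_run]
            alpha_new, beta_new = alpha_new[:max_run], beta_new[:max_run]
            log_r_new -= np.logaddexp.reduce(log_r_new)

        log_r, mu, kappa, alpha, beta = log_r_new, mu_new, kappa_new, alpha_new, beta_new

        map_hist[t] = int(np.argmax(log_r))

    # a collapse of the MAP run length proposes a change at t - run; it is
    # confirmed only if the MAP keeps tracking the new segment afterwards
    # (a single outlier collapses the MAP for one step and then reverts)
    last_cp = -10 ** 9
    for t in range(1, n):
        if not (map_hist[t - 1] >= 20 and map_hist[t] <= 3):
            continue
        cp = t - map_hist[t]
        if cp - last_cp <= min_sep:
            continue
        horizon = range(t + 2, min(n, t + 16))
        if len(horizon) == 0:
            continue
        follows = sum(1 for u in horizon if abs(map_hist[u] - (u - cp)) <= 3)
        if follows >= 0.6 * len(horizon):
            result.indices.append(cp)
            last_cp = cp

    result.indices.sort()
    return result
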