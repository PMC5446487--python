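"""Behavioral summary statistics: critical SSD, SSRT, and P(stop)-binned curves.

The critical SSD — the stop-signal delay at which stopping succeeds half the
time — is estimated by maximum likelihood on the staircase-generated sequence
of SSDs and stop outcomes, fitting a two-parameter inhibition function whose
success probability *decreases* with SSD.  Under the race model the
stop-signal reaction time is then the median go-RT minus the critical SSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "InhibitionFit",
    "BinnedCurve",
    "estimate_critical_ssd",
    "ssrt",
    "binned_group_curve",
]


@dataclass
class InhibitionFit:
    """Fitted inhibition function P(stop success | SSD).

    ``critical_ssd_ms`` is its 50% point; ``slope`` is the steepness 1/sigma
    (per ms) of the fitted family at that point.
    """

    critical_ssd_ms: float
    slope: float
    loglik: float
    family: str = "gaussian"


def _success_prob(ssd, theta, sigma, family):
    # success probability decreases with SSD: 50% point at theta
    z = (theta - ssd) / sigma
    if family == "gaussian":
        return stats.norm.cdf(z)
    if family == "logistic":
        return stats.logistic.cdf(z)
    raise ValueError(f"unknown family {family!r}")


def estimate_critical_ssd(trials: pd.DataFrame, family: str = "gaussian") -> InhibitionFit:
    """ML fit of the inhibition function over all staircase-generated SSDs.

    Maximizes the Bernoulli likelihood of stop outcomes given SSD under a
    cumulative-Gaussian (default) or logistic family.

    Raises
    ------
    ValueError
        With < 20 stop trials, < 3 distinct SSDs, or all-success /
        all-failure outcomes (the 50% point is not identifiable).
    """
    st = trials[trials["trial_type"] == "stop"]
    ssd = st["ssd_ms"].to_numpy(dtype=float)
    y = (st["outcome"] == "stop_success").to_numpy(dtype=float)
    if ssd.size < 20:
        raise ValueError(f"need >= 20 stop trials, got {ssd.size}")
    if np.unique(ssd).size < 3:
        raise ValueError("need >= 3 distinct SSDs")
    if y.all() or not y.any():
        raise ValueError("all-success or all-failure stop outcomes: not identifiable")

    def nll(x):
        theta, log_sigma = x
        p = _success_prob(ssd, theta, np.exp(log_sigma), family)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum()

    theta0 = float(np.mean(ssd))
    sigma0 = max(float(np.std(ssd)), 10.0)
    res = optimize.minimize(
        nll, x0=[theta0, np.log(sigma0)], method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000},
    )
    theta, log_sigma = res.x
    return InhibitionFit(
        critical_ssd_ms=float(theta),
        slope=float(1.0 / np.exp(log_sigma)),
        loglik=float(-res.fun),
        family=family,
    )


def ssrt(trials: pd.DataFrame, fit: InhibitionFit) -> float:
    """Stop-signal reaction time: median successful-go RT minus critical SSD."""
    go = trials[(trials["outcome"] == "go_success") & np.isfinite(trials["rt_ms"])]
    if len(go) < 1:
        raise ValueError("need at least one successful go trial")
    return float(np.median(go["rt_ms"])) - fit.critical_ssd_ms


@dataclass
class BinnedCurve:
    """Group curve of a behavioral quantity against P(stop) bins (width 0.01).

    Two-stage averaging: within subject per bin, then across subjects per
    bin; bins represented by <= 2 subjects are dropped.  ``r`` is the Pearson
    correlation between bin center and group mean.
    """

    bin_centers: np.ndarray
    mean_value: np.ndarray
    n_subjects_per_bin: np.ndarray
    r: float


def binned_group_curve(
    cohort: list[pd.DataFrame],
    value: str = "go_rt",
    bin_width: float = 0.01,
    min_subjects: int = 3,
) -> BinnedCurve:
    """P(stop)-binned group average of go-RT or stop-error rate."""
    if value not in ("go_rt", "stop_error_rate"):
        raise ValueError("value must be 'go_rt' or 'stop_error_rate'")
    per_subject: list[pd.Series] = []
    for tab in cohort:
        if "pstop" not in tab.columns:
            raise ValueError("trial tables must carry a pstop column")
        if value == "go_rt":
            sel = tab[(tab["outcome"] == "go_success") & np.isfinite(tab["rt_ms"])]
            vals = sel["rt_ms"]
        else:
            sel = tab[tab["trial_type"] == "stop"]
            vals = (sel["outcome"] == "stop_error").astype(float)
        idx = np.floor(sel["pstop"].to_numpy() / bin_width).astype(int)
        per_subject.append(vals.groupby(idx).mean())

    wide = pd.concat(per_subject, axis=1)
    n_subj = wide.notna().sum(axis=1).to_numpy()
    keep = n_subj >= min_subjects
    if not keep.any():
        raise ValueError("no P(stop) bin retained after truncation")
    centers = (wide.index.to_numpy()[keep] + 0.5) * bin_width
    means = wide.mean(axis=1).to_numpy()[keep]
    order = np.argsort(centers)
    centers, means, n_kept = centers[order], means[order], n_subj[keep][order]
    if centers.size >= 2 and np.std(means) > 0:
        r = float(stats.pearsonr(centers, means)[0])
    else:
        r = np.nan
    return BinnedCurve(
        bin_centers=centers, mean_value=means, n_subjects_per_bin=n_kept, r=r
    )
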