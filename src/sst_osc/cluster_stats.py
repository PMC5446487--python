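"""Two-loop trial-by-trial brain-behavior statistics.

Loop 1 (within subject): for every time-frequency bin, the Spearman rank
correlation between single-trial power and a behavioral covariate is
standardized against a null distribution built by shuffling the trial
mapping (default 1000 permutations), giving a z-map per subject.

Loop 2 (across subjects): a two-tailed one-sample t test per bin asks where
z differs from zero; adjacent suprathreshold bins (4-neighbor by default,
positive and negative signs clustered separately) form clusters whose
statistic is the summed t.  Family-wise error is controlled by a sign-flip
permutation null (default 2000 iterations) recording the largest
suprathreshold |sum t| per iteration; p_perm is the rank of the observed
cluster against that null, quantized in steps of 1/n_iterations with
minimum 1/n_iterations.

Also provided: observed power of the permutation test (fraction of re-run
nulls with p_perm < 0.05), the across-trial correlation between the mean
power of two clusters with a group Wilcoxon signed-rank test, and
residualization of stop-locked power against stop-outcome condition means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.diagnostic import lilliefors

from .timefreq import TFEpochs

__all__ = [
    "ZMap",
    "Cluster",
    "ClusterResult",
    "ClusterPowerResult",
    "subject_zmap",
    "group_cluster_test",
    "observed_power",
    "cluster_power_correlation",
    "regress_out_condition_means",
]


@dataclass
class ZMap:
    """Per-subject standardized EEG-behavior correlation map (freqs x times)."""

    z: np.ndarray
    covariate_name: str
    lock: str
    freqs_hz: np.ndarray
    times_s: np.ndarray


@dataclass
class Cluster:
    """One suprathreshold cluster of adjacent time-frequency bins."""

    bins: np.ndarray  # (n_bins, 2) array of (freq_idx, time_idx)
    summed_t: float
    sign: int
    p_perm: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold_p: float
    n_iterations: int
    t_map: np.ndarray
    null_max: np.ndarray

    @property
    def min_p(self) -> float:
        return min((c.p_perm for c in self.clusters), default=np.nan)


def _rank_standardize(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Midrank-transform then z-score along an axis (ddof 0)."""
    r = stats.rankdata(x, axis=axis)
    r = r - r.mean(axis=axis, keepdims=True)
    sd = r.std(axis=axis, keepdims=True)
    sd[sd == 0] = 1.0
    return r / sd


def subject_zmap(
    tf: TFEpochs,
    covariate: np.ndarray,
    covariate_name: str = "",
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> ZMap:
    """Standardized Spearman correlation map for one subject.

    ``covariate`` must align with ``tf``'s trials (post artifact rejection).
    Permutations shuffle the covariate across those retained trials.  Bins
    whose permutation null has zero spread are flagged NaN.
    """
    rng = np.random.default_rng(rng)
    cov = np.asarray(covariate, dtype=float)
    n = tf.power.shape[0]
    if cov.size != n:
        raise ValueError("covariate length must equal the trial count")
    if n < 20:
        raise ValueError(f"need >= 20 trials, got {n}")
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant")

    nf, nt = tf.power.shape[1], tf.power.shape[2]
    zp = _rank_standardize(tf.power.reshape(n, nf * nt))  # (n, bins)
    zc = _rank_standardize(cov)
    rho_obs = zc @ zp / n  # (bins,)

    perms = np.empty((n_perm, n), dtype=float)
    for i in range(n_perm):
        perms[i] = zc[rng.permutation(n)]
    rho_null = perms @ zp / n  # (n_perm, bins)
    mu = rho_null.mean(axis=0)
    sd = rho_null.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (rho_obs - mu) / sd
    z[sd == 0] = np.nan
    return ZMap(
        z=z.reshape(nf, nt),
        covariate_name=covariate_name,
        lock=tf.lock,
        freqs_hz=tf.freqs_hz,
        times_s=tf.times_s,
    )


def _adjacency_structure(adjacency: str) -> np.ndarray:
    if adjacency == "4":
        return ndimage.generate_binary_structure(2, 1)
    if adjacency == "8":
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("adjacency must be '4' or '8'")


def _signed_cluster_sums(t_map, t_crit, structure):
    """Label positive and negative suprathreshold clusters; return labels+sums."""
    out = []
    for sign in (1, -1):
        mask = (sign * t_map) > t_crit
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=structure)
        sums = ndimage.sum_labels(t_map, labels, index=np.arange(1, n + 1))
        out.append((sign, labels, sums))
    return out


def group_cluster_test(
    zmaps: list[ZMap],
    threshold_p: float = 0.02,
    n_iter: int = 2000,
    adjacency: str = "4",
    rng: np.random.Generator | int | None = None,
) -> ClusterResult:
    """Group-level cluster permutation test on subject z-maps.

    The null flips the sign of whole subject maps (exchangeable under the
    hypothesis of zero mean correlation) and records the largest
    suprathreshold |sum t| across both signs per iteration.
    """
    if len(zmaps) < 6:
        raise ValueError("need at least 6 subjects")
    rng = np.random.default_rng(rng)
    Z = np.stack([m.z for m in zmaps])  # (S, F, T)
    S = Z.shape[0]
    shape = Z.shape[1:]
    Zf = Z.reshape(S, -1)
    if np.isnan(Zf).any():
        raise ValueError("z-maps contain NaN bins")

    t_crit = stats.t.isf(threshold_p / 2.0, df=S - 1)
    sumsq = (Zf**2).sum(axis=0)
    structure = _adjacency_structure(adjacency)

    def t_from_flips(flips):  # flips: (n, S) of +-1
        m = flips @ Zf / S
        var = (sumsq - S * m**2) / (S - 1)
        var = np.maximum(var, 1e-30)
        return m / np.sqrt(var / S)

    t_obs = t_from_flips(np.ones((1, S)))[0].reshape(shape)
    observed = _signed_cluster_sums(t_obs, t_crit, structure)

    flips = rng.choice([-1.0, 1.0], size=(n_iter, S))
    t_null = t_from_flips(flips)
    null_max = np.zeros(n_iter)
    for i in range(n_iter):
        tm = t_null[i].reshape(shape)
        best = 0.0
        for _, _, sums in _signed_cluster_sums(tm, t_crit, structure):
            best = max(best, np.abs(sums).max())
        null_max[i] = best

    clusters = []
    for sign, labels, sums in observed:
        for j, s in enumerate(sums, start=1):
            count = int((null_max >= abs(s)).sum())
            p = min(1.0, max(count, 1) / n_iter)
            clusters.append(
                Cluster(
                    bins=np.argwhere(labels == j),
                    summed_t=float(s),
                    sign=sign,
                    p_perm=p,
                )
            )
    clusters.sort(key=lambda c: abs(c.summed_t), reverse=True)
    return ClusterResult(
        clusters=clusters,
        threshold_p=threshold_p,
        n_iterations=n_iter,
        t_map=t_obs,
        null_max=null_max,
    )


def observed_power(
    zmaps: list[ZMap],
    threshold_p: float = 0.02,
    n_iter: int = 2000,
    n_repeats: int = 200,
    adjacency: str = "4",
    rng: np.random.Generator | int | None = None,
) -> float:
    """Fraction of re-randomized permutation tests with min p_perm < 0.05.

    The data (z-maps) stay fixed; only the sign-flip null is redrawn.
    """
    rng = np.random.default_rng(rng)
    hits = 0
    for _ in range(n_repeats):
        res = group_cluster_test(zmaps, threshold_p, n_iter, adjacency, rng)
        if res.clusters and res.min_p < 0.05:
            hits += 1
    return hits / n_repeats


def _cluster_mask(shape, bins):
    mask = np.zeros(shape, dtype=bool)
    mask[bins[:, 0], bins[:, 1]] = True
    return mask


@dataclass
class ClusterPowerResult:
    """Across-trial correlation between two clusters' mean power, per subject."""

    coefficients: np.ndarray
    wilcoxon_p: float
    ks_p: float  # Lilliefors test of normality of the coefficients
    median_r: float


def cluster_power_correlation(
    tfs_a: list[TFEpochs],
    bins_a: np.ndarray,
    tfs_b: list[TFEpochs],
    bins_b: np.ndarray,
    min_common: int = 10,
) -> ClusterPowerResult:
    """Correlate two clusters' single-trial mean power across common trials.

    For each subject the two locks are aligned through their trial indices;
    the Pearson coefficients are tested against zero with a two-tailed
    Wilcoxon signed-rank test, and their normality is reported (Lilliefors).
    """
    coeffs = []
    for tfa, tfb in zip(tfs_a, tfs_b):
        common, ia, ib = np.intersect1d(
            tfa.trial_index, tfb.trial_index, return_indices=True
        )
        if common.size < min_common:
            raise ValueError(
                f"only {common.size} common trials for a subject (need >= {min_common})"
            )
        ma = _cluster_mask(tfa.power.shape[1:], np.asarray(bins_a))
        mb = _cluster_mask(tfb.power.shape[1:], np.asarray(bins_b))
        pa = tfa.power[ia][:, ma].mean(axis=1)
        pb = tfb.power[ib][:, mb].mean(axis=1)
        coeffs.append(stats.pearsonr(pa, pb)[0])
    coeffs = np.asarray(coeffs)
    wilcoxon_p = float(stats.wilcoxon(coeffs, alternative="two-sided").pvalue)
    # normality check is undefined for degenerate (constant) coefficients
    ks_p = float(lilliefors(coeffs, dist="norm")[1]) if np.ptp(coeffs) > 0 else np.nan
    return ClusterPowerResult(
        coefficients=coeffs,
        wilcoxon_p=wilcoxon_p,
        ks_p=ks_p,
        median_r=float(np.median(coeffs)),
    )


def regress_out_condition_means(tf: TFEpochs, condition: np.ndarray) -> TFEpochs:
    """Residualize power against a two-level stop-outcome factor.

    Subtracts each condition's mean power per bin from its trials, so
    residuals have zero mean within condition; used to check that the
    prediction-error correlation is not a stop-success/stop-error contrast
    in disguise.
    """
    condition = np.asarray(condition)
    if condition.size != tf.power.shape[0]:
        raise ValueError("condition labels must align with trials")
    out = tf.power.copy()
    for level in np.unique(condition):
        sel = condition == level
        if sel.sum() < 2:
            raise ValueError(f"condition {level!r} has fewer than 2 trials")
        out[sel] -= out[sel].mean(axis=0, keepdims=True)
    return TFEpochs(
        power=out,
        freqs_hz=tf.freqs_hz,
        times_s=tf.times_s,
        lock=tf.lock,
        trial_index=tf.trial_index,
        baseline_applied=tf.baseline_applied,
    )
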