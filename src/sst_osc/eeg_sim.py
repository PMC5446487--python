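"""Synthetic single-channel EEG epochs with behavior-coupled oscillatory bursts.

Each epoch is 1/f-shaped background noise plus one Gaussian-windowed
sinusoidal burst whose amplitude tracks a behavioral covariate:

    amplitude_i = max(0, base_amp + gain * z(covariate_i))        [uV]

with a random uniform phase per trial.  Three event locks carry the planted
effects the trial-by-trial analysis is meant to recover:

* fixation-locked — low-theta burst (~4 Hz, 0-200 ms) scaling with P(stop);
* go-locked — delta-theta burst (~4 Hz, 200-700 ms) scaling *negatively*
  with go-RT (successful go trials only);
* stop-locked — low-beta burst (~16 Hz, 300-400 ms) scaling with prediction
  error (stop trials only).

Amplitude, not power, is linear in the z-scored covariate, so any monotone
power measure preserves the planted rank correlation.  A small fraction of
trials receive a large square pulse to exercise the 150 uV peak-to-peak
artifact-rejection rule.  Epochs carry padding beyond the analysis window so
that downstream wavelet transforms see no edge artifacts inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "BurstSpec",
    "EEGSimConfig",
    "EpochSet",
    "covariate_for_lock",
    "simulate_epochs",
    "reject_artifacts",
    "save_epochs",
    "load_epochs",
]

LOCKS = ("fixation", "go", "stop")

#: behavioral covariate attached to each event lock
LOCK_COVARIATE = {"fixation": "pstop", "go": "rt_ms", "stop": "pe"}


@dataclass(frozen=True)
class BurstSpec:
    """One planted oscillatory burst: place, width and behavioral coupling."""

    center_freq_hz: float
    center_time_s: float
    time_sd_s: float
    base_amp_uv: float
    gain_uv: float  # signed, per unit of the z-scored covariate

    def __post_init__(self) -> None:
        if not 2.0 <= self.center_freq_hz <= 50.0:
            raise ValueError("burst frequency must lie within 2-50 Hz")
        if self.time_sd_s <= 0:
            raise ValueError("time_sd_s must be positive")


def _default_bursts() -> dict[str, BurstSpec]:
    return {
        "fixation": BurstSpec(4.0, 0.10, 0.050, base_amp_uv=6.0, gain_uv=2.0),
        "go": BurstSpec(4.0, 0.45, 0.120, base_amp_uv=6.0, gain_uv=-1.6),
        "stop": BurstSpec(16.0, 0.35, 0.025, base_amp_uv=6.0, gain_uv=4.0),
    }


@dataclass(frozen=True)
class EEGSimConfig:
    """Synthetic-EEG generator settings (single channel).

    ``noise_exponent`` is the 1/f slope of the background spectrum;
    ``noise_scale_uv`` its RMS amplitude.  Burst gains are pilot-calibrated
    so single-trial band power carries a modest rank correlation with the
    covariate, comparable to within-subject EEG-behavior effect sizes.
    ``pad_s`` extends each stored epoch beyond the analysis window for
    edge-free time-frequency transforms.
    """

    fs_hz: float = 250.0
    epoch_window_s: tuple[float, float] = (-0.5, 1.0)
    pad_s: float = 1.0
    noise_exponent: float = 1.0
    noise_scale_uv: float = 15.0
    bursts: dict[str, BurstSpec] = field(default_factory=_default_bursts)
    artifact_rate: float = 0.05
    artifact_amp_uv: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.epoch_window_s
        if not (lo <= -0.3 and hi >= -0.1):
            raise ValueError("epoch window must cover the baseline interval [-0.3, -0.1] s")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must be in [0, 1)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")


@dataclass
class EpochSet:
    """Epoched single-channel voltage: trials x samples, with alignment.

    ``trial_index`` maps each epoch row back to its row in the trial table
    (stop-locked epochs exist only for stop trials, go-locked only for
    successful go trials).
    """

    data: np.ndarray  # (n_trials, n_samples), uV
    times_s: np.ndarray
    fs_hz: float
    lock: str
    trial_index: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        if self.data.ndim != 2 or self.data.shape[1] != self.times_s.size:
            raise ValueError("data must be (n_trials, n_samples) matching times_s")
        if self.data.shape[0] != self.trial_index.size:
            raise ValueError("trial_index must have one entry per epoch")
        if self.lock not in LOCKS:
            raise ValueError(f"lock must be one of {LOCKS}")


def covariate_for_lock(trials: pd.DataFrame, lock: str) -> tuple[np.ndarray, np.ndarray]:
    """Trial subset and covariate values entering a given event lock.

    fixation -> P(stop) on all trials; go -> RT on successful go trials;
    stop -> prediction error on stop trials.
    """
    name = LOCK_COVARIATE[lock]
    if name not in trials.columns:
        raise ValueError(f"trial table lacks required covariate column {name!r}")
    if lock == "fixation":
        mask = np.ones(len(trials), dtype=bool)
    elif lock == "go":
        mask = (trials["outcome"] == "go_success").to_numpy()
    else:
        mask = (trials["trial_type"] == "stop").to_numpy()
    vals = trials.loc[mask, name].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError(f"covariate {name!r} is not finite on all {lock}-locked trials")
    return np.flatnonzero(mask), vals


def _one_over_f_noise(rng, n_trials, n_samples, fs, exponent, rms):
    """Spectrally shaped Gaussian noise with |X(f)| ~ f^(-exponent/2)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal((n_trials, n_samples))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * shape, n=n_samples, axis=1)
    scale = shaped.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return shaped / scale * rms


def simulate_epochs(
    trials: pd.DataFrame,
    cfg: EEGSimConfig,
    lock: str,
    rng: np.random.Generator | None = None,
) -> EpochSet:
    """Generate epochs for one event lock from a trial table with covariates."""
    if lock not in LOCKS:
        raise ValueError(f"lock must be one of {LOCKS}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    idx, cov = covariate_for_lock(trials, lock)
    n = idx.size
    if n == 0:
        raise ValueError(f"no trials available for {lock} lock")

    lo, hi = cfg.epoch_window_s
    dt = 1.0 / cfg.fs_hz
    times = np.arange(round((lo - cfg.pad_s) / dt), round((hi + cfg.pad_s) / dt) + 1) * dt
    data = _one_over_f_noise(
        rng, n, times.size, cfg.fs_hz, cfg.noise_exponent, cfg.noise_scale_uv
    )

    spec = cfg.bursts[lock]
    sd_cov = cov.std()
    z = (cov - cov.mean()) / sd_cov if sd_cov > 0 else np.zeros(n)
    amp = np.maximum(0.0, spec.base_amp_uv + spec.gain_uv * z)
    phase = rng.uniform(0.0, 2 * np.pi, n)
    env = np.exp(-((times - spec.center_time_s) ** 2) / (2 * spec.time_sd_s**2))
    carrier = 2 * np.pi * spec.center_freq_hz * (times - spec.center_time_s)
    data += amp[:, None] * env[None, :] * np.cos(carrier[None, :] + phase[:, None])

    # square artifact pulse, guaranteed > 150 uV peak-to-peak
    bad = rng.random(n) < cfg.artifact_rate
    if bad.any():
        start = rng.uniform(lo, hi - 0.1, n)
        for i in np.flatnonzero(bad):
            sel = (times >= start[i]) & (times < start[i] + 0.1)
            data[i, sel] += cfg.artifact_amp_uv
    return EpochSet(data=data, times_s=times, fs_hz=cfg.fs_hz, lock=lock, trial_index=idx)


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 150.0,
                     window_s: tuple[float, float] | None = None) -> EpochSet:
    """Drop epochs whose peak-to-peak voltage exceeds the threshold.

    The peak-to-peak check runs over the analysis window (defaults to the
    full stored epoch); surviving epochs keep their trial alignment.
    """
    if epochs.data.shape[0] == 0:
        raise ValueError("empty epoch set")
    tmask = (
        slice(None)
        if window_s is None
        else (epochs.times_s >= window_s[0]) & (epochs.times_s <= window_s[1])
    )
    ptp = np.ptp(epochs.data[:, tmask], axis=1)
    keep = ptp <= threshold_uv
    if not keep.any():
        raise ValueError("all epochs exceeded the artifact threshold")
    return EpochSet(
        data=epochs.data[keep],
        times_s=epochs.times_s,
        fs_hz=epochs.fs_hz,
        lock=epochs.lock,
        trial_index=epochs.trial_index[keep],
    )


def save_epochs(path, epochs: EpochSet) -> None:
    """Write an EpochSet to an HDF5 container (datasets data/times_s/trial_index)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times_s", data=epochs.times_s)
        f.create_dataset("trial_index", data=epochs.trial_index)
        f.attrs["fs_hz"] = epochs.fs_hz
        f.attrs["lock"] = epochs.lock


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times_s=f["times_s"][()],
            fs_hz=float(f.attrs["fs_hz"]),
            lock=str(f.attrs["lock"]),
            trial_index=f["trial_index"][()],
        )
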