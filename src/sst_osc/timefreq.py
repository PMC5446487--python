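"""Morlet wavelet time-frequency decomposition and baseline correction.

Power is computed by convolving each epoch with complex Morlet wavelets on a
logarithmic frequency axis (default: 59 bins, 2-50 Hz).  The wavelet's
temporal resolution is specified through the full-width-at-half-maximum
(FWHM) of its Gaussian amplitude envelope, expressed in oscillation periods:
1 period at the lowest bin up to 4 periods at the highest, interpolated
linearly across bin index (a linear-in-Hz interpolation is available).  The
Gaussian sd follows from sd = FWHM / (2 * sqrt(2 * ln 2)).

Wavelets are amplitude-normalized: a unit-amplitude sinusoid at a bin's
frequency yields peak power 1 at that bin regardless of frequency.  Epochs
are transformed on their padded extent and only then cropped to the analysis
window, so wavelet edge artifacts stay outside it.  Baseline correction
divides by (relative change) or subtracts the mean pre-event power per trial
and frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal

from .eeg_sim import EpochSet

__all__ = ["TFConfig", "TFEpochs", "morlet_transform", "baseline_correct",
           "save_tfr", "load_tfr"]

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _default_freqs() -> np.ndarray:
    return np.geomspace(2.0, 50.0, 59)


@dataclass(frozen=True)
class TFConfig:
    """Time-frequency decomposition settings."""

    freqs_hz: np.ndarray = field(default_factory=_default_freqs)
    fwhm_periods_low: float = 1.0
    fwhm_periods_high: float = 4.0
    width_interp: str = "index"  # or "hz"
    baseline_window_s: tuple[float, float] = (-0.3, -0.1)
    baseline_mode: str = "relative_change"  # or "subtract"
    crop_window_s: tuple[float, float] | None = (-0.5, 1.0)
    decimate: int = 1  # keep every n-th output sample

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=float)
        object.__setattr__(self, "freqs_hz", f)
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs_hz must be strictly increasing")
        if self.baseline_mode not in ("relative_change", "subtract"):
            raise ValueError("baseline_mode must be 'relative_change' or 'subtract'")
        if self.width_interp not in ("index", "hz"):
            raise ValueError("width_interp must be 'index' or 'hz'")
        if self.decimate < 1:
            raise ValueError("decimate must be >= 1")

    def fwhm_periods(self) -> np.ndarray:
        """Envelope FWHM in periods for every frequency bin."""
        f = self.freqs_hz
        if f.size == 1:
            return np.array([self.fwhm_periods_low])
        if self.width_interp == "index":
            x = np.linspace(0.0, 1.0, f.size)
        else:
            x = (f - f[0]) / (f[-1] - f[0])
        return self.fwhm_periods_low + x * (self.fwhm_periods_high - self.fwhm_periods_low)


@dataclass
class TFEpochs:
    """Single-trial power: trials x frequencies x times."""

    power: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    lock: str
    trial_index: np.ndarray
    baseline_applied: bool = False

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        if self.power.shape != (
            self.trial_index.size,
            self.freqs_hz.size,
            self.times_s.size,
        ):
            raise ValueError("power shape must be (n_trials, n_freqs, n_times)")


def _morlet_wavelet(freq: float, fwhm_s: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet, amplitude-normalized (see module docstring)."""
    sd = fwhm_s / _FWHM_TO_SD
    half = int(np.ceil(4 * sd * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-(t**2) / (2 * sd**2))
    w = env * np.exp(2j * np.pi * freq * t)
    # response of conj-symmetric convolution to cos(2*pi*f*t) has magnitude
    # ~ sum(env)/2; normalize so that magnitude (amplitude estimate) is 1
    return w * (2.0 / env.sum())


def morlet_transform(epochs: EpochSet, cfg: TFConfig | None = None) -> TFEpochs:
    """Morlet power per trial, frequency and time.

    The convolution runs over the full (padded) epoch; the output is cropped
    to ``cfg.crop_window_s`` and optionally decimated in time.
    """
    if cfg is None:
        cfg = TFConfig()
    nyq = epochs.fs_hz / 2.0
    if np.any(cfg.freqs_hz >= nyq):
        raise ValueError(f"frequencies must stay below Nyquist ({nyq} Hz)")
    fwhms = cfg.fwhm_periods() / cfg.freqs_hz  # seconds
    n_tr, n_t = epochs.data.shape
    power = np.empty((n_tr, cfg.freqs_hz.size, n_t))
    for i, (f, fw) in enumerate(zip(cfg.freqs_hz, fwhms)):
        w = _morlet_wavelet(f, fw, epochs.fs_hz)
        z = signal.fftconvolve(epochs.data, w[None, :], mode="same", axes=1)
        power[:, i, :] = np.abs(z) ** 2

    times = epochs.times_s
    if cfg.crop_window_s is not None:
        lo, hi = cfg.crop_window_s
        sel = (times >= lo - 1e-9) & (times <= hi + 1e-9)
        power, times = power[:, :, sel], times[sel]
    if cfg.decimate > 1:
        power, times = power[:, :, :: cfg.decimate], times[:: cfg.decimate]
    return TFEpochs(
        power=power,
        freqs_hz=cfg.freqs_hz.copy(),
        times_s=times,
        lock=epochs.lock,
        trial_index=epochs.trial_index.copy(),
    )


def baseline_correct(tf: TFEpochs, cfg: TFConfig | None = None) -> TFEpochs:
    """Baseline-correct power per trial and frequency bin.

    relative_change: P/B - 1;  subtract: P - B, with B the mean power over
    the baseline window.  Refuses to run twice on the same data.
    """
    if cfg is None:
        cfg = TFConfig()
    if tf.baseline_applied:
        raise ValueError("baseline correction was already applied")
    lo, hi = cfg.baseline_window_s
    sel = (tf.times_s >= lo - 1e-9) & (tf.times_s <= hi + 1e-9)
    if not sel.any():
        raise ValueError("baseline window lies outside the epoch")
    base = tf.power[:, :, sel].mean(axis=2, keepdims=True)
    if cfg.baseline_mode == "relative_change":
        if np.any(base <= 0):
            raise ValueError("zero baseline power; cannot form relative change")
        out = tf.power / base - 1.0
    else:
        out = tf.power - base
    return TFEpochs(
        power=out,
        freqs_hz=tf.freqs_hz,
        times_s=tf.times_s,
        lock=tf.lock,
        trial_index=tf.trial_index,
        baseline_applied=True,
    )


def save_tfr(path, tf: TFEpochs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=tf.power)
        f.create_dataset("freqs_hz", data=tf.freqs_hz)
        f.create_dataset("times_s", data=tf.times_s)
        f.create_dataset("trial_index", data=tf.trial_index)
        f.attrs["lock"] = tf.lock
        f.attrs["baseline_applied"] = tf.baseline_applied


def load_tfr(path) -> TFEpochs:
    with h5py.File(path, "r") as f:
        return TFEpochs(
            power=f["power"][()],
            freqs_hz=f["freqs_hz"][()],
            times_s=f["times_s"][()],
            trial_index=f["trial_index"][()],
            lock=str(f.attrs["lock"]),
            baseline_applied=bool(f.attrs["baseline_applied"]),
        )
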