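"""Grid-search fitting of observer parameters to the behavioral sequential effect.

For each candidate (alpha, pm) pair on a fixed grid (sc held at 10), the
observer is run over the subject's full go/stop sequence and the resulting
P(stop) trace is Pearson-correlated with reaction time over successful go
trials.  The fitted parameters are the grid point maximizing that
correlation — the strength of the sequential effect.  Group-level analyses
then recompute each subject's trace with the group-averaged parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observer import ObserverParams, run_sequence_batch

__all__ = ["FitGrid", "FitResult", "fit_subject", "group_average_params"]


def _default_alphas() -> np.ndarray:
    return np.round(np.arange(1, 50) * 0.02, 10)  # 0.02 .. 0.98


def _default_pms() -> np.ndarray:
    return np.round(0.01 + np.arange(25) * 0.02, 10)  # 0.01 .. 0.49


@dataclass(frozen=True)
class FitGrid:
    """Search grid over (alpha, pm) with sc fixed."""

    alpha_values: np.ndarray = field(default_factory=_default_alphas)
    pm_values: np.ndarray = field(default_factory=_default_pms)
    sc_fixed: float = 10.0

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha_values, dtype=float)
        p = np.asarray(self.pm_values, dtype=float)
        object.__setattr__(self, "alpha_values", a)
        object.__setattr__(self, "pm_values", p)
        if np.any((a < 0) | (a > 1)):
            raise ValueError("alpha values must lie in [0, 1]")
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("pm values must lie in (0, 1)")


@dataclass
class FitResult:
    """Best-fitting observer parameters and the full correlation surface."""

    best_params: ObserverParams
    best_r: float
    r_surface: np.ndarray  # shape (n_alpha, n_pm)
    alpha_values: np.ndarray
    pm_values: np.ndarray


def fit_subject(
    trials: pd.DataFrame,
    grid: FitGrid | None = None,
    readout: str = "map",
    grid_size: int = 200,
) -> FitResult:
    """Fit (alpha, pm) for one subject by maximizing the sequential effect.

    The observer consumes the full go/stop sequence; the correlation is
    computed over successful go trials only (premature/omitted responses and
    stop trials carry no usable RT).  Ties in the argmax resolve to the
    larger alpha, then the larger pm.

    Raises
    ------
    ValueError
        If fewer than 20 successful go trials with finite RT exist, or the
        RT vector is constant (correlation undefined).
    """
    if grid is None:
        grid = FitGrid()
    s = (trials["trial_type"] == "stop").to_numpy().astype(int)
    go_ok = (trials["outcome"] == "go_success").to_numpy() & np.isfinite(
        trials["rt_ms"].to_numpy()
    )
    rt = trials.loc[go_ok, "rt_ms"].to_numpy(dtype=float)
    if rt.size < 20:
        raise ValueError(f"need >= 20 successful go trials with finite RT, got {rt.size}")
    if np.std(rt) == 0:
        raise ValueError("RT is constant; correlation undefined")

    traces = run_sequence_batch(
        s, grid.alpha_values, grid.pm_values, sc=grid.sc_fixed,
        readout=readout, grid_size=grid_size,
    )
    x = traces[:, :, go_ok]  # (n_alpha, n_pm, n_go)
    xm = x - x.mean(axis=2, keepdims=True)
    ym = rt - rt.mean()
    denom = np.sqrt((xm**2).sum(axis=2) * (ym**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r_surface = (xm @ ym) / denom
    r_surface = np.where(denom > 0, r_surface, -np.inf)

    best = r_surface.max()
    ia, ip = np.argwhere(r_surface == best)[-1]  # row-major: last hit has the
    # largest alpha; among equal alphas the largest pm
    best_params = ObserverParams(
        alpha=float(grid.alpha_values[ia]),
        pm=float(grid.pm_values[ip]),
        sc=float(grid.sc_fixed),
        readout=readout,
        grid_size=grid_size,
    )
    return FitResult(
        best_params=best_params,
        best_r=float(best),
        r_surface=r_surface,
        alpha_values=grid.alpha_values,
        pm_values=grid.pm_values,
    )


def group_average_params(fits: list[FitResult]) -> ObserverParams:
    """Arithmetic mean of fitted alpha and pm across subjects (sc fixed).

    The group-averaged parameters are what the pipeline uses to recompute
    every subject's P(stop)/PE trace for the EEG analyses.
    """
    if not fits:
        raise ValueError("need at least one fit")
    alphas = [f.best_params.alpha for f in fits]
    pms = [f.best_params.pm for f in fits]
    ref = fits[0].best_params
    return ObserverParams(
        alpha=float(np.mean(alphas)),
        pm=float(np.mean(pms)),
        sc=ref.sc,
        readout=ref.readout,
        grid_size=ref.grid_size,
    )
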