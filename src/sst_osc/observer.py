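"""Dynamic Bayesian observer for trial-by-trial stop-signal anticipation.

The observer assumes each trial k carries a stop signal with probability
``r_k``.  Between trials the rate either persists (probability ``alpha``) or
is resampled from a fixed beta prior with mean ``pm`` and concentration
``sc`` (``beta(a, b)`` with ``a = pm*sc``, ``b = (1-pm)*sc``).  Under these
assumptions the predictive distribution for trial k is a mixture of the
previous posterior and the generic prior,

    p(r_k | s_1..k-1) = alpha * p(r_{k-1} | s_1..k-1) + (1 - alpha) * pi(r),

and the Bayes update after observing trial type ``s_k`` (1 = stop) multiplies
by the Bernoulli likelihood ``r`` or ``1 - r``.  The trial-wise stop-signal
belief P(stop) is the readout of the predictive distribution *before* the
trial outcome is seen: either its mean (the exact predictive probability) or
its maximum a posteriori (MAP) point, which is how the belief is approximated
here by default.  On stop trials the stimulus prediction error (Bayesian
surprise) is ``1 - P(stop)``.

The alpha-mixture destroys beta conjugacy, so beliefs are represented
numerically on a fixed midpoint grid over (0, 1).  With ``alpha = 1`` the
model reduces to exact beta-Bernoulli updating, which the tests use as a
closed-form check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ObserverParams",
    "BeliefState",
    "PstopTrace",
    "init_prior",
    "predict_step",
    "update_step",
    "pstop_readout",
    "run_sequence",
    "exponential_filter_pstop",
]


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the dynamic Bayesian observer.

    Parameters
    ----------
    alpha : float
        Persistence probability of the stop rate across trials, in [0, 1].
        ``alpha = 1`` never resamples (pure beta-Bernoulli accumulation);
        ``alpha = 0`` resamples every trial (no memory).
    pm : float
        Mean of the generic beta prior over the stop rate, in (0, 1).
    sc : float
        Concentration (a + b) of the generic beta prior; larger is tighter.
    readout : {"map", "mean"}
        How P(stop) is read off the predictive distribution.
    grid_size : int
        Number of midpoint cells discretizing (0, 1).
    """

    alpha: float
    pm: float
    sc: float = 10.0
    readout: str = "map"
    grid_size: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 < self.pm < 1.0:
            raise ValueError(f"pm must be strictly inside (0, 1), got {self.pm}")
        if self.sc <= 0:
            raise ValueError(f"sc must be positive, got {self.sc}")
        if self.readout not in ("map", "mean"):
            raise ValueError(f"readout must be 'map' or 'mean', got {self.readout!r}")
        if self.grid_size < 10:
            raise ValueError(f"grid_size must be >= 10, got {self.grid_size}")

    @property
    def a(self) -> float:
        return self.pm * self.sc

    @property
    def b(self) -> float:
        return (1.0 - self.pm) * self.sc


@dataclass
class BeliefState:
    """Discretized belief over the stop rate r.

    ``mass`` holds Riemann probability masses on the strictly increasing
    midpoint grid ``r_grid``; it sums to one.
    """

    r_grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.r_grid.shape != self.mass.shape or self.r_grid.ndim != 1:
            raise ValueError("r_grid and mass must be 1-d arrays of equal length")
        if np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r_grid must be strictly increasing")
        if np.any(self.mass < 0):
            raise ValueError("mass must be nonnegative")
        if abs(self.mass.sum() - 1.0) > 1e-12:
            raise ValueError("mass must sum to 1 within 1e-12")

    @property
    def mean(self) -> float:
        """Expected stop rate under this belief."""
        return float(np.dot(self.r_grid, self.mass))

    @property
    def map(self) -> float:
        """Grid point of maximal mass; ties resolve to the lowest r."""
        return float(self.r_grid[int(np.argmax(self.mass))])


@dataclass
class PstopTrace:
    """Per-trial P(stop) and, on stop trials, prediction error (1 - P(stop)).

    ``pe`` is NaN on go trials, where surprise at a stop signal is undefined.
    """

    pstop: np.ndarray
    pe: np.ndarray

    def __post_init__(self) -> None:
        self.pstop = np.asarray(self.pstop, dtype=float)
        self.pe = np.asarray(self.pe, dtype=float)
        if self.pstop.shape != self.pe.shape:
            raise ValueError("pstop and pe must have equal length")


def _midpoint_grid(grid_size: int) -> np.ndarray:
    return (np.arange(grid_size) + 0.5) / grid_size


def init_prior(params: ObserverParams) -> BeliefState:
    """Generic prior pi(r): beta(pm*sc, (1-pm)*sc) discretized on the grid."""
    r = _midpoint_grid(params.grid_size)
    dens = stats.beta.pdf(r, params.a, params.b)
    total = dens.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("degenerate prior density on the grid")
    return BeliefState(r_grid=r, mass=dens / total)


def predict_step(posterior: BeliefState, params: ObserverParams) -> BeliefState:
    """One-trial-ahead predictive belief: mix posterior with the generic prior."""
    prior = init_prior(params)
    if prior.r_grid.shape != posterior.r_grid.shape or not np.allclose(
        prior.r_grid, posterior.r_grid
    ):
        raise ValueError("posterior grid does not match params.grid_size")
    mass = params.alpha * posterior.mass + (1.0 - params.alpha) * prior.mass
    return BeliefState(r_grid=posterior.r_grid, mass=mass / mass.sum())


def update_step(prior: BeliefState, s_k: int) -> BeliefState:
    """Bayes update of a predictive belief with the observed trial type."""
    if s_k not in (0, 1):
        raise ValueError(f"s_k must be 0 or 1, got {s_k}")
    lik = prior.r_grid if s_k == 1 else 1.0 - prior.r_grid
    mass = prior.mass * lik
    total = mass.sum()
    if total <= 0:
        raise ValueError("posterior mass vanished; pathological grid or prior")
    return BeliefState(r_grid=prior.r_grid, mass=mass / total)


def pstop_readout(predictive: BeliefState, readout: str = "map") -> float:
    """Read P(stop) off a predictive belief (mean or MAP point)."""
    if readout == "mean":
        return predictive.mean
    if readout == "map":
        return predictive.map
    raise ValueError(f"readout must be 'map' or 'mean', got {readout!r}")


def run_sequence(s, params: ObserverParams) -> PstopTrace:
    """Run the observer over a go/stop sequence and return the P(stop) trace.

    P(stop) on trial k is read off the predictive distribution *before*
    ``s[k]`` is observed; trial 1 uses the generic prior.  ``pe = 1 - pstop``
    on stop trials, NaN on go trials.
    """
    s = np.asarray(s, dtype=int)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("s must be a nonempty 1-d sequence")
    if not np.isin(s, (0, 1)).all():
        raise ValueError("s may contain only 0 (go) and 1 (stop)")

    prior = init_prior(params)
    r, prior_mass = prior.r_grid, prior.mass
    mass = prior_mass.copy()
    one_minus_r = 1.0 - r
    pstop = np.empty(s.size)
    for k, s_k in enumerate(s):
        if k > 0:
            mass = params.alpha * mass + (1.0 - params.alpha) * prior_mass
            mass /= mass.sum()
        if params.readout == "mean":
            pstop[k] = np.dot(r, mass)
        else:
            pstop[k] = r[int(np.argmax(mass))]
        mass = mass * (r if s_k == 1 else one_minus_r)
        mass /= mass.sum()
    pe = np.where(s == 1, 1.0 - pstop, np.nan)
    return PstopTrace(pstop=pstop, pe=pe)


def run_sequence_batch(
    s,
    alphas,
    pms,
    sc: float = 10.0,
    readout: str = "map",
    grid_size: int = 200,
) -> np.ndarray:
    """P(stop) traces for every (alpha, pm) pair at once.

    Vectorized equivalent of calling :func:`run_sequence` on the outer product
    of ``alphas`` and ``pms``; returns an array of shape
    ``(len(alphas), len(pms), len(s))``.  Used by the grid-search fit.
    """
    s = np.asarray(s, dtype=int)
    alphas = np.asarray(alphas, dtype=float)
    pms = np.asarray(pms, dtype=float)
    r = _midpoint_grid(grid_size)
    # prior mass per pm: shape (n_pm, G)
    prior_mass = stats.beta.pdf(r[None, :], pms[:, None] * sc, (1 - pms[:, None]) * sc)
    prior_mass /= prior_mass.sum(axis=1, keepdims=True)

    n_a, n_p = alphas.size, pms.size
    mass = np.broadcast_to(prior_mass[None, :, :], (n_a, n_p, grid_size)).copy()
    al = alphas[:, None, None]
    pstop = np.empty((n_a, n_p, s.size))
    for k, s_k in enumerate(s):
        if k > 0:
            mass = al * mass + (1.0 - al) * prior_mass[None, :, :]
            mass /= mass.sum(axis=2, keepdims=True)
        if readout == "mean":
            pstop[:, :, k] = mass @ r
        else:
            pstop[:, :, k] = r[np.argmax(mass, axis=2)]
        mass = mass * (r if s_k == 1 else 1.0 - r)
        mass /= mass.sum(axis=2, keepdims=True)
    return pstop


def exponential_filter_pstop(s, decay: float, init: float = 0.25) -> np.ndarray:
    """Causal exponentially weighted running estimate of the stop rate.

    Returns the estimate *before* each trial's outcome:
    ``p[0] = init``, ``p[k] = decay * p[k-1] + (1 - decay) * s[k-1]``.
    The dynamic observer's predictive mean is approximately such a filter;
    the equivalence is checked as a correlation property in the tests.
    """
    s = np.asarray(s, dtype=float)
    if not 0.0 < decay < 1.0:
        raise ValueError(f"decay must be in (0, 1), got {decay}")
    p = np.empty(s.size)
    prev = float(init)
    for k in range(s.size):
        p[k] = prev
        prev = decay * prev + (1.0 - decay) * s[k]
    return p
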