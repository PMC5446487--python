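"""Synthetic stop-signal task behavior.

Generates randomized go/stop sequences with variable foreperiods, then
simulates a responder whose go process races an independent stop process.
The responder runs the dynamic Bayesian observer online, and its go finishing
time slows linearly with the current stop-signal belief:

    T_go = rt_base + slowing_slope * P(stop) + N(0, rt_noise_sd)   [ms]

On stop trials the stop process finishes at SSD + SSRT; the stop wins (stop
success, no button press) iff it finishes before the go process, otherwise
the press at T_go is a stop error.  The stop-signal delay follows a
one-up-one-down staircase (+step after a stop success, -step after a stop
error), which drives the long-run stop-success rate toward 50%.  Go responses
slower than the response window are omissions.

Trial tables are plain pandas DataFrames (one row per trial) serialized as
CSV; see :data:`TRIAL_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observer import ObserverParams, init_prior

__all__ = [
    "TaskConfig",
    "RaceConfig",
    "TRIAL_COLUMNS",
    "generate_sequence",
    "simulate_responder",
    "simulate_cohort",
]

#: Column order of a serialized trial table.
TRIAL_COLUMNS = [
    "trial",
    "trial_type",
    "foreperiod_s",
    "ssd_ms",
    "rt_ms",
    "outcome",
    "pstop",
    "pe",
]


@dataclass(frozen=True)
class TaskConfig:
    """Stop-signal task schedule parameters.

    Defaults mirror a standard laboratory session: 400 trials with ~3:1
    go:stop mixing, 1-3 s foreperiods, a staircased stop-signal delay
    starting at 200 ms with 64 ms steps, and a 1 s response window.
    """

    n_trials: int = 400
    stop_fraction: float = 0.25
    iti_s: float = 2.0
    foreperiod_range_s: tuple[float, float] = (1.0, 3.0)
    ssd_initial_ms: float = 200.0
    ssd_step_ms: float = 64.0
    response_window_ms: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.stop_fraction < 1.0:
            raise ValueError("stop_fraction must be in [0, 1)")
        if not 0.0 <= self.ssd_initial_ms <= self.response_window_ms:
            raise ValueError("initial SSD must lie within [0, response window]")
        lo, hi = self.foreperiod_range_s
        if lo <= 0 or hi < lo:
            raise ValueError("foreperiod range must be positive and ordered")


@dataclass(frozen=True)
class RaceConfig:
    """Generative parameters of the simulated responder.

    ``rt_base_ms``, ``slowing_slope_ms`` and ``rt_noise_sd_ms`` define the go
    finishing time; ``ssrt_true_ms`` is the latency of the covert stop
    process.  ``go_mu_ms`` and ``go_sd_ms`` describe the cohort-level go-RT
    distribution these defaults are calibrated to produce (base 345 ms plus
    300 ms/unit slowing at typical beliefs ~ 405 ms mean) and serve as
    validation targets; they do not enter the trial-level generator.
    """

    go_mu_ms: float = 405.0
    go_sd_ms: float = 64.0
    ssrt_true_ms: float = 216.0
    slowing_slope_ms: float = 300.0
    rt_base_ms: float = 345.0
    rt_noise_sd_ms: float = 60.0
    go_omission_rate: float = 0.016

    def __post_init__(self) -> None:
        if self.rt_noise_sd_ms < 0:
            raise ValueError("rt_noise_sd_ms must be nonnegative")
        if self.ssrt_true_ms <= 0 or self.rt_base_ms <= 0:
            raise ValueError("latencies must be positive")


def generate_sequence(cfg: TaskConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Randomized trial types and foreperiods (no responses yet).

    Trial types are i.i.d. Bernoulli(``stop_fraction``); foreperiods are
    uniform on the configured range.  Reproducible from ``cfg.seed`` when no
    generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    is_stop = rng.random(cfg.n_trials) < cfg.stop_fraction
    lo, hi = cfg.foreperiod_range_s
    fp = rng.uniform(lo, hi, cfg.n_trials)
    return pd.DataFrame(
        {
            "trial": np.arange(cfg.n_trials),
            "trial_type": np.where(is_stop, "stop", "go"),
            "foreperiod_s": fp,
        }
    )


def simulate_responder(
    seq: pd.DataFrame,
    race: RaceConfig,
    observer_params: ObserverParams,
    cfg: TaskConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Race-model outcomes, staircased SSDs and belief-slowed go RTs.

    The observer runs online over the true trial types; its predictive
    readout before each trial is the P(stop) that slows the go process.  The
    returned table carries ``pstop`` and ``pe`` (the generative trace).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = len(seq)
    is_stop = (seq["trial_type"] == "stop").to_numpy()

    prior = init_prior(observer_params)
    r, prior_mass = prior.r_grid, prior.mass
    mass = prior_mass.copy()
    alpha = observer_params.alpha

    ssd = float(cfg.ssd_initial_ms)
    win = cfg.response_window_ms
    noise = rng.normal(0.0, race.rt_noise_sd_ms, n)

    pstop = np.empty(n)
    ssd_ms = np.full(n, np.nan)
    rt_ms = np.full(n, np.nan)
    outcome = np.empty(n, dtype=object)

    for k in range(n):
        if k > 0:
            mass = alpha * mass + (1.0 - alpha) * prior_mass
            mass /= mass.sum()
        if observer_params.readout == "mean":
            p = float(np.dot(r, mass))
        else:
            p = float(r[int(np.argmax(mass))])
        pstop[k] = p

        t_go = race.rt_base_ms + race.slowing_slope_ms * p + noise[k]
        if is_stop[k]:
            ssd_ms[k] = ssd
            t_stop = ssd + race.ssrt_true_ms
            # no press within the window also counts as a successful stop
            if t_stop < t_go or t_go > win:
                outcome[k] = "stop_success"
                ssd = min(ssd + cfg.ssd_step_ms, win)
            else:
                outcome[k] = "stop_error"
                rt_ms[k] = t_go
                ssd = max(ssd - cfg.ssd_step_ms, 0.0)
        else:
            if t_go > win:
                outcome[k] = "go_omit"
            else:
                outcome[k] = "go_success"
                rt_ms[k] = t_go

        mass = mass * (r if is_stop[k] else 1.0 - r)
        mass /= mass.sum()

    out = seq.copy()
    out["ssd_ms"] = ssd_ms
    out["rt_ms"] = rt_ms
    out["outcome"] = outcome
    out["pstop"] = pstop
    out["pe"] = np.where(is_stop, 1.0 - pstop, np.nan)
    return out[TRIAL_COLUMNS]


def simulate_cohort(
    n_subjects: int,
    cfg: TaskConfig,
    race: RaceConfig,
    observer_params: ObserverParams,
    seed: int | None = None,
    go_mu_jitter_sd_ms: float = 30.0,
) -> list[pd.DataFrame]:
    """Independent per-subject task simulations from one master seed.

    Each subject gets an independent random stream and, by default, a
    Gaussian between-subject offset (sd 30 ms) of the go-RT base, emulating
    cohort spread in mean go-RT.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.default_rng(cfg.seed if seed is None else seed)
    tables = []
    for _ in range(n_subjects):
        rng = np.random.default_rng(master.integers(2**31))
        offset = rng.normal(0.0, go_mu_jitter_sd_ms) if go_mu_jitter_sd_ms > 0 else 0.0
        subj_race = RaceConfig(
            go_mu_ms=race.go_mu_ms + offset,
            go_sd_ms=race.go_sd_ms,
            ssrt_true_ms=race.ssrt_true_ms,
            slowing_slope_ms=race.slowing_slope_ms,
            rt_base_ms=race.rt_base_ms + offset,
            rt_noise_sd_ms=race.rt_noise_sd_ms,
            go_omission_rate=race.go_omission_rate,
        )
        seq = generate_sequence(cfg, rng)
        tables.append(simulate_responder(seq, subj_race, observer_params, cfg, rng))
    return tables
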