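"""Delimited-text serialization of trial tables."""

from __future__ import annotations

import pandas as pd

from .behavior_sim import TRIAL_COLUMNS


def save_trials(path, trials: pd.DataFrame) -> None:
    """Write a trial table as CSV with the canonical column order."""
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    trials[cols].to_csv(path, index=False)


def load_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"trial", "trial_type", "outcome"} - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df
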