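"""Spike dataset container, validation, and CSV/HDF5 readers and writers.

A :class:`SpikeDataset` holds three tables:

* ``units``:  unit_id, session, state ("estrus"/"non_estrus")
* ``trials``: trial_id, session, stimulus (panel token), t_application, t_snt (s)
* ``spikes``: unit_id, session, time (s, origin at session start)

The CSV form is a directory with ``units.csv``, ``trials.csv``,
``spikes.csv``; the HDF5 form is one file with the same three tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stimuli import PANEL_TOKENS, parse_label

logger = logging.getLogger(__name__)

__all__ = ["SpikeDataset", "SchemaError", "read_dataset", "write_dataset"]

STATES = ("estrus", "non_estrus")

_UNIT_COLS = ["unit_id", "session", "state"]
_TRIAL_COLS = ["trial_id", "session", "stimulus", "t_application", "t_snt"]
_SPIKE_COLS = ["unit_id", "session", "time"]


class SchemaError(ValueError):
    """Dataset violates the schema; message lists offending rows."""


@dataclass
class SpikeDataset:
    """Units, trials, and spike timestamps for a set of recording sessions."""

    units: pd.DataFrame
    trials: pd.DataFrame
    spikes: pd.DataFrame
    stimuli: list[str] = field(default_factory=lambda: list(PANEL_TOKENS))

    def __post_init__(self) -> None:
        self.units = self.units.reset_index(drop=True)
        self.trials = self.trials.reset_index(drop=True)
        self.spikes = self.spikes.reset_index(drop=True)
        self._spikes_by_unit: dict | None = None

    # -- validation ---------------------------------------------------------
    def validate(self) -> "SpikeDataset":
        problems: list[str] = []
        for name, df, cols in (("units", self.units, _UNIT_COLS),
                               ("trials", self.trials, _TRIAL_COLS),
                               ("spikes", self.spikes, _SPIKE_COLS)):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                problems.append(f"{name}: missing columns {missing}")
        if problems:
            raise SchemaError("; ".join(problems))

        bad_state = self.units.loc[~self.units["state"].isin(STATES)]
        if len(bad_state):
            problems.append(f"units with invalid state (rows {list(bad_state.index)})")

        dup = self.units.loc[self.units["unit_id"].duplicated()]
        if len(dup):
            problems.append(f"duplicate unit ids (rows {list(dup.index)})")

        for tok in self.trials["stimulus"].unique():
            try:
                parse_label(tok)
            except ValueError:
                problems.append(f"trials with unknown stimulus token {tok!r}")
        bad_panel = self.trials.loc[~self.trials["stimulus"].isin(self.stimuli)]
        if len(bad_panel):
            problems.append(
                f"trials with stimulus outside the panel (rows {list(bad_panel.index)})"
            )

        bad_t = self.trials.loc[self.trials["t_snt"] <= self.trials["t_application"]]
        if len(bad_t):
            problems.append(
                f"trials with t_snt <= t_application (rows {list(bad_t.index)})"
            )

        neg = self.spikes.loc[self.spikes["time"] < 0]
        if len(neg):
            problems.append(f"spikes before session start (rows {list(neg.index[:10])}...)")

        known_units = set(self.units["unit_id"])
        orphan = self.spikes.loc[~self.spikes["unit_id"].isin(known_units)]
        if len(orphan):
            problems.append(f"spikes for unknown units (rows {list(orphan.index[:10])}...)")

        if problems:
            raise SchemaError("; ".join(problems))
        return self

    # -- access -------------------------------------------------------------
    def unit_spikes(self, unit_id) -> np.ndarray:
        if self._spikes_by_unit is None:
            self._spikes_by_unit = {
                uid: np.sort(grp["time"].to_numpy(dtype=float))
                for uid, grp in self.spikes.groupby("unit_id")
            }
        return self._spikes_by_unit.get(unit_id, np.empty(0))

    def session_trials(self, session) -> pd.DataFrame:
        return self.trials.loc[self.trials["session"] == session]

    @property
    def n_units(self) -> int:
        return len(self.units)

    def equals(self, other: "SpikeDataset") -> bool:
        def norm(df, cols):
            return df[cols].reset_index(drop=True)
        return (
            norm(self.units, _UNIT_COLS).equals(norm(other.units, _UNIT_COLS))
            and norm(self.trials, _TRIAL_COLS).equals(norm(other.trials, _TRIAL_COLS))
            and norm(self.spikes, _SPIKE_COLS).equals(norm(other.spikes, _SPIKE_COLS))
        )


# ---------------------------------------------------------------------------
# Readers / writers


def write_dataset(dataset: SpikeDataset, path: str | Path, format: str = "csv") -> Path:
    """Write a dataset as a CSV directory (``format='csv'``) or an HDF5 file."""
    path = Path(path)
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        # %.17g + round_trip parsing on read keeps float64 times bit-exact
        dataset.units[_UNIT_COLS].to_csv(path / "units.csv", index=False)
        dataset.trials[_TRIAL_COLS].to_csv(path / "trials.csv", index=False,
                                           float_format="%.17g")
        dataset.spikes[_SPIKE_COLS].to_csv(path / "spikes.csv", index=False,
                                           float_format="%.17g")
    elif format == "hdf5":
        with pd.HDFStore(path, mode="w") as store:
            store.put("units", dataset.units[_UNIT_COLS], format="table")
            store.put("trials", dataset.trials[_TRIAL_COLS], format="table")
            store.put("spikes", dataset.spikes[_SPIKE_COLS], format="table")
    else:
        raise ValueError(f"unknown format {format!r} (use 'csv' or 'hdf5')")
    return path


def read_dataset(path: str | Path, format: str | None = None) -> SpikeDataset:
    """Read and validate a dataset written by :func:`write_dataset`."""
    path = Path(path)
    if format is None:
        format = "csv" if path.is_dir() else "hdf5"
    if format == "csv":
        try:
            units = pd.read_csv(path / "units.csv")
            trials = pd.read_csv(path / "trials.csv", float_precision="round_trip")
            spikes = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
        except FileNotFoundError as exc:
            raise SchemaError(f"missing dataset table under {path}: {exc}") from exc
    elif format == "hdf5":
        with pd.HDFStore(path, mode="r") as store:
            units = store["units"]
            trials = store["trials"]
            spikes = store["spikes"]
    else:
        raise ValueError(f"unknown format {format!r}")
    trials = trials.astype({"t_application": float, "t_snt": float})
    spikes = spikes.astype({"time": float})
    return SpikeDataset(units=units, trials=trials, spikes=spikes).validate()
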