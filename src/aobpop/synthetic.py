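"""Synthetic spike-train and response-matrix generators with known ground truth.

The generator emulates the experimental design the analyses assume: the
canonical 11-stimulus panel presented in randomized blocks (5 repeats by
default), a 17 s pre-application baseline, a 20 s application-to-SNT delay,
and a response window ending 40 s after SNT stimulation, with an 18 s
inter-trial interval. Spikes are drawn from a piecewise-homogeneous Poisson
process: the unit's baseline rate outside the response window, baseline plus
a per-stimulus evoked rate change within it. Rate changes are mostly
excitatory (85% by default); suppressive changes are negative and the total
rate is clipped at 0 Hz.

Selectivity is controlled by a breadth mixture over the number of effective
stimuli per unit (skewed toward one stimulus with extra mass at all eleven),
and structure can be implanted: a configurable fraction of units per state is
constructed to fulfil a named receptive-field pattern, and state-specific
multiplicative gains can be applied to chosen stimuli.

Two entry points share the same ground-truth draw: ``generate_spike_dataset``
produces spike timestamps for the full pipeline, and
``generate_response_matrix`` shortcuts straight to a magnitude matrix (true
rate change plus Gaussian noise) for fast statistical tests of downstream
modules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import SpikeDataset
from .patterns import PatternRegistry, default_registry, fulfills
from .quantify import ResponseMatrix
from .stimuli import PANEL_TOKENS

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "GroundTruth", "generate_spike_dataset",
           "generate_response_matrix"]

#: Default mixture over the number of effective stimuli per unit (0..11).
#: Skewed toward single-stimulus responders with extra mass at the full
#: panel, emulating the observed breadth distribution (mode at 1, a
#: secondary bump at 11, and a sizeable unresponsive fraction).
DEFAULT_BREADTH = {
    0: 0.25, 1: 0.30, 2: 0.10, 3: 0.07, 4: 0.05, 5: 0.04,
    6: 0.03, 7: 0.03, 8: 0.03, 9: 0.02, 10: 0.02, 11: 0.06,
}


@dataclass
class StateGain:
    """Multiplicative gain on the evoked rate change of some stimuli in one state."""

    stimuli: list[str]
    state: str
    gain: float


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic experiment; the seed fully determines output."""

    n_units_per_state: int = 100
    stimuli: list[str] = field(default_factory=lambda: list(PANEL_TOKENS))
    trials_per_stimulus: int = 5
    snt_delay: float = 20.0             # s, application -> SNT
    response_tail: float = 40.0         # s, SNT -> window end
    baseline_duration: float = 17.0     # s
    iti: float = 18.0                   # s between presentations
    baseline_lognormal: tuple[float, float] = (0.0, 1.0)  # (mu, sigma) of log rate, Hz
    p_excitatory: float = 0.85
    effect_gamma: tuple[float, float] = (2.0, 1.5)        # (shape, scale), Hz
    breadth_weights: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_BREADTH))
    implanted_patterns: dict[str, float | dict[str, float]] = field(default_factory=dict)
    state_gain: list[StateGain] = field(default_factory=list)
    matrix_noise_sd: float = 0.5        # Hz, matrix-level shortcut only
    units_per_session: int = 8
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_units_per_state < 1:
            raise ValueError("n_units_per_state must be >= 1")
        if not 0.0 <= self.p_excitatory <= 1.0:
            raise ValueError("p_excitatory must lie in [0, 1]")
        w = np.array(list(self.breadth_weights.values()), dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("breadth weights must be nonnegative with positive sum")
        if any(k < 0 or k > len(self.stimuli) for k in self.breadth_weights):
            raise ValueError("breadth counts must lie in [0, n_stimuli]")
        for state in ("estrus", "non_estrus"):
            total = sum(self._prevalence(pid, state) for pid in self.implanted_patterns)
            if total > 1.0 + 1e-12:
                raise ValueError(f"implanted prevalences for {state} exceed 1")
        if self.matrix_noise_sd < 0:
            raise ValueError("matrix_noise_sd must be >= 0")
        return self

    def _prevalence(self, pattern_id: str, state: str) -> float:
        v = self.implanted_patterns[pattern_id]
        return float(v[state]) if isinstance(v, dict) else float(v)

    @property
    def slot_duration(self) -> float:
        return self.baseline_duration + self.snt_delay + self.response_tail + self.iti


@dataclass
class GroundTruth:
    """Generating parameters per unit, for recovery tests.

    ``units`` holds state, session, baseline rate, and the implanted pattern
    id (or None); ``delta`` holds the true evoked rate change (Hz) per unit
    and stimulus, after state gains.
    """

    units: pd.DataFrame          # index unit_id: state, session, baseline_rate, pattern
    delta: pd.DataFrame          # index unit_id, columns stimuli

    def to_json(self, path: str | Path) -> None:
        payload = {
            "units": self.units.reset_index().to_dict(orient="list"),
            "delta": {
                "index": list(self.delta.index),
                "columns": list(self.delta.columns),
                "values": self.delta.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        units = pd.DataFrame(payload["units"]).set_index("unit_id")
        d = payload["delta"]
        delta = pd.DataFrame(d["values"], index=d["index"], columns=d["columns"])
        return cls(units=units, delta=delta)


# ---------------------------------------------------------------------------
# Ground-truth draw


def _pattern_delta(pattern, stimuli: list[str], rng: np.random.Generator) -> np.ndarray:
    """A rate-change vector guaranteed to fulfil ``pattern`` (checked)."""
    preferred = set().union(*(c.preferred for c in pattern.conditions))
    compared = set().union(*(c.compared for c in pattern.conditions)) - preferred
    delta = rng.uniform(0.0, 1.0, size=len(stimuli))  # irrelevant stimuli: weak
    for i, tok in enumerate(stimuli):
        if tok in preferred:
            delta[i] = rng.uniform(2.5, 4.0)
        elif tok in compared:
            delta[i] = rng.uniform(0.0, 1.0)
    assert fulfills(delta, pattern, stimuli), "implanted vector failed its own pattern"
    return delta


def _draw_ground_truth(config: SyntheticConfig, rng: np.random.Generator,
                       registry: PatternRegistry) -> GroundTruth:
    stimuli = config.stimuli
    n_stim = len(stimuli)
    breadth_vals = np.array(sorted(config.breadth_weights), dtype=int)
    breadth_p = np.array([config.breadth_weights[k] for k in breadth_vals], dtype=float)
    breadth_p = breadth_p / breadth_p.sum()

    rows, deltas = [], []
    for state in ("non_estrus", "estrus"):
        n = config.n_units_per_state
        # deterministic implanted counts, remainder unstructured
        plan: list[str | None] = []
        for pid in config.implanted_patterns:
            plan.extend([pid] * int(round(config._prevalence(pid, state) * n)))
        plan.extend([None] * (n - len(plan)))
        for i, pattern_id in enumerate(plan):
            uid = f"{state[:3]}{i:04d}"
            session = f"S_{state[:3]}_{i // config.units_per_session:03d}"
            baseline = float(rng.lognormal(*config.baseline_lognormal))
            if pattern_id is not None:
                delta = _pattern_delta(registry[pattern_id], stimuli, rng)
            else:
                k = int(rng.choice(breadth_vals, p=breadth_p))
                delta = np.zeros(n_stim)
                if k > 0:
                    eff = rng.choice(n_stim, size=k, replace=False)
                    mag = rng.gamma(*config.effect_gamma, size=k)
                    sign = np.where(rng.random(k) < config.p_excitatory, 1.0, -1.0)
                    delta[eff] = sign * mag
            rows.append({"unit_id": uid, "state": state, "session": session,
                         "baseline_rate": baseline, "pattern": pattern_id})
            deltas.append(delta)

    units = pd.DataFrame(rows).set_index("unit_id")
    delta = pd.DataFrame(np.vstack(deltas), index=units.index, columns=stimuli)

    for sg in config.state_gain:
        mask = units["state"] == sg.state
        delta.loc[mask, sg.stimuli] = delta.loc[mask, sg.stimuli] * sg.gain
    return GroundTruth(units=units, delta=delta)


# ---------------------------------------------------------------------------
# Spike-level generation


def _session_schedule(config: SyntheticConfig, session: str,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Randomized-block trial schedule for one session."""
    order: list[str] = []
    for _ in range(config.trials_per_stimulus):
        order.extend(rng.permutation(config.stimuli))
    rows = []
    for i, stim in enumerate(order):
        t0 = i * config.slot_duration
        t_app = t0 + config.baseline_duration
        rows.append({
            "trial_id": f"{session}_t{i:03d}", "session": session, "stimulus": stim,
            "t_application": t_app, "t_snt": t_app + config.snt_delay,
        })
    return pd.DataFrame(rows)


def _poisson_segment(rate: float, t0: float, t1: float,
                     rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return t0 + rng.random(n) * (t1 - t0)


def _unit_spikes(config: SyntheticConfig, trials: pd.DataFrame, baseline: float,
                 delta: pd.Series, rng: np.random.Generator) -> np.ndarray:
    times = []
    clipped = False
    for trial in trials.itertuples():
        slot0 = trial.t_application - config.baseline_duration
        evoked_end = trial.t_snt + config.response_tail
        slot1 = slot0 + config.slot_duration
        evoked_rate = baseline + float(delta[trial.stimulus])
        if evoked_rate < 0:
            evoked_rate = 0.0
            clipped = True
        times.append(_poisson_segment(baseline, slot0, trial.t_application, rng))
        times.append(_poisson_segment(evoked_rate, trial.t_application, evoked_end, rng))
        times.append(_poisson_segment(baseline, evoked_end, slot1, rng))
    if clipped:
        logger.warning("suppressive rate change clipped at 0 Hz for some trials")
    return np.sort(np.concatenate(times)) if times else np.empty(0)


def generate_spike_dataset(config: SyntheticConfig,
                           registry: PatternRegistry | None = None
                           ) -> tuple[SpikeDataset, GroundTruth]:
    """Generate a full spike-level dataset plus its generating ground truth."""
    config.validate()
    registry = registry or default_registry()
    ss = np.random.SeedSequence(config.seed)
    truth_ss, sched_ss, spike_ss = ss.spawn(3)
    truth = _draw_ground_truth(config, np.random.default_rng(truth_ss), registry)

    sched_rng = np.random.default_rng(sched_ss)
    sessions = truth.units["session"].unique()
    trials = pd.concat(
        [_session_schedule(config, s, sched_rng) for s in sessions], ignore_index=True
    )
    trials_by_session = dict(tuple(trials.groupby("session")))

    unit_streams = spike_ss.spawn(len(truth.units))
    spike_frames = []
    for (uid, row), child in zip(truth.units.iterrows(), unit_streams):
        rng = np.random.default_rng(child)
        st = _unit_spikes(config, trials_by_session[row["session"]],
                          row["baseline_rate"], truth.delta.loc[uid], rng)
        spike_frames.append(pd.DataFrame({
            "unit_id": uid, "session": row["session"], "time": st,
        }))
    spikes = pd.concat(spike_frames, ignore_index=True)

    units = truth.units.reset_index()[["unit_id", "session", "state"]]
    dataset = SpikeDataset(units=units, trials=trials, spikes=spikes,
                           stimuli=list(config.stimuli)).validate()
    return dataset, truth


# ---------------------------------------------------------------------------
# Matrix-level shortcut


def generate_response_matrix(config: SyntheticConfig,
                             registry: PatternRegistry | None = None
                             ) -> tuple[ResponseMatrix, GroundTruth]:
    """Draw unit x stimulus magnitudes directly from the generative means.

    Magnitudes are the true evoked rate change plus i.i.d. Gaussian noise of
    SD ``matrix_noise_sd``; significance flags come straight from the ground
    truth (a cell is flagged iff its true rate change is nonzero), so the
    matrix can exercise downstream statistics without spike-level variance.
    """
    config.validate()
    registry = registry or default_registry()
    ss = np.random.SeedSequence(config.seed)
    truth_ss, noise_ss = ss.spawn(2)
    truth = _draw_ground_truth(config, np.random.default_rng(truth_ss), registry)

    noise_rng = np.random.default_rng(noise_ss)
    values = truth.delta.to_numpy()
    if config.matrix_noise_sd > 0:
        values = values + noise_rng.normal(0.0, config.matrix_noise_sd, size=values.shape)
    magnitudes = pd.DataFrame(values, index=truth.delta.index, columns=truth.delta.columns)
    significant = truth.delta != 0.0
    p_values = pd.DataFrame(np.where(significant, 0.0, 1.0),
                            index=magnitudes.index, columns=magnitudes.columns)
    info = truth.units[["session", "state"]]
    matrix = ResponseMatrix(magnitudes, p_values, significant, info,
                            meta={"source": "synthetic-matrix", "seed": config.seed})
    return matrix, truth
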