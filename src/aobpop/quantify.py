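"""From spike timestamps and trial events to a unit x stimulus response matrix.

The response of a unit to one trial is the firing rate in the window from
stimulus application to 40 s after sympathetic-nerve-trunk (SNT) stimulation,
minus the rate in the 17 s baseline immediately preceding application. The
per-stimulus response magnitude is the mean of this difference over the
stimulus's trials. Response significance is a two-group Kruskal-Wallis test
of that stimulus's evoked-window rates against the unit's baseline rates
pooled across every trial of the session.

All windows are half-open ``[t0, t1)`` so no spike is counted twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stimuli import PANEL_TOKENS

logger = logging.getLogger(__name__)

__all__ = [
    "trial_rate",
    "trial_windows",
    "response_magnitude",
    "response_significance",
    "kruskal_p",
    "build_response_matrix",
    "normalize_matrix",
    "shape_symmetry",
    "ResponseMatrix",
]

BASELINE_DURATION = 17.0   # s before stimulus application
RESPONSE_TAIL = 40.0       # s after SNT stimulation
MIN_TRIALS = 4             # minimum presentations per stimulus


def trial_rate(spike_times: np.ndarray, t0: float, t1: float) -> float:
    """Firing rate (Hz) in the half-open window [t0, t1)."""
    if not t1 > t0:
        raise ValueError(f"invalid window [{t0}, {t1}): end must exceed start")
    spike_times = np.asarray(spike_times, dtype=float)
    n = int(np.count_nonzero((spike_times >= t0) & (spike_times < t1)))
    return n / (t1 - t0)


def trial_windows(t_application: float, t_snt: float,
                  baseline_duration: float = BASELINE_DURATION,
                  response_tail: float = RESPONSE_TAIL) -> tuple[tuple[float, float], tuple[float, float]]:
    """(baseline, evoked) windows for one trial; disjoint by construction."""
    if not t_snt > t_application:
        raise ValueError("SNT stimulation must follow stimulus application")
    baseline = (t_application - baseline_duration, t_application)
    evoked = (t_application, t_snt + response_tail)
    return baseline, evoked


def _trial_rates(spikes: np.ndarray, trials: pd.DataFrame,
                 baseline_duration: float, response_tail: float) -> pd.DataFrame:
    """Per-trial baseline and evoked rates for one unit."""
    rows = []
    for trial in trials.itertuples():
        (b0, b1), (e0, e1) = trial_windows(
            trial.t_application, trial.t_snt, baseline_duration, response_tail
        )
        rows.append({
            "trial_id": trial.trial_id,
            "stimulus": trial.stimulus,
            "baseline_rate": trial_rate(spikes, b0, b1),
            "evoked_rate": trial_rate(spikes, e0, e1),
        })
    return pd.DataFrame(rows)


def response_magnitude(baseline_rates: Sequence[float], evoked_rates: Sequence[float],
                       min_trials: int = MIN_TRIALS, strict: bool = False) -> float:
    """Mean baseline-subtracted evoked rate (Hz) over a stimulus's trials.

    The baseline is per-trial: each trial contributes (evoked - its own
    baseline). With fewer than ``min_trials`` trials the value is still
    computed but a warning is logged (or an error raised when ``strict``).
    """
    b = np.asarray(baseline_rates, dtype=float)
    e = np.asarray(evoked_rates, dtype=float)
    if b.shape != e.shape or b.ndim != 1 or b.size == 0:
        raise ValueError("need matching, nonempty per-trial baseline and evoked rates")
    if b.size < min_trials:
        msg = f"only {b.size} trials (< {min_trials} presentations)"
        if strict:
            raise ValueError(msg)
        logger.warning("response_magnitude: %s; computing anyway", msg)
    return float(np.mean(e - b))


def kruskal_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-group Kruskal-Wallis p-value; fully tied data give p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.kruskal(a, b).pvalue)


def response_significance(evoked_rates: Sequence[float],
                          pooled_baseline_rates: Sequence[float]) -> float:
    """Kruskal-Wallis p for one stimulus's evoked rates vs. session-pooled baselines."""
    return kruskal_p(evoked_rates, pooled_baseline_rates)


# ---------------------------------------------------------------------------
# Response matrix


@dataclass
class ResponseMatrix:
    """Units x stimuli response magnitudes with significance and unit metadata.

    Attributes
    ----------
    magnitudes : DataFrame
        Baseline-subtracted mean rates (Hz), index = unit ids, columns =
        canonical stimulus tokens. After :meth:`normalize`, values lie in
        [-1, 1].
    p_values, significant : DataFrame
        Cell-level Kruskal-Wallis p-values and p < alpha flags.
    unit_info : DataFrame
        Per-unit metadata indexed like ``magnitudes``; at least ``state``
        ("estrus"/"non_estrus") and ``session``.
    """

    magnitudes: pd.DataFrame
    p_values: pd.DataFrame
    significant: pd.DataFrame
    unit_info: pd.DataFrame
    alpha: float = 0.05
    is_normalized: bool = False
    nonsignificant_zeroed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("p_values", "significant"):
            df = getattr(self, name)
            if df.shape != self.magnitudes.shape:
                raise ValueError(f"{name} shape does not match magnitudes")
        if not self.unit_info.index.equals(self.magnitudes.index):
            raise ValueError("unit_info index must match magnitudes index")

    @property
    def n_units(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def stimuli(self) -> list[str]:
        return list(self.magnitudes.columns)

    @property
    def states(self) -> pd.Series:
        return self.unit_info["state"]

    def sign(self) -> pd.DataFrame:
        """Per-cell response sign: 'increase'/'decrease' when significant, else 'none'."""
        out = pd.DataFrame("none", index=self.magnitudes.index, columns=self.magnitudes.columns)
        sig = self.significant.to_numpy()
        pos = self.magnitudes.to_numpy() > 0
        out = out.where(~(sig & pos), "increase")
        out = out.where(~(sig & ~pos), "decrease")
        return out

    def subset_state(self, state: str) -> "ResponseMatrix":
        mask = self.states == state
        if not mask.any():
            raise ValueError(f"no units with state {state!r}")
        return replace(
            self,
            magnitudes=self.magnitudes.loc[mask],
            p_values=self.p_values.loc[mask],
            significant=self.significant.loc[mask],
            unit_info=self.unit_info.loc[mask],
        )

    def normalize(self, zero_nonsignificant: bool = True) -> "ResponseMatrix":
        """Per-unit normalization by the maximal absolute response.

        When ``zero_nonsignificant`` every nonsignificant cell is set to
        exactly 0 before dividing. A unit whose (possibly zeroed) row is all
        zero stays all zero. Idempotent.
        """
        values = self.magnitudes.to_numpy(dtype=float).copy()
        if zero_nonsignificant:
            values[~self.significant.to_numpy()] = 0.0
        peak = np.abs(values).max(axis=1, keepdims=True)
        safe = np.where(peak > 0, peak, 1.0)
        normed = values / safe
        return replace(
            self,
            magnitudes=pd.DataFrame(normed, index=self.magnitudes.index,
                                    columns=self.magnitudes.columns),
            is_normalized=True,
            nonsignificant_zeroed=zero_nonsignificant or self.nonsignificant_zeroed,
        )

    def effective_stimulus_counts(self) -> pd.Series:
        """Number of significant responses per unit (0-11)."""
        return self.significant.sum(axis=1)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: unit, stimulus, magnitude, p, significant, state, session."""
        tidy = (
            self.magnitudes.stack().rename("magnitude").reset_index()
            .rename(columns={"level_0": "unit", "level_1": "stimulus"})
        )
        tidy.columns = ["unit", "stimulus", "magnitude"]
        tidy["p_value"] = self.p_values.stack().to_numpy()
        tidy["significant"] = self.significant.stack().to_numpy()
        info = self.unit_info[["state", "session"]]
        tidy = tidy.merge(info, left_on="unit", right_index=True)
        return tidy

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, alpha: float = 0.05, **kwargs) -> "ResponseMatrix":
        mags = tidy.pivot(index="unit", columns="stimulus", values="magnitude")
        pvals = tidy.pivot(index="unit", columns="stimulus", values="p_value")
        sig = tidy.pivot(index="unit", columns="stimulus", values="significant").astype(bool)
        cols = [c for c in PANEL_TOKENS if c in mags.columns] or list(mags.columns)
        info = tidy.drop_duplicates("unit").set_index("unit")[["state", "session"]]
        info = info.loc[mags.index]
        return cls(mags[cols], pvals[cols], sig[cols], info, alpha=alpha, **kwargs)


def build_response_matrix(dataset, alpha: float = 0.05,
                          baseline_duration: float = BASELINE_DURATION,
                          response_tail: float = RESPONSE_TAIL,
                          min_trials: int = MIN_TRIALS,
                          drop_incomplete: bool = True) -> ResponseMatrix:
    """Quantify every unit x stimulus cell of a :class:`~aobpop.datasets.SpikeDataset`.

    Units missing any panel stimulus, or with fewer than ``min_trials``
    repeats of any stimulus (when ``drop_incomplete``), are dropped with a
    logged reason.
    """
    stimuli = dataset.stimuli
    mags, pvals, keep_units = {}, {}, []
    trials_by_session = {s: t.sort_values("t_application")
                         for s, t in dataset.trials.groupby("session")}

    for unit in dataset.units.itertuples():
        uid, session = unit.unit_id, unit.session
        trials = trials_by_session.get(session)
        if trials is None:
            logger.warning("unit %s dropped: session %s has no trials", uid, session)
            continue
        spikes = dataset.unit_spikes(uid)
        rates = _trial_rates(spikes, trials, baseline_duration, response_tail)
        counts = rates["stimulus"].value_counts()
        missing = [s for s in stimuli if s not in counts.index]
        if missing:
            logger.warning("unit %s dropped: no trials for %s", uid, missing)
            continue
        if drop_incomplete and (counts < min_trials).any():
            low = counts[counts < min_trials]
            logger.warning("unit %s dropped: fewer than %d repeats for %s",
                           uid, min_trials, list(low.index))
            continue
        pooled_baseline = rates["baseline_rate"].to_numpy()
        m_row, p_row = {}, {}
        for stim, grp in rates.groupby("stimulus"):
            m_row[stim] = response_magnitude(
                grp["baseline_rate"], grp["evoked_rate"], min_trials=min_trials
            )
            p_row[stim] = response_significance(grp["evoked_rate"], pooled_baseline)
        mags[uid] = m_row
        pvals[uid] = p_row
        keep_units.append(uid)

    if not keep_units:
        raise ValueError("no unit passed quantification; check the dataset")
    mag_df = pd.DataFrame.from_dict(mags, orient="index")[stimuli].loc[keep_units]
    p_df = pd.DataFrame.from_dict(pvals, orient="index")[stimuli].loc[keep_units]
    sig_df = p_df < alpha
    info = dataset.units.set_index("unit_id").loc[keep_units, ["session", "state"]]
    return ResponseMatrix(mag_df, p_df, sig_df, info, alpha=alpha)


def normalize_matrix(matrix: ResponseMatrix, zero_nonsignificant: bool = True) -> ResponseMatrix:
    """Functional alias for :meth:`ResponseMatrix.normalize`."""
    return matrix.normalize(zero_nonsignificant=zero_nonsignificant)


# ---------------------------------------------------------------------------
# Spike-waveform QC


def shape_symmetry(waveform: Sequence[float]) -> float:
    """Symmetry of a spike waveform about its peak, in [0, 1].

    The absolute Pearson correlation between the margin left of the extremum
    and the reversed right margin, both truncated to the shorter side. A
    perfectly symmetric waveform scores 1; values above ~0.95 are suspicious
    of noise misclassified as spikes. Returns NaN (caller should flag the
    unit) when a margin is shorter than 2 samples or has zero variance.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1 or w.size < 5:
        raise ValueError("waveform must be a 1-D array of at least 5 samples")
    peak = int(np.argmax(np.abs(w)))
    k = min(peak, w.size - peak - 1)  # shorter margin decides the length
    if k < 2:
        return float("nan")
    left = w[peak - k:peak]
    right = w[peak + 1:peak + 1 + k][::-1]
    if np.std(left) == 0 or np.std(right) == 0:
        return float("nan")
    return float(abs(np.corrcoef(left, right)[0, 1]))


def flag_noise_units(waveforms: dict[str, np.ndarray], threshold: float = 0.95) -> pd.DataFrame:
    """Score mean waveforms and flag suspected-noise units (symmetry > threshold or undefined)."""
    rows = []
    for uid, wf in waveforms.items():
        s = shape_symmetry(wf)
        rows.append({"unit": uid, "shape_symmetry": s,
                     "suspect": bool(np.isnan(s) or s > threshold)})
    return pd.DataFrame(rows).set_index("unit")
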