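"""Model/results front end for the stimulus-response analysis.

`StimulusResponseModel` is built from a spike dataset (or directly from a
response matrix) and its :meth:`fit` quantifies every unit x stimulus cell,
returning a :class:`StimulusResponseResults` that carries the response
matrix and exposes each downstream analysis — receptive-field pattern
statistics, tuning metrics, population geometry, and reproductive-state
comparisons — as methods, plus a ``summary()`` table.

Typical use::

    from aobpop import StimulusResponseModel, SyntheticConfig
    from aobpop.synthetic import generate_spike_dataset

    dataset, truth = generate_spike_dataset(SyntheticConfig(seed=7))
    res = StimulusResponseModel(dataset).fit()
    print(res.summary())
    patterns = res.pattern_tests(n_shuffles=10_000, seed=7)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import compare, geometry, patterns, tuning
from .datasets import SpikeDataset
from .patterns import PatternRegistry, default_registry
from .quantify import ResponseMatrix, build_response_matrix

__all__ = ["StimulusResponseModel", "StimulusResponseResults"]


class StimulusResponseModel:
    """Stimulus-response quantification model for a set of recorded units.

    Parameters
    ----------
    dataset : SpikeDataset
        Spike timestamps plus trial events.
    alpha : float
        Cell-level significance threshold for the Kruskal-Wallis response
        test (0.05, the conventional threshold).
    registry : PatternRegistry, optional
        Receptive-field pattern registry; defaults to the shipped 8+8 basic
        and 6+6 adjusted families.
    """

    def __init__(self, dataset: SpikeDataset, alpha: float = 0.05,
                 registry: PatternRegistry | None = None,
                 min_trials: int = 4):
        self.dataset = dataset
        self.alpha = alpha
        self.registry = registry or default_registry()
        self.min_trials = min_trials

    @classmethod
    def from_dataframes(cls, units: pd.DataFrame, trials: pd.DataFrame,
                        spikes: pd.DataFrame, **kwargs) -> "StimulusResponseModel":
        return cls(SpikeDataset(units=units, trials=trials, spikes=spikes).validate(),
                   **kwargs)

    def fit(self) -> "StimulusResponseResults":
        matrix = build_response_matrix(self.dataset, alpha=self.alpha,
                                       min_trials=self.min_trials)
        return StimulusResponseResults(matrix=matrix, registry=self.registry,
                                       model=self)


@dataclass
class StimulusResponseResults:
    """Fitted response matrix plus every downstream analysis."""

    matrix: ResponseMatrix
    registry: PatternRegistry = field(default_factory=default_registry)
    model: StimulusResponseModel | None = None

    @classmethod
    def from_matrix(cls, matrix: ResponseMatrix,
                    registry: PatternRegistry | None = None) -> "StimulusResponseResults":
        """Wrap a precomputed (e.g. synthetic matrix-level) response matrix."""
        return cls(matrix=matrix, registry=registry or default_registry())

    # -- quantification views ------------------------------------------------
    @property
    def magnitudes(self) -> pd.DataFrame:
        return self.matrix.magnitudes

    def normalized(self, zero_nonsignificant: bool = True) -> ResponseMatrix:
        return self.matrix.normalize(zero_nonsignificant=zero_nonsignificant)

    def population_summary(self) -> dict:
        return compare.summarize_population(self.matrix)

    # -- patterns ------------------------------------------------------------
    def pattern_counts(self, state: str | None = None) -> pd.Series:
        m = self.matrix if state is None else self.matrix.subset_state(state)
        return patterns.count_patterns(m.magnitudes, self.registry)

    def pattern_tests(self, n_shuffles: int = 100_000,
                      seed: int | None = None, state: str | None = None,
                      **kwargs) -> pd.DataFrame:
        """Column-shuffle over-representation test for every registry pattern."""
        m = self.matrix if state is None else self.matrix.subset_state(state)
        res = patterns.shuffle_null(m.magnitudes, self.registry,
                                    n_shuffles=n_shuffles, seed=seed, **kwargs)
        return patterns.results_table(res, self.registry, alpha=self.matrix.alpha)

    # -- tuning ----------------------------------------------------------------
    def tuning_metrics(self) -> pd.DataFrame:
        return tuning.unit_metrics(self.matrix)

    def mean_pairwise_preferences(self) -> pd.DataFrame:
        return tuning.mean_pairwise_preferences(self.matrix)

    def preference_state_test(self, pair: tuple[str, str],
                              n_shuffles: int = 100_000,
                              seed: int | None = None) -> dict:
        return tuning.preference_state_test(self.matrix, pair,
                                            n_shuffles=n_shuffles, seed=seed)

    def selectivity_comparisons(self) -> pd.DataFrame:
        return tuning.selectivity_comparison_table(self.matrix)

    # -- geometry --------------------------------------------------------------
    def distances(self, metric: str = "correlation",
                  state: str | None = None) -> geometry.DistanceMatrix:
        return geometry.distance_matrix(self.matrix, metric=metric, state=state)

    def mds(self, metric: str = "correlation", k: int = 2,
            state: str | None = None) -> geometry.MDSEmbedding:
        return geometry.classical_mds(self.distances(metric=metric, state=state), k=k)

    def cross_state_geometry(self, metric: str = "correlation") -> dict:
        return geometry.cross_state_distance_correlation(
            self.distances(metric, "estrus"), self.distances(metric, "non_estrus")
        )

    # -- state comparison --------------------------------------------------------
    def responder_fraction_comparison(self) -> pd.DataFrame:
        return compare.responder_fraction_table(self.matrix, alpha=self.matrix.alpha)

    def magnitude_comparison(self) -> pd.DataFrame:
        return compare.magnitude_state_table(self.matrix, alpha=self.matrix.alpha)

    def two_way_anova(self) -> dict:
        return compare.two_way_anova(self.matrix)

    def pattern_frequency_comparison(self, n_shuffles: int = 100_000,
                                     seed: int | None = None) -> pd.DataFrame:
        est = self.matrix.subset_state("estrus")
        non = self.matrix.subset_state("non_estrus")
        counts_est = patterns.count_patterns(est.magnitudes, self.registry)
        counts_non = patterns.count_patterns(non.magnitudes, self.registry)
        sh_est = patterns.shuffle_null(est.magnitudes, self.registry,
                                       n_shuffles=n_shuffles, seed=seed)
        sh_non = patterns.shuffle_null(non.magnitudes, self.registry,
                                       n_shuffles=n_shuffles, seed=seed)
        return compare.pattern_frequency_state_test(
            counts_est, est.n_units, counts_non, non.n_units, self.registry,
            shuffle_results_est=sh_est, shuffle_results_non=sh_non,
            alpha=self.matrix.alpha,
        )

    # -- reporting ---------------------------------------------------------------
    def summary(self) -> str:
        m = self.matrix
        pop = self.population_summary()
        counts = pop["effective_counts"]
        states = m.states.value_counts()
        lines = [
            "Stimulus-response results",
            "=" * 60,
            f"units:               {m.n_units}"
            f" (estrus {states.get('estrus', 0)},"
            f" non-estrus {states.get('non_estrus', 0)})",
            f"stimuli:             {len(m.stimuli)}",
            f"alpha (cell-level):  {m.alpha}",
            f"significant cells:   {int(m.significant.to_numpy().sum())}"
            f" / {m.significant.size}"
            f" ({m.significant.to_numpy().mean() * 100:.1f}%)",
            f"modal breadth:       {int(counts[counts.index > 0].idxmax())}"
            " effective stimuli (among responsive units)"
            if counts[counts.index > 0].sum() > 0 else "modal breadth:       n/a",
            "",
            "per-stimulus responder % (increase/decrease) and mean magnitude (Hz):",
        ]
        ps = pop["per_stimulus"]
        for stim, row in ps.iterrows():
            lines.append(
                f"  {stim:<15} {row['percent_increase']:5.1f}% /"
                f" {row['percent_decrease']:4.1f}%"
                f"   {row['mean_magnitude']:+.3f} +/- {row['sem']:.3f}"
            )
        return "\n".join(lines)
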