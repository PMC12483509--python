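"""Shared fixtures: small synthetic datasets and response-matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aobpop import (StimulusResponseModel, SyntheticConfig,
                    generate_spike_dataset)
from aobpop.quantify import ResponseMatrix
from aobpop.stimuli import PANEL_TOKENS


def make_matrix(values, states=None, significant=None, stimuli=None) -> ResponseMatrix:
    """Build a ResponseMatrix from a raw value array (all cells significant by default)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    stimuli = list(stimuli) if stimuli is not None else list(PANEL_TOKENS[: values.shape[1]])
    index = [f"u{i:04d}" for i in range(n)]
    mags = pd.DataFrame(values, index=index, columns=stimuli)
    if significant is None:
        sig = pd.DataFrame(True, index=index, columns=stimuli)
    else:
        sig = pd.DataFrame(np.atleast_2d(significant), index=index, columns=stimuli)
    pvals = pd.DataFrame(np.where(sig, 0.001, 0.5), index=index, columns=stimuli)
    if states is None:
        states = ["estrus" if i % 2 else "non_estrus" for i in range(n)]
    info = pd.DataFrame({"session": "S0", "state": list(states)}, index=index)
    return ResponseMatrix(mags, pvals, sig.astype(bool), info)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SyntheticConfig(n_units_per_state=6, seed=11)
    return generate_spike_dataset(cfg)


@pytest.fixture(scope="session")
def fitted(small_dataset):
    dataset, _ = small_dataset
    return StimulusResponseModel(dataset).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
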