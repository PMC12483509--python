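"""Population representational distances and classical multidimensional scaling.

Stimuli are compared as columns of the (normalized, nonsignificant-zeroed)
response matrix. Two metrics are supported: Euclidean distance and the
correlation distance, 1 minus the Pearson correlation (range [0, 2]). The
11-stimulus panel yields 55 pairwise distances; their Pearson correlation
across reproductive states measures the stability of representational space.

Classical (Torgerson) MDS double-centres -D^2/2, eigendecomposes, and keeps
the top-k nonnegative eigenpairs; because correlation distances are generally
non-Euclidean, the embedding is an approximation and is reported together
with the mean absolute error between the original and embedded distances and
the mean original distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .quantify import ResponseMatrix

logger = logging.getLogger(__name__)

__all__ = ["DistanceMatrix", "MDSEmbedding", "distance_matrix",
           "cross_state_distance_correlation", "classical_mds"]

METRICS = ("correlation", "euclidean")


@dataclass
class DistanceMatrix:
    """Symmetric stimulus x stimulus distance matrix with its metric and state label."""

    values: pd.DataFrame
    metric: str
    state: str | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def stimuli(self) -> list[str]:
        return list(self.values.columns)

    def upper_triangle(self) -> np.ndarray:
        """The 55 pairwise distances, in squareform order."""
        return squareform(self.values.to_numpy(), checks=False)


def distance_matrix(matrix: ResponseMatrix, metric: str = "correlation",
                    state: str | None = None,
                    normalize: bool = True) -> DistanceMatrix:
    """Pairwise distances between stimulus columns of a response matrix.

    By default the matrix is first normalized per unit with nonsignificant
    cells zeroed (the representation the distance analyses use); pass
    ``normalize=False`` to use the magnitudes as given. A zero-variance
    column has no defined correlation distance; it is assigned 1 (no linear
    relation) and logged.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if state is not None:
        matrix = matrix.subset_state(state)
    if normalize:
        matrix = matrix.normalize(zero_nonsignificant=True)
    cols = matrix.magnitudes.to_numpy(dtype=float).T  # stimuli x units
    with np.errstate(invalid="ignore", divide="ignore"):
        condensed = pdist(cols, metric=metric)
    if np.isnan(condensed).any():
        logger.warning(
            "zero-variance stimulus column: correlation distance undefined, set to 1"
        )
        condensed = np.where(np.isnan(condensed), 1.0, condensed)
    values = pd.DataFrame(squareform(condensed), index=matrix.stimuli,
                          columns=matrix.stimuli)
    return DistanceMatrix(values=values, metric=metric, state=state)


def cross_state_distance_correlation(d_est: DistanceMatrix,
                                     d_non: DistanceMatrix) -> dict:
    """Pearson correlation of the 55 pairwise distances across the two states.

    The p-value is the standard no-correlation test; note that pairwise
    distances are not independent observations, so it is a descriptive
    convention rather than an exact error rate.
    """
    if d_est.metric != d_non.metric:
        raise ValueError("distance matrices use different metrics")
    if d_est.stimuli != d_non.stimuli:
        raise ValueError("distance matrices cover different stimulus panels")
    a = d_est.upper_triangle()
    b = d_non.upper_triangle()
    cc, p = stats.pearsonr(a, b)
    return {"cc": float(cc), "p_value": float(p), "n_pairs": int(a.size),
            "metric": d_est.metric,
            "caveat": "pairwise distances are not independent; p is the standard test"}


@dataclass
class MDSEmbedding:
    """2-D (or k-D) classical MDS embedding with its distortion diagnostics."""

    coordinates: pd.DataFrame       # stimuli x dims, centred at the origin
    eigenvalues: np.ndarray         # all eigenvalues, descending
    mean_absolute_error: float      # mean |original - embedded| over pairs
    mean_original_distance: float

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


def classical_mds(distances: DistanceMatrix, k: int = 2) -> MDSEmbedding:
    """Torgerson scaling of a distance matrix into k dimensions.

    Negative eigenvalues (a non-Euclidean diagnostic) are clipped to zero and
    logged; if fewer than ``k`` positive eigenvalues exist, the embedding
    dimension is reduced with a warning. The returned diagnostics mirror the
    two-number summary used for the stimulus map: the mean absolute
    difference between original and embedded distances, and the mean of the
    original distances.
    """
    d = distances.values.to_numpy(dtype=float)
    n = d.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if (eigval < -1e-9).any():
        logger.info("negative MDS eigenvalues (non-Euclidean input): min %.4g",
                    float(eigval.min()))
    n_pos = int(np.sum(eigval > 1e-12))
    if n_pos < k:
        logger.warning("only %d positive eigenvalues; reducing k from %d", n_pos, k)
        k = max(n_pos, 1)
    lam = np.clip(eigval[:k], 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(lam)
    coords_df = pd.DataFrame(coords, index=distances.stimuli,
                             columns=[f"dim{i + 1}" for i in range(k)])
    embedded = pdist(coords)
    original = squareform(d, checks=False)
    return MDSEmbedding(
        coordinates=coords_df,
        eigenvalues=eigval,
        mean_absolute_error=float(np.mean(np.abs(original - embedded))),
        mean_original_distance=float(np.mean(original)),
    )
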