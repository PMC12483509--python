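"""Minimal diagnostic figures: response-matrix heatmap, MDS map, triangle plot."""

from __future__ import annotations

import numpy as np

from .geometry import MDSEmbedding
from .quantify import ResponseMatrix
from .tuning import _triangle_vertices, triangle_coordinates


def plot_response_matrix(matrix: ResponseMatrix, ax=None):
    """Heatmap of the normalized response matrix (units x stimuli, [-1, 1])."""
    import matplotlib.pyplot as plt

    normed = matrix if matrix.is_normalized else matrix.normalize()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(normed.magnitudes.to_numpy(), aspect="auto",
                   cmap="RdBu_r", vmin=-1, vmax=1, interpolation="nearest")
    ax.set_xticks(range(len(normed.stimuli)))
    ax.set_xticklabels(normed.stimuli, rotation=90, fontsize=6)
    ax.set_ylabel("unit")
    ax.figure.colorbar(im, ax=ax, label="normalized response")
    return ax


def plot_mds(embedding: MDSEmbedding, ax=None):
    """2-D stimulus map from classical MDS, annotated with the error diagnostic."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xy = embedding.coordinates
    ax.scatter(xy.iloc[:, 0], xy.iloc[:, 1])
    for stim, row in xy.iterrows():
        ax.annotate(stim, (row.iloc[0], row.iloc[1]), fontsize=7)
    ax.set_title(f"mean |error| {embedding.mean_absolute_error:.2f}, "
                 f"mean distance {embedding.mean_original_distance:.2f}")
    ax.set_aspect("equal")
    return ax


def plot_triangle(triplets, labels=("v1", "v2", "v3"), colors=None, ax=None):
    """Triangle plot of response triplets (rows: a, b, c raw magnitudes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    verts = _triangle_vertices()
    tri = np.vstack([verts, verts[:1]])
    ax.plot(tri[:, 0], tri[:, 1], color="k", lw=1)
    for v, lab in zip(verts, labels):
        ax.annotate(lab, v * 1.1, ha="center", fontsize=8)
    pts = [triangle_coordinates(*row) for row in np.atleast_2d(np.asarray(triplets))]
    pts = np.array([p for p in pts if p is not None])
    if pts.size:
        ax.scatter(pts[:, 0], pts[:, 1], s=8,
                   c=colors if colors is not None else "tab:gray", alpha=0.6)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
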