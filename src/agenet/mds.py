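"""Sample-level correlation dissimilarity and classical metric MDS.

Samples are compared by the Pearson correlation r of their (log2 RPKM)
expression profiles across genes; the dissimilarity d = 1 - r lies in
[0, 2], with perfectly correlated samples at distance 0 and perfectly
anti-correlated ones maximally distant. The 2-D map is computed with
Torgerson's classical scaling (double-centering of squared distances
followed by an eigendecomposition), the same construction as R's
``cmdscale``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expr import ExpressionMatrix

__all__ = ["Embedding", "sample_dissimilarity", "classical_mds", "plot_embedding"]


class UndefinedCorrelationError(ValueError):
    """A sample profile has zero variance, so Pearson r is undefined."""


@dataclass
class Embedding:
    """2-D (or k-D) sample coordinates plus the centering eigenvalues."""

    coords: pd.DataFrame  # samples x dimensions
    eigenvalues: np.ndarray  # all eigenvalues, sorted descending


def sample_dissimilarity(expr_log: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise d_ij = 1 - Pearson r_ij between sample expression profiles."""
    X = expr_log.values.to_numpy(dtype=float)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need at least 2 samples and 3 genes")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = list(expr_log.values.columns[sd == 0])
        raise UndefinedCorrelationError(f"constant sample profiles: {bad}")
    r = np.corrcoef(X, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    cols = expr_log.values.columns
    return pd.DataFrame(d, index=cols, columns=cols)


def classical_mds(D: pd.DataFrame, k: int = 2) -> Embedding:
    """Torgerson classical scaling of a dissimilarity matrix.

    B = -1/2 * J * D^2 * J with J the centering projector; coordinates are
    eigvec * sqrt(eigval) for the top-k non-negative eigenvalues. If fewer
    than k eigenvalues are positive the trailing coordinates are zero and
    a warning is issued. Axis signs are canonicalized so the
    largest-magnitude loading on each axis is positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = np.asarray(D, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    B = (B + B.T) / 2
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int(np.sum(eigval > 1e-12))
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; trailing dimensions are zero",
            stacklevel=2,
        )
    coords = np.zeros((n, k))
    for j in range(min(k, n_pos)):
        axis = eigvec[:, j] * np.sqrt(eigval[j])
        if np.abs(axis).max() > 0 and axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        coords[:, j] = axis
    cols = [f"dim{j + 1}" for j in range(k)]
    index = D.index if isinstance(D, pd.DataFrame) else pd.RangeIndex(n)
    return Embedding(pd.DataFrame(coords, index=index, columns=cols), eigval)


def plot_embedding(embedding: Embedding, design: pd.DataFrame, out_path) -> None:
    """Scatter plot of the first two dimensions, colored by age, shaped by condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = embedding.coords
    ages = sorted(design["age_days"].unique())
    cmap = plt.get_cmap("viridis", len(ages))
    markers = {"control": "o", "treated": "s"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for cond, marker in markers.items():
        for i, age in enumerate(ages):
            sel = (design["condition"] == cond) & (design["age_days"] == age)
            ids = design.index[sel]
            if len(ids) == 0:
                continue
            ax.scatter(
                coords.loc[ids, "dim1"],
                coords.loc[ids, "dim2"],
                color=cmap(i),
                marker=marker,
                label=f"{cond} {age}d",
                edgecolor="k",
                linewidth=0.3,
            )
    ax.set_xlabel("MDS dimension 1")
    ax.set_ylabel("MDS dimension 2")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
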