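"""Sample-level quality control: Spearman correlation and PCA of fragment counts.

Both operate on the fragments x samples count matrix.  Replicates of the
same construct should correlate strongly and cluster together; Dam-only
controls should separate from Dam-fusion samples along the leading
principal components when genuine binding signal is present.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


class QCError(ValueError):
    pass


def spearman_correlation_matrix(
    counts: pd.DataFrame,
) -> Tuple[pd.DataFrame, list]:
    """Pairwise Spearman rho between samples (columns) plus an
    average-linkage clustering order on distance 1 - rho.

    Constant columns get rho 0 against everything (with a warning); the
    diagonal is exactly 1 and the matrix symmetric.
    """
    if counts.shape[1] < 2 or counts.shape[0] < 3:
        raise QCError("need >= 2 samples and >= 3 fragments")
    X = counts.to_numpy(dtype=float)
    constant = X.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "spearman: constant columns %s; rho set to 0",
            list(counts.columns[constant]),
        )
    ranks = np.apply_along_axis(rankdata, 0, X)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2
    matrix = pd.DataFrame(rho, index=counts.columns, columns=counts.columns)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    order_idx = leaves_list(linkage(squareform(dist, checks=False), method="average"))
    order = [counts.columns[i] for i in order_idx]
    return matrix, order


def pca_samples(
    counts: pd.DataFrame, n_components: Optional[int] = None
) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples from the count matrix.

    Columns are CPM-scaled and log2(x+1)-transformed, rows (fragments)
    centred, and components obtained by SVD.  Sample coordinates are
    returned with a fixed sign convention (the largest-magnitude coordinate
    of each component is positive) together with the percentage of variance
    per component (non-increasing, summing to <= 100).
    """
    if counts.shape[1] < 2:
        raise QCError("PCA needs >= 2 samples")
    X = counts.to_numpy(dtype=float)
    totals = X.sum(axis=0)
    if np.any(totals == 0):
        totals = np.where(totals == 0, 1.0, totals)
    X = np.log2(X / totals * 1e6 + 1.0)
    X = X - X.mean(axis=1, keepdims=True)  # centre per fragment
    k = n_components or min(X.shape)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    coords = (Vt.T * S)[:, :k]  # samples x components
    total_var = float((S**2).sum())
    if total_var == 0:
        logger.warning("pca_samples: zero variance (identical samples)")
        var_pct = np.zeros(k)
    else:
        var_pct = (S[:k] ** 2) / total_var * 100.0
    for j in range(coords.shape[1]):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    frame = pd.DataFrame(
        coords,
        index=counts.columns,
        columns=[f"PC{j + 1}" for j in range(coords.shape[1])],
    )
    return frame, var_pct


def plot_correlation_heatmap(matrix: pd.DataFrame, order: Sequence[str], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = matrix.loc[list(order), list(order)]
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(ordered.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca(coords: pd.DataFrame, var_pct: np.ndarray, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1])
    for name, row in coords.iterrows():
        ax.annotate(str(name), (row.iloc[0], row.iloc[1]), fontsize=7)
    ax.set_xlabel(f"PC1 ({var_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({var_pct[1]:.1f}%)" if len(var_pct) > 1 else "PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
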