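"""Multivariate descriptive chain: PCA, Manhattan-distance PCoA, PERMANOVA.

Feature intensities are sum-normalized per sample, log10-transformed with a
data-driven pseudo-count (half the smallest positive normalized value) and
mean-centered per feature before PCA.  PCoA (classical MDS, Gower double-
centering) and PERMANOVA run on arbitrary distance matrices, Manhattan by
convention here.  PERMANOVA is delegated to scikit-bio behind this module's
surface; PCoA is a direct eigendecomposition so that negative eigenvalues of
non-Euclidean distances are reported rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova

from .core import FeatureTable


@dataclass
class OrdinationResult:
    method: str                      # "PCA" | "PCoA"
    scores: pd.DataFrame             # samples x axes
    explained: np.ndarray            # % variance per axis (non-increasing)
    loadings: pd.DataFrame | None = None   # PCA only
    eigenvalues: np.ndarray | None = None  # PCoA only (may contain negatives)


def preprocess_features(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Sum-normalize, log10-transform, mean-center (samples x features)."""
    mat = table.matrix() if isinstance(table, FeatureTable) else table
    X = mat.to_numpy(float)
    if (X < 0).any():
        raise ValueError("intensities must be non-negative")
    totals = X.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(mat.index[zero])}")
    X = X / totals[:, None]
    eps = X[X > 0].min() / 2.0
    X = np.log10(X + eps)
    X = X - X.mean(axis=0, keepdims=True)
    return pd.DataFrame(X, index=mat.index, columns=mat.columns)


def pca(matrix: pd.DataFrame) -> OrdinationResult:
    """SVD-based principal components of a preprocessed matrix."""
    if len(matrix) < 2:
        raise ValueError("need >= 2 samples")
    X = matrix.to_numpy(float)
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if not np.any(s > 0):
        raise ValueError("rank-0 input")
    nz = s > s[0] * 1e-12
    U, s, Vt = U[:, nz], s[nz], Vt[nz]
    axes = [f"PC{i+1}" for i in range(len(s))]
    scores = pd.DataFrame(U * s, index=matrix.index, columns=axes)
    loadings = pd.DataFrame(Vt.T, index=matrix.columns, columns=axes)
    explained = 100.0 * s ** 2 / (s ** 2).sum()
    return OrdinationResult("PCA", scores, explained, loadings=loadings)


def manhattan_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    D = squareform(pdist(matrix.to_numpy(float), metric="cityblock"))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


def gower_center(D: np.ndarray) -> np.ndarray:
    """Gower double-centering of -D**2 / 2."""
    A = -0.5 * D ** 2
    row = A.mean(axis=1, keepdims=True)
    return A - row - row.T + A.mean()


def pcoa(distances: pd.DataFrame) -> OrdinationResult:
    """Principal coordinates (classical MDS) of a distance matrix.

    Eigendecomposition of the Gower-centered matrix; coordinate axes are
    returned for positive eigenvalues only, while the full eigenvalue
    spectrum — including the negative eigenvalues a non-Euclidean distance
    like Manhattan produces — is reported uncorrected.
    """
    D = distances.to_numpy(float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    G = gower_center(D)
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tolerance = 1e-10 * max(abs(eigval).max(), 1.0)
    pos = eigval > tolerance
    axes = [f"PCo{i+1}" for i in range(int(pos.sum()))]
    scores = pd.DataFrame(eigvec[:, pos] * np.sqrt(eigval[pos]),
                          index=distances.index, columns=axes)
    explained = 100.0 * eigval[pos] / eigval[pos].sum() if pos.any() \
        else np.zeros(0)
    return OrdinationResult("PCoA", scores, explained, eigenvalues=eigval)


def permanova(distances: pd.DataFrame, grouping: pd.Series,
              n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Permutational MANOVA: (pseudo-F, p) on a distance matrix."""
    grouping = grouping.reindex(distances.index)
    sizes = grouping.value_counts()
    if len(sizes) < 2:
        raise ValueError("need >= 2 groups")
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        raise ValueError(f"singleton group(s): {small}")
    ids = [str(i) for i in distances.index]
    dm = DistanceMatrix(distances.to_numpy(float), ids=ids)
    np.random.seed(seed % (2 ** 32))  # skbio draws from the global RNG
    res = _skbio_permanova(dm, grouping.to_numpy(), permutations=n_perm)
    return float(res["test statistic"]), float(res["p-value"])
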