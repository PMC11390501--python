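"""Baseline heterogeneity metrics computed on single-cell CNV profiles.

Two published strategies are reimplemented as comparison points for the
entropy-based complexity score:

* ``ma_centroid_score`` — project cells into PC space and report the mean
  Euclidean distance of cells from their centroid.
* ``guo_pairwise_score`` — report the median over all unordered cell pairs
  of D = 1 - r, with r the Pearson correlation of the two CNV profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import PCA

from cnvcomplexity.cnv_io import ContinuousCnvMatrix, DiscreteCnvMatrix

__all__ = ["ma_centroid_score", "guo_pairwise_score"]


def _cells_by_genes(m: DiscreteCnvMatrix | ContinuousCnvMatrix) -> np.ndarray:
    data = m.states if isinstance(m, DiscreteCnvMatrix) else m.values
    return np.asarray(data, dtype=float).T  # cells x genes


def ma_centroid_score(
    m: DiscreteCnvMatrix | ContinuousCnvMatrix,
    n_components: int = 30,
) -> float:
    """Mean distance of cells from their centroid in PC space.

    Genes are centered, cells are projected onto
    ``k = min(n_components, n_cells - 1, n_genes)`` principal components and
    the score is the mean Euclidean distance of the projections from their
    centroid.
    """
    X = _cells_by_genes(m)
    n_cells, n_genes = X.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if n_components < 1:
        raise ValueError("n_components must be positive")
    k = min(n_components, n_cells - 1, n_genes)
    if np.ptp(X, axis=0).max() == 0:
        return 0.0  # all cells identical; PC projections collapse to a point
    pca = PCA(n_components=k, random_state=0)
    proj = pca.fit_transform(X)
    centroid = proj.mean(axis=0)
    return float(np.linalg.norm(proj - centroid, axis=1).mean())


def guo_pairwise_score(m: DiscreteCnvMatrix | ContinuousCnvMatrix) -> float:
    """Median pairwise cell distance D = 1 - Pearson r of CNV profiles.

    Pairs involving a constant (zero-variance) profile, where Pearson r is
    undefined, score D = 0 when the two profiles are identical and D = 1
    otherwise; a warning is emitted when such cells are present.
    """
    X = _cells_by_genes(m)
    n_cells, n_genes = X.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if n_genes < 2:
        raise ValueError("need at least 2 genes")

    sd = X.std(axis=1)
    constant = sd == 0
    D = np.ones((n_cells, n_cells))
    ok = ~constant
    if ok.sum() >= 2:
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(X[ok])
        D[np.ix_(ok, ok)] = 1.0 - r
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant-profile cell(s): Pearson r "
            "undefined; using D=0 for identical profiles, D=1 otherwise",
            RuntimeWarning,
            stacklevel=2,
        )
        const_idx = np.nonzero(constant)[0]
        # constant vs constant: identical iff the constant value matches
        vals = X[const_idx, 0]
        eq = vals[:, None] == vals[None, :]
        D[np.ix_(const_idx, const_idx)] = np.where(eq, 0.0, 1.0)
        # constant vs non-constant can never be identical -> D stays 1
    iu = np.triu_indices(n_cells, k=1)
    return float(np.median(D[iu]))
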