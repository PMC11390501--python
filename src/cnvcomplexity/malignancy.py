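"""Per-cell CNV fluctuation scoring and malignant-cell calling.

A cell's score is the population variance of its CNV profile across genes
(a flat, copy-neutral profile scores 0; aberrant segments inflate it).
Malignant cells are called by thresholding observation-cell scores at the
crossing point of the kernel density estimates of the observation and
reference score distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from cnvcomplexity.cnv_io import ContinuousCnvMatrix, DiscreteCnvMatrix

__all__ = [
    "CellCnvScore",
    "MalignancyCall",
    "cell_cnv_score",
    "score_threshold",
    "call_malignant",
]

logger = logging.getLogger(__name__)

MALIGNANT = "malignant"
NON_MALIGNANT = "non_malignant"


@dataclass(frozen=True)
class CellCnvScore:
    cell_id: str
    score: float


@dataclass
class MalignancyCall:
    """Threshold plus per-cell calls and scores for the observation cells."""

    threshold: float
    calls: dict[str, str]
    obs_scores: dict[str, float]
    ref_scores: dict[str, float]
    used_fallback: bool = False
    n_shared_genes: int = 0


def cell_cnv_score(
    profile: Sequence[float] | np.ndarray,
    *,
    center: Literal["cell_mean", "neutral"] = "cell_mean",
) -> float:
    """Mean squared deviation of a cell's CNV profile.

    With ``center="cell_mean"`` (default) this is the population variance
    ``sum((x_i - mean(x))**2) / n``.  ``center="neutral"`` measures the mean
    squared deviation from the copy-neutral value 1.0 instead.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("profile must be a non-empty 1-D vector")
    if not np.isfinite(x).all():
        raise ValueError("profile contains non-finite values")
    ref = x.mean() if center == "cell_mean" else 1.0
    return float(np.mean((x - ref) ** 2))


def _kde(sample: np.ndarray) -> gaussian_kde | None:
    # gaussian_kde needs positive variance; degenerate samples get None.
    if sample.size < 2 or np.ptp(sample) == 0:
        return None
    return gaussian_kde(sample)  # Scott's rule bandwidth


def score_threshold(
    obs_scores: Sequence[float] | np.ndarray,
    ref_scores: Sequence[float] | np.ndarray,
    *,
    grid_size: int = 512,
) -> float:
    """Crossing point of the two score-density estimates.

    Gaussian KDEs (Scott's rule) of both score samples are evaluated on a
    shared grid spanning the interval between the two sample means; the
    threshold is the grid crossing of the two densities closest to the
    midpoint of the means.  If the densities do not cross in that interval
    (or either sample is degenerate), the midpoint of the two means is
    returned and a warning is emitted.
    """
    obs = np.asarray(obs_scores, dtype=float)
    ref = np.asarray(ref_scores, dtype=float)
    if obs.size == 0 or ref.size == 0:
        raise ValueError("both score vectors must be non-empty")

    mean_obs, mean_ref = obs.mean(), ref.mean()
    midpoint = 0.5 * (mean_obs + mean_ref)
    lo, hi = sorted((mean_obs, mean_ref))

    kde_obs, kde_ref = _kde(obs), _kde(ref)
    if kde_obs is None or kde_ref is None or hi - lo == 0:
        warnings.warn(
            "score distributions degenerate or coincident; falling back to "
            "the midpoint of the two means",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(midpoint)

    grid = np.linspace(lo, hi, grid_size)
    diff = kde_obs(grid) - kde_ref(grid)
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if sign_change.size == 0:
        warnings.warn(
            "KDE densities do not cross between the distribution means; "
            "falling back to the midpoint",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(midpoint)

    crossings = []
    for i in sign_change:
        x0, x1 = grid[i], grid[i + 1]
        d0, d1 = diff[i], diff[i + 1]
        crossings.append(x0 if d0 == d1 else x0 + (x1 - x0) * d0 / (d0 - d1))
    crossings = np.asarray(crossings)
    return float(crossings[np.argmin(np.abs(crossings - midpoint))])


def _matrix_scores(
    m: ContinuousCnvMatrix | DiscreteCnvMatrix,
    gene_idx: np.ndarray,
    center: str,
) -> dict[str, float]:
    data = m.values if isinstance(m, ContinuousCnvMatrix) else m.states.astype(float)
    sub = data[gene_idx, :]
    ref = sub.mean(axis=0) if center == "cell_mean" else 1.0
    scores = np.mean((sub - ref) ** 2, axis=0)
    return dict(zip(m.cell_ids, scores.astype(float)))


def call_malignant(
    obs: ContinuousCnvMatrix | DiscreteCnvMatrix,
    ref: ContinuousCnvMatrix | DiscreteCnvMatrix,
    *,
    center: Literal["cell_mean", "neutral"] = "cell_mean",
) -> MalignancyCall:
    """Score every cell and call observation cells above the KDE threshold.

    Scoring uses the genes shared between the two matrices (intersection,
    logged).  A cell is called malignant iff its score strictly exceeds the
    threshold; ties are non-malignant.
    """
    ref_genes = set(ref.gene_ids)
    shared = [g for g in obs.gene_ids if g in ref_genes]
    if not shared:
        raise ValueError("observation and reference matrices share no genes")
    if len(shared) < len(obs.gene_ids) or len(shared) < len(ref.gene_ids):
        logger.info(
            "gene intersection: %d shared of %d obs / %d ref genes",
            len(shared), len(obs.gene_ids), len(ref.gene_ids),
        )
    obs_pos = {g: i for i, g in enumerate(obs.gene_ids)}
    ref_pos = {g: i for i, g in enumerate(ref.gene_ids)}
    obs_idx = np.array([obs_pos[g] for g in shared])
    ref_idx = np.array([ref_pos[g] for g in shared])

    obs_scores = _matrix_scores(obs, obs_idx, center)
    ref_scores = _matrix_scores(ref, ref_idx, center)

    used_fallback = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        threshold = score_threshold(
            np.array(list(obs_scores.values())),
            np.array(list(ref_scores.values())),
        )
    for w in caught:  # re-emit outside the recording context
        if issubclass(w.category, RuntimeWarning):
            used_fallback = True
            warnings.warn(w.message, RuntimeWarning, stacklevel=2)

    calls = {
        cell: (MALIGNANT if score > threshold else NON_MALIGNANT)
        for cell, score in obs_scores.items()
    }
    return MalignancyCall(
        threshold=threshold,
        calls=calls,
        obs_scores=obs_scores,
        ref_scores=ref_scores,
        used_fallback=used_fallback,
        n_shared_genes=len(shared),
    )
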