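"""Sample-level subclonal complexity from discrete CNV states.

Per gene, the loss variant frequency (LVF) is the fraction of cells with
state < 3 and the gain variant frequency (GVF) the fraction with state > 3.
Each gene is mapped into one of ten equal-width loss-frequency bins and one
of ten gain-frequency bins; the complexity score is the Shannon entropy
(bits) of the resulting 20-bin gene-count distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as shannon_entropy

from cnvcomplexity.cnv_io import DiscreteCnvMatrix

__all__ = [
    "AlterationFrequencies",
    "ComplexityResult",
    "alteration_frequencies",
    "bin_gene_counts",
    "complexity_score",
    "N_BINS_PER_ARM",
    "MAX_ENTROPY_BITS",
]

N_BINS_PER_ARM = 10
MAX_ENTROPY_BITS = float(np.log2(2 * N_BINS_PER_ARM))


@dataclass
class AlterationFrequencies:
    """Per-gene gain/loss frequencies over the cells of one sample."""

    gene_ids: list[str]
    lvf: np.ndarray
    gvf: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        self.lvf = np.asarray(self.lvf, dtype=float)
        self.gvf = np.asarray(self.gvf, dtype=float)
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        for name, f in (("lvf", self.lvf), ("gvf", self.gvf)):
            if f.shape != (len(self.gene_ids),):
                raise ValueError(f"{name} length does not match gene_ids")
            if ((f < 0) | (f > 1)).any():
                raise ValueError(f"{name} outside [0, 1]")
        if ((self.lvf + self.gvf) > 1 + 1e-12).any():
            raise ValueError("lvf + gvf exceeds 1 for some gene")


@dataclass
class ComplexityResult:
    """20 bin counts (10 loss then 10 gain), their probabilities, entropy."""

    bin_counts: np.ndarray
    bin_probs: np.ndarray
    entropy: float

    def __post_init__(self) -> None:
        self.bin_counts = np.asarray(self.bin_counts, dtype=np.int64)
        self.bin_probs = np.asarray(self.bin_probs, dtype=float)
        if self.bin_counts.shape != (2 * N_BINS_PER_ARM,):
            raise ValueError("expected 20 bin counts")
        if abs(self.bin_probs.sum() - 1.0) > 1e-12:
            raise ValueError("bin probabilities must sum to 1")
        if not (0.0 <= self.entropy <= MAX_ENTROPY_BITS + 1e-12):
            raise ValueError("entropy outside [0, log2 20]")


def alteration_frequencies(m: DiscreteCnvMatrix) -> AlterationFrequencies:
    """Fraction of cells with a loss (state < 3) / gain (state > 3) per gene."""
    if m.n_cells < 1:
        raise ValueError("matrix has no cells")
    neutral = m.neutral_state
    lvf = (m.states < neutral).mean(axis=1)
    gvf = (m.states > neutral).mean(axis=1)
    return AlterationFrequencies(list(m.gene_ids), lvf, gvf, m.n_cells)


def _bin_index(freq: np.ndarray) -> np.ndarray:
    # Half-open bins [0,0.1), ..., [0.9,1.0]; the closing clip folds 1.0 into
    # the last bin.  The epsilon guards against k/n*10 landing one ulp below
    # an integer boundary (frequencies are ratios with denominator n_cells,
    # so true values are never within 1e-9 of a boundary they do not sit on).
    return np.minimum(np.floor(freq * N_BINS_PER_ARM + 1e-9).astype(np.int64), N_BINS_PER_ARM - 1)


def bin_gene_counts(f: AlterationFrequencies, *, exclude_zero: bool = False) -> np.ndarray:
    """20-vector of gene counts: 10 loss-frequency bins then 10 gain bins.

    Every gene contributes once to a loss bin and once to a gain bin.  With
    ``exclude_zero=True`` genes with frequency exactly 0 are dropped from
    that arm's histogram.
    """
    counts = np.zeros(2 * N_BINS_PER_ARM, dtype=np.int64)
    for offset, freq in ((0, f.lvf), (N_BINS_PER_ARM, f.gvf)):
        if exclude_zero:
            freq = freq[freq > 0]
        idx = _bin_index(freq)
        counts[offset:offset + N_BINS_PER_ARM] = np.bincount(idx, minlength=N_BINS_PER_ARM)
    return counts


def complexity_score(
    m: DiscreteCnvMatrix, *, exclude_zero: bool = False
) -> ComplexityResult:
    """Shannon entropy (bits) of the 20-bin gene-count distribution."""
    f = alteration_frequencies(m)
    counts = bin_gene_counts(f, exclude_zero=exclude_zero)
    total = counts.sum()
    if total == 0:
        raise ValueError("no genes contribute to the histogram (exclude_zero on an all-neutral matrix)")
    probs = counts / total
    ent = float(shannon_entropy(probs, base=2))  # 0*log(0) treated as 0
    return ComplexityResult(bin_counts=counts, bin_probs=probs, entropy=ent)
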