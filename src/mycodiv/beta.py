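"""Between-sample dissimilarity, PCoA ordination, and ANOSIM.

Bray-Curtis dissimilarities between sample columns feed a metric
principal coordinate analysis (Gower double-centering followed by a
symmetric eigendecomposition) and the rank-based ANOSIM permutation
test of group separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .tables import FeatureTable, SampleMetadata

__all__ = [
    "DissimilarityMatrix",
    "bray_curtis",
    "OrdinationResult",
    "pcoa",
    "AnosimResult",
    "anosim",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise sample dissimilarities with zero diagonal."""

    sample_ids: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} != ({n}, {n})")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix has nonzero diagonal")
        if (m < -1e-12).any():
            raise ValueError("negative dissimilarities")
        self.matrix = (m + m.T) / 2.0
        np.fill_diagonal(self.matrix, 0.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids,
                            columns=self.sample_ids)


def bray_curtis(table: FeatureTable) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis: BC(x, y) = sum |x_i - y_i| / sum (x_i + y_i)."""
    sums = table.data.sum(axis=0)
    if (sums <= 0).any():
        zero = sums[sums <= 0].index.tolist()
        raise ValueError(f"sample(s) with zero total: {zero}")
    d = squareform(pdist(table.data.to_numpy().T, metric="braycurtis"))
    return DissimilarityMatrix(table.sample_ids, d)


@dataclass
class OrdinationResult:
    """PCoA axes: eigenvalues (all, descending), coordinates on the
    positive axes, and each positive axis's share of the positive
    eigenvalue sum."""

    sample_ids: list
    eigenvalues: np.ndarray          # all n eigenvalues, descending
    coordinates: np.ndarray          # n_samples x n_positive_axes
    proportion_explained: np.ndarray  # per positive axis

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids,
                            columns=cols)


def pcoa(dm: DissimilarityMatrix, eps: float = 1e-10) -> OrdinationResult:
    """Metric multidimensional scaling of a dissimilarity matrix.

    Double-centers the squared dissimilarities, B = -1/2 J D^2 J with
    J = I - 11'/n, and eigendecomposes B.  Coordinates are
    eigenvector * sqrt(eigenvalue) on axes with eigenvalue > eps * max;
    negative eigenvalues (non-Euclidean input) are reported but excluded
    from the coordinates.  No Lingoes/Cailliez correction is applied.
    """
    d = dm.matrix
    n = dm.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(abs(evals[0]), 1.0) if n else 1.0
    pos = evals > eps * scale
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pos_sum = evals[pos].sum()
    prop = evals[pos] / pos_sum if pos_sum > 0 else evals[pos]
    return OrdinationResult(
        sample_ids=list(dm.sample_ids),
        eigenvalues=evals,
        coordinates=coords,
        proportion_explained=prop,
    )


@dataclass
class AnosimResult:
    r: float
    p_value: float
    permutations: int
    seed: int | None


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return (rb - rw) / (m / 2.0)


def anosim(dm: DissimilarityMatrix, meta: SampleMetadata,
           permutations: int = 999, seed: int | None = None) -> AnosimResult:
    """ANOSIM test of whether between-group dissimilarities exceed
    within-group dissimilarities.

    All off-diagonal pairs are ranked (mid-ranks for ties) and

        R = (mean between-group rank - mean within-group rank) / (M / 4)

    with M = n(n-1)/2 pairs, so R lies in [-1, 1].  Significance comes
    from permuting group labels:  p = (1 + #{R_perm >= R_obs}) /
    (permutations + 1).
    """
    groups = meta.groups_for(dm.sample_ids)
    meta.check_grouped(dm.sample_ids)
    n = dm.n
    cond = dm.condensed()
    ranks = rankdata(cond)

    iu, ju = np.triu_indices(n, k=1)
    labels = np.asarray(groups)
    within = labels[iu] == labels[ju]
    r_obs = _anosim_r(ranks, within)

    rng = np.random.default_rng(seed)
    # vectorised label permutations: a (permutations, n) index matrix
    perm_idx = np.argsort(rng.random((permutations, n)), axis=1)
    codes = pd.factorize(labels)[0]
    perm_codes = codes[perm_idx]                      # (P, n)
    perm_within = perm_codes[:, iu] == perm_codes[:, ju]  # (P, M)
    m = len(ranks)
    rw = (ranks * perm_within).sum(axis=1) / perm_within.sum(axis=1)
    rb = (ranks * ~perm_within).sum(axis=1) / (~perm_within).sum(axis=1)
    r_perm = (rb - rw) / (m / 2.0)
    p = (1.0 + np.count_nonzero(r_perm >= r_obs)) / (permutations + 1.0)
    return AnosimResult(r=float(r_obs), p_value=float(p),
                        permutations=permutations, seed=seed)
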