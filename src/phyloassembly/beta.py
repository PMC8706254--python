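"""Pairwise sample dissimilarity: Bray-Curtis, weighted UniFrac, betaMNTD.

Counts are converted to relative abundances before Bray-Curtis and
UniFrac so library-size differences cannot masquerade as turnover.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity.beta import weighted_unifrac as _skbio_wunifrac

from .io import CountTable
from .matrices import PairwiseMatrix
from .phylo import patristic_matrix


def bray_curtis(table: CountTable) -> PairwiseMatrix:
    """Bray-Curtis dissimilarity on per-sample relative abundances.

    BC(x, y) = sum |x_i - y_i| / sum (x_i + y_i); 0 for identical
    compositions, 1 for disjoint taxon sets.
    """
    rel = table.relative().to_numpy().T  # samples x taxa
    vals = squareform(pdist(rel, metric="braycurtis"))
    return PairwiseMatrix.from_values(vals, table.sample_ids, "bray_curtis")


def weighted_unifrac(
    table: CountTable, tree: TreeNode, normalized: bool = True
) -> PairwiseMatrix:
    """Weighted UniFrac between all sample pairs.

    Branch lengths are weighted by the absolute difference in the
    fraction of each sample's abundance descending from the branch; the
    normalized variant (default) divides by the maximum attainable value
    so results lie in [0, 1].
    """
    tips = {t.name for t in tree.tips()}
    missing = set(table.taxon_ids) - tips
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)[:5]}")
    taxa = table.taxon_ids
    rel = table.relative().to_numpy().T
    n = table.n_samples
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            raw = _skbio_wunifrac(rel[i], rel[j], taxa=taxa, tree=tree, validate=False)
            if normalized and raw > 0:
                d = _skbio_wunifrac(
                    rel[i], rel[j], taxa=taxa, tree=tree, normalized=True, validate=False
                )
            else:
                d = raw  # identical compositions: 0 exactly, no 0/0 normalization
            vals[i, j] = vals[j, i] = d
    return PairwiseMatrix.from_values(
        vals, table.sample_ids, "weighted_unifrac_normalized" if normalized else "weighted_unifrac"
    )


def _nearest_taxon_matrix(D: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """M[l, i] = distance from taxon i to its nearest taxon present in sample l."""
    S, T = presence.shape
    M = np.empty((S, T))
    for l in range(S):
        cols = np.flatnonzero(presence[l])
        M[l] = D[:, cols].min(axis=1)
    return M


def beta_mntd_from_distances(
    D: np.ndarray, weights: np.ndarray, presence: np.ndarray
) -> np.ndarray:
    """betaMNTD matrix from a patristic matrix and per-sample taxon weights.

    For samples k, l: the weight-averaged distance from each taxon in k
    to its nearest taxon in l, averaged with the reciprocal direction.
    ``weights`` rows are relative abundances (abundance-weighted) or
    1/richness indicators (unweighted); rows must sum to 1.
    """
    M = _nearest_taxon_matrix(D, presence)
    A = weights @ M.T  # A[k, l] = sum_i w_ki * dist(i -> nearest in l)
    return 0.5 * (A + A.T)


def _sample_weights(table: CountTable, weighted: bool) -> tuple[np.ndarray, np.ndarray]:
    counts = table.matrix().astype(float)
    presence = counts > 0
    if (~presence.any(axis=1)).any():
        empty = [table.sample_ids[i] for i in np.flatnonzero(~presence.any(axis=1))]
        raise ValueError(f"sample(s) with no taxa present: {empty}")
    if weighted:
        weights = counts / counts.sum(axis=1, keepdims=True)
    else:
        weights = presence / presence.sum(axis=1, keepdims=True)
    return weights, presence


def beta_mntd(table: CountTable, tree: TreeNode, weighted: bool = True) -> PairwiseMatrix:
    """Observed betaMNTD ('comdistnt') between all sample pairs.

    Abundance-weighted by default (each taxon's nearest-neighbor distance
    weighted by its relative abundance); ``weighted=False`` gives the
    presence-based variant.
    """
    D = patristic_matrix(tree, table.taxon_ids)
    weights, presence = _sample_weights(table, weighted)
    vals = beta_mntd_from_distances(D, weights, presence)
    np.fill_diagonal(vals, 0.0)
    name = "beta_mntd_weighted" if weighted else "beta_mntd_unweighted"
    return PairwiseMatrix.from_values(vals, table.sample_ids, name)
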