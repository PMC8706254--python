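"""betaNTI (phylogeny-shuffling null) and Raup-Crick on Bray-Curtis.

betaNTI
-------
Observed betaMNTD for every sample pair is compared with the betaMNTD
distribution under tip-label shuffles of the phylogeny across the full
analyzed taxon pool: betaNTI = (betaMNTD_obs - mean_null) / sd_null.
One shuffle per null replicate is shared by all sample pairs, so the
pairwise values are coherent and the computation vectorizes. |betaNTI| > 2
signals deterministic assembly (variable selection above +2, homogeneous
selection below -2).

RCbray
------
For each sample pair and replicate, both communities are probabilistically
re-assembled from the regional pool: each community draws its observed
richness without replacement with probability proportional to taxon
occupancy, seeds each drawn taxon with one read, and spreads its remaining
reads multinomially proportional to metacommunity relative abundance.
RC_raw is the fraction of null Bray-Curtis values below the observed one
(ties at half weight), rescaled to [-1, 1]: RCbray = 2 (RC_raw - 0.5).
Beyond +0.95 indicates dispersal limitation, below -0.95 homogenizing
dispersal, given |betaNTI| <= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .beta import _sample_weights, beta_mntd_from_distances
from .io import CountTable
from .matrices import PairwiseMatrix
from .phylo import patristic_matrix
from .rng import substream


@dataclass
class BetaNtiResult:
    """betaNTI z-scores plus companion observed/null-moment matrices."""

    bnti: PairwiseMatrix
    bmntd_obs: PairwiseMatrix
    null_mean: PairwiseMatrix
    null_sd: PairwiseMatrix
    n_null: int
    seed: int
    weighted: bool
    n_flagged_pairs: int = 0  # pairs with sd_null == 0 (betaNTI undefined)


def beta_nti(
    table: CountTable,
    tree: TreeNode,
    n_null: int = 999,
    weighted: bool = True,
    seed: int = 0,
) -> BetaNtiResult:
    """betaNTI for every sample pair (shared-shuffle null, 999 replicates).

    Pairs whose null sd is zero (e.g. all patristic distances equal) are
    reported as NaN and counted in ``n_flagged_pairs``.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    D = patristic_matrix(tree, table.taxon_ids)
    weights, presence = _sample_weights(table, weighted)
    obs = beta_mntd_from_distances(D, weights, presence)

    rng = substream(seed, "beta_nti")
    T = D.shape[0]
    S = weights.shape[0]
    acc = np.zeros((S, S))
    acc2 = np.zeros((S, S))
    for _ in range(n_null):
        perm = rng.permutation(T)
        Dp = D[np.ix_(perm, perm)]
        null = beta_mntd_from_distances(Dp, weights, presence)
        acc += null
        acc2 += null**2
    mean = acc / n_null
    var = acc2 / n_null - mean**2
    # guard tiny negative variance from cancellation
    sd = np.sqrt(np.clip(var, 0.0, None)) * np.sqrt(n_null / max(n_null - 1, 1))

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    np.fill_diagonal(z, np.nan)
    iu = np.triu_indices(S, k=1)
    n_flagged = int((sd[iu] == 0).sum())
    z[sd == 0] = np.nan
    np.fill_diagonal(obs, 0.0)

    ids = table.sample_ids
    return BetaNtiResult(
        bnti=PairwiseMatrix.from_values(z, ids, "beta_nti"),
        bmntd_obs=PairwiseMatrix.from_values(obs, ids, "beta_mntd_obs"),
        null_mean=PairwiseMatrix.from_values(mean, ids, "beta_mntd_null_mean"),
        null_sd=PairwiseMatrix.from_values(sd, ids, "beta_mntd_null_sd"),
        n_null=n_null,
        seed=int(seed),
        weighted=weighted,
        n_flagged_pairs=n_flagged,
    )


def beta_nti_exhaustive(table: CountTable, tree: TreeNode, weighted: bool = True) -> PairwiseMatrix:
    """Exact betaNTI by enumerating all tip-label permutations (<= 8 taxa).

    Brute-force oracle for :func:`beta_nti` on tiny trees.
    """
    taxa = table.taxon_ids
    if len(taxa) > 8:
        raise ValueError("exhaustive enumeration limited to <= 8 taxa")
    D = patristic_matrix(tree, taxa)
    weights, presence = _sample_weights(table, weighted)
    obs = beta_mntd_from_distances(D, weights, presence)
    vals = []
    for perm in permutations(range(len(taxa))):
        Dp = D[np.ix_(perm, perm)]
        vals.append(beta_mntd_from_distances(Dp, weights, presence))
    vals = np.asarray(vals)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z[sd == 0] = np.nan
    np.fill_diagonal(z, np.nan)
    return PairwiseMatrix.from_values(z, table.sample_ids, "beta_nti_exhaustive")


@dataclass
class RaupCrickResult:
    rc: PairwiseMatrix  # RCbray in [-1, 1]
    bray_obs: PairwiseMatrix
    n_null: int
    seed: int


def raup_crick_bray(table: CountTable, n_null: int = 999, seed: int = 0) -> RaupCrickResult:
    """Bray-Curtis-based Raup-Crick against probabilistic re-assembly nulls.

    Null communities preserve each sample's observed richness and read
    total; draw probabilities follow taxon occupancy, read allocation the
    metacommunity relative abundance (Stegen/Chase procedure). Within a
    replicate each sample's null assembly is shared across the pairs it
    participates in, mirroring the shared-shuffle convention of betaNTI.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    counts = table.matrix().astype(float)
    S, T = counts.shape
    presence = counts > 0
    richness = presence.sum(axis=1)
    if (richness == 0).any():
        raise ValueError("sample with no taxa present")
    reads = counts.sum(axis=1).astype(int)

    occupancy = presence.sum(axis=0).astype(float)
    p_occ = occupancy / occupancy.sum()
    rel = counts / counts.sum(axis=1, keepdims=True)
    meta_p = rel.mean(axis=0)

    obs = squareform(pdist(rel, metric="braycurtis"))

    rng = substream(seed, "raup_crick_bray")
    less = np.zeros((S, S))
    equal = np.zeros((S, S))
    null_rel = np.empty((S, T))
    for _ in range(n_null):
        null_rel[:] = 0.0
        for s in range(S):
            k = int(richness[s])
            idx = rng.choice(T, size=k, replace=False, p=p_occ)
            fill = meta_p[idx]
            fill = fill / fill.sum()
            alloc = np.ones(k) + rng.multinomial(int(reads[s]) - k, fill)
            null_rel[s, idx] = alloc / reads[s]
        null_bc = squareform(pdist(null_rel, metric="braycurtis"))
        less += null_bc < obs - 1e-12
        equal += np.abs(null_bc - obs) <= 1e-12

    rc_raw = (less + 0.5 * equal) / n_null
    rc = 2.0 * (rc_raw - 0.5)
    np.fill_diagonal(rc, np.nan)
    ids = table.sample_ids
    return RaupCrickResult(
        rc=PairwiseMatrix.from_values(rc, ids, "rc_bray"),
        bray_obs=PairwiseMatrix.from_values(obs, ids, "bray_curtis"),
        n_null=n_null,
        seed=int(seed),
    )
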