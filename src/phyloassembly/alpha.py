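"""Per-sample alpha diversity: richness estimators, entropy indices,
Faith's PD, and the nearest taxon index (NTI).

NTI is the negated standardized effect size of the mean nearest taxon
distance (MNTD) against a tip-label-shuffling ("taxa.labels") null that
preserves sample richness: NTI = -(MNTD_obs - mean_null) / sd_null, so
positive values indicate phylogenetic clustering. Values above +2 are
conventionally read as environmental filtering, below -2 as competitive
exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .io import CountTable
from .phylo import patristic_matrix
from .rng import substream

ACE_RARE_THRESHOLD = 10


def _check_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("expected a single sample's count vector")
    if (counts < 0).any():
        raise ValueError("negative counts")
    if counts.sum() == 0:
        raise ValueError("all-zero sample")
    return counts.astype(np.int64)


def richness_estimators(counts) -> dict[str, float]:
    """Observed richness plus Chao1 and ACE estimates for one sample.

    Chao1 = SR + F1^2 / (2 F2), falling back to the bias-corrected form
    SR + F1 (F1 - 1) / (2 (F2 + 1)) when there are no doubletons. ACE is
    the abundance-based coverage estimator with rare threshold 10; when
    every rare taxon is a singleton (coverage 0) the bias-corrected Chao1
    value is reported instead.
    """
    counts = _check_counts(counts)
    pos = counts[counts > 0]
    sr = int(len(pos))
    f1 = int((pos == 1).sum())
    f2 = int((pos == 2).sum())
    if f2 > 0:
        chao1 = sr + f1**2 / (2 * f2)
    else:
        chao1 = sr + f1 * (f1 - 1) / (2 * (f2 + 1))

    rare = pos[pos <= ACE_RARE_THRESHOLD]
    abund = pos[pos > ACE_RARE_THRESHOLD]
    s_rare, s_abund = len(rare), len(abund)
    n_rare = int(rare.sum())
    if s_rare == 0:
        ace = float(sr)
    else:
        c_ace = 1.0 - f1 / n_rare
        if c_ace == 0.0:
            ace = float(chao1)  # all rare taxa are singletons
        else:
            ks = np.arange(1, ACE_RARE_THRESHOLD + 1)
            fk = np.array([(rare == k).sum() for k in ks])
            gamma2 = max(
                (s_rare / c_ace) * (ks * (ks - 1) * fk).sum() / (n_rare * (n_rare - 1.0)) - 1.0
                if n_rare > 1
                else 0.0,
                0.0,
            )
            ace = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2
    return {"SR": sr, "chao1": float(chao1), "ace": float(ace)}


def diversity_indices(counts) -> dict[str, float]:
    """Shannon entropy (nats) and Gini-Simpson index for one sample."""
    counts = _check_counts(counts)
    p = counts[counts > 0] / counts.sum()
    return {
        "shannon": float(-(p * np.log(p)).sum()),
        "simpson": float(1.0 - (p**2).sum()),
    }


def faith_pd(present_taxa, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity of a taxon set (stem to root included)."""
    present = list(present_taxa)
    if not present:
        raise ValueError("faith_pd requires a non-empty taxon set")
    tips = {t.name for t in tree.tips()}
    unknown = set(present) - tips
    if unknown:
        raise ValueError(f"taxa absent from tree: {sorted(unknown)[:5]}")
    taxa = sorted(tips)
    vec = np.array([1 if t in set(present) else 0 for t in taxa])
    return float(_skbio_faith_pd(vec, taxa=taxa, tree=tree))


def _mntd_presence(D: np.ndarray, idx: np.ndarray) -> float:
    """Unweighted MNTD of the community at matrix positions ``idx``."""
    sub = D[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


@dataclass
class NtiResult:
    mntd_obs: float
    nti: float
    mean_null: float
    sd_null: float
    flagged: bool  # True when sd_null == 0 and nti is undefined


def nti(
    sample_counts: pd.Series,
    tree: TreeNode | None = None,
    n_null: int = 1000,
    seed: int = 0,
    D: np.ndarray | None = None,
    pool: list[str] | None = None,
) -> NtiResult:
    """NTI of one sample against a richness-preserving taxa-shuffle null.

    The null shuffles taxon labels across the full analyzed pool (all
    taxa indexing ``sample_counts``), which is equivalent to drawing a
    uniform random subset of the same richness per replicate.

    ``D``/``pool`` allow passing a precomputed patristic matrix; else the
    tree is used. A degenerate null (sd 0, e.g. a star tree with equal
    branch lengths) is flagged rather than silently reported as 0.
    """
    if D is None:
        if tree is None:
            raise ValueError("provide either a tree or a precomputed D/pool")
        pool = list(sample_counts.index)
        D = patristic_matrix(tree, pool)
    pos = {t: i for i, t in enumerate(pool)}
    present = [pos[t] for t in sample_counts.index[sample_counts > 0]]
    if len(present) < 2:
        raise ValueError("NTI requires at least 2 present taxa")
    idx = np.asarray(present)
    mntd_obs = _mntd_presence(D, idx)
    rng = substream(seed, "nti")
    k, T = len(idx), len(pool)
    nulls = np.empty(n_null)
    for r in range(n_null):
        perm = rng.permutation(T)[:k]
        nulls[r] = _mntd_presence(D, perm)
    mean_null, sd_null = float(nulls.mean()), float(nulls.std(ddof=1))
    if sd_null == 0.0:
        return NtiResult(mntd_obs, float("nan"), mean_null, sd_null, True)
    return NtiResult(mntd_obs, -(mntd_obs - mean_null) / sd_null, mean_null, sd_null, False)


def nti_exhaustive(sample_counts: pd.Series, tree: TreeNode) -> NtiResult:
    """Exact NTI by enumerating all tip-label permutations (tiny trees only).

    Serves as the brute-force oracle for the sampled null; feasible for
    pools of <= 8 taxa.
    """
    from itertools import permutations

    pool = list(sample_counts.index)
    if len(pool) > 8:
        raise ValueError("exhaustive enumeration limited to <= 8 taxa")
    D = patristic_matrix(tree, pool)
    pos = {t: i for i, t in enumerate(pool)}
    idx = np.asarray([pos[t] for t in sample_counts.index[sample_counts > 0]])
    mntd_obs = _mntd_presence(D, idx)
    vals = []
    for perm in permutations(range(len(pool))):
        mapped = np.asarray([perm[i] for i in idx])
        vals.append(_mntd_presence(D, mapped))
    vals = np.asarray(vals)
    mean_null, sd_null = float(vals.mean()), float(vals.std(ddof=1))
    if sd_null == 0.0:
        return NtiResult(mntd_obs, float("nan"), mean_null, sd_null, True)
    return NtiResult(mntd_obs, -(mntd_obs - mean_null) / sd_null, mean_null, sd_null, False)


def alpha_table(
    table: CountTable,
    tree: TreeNode | None = None,
    n_null: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One row of alpha-diversity indices per sample.

    Taxonomic indices (SR, Chao1, ACE, Shannon, Simpson) always; Faith PD,
    MNTD and NTI when a tree is supplied. Samples whose NTI null is
    degenerate (or with < 2 taxa) get NaN with a warning.
    """
    rows = []
    D = pool = None
    if tree is not None:
        pool = table.taxon_ids
        D = patristic_matrix(tree, pool)
    for s, sid in enumerate(table.sample_ids):
        counts = table.data[sid]
        rec: dict[str, float] = {"sample_id": sid}
        rec.update(richness_estimators(counts.to_numpy()))
        rec.update(diversity_indices(counts.to_numpy()))
        if tree is not None:
            present = list(counts.index[counts > 0])
            rec["pd"] = faith_pd(present, tree)
            if len(present) >= 2:
                res = nti(counts, n_null=n_null, seed=seed + s, D=D, pool=pool)
                rec["mntd_obs"] = res.mntd_obs
                rec["nti"] = res.nti
                if res.flagged:
                    warnings.warn(f"degenerate NTI null for sample {sid}", stacklevel=2)
            else:
                rec["mntd_obs"] = float("nan")
                rec["nti"] = float("nan")
                warnings.warn(f"sample {sid} has < 2 taxa; NTI undefined", stacklevel=2)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("sample_id")
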