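"""Environmental/geographic distance matrices and Mantel tests.

The Mantel statistic is the Pearson (or Spearman) correlation between the
upper triangles of two sample-by-sample distance matrices; significance
comes from jointly permuting the rows and columns of the second matrix.
The one-sided "greater" alternative is the default — the ecological
convention for distance-decay questions — with ``alternative="two-sided"``
available. P-values use the add-one rule, so they are never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import env_columns
from .matrices import PairwiseMatrix
from .rng import substream

EARTH_RADIUS_KM = 6371.0


def env_distance(meta: pd.DataFrame, variables: list[str] | None = None) -> PairwiseMatrix:
    """Standardized Euclidean distance on environmental variables.

    Each variable is z-scored across samples (sample sd, ddof=1) before
    computing Euclidean distances, so the result is invariant to affine
    rescaling of any input variable. Zero-variance variables are dropped
    with a warning.
    """
    import warnings

    if variables is None:
        variables = env_columns(meta)
    missing = [v for v in variables if v not in meta.columns]
    if missing:
        raise ValueError(f"metadata lacks variable(s): {missing}")
    X = meta[variables].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [v for v, k in zip(variables, keep) if not k]
        warnings.warn(f"zero-variance variable(s) dropped: {dropped}", stacklevel=2)
        X, sd = X[:, keep], sd[keep]
    if X.shape[1] == 0:
        raise ValueError("no usable environmental variables")
    Z = (X - X.mean(axis=0)) / sd
    diff = Z[:, None, :] - Z[None, :, :]
    vals = np.sqrt((diff**2).sum(axis=-1))
    return PairwiseMatrix.from_values(vals, list(meta.index), "env_distance")


def geo_distance(meta: pd.DataFrame, mode: str = "haversine_km") -> PairwiseMatrix:
    """Pairwise geographic distance from latitude/longitude.

    ``haversine_km`` (default): great-circle distance on a 6371-km
    sphere. ``euclidean_degrees``: plain Euclidean distance on raw degree
    coordinates.
    """
    lat = meta["latitude"].to_numpy(dtype=float)
    lon = meta["longitude"].to_numpy(dtype=float)
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise ValueError("coordinates out of range")
    if mode == "euclidean_degrees":
        diff2 = (lat[:, None] - lat[None, :]) ** 2 + (lon[:, None] - lon[None, :]) ** 2
        vals = np.sqrt(diff2)
    elif mode == "haversine_km":
        phi = np.radians(lat)
        lam = np.radians(lon)
        dphi = phi[:, None] - phi[None, :]
        dlam = lam[:, None] - lam[None, :]
        h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
        vals = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
        np.fill_diagonal(vals, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PairwiseMatrix.from_values(vals, list(meta.index), f"geo_distance_{mode}")


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    alternative: str
    matrices: tuple[str, str] | tuple[str, str, str]


def _aligned_values(dx: PairwiseMatrix, dy: PairwiseMatrix) -> tuple[np.ndarray, np.ndarray]:
    if set(dx.sample_ids) != set(dy.sample_ids):
        raise ValueError("matrices have different sample sets")
    ids = dx.sample_ids
    return dx.values, dy.subset(ids).values


def _triu(v: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(len(v), k=1)
    return v[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom) if denom > 0 else float("nan")


def _perm_pvalue(r_obs: float, r_perm: np.ndarray, alternative: str) -> float:
    if alternative == "greater":
        extreme = (r_perm >= r_obs).sum()
    elif alternative == "two-sided":
        extreme = (np.abs(r_perm) >= abs(r_obs)).sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float((1 + extreme) / (1 + len(r_perm)))


def mantel(
    dx: PairwiseMatrix,
    dy: PairwiseMatrix,
    method: str = "pearson",
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test between two distance matrices.

    Spearman rank-transforms each upper triangle before correlating.
    Sample ids must match (order is taken from ``dx``); n >= 4 samples.
    """
    vx, vy = _aligned_values(dx, dy)
    n = len(vx)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    x = _triu(vx)
    if method == "spearman":
        x = stats.rankdata(x)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    def stat(vy_mat: np.ndarray) -> float:
        y = _triu(vy_mat)
        if method == "spearman":
            y = stats.rankdata(y)
        return _pearson(x, y)

    r_obs = stat(vy)
    rng = substream(seed, "mantel")
    r_perm = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        r_perm[i] = stat(vy[np.ix_(perm, perm)])
    return MantelResult(
        r=r_obs,
        p=_perm_pvalue(r_obs, r_perm, alternative),
        n_perm=n_perm,
        method=method,
        alternative=alternative,
        matrices=(dx.metric_name, dy.metric_name),
    )


def partial_mantel(
    dx: PairwiseMatrix,
    dy: PairwiseMatrix,
    dz: PairwiseMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel: correlation of dx and dy controlling for dz.

    Upper triangles of dx and dy are residualized on dz's, then
    correlated; the permutation distribution jointly permutes dy's rows
    and columns and re-residualizes.
    """
    vx, vy = _aligned_values(dx, dy)
    _, vz = _aligned_values(dx, dz)
    n = len(vx)
    if n < 4:
        raise ValueError("partial Mantel needs at least 4 samples")

    def vec(v: np.ndarray) -> np.ndarray:
        t = _triu(v)
        return stats.rankdata(t) if method == "spearman" else t

    x, z = vec(vx), vec(vz)

    def residual(v: np.ndarray, z: np.ndarray) -> np.ndarray:
        zc = z - z.mean()
        vc = v - v.mean()
        denom = (zc**2).sum()
        beta = (vc * zc).sum() / denom if denom > 0 else 0.0
        return vc - beta * zc

    rx = residual(x, z)

    def stat(vy_mat: np.ndarray) -> float:
        ry = residual(vec(vy_mat), z)
        # fully controlled (dy collinear with dz): no residual signal
        if not ry.any() or not rx.any():
            return 0.0
        return _pearson(rx, ry)

    r_obs = stat(vy)
    rng = substream(seed, "partial_mantel")
    r_perm = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        r_perm[i] = stat(vy[np.ix_(perm, perm)])
    return MantelResult(
        r=r_obs,
        p=_perm_pvalue(r_obs, r_perm, alternative),
        n_perm=n_perm,
        method=method,
        alternative=alternative,
        matrices=(dx.metric_name, dy.metric_name, dz.metric_name),
    )
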