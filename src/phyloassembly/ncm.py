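"""Sloan's neutral community model and Preston log-normal SAD fits.

Sloan NCM
---------
For OTU i with metacommunity mean relative abundance p_i, the local
relative abundance at stationarity is Beta(N m p_i, N m (1 - p_i)) with
N the local community size (mean reads per sample). The neutral
expectation of the OTU's detection frequency across samples is either
the exact multinomial-detection probability (default) or the classic
sharp-threshold approximation 1 - BetaCDF(1/N; a, b) — see
:func:`ncm_predicted_frequency`. m is the probability that a death in a
local community is replaced by an immigrant from the metacommunity; it is
fit by bounded nonlinear least squares of observed occurrence frequencies
f_i against f_hat_i. Goodness of fit is the generalized
R^2 = 1 - SS_res / SS_tot (can be negative; > 0.2 is conventionally read
as a neutral-process signal). OTUs are partitioned as above / within /
below the 95% band around the prediction.

Log-normal SAD
--------------
Species are binned into Preston doubling octaves and the symmetric curve
S(R) = S0 * exp(-a^2 R^2) is fit by nonlinear least squares, with R the
signed octave offset from the modal octave, S0 the species count in the
modal octave, and 1/a the distribution width. AIC (Gaussian-residual
form) compares it against a geometric-series comparator fit on the same
octaves; the contract is relative (lower AIC wins among models fit the
same way).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.proportion import proportion_confint

from .io import CountTable


@dataclass
class NcmFit:
    """Fitted Sloan neutral community model."""

    m: float
    r2: float
    N: float  # mean reads per sample
    d: float  # detection threshold, 1/N
    n_samples: int
    per_otu: pd.DataFrame  # p, freq, predicted, lower, upper, partition

    @property
    def partition_counts(self) -> pd.Series:
        return self.per_otu["partition"].value_counts().reindex(
            ["above", "neutral", "below"], fill_value=0
        )


def ncm_predicted_frequency(
    p: np.ndarray, m: float, N: float, detection: str = "exact"
) -> np.ndarray:
    """Neutral detection-frequency prediction f_hat(m) for abundances p.

    The local relative abundance x_i of OTU i is Beta(N m p_i,
    N m (1 - p_i)) at stationarity. Two detection conventions:

    * ``"exact"`` (default): the probability that at least one of N reads
      hits the OTU, 1 - E[(1 - x)^N] = 1 - B(a, b + N) / B(a, b) — the
      closed form for multinomially sequenced samples, which makes
      migration-rate recovery from sequencing-style data unbiased.
    * ``"threshold"``: the sharp-cutoff approximation
      1 - BetaCDF(d; a, b) with d = 1/N, the convention of the widely
      used R implementations.
    """
    p = np.asarray(p, dtype=float)
    a = N * m * p
    b = N * m * (1.0 - p)
    if detection == "exact":
        log_miss = special.betaln(a, b + N) - special.betaln(a, b)
        return 1.0 - np.exp(log_miss)
    if detection == "threshold":
        return 1.0 - stats.beta.cdf(1.0 / N, a, b)
    raise ValueError(f"unknown detection model {detection!r}")


def fit_migration_rate(
    p: np.ndarray,
    freq: np.ndarray,
    N: float,
    detection: str = "exact",
    m_bounds: tuple[float, float] = (1e-6, 1.0),
) -> tuple[float, float]:
    """Least-squares migration rate and generalized R^2 for (p, freq) data.

    The core of :func:`fit_ncm`, exposed so the fit can be driven with
    frequencies constructed directly (e.g. self-consistency checks).
    """
    p = np.asarray(p, dtype=float)
    freq = np.asarray(freq, dtype=float)

    def sse(m: float) -> float:
        resid = freq - ncm_predicted_frequency(p, m, N, detection)
        return float((resid**2).sum())

    res = optimize.minimize_scalar(
        sse, bounds=m_bounds, method="bounded", options={"xatol": 1e-12}
    )
    if not res.success:
        raise RuntimeError(f"NCM optimizer failed: {res}")
    m = float(res.x)
    ss_tot = float(((freq - freq.mean()) ** 2).sum())
    r2 = 1.0 - sse(m) / ss_tot if ss_tot > 0 else float("nan")
    return m, r2


def fit_ncm(
    table: CountTable,
    ci_method: str = "wilson",
    detection: str = "exact",
    m_bounds: tuple[float, float] = (1e-6, 1.0),
) -> NcmFit:
    """Fit Sloan's neutral model to occurrence frequency vs abundance.

    N is the mean read count per sample; p_i the mean of per-sample
    relative abundances; f_i the fraction of samples where the OTU is
    detected (count >= 1). The 95% band uses Wilson score intervals
    around the predicted frequency at n = number of samples
    (``ci_method="binom"`` for exact Clopper-Pearson).
    """
    if table.n_taxa < 2:
        raise ValueError("NCM fit needs more than one OTU")
    if table.n_samples < 10:
        warnings.warn(
            f"NCM fit on {table.n_samples} samples; >= 10 recommended", stacklevel=2
        )
    table = table.drop_empty_taxa()  # unobserved OTUs carry no information
    counts = table.matrix().astype(float)  # samples x taxa
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("zero-total sample")
    N = float(totals.mean())
    rel = counts / totals[:, None]
    p = rel.mean(axis=0)
    freq = (counts > 0).mean(axis=0)
    n = table.n_samples

    m, r2 = fit_migration_rate(p, freq, N, detection=detection, m_bounds=m_bounds)
    predicted = ncm_predicted_frequency(p, m, N, detection)

    method = {"wilson": "wilson", "binom": "beta"}[ci_method]
    lower, upper = proportion_confint(predicted * n, n, alpha=0.05, method=method)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    partition = np.where(freq > upper, "above", np.where(freq < lower, "below", "neutral"))

    per_otu = pd.DataFrame(
        {
            "p": p,
            "freq": freq,
            "predicted": predicted,
            "lower": lower,
            "upper": upper,
            "partition": partition,
        },
        index=table.taxon_ids,
    )
    return NcmFit(m=m, r2=r2, N=N, d=1.0 / N, n_samples=n, per_otu=per_otu)


def ncm_per_group(
    table: CountTable,
    grouping: dict[str, str] | pd.Series,
    min_samples: int = 3,
    **kwargs,
) -> dict[str, NcmFit]:
    """Independent NCM fits per sample group (e.g. per soil layer).

    Groups with fewer than ``min_samples`` samples are skipped with a
    warning.
    """
    grouping = dict(grouping) if not isinstance(grouping, dict) else grouping
    fits: dict[str, NcmFit] = {}
    groups = sorted(set(grouping.get(s) for s in table.sample_ids) - {None})
    for g in groups:
        members = [s for s in table.sample_ids if grouping.get(s) == g]
        if len(members) < min_samples:
            warnings.warn(f"group {g!r} has {len(members)} samples; skipped", stacklevel=2)
            continue
        sub = CountTable(table.data[members]).drop_empty_taxa()
        fits[g] = fit_ncm(sub, **kwargs)
    return fits


# ---------------------------------------------------------------------------
# Preston octaves and SAD fits


def octave_binning(abundances) -> pd.Series:
    """Histogram species into Preston doubling octaves.

    Octave R spans (2^(R-1), 2^R]; abundances exactly on a power-of-two
    boundary contribute half a species to each adjacent octave (Preston's
    tie-split convention). Returns species counts indexed by octave,
    contiguous from 0 to the highest occupied octave.
    """
    a = np.asarray(abundances, dtype=float)
    a = a[a > 0]
    if len(a) == 0:
        raise ValueError("no positive abundances")
    max_oct = int(np.ceil(np.log2(a.max()))) + 1
    counts = np.zeros(max_oct + 1)
    logs = np.log2(a)
    is_power = np.isclose(logs, np.round(logs))
    for x, pow2 in zip(logs, is_power):
        if pow2:
            k = int(round(x))
            counts[k] += 0.5
            counts[k + 1] += 0.5
        else:
            counts[int(np.ceil(x))] += 1.0
    last = np.max(np.nonzero(counts))
    return pd.Series(counts[: last + 1], index=pd.RangeIndex(last + 1, name="octave"))


@dataclass
class LognormalFit:
    S0: float
    a: float
    modal_octave: int
    octave_counts: pd.Series
    fitted: pd.Series  # S(R) on the octave grid
    aic: float

    def curve(self, R) -> np.ndarray:
        return self.S0 * np.exp(-(self.a**2) * np.asarray(R, dtype=float) ** 2)


@dataclass
class GeometricFit:
    c: float
    theta: float
    octave_counts: pd.Series
    fitted: pd.Series
    aic: float


def _gaussian_aic(observed: np.ndarray, fitted: np.ndarray, k: int) -> float:
    n = len(observed)
    ss_res = float(((observed - fitted) ** 2).sum())
    return n * np.log(max(ss_res, 1e-30) / n) + 2 * k


def fit_lognormal_octaves(octave_counts: pd.Series) -> LognormalFit:
    """Fit S(R) = S0 exp(-a^2 R^2) to an octave histogram."""
    y = octave_counts.to_numpy(dtype=float)
    occupied = (y > 0).sum()
    if occupied < 2:
        raise ValueError("all species fall in one octave; log-normal fit undefined")
    if occupied < 5:
        warnings.warn(
            f"only {occupied} occupied octaves; log-normal fit is weakly constrained",
            stacklevel=2,
        )
    modal = int(np.argmax(y))
    R = octave_counts.index.to_numpy(dtype=float) - modal

    def model(R, S0, a):
        return S0 * np.exp(-(a**2) * R**2)

    popt, _ = optimize.curve_fit(
        model, R, y, p0=(max(y.max(), 1.0), 0.3), bounds=([1e-12, 1e-9], [np.inf, np.inf]),
        maxfev=10000,
    )
    S0, a = float(popt[0]), float(abs(popt[1]))
    fitted = model(R, S0, a)
    return LognormalFit(
        S0=S0,
        a=a,
        modal_octave=modal,
        octave_counts=octave_counts,
        fitted=pd.Series(fitted, index=octave_counts.index),
        aic=_gaussian_aic(y, fitted, k=2),
    )


def fit_geometric_octaves(octave_counts: pd.Series) -> GeometricFit:
    """Geometric-series comparator: S(octave) = c * theta^octave."""
    y = octave_counts.to_numpy(dtype=float)
    o = octave_counts.index.to_numpy(dtype=float)

    def model(o, c, theta):
        return c * theta**o

    popt, _ = optimize.curve_fit(
        model, o, y, p0=(max(y[0], 1.0), 0.7), bounds=([1e-12, 1e-9], [np.inf, 10.0]),
        maxfev=10000,
    )
    c, theta = float(popt[0]), float(popt[1])
    fitted = model(o, c, theta)
    return GeometricFit(
        c=c,
        theta=theta,
        octave_counts=octave_counts,
        fitted=pd.Series(fitted, index=octave_counts.index),
        aic=_gaussian_aic(y, fitted, k=2),
    )


def fit_lognormal_sad(pooled_counts) -> LognormalFit:
    """Preston log-normal fit to pooled per-taxon total abundances."""
    return fit_lognormal_octaves(octave_binning(pooled_counts))


def fit_geometric_sad(pooled_counts) -> GeometricFit:
    """Geometric-series fit to the same octave histogram (AIC comparator)."""
    return fit_geometric_octaves(octave_binning(pooled_counts))
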