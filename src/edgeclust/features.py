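"""SAX symbolic representation and autocorrelation-based dissimilarity.

Registered velocity series are reduced to length-N symbolic words (default
N = 16) by piecewise-aggregate averaging and discretized into M equiprobable
levels (default M = 4) of a Gaussian fitted to the pooled values.  The
dissimilarity between two series is the squared Euclidean distance between
the sample autocorrelation vectors of their symbol sequences,

    d2_ACF(X, Y) = sum_i (ACF(X)_i - ACF(Y)_i)^2,

which groups series by temporal pattern rather than amplitude or phase.
Two ablation distances are provided: plain Euclidean distance on the raw
(denoised) series, and the SAX lower-bounding distance (MINDIST) with an
8-symbol alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import norm

__all__ = [
    "SaxConfig",
    "SymbolicSeries",
    "fit_sax",
    "paa",
    "sax_transform",
    "acf_vector",
    "acf_distance_matrix",
    "ablation_distances",
    "sax_mindist_matrix",
]

SAX_M = 4  # alphabet size of the primary pipeline
SAX_N = 16  # word length
ACF_LAGS = 15  # autocorrelation lags used for d2_ACF (N - 1)


@dataclass(frozen=True)
class SaxConfig:
    """Gaussian pooled fit and the equiprobable breakpoints it induces."""

    M: int
    N: int
    mu: float
    sigma: float
    breakpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.M < 2 or self.N < 1:
            raise ValueError("need M >= 2 symbols and N >= 1 intervals")
        if len(self.breakpoints) != self.M - 1:
            raise ValueError("expected M - 1 breakpoints")
        if not np.all(np.diff(self.breakpoints) > 0):
            raise ValueError("breakpoints must be strictly increasing")


@dataclass(frozen=True)
class SymbolicSeries:
    symbols: tuple[int, ...]
    source_id: int = 0
    zero_variance: bool = False


def fit_sax(pool: np.ndarray, M: int = SAX_M, N: int = SAX_N) -> SaxConfig:
    """Fit a Gaussian to pooled values and place M-1 equiprobable breakpoints."""
    pool = np.asarray(pool, dtype=float).ravel()
    pool = pool[np.isfinite(pool)]
    if pool.size < 2:
        raise ValueError("need at least 2 pooled values")
    mu = float(pool.mean())
    sigma = float(pool.std(ddof=0))
    if sigma == 0:
        raise ValueError("pooled values have zero variance")
    q = np.arange(1, M) / M
    breakpoints = tuple(norm.ppf(q, loc=mu, scale=sigma))
    return SaxConfig(M=M, N=N, mu=mu, sigma=sigma, breakpoints=breakpoints)


def _paa_weights(T: int, N: int) -> np.ndarray:
    """N x T matrix of fractional frame weights for intervals of length T/N."""
    edges = np.linspace(0.0, T, N + 1)
    frames = np.arange(T)
    lo = np.maximum(edges[:-1, None], frames[None, :])
    hi = np.minimum(edges[1:, None], frames[None, :] + 1.0)
    w = np.clip(hi - lo, 0.0, None)
    return w / (T / N)


def paa(series: np.ndarray, N: int) -> np.ndarray:
    """Piecewise-aggregate means over N equal intervals (fractional weighting)."""
    series = np.asarray(series, dtype=float)
    T = series.shape[-1]
    if T < N:
        raise ValueError(f"series length {T} shorter than word length {N}")
    return series @ _paa_weights(T, N).T


def sax_transform(series: np.ndarray, config: SaxConfig, source_id: int = 0) -> SymbolicSeries:
    """Symbolize one series: PAA means binned by the config breakpoints.

    A mean exactly on a breakpoint goes to the upper bin.
    """
    means = paa(np.asarray(series, dtype=float), config.N)
    symbols = np.searchsorted(np.asarray(config.breakpoints), means, side="right")
    return SymbolicSeries(symbols=tuple(int(s) for s in symbols), source_id=source_id)


def sax_transform_set(matrix: np.ndarray, config: SaxConfig) -> np.ndarray:
    """Symbolize every row of a samples x frames matrix; returns samples x N ints."""
    means = paa(np.asarray(matrix, dtype=float), config.N)
    return np.searchsorted(np.asarray(config.breakpoints), means, side="right")


def acf_vector(series: np.ndarray, max_lag: int = ACF_LAGS) -> np.ndarray:
    """Sample autocorrelations at lags 1..max_lag (symbols treated as numbers).

    A zero-variance series maps to the zero vector by convention, so that
    constant series are mutually identical under the ACF distance.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        return np.zeros(max_lag)
    return np.array([float(xc[:-k] @ xc[k:]) / denom for k in range(1, max_lag + 1)])


def acf_matrix(symbol_matrix: np.ndarray, max_lag: int = ACF_LAGS) -> np.ndarray:
    """Row-wise ACF vectors of a samples x N matrix."""
    return np.vstack([acf_vector(row, max_lag) for row in np.asarray(symbol_matrix, float)])


def acf_distance_matrix(symbol_matrix: np.ndarray, max_lag: int = ACF_LAGS) -> np.ndarray:
    """Pairwise squared Euclidean distance between ACF vectors (d2_ACF)."""
    A = acf_matrix(symbol_matrix, max_lag)
    return squareform(pdist(A, metric="sqeuclidean"))


def sax_mindist_matrix(matrix: np.ndarray, config: SaxConfig) -> np.ndarray:
    """SAX lower-bounding distance (MINDIST) between all pairs of rows.

    MINDIST(Q, C) = sqrt(T/N) * sqrt(sum_i cell(q_i, c_i)^2), where the cell
    distance is 0 for symbols at most one level apart and otherwise the gap
    between the closest breakpoints of the two levels.  It lower-bounds the
    Euclidean distance between the raw series.
    """
    matrix = np.asarray(matrix, dtype=float)
    T = matrix.shape[1]
    words = sax_transform_set(matrix, config)
    bp = np.asarray(config.breakpoints)
    M = config.M
    cell = np.zeros((M, M))
    for r in range(M):
        for c in range(M):
            if abs(r - c) > 1:
                cell[r, c] = bp[max(r, c) - 1] - bp[min(r, c)]
    n = words.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        d = cell[words[i][None, :], words[i + 1 :]]  # (n-i-1, N) cell gaps
        out[i, i + 1 :] = out[i + 1 :, i] = np.sqrt(T / config.N) * np.sqrt((d**2).sum(axis=1))
    return out


def ablation_distances(
    matrix: np.ndarray,
    method: str,
    config: SaxConfig | None = None,
    M_mindist: int = 8,
) -> np.ndarray:
    """Alternative dissimilarities used to benchmark the ACF distance.

    ``euclidean_raw``: Euclidean distance on the series themselves;
    ``sax_mindist``: the SAX lower-bounding distance with an 8-symbol alphabet
    (a fresh pooled Gaussian fit unless a config is supplied).
    """
    matrix = np.asarray(matrix, dtype=float)
    if method == "euclidean_raw":
        return squareform(pdist(matrix, metric="euclidean"))
    if method == "sax_mindist":
        if config is None:
            config = fit_sax(matrix, M=M_mindist, N=SAX_N)
        return sax_mindist_matrix(matrix, config)
    raise ValueError(f"unknown ablation distance method: {method!r}")
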