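"""Velocity-regulator coordination: normalization, correlation, significance.

Fluorescence intensities are min-max scaled per window (x1000) before
registration so recruitment patterns are comparable across expression levels.
Two complementary correlation analyses quantify coordination with edge
velocity:

* time-lag correlation — per window, Pearson r between velocity(t) and
  intensity(t + lag) over post-onset frames, averaged over windows with a
  bootstrap CI; per-window maximum correlations feed a two-sample KS test
  between groups;
* time-specific correlation — across the sample population, Pearson r
  between intensity at t1 and velocity at t2 for every (t1, t2) pair, with
  Benjamini-Hochberg FDR control over the whole grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NormalizedIntensitySeries",
    "CorrelationMap",
    "minmax_normalize",
    "timelag_correlation",
    "compare_max_correlations",
    "timespecific_correlation",
    "bh_fdr",
    "early_late_correlation",
]

INTENSITY_SCALE = 1000.0
N_BOOT = 1000
FDR_Q = 0.05


@dataclass
class NormalizedIntensitySeries:
    values: np.ndarray
    window_id: int = 0
    constant: bool = False


@dataclass
class CorrelationMap:
    """Lag- or (t1,t2)-indexed Pearson coefficients with uncertainty."""

    axis_kind: str  # "lag" | "grid"
    coefficients: np.ndarray
    lags: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    p_values: np.ndarray | None = None
    significance_mask: np.ndarray | None = None
    per_window: np.ndarray | None = None  # windows x lags r values (lag mode)
    max_per_window: np.ndarray | None = None


def minmax_normalize(series: np.ndarray, window_id: int = 0, scale: float = INTENSITY_SCALE) -> NormalizedIntensitySeries:
    """Min-max scale one window's full intensity trace to [0, scale].

    Applied per window before event registration.  A constant trace maps to
    all zeros and is flagged.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have at least 2 values")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return NormalizedIntensitySeries(np.zeros_like(x), window_id, constant=True)
    return NormalizedIntensitySeries((x - lo) / (hi - lo) * scale, window_id)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def timelag_correlation(
    velocity: np.ndarray,
    intensity: np.ndarray,
    max_lag: int = 10,
    onset_column: int = 5,
    n_boot: int = N_BOOT,
    seed: int = 0,
    min_overlap: int = 3,
) -> CorrelationMap:
    """Per-window lagged Pearson correlation of velocity and intensity.

    Only post-onset frames (from ``onset_column`` on) enter.  Positive lag
    correlates velocity(t) with intensity(t + lag), i.e. intensity trailing
    velocity.  The mean curve over windows carries a 95% bootstrap CI
    (windows resampled, not frames); lags with fewer than ``min_overlap``
    paired frames in a window are masked for that window.
    """
    V = np.asarray(velocity, dtype=float)[:, onset_column:]
    I = np.asarray(intensity, dtype=float)[:, onset_column:]
    if V.shape != I.shape:
        raise ValueError("velocity and intensity sets must be paired (same shape)")
    n_w, T = V.shape
    lags = np.arange(-max_lag, max_lag + 1)
    per_window = np.full((n_w, lags.size), np.nan)
    for li, lag in enumerate(lags):
        if lag >= 0:
            v, i_ = V[:, : T - lag if lag else T], I[:, lag:]
        else:
            v, i_ = V[:, -lag:], I[:, :lag]
        if v.shape[1] < min_overlap:
            continue
        for w in range(n_w):
            per_window[w, li] = _pearson(v[w], i_[w])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_r = np.nanmean(per_window, axis=0)
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, lags.size))
        for b in range(n_boot):
            idx = rng.integers(0, n_w, n_w)
            boots[b] = np.nanmean(per_window[idx], axis=0)
        ci_low, ci_high = np.nanpercentile(boots, [2.5, 97.5], axis=0)
        max_per_window = np.nanmax(per_window, axis=1)
    return CorrelationMap(
        axis_kind="lag",
        coefficients=mean_r,
        lags=lags,
        ci_low=ci_low,
        ci_high=ci_high,
        per_window=per_window,
        max_per_window=max_per_window,
    )


def compare_max_correlations(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Two-sample two-tailed KS p-value on per-window maximum correlations."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(stats.ks_2samp(a, b, alternative="two-sided").pvalue)


def timespecific_correlation(
    velocity: np.ndarray,
    intensity: np.ndarray,
    q: float = FDR_Q,
) -> CorrelationMap:
    """Population Pearson r between intensity at t1 and velocity at t2.

    coefficients[t1, t2] = r({I}_t1, {V}_t2) across samples, with p-values
    from the exact null distribution of r and one BH-FDR family over the
    whole grid.
    """
    V = np.asarray(velocity, dtype=float)
    I = np.asarray(intensity, dtype=float)
    if V.shape[0] != I.shape[0]:
        raise ValueError("velocity and intensity must have the same sample count")
    n = V.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")

    def _standardize(X: np.ndarray) -> np.ndarray:
        Z = X - X.mean(axis=0)
        sd = Z.std(axis=0)
        sd[sd == 0] = np.inf  # constant columns yield r = 0
        return Z / sd

    R = _standardize(I).T @ _standardize(V) / n
    R = np.clip(R, -1.0, 1.0)
    # p-values from the beta distribution of r^2 under the bivariate-normal null
    ab = n / 2.0 - 1.0
    p = 2 * stats.beta.sf((1 + np.abs(R)) / 2, ab, ab)
    p = np.clip(p, 0.0, 1.0)
    mask = bh_fdr(p.ravel(), q).reshape(p.shape)
    return CorrelationMap(
        axis_kind="grid", coefficients=R, p_values=p, significance_mask=mask
    )


def bh_fdr(p_values: np.ndarray, q: float = FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def early_late_correlation(
    intensity: np.ndarray,
    velocity: np.ndarray,
    labels: np.ndarray,
    early: tuple[int, int] = (5, 16),
    late: tuple[int, int] = (35, 56),
    n_boot: int = N_BOOT,
    seed: int = 0,
) -> dict[int, dict]:
    """Per-cluster Pearson r of early-interval mean intensity vs late-interval
    mean velocity, with a 95% bootstrap CI; clusters with < 4 samples are
    skipped with a warning."""
    I = np.asarray(intensity, dtype=float)
    V = np.asarray(velocity, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    out: dict[int, dict] = {}
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size < 4:
            warnings.warn(f"cluster {lab} has fewer than 4 samples; skipped")
            continue
        x = I[members, early[0] : early[1]].mean(axis=1)
        y = V[members, late[0] : late[1]].mean(axis=1)
        r = _pearson(x, y)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, members.size, members.size)
            rb = _pearson(x[idx], y[idx])
            if np.isfinite(rb):
                boots.append(rb)
        lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
        out[int(lab)] = {"r": r, "ci": (float(lo), float(hi)), "n": int(members.size)}
    return out
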