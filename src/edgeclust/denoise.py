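"""EMD denoising of displacement series with DFA-based noise-component selection.

The registered velocity is integrated to displacement, decomposed by
empirical mode decomposition (EMD) into intrinsic mode functions (IMFs) plus
a trend, and each IMF is scored with the detrended fluctuation analysis (DFA)
scaling exponent alpha.  Components classified as noise-like are removed, the
displacement is rebuilt from the remaining components, and the denoised
velocity is its first difference.

EMD sifting follows the classic procedure: locate extrema, interpolate upper
and lower cubic-spline envelopes (boundary extrema mirrored), subtract the
envelope mean, and iterate until the mean is numerically zero.  Because every
IMF is obtained by exact subtraction, the decomposition reconstructs the
input to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from edgeclust.registration import velocity_to_displacement

__all__ = ["EmdDecomposition", "emd_decompose", "dfa_alpha", "denoise_velocity"]

#: DFA scaling-exponent threshold below which an IMF is treated as noise
ALPHA_THRESHOLD = 0.33


@dataclass
class EmdDecomposition:
    """IMFs, residual trend, and per-IMF DFA exponents (filled lazily)."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    alphas: list[float] | None = None

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (flat tops collapse to one)."""
    d = np.diff(x)
    s = np.sign(d)
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    maxima, minima = [], []
    for i in range(len(s) - 1):
        if s[i] > 0 and s[i + 1] < 0:
            maxima.append(i + 1)
        elif s[i] < 0 and s[i + 1] > 0:
            minima.append(i + 1)
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, with extrema mirrored at the ends."""
    n = x.size
    t = idx.astype(float)
    v = x[idx]
    # mirror up to two extrema across each boundary to anchor the spline
    k = min(2, len(idx))
    t_left, v_left = -t[:k][::-1], v[:k][::-1]
    t_right, v_right = 2 * (n - 1) - t[-k:][::-1], v[-k:][::-1]
    tt = np.concatenate([t_left, t, t_right])
    vv = np.concatenate([v_left, v, v_right])
    tt, keep = np.unique(tt, return_index=True)
    return CubicSpline(tt, vv[keep])(np.arange(n, dtype=float))


def _envelope_mean(x: np.ndarray) -> np.ndarray | None:
    maxima, minima = _local_extrema(x)
    if len(maxima) < 1 or len(minima) < 1 or len(maxima) + len(minima) < 3:
        return None
    upper = _mirrored_envelope(x, maxima)
    lower = _mirrored_envelope(x, minima)
    return (upper + lower) / 2.0


def emd_decompose(
    series: np.ndarray,
    max_imfs: int | None = None,
    max_sift: int = 12,
    tol_factor: float = 1e-8,
) -> EmdDecomposition:
    """Decompose a series into IMFs and a residual trend by sifting.

    Sifting of each IMF stops when the envelope-mean amplitude falls below
    ``tol_factor`` times the input range or after ``max_sift`` iterations
    (a small fixed cap, as in standard EMD practice; completeness does not
    depend on it because IMFs are exact subtractions);
    IMF extraction stops when the residue has fewer than 2 interior extrema.
    A series with fewer than 2 extrema (e.g. a straight line) yields zero
    IMFs and the input as residue.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 8:
        raise ValueError("series too short for EMD (need length >= 8)")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    tol = tol_factor * max(np.ptp(x), np.finfo(float).tiny)
    residue = x.copy()
    imfs: list[np.ndarray] = []
    while max_imfs is None or len(imfs) < max_imfs:
        h = residue.copy()
        m = _envelope_mean(h)
        if m is None:
            break
        for _ in range(max_sift):
            h = h - m
            m = _envelope_mean(h)
            if m is None or np.max(np.abs(m)) < tol:
                break
        imfs.append(h)
        residue = residue - h
    return EmdDecomposition(imfs=imfs, residue=residue)


def dfa_alpha(
    series: np.ndarray,
    min_window: int = 4,
    n_windows: int = 10,
    order: int = 1,
) -> float:
    """Detrended fluctuation analysis scaling exponent.

    The cumulative profile of the mean-subtracted series is split into
    non-overlapping windows of log-spaced sizes between ``min_window`` and
    len/4; each window is detrended with a polynomial of the given order and
    alpha is the slope of log RMS fluctuation against log window size.
    White noise gives alpha ~ 0.5, its integral ~ 1.5.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 8 * order + 8:
        raise ValueError("series too short for DFA")
    if np.ptp(x) == 0:
        raise ValueError("constant series has zero fluctuation")
    profile = np.cumsum(x - x.mean())
    n = profile.size
    sizes = np.unique(
        np.geomspace(min_window, max(n // 4, min_window + 1), n_windows).astype(int)
    )
    sizes = sizes[sizes >= min_window]
    t = np.arange(n, dtype=float)
    log_s, log_f = [], []
    for s in sizes:
        n_seg = n // s
        if n_seg < 2:
            continue
        segs = profile[: n_seg * s].reshape(n_seg, s)
        ts = t[:s]
        # least-squares polynomial detrend per segment, vectorized over segments
        design = np.vander(ts, order + 1)
        coef, *_ = np.linalg.lstsq(design, segs.T, rcond=None)
        resid = segs.T - design @ coef
        f = np.sqrt(np.mean(resid**2))
        if f > 0:
            log_s.append(np.log(s))
            log_f.append(np.log(f))
    if len(log_s) < 3:
        raise ValueError("too few usable window sizes for DFA")
    slope = np.polyfit(log_s, log_f, 1)[0]
    return float(slope)


def _imf_alpha(imf: np.ndarray) -> float:
    """DFA exponent of an IMF; degenerate (flat) components score +inf (trend-like)."""
    try:
        return dfa_alpha(imf)
    except ValueError:
        return float("inf")


def denoise_velocity(
    velocity: np.ndarray,
    dt: float = 5.0,
    alpha_threshold: float = ALPHA_THRESHOLD,
    keep_rule: str = "drop-below",
) -> np.ndarray:
    """Denoise a velocity series through displacement-domain EMD.

    velocity -> cumulative-trapezoid displacement -> EMD -> remove IMFs whose
    DFA alpha falls on the noise side of ``alpha_threshold`` -> reconstruct
    -> first difference / dt.  Length is preserved by prepending the first
    difference value.  ``keep_rule`` selects which side of the threshold is
    treated as noise: "drop-below" (default) removes IMFs with
    alpha < threshold, "drop-above" removes IMFs with alpha > threshold.
    """
    if keep_rule not in ("drop-below", "drop-above"):
        raise ValueError("keep_rule must be 'drop-below' or 'drop-above'")
    v = np.asarray(velocity, dtype=float)
    d = velocity_to_displacement(v, dt=dt)
    decomp = emd_decompose(d)
    decomp.alphas = [_imf_alpha(imf) for imf in decomp.imfs]
    rebuilt = decomp.residue.copy()
    for imf, alpha in zip(decomp.imfs, decomp.alphas):
        drop = alpha < alpha_threshold if keep_rule == "drop-below" else alpha > alpha_threshold
        if not drop:
            rebuilt += imf
    dv = np.diff(rebuilt) / dt
    return np.concatenate([[dv[0]], dv])
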