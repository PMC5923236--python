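"""Synthetic protrusion data with known ground truth.

No public dataset accompanies the window time-series maps this pipeline
consumes, so every downstream stage is exercised on simulated data: five
phenotype templates of onset-registered velocity (fluctuating plateau,
periodic with 1-3 velocity peaks, accelerating ramp), intensity channels
coupled to velocity with configurable lag/sign/gain/noise, raw window maps
with injected events and missing-value runs for the registration stage, and
per-cell multinomial cluster-count tables for the proportion bootstrap test.

All generators are deterministic under their seed (one RNG stream per call)
and reproduce the templates exactly at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from edgeclust.registration import (
    FRAME_INTERVAL_S,
    PRE_FRAMES,
    RegisteredSeriesSet,
    WindowTimeSeriesMap,
)

__all__ = [
    "PhenotypeTemplate",
    "CouplingModel",
    "SyntheticGroundTruth",
    "TEMPLATE_NAMES",
    "TEMPLATE_AMPLITUDE",
    "phenotype_templates",
    "generate_velocity_set",
    "generate_phase_randomized_periodic",
    "generate_intensity_set",
    "generate_raw_window_map",
    "generate_cell_label_tables",
]

N_FRAMES = PRE_FRAMES + 51  # 56-frame registered window
TEMPLATE_NAMES = ("fluctuating", "periodic1", "periodic2", "periodic3", "accelerating")

#: peak template velocity (nm/s); noise fractions in tests are relative to it
TEMPLATE_AMPLITUDE = 40.0

#: AR(1) memory of the fluctuating phenotype's wobble.  Kept short (about one
#: frame, i.e. ~5 s) so the phenotype fluctuates on the fastest observable
#: timescale and its temporal signature stays distinct from the slow ramp and
#: periodic phenotypes.
AR1_PHI = 0.3


@dataclass(frozen=True)
class PhenotypeTemplate:
    name: str
    mean_curve: np.ndarray  # length-56 velocity curve, nm/s
    noise_sd: float = 0.0
    pre_onset_frames: int = PRE_FRAMES

    def __post_init__(self) -> None:
        if len(self.mean_curve) != N_FRAMES:
            raise ValueError(f"mean_curve must have {N_FRAMES} frames")


@dataclass(frozen=True)
class CouplingModel:
    """Linear velocity->intensity coupling: I(t) = gain*sign*V(t-lag) + drift*t + noise."""

    lag_frames: int = 0
    gain: float = 1.0
    sign: int = 1
    baseline_drift: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.sign) != 1:
            raise ValueError("sign must be +1 or -1")
        if abs(self.lag_frames) > 20:
            raise ValueError("lag_frames must lie within +/-20")


@dataclass
class SyntheticGroundTruth:
    labels: np.ndarray
    seed: int
    coupling: dict[str, CouplingModel] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": [int(x) for x in self.labels],
            "seed": self.seed,
            "coupling": {
                name: {
                    "lag_frames": c.lag_frames,
                    "gain": c.gain,
                    "sign": c.sign,
                    "baseline_drift": c.baseline_drift,
                    "noise_sd": c.noise_sd,
                }
                for name, c in self.coupling.items()
            },
        }


def _pre_onset() -> np.ndarray:
    # slight retraction tail before the onset: -5 .. -1 nm/s
    return -np.arange(PRE_FRAMES, 0, -1, dtype=float)


def _periodic_curve(n_peaks: int, phase: float = 0.0) -> np.ndarray:
    t = np.arange(51, dtype=float)
    post = TEMPLATE_AMPLITUDE * 0.5 * (1.0 - np.cos(2 * np.pi * (n_peaks * t / 51 + phase)))
    return np.concatenate([_pre_onset(), post])


def phenotype_templates() -> list[PhenotypeTemplate]:
    """The five phenotype mean curves, onset at frame 5 (t = 0)."""
    post_flat = np.full(51, 20.0)
    ramp = np.linspace(5.0, 60.0, 51)
    curves = {
        "fluctuating": np.concatenate([_pre_onset(), post_flat]),
        "periodic1": _periodic_curve(1),
        "periodic2": _periodic_curve(2),
        "periodic3": _periodic_curve(3),
        "accelerating": np.concatenate([_pre_onset(), ramp]),
    }
    return [PhenotypeTemplate(name, curves[name]) for name in TEMPLATE_NAMES]


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float, phi: float = AR1_PHI) -> np.ndarray:
    innov = rng.normal(0.0, sd, size=shape)
    out = np.empty(shape)
    out[:, 0] = innov[:, 0]
    for t in range(1, shape[1]):
        out[:, t] = phi * out[:, t - 1] + innov[:, t]
    return out


def generate_velocity_set(
    n_per_cluster: int,
    noise_sd: float,
    seed: int,
) -> tuple[RegisteredSeriesSet, SyntheticGroundTruth]:
    """5 * n_per_cluster registered velocity series with known labels.

    The fluctuating phenotype wobbles with AR(1) noise (innovation sd =
    ``noise_sd``); the other templates get white Gaussian noise.  Zero noise
    reproduces the templates exactly.
    """
    if n_per_cluster < 1:
        raise ValueError("n_per_cluster must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    templates = phenotype_templates()
    rows, labels = [], []
    for lab, tmpl in enumerate(templates, start=1):
        base = np.tile(tmpl.mean_curve, (n_per_cluster, 1))
        if noise_sd > 0:
            if tmpl.name == "fluctuating":
                base = base + _ar1_noise(rng, base.shape, noise_sd)
            else:
                base = base + rng.normal(0.0, noise_sd, size=base.shape)
        else:
            rng.normal(size=base.shape)  # keep the stream position stable
        rows.append(base)
        labels.extend([lab] * n_per_cluster)
    matrix = np.vstack(rows)
    prov = [("sim", i, PRE_FRAMES) for i in range(len(matrix))]
    return (
        RegisteredSeriesSet(matrix=matrix, onset_column=PRE_FRAMES, provenance=prov, kind="velocity"),
        SyntheticGroundTruth(labels=np.asarray(labels), seed=seed),
    )


def generate_phase_randomized_periodic(
    n_per_cluster: int,
    noise_sd: float,
    seed: int,
    periods: tuple[int, ...] = (1, 2, 3),
) -> tuple[RegisteredSeriesSet, SyntheticGroundTruth]:
    """Periodic templates with random phase per series, labeled by period.

    Random phase destroys pointwise (Euclidean) alignment within a period
    class while leaving the autocorrelation structure intact, isolating the
    contribution of the ACF dissimilarity.
    """
    if n_per_cluster < 1:
        raise ValueError("n_per_cluster must be >= 1")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for lab, k in enumerate(periods, start=1):
        for _ in range(n_per_cluster):
            curve = _periodic_curve(k, phase=rng.uniform(0.0, 1.0))
            if noise_sd > 0:
                curve = curve + rng.normal(0.0, noise_sd, size=curve.shape)
            rows.append(curve)
            labels.append(lab)
    matrix = np.vstack(rows)
    prov = [("sim", i, PRE_FRAMES) for i in range(len(matrix))]
    return (
        RegisteredSeriesSet(matrix=matrix, onset_column=PRE_FRAMES, provenance=prov, kind="velocity"),
        SyntheticGroundTruth(labels=np.asarray(labels), seed=seed),
    )


def generate_intensity_set(
    velocities: RegisteredSeriesSet | np.ndarray,
    coupling: CouplingModel,
    seed: int = 0,
) -> RegisteredSeriesSet:
    """Intensity series coupled to velocity with a lag, sign, drift and noise.

    I(t) = gain * sign * V(t - lag) + drift * t + noise; the shifted series
    is edge-padded (first/last value extended).
    """
    V = velocities.matrix if isinstance(velocities, RegisteredSeriesSet) else np.asarray(velocities, float)
    if V.size == 0:
        raise ValueError("empty velocity set")
    n, T = V.shape
    if abs(coupling.lag_frames) >= T:
        raise ValueError("lag exceeds the series length")
    lag = coupling.lag_frames
    shifted = np.empty_like(V)
    if lag > 0:
        shifted[:, lag:] = V[:, :-lag]
        shifted[:, :lag] = V[:, [0]]
    elif lag < 0:
        shifted[:, :lag] = V[:, -lag:]
        shifted[:, lag:] = V[:, [-1]]
    else:
        shifted[:] = V
    rng = np.random.default_rng(seed)
    t = np.arange(T, dtype=float)
    I = coupling.gain * coupling.sign * shifted + coupling.baseline_drift * t[None, :]
    if coupling.noise_sd > 0:
        I = I + rng.normal(0.0, coupling.noise_sd, size=I.shape)
    prov = (
        list(velocities.provenance)
        if isinstance(velocities, RegisteredSeriesSet)
        else [("sim", i, PRE_FRAMES) for i in range(n)]
    )
    return RegisteredSeriesSet(matrix=I, onset_column=PRE_FRAMES, provenance=prov, kind="intensity")


def generate_raw_window_map(
    n_windows: int,
    n_frames: int,
    event_spec: list[dict] | None = None,
    missing_spec: list[tuple[int, int, int]] | None = None,
    seed: int = 0,
    baseline_retraction_nm_s: float = -1.0,
    dt: float = FRAME_INTERVAL_S,
) -> WindowTimeSeriesMap:
    """Unregistered velocity map with injected protrusion events and gaps.

    Each event dict has ``window``, ``onset``, ``end`` (frames) and
    ``distance_nm``; between events the edge retracts slowly at the baseline
    velocity.  The protrusion follows a raised-cosine displacement ramp, so
    its velocity is smooth and integrates exactly to ``distance_nm``.
    ``missing_spec`` entries (window, start_frame, run_length) blank runs of
    frames (NaN + mask).
    """
    event_spec = event_spec or []
    missing_spec = missing_spec or []
    velocity = np.full((n_windows, n_frames), baseline_retraction_nm_s, dtype=float)
    by_window: dict[int, list[dict]] = {}
    for ev in event_spec:
        if not (0 <= ev["onset"] < ev["end"] < n_frames):
            raise ValueError("event does not fit inside n_frames")
        by_window.setdefault(ev["window"], []).append(ev)
    for wid, evs in by_window.items():
        evs.sort(key=lambda e: e["onset"])
        for prev, nxt in zip(evs[:-1], evs[1:]):
            if nxt["onset"] < prev["end"]:
                raise ValueError(f"overlapping events in window {wid}")
        for ev in evs:
            span = ev["end"] - ev["onset"]
            t = np.arange(span + 1, dtype=float)
            # raised-cosine displacement from 0 to distance_nm over the event
            disp = ev["distance_nm"] * 0.5 * (1.0 - np.cos(np.pi * t / span))
            vel = np.diff(disp) / dt
            velocity[wid, ev["onset"] : ev["end"]] = vel
    mask = np.zeros_like(velocity, dtype=bool)
    for wid, start, run in missing_spec:
        mask[wid, start : start + run] = True
    velocity[mask] = np.nan
    return WindowTimeSeriesMap(values=velocity, missing_mask=mask, frame_interval_s=dt, kind="velocity")


def generate_cell_label_tables(
    n_cells: int,
    proportions: np.ndarray,
    windows_per_cell: int,
    seed: int,
) -> np.ndarray:
    """Per-cell multinomial cluster-count table (cells x clusters)."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    if n_cells < 1 or windows_per_cell < 1:
        raise ValueError("n_cells and windows_per_cell must be positive")
    rng = np.random.default_rng(seed)
    return rng.multinomial(windows_per_cell, p, size=n_cells)
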