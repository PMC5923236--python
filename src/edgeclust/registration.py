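"""Event detection and protrusion-onset registration of window time series.

The raw input is a windows x frames map of cell-edge velocity (nm/s) sampled
in ~500 nm probing windows every 5 s.  Velocity is integrated to an edge
displacement trace per window, smoothed with a cubic smoothing spline, and
significant protrusion events are detected as minimum-to-maximum excursions
of the smoothed displacement.  Small events (net distance < 720 nm) are
discarded and short protrusion/retraction switches (< 50 s) are merged into
their neighbours before the distance filter.  Each surviving event is
re-indexed so its onset sits at t = 0, and a common temporal length is chosen
by maximizing (number of retained series) x (post-onset length), yielding
fixed-length registered sets (5 pre-onset + 51 post-onset = 56 frames by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "WindowTimeSeriesMap",
    "ProtrusionEvent",
    "RegisteredSeries",
    "RegisteredSeriesSet",
    "impute_missing",
    "velocity_to_displacement",
    "smooth_displacement",
    "detect_events",
    "register",
    "select_time_length",
]

#: default frame interval (s) and window size (nm) of the probing windows
FRAME_INTERVAL_S = 5.0
WINDOW_SIZE_NM = 500.0

#: event filters: minimum net protrusion distance (nm) and minimum phase
#: duration (s) below which a protrusion/retraction switch is merged
MIN_DISTANCE_NM = 720.0
MIN_PHASE_S = 50.0

#: registration geometry: pre-onset frames kept, default post-onset length
PRE_FRAMES = 5
POST_FRAMES = 51


@dataclass
class WindowTimeSeriesMap:
    """windows x frames matrix of velocity (nm/s) or intensity (a.u.)."""

    values: np.ndarray
    missing_mask: np.ndarray | None = None
    frame_interval_s: float = FRAME_INTERVAL_S
    window_size_nm: float = WINDOW_SIZE_NM
    kind: str = "velocity"
    window_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D windows x frames matrix")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape must equal values shape")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.window_ids is None:
            self.window_ids = [f"w{i}" for i in range(self.values.shape[0])]

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ProtrusionEvent:
    """One significant protrusion: onset (displacement minimum) to end (maximum)."""

    window_id: int
    onset_frame: int
    end_frame: int
    net_distance_nm: float
    truncated: bool = False  # end coincides with the last recorded frame

    def __post_init__(self) -> None:
        if self.onset_frame >= self.end_frame:
            raise ValueError("onset_frame must precede end_frame")
        if self.net_distance_nm < 0:
            raise ValueError("net_distance_nm must be non-negative")


@dataclass
class RegisteredSeries:
    """One onset-aligned series of variable length (pre + post segment)."""

    values: np.ndarray  # concatenated [pre-onset, onset..end] samples
    pre_len: int  # frames before the onset (onset itself is post)
    movie_id: str
    window_id: int
    onset_frame: int
    pre_truncated: bool = False

    @property
    def post_len(self) -> int:
        return len(self.values) - self.pre_len


@dataclass
class RegisteredSeriesSet:
    """samples x (pre_frames + L) matrix with the onset at column ``pre_frames``."""

    matrix: np.ndarray
    onset_column: int = PRE_FRAMES
    provenance: list[tuple[str, int, int]] = field(default_factory=list)
    kind: str = "velocity"
    frame_interval_s: float = FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x frames)")
        if not self.provenance:
            self.provenance = [("sim", i, self.onset_column) for i in range(len(self.matrix))]
        if len(self.provenance) != self.matrix.shape[0]:
            raise ValueError("provenance length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


def impute_missing(
    values: np.ndarray,
    mask: np.ndarray | None = None,
    max_run: int = 8,
    n_flank: int = 4,
) -> np.ndarray | None:
    """Impute short missing runs; return None (reject) for runs longer than 8.

    Each missing value is replaced by the mean of up to ``n_flank`` valid
    values before and up to ``n_flank`` valid values after it.  A series whose
    longest run of consecutive missing values exceeds ``max_run``, or that has
    no valid values at all, is rejected.
    """
    values = np.asarray(values, dtype=float)
    mask = ~np.isfinite(values) if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        return values.copy()
    if mask.all():
        return None
    # longest run of consecutive missing values
    run, longest = 0, 0
    for m in mask:
        run = run + 1 if m else 0
        longest = max(longest, run)
    if longest > max_run:
        return None
    valid_idx = np.flatnonzero(~mask)
    out = values.copy()
    for i in np.flatnonzero(mask):
        before = valid_idx[valid_idx < i][-n_flank:]
        after = valid_idx[valid_idx > i][:n_flank]
        neighbours = np.concatenate([before, after])
        out[i] = values[neighbours].mean()
    return out


def velocity_to_displacement(velocity: np.ndarray, dt: float = FRAME_INTERVAL_S) -> np.ndarray:
    """Cumulative trapezoidal integral of velocity; displacement(0) = 0."""
    velocity = np.asarray(velocity, dtype=float)
    if not np.all(np.isfinite(velocity)):
        raise ValueError("velocity contains non-finite values; impute first")
    return cumulative_trapezoid(velocity, dx=dt, initial=0.0)


def smooth_displacement(
    displacement: np.ndarray,
    smoothing_param: float = 0.01,
    dt: float = FRAME_INTERVAL_S,
) -> np.ndarray:
    """Cubic smoothing spline evaluated at the original frames.

    ``smoothing_param`` follows the convention in which p = 1 interpolates the
    data and p -> 0 approaches the least-squares straight line; internally it
    maps to the penalized-spline weight lam = (1 - p) / p.
    """
    displacement = np.asarray(displacement, dtype=float)
    if displacement.size < 4:
        raise ValueError("need at least 4 points for a cubic smoothing spline")
    p = float(smoothing_param)
    if not 0.0 < p <= 1.0:
        raise ValueError("smoothing_param must be in (0, 1]")
    x = np.arange(displacement.size, dtype=float) * dt
    lam = (1.0 - p) / p
    spline = make_smoothing_spline(x, displacement, lam=lam)
    return np.asarray(spline(x), dtype=float)


def _turning_points(x: np.ndarray) -> list[int]:
    """Indices of strict sign changes of the first difference (interior extrema)."""
    d = np.diff(x)
    signs = np.sign(d)
    # carry the previous sign through flat segments
    for i in range(1, len(signs)):
        if signs[i] == 0:
            signs[i] = signs[i - 1]
    turns = [i + 1 for i in range(len(signs) - 1) if signs[i] != 0 and signs[i + 1] != 0 and signs[i] != signs[i + 1]]
    return turns


def detect_events(
    displacement: np.ndarray,
    dt: float = FRAME_INTERVAL_S,
    min_distance_nm: float = MIN_DISTANCE_NM,
    min_phase_s: float = MIN_PHASE_S,
    window_id: int = 0,
) -> list[ProtrusionEvent]:
    """Detect significant protrusion events on a smoothed displacement trace.

    Phases shorter than ``min_phase_s`` are merged into their neighbours
    first; then minimum-to-maximum excursions with net distance below
    ``min_distance_nm`` are discarded.  A monotone trace yields no interior
    extrema and at most one (possibly truncated) event.
    """
    x = np.asarray(displacement, dtype=float)
    n = x.size
    if n < 3:
        return []
    turns = _turning_points(x)
    bounds = [0] + turns + [n - 1]

    # merge phases shorter than min_phase_s (iteratively drop boundary pairs)
    min_frames = min_phase_s / dt
    while len(bounds) > 2:
        durations = np.diff(bounds)
        short = [i for i in range(len(durations)) if durations[i] < min_frames]
        if not short:
            break
        i = int(min(short, key=lambda j: durations[j]))
        if i == 0:
            del bounds[1]  # merge leading short phase into the next one
        elif i == len(durations) - 1:
            del bounds[-2]  # merge trailing short phase into the previous one
        else:
            del bounds[i + 1], bounds[i]  # merge interior phase with both sides
    # classify remaining interior boundaries as minima/maxima by value
    events: list[ProtrusionEvent] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if x[b] <= x[a]:
            continue  # retraction phase
        net = float(x[b] - x[a])
        if net < min_distance_nm:
            continue
        events.append(
            ProtrusionEvent(
                window_id=window_id,
                onset_frame=int(a),
                end_frame=int(b),
                net_distance_nm=net,
                truncated=b == n - 1,
            )
        )
    return events


def register(
    tsmap: WindowTimeSeriesMap,
    events: dict[int, list[ProtrusionEvent]] | list[ProtrusionEvent],
    pre_frames: int = PRE_FRAMES,
    movie_id: str = "movie",
    max_run: int = 8,
) -> list[RegisteredSeries]:
    """Extract onset-aligned variable-length series for each event.

    The pre-onset segment extends up to ``pre_frames`` frames back, bounded by
    the start of the recording; the post-onset segment runs from the onset to
    the event end (the subsequent retraction onset).  Series whose missing
    values cannot be imputed are dropped.
    """
    if isinstance(events, list):
        grouped: dict[int, list[ProtrusionEvent]] = {}
        for ev in events:
            grouped.setdefault(ev.window_id, []).append(ev)
        events = grouped
    out: list[RegisteredSeries] = []
    for wid, evs in sorted(events.items()):
        if not 0 <= wid < tsmap.n_windows:
            raise ValueError(f"event references window {wid} outside the map")
        row = tsmap.values[wid]
        mask = tsmap.missing_mask[wid]
        for ev in sorted(evs, key=lambda e: e.onset_frame):
            if ev.end_frame >= tsmap.n_frames:
                raise ValueError("event extends past the end of the map")
            start = max(0, ev.onset_frame - pre_frames)
            seg = row[start : ev.end_frame + 1]
            seg_mask = mask[start : ev.end_frame + 1]
            imputed = impute_missing(seg, seg_mask, max_run=max_run)
            if imputed is None:
                continue
            out.append(
                RegisteredSeries(
                    values=imputed,
                    pre_len=ev.onset_frame - start,
                    movie_id=movie_id,
                    window_id=wid,
                    onset_frame=ev.onset_frame,
                    pre_truncated=ev.onset_frame - start < pre_frames,
                )
            )
    return out


def select_time_length(
    series: list[RegisteredSeries],
    pre_frames: int = PRE_FRAMES,
    fixed_length: int | None = None,
    kind: str = "velocity",
    frame_interval_s: float = FRAME_INTERVAL_S,
) -> RegisteredSeriesSet:
    """Choose the common post-onset length and assemble the registered matrix.

    The post-onset length L* maximizes (number of series with post length
    >= L) x L over the observed lengths; ``fixed_length`` bypasses the
    optimization (51 reproduces the canonical 56-frame window).  Series
    shorter than L* post-onset or ``pre_frames`` pre-onset are dropped;
    retained series are truncated to ``pre_frames`` + L* frames.
    """
    if not series:
        raise ValueError("no registered series to select from")
    post_lens = np.array([s.post_len for s in series])
    if fixed_length is not None:
        l_star = int(fixed_length)
    else:
        candidates = np.unique(post_lens)
        l_star = int(max(candidates, key=lambda L: (post_lens >= L).sum() * L))
    rows, prov = [], []
    for s in series:
        if s.post_len < l_star or s.pre_len < pre_frames:
            continue
        onset = s.pre_len
        rows.append(s.values[onset - pre_frames : onset + l_star])
        prov.append((s.movie_id, s.window_id, s.onset_frame))
    if not rows:
        raise ValueError(f"no series long enough for post-onset length {l_star}")
    return RegisteredSeriesSet(
        matrix=np.vstack(rows),
        onset_column=pre_frames,
        provenance=prov,
        kind=kind,
        frame_interval_s=frame_interval_s,
    )
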