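"""Kymograph construction and run/pause/passive motility segmentation.

A kymograph is a time (rows) × arc-position (columns) image built by
resampling a time-lapse stack along a drawn polyline. Particle tracks on
the kymograph are partitioned into motion states using the rule set of
the original cargo-trafficking analysis:

* **run** — a stretch of same-sign frame-to-frame displacement spanning at
  least ``run_min_frames`` frames and at least ``run_min_px`` pixels of
  total displacement. A run may absorb at most one zero-displacement frame
  (pixel quantisation of sub-pixel motion).
* **pause** — the particle stalls at the same position for at least
  ``pause_min_frames`` frames (a stall of k zero displacements occupies
  k + 1 frames).
* **passive** — remaining frames whose per-frame move is at most 1 px:
  the move-one-pixel / stop-one-frame jitter that is neither stationary
  nor active transport. Cargo preset only.

A track is *mobile* iff it contains at least one run. Direction (antero-
vs retrograde) follows the sign of the net displacement; extraction paths
are drawn soma → distal, so increasing arc position is anterograde.

Two presets are provided: ``cargo`` (5 px / 5 frames runs, 3-frame
pauses, passive enabled) and ``eb3`` for microtubule plus-end comets
(2 px / 2 frame runs, pauses of 2–10 frames, no passive class; a stall
longer than 10 frames is a catastrophe and terminates the comet).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import PixelCalibration

__all__ = [
    "Kymograph",
    "TrajectoryTrace",
    "MotilityParams",
    "MotionSegment",
    "TrajectoryStats",
    "CARGO_PARAMS",
    "EB3_PARAMS",
    "extract_kymograph",
    "segment_trajectory",
    "classify_direction",
    "summarize_motility",
]


@dataclass
class Kymograph:
    matrix: np.ndarray  # (n_frames, n_positions)
    calibration: PixelCalibration
    path_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("kymograph matrix must be 2-D (time × arc position)")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


@dataclass
class TrajectoryTrace:
    """One kymograph track: position (px along the path) per frame."""

    frames: np.ndarray
    positions_px: np.ndarray
    calibration: PixelCalibration
    track_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        if self.frames.size != self.positions_px.size:
            raise ValueError("frames and positions must have equal length")
        if self.frames.size and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing (one position per frame)")

    def __len__(self) -> int:
        return int(self.frames.size)


@dataclass(frozen=True)
class MotilityParams:
    """Threshold bundle for run/pause/passive segmentation."""

    run_min_px: float = 5.0
    run_min_frames: int = 5
    pause_min_frames: int = 3
    pause_max_frames: int | None = None  # eb3 only: longer stalls end the comet
    passive_enabled: bool = True
    passive_max_px: float = 1.0
    absorb_zero_frames: int = 1  # 0 or 1 zero frames absorbable into a run
    position_tol_px: float = 0.0  # equality tolerance for sub-pixel traces
    preset: str = "cargo"

    def __post_init__(self) -> None:
        if self.run_min_px < 1:
            raise ValueError("run_min_px must be >= 1")
        if self.pause_min_frames < 2:
            raise ValueError("pause_min_frames must be >= 2")
        if self.absorb_zero_frames not in (0, 1):
            raise ValueError("absorb_zero_frames must be 0 or 1")


CARGO_PARAMS = MotilityParams()
EB3_PARAMS = MotilityParams(
    run_min_px=2.0,
    run_min_frames=2,
    pause_min_frames=2,
    pause_max_frames=10,
    passive_enabled=False,
    preset="eb3",
)


@dataclass(frozen=True)
class MotionSegment:
    kind: str  # "run" | "pause" | "passive"
    frame_start: int  # first frame index of the segment
    frame_end: int  # last frame index (inclusive); spans frame_end - frame_start intervals
    displacement_px: float  # signed
    length_um: float
    duration_s: float
    velocity_um_s: float | None = None  # runs only


@dataclass
class TrajectoryStats:
    track_id: str
    mobile: bool
    direction: str  # "anterograde" | "retrograde" | "none"
    net_displacement_px: float
    runs: list[MotionSegment]
    pauses: list[MotionSegment]
    passive: list[MotionSegment]
    fraction_time_running: float
    fraction_time_pausing: float
    fraction_time_passive: float
    fraction_time_unclassified: float
    n_direction_changes: int
    n_pauses_per_min: float
    terminated_by_stall: bool = False


# ---------------------------------------------------------------------------
# kymograph extraction
# ---------------------------------------------------------------------------

def _resample_path(path: np.ndarray, step_px: float = 1.0) -> np.ndarray:
    """Sample a polyline ((x, y) vertices, px) at uniform arc steps."""
    path = np.asarray(path, dtype=float)
    seg = np.diff(path, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arc[-1]
    n = int(math.floor(total / step_px)) + 1
    s = np.arange(n) * step_px
    x = np.interp(s, arc, path[:, 0])
    y = np.interp(s, arc, path[:, 1])
    return np.column_stack([x, y])


def extract_kymograph(
    stack: np.ndarray,
    path: np.ndarray,
    calibration: PixelCalibration,
    width_px: int = 3,
    path_id: str = "",
) -> Kymograph:
    """Reslice a time-lapse stack along a polyline into a kymograph.

    For each frame the intensity is sampled at 1-px arc steps along the
    path; at each step the mean over ``width_px`` samples taken along the
    local normal is used, so the line width covers the structure of
    interest. Bilinear interpolation throughout.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError("width_px must be an odd positive integer")
    pts = _resample_path(path)
    h, w = stack.shape[1:]
    if (
        pts[:, 0].min() < 0 or pts[:, 0].max() > w - 1
        or pts[:, 1].min() < 0 or pts[:, 1].max() > h - 1
    ):
        raise ValueError("path exits the image field")

    # local tangent -> unit normal per sample
    tang = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tang /= norms
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    offsets = np.arange(width_px) - width_px // 2
    rows = []
    for frame in stack:
        acc = np.zeros(len(pts))
        for o in offsets:
            sx = pts[:, 0] + o * normal[:, 0]
            sy = pts[:, 1] + o * normal[:, 1]
            acc += ndimage.map_coordinates(frame, [sy, sx], order=1, mode="nearest")
        rows.append(acc / width_px)
    return Kymograph(np.asarray(rows), calibration, path_id=path_id)


# ---------------------------------------------------------------------------
# trajectory segmentation
# ---------------------------------------------------------------------------

def _sign(x: float, tol: float) -> int:
    if x > tol:
        return 1
    if x < -tol:
        return -1
    return 0


def segment_trajectory(
    trace: TrajectoryTrace, params: MotilityParams = CARGO_PARAMS
) -> tuple[list[MotionSegment], bool]:
    """Partition a track into runs, pauses and passive segments.

    Returns the segment list (sorted by frame) and the mobile flag
    (at least one run). Works on the n−1 frame-to-frame displacement
    intervals of an n-point trace; every interval ends up in exactly one
    of run / pause / passive / unclassified.
    """
    if len(trace) < 2:
        raise ValueError("trajectory needs at least 2 points")
    pos = trace.positions_px
    d = np.diff(pos)
    m = d.size
    tol = params.position_tol_px
    signs = np.array([_sign(v, tol) for v in d])

    # eb3: a stall occupying more than pause_max_frames frames is a
    # catastrophe; the comet ends at the stall start.
    terminated = False
    if params.pause_max_frames is not None:
        i = 0
        while i < m:
            if signs[i] == 0:
                j = i
                while j < m and signs[j] == 0:
                    j += 1
                if (j - i) + 1 > params.pause_max_frames:
                    d, signs, m = d[:i], signs[:i], i
                    terminated = True
                    break
                i = j
            else:
                i += 1

    state = np.full(m, "unclassified", dtype=object)
    run_bounds: list[tuple[int, int]] = []  # adjacent opposite runs stay distinct

    # 1) runs: same-sign stretches, absorbing at most `absorb_zero_frames`
    #    zero intervals in total per run.
    i = 0
    while i < m:
        if signs[i] == 0:
            i += 1
            continue
        s = signs[i]
        j = i + 1
        zeros_used = 0
        end = i  # last index committed to the candidate (always nonzero sign)
        while j < m:
            if signs[j] == s:
                end = j
                j += 1
            elif (
                signs[j] == 0
                and zeros_used < params.absorb_zero_frames
                and j + 1 < m
                and signs[j + 1] == s
            ):
                zeros_used += 1
                j += 2
                end = j - 1
            else:
                break
        span = end - i + 1
        disp = float(np.sum(d[i : end + 1]))
        if span >= params.run_min_frames and abs(disp) >= params.run_min_px:
            state[i : end + 1] = "run"
            run_bounds.append((i, end))
            i = end + 1
        else:
            # a shorter window starting later may still qualify
            i += 1

    # 2) pauses: maximal zero stretches not absorbed into runs, stalled
    #    for at least pause_min_frames frames (k intervals = k+1 frames).
    i = 0
    while i < m:
        if signs[i] == 0 and state[i] == "unclassified":
            j = i
            while j < m and signs[j] == 0 and state[j] == "unclassified":
                j += 1
            if (j - i) + 1 >= params.pause_min_frames:
                state[i:j] = "pause"
            i = j
        else:
            i += 1

    # 3) passive: leftover small moves (cargo preset only)
    if params.passive_enabled:
        for k in range(m):
            if state[k] == "unclassified" and abs(d[k]) <= params.passive_max_px:
                state[k] = "passive"

    # build segments: runs split at their recorded bounds (back-to-back
    # runs of opposite sign must stay separate segments), pauses/passive
    # from contiguous same-state stretches
    run_end_at = {a: b for a, b in run_bounds}
    px = trace.calibration.pixel_size_um
    dt = trace.calibration.frame_interval_s or 1.0
    f0 = int(trace.frames[0])
    segments: list[MotionSegment] = []
    i = 0
    while i < m:
        kind = state[i]
        if kind == "run":
            j = run_end_at[i] + 1
        else:
            j = i
            while j < m and state[j] == kind:
                j += 1
        if kind != "unclassified":
            disp = float(np.sum(d[i:j]))
            n_int = j - i
            seg = MotionSegment(
                kind=str(kind),
                frame_start=f0 + i,
                frame_end=f0 + j,
                displacement_px=disp,
                length_um=abs(disp) * px,
                duration_s=n_int * dt,
                velocity_um_s=(abs(disp) * px / (n_int * dt)) if kind == "run" else None,
            )
            segments.append(seg)
        i = j
    mobile = any(s.kind == "run" for s in segments)
    return segments, mobile


def classify_direction(
    segments: list[MotionSegment],
    trace: TrajectoryTrace,
    params: MotilityParams = CARGO_PARAMS,
) -> TrajectoryStats:
    """Compute per-track motility statistics from its segmentation.

    Net displacement is last − first position; a mobile track with net
    displacement above zero is anterograde, below zero retrograde.
    Direction changes count sign flips between consecutive runs. Time
    fractions are over the track's full frame span.
    """
    if len(trace) < 2:
        raise ValueError("zero-length track")
    m = len(trace) - 1  # total displacement intervals
    runs = [s for s in segments if s.kind == "run"]
    pauses = [s for s in segments if s.kind == "pause"]
    passive = [s for s in segments if s.kind == "passive"]
    mobile = bool(runs)
    net = float(trace.positions_px[-1] - trace.positions_px[0])

    if not mobile or net == 0:
        direction = "none"
    else:
        direction = "anterograde" if net > 0 else "retrograde"

    def n_intervals(ss: list[MotionSegment]) -> int:
        return sum(s.frame_end - s.frame_start for s in ss)

    fr_run = n_intervals(runs) / m
    fr_pause = n_intervals(pauses) / m
    fr_pass = n_intervals(passive) / m
    fr_un = 1.0 - fr_run - fr_pause - fr_pass

    run_signs = [1 if s.displacement_px > 0 else -1 for s in runs]
    flips = sum(1 for a, b in zip(run_signs, run_signs[1:]) if a != b)

    dt = trace.calibration.frame_interval_s or 1.0
    minutes = m * dt / 60.0
    return TrajectoryStats(
        track_id=trace.track_id,
        mobile=mobile,
        direction=direction,
        net_displacement_px=net,
        runs=runs,
        pauses=pauses,
        passive=passive,
        fraction_time_running=fr_run,
        fraction_time_pausing=fr_pause,
        fraction_time_passive=fr_pass,
        fraction_time_unclassified=fr_un,
        n_direction_changes=flips,
        n_pauses_per_min=len(pauses) / minutes if minutes > 0 else 0.0,
    )


def analyze_trajectory(
    trace: TrajectoryTrace, params: MotilityParams = CARGO_PARAMS
) -> TrajectoryStats:
    """Convenience: segmentation followed by direction/statistics."""
    segments, _ = segment_trajectory(trace, params)
    return classify_direction(segments, trace, params)


def summarize_motility(
    tracks_by_region: dict[str, list[TrajectoryTrace]],
    params: MotilityParams = CARGO_PARAMS,
    region_path_length_um: dict[str, float] | None = None,
    region_recording_min: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-region motility summary table.

    Reports, per region: % mobile, % anterograde / retrograde among mobile
    tracks, mean run length (µm), duration (s) and velocity (µm/s) split
    by direction, time fractions, pause statistics. Direction-split fields
    are absent (NaN) when a region has no mobile track of that direction.
    With the eb3 preset, comet density (traces per µm of path per minute)
    and growth rate (mean run velocity) are added when path length and
    recording time are supplied.
    """
    rows = []
    for region, tracks in tracks_by_region.items():
        if not tracks:
            raise ValueError(f"region {region!r} has no tracks")
        stats = [analyze_trajectory(t, params) for t in tracks]
        n = len(stats)
        mobile = [s for s in stats if s.mobile]
        row: dict = {
            "region": region,
            "n_tracks": n,
            "pct_mobile": 100.0 * len(mobile) / n,
            "pct_stationary": 100.0 * (n - len(mobile)) / n,
            "pct_time_running": 100.0 * float(np.mean([s.fraction_time_running for s in stats])),
            "pct_time_pausing": 100.0 * float(np.mean([s.fraction_time_pausing for s in stats])),
            "pct_time_passive": 100.0 * float(np.mean([s.fraction_time_passive for s in stats])),
            "pauses_per_min": float(np.mean([s.n_pauses_per_min for s in stats])),
            "n_direction_changes": float(np.mean([s.n_direction_changes for s in stats])),
        }
        all_pauses = [p for s in stats for p in s.pauses]
        row["mean_pause_duration_s"] = (
            float(np.mean([p.duration_s for p in all_pauses])) if all_pauses else np.nan
        )
        row["total_pause_time_s"] = float(np.sum([p.duration_s for p in all_pauses])) if all_pauses else 0.0

        if mobile:
            n_antero = sum(1 for s in mobile if s.direction == "anterograde")
            n_retro = sum(1 for s in mobile if s.direction == "retrograde")
            row["pct_anterograde"] = 100.0 * n_antero / len(mobile)
            row["pct_retrograde"] = 100.0 * n_retro / len(mobile)
            for direction, key in (("anterograde", "antero"), ("retrograde", "retro")):
                runs = [r for s in mobile if s.direction == direction for r in s.runs]
                row[f"mean_run_length_um_{key}"] = (
                    float(np.mean([r.length_um for r in runs])) if runs else np.nan
                )
                row[f"mean_run_duration_s_{key}"] = (
                    float(np.mean([r.duration_s for r in runs])) if runs else np.nan
                )
                row[f"mean_run_velocity_um_s_{key}"] = (
                    float(np.mean([r.velocity_um_s for r in runs])) if runs else np.nan
                )
            all_runs = [r for s in mobile for r in s.runs]
            row["mean_run_velocity_um_s"] = float(np.mean([r.velocity_um_s for r in all_runs]))
        else:
            row["pct_anterograde"] = np.nan
            row["pct_retrograde"] = np.nan

        if params.preset == "eb3":
            row["growth_rate_um_s"] = row.get("mean_run_velocity_um_s", np.nan)
            if region_path_length_um and region_recording_min:
                L = region_path_length_um.get(region)
                T = region_recording_min.get(region)
                if L and T:
                    row["comet_density_per_um_min"] = n / (L * T)
        rows.append(row)
    return pd.DataFrame(rows)
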