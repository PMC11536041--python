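"""File I/O, run configuration and the deterministic pipeline driver.

Formats: TIFF for image matrices, CSV for profiles/traces/tables, JSON
for annotations, configs and manifests. Coordinates in files are 0-based
pixel indices, (x, y) = (column, row); geometry is converted to µm at
load time using the file's calibration. Every numeric default equals the
published analysis constant (40% edge threshold, 4 µm smoothing, 5 px
smoothing at 20 nm/px, 5 px / 5 frame runs, 3-frame pauses, EB3 2 px and
2–10 frames, 8 px colocalization box, 2 µm axon-distance threshold).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import LineProfile, PixelCalibration
from .morphology import NeuronAnnotation

__all__ = [
    "RunConfig",
    "read_image_stack",
    "write_image_stack",
    "read_annotations",
    "read_profile_csv",
    "write_profile_csv",
    "read_trace_csv",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """All tunable stage parameters with their published defaults."""

    stage: str = ""
    input_path: str = ""
    output_dir: str = "results"
    seed: int = 0
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None
    # AIS geometry
    ais_threshold_fraction: float = 0.4
    ais_smooth_window_um: float = 4.0
    # MPS periodicity
    mps_smooth_window_px: int = 5
    mps_min_prominence: float = 0.2
    mps_pixel_nm: float = 20.0
    # kymograph motility
    preset: str = "cargo"
    run_min_px: float = 5.0
    run_min_frames: int = 5
    pause_min_frames: int = 3
    eb3_run_min_px: float = 2.0
    eb3_pause_frames: tuple[int, int] = (2, 10)
    # puncta / colocalization
    coloc_box_px: float = 8.0
    density_per_um: float = 5.0
    puncta_threshold: str | float = "otsu"
    min_area_px: int = 4
    # morphology
    axon_distance_threshold_um: float = 2.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eb3_pause_frames"] = list(d["eb3_pause_frames"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "eb3_pause_frames" in d:
            d = {**d, "eb3_pause_frames": tuple(d["eb3_pause_frames"])}
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls.from_dict(data)

    def dump(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image_stack(
    path: str | Path,
    calibration: PixelCalibration | None = None,
) -> tuple[np.ndarray, PixelCalibration]:
    """Read a TIFF stack with its calibration.

    An explicit ``calibration`` override always wins; otherwise the
    ImageJ-style metadata written by :func:`write_image_stack` is used.
    A stack without either is rejected — uncalibrated geometry is
    meaningless downstream.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if calibration is None:
            meta = tif.imagej_metadata or {}
            px = meta.get("pixel_size_um")
            dt = meta.get("frame_interval_s")
            if px is None:
                raise ValueError(
                    f"{path.name}: no pixel calibration in metadata and no override given"
                )
            calibration = PixelCalibration(float(px), float(dt) if dt else None)
    return np.asarray(data, dtype=float), calibration


def write_image_stack(
    path: str | Path, data: np.ndarray, calibration: PixelCalibration
) -> None:
    meta = {"pixel_size_um": calibration.pixel_size_um}
    if calibration.frame_interval_s is not None:
        meta["frame_interval_s"] = calibration.frame_interval_s
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32), imagej=True, metadata=meta)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_REQUIRED_ANNOTATION_FIELDS = ("cell_id", "pixel_size_um", "soma_boundary_px", "axon_origin_px")


def read_annotations(path: str | Path) -> list[NeuronAnnotation]:
    """Read per-cell JSON annotations (pixel coordinates) into µm geometry.

    The file holds one object or a list of objects with fields
    ``cell_id``, ``pixel_size_um``, ``soma_boundary_px``,
    ``axon_origin_px`` and optionally ``stem_path_px``,
    ``soma_edge_point_px``, ``axon_origin_edge_px``, ``d1_px``, ``d2_px``.
    Schema violations are rejected naming the offending field.
    """
    raw = json.loads(Path(path).read_text())
    records = raw if isinstance(raw, list) else [raw]
    out = []
    for rec in records:
        for f in _REQUIRED_ANNOTATION_FIELDS:
            if f not in rec:
                raise ValueError(f"annotation record missing required field {f!r}")
        px = float(rec["pixel_size_um"])
        if px <= 0:
            raise ValueError("field 'pixel_size_um' must be > 0")

        def scale(v):
            return np.asarray(v, dtype=float) * px

        def scale_pt(v):
            return tuple(np.asarray(v, dtype=float) * px)

        out.append(
            NeuronAnnotation(
                cell_id=str(rec["cell_id"]),
                soma_boundary=scale(rec["soma_boundary_px"]),
                axon_origin=scale_pt(rec["axon_origin_px"]),
                stem_path=scale(rec["stem_path_px"]) if rec.get("stem_path_px") else None,
                soma_edge_point=(
                    scale_pt(rec["soma_edge_point_px"]) if rec.get("soma_edge_point_px") else None
                ),
                axon_origin_edge=(
                    scale(rec["axon_origin_edge_px"]) if rec.get("axon_origin_edge_px") else None
                ),
                d1_um=float(rec["d1_px"]) * px if rec.get("d1_px") is not None else None,
                d2_um=float(rec["d2_px"]) * px if rec.get("d2_px") is not None else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# profiles and traces
# ---------------------------------------------------------------------------

def write_profile_csv(path: str | Path, profile: LineProfile) -> None:
    df = pd.DataFrame(
        {"index": np.arange(len(profile)), "intensity": profile.intensities}
    )
    with open(path, "w") as fh:
        fh.write(f"# pixel_size_um={profile.pixel_size_um}\n")
        df.to_csv(fh, index=False)


def read_profile_csv(path: str | Path) -> LineProfile:
    """CSV of (index, intensity) with a ``# pixel_size_um=…`` header."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# pixel_size_um="):
            raise ValueError("profile CSV must start with a '# pixel_size_um=' header")
        px = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    return LineProfile(df["intensity"].to_numpy(), px)


def read_trace_csv(path: str | Path, calibration: PixelCalibration):
    """CSV of (frame, position_px) -> TrajectoryTrace."""
    from .kymo import TrajectoryTrace

    df = pd.read_csv(path)
    for col in ("frame", "position_px"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
    return TrajectoryTrace(
        frames=df["frame"].to_numpy(),
        positions_px=df["position_px"].to_numpy(),
        calibration=calibration,
        track_id=Path(path).stem,
    )


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> Path:
    """Execute one analysis stage deterministically and write a manifest.

    Dispatches on ``config.stage`` (classify | ais | mps | kymo | puncta |
    simulate), writes the stage's CSV outputs into ``config.output_dir``
    and a ``manifest.json`` recording the package version, the full
    config, its hash and the applied thresholds.
    """
    from . import __version__, pipeline

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_fn = {
        "classify": pipeline.stage_classify,
        "ais": pipeline.stage_ais,
        "mps": pipeline.stage_mps,
        "kymo": pipeline.stage_kymo,
        "puncta": pipeline.stage_puncta,
        "simulate": pipeline.stage_simulate,
    }.get(config.stage)
    if stage_fn is None:
        raise ValueError(f"unknown stage {config.stage!r}")
    logs = stage_fn(config, out_dir)
    manifest = {
        "package": "acdkit",
        "version": __version__,
        "stage": config.stage,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "log": logs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out_dir
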