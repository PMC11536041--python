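"""Classification of axon-carrying-dendrite (AcD) versus nonAcD neurons.

An AcD neuron's axon emanates from a basal dendrite rather than directly
from the soma. Classification rests on two manual-annotation-derived
quantities:

* **axon distance** — arc length of the stem-dendrite path from the end of
  the soma to the point where the AnkG-positive axon begins;
* **stem dendrite diameter** — the mean of two width chords (d1 at the
  start, d2 at the end of the stem dendrite).

A cell is AcD iff its axon distance is strictly greater than 2 µm AND
strictly greater than the stem dendrite diameter. Everything else —
including "shared root" cells whose axon grows fused with a dendrite —
is nonAcD. Cells with more than one axon are excluded upstream and never
reach this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "NeuronAnnotation",
    "MorphClassification",
    "AXON_DISTANCE_THRESHOLD_UM",
    "OBLIQUE_ANGLE_DEG",
    "axon_distance",
    "stem_diameter",
    "width_along_chords",
    "classify_neuron",
    "classify_table",
    "summarize_events",
]

#: AcD rule: axon distance must exceed this (strict inequality).
AXON_DISTANCE_THRESHOLD_UM = 2.0

#: Angle (degrees) between the axon-origin edge and the local soma-edge
#: tangent above which the perpendicular-axis construction replaces the
#: plain arc length. Near-parallel edges stay on the arc-length rule so
#: the measurement does not flip-flop on annotation jitter.
OBLIQUE_ANGLE_DEG = 15.0


@dataclass
class NeuronAnnotation:
    """Geometric annotation of one neuron, all coordinates in µm.

    ``stem_path`` runs from the soma edge to the axon origin; it may be
    empty (``None`` or a single point) when the axon leaves the soma
    directly. ``axon_origin_edge`` is the short segment marking the
    border of the axon start; when it is oblique to the soma edge the
    axon distance uses the perpendicular-axis construction.
    """

    cell_id: str
    soma_boundary: np.ndarray  # (n, 2) closed polygon
    axon_origin: tuple[float, float]
    stem_path: np.ndarray | None = None  # (m, 2) polyline, soma edge -> axon origin
    soma_edge_point: tuple[float, float] | None = None
    axon_origin_edge: np.ndarray | None = None  # (2, 2) segment endpoints
    d1_um: float | None = None
    d2_um: float | None = None
    n_axons: int = 1

    def __post_init__(self) -> None:
        self.soma_boundary = np.asarray(self.soma_boundary, dtype=float)
        if self.soma_boundary.ndim != 2 or self.soma_boundary.shape[0] < 3:
            raise ValueError("soma_boundary must be a polygon with >= 3 vertices")
        if self.stem_path is not None:
            self.stem_path = np.asarray(self.stem_path, dtype=float)
        if self.axon_origin_edge is not None:
            self.axon_origin_edge = np.asarray(self.axon_origin_edge, dtype=float)
        for name in ("d1_um", "d2_um"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValueError(f"{name} must be > 0 when present, got {v}")


@dataclass(frozen=True)
class MorphClassification:
    label: str  # "AcD" | "nonAcD"
    axon_distance_um: float
    stem_diameter_um: float | None = None


def _polyline_length(path: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(path, axis=0).T)))


def _soma_tangent_at(ann: NeuronAnnotation, point: tuple[float, float]) -> np.ndarray:
    """Direction of the soma-boundary segment nearest to *point*."""
    ring = ann.soma_boundary
    segs = np.stack([ring[:-1], ring[1:]], axis=1) if np.allclose(ring[0], ring[-1]) else \
        np.stack([ring, np.roll(ring, -1, axis=0)], axis=1)
    p = Point(point)
    best, best_d = None, math.inf
    for a, b in segs:
        d = LineString([a, b]).distance(p)
        if d < best_d:
            best_d, best = d, (a, b)
    a, b = best
    t = np.asarray(b) - np.asarray(a)
    n = np.linalg.norm(t)
    return t / n if n > 0 else np.array([1.0, 0.0])


def axon_distance(ann: NeuronAnnotation) -> float:
    """Axon distance (µm): arc length of the stem path from soma edge to
    axon origin.

    When the axon-origin edge is oblique (more than ``OBLIQUE_ANGLE_DEG``
    away from the local soma-edge tangent), the distance is instead taken
    from the soma edge point to the axis that passes through the centre of
    the axon-origin edge perpendicular to that edge.
    """
    if ann.stem_path is None or len(ann.stem_path) < 2:
        return 0.0
    path = np.asarray(ann.stem_path, dtype=float)
    line = LineString(path)
    if not line.is_simple:
        raise ValueError(f"stem_path of cell {ann.cell_id!r} is self-intersecting")

    if ann.axon_origin_edge is not None and ann.soma_edge_point is not None:
        e0, e1 = ann.axon_origin_edge
        edge_dir = np.asarray(e1, dtype=float) - np.asarray(e0, dtype=float)
        norm = np.linalg.norm(edge_dir)
        if norm > 0:
            edge_dir = edge_dir / norm
            tangent = _soma_tangent_at(ann, ann.soma_edge_point)
            cosang = abs(float(np.dot(edge_dir, tangent)))
            ang = math.degrees(math.acos(min(1.0, cosang)))
            if ang > OBLIQUE_ANGLE_DEG:
                # Distance from the soma edge point to the axis through the
                # edge centre, perpendicular to the edge: the component of
                # the offset along the edge direction.
                centre = (np.asarray(e0, dtype=float) + np.asarray(e1, dtype=float)) / 2.0
                offset = np.asarray(ann.soma_edge_point, dtype=float) - centre
                return abs(float(np.dot(offset, edge_dir)))
    return _polyline_length(path)


def stem_diameter(ann: NeuronAnnotation) -> float:
    """Stem dendrite diameter (µm), d = (d1 + d2) / 2."""
    if ann.d1_um is None or ann.d2_um is None:
        raise ValueError(f"cell {ann.cell_id!r}: both width chords d1/d2 are required")
    return width_along_chords(ann.d1_um, ann.d2_um)


def width_along_chords(d1_um: float, d2_um: float) -> float:
    """Average width of a structure from two chords drawn across it (µm).

    Shared helper for stem-dendrite and AIS diameter measurements.
    """
    if not (d1_um > 0 and d2_um > 0):
        raise ValueError("width chords must both be > 0")
    return (d1_um + d2_um) / 2.0


def classify_neuron(ann: NeuronAnnotation) -> MorphClassification:
    """Apply the AcD rule: axon distance > 2 µm AND > stem diameter (both strict)."""
    if ann.n_axons != 1:
        raise ValueError(f"cell {ann.cell_id!r} has {ann.n_axons} axons; excluded upstream")
    dist = axon_distance(ann)
    if dist == 0.0:
        # Axon leaves the soma directly; the stem dendrite does not exist.
        return MorphClassification("nonAcD", 0.0, None)
    if ann.d1_um is None or ann.d2_um is None:
        raise ValueError(
            f"cell {ann.cell_id!r}: nonzero axon distance but stem width chords missing"
        )
    diam = stem_diameter(ann)
    is_acd = dist > AXON_DISTANCE_THRESHOLD_UM and dist > diam
    return MorphClassification("AcD" if is_acd else "nonAcD", dist, diam)


def classify_table(annotations: list[NeuronAnnotation]) -> pd.DataFrame:
    """Classify a batch of cells into a flat results table."""
    rows = []
    for ann in annotations:
        c = classify_neuron(ann)
        rows.append(
            {
                "cell_id": ann.cell_id,
                "label": c.label,
                "axon_distance_um": c.axon_distance_um,
                "stem_diameter_um": c.stem_diameter_um,
            }
        )
    return pd.DataFrame(rows)


def summarize_events(table: pd.DataFrame) -> dict[str, dict]:
    """Summarize a per-cell event table (columns cell_id, event, value).

    For each event, returns the per-category proportions (count / total);
    for numeric-valued events (e.g. formation-time bins in hours) also the
    count-weighted mean of the values.
    """
    required = {"cell_id", "event", "value"}
    if table is None or len(table) == 0:
        raise ValueError("event table is empty")
    if not required.issubset(table.columns):
        raise ValueError(f"event table needs columns {sorted(required)}")
    if table.duplicated(subset=["cell_id", "event"]).any():
        raise ValueError("event table must have one row per (cell, event)")

    out: dict[str, dict] = {}
    for event, grp in table.groupby("event"):
        values = grp["value"]
        counts = values.value_counts()
        total = int(counts.sum())
        summary: dict = {
            "n": total,
            "proportions": {k: c / total for k, c in counts.items()},
        }
        numeric = pd.to_numeric(values, errors="coerce")
        if numeric.notna().all():
            summary["weighted_mean"] = float(numeric.mean())
        out[str(event)] = summary
    return out
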