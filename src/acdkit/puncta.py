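"""Puncta detection, density, axis mapping, colocalization and ROI
intensity measurements.

Covers the cluster-level readouts around the AIS: synaptopodin-marked
cisternal organelles (count, size, along-axis position), inhibitory
synapse markers (gephyrin/VGAT pair counting with the 8×8-px box rule),
linear densities per 5 µm of AIS, and background-normalized ROI
intensities, plus the IQR outlier rule applied before group statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon
from skimage import filters, measure

__all__ = [
    "Punctum",
    "PunctaSet",
    "AxisMapping",
    "ColocParams",
    "detect_puncta",
    "linear_density",
    "map_to_axis",
    "coloc_count",
    "roi_intensity",
    "iqr_filter",
]


@dataclass(frozen=True)
class Punctum:
    centroid_px: tuple[float, float]  # (x, y)
    area_um2: float
    channel: str = ""

    def __post_init__(self) -> None:
        if not (self.area_um2 > 0):
            raise ValueError("punctum area must be > 0")


@dataclass
class PunctaSet:
    puncta: list[Punctum]
    channel: str = ""

    def __len__(self) -> int:
        return len(self.puncta)

    @property
    def centroids(self) -> np.ndarray:
        if not self.puncta:
            return np.empty((0, 2))
        return np.asarray([p.centroid_px for p in self.puncta], dtype=float)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.asarray([p.area_um2 for p in self.puncta], dtype=float)


@dataclass(frozen=True)
class AxisMapping:
    punctum_id: int
    arc_position_um: float
    lateral_offset_px: float
    mapped: bool = True


@dataclass(frozen=True)
class ColocParams:
    """8×8-px box rule: partners must be within this half-width on each axis."""

    box_halfwidth_px: float = 8.0

    def __post_init__(self) -> None:
        if not (self.box_halfwidth_px > 0):
            raise ValueError("box_halfwidth_px must be > 0")


def _roi_mask(roi: np.ndarray | Polygon, shape: tuple[int, int]) -> np.ndarray:
    poly = roi if isinstance(roi, Polygon) else Polygon(np.asarray(roi, dtype=float))
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.column_stack([xs.ravel() + 0.0, ys.ravel() + 0.0])
    # vectorized point-in-polygon via matplotlib-free shapely prepared ops
    from shapely import contains_xy, prepare

    prepare(poly)
    mask = contains_xy(poly, pts[:, 0], pts[:, 1]).reshape(shape)
    return mask


def detect_puncta(
    image: np.ndarray,
    roi: np.ndarray | Polygon | None = None,
    threshold: float | str = "otsu",
    min_area_px: int = 4,
    pixel_size_um: float = 1.0,
    channel: str = "",
) -> PunctaSet:
    """Threshold-and-outline puncta detection inside a polygonal ROI.

    The channel is thresholded (numeric value, or ``"otsu"``), a
    gradient-magnitude (fine-edges) map delineates cluster outlines, and
    connected components of at least ``min_area_px`` pixels become
    puncta. A cluster straddling the ROI border keeps its full area and
    counts iff its centroid lies inside the ROI.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("detect_puncta expects a single-channel 2-D image")
    if roi is not None:
        mask = _roi_mask(roi, image.shape)
        if not mask.any():
            raise ValueError("ROI is empty (covers no pixels)")
    else:
        mask = np.ones(image.shape, dtype=bool)

    if threshold == "otsu":
        vals = image[mask]
        if np.ptp(vals) == 0:
            return PunctaSet([], channel=channel)
        thr = float(filters.threshold_otsu(vals))
    else:
        thr = float(threshold)

    binary = image >= thr
    # fine-edges step: gradient magnitude outlines each cluster; the
    # filled outline of a solid cluster is the thresholded component
    # itself, which keeps areas exact.
    edges = filters.sobel(binary.astype(float)) > 0
    outlined = ndimage.binary_fill_holes(binary | (edges & binary))

    labels = measure.label(outlined)
    puncta = []
    poly = None
    if roi is not None:
        poly = roi if isinstance(roi, Polygon) else Polygon(np.asarray(roi, dtype=float))
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        cy, cx = region.centroid
        if poly is not None and not poly.covers(Point(cx, cy)):
            continue
        puncta.append(
            Punctum(
                centroid_px=(float(cx), float(cy)),
                area_um2=float(region.area) * pixel_size_um**2,
                channel=channel,
            )
        )
    return PunctaSet(puncta, channel=channel)


def linear_density(puncta: PunctaSet | int, ais_length_um: float, per_um: float = 5.0) -> float:
    """Puncta per ``per_um`` µm of AIS (default: per 5 µm)."""
    if not (ais_length_um > 0):
        raise ValueError("AIS length must be > 0")
    count = puncta if isinstance(puncta, int) else len(puncta)
    return count / ais_length_um * per_um


def map_to_axis(
    puncta: PunctaSet,
    reference_line: np.ndarray,
    pixel_size_um: float = 1.0,
    max_lateral_px: float = 10.0,
) -> list[AxisMapping]:
    """Project each punctum onto the reference polyline (drawn from the
    axon start).

    Arc position is the distance along the line from its start to the
    nearest point; centroids farther than ``max_lateral_px`` from the
    line are flagged unmapped rather than force-projected.
    """
    line = LineString(np.asarray(reference_line, dtype=float))
    if line.length == 0:
        raise ValueError("reference line is degenerate")
    out = []
    for i, (x, y) in enumerate(puncta.centroids):
        p = Point(x, y)
        lateral = line.distance(p)
        arc_px = line.project(p)
        out.append(
            AxisMapping(
                punctum_id=i,
                arc_position_um=float(arc_px * pixel_size_um),
                lateral_offset_px=float(lateral),
                mapped=bool(lateral <= max_lateral_px),
            )
        )
    return out


def coloc_count(
    a: PunctaSet,
    b: PunctaSet,
    params: ColocParams = ColocParams(),
    pixel_size_um: float = 1.0,
) -> tuple[list[tuple[int, int]], int, np.ndarray]:
    """Count colocalized puncta pairs under the per-axis box rule.

    Candidate pairs satisfy |Δx| <= box AND |Δy| <= box (inclusive).
    One-to-one matching proceeds greedily by increasing Euclidean centre
    distance — one presynaptic punctum pairs with one postsynaptic
    punctum. Returns (pair index list, count, centre distances in µm).
    """
    ca, cb = a.centroids, b.centroids
    if len(ca) == 0 or len(cb) == 0:
        return [], 0, np.empty(0)
    dx = np.abs(ca[:, 0][:, None] - cb[:, 0][None, :])
    dy = np.abs(ca[:, 1][:, None] - cb[:, 1][None, :])
    inside = (dx <= params.box_halfwidth_px) & (dy <= params.box_halfwidth_px)
    ii, jj = np.nonzero(inside)
    dist = np.hypot(ca[ii, 0] - cb[jj, 0], ca[ii, 1] - cb[jj, 1])
    order = np.argsort(dist, kind="stable")
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    dists: list[float] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
        dists.append(float(dist[k]))
    return pairs, len(pairs), np.asarray(dists) * pixel_size_um


def roi_intensity(
    image: np.ndarray,
    roi: np.ndarray | Polygon,
    background: np.ndarray | Polygon | str = "auto",
) -> float:
    """Mean ROI intensity normalized to background.

    ``background`` is a second polygon (disjoint from the ROI) or
    ``"auto"``: the mean over pixels outside the ROI whose intensity lies
    below the image's 20th percentile.
    """
    image = np.asarray(image, dtype=float)
    mask = _roi_mask(roi, image.shape)
    if not mask.any():
        raise ValueError("ROI covers no pixels")
    if isinstance(background, str):
        if background != "auto":
            raise ValueError("background must be a polygon or 'auto'")
        outside = ~mask
        cutoff = np.percentile(image, 20)
        bg_mask = outside & (image <= cutoff)
        if not bg_mask.any():
            raise ValueError("auto background found no pixels")
    else:
        bg_mask = _roi_mask(background, image.shape)
        if (bg_mask & mask).any():
            raise ValueError("ROI and background must be disjoint")
    bg_mean = float(image[bg_mask].mean())
    if bg_mean == 0:
        raise ValueError("background mean is zero; cannot normalize")
    return float(image[mask].mean()) / bg_mean


def iqr_filter(values) -> tuple[np.ndarray, np.ndarray]:
    """Tukey outlier removal: drop values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR].

    Quartiles use linear interpolation so the rule is reproducible across
    implementations. Fewer than 4 values pass through unchanged with a
    warning (quartiles would be meaningless).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("fewer than 4 values: IQR filter passed through", stacklevel=2)
        return values.copy(), np.empty(0)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], values[~keep]
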