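"""Synthetic ground-truth generators for every analysis stage.

No raw microscopy data accompanies the measurements this package
re-implements, so each analysis is exercised on synthetic inputs whose
truth is known by construction:

* AnkG-like plateau profiles with smooth shoulders (AIS geometry),
* ~190–200 nm periodic profiles at 20 nm/px (MPS periodicity),
* kymographs of particles alternating runs/pauses/passive jitter,
* neuron annotation tables with a controllable AcD fraction,
* 2-D puncta fields with planted colocalized pairs.

Every generator is a pure function of (parameters, seed) — identical
inputs reproduce identical output bit-for-bit — and returns its ground
truth next to the data. Noise is additive Gaussian on intensity, clipped
at zero. Optics are deliberately idealized: no depth, no spectral
bleed-through, no drift, no photobleaching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .core import LineProfile, PixelCalibration
from .kymo import Kymograph, TrajectoryTrace
from .morphology import AXON_DISTANCE_THRESHOLD_UM, NeuronAnnotation
from .puncta import PunctaSet, Punctum

__all__ = [
    "SyntheticTruth",
    "make_mps_profile",
    "make_ais_profile",
    "make_kymograph",
    "make_neuron_table",
    "make_puncta_field",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Provenance record of one generated object."""

    kind: str  # ais_profile | mps_profile | kymograph | neuron_table | puncta_field
    parameters: dict
    seed: int


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _add_noise(signal: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd == 0:
        return np.clip(signal, 0, None)
    amplitude = float(signal.max()) if signal.max() > 0 else 1.0
    noisy = signal + rng.normal(0.0, noise_sd * amplitude, signal.shape)
    return np.clip(noisy, 0, None)


# ---------------------------------------------------------------------------
# MPS profiles
# ---------------------------------------------------------------------------

def make_mps_profile(
    period_nm: float,
    n_periods: int = 40,
    pixel_nm: float = 20.0,
    peak_width_nm: float = 80.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    antiphase: bool = False,
) -> tuple[LineProfile, SyntheticTruth] | tuple[LineProfile, LineProfile, SyntheticTruth]:
    """Periodic ring profile: Gaussian peaks every ``period_nm`` on a
    ``pixel_nm`` grid.

    ``peak_width_nm`` is the FWHM of each ring's intensity peak (roughly
    the STED PSF). With ``antiphase`` a second profile shifted by half a
    period is returned as well — the spectrin channel interleaving the
    actin rings.
    """
    if period_nm < 2 * pixel_nm:
        raise ValueError(
            f"period {period_nm} nm is below the Nyquist limit for {pixel_nm} nm pixels"
        )
    if n_periods < 3:
        raise ValueError("need at least 3 periods")
    rng = _rng(seed)
    n_px = int(round(n_periods * period_nm / pixel_nm)) + 1
    x = np.arange(n_px) * pixel_nm
    sigma = peak_width_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def comb(shift_nm: float) -> np.ndarray:
        centers = np.arange(-1, n_periods + 2) * period_nm + shift_nm
        return np.exp(-0.5 * ((x[:, None] - centers[None, :]) / sigma) ** 2).sum(axis=1)

    px_um = pixel_nm / 1000.0
    prof_a = LineProfile(_add_noise(comb(0.0), noise_sd, rng), px_um)
    truth = SyntheticTruth(
        kind="mps_profile",
        parameters={
            "period_nm": period_nm,
            "n_periods": n_periods,
            "pixel_nm": pixel_nm,
            "peak_width_nm": peak_width_nm,
            "noise_sd": noise_sd,
            "antiphase": antiphase,
        },
        seed=seed,
    )
    if not antiphase:
        return prof_a, truth
    prof_b = LineProfile(_add_noise(comb(period_nm / 2.0), noise_sd, rng), px_um)
    return prof_a, prof_b, truth


# ---------------------------------------------------------------------------
# AnkG plateau profiles
# ---------------------------------------------------------------------------

def make_ais_profile(
    axon_len_um: float,
    ais_start_um: float,
    ais_end_um: float,
    edge_softness_um: float = 1.0,
    pixel_um: float = 0.08,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[LineProfile, SyntheticTruth]:
    """AnkG-like plateau of unit amplitude between start and end.

    Shoulders are error-function ramps with scale ``edge_softness_um``
    (0 → ideal rectangle). Samples sit at pixel centres
    x_i = (i + 0.5) · pixel, so a 5–35 µm plateau at 0.08 µm/px occupies
    indices 62..437 exactly.
    """
    if not (0 <= ais_start_um < ais_end_um <= axon_len_um):
        raise ValueError(
            f"need 0 <= start < end <= axon length, got {ais_start_um}, {ais_end_um}, {axon_len_um}"
        )
    rng = _rng(seed)
    n_px = int(round(axon_len_um / pixel_um))
    x = (np.arange(n_px) + 0.5) * pixel_um
    if edge_softness_um == 0:
        signal = ((x >= ais_start_um) & (x <= ais_end_um)).astype(float)
    else:
        s = edge_softness_um * math.sqrt(2.0)
        signal = 0.5 * (erf((x - ais_start_um) / s) - erf((x - ais_end_um) / s))
    profile = LineProfile(_add_noise(signal, noise_sd, rng), pixel_um)
    truth = SyntheticTruth(
        kind="ais_profile",
        parameters={
            "axon_len_um": axon_len_um,
            "ais_start_um": ais_start_um,
            "ais_end_um": ais_end_um,
            "ais_length_um": ais_end_um - ais_start_um,
            "edge_softness_um": edge_softness_um,
            "pixel_um": pixel_um,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return profile, truth


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------

def _integrate_schedule(schedule: list[tuple[str, int, float]]) -> np.ndarray:
    """Frame-by-frame integer/float positions from a state schedule.

    Runs move at the stated velocity (px/frame), pauses sit still, and
    passive motion is the deterministic jitter the classifier must
    recognise: move +1 px, stop one frame, move −1 px, stop one frame, …
    Positions has one more entry than the total frame count.
    """
    pos = [0.0]
    passive_cycle = [1.0, 0.0, -1.0, 0.0]
    k = 0
    for state, duration, velocity in schedule:
        if duration < 1:
            raise ValueError("schedule durations must be >= 1 frame")
        if state == "run":
            for _ in range(duration):
                pos.append(pos[-1] + velocity)
        elif state == "pause":
            for _ in range(duration):
                pos.append(pos[-1])
        elif state == "passive":
            for _ in range(duration):
                pos.append(pos[-1] + passive_cycle[k % 4])
                k += 1
        else:
            raise ValueError(f"unknown state {state!r}; use run/pause/passive")
    return np.asarray(pos)


def make_kymograph(
    schedule: list[tuple[str, int, float]],
    calibration: PixelCalibration,
    psf_sigma_px: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_positions: int | None = None,
    start_px: float | None = None,
) -> tuple[Kymograph, TrajectoryTrace, SyntheticTruth]:
    """Render one particle following a state schedule into a kymograph.

    Returns the rendered time × position matrix, the exact trace (the
    ground truth a kymograph tracer should recover) and the provenance
    record. The spatial field defaults to the trajectory's span plus a
    4·PSF margin; an explicit field that the trajectory leaves is an
    error.
    """
    if calibration.frame_interval_s is None:
        raise ValueError("kymograph rendering needs a frame interval")
    rng = _rng(seed)
    rel = _integrate_schedule(schedule)
    margin = 4.0 * psf_sigma_px + 2.0
    if start_px is None:
        start_px = margin - rel.min()
    positions = rel + start_px
    if n_positions is None:
        n_positions = int(math.ceil(positions.max() + margin)) + 1
    if positions.min() < 0 or positions.max() > n_positions - 1:
        raise ValueError("trajectory leaves the spatial field")

    xs = np.arange(n_positions)
    matrix = np.exp(-0.5 * ((xs[None, :] - positions[:, None]) / psf_sigma_px) ** 2)
    matrix = _add_noise(matrix, noise_sd, rng)

    trace = TrajectoryTrace(
        frames=np.arange(positions.size),
        positions_px=positions,
        calibration=calibration,
        track_id="synthetic",
    )
    truth = SyntheticTruth(
        kind="kymograph",
        parameters={
            "schedule": [list(s) for s in schedule],
            "psf_sigma_px": psf_sigma_px,
            "noise_sd": noise_sd,
            "start_px": float(start_px),
            "n_positions": int(n_positions),
            "pixel_size_um": calibration.pixel_size_um,
            "frame_interval_s": calibration.frame_interval_s,
        },
        seed=seed,
    )
    return Kymograph(matrix, calibration, path_id="synthetic"), trace, truth


# ---------------------------------------------------------------------------
# neuron annotation tables
# ---------------------------------------------------------------------------

def _sample_dist(spec: tuple, rng: np.random.Generator) -> float:
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "normal":
        return float(rng.normal(spec[1], spec[2]))
    if kind == "lognormal":
        return float(rng.lognormal(spec[1], spec[2]))
    raise ValueError(f"unknown distribution spec {spec!r}")


#: Median AcD axon distance is ~7.75 µm in culture; a lognormal with that
#: median and moderate spread reproduces the long right tail.
DEFAULT_AXON_DISTANCE_DIST = ("lognormal", math.log(7.75), 0.45)
#: Stem dendrite diameters cluster around ~2 µm.
DEFAULT_STEM_DIAMETER_DIST = ("normal", 2.0, 0.4)

_SOMA_RADIUS_UM = 7.5
_MAX_DRAWS = 10_000


def _build_annotation(
    cell_id: str, distance_um: float, diameter_um: float, theta: float
) -> NeuronAnnotation:
    """Concrete geometry realizing a given axon distance and diameter:
    a circular soma with a straight stem path leaving at angle theta."""
    phis = np.linspace(0, 2 * np.pi, 65)
    soma = _SOMA_RADIUS_UM * np.column_stack([np.cos(phis), np.sin(phis)])
    u = np.array([math.cos(theta), math.sin(theta)])
    edge_pt = _SOMA_RADIUS_UM * u
    origin = edge_pt + distance_um * u
    if distance_um > 0:
        path = np.vstack([edge_pt, origin])
        # axon-origin edge parallel to the local soma tangent (no oblique case)
        t = np.array([-u[1], u[0]])
        origin_edge = np.vstack([origin - 0.5 * t, origin + 0.5 * t])
        return NeuronAnnotation(
            cell_id=cell_id,
            soma_boundary=soma,
            axon_origin=tuple(origin),
            stem_path=path,
            soma_edge_point=tuple(edge_pt),
            axon_origin_edge=origin_edge,
            d1_um=diameter_um,
            d2_um=diameter_um,
        )
    return NeuronAnnotation(
        cell_id=cell_id,
        soma_boundary=soma,
        axon_origin=tuple(edge_pt),
        stem_path=None,
        soma_edge_point=tuple(edge_pt),
    )


def make_neuron_table(
    n: int,
    acd_fraction: float,
    axon_distance_dist: tuple = DEFAULT_AXON_DISTANCE_DIST,
    stem_diameter_dist: tuple = DEFAULT_STEM_DIAMETER_DIST,
    seed: int = 0,
) -> tuple[list[tuple[NeuronAnnotation, str]], SyntheticTruth]:
    """Annotated cells with planted AcD / nonAcD labels.

    AcD cells satisfy the classification rule by construction (axon
    distance strictly greater than both 2 µm and the stem diameter);
    nonAcD cells violate it, either by a short axon distance (< 2 µm,
    including direct somatic origin) or by a stem thicker than the axon
    distance. A distance distribution that cannot produce a valid AcD
    draw is rejected.
    """
    if not (0 <= acd_fraction <= 1):
        raise ValueError("acd_fraction must be in [0, 1]")
    rng = _rng(seed)
    cells: list[tuple[NeuronAnnotation, str]] = []
    n_acd = int(round(n * acd_fraction))
    for i in range(n):
        label = "AcD" if i < n_acd else "nonAcD"
        diameter = abs(_sample_dist(stem_diameter_dist, rng)) + 0.1
        theta = float(rng.uniform(0, 2 * np.pi))
        if label == "AcD":
            for attempt in range(_MAX_DRAWS):
                dist = _sample_dist(axon_distance_dist, rng)
                if dist > AXON_DISTANCE_THRESHOLD_UM and dist > diameter:
                    break
            else:
                raise ValueError(
                    "axon_distance_dist cannot produce AcD cells: all mass at or "
                    f"below max(2 µm, stem diameter {diameter:.2f} µm)"
                )
        else:
            # choose the violation mode: short distance, somatic origin,
            # or distance dominated by the stem diameter
            mode = rng.integers(0, 3)
            if mode == 0:
                dist = float(rng.uniform(0.2, AXON_DISTANCE_THRESHOLD_UM * 0.95))
            elif mode == 1:
                dist = 0.0
            else:
                dist = float(rng.uniform(AXON_DISTANCE_THRESHOLD_UM, diameter)) \
                    if diameter > AXON_DISTANCE_THRESHOLD_UM else 0.0
        cells.append((_build_annotation(f"cell_{i:04d}", dist, diameter, theta), label))
    truth = SyntheticTruth(
        kind="neuron_table",
        parameters={
            "n": n,
            "acd_fraction": acd_fraction,
            "axon_distance_dist": list(axon_distance_dist),
            "stem_diameter_dist": list(stem_diameter_dist),
        },
        seed=seed,
    )
    return cells, truth


# ---------------------------------------------------------------------------
# puncta fields
# ---------------------------------------------------------------------------

def make_puncta_field(
    n_a: int,
    n_b: int,
    n_pairs: int,
    field_px: tuple[int, int] = (512, 512),
    pair_offset_px: tuple[float, float] = (3.0, 3.0),
    box_halfwidth_px: float = 8.0,
    seed: int = 0,
) -> tuple[PunctaSet, PunctaSet, list[tuple[int, int]], SyntheticTruth]:
    """Two puncta channels with exactly ``n_pairs`` planted colocalized
    pairs.

    Planted partners sit at ``pair_offset_px`` from their anchors (must be
    inside the colocalization box); every other point is placed farther
    than the box from any opposite-channel point, so a correct counter
    returns exactly ``n_pairs``. Raises when the field is too small to
    hold the points at the required separation.
    """
    if n_pairs > min(n_a, n_b):
        raise ValueError("n_pairs cannot exceed the size of either channel")
    if max(abs(pair_offset_px[0]), abs(pair_offset_px[1])) > box_halfwidth_px:
        raise ValueError("pair_offset_px must lie inside the colocalization box")
    w, h = field_px
    clearance = 2 * box_halfwidth_px + max(abs(pair_offset_px[0]), abs(pair_offset_px[1])) + 1
    # capacity heuristic before attempting placement
    if (n_a + n_b) * (clearance**2) > 0.5 * w * h:
        raise ValueError("field too small to separate the requested points")
    rng = _rng(seed)

    placed_a: list[np.ndarray] = []
    placed_b: list[np.ndarray] = []
    pairs: list[tuple[int, int]] = []

    def far_from_all(p: np.ndarray, others: list[np.ndarray], min_cheb: float) -> bool:
        return all(np.max(np.abs(p - q)) > min_cheb for q in others)

    def draw_point(min_cheb_from: list[np.ndarray]) -> np.ndarray:
        for _ in range(_MAX_DRAWS):
            p = rng.uniform([clearance, clearance], [w - clearance, h - clearance])
            if far_from_all(p, min_cheb_from, clearance):
                return p
        raise ValueError("field too small to satisfy the separation constraints")

    offset = np.asarray(pair_offset_px, dtype=float)
    for k in range(n_pairs):
        anchor = draw_point(placed_a + placed_b)
        placed_a.append(anchor)
        placed_b.append(anchor + offset)
        pairs.append((len(placed_a) - 1, len(placed_b) - 1))
    for _ in range(n_a - n_pairs):
        placed_a.append(draw_point(placed_a + placed_b))
    for _ in range(n_b - n_pairs):
        placed_b.append(draw_point(placed_a + placed_b))

    def to_set(points: list[np.ndarray], channel: str) -> PunctaSet:
        puncta = [
            Punctum(centroid_px=(float(p[0]), float(p[1])), area_um2=0.1, channel=channel)
            for p in points
        ]
        return PunctaSet(puncta, channel=channel)

    truth = SyntheticTruth(
        kind="puncta_field",
        parameters={
            "n_a": n_a,
            "n_b": n_b,
            "n_pairs": n_pairs,
            "field_px": list(field_px),
            "pair_offset_px": list(pair_offset_px),
            "box_halfwidth_px": box_halfwidth_px,
        },
        seed=seed,
    )
    return to_set(placed_a, "a"), to_set(placed_b, "b"), pairs, truth
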