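"""Stage implementations behind :func:`acdkit.io.run_pipeline`.

Each stage reads the inputs named in the config, runs the corresponding
analysis module with the configured thresholds, writes CSV outputs into
the results directory and returns a structured log of what was applied.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ais, io, kymo, morphology, mps, synthetic
from .core import PixelCalibration


def _calibration(config) -> PixelCalibration:
    if config.pixel_size_um is None:
        raise ValueError("config.pixel_size_um is required for this stage")
    return PixelCalibration(config.pixel_size_um, config.frame_interval_s)


def stage_classify(config, out_dir: Path) -> dict:
    annotations = io.read_annotations(config.input_path)
    table = morphology.classify_table(annotations)
    table.to_csv(out_dir / "classification.csv", index=False)
    return {
        "n_cells": len(table),
        "n_acd": int((table["label"] == "AcD").sum()),
        "axon_distance_threshold_um": config.axon_distance_threshold_um,
    }


def stage_ais(config, out_dir: Path) -> dict:
    paths = sorted(Path(config.input_path).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no profile CSVs under {config.input_path}")
    profiles = [io.read_profile_csv(p) for p in paths]
    groups = [p.stem.split("__")[0] for p in paths]
    cell_ids = [p.stem for p in paths]
    table, summary = ais.measure_ais_batch(
        profiles,
        groups,
        cell_ids,
        threshold_fraction=config.ais_threshold_fraction,
        smooth_window_um=config.ais_smooth_window_um,
    )
    table.to_csv(out_dir / "ais_measurements.csv", index=False)
    summary.to_csv(out_dir / "ais_group_summary.csv", index=False)
    return {
        "n_profiles": len(profiles),
        "threshold_fraction": config.ais_threshold_fraction,
        "smooth_window_um": config.ais_smooth_window_um,
    }


def stage_mps(config, out_dir: Path) -> dict:
    paths = sorted(Path(config.input_path).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no profile CSVs under {config.input_path}")
    rows = []
    for p in paths:
        prof = io.read_profile_csv(p)
        res = mps.peak_spacings(
            prof,
            smooth_window_px=config.mps_smooth_window_px,
            min_prominence=config.mps_min_prominence,
        )
        try:
            period = mps.autocorr_period(prof)
        except ValueError:
            period = np.nan
        rows.append(
            {
                "profile": p.stem,
                "n_peaks": res.n_peaks,
                "mean_spacing_nm": res.mean_spacing_nm,
                "autocorr_period_nm": period,
            }
        )
        (out_dir / f"{p.stem}_spacings.json").write_text(
            json.dumps({"spacings_nm": res.spacings_nm.tolist()})
        )
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "mps_periodicity.csv", index=False)
    # spacing histogram table (10 nm bins), the population-level readout
    all_spacings = np.concatenate(
        [
            json.loads((out_dir / f"{p.stem}_spacings.json").read_text())["spacings_nm"]
            for p in paths
        ]
    )
    edges = np.arange(100, 401, 10.0)
    counts, _ = np.histogram(all_spacings, bins=edges)
    pd.DataFrame({"bin_left_nm": edges[:-1], "count": counts}).to_csv(
        out_dir / "spacing_histogram.csv", index=False
    )
    return {"n_profiles": len(paths), "smooth_window_px": config.mps_smooth_window_px}


def stage_kymo(config, out_dir: Path) -> dict:
    cal = _calibration(config)
    params = kymo.EB3_PARAMS if config.preset == "eb3" else kymo.CARGO_PARAMS
    paths = sorted(Path(config.input_path).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no trace CSVs under {config.input_path}")
    seg_rows, tracks = [], []
    for p in paths:
        trace = io.read_trace_csv(p, cal)
        tracks.append(trace)
        segments, mobile = kymo.segment_trajectory(trace, params)
        for s in segments:
            seg_rows.append(
                {
                    "track_id": trace.track_id,
                    "kind": s.kind,
                    "frame_start": s.frame_start,
                    "frame_end": s.frame_end,
                    "displacement_px": s.displacement_px,
                    "length_um": s.length_um,
                    "duration_s": s.duration_s,
                    "velocity_um_s": s.velocity_um_s,
                    "mobile": mobile,
                }
            )
    pd.DataFrame(seg_rows).to_csv(out_dir / "segments.csv", index=False)
    summary = kymo.summarize_motility({"all": tracks}, params)
    summary.to_csv(out_dir / "motility_summary.csv", index=False)
    return {"n_tracks": len(tracks), "preset": params.preset}


def stage_puncta(config, out_dir: Path) -> dict:
    from . import puncta as pc

    image, cal = io.read_image_stack(
        config.input_path,
        _calibration(config) if config.pixel_size_um else None,
    )
    if image.ndim == 3:
        image = image[0]
    ps = pc.detect_puncta(
        image,
        threshold=config.puncta_threshold,
        min_area_px=config.min_area_px,
        pixel_size_um=cal.pixel_size_um,
    )
    pd.DataFrame(
        {
            "x_px": [p.centroid_px[0] for p in ps.puncta],
            "y_px": [p.centroid_px[1] for p in ps.puncta],
            "area_um2": [p.area_um2 for p in ps.puncta],
        }
    ).to_csv(out_dir / "puncta.csv", index=False)
    return {"n_puncta": len(ps), "threshold": str(config.puncta_threshold)}


def stage_simulate(config, out_dir: Path) -> dict:
    """Write one synthetic example of each input kind with its truth."""
    seed = config.seed
    prof, truth = synthetic.make_ais_profile(60, 5, 35, 1.0, 0.08, 0.05, seed)
    io.write_profile_csv(out_dir / "ais_profile.csv", prof)
    mps_prof, mps_truth = synthetic.make_mps_profile(190, 40, 20, seed=seed, noise_sd=0.15)
    io.write_profile_csv(out_dir / "mps_profile.csv", mps_prof)
    cal = PixelCalibration(0.13, 0.2)
    kg, trace, kg_truth = synthetic.make_kymograph(
        [("run", 10, 1.0), ("pause", 5, 0.0), ("run", 8, 1.0)], cal, seed=seed
    )
    io.write_image_stack(out_dir / "kymograph.tif", kg.matrix, cal)
    pd.DataFrame({"frame": trace.frames, "position_px": trace.positions_px}).to_csv(
        out_dir / "kymograph_truth_trace.csv", index=False
    )
    truths = {
        "ais_profile": truth.parameters,
        "mps_profile": mps_truth.parameters,
        "kymograph": kg_truth.parameters,
        "seed": seed,
    }
    (out_dir / "truth.json").write_text(json.dumps(truths, indent=2, sort_keys=True))
    return {"seed": seed, "outputs": sorted(t for t in truths if t != "seed")}
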