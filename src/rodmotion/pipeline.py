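"""End-to-end orchestration: simulate -> measure -> compare -> report.

``run_pipeline`` executes the stages requested by a single configuration
mapping (typically loaded from YAML) and writes all tabular outputs as CSV
plus one machine-readable JSON summary.  Every source of randomness derives
from the single ``seed``, so a fixed configuration reproduces its summary
bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .geometry import (IlluminationModel, Spherocylinder, illuminated_fraction,
                       illuminated_surface_area, projected_area,
                       total_surface_area)
from .filaments import batch_measure
from .membrane import (demultiplex_by_marker, estimate_field_background,
                       paired_ratio_experiment, simulate_mixed_field,
                       tirf_widefield_ratio)
from .stats import HistogramSpec, histogram, mann_whitney_u, summarize
from .synthetic import (ImagingConfig, generate_population,
                        simulate_filament_snapshot, simulate_movie,
                        write_outputs)
from .tracking import (TrackFilterConfig, assign_to_cell, detect_movie,
                       filter_tracks, link_tracks, track_velocity,
                       tracks_per_area)

__all__ = ["run_pipeline", "load_config"]

SCHEMA_VERSION = 1
log = logging.getLogger("rodmotion")


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return cfg


def _imaging_config(section: dict, seed: int) -> ImagingConfig:
    known = {k: v for k, v in section.items()
             if k in ImagingConfig.__dataclass_fields__}
    known.setdefault("seed", seed)
    return ImagingConfig(**known)


def _stage_geometry(cfg: dict) -> dict:
    cell = Spherocylinder(length=cfg["length_um"], width=cfg["width_um"])
    illum = IlluminationModel(depth=cfg.get("depth_um", 0.2))
    return {
        "length_um": cell.length,
        "width_um": cell.width,
        "depth_um": illum.depth,
        "total_area_um2": total_surface_area(cell),
        "illuminated_area_um2": illuminated_surface_area(cell, illum),
        "illuminated_fraction": illuminated_fraction(cell, illum),
        "projected_area_um2": projected_area(cell),
    }


def _stage_tracking(cfg: dict, seed: int, out: pathlib.Path) -> dict:
    img = _imaging_config(cfg.get("imaging", {}), seed)
    cells = generate_population(
        n_cells=cfg.get("n_cells", 25),
        emitter_density=cfg.get("emitter_density", 3.0),
        speed_distribution=(cfg.get("speed_mean", 22.0),
                            cfg.get("speed_sd", 6.0)),
        seed=seed,
        speed_lower=cfg.get("speed_lower", 5.0),
    )
    movie, truth = simulate_movie(cells, img)
    if cfg.get("write_movie", False):
        write_outputs(movie, truth, out / "simulate")
    filt = TrackFilterConfig(
        min_frames=cfg.get("min_frames", 5),
        min_displacement=cfg.get("min_displacement_nm", 70.0),
        max_link_distance=cfg.get("max_link_distance_nm", 250.0),
    )
    detections = detect_movie(movie, snr_min=cfg.get("snr_min", 5.0))
    tracks = link_tracks(detections, filt)
    survivors, report = filter_tracks(tracks, filt)

    def _speed(tr):
        ci = assign_to_cell(tr, cells)
        cell = cells[ci]
        u = np.array([np.cos(cell.orientation), np.sin(cell.orientation)])
        return track_velocity(tr, img.frame_interval, method="arc",
                              cell_axis_point=np.asarray(cell.center),
                              cell_axis_dir=u, cell_width=cell.width)

    velocities = np.array([_speed(t) for t in survivors]) \
        if survivors else np.array([])

    rows = []
    for tid, tr in enumerate(tracks):
        kept = tr.n_frames >= filt.min_frames and \
            tr.net_displacement_nm >= filt.min_displacement
        rows.append((tid, tr.n_frames, tr.net_displacement_nm,
                     track_velocity(tr, img.frame_interval)
                     if tr.n_frames >= 2 else float("nan"), kept))
    pd.DataFrame(rows, columns=[
        "track_id", "n_frames", "displacement_nm", "velocity_nm_s", "kept",
    ]).to_csv(out / "tracks_summary.csv", index=False)

    density = tracks_per_area(
        survivors, sum(c.projected_area_um2 for c in cells))
    result = {
        "n_detections": int(sum(len(d) for d in detections)),
        "n_tracks": len(tracks),
        "filter_report": report,
        "tracks_per_um2": density,
    }
    if velocities.size:
        result["velocity"] = asdict(summarize(velocities))
        edges, counts = histogram(velocities, HistogramSpec(bin_width=5.0))
        result["velocity_histogram"] = {
            "edges_nm_s": edges.tolist(), "counts": counts.tolist()}
    return result


def _stage_filaments(cfg: dict, seed: int, out: pathlib.Path) -> dict:
    img, table = simulate_filament_snapshot(
        n_filaments=cfg.get("n_filaments", 200),
        length_distribution=(cfg.get("length_mean", 520.0),
                             cfg.get("length_sd", 190.0)),
        seed=seed,
        length_lower=cfg.get("length_lower", 120.0),
    )
    pixel = cfg.get("pixel_size_nm", 40.6)
    rois = table[["x0", "y0", "x1", "y1"]].to_numpy().tolist()
    measurements = batch_measure(img, rois, pixel,
                                 psf_sigma_nm=cfg.get("psf_sigma_nm", 40.0))
    df = pd.DataFrame([
        (m.filament_id, m.orientation, m.background, m.threshold,
         m.length_nm, m.flag) for m in measurements
    ], columns=["id", "angle_rad", "background", "threshold",
                "length_nm", "flag"])
    df.to_csv(out / "filaments.csv", index=False)
    ok = df[np.isfinite(df["length_nm"]) & (df["length_nm"] > 0)]
    result = {
        "n_measured": int(len(ok)),
        "n_flagged": int((df["flag"] != "").sum()),
        "length": asdict(summarize(ok["length_nm"].to_numpy())),
        "true_length": asdict(summarize(table["length_nm"].to_numpy())),
    }
    edges, counts = histogram(ok["length_nm"].to_numpy(),
                              HistogramSpec(bin_width=120.0))
    result["length_histogram"] = {
        "edges_nm": edges.tolist(), "counts": counts.tolist()}
    return result


def _stage_ratio(cfg: dict, seed: int, out: pathlib.Path) -> dict:
    rng = np.random.default_rng(seed)
    n = cfg.get("n_cells_per_strain", 60)
    fractions = (cfg.get("membrane_fraction_strain1",
                         cfg.get("membrane_fraction", 0.5)),
                 cfg.get("membrane_fraction_strain2",
                         cfg.get("membrane_fraction", 0.5)))
    frames = []
    n_correct = n_called = 0
    for orient, marked_strain in (("A", 0), ("B", 1)):
        tirf, wf, red, masks, true_strains = simulate_mixed_field(
            n_per_strain=n, membrane_fractions=fractions,
            marked_strain=marked_strain, rng=rng)
        calls = demultiplex_by_marker(red, masks)
        bg_t = estimate_field_background(tirf, masks)
        bg_w = estimate_field_background(wf, masks)
        recs = []
        for m, call, true_s in zip(masks, calls, true_strains):
            if call == "ambiguous":
                continue
            strain_idx = marked_strain if call == "marked" \
                else 1 - marked_strain
            n_called += 1
            n_correct += int(strain_idx == true_s)
            r = tirf_widefield_ratio(tirf, wf, m, (bg_t, bg_w))
            recs.append((f"strain{strain_idx + 1}", call, r.ratio))
        frames.append(pd.DataFrame(recs,
                                   columns=["strain", "marker_call", "ratio"]))
    pd.concat(frames).to_csv(out / "ratios.csv", index=False)
    pooled = paired_ratio_experiment(frames[0], frames[1])
    result = {
        "per_strain": {k: asdict(v) for k, v in pooled["per_strain"].items()},
        "consistency": pooled["consistency"],
        "demultiplex_accuracy": n_correct / n_called if n_called else None,
    }
    if "comparison" in pooled:
        c = pooled["comparison"]
        result["comparison"] = {
            "U": c.u_statistic, "p": c.p_value, "test": c.test_name}
    return result


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the configured stages and write the JSON summary.

    ``config`` may contain sections ``geometry``, ``tracking``,
    ``filaments`` and ``ratio``; only the sections present are run.  Any
    stage failure aborts with the stage name, leaving earlier outputs in
    place.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "rodmotion_version": __version__,
        "seed": seed,
    }
    stages = {
        "geometry": _stage_geometry,
        "tracking": lambda c: _stage_tracking(c, seed, out),
        "filaments": lambda c: _stage_filaments(c, seed, out),
        "ratio": lambda c: _stage_ratio(c, seed, out),
    }
    for name, fn in stages.items():
        if name not in config:
            continue
        log.info("running stage %s", name)
        try:
            summary[name] = fn(config[name])
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
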