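"""Stage orchestration: each stage reads/writes the interchange files and
records per-stage record counts in a run manifest, so cohort accounting
(how many birds/fixes/sites each filter removed) is reproducible on any
input."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._geo import read_geojson, write_geojson
from .chronology import arrival_stats, onset_latitude_regression, ownership_summary
from .config import PipelineConfig
from .sma import (EndmemberSet, HabitatMap, classify_flooded, composite_water_fraction,
                  polygonize_flooded, read_stack, water_fraction_raster)
from .segmentation import segment_track, segmentation_frame
from .selection import ManlySelectionModel, assign_ecoregion, assign_point_class, site_table
from .stopovers import detect_stopovers, sites_frame
from .synthetic import SimConfig, simulate_cohort
from .tracks import fall_window, read_tracks

logger = logging.getLogger(__name__)


class Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig):
        self.path = Path(outdir) / "MANIFEST.json"
        cfg = json.dumps(asdict(config), sort_keys=True, default=str)
        self.data = {
            "version": __version__,
            "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
            "seed": config.seed,
            "stages": {},
            "status": "running",
        }

    def record(self, stage: str, **counts):
        self.data["stages"][stage] = counts
        self.write()

    def finish(self, ok: bool):
        self.data["status"] = "ok" if ok else "failed"
        self.write()

    def write(self):
        self.path.write_text(json.dumps(self.data, indent=2, default=str))


def _require(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"missing input file: {p}")
    return p


def stage_simulate(config: PipelineConfig, outdir: Path, manifest: Manifest):
    cohort = simulate_cohort(SimConfig(seed=config.seed, n_birds=config.n_birds))
    paths = cohort.write(outdir)
    config.scene_paths = [str(paths[k]) for k in paths if str(k).startswith("scene_")]
    manifest.record("simulate", n_birds=len(cohort.tracks),
                    n_fixes=int(sum(len(t) for t in cohort.tracks)))
    return cohort


def stage_segment(config: PipelineConfig, outdir: Path, manifest: Manifest):
    tracks = read_tracks(_require(Path(outdir) / config.tracks_csv))
    windowed = [fall_window(t) for t in tracks]
    kept = [t for t in windowed if len(t) > 0]
    segs = [segment_track(t, config.r_local_km, config.r_migrant_km,
                          config.max_departure_gap_h, config.min_residency_days)
            for t in kept]
    df = segmentation_frame(segs, kept)
    df.to_csv(Path(outdir) / "segmentation.csv", index=False)
    manifest.record(
        "segment",
        n_tracks=len(tracks),
        n_empty_fall_window=len(tracks) - len(kept),
        n_migrants=int(df["is_migrant"].sum()),
        n_complete=int(df["complete"].sum()),
    )
    return kept, segs


def stage_stopovers(config: PipelineConfig, outdir: Path, manifest: Manifest):
    kept, segs = stage_segment(config, outdir, manifest)
    all_sites, all_tracks = [], {}
    use_rows = []
    for trk, seg in zip(kept, segs):
        if not seg.is_migrant or seg.departure is None:
            continue
        t_end = seg.terminus.arrival_time if seg.terminus else trk.t[-1] + pd.Timedelta(seconds=1)
        mask = (trk.t >= seg.departure.departure_time) & (trk.t < t_end)
        sub = trk.slice(np.asarray(mask))
        if len(sub) == 0:
            continue
        sites = detect_stopovers(
            sub, config.nn_threshold_km, config.window_h, config.flight_speed_kmh,
            config.min_use_fixes, config.min_span_h, config.buffer_km,
        )
        all_tracks[trk.bird_id] = sub
        all_sites.extend(sites)
        for s in sites:
            for i in s.use_index:
                use_rows.append(
                    {"site_id": s.site_id, "bird_id": s.bird_id,
                     "timestamp": sub.t[i].isoformat(), "lon": sub.lon[i], "lat": sub.lat[i]}
                )
    sf = sites_frame(all_sites)
    sf.to_csv(Path(outdir) / "sites.csv", index=False)
    write_geojson(
        Path(outdir) / "sites.geojson",
        [s.polygon for s in all_sites],
        [
            {"site_id": s.site_id, "bird_id": s.bird_id,
             "arrival_time": s.arrival_time.isoformat(),
             "departure_time": s.departure_time.isoformat(),
             "n_use_fixes": s.n_use_fixes}
            for s in all_sites
        ],
    )
    pd.DataFrame(use_rows, columns=["site_id", "bird_id", "timestamp", "lon", "lat"]).to_csv(
        Path(outdir) / "use_points.csv", index=False
    )
    manifest.record("stopovers", n_sites=len(all_sites), n_use_points=len(use_rows))
    return all_sites, all_tracks


def stage_sma(config: PipelineConfig, outdir: Path, manifest: Manifest):
    if not config.scene_paths:
        raise FileNotFoundError("missing input file: no reflectance scenes configured")
    endmembers = EndmemberSet.read_csv(_require(Path(outdir) / config.endmembers_csv))
    rasters = []
    for p in config.scene_paths:
        stack, mask, transform, origin = read_stack(_require(p))
        rasters.append(water_fraction_raster(stack, mask, endmembers, transform, origin))
    mean = composite_water_fraction(rasters)
    flooded = classify_flooded(mean, config.flood_threshold)
    polys = polygonize_flooded(flooded, mean.transform, config.min_unit_ha)
    proj = mean.projection()
    write_geojson(
        Path(outdir) / "flooded.geojson",
        [proj.unproject(p) for p in polys],
        [{"flooded_id": i} for i in range(len(polys))],
    )
    np.savetxt(Path(outdir) / "water_fraction.csv", mean.data, delimiter=",")
    manifest.record("sma", n_scenes=len(rasters), n_flooded_polygons=len(polys),
                    n_flooded_pixels=int(flooded.sum()))
    return mean, flooded, polys


def stage_select(config: PipelineConfig, outdir: Path, manifest: Manifest):
    sites, tracks = stage_stopovers(config, outdir, manifest)
    geoms, props = read_geojson(_require(Path(outdir) / config.habitat_map_geojson))
    hmap = HabitatMap(
        geoms, [p["class"] for p in props], [p.get("ownership", "private") for p in props]
    )
    eco_geoms, eco_props = read_geojson(_require(Path(outdir) / config.ecoregions_geojson))
    eco_names = [p.get("NA_L2NAME") or p.get("NA_L1NAME") or "" for p in eco_props]
    tables, strata = [], []
    for s in sites:
        tables.append(site_table(s, tracks[s.bird_id], hmap, config.snap_m))
        region = assign_ecoregion(s, eco_geoms, eco_names, config.ecoregion_merges)
        strata.append(region if region is not None else "unassigned")
    res = ManlySelectionModel(tables, strata).fit(config.alpha, config.low_avail_frac)
    res.frame.to_csv(Path(outdir) / "selection.csv", index=False)
    res.chisq.to_csv(Path(outdir) / "selection_chisq.csv", index=False)
    manifest.record("select", n_sites=len(tables),
                    n_strata=int(res.frame["stratum"].nunique()) - 1)
    return res, sites, tracks, hmap, strata


def stage_chronology(config: PipelineConfig, outdir: Path, manifest: Manifest):
    res, sites, tracks, hmap, strata = stage_select(config, outdir, manifest)
    seg_df = pd.read_csv(Path(outdir) / "segmentation.csv")
    mig = seg_df[seg_df["is_migrant"] & seg_df["departure_doy"].notna()]
    regression = onset_latitude_regression(mig["departure_doy"], mig["departure_lat"])
    pd.DataFrame([regression]).to_csv(Path(outdir) / "onset_regression.csv", index=False)
    arrivals = arrival_stats(
        pd.Series([s.arrival_doy for s in sites]), pd.Series(strata)
    )
    arrivals.to_csv(Path(outdir) / "arrival_stats.csv", index=False)
    # ownership of every nonflight use point
    owners = []
    from ._geo import LocalProjection

    for s in sites:
        aeqd = LocalProjection(*s.centroid, "aeqd")
        projected = [aeqd.project(p) for p in hmap.polygons]
        trk = tracks[s.bird_id]
        for i in s.use_index:
            pt_cls = assign_point_class(trk.lon[i], trk.lat[i], hmap, aeqd,
                                        config.snap_m, _projected=projected)
            # ownership of the polygon actually containing/snapped: use the
            # covering polygon's ownership, defaulting private
            own = "private"
            from shapely.geometry import Point

            p = Point(*aeqd.forward(trk.lon[i], trk.lat[i]))
            best_d = np.inf
            for g, cls, ow in zip(projected, hmap.classes, hmap.ownership):
                if cls != pt_cls:
                    continue
                d = g.distance(p)
                if d < best_d:
                    best_d, own = d, ow
            owners.append(own)
    pct_private = ownership_summary(np.array(owners))
    pd.DataFrame([{"pct_private": pct_private, "n_use_points": len(owners)}]).to_csv(
        Path(outdir) / "ownership.csv", index=False
    )
    manifest.record("chronology", n_regions=len(arrivals),
                    pct_private=float(pct_private), slope=regression["slope"])
    return arrivals, regression, pct_private


STAGES = ("simulate", "segment", "stopovers", "sma", "select", "chronology", "all")


def run(stage: str, config: PipelineConfig, outdir) -> None:
    """Run one pipeline stage (or `all`); writes artifacts and MANIFEST.json."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir, config)
    manifest.write()
    try:
        if stage == "simulate":
            stage_simulate(config, outdir, manifest)
        elif stage == "segment":
            stage_segment(config, outdir, manifest)
        elif stage == "stopovers":
            stage_stopovers(config, outdir, manifest)
        elif stage == "sma":
            stage_sma(config, outdir, manifest)
        elif stage == "select":
            stage_select(config, outdir, manifest)
        elif stage == "chronology":
            stage_chronology(config, outdir, manifest)
        else:
            stage_simulate(config, outdir, manifest)
            stage_sma(config, outdir, manifest)
            stage_chronology(config, outdir, manifest)
    except Exception:
        manifest.finish(ok=False)
        raise
    manifest.finish(ok=True)
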