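"""Synthetic cohorts with known truth for end-to-end testing.

Emulates the study's data-generating conditions: GPS fixes at mixed
intervals (15 min-6 h), two-regime movement (local movement at walking/
swimming speed below ~5 km/h versus directed migratory flight at the median
teal flight speed of 36.5 km/h), fall onset around late September,
scheduled stopovers inside habitat patches where fixes sample habitat
classes with known multinomial preferences, and reflectance imagery formed
as known linear mixtures of endmember spectra plus Gaussian noise.

All randomness derives from one seed through per-bird counter-based
substreams, so equal seeds give byte-identical outputs. Truth (onset times,
stopover intervals and centroids, per-class use counts, per-pixel water
fractions) is recorded alongside the emitted data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union

from ._geo import LocalProjection, write_geojson
from .sma import EndmemberSet, HabitatMap, write_stack
from .tracks import Track, write_tracks

#: Default synthetic endmembers: Landsat 8 OLI bands 2-7 reflectance.
DEFAULT_ENDMEMBERS = EndmemberSet(
    np.array(
        [
            # water  vegetation  soil
            [0.060, 0.040, 0.100],   # B2 blue
            [0.050, 0.070, 0.140],   # B3 green
            [0.040, 0.050, 0.180],   # B4 red
            [0.020, 0.450, 0.250],   # B5 NIR
            [0.010, 0.250, 0.320],   # B6 SWIR1
            [0.005, 0.120, 0.280],   # B7 SWIR2
        ]
    ),
    ["water", "vegetation", "soil"],
    water_index=0,
)

DEFAULT_CLASS_PROPORTIONS = {
    "dry nonhabitat": 0.40,
    "dry agriculture": 0.15,
    "wet agriculture": 0.15,
    "natural wetland": 0.12,
    "managed wetland": 0.10,
    "riparian": 0.08,
}

DEFAULT_USE_PROBS = {
    "wet agriculture": 0.35,
    "natural wetland": 0.25,
    "managed wetland": 0.20,
    "riparian": 0.15,
    "dry nonhabitat": 0.04,
    "dry agriculture": 0.01,
}

#: Raw ecoregion names per route node, south to north; the first exercises
#: the configured merge into Cold Deserts.
NODE_ECOREGIONS = (
    "Northwestern Forested Mountains",
    "Cold Deserts",
    "Warm Deserts",
    "Southern Semi-arid Highlands",
    "Tropical Forests",
    "Great Plains",
)


@dataclass
class SimConfig:
    seed: int = 0
    n_birds: int = 20
    year: int = 2018
    # fix schedule (hours); stopover/terminus phases use only intervals >= 1 h
    # so within-patch speeds stay below the walking bound
    fix_intervals_h: tuple = (0.25, 0.5, 1.0, 2.0, 3.0, 6.0)
    fix_interval_weights: tuple = (0.10, 0.15, 0.25, 0.20, 0.20, 0.10)
    # movement regimes
    migration_speed_kmh: float = 36.5
    local_speed_kmh: float = 5.0
    summer_radius_km: float = 30.0
    # phenology: median departure 28 September (day of year 271)
    onset_doy_mean: float = 271.0
    onset_doy_sd: float = 8.0
    # stopover schedule
    n_stopovers: int = 3
    stopover_duration_days: float = 2.0
    stopover_spacing_km: float = 250.0
    terminus_residency_days: float = 10.0
    # landscape
    origin_lonlat: tuple = (-119.5, 42.5)
    cell_km: float = 0.8
    node_half_cells: int = 9              # node frame = (2n)² cells
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    use_probs: dict = field(default_factory=lambda: dict(DEFAULT_USE_PROBS))
    private_prob: float = 0.725
    # imagery
    endmembers: EndmemberSet = field(default_factory=lambda: DEFAULT_ENDMEMBERS)
    snr: float = 100.0
    n_scenes: int = 2
    raster_size_px: int = 100

    def __post_init__(self):
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if abs(sum(self.use_probs.values()) - 1.0) > 1e-9:
            raise ValueError("use probabilities must sum to 1")
        if self.stopover_spacing_km <= 4 * self.cell_km * self.node_half_cells:
            raise ValueError("stopover spacing must exceed twice the node frame size")

    def bird_rng(self, k: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, k]))


@dataclass
class LandscapeNode:
    index: int
    center_xy: tuple[float, float]        # cohort-frame meters
    centroid_lonlat: tuple[float, float]
    cell_class: dict                      # (row, col) -> class name


@dataclass
class Landscape:
    proj: LocalProjection                 # cohort AEQD frame
    nodes: list[LandscapeNode]
    habitat_map: HabitatMap               # lon/lat class+ownership multipolygons
    realized_proportions: pd.DataFrame    # per node, per class
    ecoregion_polys: list
    ecoregion_names: list[str]


@dataclass
class Cohort:
    config: SimConfig
    landscape: Landscape
    tracks: list[Track]
    truth_birds: pd.DataFrame             # onset, origin, terminus truth per bird
    truth_stopovers: pd.DataFrame         # scheduled stopover intervals/centroids
    truth_use: pd.DataFrame               # per bird/node true class-use counts
    scenes: list                          # (stack, mask) reflectance scenes, node 0
    truth_fractions: np.ndarray           # per-pixel true water fraction
    scene_transform: tuple
    scene_origin: tuple

    def write(self, outdir) -> dict:
        """Write the pipeline-readable files plus truth_*.csv; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["tracks"] = outdir / "tracks.csv"
        write_tracks(paths["tracks"], self.tracks)
        hm = self.landscape.habitat_map
        paths["habitat_map"] = outdir / "habitat_map.geojson"
        write_geojson(
            paths["habitat_map"], hm.polygons,
            [{"class": c, "ownership": o} for c, o in zip(hm.classes, hm.ownership)],
        )
        paths["ecoregions"] = outdir / "ecoregions.geojson"
        write_geojson(
            paths["ecoregions"], self.landscape.ecoregion_polys,
            [{"NA_L2NAME": n} for n in self.landscape.ecoregion_names],
        )
        paths["endmembers"] = outdir / "endmembers.csv"
        self.config.endmembers.write_csv(paths["endmembers"])
        for i, (stack, mask) in enumerate(self.scenes):
            p = outdir / f"scene_{i}.tif"
            write_stack(p, stack, mask, self.scene_transform, self.scene_origin)
            paths[f"scene_{i}"] = p
        paths["truth_birds"] = outdir / "truth_birds.csv"
        self.truth_birds.to_csv(paths["truth_birds"], index=False)
        paths["truth_stopovers"] = outdir / "truth_stopovers.csv"
        self.truth_stopovers.to_csv(paths["truth_stopovers"], index=False)
        paths["truth_use"] = outdir / "truth_use.csv"
        self.truth_use.to_csv(paths["truth_use"], index=False)
        np.savetxt(outdir / "truth_water_fraction.csv", self.truth_fractions, delimiter=",")
        paths["truth_water_fraction"] = outdir / "truth_water_fraction.csv"
        return paths


# ---------------------------------------------------------------------------
# landscape

def _exact_class_counts(proportions: dict, n_cells: int) -> dict:
    """Largest-remainder apportionment of cells to classes."""
    items = list(proportions.items())
    raw = np.array([p * n_cells for _, p in items])
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n_cells - counts.sum()]:
        counts[i] += 1
    return {c: int(k) for (c, _), k in zip(items, counts)}


def _core_layout(use_probs: dict) -> list[str]:
    """Classes of the inner 3x3 cell block: every used class present so that
    class-conditional sampling near the centroid is always feasible."""
    classes = sorted(use_probs, key=use_probs.get, reverse=True)
    core = list(classes)
    i = 0
    while len(core) < 9:
        core.append(classes[i % len(classes)])
        i += 1
    return core[:9]


def simulate_landscape(config: SimConfig) -> Landscape:
    """Shared cohort landscape: a ladder of habitat nodes along the route.

    Each node is a square frame of `cell_km` cells whose classes realize the
    configured proportions exactly (largest-remainder apportionment, then a
    seeded shuffle), except that the inner 3x3 block is laid out so every
    used class occurs next to the node centroid. Cell ownership is Bernoulli
    (private_prob). Per class x ownership, cells are unioned into one
    multipolygon and georeferenced through the cohort projection.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10_000]))
    proj = LocalProjection(*config.origin_lonlat, "aeqd")
    n_nodes = config.n_stopovers + 1          # stopovers + terminus
    spacing_m = config.stopover_spacing_km * 1000.0
    cell_m = config.cell_km * 1000.0
    half = config.node_half_cells
    side = 2 * half

    nodes = []
    polys, classes, owners = [], [], []
    realized = []
    for k in range(n_nodes):
        cx = rng.uniform(-0.1, 0.1) * spacing_m
        cy = -(k + 1) * spacing_m
        counts = _exact_class_counts(config.class_proportions, side * side)
        core = _core_layout(config.use_probs)
        cells = [(r, c) for r in range(side) for c in range(side)]
        core_cells = [(half + dr, half + dc) for dr in range(-1, 2) for dc in range(-1, 2)]
        cell_class = {}
        for cell, cls in zip(core_cells, core):
            cell_class[cell] = cls
            counts[cls] -= 1
            if counts[cls] < 0:
                raise ValueError(f"class {cls!r} proportion too small for the core block")
        rest = [cell for cell in cells if cell not in cell_class]
        pool = [cls for cls, n in counts.items() for _ in range(n)]
        rng.shuffle(rest)
        for cell, cls in zip(rest, pool):
            cell_class[cell] = cls

        node_lon, node_lat = (float(v) for v in proj.inverse(cx, cy))
        nodes.append(LandscapeNode(k, (cx, cy), (node_lon, node_lat), cell_class))
        groups: dict[tuple[str, str], list] = {}
        for (r, c), cls in cell_class.items():
            own = "private" if rng.random() < config.private_prob else "public"
            x0 = cx + (c - half) * cell_m
            y0 = cy + (r - half) * cell_m
            groups.setdefault((cls, own), []).append(box(x0, y0, x0 + cell_m, y0 + cell_m))
        for (cls, own), boxes in sorted(groups.items()):
            polys.append(proj.unproject(unary_union(boxes)))
            classes.append(cls)
            owners.append(own)
        tot = side * side
        for cls in config.class_proportions:
            realized.append(
                {"node": k, "class": cls,
                 "proportion": sum(1 for v in cell_class.values() if v == cls) / tot}
            )

    # ecoregion bands: one latitude band per node (plus generous margins)
    eco_polys, eco_names = [], []
    for k, node in enumerate(nodes):
        lon0, lat0 = node.centroid_lonlat
        band = spacing_m / 2 / 111_000.0      # half-spacing in degrees latitude
        eco_polys.append(box(lon0 - 4.0, lat0 - band, lon0 + 4.0, lat0 + band))
        eco_names.append(NODE_ECOREGIONS[k % len(NODE_ECOREGIONS)])

    return Landscape(
        proj=proj,
        nodes=nodes,
        habitat_map=HabitatMap(polys, classes, owners),
        realized_proportions=pd.DataFrame(realized),
        ecoregion_polys=eco_polys,
        ecoregion_names=eco_names,
    )


# ---------------------------------------------------------------------------
# tracks

def _sample_dt(rng, config, min_h=None) -> float:
    ivals = np.array(config.fix_intervals_h)
    w = np.array(config.fix_interval_weights, float)
    if min_h is not None:
        keep = ivals >= min_h
        ivals, w = ivals[keep], w[keep]
    return float(rng.choice(ivals, p=w / w.sum()))


def _class_cells_near(node: LandscapeNode, cls: str, half: int, radius_cells: float):
    out = [
        (r, c)
        for (r, c), v in node.cell_class.items()
        if v == cls and math.hypot(r - half, c - half) <= radius_cells
    ]
    return out


def simulate_track(config: SimConfig, landscape: Landscape, bird_idx: int):
    """One bird: bounded summer walk, directed flights, scheduled stopovers.

    Returns (Track, bird truth dict, stopover truth rows, use truth rows).
    Stopover fixes sample a habitat class from the true use probabilities
    and land uniformly inside a cell of that class near the node centroid.
    """
    rng = config.bird_rng(bird_idx)
    bird_id = f"bird{bird_idx:03d}"
    proj = landscape.proj
    cell_m = config.cell_km * 1000.0
    half = config.node_half_cells
    classes = list(config.use_probs)
    probs = np.array([config.use_probs[c] for c in classes])

    # origin near the cohort frame center
    ox, oy = rng.uniform(-10_000, 10_000, 2)
    t0 = pd.Timestamp(f"{config.year}-08-01", tz="UTC") + pd.Timedelta(hours=rng.uniform(0, 6))
    onset_doy = rng.normal(config.onset_doy_mean, config.onset_doy_sd)
    onset = pd.Timestamp(f"{config.year}-01-01", tz="UTC") + pd.Timedelta(days=onset_doy - 1)

    times, xs, ys = [t0], [ox], [oy]
    truth_classes: list[tuple] = []       # (node, class) per stopover use fix

    # -- summer: bounded random walk at walking speed
    t, x, y = t0, ox, oy
    rmax = config.summer_radius_km * 1000.0
    while True:
        dt = _sample_dt(rng, config)
        if t + pd.Timedelta(hours=dt) >= onset:
            break
        t = t + pd.Timedelta(hours=dt)
        step = rng.uniform(0, config.local_speed_kmh * 0.9) * dt * 1000.0
        theta = rng.uniform(0, 2 * math.pi)
        nx, ny = x + step * math.cos(theta), y + step * math.sin(theta)
        if math.hypot(nx - ox, ny - oy) > rmax:   # head back toward the origin
            norm = math.hypot(ox - x, oy - y) or 1.0
            nx, ny = x + step * (ox - x) / norm, y + step * (oy - y) / norm
        x, y = nx, ny
        times.append(t)
        xs.append(x)
        ys.append(y)

    def fly_to(t, x, y, tx, ty):
        """Directed flight at migration speed; returns arrival time."""
        v = config.migration_speed_kmh * 1000.0   # m/h
        while True:
            remaining = math.hypot(tx - x, ty - y)
            dt = _sample_dt(rng, config)
            if remaining <= v * dt:
                t = t + pd.Timedelta(hours=remaining / v)
                x, y = tx, ty
                times.append(t)
                xs.append(x)
                ys.append(y)
                return t, x, y
            t = t + pd.Timedelta(hours=dt)
            frac = v * dt / remaining
            x, y = x + frac * (tx - x), y + frac * (ty - y)
            times.append(t)
            xs.append(x)
            ys.append(y)

    def residence(t, node: LandscapeNode, days: float, record_node: int):
        nonlocal x, y
        end = t + pd.Timedelta(days=days)
        while True:
            dt = _sample_dt(rng, config, min_h=1.0)
            if t + pd.Timedelta(hours=dt) > end:
                break
            t = t + pd.Timedelta(hours=dt)
            cls = classes[rng.choice(len(classes), p=probs)]
            cands = _class_cells_near(node, cls, half, 1.9)   # inner 3x3 guaranteed
            r, c = cands[rng.integers(len(cands))]
            x = node.center_xy[0] + (c - half + rng.uniform(0, 1)) * cell_m
            y = node.center_xy[1] + (r - half + rng.uniform(0, 1)) * cell_m
            times.append(t)
            xs.append(x)
            ys.append(y)
            truth_classes.append((record_node, cls))
        return t

    # -- migration: flights between scheduled nodes, then terminus residence
    t = onset
    stop_rows = []
    for k, node in enumerate(landscape.nodes):
        is_terminus = k == len(landscape.nodes) - 1
        t, x, y = fly_to(t, x, y, *node.center_xy)
        arr = t
        days = config.terminus_residency_days if is_terminus else config.stopover_duration_days
        t = residence(t, node, days, k)
        stop_rows.append(
            {
                "bird_id": bird_id,
                "node": k,
                "is_terminus": is_terminus,
                "t_start": arr,
                "t_end": times[-1],
                "lon": node.centroid_lonlat[0],
                "lat": node.centroid_lonlat[1],
            }
        )

    lon, lat = proj.inverse(np.array(xs), np.array(ys))
    track = Track(bird_id, pd.DatetimeIndex(times), lon, lat)
    dts = np.diff(pd.DatetimeIndex(times).asi8) / 3.6e12
    bird_truth = {
        "bird_id": bird_id,
        "onset_time": onset,
        "onset_doy": float(onset_doy),
        "origin_lon": float(lon[0]),
        "origin_lat": float(lat[0]),
        "max_fix_interval_h": float(dts.max()),
        "terminus_lon": landscape.nodes[-1].centroid_lonlat[0],
        "terminus_lat": landscape.nodes[-1].centroid_lonlat[1],
    }
    use_rows = [
        {"bird_id": bird_id, "node": node, "class": cls, "n": n}
        for (node, cls), n in pd.Series(truth_classes).value_counts().sort_index().items()
    ]
    return track, bird_truth, stop_rows, use_rows


# ---------------------------------------------------------------------------
# imagery

def simulate_scenes(config: SimConfig, landscape: Landscape):
    """Reflectance scenes over node 0 as known linear mixtures.

    Per pixel, the true water fraction depends on the underlying habitat
    cell (wet classes mostly flooded, dry classes nearly dry); the remaining
    fraction splits between vegetation and soil. Each scene adds independent
    zero-mean Gaussian noise at the configured SNR and an independent
    validity mask. Returns (scenes, truth_fractions, transform, origin).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 20_000]))
    node = landscape.nodes[0]
    n = config.raster_size_px
    px = 30.0
    cell_m = config.cell_km * 1000.0
    half = config.node_half_cells
    x0 = node.center_xy[0] - n * px / 2.0
    ytop = node.center_xy[1] + n * px / 2.0
    transform = (x0, ytop, px)

    wet = {"wet agriculture", "natural wetland", "managed wetland", "riparian",
           "lake and reservoir", "tidal", "wastewater", "golf and urban",
           "ocean", "shrimp farm"}
    frac = np.empty((n, n))
    for r in range(n):
        for c in range(n):
            xc = x0 + (c + 0.5) * px
            yc = ytop - (r + 0.5) * px
            cr = int(np.floor((yc - node.center_xy[1]) / cell_m)) + half
            cc = int(np.floor((xc - node.center_xy[0]) / cell_m)) + half
            cls = node.cell_class.get((cr, cc), "dry nonhabitat")
            frac[r, c] = rng.uniform(0.2, 1.0) if cls in wet else rng.uniform(0.0, 0.05)
    veg_share = rng.uniform(0.0, 1.0, (n, n))
    E = config.endmembers.spectra
    fractions = np.stack([frac, (1 - frac) * veg_share, (1 - frac) * (1 - veg_share)])
    clean = np.einsum("be,erc->brc", E, fractions)

    scenes = []
    for _ in range(config.n_scenes):
        sigma = np.sqrt(np.mean(clean**2)) / config.snr
        noisy = clean + rng.normal(0.0, sigma, clean.shape)
        mask = rng.random((n, n)) > 0.1       # ~10% of pixels cloud-masked
        scenes.append((noisy, mask))
    return scenes, frac, transform, tuple(config.origin_lonlat)


# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> Cohort:
    """Full cohort: shared landscape, n_birds tracks, imagery, truth tables."""
    landscape = simulate_landscape(config)
    tracks, bird_rows, stop_rows, use_rows = [], [], [], []
    for k in range(config.n_birds):
        trk, bt, st, ut = simulate_track(config, landscape, k)
        tracks.append(trk)
        bird_rows.append(bt)
        stop_rows.extend(st)
        use_rows.extend(ut)
    scenes, frac, transform, origin = simulate_scenes(config, landscape)
    cols_b = ["bird_id", "onset_time", "onset_doy", "origin_lon", "origin_lat",
              "max_fix_interval_h", "terminus_lon", "terminus_lat"]
    cols_s = ["bird_id", "node", "is_terminus", "t_start", "t_end", "lon", "lat"]
    cols_u = ["bird_id", "node", "class", "n"]
    return Cohort(
        config=config,
        landscape=landscape,
        tracks=tracks,
        truth_birds=pd.DataFrame(bird_rows, columns=cols_b),
        truth_stopovers=pd.DataFrame(stop_rows, columns=cols_s),
        truth_use=pd.DataFrame(use_rows, columns=cols_u),
        scenes=scenes,
        truth_fractions=frac,
        scene_transform=transform,
        scene_origin=origin,
    )
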