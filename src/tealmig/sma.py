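"""Surface-water mapping by linear spectral mixture analysis (SMA).

Each 30-m pixel's reflectance spectrum (Landsat 8 OLI bands 2-7, i.e. all
visible/NIR/SWIR bands excluding coastal aerosol) is modeled as a convex
combination of pure endmember spectra. The water endmember's coefficient is
the flooded fraction of the pixel, which resolves small and shallowly
flooded emergent wetlands that a hard classifier would miss. Per-scene
fractions are averaged over the 1 Aug-31 Oct compositing window, pixels
with mean water fraction >10% are classified as flooded, flooded regions
are traced to polygons (8-connected, 0.25 ha minimum mapped unit), and the
polygons are typed from a user-supplied label layer to build the 12-class
habitat map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.optimize import nnls
from shapely.geometry import box
from shapely.ops import unary_union

from ._geo import LocalProjection

#: The twelve habitat classes of the analysis.
HABITAT_CLASSES = (
    "dry agriculture",
    "dry nonhabitat",
    "golf and urban",
    "lake and reservoir",
    "managed wetland",
    "natural wetland",
    "ocean",
    "riparian",
    "shrimp farm",
    "tidal",
    "wastewater",
    "wet agriculture",
)
#: Classes that are flooded/wet (everything except the two dry fills).
WET_CLASSES = tuple(c for c in HABITAT_CLASSES if c not in ("dry agriculture", "dry nonhabitat"))

FLOOD_THRESHOLD = 0.10      # mean water fraction above which a pixel is flooded
MIN_UNIT_HA = 0.25          # minimum mapped wetland unit
PIXEL_M = 30.0              # Landsat pixel size


@dataclass
class EndmemberSet:
    """Pure-surface reference spectra, one column per endmember."""

    spectra: np.ndarray          # (n_bands, n_endmembers) reflectance
    names: list[str]
    water_index: int

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("endmember spectra must be a 2-D (bands x endmembers) matrix")
        if np.any(self.spectra < 0):
            raise ValueError("endmember reflectances must be non-negative")
        if np.linalg.matrix_rank(self.spectra) < self.spectra.shape[1]:
            raise ValueError("endmember matrix is rank-deficient; columns must be distinct")

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[0]

    @classmethod
    def read_csv(cls, path, water_name: str = "water") -> "EndmemberSet":
        """CSV with rows = bands, columns = endmembers."""
        df = pd.read_csv(path)
        names = list(df.columns)
        if water_name not in names:
            raise ValueError(f"{path}: no '{water_name}' endmember column")
        return cls(df.to_numpy(float), names, names.index(water_name))

    def write_csv(self, path) -> None:
        pd.DataFrame(self.spectra, columns=self.names).to_csv(path, index=False)


@dataclass
class RasterGrid:
    """A single-band raster on a local projected grid (meters, 30-m pixels).

    `transform` is (x0, y0, pixel): x of the left edge, y of the TOP edge,
    pixel size; row r / col c covers x0+c*px..x0+(c+1)*px, y0-(r+1)*px..y0-r*px.
    `origin_lonlat` is the center of the local azimuthal-equidistant frame.
    """

    data: np.ndarray
    mask: np.ndarray             # True = valid
    transform: tuple[float, float, float]
    origin_lonlat: tuple[float, float]

    def projection(self) -> LocalProjection:
        return LocalProjection(*self.origin_lonlat, "aeqd")


def unmix_pixel(spectrum: np.ndarray, endmembers: EndmemberSet) -> np.ndarray:
    """Fully constrained unmixing of one spectrum: f >= 0, sum(f) = 1.

    Solved as non-negative least squares on the system augmented with a
    heavily weighted sum-to-one row, then renormalized exactly."""
    return unmix_image(np.asarray(spectrum, float).reshape(1, -1), endmembers)[0]


def unmix_image(spectra: np.ndarray, endmembers: EndmemberSet) -> np.ndarray:
    """FCLS unmixing of (n_pixels, n_bands) spectra -> (n_pixels, n_end) fractions."""
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[1] != endmembers.n_bands:
        raise ValueError(
            f"spectra have {spectra.shape[1]} bands, endmembers {endmembers.n_bands}"
        )
    E = endmembers.spectra
    delta = 1e3 * max(1.0, float(np.abs(E).max()))
    A = np.vstack([E, delta * np.ones((1, E.shape[1]))])
    out = np.empty((spectra.shape[0], E.shape[1]))
    b = np.empty(E.shape[0] + 1)
    b[-1] = delta
    for i in range(spectra.shape[0]):
        b[:-1] = spectra[i]
        f, _ = nnls(A, b)
        s = f.sum()
        out[i] = f / s if s > 0 else f
    return out


def water_fraction_raster(
    stack: np.ndarray, mask: np.ndarray, endmembers: EndmemberSet,
    transform=(0.0, 0.0, PIXEL_M), origin_lonlat=(0.0, 0.0),
) -> RasterGrid:
    """Unmix a (bands, rows, cols) reflectance stack into a water-fraction grid."""
    nb, nr, nc = stack.shape
    frac = np.zeros((nr, nc))
    valid = np.asarray(mask, bool)
    pix = stack.reshape(nb, -1).T[valid.ravel()]
    if len(pix):
        frac.ravel()[np.flatnonzero(valid.ravel())] = unmix_image(pix, endmembers)[
            :, endmembers.water_index
        ]
    return RasterGrid(frac, valid, tuple(transform), tuple(origin_lonlat))


def composite_water_fraction(scenes: list[RasterGrid]) -> RasterGrid:
    """Per-pixel mean water fraction over valid scenes (the seasonal composite)."""
    if not scenes:
        raise ValueError("no scenes to composite")
    ref = scenes[0]
    for s in scenes[1:]:
        if s.data.shape != ref.data.shape or s.transform != ref.transform:
            raise ValueError("scenes are not co-registered")
    stack = np.stack([s.data for s in scenes])
    masks = np.stack([s.mask for s in scenes])
    n_valid = masks.sum(axis=0)
    total = np.where(masks, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_valid > 0, total / np.maximum(n_valid, 1), 0.0)
    return RasterGrid(mean, n_valid > 0, ref.transform, ref.origin_lonlat)


def classify_flooded(mean_fraction: RasterGrid, threshold: float = FLOOD_THRESHOLD) -> np.ndarray:
    """Boolean flooded raster: valid pixels with fraction strictly > threshold."""
    return (mean_fraction.data > threshold) & mean_fraction.mask


def polygonize_flooded(
    flooded: np.ndarray,
    transform=(0.0, 0.0, PIXEL_M),
    min_area_ha: float = MIN_UNIT_HA,
) -> list:
    """Trace 8-connected flooded components to polygons (projected meters),
    dropping components smaller than the minimum mapped unit."""
    labels, n = ndimage.label(np.asarray(flooded, bool), structure=np.ones((3, 3), int))
    x0, y0, px = transform
    min_m2 = min_area_ha * 1e4
    polys = []
    for k in range(1, n + 1):
        rows, cols = np.nonzero(labels == k)
        if len(rows) * px * px < min_m2:
            continue
        cells = [
            box(x0 + c * px, y0 - (r + 1) * px, x0 + (c + 1) * px, y0 - r * px)
            for r, c in zip(rows, cols)
        ]
        polys.append(unary_union(cells).buffer(0))
    return polys


@dataclass
class HabitatMap:
    """Typed habitat polygons (lon/lat) tiling each site's analysis frame."""

    polygons: list            # shapely geometries, lon/lat
    classes: list[str]
    ownership: list[str] = field(default_factory=list)   # "public" / "private"

    def __post_init__(self):
        bad = set(self.classes) - set(HABITAT_CLASSES)
        if bad:
            raise ValueError(f"unknown habitat class(es): {sorted(bad)}")
        if not self.ownership:
            self.ownership = ["private"] * len(self.polygons)

    def __len__(self):
        return len(self.polygons)

    def wet_entries(self):
        return [
            (i, p, c)
            for i, (p, c) in enumerate(zip(self.polygons, self.classes))
            if c in WET_CLASSES
        ]


def build_habitat_map(
    flooded_polys: list,
    label_polys: list,
    label_classes: list[str],
    frame,
    dry_ag_mask: list | None = None,
    label_ownership: list[str] | None = None,
) -> HabitatMap:
    """Assemble the habitat map for one analysis frame.

    Flooded polygons take the class (and ownership) of the label polygon with
    majority area overlap; flooded area with no label defaults to natural
    wetland. Unflooded area inside the dry-agriculture mask becomes dry
    agriculture; all remaining unflooded area becomes dry nonhabitat, so the
    map tiles the frame with no gaps. All geometries share one CRS (either
    lon/lat or a common projected frame).
    """
    if label_ownership is None:
        label_ownership = ["private"] * len(label_polys)
    polys, classes, owner = [], [], []
    for fp in flooded_polys:
        if not frame.contains(fp.buffer(-1e-9)):
            raise ValueError("analysis frame does not cover a flooded polygon")
        best, best_area = None, 0.0
        for lp, lc, lo in zip(label_polys, label_classes, label_ownership):
            a = fp.intersection(lp).area
            if a > best_area:
                best, best_area = (lc, lo), a
        if best is None:
            import warnings

            warnings.warn("flooded polygon outside label layer; typed as natural wetland", stacklevel=2)
            best = ("natural wetland", "private")
        polys.append(fp)
        classes.append(best[0])
        owner.append(best[1])
    flooded_union = unary_union(flooded_polys) if flooded_polys else None
    dry = frame if flooded_union is None else frame.difference(flooded_union)
    if dry_ag_mask:
        ag = dry.intersection(unary_union(dry_ag_mask))
        if not ag.is_empty:
            polys.append(ag)
            classes.append("dry agriculture")
            owner.append("private")
            dry = dry.difference(ag)
    if not dry.is_empty:
        polys.append(dry)
        classes.append("dry nonhabitat")
        owner.append("private")
    return HabitatMap(polys, classes, owner)


# -- raster I/O (plain multiband TIFF + JSON sidecar with the grid info) -----

def write_stack(path, stack: np.ndarray, mask: np.ndarray, transform, origin_lonlat) -> None:
    path = Path(path)
    arr = np.concatenate([np.asarray(stack, np.float32), np.asarray(mask, np.float32)[None]])
    tifffile.imwrite(path, arr, photometric="minisblack")
    meta = {"transform": list(transform), "origin_lonlat": list(origin_lonlat),
            "n_bands": int(stack.shape[0])}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_stack(path):
    path = Path(path)
    arr = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    nb = meta["n_bands"]
    return (
        arr[:nb].astype(float),
        arr[nb] > 0.5,
        tuple(meta["transform"]),
        tuple(meta["origin_lonlat"]),
    )
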