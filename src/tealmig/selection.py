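"""Manly design-III habitat selection at stopover sites.

Third-order selection (habitat components within a site) is measured with
Manly selectivity ratios under design III: availability is measured
separately for every sampling unit (stopover site). For habitat i and sites
j = 1..J with use counts u_ij, total use u_+j and availability proportions
pi_ij, the global selection ratio is

    w_i = (sum_j u_ij) / (sum_j u_+j * pi_ij)

with the across-site ratio-estimator variance

    var(w_i) = [J/(J-1)] * sum_j (u_ij - w_i e_ij)^2 / (sum_j e_ij)^2,
    e_ij = u_+j * pi_ij,

J counting sites where habitat i is available. Confidence intervals are
Bonferroni-adjusted normal intervals (z at alpha/(2K) for K habitats
tested), with the lower limit truncated at 0 since negative selection
ratios are impossible. Selection is indicated when LCL > 1, avoidance when
UCL < 1. Overall departure from proportional use is tested with the
log-likelihood chi-square G = 2 * sum u ln(u/e).

Because birds heavily use wetland edges, a use point that falls outside all
mapped wetland polygons but within 100 m of one is attributed to the
nearest wetland class before tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point
from shapely.strtree import STRtree

from ._geo import LocalProjection, geodesic_area_m2
from .sma import HABITAT_CLASSES, WET_CLASSES, HabitatMap
from .stopovers import StopoverSite
from .tracks import Track

#: Edge-snap radius (m): use points this close to a wetland take its class.
SNAP_M = 100.0
#: Availability share below which an unused habitat is "undetermined".
LOW_AVAIL_FRAC = 0.01

#: The study's ecoregion merges: small adjacent regions are pooled into the
#: six analysis regions to represent contiguous habitat and give workable
#: sample sizes.
DEFAULT_ECOREGION_MERGES = {
    "Northwestern Forested Mountains": "Cold Deserts",
    "Temperate Sierras": "Southern Semi-arid Highlands",
    "Tropical Dry Forests": "Tropical Forests",
    "Tropical Wet Forests": "Tropical Forests",
    "Baja Tropical Dry Forests": "Warm Deserts",
}

ANALYSIS_REGIONS = (
    "Cold Deserts",
    "Great Plains",
    "Mediterranean California",
    "Southern Semi-arid Highlands",
    "Tropical Forests",
    "Warm Deserts",
)


@dataclass
class SiteTable:
    """Use and availability for one stopover site over the 12 habitat classes."""

    site_id: str
    pi: np.ndarray            # availability proportions, sums to 1
    use: np.ndarray           # use counts (nonflight fixes) per class
    area_m2: float = np.nan   # site polygon area (for the low-availability rule)
    habitats: tuple = HABITAT_CLASSES

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.use = np.asarray(self.use, dtype=float)
        if self.pi.shape != self.use.shape or len(self.pi) != len(self.habitats):
            raise ValueError("pi/use must align with the habitat list")
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"site {self.site_id}: availability must be proportions summing to 1")

    @property
    def u_total(self) -> float:
        return float(self.use.sum())


def assign_point_class(
    lon: float,
    lat: float,
    habitat_map: HabitatMap,
    proj: LocalProjection | None = None,
    snap_m: float = SNAP_M,
    _projected: list | None = None,
) -> str:
    """Habitat class of a use point, with 100-m snapping to wetland edges.

    Inside a wet-class polygon -> that class. Otherwise, if the nearest
    wet-class polygon boundary is within snap_m, that polygon's class (ties
    broken by smaller polygon index). Otherwise the underlying dry class.
    """
    if proj is None:
        proj = LocalProjection(lon, lat, "aeqd")
    pt = Point(*proj.forward(lon, lat))
    geoms = _projected if _projected is not None else [proj.project(p) for p in habitat_map.polygons]
    wet = [(i, geoms[i]) for i, _, _ in habitat_map.wet_entries()]
    best_i, best_d = None, np.inf
    for i, g in wet:
        if g.covers(pt):
            return habitat_map.classes[i]
        d = g.distance(pt)
        if d < best_d - 1e-9:
            best_i, best_d = i, d
    if best_i is not None and best_d <= snap_m:
        return habitat_map.classes[best_i]
    # dry fallback: containing dry polygon, else generic dry nonhabitat
    for i, g in enumerate(geoms):
        if habitat_map.classes[i] not in WET_CLASSES and g.covers(pt):
            return habitat_map.classes[i]
    return "dry nonhabitat"


def site_table(
    site: StopoverSite, track: Track, habitat_map: HabitatMap, snap_m: float = SNAP_M
) -> SiteTable:
    """Availability from clipped class areas inside the 5-km site polygon
    (equal-area projection); use from snap-classified nonflight fixes."""
    if site.polygon is None:
        raise ValueError(f"site {site.site_id} has no polygon; run buffer_site first")
    lon0, lat0 = site.centroid
    ea = LocalProjection(lon0, lat0, "laea")
    frame = ea.project(site.polygon)
    if frame.area <= 0:
        raise ValueError(f"site {site.site_id}: zero-area polygon")
    areas = np.zeros(len(HABITAT_CLASSES))
    for poly, cls in zip(habitat_map.polygons, habitat_map.classes):
        a = ea.project(poly).intersection(frame).area
        areas[HABITAT_CLASSES.index(cls)] += a
    # unlabeled area inside the site frame counts as dry nonhabitat
    gap = frame.area - areas.sum()
    if gap > 1e-6 * frame.area:
        areas[HABITAT_CLASSES.index("dry nonhabitat")] += gap
    pi = areas / areas.sum()

    aeqd = LocalProjection(lon0, lat0, "aeqd")
    projected = [aeqd.project(p) for p in habitat_map.polygons]
    use = np.zeros(len(HABITAT_CLASSES))
    for idx in site.use_index:
        cls = assign_point_class(
            track.lon[idx], track.lat[idx], habitat_map, aeqd, snap_m, _projected=projected
        )
        use[HABITAT_CLASSES.index(cls)] += 1
    return SiteTable(site.site_id, pi, use, area_m2=float(frame.area))


def manly_wi_design3(tables: list[SiteTable], alpha: float = 0.05) -> pd.DataFrame:
    """Selection ratios, SEs and Bonferroni CIs for one stratum of sites."""
    return ManlySelectionModel(tables).fit(alpha=alpha).frame


def classify_selection(lcl: float, ucl: float) -> str:
    """Selected iff LCL > 1, avoided iff UCL < 1, else neutral."""
    if lcl > 1.0:
        return "selected"
    if ucl < 1.0:
        return "avoided"
    return "neutral"


def loglik_chisq(tables: list[SiteTable]) -> tuple[float, int, float]:
    """Log-likelihood chi-square test of use == availability across sites.

    G = 2 * sum_j sum_i u_ij ln(u_ij / e_ij) over cells with u > 0, e > 0;
    df = sum_j (I_j - 1) with I_j the number of habitats available at site j.
    """
    g = 0.0
    df = 0
    for tb in tables:
        e = tb.u_total * tb.pi
        ok = (tb.use > 0) & (e > 0)
        g += 2.0 * float(np.sum(tb.use[ok] * np.log(tb.use[ok] / e[ok])))
        df += int(np.sum(tb.pi > 0)) - 1
    p = float(stats.chi2.sf(g, df)) if df > 0 else float("nan")
    return g, df, p


class ManlySelectionModel:
    """Design-III selection-ratio model over stopover-site use/availability
    tables, optionally stratified by ecoregion.

    Parameters
    ----------
    tables : list of SiteTable
    strata : optional list of stratum labels aligned with `tables`; when
        given, `fit` estimates ratios within each stratum as well as pooled
        over all sites (stratum label "all").
    """

    def __init__(self, tables: list[SiteTable], strata: list[str] | None = None):
        if not tables:
            raise ValueError("no site tables")
        if all(tb.u_total == 0 for tb in tables):
            raise ValueError("all site tables have zero use")
        if strata is not None and len(strata) != len(tables):
            raise ValueError("strata must align with tables")
        self.tables = list(tables)
        self.strata = list(strata) if strata is not None else None
        self.habitats = tables[0].habitats

    @classmethod
    def from_sites(cls, sites, tracks_by_bird, habitat_map, strata=None, snap_m=SNAP_M):
        tables = [
            site_table(s, tracks_by_bird[s.bird_id], habitat_map, snap_m) for s in sites
        ]
        return cls(tables, strata)

    # -- estimation ----------------------------------------------------------
    def _fit_stratum(self, tables, stratum, alpha, low_avail_frac):
        pi = np.array([tb.pi for tb in tables])          # (J, I)
        u = np.array([tb.use for tb in tables])
        areas = np.array([tb.area_m2 for tb in tables])
        u_tot = u.sum(axis=1)
        e = u_tot[:, None] * pi
        tested = pi.sum(axis=0) > 0                      # habitats available somewhere
        K = int(tested.sum())
        z = stats.norm.ppf(1.0 - alpha / (2.0 * K))
        if np.all(np.isfinite(areas)):
            avail_share = (pi * areas[:, None]).sum(axis=0) / areas.sum()
        else:  # equal-weight fallback when site areas are unknown
            avail_share = pi.mean(axis=0)

        rows = []
        for i, hab in enumerate(self.habitats):
            if not tested[i]:
                continue
            contributing = pi[:, i] > 0
            J = int(contributing.sum())
            sum_u, sum_e = float(u[:, i].sum()), float(e[:, i].sum())
            w = sum_u / sum_e
            if J > 1:
                var = (J / (J - 1)) * float(np.sum((u[:, i] - w * e[:, i]) ** 2)) / sum_e**2
                se = float(np.sqrt(var))
                lcl, ucl = max(0.0, w - z * se), w + z * se
            else:
                se = lcl = ucl = np.nan
            if sum_u == 0 and avail_share[i] < low_avail_frac:
                call = "undetermined"
            elif J <= 1:
                call = "single-site-unreliable"
            else:
                call = classify_selection(lcl, ucl)
            rows.append(
                {
                    "stratum": stratum,
                    "habitat": hab,
                    "n_sites": J,
                    "availability_pct": 100.0 * avail_share[i],
                    "use_pct": 100.0 * sum_u / u_tot.sum(),
                    "w": w,
                    "se": se,
                    "lcl": lcl,
                    "ucl": ucl,
                    "call": call,
                }
            )
        g, df, p = loglik_chisq(tables)
        return pd.DataFrame(rows), {"stratum": stratum, "G": g, "df": df, "p": p}

    def fit(self, alpha: float = 0.05, low_avail_frac: float = LOW_AVAIL_FRAC) -> "SelectionResults":
        frames, chis = [], []
        fr, chi = self._fit_stratum(self.tables, "all", alpha, low_avail_frac)
        frames.append(fr)
        chis.append(chi)
        if self.strata is not None:
            for s in dict.fromkeys(self.strata):   # first-appearance order
                sub = [tb for tb, lab in zip(self.tables, self.strata) if lab == s]
                fr, chi = self._fit_stratum(sub, s, alpha, low_avail_frac)
                frames.append(fr)
                chis.append(chi)
        return SelectionResults(self, pd.concat(frames, ignore_index=True), pd.DataFrame(chis), alpha)


@dataclass
class SelectionResults:
    """Fitted selection ratios with uncertainties and selection calls.

    `frame` has one row per (stratum, habitat):
    stratum, habitat, n_sites, availability_pct, use_pct, w, se, lcl, ucl, call.
    `chisq` has the per-stratum log-likelihood chi-square tests.
    """

    model: ManlySelectionModel
    frame: pd.DataFrame
    chisq: pd.DataFrame
    alpha: float

    def stratum(self, name: str) -> pd.DataFrame:
        return self.frame[self.frame["stratum"] == name].reset_index(drop=True)

    def bootstrap_se(self, n_boot: int = 2000, seed: int = 0, stratum: str = "all") -> pd.Series:
        """Nonparametric bootstrap over sites of the pooled selection ratios."""
        if stratum == "all":
            tables = self.model.tables
        else:
            tables = [
                tb for tb, s in zip(self.model.tables, self.model.strata) if s == stratum
            ]
        rng = np.random.default_rng(seed)
        pi = np.array([tb.pi for tb in tables])
        u = np.array([tb.use for tb in tables])
        e = u.sum(axis=1)[:, None] * pi
        J = len(tables)
        ws = np.full((n_boot, len(self.model.habitats)), np.nan)
        for b in range(n_boot):
            idx = rng.integers(0, J, J)
            se_ = e[idx].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                ws[b] = np.where(se_ > 0, u[idx].sum(axis=0) / np.where(se_ > 0, se_, 1.0), np.nan)
        return pd.Series(np.nanstd(ws, axis=0, ddof=1), index=list(self.model.habitats))

    def summary(self) -> str:
        lines = [
            "Manly design-III selection ratios",
            f"  sites: {len(self.model.tables)}   alpha: {self.alpha} (Bonferroni-adjusted CIs)",
            "",
            self.frame.to_string(
                index=False,
                float_format=lambda v: f"{v:.3f}",
                columns=["stratum", "habitat", "n_sites", "availability_pct",
                         "use_pct", "w", "se", "lcl", "ucl", "call"],
            ),
            "",
            "Log-likelihood chi-square (use == availability):",
            self.chisq.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


def assign_ecoregion(
    site: StopoverSite,
    region_polys: list,
    region_names: list[str],
    merge_map: dict | None = None,
) -> str | None:
    """Analysis ecoregion of a site: point-in-polygon on the use centroid,
    then the configured merge map (defaults encode the study's merges).
    Returns None when the centroid falls in no region polygon."""
    merges = DEFAULT_ECOREGION_MERGES if merge_map is None else merge_map
    pt = Point(*site.centroid)
    raw = None
    for poly, name in zip(region_polys, region_names):
        if poly.covers(pt):
            raw = name
            break
    if raw is None:
        return None
    return merges.get(raw, raw)
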