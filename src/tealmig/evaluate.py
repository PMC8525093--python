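"""Validation routines against synthetic truth.

These run the pipeline on generated cohorts (or direct multinomial
simulations) and score recovery of the known truth: departure-time error,
stopover recall/precision, selection-ratio CI coverage, SE versus
bootstrap, chi-square type-I error, and unmixing accuracy. The test suite
and the reproduction script both call these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._geo import haversine_km
from .segmentation import segment_track
from .selection import ManlySelectionModel, SiteTable, loglik_chisq
from .sma import unmix_image
from .stopovers import detect_stopovers
from .synthetic import Cohort, SimConfig, simulate_cohort
from .tracks import fall_window


def run_cohort_segmentation(cohort: Cohort):
    """Fall-window + segment every track; returns (subtracks, segs, sites)
    with stopover detection restricted to the migratory span of each bird."""
    out = []
    for trk in cohort.tracks:
        w = fall_window(trk)
        seg = segment_track(w)
        sites = []
        sub = None
        if seg.is_migrant and seg.departure is not None:
            t_end = seg.terminus.arrival_time if seg.terminus else w.t[-1] + pd.Timedelta(seconds=1)
            sub = w.slice(np.asarray((w.t >= seg.departure.departure_time) & (w.t < t_end)))
            sites = detect_stopovers(sub)
        out.append((w, seg, sub, sites))
    return out


def departure_recovery(cohort: Cohort) -> pd.DataFrame:
    """Per-bird departure-time error (h) versus the true flight onset, with
    the bird's largest fix interval as the natural resolution limit."""
    truth = cohort.truth_birds.set_index("bird_id")
    rows = []
    for w, seg, _, _ in run_cohort_segmentation(cohort):
        tr = truth.loc[seg.bird_id]
        err_h = abs((seg.departure.departure_time - tr["onset_time"]).total_seconds()) / 3600.0
        rows.append(
            {
                "bird_id": seg.bird_id,
                "error_h": err_h,
                "max_fix_interval_h": float(tr["max_fix_interval_h"]),
                "within_one_interval": err_h <= float(tr["max_fix_interval_h"]),
            }
        )
    return pd.DataFrame(rows)


def stopover_confusion(cohort: Cohort, match_km: float = 10.0) -> dict:
    """Recall/precision of detected stopover sites against the scheduled
    (non-terminus) stopovers: a match is a detected site whose centroid lies
    within match_km of a true stopover centroid of the same bird, with
    overlapping time span."""
    truth = cohort.truth_stopovers
    truth = truth[~truth["is_terminus"]]
    n_true = len(truth)
    n_det = 0
    tp_det = 0
    matched_truth = set()
    for _, _, _, sites in run_cohort_segmentation(cohort):
        for s in sites:
            n_det += 1
            cand = truth[truth["bird_id"] == s.bird_id]
            for idx, row in cand.iterrows():
                d = float(haversine_km(s.centroid[0], s.centroid[1], row["lon"], row["lat"]))
                overlap = s.arrival_time <= row["t_end"] and s.departure_time >= row["t_start"]
                if d <= match_km and overlap:
                    tp_det += 1
                    matched_truth.add(idx)
                    break
    return {
        "n_true": n_true,
        "n_detected": n_det,
        "recall": len(matched_truth) / n_true if n_true else float("nan"),
        "precision": tp_det / n_det if n_det else float("nan"),
    }


# ---------------------------------------------------------------------------
# selection estimator simulations

def _sim_tables(rng, n_sites, n_per_site, pi, w_true):
    """Sites with identical availability and multinomial use at true ratios."""
    pi = np.asarray(pi, float)
    p = pi * np.asarray(w_true, float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("w_true and pi must satisfy sum(w*pi) = 1")
    habitats = tuple(f"h{i}" for i in range(len(pi)))
    return [
        SiteTable(f"s{j}", pi, rng.multinomial(n_per_site, p), area_m2=1.0, habitats=habitats)
        for j in range(n_sites)
    ]


def ci_coverage(
    seed: int,
    n_reps: int = 500,
    n_sites: int = 50,
    n_per_site: int = 50,
    pi=(0.5, 0.3, 0.2),
    w_true=(0.2, 1.0, 3.0),
    alpha: float = 0.05,
) -> float:
    """Fraction of replicates in which every habitat's true ratio falls
    inside its Bonferroni-adjusted CI (simultaneous coverage)."""
    rng = np.random.default_rng(seed)
    w_true = np.asarray(w_true, float)
    hit = 0
    for _ in range(n_reps):
        tables = _sim_tables(rng, n_sites, n_per_site, pi, w_true)
        fr = ManlySelectionModel(tables).fit(alpha=alpha).frame
        ok = (fr["lcl"].to_numpy() <= w_true) & (w_true <= fr["ucl"].to_numpy())
        hit += bool(ok.all())
    return hit / n_reps


def se_vs_bootstrap(
    seed: int,
    n_boot: int = 2000,
    n_sites: int = 50,
    n_per_site: int = 50,
    pi=(0.5, 0.3, 0.2),
    w_true=(0.2, 1.0, 3.0),
) -> pd.DataFrame:
    """Analytic SE versus a nonparametric bootstrap over sites."""
    rng = np.random.default_rng(seed)
    tables = _sim_tables(rng, n_sites, n_per_site, pi, w_true)
    res = ManlySelectionModel(tables).fit()
    boot = res.bootstrap_se(n_boot=n_boot, seed=seed)
    fr = res.frame.set_index("habitat")
    out = pd.DataFrame({"se": fr["se"], "boot_se": boot})
    out["rel_diff"] = (out["se"] - out["boot_se"]).abs() / out["boot_se"]
    return out


def chisq_type1_rate(
    seed: int,
    n_reps: int = 2000,
    n_sites: int = 5,
    n_per_site: int = 200,
    pi=(0.5, 0.3, 0.2),
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the log-likelihood chi-square when use is exactly
    proportional to availability (should sit near alpha)."""
    rng = np.random.default_rng(seed)
    pi = np.asarray(pi, float)
    habitats = tuple(f"h{i}" for i in range(len(pi)))
    rej = 0
    for _ in range(n_reps):
        tables = [
            SiteTable(f"s{j}", pi, rng.multinomial(n_per_site, pi), habitats=habitats)
            for j in range(n_sites)
        ]
        _, _, p = loglik_chisq(tables)
        rej += p < alpha
    return rej / n_reps


# ---------------------------------------------------------------------------
# unmixing accuracy

def sma_accuracy(seed: int, n_pixels: int = 10_000, snr: float = 100.0,
                 endmembers=None) -> dict:
    """Unmixing error on synthetic mixtures: exact recovery without noise,
    water-fraction RMSE with zero-mean Gaussian noise at the given SNR."""
    from .synthetic import DEFAULT_ENDMEMBERS

    em = endmembers or DEFAULT_ENDMEMBERS
    rng = np.random.default_rng(seed)
    f = rng.dirichlet(np.ones(em.spectra.shape[1]), size=n_pixels)
    clean = f @ em.spectra.T
    est0 = unmix_image(clean, em)
    noise_sd = float(np.sqrt(np.mean(clean**2))) / snr
    noisy = clean + rng.normal(0.0, noise_sd, clean.shape)
    est1 = unmix_image(noisy, em)
    wi = em.water_index
    return {
        "noiseless_max_abs_error": float(np.max(np.abs(est0 - f))),
        "water_rmse_snr": float(np.sqrt(np.mean((est1[:, wi] - f[:, wi]) ** 2))),
    }


def flight_speed_recovery(cohort: Cohort) -> float:
    """Median empirical speed (km/h) over migratory flight legs."""
    speeds = []
    for trk, (_, tr) in zip(cohort.tracks, cohort.truth_birds.iterrows()):
        onset = tr["onset_time"]
        d = haversine_km(trk.lon[:-1], trk.lat[:-1], trk.lon[1:], trk.lat[1:])
        dt = np.diff(trk.t.asi8) / 3.6e12
        v = d / dt
        seg_t = trk.t[1:]
        flight = (seg_t > onset) & (v > 10.0)
        speeds.extend(v[np.asarray(flight)])
    return float(np.median(speeds))
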