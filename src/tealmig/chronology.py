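"""Migration chronology statistics.

Arrival timing at stopover sites is summarized per ecoregion as the median
day of year with the interquartile range (type-7 interpolated quantiles)
and the median absolute deviation scaled by 1.4826 (consistent with the
normal SD). Migration-onset timing versus departure latitude is an ordinary
least-squares regression of departure day of year on latitude, reported as
slope (days per degree), SE, residual df and two-sided t-test p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import median_abs_deviation


def arrival_stats(arrival_doy: pd.Series, region: pd.Series) -> pd.DataFrame:
    """Per-region median/IQR/MAD of stopover arrival day of year.

    Returns columns: ecoregion, n_stopovers, median_arrival_doy, iqr, mad.
    Empty regions are simply absent.
    """
    df = pd.DataFrame({"doy": np.asarray(arrival_doy, float), "region": np.asarray(region)})
    rows = []
    for reg, g in df.groupby("region", sort=True):
        x = g["doy"].to_numpy()
        q1, q3 = np.quantile(x, [0.25, 0.75])  # numpy default = type-7 linear
        rows.append(
            {
                "ecoregion": reg,
                "n_stopovers": len(x),
                "median_arrival_doy": float(np.median(x)),
                "iqr": float(q3 - q1),
                # R's convention: literal 1.4826, not the exact 1/qnorm(3/4)
                "mad": 1.4826 * float(median_abs_deviation(x)),
            }
        )
    return pd.DataFrame(rows, columns=["ecoregion", "n_stopovers", "median_arrival_doy", "iqr", "mad"])


def onset_latitude_regression(departure_doy, departure_lat) -> dict:
    """OLS of departure day-of-year on departure latitude.

    Returns slope (days/degree; negative = earlier departure farther north),
    se, intercept, df (n - 2) and two-sided p.
    """
    y = np.asarray(departure_doy, float)
    x = np.asarray(departure_lat, float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError("need at least 3 birds with departure and latitude")
    if np.ptp(x) == 0:
        raise ValueError("departure latitude has zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(res.params[1]),
        "se": float(res.bse[1]),
        "intercept": float(res.params[0]),
        "df": int(res.df_resid),
        "p": float(res.pvalues[1]),
        "n": int(len(y)),
    }


def ownership_summary(ownership) -> float:
    """Percent of nonflight use points on private land; NaN for an empty set."""
    vals = np.asarray(ownership)
    if len(vals) == 0:
        return float("nan")
    return 100.0 * float(np.sum(vals == "private")) / len(vals)
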