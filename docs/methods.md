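# Methods

This note documents the models and procedures `tealmig` implements, the
parameters that matter, the choices made where the design was genuinely
open, and what validation on synthetic data does and does not establish.

## Geometry

All distances are great-circle (haversine) on the IUGG authalic sphere,
R = 6371.0088 km. At stopover scale (tens of km) the error against
ellipsoidal geodesics is below 0.5%, far inside every threshold used.
Buffers and nearest-distance queries run in a local azimuthal-equidistant
projection centered on each site; areal availability runs in a local
Lambert azimuthal equal-area projection. Both are hand-written spherical
forms (`_geo.py`): at local scales they agree with ellipsoidal projections
to well under the 30-m pixel size. Timestamps are UTC throughout; day of
year is computed in UTC with actual leap-year calendars.

## Migration segmentation

Origin = first fix at/after 1 August; the fall window is 1 Aug–31 Dec,
inclusive at both ends. Tunables (all configurable, defaults are the
study-system constants):

- `r_local_km = 50` — radius of local summer movement around the origin.
- `r_migrant_km = 150` — ultimate displacement required to call a bird a
  migrant; recursive exploratory flights reach ~148 km, so both thresholds
  are strict `>` comparisons.
- `max_departure_gap_h = 14` — the largest pre-departure fix gap considered
  reliable; a larger gap flags the midpoint departure estimate (one bird in
  the motivating dataset had a 23-day gap over departure).
- `min_residency_days = 7` — terminal residency required to call a
  migration complete. The original analysis used known fates, which are not
  reproducible from coordinates alone; terminal residency is the
  reproducible proxy.

"Left without returning" is operationalized as the **last upcrossing** of
`r_local` with no subsequent fix at or below it; an equivalent brute-force
scan serves as the test oracle. Per-fix speed is attributed to the incoming
segment (the first fix takes its outgoing segment); speed over a long gap
underestimates flight speed, which only makes the downstream flight filter
conservative.

## Stopover detection

The per-fix statistic is the minimum distance to any other fix within a
symmetric ±48 h window (the self-fix excluded; ∞ when no temporal neighbor
exists). A forward-only window was the main alternative reading; the
symmetric window is used because the statistic is about local residency,
which is time-symmetric. Fixes with `nn ≤ 5.0` km (inclusive) are stopover
behavior; speeds strictly above 10 km/h mark flight.

Turning labeled points into discrete sites is under-determined by any
threshold rule, so sites are formed by greedy temporal chaining: a stopover
fix joins the open site iff its gap to the site's latest fix is ≤ 48 h and
it lies within 5 km of at least one site member; otherwise a new site
starts. Flight fixes never enter use points but do not break the temporal
chain. On every synthetic cohort tested this equals the brute-force
connected components under the (≤5 km, ≤48 h) relation, which is asserted
in the tests; pathological tracks could make the two differ, and the
connected-components oracle defines the intended semantics.

Candidate sites are kept with ≥3 nonflight fixes spanning ≥3 h (both
inclusive; the span is measured over nonflight fixes — the other reading,
all fixes, differs only when a site is bracketed by flight fixes). Site
arrival is the first member fix's timestamp. Overlapping sites from
different birds are deliberately kept separate, as the sampling unit of the
selection analysis is the bird-site. The pipeline restricts stopover
detection to fixes between the estimated departure and the terminus
arrival (or last fix), so the summer residence cluster and the terminal
wintering residence are not counted as migration stopovers.

## Surface-water mapping

Unmixing is fully constrained (non-negativity and sum-to-one): fractions
are then directly interpretable as within-pixel proportions. The FCLS
problem is solved by non-negative least squares on the system augmented
with a heavily weighted sum-to-one row, then renormalized exactly; on
noiseless mixtures recovery is exact to machine precision, and the
constraints hold to 1e-9 for arbitrary input spectra. A rank-deficient
endmember matrix is a fatal configuration error.

Order of operations: per-scene fractions are composited (per-pixel mean
over cloud-free scenes) **then** thresholded at >10% — the mean-wetland-
condition reading. Thresholding per scene first would mark ephemerally
flooded pixels; with the synthetic generator's static truth the two orders
agree, so this choice is untested against real inter-scene variability.

Flooded pixels are traced with 8-connectivity and components below 0.25 ha
(2500 m², i.e. fewer than three 30-m pixels) are dropped. Flooded polygons
take the class of the label-layer polygon with majority area overlap;
unlabeled flooded area defaults to natural wetland with a warning;
unflooded area becomes dry agriculture inside the supplied mask and dry
nonhabitat elsewhere, so the map tiles each analysis frame with no gaps.
Ownership is carried from the label layer and defaults to private.

Endmember spectra are user-supplied; the bundled synthetic set (water,
vegetation, soil over Landsat 8 bands 2–7) is a stylized stand-in, not a
spectral library. No independent map-accuracy assessment is attempted.

## Habitat selection

The design-III estimator and its across-site ratio-estimator variance are
given in the README. Decisions:

- **CIs** are normal intervals at the Bonferroni-adjusted level α/(2K) for
  K habitats tested per stratum, LCL truncated at 0. Simulation shows
  simultaneous coverage of true ratios of ~0.93–0.95 at the default
  settings, and the analytic SE within a few percent of a 2,000-resample
  site bootstrap.
- A habitat available at only **one** site has no estimable across-site
  variance: the call is `single-site-unreliable` and the point estimate
  should be interpreted with caution.
- A habitat with **no use** whose availability is below 1% of stratum area
  is `undetermined` — there was nothing to detect selection or avoidance
  with.
- Edge snapping: a use point outside all wet-class polygons but within
  100 m of one takes the nearest polygon's class (ties go to the
  lower-index polygon, deterministically). 100 m is ~3 Landsat pixels and
  captures heavy wetland-edge use.
- The chi-square is the log-likelihood form `G = 2Σ u ln(u/e)` with
  `df = Σ_j (I_j − 1)`; its type-I error rate at the defaults is ~0.05 by
  simulation. The exact variant used by other implementations of the
  method is not documented; calibration is therefore established by
  simulation rather than cross-package comparison.
- Ecoregion stratification assigns each site by point-in-polygon on its
  use centroid, then applies a configurable merge map whose defaults pool
  small adjacent regions (e.g., Northwestern Forested Mountains into Cold
  Deserts) into the six analysis regions.
- Random effects for individual birds are out of scope: with few birds
  contributing replicate sites per stratum they are not estimable, and
  site-level independence is assumed instead.

## Chronology

IQR uses type-7 (linear) quantile interpolation and MAD uses the literal
1.4826 consistency constant — both matching R's defaults, and the only
conventions consistent with fractional IQRs and MAD/IQR ratios near 0.77
that this kind of arrival-date table shows. The onset–latitude relation is
plain OLS of departure day-of-year on departure latitude (slope in days
per degree; negative means farther-north birds leave earlier), verified
against the closed-form normal equations to 1e-10.

## Synthetic generator

The generator emulates the study conditions rather than any particular
dataset: fix intervals drawn from {0.25, 0.5, 1, 2, 3, 6} h; pre-onset
movement a bounded random walk under 5 km/h within 30 km of the origin;
onset ~ Normal(day-of-year 271, sd 8), i.e. a late-September median
departure; directed flight legs at 36.5 km/h; three scheduled stopovers of
2 days spaced 250 km along a southbound route plus a 10-day terminal
residence; stopover fixes sample a habitat class from configured
multinomial preferences and land in a cell of that class near the node
centroid (fix intervals ≥1 h within residences keep within-patch speeds
below the walking bound). Landscape nodes realize configured class
proportions exactly by largest-remainder apportionment with a seeded
shuffle; the inner 3×3 cell block contains every used class so
class-conditional placement is always feasible. Cell ownership is
Bernoulli(0.725 private). Imagery over the first node is formed as exact
endmember mixtures of the truth water-fraction field plus Gaussian noise
at SNR 100 with ~10% of pixels cloud-masked per scene. All randomness
derives from one seed through per-bird substreams, so outputs are
reproducible bit-for-bit.

What passing on this generator does **not** show: real tracks have GPS
error, irregular duty cycles, mid-track data gaps, mortality, recursive
movements between nearby sites and spatially autocorrelated habitat; real
imagery has atmospheric residuals, mixed phenology and endmember
variability. Recovery being exact here demonstrates the algorithms
implement their definitions, not that the thresholds are optimal for any
particular sensor or species.

Problem sizes used in the validation runs — a 20-bird cohort (~15,000
fixes, 60 scheduled stopovers), 500 coverage replicates of 50 sites × 50
points, 2,000 bootstrap resamples, 2,000 chi-square replicates, 10,000
unmixed pixels — are large enough that every reported rate is stable to
the tolerance asserted while keeping a full run in seconds.

Note also that at cohort scale the configured use/availability quotient is
not exactly the site-level estimand: site polygons are centered on
patch-enriched cores and edge snapping reassigns a small fraction of dry
points, so pipeline-level selection ratios are compared to truth through
the realized availability (they agree within a few percent), while CI
calibration is established by direct multinomial simulation where the
estimand is exact.

## Known limitations

- The site-chaining rule is validated against connected components only on
  synthetic data; adversarial fix geometries could order-depend.
- The departure midpoint is only as good as the bracketing fixes; gaps
  longer than `max_departure_gap_h` are flagged, not fixed.
- Unmixing assumes the supplied endmembers span the scene; no endmember
  selection or shade normalization is performed.
- Ecoregion assignment uses the use-centroid only; a site polygon
  straddling a boundary is assigned wholly to one region.
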