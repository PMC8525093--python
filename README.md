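# tealmig

Fall-migration stopover ecology for GPS-tracked waterfowl.

Dabbling ducks such as Cinnamon Teal (*Spatula cyanoptera*) cross the arid
western United States and Mexico each fall, pausing at wetlands whose
availability is limited and highly variable. `tealmig` is a tested,
reusable pipeline for the analyses such a tracking study needs: it turns
raw GPS tracks into migration chronology, discrete stopover sites, a
surface-water habitat map, and habitat-selection inference — and ships a
synthetic-data generator with known truth so every stage can be validated
end to end without any downloads.

It is aimed at movement ecologists and wildlife-telemetry analysts working
with GPS-GSM transmitter data (mixed fix intervals, 15 min to 6 h).

## What it computes

**Migration segmentation.** For each bird, net displacement from its
1-August origin, `d_k = haversine(x_0, x_k)`. Birds are migrants when
`max d_k > 150` km (recursive exploratory flights reach ~148 km and must
not count). Onset is the last exit from the 50-km summer radius with no
return; departure time is the midpoint between the last summer fix and the
first migratory fix. The terminus is where no further >50 km movements
occur, accepted when terminal residency is at least 7 days.

**Stopover detection.** For each fix, the minimum distance to any other fix
within a ±48 h window. The distribution is bimodal with a gap at 5 km:
fixes with `nn ≤ 5` km are stopover behavior, the rest migratory. Fixes
faster than 10 km/h are in flight (ducks walk/swim below ~5 km/h; teal fly
at ~36.5 km/h) and excluded from habitat use. A stopover needs ≥3 nonflight
fixes spanning ≥3 h; its available-habitat boundary is the union of 5-km
disks around its use points.

**Surface-water mapping.** Per-pixel water fraction by fully constrained
linear spectral unmixing of Landsat 8 bands 2–7: solve
`min ‖s − E f‖²  s.t.  f ≥ 0, Σf = 1`, water fraction `f_water`. Fractions
are averaged over the 1 Aug–31 Oct compositing window; pixels with mean
fraction >10% are flooded; flooded regions are polygonized (8-connected,
0.25 ha minimum unit) and typed from a label layer into 12 habitat classes.

**Habitat selection (Manly design III).** With use counts `u_ij` and
per-site availability proportions `π_ij`,

    ŵ_i = Σ_j u_ij / Σ_j u_+j π_ij,
    var(ŵ_i) = [J/(J−1)] Σ_j (u_ij − ŵ_i e_ij)² / (Σ_j e_ij)²,  e_ij = u_+j π_ij,

with Bonferroni-adjusted normal CIs (LCL truncated at 0). LCL > 1 means
selection, UCL < 1 avoidance. Overall departure from proportional use is
tested with `G = 2 Σ u ln(u/e)`. Use points within 100 m of a mapped
wetland take its class (edge use is heavy). Analyses are stratified by
ecoregion with the study-system merges built in.

**Chronology.** Per-ecoregion arrival medians with IQR (type-7 quantiles)
and MAD (×1.4826), plus an OLS regression of departure day-of-year on
departure latitude.

## Worked example

```python
import numpy as np
from tealmig import SimConfig, simulate_cohort, segment_track, detect_stopovers, fall_window
from tealmig.selection import ManlySelectionModel, site_table

cohort = simulate_cohort(SimConfig(seed=42, n_birds=6))
tables = []
for track in cohort.tracks:
    fallt = fall_window(track)
    seg = segment_track(fallt)
    if not seg.is_migrant:
        continue
    end = seg.terminus.arrival_time if seg.terminus else fallt.t[-1]
    mig = fallt.slice(np.asarray((fallt.t >= seg.departure.departure_time) & (fallt.t < end)))
    for site in detect_stopovers(mig):
        tables.append(site_table(site, mig, cohort.landscape.habitat_map))

result = ManlySelectionModel(tables).fit()
print(result.summary())
```

prints

```
Manly design-III selection ratios
  sites: 18   alpha: 0.05 (Bonferroni-adjusted CIs)

stratum         habitat  n_sites  availability_pct  use_pct     w    se   lcl   ucl     call
    all dry agriculture       18            16.310    0.000 0.000 0.000 0.000 0.000  avoided
    all  dry nonhabitat       18            38.684    1.445 0.037 0.015 0.000 0.076  avoided
    all managed wetland       18            10.476   18.497 1.766 0.194 1.255 2.277 selected
    all natural wetland       18            12.077   33.526 2.787 0.268 2.080 3.495 selected
    all        riparian       18             6.323   14.162 2.255 0.300 1.462 3.047 selected
    all wet agriculture       18            16.131   32.370 2.002 0.132 1.655 2.349 selected

Log-likelihood chi-square (use == availability):
stratum       G  df     p
    all 586.989  90 0.000
```

Six simulated birds produced 18 stopover sites. The wet habitat classes
(generated with high true use preference) come out selected with ratios
near 2–3, the dry classes avoided with ratios near 0 — exactly the
configured truth — and the chi-square overwhelmingly rejects proportional
use.

The same analysis runs from the shell:

```sh
tealmig all --seed 42 --out-dir out/
```

which writes `segmentation.csv`, `sites.geojson`, `use_points.csv`,
`flooded.geojson`, `selection.csv`, `arrival_stats.csv`,
`onset_regression.csv`, `ownership.csv` and a `MANIFEST.json` recording
per-stage record counts.

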