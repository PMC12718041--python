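# vinearch

Whole-plant 3-D architecture analysis for field-grown grafted grapevines.

During vineyard establishment the rootstock genotype shapes where a vine
puts its roots — how deep, how wide, how strongly aligned with the planting
row — and how it splits dry matter between below- and above-ground organs.
Quantifying this requires going from digitized 3-D geometry (excavated root
systems in RSML, shoots and six-landmark leaves from an electromagnetic
digitizer) to a reproducible table of architectural statistics, and from
there to allometric and multivariate comparisons between genotypes.
`vinearch` implements that pipeline end to end for researchers in root
phenotyping and viticulture:

* **I/O** — RSML 1.0 reading/writing (cm units, strict validation, stable
  round trip), digitizer point-table import (stem / main shoot / laterals /
  PL1–PL6 leaves / dotted root ids), VTK PolyData (`.vtp`) export for
  ParaView.
* **Root-system architecture traits** — total root length; maximum rooting
  depth below a configurable soil surface; maximum horizontal spread (XY
  diameter of the point cloud); 3-D convex-hull volume (dm³) and XY hull
  area (dm²); aspect ratio `(projx_max − projx_min)/(projy_max − projy_min)`;
  the Directional Bias Index
  `DBI = (L_h − L_v)/(L_h + L_v)` over 10 × 10 cm grid-aggregated root
  length (negative = biased along the planting row); the fraction of root
  length outside the 2 m × 1 m planting area (`L_outside/L_total`); root
  length per soil layer by exact partitioning of each segment across the
  layers it traverses; specific root length `SRL = length / root dry weight`.
* **Shoot & canopy** — internode lengths, main/secondary shoot lengths and
  phytomer counts, single-leaf area from the two secondary vein lengths
  (`area = c·(L_left·L_right)^k`), `SLA` and `SSL`.
* **Allometry** — woody mass fractions, root:shoot biomass and length
  ratios, standardized major axis (SMA) regression on log–log data with the
  standard 95 % slope interval, per-genotype grouping.
* **Multivariate** — PLS-DA via an in-repo NIPALS implementation
  (unit-variance scaling, two predictive components by default),
  stratified-fold cross-validated Q², and VIP scores (`mean(VIP²) = 1`).
* **Synthetic cohorts** — a stochastic apical-growth generator with
  genotype archetypes (`deep`, `shallow_wide`, `intermediate`) contrasting
  vertical-deep against shallow-wide habits, phytomer-chain shoots with
  six-point leaves, seasonal growth schedules with winter dormancy, and dry
  weights with age-dependent secondary thickening — so the entire pipeline
  is testable without excavation data.

## Worked example

```python
import vinearch as va

plant = va.generate_plant(va.ARCHETYPES["deep"], "T4", seed=42, plant_id="demo")
traits = va.compute_rsa_traits(plant)
print(f"total root length : {traits.total_root_length:8.1f} cm")
print(f"max rooting depth : {traits.max_rooting_depth:8.1f} cm")
print(f"DBI               : {traits.dbi:8.2f}")
print(f"outside fraction  : {traits.outside_fraction:8.3f}")
print(f"SRL               : {traits.srl:8.1f} cm/g")
```

```
total root length :   6652.8 cm
max rooting depth :    190.0 cm
DBI               :    -0.56
outside fraction  :    0.031
SRL               :     25.6 cm/g
```

An 18-month "deep" vine explores almost 2 m down but keeps 97 % of its
root length inside its own planting area, with a clearly row-aligned
horizontal distribution (DBI < 0). The same traits come from real data via
`va.read_rsml("vine.rsml")` followed by `va.compute_rsa_traits(...)`, or in
batch from the command line:

```bash
vinearch simulate --n 8 --time T4 --seed 42 --out cohort/
vinearch traits --rsml cohort/ --weights cohort/weights.csv --out traits.csv
vinearch plsda --table traits.csv --class-col genotype
vinearch sma --table traits.csv --x shoot_dry_weight --y root_dry_weight --out sma.csv
```

Coordinates are centimetres with the grafting point at the origin and z
positive up; the soil surface defaults to z = −5 cm and the buried stem
base to z = −25 cm (both configurable, as is an axis-flip flag for
depth-positive RSML files).

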