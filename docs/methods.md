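# Methods

## Model structure

The model is deterministic given its parameters and consists of three
stages run in sequence for every parameter draw.

### Study domain

The domain is a pre-projected equal-area grid of `nx × ny` square cells
(default 76 × 76 at 20 km, 2 310 400 km²) with three depth strata, 0–20,
20–50 and 50–200 m. Each (cell, stratum) pair is a *water mass*, the atomic
accounting unit. Stratum volumes are truncated at the seafloor
(`V = A · max(0, min(bottom, seafloor) − top)`); a seafloor depth of 0 marks
land. Truncation is a modelling choice — without it, shelf cells would carry
phantom deep-water volume and biomass.

All geometry is in projected kilometres. Colony-buffer membership uses the
cell-centre rule (a cell belongs to a foraging disc iff its centre is within
the radius); at 20 km resolution a fractional-overlap rule would change mask
areas by well under the 10% calibration tolerance used for them. Lon/lat
colony inputs are supported through great-circle distances against
caller-supplied cell-centre coordinates.

### Prey field

Column copepod biomass `B` (g m⁻²) becomes seasonal mesozooplankton
production through a separable product
`P = B · pb_ratio · season_fraction · copepod_to_meso`. The three factors
are: annual production-to-biomass ratio, the fraction of annual secondary
production falling in the mid-May–mid-August season, and the scaling from
copepods to total mesozooplankton. Their default product ≈ 1.63 calibrates
the domain total to the reported ~126 Mt seasonal production at the reported
33.2 g m⁻² mean standing biomass. Modelling *production* rather than
standing stock encodes the assumption that each water mass is subject to a
single act of foraging just after a local production peak.

Column production is split across strata by fractions `f = (0.45, 0.35,
0.20)`. These defaults are plausible for a surface-concentrated summer
community but uncalibrated against any stratification dataset; they carry
generous uncertainty in the Monte Carlo ledger. On truncated columns the
fractions are renormalised over wet strata, so shelf columns keep their full
production rather than losing the share of dry strata.

Within each water mass, biomass divides into patches and background by two
patchiness intensities: the patch volume fraction φ (default mean 0.084) and
the patch biomass fraction p (default mean 0.415). Patch density is
`d_patch = p·B/(φ·V)` and background density `d_bg = (1−p)·B/((1−φ)·V)`;
conservation `φV·d_patch + (1−φ)V·d_bg = B` holds by construction. The two
intensities are drawn independently per water mass each Monte Carlo
iteration, representing unresolved mesoscale heterogeneity. Patches are
static in space and time over the 92-day season: no advection, vertical
migration or patch plasticity (and no sub-2-km microscale structure).

### Niche overlap

A predator's trophic niche is three criteria: foraging area (whole domain
for bowhead whales; 150 km discs around colonies for little auks), foraging
depth (all three strata vs the 0–20 m stratum; the auk set is configurable
to {1, 2} for sensitivity runs), and a minimum profitable patch density
(9.4 g m⁻³ vs 13.7 g m⁻³). Accessibility is all-or-nothing at the
water-mass level — if the criteria pass, the entire patch biomass `p·B` is
accessible; background biomass never is. The threshold comparison is
inclusive (≥), which keeps the limit θ → d continuous from below; no
tie-break rule is otherwise defensible.

Consumption is a demand-capped ration: `C = min(N·r·n, Q)` with season
length n = 92 days. Per-capita daily rations are calibration constants
back-solved from the reported mean consumptions and populations: bowhead
1.413 × 10⁶ g day⁻¹ (6.5 Mt over 50 000 whales × 92 d), little auk
294 g day⁻¹ per breeder (0.26 Mt over 9.6 × 10⁶ breeders × 92 d, breeders =
2 × pairs). They are ledger entries, not bioenergetic derivations.

The discrepancy `Qb − Qs` between the niches is attributed per water mass to
the *first* little-auk criterion that fails, in the fixed order geography →
depth → threshold. The order is a reporting convention; because the
criteria are not mutually exclusive, other orders would shift shares between
categories.

### Backcast

`Za = Ca21 / (Qa − Cb21·Y)` is the auks' realised share of their niche net
of current whale consumption, treated as century-invariant (it absorbs
competition with unmodelled zooplanktivores such as polar cod and capelin).
The released consumption `Cb17 − Cb21` reaches auks only in proportion to
the overlap degree Y, of which they capture Za:
`Na17 = Na21 · (Ca21 − (Cb17 − Cb21)·Y·Za)/Ca21`. This is a static
cross-multiplication, not a population-dynamic model. All internal biomass
bookkeeping is in grams; megatonnes (10¹² g) appear only at I/O.

## Monte Carlo propagation

10 000 iterations by default (1 000 in the shipped acceptance run; the
qualitative summaries stabilise well below that). Each iteration draws:

| parameter | law | default | units |
|---|---|---|---|
| `na21_pairs` | normal | 4.8 × 10⁶ ± 3 × 10⁵ | pairs |
| `nb17` | normal | 50 000 ± 2 500 | whales |
| `nb21` | normal | 343 ± 50 | whales |
| `threshold_bowhead_gm3` | normal | 9.4 ± 1.0 | g m⁻³ |
| `threshold_auk_gm3` | lognormal | median 13.7, σ_log 0.267 | g m⁻³ |
| `ration_bowhead_g_day` | normal | 1.413 × 10⁶ ± 10% | g day⁻¹ |
| `ration_auk_g_day` | normal | 294 ± 10% | g day⁻¹ |
| `pb_ratio` | normal | 3.8 ± 0.5 | – |
| `season_fraction` | normal | 0.43 ± 0.05, ≤ 1 | – |
| `copepod_to_meso` | normal | 1.0 ± 0.05 | – |
| `stratum_f1/f2/f3` | normal | 0.45/0.35/0.20 ± 0.04/0.04/0.03, renormalised | – |
| `phi` (per water mass) | normal | 0.084 ± 0.005, (0, 1) | – |
| `p` (per water mass) | normal | 0.415 ± 0.05, (0, 1] | – |
| `biomass_block` (per block) | normal | block mean ± block SD | g m⁻² |
| `season_days`, `foraging_radius_km` | fixed | 92, 150 | d, km |

The auk threshold is lognormal because its reported 95% interval
(7.8–22.2 g m⁻³ around 13.7) is strongly right-skewed; σ_log =
ln(22.2/7.8)/(2 × 1.96) ≈ 0.267 reproduces that interval around the median.
Normal draws are truncated at physical bounds by resampling. Per-block
biomass draws redraw each coarse block's mean as Normal(block mean, block
SD) truncated at zero and scale the block's cells proportionally, mimicking
uncertainty in a coarse-resolution climatology.

An iteration is screened out as unrealistic when any predator's seasonal
demand exceeds the biomass accessible to it (checked for the historical
whale population, the current whale population and the current auk
population, in that order), and additionally when the backcast arithmetic
turns pathological: Za outside [0, 1] or Na17 < 0. The arithmetic screens
extend the insufficiency rule because the backcast equation can go negative
under extreme joint draws; the reasons are logged separately in the records.
Summaries (mean and empirical 2.5/97.5 percentiles, reported as 95%
prediction intervals) use retained iterations only.

Reproducibility: one master seed spawns an independent substream per
iteration (`numpy.random.SeedSequence`), so results are bit-identical across
reruns and independent of execution order.

## Sensitivity analysis

A main-effects ordinary-least-squares ANOVA of the retained iterations'
`Na17` on the sampled global parameter values (per-water-mass fields enter
through their iteration means). Shares are sequential (type I) sums of
squares over the total; draws are independent, so the ordering has a
negligible effect. Interactions are excluded and the unexplained share is
reported as the residual, which also absorbs the per-water-mass sampling
noise that iteration means cannot capture.

## Synthetic domain

The generator emulates the *statistical* structure of the study inputs, not
Arctic geography:

* eight compact islands (2% land) on a jittered lattice at least 200 km from
  the boundary, so every 150 km colony disc fits inside the domain; shelf
  bathymetry deepens with distance to land (multiplicative lognormal noise,
  cap 3 500 m), providing seafloor truncation cases;
* a log-Gaussian biomass field: smoothed white noise (correlation length
  200 km) re-standardised and exponentiated to spatial CV 0.8, then rescaled
  so the sea-cell mean is exactly 33.2 g m⁻². The CV was chosen so the
  whale-accessible fraction of production in the all-means run falls in the
  reported ~14% regime — with uniform production, no water mass would reach
  the 9.4 g m⁻³ patch threshold at these stratum fractions, so the upper
  tail of the spatial distribution is what feeds both niches;
* per-block (5 × 5 cells = 100 km, standing in for one-degree aggregation)
  means and SDs of the field;
* eight colonies spread over the island coastlines by greedy farthest-point
  sampling, splitting 4.8 × 10⁶ breeding pairs by a Dirichlet draw. With the
  defaults the auk foraging mask covers ~518 000 km² and the whale mask
  ~2 262 000 km², both within 10% of the reported 559 000 and
  2 317 000 km².

What passing tests on this domain do **not** show: agreement with the real
copepod climatology's spatial covariance (unknown to us), real coastline and
regional geography (the three pseudo-regions are arbitrary bands), or the
published raster-dependent magnitudes (Qb, discard rate, Na17). Those are
reproduced qualitatively — same ordering, same regimes — not numerically.

## Numerical choices and degenerate inputs

* Biomass conservation (patch + background per water mass) holds to
  floating-point exactness; totals are checked to 10⁻⁹ relative.
* Zero-volume water masses carry zero biomass and zero densities; columns
  whose wet strata sum to zero fraction receive no biomass.
* `W`/`Y` are NaN when the corresponding accessible biomass is zero; the
  discrepancy decomposition returns a flagged empty result when Qb = Qs.
* Truncated sampling resamples up to 1 000 rounds and then clips — reached
  only for pathological override configurations.
* A deterministic run is the all-means draw; with every ledger SD set to
  zero the Monte Carlo mean of each output equals the deterministic value
  exactly.

## Known limitations

* Supply-side patchiness parameters (φ, p) are calibrated to reported
  domain-level shares (8.4% volume, 41.5% biomass), not to optical plankton
  counter profiles; their spatial independence per water mass is an
  assumption.
* The separable production form and the stratum fractions are reconstructions;
  consumption is a demand cap rather than a bioenergetic model.
* Deterministic (all-means) values of nonlinear outputs (Za, W, Na17) differ
  from Monte Carlo means of the same outputs — means do not commute through
  ratios — so point runs and MC summaries should not be compared naively.
* The screening rate depends on the prey-field realisation; on the synthetic
  domain it is higher (~35% at the default CV) than the published
  raster-based rate, because the synthetic upper tail is thinner than the
  real climatology's.
* No behavioural interactions between the predators, no competitor species
  modelled explicitly, no climate or fisheries scenarios.
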