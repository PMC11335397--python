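# nichecast

Deterministic trophic modelling of the competition between bowhead whales
(*Balaena mysticetus*) and little auks (*Alle alle*) for Arctic
mesozooplankton, and backcasting of little auk abundance to a
pre-whaling ocean.

## The problem

Between the seventeenth and nineteenth centuries, whaling reduced the East
Greenland–Svalbard–Barents Sea bowhead population from tens of thousands of
animals to a few hundred, releasing an enormous predation pressure on
*Calanus*-dominated mesozooplankton. The little auk — the Atlantic Arctic's
most abundant seabird and a zooplanktivorous competitor of the bowhead —
plausibly benefited. `nichecast` quantifies that competition release with a
three-stage deterministic model, propagates parameter uncertainty by Monte
Carlo, and decomposes the output variance by parameter.

1. **Prey field.** Column copepod biomass *B* (g m⁻²) on an equal-area grid
   (20 × 20 km cells, depth strata 0–20, 20–50, 50–200 m) is converted to
   seasonal mesozooplankton production, split across strata, and partitioned
   within each *water mass* (cell × stratum, volume *V*) into dense patches
   and diffuse background using two patchiness intensities: the patch volume
   fraction φ and patch biomass fraction *p*. Patch density is
   *d* = *pB*/(φ*V*); biomass is conserved exactly.
2. **Niche overlap.** A predator can exploit a water mass iff the cell is in
   its foraging area, the stratum within its foraging depth, and the patch
   density at or above its profitability threshold θ (bowhead 9.4 g m⁻³ over
   the whole domain and all strata; little auk 13.7 g m⁻³ within 150 km of
   its colonies and the 0–20 m stratum). Accessible biomasses *Qa*, *Qb*,
   the shared amount *Qs*, overlap degrees *W = Qs/Qa*, *Y = Qs/Qb*, and
   demand-capped consumptions *C = min(N·r·n, Q)* follow.
3. **Backcast.** The competitive share *Za = Ca21 / (Qa − Cb21·Y)* is
   assumed time-invariant, and little auk abundance under pre-whaling whale
   numbers is *Na17 = Na21 · (Ca21 − (Cb17 − Cb21)·Y·Za) / Ca21*.

Because the original gridded copepod climatology is an external product, the
package ships a synthetic-Arctic generator producing a statistically
comparable domain: an island-dotted equal-area grid, shelf bathymetry, a
log-Gaussian autocorrelated biomass field with a calibrated 33.2 g m⁻²
sea-cell mean and per-block dispersions, and coastal breeding colonies.

## Worked example

```python
import nichecast as nc

config = nc.RunConfig()                          # 76x76 grid, defaults
inputs = nc.prepare_synthetic_inputs(config, seed=1)
record = nc.deterministic_run(config, inputs)    # all parameters at means

from nichecast.pipeline import report_deterministic
print(report_deterministic(record))
```

prints (abridged):

```
B_Mt                             122.7
patch_volume_pct                 8.4
patch_biomass_pct                41.5
Qa_Mt                            0.6483
Qb_Mt                            10.71
W_pct                            100
Y_pct                            6.052
whale_consumed_frac_17_pct       60.68
Za_pct                           40.22
Na17_Mpairs                      1.895
```

i.e. ~123 Mt of mesozooplankton produced over the 92-day season, 41.5% of it
concentrated in patches filling 8.4% of the water volume; historical whales
could reach 10.7 Mt and would have consumed ~61% of that; auks reach
0.65 Mt, all of it inside the whale niche (W = 100%), and the backcast puts
the pre-whaling auk population at 1.9 million pairs against 4.8 million
today. Monte Carlo propagation (`nc.run_mc`) adds 95% prediction intervals
and screening of unrealistic iterations; `nc.anova_sensitivity` attributes
the variance of the backcast abundance to individual parameters.

The same pipeline is scriptable from the shell:

```bash
nichecast generate --seed 1 --out fixture/
nichecast mc --fixtures fixture/ --iters 1000 --seed 1 --out results/
nichecast sensitivity --records results/records.csv
nichecast backcast --na21 4.8e6 --ca21 0.26 --cb17 6.5 --cb21 0.04 \
    --qa 1.69 --y 0.088 --za 0.256
```

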