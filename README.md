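# eiflux

Inferring canopy rainfall-interception evaporation (E_i) from eddy-covariance
latent heat flux with paired physics-constrained hybrid models.

## The problem

When rain falls on vegetation, part of it is intercepted by leaves and stems
and evaporates back to the atmosphere before ever reaching the soil. This
interception loss E_i shapes how much water is left for soil moisture,
streamflow and plants, yet flux towers do not measure it: the eddy-covariance
latent heat flux LE mixes transpiration, soil evaporation and E_i.

`eiflux` implements an inference scheme that separates E_i from tower LE:

1. **Rain events** are detected in the hourly precipitation record (an event
   starts at P ≥ 0.5 mm h⁻¹, keeps a 6 h tail after the last rain — 12 h at
   night — and events longer than 60 h are re-segmented). Hours inside events
   are *wet*; the rest are *dry*.
2. Two **hybrid models** are trained. Each couples a feed-forward network to
   the Penman-Monteith (PM) equation: the network maps environmental
   predictors (Ta, VPD, Rn, WS, LAI, PFT) to ln R_s, the log surface
   resistance, and LE follows from the PM forward operator — so every
   prediction conserves the surface energy balance (H + LE = R_n − G) and is
   non-negative by construction. The PM variant is *quadratic*: it keeps the
   second-order curvature of the saturation vapor pressure curve, and inverts
   in closed form from LE to R_s.
3. **HM_dry** is trained only on dry hours. Applied to the meteorology of wet
   hours it predicts the counterfactual LE that would have occurred without
   rain. **HM_wet** is trained on wet hours with one extra predictor, the
   canopy water storage (CWS), itself inferred by a third network from LAI,
   PFT and eight descriptors of the ongoing rain event.
4. The difference `predict(HM_wet) − predict(HM_dry)` on identical wet-hour
   forcing is the hourly E_i flux (energy units), converted to mm through the
   latent heat of vaporization and summed per event.

The package also contains the surrounding machinery: FLUXNET-style CSV
ingest with quality filtering, the humidity/rain LE correction and
Bowen-ratio energy-balance closure, upscaling of the trained models to
gridded forcing (LAI spline interpolation, dominant-PFT aggregation,
vegetated-fraction masking, sub-grid light-rain correction), and rainfall
regime metrics (wet-hour and intense-hour fractions, trends, driver
correlations).

Because the real global archives are far beyond a desk-scale test, the
package ships a first-class **synthetic generator**: diurnal/seasonal
meteorology, stochastic rain (Poisson event arrivals, geometric durations,
gamma intensities, persistent cloud cover), a prescribed dry surface
resistance law and a Rutter-type canopy water bucket give every site a known
E_i ground truth, so the full chain can be validated as a parameter-recovery
experiment.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from eiflux import SynthConfig, run_recovery

cfg = SynthConfig(n_sites=5, years=2, noise_sd=10.0, seed=0)
res = run_recovery(cfg)
m = res.metrics
print(f"events: {m['n_events']}")
print(f"event-level Pearson r (estimated vs true Ei): {m['event_pearson_r']:.3f}")
print(f"relative bias: {m['relative_bias']:+.1%}")
print(f"median event Ei/P: {res.event_table['ratio'].median():.1%}")
```

prints (exact values depend on the seed):

```
events: 2182
event-level Pearson r (estimated vs true Ei): 0.925
relative bias: -19.2%
median event Ei/P: 10.3%
```

So across ~2200 synthetic rain events the recovered event totals track the
true interception closely (r ≈ 0.93); the estimate runs somewhat low because
the wet-hour meteorology sits at the edge of the dry model's training
support. The median event-level E_i/P says that for a typical event roughly
a tenth of the rain evaporates back from the canopy under these study
conditions.

The same models can then be pushed onto a grid:

```python
from eiflux import tile_site_to_grid, predict_grid_ei, anchor_ratios
from eiflux.upscale import cws_window_stats

sp = res.sites[0]
grid = tile_site_to_grid(sp.series, f_veg=1.0)
stats = cws_window_stats(res.cws_model.predict(sp.descriptors))
ei = predict_grid_ei(res.hm_wet, res.hm_dry, res.cws_model, grid,
                     stats, anchor_ratios(res.event_table))   # mm h-1 maps
```

A thin CLI covers the site-level steps:
`eiflux simulate`, `eiflux preprocess`, `eiflux detect-events`,
`eiflux recover` (see `eiflux --help`).

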