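# Methods

This note documents the models, the synthetic study conditions, the numerical
choices and the known limitations of `eiflux`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The quadratic Penman-Monteith operator

The physical core couples the surface energy balance with vapor diffusion:

    H  = ρ c_p δT / r_a
    LE = (ρ c_p / γ) · (VPD + Δ δT + ½ k δT²) / (r_a + R_s)
    A  = H + LE,     A = R_n − G

where δT is the surface-air temperature difference, Δ and k are the first
and second derivatives of the Tetens saturation curve at air temperature
(the ½ k δT² term is the "quadratic" extension; the classical equation is
the k = 0 limit), γ the psychrometric constant, R_s and r_a surface and
aerodynamic resistance. Eliminating H and LE gives a quadratic in δT,

    (½ b k) δT² + (a + b Δ) δT + (b VPD − A) = 0,
    a = ρ c_p / r_a,  b = ρ c_p / (γ (r_a + R_s)),

whose physical root is chosen by continuity with the k → 0 closed form (the
"+" branch; where k vanishes numerically the linear root is used directly).
The discriminant can be negative for states that are not physically
consistent (e.g. super-saturated air, or a saturated surface in very hot and
very dry air with little available energy): these raise, or yield NaN on the
prediction path, and the hour is skipped.

The inversion is closed-form: δT from the sensible-heat branch, the surface
saturation pressure from the quadratic expansion, then the resistor equation
solved for R_s and clipped at zero. Inversion is undefined when the
surface-air vapor gradient is non-positive; such hours are excluded from
training. Forward and inverse are exact algebraic inverses — the round trip
is verified to < 1e−6 W m⁻² over 10⁴ random states in the acceptance
script.

Constants: c_p = 1013 J kg⁻¹ K⁻¹; air pressure fixed at 101.325 kPa (the
input schema carries no site pressure); λ(T) = (2.501 − 0.002361 T)·10⁶
J kg⁻¹; γ = c_p P / (0.622 λ); ρ from the dry-air ideal gas law.
Aerodynamic resistance uses the neutral log profile with d = 0.67 h,
z0m = 0.123 h, z0h = 0.1 z0m, κ = 0.41, and wind speed floored at
0.5 m s⁻¹; no stability correction is applied.

The quadratic construction is this module's central interpretive decision
(the hybrid-model lineage it follows states the idea but not the algebra);
it is isolated behind `pm_forward` / `pm_invert` so an alternative form can
be swapped in.

## Rain events and descriptors

An event starts at the first hour with P ≥ 0.5 mm; after each qualifying
hour a 6 h tail is retained (12 h when that hour is at night, night being
solar elevation < 0° at the site latitude), and qualifying hours inside the
tail extend it (rolling lookahead). Events longer than 60 h — tail included
— are re-segmented at hours with P ≥ 1 mm spaced more than 6 h apart, each
sub-event re-receiving its own tail but never crossing the next sub-event's
start; the split is applied once, not recursively. A long span with no hour
≥ 1 mm is discarded with a warning (the rules are silent on this case).
Within an event, maximal runs of P > 0 are rain pulses.

Eight per-hour descriptors feed the CWS network, all computed causally
(using only hours up to the current one): event-cumulative, event-mean and
event-maximum hourly rain, current-hour rain, cumulative and maximum rain of
the last pulse, dry hours since that pulse, and the local solar hour-of-day
at which the last pulse ended (entering the network as sin/cos of the
24-hour phase). Before any pulse has ended, the pulse fields refer to the
ongoing first pulse.

An independent brute-force re-implementation of the rules (iterative
fixed-point growth instead of a greedy scan) serves as the oracle in the
tests; the two agree hour-for-hour on 200 random series per run.

## Preprocessing

Quality filtering masks (never deletes, so event detection sees the original
time axis) hours with missing inputs, negative LE, poor-quality flags
(threshold configurable; FLUXNET gap-fill codes grow worse with magnitude,
default ≥ 2), and freezing air (Ta < 0 °C, excluding snowfall interception).

The humidity/rain LE correction addresses the known underestimation of
eddy-covariance LE in rain and high humidity: a per-site network (1 × 16,
lbfgs) regresses the latent energy ratio LER = LE/(R_n − G − H) on RH and
log-transformed rain (offset 0.01 mm admits P = 0), and LE is rescaled so
its LER sits at the reference level LER(RH = 50 %, P = 0). The fit uses all
hours with positive available energy (wet and dry alike). By construction
the correction factor is exactly 1 at the reference state, and a site whose
LER does not depend on RH or rain is statistically unchanged.

Bowen-ratio closure rescales LE *and* H by (R_n − G)/(LE + H), preserving
their ratio while closing the balance exactly; hours with LE + H ≤ 0 are
flagged and left alone. In the synthetic recovery experiment neither
correction is applied (the generator injects additive noise, not the
humidity bias or closure gap these corrections target); both are exercised
by their own tests.

## Hybrid models

Both flavors share the architecture: standardized numeric predictors plus
one-hot PFT into a 2 × 64 relu MLP (Adam, early stopping on a 10 %
validation split, fixed seed) predicting ln R_s. One-hot encoding was chosen
for PFT because ordinal category values have no meaning for a gradient
model. Training targets are ln R_s from the exact PM inversion of observed
LE — the inversion is a bijection at fixed meteorological state, so matching
ln R_s matches LE through the forward operator; this replaces running the
forward operator inside the loss, which the sklearn backend cannot express.
Resistances below 1 s m⁻¹ (including the clipped wet-canopy limit R_s = 0)
are floored at 1 s m⁻¹ for the log target rather than dropped, so the wet
model is not biased low at the wet-canopy limit.

Because the network estimates the *conditional mean of ln R_s* and LE is
convex in ln R_s, evaluating the forward operator at the point prediction
under-estimates mean LE. Predictions therefore use Duan's smearing
estimator: the forward operator is averaged over 25 quantiles of the
held-out ln R_s residual distribution stored with the model.

The CWS proxy on wet hours is observed LE minus the dry model's
counterfactual baseline; negative proxies (measurement noise) are removed
from CWS training. The CWS network (same architecture) regresses the proxy
on LAI, PFT and the eight rain descriptors; its predictions provide the wet
model's extra predictor both in training and at prediction time, keeping
the two phases consistent. Training pools all sites with uniform sample
weights; hours with undefined inversion are excluded from training but
retained for prediction.

Hourly E_i is the wet-minus-dry LE difference on identical forcing,
converted to depth via λ(Ta); negative differences are removed (not zeroed)
before event aggregation, mirroring how anomalous negative estimates arise
from flux noise. Event E_i/P uses gross event rain including tail-hour rain.
The event-level driver analysis fits E_i/P = p/(x + q) (a rational form —
the coefficients p, q are named but the form is a package choice, isolated
behind `fit_rational`) against rain amount and intensity metrics, and linear
fits against LAI and wind speed, with Pearson correlations throughout.

## Synthetic study conditions

The generator is the package's test bed and defines the study conditions:

* **Meteorology** — seasonal + diurnal temperature harmonics with AR(1)
  noise; net radiation following the solar arc (zero at night), attenuated
  by a persistent AR(1) cloud-cover process. Cloudiness is correlated with
  rain (rain hours are forced mostly overcast) but overcast spells also
  occur in dry weather, as in real climates; this matters because the dry
  model must see humid low-radiation daytime hours outside events for its
  counterfactual to be identified. RH rises with cloud cover and at night
  (90–99 % while raining); VPD follows from the Tetens curve; wind is
  lognormal.
* **Rain** — Poisson event arrivals (default 1 day⁻¹), geometric durations
  (mean 3 h), gamma hourly intensities (shape 1.2, scale 1.5 mm h⁻¹):
  a mid-latitude mix of drizzle and convective bursts.
* **Truth** — surface resistance follows a monotone Jarvis-style law
  (rising with VPD, falling with radiation and LAI); the canopy bucket has
  capacity S = 0.2 mm per unit LAI, intercepts 0.7 of hourly rain up to S
  (free throughfall 0.3), and evaporates at the wet-canopy (R_s = 0)
  potential scaled by the wet fraction C/S — the simplest Rutter variant.
  Observed LE is the dry baseline plus the energy equivalent of E_i plus
  Gaussian noise (default SD 10 W m⁻²); H closes the balance up to that
  noise. The additive composition is the generator's core assumption: it
  matches the subtraction logic of the estimator, so recovery error measures
  estimation quality, not structural mismatch.
* **Network** — `generate_network` cycles five biome archetypes (deciduous
  and evergreen forests, tropical broadleaf, grassland, savanna) with
  distinct LAI ranges, canopy heights and latitudes.

What the generator does *not* emulate: stomatal suppression by leaf wetting,
post-rain soil-evaporation pulses, storage-dependent throughfall dynamics,
advection, energy-balance non-closure, or instrument-specific (open- vs
closed-path) biases. Passing the recovery test therefore shows the inference
chain is correct and well-conditioned under additive composition and noise —
not that these real-world confounds are overcome.

The reference recovery experiment uses 5 sites × 2 years at 10 W m⁻² noise
(≈ 2 200 events, ≈ 26 000 wet training hours) — large enough for stable
network training while the whole pipeline runs in well under a minute on one
CPU. The residual negative bias of the recovered event totals (the tests
assert it stays within ±25 %) comes mostly from the dry model extrapolating
into wet-hour meteorology at the edge of its training support, the same
out-of-support step the method takes on real towers.

## Upscaling

Gridded forcing is an xarray Dataset (time, lat, lon; NetCDF3 via the scipy
engine). Per cell: events are detected from the cell's own rain series,
descriptors and CWS are computed as at sites, and both models predict wet
hours. Non-CWS features are standardized with the site-derived statistics
stored in the models; CWS alone is re-standardized with mean/SD from grid
cells around the training sites (5° windows), because site- and grid-derived
CWS differ systematically and only the wet model consumes it. Predicted E_i
scales with the cell's vegetated fraction. Canopy height per PFT comes from
a documented lookup table (reference height = canopy + 10 m).

8-day LAI composites are interpolated to hourly with a cubic smoothing
spline (small fixed smoothing weight λ = 1e−3, near-interpolating; GCV
selection available), clipped at 0. Dominant PFT is the argmax of merged
IGBP cover fractions, ties broken by the fixed PFT order.

Light rain (0 < P < 0.5 mm outside events) would otherwise contribute no
E_i. Its interception ratio interpolates linearly between the vegetated
fraction at P → 0 (rain over canopy completely intercepted) and the per-PFT
event-derived ratio near 0.6 mm (events with mean hourly rain in 0.5–0.7 mm,
a band wide enough to populate every PFT, with a pooled fallback). The 0.6 mm
anchor lies outside the (0, 0.5) application domain; the line is used there
regardless, which keeps the ratio continuous and piecewise linear.

## Rainfall regimes

The intensity threshold is the 90th percentile (linear-interpolation
convention) of hourly rain over all rainy hours of the full record, fixed
once per cell and undefined below 100 rainy hours. Yearly fractions:
F_rain = share of hours with 0 < P < p90, I_rain = share with P > p90,
denominators counting non-gap hours; dry hours and hours exactly at the
threshold make up the remainder, so the three parts partition each year
exactly. Trends are OLS per year with the two-sided t-test; percent change
is slope × (n − 1) / mean × 100; a constant series reports slope 0, p = 1.
Annual driver correlations are Pearson on raw (non-detrended) series.

## Known limitations

* The quadratic PM algebra is a reconstruction; alternative second-order
  forms would differ in the third decimal of LE but are swappable behind the
  module interface.
* sklearn MLPs preclude the forward-operator-in-the-loss formulation and ELU
  activations; the ln R_s surrogate plus smearing is a close but not
  identical training objective.
* Models are serialized only as in-memory objects; persisting trained
  bundles to disk is left to the caller (pickle works).
* The grid path loops over cells in Python; it is meant for validation-scale
  grids, not production global runs.
* Event-level E_i/P can exceed 1 under noise; values are flagged, not
  clipped.
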