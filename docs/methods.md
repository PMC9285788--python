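# Methods

## Model

A chlorophyll-a profile B(z) is made dimensionless twice over: depth
becomes optical depth τ = z·K_d, and concentration is normalized by the
surface value B_s, taken as the median chlorophyll within the first
optical depth after discarding unrealistically low samples
(< 0.01 mg m⁻³). Working in (τ, B*) space makes profiles from different
seasons and trophic states directly comparable and ties the model's two
inputs (B_s, K_d) to quantities a satellite can observe.

The normalized profile is the sum of two communities:

- **Community 1** (surface mixed layer): a two-parameter sigmoid
  B1*(τ) = 1 − 1/(1 + exp(−(P1/τ1)(τ − τ1))). τ1 is the midpoint of the
  roll-off; P1 = S1·τ1 aggregates midpoint and steepness. The lower
  bound P1 ≥ 4.6 forces B1*(0) = 1 − 1/(1+e^P1) > 0.99: community 1 is
  at least 99% of the surface total. The sigmoid decays to zero at
  depth, unlike the constant-background Gaussian profile models it
  generalizes.
- **Community 2** (deep chlorophyll maximum): a Gaussian
  B2*(τ) = B2m*·exp(−((τ−τ2)/σ)²) with peak height B2m* ∈ [0, 100],
  peak position τ2 and width σ > 0. The constraint τ2 ≥ 3σ keeps the
  Gaussian's surface leakage below e⁻⁹ of its peak — under 1% of the
  surface total for any B2m* ≤ 80.

### Two-step tuning

Profiles need more than 6 usable samples; when Z_m·K_d < 9.2 the fit
uses only τ < 9.2 (twice the euphotic depth) so the deep tail of
stratified profiles does not dominate the residuals, and full profiles
otherwise.

**Step 1** fits the sigmoid alone by bounded least squares
(scipy trust-region reflective; initial guess τ1 = Z_m·K_d, P1 = 9;
bounds P1 ∈ [4.6, 100], τ1 ≥ 0; parameter/function tolerance 1e-8).
If the squared Pearson correlation between observed and fitted B*
exceeds 0.9 the profile is one-community and the step-1 parameters are
kept: community 2 must explain at least 10% of the profile variance to
be admitted at all.

**Step 2** runs only when step 1 fails the gate. P1 and τ1 are then
fixed from empirical relations calibrated on one-community fits from
mixed-water profiles (Z_p < Z_m): τ1 = 0.62·Z_m·K_d + 2.29 and
P1 = 10^(0.08·τ1 + 0.66) (clipped to the P1 box), and the three Gaussian
parameters are fitted. The constraint τ2 ≥ 3σ is enforced exactly by
reparameterization τ2 = 3σ + δ with δ ≥ 0, which keeps the bound sharp
without constraint-aware optimizers. Step-2 initial values are
data-driven: the peak residual over the sigmoid sets B2m* and τ2, with
σ started at τ2/6 (capped at τ2/3 to stay feasible). The two-community
model is retained only if its AIC improves on step 1, with the
least-squares form AIC = n·ln(RSS/n) + 2k (k = 2 for step 1, 3 for
step 2); otherwise the profile reverts to one-community with the
step-1 parameters.

**Uncertainty** comes from a case-resampling bootstrap: (τ, B*) pairs
are resampled with replacement and refitted (default 1,000 replicates);
reported parameters are the per-parameter bootstrap medians with
2.5/97.5 percentile intervals. Replicates whose fit fails are dropped;
more than 50% failures aborts the fit. Per-parameter medians can
violate the joint constraint τ2 ≥ 3σ; if so, τ2 is re-projected onto
the constraint and the result flagged (`medians_reprojected`). Model
selection (r², AIC) always uses the direct full-data fit, so the gate
decision does not depend on the bootstrap; setting `bootstrap_n=0`
short-circuits to the direct fit for fast exploratory runs.

### Backscattering extension

Normalized backscattering b_bp*(τ) = b_bp/b_bp,s (surface median over
the first optical depth, samples above 500 m only) is modelled as
community contributions proportional to the fitted chlorophyll shapes
plus a constant non-algal background:

b_bp* = (1 − b*_bp,k)·B1* + ω2·B2* + b*_bp,k

The surface closure ω1 + b*_bp,k = 1 is substituted in, so only
(ω2, b*_bp,k) are free: initial guesses 0.3 and 0.2, both bounded below
by 0.01, b*_bp,k bounded above by 0.95 (the background may not exceed
95% of surface b_bp). One-community profiles drop the ω2 term. The
community shapes entering this fit are evaluated from the chlorophyll
fit's median parameters (not per-replicate), decoupling the two
bootstraps. Derived coefficients: chlorophyll-specific backscattering
b^B_bp,1 = (1 − b*_bp,k)·b_bp,s/B_s and b^B_bp,2 = ω2·b_bp,s/B_s, and
the background b^k_bp = b*_bp,k·b_bp,s. Despiking (11-sample running
median, nearest-edge padding) is available for reporting only; fits
always see the raw normalized data.

## Environmental context

- **K_d**: log-linear least squares of ln(PAR) on depth over the top
  100 m (≥4 positive daytime samples). Log-space fitting is closed-form
  and matches a multiplicative error model for PAR. Fallback when PAR
  is missing or the profile is nocturnal: K_d = 0.036·B_s10 + 0.049
  with B_s10 the mean chlorophyll in the top 10 m.
- **Daily PAR**: day length from the standard solar-declination /
  hour-angle formula; the instantaneous measurement is mapped to the
  noon amplitude of a sinusoidal light cycle via its time since local
  sunrise, and the daily integral is (2D/π)·E_noon, reported in
  mol quanta m⁻² d⁻¹. Night-time measurements are disregarded. Layer
  means (mixed layer; between Z_m and Z_p) are computed analytically
  from the Beer-Lambert profile with the fitted K_d rather than from
  the sampled PAR, which keeps them consistent with the K_d actually
  used elsewhere.
- **Density / N²**: EOS-80 (UNESCO 1983) in-situ density and potential
  temperature, implemented in `phytopart.seawater` and verified against
  the published check values (e.g. ρ(35, 5, 0) = 1027.67547). N² is
  computed from potential density referenced to the surface, by
  adjacent differences at layer midpoints. The stratification index is
  the trapezoid-weighted mean N² over τ ≤ 6.9 (1.5 × the euphotic
  depth), interpolated to the τ limit.
- **Mixed-layer depth**: the temperature algorithm follows the
  Holte-Talley construction — candidate depths from the ΔT = 0.2 °C
  threshold (10 m reference, interpolated to the exact crossing), the
  steepest adjacent-gradient segment, and the intersection of a fitted
  mixed-layer line with the local thermocline line; the fit
  intersection is preferred when it agrees with the threshold within
  25%, otherwise the threshold depth is used. A profile that never
  exceeds the threshold is flagged fully mixed with Z_m at the deepest
  sample. The plain threshold method is available by configuration.

## Phenology

Per community, modelled chlorophyll is reconstructed on each profile's
depth grid and trapezoid-integrated to z = 6.9/K_d; an absent community
contributes zero. The series is linearly interpolated to daily steps,
smoothed with a 15-day Savitzky-Golay filter (order 2 — the lowest
order that tracks bloom curvature; nearest-edge mode), and compared
with a threshold of 1.05 × the window median ("median plus 5%",
multiplicative; an amplitude-based variant is configurable). The
gradient of the cumulative anomaly sum marks initiation (first day it
turns positive and stays positive for more than 15 days, i.e. ≥16
consecutive days) and termination (first subsequent day it turns
negative with the same persistence); duration is the difference. No
qualifying initiation is an explicit no-bloom result. Annual windows
are caller-supplied so each community's window can start in its
low-chlorophyll season. Because detection is relative to the median,
results are invariant to rescaling the series.

A known property: smoothing a sharp bloom edge with the 15-day filter
moves the detected threshold crossing outward by several days at each
edge, so a smoothed 150-day boxcar reads a few days long (~157 d); on
the unsmoothed daily series the edges are recovered to within ±5 days.

## Synthetic scenarios

The generator forward-evaluates the model equations onto a 1-m grid
(0–300 m) and emulates a subtropical seasonal cycle of the northern
Red Sea type: deep winter mixed layers (180 m) with elevated uniform
chlorophyll (B_s 0.5 mg m⁻³, community 1 active roughly
November–March), and summer stratification (Z_m 20 m, B_s
0.08 mg m⁻³) with a DCM at 100 m (community 2 active roughly mid-April
to mid-October, peak B2m* = 3). K_d follows the empirical chlorophyll
relation so the scenario is optically self-consistent; τ1 and P1
follow the empirical Z_m·K_d relations; backscattering uses ω2 = 0.3,
b*_bp,k = 0.2 and b_bp,s = 1.75e-3 m⁻¹ (background 3.5e-4 m⁻¹, a
realistic non-algal level for clear subtropical water). Temperature
and salinity are smooth two-layer profiles whose transition sits at
the prescribed Z_m; PAR is Beer-Lambert with a sinusoidal-day surface
value. Noise is multiplicative Gaussian (relative σ 0.05 on
chlorophyll, b_bp and PAR) — fluorometric and backscatter noise scale
with signal — and a fixed seed makes output byte-identical.

What the generator does **not** emulate: mixing dynamics, eddies and
subduction, double DCMs, depth-varying carbon-to-chlorophyll ratios,
fluorescence quenching artefacts, or sensor spikes. Passing tests on
these scenarios therefore demonstrate correctness of the fitting
machinery and the seasonal logic, not robustness to every pathology of
real float data; the model is explicitly not designed for double-DCM
profiles.

## Numerical choices and edge cases

- Bounded fits use scipy's trust-region reflective least squares with
  tolerances 1e-8 (1e-10 for the near-linear backscattering fit); the
  backscattering solution is insensitive to swapping the two initial
  guesses.
- Surface medians and the B_s floor make normalization robust to
  individual bad samples; profiles with no valid surface sample, or
  N ≤ 6, are skipped with a logged reason and never abort a run.
- Column integrals interpolate linearly to the integration limit; a
  limit above the shallowest sample is an error, and a limit beyond
  the deepest sample truncates at the profile bottom.
- `integrate_column`, `stratification_index` and the layer-mean light
  all agree with fine-grid quadrature to well under 1% on the test
  profiles.
- Degenerate phenology inputs (duplicate timestamps) are averaged with
  a warning; series shorter than the smoothing window are an error.
- Bootstrap seeds are configuration values, so confidence intervals
  are reproducible; the pipeline is deterministic end-to-end for a
  fixed seed.

## Problem sizes

Tests and the acceptance script use 50-point dimensionless profiles,
100 simulations per stochastic check, and 200 bootstrap replicates
(the production default is 1,000); the synthetic seasonal scenario is
111 profiles at 5-day cadence. These sizes keep the whole suite at a
few minutes while leaving all rates (CI coverage, model selection)
well resolved.

## Known limitations

- The empirical τ1/P1 relations are calibrated for one float record;
  other regions need re-derivation (a pooled regression over
  one-community mixed-water fits reproduces them).
- Percentile bootstrap intervals for the constrained step-2 parameters
  (τ2, σ are strongly correlated near τ2 = 3σ) run slightly
  anti-conservative: coverage of nominal 95% intervals sits near
  90–95% at 5% noise.
- The Holte-Talley temperature algorithm is re-implemented in its core
  construction (threshold/gradient/fit-intersection candidates), not
  ported line-for-line; on smooth thermoclines the two differ by a few
  metres.
- K_d is treated as exact when mapping τ = z·K_d; uncertainty in K_d
  is not propagated into the partition.
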