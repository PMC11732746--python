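# Methods

## Measurement model

A marine snow catcher closes at depth, is brought on deck and left to
stand for a settling period t (default 2 h). Particles are classed by
what they did in that window: stayed in suspension (sampled in the
*top* section), settled into the *base* section (slow-sinking), or
settled the full catcher height onto the collection *tray*
(fast-sinking). The pool concentrations follow from volume bookkeeping:

- P_susp = P_top — the suspended pool is whatever remains up top;
- P_slow = (P_base − P_top) · V_base/V_MSC — base enrichment over the
  top, diluted back to the whole catcher volume;
- P_fast = (P_tray − P_base) · V_tray/(A_tray·h·1000) — tray enrichment
  over the base, normalized by the tray collection geometry; the
  syphoned-tray variant (P_tray* − P_base) · V_tray*/V_MSC covers
  deployments where a larger volume was drawn from around the tray.

Fluxes: F_slow = P_slow · V_MSC/(A_MSC·t·1000), which for a cylindrical
catcher reduces to P_slow·h/t — the settled mass is attributed to
particles traversing at most the catcher height within t. F_fast =
P_fast · v_fast with an *assumed* bulk sinking velocity, because tray
material sank faster than h/t and its true speed is unidentifiable from
the catcher alone. Because 1 µg l⁻¹ ≡ 1 mg m⁻³ (1 µmol l⁻¹ ≡
1 mmol m⁻³), a concentration times a velocity in m d⁻¹ is directly a
flux in mg (mmol) m⁻² d⁻¹.

Signed negative slow pools (base less concentrated than top — an upward
flux of material, or plain measurement noise) are preserved through the
partition and flux stages; clamping to zero is available as an explicit
switch (`clamp_negative_slow`) for sensitivity checks only, and a report
quantifies the difference between the signed and clamped totals.

## Instrument constants

| constant | default | unit | note |
| --- | --- | --- | --- |
| V_MSC | 95 | l | full catcher |
| V_base | 8 | l | base section |
| V_tray | 1 | l | nominal, approximate — overridable |
| A_tray | 0.026 | m² | tray collection area |
| h | 1.58 | m | catcher height |
| t | 2 | h | settling period; converted to days internally |
| A_MSC | V_MSC/(h·1000) ≈ 0.0601 | m² | derived assuming a vertical cylinder (not printed on the instrument sheet) |

All are config-overridable; validation enforces positivity,
V_tray < V_base < V_MSC, and consistency of A_MSC with V_MSC/h to 1e−9
relative.

## Sinking velocities

Per-cruise defaults: 60 m d⁻¹ (DY086; in-situ particle-specific and
polonium-derived velocities) and 40 m d⁻¹ (DY111; thorium-derived
velocities and nutrient-budget closure). Because v_fast is the dominant
structural uncertainty, two sensitivity analyses are built in:

1. a uniform-velocity grid, default {20, 40, 60, 100} m d⁻¹ — 20 is
   near the catcher's own theoretical lower limit (h/t ≈ 19 m d⁻¹);
2. depth-split schemes using the (40, 60) m d⁻¹ pair: *minimized b*
   gives 40 to deployments shallower than the arithmetic midpoint of
   the profile's depth range and 60 to deeper ones (inflating deep
   fluxes, flattening the fit); *maximized b* swaps them. Deployments
   exactly at the midpoint count as shallow (documented tie-break).

The velocity actually used is stored on every flux record.

## Uncertainty propagation

First-order propagation with independent errors: differences add
standard deviations in quadrature, multiplicative constants scale them
linearly, and the total-flux sd combines slow and fast in quadrature.
Deployments without reported sds yield null (not fabricated) output
sds.

## Attenuation fits

Profiles pool total fluxes per substance by either convention —
per-occupation (one profile per station occupation) or per-station
(occupations merged). The reference depth z₀ is the shallowest depth
actually present in each pooled profile. The Martin exponent comes from
OLS of ln F on ln(z/z₀): b = −slope, with the slope's OLS standard
error. The log-log linear model was chosen over nonlinear least squares
in flux space because the reported uncertainties are standard errors of
linear models; an inverse-variance weighted variant (delta-method
weights (F/sd)²) sits behind a flag, unweighted being the default.
Non-positive total fluxes have no logarithm; they are excluded and
counted in `n_excluded_nonpositive`, and a profile with fewer than
three positive points is flagged unfittable rather than fitted.

The 95% confidence interval on b uses the Student-t quantile with
n − 2 degrees of freedom. With the 3–5 point profiles this instrument
produces, the normal-approximation ±1.96·se interval would cover the
truth only ~81% of the time at n = 4; the t interval is the honest
small-sample choice and its empirical coverage on the synthetic
conditions is 94–97%.

Ties in the fit are absent by construction (depths are distinct within
a deployment scheme); repeated fits of the same profile are
byte-identical because the OLS path is deterministic.

## Stoichiometry

BSi is molar, POC is mass; POC divides by 12.011 g mol⁻¹ (standard
atomic weight of carbon) before any ratio. Total-sinking ratios sum
slow and fast pools first, applying the **magnitude rule**: a negative
slow concentration contributes its absolute value to the fast pool.
The rule is applied only to the total-sinking sum; per-fraction ratios
(time-zero, suspended, slow, fast) are computed directly and flagged if
negative. A zero-or-negative denominator after the rule yields a
flagged NaN record, never a silent drop. Aggregation is the arithmetic
mean with the n−1 sample standard deviation (null for singletons),
deployments weighted equally within a group.

## Deep projection

Below the deepest measurement, fluxes extend by the fitted power law or
by an exponential F(z) = F_a·exp(−(z−z_a)/v) with remineralization
length scale v. Depth in the exponential is measured below the anchor
so the curve is continuous at z_a — an absolute-depth reading of the
exponent would introduce a discontinuity there; that literal variant is
available behind `absolute_depth_exponent` for comparison. The
projected molar-ratio profile is the elementwise ratio of the projected
BSi flux to the mol-converted POC flux. Under the power law the ratio
varies as z^−(b_BSi−b_POC), so faster BSi attenuation forces a
decreasing deep ratio.

## Synthetic campaigns

The generator inverts the measurement model exactly: a power-law true
total flux per substance is split into slow/fast pools by a constant
`slow_fraction`, the partition and flux equations are solved for the
fraction concentrations given a suspended background and a true bulk
velocity, and each *measured* fraction (t0, top, base, tray) is then
multiplied by independent mean-preserving lognormal noise (log-scale
mean −σ²/2, σ² = ln(1+cv²)). Lognormal multiplicative noise was chosen
over additive Gaussian because concentrations are positive and span
orders of magnitude. All randomness flows from one integer seed through
a single `numpy.random.Generator`.

Default study conditions: depths MLD+10, MLD+110, 400, 700 m with
MLD = 50 m (typical summer Southern Ocean mixed layer); b = 1.0 and
f₀ = 5 mmol m⁻² d⁻¹ for BSi, b = 0.4 and f₀ = 200 mg m⁻² d⁻¹ for POC
(within the observed b ranges and giving a ~0.3 mol mol⁻¹ export-depth
sinking ratio); suspended backgrounds 1 µmol l⁻¹ BSi, 50 µg l⁻¹ POC,
0.5 µg l⁻¹ Chl; slow_fraction 0.3; v_fast 40 m d⁻¹; noise cv 0.2. A
small *negative* slow_fraction generates the upward-slow-flux pathology
that exercises the magnitude rule. Monte-Carlo summaries in the tests
and the acceptance script use 500 replicate profiles, a size at which
the median and coverage statistics are stable to well under their
assertion margins.

What the generator does **not** emulate: depth-varying slow/fast
partitioning, correlated errors between fractions or substances,
particle aggregation or remineralization inside the catcher, advective
decoupling between deployment depths, or sample-volume-dependent
analytical uncertainty. Passing tests therefore demonstrate that the
*inference chain* is correct under the stated statistical assumptions,
not that those assumptions hold at sea. The time-zero sample is emitted
(closing exactly over the three pools in the noise-free case) but no
closure constraint is enforced on real data, where the equivalence is
not guaranteed.

## Numerical notes and edge cases

- Inversion feasibility: a true flux too small relative to the
  geometry and background can demand negative base/tray
  concentrations; the generator raises a parameter error with guidance
  instead of emitting impossible data.
- CSV round trips are bit-exact (full-precision write, round-trip float
  parsing); a 6-significant-digit output mode exists for human-facing
  tables.
- A perfect power-law profile gives a zero residual sum of squares; the
  fit reports R² = 1 there rather than evaluating 0/0.
- Negative sds, non-positive depths/velocities, unknown substances,
  duplicate (deployment, substance, fraction) keys and ambiguous
  dual-tray deployments are all rejected with named errors.

## Known limitations

- Bulk velocities only: no particle-size- or density-resolved velocity
  spectra.
- The attenuation alternatives are limited to the power law and the
  anchored exponential; transfer-efficiency metrics beyond these are
  out of scope.
- The workbook importer relies on fuzzy header matching; genuinely
  novel layouts need the explicit mapping override.
- Martin-b standard errors are plain OLS (not
  heteroscedasticity-robust), matching the linear-model convention the
  uncertainties are reported under.
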