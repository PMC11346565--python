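# Methods

This note documents the models behind `heatadapt`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions that matter.

## Study design assumed throughout

A seasonal heat-acclimatization design: 15 adolescents (5 female) complete
a heat response test (HRT) before and after an austral summer. Each HRT is
10 min seated rest followed by 45 min walking at 60% V̇O₂peak in a 40 °C /
30% RH chamber; gastro-intestinal temperature (T_gi) is telemetered every
15 s, four skin sites every minute, heart rate every 5 min, and two 4-cm²
ventilated capsules (back, forearm; 500 mL·min⁻¹ anhydrous air, 0.2 Hz
hygrometry) record local sweating. Resting hematology comes from CO
rebreathing; summer exposure from hourly meteorological records and
one-week activity diaries with a waist accelerometer.

## Thermometry

Mean skin temperature uses the 30/30/20/20 chest/shoulder/thigh/calf
weighting. Telemetry QC rejects samples outside 30–43 °C or jumping more
than 0.5 °C per 15-s step from the last accepted sample (capsule dropouts
read near zero); rejected points are linearly interpolated and a trace with
more than 20% rejections is declared unusable. The jump threshold and
rejection cap are package choices — capsule telemetry QC conventions are
not standardized — and both are keyword arguments.

Two genuinely open choices, made explicit and configurable:

* **Resting baseline** = the mean of the final 5 min of the 10-min rest
  (the first minutes carry instrumentation transients). The window length
  is a keyword argument.
* **Rise in T_gi** is referenced to the exercise-onset sample rather than
  the temperate-room baseline, matching how exercise thermal strain is
  tabulated in this literature; end-exercise values are the final sample
  before 45 min or before a 39.5 °C safety stop, and exercising means run
  over the same truncated window.

## Local sweat rate and sweating onset

LSR = ρ_v(RH, T)·flow/area, with the water-vapor density from the
saturation pressure (Antoine-type form 0.61121·exp(17.502·T/(240.97 + T)),
valid −20…60 °C) scaled by RH and converted through the ideal-gas law
(R_v = 461.52 J·kg⁻¹·K⁻¹). The psychrometric formulation is a package
choice; it reproduces tabulated saturation vapor densities within 1%.

The onset model is LSR(t) = a for t ≤ t₀ and a + b·(t − t₀) after. The
breakpoint is found by exhaustive search over the observed sample times
(the 5-s hygrometry grid), with closed-form least squares for (a, b) at
each candidate; ties break toward the earliest t₀. This guarantees the
global optimum on the grid — matching the data resolution rather than
pretending to continuous precision. A trace whose segmented fit does not
beat a flat line (F-test, α = 0.05, df 2 and n − 3) has no detectable
onset. Thermosensitivity is the post-onset slope **versus time**
(mg·cm⁻²·min⁻¹·min⁻¹); the onset is additionally referenced to core
temperature by interpolating the cleaned T_gi trace at t₀. The two capsule
sites are fit independently.

Whole-body sweat loss: nude mass change from clothed and clothing masses
(so sweat trapped in clothing counts as sweat produced), plus fluid intake,
minus respiratory water loss. Respiratory water is estimated from the
calorimetric respiratory evaporative flux (E_res/λ with λ = 2426 J·g⁻¹)
because measured ventilation is typically unavailable in this design.

## Partitional calorimetry

Single steady-state balance per visit (no transient heat-storage model).
Coefficients follow the standard partitional-calorimetry literature:
h_c = 8.3·v^0.6; linearized radiative coefficient with ε = 0.95 and
A_r/A_D = 0.70; mean radiant temperature equal to air temperature inside
the chamber; respiratory terms C_res = 0.0014·M·(34 − T_a) and
E_res = 0.0173·M·(5.87 − P_a); E_max = 16.5·h_c·BSA·(P_sat(T_sk) − P_a)
via the Lewis relation; Du Bois body surface area. The metabolic energy
equivalent of O₂ interpolates 19 630–21 130 J·L⁻¹ over RER 0.7–1.0 (RER
clamped at 1.0). All constants are keyword arguments and the assumptions
are recorded on the result object. Clothing resistance is omitted
(minimal-clothing exercise); that is a documented limitation, not a toggle
the defaults hide.

**Chamber air velocity** defaults to 0.3 m·s⁻¹. Chamber air movement for
treadmill walking is rarely printed; with the coefficients above, the study
condition (40 °C, 30% RH, V̇O₂ ≈ 36 mL·kg⁻¹·min⁻¹, T̄sk 36.3 °C, 57-kg
adolescent) gives E_req/E_max ≈ 1.5 at 0.3 m·s⁻¹ — inside the 1.4–2.2
uncompensable range this protocol reports — whereas at 1 m·s⁻¹ the same
balance is compensable (ratio ≈ 0.75). The default therefore encodes the
low-air-movement chamber convention; the ratio crosses 1 near 0.6 m·s⁻¹,
which is worth remembering when comparing across laboratories.

## CO-rebreathing hematology

Hb mass = CO_absorbed·100/(ΔHbCO·1.39), with the Hüfner capacity
(1.39 mL CO·g⁻¹) configurable; the single `co_unabsorbed` field absorbs the
exhaled/lung-residual accounting. Volumes: BV = Hb/[Hb]·100;
RCV = BV·hct·0.91 (f-cell); PV = BV − RCV. When [Hb] is not measured it is
reconstructed from hematocrit via an assumed MCHC of 33 g·dL⁻¹ with a
warning. Duplicate typical error is SD(differences)/√2 as a percentage of
the grand mean.

## WBGT reconstruction

Solar irradiance: solar position from the standard fractional-year
declination/equation-of-time series; global horizontal irradiance
S = 1367·cos z·0.75^(1/cos z), attenuated by clouds as 1 − 0.75·c^3.4;
zero below the horizon. Timestamps are local standard time; the timezone
defaults to the longitude's nominal meridian.

Globe and natural wet bulb are iterative energy balances in the Liljegren
spirit: the 150-mm globe balances absorbed shortwave (α = 0.95, effective
solar view factor 0.40, lumping the sphere's projected-area fraction with
diffuse and ground-reflected radiation) against convection (sphere Nusselt
correlation) and longwave exchange with surroundings at air temperature;
the wet wick (7-mm cylinder) balances evaporation (Lewis-relation coupling,
16.5 °C·kPa⁻¹) against convection, longwave and absorbed solar (α = 0.70,
view factor 0.30). Both residuals are monotone in the unknown temperature,
so the iteration is a bracketed Brent solve (tolerance 0.005 °C, ≤ 100
iterations; non-convergence raises). In the no-sun limit the wick balance
reduces to the psychrometric wet bulb to within the small radiative term
(< 0.5 °C for winds ≥ 1 m·s⁻¹), and the globe returns the dry bulb
exactly. The solar view factors are the one place this reconstruction is
genuinely calibrated by judgment; 0.40 puts daytime globe excursions
(T_g − T_db ≈ 10–12 °C under ~550 W·m⁻² and 2 m·s⁻¹ wind) where summer
field reports put them.

WBGT = 0.7·T_nw + 0.2·T_g + 0.1·T_db. Daytime summaries use the 08:00
(inclusive) to 18:00 (exclusive) clock-time window — clock time, not solar
time, is the documented choice — and drop days with under 50% window
coverage.

Accelerometry: vector magnitude per 60-s epoch; MVPA at ≥ 2690
counts·min⁻¹ (the conventional Freedson vector-magnitude cutpoint —
configurable); non-wear is ≥ 60 consecutive zero epochs; days with under
60 min of wear do not contribute. Diary RPE bands: 1–3 light, 4–6
moderate, 7–10 high; time-of-day histogram in 3-h bins.

## Inference

Scalar outcomes: y_ij = β₀ + β₁·[post] + β₂·(V̇O₂peak_i − mean) + u_i +
ε_ij, u_i ~ N(0, τ²), ε ~ N(0, σ²). Priors are weakly informative on the
outcome's own scale: N(0, (10·SD(y))²) on the intercept,
N(0, (2.5·SD(y)/SD(x))²) on the period indicator and covariate, and
half-N(0, 2.5·SD(y)) on τ and σ. The exact prior scales are package
decisions, not reproductions of any particular analysis. The covariate is
centered at the arithmetic mean, so the intercept and period effect are
estimates at the mean V̇O₂peak.

The sampler is Gibbs: joint conjugate normal draw for the coefficients,
independent normal draws for the participant intercepts, and univariate
slice-sampling steps for τ and σ under their half-normal priors. Two extra
moves repair the classic mixing pathologies of the centered
parameterization: an ancillarity–sufficiency interweaving re-draw of τ with
u/τ held fixed (a truncated-normal conditional), and a translation move
along the likelihood-invariant direction (β₀ + m, u − m). With these, all
parameters reach split-R̂ < 1.01 at the default 4 chains × 2500 draws
(500 warmup). Sampling is invariant to input row order because rows are
canonically sorted before fitting. Convergence diagnostics (split-R̂,
autocorrelation-based ESS) are computed in-package.

Posterior summaries are means with equal-tailed 90% credible intervals
(90% rather than 95% for quantile stability at moderate draw counts), and
Pd = 100·max(P(θ>0), P(θ<0)). The companion identity
Pd = 100·Φ(|mean|·2z/(CrI width)), z = Φ⁻¹(0.95), recovers Pd from printed
summaries under posterior normality; on exactly normal posteriors it agrees
with the draw-based Pd within one percentage point, which is what makes
published mean/CrI/Pd triples checkable without the original draws.

Time courses (5-min cadence signals): period-specific cubic B-splines
(default 8 basis functions, second-difference penalty as a normal prior on
coefficient differences, conjugate gamma update for the penalty precision)
plus shared participant intercepts; residual and intercept variances use
inverse-gamma conjugate updates here, a deliberate simplification of the
scalar-model machinery. This hierarchical penalized-spline model is a
simpler stand-in for thin-plate-spline HGAMs: it reproduces the estimands
(period curves, bands, time-resolved contrast) without a probabilistic-
programming engine, and ordinal perceptual scales are analyzed with the
same Gaussian machinery, flagged as an approximation.

## Synthetic data: what it does and does not emulate

Generator defaults are the study conditions: cohort anthropometry
(56.84 ± 9.05 kg, 1.70 ± 0.08 m, V̇O₂peak 60.4 mL·kg⁻¹·min⁻¹), outcome
baselines and pre→post shifts matching the published pre/post summaries
(e.g. resting T_gi 37.28 → −0.19 °C, resting HR 80 → −7, rise in T_gi
1.78 → −0.22), between/within dispersions set so the implied 90% CrIs are
on the printed scale, a Canberra-like meteorological half-year (annual mean
12.5 °C, seasonal amplitude 7 °C peaking mid-January, diurnal amplitude
5.5 °C peaking 15:00, AR(1) hourly noise, humidity anti-correlated with
the diurnal anomaly, gamma winds, beta daily cloud), and activity weeks
with 7 h·wk⁻¹ outdoors, 49% of outdoor bouts starting 15:00–18:00 and 28%
05:00–08:00. Day-to-day within-participant variability of T_gi is not
reported in this literature; the within-SD defaults are stated in
`OUTCOME_DEFAULTS`, not asserted against any source.

Templates: T_gi rises logistically (midpoint 15 min, scale 6 min,
normalized to hit baseline and baseline + rise exactly at 0 and 45 min) —
monotone and plateauing, the functional form itself being unconstrained by
any published equation; skin temperature and heart rate saturate
exponentially; LSR is flat-then-linear, capped at a plateau, which matches
the segmented-regression estimand by construction. Capsule noise is
injected on the LSR scale and converted exactly into effluent humidity, so
the hygrometry step inverts it without approximation. One random stream is
spawned per signal per visit, so adding a signal never perturbs the others.
Every generator is byte-reproducible under a fixed seed.

For estimator-recovery studies (onset 10 min, sensitivity
0.05 mg·cm⁻²·min⁻¹·min⁻¹, noise 5% of the end-of-bout level), the plateau
cap is set above the reachable range so the trace is genuinely
flat-then-linear over the whole bout; a 45-min linear rise at that
sensitivity would otherwise hit the default plateau near 36 min and bias
the breakpoint.

What passing tests on these data do **not** show: real capsule telemetry
has burst dropouts and drift, real sweating onsets are not perfectly sharp,
real weather has fronts and serial cloud structure, and real pre/post
effects need not be additive on every outcome's scale. The generator
validates the estimators' mechanics and calibration under the stated
conditions, not their robustness to every field artifact.

## Problem sizes used by the validation runs

Segmented-regression recovery uses 200 synthetic traces; hierarchical
calibration uses 500 simulated cohorts fit with 2 chains × 350 draws after
150 warmup (coverage of the 90% CrI lands at 90–91% with posterior-mean
bias below 0.1 within-participant SD); the WBGT solver grid uses 10 000
random physical inputs; the duplicate-rebreathe error uses 5000 pairs. The
full validation script runs in about a minute on one core.

## Known limitations

* Steady-state calorimetry only; no time-resolved heat storage.
* The WBGT reconstruction is an energy-balance model, not a measurement;
  its absolute level depends on the solar view factors discussed above.
* Ordinal perceptual outcomes are treated as Gaussian.
* The CO-rebreathing model has no diffusion kinetics; unabsorbed CO is a
  single lumped correction.
* No sweat-electrolyte chemistry; sweat [Na⁺] passes through as a measured
  covariate.
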