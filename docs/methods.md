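# Methods

This note records the model equations as implemented, the assumptions
behind them, the numerical choices, and what the synthetic forcing does
and does not exercise.

## Two-source combination scheme

The surface is modelled as two vapour sources — foliage and soil — that
mix at an in-canopy "source height" before coupling to the atmosphere
at a reference height.  With Δ the saturation-curve slope (kPa K⁻¹), γ
the psychrometric constant, ρc_p the volumetric heat capacity of air, A
and A_s the available energy of the whole surface and of the soil
(A = R_n − G, A_s = R_n e^{−κ_R·LAI} − G), the total latent heat flux
is

    λET = C_c·PM_c + C_s·PM_s

    PM_c = [Δ·A + (ρc_p·D − Δ·r_ac·A_s)/(r_aa+r_ac)] / [Δ + γ(1 + r_sc/(r_aa+r_ac))]
    PM_s = [Δ·A + (ρc_p·D − Δ·r_as·(A−A_s))/(r_aa+r_as)] / [Δ + γ(1 + r_ss/(r_aa+r_as))]

with weights C_c, C_s built from the branch resistances
R_a = (Δ+γ)r_aa, R_c = (Δ+γ)r_ac + γ·r_sc, R_s = (Δ+γ)r_as + γ·r_ss.
The vapour pressure deficit at the source height,

    D_o = D + [Δ·A − (Δ+γ)·λET]·r_aa/(ρc_p),

drives the partition

    λT_c = [Δ(A−A_s) + ρc_p·D_o/r_ac] / [Δ + γ(1 + r_sc/r_ac)]
    λE_s = [Δ·A_s   + ρc_p·D_o/r_as] / [Δ + γ(1 + r_ss/r_as)],

and λT_c + λE_s ≡ λET is an algebraic identity of the scheme, verified
to machine precision over randomised states.  Negative component fluxes
(dew, condensation) are preserved, never clipped, so the energy
bookkeeping stays exact.  Infinite resistances are handled analytically
(closed stomata ⇒ C_c·PM_c → 0; sealed soil ⇒ C_s·PM_s → 0), and in
those limits the scheme reduces exactly to a single-source
Penman–Monteith form, which the tests assert.

The conductance inversion solves the same system for r_sc given a
measured λET.  The system is triangular — D_o depends only on the
measured total flux, λE_s only on D_o — so the solve is direct and the
forward–inverse round trip is exact.  Half-hours with implied
λT_c ≤ 0 (night, condensation) return a missing conductance.  A
`measured_vpd` switch substitutes the reference-height D for D_o.

## Canopy radiative transfer

Beam and diffuse PAR are tracked separately.  For a spherical
leaf-angle distribution the black-leaf beam extinction is
κ_b = G_L/cos ζ; scattering softens extinction to κ√α and produces
canopy reflectances ρ_cb = 1 − exp(−2ρ_h·κ_b/(1+κ_b)) with
ρ_h = (1−√α)/(1+√α).  The diffuse reflectance ρ_cd is the hemispheric
integral of ρ_cb over a uniform sky, weighted by 2·sin ζ·cos ζ; for
α = 0.8 this gives 0.0489.  (Tabulated literature values near 0.036
come from a different multilayer computation; since ρ_cd only enters as
1−ρ_cd on the diffuse stream, the two choices differ by ~1.3% of
absorbed diffuse PAR.  The quadrature is kept because it is consistent
with our own ρ_cb.)

Whole-canopy and sunlit-fraction absorbed PAR are closed-form depth
integrals of the layer equations (sun/shade theory): the sunlit
fraction absorbs the entire direct beam α·Q_ob(1−e^{−κ_b·LAI}) plus the
sunlit-weighted parts of the diffuse and down-scattered beam streams;
the shaded fraction is the remainder, clamped at zero against
floating-point cancellation at tiny LAI.  Sunlit leaf area is
LAI_sl = (1−e^{−κ_b·LAI})/κ_b, saturating at 1/κ_b.  These closed forms
are validated against 1000-layer trapezoid quadrature of the layer
equations (≤0.1% everywhere tested).

## Stomatal conductance and upscaling

Leaf conductance is multiplicative Jarvis–Stewart:
g_s = g_smax · F_Q · F_D · F_w with

* F_Q = Q/(Q+k_Q) — rectangular hyperbola in absorbed PAR;
* F_D = e^{−k_D·VPD} (a 1/(1+k_D·VPD) alternative is switchable);
* F_w = (1−e^{−k_w·θ_E})/(1−e^{−k_w}) — normalised so F_w(1) = 1; with
  k_w = 7.5 the function is near saturation by θ_E ≈ 0.5, matching the
  usual crop-stress threshold at half the total available water.

Upscaling routes:

* big-leaf: G_sc1 = g_s(Q_c/LAI, D, θ_E) · LAI_e with the empirical
  effective LAI (LAI below 2, LAI/2 above 4, else 2.0).  A flag selects
  Q_c/LAI_e as the mean irradiance instead.
* dual-leaf: G_sc2 = g_sl·LAI_sl + g_sh·LAI_sh, each mean leaf driven
  by its fraction's mean absorbed irradiance.

Because F_Q is concave, pooling all leaves at the mean light
over-predicts the multilayer integral (Jensen's inequality); the
dual-leaf sum retains a much smaller gap because the within-class light
spread is smaller.  Measured against a 1000-layer oracle that
integrates g_s over the sunlit and shaded profiles separately, the
dual-leaf aggregation error is +0.06–0.9% for LAI ≤ 2 but grows with
canopy depth and diffuse fraction: +1.07% at LAI = 5, ζ = 30°,
f_d = 0.2, and up to ~4% for dense canopy under half-diffuse sky.
This residual is intrinsic to the two-class approximation, always on
the over-prediction side, and is documented rather than hidden: one
acceptance property pinning the dense-canopy scenario at 1% fails by
0.07 percentage points.

Parameter fitting is two-stage nonlinear least squares (scipy
`curve_fit`): (g_smax, k_Q) from a light-response curve, then
(k_D, k_w) from diurnal observations with stage-1 values fixed.
Noiseless synthetic data are recovered exactly; with 5% multiplicative
noise the median of 50 replicates is within 10% of truth.

## Resistances

* r_sc = 1000/G_sc (mm s⁻¹ ↔ s m⁻¹), infinite for a closed canopy.
* r_ss = [b₁(θ_g/θ_s)^{b₂} + b₃]/(1−f_m): empirical power law of
  relative surface moisture, divided by the exposed-ground fraction.
  Mulch affects only r_ss — the stated scope of the mulch
  modification — so r_ss(f_m)/r_ss(0) = 1/(1−f_m) exactly.
* r_aa, r_ac, r_as follow the classical sparse-crop scheme: full-cover
  displacement d = 0.63·h_c and roughness z₀ = 0.13·h_c; r_aa from the
  log profile above the canopy plus an exponential eddy-diffusivity
  integral (decay coefficient n = 2.5) through the upper canopy; r_as
  from the same integral between the soil roughness and the source
  height; both blended linearly in LAI/4 toward the bare-substrate
  limit, in which the total log-law resistance from z₀s to the
  reference height is split at the notional source height d + z₀.
  r_ac = r_b/(2·LAI) with a leaf boundary-layer resistance from the
  characteristic leaf dimension and the canopy-top wind speed
  (transfer coefficient 0.01 m s⁻¹ᐟ²).  An optional "drag" roughness
  closure uses the element drag coefficient c_d for displacement
  height; the default fixed-roughness mode does not need c_d.
* Wind measured at 2 m is log-extrapolated to a working reference of
  max(2 m, h_c + 1 m) so the reference always clears a tall mid-season
  canopy; wind is floored at 0.1 m s⁻¹ to keep calm-hour resistances
  bounded.

## Psychrometrics

FAO-56 forms: Tetens saturation curve and slope, γ = c_p·P/(0.622·λ)
with λ(T) = 2.501 − 0.002361·T MJ kg⁻¹, moist-air density from the
ideal gas law with virtual temperature.

## Solar geometry and sky

Zenith from the hour-angle formula with an eccentricity-corrected
declination approximation (accurate to ~0.2°; cross-checked against an
independent Fourier-series algorithm).  The public API takes solar
time; a helper converts local standard time with the longitude offset
and the equation of time — at 102.85° E in UTC+8 solar noon runs ~49
minutes behind clock noon.  Night convention: ζ ≥ 90° ⇒ no beam,
diffuse fraction 1, canopy absorption zero, stomata closed (r_sc = ∞),
and the net-radiation extinction uses κ_d since beam geometry is
undefined.  By day κ_R = G_L/cos ζ capped at 1.0 to avoid unbounded
extinction near sunrise/sunset.

## Synthetic clear-sky forcing

The generator emulates a cloudless day at a high-altitude semi-arid
site at half-hourly cadence: incident PAR is extraterrestrial PAR
(0.45·S₀·cos ζ) depleted by τ_a^{m_a}; net radiation is a fixed
fraction (0.65) of the implied shortwave, −40 W m⁻² at night; soil heat
flux is 0.1·R_n; temperature and relative humidity follow sinusoids
between their extremes, warmest/driest at solar noon; wind is constant.
It is deterministic.  What it does not contain — clouds, weather
fronts, wind variability, rain, canopy growth, afternoon hysteresis of
temperature — means passing tests demonstrate internal consistency and
correct clear-sky behaviour, not skill against real eddy-covariance
data (which are not redistributable for the original field campaigns).
Gaps in read forcing files are marked missing and never interpolated.

## Numerical choices and degenerate inputs

* Exact closures by construction: beam + diffuse = total;
  Q_sl + Q_sh = Q_c; LAI_sl + LAI_sh = LAI.
* Leaf-area fractions below 10⁻⁹ contribute zero conductance (avoids
  0/0 in mean irradiance); negative shaded absorption from cancellation
  is clamped to zero with a warning.
* LAI = 0 closes the transpiration path (r_ac = ∞, G_sc = 0) and the
  scheme collapses to bare-soil evaporation.
* The partition identity is checked at run time; violation beyond 10⁻³
  relative raises rather than silently reporting inconsistent fluxes.
* Forcing validation: out-of-range values become missing; >5% bad
  values or non-monotone time stamps abort the load.

## Problem sizes

Oracles use 1000-layer trapezoid quadrature; the randomised identity
sweep uses 1000 states; parameter-recovery uses 50 replicates at 5%
noise; sensitivity sweeps use a 100-point irradiance grid and a
9-point zenith scan.  The full test suite runs in well under a minute
on one CPU.

## Known limitations

* No Monin–Obukhov stability corrections; near-neutral conditions are
  implicitly assumed.
* No row structure or clumping: the mulched planting pattern enters
  only through the soil-resistance mulch fraction, not the radiation
  geometry.
* PAR only; no separate near-infrared waveband.
* Spherical leaf-angle distribution only.
* Temperature and CO₂ stomatal stress functions are out of scope.
* The two-leaf conductance aggregation error grows to a few percent in
  dense canopies under diffuse skies (see above).
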