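# Methods

This note documents the models behind `sgdco2`, the parameters that
matter, the synthetic study conditions, and the numerical choices made
where the design was genuinely open.

## Gas exchange

The water–air CO₂ flux is `F = k K₀ ΔpCO₂` with the wind-only transfer
velocity `k = 0.31 u² (Sc/660)^-0.5` (cm h⁻¹, converted with the exact
factor 0.24 to m d⁻¹). Wind is taken at 10 m with no height correction,
and no current- or rain-enhanced exchange is modelled: the fluxes are
deliberately conservative and comparable across sites. Schmidt numbers
use quartic temperature polynomials for freshwater and seawater (S = 35)
with linear interpolation in salinity; CO₂ solubility K₀(T, S) is the
standard Weiss-form fit (mol kg⁻¹ atm⁻¹), and the unit chain to
mmol m⁻² d⁻¹ assumes a constant density of 1025 kg m⁻³ (configurable per
call). Radon evasion `J_atm = k_Rn (C_w − αC_air)` uses the same velocity
rescaled by (Sc_Rn/Sc_CO₂)^-0.5; the radon air–water partition
coefficient α(T, S) is a Weiss-form ln-fit that decreases with
temperature and salinity. The instrument-side conversions (dry CO₂ mole
fraction → pCO₂ via the saturation vapour pressure p_H₂O(T, S); closed
air-loop radon → in-water radon via α) live in the IO module; the source
literature prints no coefficients for these steps, so the chosen
formulations are stated here and verified in tests by independent
re-evaluation and by their physical monotonicity properties.

## Radon mass balance

The budget solved for groundwater discharge F_gw (m³ d⁻¹) is

```
F_gw·Rn_gw + F_up·Rn_up + D_dif·A + ²²⁶Ra·λ·V
    = F_down·Rn_down + ²²²Rn·λ·V + J_atm·A + storage
```

with λ = ln2 / 3.8235 d = 0.1813 d⁻¹. Concentrations are carried in
dpm m⁻³ internally (surface series report dpm L⁻¹; ×1000 at the
boundary). Choices the literature leaves open:

* **J_atm units.** The budget's evasion term is implemented as the areal
  rate of the evasion equation times the wetted area A (dpm d⁻¹), the
  only dimensionally consistent reading; a unit test locks it.
* **Offshore export.** Parameterized as first-order flushing
  `q_ex · V · (Rn − Rn_offshore)` with q_ex (d⁻¹) supplied per site; a
  fixed total export term is also accepted. Sediment diffusion D_dif
  defaults to 0 unless provided.
* **Storage.** The non-steady estimator uses `V · dC/dt` per step
  (default 1 h): tidal volume change is treated as exchange at the
  ambient concentration and therefore carries no net radon. Attributing
  the full d(CV)/dt to the budget would book tidal inflow as discharge.
* **Noise damping.** Radon counting noise is amplified by differencing,
  so the non-steady estimator applies a centred 3-step rolling mean to
  the radon channel before differencing (configurable; 1 disables).
* **Negative steps** are floored at zero (interpreted as unresolved
  mixing or recharge), counted, and the floored time mean is reported;
  the unclipped mean is kept for uncertainty propagation.
* **Tidal-cycle integration** detects complete low-to-low windows from
  the depth record and trapezoid-integrates every term over each window;
  the storage integral closes when start and end inventories match.

Monte-Carlo uncertainty perturbs each budget term independently with
normal noise (truncated at zero for concentration-like terms; no
covariances, none being known) and reports sd/mean of the unclipped
discharge draws. When the mean draw is non-positive the uncertainty is
undefined and flagged — the near-zero-discharge regime where radon
budgets are intrinsically unconstrained.

## Driver attribution

CUSUM curves standardize the response with the **population** standard
deviation (the convention is unstated in the method literature; the
choice only rescales the curve) and sort pairs by ascending driver with a
stable sort, ties keeping time order. The changepoint estimator is a
continuous two-segment piecewise-linear least-squares fit of the
cumulative sum against rank, scanned over all interior breakpoints; a
threshold is reported only when the slope turns from negative to positive
(the V shape produced by a response that switches on above a driver
value). Raw pairs are used without pre-binning.

Tidal extremes come from a ~2-h centred rolling mean of depth with an 8-h
minimum same-kind separation (semidiurnal default) and enforced
low/high alternation; records with < 0.05 m smoothed depth range are
classified nontidal and yield no tidal indices. TEI and DEI are computed
per successive low→high and night→day cycle from ±1 h brackets around
each event (day anchored at 12:00, night at 00:00 local clock time — no
solar-noon correction) and averaged arithmetically across cycles, with
η̄ the whole-record mean; per-cycle values are also emitted. Sites are
called tidally controlled when |TEI|/|DEI| > 1.

## End-member mixing

The regression of pCO₂ on Rn is ordinary least squares (the simplest
reading of "linear regression"; the estimator is isolated behind
`mixing_regression` and swappable). End-member means are unweighted
arithmetic means of the discrete samples. The DQ band is closed at ±100 %.
Both per-site and pooled (multi-series) regressions are supported, since
ecosystem-level diagnostics can reasonably pool sites.

## Synthetic study conditions

The generator integrates a well-mixed box with explicit Euler at
dt ≤ 10 min (default 5 min; a stability guard rejects configurations with
rate·dt > 0.5). Transparency was preferred over solver sophistication: the
scheme is the same arithmetic the estimators assume, making discrepancies
attributable. Forcings: sinusoidal depth (period 12.42 h), discharge
`q = base + gain · max(0, head)` on the lagged low-tide hydraulic head,
optional spring–neap-scale modulation of the base rate (period 14.77 d),
truncated-sine light peaking at noon, constant wind with optional AR(1)
jitter. The groundwater term is a pure source for Rn and CO₂; the DO
groundwater term is a replacement flux so low-oxygen groundwater pulls DO
down, reproducing the observed Rn–DO anticorrelation. Tracer noise is
mean-preserving multiplicative lognormal (Gaussian noise could produce
negative activities). Offshore end-members default to
atmospheric-equilibrium values.

Presets:

* `tidal_dominated` — shallow mangrove creek, fast flushing (16 d⁻¹),
  discharge 3–35 cm d⁻¹ peaking at low tide, plus CO₂-rich porewater
  plumes co-occurring with radon above 5 dpm L⁻¹ (a step enrichment
  applied to the emitted pCO₂, giving threshold detectors a known
  changepoint; a dynamically lagged source would smear the threshold).
* `diel_dominated` — productive reef flat, constant background SGD,
  strong diel metabolism (P = 30, R = 15 mmol C m⁻³ d⁻¹).
* `conservative_mixing` — diagnostic regime with biology, gas exchange
  and decay disabled, so pCO₂ and Rn are exactly collinear responses to
  the same discharge forcing. Slow flushing (0.4 d⁻¹) and ~20–30 cm d⁻¹
  discharge put the mean enrichment ratio q/(h·f) near 0.5: strong enough
  that a respiration source carrying twice the SGD CO₂ load pushes DQ
  beyond +100 %. The spring–neap modulation (half-amplitude, 10-day
  record) gives the regression a wide, noise-dominating radon range so
  the zero-radon intercept is tightly estimated.
* `nontidal_lake` — 1-cm tidal amplitude (below the nontidal threshold),
  0.5 cm d⁻¹ discharge, diel metabolism dominant.

What the generator does **not** emulate: spatial gradients and advective
plumes, temperature/salinity dynamics (both constant by default),
stratification, spring–neap modulation of tidal amplitude itself,
carbonate-system buffering (pCO₂ maps linearly to dissolved CO₂ via K₀),
and instrument drift or data gaps. Passing recovery tests therefore show
the estimators are correct for a well-mixed, wind-ventilated water column
with known budget terms — not that field budgets are free of structural
error (offshore exchange and diffusion must still be constrained per
site).

## Validation problem sizes

The recovery experiment uses 6-day records at 2-min integration / 30-min
output, rates {1, 5, 20, 50} cm d⁻¹, flushing 3 d⁻¹, end-member
300 dpm L⁻¹ and a known sediment diffusion of 1000 dpm m⁻² d⁻¹; both
time-resolved estimators recover the mean rate to well under a percent
noise-free and ~1 % under 10 % multiplicative radon noise. Monte-Carlo
runs use 300–500 draws with a 15 % end-member CV plus a ±50 % absolute
spread on diffusion, which makes relative uncertainty fall from ~22–24 %
at 1 cm d⁻¹ toward ~16 % at 50 cm d⁻¹ (common random numbers across rates
isolate the rate dependence; the curve flattens at high rates, so the
trend, not strict sample monotonicity, is the tested property).

## Known limitations

Lag correction is a fixed whole-step shift (sub-step lags round with a
warning) rather than per-deployment cross-correlation optimisation. The
changepoint fit assumes a single threshold. TEI/DEI at semidiurnal sites
alias slightly into each other on short records because tide and clock
drift relative phase; multi-day records average this out. The pipeline's
`auto` mass-balance mode simply picks tidal-cycle integration when tides
are detected and hourly non-steady otherwise; site geometry may warrant
overriding it.
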