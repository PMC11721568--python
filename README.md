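# sgdco2

Radon-traced submarine groundwater discharge (SGD) and CO₂ flux analysis
for coastal surface-water time series.

Coastal ecosystems — mangrove creeks, salt marshes, estuaries, reef flats,
coastal lakes — are often strongly oversaturated in CO₂, and groundwater
and porewater seeping through the seabed can be a major, tidally modulated
CO₂ source alongside rivers and respiration. `sgdco2` is for coastal
biogeochemists who run coupled pCO₂ / ²²²Rn equilibrator deployments and
want a reproducible path from raw multivariate time series to: water–air
CO₂ fluxes, radon-mass-balance SGD rates, SGD-derived CO₂ fluxes, driver
attribution, and end-member mixing diagnostics.

## What it computes

**Water–air CO₂ flux** (positive = evasion):

```
F = k · K₀ · ΔpCO₂             k = 0.31 u² (Sc/660)^-1/2   [cm h⁻¹ → ×0.24 m d⁻¹]
```

with K₀(T, S) the CO₂ solubility and Sc the Schmidt number (freshwater /
seawater polynomials, linear in salinity). Radon evasion uses the same
velocity Schmidt-corrected for Rn: `J_atm = k (C_w − αC_air)`, α the
air–water partition coefficient.

**Radon mass balance.** Treating the water column as a well-mixed box,
sources (groundwater F_gw·Rn_gw, upstream input, sediment diffusion
D_dif·A, ²²⁶Ra production) balance sinks (offshore export, decay λ²²²Rn·V,
atmospheric evasion) plus storage. Solving for the groundwater term gives
the discharge F_gw (m³ d⁻¹) and the areal SGD rate (cm d⁻¹). Three
estimator archetypes: steady state, non-steady 1-h steps with a V·dC/dt
storage term (straight shorelines), and tidal-cycle-integrated budgets
(tidal creeks). Monte-Carlo perturbation of the budget terms yields a
relative uncertainty. Multiplying the SGD rate by the groundwater
end-member CO₂ concentration gives the SGD-derived CO₂ flux.

**Driver attribution.** Pearson correlations of pCO₂ against Rn, DO,
salinity and depth; CUSUM driver-response curves (cumulative sum of the
standardized response ordered by ascending driver, with a two-segment
changepoint fit that reads off driver thresholds); and tidal/diel effect
indices from ±1 h brackets around tide peaks and local noon/midnight:

```
TEI = (η_H − η_L) / 2η̄        DEI = (η_D − η_N) / 2η̄
```

|TEI|/|DEI| > 1 marks tidal control (groundwater pumping), < 1 diel
control (photosynthesis/respiration).

**End-member mixing.** The OLS regression of pCO₂ on Rn is projected to
the mean groundwater end-member; the deviation `D = S·R̄n_gw + In − P̄CO₂gw`
and deviation quotient `DQ = 100·D/P̄CO₂gw` classify each site:
−100 % ≤ DQ ≤ 100 % → SGD is the primary CO₂ driver; above/below →
additional sources/sinks.

**Synthetic generator.** A seeded box model with tidally modulated
groundwater input (peaking near low tide), diel net ecosystem production,
gas exchange, radioactive decay, flushing and lognormal measurement noise,
with full ground truth recorded — the validation bed for every estimator.

## Worked example

Generate a synthetic tidally dominated mangrove creek and analyse it:

```
$ sgdco2 --quiet simulate --preset tidal_dominated --seed 7 --out demo_site
$ sgdco2 --quiet analyze --surface demo_site/surface.csv \
      --endmember demo_site/endmember.csv --meta demo_site/meta.yaml \
      --out demo_reports --seed 7

Site tidal_dominated (mangrove)
  mean pCO2        562.3 uatm   (saturation 134 %)
  mean Rn           6.19 dpm/L
  mean DO           98.9 %
  water-air CO2 flux 3.2 +/- 3.4 mmol/m2/d
  SGD rate         13.12 cm/d (tidal_cycle)
  SGD CO2 flux      11.2 mmol/m2/d
  mixing DQ        535.2 % -> other_sources
```

Reading the numbers: the creek is 34 % oversaturated in CO₂ and degasses
~3 mmol CO₂ m⁻² d⁻¹; the tidal-cycle radon budget recovers ~13 cm d⁻¹ of
groundwater discharge (the preset's true mean is ~13 cm d⁻¹), which carries
~11 mmol CO₂ m⁻² d⁻¹ into the water column. The mixing diagnostic flags
`other_sources` because this preset injects CO₂-rich porewater plumes
above 5 dpm/L radon — a threshold response, not a linear mixing line, so
the projection overshoots the end-member exactly as it should. The same
threshold is what the CUSUM changepoint recovers (≈5 dpm/L). The full
machine-readable report lands in `demo_reports/tidal_dominated.json`;
`sgdco2 summarize --reports demo_reports --out summary.csv` aggregates
many such reports into per-ecosystem means/medians.

The same analysis is available as library calls (`SiteModel(...).fit()`,
`RadonMassBalance(...).fit()`, `MixingModel(...).fit()`), each returning a
results object with a `summary()`.

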