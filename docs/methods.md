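# Methods

## Problem and unit of analysis

`dietfootprint` estimates the dietary environmental footprint of a
population from household food-purchase diaries. Households record all
food and beverages purchased for home consumption over 7 consecutive
days; purchases are aggregated into sampling **strata** (clusters of
geographically and socioeconomically homogeneous households), each
carrying an **expansion weight** — the population the stratum
represents. All analyses are stratum-level and expansion-weighted.

## Accounting model

For a purchased quantity *q* (kg or litres, as purchased) of item *i*:

- energy: `E_i = q · f_i · 10 · d_i` kcal, where `f_i ∈ (0, 1]` is the
  edible fraction and `d_i` the energy density in kcal per 100 g of
  edible portion. Seeds, husks and bones feed nobody, so they are
  excluded from energy via `f_i` (the multiplicative correction factor
  of food-composition practice is `1/f_i`; converters are provided).
- carbon and water footprints: `C_i = q · c_i`, `W_i = q · w_i`, with
  `c_i` (gCO2eq/kg) and `w_i` (l/kg) cradle-to-retail intensities per
  **as-purchased** mass. The edible fraction is deliberately *not*
  applied: the impact of inedible parts is inseparable from producing
  the edible ones. Cooking-stage impacts are outside the accounting
  scope; the intensity coefficients are inputs, never recomputed.

Stratum totals are divided by 7 and by the stratum's resident count to
give per-capita daily values. Two derived quantities drive everything
downstream:

- **exposure shares**: % of energy from ultra-processed foods (Nova
  group 4, any source) and % of energy from beef items, which occur in
  Nova groups 1 (fresh cuts and offal), 3 (salted/cured/smoked) and 4
  (reconstituted products) but never in group 2;
- **footprint intensity**: footprint / energy × 1000, per 1000 kcal —
  the outcome of the association models. Strata with zero energy have
  undefined intensity and are excluded from regression with a logged
  count.

The contribution table attributes energy, carbon and water across Nova
groups, subgroups and total beef by pooling expansion-weighted
per-capita stratum quantities into national totals (weights enter as
`weight / (7 · residents)` per stratum). Whether the survey intends
weight or weight × residents is not derivable from the inputs; plain
expansion weight was chosen as it reproduces national-availability
semantics, and the alternative is a one-line change flagged for
sensitivity analysis. The **footprint/energy ratio** of a group is its
percentage share of a footprint divided by its percentage share of
energy: 1 means footprint proportional to calories. All internal math
is full precision; rounding to 1 decimal happens only in the reporting
layer.

## Association models

Exposure shares are cut into **weighted quintiles** across strata:
cut-points at weighted cumulative probability 0.2…0.8 of the values
sorted ascending, ties sharing the quintile of their first occurrence.
Assignments are invariant to rescaling all weights; unweighted
cut-points are available for sensitivity analysis. Fewer than five
distinct values is an error.

Footprint intensity is regressed on quintile indicators (reference Q1)
by weighted least squares with expansion weights — the desk-scale
analogue of survey (pweight) regression. The adjusted model adds
per-capita income (untransformed by default; log option), area of
residence (urban reference), macro-region (Southeast reference) and
the out-of-home expenditure share. Quintile means are
**population-averaged predictive margins**: set every stratum to
quintile *q*, keep observed covariates, average predictions with the
expansion weights. In the additive model the Q1 margin plus each
quintile coefficient reproduces that quintile's margin, and averaging
margins over the observed weighted quintile distribution returns the
weighted mean outcome.

- **P for trend** refits the model with the integer score 1–5 in place
  of the indicators and reports the robust two-sided p-value of the
  score — the common epidemiological convention.
- The **interaction Wald test** fits both indicator sets plus their 16
  products and jointly tests the products (F reference, the convention
  of survey regression software).

### Variance estimation

Standard errors use the **HC3** sandwich. Under an additive null the
16-df interaction Wald over-rejects badly with HC1 (≈15–18 % at
n = 120–250 strata — the known anti-conservatism of many-restriction
HC1 tests), while HC3 is near-nominal (≈6.5 %); the single-parameter
trend test is calibrated under either (measured 0.058 with HC3 over
1000 null simulations). Full design-based (Taylor-linearised) variance
is a known limitation, not implemented. Even a correctly implemented
16-df Wald remains anti-conservative when cells are sparse and
expansion weights heavy-tailed (25 cells over 120 strata); its
calibration tests therefore run at 250 strata with mild weight
dispersion, where the asymptotics apply.

## Counterfactual scenarios

Three "first-quintile" scenarios are computed by marginal
standardisation (G-computation) on the joint adjusted main-effects
model (both quintile indicator sets, no products — justified when the
interaction Wald is non-significant; a flag refits with products):
overwrite the UPF quintile (S1), the beef quintile (S2) or both (S3)
with 1 for every stratum, keep covariates observed, and average
predictions with expansion weights. The baseline is the weighted mean
fitted value, which for WLS with an intercept equals the weighted mean
observed outcome — so "predicted baseline" and "observed national
mean" coincide by construction. Percent changes are signed
(reductions negative) relative to the same run's baseline. In the
main-effects model the S3 change equals S1 + S2 changes exactly. No
uncertainty intervals are attached to scenario means; a bootstrap is
future work.

## Synthetic survey generator

Real household-budget microdata and footprint coefficient tables are
not redistributable, so the generator builds a reduced-scale survey
with the structure the analysis assumes. Defaults are the stated
world, fixed a priori:

| parameter | default | why |
|---|---|---|
| `n_strata` | 120 | reduced scale of the ~575-strata survey emulated; keeps the suite fast while preserving quintile granularity |
| `households_per_stratum` | 16–120 | lower end of the observed 16–524 range |
| `residents_per_household` | 2.5–3.5 | typical household size in the population emulated |
| `n_items` | 40 | ≥2 per Nova group; 4 beef items spread over groups 1/3/4 |
| `beef_share_range` | 3.0–8.2 % | observed beef-energy quintile spread (Q1≈3.0, Q5≈8.2) |
| `upf_share_range` | 10.1–28.1 % | observed UPF-energy quintile spread |
| `beef_carbon_multiplier` | 13 | beef intensities ≈13× the non-beef mean put beef's footprint/energy ratio near its observed order of magnitude (~9) |
| `mean_energy` | 1221.5 kcal/p-d | observed national home food availability |
| `noise_sd` | 0.10 | 10 % log-normal quantity noise, plausible diary error |

Generation is **energy-share-first**: each stratum draws target beef
and UPF shares uniformly from their ranges (optionally tilted toward a
covariate index for confounding experiments), splits them across items
by symmetric Dirichlet compositions, allocates the remainder to
non-beef groups 1–3, and inverts energy targets to as-purchased masses
through each item's energy density and edible fraction. Group 2 items
get near-zero intensities (culinary ingredients); group-level energy
density and intensity means are set so that ultra-processed foods
displace cheaper-than-average calories (positive UPF intensity
gradient), mirroring the displacement mechanism in real diets.
`noise_sd` is a single mechanism — mean-one log-normal multipliers on
quantities — whose induced intensity scatter is the "residual sd".

Ground truth is exact in share space: per-stratum expected intensity
is `10 · Σ s_i k_i` with `k_i = intensity_i / (kcal per kg)_i`, and the
closed-form slopes per percentage point of share are

    slope_beef = 10 (k̄_beef − w₄ k̄_upf − (1 − w₄) k̄_other)
    slope_upf  = 10 (k̄_upf − k̄_other)

where `w₄` is the expected fraction of beef energy in group 4 (those
items count toward both exposures). Because truth for the
quintile-score slope has no closed form, parameter-recovery tests use
the continuous-share WLS fit, whose estimand these slopes are;
measured coverage of the 95 % CI is 95 % (beef) / 97 % (UPF) over 200
seeded replicates.

What the generator does **not** emulate: real item codes or price
structures, two-stage PSU selection, within-stratum household
heterogeneity (records are attributed to synthetic households only for
schema realism), seasonal purchase patterns, and item-level exposure
measurement error independent of the outcome. The last point matters:
quantity noise moves realised shares and intensities together, so a
world with a constant beef-share *target* still shows a small
mechanical quintile slope on realised shares (~¼ of the default
world's); a green recovery test establishes that the estimator tracks
the generator's structural slopes, not that it would be unbiased under
arbitrary measurement-error regimes.

## Numerical choices and degenerate inputs

- Quintile cut-points use a 1e−9 slack against floating-point edge
  effects at exact 0.2 multiples; identical values across all strata
  are an error (no distinct cut-points).
- Rank deficiency of a design matrix raises an error naming the
  collinear columns (QR-diagnosed) rather than silently pinv-fitting.
- Unknown purchase item codes are a hard error; `allow_missing` drops
  them with a logged count. Zero quantities are accepted and
  contribute nothing.
- Zero-energy strata: shares reported as 0, intensities undefined,
  excluded from models, counted in the log.
- Weighted means use `numpy.average`; scenario results are invariant
  to rescaling all expansion weights by a positive constant.
- All randomness flows from a single integer seed through named
  `numpy` generator streams (reference stream 101, population 202); no
  global RNG state.

## Known limitations

- No design-based variance (replicate weights / linearisation); robust
  HC3 on the weighted fit is the stand-in.
- The interaction Wald is anti-conservative at small strata-per-cell
  counts with heavy-tailed weights (see above).
- Contribution-table weighting (weight vs weight × residents) is a
  declared convention, not identifiable from the inputs.
- Scenario means carry no uncertainty intervals.
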