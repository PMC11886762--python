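# Methods

## Scope and data model

The unit of analysis is a site-condition record: one ditch site under one
set of descriptors, with up to four annualized areal fluxes (CO₂, N₂O,
diffusive CH₄, ebullitive CH₄; g gas m⁻² yr⁻¹, atmosphere-positive) and
optional water-quality, hydraulic and climatic covariates. Records live in
a flat CSV (RFC 4180, UTF-8, `.` decimal separator) with lower_snake_case
columns; a user-supplied column map absorbs third-party headers. Missing
values are empty fields; unknown categorical strings are mapped to
`unknown` with a logged warning rather than rejected, and `unknown` levels
are excluded from group tests rather than imputed — explicit missing-data
policy in place of any interpolation.

## Harmonization

Raw rates are converted in three orthogonal steps:

1. **Mass basis.** Element-basis rates (g C or g N) are multiplied by
   molar-mass ratios built from 2-decimal standard atomic weights
   (CO₂ 44.01, N₂O 44.01, CH₄ 16.04; C 12.01, N₂ 28.01 g mol⁻¹); molar
   rates by the gas molar mass. The 2-decimal masses agree with crude
   12/44-style ratios to well under 0.5%, so either convention reproduces
   printed-precision results.
2. **Annualization.** Daily rates are multiplied by the ice-free season
   length (1–365 d) where seasonal ice/snow cover is recorded, else by
   365 (not 365.25 — the annualization is defined as a 365-day
   multiplication).
3. **Night correction.** Daytime-only CO₂ rates may be multiplied by 1.27
   (27% higher night-time emissions). This is **off** by default at the
   site level: the summary statistics and global totals of the synthesis
   are built from uncorrected fluxes, and the correction belongs only to
   the refined Tier-1 emission-factor variant. A config switch exposes it.

## Classification

* **Climate**: first letter of the Köppen–Geiger code (A tropical, B arid,
  C temperate, D continental); polar codes map to `unknown` because no
  polar sites exist in this domain.
* **Land use**: Corine Land Cover labels folded to agriculture /
  natural_forest / urban / wetland.
* **Trophic state**: each available nutrient variable votes through its own
  cut points — TP (µg L⁻¹) 10/30/100, TN (µg L⁻¹) 350/650/1200, chl-a
  (µg L⁻¹) 3.5/9/25, the freshwater scheme of Smith et al. — and the final
  class is the most eutrophic vote (precautionary maximum). The cited
  scheme prints no tie rule; a TP-priority alternative is selectable by
  config. All thresholds are config-overridable.
* **Hydrology**: never-dry → perennial; ever-dry → non-perennial, split by
  whether the ditch was dry at sampling.

All classifiers are pure, total and idempotent; `classify_trophic` is
monotone (raising any concentration never moves the class toward
oligotrophic) — both properties are tested.

## Group statistics

Flux distributions are strongly right-skewed with occasional negative
values, so all inference is rank-based: Kruskal–Wallis (tie-corrected H,
chi-square reference) for factors with >2 populated levels, Mann–Whitney U
otherwise, pairwise Wilcoxon post hocs adjusted by Holm (default; the
conventional default of the pairwise procedure — Bonferroni and
Benjamini–Hochberg are selectable), and Spearman correlations on
pairwise-complete observations. α = 0.05. Corrections are applied per
family (gas × factor), not pooled across gases.

The Mann–Whitney p-value is exact by enumeration when both samples have
n ≤ 8 and no ties (a reproducibility/speed cutoff), else a tie-corrected
normal approximation with continuity correction. The exact branch is
verified in the test suite against an independent brute-force enumeration
of all rank assignments for every tie-free input with n₁, n₂ ≤ 6.
Degenerate inputs: all-identical values report H = 0, p = 1; correlations
with fewer than 3 complete pairs or zero rank variance are reported absent
with a warning, never as numbers.

## CO₂-equivalent accounting

CH₄ is totalled as diffusive + ebullitive; records without measured
ebullition contribute 0 and carry an `ebullition_missing` flag (CH₄ is then
likely underestimated — ebullition averages ~80% of total CH₄ where
measured). Under `gwp100` each gas is scaled by its 100-year pulse factor
regardless of sign; under `sustained`, persistent emissions use the SGWP
and persistent uptake the SGCP, per gas. Shares are percentages of the
summed absolute contributions, so they total 100% even with net sinks
present. Subset aggregation defaults to the mean of per-record shares;
the pooled-total alternative is computed and reported alongside, since
either convention is defensible for a small all-three-gas subset.

## Upscaling and uncertainty

Global emission = mean areal flux × ditch area × element fraction, reported
in Tg C or Tg N yr⁻¹. The 95% CI propagates flux-mean uncertainty only
(t-interval) at the fixed central area of 5,353,000 ha; this mirrors how
the synthesis's printed CIs were produced. An optional Monte Carlo mode
additionally samples the area uniformly over its published range
(1.42–10.7 Mha) and reports the widened percentile interval separately —
never in place of the fixed-area CI. Budget denominators (11.1 and 3.9 Pg
C yr⁻¹; 6.5 and 0.5 Tg N yr⁻¹) are config constants, never hard-coded in
operations. The Tier-1 emission factor is the same mean in
t element ha⁻¹ yr⁻¹ (× element fraction × 10⁻²).

Note an internal tension in the published inputs this package makes
visible: the printed CO₂ mean of 2060 g m⁻² yr⁻¹ implies an emission
factor of 5.62 t C ha⁻¹ yr⁻¹, while the published Tier-1 factor is 6.19
(an unspecified subset). The package therefore treats 6.19 as an *input*
to the night-adjustment step (6.19 × 1.27 = 7.86), not as a quantity
derivable from 2060. Likewise 2060 × area gives 30.09 Tg C — the printed
30.0 evidently reflects an unrounded mean.

## Synthetic-data generator

The generator emulates the compiled database's statistical shape; its
defaults are the study conditions, not free dials:

* 119 sites; 99 CO₂, 56 N₂O, 94 diffusive-CH₄, 20 ebullitive-CH₄
  observations (ebullition only at diffusive sites).
* Source fluxes are lognormal with moments matched to the published
  mean ± SD (CO₂ 2060 ± 2620; N₂O 0.892 ± 1.83 g gas m⁻² yr⁻¹) via
  σ² = ln(1 + (SD/mean)²), µ = ln(mean) − σ²/2. Diffusive CH₄ uses
  30 ± 60 g CH₄ m⁻² yr⁻¹ — no main-text value exists; this is a realistic
  right-skewed ditch CH₄ distribution chosen once.
* 5 CO₂ and 6 N₂O records are net sinks with the published sink
  distributions (−63.4 ± 27.4; −0.0217 ± 0.0163). Sink sites are the
  lowest-latent-quantile observed sites of each gas, with magnitudes
  assigned order-preserving. Placing sinks uniformly at random instead
  demotes ~5–11% of observations to the bottom ranks independently of the
  latent structure and measurably destroys the injected rank correlations
  (empirical attenuation ≈0.83 on N₂O pairs), to the point where the
  stronger targets become jointly infeasible; the low-tail placement is
  also the physically plausible one (net uptake at the lowest-emission
  sites).
* Rank dependence is injected through a latent-Gaussian copula. Latent
  Pearson entries use r = 2 sin(πρ/6). The matrix is assembled as a factor
  model: the three fluxes form the factor block and each covariate loads
  on the fluxes it has targets with (loadings by regression), plus unique
  variance — positive semi-definite by construction, and every specified
  flux–covariate correlation is reproduced exactly; genuinely infeasible
  target sets raise with the offending pair named. Default targets follow
  the published screen (CO₂: DO −0.74, pH −0.43, velocity 0.49, TP 0.55,
  N₂O 0.50; N₂O: diffusive CH₄ 0.58, velocity 0.47, TN 0.53, NO₃-N 0.58).
* Categorical N₂O effects are multiplicative and mean-normalized:
  temperate 6× continental (arid/tropical 2×), eutrophic and
  hypereutrophic 6× oligo/mesotrophic, dry ditches 1/16 of perennial. The
  1/16 ratio is the published one; the other magnitudes are generator
  choices sized by a power analysis so the comparison battery detects each
  main effect in ≥80% of seeds at the study's sample sizes (the published
  contrasts are themselves very strong, p ≤ 0.001). No CO₂ effects are
  injected — none were found in the synthesis.
* Because these multiplicative effects add rank noise to N₂O, the
  generator inflates the latent correlations of affected fluxes by the
  analytically derived attenuation factor √((σ² + v_eff)/σ²), where v_eff
  is the log-variance of the configured multipliers under the level
  probabilities; empirical Spearman values then land on target (10-seed
  mean errors ≤ 0.06, tolerance ±0.15).
* Covariate marginals are lognormal (positive, right-skewed) or normal
  (pH, C:N); MAT/MAP and latitude bands are climate-consistent. ~10% of
  covariate values are missing completely at random, emulating
  pairwise-complete sample sizes. Coordinates have no further geographic
  realism.
* A 22-record all-three-gas subset generator calibrates CH₄ and N₂O
  magnitudes to the GWP₁₀₀ share structure (51/43.5/5.5) with mean-one
  lognormal jitter, and gives exactly 2 records measured ebullition.

What passing tests on this generator do *not* show: real literature data
have correlated missingness, digitization error, within-study dependence
and geographic clustering, none of which are emulated; recovery results
demonstrate the pipeline's correctness, not field-data robustness.

## Determinism and problem sizes

Every stochastic path takes a single integer seed through
`numpy.random.default_rng`; the same seed yields byte-identical CSV output.
Simulation-based tests use fixed seed ranges and modest sizes chosen for
desk-scale runtimes: 10 seeds for moment/correlation recovery (single-seed
sample means vary ~13% for a lognormal with CV 1.27 at n ≈ 95, so
multi-seed averages are the meaningful check), 100 seeds for effect
detection and false-positive control, 2000 replicates for CI coverage.
The false-positive check allows binomial sampling error (≤15/100 per
factor at a nominal ≤10% rate) rather than asserting the point rate.

## Known limitations

* The exact schema of the deposited database is unknown; the column map is
  the escape hatch, and `read_observations` never drops rows.
* The Kruskal–Wallis chi-square reference is approximate for very small
  groups (the dry-ditch level has ~3 sites); the published synthesis had
  the same limitation, and the dry-ditch contrast is correspondingly not
  part of the detection guarantee.
* No gas-transfer-velocity modelling, no flux computation from dissolved
  concentrations, no spatial disaggregation, and no CH₄ budget upscaling —
  all upstream or out of scope of this synthesis.
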