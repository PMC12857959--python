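# Methods

## Equilibrium length-structured per-recruit model

The population is in equilibrium: constant recruitment, constant mortality,
and a catch length composition representative of the harvested population at
steady state. Individual growth variability is represented by growth-type
groups (GTGs): `n_gtg = 13` sub-cohorts whose asymptotic lengths are equally
spaced on `linf ± 2.5 · cv_linf · linf` and whose recruitment weights are
proportional to a Normal(`linf`, `cv_linf · linf`) density at those points,
renormalised to 1. Thirteen groups truncated at ±2.5 SD is the conventional
GTG discretisation; both the count and the truncation are configurable, and
`cv_linf = 0` collapses to a single group.

Within a group, survivorship between the lower edges of consecutive length
bins follows the length-converted exponent

    N[l+1] = N[l] · ((Linf_g − L[l+1]) / (Linf_g − L[l]))^(mk · (1 + fm · S(mid_l)))

so only the dimensionless ratios `mk = M/K` and `fm = F/M` enter; absolute
`m` and `k` are bookkeeping. Bins whose lower edge reaches the group's
asymptotic length get zero numbers; a bin straddling it truncates to zero
rather than raising a domain error.

Egg production per recruit is

    EPR = Σ_g Σ_l N̄[g,l] · Mat(mid_l) · mid_l^b,     SPR = EPR(F) / EPR(0)

with `Mat` the logistic maturity ogive and `b` the fecundity–length
exponent. `N̄[g,l]` is the **trapezoidal within-bin abundance** — the mean
of the two bounding edge survivorships — not the lower-edge value. A
left-edge sum carries a half-bin-shift bias of a few percent at 2-mm bins
that does not cancel in the fished/unfished ratio; the trapezoidal abundance
makes the discretisation error O(Δ²), so halving the bin width changes SPR
by well under 0.5% and the model agrees with the independent age-structured
integrator to well within 2%. The raw edge survivorships remain available
via `equilibrium.edge_survival`.

Expected catch proportions are `C_l ∝ Σ_g N̄[g,l] · S(mid_l)`, normalised to
one. Selectivity and maturity are evaluated at bin midpoints rather than
integrated across bins — simple, consistent with 2-mm data, and guarded by
the grid-refinement check above.

### Defaults and units

| parameter | default | units | role |
|---|---|---|---|
| `linf` | 60 | mm | von Bertalanffy asymptotic total length |
| `cv_linf` | 0.1 | — | CV of `linf` across growth-type groups |
| `m`, `k` | 0.4, 0.45 | 1/yr | base anchors; model uses `mk = m/k ≈ 0.889` |
| `l50_mat`, `l95_mat` | 35, 40 | mm | maturity ogive (consistent with the 36-mm recruit threshold) |
| `fec_exp` | 3 | — | egg output ∝ length³ (volumetric fecundity law) |
| bin width | 2 | mm | length-composition resolution |
| `n_gtg` | 13 | — | growth-type groups, ±2.5 SD truncation |

Two further named presets anchor the growth ratio: `management_krill`
(k = 0.7, the value used in current krill management) and `type_i_krill`
(k = 0.43, the Type-I life-strategy anchor with M/k ≈ 1). The length grid
spans `[0, max(1.3·linf, linf·(1 + 2.5·cv_linf))]` rounded up to a whole
bin, guaranteeing coverage of the largest growth-type group.

## Maximum-likelihood fitting

The multinomial negative log-likelihood
`NLL = −Σ_l counts_l · ln(p_l + 1e-12)` is minimised over the transformed
parameters `(log fm, sl50, log(sl95 − sl50))`, which enforce `fm > 0` and
`sl50 < sl95`. Optimisation is Nelder–Mead from a data-driven start (SL50 and
SL95 at the 25th/75th percentiles of the composition, `fm = 1`), with one
restart from a +25% `fm` perturbation if the first run fails (lowest NLL
wins). Compositions with fewer than 100 animals are skipped with an explicit
"insufficient sample" record (threshold configurable); compositions with
fewer than four occupied bins cannot pin down three parameters and are
flagged "insufficient information" rather than optimised.

`spr_sd` is the delta-method standard deviation using the numerical Hessian
of the NLL in transformed space; when the Hessian is not positive definite
the SD is reported missing and flagged. Monthly compositions are pooled to
annual stratum cells before fitting (annual tables are the reporting unit);
monthly fitting is available behind a flag.

## Sensitivity scenarios

One scenario per L∞ value (growth ratio at base) plus one per k value
(L∞ at base), crossed with strata. The default preset uses ten L∞ values
(55–64 mm by 1 mm) plus three growth scenarios (k = 0.2 low, 0.7 medium,
1.2 high) over five strata — 65 scenario–stratum combinations; an alternative
preset uses the eleven-value sweep 55–65 mm (70 combinations) and logs a note,
since the two readings of the design are mutually inconsistent. k-scenarios
hold `m` fixed at 0.4 and set `mk = 0.4/k`, because only the ratio enters the
model; L∞ scenarios keep maturity and selectivity in absolute mm (no
rescaling rule is assumed). Summaries are the per-stratum median and SD of
annual fitted SPR, with the annual values retained.

A note on direction: for a **fixed** fleet, SPR increases with k (smaller
M/K means less length-specific depletion at a given F/M). The headline
pattern — slow growth implying **higher** estimated SPR — arises when the
model is **re-fitted** under each growth assumption: a low-k model expects a
small-bodied unfished stock, so the same data imply light exploitation.
Both directions are asserted in the tests, each on the evaluation it
belongs to.

## Reference points and harvest control rule

SPR 20% is the limit and SPR 75% the target, mirroring the depletion and
escapement levels of the krill management scheme; SPR_MSY is identified
with the 75% target (configurable). The hockey-stick rule is implemented in
two variants: the **printed** form divides the ramp by 0.75 and is therefore
discontinuous at the target (a jump of `FMSY·(1 − 0.55/0.75)`), and a
**continuous** correction divides by 0.55. The printed form is the default
for faithfulness; the discontinuity is asserted in tests. Status
classification operates on the same ratio the rule uses, so "closed"
(`F = 0`) and "below limit" coincide at the default thresholds.

## Environment–length mixed model

The response is the cell-level mean length (stratum × year × month cells);
fitting per-animal records at full scale is supported but not the test
default. The fixed effects are a stratum factor, SIC (%), SST (°C), Chla
(mg m⁻³) and SST×Chla; a random intercept per year absorbs interannual
variability. Estimation is profiled REML: the variance ratio
`var_year/var_resid` is optimised in one dimension with a GLS solve for the
fixed effects at each candidate, and the zero-variance boundary is checked
explicitly (a boundary estimate is flagged, not an error). Wald-*t*
confidence intervals use residual degrees of freedom `n − p` — a documented
approximation; Satterthwaite adjustment is out of scope. The fit is
cross-checked against an independent general-purpose mixed-model
implementation in the test suite.

For model ranking, AIC and BIC are computed from the **ML** log-likelihood
evaluated at the REML estimates, since REML likelihoods are not comparable
across fixed-effect structures; the REML log-likelihood is reported
separately. RMSE and R² use conditional residuals (fixed effects plus BLUP
year intercepts). Panels with one observation per year leave the two
variance components unidentifiable; such fits are flagged. A
75th-percentile response variant is deliberately excluded from the
candidate set.

## Synthetic data generator

The generator emulates the *structure* of stratified fishery monitoring:
per-animal lengths by month, year and stratum (five strata; the Joinville
Island stratum only in its two monitored years, reproducing the gap pattern
of real monitoring), and a monthly environmental panel. Its defaults are the
study conditions used throughout the tests:

- lengths drawn multinomially from the equilibrium model's expected catch
  composition under per-stratum fleet truths (SL50 = 38 mm, SL95 = 45 mm,
  F/M between 0.8 and 2.5 across strata), ~8000 animals per stratum-year by
  default;
- (SST, Chla) drawn with correlation −0.73 via a Cholesky factor
  (SST ~ N(0.5, 1.5²) °C; Chla ~ N(1.2, 0.5²) mg m⁻³ clipped at 0.01); SIC
  independent, N(45, 25²) clipped to [0, 100] %;
- cell mean length = 45 + stratum offset (EI +1.8, GS +4.07, JOIN +0.49,
  SSWI +1.2 mm) − 0.0086·SIC + 0.25·SST − 1.6·Chla − 0.11·SST·Chla +
  year effect (variance 0.5) + residual (variance 1.0). With these values
  the implied marginal corr(Chla, mean length) is ≈ −0.43 (verified by an
  analytic variance budget and asserted in tests).

One global seed expands into independent substreams (environment, year
effects, cell noise, length sampling), so identical configurations are
byte-identical and modules can be tested in isolation. A truth ledger
(all parameters, per-stratum true SPR, substream seeds) accompanies every
simulated study.

What the generator does **not** emulate: environmental effects act only on
the panel's cell-mean-length scale and do not distort the within-cell
composition shape, so the LBSPR truth stays exactly interpretable;
real-data features such as vessel/gear heterogeneity, spatially clustered
sampling within strata, age-structured recruitment pulses and measurement
error are absent. Passing the recovery tests therefore demonstrates
correctness of the estimators under the model's own assumptions, not
robustness to their violation.

## Problem sizes used in the checks

The packaged checks run at deliberately modest scale, chosen as the smallest
sizes at which the statistical assertions are stable: parameter recovery
uses 50 replicate compositions of 10,000 animals; the directional
sensitivity panel uses 20,000 animals per stratum-year over three years
(11 + 3 scenarios × 5 strata); mixed-model recovery uses 200 replicate
balanced panels of 600 cells; the ingest stress check uses 50,000 records.
The full-scale monitoring volume (hundreds of thousands of records) is
generated on demand by the same code paths.

## Known limitations

- Equilibrium and representative-sampling assumptions are inherited from
  the length-based approach; estimates are biased when recruitment is
  strongly variable or samples over-represent a life stage.
- The same life history is applied across strata (parameter knowledge for
  krill is regional/circumpolar); the sensitivity engine is the tool for
  exploring that uncertainty.
- SPR standard deviations are delta-method approximations and can be
  reported missing when the likelihood surface is flat at the optimum.
- The printed harvest control rule is discontinuous at the target by
  construction; use the continuous variant when a smooth rule is needed.
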