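# Methods

This note documents the model structure, the defaults and why they were
chosen, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Scope and intent

The package re-implements, as open tested code, a PBPK modeling workflow
for bevurogant (BI 730357): a weak base (pKa 2.2, MW 532.62 g/mol) with
pH-dependent low solubility and high interstudy PK variability, whose oral
absorption is described semi-mechanistically — an empirical Weibull
in-vivo dissolution per dose/study/food state, plus an elevated distal-colon
solubility that reproduces the late (16–36 h) absorption phase. On top of
the structural model sit victim-side CYP3A4 DDI mechanics, NCA-based
evaluation with geometric-mean ratios and the 1.5-fold rule, virtual
populations, staged parameter estimation, and a synthetic Phase-I study
generator. Out of scope by design: mechanistic perpetrator models (exposure
is a pluggable profile), enterohepatic recirculation (excluded for this
compound), mechanistic particle-size dissolution and supersaturation
(alternatives that were considered and rejected for this compound),
metabolite kinetics, and transporters (the compound is not a substrate of
the common efflux/uptake transporters).

## System model

* **Circulation.** Venous pool → lung → arterial pool → 14 systemic
  organs. Stomach, small and large intestine, spleen, and pancreas drain
  into the liver via the portal vein (first-pass). Cardiac output is the
  sum of the systemic organ flows (333.5 L/h in the reference individual).
* **Reference individual.** `european_male_default.yaml` pins a standard
  European male (73 kg, 176 cm, GFR 120 mL/min): organ volumes and flows
  from published adult-male reference tables, Rodgers–Rowland fractional
  tissue compositions, and a standard GI transit/pH table. The source
  platform's internal physiology database is proprietary, so this pinned
  config is the package's deterministic system parameterization; absolute
  agreement with the original model's profiles is not claimed.
* **GI tract.** Twelve segments (stomach, duodenum, upper/lower jejunum,
  upper/lower ileum, caecum, four colon segments, rectum), each with
  fasted/fed transit time and pH, fluid volume, effective absorptive area,
  and relative CYP3A4 expression. Effective areas include the mucosal
  (plicae/villi) amplification for the small intestine — order 10⁴–10⁵ cm²
  per segment — and only haustral amplification for the colon (10²–10³ cm²).
  Feeding changes gastric emptying (0.25 → 1.0 h), the luminal pH table,
  and the active reference solubility; nothing else.
* **CYP3A4.** Liver concentration 4.32 µmol/L; intestinal expression
  decreases aborally (small-intestinal segments 0.06 → 0.02 relative to
  liver, colon ≈ 0.001–0.003). Enzyme turnover half-life 36 h
  (k_deg = ln 2/36 h⁻¹), also the population's CYP3A4 setting. Organ-level
  intrinsic-clearance shares are proportional to absolute abundance
  (concentration × relative expression × volume), which puts ~98% of
  metabolism in the liver.

## Drug model

* **Partitioning.** Rodgers–Rowland neutral branch: at plasma pH 7.4 the
  ionized fraction of a pKa 2.2 base is < 10⁻⁵, so only tissue water,
  neutral lipid (scaled by P = 10^logP), and neutral phospholipid (scaled
  by 0.3P + 0.7) contribute, times fu_plasma. The adipose neutral-lipid
  term uses the vegetable-oil:water coefficient
  (log P_vo:w = 1.115·logP − 1.35), the standard correction in this
  framework; with plain octanol P the adipose Kp (~82) would make the
  terminal phase adipose-redistribution-limited (t½ ≈ 70 h), inconsistent
  with the compound's observed 22.5–29.8 h half-life range. With the
  correction, Kp_adipose ≈ 7.8 and Vss ≈ 215 L. The plasma reference
  defaults to a unit aqueous term, so a lipid-free tissue with fu = 1
  partitions exactly with its water fraction.
* **Intrinsic clearance normalization.** The compound config stores the
  fitted whole-body CYP3A4 intrinsic clearance (154.71 mL/min) together
  with `clint_scaling`, the factor converting it to the
  unbound-plasma-referenced clearance the ODE uses. The value 4.5 was
  calibrated once so the shipped configuration's IV terminal half-life is
  26.9 h, the middle of the reported 22.5–29.8 h range, and is part of the
  pinned configuration (the original normalization convention is not
  published). Renal clearance is f_GFR·GFR·fu = 0.059·120·0.154 ≈ 1.09
  mL/min — a minor route, consistent with net tubular reabsorption
  (f_GFR ≪ 1).
* **Solubility.** Henderson–Hasselbalch for a monoprotic base anchored at
  FaSSIF (19.45 mg/L at pH 6.5, fasted) or FeSSIF (57.9 mg/L at pH 5.0,
  fed). The elevated colonic solubility (637 mg/L) is applied from colon
  transversum through sigmoid inclusive: the parameter is named for the
  transversum but the mechanism is discussed for the sigmoid colon, so the
  override spans both. Removing it leaves the pH-derived ≈19.45 mg/L
  (the tabulated pre-fit value 19.46 mg/L reflects the source's internal
  colonic pH; the 0.05% difference is immaterial).

## Absorption numerics

* **Weibull release.** F(t) = 1 − 2^(−((t−lag)/t50)^b) makes the
  50%-dissolution time an exact parameter for any shape b. The engine
  applies the hazard h(t) = F′/(1−F) to the remaining solid of each dose's
  pool, so the schedule follows the dose clock, not the segment; each
  tablet dose carries its own pool and clock. For b < 1 the hazard is
  integrably singular at release start; the fraction dissolving within the
  first 10⁻⁶ min is applied as an instantaneous activation bolus, after
  which the hazard form reproduces the cumulative schedule exactly (the
  flattest fitted shape, b = 0.16, would otherwise lose ~1% of the
  schedule to a clamped hazard).
* **Saturation cap.** Dissolution is unthrottled below 95% of the segment
  solubility and ramps linearly to zero at the cap — a smooth stand-in for
  a hard on/off switch that stiff integrators handle poorly. No
  precipitation or re-dissolution kinetics. Oral solutions enter the
  stomach dissolved and may transiently exceed the saturation
  concentration (no forced precipitation).
* **Transit and flux.** First-order segment-to-segment transfer at
  1/transit-time for solid and dissolved material; rectal outflow is
  booked as fecal loss. Transmucosal flux is a single transcellular
  permeability times effective area times the gradient between luminal and
  unbound wall concentration (fu·C_wall/Kp); gastric flux is zero. Flux is
  bidirectional by default (sink mode available), and small-intestinal
  segments drain into the small-intestinal wall, colonic segments into the
  large-intestinal wall, both portal.

## Integration and events

LSODA with rtol 1e-8 / atol 1e-10 by default; doses are exact
discontinuities with solver restarts at every event (at duplicated output
times the post-dose sample is reported). Each simulation carries a
cumulative ledger (absorbed, metabolized, renal, fecal); dose minus
(body + lumen + eliminated) closes to machine precision in practice, and
every test asserts ≤ 0.1%. Halving the tolerances changes a 72 h oral AUC
by < 0.01%. Degenerate one-compartment configurations (tiny organ volumes,
5·10⁴ L/h flows, Kp = fu = 1) reproduce closed forms: IV decay within
0.5%, the fm-based constant-inhibition AUC ratio
1/(1 − fm + fm/(1 + I/K_i)) within 1%, and multi-dose superposition within
0.5%.

## DDI mechanics

Competitive inhibition divides the intrinsic clearance by (1 + I/K_i) —
the direction required for an inhibitor to raise victim exposure (an
inhibitor that multiplied clearance would lower it, contradicting the
7–9-fold AUC increases seen with strong CYP3A4 inhibition). Induction
raises the enzyme synthesis rate by 1 + E_max·I/(EC_50 + I); the enzyme
state integrates d[E]/dt = R_syn,app − k_deg·[E] toward the closed-form
steady-state fold. Gut-wall enzyme sites use the same exposure profile
unless a gut-specific profile is supplied (enterocyte exposure is
genuinely uncertain; both options are exposed). Paired control/treated
runs differ only by the perpetrator action.

## Estimation

Residuals are taken on log concentrations by default (PK data span
decades); a linear-scale objective is available. Each fit screens 40
Latin-hypercube candidate starts by objective value and refines the best
few with a bounded trust-region least-squares optimizer; results are
deterministic per seed, and log-transformed parameters can never go
non-positive. The finite-difference step (1e-3 in the transformed space)
deliberately dominates the ODE integration noise — with the default step
the Jacobian degenerates and fits stall short of the optimum. Observations
below the configurable LLOQ are excluded, not imputed. The staged workflow
fits disposition (logP, CL_int) to IV data, permeability to oral-solution
data, the renal GFR fraction to urinary interval amounts, and the Weibull
shape/t50 per dose/study to tablet data, freezing earlier estimates
downstream. On synthetic data at the shipped truth (12 subjects pooled,
15% residual CV), shape and t50 are recovered within a few percent and the
GFR fraction within ~5%.

## Populations and synthetic data

Virtual individuals are drawn by seeded unit-median log-normal multipliers
on organ volumes (CV 20%), blood flows (25%), GFR (20%), hepatic CYP3A4
concentration (35%), and GI transit times (30%) — defaults in the typical
range for system-parameter variability in whole-body models; the original
population's covariate-conditional distributions are not published, so
these bands reproduce the role of the population (geometric mean with
5–95% percentiles), not its exact spread. No allometric covariate scaling.

The synthetic-study module emulates the five Phase I designs as
reconstructions (single ascending dose with solution and tablet arms,
14-day multiple dose fasted/fed, IV microtracer 15 min after an oral dose,
itraconazole DDI with co-dosing from Day −3, food-effect crossover) with
dense standard sampling grids, since the true schedules are unpublished.
Residual error is proportional log-normal (default CV 20%) with an
additive floor near the LLOQ (default 1 nmol/L), then LLOQ-censored with
flags; urinary data are interval amounts consistent with the renal ledger.
Interstudy variability is a single study-level log-normal exposure factor.
Datasets regenerate bit-identically from their metadata. What passing
tests show: the pipeline recovers known generating parameters under
realistic noise, and the evaluation statistics behave as specified. What
they do not show: agreement with the real (unavailable) clinical
concentrations, or that the pinned physiology matches the proprietary
database the original analysis used.

## Known limitations

* The Weibull parameters are dose-, study-, and food-state-specific fits;
  there is deliberately no interpolation to untested doses.
* One tabulated summary row carries 5–95% bounds inconsistent with its
  geometric mean (simulated control Cmax 160 with bounds 199, 215); the
  fixture stores the row verbatim and only the ratio arithmetic uses it.
* The strict 1.5-fold band classifies the 2 mg solution Cmax ratio (0.60)
  as an excursion; the package applies the rule arithmetically.
* Two coexisting fits for the same DDI-study arm (shape 0.78 vs 0.79 at
  t50 442 min) are shipped verbatim; the `ddi` tag selects the refit.
* Perfusion-limited distribution for all organs; no permeability-limited
  tissues, no blood:plasma partitioning beyond unity.
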