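# Bevurogant (BI 730357) — initial (pre-optimization) compound parameterization.
# LogP and permeability are the experimentally measured values (Caco-2 for
# permeability); the colonic override is the unmodified pH-derived solubility;
# GFR fraction 1 assumes renal handling by passive filtration only.
name: bi730357_initial
mw_g_mol: 532.62
pka: 2.2
pka_type: base
logp: 3.4
intestinal_permeability_cm_s: 1.10e-4
sol_ref_fasted_mg_l: 19.45
sol_ref_fasted_ph: 6.5
sol_ref_fed_mg_l: 57.9
sol_ref_fed_ph: 5.0
colon_solubility_override_mg_l: 19.46
fu_plasma: 0.154
clint_hepatic_ml_min: 63.9
clint_scaling: 4.5
gfr_fraction: 1.0
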