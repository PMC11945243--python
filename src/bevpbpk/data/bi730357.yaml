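# Bevurogant (BI 730357) — final compound parameterization.
# The intrinsic-clearance entry is the optimized whole-body CYP3A4 value;
# clint_scaling maps it to the unbound-plasma-referenced intrinsic clearance
# used by the ODE model (normalization interpretation; see docs/methods.md).
name: bi730357
mw_g_mol: 532.62
pka: 2.2
pka_type: base
logp: 2.8
intestinal_permeability_cm_s: 4.42e-7
sol_ref_fasted_mg_l: 19.45      # FaSSIF-24 h, reference pH 6.5
sol_ref_fasted_ph: 6.5
sol_ref_fed_mg_l: 57.9          # FeSSIF-24 h, reference pH 5.0
sol_ref_fed_ph: 5.0
colon_solubility_override_mg_l: 637.0
fu_plasma: 0.154
clint_hepatic_ml_min: 154.71
clint_scaling: 4.5
gfr_fraction: 0.059
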