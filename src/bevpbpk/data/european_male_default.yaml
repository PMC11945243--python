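# Reference virtual individual: standard European male, ~73 kg.
# Organ volumes and blood flows follow published adult-male reference tables
# (ICRP-style); tissue composition fractions are the Rodgers-Rowland
# fractional tissue volumes (extracellular water, intracellular water,
# neutral lipid, neutral phospholipid); GI transit times and pH follow
# standard human gastrointestinal physiology compilations.
# All quantities are deterministic inputs: every simulation in this package
# that uses the default individual reads this file.
name: european_male_default
version: "1.0"
body_weight_kg: 73.0
height_cm: 176.0
gfr_ml_min: 120.0
liver_cyp3a4_umol_per_l: 4.32
liver_protein_mg_per_g: 40.0
cyp3a4_halflife_h: 36.0
blood:
  venous_l: 3.2
  arterial_l: 1.4
plasma_composition:
  f_intracellular_water: 0.0
  f_extracellular_water: 1.0
  f_neutral_lipid: 0.0
  f_neutral_phospholipid: 0.0
organs:
  lung:
    volume_l: 1.17
    blood_flow_l_h: 333.5          # pulmonary flow = cardiac output
    cyp3a4_rel_expression: 0.0
    composition: {f_intracellular_water: 0.446, f_extracellular_water: 0.336, f_neutral_lipid: 0.022, f_neutral_phospholipid: 0.0128}
  heart:
    volume_l: 0.33
    blood_flow_l_h: 14.0
    cyp3a4_rel_expression: 0.0
    composition: {f_intracellular_water: 0.456, f_extracellular_water: 0.320, f_neutral_lipid: 0.014, f_neutral_phospholipid: 0.0111}
  brain:
    volume_l: 1.45
    blood_flow_l_h: 46.0
    cyp3a4_rel_expression: 0.0
    composition: {f_intracellular_water: 0.620, f_extracellular_water: 0.162, f_neutral_lipid: 0.039, f_neutral_phospholipid: 0.0015}
  muscle:
    volume_l: 29.0
    blood_flow_l_h: 54.0
    cyp3a4_rel_expression: 0.0
    composition: {f_intracellular_water: 0.630, f_extracellular_water: 0.118, f_neutral_lipid: 0.010, f_neutral_phospholipid: 0.0072}
  adipose:
    volume_l: 14.5
    blood_flow_l_h: 19.0
    cyp3a4_rel_expression: 0.0
    composition: {f_intracellular_water: 0.017, f_extracellular_water: 0.135, f_neutral_lipid: 0.846, f_neutral_phospholipid: 0.0016}
  skin:
    volume_l: 3.3
    blood_flow_l_h: 20.0
    cyp3a4_rel_expression: 0.0
    composition: {f_intracellular_water: 0.291, f_extracellular_water: 0.382, f_neutral_lipid: 0.060, f_neutral_phospholipid: 0.0044}
  bone:
    volume_l: 10.5
    blood_flow_l_h: 15.0
    cyp3a4_rel_expression: 0.0
    composition: {f_intracellular_water: 0.346, f_extracellular_water: 0.100, f_neutral_lipid: 0.017, f_neutral_phospholipid: 0.0017}
  liver:
    volume_l: 2.1
    blood_flow_l_h: 25.0           # hepatic-artery share; portal inflow is added from the splanchnic organs
    cyp3a4_rel_expression: 1.0
    composition: {f_intracellular_water: 0.573, f_extracellular_water: 0.161, f_neutral_lipid: 0.0135, f_neutral_phospholipid: 0.0238}
  kidney:
    volume_l: 0.31
    blood_flow_l_h: 70.0
    cyp3a4_rel_expression: 0.0
    composition: {f_intracellular_water: 0.483, f_extracellular_water: 0.273, f_neutral_lipid: 0.012, f_neutral_phospholipid: 0.0242}
  spleen:
    volume_l: 0.19
    blood_flow_l_h: 10.0
    cyp3a4_rel_expression: 0.0
    composition: {f_intracellular_water: 0.579, f_extracellular_water: 0.207, f_neutral_lipid: 0.0077, f_neutral_phospholipid: 0.0113}
  pancreas:
    volume_l: 0.14
    blood_flow_l_h: 4.0
    cyp3a4_rel_expression: 0.0
    composition: {f_intracellular_water: 0.664, f_extracellular_water: 0.120, f_neutral_lipid: 0.041, f_neutral_phospholipid: 0.0093}
  stomach:
    volume_l: 0.15
    blood_flow_l_h: 3.0
    cyp3a4_rel_expression: 0.0
    composition: {f_intracellular_water: 0.475, f_extracellular_water: 0.282, f_neutral_lipid: 0.0487, f_neutral_phospholipid: 0.0163}
  small_intestine:
    volume_l: 0.64
    blood_flow_l_h: 38.0
    cyp3a4_rel_expression: 0.06
    composition: {f_intracellular_water: 0.475, f_extracellular_water: 0.282, f_neutral_lipid: 0.0487, f_neutral_phospholipid: 0.0163}
  large_intestine:
    volume_l: 0.37
    blood_flow_l_h: 14.0
    cyp3a4_rel_expression: 0.004
    composition: {f_intracellular_water: 0.475, f_extracellular_water: 0.282, f_neutral_lipid: 0.0487, f_neutral_phospholipid: 0.0163}
  gonads:
    volume_l: 0.035
    blood_flow_l_h: 1.5
    cyp3a4_rel_expression: 0.0
    composition: {f_intracellular_water: 0.595, f_extracellular_water: 0.141, f_neutral_lipid: 0.018, f_neutral_phospholipid: 0.0092}
# Twelve luminal segments, stomach -> rectum; the last six (caecum through
# rectum) are the large-intestinal sub-compartments.  Effective areas for the
# small-intestinal segments include the mucosal (plicae/villi) amplification
# of the cylindrical surface; colonic areas carry only the modest haustral
# amplification.  Feeding changes gastric emptying and the luminal pH table;
# everything else is food-state independent.
gi_tract:
  - name: stomach
    transit_time_h: {fasted: 0.25, fed: 1.0}
    ph: {fasted: 2.0, fed: 5.0}
    fluid_volume_l: 0.25
    effective_area_cm2: 500.0
    cyp3a4_rel_expression: 0.0
  - name: duodenum
    transit_time_h: {fasted: 0.25, fed: 0.25}
    ph: {fasted: 6.0, fed: 5.4}
    fluid_volume_l: 0.06
    effective_area_cm2: 70000.0
    cyp3a4_rel_expression: 0.06
  - name: upper_jejunum
    transit_time_h: {fasted: 0.75, fed: 0.75}
    ph: {fasted: 6.2, fed: 5.6}
    fluid_volume_l: 0.12
    effective_area_cm2: 180000.0
    cyp3a4_rel_expression: 0.06
  - name: lower_jejunum
    transit_time_h: {fasted: 0.75, fed: 0.75}
    ph: {fasted: 6.4, fed: 6.0}
    fluid_volume_l: 0.12
    effective_area_cm2: 160000.0
    cyp3a4_rel_expression: 0.04
  - name: upper_ileum
    transit_time_h: {fasted: 1.0, fed: 1.0}
    ph: {fasted: 6.8, fed: 6.6}
    fluid_volume_l: 0.10
    effective_area_cm2: 100000.0
    cyp3a4_rel_expression: 0.03
  - name: lower_ileum
    transit_time_h: {fasted: 1.0, fed: 1.0}
    ph: {fasted: 7.2, fed: 7.0}
    fluid_volume_l: 0.10
    effective_area_cm2: 80000.0
    cyp3a4_rel_expression: 0.02
  - name: caecum
    transit_time_h: {fasted: 4.0, fed: 4.0}
    ph: {fasted: 6.0, fed: 6.0}
    fluid_volume_l: 0.05
    effective_area_cm2: 500.0
    cyp3a4_rel_expression: 0.003
  - name: colon_ascendens
    transit_time_h: {fasted: 8.0, fed: 8.0}
    ph: {fasted: 6.3, fed: 6.3}
    fluid_volume_l: 0.05
    effective_area_cm2: 2500.0
    cyp3a4_rel_expression: 0.002
  - name: colon_transversum
    transit_time_h: {fasted: 9.0, fed: 9.0}
    ph: {fasted: 6.6, fed: 6.6}
    fluid_volume_l: 0.05
    effective_area_cm2: 2200.0
    cyp3a4_rel_expression: 0.002
  - name: colon_descendens
    transit_time_h: {fasted: 9.0, fed: 9.0}
    ph: {fasted: 6.9, fed: 6.9}
    fluid_volume_l: 0.04
    effective_area_cm2: 1800.0
    cyp3a4_rel_expression: 0.001
  - name: colon_sigmoid
    transit_time_h: {fasted: 9.0, fed: 9.0}
    ph: {fasted: 7.0, fed: 7.0}
    fluid_volume_l: 0.03
    effective_area_cm2: 1300.0
    cyp3a4_rel_expression: 0.001
  - name: rectum
    transit_time_h: {fasted: 1.5, fed: 1.5}
    ph: {fasted: 7.2, fed: 7.2}
    fluid_volume_l: 0.01
    effective_area_cm2: 300.0
    cyp3a4_rel_expression: 0.0
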