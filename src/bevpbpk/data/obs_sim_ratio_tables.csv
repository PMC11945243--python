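table,arm,food_state,dose,auc_ratio,cmax_ratio
single_dose,iv,fasted,100ug,0.91,0.74
single_dose,oral_solution,fasted,2mg,1.04,0.60
single_dose,oral_solution,fasted,25mg,1.19,0.79
single_dose,oral_tablet,fasted,50mg,1.14,1.09
single_dose,oral_tablet,fasted,100mg,0.81,0.95
single_dose,oral_tablet,fasted,200mg,1.18,0.93
single_dose,oral_tablet,fasted,400mg,1.14,1.00
day14,oral_tablet,fasted,25mg,0.90,0.98
day14,oral_tablet,fasted,50mg,0.88,1.02
day14,oral_tablet,fasted,100mg,0.87,0.89
day14,oral_tablet,fasted,200mg,0.77,0.92
day14,oral_tablet,fed,50mg,1.28,1.28
day14,oral_tablet,fed,200mg,1.26,1.20
day14,oral_tablet,fed,400mg,0.92,1.01
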