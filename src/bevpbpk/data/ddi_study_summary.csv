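source,parameter,unit,control_geomean,control_p5,control_p95,treated_geomean,treated_p5,treated_p95
observed,auc_inf,nmol_h_per_l,6960,4040,9890,65600,35600,107000
observed,auc_last,nmol_h_per_l,6650,3840,9570,43200,26600,60000
observed,cmax,nmol_per_l,186,131,280,311,218,422
simulated,auc_inf,nmol_h_per_l,8770,4690,15000,60800,15600,142000
simulated,auc_last,nmol_h_per_l,8590,4650,14500,40000,15500,67300
simulated,cmax,nmol_per_l,160,199,215,256,182,344
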