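# In-vivo Weibull dissolution parameters of the immediate-release tablet
# formulations, fitted per study, dose and food state (no interpolation to
# untested doses is meaningful: the 50%-dissolution time is dose dependent).
# The 1407-0014 entry tagged "ddi" is the refit used for the DDI prediction;
# it coexists verbatim with the overview-table value for the same arm.
entries:
  - {study: "1407-0001", dose_mg: 25,  food_state: fasted, shape: 0.58, t50_min: 404}
  - {study: "1407-0001", dose_mg: 50,  food_state: fasted, shape: 0.58, t50_min: 728}
  - {study: "1407-0001", dose_mg: 100, food_state: fasted, shape: 0.58, t50_min: 1052}
  - {study: "1407-0001", dose_mg: 200, food_state: fasted, shape: 0.58, t50_min: 1946}
  - {study: "1407-0001", dose_mg: 400, food_state: fasted, shape: 0.58, t50_min: 2570}
  - {study: "1407-0002", dose_mg: 25,  food_state: fasted, shape: 0.78, t50_min: 243}
  - {study: "1407-0002", dose_mg: 50,  food_state: fasted, shape: 0.78, t50_min: 328}
  - {study: "1407-0002", dose_mg: 100, food_state: fasted, shape: 0.78, t50_min: 370}
  - {study: "1407-0002", dose_mg: 200, food_state: fasted, shape: 0.78, t50_min: 736}
  - {study: "1407-0002", dose_mg: 50,  food_state: fed,    shape: 0.16, t50_min: 9.9}
  - {study: "1407-0002", dose_mg: 200, food_state: fed,    shape: 0.16, t50_min: 293}
  - {study: "1407-0002", dose_mg: 400, food_state: fed,    shape: 0.16, t50_min: 5000}
  - {study: "1407-0014", dose_mg: 50,  food_state: fasted, shape: 0.78, t50_min: 442}
  - {study: "1407-0014", dose_mg: 50,  food_state: fasted, shape: 0.79, t50_min: 442, tag: ddi}
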