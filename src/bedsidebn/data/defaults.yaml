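# Default configuration: variable definitions, discretization cutoffs and
# the calibrated ground-truth generator.  Cutoffs follow common critical-care
# conventions and are editable; every published summary value used for
# calibration is marked with its source table in the adjacent comment.

variables:
  high_age:            {states: ["no", "yes"], role: clinical}   # age >= 65 y
  male_gender:         {states: ["no", "yes"], role: clinical}
  cold_temperature:    {states: ["no", "yes"], role: clinical}   # subjective cold
  irregular_rhythm:    {states: ["no", "yes"], role: clinical}
  tachycardia:         {states: ["no", "yes"], role: clinical}   # HR > 100/min
  high_respiratory_rate: {states: ["no", "yes"], role: clinical} # RR > 22/min
  mechanical_ventilation: {states: ["no", "yes"], role: clinical}
  dcrtm:               {states: ["no", "yes"], role: clinical}   # delayed CRT (> 4.5 s any site) OR mottling beyond none
  low_sbp:             {states: ["no", "yes"], role: clinical}   # SBP < 90 mmHg
  low_dbp:             {states: ["no", "yes"], role: clinical}   # DBP < 60 mmHg
  low_map:             {states: ["no", "yes"], role: clinical}   # MAP < 70 mmHg
  elevated_lactate:    {states: ["no", "yes"], role: clinical}   # lactate > 2.0 mmol/L
  oliguria:            {states: ["no", "yes"], role: clinical}   # urine output < 0.5 mL/kg/h
  noradrenaline:       {states: ["no", "yes"], role: clinical}
  estimate:            {states: [poor, moderate, reasonable, good], role: estimate}
  cardiac_index:       {states: [low, high], role: outcome}  # low: CI <= 2.2 L/min/m2

discretization:
  high_age:            {source: age, op: ">=", cutoff: 65}
  tachycardia:         {source: heart_rate, op: ">", cutoff: 100}
  high_respiratory_rate: {source: respiratory_rate, op: ">", cutoff: 22}
  low_sbp:             {source: sbp, op: "<", cutoff: 90}
  low_dbp:             {source: dbp, op: "<", cutoff: 60}
  low_map:             {source: map, op: "<", cutoff: 70}
  elevated_lactate:    {source: lactate, op: ">", cutoff: 2.0}
  oliguria:            {source: urine_output, op: "<", cutoff: 0.5}
  dcrtm:
    composite_any:
      - {source: crt_knee, op: ">", cutoff: 4.5}
      - {source: crt_sternum, op: ">", cutoff: 4.5}
      - {source: crt_finger, op: ">", cutoff: 4.5}
      - {source: mottling_score, op: ">", cutoff: 0}

ground_truth:
  # consensus arcs after expert orientation of the ventilation/respiratory-rate edge
  arcs:
    - [high_age, irregular_rhythm]
    - [irregular_rhythm, tachycardia]
    - [tachycardia, high_respiratory_rate]
    - [tachycardia, low_sbp]
    - [tachycardia, elevated_lactate]
    - [high_respiratory_rate, mechanical_ventilation]
    - [noradrenaline, mechanical_ventilation]
    - [mechanical_ventilation, dcrtm]
    - [low_sbp, low_map]
    - [low_dbp, low_map]
    - [elevated_lactate, oliguria]
    - [elevated_lactate, noradrenaline]
    - [noradrenaline, estimate]
    - [dcrtm, estimate]
  # exact marginal targets for P(variable = yes); published cohort
  # proportions where available, conventional defaults otherwise
  marginals:
    high_age: 0.42          # default (age 62 +/- 15 y)
    male_gender: 0.627      # 674/1075
    cold_temperature: 0.372 # 398/1075
    irregular_rhythm: 0.108 # 116/1075
    tachycardia: 0.28       # default
    high_respiratory_rate: 0.25  # default
    mechanical_ventilation: 0.587  # 631/1075
    low_sbp: 0.25           # default
    low_dbp: 0.35           # default
    low_map: 0.28           # default
    elevated_lactate: 0.27  # default (median 1.4, IQR upper 2.2)
    oliguria: 0.30          # default (median 0.6, IQR lower 0.4)
    noradrenaline: 0.491    # 528/1075
  # additive per-parent effects on P(child = yes); strengths chosen so the
  # published arcs are comfortably identifiable at the cohort size
  effects:
    irregular_rhythm: {high_age: 0.15}
    tachycardia: {irregular_rhythm: 0.30}
    high_respiratory_rate: {tachycardia: 0.35}
    mechanical_ventilation: {high_respiratory_rate: 0.25, noradrenaline: 0.25}
    low_sbp: {tachycardia: 0.25}
    elevated_lactate: {tachycardia: 0.25}
    low_map: {low_sbp: 0.45, low_dbp: 0.30}
    oliguria: {elevated_lactate: 0.20}
    noradrenaline: {elevated_lactate: 0.35}
  # P(dcrtm = yes | mechanical_ventilation); unpublished, assumed
  p_dcrtm_given_mv: {"no": 0.30, "yes": 0.45}
  # published conditionals P(estimate reasonable-or-good | ventilation, noradrenaline)
  p_erg_targets:
    mv_yes_na_yes: 0.63
    mv_yes_na_no: 0.91
    mv_no_na_yes: 0.67
    mv_no_na_no: 0.93
  # within-group splits of the 4-level estimate (cohort totals 26/211/513/323)
  estimate_splits:
    poor_within_low: 0.1097046413502110   # 26/237
    reasonable_within_high: 0.6136363636363636  # 513/836
  # outcome attachment: P(cardiac index low | dichotomized estimate)
  outcome:
    p_low_given_estimate_low: 0.464
    p_low_given_estimate_high: 0.33
  missingness: 0.2716279069767442  # 292/1075 without a validated measurement

learning:
  ess: 1.0
  alpha: 0.05
  strength_floor: 0.700
  direction_threshold: 0.666
  pseudocount: 1.0
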