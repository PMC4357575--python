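# Default 34-item deficit codebook (synthetic stand-in).
#
# Structure follows the deficit-accumulation convention for questionnaire
# cohorts: 6 symptoms/signs, 15 comorbidities, 12 activities of daily
# living, 1 healthcare-utilization item.  Ordinal items use evenly spaced
# values on [0, 1] over their declared level order (best -> worst); binary
# items use {0, 1}.  Replace this file (``--codebook`` / ``codebook=`` )
# to use a cohort's true item coding.
items:
  # --- symptoms / signs (6), 5-level frequency scales ---
  - id: feels_full_of_life
    domain: symptoms_signs
    levels: ["all the time", "most of time", "some time", "a little time", "none of time"]
    values: [0.0, 0.25, 0.5, 0.75, 1.0]
  - id: feels_worn_out
    domain: symptoms_signs
    levels: ["none of time", "a little time", "some time", "most of time", "all the time"]
    values: [0.0, 0.25, 0.5, 0.75, 1.0]
  - id: feels_tired
    domain: symptoms_signs
    levels: ["none of time", "a little time", "some time", "most of time", "all the time"]
    values: [0.0, 0.25, 0.5, 0.75, 1.0]
  - id: pain_interference
    domain: symptoms_signs
    levels: ["none of time", "a little time", "some time", "most of time", "all the time"]
    values: [0.0, 0.25, 0.5, 0.75, 1.0]
  - id: feels_downhearted
    domain: symptoms_signs
    levels: ["none of time", "a little time", "some time", "most of time", "all the time"]
    values: [0.0, 0.25, 0.5, 0.75, 1.0]
  - id: trouble_sleeping
    domain: symptoms_signs
    levels: ["none of time", "a little time", "some time", "most of time", "all the time"]
    values: [0.0, 0.25, 0.5, 0.75, 1.0]
  # --- comorbidities (15), binary ---
  - {id: arthritis,        domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: osteoporosis,     domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: hypertension,     domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: heart_disease,    domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: diabetes,         domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: lung_disease,     domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: stroke,           domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: cancer,           domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: depression,       domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: parkinsons,       domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: kidney_disease,   domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: liver_disease,    domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: ulcer,            domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: thyroid_disease,  domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  - {id: anemia,           domain: comorbidity, levels: ["no", "yes"], values: [0.0, 1.0]}
  # --- activities of daily living (12), 3-level limitation scales ---
  - {id: adl_vigorous,       domain: adl, levels: ["not limited", "limited a little", "limited a lot"], values: [0.0, 0.5, 1.0]}
  - {id: adl_moderate,       domain: adl, levels: ["not limited", "limited a little", "limited a lot"], values: [0.0, 0.5, 1.0]}
  - {id: adl_lifting,        domain: adl, levels: ["not limited", "limited a little", "limited a lot"], values: [0.0, 0.5, 1.0]}
  - {id: adl_stairs_several, domain: adl, levels: ["not limited", "limited a little", "limited a lot"], values: [0.0, 0.5, 1.0]}
  - {id: adl_stairs_one,     domain: adl, levels: ["not limited", "limited a little", "limited a lot"], values: [0.0, 0.5, 1.0]}
  - {id: adl_bending,        domain: adl, levels: ["not limited", "limited a little", "limited a lot"], values: [0.0, 0.5, 1.0]}
  - {id: adl_walk_mile,      domain: adl, levels: ["not limited", "limited a little", "limited a lot"], values: [0.0, 0.5, 1.0]}
  - {id: adl_walk_blocks,    domain: adl, levels: ["not limited", "limited a little", "limited a lot"], values: [0.0, 0.5, 1.0]}
  - {id: adl_walk_one_block, domain: adl, levels: ["not limited", "limited a little", "limited a lot"], values: [0.0, 0.5, 1.0]}
  - {id: adl_bathing,        domain: adl, levels: ["not limited", "limited a little", "limited a lot"], values: [0.0, 0.5, 1.0]}
  - {id: adl_shopping,       domain: adl, levels: ["not limited", "limited a little", "limited a lot"], values: [0.0, 0.5, 1.0]}
  - {id: adl_housework,      domain: adl, levels: ["not limited", "limited a little", "limited a lot"], values: [0.0, 0.5, 1.0]}
  # --- healthcare utilization (1) ---
  - id: overnight_hospitalizations
    domain: healthcare_utilization
    levels: ["0", "1", "2+"]
    values: [0.0, 0.5, 1.0]
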