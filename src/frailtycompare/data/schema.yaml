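# Column manifest for the cohort CSV (non-deficit columns).
# Deficit item columns are declared by the deficit codebook, not here.
# kind: id | numeric | integer | binary | ordinal | categorical
# Missing cells are empty strings in CSV (pandas NaN in memory).
columns:
  - {name: participant_id, kind: id}
  - {name: age, kind: numeric, min: 55}            # eligibility: women aged >= 55
  - {name: bmi, kind: numeric, min_exclusive: 0}
  - {name: smoker, kind: binary}
  - {name: drinks_per_week, kind: ordinal, levels: [0, 1, 2, 3]}   # 0 / <7 / 7-13 / >=14 drinks per week
  - {name: education, kind: binary}                # 0 = high school or less, 1 = more
  - {name: baseline_falls, kind: ordinal, levels: [0, 1, 2]}       # 0 / 1 / >=2 falls in last 12 months
  - {name: prior_fracture, kind: binary}
  - {name: family_history_fracture, kind: binary}
  - {name: sf36_pf_01, kind: categorical, levels: ["limited a lot", "limited a little", "not limited"]}
  - {name: sf36_pf_02, kind: categorical, levels: ["limited a lot", "limited a little", "not limited"]}
  - {name: sf36_pf_03, kind: categorical, levels: ["limited a lot", "limited a little", "not limited"]}
  - {name: sf36_pf_04, kind: categorical, levels: ["limited a lot", "limited a little", "not limited"]}
  - {name: sf36_pf_05, kind: categorical, levels: ["limited a lot", "limited a little", "not limited"]}
  - {name: sf36_pf_06, kind: categorical, levels: ["limited a lot", "limited a little", "not limited"]}
  - {name: sf36_pf_07, kind: categorical, levels: ["limited a lot", "limited a little", "not limited"]}
  - {name: sf36_pf_08, kind: categorical, levels: ["limited a lot", "limited a little", "not limited"]}
  - {name: sf36_pf_09, kind: categorical, levels: ["limited a lot", "limited a little", "not limited"]}
  - {name: sf36_pf_10, kind: categorical, levels: ["limited a lot", "limited a little", "not limited"]}
  - {name: vitality_worn_out, kind: categorical, levels: ["none of the time", "a little of the time", "some of the time", "most of the time", "all of the time"]}
  - {name: vitality_full_of_life, kind: categorical, levels: ["none of the time", "a little of the time", "some of the time", "most of the time", "all of the time"]}
  - {name: vitality_tired, kind: categorical, levels: ["none of the time", "a little of the time", "some of the time", "most of the time", "all of the time"]}
  - {name: vitality_energy, kind: categorical, levels: ["none of the time", "a little of the time", "some of the time", "most of the time", "all of the time"]}
  - {name: walk20_days, kind: integer, min: 0, max: 30}
  - {name: weight_loss_10lb, kind: binary}
  - {name: fall_year3, kind: binary, allow_missing: true}
  - {name: fracture_event, kind: binary}
  - {name: fracture_time, kind: numeric, min_exclusive: 0, max: 3.02, allow_missing: true}
  - {name: death, kind: binary}
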