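{
  "columns": {
    "age": {
      "kind": "numeric"
    },
    "bio_CRP": {
      "kind": "numeric"
    },
    "bio_GH": {
      "kind": "numeric"
    },
    "bio_Hb": {
      "kind": "numeric"
    },
    "bio_IL15": {
      "kind": "numeric"
    },
    "bio_IL1b": {
      "kind": "numeric"
    },
    "bio_IL6": {
      "kind": "numeric"
    },
    "bio_IL7": {
      "kind": "numeric"
    },
    "bio_TNFa": {
      "kind": "numeric"
    },
    "bio_WCC": {
      "kind": "numeric"
    },
    "bio_creatinine": {
      "kind": "numeric"
    },
    "bio_eGFR": {
      "kind": "numeric"
    },
    "bio_lymphocytes": {
      "kind": "numeric"
    },
    "bio_neutrophils": {
      "kind": "numeric"
    },
    "bio_resistin": {
      "kind": "numeric"
    },
    "cond_CKD": {
      "kind": "binary"
    },
    "cond_COPD": {
      "kind": "binary"
    },
    "cond_IHD": {
      "kind": "binary"
    },
    "cond_anxiety_depression": {
      "kind": "binary"
    },
    "cond_asthma": {
      "kind": "binary"
    },
    "cond_cancer": {
      "kind": "binary"
    },
    "cond_delirium": {
      "kind": "binary"
    },
    "cond_diabetes": {
      "kind": "binary"
    },
    "cond_hypertension": {
      "kind": "binary"
    },
    "cond_stroke": {
      "kind": "binary"
    },
    "echogenicity_gsu": {
      "kind": "numeric"
    },
    "ethnicity": {
      "kind": "categorical"
    },
    "gait_speed_mps": {
      "kind": "numeric"
    },
    "group": {
      "kind": "categorical"
    },
    "handgrip_kg": {
      "kind": "numeric"
    },
    "height_cm": {
      "kind": "numeric"
    },
    "med_digoxin": {
      "kind": "binary"
    },
    "med_diuretic": {
      "kind": "binary"
    },
    "med_metformin": {
      "kind": "binary"
    },
    "med_statin": {
      "kind": "binary"
    },
    "med_steroids": {
      "kind": "binary"
    },
    "participant_id": {
      "kind": "categorical"
    },
    "phase_angle_deg": {
      "kind": "numeric"
    },
    "promis_pf_score": {
      "kind": "numeric"
    },
    "reactance_ohm": {
      "kind": "numeric"
    },
    "resistance_ohm": {
      "kind": "numeric"
    },
    "rf_left_cm": {
      "kind": "numeric"
    },
    "rf_right_cm": {
      "kind": "numeric"
    },
    "sarc_status": {
      "kind": "binary"
    },
    "sex": {
      "kind": "categorical"
    },
    "smoking": {
      "kind": "categorical"
    },
    "sppb_score": {
      "kind": "numeric"
    },
    "timepoint": {
      "kind": "categorical"
    },
    "vi_left_cm": {
      "kind": "numeric"
    },
    "vi_right_cm": {
      "kind": "numeric"
    },
    "weight_kg": {
      "kind": "numeric"
    }
  },
  "groups": [
    "elective",
    "emergency",
    "medical"
  ],
  "timepoints": [
    "preop",
    "h48",
    "d7",
    "w13"
  ]
}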