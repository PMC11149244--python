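{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "ckd-labscan pipeline summary",
  "type": "object",
  "required": [
    "n_indexed",
    "n_paired",
    "n_unpaired",
    "unpaired_fraction",
    "ckd_fraction_among_paired",
    "stage_share_among_ckd",
    "pairing_fraction_by_stage",
    "a3_fraction_by_stage",
    "crosstab",
    "risk_counts",
    "mean_age_by_ckd_status",
    "diabetes_prev_by_ckd_status",
    "specialty_share_overall",
    "specialty_share_by_stage"
  ],
  "properties": {
    "n_indexed": {"type": "integer"},
    "n_paired": {"type": "integer"},
    "n_unpaired": {"type": "integer"},
    "unpaired_fraction": {"type": "number"},
    "ckd_fraction_among_paired": {"type": "number"},
    "stage_share_among_ckd": {"type": "object"},
    "pairing_fraction_by_stage": {"type": "object"},
    "a3_fraction_by_stage": {"type": "object"},
    "crosstab": {"type": "object"},
    "risk_counts": {"type": "object"},
    "mean_age_by_ckd_status": {"type": "object"},
    "diabetes_prev_by_ckd_status": {"type": "object"},
    "specialty_share_overall": {"type": "object"},
    "specialty_share_by_stage": {"type": "object"},
    "km_ci_6mo_by_stage": {"type": "object"},
    "km_se_6mo_by_stage": {"type": "object"}
  }
}
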