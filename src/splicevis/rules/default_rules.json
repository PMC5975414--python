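[
  {
    "name": "sample_type",
    "kind": "passthrough",
    "source": "sample_type"
  },
  {
    "name": "pack_years",
    "kind": "pack-years",
    "source": "number_pack_years_smoked"
  },
  {
    "name": "overall_survival",
    "kind": "survival",
    "source": ["day_to_death", "days_to_last_follow-up"]
  },
  {
    "name": "stage",
    "kind": "stage",
    "source": "pathology_stage"
  },
  {
    "name": "risk_factor",
    "kind": "lihc-risk",
    "source": "risk_factor"
  },
  {
    "name": "alcohol_per_day",
    "kind": "alcohol",
    "source": "alcohol_per_day"
  },
  {
    "name": "pregnancies",
    "kind": "pregnancies",
    "source": "number_of_pregnancies"
  }
]
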