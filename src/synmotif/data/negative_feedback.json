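{
  "schema": "synmotif-model/1",
  "species": [
    {
      "name": "B",
      "initial": 1.0,
      "pool_partner": "B-P",
      "pool_total": 1.0
    },
    {
      "name": "B-P",
      "initial": 0.0
    },
    {
      "name": "C",
      "initial": 1.0,
      "pool_partner": "C-P",
      "pool_total": 1.0
    },
    {
      "name": "C-P",
      "initial": 0.0
    }
  ],
  "reactions": [
    {
      "kind": "mm_activation",
      "substrate": "B",
      "product": "B-P",
      "modifier": "A",
      "vmax": 1.0,
      "km": 0.5,
      "label": "activation_B"
    },
    {
      "kind": "mm_deactivation",
      "substrate": "B-P",
      "product": "B",
      "vmax": 0.5,
      "km": 0.5,
      "label": "deactivation_B"
    },
    {
      "kind": "mm_activation",
      "substrate": "C",
      "product": "C-P",
      "modifier": "B-P",
      "vmax": 1.0,
      "km": 0.5,
      "label": "activation_C"
    },
    {
      "kind": "mm_deactivation",
      "substrate": "C-P",
      "product": "C",
      "vmax": 0.5,
      "km": 0.5,
      "label": "deactivation_C"
    },
    {
      "kind": "mm_deactivation",
      "substrate": "B-P",
      "product": "B",
      "modifier": "C-P",
      "vmax": 1.0,
      "km": 0.5,
      "label": "feedback"
    }
  ],
  "output": "C-P",
  "inputs": {
    "A": 1.0
  }
}
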