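{
  "schema": "synmotif-model/1",
  "species": [
    {
      "name": "B1",
      "initial": 1.0,
      "pool_partner": "B1-P",
      "pool_total": 1.0
    },
    {
      "name": "B1-P",
      "initial": 0.0
    },
    {
      "name": "B2",
      "initial": 1.0,
      "pool_partner": "B2-P",
      "pool_total": 1.0
    },
    {
      "name": "B2-P",
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
      "substrate": "B1",
      "product": "B1-P",
      "modifier": "A1",
      "vmax": 1.0,
      "km": 0.5,
      "label": "activation_B1"
    },
    {
      "kind": "mm_deactivation",
      "substrate": "B1-P",
      "product": "B1",
      "vmax": 0.5,
      "km": 0.5,
      "label": "deactivation_B1"
    },
    {
      "kind": "mm_activation",
      "substrate": "B2",
      "product": "B2-P",
      "modifier": "A2",
      "vmax": 1.0,
      "km": 0.5,
      "label": "activation_B2"
    },
    {
      "kind": "mm_deactivation",
      "substrate": "B2-P",
      "product": "B2",
      "vmax": 0.5,
      "km": 0.5,
      "label": "deactivation_B2"
    },
    {
      "kind": "mm_activation",
      "substrate": "C",
      "product": "C-P",
      "modifier": "B1-P",
      "vmax": 1.0,
      "km": 0.5,
      "label": "activation_C_via_B1"
    },
    {
      "kind": "mm_activation",
      "substrate": "C",
      "product": "C-P",
      "modifier": "B2-P",
      "vmax": 1.0,
      "km": 0.5,
      "label": "activation_C_via_B2"
    },
    {
      "kind": "mm_deactivation",
      "substrate": "C-P",
      "product": "C",
      "vmax": 0.5,
      "km": 0.5,
      "label": "deactivation_C"
    }
  ],
  "output": "C-P",
  "inputs": {
    "A1": 1.0,
    "A2": 1.0
  }
}
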