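{
  "activation": {
    "cycle_length": 0.8,
    "systole_length": 0.34,
    "ramp_up": 0.08,
    "ramp_down": 0.45,
    "alpha": 0.8218,
    "q": 6.283185307179586
  },
  "left": {
    "side": "left",
    "e_dia": 0.04,
    "e_sys": 1.375,
    "u0": 50.0,
    "r_in": 0.008,
    "r_out": 0.008,
    "r_visc": 0.02,
    "k_ej": 0.0001,
    "v_unstressed": 10.0,
    "passive_scale": 5.0,
    "passive_knee": 150.0,
    "passive_lambda": 25.0
  },
  "right": {
    "side": "right",
    "e_dia": 0.01,
    "e_sys": 0.23,
    "u0": 24.0,
    "r_in": 0.02,
    "r_out": 0.02,
    "r_visc": 0.01,
    "k_ej": 3e-05,
    "v_unstressed": 10.0,
    "passive_scale": 2.0,
    "passive_knee": 180.0,
    "passive_lambda": 30.0
  },
  "segments": [
    {
      "id": "ascending_aorta",
      "ra": 0.0,
      "rb": 0.01,
      "inertance": 0.0,
      "compliance": 0.35,
      "gamma": 0.0,
      "y_cm": 5.0,
      "v_unstressed": 25.0
    },
    {
      "id": "aortic_arch",
      "ra": 0.012,
      "rb": 0.012,
      "inertance": 0.0005,
      "compliance": 0.42,
      "gamma": 0.02,
      "y_cm": 10.0,
      "v_unstressed": 20.0
    },
    {
      "id": "thoracic_aorta",
      "ra": 0.012,
      "rb": 0.012,
      "inertance": 0.0008,
      "compliance": 0.49,
      "gamma": 0.02,
      "y_cm": -10.0,
      "v_unstressed": 60.0
    },
    {
      "id": "abdominal_aorta",
      "ra": 0.015,
      "rb": 0.015,
      "inertance": 0.001,
      "compliance": 0.35,
      "gamma": 0.03,
      "y_cm": -25.0,
      "v_unstressed": 40.0
    },
    {
      "id": "iliac",
      "ra": 0.02,
      "rb": 0.85,
      "inertance": 0.0015,
      "compliance": 0.28,
      "gamma": 0.04,
      "y_cm": -40.0,
      "v_unstressed": 50.0
    },
    {
      "id": "cerebral",
      "ra": 6.0,
      "rb": 1.0,
      "inertance": 0.0,
      "compliance": 0.1,
      "gamma": 0.0,
      "y_cm": 35.0,
      "v_unstressed": 30.0
    },
    {
      "id": "pulmonary",
      "ra": 0.0,
      "rb": 0.06,
      "inertance": 0.0,
      "compliance": 4.0,
      "gamma": 0.0,
      "y_cm": 5.0,
      "v_unstressed": 60.0
    }
  ],
  "peripheral": {
    "compliance": 2.5,
    "v_unstressed": 250.0,
    "r_out": 0.15
  },
  "veins": {
    "compliance": 18.0,
    "v_unstressed": 2000.0,
    "r_out": 0.02
  },
  "pulmonary_veins": {
    "compliance": 80.0,
    "v_unstressed": 250.0,
    "r_out": 0.0
  },
  "total_blood_volume": 4100.0,
  "rho_b": 1.05,
  "store_resistance": 0.05,
  "occlusion": null
}
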