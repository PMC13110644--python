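{
 "description": "Synthetic reference parameter set (version-pinned; field-realistic values, not the study's unpublished supplement).",
 "config": {
  "discount_rate": 0.035,
  "start_age": 40,
  "end_age": 100,
  "cycle_length": 1.0,
  "cohort_size": 1000.0,
  "fracture_type": "HF",
  "thresholds": [
   15000.0,
   20000.0,
   30000.0
  ],
  "horizon_mode": "lifetime",
  "risk_model": "constant_hazard"
 },
 "screening": {
  "S1": {
   "screened_fraction": 0.03,
   "sensitivity": 0.65,
   "specificity": 0.82,
   "tool": "QFracture"
  },
  "S2": {
   "screened_fraction": 1.0,
   "sensitivity": 0.78,
   "specificity": 0.85,
   "tool": "IDFracture"
  },
  "S3": {
   "screened_fraction": 1.0,
   "sensitivity": 1.0,
   "specificity": 1.0,
   "tool": "DXA_direct"
  }
 },
 "epidemiology": {
  "prev_osteoporosis": 0.2,
  "prev_osteopenia": 0.4,
  "prev_normal": 0.4,
  "frac_no_fracture": 0.5,
  "p10_fracture_by_state": {
   "osteoporosis": 0.1,
   "osteopenia": 0.05,
   "normal": 0.02
  },
  "refracture_annual": 0.04,
  "rr_bisphosphonate": 0.6,
  "rr_vitd_calcium": 0.9,
  "adherence_annual": 0.8,
  "background_mortality": {
   "40": 0.005000000000000006,
   "41": 0.005389403658339073,
   "42": 0.005809134358503713,
   "43": 0.006261553992700615,
   "44": 0.006749208399029661,
   "45": 0.007274841687324648,
   "46": 0.007841411680701007,
   "47": 0.008452106559702546,
   "48": 0.009110362802706502,
   "49": 0.009819884523540523,
   "50": 0.010584664315127293,
   "51": 0.01140900571644761,
   "52": 0.012297547429246823,
   "53": 0.013255289420756211,
   "54": 0.014287621059313341,
   "55": 0.01540035144120512,
   "56": 0.01659974207938765,
   "57": 0.01789254213802736,
   "58": 0.019286026411134128,
   "59": 0.020788036258998024,
   "60": 0.022407023732785837,
   "61": 0.024152099135593276,
   "62": 0.02603308228758686,
   "63": 0.02806055778371251,
   "64": 0.03024593455491502,
   "65": 0.03260151006802862,
   "66": 0.03514053952560227,
   "67": 0.03787731045505791,
   "68": 0.040827223106906764,
   "69": 0.04400687711443775,
   "70": 0.04743416490252571,
   "71": 0.051128372371186157,
   "72": 0.05511028742043859,
   "73": 0.059402316927165875,
   "74": 0.06402861283221688,
   "75": 0.06901520804726512,
   "76": 0.07439016294619254,
   "77": 0.08018372326532992,
   "78": 0.08642849030108327,
   "79": 0.09315960436267622,
   "80": 0.10041494251232552,
   "81": 0.10823533170556683,
   "82": 0.11666477853110493,
   "83": 0.12575071684297087,
   "84": 0.13554427467845356,
   "85": 0.14610056196379456,
   "86": 0.1574789806266137,
   "87": 0.16974355886011588,
   "88": 0.18296331142004038,
   "89": 0.1972126279817991,
   "90": 0.21257169174315402,
   "91": 0.2291269306279759,
   "92": 0.24697150363008316,
   "93": 0.266205825033894,
   "94": 0.2869381294617678,
   "95": 0.30928508092764423,
   "96": 0.33337242932422795,
   "97": 0.35933571803787545,
   "98": 0.38732104667304457,
   "99": 0.41748589317828483,
   "100": 0.4500000000000001
  },
  "fracture_mortality_multiplier": 3.0,
  "postfracture_mortality_multiplier": 1.8,
  "sex_fracture_multiplier": {
   "men": 0.75,
   "women": 1.25,
   "all": 1.0
  },
  "sex_mortality_multiplier": {
   "men": 1.15,
   "women": 0.9,
   "all": 1.0
  }
 },
 "costs": {
  "cost_risk_score": 5.0,
  "cost_dxa": 80.0,
  "cost_treat_osteoporosis_annual": 65.0,
  "cost_treat_osteopenia_annual": 45.0,
  "cost_fracture_year1": 14000.0,
  "cost_postfracture_annual": 3500.0
 },
 "utilities": {
  "baseline_utility_by_age": {
   "40": 0.88,
   "41": 0.878,
   "42": 0.876,
   "43": 0.874,
   "44": 0.872,
   "45": 0.87,
   "46": 0.868,
   "47": 0.866,
   "48": 0.864,
   "49": 0.862,
   "50": 0.86,
   "51": 0.858,
   "52": 0.856,
   "53": 0.854,
   "54": 0.852,
   "55": 0.85,
   "56": 0.848,
   "57": 0.846,
   "58": 0.844,
   "59": 0.842,
   "60": 0.84,
   "61": 0.838,
   "62": 0.836,
   "63": 0.834,
   "64": 0.832,
   "65": 0.83,
   "66": 0.828,
   "67": 0.826,
   "68": 0.824,
   "69": 0.822,
   "70": 0.8200000000000001,
   "71": 0.8180000000000001,
   "72": 0.8160000000000001,
   "73": 0.8140000000000001,
   "74": 0.812,
   "75": 0.81,
   "76": 0.808,
   "77": 0.806,
   "78": 0.804,
   "79": 0.802,
   "80": 0.8,
   "81": 0.798,
   "82": 0.796,
   "83": 0.794,
   "84": 0.792,
   "85": 0.79,
   "86": 0.788,
   "87": 0.786,
   "88": 0.784,
   "89": 0.782,
   "90": 0.78,
   "91": 0.778,
   "92": 0.776,
   "93": 0.774,
   "94": 0.772,
   "95": 0.77,
   "96": 0.768,
   "97": 0.766,
   "98": 0.764,
   "99": 0.762,
   "100": 0.76
  },
  "fracture_year_multiplier": 0.7,
  "postfracture_multiplier": 0.8
 },
 "uncertainty": {
  "probabilities": 0.2,
  "utilities": 0.2,
  "costs": 0.2
 }
}
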