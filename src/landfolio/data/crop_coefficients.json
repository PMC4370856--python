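{
  "discount": {"d": 0.05, "horizon": 30},
  "crops": {
    "banana": {
      "price": 292, "yield_": 23, "annual_cost": 4745,
      "establishment_cost": 2835, "cycle_length": 10
    },
    "organic_banana": {
      "price": 398, "yield_": 15, "annual_cost": 4945,
      "establishment_cost": 3150, "cycle_length": 10
    },
    "cocoa": {
      "price": 1694, "yield_": 0.3, "annual_cost": 353,
      "establishment_cost": 1606, "cycle_length": 15
    },
    "rice": {"price": 300, "yield_": 3.7, "annual_cost": 744},
    "maize": {"price": 277, "yield_": 3.1, "annual_cost": 603},
    "soybean": {"price": 404, "yield_": 1.7, "annual_cost": 520}
  },
  "forestry": {
    "balsa": {
      "density": 833, "mortality": 0.20, "establishment_cost": 1584,
      "cycle_length": 6, "cycle_revenue": 6000, "cycle_harvest_cost": 600,
      "price_cv": 0.10, "growth_cv": 0.10,
      "interventions": [
        {"year": 3, "dbh": 0.20, "height": 8, "form_factor": 0.70,
         "removal_fraction": 0.50},
        {"year": 5, "dbh": 0.35, "height": 10, "form_factor": 0.70,
         "removal_fraction": 1.00}
      ]
    },
    "laurel": {
      "density": 833, "mortality": 0.20, "establishment_cost": 1554,
      "cycle_length": 15, "cycle_revenue": 10621, "cycle_harvest_cost": 2200,
      "price_cv": 0.10, "growth_cv": 0.10,
      "interventions": [
        {"year": 8, "dbh": 0.20, "height": 8, "form_factor": 0.70,
         "removal_fraction": 0.50},
        {"year": 15, "dbh": 0.35, "height": 12, "form_factor": 0.70,
         "removal_fraction": 1.00}
      ]
    }
  }
}
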