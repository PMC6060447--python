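# Gas carriage constants (37 degC). Tensions in kPa; contents in ml STPD per
# liter of medium. These are assumption-level defaults from the cetacean /
# mammalian literature; see docs/methods.md.
hb_o2_capacity_ml_per_g: 1.34
hb_p50_kpa: 3.7
hb_hill_n: 2.7
mb_o2_capacity_ml_per_g: 1.34
mb_p50_kpa: 0.32
co2_capacitance_ml_per_l_kpa:   # effective linear slope (incl. bicarbonate)
  blood: 40.0
  lean: 45.0
  fat: 20.0
ostwald_n2_ml_per_l_kpa:
  blood: 0.150
  lean: 0.150
  fat: 0.680                    # fat N2 solubility >> aqueous
ostwald_o2_ml_per_l_kpa:
  blood: 0.225
  lean: 0.225
  fat: 0.225
ostwald_co2_ml_per_l_kpa:       # physically dissolved fraction only
  blood: 5.9
  lean: 5.9
  fat: 5.9
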