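# Coastal (Sarasota Bay) bottlenose dolphin physiology, 200 kg reference animal.
ecotype: sarasota
reference_mass_kg: 200.0
blood_fraction: 0.071
hb_g_per_100g: 16.0
mb_g_per_100g_muscle: 3.0
hct_percent: 44.0
muscle_locomotor_fraction: 0.35
q_rest_l_per_min: 6.0
surface_q_multiplier: 3.0
dive_q_multiplier: 1.0
dive_response_depth_m: 0.0      # dive schedule engages on any submergence
vo2_rest_total_l_per_min: 0.67  # printed total; per-compartment rates sum to 0.668
compartments:
  brain:
    mass_fraction: 0.010
    vo2_rest_l_per_min: 0.035
    perfusion_surface: 0.07
    perfusion_dive: 0.07
  fat:
    mass_fraction: 0.311
    vo2_rest_l_per_min: 0.039
    perfusion_surface: 0.03
    perfusion_dive: 0.06
  central_circulation:
    mass_fraction: 0.0373
    vo2_rest_l_per_min: 0.321
    perfusion_surface: 0.25
    perfusion_dive: 0.70
  muscle:
    mass_fraction: 0.57
    vo2_rest_l_per_min: 0.273
    perfusion_surface: 0.65
    perfusion_dive: 0.17
surface_alveolar_ata:
  n2: 0.74
  o2: 0.133
  co2: 0.065
  h2o: 0.062
# Published per-compartment O2 stores for a 200 kg animal (liters); used for the
# headline store/cADL arithmetic alongside the formula-based path.
reference_o2_stores_l:
  lung: 2.21
  tissue: 3.82
  blood: 2.68
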