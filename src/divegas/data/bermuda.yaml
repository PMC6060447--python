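# Offshore (Bermuda) bottlenose dolphin physiology, 200 kg reference animal.
# Body composition follows the deep-diving (beaked-whale-like) adjustment:
# elevated blood fraction, locomotor muscle fraction, [Mb] and Hct.
ecotype: bermuda
reference_mass_kg: 200.0
blood_fraction: 0.191
hb_g_per_100g: 16.0
mb_g_per_100g_muscle: 7.3
hct_percent: 57.0
muscle_locomotor_fraction: 0.50
q_rest_l_per_min: 6.0
surface_q_multiplier: 7.0
dive_q_multiplier: 1.0
dive_response_depth_m: 20.0     # dive response only for dives deeper than 20 m
vo2_rest_total_l_per_min: 0.54  # printed total; per-compartment rates sum to 0.535
compartments:
  brain:
    mass_fraction: 0.002
    vo2_rest_l_per_min: 0.011
    perfusion_surface: 0.04
    perfusion_dive: 0.06
  fat:
    mass_fraction: 0.207
    vo2_rest_l_per_min: 0.024
    perfusion_surface: 0.02
    perfusion_dive: 0.04
  central_circulation:
    mass_fraction: 0.030
    vo2_rest_l_per_min: 0.255
    perfusion_surface: 0.60
    perfusion_dive: 0.81
  muscle:
    mass_fraction: 0.57
    vo2_rest_l_per_min: 0.245
    perfusion_surface: 0.34
    perfusion_dive: 0.09
surface_alveolar_ata:
  n2: 0.74
  o2: 0.133
  co2: 0.065
  h2o: 0.062
reference_o2_stores_l:
  lung: 2.21
  tissue: 10.00
  blood: 7.50
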