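# Reference constants for the rat choroid plexus analysis chain.
# Units are encoded in key names.  "printed" anchors are the published
# point estimates used downstream exactly as printed; the report also
# recomputes each derivable quantity from its upstream inputs.

morphometry:
  length_um: 1.71
  base_radius_um: 0.06
  tip_radius_um: 0.12
  density_per_um2: 18.0
  brush_border_extent_um: 1.5

tissue:
  epithelium_mass_mg: 4.6
  cell_density_g_per_cm3: 1.0
  cell_height_um: 10.0

secretion:
  observed_vp_ul_min: 6.8
  slope_ul_min_mosm: 0.023
  infusion_rate_ul_min: 9.0
  baseline_window_min: [50.0, 65.0]
  treatment_window_min: [100.0, 120.0]
  osmotic_window_min: [50.0, 75.0]

osmolality:
  plasma_mosm: 307.0
  csf_mosm: 307.0
  density_g_ml: 1.0

model:
  # printed anchors
  lp_trans_printed_cm_s_osm: 8.7e-5
  lp_luminal_true_printed_cm_s_osm: 1.4e-5
  total_solute_rate_printed_mmol_s: 3.48e-5
  # unstated physical constants (package defaults)
  diffusion_cm2_s: 1.5e-5
  reflection_coeff: 1.0
  partial_molar_vol_water_cm3_mol: 18.0
  temperature_k: 310.0
  channel_length: brush_border
  equivalence: equal_area
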