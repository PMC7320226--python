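input_mode: phantom
manifest: null
outdir: nirhsi_run
seed: 0
n_train: 5
n_test: 24
phantom:
  rows: 96
  cols: 96
  n_bands: 168
  wavelength_min: 900.0
  wavelength_max: 1700.0
  n_lesions:
  - 1
  - 3
  lesion_axes:
  - 6.0
  - 14.0
  tissue_fraction: 0.7
  illumination_amplitude: 0.15
  noise_sigma: 170.0
  variability_sigma: 0.116
  variability_center: 1390.0
  variability_width: 25.0
  dark_level: 100.0
  white_level: 12000.0
  panel_reflectance: 0.9
  quantize: true
  seed: 0
mask_band_nm: 1181.0
mask_method: otsu
seed_pixels: 4
std_multiplier: 12.0
connectivity: 8
zero_std_floor: 0.01
components: null
prominence: 0.15
cumulative_variance: 0.97
variance_floor: 0.01
max_angle: null
save_cubes: false
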