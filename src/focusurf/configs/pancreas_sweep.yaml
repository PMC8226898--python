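# Pancreas soft-tissue necrosis sweep scenario, full resolution.
# 50 x 10 mm^2 aperture, 1 um kerf; element counts 16-128 (x, step 4) and
# 16-64 (y, step 4); focus 25-75 mm (step 1 mm) inside the pancreas:
# 29 x 13 x 51 = 19,227 combinations. Tissue properties below are
# implementer-chosen literature-typical values (the published table for
# this stack is not available); the operating frequency is likewise a
# choice (1 MHz, a common soft-tissue therapy frequency).
name: pancreas_sweep
media:
  couplant:
    density: 1000
    sound_speed: 1480
    attenuation_db_cm_mhz: 0.00025
    power_law_exponent: 2
    specific_heat: 4180
    thermal_conductivity: 0.615
    blood_perfusion: 0
    blood_specific_heat: 3480
    nonlinearity: 0
  skin:
    density: 1090
    sound_speed: 1610
    attenuation_db_cm_mhz: 0.4
    power_law_exponent: 1
    specific_heat: 3390
    thermal_conductivity: 0.37
    blood_perfusion: 2.0
    blood_specific_heat: 3720
    nonlinearity: 1
  fat:
    density: 950
    sound_speed: 1450
    attenuation_db_cm_mhz: 0.48
    power_law_exponent: 1
    specific_heat: 2350
    thermal_conductivity: 0.21
    blood_perfusion: 0.5
    blood_specific_heat: 3720
    nonlinearity: 1
  pancreas:
    density: 1050
    sound_speed: 1590
    attenuation_db_cm_mhz: 0.6
    power_law_exponent: 1
    specific_heat: 3160
    thermal_conductivity: 0.51
    blood_perfusion: 3.0
    blood_specific_heat: 3720
    nonlinearity: 1
stack:
  layers:
    - {medium: couplant, thickness_mm: 10}
    - {medium: skin, thickness_mm: 2}
    - {medium: fat, thickness_mm: 10}
    - {medium: pancreas, thickness_mm: 62}
grid:
  extent_mm: [60, 12, 84]
  spacing_mm: [0.7, 0.7, 0.7]
array:
  aperture_mm: [50, 10]
  nx: 64
  ny: 32
  kerf_um: 1
  frequency_mhz: 1.0
  focus_mm: [0, 0, 50]
  v0_m_per_s: 0.2
sweep:
  x_elements: {start: 16, stop: 128, step: 4}
  y_elements: {start: 16, stop: 64, step: 4}
  focus_mm: {start: 25, stop: 75, step: 1}
  target_layer: pancreas
surrogate:
  seed: 42
  test_fraction: 0.2
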