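# Fast profile of the pancreas sweep: same tissue stack and aperture, but
# 0.5 MHz and a coarse grid so one simulation takes well under a second,
# and a 5 x 3 x 8 = 120-combination sweep spanning the same input ranges
# with the same relative axis densities as the full design (x:y:focus =
# 29:13:51, focus densest). Intended for tests and quick demonstrations.
name: pancreas_sweep_fast
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
  extent_mm: [60, 15, 84]
  spacing_mm: [1.25, 1.25, 2.0]
array:
  aperture_mm: [50, 10]
  nx: 64
  ny: 32
  kerf_um: 1
  frequency_mhz: 0.5
  focus_mm: [0, 0, 50]
  v0_m_per_s: 0.2
sweep:
  x_elements: {start: 16, stop: 128, step: 28}
  y_elements: {start: 16, stop: 64, step: 24}
  focus_mm: {start: 25, stop: 74, step: 7}
  target_layer: pancreas
surrogate:
  seed: 42
  test_fraction: 0.2
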