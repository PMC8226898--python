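# Endorectal prostate heating validation scenario (semi-quantitative).
# Tissue properties are the published degassed-water / rectal-wall /
# periprostate / prostate set; layer THICKNESSES are implementer
# assumptions (not published) and the source amplitude v0 is a free scale,
# so this scenario is compared by calibrated peak rise + contour width,
# never by absolute amplitude. 2.3 MHz, focus 40 mm deep.
name: prostate_validation
validation_scenario: true
media:
  water:
    density: 1000
    sound_speed: 1480
    attenuation_db_cm_mhz: 0.00025
    power_law_exponent: 2
    specific_heat: 4180
    thermal_conductivity: 0.615
    blood_perfusion: 0
    blood_specific_heat: 3480
    nonlinearity: 0
  rectal_wall:
    density: 1060
    sound_speed: 1500
    attenuation_db_cm_mhz: 0.5211
    power_law_exponent: 1
    specific_heat: 3500
    thermal_conductivity: 0.56
    blood_perfusion: 4
    blood_specific_heat: 3720
    nonlinearity: 1
  periprostate:
    density: 1060
    sound_speed: 1500
    attenuation_db_cm_mhz: 0.4343
    power_law_exponent: 1
    specific_heat: 3500
    thermal_conductivity: 0.50
    blood_perfusion: 5
    blood_specific_heat: 3720
    nonlinearity: 1
  prostate:
    density: 1060
    sound_speed: 1500
    attenuation_db_cm_mhz: 0.504
    power_law_exponent: 1
    specific_heat: 3600
    thermal_conductivity: 0.50
    blood_perfusion: 2.5
    blood_specific_heat: 3720
    nonlinearity: 1
stack:
  layers:
    # thicknesses assumed (couplant water bolus, thin rectal wall,
    # periprostatic tissue, prostate filling the rest of the grid)
    - {medium: water, thickness_mm: 5}
    - {medium: rectal_wall, thickness_mm: 4}
    - {medium: periprostate, thickness_mm: 6}
    - {medium: prostate, thickness_mm: 45}
grid:
  extent_mm: [44, 26, 55]
  spacing_mm: [0.3, 0.3, 0.5]
array:
  # 990 elements over a 40 x 23 mm^2 aperture, arranged 55 x 18 (assumed)
  aperture_mm: [40, 23]
  nx: 55
  ny: 18
  kerf_um: 1
  frequency_mhz: 2.3
  focus_mm: [0, 0, 40]
  v0_m_per_s: 0.05
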