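# Default material configuration: four-layer skin stack with an embedded
# cylindrical squamous-cell-carcinoma tumor, 1064 nm laser.
# Lengths in mm, rho kg/m^3, cp J/(kg K), k W/(m K), mu_a & mu_s mm^-1.
domain:
  extents_mm: [30.0, 30.0, 10.0]

layers:  # ordered from the irradiated surface downward
  - {name: epidermis,        thickness_mm: 0.08, rho: 1200.0, cp: 3589.0, k: 0.235, mu_a: 0.40, mu_s: 45.0, g: 0.80}
  - {name: papillary_dermis, thickness_mm: 0.50, rho: 1200.0, cp: 3300.0, k: 0.445, mu_a: 0.38, mu_s: 30.0, g: 0.90}
  - {name: reticular_dermis, thickness_mm: 0.60, rho: 1200.0, cp: 3300.0, k: 0.445, mu_a: 0.48, mu_s: 25.0, g: 0.80}
  - {name: subcutaneous_fat, thickness_mm: 7.82, rho: 1000.0, cp: 2500.0, k: 0.190, mu_a: 0.43, mu_s: 5.0,  g: 0.75}

tumor:
  diameter_mm: 10.0
  length_mm: 3.5
  top_depth_mm: 0.1
  rho: 1070.0
  cp: 3421.0
  k: 0.495
  mu_a: 0.08
  mu_s: 1.28
  g: 0.925

gnr:
  length_nm: 67.0
  diameter_nm: 10.0
  fv: 1.0e-6
  # Efficiencies are calibrated at run time so that the mixed tumor
  # coefficients at the calibration fv match the values below.
  calibration:
    fv: 1.0e-3
    mu_a_mixed: 118.419
    mu_s_mixed: 6.101

beam:
  diameter_mm: 10.0
  profile: tophat

phantom:
  # Acrylamide tissue-equivalent phantom: outer cylinder of plain phantom
  # ("normal tissue"), inner cylinder loaded with GNR ("tumor").
  outer_diameter_mm: 40.0
  outer_length_mm: 30.0
  tumor_diameter_mm: 10.0
  tumor_depth_mm: 10.0
  gnr_fv: 2.0e-5
  rho: 1070.0
  cp: 3810.0
  k: 0.56
  # Host optical properties are an assumption (water-dominated acrylamide
  # gel at 1064 nm); see docs/methods.md.
  mu_a: 0.012
  mu_s: 0.1
  g: 0.9
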