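# Default configuration: four-layer skin stack with tabulated 800-900 nm
# optical properties (mu_a, mu_s in cm^-1), the 850 nm LED source model,
# and the standard run settings.
tissue:
  n_above: 1.0
  layers:
    - name: epidermis
      thickness_mm: 0.065
      wavelength_independent: true
      properties:
        - {wavelength_nm: 850, mu_a_percm: 55.0, mu_s_percm: 450.0, g: 0.8, n: 1.34}
    - name: dermis
      thickness_mm: 1.25
      properties:
        - {wavelength_nm: 800, mu_a_percm: 0.127, mu_s_percm: 19.07, g: 0.86, n: 1.55}
        - {wavelength_nm: 825, mu_a_percm: 0.121, mu_s_percm: 18.24, g: 0.87, n: 1.55}
        - {wavelength_nm: 850, mu_a_percm: 0.122, mu_s_percm: 17.57, g: 0.87, n: 1.55}
        - {wavelength_nm: 875, mu_a_percm: 0.122, mu_s_percm: 16.98, g: 0.88, n: 1.55}
        - {wavelength_nm: 900, mu_a_percm: 0.134, mu_s_percm: 16.30, g: 0.89, n: 1.55}
    - name: fat
      thickness_mm: 12.0
      properties:
        - {wavelength_nm: 800, mu_a_percm: 0.083, mu_s_percm: 11.09, g: 0.64, n: 1.45}
        - {wavelength_nm: 825, mu_a_percm: 0.085, mu_s_percm: 11.12, g: 0.63, n: 1.45}
        - {wavelength_nm: 850, mu_a_percm: 0.086, mu_s_percm: 11.09, g: 0.62, n: 1.45}
        - {wavelength_nm: 875, mu_a_percm: 0.091, mu_s_percm: 10.97, g: 0.60, n: 1.45}
        - {wavelength_nm: 900, mu_a_percm: 0.125, mu_s_percm: 10.88, g: 0.59, n: 1.45}
    - name: muscle
      thickness_mm: 1.0e8
      properties:
        - {wavelength_nm: 800, mu_a_percm: 0.284, mu_s_percm: 6.60, g: 0.85, n: 1.37}
        - {wavelength_nm: 825, mu_a_percm: 0.309, mu_s_percm: 6.78, g: 0.85, n: 1.37}
        - {wavelength_nm: 850, mu_a_percm: 0.343, mu_s_percm: 6.60, g: 0.85, n: 1.37}
        - {wavelength_nm: 875, mu_a_percm: 0.368, mu_s_percm: 6.43, g: 0.85, n: 1.37}
        - {wavelength_nm: 900, mu_a_percm: 0.393, mu_s_percm: 6.32, g: 0.85, n: 1.37}

source:
  spectrum:
    a1: 0.5494
    b1_nm: 850.0
    c1_nm: 24.93
    wavelengths_nm: [800, 825, 850, 875, 900]
  power_mW: 10.0
  lens: {D_mm: 25.0, R_mm: 12.5, n: 1.5}
  l_mm: 5.0
  divergence_theta_deg: 60.0
  safety: {base_limit_W_m2: 2000.0, C_A: 1.0, max_hours: 8.33}

run:
  n_photons: 100000
  seed: 1
  beam_radius_mm: 10.0
  beam_profile: flat
  dr_mm: 0.05
  dz_mm: 0.05
  nr: 1600
  nz: 400
  roulette_threshold: 1.0e-4
  roulette_survival: 0.1

incident_energy_J: 10.0
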