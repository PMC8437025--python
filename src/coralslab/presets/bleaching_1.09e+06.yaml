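domain:
  Lx_mm: 10.0
  Ly_mm: 2.5
  I_id_umol_m2_s: 320.0
  wavelength_nm: 636.0
  v0_cm_s: 0.4
  T0_C: 25.0
  c0_mol_m3: 0.25
  f_heat: 0.96
  f_ps: 0.04
  eta_wat_Pa_s: 0.0009
  PR: 3.5
layers:
- name: air
  thickness_mm: 1.0
  optical:
    mu_a_per_cm: 0.0001
    mu_s_per_cm: 1.0e-05
    g: 1.0
    n: 1.0
  thermal:
    rho_kg_per_m3: 1.184
    k_W_per_m_K: 0.026
    cp_J_per_kg_K: 1005.0
  kinetics:
    D_O2_m2_per_s: 0.0
    Q_mol_per_mol: 0.0
    R_max_mol_per_m3_s: 0.0
    K_O2_mol_per_m3: 0.00313
  is_fluid: false
- name: water
  thickness_mm: 2.0
  optical:
    mu_a_per_cm: 0.0036
    mu_s_per_cm: 1.0e-05
    g: 1.0
    n: 1.33
  thermal:
    rho_kg_per_m3: 997.0
    k_W_per_m_K: 0.6
    cp_J_per_kg_K: 4183.0
  kinetics:
    D_O2_m2_per_s: 2.0e-09
    Q_mol_per_mol: 0.0
    R_max_mol_per_m3_s: 0.0
    K_O2_mol_per_m3: 0.00313
  is_fluid: true
- name: mucus
  thickness_mm: 0.1
  optical:
    mu_a_per_cm: 0.0036
    mu_s_per_cm: 1.15
    g: 0.93
    n: 1.36
  thermal:
    rho_kg_per_m3: 1109.0
    k_W_per_m_K: 0.37
    cp_J_per_kg_K: 3391.0
  kinetics:
    D_O2_m2_per_s: 1.0e-09
    Q_mol_per_mol: 0.0
    R_max_mol_per_m3_s: 0.0
    K_O2_mol_per_m3: 0.00313
  is_fluid: false
- name: epidermis
  thickness_mm: 0.1
  optical:
    mu_a_per_cm: 0.0036
    mu_s_per_cm: 126.0
    g: 0.34
    n: 1.38
  thermal:
    rho_kg_per_m3: 1109.0
    k_W_per_m_K: 0.37
    cp_J_per_kg_K: 3391.0
  kinetics:
    D_O2_m2_per_s: 1.0e-09
    Q_mol_per_mol: 0.0
    R_max_mol_per_m3_s: 0.0
    K_O2_mol_per_m3: 0.00313
  is_fluid: false
- name: mesoglea
  thickness_mm: 0.1
  optical:
    mu_a_per_cm: 0.0016
    mu_s_per_cm: 150.0
    g: 0.68
    n: 1.45
  thermal:
    rho_kg_per_m3: 1109.0
    k_W_per_m_K: 0.37
    cp_J_per_kg_K: 3391.0
  kinetics:
    D_O2_m2_per_s: 1.0e-09
    Q_mol_per_mol: 0.0
    R_max_mol_per_m3_s: 0.0
    K_O2_mol_per_m3: 0.00313
  is_fluid: false
- name: oral_gastrodermis
  thickness_mm: 0.2
  optical:
    mu_a_per_cm: 30.663442962962964
    mu_s_per_cm: 97.65
    g: 0.98
    n: 1.42
  thermal:
    rho_kg_per_m3: 1109.0
    k_W_per_m_K: 0.37
    cp_J_per_kg_K: 3391.0
  kinetics:
    D_O2_m2_per_s: 1.0e-09
    Q_mol_per_mol: 0.02422222222222222
    R_max_mol_per_m3_s: 0.012
    K_O2_mol_per_m3: 0.00313
  is_fluid: false
- name: gastric_cavity
  thickness_mm: 0.6
  optical:
    mu_a_per_cm: 0.0036
    mu_s_per_cm: 1.0e-05
    g: 1.0
    n: 1.33
  thermal:
    rho_kg_per_m3: 997.0
    k_W_per_m_K: 0.6
    cp_J_per_kg_K: 4183.0
  kinetics:
    D_O2_m2_per_s: 2.0e-09
    Q_mol_per_mol: 0.0
    R_max_mol_per_m3_s: 0.0
    K_O2_mol_per_m3: 0.00313
  is_fluid: false
- name: aboral_gastrodermis
  thickness_mm: 0.5
  optical:
    mu_a_per_cm: 12.153628148148151
    mu_s_per_cm: 38.7
    g: 0.98
    n: 1.42
  thermal:
    rho_kg_per_m3: 1109.0
    k_W_per_m_K: 0.37
    cp_J_per_kg_K: 3391.0
  kinetics:
    D_O2_m2_per_s: 1.0e-09
    Q_mol_per_mol: 0.04117777777777778
    R_max_mol_per_m3_s: 0.012
    K_O2_mol_per_m3: 0.00313
  is_fluid: false
- name: aboral_mesoglea
  thickness_mm: 0.1
  optical:
    mu_a_per_cm: 0.0016
    mu_s_per_cm: 150.0
    g: 0.68
    n: 1.45
  thermal:
    rho_kg_per_m3: 1109.0
    k_W_per_m_K: 0.37
    cp_J_per_kg_K: 3391.0
  kinetics:
    D_O2_m2_per_s: 1.0e-09
    Q_mol_per_mol: 0.0
    R_max_mol_per_m3_s: 0.0
    K_O2_mol_per_m3: 0.00313
  is_fluid: false
- name: skeleton
  thickness_mm: 3.0
  optical:
    mu_a_per_cm: 0.01
    mu_s_per_cm: 34.0
    g: 0.9
    n: 1.66
  thermal:
    rho_kg_per_m3: 2930.0
    k_W_per_m_K: 1.5
    cp_J_per_kg_K: 811.0
  kinetics:
    D_O2_m2_per_s: 2.0e-11
    Q_mol_per_mol: 0.0
    R_max_mol_per_m3_s: 3.75e-05
    K_O2_mol_per_m3: 0.00313
  is_fluid: false
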