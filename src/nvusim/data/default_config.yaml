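# Default neurovascular-unit phantom parameters.
#
# Literature parameter set for a cortical capillary segment: geometry of
# the four-region phantom, Carreau blood rheology, interstitial-fluid
# Darcy properties, glucose diffusion/consumption and GLUT1 carrier
# kinetics.  Lengths in metres, pressures in Pa (or *_mmhg), times in
# seconds, concentrations in mM (= mol/m^3).

geometry:
  L_capillary: 25.0e-6     # capillary segment length
  R0: 7.0e-6               # lumen radius
  h_end: 1.0e-6            # endothelium thickness
  h_bl: 100.0e-9           # basal lamina thickness
  L_surround: 25.0e-6      # parenchyma radial extent

endfeet:
  coverage_fraction: 0.856 # fraction of basal-lamina surface under end-feet
  n_bands: 8               # annular end-foot stripes along z

rheology:
  rho_blood: 1070.0        # kg/m^3
  mu_0: 5.6e-2             # Pa s, zero-shear viscosity
  mu_inf: 3.45e-3          # Pa s, infinite-shear viscosity
  lambda_c: 3.131          # s, Carreau time constant
  n_idx: 0.3568            # Carreau index

isf:
  rho_isf: 1000.0          # kg/m^3
  mu_isf: 7.0e-4           # kg/m/s
  kappa: 6.5e-15           # m^2, Darcy permeability
  alpha_icf: 0.36          # porosity (ISF volume fraction)
  tau: 1.635               # tortuosity

transport:
  D_lumen: 3.1e-10         # m^2/s, glucose in flowing blood
  D_bl: 1.6e-10            # m^2/s, glucose in basal lamina
  D_tissue: 8.7e-10        # m^2/s, cytosolic value (astrocytes/neurons)
  D_endothelium: 8.7e-10   # m^2/s, set equal to the cytosolic value
  sigma_long: 1.0          # axial anisotropy factor
  sigma_trans: 0.33        # radial anisotropy factor
  Km_glut: 8.0             # mM, GLUT1 affinity
  N_glut_endo_inner: 1.0e+15   # 1/m^2  (1.0e3 per um^2)
  N_glut_endo_outer: 1.0e+15   # 1/m^2
  N_glut_endfeet: 1.8e+13      # 1/m^2  (0.018e3 per um^2)
  k_cat: 1.166e+3          # 1/s, GLUT1 turnover at 37 C

kinetics:
  k_glc_E: 0.12            # 1/s, hexokinase-PFK system, endothelium
  k_glc_II: 0.12           # 1/s, parenchyma
  k_glc_I: 1.2e-3          # 1/s, blood (eps_I << eps_E ~ eps_II)
  K_I_ATP: 1.0             # mM, ATP inhibition constant
  n_H: 4.0                 # Hill degree
  c_ATP: 1.0               # mM
  K_glc: 0.05              # mM, glucose affinity of consumption

scenario:
  p0_mmhg: 18.5            # baseline mid-capillary pressure
  dp: 10.1393              # Pa, half inlet-to-mid pressure difference
                           # (calibrated: baseline mean lumen speed 1.28 mm/s)
  t0: 2.0                  # s, shift mid-point
  dt_smooth: 0.5           # s, smoothing window
  amplitude_a: 0.7         # terminal |delta|
  direction: decrease      # baseline | decrease | increase
  t_end: 4.0               # s
  c_inlet: 5.0             # mM, feed concentration
  c_init_lumen: 5.0        # mM
  c_init_endo: 1.0         # mM
  c_init_bl: 1.0           # mM
  c_init_tissue: 1.0       # mM
  dp_isf: 1.3462           # Pa, axial ISF drive (mean percolation ~5e-7 m/s)

numerics:
  nr: 60
  nz: 120
  dt: 1.0e-3               # s
  record_every: 1.0e-2     # s
  snapshot_every: 0.25     # s
  carrier_mode: symmetric  # symmetric | one_sided
  lumen_mode: quasi_steady # quasi_steady | transient
  flow_resolve_threshold: 0.05
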