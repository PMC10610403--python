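# Respiratory-tract geometry, transport and deposition constants.
#
# Regions (mouth inward): ET2 extrathoracic, BB bronchial, bb bronchiolar,
# AL alveolar.  Transport-rate defaults follow the ICRP human-respiratory-
# tract compartmental clearance rates; permeability-surface-area products
# are fixed by documented defaults with the bronchiolar value set by the
# one-time absorption calibration.
version: 1
regions: [ET2, BB, bb, AL]
surface_area_cm2:    {ET2: 45.0, BB: 300.0, bb: 2400.0, AL: 1.4e+06}
h_elf_cm:            {ET2: 1.5e-03, BB: 1.1e-03, bb: 6.0e-04, AL: 7.0e-06}
v_elf_mL:            {ET2: 0.0675, BB: 0.33, bb: 1.44, AL: 9.8}
v_ep_mL:             {ET2: 0.225, BB: 1.65, bb: 3.6, AL: 25.0}
v_int_mL:            {ET2: 0.225, BB: 1.65, bb: 3.6, AL: 150.0}
psa_L_h:             {ET2: 0.005, BB: 0.05, bb: 0.6, AL: 3.0}
kmcc_per_h:          {ET2: 4.0, BB: 0.417, bb: 0.083, AL: 0.0}
ktr_per_h:           {ET2: 4.0, BB: 0.417, bb: 0.083, AL: 0.0}
ph:                  {elf: 6.6, ep: 7.0, int: 7.4}
kdiss_max_L_h: 1000.0        # numerical cap on the film-model dissolution rate
# Breathing parameters during smoking
tidal_volume_mL: 750.0
breath_frequency_per_min: 12.0
air_viscosity_Pa_s: 1.81e-5
air_temperature_K: 310.0
mean_free_path_um: 0.066
# Filters-in-series deposition: single-pass efficiencies
#   ET2/BB (impaction-dominated): eta = 1 - exp(-k * d_ae_um^2)
#   bb/AL  (diffusion-dominated): eta = 1 - exp(-k * sqrt(D_p m2_s))
# Scale constants k calibrated once so the reference smoke particle
# (d_ae 0.39 um, rho 3 g/cm3, chi 1.5, f_hyg 1.5) reproduces the regional
# deposition pattern 0.76 / 1.4 / 37 / 24 %.  Values frozen below.
deposition_k:
  ET2: 0.0365617349
  BB: 0.0675941912
  bb: 31088.8124
  AL: 42556.7990
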