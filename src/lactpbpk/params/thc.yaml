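# Drug-specific parameters for delta-9-tetrahydrocannabinol (THC).
# One entry per physicochemical / biochemical constant; substitute a
# different file to model another inhaled lipophilic compound.
version: 1
name: THC
dose_mg: 45.2              # standard joint: 0.32 g at 14.14% THC
mw: 314.5                  # g/mol
logp: 6.97
bp: 0.667                  # blood-to-plasma ratio
pka: 10.6                  # weak (phenolic) acid
fup: 0.0022                # unbound fraction in plasma
fumic: 0.04                # unbound fraction in liver microsomes
vmax_cyp2c9: 624.0         # pmol/min/mg microsomal protein
km_cyp2c9: 0.07            # umol/L
vmax_cyp3a4: 4905.0        # pmol/min/mg
km_cyp3a4: 5.48            # umol/L
solubility_mg_L: 2.8       # aqueous solubility
psa_A2: 29.5               # polar surface area
hbd: 1                     # hydrogen-bond donors
# Smoke-particle aerosol properties
d_ae_um: 0.39              # aerodynamic diameter
particle_density: 3.0      # g/cm^3
shape_factor: 1.5          # dynamic shape factor chi
f_hyg: 1.5                 # hygroscopic growth factor (thermodynamic diameter)
# Scaling constants
mppgl_mg_per_g: 40.0       # adult microsomal protein per g liver
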