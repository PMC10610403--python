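# SYNTHETIC / representative infant growth and ontogeny constants (0-1 y).
#
# The growth function is y = (a + b*age) / (1 + c*age + d*age^2) with age in
# years.  The published constant set this file stands in for is not
# redistributable; the values below were constructed to match standard term-
# infant anatomy at birth and at one year (organ weights in kg, cardiac
# output in L/min) and the ontogeny shape constraints for CYP2C9/3A4
# (fractional activity ~0.21 / ~0.11 at birth, approaching the adult level
# with age).  Treat these as representative defaults, not a transcription.
version: 1
cardiac_output_L_min: {a: 0.65, b: 0.75, c: 0.10, d: 0.0}
height_cm: {a: 50.0, b: 26.0, c: 0.0, d: 0.0}
blood_L: {a: 0.30, b: 0.50, c: 0.0, d: 0.0}
organ_weights_kg:
  adipose: {a: 0.70, b: 2.10, c: 0.0, d: 0.0}
  bone:    {a: 0.60, b: 1.00, c: 0.0, d: 0.0}
  brain:   {a: 0.37, b: 0.58, c: 0.0, d: 0.0}
  gut:     {a: 0.06, b: 0.12, c: 0.0, d: 0.0}
  muscle:  {a: 0.80, b: 1.40, c: 0.0, d: 0.0}
  heart:   {a: 0.021, b: 0.026, c: 0.0, d: 0.0}
  spleen:  {a: 0.010, b: 0.016, c: 0.0, d: 0.0}
  kidney:  {a: 0.025, b: 0.045, c: 0.0, d: 0.0}
  lungs:   {a: 0.064, b: 0.086, c: 0.0, d: 0.0}
  liver:   {a: 0.130, b: 0.200, c: 0.0, d: 0.0}
# fCYP = x*age^n / (y + age^n) + z, age in years.
cyp_ontogeny:
  cyp2c9: {x: 0.79, y: 0.33, z: 0.21, n: 1.0}
  cyp3a4: {x: 0.89, y: 0.64, z: 0.11, n: 1.0}
# Microsomal protein per gram of liver for infants (mg/g); the adult default
# (40 mg/g) lives in thc.yaml with the clearance parameters.
mppgl_mg_per_g: 26.0
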