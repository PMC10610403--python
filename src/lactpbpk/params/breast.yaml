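# Breast / milk compartment constants for the lactation model.
version: 1
v_breast_L: 0.5
v_milk_L: 0.21             # milk storage capacity (population SD 0.011)
flow_fraction: 0.035       # breast blood flow as fraction of cardiac output
kp_breast_fraction: 0.5    # Ktp,breast = fraction * Ktp,adipose (range 0.25-0.7)
ph_breast: 7.4
ph_milk: 7.0
fw_skim_milk: 0.955        # fractional water volume of skimmed milk
f_fat_milk: 0.045          # fractional fat volume of whole milk
h_bt_um: 20.0              # mammary epithelial thickness
n_lobes: 20
n_lobules_per_lobe: 40
# Lobule radius (cm): the one calibrated lactation constant, fixed once so
# the typical-subject milk/plasma AUC(0-24 h) ratio for the single-joint
# scenario falls in the 3.3-3.6 range; never re-fit at run time.
lobule_radius_cm: 0.20384
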