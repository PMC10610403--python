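# Methods

`lactpbpk` is a whole-body physiologically based pharmacokinetic (PBPK)
simulator for Δ9-tetrahydrocannabinol (THC) in a lactating mother who smokes
cannabis, coupled to an oral-absorption PBPK model of her breastfed infant.
This note records the model structure, the parameter choices that matter,
the numerical conventions, and the known limitations.

## Maternal model

**Structure.** Perfusion-limited compartments for adipose, bone, brain, gut,
muscle, heart, spleen, kidney, lungs, liver, rest-of-body, plus arterial and
venous blood pools, a breast tissue compartment with a milk sub-compartment,
and a four-region airway absorption chain (ET2 extrathoracic, BB bronchial,
bb bronchiolar, AL alveolar; each region holds undissolved lumen material,
epithelial lining fluid, epithelium and interstitium). Non-eliminating
tissues follow dA/dt = Q·(C_art − C/(Kp/BP)); the liver receives hepatic
arterial plus portal (gut + spleen) inflow and eliminates at CLh·C_liver
with CLh from the well-stirred model, CLh = Qh·fub·ΣCLint/(Qh + fub·ΣCLint).
Intrinsic clearances for CYP2C9 and CYP3A4 are scaled from microsomal
kinetics by MPPGL (40 mg/g adult liver) and liver mass, divided by the
microsomal unbound fraction. Renal clearance is zero (<2% excreted
unchanged). Venous blood passes the alveolar interstitium (where airway
absorption enters, Q = cardiac output) and the lung tissue before reaching
the arterial pool.

The printed organ blood-flow fractions sum to 1.13 if liver (0.27) is read
as arterial; we read it as total hepatic flow (portal 0.20 + arterial 0.07),
which leaves a 3.5% arteriovenous shunt closing the arterial balance.

**Partitioning.** Tissue:plasma coefficients use the Berezhkovskiy-corrected
Poulin–Theil method, with the distribution coefficient logD7.4 (computed
from logP and pKa) for adipose and logP elsewhere; tissue unbound fractions
follow fut = 1/(1 + (1−fup)/fup·R), R = 0.15 (adipose) / 0.5 (other). The
resulting whole-body Vss for the typical 78-kg mother is 8.41 L/kg. Using
logP for adipose instead would give Vss ≈ 70 L/kg, far outside the
literature window (6.5–10 L/kg), which fixes the logD convention. The
breast Kp is a fraction (default 0.5, population range 0.25–0.7) of the
adipose Kp.

## Inhalation

**Deposition.** The airway is four filters in series; ET2/BB/bb filter the
stream on inhalation and exhalation, the closed-ended alveolar region once.
Single-pass efficiencies are 1 − exp(−k·x) with x the impaction parameter
(aerodynamic diameter squared) for ET2/BB and the square root of the
Brownian diffusion coefficient (Stokes–Einstein with Cunningham slip, at
the hygroscopically grown thermodynamic diameter) for bb/AL. The four scale
constants k are calibrated once so the reference smoke particle (d_ae
0.39 µm, density 3 g/cm³, shape factor 1.5, hygroscopic growth 1.5)
reproduces the regional pattern 0.76 / 1.4 / 37 / 24 %, and are frozen in
`params/airway.yaml`. Hygroscopic growth applies to the thermodynamic
diameter only, so only the diffusion-driven small-airway efficiencies
respond to it.

**Absorption.** The deposited dose enters the regional lumens uniformly over
the smoking session (13 puffs × 40 s by default); dissolution into the
lining fluid follows the film model kdiss·(S_THC − C_elf) with kdiss =
D·SA/h capped at 1000 L/h (the nominal alveolar film is vanishingly thin),
and permeation proceeds lumen → fluid → epithelium → interstitium with
regional permeability-surface-area products. Undissolved and dissolved
material moves bb → BB → ET2 by particle transit and mucociliary clearance
(ICRP-like rates 0.083 / 0.417 / 4.0 h⁻¹); material leaving ET2 is
swallowed and discarded (maternal oral bioavailability of THC is low and
not modelled). Bronchial-region interstitial drug drains to venous blood;
the alveolar interstitium exchanges with the full cardiac output.

Because the dissolution flux is solubility-capped (S_THC = 2.8 mg/L),
smoked-route absorption is zero-order whenever lining fluid is saturated,
while the competing mucociliary losses are first-order: the absorbed
fraction — and therefore AUC — is sub-proportional in the smoked dose
(measured 2×-dose AUC ratio ≈ 1.7). IV and infant-oral kinetics are
strictly linear. Within one scenario this does not matter: every joint in
the multi-session scenarios is the same 45.25 mg.

Two constants were fixed by a one-time calibration against the published
exposure predictions and then frozen: the bronchiolar PSA (0.6 L/h, sets
the absorbed fraction and hence plasma AUC(0–24 h) ≈ 259 ng·h/mL for the
single joint) and the alveolar PSA (3.0 L/h, sets the absorption-phase
shape; milk Tmax ≈ 0.7 h in the 23.18 mg/15 min scenario).

## Lactation

Breast tissue exchanges with milk through two parallel routes: a
secretion/reabsorption clearance pair predicted from molecular descriptors
(CL_bt→mk = 3.39 L/h, CL_mk→bt = 8.10 L/h) and passive permeation with
PSA_bt = SA·D/h over 800 spherical lobules. Fluxes are weighted by the
unbound milk fraction (fu_milk = 0.529 from the Atkinson–Begg relations,
taking the printed fat term ff·logP_milk literally — the antilog variant
drives fu_milk to ~1e-10 and makes milk an absorbing trap) and by the
non-ionized fractions.

**Ionization convention.** THC (pKa 10.6) is a weak phenolic acid,
essentially neutral at pH 7.0–7.4, so the default non-ionized fractions use
the acid-form Henderson–Hasselbalch expression (fun ≈ 0.999). The base-form
expression (fun ≈ 6×10⁻⁴) is available as a mode switch but suppresses
milk transfer by three orders of magnitude, which is incompatible with any
appreciable milk concentration one hour after smoking; under the acid
convention the milk pool equilibrates with breast tissue within minutes and
the milk-to-plasma AUC(0–24 h) ratio is governed by the flux-coefficient
ratio times the breast Kp.

The lobule radius is the one calibrated lactation constant (0.204 cm →
PSA_bt = 5.5 L/h), fixed once so the typical-subject M/P AUC ratio for the
single-joint scenario is 3.44 (inside the 3.3–3.6 target band), and never
re-fit at run time.

**Feeding.** Milk storage is constant-volume (0.21 L); a feed removes the
drug amount in proportion to the volume drunk (capped at the storage
volume), with drug-free secreted milk replacing it. The default schedule is
the first feed 1 h after the first smoking session, then every 3 h. The
feed log (time, volume, milk concentration, ingested dose) is the hand-off
contract to the infant model.

**Milk terminal half-life.** With q3h feeds the milk pool re-equilibrates
from breast tissue between feeds, so its terminal slope equals the body's
terminal phase for any transfer parameters. The body terminal half-life
implied by the printed physiology is ≈ 13 h (one-compartment bound
ln2·Vss/CL = 6.5 h, slowed by adipose/bone redistribution); the published
model reports ≈ 39 h, which is not derivable from the printed Vss and a
flow-limited hepatic clearance. We report the simulated value as-is.

## Infant model

Infants (0–1 y) are built by scaling: weight (age·12+9)/2; organ weights,
blood volume and cardiac output from linear-rational growth functions
(`params/infant_growth.yaml`, a synthetic/representative constant set
matching standard term-infant anatomy — the published constants are not
redistributable); plasma binding from the albumin–age relation (natural
log, floored at one day; the same relation evaluated at the maternal age
supplies the adult reference, ≈ 37.5 g/L); blood-to-plasma ratio through
red-cell partition invariance, BP_child = 1 + Ht_child·(fup_child·KpRBC − 1);
and CYP2C9/3A4 ontogeny fCYP = x·age^n/(y + age^n) + z with fCYP2C9(birth)
= 0.21. Infant MPPGL is 26 mg/g (neonatal literature value). Infant Kp
values are recomputed with the infant unbound fraction.

Each feed delivers F·(C_milk·V_feed) into a first-order gut depot
(ka = 2·Peff/R with Peff = 1×10⁻⁴ cm/s and an age-scaled intestinal
radius), with overall bioavailability F = Fa·Fg·Fh; Fa = 0.9 and Fg = 0.75
are external-source defaults, and Fh = 1 − CLh,blood/Qh,blood is the
well-stirred first-pass survival (≈ 0.14 at one month; F ≈ 0.09 — the high
hepatic extraction of THC makes infant oral bioavailability low). The feed
volume per feed is the age-based daily intake regression (natural log;
649 mL/day at one month) divided by the number of daily feeds (default 8).

Two daily-dose estimators are provided: per-feed summation
Σ C_milk(t_i)·V_feed (used for the RID sweep) and the lactation-convention
average-concentration estimator Cavg·V_daily/weight over a stated sampling
window (used for the pilot-study comparison, whose published AUC/Cavg pair
implies a ~4 h window).

## Population simulation

One hundred virtual mothers (mean 28 y, 78 kg, BMI 27.7): lognormal body
weight (CV 20%, organs rescaled isometrically from the typical subject —
the printed age-only adipose regression cannot apply to an arbitrary
individual), uniform breast:adipose partition fraction on 0.25–0.7,
lognormal CYP abundance (CV 30%), normal milk storage volume
(0.21 ± 0.011 L). All sampling is seeded and reproducible.

## Numerics

LSODA (stiff-capable) with rtol 1e-8 / atol 1e-10; output grid 0.05 h.
Dosing and feeding are handled by stop–restart at exact event times, never
by step interpolation; smoking sessions and IV infusions are zero-order
inputs over their stated durations. States are amounts (ng); negative
excursions are clamped at zero inside the RHS only. Global mass balance
(input = body + eliminated + swallowed + removed milk) holds to ~1e-14
relative in practice and is asserted below 0.1%.

Moment analysis of an IV bolus (Vss = CL·(AUMC/AUC − T_inf/2)) recovers
the algebraic Vss within ~4%: elimination from the high-partition liver
violates the central-elimination assumption of the moment identity, biasing
the estimate slightly low; the cross-check is asserted at 5%.

Non-compartmental half-life uses a log-linear fit over the last 20% of the
simulated span (≥ 5 positive points). Test-suite population runs use
reduced seeded samples (n = 30 single-joint, n = 10 pilot-study); the
acceptance script uses the full n = 100.

## What the synthetic data do and do not show

Test inputs are generated entirely in code: scenario configurations
mirroring the published dosing designs, seeded virtual populations, and
synthetic "observed" profiles (simulated truth × lognormal noise) for
exercising the AAFE evaluation workflow. Passing tests therefore
demonstrate internal consistency, calibration to the published summary
predictions, and correct statistics — not agreement with real digitized
concentration data, which users can supply as delimited files (time,
concentration, matrix, study, unit) through the `evaluate` workflow.

## Known limitations

No THC metabolites (11-OH-THC, 11-COOH-THC); no brain P-gp efflux; no
enzyme auto-induction in chronic users; monodisperse smoke particles; no
maternal oral absorption of swallowed airway material; infant renal
elimination zero; infant age fixed within a run. The milk terminal
half-life and the smoked-route dose-linearity deviations discussed above
are structural consequences of the printed equations and parameters.
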