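"""Virtual-subject physiology: adult (maternal) and infant anatomy.

Adults are parameterised from sex, age, weight and BMI using published
anthropometric regressions (cardiac output, lean body mass, organ-weight
polynomials).  Infants (0-1 y) are built by scaling organ weights, cardiac
output, plasma protein binding, blood-to-plasma ratio and CYP activity down
from the adult reference with age-dependent growth and ontogeny functions.

Units: weights kg, volumes L, flows L/h (cardiac output), age years,
albumin g/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .params import load_params

#: Organs with an explicit perfusion-limited compartment in the model.
ORGANS = (
    "adipose", "bone", "brain", "gut", "muscle", "heart",
    "spleen", "kidney", "lungs", "liver", "rest",
)

#: Fractional tissue composition: water, neutral lipid, phospholipid,
#: extracellular water, intracellular water, specific gravity (g/cm^3).
#: The rest-of-body intracellular-water entry in the source table (1.581)
#: exceeds unity and cannot be a volume fraction; the total-water fraction
#: (0.70) is what the partition method consumes, so the ew/iw split of the
#: rest compartment is renormalised to sum to the total water.
TISSUE_COMPOSITION: dict[str, dict[str, float]] = {
    "adipose": dict(fVwt=0.286, fVnl=0.609, fVph=0.005, fVew=0.135, fViw=0.017, rho=0.9196),
    "bone":    dict(fVwt=0.45,  fVnl=0.074, fVph=0.0011, fVew=0.1,   fViw=0.346, rho=1.176),
    "brain":   dict(fVwt=0.78,  fVnl=0.051, fVph=0.0565, fVew=0.162, fViw=0.62,  rho=1.04),
    "gut":     dict(fVwt=0.76,  fVnl=0.0487, fVph=0.0163, fVew=0.282, fViw=0.475, rho=1.045),
    "muscle":  dict(fVwt=0.71,  fVnl=0.022, fVph=0.0072, fVew=0.118, fViw=0.63,  rho=1.06),
    "heart":   dict(fVwt=0.78,  fVnl=0.0115, fVph=0.0166, fVew=0.32,  fViw=0.456, rho=1.055),
    "spleen":  dict(fVwt=0.79,  fVnl=0.0201, fVph=0.0198, fVew=0.207, fViw=0.579, rho=1.06),
    "kidney":  dict(fVwt=0.76,  fVnl=0.0207, fVph=0.0162, fVew=0.273, fViw=0.483, rho=1.035),
    "lungs":   dict(fVwt=0.78,  fVnl=0.003, fVph=0.009,  fVew=0.336, fViw=0.446, rho=1.05),
    "liver":   dict(fVwt=0.73,  fVnl=0.0348, fVph=0.0252, fVew=0.161, fViw=0.573, rho=1.054),
    "rest":    dict(fVwt=0.70,  fVnl=0.02,  fVph=0.01,   fVew=0.3358, fViw=0.3642, rho=1.0),
}

PLASMA_COMPOSITION = dict(fVwt=0.95, fVnl=0.0032, fVph=0.0021)

#: Fraction of cardiac output per organ.  Liver (0.27) is total hepatic flow;
#: the portal contribution comes through gut (0.17) and spleen (0.03), so the
#: hepatic-arterial fraction is 0.07.  Arterial fractions including the
#: lactating breast (0.035) sum to 0.965; the remainder is an arteriovenous
#: shunt so the arterial pool balances exactly.
BLOOD_FLOW_FRACTIONS = {
    "adipose": 0.085, "bone": 0.05, "brain": 0.12, "gut": 0.17,
    "muscle": 0.12, "heart": 0.05, "spleen": 0.03, "kidney": 0.17,
    "lungs": 1.0, "liver": 0.27, "rest": 0.065,
}
HEPATIC_ARTERIAL_FRACTION = (
    BLOOD_FLOW_FRACTIONS["liver"]
    - BLOOD_FLOW_FRACTIONS["gut"]
    - BLOOD_FLOW_FRACTIONS["spleen"]
)
BREAST_FLOW_FRACTION = 0.035


class AnthropometryError(ValueError):
    """Raised when an anthropometry combination yields a non-physical body."""


def cardiac_output(is_male: int, age: float, weight: float) -> float:
    """Cardiac output (L/h) from sex, age (y) and weight (kg)."""
    return (6.963 + 0.446 * is_male - 0.037 * age + 0.013 * weight) * 60.0


def height_from_bmi(weight: float, bmi: float) -> float:
    """Height (m) implied by weight (kg) and BMI (kg/m^2)."""
    return math.sqrt(weight / bmi)


def lean_body_mass(weight: float, height_m: float) -> float:
    return 0.252 * weight + 0.473 * (height_m * 100.0) - 48.3


def _adult_organ_weights(age: float, weight: float, height_m: float) -> dict[str, float]:
    """Organ weights (kg) from the adult regressions.

    Polynomial regressions return grams and are rescaled; adipose, muscle and
    bone regressions are in kg.
    """
    a = age
    lbm = lean_body_mass(weight, height_m)
    w = {
        "adipose": 17.4 + 0.65 * a - 0.01 * a**2 + 9e-5 * a**3,
        "bone": 0.21 * lbm,
        "brain": (653 + 95.4 * a - 4.32 * a**2 + 0.0729 * a**3 - 0.000413 * a**4) / 1000.0,
        "gut": 1.100,
        "muscle": 0.29 * weight,
        "heart": (25.39 + 15.70 * a - 0.3603 * a**2 + 0.004 * a**3 - 1.75e-5 * a**4) / 1000.0,
        "spleen": (8.99 + 10.13 * a - 0.24 * a**2 + 0.0018 * a**3 - 2.95e-6 * a**4) / 1000.0,
        "kidney": (20.4 + 18.7 * a - 0.511 * a**2 + 0.0054 * a**3 - 1.88e-5 * a**4) / 1000.0,
        "lungs": (115 + 36.8 * a - 0.4 * a**2) / 1000.0,
        "liver": (145 + 104 * a - 3.2 * a**2 + 0.043 * a**3 - 0.0002134 * a**4) / 1000.0,
    }
    return w


@dataclass
class AdultSubject:
    sex: int                 # 0 female, 1 male
    age: float               # years
    weight: float            # kg
    bmi: float               # kg/m^2
    height: float            # m
    cardiac_output: float    # L/h
    organ_weights: dict[str, float]   # kg, incl. rest/blood/plasma/venous/artery
    organ_volumes: dict[str, float]   # L
    blood_flow_fractions: dict[str, float]
    tissue_composition: dict[str, dict[str, float]] = field(default_factory=lambda: TISSUE_COMPOSITION)

    @property
    def liver_weight_g(self) -> float:
        return self.organ_weights["liver"] * 1000.0

    def organ_flow(self, organ: str) -> float:
        """Blood flow to an organ (L/h)."""
        return self.blood_flow_fractions[organ] * self.cardiac_output


def build_adult_subject(sex: int, age: float, weight: float, bmi: float) -> AdultSubject:
    """Construct a virtual adult from demographics.

    Raises
    ------
    AnthropometryError
        If the modelled organ weights exceed total body weight (negative
        rest-of-body remainder).
    """
    if not (18 <= age <= 60):
        raise AnthropometryError(f"adult age {age} outside [18, 60]")
    if weight <= 0 or bmi <= 0:
        raise AnthropometryError("weight and BMI must be positive")
    height = height_from_bmi(weight, bmi)
    co = cardiac_output(sex, age, weight)
    w = _adult_organ_weights(age, weight, height)
    blood = 0.36 * height**3 + 0.03 * weight + 0.1833
    tissue_sum = sum(w.values()) + blood
    rest = weight - tissue_sum
    if rest <= 0:
        raise AnthropometryError(
            f"modelled organ weights ({tissue_sum:.1f} kg) exceed body weight {weight} kg"
        )
    w["rest"] = rest
    w["blood"] = blood
    w["plasma"] = 0.6 * blood
    w["venous"] = 0.7 * blood
    w["artery"] = blood - w["venous"]
    volumes = {}
    for organ in ORGANS:
        rho = TISSUE_COMPOSITION[organ]["rho"]
        volumes[organ] = w[organ] / rho
    # blood-side volumes: unit specific gravity
    for pool in ("blood", "plasma", "venous", "artery"):
        volumes[pool] = w[pool]
    return AdultSubject(
        sex=sex, age=age, weight=weight, bmi=bmi, height=height,
        cardiac_output=co, organ_weights=w, organ_volumes=volumes,
        blood_flow_fractions=dict(BLOOD_FLOW_FRACTIONS),
    )


# ---------------------------------------------------------------------------
# Infant physiology
# ---------------------------------------------------------------------------

#: Hematocrit by age (years) for term infants; linearly interpolated.
INFANT_HEMATOCRIT_TABLE = (
    (0.0, 0.50), (1 / 12, 0.38), (2 / 12, 0.33), (3 / 12, 0.33),
    (6 / 12, 0.35), (1.0, 0.36),
)
ADULT_HEMATOCRIT = 0.45

MIN_INFANT_AGE_YEARS = 1.0 / 365.0  # albumin/log terms diverge at age 0


def infant_weight(age_years: float) -> float:
    """Infant body weight (kg) for age 0-1 y."""
    return (age_years * 12.0 + 9.0) / 2.0


def serum_albumin(age_years: float) -> float:
    """Serum albumin (g/L) as a function of age; natural logarithm.

    Age is floored at one day so the logarithm stays finite; the same
    relation evaluated at the adult age supplies the adult reference.
    """
    a = max(age_years, MIN_INFANT_AGE_YEARS)
    return 1.1287 * math.log(a) + 33.746


def fup_child(fup_adult: float, calb_child: float, calb_adult: float) -> float:
    """Infant plasma unbound fraction from the albumin ratio."""
    if not (0 < fup_adult <= 1):
        raise ValueError("fup_adult must be in (0, 1]")
    return 1.0 / (1.0 + (1.0 - fup_adult) / fup_adult * calb_child / calb_adult)


def kp_rbc(bp: float, hematocrit: float, fup: float) -> float:
    """Red-blood-cell partition coefficient of unbound drug."""
    return (bp - 1.0 + hematocrit) / (hematocrit * fup)


def bp_child(fup_c: float, hematocrit_child: float, kprbc: float) -> float:
    """Infant blood-to-plasma ratio via RBC-partition invariance."""
    return 1.0 + hematocrit_child * (fup_c * kprbc - 1.0)


def infant_hematocrit(age_years: float) -> float:
    ages, vals = zip(*INFANT_HEMATOCRIT_TABLE)
    return float(np.interp(age_years, ages, vals))


def _growth(coeffs: dict[str, float], age_years: float) -> float:
    """Linear-rational growth function y = (a + b*age) / (1 + c*age + d*age^2)."""
    a, b = coeffs["a"], coeffs["b"]
    c, d = coeffs.get("c", 0.0), coeffs.get("d", 0.0)
    return (a + b * age_years) / (1.0 + c * age_years + d * age_years**2)


def fcyp(age_years: float, x: float, y: float, z: float, n: float) -> float:
    """Fractional CYP activity relative to the adult: x*age^n/(y+age^n) + z."""
    a = max(age_years, 0.0)
    return x * a**n / (y + a**n) + z


@dataclass
class InfantSubject:
    age: float
    weight: float
    cardiac_output: float            # L/h
    organ_weights: dict[str, float]  # kg
    organ_volumes: dict[str, float]  # L
    blood_flow_fractions: dict[str, float]
    albumin: float                   # g/L
    hematocrit: float
    fup_child: float
    bp_child: float
    fcyp2c9: float
    fcyp3a4: float
    mppgl: float                     # mg microsomal protein / g liver

    @property
    def liver_weight_g(self) -> float:
        return self.organ_weights["liver"] * 1000.0

    def organ_flow(self, organ: str) -> float:
        return self.blood_flow_fractions[organ] * self.cardiac_output


def build_infant_subject(
    age_years: float,
    fup_adult: float = 0.0022,
    bp_adult: float = 0.667,
    adult_age: float = 28.0,
    growth_params: dict | None = None,
) -> InfantSubject:
    """Build a virtual infant (0-1 y) by scaling the adult reference down."""
    if not (0.0 <= age_years <= 1.0):
        raise ValueError(f"infant age {age_years} outside [0, 1] years")
    p = growth_params or load_params("infant_growth")
    weight = infant_weight(age_years)
    co = _growth(p["cardiac_output_L_min"], age_years) * 60.0
    w = {organ: _growth(p["organ_weights_kg"][organ], age_years)
         for organ in p["organ_weights_kg"]}
    blood = _growth(p["blood_L"], age_years)
    rest = weight - sum(w.values()) - blood
    if rest <= 0:
        raise ValueError("infant organ weights exceed body weight")
    w["rest"] = rest
    w["blood"] = blood
    w["plasma"] = 0.6 * blood
    w["venous"] = 0.7 * blood
    w["artery"] = blood - w["venous"]
    volumes = {organ: w[organ] / TISSUE_COMPOSITION[organ]["rho"] for organ in ORGANS}
    for pool in ("blood", "plasma", "venous", "artery"):
        volumes[pool] = w[pool]

    calb_child = serum_albumin(age_years)
    calb_adult = serum_albumin(adult_age)
    fup_c = fup_child(fup_adult, calb_child, calb_adult)
    kprbc = kp_rbc(bp_adult, ADULT_HEMATOCRIT, fup_adult)
    ht_c = infant_hematocrit(age_years)
    bp_c = bp_child(fup_c, ht_c, kprbc)
    ont = p["cyp_ontogeny"]
    f2c9 = fcyp(age_years, **ont["cyp2c9"])
    f3a4 = fcyp(age_years, **ont["cyp3a4"])
    return InfantSubject(
        age=age_years, weight=weight, cardiac_output=co,
        organ_weights=w, organ_volumes=volumes,
        blood_flow_fractions=dict(BLOOD_FLOW_FRACTIONS),
        albumin=calb_child, hematocrit=ht_c,
        fup_child=fup_c, bp_child=bp_c,
        fcyp2c9=f2c9, fcyp3a4=f3a4,
        mppgl=p["mppgl_mg_per_g"],
    )


# ---------------------------------------------------------------------------
# Virtual populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Sampling plan for a virtual lactating population.

    Body weight is lognormal around the mean; the breast:adipose partition
    fraction is uniform on its plausible range; CYP abundance is a lognormal
    multiplier on intrinsic clearance; milk storage volume is normal.
    """
    n: int = 100
    mean_age: float = 28.0
    mean_weight: float = 78.0
    bmi: float = 27.7
    weight_cv: float = 0.20
    kp_breast_fraction_range: tuple[float, float] = (0.25, 0.7)
    cyp_cv: float = 0.30
    milk_volume_mean_L: float = 0.21
    milk_volume_sd_L: float = 0.011
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if self.weight_cv < 0 or self.cyp_cv < 0:
            raise ValueError("CVs must be >= 0")


@dataclass
class PopulationDraw:
    subject: AdultSubject
    kp_breast_fraction: float
    cyp_multiplier: float
    milk_volume_L: float


def scaled_adult_subject(reference: AdultSubject, weight: float) -> AdultSubject:
    """Rescale a reference adult to a new body weight.

    Organ weights and volumes scale isometrically with body weight (the
    reference regressions describe the typical adult, and an age-only
    adipose mass cannot apply to an arbitrary individual); cardiac output
    is re-evaluated at the new weight.
    """
    f = weight / reference.weight
    w = {k: v * f for k, v in reference.organ_weights.items()}
    v = {k: vol * f for k, vol in reference.organ_volumes.items()}
    return replace(reference, weight=weight,
                   cardiac_output=cardiac_output(reference.sex, reference.age, weight),
                   organ_weights=w, organ_volumes=v)


def sample_population(spec: PopulationSpec) -> list[PopulationDraw]:
    """Draw a seeded virtual population of lactating mothers.

    Inter-individual variability: lognormal body weight (organs rescaled
    isometrically from the typical subject), uniform breast:adipose
    partition fraction, lognormal CYP abundance, normal milk storage
    volume.
    """
    rng = np.random.default_rng(spec.seed)
    draws = []
    lo, hi = spec.kp_breast_fraction_range
    typical = build_adult_subject(0, spec.mean_age, spec.mean_weight, spec.bmi)
    for _ in range(spec.n):
        if spec.weight_cv > 0:
            sigma = math.sqrt(math.log(1.0 + spec.weight_cv**2))
            mu = math.log(spec.mean_weight) - sigma**2 / 2.0
            weight = float(rng.lognormal(mu, sigma))
        else:
            weight = spec.mean_weight
        if spec.cyp_cv > 0:
            s = math.sqrt(math.log(1.0 + spec.cyp_cv**2))
            cyp = float(rng.lognormal(-s**2 / 2.0, s))
        else:
            cyp = 1.0
        frac = float(rng.uniform(lo, hi)) if hi > lo else lo
        vmilk = float(rng.normal(spec.milk_volume_mean_L, spec.milk_volume_sd_L))
        vmilk = max(vmilk, 0.05)
        subject = (typical if weight == spec.mean_weight
                   else scaled_adult_subject(typical, weight))
        draws.append(PopulationDraw(subject, frac, cyp, vmilk))
    return draws
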