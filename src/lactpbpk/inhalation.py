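"""Cannabis-smoke particle deposition and airway absorption parameters.

The respiratory tract is four filters in series (ET2, BB, bb, AL).  During
inhalation air passes ET2 -> BB -> bb -> AL and back out on exhalation, so
ET2/BB/bb each filter the stream twice while the closed-ended alveolar
region filters once.  Single-pass collection efficiencies are
impaction-driven in the large airways (aerodynamic diameter) and
diffusion-driven in the small airways (thermodynamic diameter after
hygroscopic growth); the per-region efficiency scale constants are frozen
in the parameter file, calibrated once against the reference smoke
particle's regional deposition pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .drug import DrugParams, molecular_diffusion_coefficient
from .params import load_params

REGIONS = ("ET2", "BB", "bb", "AL")
BOLTZMANN = 1.380649e-23


@dataclass(frozen=True)
class Topography:
    """Smoking topography for one session."""
    n_puffs: int = 13
    puff_duration_s: float = 5.0
    interpuff_interval_s: float = 35.0
    inhaled_dose_mg: float = 45.25

    def __post_init__(self):
        if min(self.n_puffs, self.puff_duration_s, self.interpuff_interval_s) <= 0:
            raise ValueError("topography values must be positive")

    @property
    def session_duration_h(self) -> float:
        return self.n_puffs * (self.puff_duration_s + self.interpuff_interval_s) / 3600.0


@dataclass
class AirwayParams:
    """Regional geometry and transport constants (see params/airway.yaml)."""
    surface_area_cm2: dict[str, float]
    h_elf_cm: dict[str, float]
    v_elf_mL: dict[str, float]
    v_ep_mL: dict[str, float]
    v_int_mL: dict[str, float]
    psa_L_h: dict[str, float]
    kmcc_per_h: dict[str, float]
    ktr_per_h: dict[str, float]
    ph: dict[str, float]
    kdiss_max_L_h: float
    deposition_k: dict[str, float]
    air_viscosity_Pa_s: float = 1.81e-5
    air_temperature_K: float = 310.0
    mean_free_path_um: float = 0.066

    @classmethod
    def from_file(cls, name: str = "airway") -> "AirwayParams":
        p = load_params(name)
        return cls(
            surface_area_cm2=p["surface_area_cm2"], h_elf_cm=p["h_elf_cm"],
            v_elf_mL=p["v_elf_mL"], v_ep_mL=p["v_ep_mL"], v_int_mL=p["v_int_mL"],
            psa_L_h=p["psa_L_h"], kmcc_per_h=p["kmcc_per_h"],
            ktr_per_h=p["ktr_per_h"], ph=p["ph"],
            kdiss_max_L_h=p["kdiss_max_L_h"], deposition_k=p["deposition_k"],
            air_viscosity_Pa_s=p["air_viscosity_Pa_s"],
            air_temperature_K=p["air_temperature_K"],
            mean_free_path_um=p["mean_free_path_um"],
        )


@dataclass(frozen=True)
class DepositionResult:
    """Fraction of the inhaled dose deposited per region, plus exhaled."""
    fde: dict[str, float]
    exhaled: float

    def __post_init__(self):
        tot = sum(self.fde.values()) + self.exhaled
        if any(f < 0 for f in self.fde.values()) or self.exhaled < 0:
            raise ValueError("negative deposition fraction")
        if tot > 1.0 + 1e-9:
            raise ValueError(f"deposited + exhaled fractions exceed 1 ({tot})")


def thermodynamic_diameter_um(drug: DrugParams, hygroscopic: bool = True) -> float:
    """Thermodynamic (volume-equivalent) particle diameter in um.

    d_th = d_ae * sqrt(chi / rho); hygroscopic growth multiplies the
    thermodynamic diameter only.
    """
    d = drug.d_ae_um * math.sqrt(drug.shape_factor / drug.particle_density)
    return d * drug.f_hyg if hygroscopic else d


def particle_diffusion_coefficient(drug: DrugParams, airway: AirwayParams) -> float:
    """Brownian diffusion coefficient of the smoke particle (m^2/s).

    Stokes-Einstein with the Cunningham slip correction, evaluated at the
    hygroscopically grown thermodynamic diameter.
    """
    d_m = thermodynamic_diameter_um(drug) * 1e-6
    lam = airway.mean_free_path_um * 1e-6
    kn = 2.0 * lam / d_m
    cc = 1.0 + kn * (1.257 + 0.4 * math.exp(-1.1 / kn))
    return (BOLTZMANN * airway.air_temperature_K * cc
            / (3.0 * math.pi * airway.air_viscosity_Pa_s * d_m))


def region_efficiencies(drug: DrugParams, airway: AirwayParams) -> dict[str, float]:
    """Single-pass collection efficiency per region for the given particle."""
    x_imp = drug.d_ae_um ** 2                      # impaction parameter
    x_dif = math.sqrt(particle_diffusion_coefficient(drug, airway))
    k = airway.deposition_k
    eta = {
        "ET2": 1.0 - math.exp(-k["ET2"] * x_imp),
        "BB": 1.0 - math.exp(-k["BB"] * x_imp),
        "bb": 1.0 - math.exp(-k["bb"] * x_dif),
        "AL": 1.0 - math.exp(-k["AL"] * x_dif),
    }
    for region, e in eta.items():
        if not (0.0 <= e <= 1.0):
            raise ValueError(f"non-physical efficiency {e} in {region}")
    return eta


def deposition_fractions(drug: DrugParams, topography: Topography | None = None,
                         airway: AirwayParams | None = None) -> DepositionResult:
    """Regional deposited fractions of the inhaled dose.

    Filters in series over the inhalation and exhalation passes; the
    alveolar region is closed-ended and filters the stream once.
    Fractions are independent of dose.
    """
    airway = airway or AirwayParams.from_file()
    eta = region_efficiencies(drug, airway)
    t = {r: 1.0 - eta[r] for r in REGIONS}
    fde = {}
    # inhalation pass
    fde["ET2"] = eta["ET2"]
    fde["BB"] = t["ET2"] * eta["BB"]
    fde["bb"] = t["ET2"] * t["BB"] * eta["bb"]
    fde["AL"] = t["ET2"] * t["BB"] * t["bb"] * eta["AL"]
    # exhalation pass: alveolar air returns through bb, BB, ET2
    back = t["ET2"] * t["BB"] * t["bb"] * t["AL"]
    fde["bb"] += back * eta["bb"]
    fde["BB"] += back * t["bb"] * eta["BB"]
    fde["ET2"] += back * t["bb"] * t["BB"] * eta["ET2"]
    exhaled = back * t["bb"] * t["BB"] * t["ET2"]
    return DepositionResult(fde=fde, exhaled=exhaled)


def initialize_lumen(dose_mg: float, deposition: DepositionResult) -> dict[str, float]:
    """Undissolved luminal amount per region (mg) at the start of absorption."""
    if dose_mg < 0:
        raise ValueError("dose must be non-negative")
    return {r: deposition.fde[r] * dose_mg for r in REGIONS}


def dissolution_rate_constant(drug: DrugParams, region: str,
                              airway: AirwayParams | None = None) -> float:
    """Film-model dissolution rate constant (L/h) for a region.

    kdiss = D * SA / h_elf with the molecular aqueous diffusion coefficient;
    capped for the alveolar region where the nominal film is vanishingly
    thin and dissolution is effectively instantaneous.
    """
    airway = airway or AirwayParams.from_file()
    d_cm2_s = molecular_diffusion_coefficient(drug.mw)
    k_cm3_s = d_cm2_s * airway.surface_area_cm2[region] / airway.h_elf_cm[region]
    k_L_h = k_cm3_s * 3600.0 / 1000.0
    return min(k_L_h, airway.kdiss_max_L_h)


def mucociliary_rates(airway: AirwayParams | None = None) -> dict[str, float]:
    """Mucociliary clearance rate constants (1/h), peripheral -> central."""
    airway = airway or AirwayParams.from_file()
    return dict(airway.kmcc_per_h)
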