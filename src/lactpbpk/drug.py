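"""THC physicochemical constants and derived binding/partitioning quantities.

Houses the drug parameter table and everything computed from it: tissue
unbound fractions, tissue:plasma partition coefficients (Berezhkovskiy-
corrected Poulin-Theil), ionization, milk protein binding (Atkinson-Begg),
and the breast partition coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import load_params
from . import physiology
from .physiology import ORGANS, PLASMA_COMPOSITION, TISSUE_COMPOSITION


@dataclass(frozen=True)
class DrugParams:
    """Physicochemical and enzymatic constants for the modelled compound."""
    name: str = "THC"
    dose_mg: float = 45.2
    mw: float = 314.5
    logp: float = 6.97
    bp: float = 0.667
    pka: float = 10.6
    fup: float = 0.0022
    fumic: float = 0.04
    vmax_cyp2c9: float = 624.0     # pmol/min/mg
    km_cyp2c9: float = 0.07       # umol/L
    vmax_cyp3a4: float = 4905.0
    km_cyp3a4: float = 5.48
    solubility_mg_L: float = 2.8
    psa_A2: float = 29.5
    hbd: float = 1.0
    d_ae_um: float = 0.39
    particle_density: float = 3.0
    shape_factor: float = 1.5
    f_hyg: float = 1.5
    mppgl_mg_per_g: float = 40.0

    def __post_init__(self):
        if not (0 < self.fup <= 1) or not (0 < self.fumic <= 1):
            raise ValueError("fup and fumic must lie in (0, 1]")

    @classmethod
    def from_file(cls, name: str = "thc") -> "DrugParams":
        p = load_params(name)
        return cls(
            name=p["name"], dose_mg=p["dose_mg"], mw=p["mw"], logp=p["logp"],
            bp=p["bp"], pka=p["pka"], fup=p["fup"], fumic=p["fumic"],
            vmax_cyp2c9=p["vmax_cyp2c9"], km_cyp2c9=p["km_cyp2c9"],
            vmax_cyp3a4=p["vmax_cyp3a4"], km_cyp3a4=p["km_cyp3a4"],
            solubility_mg_L=p["solubility_mg_L"], psa_A2=p["psa_A2"],
            hbd=p["hbd"], d_ae_um=p["d_ae_um"],
            particle_density=p["particle_density"],
            shape_factor=p["shape_factor"], f_hyg=p["f_hyg"],
            mppgl_mg_per_g=p["mppgl_mg_per_g"],
        )

    @property
    def logd74(self) -> float:
        """log D at pH 7.4, consistent with the acid ionization convention."""
        return self.logp - math.log10(1.0 + 10.0 ** (self.pka - 7.4))


def compute_fut(fup: float, tissue_class: str) -> float:
    """Tissue unbound fraction: fut = 1/(1 + (1-fup)/fup * R).

    R = 0.15 for adipose, 0.5 for all other tissues.
    """
    if not (0 < fup <= 1):
        raise ValueError("fup must lie in (0, 1]")
    r = {"adipose": 0.15, "non-adipose": 0.5}[tissue_class]
    return 1.0 / (1.0 + (1.0 - fup) / fup * r)


def compute_fub(fup: float, bp: float) -> float:
    """Blood unbound fraction fub = fup / BP."""
    if bp <= 0:
        raise ValueError("BP must be positive")
    return fup / bp


def fraction_unionized(pka: float, ph: float, mode: str = "base") -> float:
    """Fraction non-ionized by Henderson-Hasselbalch.

    ``mode="base"`` is the form 1/(1 + 10^(pKa - pH)); ``mode="acid"`` is
    1/(1 + 10^(pH - pKa)), the chemically appropriate form for a weak acid
    such as THC (pKa 10.6, essentially neutral at physiologic pH).  The
    default simulation configuration uses acid mode; the base form is kept
    for comparison.
    """
    if not (0.0 <= ph <= 14.0):
        raise ValueError("pH must lie in [0, 14]")
    if mode == "base":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    if mode == "acid":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    raise ValueError(f"unknown ionization mode {mode!r}")


def compute_kp(composition: dict[str, float], drug: DrugParams,
               tissue_class: str = "non-adipose", fup: float | None = None) -> float:
    """Tissue:plasma partition coefficient, Berezhkovskiy-corrected
    Poulin-Theil.

    Neutral lipid and phospholipid fractions partition with the octanol-water
    coefficient (the distribution coefficient logD7.4 for adipose); tissue
    and plasma water terms are scaled by the respective unbound fractions.
    """
    for key in ("fVwt", "fVnl", "fVph"):
        if key not in composition:
            raise KeyError(f"tissue composition missing {key}")
    fup = drug.fup if fup is None else fup
    logp = drug.logd74 if tissue_class == "adipose" else drug.logp
    p = 10.0 ** logp
    fut = compute_fut(fup, tissue_class)
    num = (p * (composition["fVnl"] + 0.3 * composition["fVph"])
           + (composition["fVwt"] + 0.7 * composition["fVph"]) / fut)
    pc = PLASMA_COMPOSITION
    den = (p * (pc["fVnl"] + 0.3 * pc["fVph"])
           + (pc["fVwt"] + 0.7 * pc["fVph"]) / fup)
    return num / den


@dataclass
class PartitionSet:
    """Organ partition coefficients plus the derived breast value."""
    ktp: dict[str, float]
    kp_breast: float
    fut: dict[str, float]

    def kp_over_bp(self, organ: str, bp: float) -> float:
        return self.ktp[organ] / bp


def compute_partition_set(drug: DrugParams, kp_breast_fraction: float = 0.5,
                          fup: float | None = None) -> PartitionSet:
    """All organ Kp values; breast as a fraction of the adipose Kp."""
    if not (0.25 <= kp_breast_fraction <= 0.7):
        raise ValueError("kp_breast_fraction must lie in [0.25, 0.7]")
    ktp, fut = {}, {}
    for organ in ORGANS:
        cls = "adipose" if organ == "adipose" else "non-adipose"
        ktp[organ] = compute_kp(TISSUE_COMPOSITION[organ], drug, cls, fup=fup)
        fut[organ] = compute_fut(fup if fup is not None else drug.fup, cls)
    return PartitionSet(ktp=ktp, kp_breast=kp_breast_fraction * ktp["adipose"], fut=fut)


def steady_state_vd(subject: "physiology.AdultSubject | physiology.InfantSubject",
                    partitions: PartitionSet,
                    include_breast: bool = True,
                    v_breast_L: float = 0.5) -> float:
    """Whole-body steady-state volume of distribution (L/kg, plasma-referenced).

    Vss = (Vplasma + sum Kp_i * V_i) / body weight, over the perfusion-limited
    tissues (plus the breast compartment for a lactating subject).
    """
    v = subject.organ_volumes["plasma"]
    for organ in ORGANS:
        v += partitions.ktp[organ] * subject.organ_volumes[organ]
    if include_breast:
        v += partitions.kp_breast * v_breast_L
    return v / subject.weight


@dataclass(frozen=True)
class MilkBinding:
    """Unbound/unionized fractions governing breast-milk transfer."""
    fu_milk: float
    fu_skim: float
    logp_milk: float
    fun_bt: float
    fun_mk: float
    ph_bt: float = 7.4
    ph_mk: float = 7.0
    fw_skim: float = 0.955
    f_fat: float = 0.045


def compute_milk_binding(drug: DrugParams, ph_bt: float = 7.4, ph_mk: float = 7.0,
                         fw_skim: float = 0.955, f_fat: float = 0.045,
                         ionization_mode: str = "acid") -> MilkBinding:
    """Milk protein binding by the Atkinson-Begg relations.

    fu_skim from the plasma unbound fraction; logP(milk) from logP; fu_milk
    from the skim and fat terms (the fat term uses the literal logP(milk)
    value, under which the milk pool stays finite — see package docs).
    """
    if drug.fup <= 0:
        raise ValueError("fup must be positive")
    fu_skim = drug.fup**0.448 / (0.000694**0.448 + drug.fup**0.448)
    logp_milk = -0.88 + 1.29 * drug.logp
    fu_milk = 1.0 / (fw_skim / fu_skim + f_fat * logp_milk)
    return MilkBinding(
        fu_milk=fu_milk, fu_skim=fu_skim, logp_milk=logp_milk,
        fun_bt=fraction_unionized(drug.pka, ph_bt, ionization_mode),
        fun_mk=fraction_unionized(drug.pka, ph_mk, ionization_mode),
        ph_bt=ph_bt, ph_mk=ph_mk, fw_skim=fw_skim, f_fat=f_fat,
    )


def molecular_diffusion_coefficient(mw: float) -> float:
    """Aqueous diffusion coefficient (cm^2/s) from molecular weight.

    Empirical small-molecule correlation D = 9.9e-5 * MW^-0.453, giving
    ~7.3e-6 cm^2/s for THC.
    """
    return 9.9e-5 * mw ** -0.453
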