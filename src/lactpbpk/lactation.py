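"""Breast tissue and milk compartments: transfer clearances and feeding.

THC reaches milk from breast tissue by two parallel routes — an active
secretion/reabsorption clearance pair predicted from its physicochemical
descriptors, and passive permeation across the mammary epithelium
(permeability-surface-area product from lobule geometry).  Milk removal at
a feed is proportional: the infant drinks a volume V_feed out of a
constant-volume storage pool, taking the corresponding fraction of the
drug amount with it (fresh drug-free milk replaces the volume).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .drug import DrugParams, MilkBinding, compute_milk_binding, molecular_diffusion_coefficient
from .params import load_params


def milk_transfer_clearances(drug: DrugParams) -> tuple[float, float]:
    """Breast->milk and milk->breast clearances (L/h) from drug descriptors.

    CL_btmk = 10^(-3.912 - 0.015*PSA + 3.367*log10(MW) - 0.164*(logP - logD7.4)) / 1000
    CL_mkbt = 10^(2.793 + 0.179*logP - 0.132*HBD) / 1000
    """
    cl_btmk = 10.0 ** (-3.912 - 0.015 * drug.psa_A2 + 3.367 * math.log10(drug.mw)
                       - 0.164 * (drug.logp - drug.logd74)) / 1000.0
    cl_mkbt = 10.0 ** (2.793 + 0.179 * drug.logp - 0.132 * drug.hbd) / 1000.0
    return cl_btmk, cl_mkbt


def psa_breast(lobule_radius_cm: float, drug: DrugParams,
               n_lobules_per_lobe: int = 40, n_lobes: int = 20,
               h_bt_um: float = 20.0) -> float:
    """Mammary permeability-surface-area product (L/h).

    The gland is n_lobes * n_lobules_per_lobe spherical lobules of the
    given radius; PSA = SA * D / h with the molecular aqueous diffusion
    coefficient and the epithelial thickness h.
    """
    if lobule_radius_cm <= 0:
        raise ValueError("lobule radius must be positive")
    sa_cm2 = n_lobes * n_lobules_per_lobe * 4.0 * math.pi * lobule_radius_cm**2
    d_cm2_s = molecular_diffusion_coefficient(drug.mw)
    h_cm = h_bt_um * 1e-4
    return sa_cm2 * d_cm2_s / h_cm * 3600.0 / 1000.0


@dataclass
class BreastParams:
    """Everything the maternal model needs about the lactating breast."""
    v_breast_L: float
    v_milk_L: float
    flow_fraction: float
    kp_breast_fraction: float
    cl_btmk: float          # L/h
    cl_mkbt: float          # L/h
    psa_bt: float           # L/h
    binding: MilkBinding

    @classmethod
    def from_file(cls, drug: DrugParams, name: str = "breast",
                  kp_breast_fraction: float | None = None,
                  v_milk_L: float | None = None,
                  ionization_mode: str = "acid") -> "BreastParams":
        p = load_params(name)
        cl_btmk, cl_mkbt = milk_transfer_clearances(drug)
        psa = psa_breast(p["lobule_radius_cm"], drug,
                         n_lobules_per_lobe=p["n_lobules_per_lobe"],
                         n_lobes=p["n_lobes"], h_bt_um=p["h_bt_um"])
        binding = compute_milk_binding(
            drug, ph_bt=p["ph_breast"], ph_mk=p["ph_milk"],
            fw_skim=p["fw_skim_milk"], f_fat=p["f_fat_milk"],
            ionization_mode=ionization_mode,
        )
        return cls(
            v_breast_L=p["v_breast_L"],
            v_milk_L=v_milk_L if v_milk_L is not None else p["v_milk_L"],
            flow_fraction=p["flow_fraction"],
            kp_breast_fraction=(kp_breast_fraction if kp_breast_fraction is not None
                                else p["kp_breast_fraction"]),
            cl_btmk=cl_btmk, cl_mkbt=cl_mkbt, psa_bt=psa, binding=binding,
        )

    def flux_coefficients(self, fup: float) -> tuple[float, float]:
        """(breast->milk, milk->breast) flux coefficients in L/h.

        Breast -> milk: secretion fup*fun_bt*CL_btmk plus permeation
        fun_bt*PSA; milk -> breast: reabsorption fumk*fun_mk*CL_mkbt plus
        permeation fumk*fun_mk*PSA.  Multiplying by the respective total
        concentrations gives the antisymmetric exchange fluxes.
        """
        b = self.binding
        to_milk = b.fun_bt * (fup * self.cl_btmk + self.psa_bt)
        to_breast = b.fu_milk * b.fun_mk * (self.cl_mkbt + self.psa_bt)
        return to_milk, to_breast


def lactation_rhs(a_breast: float, a_milk: float, c_arterial: float,
                  params: BreastParams, fup: float, kp_breast: float,
                  bp: float, q_breast_L_h: float) -> tuple[float, float]:
    """(dA_breast/dt, dA_milk/dt) in ng/h for given amounts (ng).

    Perfusion into breast tissue plus the antisymmetric breast<->milk
    exchange; used standalone in tests, inlined by the ODE engine.
    """
    c_breast = a_breast / (params.v_breast_L * 1000.0)    # ng/mL
    c_milk = a_milk / (params.v_milk_L * 1000.0)
    to_milk, to_breast = params.flux_coefficients(fup)
    to_milk_mL = to_milk * 1000.0
    to_breast_mL = to_breast * 1000.0
    q = q_breast_L_h * 1000.0
    perf = q * (c_arterial - c_breast / (kp_breast / bp))
    exch = to_milk_mL * c_breast - to_breast_mL * c_milk
    return perf - exch, exch


def breastfeed_event(a_milk: float, feed_volume_mL: float,
                     v_milk_L: float) -> tuple[float, float]:
    """Apply one feed: returns (remaining milk amount, amount removed).

    Removal is proportional to the fraction of stored volume drunk; the
    feed volume is capped at the storage volume.
    """
    if feed_volume_mL < 0:
        raise ValueError("feed volume must be non-negative")
    v_store = v_milk_L * 1000.0
    v_feed = min(feed_volume_mL, v_store)
    removed = a_milk * v_feed / v_store
    return a_milk - removed, removed
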