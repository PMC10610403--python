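"""Whole-body ODE system and the event-driven stiff integration engine.

The maternal model couples perfusion-limited tissue compartments (venous
equilibration C_tissue/(Kp/BP)), a well-stirred liver, the four-region
airway absorption chain, and the breast/milk pair.  All amounts are in ng,
volumes in mL, flows in mL/h, time in h.  Dosing (smoking sessions, IV
infusions) is zero-order input over the stated duration; feeds are
discrete events applied between integration segments (stop-restart, never
step interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .drug import DrugParams, PartitionSet, compute_fub, compute_partition_set, fraction_unionized
from .inhalation import (
    REGIONS, AirwayParams, deposition_fractions, dissolution_rate_constant,
)
from .lactation import BreastParams
from .physiology import AdultSubject, InfantSubject

AIRWAY_LAYERS = ("lumen", "elf", "ep", "int")

MATERNAL_COMPARTMENTS = (
    ["venous", "arterial", "lung", "adipose", "bone", "brain", "gut", "muscle",
     "heart", "spleen", "kidney", "liver", "rest", "breast", "milk"]
    + [f"{r}_{l}" for r in REGIONS for l in AIRWAY_LAYERS]
    + ["eliminated", "swallowed", "milk_removed"]
)

#: Organs whose outflow returns directly to the venous pool.
VENOUS_ORGANS = ("adipose", "bone", "brain", "muscle", "heart", "kidney", "rest")


class SolverError(RuntimeError):
    """Raised when the stiff integrator fails; carries the last good time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time {last_time:.4f} h)")
        self.last_time = last_time


@dataclass(frozen=True)
class DoseEvent:
    """A dosing or feeding event.

    kind: ``smoke`` (payload: dose_mg, duration_h), ``iv`` (dose_mg,
    duration_h) or ``feed`` (volume_mL drunk by the infant).
    """
    time: float
    kind: str
    dose_mg: float = 0.0
    duration_h: float = 0.0
    volume_mL: float = 0.0

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.kind not in ("smoke", "iv", "feed", "oral_bolus"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class SimulationResult:
    """Time grids, concentration traces and bookkeeping for one simulation."""
    time: np.ndarray                       # h
    traces: dict[str, np.ndarray]          # ng/mL per matrix
    states: np.ndarray                     # amounts (ng), time x compartment
    compartments: list[str]
    feed_log: pd.DataFrame                 # time_h, volume_mL, c_milk, dose_ng
    input_cumulative: np.ndarray           # ng entered the body
    n_rhs_evaluations: int = 0

    def amount(self, name: str) -> np.ndarray:
        return self.states[:, self.compartments.index(name)]

    def mass_balance_error(self) -> float:
        """Max relative error of (input = body + eliminated + removed)."""
        body = self.states.sum(axis=1)
        scale = max(self.input_cumulative.max(), 1e-12)
        return float(np.max(np.abs(self.input_cumulative - body)) / scale)

    def to_tidy(self, subject_id: int = 0) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"time_h": self.time, "matrix": name,
                          "conc_ng_mL": vals, "subject_id": subject_id})
            for name, vals in self.traces.items()
        ]
        return pd.concat(frames, ignore_index=True)


def intrinsic_clearance(vmax_pmol_min_mg: float, km_umol_L: float,
                        mppgl_mg_g: float, liver_weight_g: float,
                        fumic: float) -> float:
    """Whole-liver intrinsic clearance (L/h) from in-vitro enzyme kinetics.

    (Vmax/Km) [uL/min/mg microsomal protein] scaled by microsomal protein
    content and liver mass, divided by the microsomal unbound fraction.
    """
    if min(vmax_pmol_min_mg, km_umol_L, mppgl_mg_g, liver_weight_g, fumic) <= 0:
        raise ValueError("clearance inputs must be positive")
    ul_per_min = vmax_pmol_min_mg / km_umol_L * mppgl_mg_g * liver_weight_g
    return ul_per_min * 60.0 / 1e6 / fumic


def hepatic_clearance(qh_L_h: float, fub: float, clint_L_h: float) -> float:
    """Well-stirred liver model: CLh = Qh*fub*CLint / (Qh + fub*CLint)."""
    return qh_L_h * fub * clint_L_h / (qh_L_h + fub * clint_L_h)


def total_intrinsic_clearance(drug: DrugParams, liver_weight_g: float,
                              mppgl: float | None = None,
                              fcyp2c9: float = 1.0, fcyp3a4: float = 1.0,
                              cyp_multiplier: float = 1.0) -> float:
    """Summed CYP2C9 + CYP3A4 intrinsic clearance (L/h), ontogeny-scaled."""
    mppgl = drug.mppgl_mg_per_g if mppgl is None else mppgl
    cl = (fcyp2c9 * intrinsic_clearance(drug.vmax_cyp2c9, drug.km_cyp2c9,
                                        mppgl, liver_weight_g, drug.fumic)
          + fcyp3a4 * intrinsic_clearance(drug.vmax_cyp3a4, drug.km_cyp3a4,
                                          mppgl, liver_weight_g, drug.fumic))
    return cl * cyp_multiplier


@dataclass
class SolverOptions:
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    grid_dt: float = 0.05


class MaternalModel:
    """Maternal lactation PBPK model for one virtual subject."""

    def __init__(self, subject: AdultSubject, drug: DrugParams,
                 partitions: PartitionSet | None = None,
                 breast: BreastParams | None = None,
                 airway: AirwayParams | None = None,
                 ionization_mode: str = "acid",
                 cyp_multiplier: float = 1.0,
                 options: SolverOptions | None = None):
        self.subject = subject
        self.drug = drug
        self.ionization_mode = ionization_mode
        self.breast = breast or BreastParams.from_file(drug, ionization_mode=ionization_mode)
        self.partitions = partitions or compute_partition_set(
            drug, kp_breast_fraction=self.breast.kp_breast_fraction)
        self.airway = airway or AirwayParams.from_file()
        self.cyp_multiplier = cyp_multiplier
        self.options = options or SolverOptions()
        self.idx = {name: i for i, name in enumerate(MATERNAL_COMPARTMENTS)}
        self._precompute()

    # -- parameter assembly -------------------------------------------------
    def _precompute(self):
        s, d, p = self.subject, self.drug, self.partitions
        bp = d.bp
        co = s.cardiac_output * 1000.0                      # mL/h
        self.co = co
        self.q = {o: s.blood_flow_fractions[o] * co for o in VENOUS_ORGANS}
        self.q["gut"] = s.blood_flow_fractions["gut"] * co
        self.q["spleen"] = s.blood_flow_fractions["spleen"] * co
        self.q_ha = (s.blood_flow_fractions["liver"]
                     - s.blood_flow_fractions["gut"]
                     - s.blood_flow_fractions["spleen"]) * co
        self.q_liver_out = self.q_ha + self.q["gut"] + self.q["spleen"]
        self.q_breast = self.breast.flow_fraction * co
        arterial_total = (sum(s.blood_flow_fractions[o] for o in VENOUS_ORGANS)
                          + s.blood_flow_fractions["gut"]
                          + s.blood_flow_fractions["spleen"]) * co \
            + self.q_ha + self.q_breast
        self.q_shunt = max(co - arterial_total, 0.0)
        self.r = {o: p.ktp[o] / bp for o in p.ktp}          # Kp/BP
        self.r_breast = p.kp_breast / bp

        # volumes (mL)
        self.v = np.ones(len(MATERNAL_COMPARTMENTS))
        for o in ("adipose", "bone", "brain", "gut", "muscle", "heart",
                  "spleen", "kidney", "liver", "rest"):
            self.v[self.idx[o]] = s.organ_volumes[o] * 1000.0
        self.v[self.idx["lung"]] = s.organ_volumes["lungs"] * 1000.0
        self.v[self.idx["venous"]] = s.organ_volumes["venous"] * 1000.0
        self.v[self.idx["arterial"]] = s.organ_volumes["artery"] * 1000.0
        self.v[self.idx["breast"]] = self.breast.v_breast_L * 1000.0
        self.v[self.idx["milk"]] = self.breast.v_milk_L * 1000.0
        for rgn in REGIONS:
            self.v[self.idx[f"{rgn}_elf"]] = self.airway.v_elf_mL[rgn]
            self.v[self.idx[f"{rgn}_ep"]] = self.airway.v_ep_mL[rgn]
            self.v[self.idx[f"{rgn}_int"]] = self.airway.v_int_mL[rgn]

        # hepatic clearance (mL/h)
        fub = compute_fub(d.fup, bp)
        clint = total_intrinsic_clearance(d, s.liver_weight_g,
                                          cyp_multiplier=self.cyp_multiplier)
        qh_L = self.q_liver_out / 1000.0
        self.clh = hepatic_clearance(qh_L, fub, clint) * 1000.0

        # breast exchange coefficients (mL/h)
        to_milk, to_breast = self.breast.flux_coefficients(d.fup)
        self.k_to_milk = to_milk * 1000.0
        self.k_to_breast = to_breast * 1000.0

        # airway constants
        mode = self.ionization_mode
        self.fun_elf = fraction_unionized(d.pka, self.airway.ph["elf"], mode)
        self.fun_ep = fraction_unionized(d.pka, self.airway.ph["ep"], mode)
        self.fun_int = fraction_unionized(d.pka, self.airway.ph["int"], mode)
        self.kdiss = {rgn: dissolution_rate_constant(d, rgn, self.airway) * 1000.0
                      for rgn in REGIONS}
        self.psa_air = {rgn: self.airway.psa_L_h[rgn] * 1000.0 for rgn in REGIONS}
        self.ktr = dict(self.airway.ktr_per_h)
        self.kmcc = dict(self.airway.kmcc_per_h)
        self.solubility = d.solubility_mg_L                  # mg/L == ug/mL
        self.s_ng_mL = self.solubility * 1000.0

    # -- right-hand side ----------------------------------------------------
    def rhs(self, t: float, y: np.ndarray,
            lumen_input: np.ndarray | None = None,
            iv_rate: float = 0.0) -> np.ndarray:
        """Time derivative of the amount vector (ng/h)."""
        ix = self.idx
        yc = np.maximum(y, 0.0)
        c = yc / self.v
        dy = np.zeros_like(y)
        bp = self.drug.bp
        cart = c[ix["arterial"]]
        cven = c[ix["venous"]]

        venous_in = iv_rate
        for o in VENOUS_ORGANS:
            cout = c[ix[o]] / self.r[o]
            dy[ix[o]] = self.q[o] * (cart - cout)
            venous_in += self.q[o] * cout
        # portal organs drain into the liver
        cout_gut = c[ix["gut"]] / self.r["gut"]
        cout_spl = c[ix["spleen"]] / self.r["spleen"]
        dy[ix["gut"]] = self.q["gut"] * (cart - cout_gut)
        dy[ix["spleen"]] = self.q["spleen"] * (cart - cout_spl)
        cliv = c[ix["liver"]]
        cout_liv = cliv / self.r["liver"]
        dy[ix["liver"]] = (self.q_ha * cart + self.q["gut"] * cout_gut
                           + self.q["spleen"] * cout_spl
                           - self.q_liver_out * cout_liv - self.clh * cliv)
        dy[ix["eliminated"]] = self.clh * cliv
        venous_in += self.q_liver_out * cout_liv

        # breast / milk
        cbre = c[ix["breast"]]
        cmilk = c[ix["milk"]]
        cout_bre = cbre / self.r_breast
        exch = self.k_to_milk * cbre - self.k_to_breast * cmilk
        dy[ix["breast"]] = self.q_breast * (cart - cout_bre) - exch
        dy[ix["milk"]] = exch
        venous_in += self.q_breast * cout_bre
        venous_in += self.q_shunt * cart

        # airway chain
        swallowed = 0.0
        int_to_venous = 0.0
        for i, rgn in enumerate(REGIONS):
            alu = yc[ix[f"{rgn}_lumen"]]
            celf = c[ix[f"{rgn}_elf"]]
            cep = c[ix[f"{rgn}_ep"]]
            diss = self.kdiss[rgn] * (self.s_ng_mL - celf) * alu / (alu + 1.0)
            d_lumen = -diss - self.ktr[rgn] * alu
            d_elf = diss - self.kmcc[rgn] * yc[ix[f"{rgn}_elf"]] \
                - self.fun_elf * self.psa_air[rgn] * celf
            if lumen_input is not None:
                d_lumen += lumen_input[i]
            if rgn == "ET2":
                d_lumen += self.ktr["BB"] * yc[ix["BB_lumen"]]
                d_elf += self.kmcc["BB"] * yc[ix["BB_elf"]]
                swallowed += self.ktr["ET2"] * alu + self.kmcc["ET2"] * yc[ix["ET2_elf"]]
            elif rgn == "BB":
                d_lumen += self.ktr["bb"] * yc[ix["bb_lumen"]]
                d_elf += self.kmcc["bb"] * yc[ix["bb_elf"]]
            dy[ix[f"{rgn}_lumen"]] = d_lumen
            dy[ix[f"{rgn}_elf"]] = d_elf
            perm_in = self.fun_elf * self.psa_air[rgn] * celf
            perm_out = self.fun_ep * self.psa_air[rgn] * cep
            dy[ix[f"{rgn}_ep"]] = perm_in - perm_out
            if rgn == "AL":
                cint = c[ix["AL_int"]]
                dy[ix["AL_int"]] = perm_out + self.co * (cven - cint)
            else:
                cint = c[ix[f"{rgn}_int"]]
                out = self.fun_int * self.psa_air[rgn] * cint
                dy[ix[f"{rgn}_int"]] = perm_out - out
                int_to_venous += out
        dy[ix["swallowed"]] = swallowed

        # pulmonary path: venous -> alveolar interstitium -> lung tissue -> arterial
        cint_al = c[ix["AL_int"]]
        clung = c[ix["lung"]]
        cout_lung = clung / self.r["lungs"]
        dy[ix["lung"]] = self.co * (cint_al - cout_lung)
        dy[ix["arterial"]] = self.co * (cout_lung - cart)
        dy[ix["venous"]] = venous_in + int_to_venous - self.co * cven

        if not np.all(np.isfinite(dy)):
            raise FloatingPointError(f"non-finite derivative at t={t}")
        return dy

    # -- simulation ---------------------------------------------------------
    def simulate(self, schedule: Sequence[DoseEvent], horizon_h: float,
                 options: SolverOptions | None = None) -> SimulationResult:
        """Integrate the model over [0, horizon] with exact event handling."""
        opt = options or self.options
        events = sorted(schedule, key=lambda e: e.time)
        if events and events[-1].time >= horizon_h:
            raise ValueError("horizon must exceed the last event time")

        # piecewise-constant inputs
        dep = deposition_fractions(self.drug, airway=self.airway)
        fde = np.array([dep.fde[r] for r in REGIONS])
        breakpoints = {0.0, horizon_h}
        for e in events:
            breakpoints.add(e.time)
            if e.kind in ("smoke", "iv") and e.duration_h > 0:
                breakpoints.add(min(e.time + e.duration_h, horizon_h))
        times = sorted(breakpoints)

        def inputs_at(t0: float, t1: float):
            lumen = np.zeros(4)
            iv = 0.0
            tm = 0.5 * (t0 + t1)
            for e in events:
                if e.kind == "smoke" and e.time <= tm < e.time + e.duration_h:
                    lumen += fde * e.dose_mg * 1e6 / e.duration_h
                elif e.kind == "iv" and e.time <= tm < e.time + e.duration_h:
                    iv += e.dose_mg * 1e6 / e.duration_h
            return lumen, iv

        feeds_by_time = {}
        for e in events:
            if e.kind == "feed":
                feeds_by_time.setdefault(e.time, 0.0)
                feeds_by_time[e.time] += e.volume_mL

        y = np.zeros(len(MATERNAL_COMPARTMENTS))
        ts_all = [np.array([0.0])]
        ys_all = [y.reshape(1, -1).copy()]
        input_rate_segments = []
        feed_rows = []
        n_rhs = 0
        ix_milk = self.idx["milk"]
        ix_removed = self.idx["milk_removed"]

        for t0, t1 in zip(times[:-1], times[1:]):
            if t0 in feeds_by_time:
                v_feed = feeds_by_time[t0]
                v_store = self.breast.v_milk_L * 1000.0
                v_taken = min(v_feed, v_store)
                c_milk = max(y[ix_milk], 0.0) / v_store
                removed = y[ix_milk] * v_taken / v_store
                y[ix_milk] -= removed
                y[ix_removed] += removed
                feed_rows.append(dict(time_h=t0, volume_mL=v_feed,
                                      c_milk_ng_mL=c_milk,
                                      dose_ng=c_milk * v_feed))
            lumen, iv = inputs_at(t0, t1)
            input_rate_segments.append((t0, t1, float(lumen.sum() + iv)))
            grid = np.arange(t0, t1, opt.grid_dt)[1:]
            grid = grid[grid < t1 - 1e-9]
            t_eval = np.concatenate([grid, [t1]])
            sol = solve_ivp(
                lambda t, yy: self.rhs(t, yy, lumen_input=lumen, iv_rate=iv),
                (t0, t1), y, method=opt.method, t_eval=t_eval,
                rtol=opt.rtol, atol=opt.atol)
            n_rhs += sol.nfev
            if not sol.success:
                raise SolverError(sol.message, t0)
            y = sol.y[:, -1].copy()
            ts_all.append(sol.t)
            ys_all.append(sol.y.T)

        time = np.concatenate(ts_all)
        states = np.vstack(ys_all)
        # cumulative input on the grid
        cum = np.zeros_like(time)
        for (t0, t1, rate) in input_rate_segments:
            cum += rate * (np.clip(time, t0, t1) - t0)
        bp = self.drug.bp
        traces = {
            "maternal_plasma": states[:, self.idx["venous"]]
            / self.v[self.idx["venous"]] / bp,
            "milk": states[:, ix_milk] / self.v[ix_milk],
            "breast": states[:, self.idx["breast"]] / self.v[self.idx["breast"]],
        }
        feed_log = pd.DataFrame(
            feed_rows, columns=["time_h", "volume_mL", "c_milk_ng_mL", "dose_ng"])
        return SimulationResult(
            time=time, traces=traces, states=states,
            compartments=list(MATERNAL_COMPARTMENTS), feed_log=feed_log,
            input_cumulative=cum, n_rhs_evaluations=n_rhs)


# ---------------------------------------------------------------------------
# Infant model
# ---------------------------------------------------------------------------

INFANT_COMPARTMENTS = (
    ["depot", "venous", "arterial", "lung", "adipose", "bone", "brain", "gut",
     "muscle", "heart", "spleen", "kidney", "liver", "rest", "eliminated"]
)


@dataclass(frozen=True)
class OralAbsorption:
    """First-order oral absorption with overall bioavailability F = Fa*Fg*Fh."""
    fa: float
    fg: float
    fh: float
    ka: float              # 1/h
    peff_cm_s: float
    r_intestine_cm: float

    @property
    def f(self) -> float:
        return self.fa * self.fg * self.fh

    def __post_init__(self):
        if not (0 < self.f <= 1):
            raise ValueError(f"bioavailability F={self.f} outside (0, 1]")
        if self.ka <= 0:
            raise ValueError("ka must be positive")


def oral_absorption_params(infant: InfantSubject, drug: DrugParams,
                           clh_blood_L_h: float, qh_blood_L_h: float,
                           fa: float = 0.9, fg: float = 0.75,
                           peff_cm_s: float = 1.0e-4,
                           r_intestine_cm: float | None = None) -> OralAbsorption:
    """Infant oral absorption parameters.

    Fh = 1 - E with hepatic extraction E = CLh,blood/Qh,blood (equivalently
    1 - CLh,plasma/(Qh*BP)); ka = 2*Peff/R with the age-scaled small-
    intestinal radius.
    """
    e = clh_blood_L_h / qh_blood_L_h
    fh = 1.0 - e
    if fh <= 0:
        raise ValueError("hepatic extraction >= 1; infant model inconsistent")
    if r_intestine_cm is None:
        r_intestine_cm = 0.6 + 0.4 * infant.age
    ka = 2.0 * peff_cm_s / r_intestine_cm * 3600.0
    return OralAbsorption(fa=fa, fg=fg, fh=fh, ka=ka,
                          peff_cm_s=peff_cm_s, r_intestine_cm=r_intestine_cm)


class InfantModel:
    """Infant oral PBPK model driven by the maternal feed log."""

    def __init__(self, subject: InfantSubject, drug: DrugParams,
                 fa: float = 0.9, fg: float = 0.75, peff_cm_s: float = 1.0e-4,
                 options: SolverOptions | None = None):
        self.subject = subject
        self.drug = drug
        self.options = options or SolverOptions()
        self.partitions = compute_partition_set(drug, fup=subject.fup_child)
        self.idx = {name: i for i, name in enumerate(INFANT_COMPARTMENTS)}
        self._precompute(fa, fg, peff_cm_s)

    def _precompute(self, fa, fg, peff):
        s, d = self.subject, self.drug
        bp = s.bp_child
        co = s.cardiac_output * 1000.0
        self.co = co
        self.bp = bp
        self.q = {o: s.blood_flow_fractions[o] * co for o in VENOUS_ORGANS}
        self.q["gut"] = s.blood_flow_fractions["gut"] * co
        self.q["spleen"] = s.blood_flow_fractions["spleen"] * co
        self.q_ha = (s.blood_flow_fractions["liver"]
                     - s.blood_flow_fractions["gut"]
                     - s.blood_flow_fractions["spleen"]) * co
        self.q_liver_out = self.q_ha + self.q["gut"] + self.q["spleen"]
        arterial_total = (sum(self.q[o] for o in VENOUS_ORGANS)
                          + self.q["gut"] + self.q["spleen"] + self.q_ha)
        self.q_shunt = max(co - arterial_total, 0.0)
        self.r = {o: self.partitions.ktp[o] / bp for o in self.partitions.ktp}
        self.v = np.ones(len(INFANT_COMPARTMENTS))
        for o in ("adipose", "bone", "brain", "gut", "muscle", "heart",
                  "spleen", "kidney", "liver", "rest"):
            self.v[self.idx[o]] = s.organ_volumes[o] * 1000.0
        self.v[self.idx["lung"]] = s.organ_volumes["lungs"] * 1000.0
        self.v[self.idx["venous"]] = s.organ_volumes["venous"] * 1000.0
        self.v[self.idx["arterial"]] = s.organ_volumes["artery"] * 1000.0

        fub = s.fup_child / bp
        clint = total_intrinsic_clearance(
            d, s.liver_weight_g, mppgl=s.mppgl,
            fcyp2c9=s.fcyp2c9, fcyp3a4=s.fcyp3a4)
        qh_L = self.q_liver_out / 1000.0
        clh_L = hepatic_clearance(qh_L, fub, clint)
        self.clh = clh_L * 1000.0
        self.absorption = oral_absorption_params(
            s, d, clh_L, qh_L, fa=fa, fg=fg, peff_cm_s=peff)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        ix = self.idx
        yc = np.maximum(y, 0.0)
        c = yc / self.v
        dy = np.zeros_like(y)
        cart = c[ix["arterial"]]
        cven = c[ix["venous"]]
        ka = self.absorption.ka
        dy[ix["depot"]] = -ka * yc[ix["depot"]]
        venous_in = ka * yc[ix["depot"]]
        for o in VENOUS_ORGANS:
            cout = c[ix[o]] / self.r[o]
            dy[ix[o]] = self.q[o] * (cart - cout)
            venous_in += self.q[o] * cout
        cout_gut = c[ix["gut"]] / self.r["gut"]
        cout_spl = c[ix["spleen"]] / self.r["spleen"]
        dy[ix["gut"]] = self.q["gut"] * (cart - cout_gut)
        dy[ix["spleen"]] = self.q["spleen"] * (cart - cout_spl)
        cliv = c[ix["liver"]]
        cout_liv = cliv / self.r["liver"]
        dy[ix["liver"]] = (self.q_ha * cart + self.q["gut"] * cout_gut
                           + self.q["spleen"] * cout_spl
                           - self.q_liver_out * cout_liv - self.clh * cliv)
        dy[ix["eliminated"]] = self.clh * cliv
        venous_in += self.q_liver_out * cout_liv + self.q_shunt * cart
        clung = c[ix["lung"]]
        cout_lung = clung / self.r["lungs"]
        dy[ix["lung"]] = self.co * (cven - cout_lung)
        dy[ix["arterial"]] = self.co * (cout_lung - cart)
        dy[ix["venous"]] = venous_in - self.co * cven
        return dy

    def simulate(self, feed_doses: Sequence[tuple[float, float]],
                 horizon_h: float,
                 options: SolverOptions | None = None) -> SimulationResult:
        """Integrate given (time_h, ingested_dose_ng) feed events.

        The overall bioavailability F is applied at input: each feed adds
        F * dose to the gut depot.
        """
        opt = options or self.options
        feeds = sorted(feed_doses)
        times = sorted({0.0, horizon_h} | {t for t, _ in feeds if t < horizon_h})
        y = np.zeros(len(INFANT_COMPARTMENTS))
        ts_all = [np.array([0.0])]
        ys_all = [y.reshape(1, -1).copy()]
        dose_in = 0.0
        cum_rows = [(0.0, 0.0)]
        n_rhs = 0
        for t0, t1 in zip(times[:-1], times[1:]):
            for tf, dose in feeds:
                if tf == t0:
                    y[self.idx["depot"]] += self.absorption.f * dose
                    dose_in += self.absorption.f * dose
            cum_rows.append((t0, dose_in))
            grid = np.arange(t0, t1, opt.grid_dt)[1:]
            grid = grid[grid < t1 - 1e-9]
            t_eval = np.concatenate([grid, [t1]])
            sol = solve_ivp(self.rhs, (t0, t1), y, method=opt.method,
                            t_eval=t_eval, rtol=opt.rtol, atol=opt.atol)
            n_rhs += sol.nfev
            if not sol.success:
                raise SolverError(sol.message, t0)
            y = sol.y[:, -1].copy()
            ts_all.append(sol.t)
            ys_all.append(sol.y.T)
        time = np.concatenate(ts_all)
        states = np.vstack(ys_all)
        cum = np.zeros_like(time)
        for tf, dose in feeds:
            if tf < horizon_h:
                # boundary samples record the pre-dose state (stop-restart)
                cum[time > tf + 1e-12] += self.absorption.f * dose
        traces = {
            "infant_plasma": states[:, self.idx["venous"]]
            / self.v[self.idx["venous"]] / self.bp,
        }
        return SimulationResult(
            time=time, traces=traces, states=states,
            compartments=list(INFANT_COMPARTMENTS),
            feed_log=pd.DataFrame(columns=["time_h", "volume_mL",
                                           "c_milk_ng_mL", "dose_ng"]),
            input_cumulative=cum, n_rhs_evaluations=n_rhs)
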