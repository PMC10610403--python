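"""Non-compartmental metrics, lactation exposure ratios, model evaluation
and local sensitivity analysis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PKMetrics:
    cmax: float            # ng/mL
    tmax: float            # h
    auc: float             # ng*h/mL over the profile span
    cavg: float            # ng/mL
    half_life: float       # h (nan if not estimable)


def nca(time_h: np.ndarray, conc: np.ndarray,
        terminal_fraction: float = 0.2, min_terminal_points: int = 5) -> PKMetrics:
    """Non-compartmental analysis of one concentration-time profile.

    Cmax/Tmax by grid maximum, AUC by linear trapezoid, Cavg = AUC/span,
    terminal half-life by log-linear regression over the last
    ``terminal_fraction`` of the span (at least ``min_terminal_points``
    positive samples, else NaN).
    """
    t = np.asarray(time_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(np.diff(t) < 0):
        raise ValueError("time grid must be non-decreasing")
    imax = int(np.argmax(c))
    auc = float(np.trapezoid(c, t))
    span = t[-1] - t[0]
    t_start = t[-1] - terminal_fraction * span
    mask = (t >= t_start) & (c > 0)
    if mask.sum() >= min_terminal_points:
        slope = np.polyfit(t[mask], np.log(c[mask]), 1)[0]
        half_life = float(np.log(2) / -slope) if slope < 0 else float("nan")
    else:
        half_life = float("nan")
    return PKMetrics(cmax=float(c[imax]), tmax=float(t[imax]), auc=auc,
                     cavg=auc / span, half_life=half_life)


def auc_window(time_h: np.ndarray, conc: np.ndarray,
               lo: float = 0.0, hi: float = 24.0) -> float:
    """Trapezoidal AUC over [lo, hi] (grid must cover the window)."""
    t = np.asarray(time_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    if hi > t[-1] + 1e-9:
        raise ValueError("window exceeds the simulated horizon")
    mask = (t >= lo) & (t <= hi)
    return float(np.trapezoid(c[mask], t[mask]))


def relative_infant_dose(infant_dose_ug_kg_d: float, maternal_dose_mg_d: float,
                         maternal_weight_kg: float) -> float:
    """RID (%) = 100 * infant dose / maternal weight-normalised dose."""
    if min(infant_dose_ug_kg_d, maternal_dose_mg_d, maternal_weight_kg) < 0:
        raise ValueError("inputs must be non-negative")
    maternal_ug_kg_d = maternal_dose_mg_d * 1000.0 / maternal_weight_kg
    return 100.0 * infant_dose_ug_kg_d / maternal_ug_kg_d


def aafe(predicted, observed) -> float:
    """Absolute average fold error: 10^(mean |log10(pred/obs)|).

    Always >= 1; equals 1 only for a perfect prediction.  The absolute
    value inside the mean is what distinguishes AAFE from the (signed)
    average fold error, in which over- and under-predictions cancel.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("predicted/observed must be equal-length and non-empty")
    if np.any(p <= 0) or np.any(o <= 0):
        raise ValueError("AAFE requires strictly positive values")
    return float(10.0 ** np.mean(np.abs(np.log10(p / o))))


def sensitivity_coefficient(model_fn: Callable[[float], float], parameter: float,
                            perturbation: float = 0.1) -> float:
    """Normalised local sensitivity S = (P/dP) * (dPK/PK).

    ``model_fn`` maps the parameter value to the output metric (AUC by
    convention); the parameter is perturbed by the given relative amount.
    """
    if perturbation == 0:
        raise ValueError("perturbation must be non-zero")
    base = model_fn(parameter)
    pert = model_fn(parameter * (1.0 + perturbation))
    return (pert - base) / base / perturbation


def flag_influential(sensitivities: dict[str, float],
                     threshold: float = 10.0) -> list[str]:
    """Parameters whose |S| meets the influence threshold."""
    return [k for k, s in sensitivities.items() if abs(s) >= threshold]


@dataclass(frozen=True)
class LactationMetrics:
    """One scenario row mirroring the exposure-summary layout."""
    joints_per_day: int
    milk_cmax: float
    milk_auc24: float
    milk_cavg: float
    plasma_cmax: float
    plasma_auc24: float
    mp_auc_ratio: float
    infant_auc24: float | None = None
    infant_dose_ug_kg_d: float | None = None
    rid_pct: float | None = None
    mother_to_infant_auc_pct: float | None = None

    def as_row(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def scenario_metrics(time_h, plasma, milk, joints_per_day: int = 1,
                     infant_time=None, infant_plasma=None,
                     infant_dose_ug_kg_d: float | None = None,
                     maternal_dose_mg_d: float | None = None,
                     maternal_weight_kg: float | None = None) -> LactationMetrics:
    """Exposure metrics for one maternal (+ optional infant) simulation."""
    p24 = auc_window(time_h, plasma)
    m24 = auc_window(time_h, milk)
    mask = np.asarray(time_h) <= 24.0
    out = dict(
        joints_per_day=joints_per_day,
        milk_cmax=float(np.max(np.asarray(milk)[mask])),
        milk_auc24=m24, milk_cavg=m24 / 24.0,
        plasma_cmax=float(np.max(np.asarray(plasma)[mask])),
        plasma_auc24=p24, mp_auc_ratio=m24 / p24,
    )
    if infant_plasma is not None:
        i24 = auc_window(infant_time, infant_plasma)
        out["infant_auc24"] = i24
        out["mother_to_infant_auc_pct"] = 100.0 * i24 / p24
    if infant_dose_ug_kg_d is not None:
        out["infant_dose_ug_kg_d"] = infant_dose_ug_kg_d
        if maternal_dose_mg_d is not None and maternal_weight_kg is not None:
            out["rid_pct"] = relative_infant_dose(
                infant_dose_ug_kg_d, maternal_dose_mg_d, maternal_weight_kg)
    return LactationMetrics(**out)


def evaluate_predictions(pred: pd.DataFrame, obs: pd.DataFrame,
                         band: tuple[float, float] = (1.0, 2.0)) -> pd.DataFrame:
    """Per-study AAFE report from tidy (study, matrix, metric, value) tables."""
    keys = ["study", "matrix", "metric"]
    merged = pred.merge(obs, on=keys, suffixes=("_pred", "_obs"))
    if merged.empty:
        raise ValueError("no matching (study, matrix, metric) rows")
    rows = []
    for study, grp in merged.groupby("study"):
        a = aafe(grp.value_pred.to_numpy(), grp.value_obs.to_numpy())
        rows.append(dict(study=study, n=len(grp), aafe=a,
                         ratio_median=float(np.median(grp.value_pred / grp.value_obs)),
                         passes=band[0] <= a <= band[1]))
    return pd.DataFrame(rows)
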