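"""Scenario library and simulation drivers.

Named scenarios reproduce the dosing designs used to exercise the model:
a 5 mg/2 min IV infusion, the standard single joint (0.32 g at 14.14% THC
= 45.25 mg smoked over the 13-puff topography), the pilot postpartum
smoking study (23.18 mg over 15 min), and 1-6 joints/day spaced evenly
over 24 h.  Feeding defaults to the first feed one hour after the first
smoking session and every three hours thereafter.  Everything is generated
programmatically — no external data are required.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import DoseEvent, InfantModel, MaternalModel, SimulationResult, SolverOptions
from .drug import DrugParams, compute_partition_set
from .infant import FeedingSchedule, infant_daily_dose_per_kg
from .inhalation import Topography
from .lactation import BreastParams
from .physiology import (
    PopulationDraw, PopulationSpec, build_adult_subject, build_infant_subject,
    sample_population,
)

STANDARD_JOINT_MG = 0.32 * 1000 * 0.1414          # 45.25 mg


@dataclass
class ScenarioConfig:
    """A fully specified simulation scenario."""
    name: str
    smoke_times_h: list[float] = field(default_factory=list)
    smoke_dose_mg: float = STANDARD_JOINT_MG
    smoke_duration_h: float = Topography().session_duration_h
    iv_dose_mg: float = 0.0
    iv_duration_h: float = 0.0
    iv_time_h: float = 0.0
    first_feed_h: float = 1.0
    feeds_per_day: int = 8
    infant_age_years: float = 1.0 / 12.0
    horizon_h: float = 24.0
    ionization_mode: str = "acid"
    seed: int = 0
    n_subjects: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(text))


def make_scenario(name: str, **overrides) -> ScenarioConfig:
    """Build a named scenario from the library."""
    if name == "iv_5mg_2min":
        cfg = ScenarioConfig(name=name, iv_dose_mg=5.0, iv_duration_h=2 / 60,
                             feeds_per_day=0)
    elif name == "smoke_single_joint":
        cfg = ScenarioConfig(name=name, smoke_times_h=[0.0],
                             smoke_dose_mg=STANDARD_JOINT_MG,
                             smoke_duration_h=8.7 / 60)
    elif name == "smoke_baker":
        cfg = ScenarioConfig(name=name, smoke_times_h=[0.0],
                             smoke_dose_mg=23.18, smoke_duration_h=15 / 60,
                             infant_age_years=3.0 / 12.0)
    elif name.startswith("multi_joint_"):
        k = int(name.rsplit("_", 1)[1])
        if not (1 <= k <= 6):
            raise KeyError(f"joints/day must be 1..6, got {k}")
        cfg = ScenarioConfig(name=name,
                             smoke_times_h=[24.0 / k * i for i in range(k)],
                             smoke_dose_mg=STANDARD_JOINT_MG,
                             smoke_duration_h=8.7 / 60)
    else:
        raise KeyError(f"unknown scenario {name!r}")
    for k_, v in overrides.items():
        setattr(cfg, k_, v)
    return cfg


def build_schedule(cfg: ScenarioConfig) -> list[DoseEvent]:
    """Dose/feed event list for one scenario."""
    events = [DoseEvent(t, "smoke", dose_mg=cfg.smoke_dose_mg,
                        duration_h=cfg.smoke_duration_h)
              for t in cfg.smoke_times_h]
    if cfg.iv_dose_mg > 0:
        events.append(DoseEvent(cfg.iv_time_h, "iv", dose_mg=cfg.iv_dose_mg,
                                duration_h=cfg.iv_duration_h))
    if cfg.feeds_per_day > 0:
        feeding = FeedingSchedule(infant_age_years=cfg.infant_age_years,
                                  feeds_per_day=cfg.feeds_per_day,
                                  first_feed_h=cfg.first_feed_h)
        v = feeding.volume_per_feed_mL
        events += [DoseEvent(t, "feed", volume_mL=v)
                   for t in feeding.feed_times(cfg.horizon_h)]
    return sorted(events, key=lambda e: e.time)


def run_mother(cfg: ScenarioConfig, draw: PopulationDraw | None = None,
               drug: DrugParams | None = None,
               options: SolverOptions | None = None) -> SimulationResult:
    """Simulate the maternal model for one subject under a scenario."""
    drug = drug or DrugParams.from_file()
    if draw is None:
        subject = build_adult_subject(0, 28.0, 78.0, 27.7)
        draw = PopulationDraw(subject, 0.5, 1.0, 0.21)
    breast = BreastParams.from_file(
        drug, kp_breast_fraction=draw.kp_breast_fraction,
        v_milk_L=draw.milk_volume_L, ionization_mode=cfg.ionization_mode)
    model = MaternalModel(draw.subject, drug, breast=breast,
                          ionization_mode=cfg.ionization_mode,
                          cyp_multiplier=draw.cyp_multiplier,
                          options=options)
    return model.simulate(build_schedule(cfg), cfg.horizon_h)


def run_infant(cfg: ScenarioConfig, maternal: SimulationResult,
               drug: DrugParams | None = None,
               options: SolverOptions | None = None) -> SimulationResult:
    """Simulate the infant model from a maternal feed log."""
    drug = drug or DrugParams.from_file()
    infant = build_infant_subject(cfg.infant_age_years)
    model = InfantModel(infant, drug, options=options)
    feeds = [(row.time_h, row.dose_ng)
             for row in maternal.feed_log.itertuples()]
    return model.simulate(feeds, cfg.horizon_h)


def run_pair(cfg: ScenarioConfig, draw: PopulationDraw | None = None,
             drug: DrugParams | None = None,
             options: SolverOptions | None = None
             ) -> tuple[SimulationResult, SimulationResult]:
    mother = run_mother(cfg, draw, drug, options)
    baby = run_infant(cfg, mother, drug, options)
    return mother, baby


def run_population(cfg: ScenarioConfig, spec: PopulationSpec | None = None,
                   drug: DrugParams | None = None,
                   options: SolverOptions | None = None) -> list[SimulationResult]:
    """Simulate the maternal model across a seeded virtual population."""
    spec = spec or PopulationSpec(n=cfg.n_subjects, seed=cfg.seed)
    return [run_mother(cfg, draw, drug, options)
            for draw in sample_population(spec)]


def synthetic_observed(time_h: np.ndarray, conc: np.ndarray, noise_cv: float,
                       seed: int, matrix: str = "milk",
                       study: str = "synthetic") -> pd.DataFrame:
    """Lognormal multiplicative noise on a simulated truth profile.

    Stands in for digitized literature profiles when exercising the AAFE
    evaluation workflow; noise_cv = 0 returns the truth itself.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + noise_cv**2))
        mult = rng.lognormal(-sigma**2 / 2.0, sigma, size=len(conc))
    else:
        mult = np.ones(len(conc))
    return pd.DataFrame({
        "time_h": np.asarray(time_h, dtype=float),
        "conc_ng_mL": np.asarray(conc, dtype=float) * mult,
        "matrix": matrix, "study": study, "unit": "ng/mL",
    })
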