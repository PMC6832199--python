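"""Synthetic right-censored ICU cohorts with configurable marker effects.

The generator draws, per patient, a fixed-length block of uniforms from a
single PCG64 stream (all draws for patient i precede those for patient i+1),
so cohorts simulated from the same seed share a common prefix across cohort
sizes.  Marker levels are log-normal; group effects act additively on the
log scale, conditioned on the patient's sampled states:

* ``patients_vs_control`` — applied to every patient record (a healthy
  control panel omits it),
* ``sepsis_vs_nonsepsis`` — applied when the sepsis flag is drawn,
* ``icu_death`` — applied when the patient dies during the ICU stay,
* ``overall_death`` — applied when the patient dies after ICU discharge
  during follow-up (latent status, before censoring is imposed).

Conditioning the two outcome effects on disjoint latent classes keeps the
ICU contrast as free as possible of the long-term effect and vice versa;
because ICU deaths are a subset of overall deaths, some cross-talk between
the two selections is unavoidable in any additive generative model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .cohort import MARKERS, CohortRecord
from .errors import ConfigError

CONTRASTS = (
    "patients_vs_control",
    "sepsis_vs_nonsepsis",
    "icu_death",
    "overall_death",
)

# uniform draw block per patient: sepsis, icu death, late death, age,
# icu los, late death time, censoring time, 7 marker z-scores
_DRAWS_PER_PATIENT = 7 + len(MARKERS)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic cohort."""

    n_patients: int = 204
    sepsis_fraction: float = 127 / 204
    p_icu_death: float = 45 / 204
    p_late_death_given_icu_survival: float = 40 / 159
    age_mean_survivor: float = 59.0
    age_mean_nonsurvivor: float = 70.5
    age_sd: float = 11.5
    marker_params: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    effect_matrix: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    icu_los_mean_days: float = 10.0
    late_death_mean_days: float = 300.0
    followup_max_days: float = 1095.0
    censor_rate: float = 1.25e-4
    seed: int = 0

    def effect(self, marker: str, contrast: str) -> float:
        """Log-scale shift for (marker, contrast); absent entries are 0."""
        return float(self.effect_matrix.get(marker, {}).get(contrast, 0.0))

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        for name in (
            "sepsis_fraction",
            "p_icu_death",
            "p_late_death_given_icu_survival",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be > 0")
        for mname in self.marker_params:
            if mname not in MARKERS:
                raise ConfigError(f"unknown marker in marker_params: {mname}")
        for mname in MARKERS:
            if mname not in self.marker_params:
                raise ConfigError(f"marker_params missing {mname}")
            _, sigma = self.marker_params[mname]
            if sigma <= 0:
                raise ConfigError(f"log_sigma must be > 0 for {mname}")
        for mname, row in self.effect_matrix.items():
            if mname not in MARKERS:
                raise ConfigError(f"unknown marker in effect_matrix: {mname}")
            for contrast in row:
                if contrast not in CONTRASTS:
                    raise ConfigError(
                        f"unknown contrast in effect_matrix: {contrast}"
                    )
        if self.icu_los_mean_days <= 0 or self.late_death_mean_days <= 0:
            raise ConfigError("duration means must be > 0")
        if self.followup_max_days <= 0:
            raise ConfigError("followup_max_days must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["marker_params"] = {k: list(v) for k, v in self.marker_params.items()}
        d["effect_matrix"] = {
            k: dict(v) for k, v in self.effect_matrix.items()
        }
        return json.dumps(d, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["marker_params"] = {
            k: (float(v[0]), float(v[1])) for k, v in d["marker_params"].items()
        }
        d["effect_matrix"] = {
            k: {c: float(s) for c, s in row.items()}
            for k, row in d["effect_matrix"].items()
        }
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


def default_study_config(seed: int = 0) -> SimulationConfig:
    """Frozen reference configuration for a 204-patient medical-ICU cohort.

    Cohort composition: 127 septic / 77 non-septic in expectation, 45
    expected ICU deaths, 40 expected further deaths among ICU survivors
    during a 3-year follow-up.  Effect signs follow the reference direction
    matrix (zero where no group difference is reported); magnitudes give the
    shifted contrasts >90% rank-sum power at the default cohort size.
    """
    marker_params = {
        "miR-122": (np.log(8.0), 0.7),
        "miR-133a": (np.log(2.2), 0.6),
        "miR-143": (np.log(5.0), 0.6),
        "miR-150": (np.log(35.0), 0.6),
        "miR-155": (np.log(1.5), 0.6),
        "miR-192": (np.log(12.0), 0.7),
        "miR-223": (np.log(60.0), 0.6),
    }
    effect_matrix = {
        "miR-122": {"patients_vs_control": 0.7},
        "miR-133a": {
            "patients_vs_control": 0.7,
            "sepsis_vs_nonsepsis": 0.45,
            "icu_death": 0.8,
            "overall_death": 0.5,
        },
        "miR-143": {"icu_death": -0.8},
        "miR-150": {"overall_death": -1.2},
        "miR-155": {"patients_vs_control": 0.5},
        "miR-192": {"patients_vs_control": 0.6},
        "miR-223": {"patients_vs_control": -0.3, "icu_death": -0.8},
    }
    return SimulationConfig(
        marker_params=marker_params,
        effect_matrix=effect_matrix,
        seed=seed,
    )


def _truncnorm_ppf(u: np.ndarray, mean: np.ndarray, sd: float,
                   lo: float, hi: float) -> np.ndarray:
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return sps.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def simulate_cohort(config: SimulationConfig) -> list[CohortRecord]:
    """Draw a cohort of ``config.n_patients`` records; deterministic per seed."""
    config.validate()
    n = config.n_patients
    rng = np.random.Generator(np.random.PCG64(config.seed))
    u = rng.random((n, _DRAWS_PER_PATIENT))
    if n == 0:
        return []
    u = np.clip(u, 1e-12, 1.0 - 1e-12)

    sepsis = u[:, 0] < config.sepsis_fraction
    icu_death = u[:, 1] < config.p_icu_death
    late_death = (~icu_death) & (u[:, 2] < config.p_late_death_given_icu_survival)
    died_latent = icu_death | late_death

    age_mean = np.where(
        died_latent, config.age_mean_nonsurvivor, config.age_mean_survivor
    )
    age = _truncnorm_ppf(u[:, 3], age_mean, config.age_sd, 18.0, 95.0)

    icu_los = np.maximum(-config.icu_los_mean_days * np.log1p(-u[:, 4]), 1e-9)
    late_time = -config.late_death_mean_days * np.log1p(-u[:, 5])
    if config.censor_rate > 0:
        censor = -np.log1p(-u[:, 6]) / config.censor_rate
    else:
        censor = np.full(n, np.inf)
    censor = np.maximum(np.minimum(censor, config.followup_max_days), 1e-9)

    death_time = np.where(
        icu_death, icu_los, np.where(late_death, icu_los + late_time, np.inf)
    )
    # ICU deaths are always observed; later deaths race against censoring
    overall_event = icu_death | (late_death & (death_time <= censor))
    followup = np.where(icu_death, icu_los, np.minimum(death_time, censor))

    levels = np.empty((n, len(MARKERS)))
    for j, m in enumerate(MARKERS):
        log_mu, sigma = config.marker_params[m]
        shift = (
            config.effect(m, "patients_vs_control")
            + sepsis * config.effect(m, "sepsis_vs_nonsepsis")
            + icu_death * config.effect(m, "icu_death")
            + late_death * config.effect(m, "overall_death")
        )
        z = sps.norm.ppf(u[:, 7 + j])
        levels[:, j] = np.exp(log_mu + shift + sigma * z)

    records = []
    for i in range(n):
        records.append(
            CohortRecord(
                patient_id=f"P{i:04d}",
                age=float(age[i]),
                sepsis=bool(sepsis[i]),
                icu_death=bool(icu_death[i]),
                icu_los=float(icu_los[i]),
                overall_event=bool(overall_event[i]),
                followup_time=float(followup[i]),
                markers={m: float(levels[i, j]) for j, m in enumerate(MARKERS)},
            )
        )
    return records


def simulate_controls(config: SimulationConfig, n_controls: int):
    """Healthy-control marker panel: baseline log-normals, no group shifts.

    Returns a list of ``{"patient_id", "age", <marker levels>}`` dicts
    matching the control-CSV schema (cohort schema minus outcome columns).
    """
    config.validate()
    if n_controls < 0:
        raise ConfigError("n_controls must be >= 0")
    rng = np.random.Generator(np.random.PCG64([config.seed, 0xC0]))
    u = np.clip(rng.random((n_controls, 1 + len(MARKERS))),
                1e-12, 1.0 - 1e-12)
    out = []
    for i in range(n_controls):
        age = float(
            _truncnorm_ppf(
                u[i, 0:1],
                np.array([config.age_mean_survivor]),
                config.age_sd,
                18.0,
                95.0,
            )[0]
        )
        row: dict = {"patient_id": f"C{i:04d}", "age": age}
        for j, m in enumerate(MARKERS):
            log_mu, sigma = config.marker_params[m]
            row[m] = float(np.exp(log_mu + sigma * sps.norm.ppf(u[i, 1 + j])))
        out.append(row)
    return out
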