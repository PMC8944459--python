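"""Seeded generator of ICU-like therapy and monitoring data with known structure.

Emulates a PDMS extract: per-patient ICU stays (log-normal length), antibiotic
courses as contiguous day-blocks over a ~90-drug vocabulary (so the
consecutive-day counters are exercised with known answers), and hourly readings
of a 46-parameter monitoring schema with per-parameter missingness and
subpopulation gating (e.g. intracranial pressure only in neuromonitored
patients).  Course lengths come from a short-geometric + long-tail mixture so
all five duration categories (ultra-short .. ultra-long) are populated.

Two planted-structure facilities back the clustering tests: hourly monitoring
values can be drawn from K latent profiles (categorical modes mapped to
quintile bands of each parameter's distribution), and
:func:`simulate_patterns` emits category patterns directly from planted modes
with attribute-flip noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MonitoringParameter",
    "SimConfig",
    "SimOutput",
    "DEFAULT_DRUG_VOCABULARY",
    "DEFAULT_MONITORING_SCHEMA",
    "simulate_cohort",
    "simulate_patterns",
]

# ~90 antimicrobials (antibacterials, antifungals, antivirals) as seen on an
# adult general ICU over several years; usage weights in the generator are
# rank-skewed so a few workhorse drugs dominate, as in real prescribing.
DEFAULT_DRUG_VOCABULARY: tuple[str, ...] = (
    "piperacillin-tazobactam", "meropenem", "vancomycin", "ceftriaxone", "levofloxacin",
    "amoxicillin-clavulanate", "cefepime", "linezolid", "metronidazole", "ciprofloxacin",
    "amikacin", "gentamicin", "ceftazidime", "azithromycin", "daptomycin",
    "colistin", "tigecycline", "imipenem-cilastatin", "ertapenem", "teicoplanin",
    "clindamycin", "ampicillin-sulbactam", "cefazolin", "oxacillin", "penicillin-g",
    "trimethoprim-sulfamethoxazole", "doxycycline", "rifampin", "fosfomycin", "aztreonam",
    "cefotaxime", "cefuroxime", "ampicillin", "amoxicillin", "moxifloxacin",
    "tobramycin", "ceftolozane-tazobactam", "ceftazidime-avibactam", "ceftaroline", "cefiderocol",
    "meropenem-vaborbactam", "imipenem-relebactam", "dalbavancin", "telavancin", "oritavancin",
    "tedizolid", "plazomicin", "polymyxin-b", "chloramphenicol", "minocycline",
    "tetracycline", "erythromycin", "clarithromycin", "nitrofurantoin", "norfloxacin",
    "ofloxacin", "cefoxitin", "cefotetan", "ceftobiprole", "temocillin",
    "nafcillin", "flucloxacillin", "fusidic-acid", "quinupristin-dalfopristin", "streptomycin",
    "isoniazid", "rifabutin", "ethambutol", "pyrazinamide", "cycloserine",
    "fluconazole", "voriconazole", "posaconazole", "isavuconazole", "itraconazole",
    "caspofungin", "micafungin", "anidulafungin", "amphotericin-b", "flucytosine",
    "terbinafine", "acyclovir", "ganciclovir", "valganciclovir", "foscarnet",
    "cidofovir", "oseltamivir", "ribavirin", "zanamivir", "brincidofovir",
)


@dataclass(frozen=True)
class MonitoringParameter:
    """One monitoring channel: native-unit distribution, missingness, gating.

    ``missing_p`` is the probability that an eligible patient-hour has no
    reading of this parameter; ``gate_p`` the fraction of patients monitored
    for it at all (1.0 = everyone).
    """

    name: str
    unit: str
    mean: float
    sd: float
    missing_p: float
    gate_p: float = 1.0


# 46 channels: vitals, ventilation, ABG, chemistry from point-of-care gas
# analysers, fluid balance, neuro/hemodynamic extras gated to subpopulations.
DEFAULT_MONITORING_SCHEMA: tuple[MonitoringParameter, ...] = (
    MonitoringParameter("heart_rate", "bpm", 86, 16, 0.05),
    MonitoringParameter("arterial_pressure_systolic", "mmHg", 122, 20, 0.08),
    MonitoringParameter("arterial_pressure_diastolic", "mmHg", 64, 12, 0.08),
    MonitoringParameter("mean_arterial_pressure", "mmHg", 84, 14, 0.08),
    MonitoringParameter("central_venous_pressure", "mmHg", 9, 4, 0.35),
    MonitoringParameter("intracranial_pressure", "mmHg", 12, 5, 0.20, gate_p=0.10),
    MonitoringParameter("cerebral_perfusion_pressure", "mmHg", 72, 10, 0.25, gate_p=0.10),
    MonitoringParameter("spo2", "%", 96.5, 2.2, 0.05),
    MonitoringParameter("temperature", "degC", 37.1, 0.7, 0.30),
    MonitoringParameter("respiratory_rate", "breaths/min", 18, 5, 0.10),
    MonitoringParameter("etco2", "mmHg", 36, 6, 0.50),
    MonitoringParameter("fio2", "fraction", 0.45, 0.12, 0.20),
    MonitoringParameter("peep", "cmH2O", 7, 2.5, 0.30),
    MonitoringParameter("tidal_volume", "mL", 470, 80, 0.30),
    MonitoringParameter("minute_ventilation", "L/min", 8.2, 2.2, 0.35),
    MonitoringParameter("plateau_pressure", "cmH2O", 21, 5, 0.50),
    MonitoringParameter("peak_pressure", "cmH2O", 26, 6, 0.40),
    MonitoringParameter("ph", "", 7.39, 0.06, 0.70),
    MonitoringParameter("pao2", "mmHg", 96, 24, 0.70),
    MonitoringParameter("paco2", "mmHg", 41, 8, 0.70),
    MonitoringParameter("hco3", "mmol/L", 24.5, 3.5, 0.70),
    MonitoringParameter("base_excess", "mmol/L", 0.2, 3.2, 0.70),
    MonitoringParameter("lactate", "mmol/L", 1.9, 1.1, 0.70),
    MonitoringParameter("sao2", "%", 96, 2.5, 0.70),
    MonitoringParameter("pf_ratio", "mmHg", 255, 85, 0.75),
    MonitoringParameter("glucose", "mg/dL", 135, 35, 0.60),
    MonitoringParameter("sodium", "mmol/L", 139, 4, 0.75),
    MonitoringParameter("potassium", "mmol/L", 4.1, 0.5, 0.75),
    MonitoringParameter("ionized_calcium", "mmol/L", 1.15, 0.08, 0.80),
    MonitoringParameter("chloride", "mmol/L", 105, 5, 0.80),
    MonitoringParameter("hemoglobin", "g/dL", 10.5, 1.8, 0.80),
    MonitoringParameter("urine_output", "mL/h", 70, 45, 0.25),
    MonitoringParameter("infusion_rate", "mL/h", 125, 60, 0.20),
    MonitoringParameter("fluid_balance", "mL/h", 15, 85, 0.40),
    MonitoringParameter("ultrafiltrate", "mL/h", 85, 45, 0.20, gate_p=0.15),
    MonitoringParameter("dialysate_flow", "mL/h", 2400, 600, 0.25, gate_p=0.15),
    MonitoringParameter("svo2", "%", 70, 8, 0.40, gate_p=0.30),
    MonitoringParameter("cardiac_output", "L/min", 5.4, 1.3, 0.40, gate_p=0.20),
    MonitoringParameter("cardiac_index", "L/min/m2", 2.9, 0.7, 0.40, gate_p=0.20),
    MonitoringParameter("svri", "dyn*s/cm5/m2", 1950, 450, 0.45, gate_p=0.20),
    MonitoringParameter("gcs", "points", 11, 3, 0.60),
    MonitoringParameter("rass", "points", -1.5, 1.5, 0.50),
    MonitoringParameter("pupil_diameter", "mm", 3.0, 0.8, 0.70),
    MonitoringParameter("cuff_pressure", "cmH2O", 26, 4, 0.60),
    MonitoringParameter("abdominal_pressure", "mmHg", 11, 4, 0.40, gate_p=0.25),
    MonitoringParameter("train_of_four", "count", 3.2, 1.0, 0.70, gate_p=0.20),
)

assert len(DEFAULT_DRUG_VOCABULARY) == 90
assert len(DEFAULT_MONITORING_SCHEMA) == 46

# Standard-normal quintile boundaries, used to map planted categories 1..5 to
# value bands of a parameter's distribution.
_QUINTILES = (-2.2, -0.8416212335729143, -0.2533471031357997, 0.2533471031357997, 0.8416212335729143, 2.2)


@dataclass
class SimConfig:
    """Study-condition knobs for the cohort generator (seed is mandatory)."""

    seed: int
    n_patients: int = 200
    stay_lognorm_mu: float = 2.1
    stay_lognorm_sigma: float = 0.6
    max_stay_days: int = 60
    p_untreated: float = 0.10
    mean_extra_courses: float = 0.8
    p_long_course: float = 0.30
    geom_p_short: float = 0.40
    geom_p_long: float = 0.15
    long_course_offset: int = 5
    max_course_days: int = 35
    drug_vocabulary: tuple[str, ...] = DEFAULT_DRUG_VOCABULARY
    monitoring_schema: tuple[MonitoringParameter, ...] = DEFAULT_MONITORING_SCHEMA
    ar1: float = 0.0
    start_date: str = "2015-01-01"
    planted_k: Optional[int] = None
    planted_eps: float = 0.05

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("p_untreated", "p_long_course", "geom_p_short", "geom_p_long", "planted_eps"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 must be in [0, 1)")
        for p in self.monitoring_schema:
            if not (0.0 <= p.missing_p <= 1.0 and 0.0 < p.gate_p <= 1.0):
                raise ValueError(f"invalid probabilities for parameter {p.name}")
        if self.planted_k is not None and self.planted_k < 1:
            raise ValueError("planted_k must be >= 1 when given")


@dataclass
class SimOutput:
    """Generated tables in the ingest schemas, plus ground truth when planted."""

    administrations: pd.DataFrame
    readings: pd.DataFrame
    truth: Optional[pd.DataFrame] = None


def _course_length(rng: np.random.Generator, cfg: SimConfig) -> int:
    if rng.random() < cfg.p_long_course:
        length = cfg.long_course_offset + rng.geometric(cfg.geom_p_long)
    else:
        length = rng.geometric(cfg.geom_p_short)
    return int(min(length, cfg.max_course_days))


def simulate_cohort(config: SimConfig) -> SimOutput:
    """Generate administrations and readings tables, reproducible from the seed.

    Drug courses are contiguous day blocks (clipped to the stay); readings are
    hourly per-parameter draws honouring gates and missingness, optionally
    AR(1)-correlated within a patient.  With ``planted_k`` set, each
    patient-hour follows one of K latent category profiles and the true
    profile id per (patient, date, hour) is returned in ``truth``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.start_date)
    n_params = len(config.monitoring_schema)
    means = np.array([p.mean for p in config.monitoring_schema])
    sds = np.array([p.sd for p in config.monitoring_schema])
    missing_p = np.array([p.missing_p for p in config.monitoring_schema])
    gate_p = np.array([p.gate_p for p in config.monitoring_schema])
    param_names = np.array([p.name for p in config.monitoring_schema])

    # rank-skewed prescribing weights
    drug_w = 1.0 / np.arange(1, len(config.drug_vocabulary) + 1)
    drug_w /= drug_w.sum()

    planted_modes = None
    if config.planted_k is not None:
        # mode entry 0 (absent) with the parameter's own missingness, else uniform 1..5
        planted_modes = np.where(
            rng.random((config.planted_k, n_params)) < missing_p[None, :],
            0,
            rng.integers(1, 6, size=(config.planted_k, n_params)),
        )

    admin_frames: list[pd.DataFrame] = []
    reading_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []

    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        stay_days = int(np.clip(round(rng.lognormal(config.stay_lognorm_mu, config.stay_lognorm_sigma)), 2, config.max_stay_days))
        admission = start + pd.Timedelta(days=int(rng.integers(0, 365)))

        # --- therapy courses ---
        if rng.random() >= config.p_untreated:
            n_courses = 1 + rng.poisson(config.mean_extra_courses)
            recs = []
            for _ in range(n_courses):
                drug = str(rng.choice(np.asarray(config.drug_vocabulary), p=drug_w))
                first = int(rng.integers(0, stay_days))
                length = _course_length(rng, config)
                for day in range(first, min(first + length, stay_days)):
                    recs.append((pid, drug, admission + pd.Timedelta(days=day)))
            if recs:
                admin_frames.append(pd.DataFrame(recs, columns=["patient_id", "drug", "date"]).drop_duplicates())

        # --- hourly monitoring ---
        n_hours = stay_days * 24
        gates = rng.random(n_params) < gate_p
        if config.planted_k is not None:
            labels = rng.integers(0, config.planted_k, size=n_hours)
            codes = planted_modes[labels].copy()
            flip = rng.random((n_hours, n_params)) < config.planted_eps
            codes[flip] = rng.integers(0, 6, size=int(flip.sum()))
            present = (codes > 0) & gates[None, :]
            z = np.zeros((n_hours, n_params))
            for c in range(1, 6):
                sel = codes == c
                lo, hi = _QUINTILES[c - 1], _QUINTILES[c]
                z[sel] = rng.uniform(lo, hi, size=int(sel.sum()))
            values = means[None, :] + sds[None, :] * z
        else:
            labels = None
            present = (rng.random((n_hours, n_params)) >= missing_p[None, :]) & gates[None, :]
            if config.ar1 > 0:
                eps = rng.standard_normal((n_hours, n_params)) * np.sqrt(1 - config.ar1**2)
                z = np.empty((n_hours, n_params))
                z[0] = rng.standard_normal(n_params)
                for t in range(1, n_hours):
                    z[t] = config.ar1 * z[t - 1] + eps[t]
            else:
                z = rng.standard_normal((n_hours, n_params))
            values = means[None, :] + sds[None, :] * z

        hr_idx, pr_idx = np.nonzero(present)
        timestamps = admission + pd.to_timedelta(hr_idx, unit="h")
        reading_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "timestamp": timestamps,
                    "parameter": param_names[pr_idx],
                    "value": np.round(values[hr_idx, pr_idx], 3),
                }
            )
        )
        if labels is not None:
            hours = np.arange(n_hours)
            truth_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "date": admission + pd.to_timedelta(hours // 24, unit="D"),
                        "hour": hours % 24,
                        "label": labels,
                    }
                )
            )

    administrations = (
        pd.concat(admin_frames, ignore_index=True)
        if admin_frames
        else pd.DataFrame(columns=["patient_id", "drug", "date"])
    )
    administrations = administrations.sort_values(["patient_id", "drug", "date"], kind="stable").reset_index(drop=True)
    readings = pd.concat(reading_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True) if truth_frames else None
    return SimOutput(administrations=administrations, readings=readings, truth=truth)


def simulate_patterns(K: int, length: int, n: int, eps: float, seed: int):
    """Category patterns from K planted modes with attribute-flip noise.

    Each pattern copies its mode, then every attribute is independently
    resampled uniformly over {0..5} with probability ``eps`` (the resample may
    restore the original category, so the expected perturbed fraction is
    eps * 5/6).  Returns (patterns, truth labels, modes).
    """
    if K < 1 or not K <= 6**length:
        raise ValueError(f"K={K} not representable with length {length}")
    if not 0.0 <= eps <= 1.0:
        raise ValueError("eps outside [0, 1]")
    rng = np.random.default_rng(seed)
    while True:
        modes = rng.integers(0, 6, size=(K, length))
        if np.unique(modes, axis=0).shape[0] == K:
            break
    labels = rng.integers(0, K, size=n)
    patterns = modes[labels].copy()
    flip = rng.random((n, length)) < eps
    patterns[flip] = rng.integers(0, 6, size=int(flip.sum()))
    return patterns, labels, modes
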