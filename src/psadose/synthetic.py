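"""Synthetic prostate-cancer cohort generator.

Emulates the two tables the analysis consumes: a one-row-per-patient
clinical table and a long-format PSA trajectory table.  The generative
model mirrors the structure the dose-response analysis assumes:

* four total-dose groups with configurable membership probabilities;
* a per-patient true PSA slope drawn Normal(mu_g, sigma_slope^2) around its
  dose group's mean response mu_g (ng/ml/month);
* observed PSA = max(0, baseline + true_slope * t + noise), with one
  pre-treatment measurement (time < 0) anchoring each trajectory;
* recurrence times exponential with log-hazard linear in total dose
  (protective) and in the positive-slope indicator (harmful), censored
  administratively at the end of follow-up.

Defaults describe a cohort of 195 patients with the dose-group mix,
follow-up span (4-67 months), visit cap (19 measurements) and ~90%
negative-slope fraction of the study population this pipeline analyzes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    DOSE_GROUP_LABELS,
    PatientRecord,
    records_to_frame,
    write_patient_table,
    write_trajectory_table,
)
from .slopes import PsaSeries

__all__ = [
    "RecurrenceModel",
    "SyntheticCohortConfig",
    "ConfigError",
    "generate_cohort",
    "generate_records",
    "truth_record",
    "default_config",
    "mediated_benchmark_config",
    "broken_mediation_config",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The generator configuration violates its invariants."""


def _default_dose_probs() -> tuple:
    # observed dose-group mix 24/30/119/22 of 195; last component closes
    # the simplex exactly so the sum-to-one invariant holds in floats
    p1, p2, p3 = 24 / 195, 30 / 195, 119 / 195
    return (p1, p2, p3, 1.0 - p1 - p2 - p3)


@dataclass(frozen=True)
class RecurrenceModel:
    """Log-hazard coefficients of the exponential recurrence process.

    hazard = exp(intercept + dose_coef * dose_Gy
                 + positive_slope_coef * 1[true slope > 0])
    per month.  A negative ``dose_coef`` makes dose protective; a positive
    ``positive_slope_coef`` makes a rising PSA harmful.
    """

    intercept: float = 0.5
    dose_coef: float = -0.08
    positive_slope_coef: float = 1.5

    def hazard(self, dose: float, positive_slope: bool) -> float:
        return math.exp(
            self.intercept
            + self.dose_coef * dose
            + self.positive_slope_coef * float(positive_slope)
        )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Ground truth and sampling plan for one synthetic cohort."""

    n_patients: int = 195
    dose_group_probs: tuple = field(default_factory=_default_dose_probs)
    representative_doses: tuple = (45.0, 60.0, 70.0, 75.0)  # Gy, one per group
    true_group_slope_means: tuple = (-0.1543, -0.2733, -0.2203, -0.332)
    slope_sd: float = 0.17            # ng/ml/month, between-patient
    measurement_noise_sd: float = 0.5  # ng/ml, within-patient
    baseline_psa_log_mean: float = 2.2
    baseline_psa_log_sd: float = 0.77
    followup_range: tuple = (4.0, 67.0)  # months
    visits_per_year: float = 4.0
    recurrence_model: RecurrenceModel = field(default_factory=RecurrenceModel)
    censoring_rate: float = 0.0       # probability of early (random) censoring
    seed: int = 0
    max_measurements: int = 19
    max_group_redraws: int = 100
    # which slope sign drives the recurrence hazard: the latent true slope
    # ("true") or the OLS slope of the generated measurements ("measured").
    # "measured" makes the analyst's surrogate the exact mediator, the
    # construction needed for a full-mediation benchmark (with "true", the
    # measured surrogate carries classification error and mediation is
    # diluted).
    mediator: str = "true"

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ConfigError("n_patients must be >= 4 (one per dose group)")
        probs = np.asarray(self.dose_group_probs, dtype=float)
        if probs.size != 4 or np.any(probs <= 0):
            raise ConfigError("dose_group_probs must be 4 positive probabilities")
        if abs(float(probs.sum()) - 1.0) > 1e-12:
            raise ConfigError("dose_group_probs must sum to 1 within 1e-12")
        doses = np.asarray(self.representative_doses, dtype=float)
        if doses.size != 4 or np.any(np.diff(doses) <= 0):
            raise ConfigError("representative_doses must be 4 strictly increasing values")
        if len(self.true_group_slope_means) != 4:
            raise ConfigError("true_group_slope_means must have 4 entries")
        if self.slope_sd < 0 or self.measurement_noise_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        lo, hi = self.followup_range
        if not (0 < lo <= hi):
            raise ConfigError("followup_range must satisfy 0 < min <= max")
        if self.visits_per_year <= 0:
            raise ConfigError("visits_per_year must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ConfigError("censoring_rate must be in [0, 1)")
        if self.max_measurements < 2:
            raise ConfigError("max_measurements must allow >= 2 points")
        if self.mediator not in ("true", "measured"):
            raise ConfigError("mediator must be 'true' or 'measured'")


def default_config(**overrides) -> SyntheticCohortConfig:
    """The study-population configuration, with keyword overrides."""
    return replace(SyntheticCohortConfig(), **overrides)


def mediated_benchmark_config(seed: int = 0, n_patients: int = 400) -> SyntheticCohortConfig:
    """Cohort in which dose affects recurrence only through the PSA slope.

    A full-mediation positive control for the Prentice evaluation: the
    hazard carries no direct dose term (``dose_coef = 0``) and is driven by
    the sign of the measured slope — the analyst's surrogate variable —
    so all four criteria hold by construction.  Dose groups are balanced
    and the dose-to-slope gradient is strong, giving each criterion's test
    high power at this sample size.
    """
    return default_config(
        n_patients=n_patients,
        seed=seed,
        dose_group_probs=(0.25, 0.25, 0.25, 0.25),
        true_group_slope_means=(0.05, -0.12, -0.25, -0.35),
        slope_sd=0.25,
        measurement_noise_sd=0.2,
        baseline_psa_log_mean=2.8,
        mediator="measured",
        recurrence_model=RecurrenceModel(
            intercept=-5.6, dose_coef=0.0, positive_slope_coef=3.0
        ),
    )


def broken_mediation_config(seed: int = 0, n_patients: int = 400) -> SyntheticCohortConfig:
    """Cohort in which dose affects recurrence but not the PSA slope.

    All dose groups share the same mean slope, so the surrogate carries no
    treatment signal and the dose-predicts-surrogate criterion fails by
    construction (mirroring a direct, unmediated dose effect).
    """
    return default_config(
        n_patients=n_patients,
        seed=seed,
        true_group_slope_means=(-0.22, -0.22, -0.22, -0.22),
        slope_sd=0.17,
    )


# clinical covariate mixes: chosen so all three D'Amico strata occur, with
# a roughly 13/52/35 Low/Intermediate/High split under the default iPSA law
_GLEASON_VALUES = (5, 6, 7, 8, 9)
_GLEASON_PROBS = (0.08, 0.30, 0.47, 0.10, 0.05)
_STAGE_VALUES = ("T1c", "T2a", "T2b", "T2c", "T3")
_STAGE_PROBS = (0.25, 0.28, 0.35, 0.07, 0.05)

# follow-up is right-skewed within its range: most patients are seen for a
# year or two, a minority for 5+ years (Beta(1, 3) over the range gives a
# mean near (min + range/4))
_FOLLOWUP_BETA = (1.0, 3.0)

# dose draw per group: uniform inside the bin (group 3 is the nominal 70 Gy)
_DOSE_RANGES = {1: (40.0, 48.0), 2: (50.0, 68.0), 4: (72.0, 78.0)}


def _draw_groups(rng: np.random.Generator, cfg: SyntheticCohortConfig) -> np.ndarray:
    probs = np.asarray(cfg.dose_group_probs, dtype=float)
    for _ in range(cfg.max_group_redraws):
        g = rng.choice(4, size=cfg.n_patients, p=probs) + 1
        if np.unique(g).size == 4:
            return g
    raise ConfigError(
        f"could not populate all 4 dose groups in {cfg.max_group_redraws} draws "
        f"(n_patients={cfg.n_patients})"
    )


def _visit_times(
    rng: np.random.Generator, cfg: SyntheticCohortConfig, followup: float
) -> np.ndarray:
    """One pre-treatment time plus jittered regular follow-up visits."""
    interval = 12.0 / cfg.visits_per_year
    t_pre = -rng.uniform(0.5, 2.0)
    grid = np.arange(interval, followup + 1e-9, interval)
    if grid.size == 0:
        grid = np.array([followup])
    jitter = rng.normal(0.0, 0.1 * interval, size=grid.size)
    post = np.clip(grid + jitter, 0.25, followup)
    post = np.unique(np.round(post, 3))
    max_post = cfg.max_measurements - 1
    if post.size > max_post:
        # thin evenly, keeping the first and last visit
        idx = np.unique(np.linspace(0, post.size - 1, max_post).round().astype(int))
        post = post[idx]
    return np.concatenate([[round(t_pre, 3)], post])


def _simulate(cfg: SyntheticCohortConfig):
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    groups = _draw_groups(rng, cfg)
    records: list[PatientRecord] = []
    series: dict[str, PsaSeries] = {}
    truths = []
    n_floor = 0
    width = len(str(cfg.n_patients))
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:0{width}d}"
        g = int(groups[i])
        if g == 3:
            dose = 70.0
        else:
            lo, hi = _DOSE_RANGES[g]
            dose = float(np.round(rng.uniform(lo, hi), 1))
        ipsa = float(np.round(
            rng.lognormal(cfg.baseline_psa_log_mean, cfg.baseline_psa_log_sd), 2
        ))
        ipsa = max(ipsa, 0.1)
        gleason = int(rng.choice(_GLEASON_VALUES, p=_GLEASON_PROBS))
        t_stage = str(rng.choice(_STAGE_VALUES, p=_STAGE_PROBS))
        lo, hi = cfg.followup_range
        followup = float(np.round(lo + (hi - lo) * rng.beta(*_FOLLOWUP_BETA), 1))

        mu_g = cfg.true_group_slope_means[g - 1]
        true_slope = float(rng.normal(mu_g, cfg.slope_sd))

        times = _visit_times(rng, cfg, followup)
        noise = (
            rng.normal(0.0, cfg.measurement_noise_sd, size=times.size)
            if cfg.measurement_noise_sd > 0
            else np.zeros(times.size)
        )
        psa = ipsa + true_slope * times + noise
        floored = psa < 0
        n_floor += int(floored.sum())
        psa = np.maximum(psa, 0.0)
        s = PsaSeries(pid, times, np.round(psa, 3))
        series[pid] = s

        if cfg.mediator == "measured":
            yc = s.psa - s.psa.mean()
            tc = s.times - s.times.mean()
            positive = float(np.dot(tc, yc)) > 0.0
        else:
            positive = true_slope > 0
        hazard = cfg.recurrence_model.hazard(dose, positive)
        t_event = float(rng.exponential(1.0 / hazard))
        t_censor = followup
        if cfg.censoring_rate > 0 and rng.uniform() < cfg.censoring_rate:
            t_censor = float(rng.uniform(0.1, followup))
        if t_event <= t_censor:
            event, t_obs = True, t_event
        else:
            event, t_obs = False, t_censor
        t_obs = max(round(t_obs, 2), 0.01)

        records.append(
            PatientRecord(
                patient_id=pid,
                ipsa=ipsa,
                gleason=gleason,
                t_stage=t_stage,
                total_dose=dose,
                followup_months=followup,
                recurrence=event,
                time_to_event_months=t_obs,
            )
        )
        truths.append(
            {
                "patient_id": pid,
                "dose_group": g,
                "dose_group_label": DOSE_GROUP_LABELS[g - 1],
                "total_dose": dose,
                "true_group_mean": mu_g,
                "true_slope": true_slope,
                "followup_months": followup,
            }
        )
    if n_floor:
        logger.info("PSA assay floor applied to %d measurements", n_floor)
    truth = pd.DataFrame(truths)
    truth.attrs["recurrence_model"] = {
        "intercept": cfg.recurrence_model.intercept,
        "dose_coef": cfg.recurrence_model.dose_coef,
        "positive_slope_coef": cfg.recurrence_model.positive_slope_coef,
    }
    truth.attrs["true_group_slope_means"] = tuple(cfg.true_group_slope_means)
    truth.attrs["slope_sd"] = cfg.slope_sd
    return records, series, truth


def generate_records(cfg: SyntheticCohortConfig):
    """Generate (PatientRecord list, {patient_id: PsaSeries}) in memory."""
    records, series, _ = _simulate(cfg)
    return records, series


def generate_cohort(cfg: SyntheticCohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the patient and trajectory tables as DataFrames.

    The layouts match what :func:`psadose.io.read_patient_table` and
    :func:`psadose.io.read_psa_trajectories` accept unchanged.
    """
    records, series, _ = _simulate(cfg)
    patients = records_to_frame(records)
    rows = []
    for pid, s in series.items():
        for t, y in zip(s.times, s.psa):
            rows.append({"patient_id": pid, "time_months": t, "psa": y})
    trajectories = pd.DataFrame(rows, columns=["patient_id", "time_months", "psa"])
    return patients, trajectories


def write_cohort(cfg: SyntheticCohortConfig, patients_path, trajectories_path) -> None:
    """Generate a cohort and write both tables as CSV."""
    records, series, _ = _simulate(cfg)
    write_patient_table(records, patients_path)
    write_trajectory_table(series, trajectories_path)


def truth_record(cfg: SyntheticCohortConfig) -> pd.DataFrame:
    """Ground truth for parameter-recovery tests.

    One row per patient (dose group, its true mean response, the patient's
    drawn true slope); the recurrence-model coefficients and per-group true
    means ride along in ``DataFrame.attrs``.
    """
    _, _, truth = _simulate(cfg)
    return truth
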