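"""Synthetic minute-level step-count data with known ground truth.

Generates cohorts with the statistical structure the downstream analysis
assumes: a diurnal per-minute Poisson intensity modulated by weekday and
temperature covariates, additive day-level treatment effects, AR(1)
day-to-day noise, and a missingness mechanism in which non-wear minutes
record a zero step count and an absent heart rate.

Day-level effects are specified on the daily-steps scale and folded into the
minute rates multiplicatively, so conditional on the day the minute counts
stay Poisson while the expected daily total remains exactly additive:

    E[daily total | day i] = base(day i covariates) + treatment effect + AR(1) noise
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from datetime import timedelta
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .design import (
    ACTIVE_TREATMENTS,
    BASELINE,
    MINUTES_PER_DAY,
    USUAL_CARE,
    InvalidDesignError,
    TrialDesign,
)

MINUTE_CSV_COLUMNS = ["participant_id", "date", "minute", "steps", "heart_rate"]
COVARIATE_CSV_COLUMNS = ["date", "temperature_f"]


def default_minute_intensity(total_daily_steps: float = 7000.0) -> np.ndarray:
    """A plausible diurnal steps/minute profile scaled to a given daily total.

    Morning and evening activity peaks, a midday plateau and near-zero
    night-time activity.
    """
    t = np.arange(MINUTES_PER_DAY, dtype=float)
    profile = (
        1.0 * np.exp(-0.5 * ((t - 8.5 * 60) / 90.0) ** 2)
        + 0.6 * np.exp(-0.5 * ((t - 13.0 * 60) / 150.0) ** 2)
        + 0.9 * np.exp(-0.5 * ((t - 18.0 * 60) / 110.0) ** 2)
    )
    profile += 0.002  # tiny floor so night minutes are rarely-but-possibly active
    profile *= total_daily_steps / profile.sum()
    return profile


def default_wear_probability() -> np.ndarray:
    """Wear probability by minute of day: high during waking hours, lower at night."""
    t = np.arange(MINUTES_PER_DAY, dtype=float)
    night = (t < 6 * 60) | (t >= 23 * 60)
    prob = np.full(MINUTES_PER_DAY, 0.96)
    prob[night] = 0.85
    return prob


@dataclass
class SimulationParams:
    """Knobs of the synthetic data generator.

    ``treatment_daily_effect`` maps active-treatment labels to the expected
    change in *daily total steps* relative to usual care; ``ar1_rho`` /
    ``daily_sd`` parameterize a stationary AR(1) day-level disturbance on the
    same scale.
    """

    minute_intensity: np.ndarray = field(default_factory=default_minute_intensity)
    weekday_log_effect: float = 0.05
    temp_log_effect: float = 0.004
    treatment_daily_effect: Dict[str, float] = field(
        default_factory=lambda: {"YOGA": 0.0, "MASSAGE": 0.0}
    )
    ar1_rho: float = 0.3
    daily_sd: float = 1000.0
    wear_prob_profile: np.ndarray = field(default_factory=default_wear_probability)
    carry_prob: float = 0.05
    temp_mean: float = 60.0
    temp_sd: float = 10.0
    start_date: _date = _date(2020, 1, 6)  # a Monday

    def __post_init__(self) -> None:
        self.minute_intensity = np.asarray(self.minute_intensity, dtype=float)
        self.wear_prob_profile = np.asarray(self.wear_prob_profile, dtype=float)
        if self.minute_intensity.shape != (MINUTES_PER_DAY,):
            raise ValueError(f"minute_intensity must have length {MINUTES_PER_DAY}")
        if np.any(self.minute_intensity < 0):
            raise ValueError("minute_intensity must be non-negative")
        if self.wear_prob_profile.shape != (MINUTES_PER_DAY,):
            raise ValueError(f"wear_prob_profile must have length {MINUTES_PER_DAY}")
        if np.any((self.wear_prob_profile < 0) | (self.wear_prob_profile > 1)):
            raise ValueError("wear probabilities must lie in [0, 1]")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in (-1, 1)")
        if self.daily_sd < 0:
            raise ValueError("daily_sd must be non-negative")
        if not 0.0 <= self.carry_prob <= 1.0:
            raise ValueError("carry_prob must lie in [0, 1]")
        unknown = set(self.treatment_daily_effect) - set(ACTIVE_TREATMENTS)
        if unknown:
            raise ValueError(f"treatment_daily_effect has unknown labels: {sorted(unknown)}")
        if isinstance(self.start_date, str):
            self.start_date = _date.fromisoformat(self.start_date)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must not see."""

    participant_id: str
    sequence_index: int
    treatment_daily_effect: Dict[str, float]
    ar1_rho: float
    daily_sd: float
    day_labels: list
    wear: np.ndarray  # (n_days, 1440) bool, True = worn
    true_counts: np.ndarray  # (n_days, 1440) pre-missingness counts
    weekday: np.ndarray  # (n_days,) 0/1
    temperature_f: np.ndarray  # (n_days,)
    expected_daily_total: np.ndarray  # (n_days,) conditional Poisson mean

    @property
    def true_daily_totals(self) -> np.ndarray:
        return self.true_counts.sum(axis=1)


def assign_sequences(
    n_participants: int, design: TrialDesign, seed: int
) -> np.ndarray:
    """Block-randomize participants between the two sequences.

    Uses permuted blocks of size ``sum(randomization_ratio)``, so counts per
    sequence differ by at most the within-block imbalance (at most 1 for a
    1:1 ratio). Deterministic given ``seed``.

    Returns an array of sequence indices (0 or 1), one per participant.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    a, b = design.randomization_ratio
    if a <= 0 or b <= 0:
        raise InvalidDesignError("randomization_ratio entries must be positive")
    rng = np.random.default_rng(seed)
    block = np.array([0] * a + [1] * b)
    n_blocks = -(-n_participants // block.size)
    out = np.concatenate([rng.permutation(block) for _ in range(n_blocks)])
    return out[:n_participants]


def _day_covariates(params: SimulationParams, n_days: int, rng: np.random.Generator):
    dates = np.array(
        [params.start_date + timedelta(days=int(i)) for i in range(n_days)]
    )
    weekday = np.array([1 if d.weekday() < 5 else 0 for d in dates], dtype=int)
    temperature = rng.normal(params.temp_mean, params.temp_sd, size=n_days)
    return dates, weekday, temperature


def _ar1_path(rho: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) path with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + rng.normal(0.0, innov_sd)
    return e


def _daily_means(
    params: SimulationParams,
    labels: Iterable[str],
    weekday: np.ndarray,
    temperature: np.ndarray,
    ar1: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-day covariate multiplier and expected daily total (clamped at 0)."""
    cov_mult = np.exp(
        params.weekday_log_effect * weekday
        + params.temp_log_effect * (temperature - params.temp_mean)
    )
    base_total = params.minute_intensity.sum() * cov_mult
    effects = np.array(
        [params.treatment_daily_effect.get(lbl, 0.0) for lbl in labels]
    )
    expected = np.maximum(base_total + effects + ar1, 0.0)
    return cov_mult, expected


def generate_participant(
    params: SimulationParams,
    design: TrialDesign,
    sequence_index: int,
    seed: int,
    participant_id: str = "P001",
    covariates: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one participant's pre-missingness minute records.

    Returns ``(minutes, covariates, truth)`` where ``minutes`` has one row
    per (day, minute) with the *true* step count and true wear status, and
    ``covariates`` is the day-level table (date, temperature).
    ``apply_missingness`` turns ``minutes`` into what a device would record.
    Pass a shared ``covariates`` table (columns ``date, temperature_f``) to
    give every cohort member the same weather.
    """
    rng = np.random.default_rng(seed)
    n_days = design.n_days
    labels = design.day_labels(sequence_index)
    if covariates is not None:
        if len(covariates) != n_days:
            raise ValueError("covariates must have one row per trial day")
        dates = np.asarray(covariates["date"])
        temperature = covariates["temperature_f"].to_numpy(dtype=float)
        weekday = np.array(
            [1 if pd.Timestamp(d).weekday() < 5 else 0 for d in dates], dtype=int
        )
    else:
        dates, weekday, temperature = _day_covariates(params, n_days, rng)
    ar1 = _ar1_path(params.ar1_rho, params.daily_sd, n_days, rng)
    cov_mult, expected = _daily_means(params, labels, weekday, temperature, ar1)

    base_total = params.minute_intensity.sum() * cov_mult
    # Minute rates: diurnal shape x covariate multiplier, rescaled so the
    # day's expected total hits the additive target exactly.
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(base_total > 0, expected / base_total, 0.0)
    rates = params.minute_intensity[None, :] * (cov_mult * scale)[:, None]
    true_counts = rng.poisson(rates)
    wear = rng.random((n_days, MINUTES_PER_DAY)) < params.wear_prob_profile[None, :]

    minutes = pd.DataFrame(
        {
            "participant_id": participant_id,
            "date": np.repeat(dates, MINUTES_PER_DAY),
            "day_index": np.repeat(np.arange(n_days), MINUTES_PER_DAY),
            "minute": np.tile(np.arange(MINUTES_PER_DAY), n_days),
            "steps": true_counts.ravel(),
            "wear": wear.ravel(),
        }
    )
    covariates = pd.DataFrame({"date": dates, "temperature_f": temperature})
    truth = GroundTruth(
        participant_id=participant_id,
        sequence_index=sequence_index,
        treatment_daily_effect=dict(params.treatment_daily_effect),
        ar1_rho=params.ar1_rho,
        daily_sd=params.daily_sd,
        day_labels=labels,
        wear=wear,
        true_counts=true_counts,
        weekday=weekday,
        temperature_f=temperature,
        expected_daily_total=expected,
    )
    return minutes, covariates, truth


def apply_missingness(
    minutes: pd.DataFrame, params: SimulationParams, seed: int
) -> pd.DataFrame:
    """Degrade true records into device records.

    Worn minutes keep their step count and gain a heart-rate reading.
    Non-wear minutes lose the heart rate; with probability ``carry_prob``
    the device was carried and the step count survives, otherwise the count
    is recorded as 0.
    """
    if "wear" not in minutes.columns:
        raise ValueError("records must carry true wear status (wear column)")
    rng = np.random.default_rng(seed)
    n = len(minutes)
    wear = minutes["wear"].to_numpy()
    carried = (~wear) & (rng.random(n) < params.carry_prob)
    steps = np.where(wear | carried, minutes["steps"].to_numpy(), 0)
    heart_rate = np.where(wear, rng.integers(55, 120, size=n), -1)
    out = minutes.drop(columns=["wear"]).copy()
    out["steps"] = steps
    out["heart_rate"] = pd.array(
        np.where(wear, heart_rate, np.iinfo(np.int64).min), dtype="Int64"
    )
    out.loc[~wear, "heart_rate"] = pd.NA
    return out


def generate_daily_series(
    params: SimulationParams,
    design: TrialDesign,
    sequence_index: int,
    seed: int,
    participant_id: str = "P001",
) -> pd.DataFrame:
    """Simulate daily step totals directly, skipping the minute level.

    A sum of independent Poisson minute counts is Poisson with the summed
    rate, so drawing the daily total from ``Poisson(expected daily total)``
    is distributionally identical to summing a full generated day. Useful
    for large replicate studies of the day-level analysis.
    """
    rng = np.random.default_rng(seed)
    n_days = design.n_days
    labels = design.day_labels(sequence_index)
    dates, weekday, temperature = _day_covariates(params, n_days, rng)
    ar1 = _ar1_path(params.ar1_rho, params.daily_sd, n_days, rng)
    _, expected = _daily_means(params, labels, weekday, temperature, ar1)
    totals = rng.poisson(expected)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "day_index": np.arange(n_days),
            "date": dates,
            "block": labels,
            "total_steps": totals.astype(float),
            "fraction_imputed": 0.0,
            "weekday": weekday,
            "temperature_f": temperature,
        }
    )


def simulate_cohort(
    n_participants: int,
    params: SimulationParams,
    design: TrialDesign,
    seed: int,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, GroundTruth], np.ndarray]:
    """Generate a full cohort of observed device records.

    Returns ``(minutes, covariates, truths, sequence_indices)`` with
    missingness applied; ``minutes`` concatenates all participants.
    """
    seq = assign_sequences(n_participants, design, seed)
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=(n_participants, 2))
    dates, _, temperature = _day_covariates(params, design.n_days, rng)
    covariates = pd.DataFrame({"date": dates, "temperature_f": temperature})
    frames = []
    truths: Dict[str, GroundTruth] = {}
    for i in range(n_participants):
        pid = f"P{i + 1:03d}"
        minutes, _, truth = generate_participant(
            params,
            design,
            int(seq[i]),
            int(child_seeds[i, 0]),
            participant_id=pid,
            covariates=covariates,
        )
        observed = apply_missingness(minutes, params, int(child_seeds[i, 1]))
        frames.append(observed)
        truths[pid] = truth
    all_minutes = pd.concat(frames, ignore_index=True)
    return all_minutes, covariates, truths, seq


def write_minute_csv(minutes: pd.DataFrame, path) -> None:
    """Write device records in the minute CSV dialect.

    Columns ``participant_id,date,minute,steps,heart_rate``; an absent heart
    rate serializes as an empty field. Round-trips losslessly with
    :func:`nof1steps.ingest.read_minute_csv`.
    """
    out = minutes.loc[:, ["participant_id", "date", "minute", "steps", "heart_rate"]]
    out.to_csv(path, index=False, date_format="%Y-%m-%d")


def write_covariate_csv(covariates: pd.DataFrame, path) -> None:
    """Write the day-level covariate table (``date,temperature_f``)."""
    out = covariates.loc[:, COVARIATE_CSV_COLUMNS]
    out.to_csv(path, index=False, date_format="%Y-%m-%d")
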