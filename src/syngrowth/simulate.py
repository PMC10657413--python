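"""Seeded synthetic syngeneic-cohort generator with known ground truth.

Emulates the design of a subcutaneous-allograft efficacy study: animals
are enrolled when tumors reach ~30 mm^3 mean volume, randomized to arms
on Day 0, and measured three times weekly (days 0, 2, 4, then +7 per
week) until study end or humane removal.  Each animal grows
exponentially at its own latent rate, drawn around the arm mean with
between-animal heterogeneity; measurement noise is multiplicative
lognormal on volumes (additive Gaussian on the log scale, so the
log-linear fitting model is correctly specified under the default
generator; an additive-Gaussian misspecification scenario is available
via ``noise_model="additive"``).  Complete responders switch to a
negative regression rate at an onset day, producing decaying series
that hit the detection floor and record 0 (no palpable tumor).  Humane
removal keys on the latent, noise-free volume so dropout is
reproducible and independent of the noise draw on the removal day.

Identical (seed, config) pairs yield byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .efficacy import complete_responders, growth_rate_inhibition, synergy_score
from .errors import DegenerateInputError, InsufficientDataError, ValidationError
from .growth import fit_study, summarize_study
from .io import MeasurementTable

NULL_ARM_LABELS = ("control", "A", "B", "AB")


def thrice_weekly_schedule(end_day: int, start_day: int = 0) -> tuple[int, ...]:
    """Mon/Wed/Fri-like measurement days: offsets 0, 2, 4 each week."""
    days = [
        week * 7 + off
        for week in range(end_day // 7 + 1)
        for off in (0, 2, 4)
    ]
    return tuple(d for d in days if start_day <= d <= end_day)


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm of a synthetic study."""

    label: str
    n: int = 10
    rate: float = 0.30  # true mean exponential growth rate, per day
    rate_sd: float = 0.05  # between-animal SD of the rate, per day
    p_cr: float = 0.0  # probability an animal is a complete responder
    cr_regression_rate: float = -0.25  # per day, applied after onset
    cr_onset_day: float = 7.0
    weight_slope: float = 0.0  # g per day, for body-weight-loss scenarios


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic cohort.

    Defaults mirror the emulated study design: enrollment at a mean
    tumor volume of 30 mm^3, thrice-weekly calipering from Day 0, a
    1200 mm^3 surrogate-mortality endpoint and humane removal at
    2000 mm^3, with ~10% multiplicative measurement noise.
    """

    seed: int = 0
    arms: tuple[ArmSpec, ...] = ()
    baseline_mtv: float = 30.0  # mm^3, mean enrollment volume
    baseline_cv: float = 0.25  # CV of starting volumes
    noise_sd: float = 0.10  # SD of log-scale measurement noise
    noise_model: Literal["lognormal", "additive"] = "lognormal"
    schedule: tuple[int, ...] | None = None  # None -> thrice weekly
    study_end_day: int = 16
    endpoint_volume: float = 1200.0
    humane_removal_volume: float = 2000.0
    detection_floor: float = 1.0  # mm^3; observed volumes below record 0
    baseline_weight: float = 20.0  # g

    def resolved_schedule(self) -> tuple[int, ...]:
        if self.schedule is not None:
            return tuple(self.schedule)
        return thrice_weekly_schedule(self.study_end_day)

    def validate(self) -> None:
        """Raise ValidationError enumerating every violated constraint."""
        problems: list[str] = []
        if not self.arms:
            problems.append("at least one arm required")
        labels = [a.label for a in self.arms]
        if len(set(labels)) != len(labels):
            problems.append(f"duplicate arm labels: {labels}")
        for a in self.arms:
            if a.n < 2:
                problems.append(f"arm {a.label!r}: n must be >= 2, got {a.n}")
            if not 0.0 <= a.p_cr <= 1.0:
                problems.append(f"arm {a.label!r}: p_cr must be in [0, 1], got {a.p_cr}")
            if a.rate_sd < 0:
                problems.append(f"arm {a.label!r}: rate_sd must be >= 0")
            if not math.isfinite(a.rate):
                problems.append(f"arm {a.label!r}: rate must be finite")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if self.baseline_mtv <= 0:
            problems.append("baseline_mtv must be > 0")
        if self.baseline_cv < 0:
            problems.append("baseline_cv must be >= 0")
        if self.endpoint_volume > self.humane_removal_volume:
            problems.append(
                "endpoint_volume must be <= humane_removal_volume "
                f"({self.endpoint_volume} > {self.humane_removal_volume})"
            )
        if self.detection_floor < 0:
            problems.append("detection_floor must be >= 0")
        sched = self.resolved_schedule()
        if not sched or sched[0] != 0 or any(np.diff(sched) <= 0):
            problems.append("schedule must start at day 0 and strictly increase")
        if problems:
            raise ValidationError("invalid SimConfig:\n  " + "\n  ".join(problems))


@dataclass(frozen=True)
class SimulatedStudy:
    """A generated cohort plus its per-animal ground truth."""

    table: MeasurementTable
    truth: pd.DataFrame  # animal_id, group, true_rate, is_cr, removal_day
    config: SimConfig

    def true_arm_rates(self) -> dict[str, float]:
        """Configured (not sampled) mean growth rate per arm."""
        return {a.label: a.rate for a in self.config.arms}


def _latent_volume(
    t: np.ndarray, v0: float, rate: float, is_cr: bool, cr_rate: float, onset: float
) -> np.ndarray:
    log_v = math.log(v0) + rate * np.minimum(t, onset if is_cr else np.inf)
    if is_cr:
        log_v = log_v + cr_rate * np.maximum(t - onset, 0.0)
    return np.exp(log_v)


def simulate_cohort(config: SimConfig) -> SimulatedStudy:
    """Generate one synthetic study from a validated config.

    Per animal: starting volume V0 ~ lognormal with mean ``baseline_mtv``
    and CV ``baseline_cv``; latent rate ~ Normal(arm mean, arm SD);
    responders (probability ``p_cr``) switch to the regression rate at
    the onset day.  Observed volumes are latent x lognormal(0,
    ``noise_sd``) (or latent + Gaussian under the additive
    misspecification scenario), recorded as 0 below the detection floor.
    Rows follow the schedule through the first day the latent volume
    reaches the humane-removal threshold (that day's measurement is
    taken, then the animal is removed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    schedule = np.asarray(config.resolved_schedule(), dtype=float)
    sigma0 = math.sqrt(math.log(1.0 + config.baseline_cv**2))
    mu0 = math.log(config.baseline_mtv) - 0.5 * sigma0**2

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for arm in config.arms:
        for i in range(arm.n):
            animal = f"{arm.label}-{i + 1:02d}"
            v0 = float(rng.lognormal(mu0, sigma0))
            rate = float(rng.normal(arm.rate, arm.rate_sd))
            is_cr = bool(rng.random() < arm.p_cr)
            latent = _latent_volume(
                schedule, v0, rate, is_cr, arm.cr_regression_rate, arm.cr_onset_day
            )
            if config.noise_model == "lognormal":
                noise = rng.lognormal(0.0, config.noise_sd, size=latent.size)
                observed = latent * noise
            else:
                observed = latent + rng.normal(
                    0.0, config.noise_sd * latent.mean(), size=latent.size
                )
                observed = np.maximum(observed, 0.0)
            observed = np.where(observed < config.detection_floor, 0.0, observed)
            removal_idx = np.flatnonzero(latent >= config.humane_removal_volume)
            last = int(removal_idx[0]) if removal_idx.size else latent.size - 1
            removal_day = float(schedule[last]) if removal_idx.size else math.nan
            weight = config.baseline_weight + arm.weight_slope * schedule
            for k in range(last + 1):
                rows.append(
                    {
                        "animal_id": animal,
                        "group": arm.label,
                        "day": int(schedule[k]),
                        "volume": float(observed[k]),
                        "body_weight": float(weight[k]),
                    }
                )
            truth_rows.append(
                {
                    "animal_id": animal,
                    "group": arm.label,
                    "true_rate": rate,
                    "is_cr": is_cr,
                    "removal_day": removal_day,
                    "v0": v0,
                }
            )
    table = MeasurementTable.from_dataframe(
        pd.DataFrame(rows), metadata={"simulated": True, "seed": config.seed}
    )
    return SimulatedStudy(table=table, truth=pd.DataFrame(truth_rows), config=config)


def simulate_additive_null(config: SimConfig) -> SimulatedStudy:
    """Four-arm study whose true synergy score is exactly 0.

    Requires arms labeled ``control, A, B, AB``; the AB arm's true mean
    rate is overridden to ``rate_A + rate_B - rate_control`` before
    sampling, making the interaction contrast zero by construction.
    """
    labels = tuple(a.label for a in config.arms)
    if sorted(labels) != sorted(NULL_ARM_LABELS):
        raise ValidationError(
            f"additive-null design needs arms {NULL_ARM_LABELS}, got {labels}"
        )
    by_label = {a.label: a for a in config.arms}
    ab_rate = by_label["A"].rate + by_label["B"].rate - by_label["control"].rate
    arms = tuple(
        replace(a, rate=ab_rate) if a.label == "AB" else a for a in config.arms
    )
    return simulate_cohort(replace(config, arms=arms))


def four_arm_config(
    seed: int = 0,
    n: int = 10,
    rate_control: float = 0.30,
    rate_a: float = 0.20,
    rate_b: float = 0.22,
    rate_ab: float | None = None,
    **kwargs,
) -> SimConfig:
    """Convenience constructor for a control/A/B/AB factorial design.

    ``rate_ab=None`` leaves the combination at the additive prediction
    ``rate_a + rate_b - rate_control``.
    """
    if rate_ab is None:
        rate_ab = rate_a + rate_b - rate_control
    arm_kwargs = {k: kwargs.pop(k) for k in ("rate_sd",) if k in kwargs}
    arms = (
        ArmSpec("control", n=n, rate=rate_control, **arm_kwargs),
        ArmSpec("A", n=n, rate=rate_a, **arm_kwargs),
        ArmSpec("B", n=n, rate=rate_b, **arm_kwargs),
        ArmSpec("AB", n=n, rate=rate_ab, **arm_kwargs),
    )
    return SimConfig(seed=seed, arms=arms, **kwargs)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo operating characteristics of the analysis pipeline."""

    n_reps: int
    alpha: float
    rejection_rate: float | None  # synergy test; None if not a 4-arm design
    rejection_mc_se: float | None
    rate_bias: dict[str, float]  # per arm, mean(est - true)
    rate_rmse: dict[str, float]
    rate_mc_se: dict[str, float]
    gri_bias: dict[str, float]  # per non-reference arm
    gri_mean: dict[str, float]
    gri_true: dict[str, float]
    gri_mc_se: dict[str, float]
    cr_count_mean: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm in self.rate_bias:
            rows.append(
                {
                    "group": arm,
                    "rate_bias": self.rate_bias[arm],
                    "rate_rmse": self.rate_rmse[arm],
                    "rate_mc_se": self.rate_mc_se[arm],
                    "gri_true": self.gri_true.get(arm),
                    "gri_mean": self.gri_mean.get(arm),
                    "gri_bias": self.gri_bias.get(arm),
                    "gri_mc_se": self.gri_mc_se.get(arm),
                    "cr_count_mean": self.cr_count_mean[arm],
                }
            )
        return pd.DataFrame(rows)


def run_operating_characteristics(
    config: SimConfig,
    n_reps: int,
    alpha: float = 0.05,
    additive_null: bool = False,
    floor: float = 1.0,
) -> OperatingCharacteristics:
    """Replicate the full pipeline (simulate -> fit -> GRI/synergy) and
    summarize estimator quality and test behavior against ground truth.

    Per replicate: per-arm mean-rate estimation error, GRI of each
    non-reference arm vs the reference (the arm labeled ``control``, or
    the first arm), synergy-test rejection when the design is the
    control/A/B/AB factorial, and CR counts.  Monte-Carlo SEs accompany
    every rate.  ``n_reps`` below 100 is refused — smaller runs say
    nothing about operating characteristics.
    """
    if n_reps < 100:
        raise ValidationError(f"n_reps must be >= 100, got {n_reps}")
    config.validate()
    labels = [a.label for a in config.arms]
    ref = "control" if "control" in labels else labels[0]
    is_factorial = sorted(labels) == sorted(NULL_ARM_LABELS)

    true_rates = {a.label: a.rate for a in config.arms}
    if additive_null and is_factorial:
        true_rates["AB"] = (
            true_rates["A"] + true_rates["B"] - true_rates["control"]
        )
    true_gri = {
        g: 100.0 * (true_rates[ref] - true_rates[g]) / true_rates[ref]
        for g in labels
        if g != ref
    }

    child_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(config.seed).spawn(n_reps)
    ]
    rate_err: dict[str, list[float]] = {g: [] for g in labels}
    gri_est: dict[str, list[float]] = {g: [] for g in true_gri}
    cr_counts: dict[str, list[int]] = {g: [] for g in labels}
    rejections: list[bool] = []
    for s in child_seeds:
        cfg = replace(config, seed=s)
        study = (
            simulate_additive_null(cfg) if additive_null and is_factorial else simulate_cohort(cfg)
        )
        fits = fit_study(study.table, floor=floor)
        summaries = summarize_study(fits)
        if set(summaries) != set(labels):  # an arm lost too many animals
            continue
        for g in labels:
            rate_err[g].append(summaries[g].mean_rate - true_rates[g])
        for g in true_gri:
            gri_est[g].append(
                growth_rate_inhibition(summaries[g], summaries[ref]).gri_percent
            )
        if is_factorial:
            syn = synergy_score(
                summaries["AB"],
                summaries["A"],
                summaries["B"],
                summaries["control"],
                alpha=alpha,
            )
            rejections.append(syn.p_value < alpha)
        crs = complete_responders(study.table)
        for g in labels:
            cr_counts[g].append(crs[g].cr_count if g in crs else 0)

    def _mc_se(x: Sequence[float]) -> float:
        a = np.asarray(x, dtype=float)
        return float(a.std(ddof=1) / math.sqrt(a.size)) if a.size > 1 else math.nan

    rej_rate = rej_se = None
    if rejections:
        rej = np.asarray(rejections, dtype=float)
        rej_rate = float(rej.mean())
        rej_se = float(math.sqrt(rej_rate * (1 - rej_rate) / rej.size))
    return OperatingCharacteristics(
        n_reps=n_reps,
        alpha=alpha,
        rejection_rate=rej_rate,
        rejection_mc_se=rej_se,
        rate_bias={g: float(np.mean(v)) for g, v in rate_err.items()},
        rate_rmse={g: float(np.sqrt(np.mean(np.square(v)))) for g, v in rate_err.items()},
        rate_mc_se={g: _mc_se(v) for g, v in rate_err.items()},
        gri_bias={g: float(np.mean(v) - true_gri[g]) for g, v in gri_est.items()},
        gri_mean={g: float(np.mean(v)) for g, v in gri_est.items()},
        gri_true=dict(true_gri),
        gri_mc_se={g: _mc_se(v) for g, v in gri_est.items()},
        cr_count_mean={g: float(np.mean(v)) for g, v in cr_counts.items()},
    )
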