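"""Growth-rate inhibition, combination synergy, T/C, body-weight-loss and
complete-responder statistics.

The central quantities, all built on arm-mean exponential growth rates
(see :mod:`syngrowth.growth`):

* **GRI** (growth-rate inhibition), in percent::

      GRI = 100 * (mu_control - mu_treatment) / mu_vehicle

  Positive GRI means the treated tumors grew at a reduced rate.  The
  accompanying p-value is a two-sided Welch two-sample t-test on the
  per-animal rates (the comparison object is the arms' mean growth rates,
  with no equal-variance assumption).

* **Synergy score** for a four-arm factorial design (control, drug A,
  drug B, combination AB), in percent::

      score = (mu_AB - mu_A - mu_B + mu_control) / mu_V * 100

  Under rate additivity on the log-volume scale the interaction contrast
  ``mu_AB - mu_A - mu_B + mu_control`` is zero, so a significantly
  negative score is synergy (the combination grows slower than additivity
  predicts).  The score's standard error combines the four group SEs in
  quadrature, scaled by ``100 / |mu_V|`` (the vehicle mean is treated as
  a fixed normalizer by default); the effective degrees of freedom come
  from the Welch-Satterthwaite equation over the four groups; ``t =
  score / se`` is referred to a two-tailed t distribution.

Classification at level alpha (default 0.05): non-significant -> additive;
significant and negative -> synergistic; significant and positive ->
sub-additive if the combination still beats the best single agent
(lower mean rate), antagonistic otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, ValidationError
from .growth import GroupGrowthSummary
from .io import MeasurementTable

CombinationLabel = Literal["synergistic", "additive", "sub-additive", "antagonistic"]


@dataclass(frozen=True)
class GriResult:
    gri_percent: float
    treatment: str
    control: str
    vehicle: str
    p_value: float
    test_df: float
    day_window: tuple[float, float] | None = None


@dataclass(frozen=True)
class SynergyResult:
    score_percent: float
    se: float
    df: float
    t_stat: float
    p_value: float
    label: CombinationLabel
    arms: Mapping[str, str]  # keys: ab, a, b, control, vehicle


@dataclass(frozen=True)
class BwlSummary:
    group: str
    mean_bwl_percent_by_day: Mapping[int, float]  # mean % change vs Day 0
    max_mean_bwl_percent: float  # loss magnitude, >= 0
    max_day: int


@dataclass(frozen=True)
class CrSummary:
    group: str
    n: int
    cr_count: int
    cr_animals: tuple[str, ...]


# ----------------------------------------------------------------------- GRI

def gri_test(
    treatment: GroupGrowthSummary, control: GroupGrowthSummary
) -> tuple[float, float]:
    """Two-sided Welch t-test on the per-animal growth rates.

    Returns ``(p_value, welch_df)``.  A significant p indicates the two
    arms' growth trends over time differ.
    """
    for g in (treatment, control):
        if g.n < 2:
            raise InsufficientDataError(
                f"group {g.group!r}: Welch test needs n >= 2, got {g.n}"
            )
    import warnings

    with warnings.catch_warnings():
        # noiseless arms have (near-)identical rates; the moment
        # computation's precision warning is expected there
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        res = stats.ttest_ind(treatment.rates, control.rates, equal_var=False)
    p = float(res.pvalue)
    if math.isnan(p):  # both arms zero-variance and equal means
        p = 1.0
    return p, float(res.df)


def growth_rate_inhibition(
    treatment: GroupGrowthSummary,
    control: GroupGrowthSummary,
    vehicle: GroupGrowthSummary | None = None,
    day_window: tuple[float, float] | None = None,
) -> GriResult:
    """Growth-rate inhibition of ``treatment`` relative to ``control``,
    normalized by the vehicle arm's mean rate.

    ``vehicle`` defaults to ``control`` (the usual design, where the
    reference arm is the vehicle arm).  Raises
    :class:`DegenerateInputError` when the vehicle mean rate is 0.
    """
    if vehicle is None:
        vehicle = control
    if vehicle.mean_rate == 0:
        raise DegenerateInputError(
            f"vehicle arm {vehicle.group!r} has mean growth rate 0; GRI undefined"
        )
    gri = 100.0 * (control.mean_rate - treatment.mean_rate) / vehicle.mean_rate
    p, df = gri_test(treatment, control)
    return GriResult(
        gri_percent=float(gri),
        treatment=treatment.group,
        control=control.group,
        vehicle=vehicle.group,
        p_value=p,
        test_df=df,
        day_window=day_window,
    )


# ------------------------------------------------------------------- synergy

def welch_satterthwaite_df(ses: np.ndarray, ns: np.ndarray) -> float:
    """Effective df of a linear combination of independent sample means.

    ``(sum se_i^2)^2 / sum(se_i^4 / (n_i - 1))`` — the Welch-Satterthwaite
    approximation with each mean's squared SE as its variance component.
    """
    ses = np.asarray(ses, dtype=float)
    ns = np.asarray(ns, dtype=float)
    num = float(np.sum(ses**2)) ** 2
    den = float(np.sum(ses**4 / (ns - 1)))
    if den == 0.0:
        raise DegenerateInputError(
            "all group standard errors are 0; degrees of freedom undefined"
        )
    return num / den


def synergy_score_value(
    mu_ab: float, mu_a: float, mu_b: float, mu_control: float, mu_v: float
) -> float:
    """The bare synergy score, in percent:
    ``(mu_AB - mu_A - mu_B + mu_control) / mu_V * 100``."""
    if mu_v == 0:
        raise DegenerateInputError("vehicle mean growth rate 0; score undefined")
    return 100.0 * (mu_ab - mu_a - mu_b + mu_control) / mu_v


def synergy_score(
    ab: GroupGrowthSummary,
    a: GroupGrowthSummary,
    b: GroupGrowthSummary,
    control: GroupGrowthSummary,
    vehicle: GroupGrowthSummary | None = None,
    alpha: float = 0.05,
    vehicle_error_term: bool = False,
) -> SynergyResult:
    """Four-group growth-rate synergy score with SE, Welch df and t-test.

    Parameters
    ----------
    ab, a, b, control
        Arm summaries for the combination, the two single agents, and the
        control arm (each n >= 2).
    vehicle
        Normalizer arm; defaults to ``control``.
    alpha
        Significance level used for the classification label.
    vehicle_error_term
        If True, add the delta-method variance contribution of the vehicle
        mean to the SE (first-order ratio expansion).  Off by default: the
        vehicle normalizer is treated as fixed, matching a
        Welch-Satterthwaite df computed over the four groups only.

    Raises
    ------
    DegenerateInputError
        Vehicle mean rate 0, or all four group SEs simultaneously 0
        (the t statistic is undefined).
    """
    if vehicle is None:
        vehicle = control
    groups = (ab, a, b, control)
    for g in groups:
        if g.n < 2:
            raise InsufficientDataError(
                f"group {g.group!r}: synergy score needs n >= 2 per arm, got {g.n}"
            )
    mu_v = vehicle.mean_rate
    if mu_v == 0:
        raise DegenerateInputError(
            f"vehicle arm {vehicle.group!r} has mean growth rate 0; score undefined"
        )
    contrast = ab.mean_rate - a.mean_rate - b.mean_rate + control.mean_rate
    score = synergy_score_value(
        ab.mean_rate, a.mean_rate, b.mean_rate, control.mean_rate, mu_v
    )
    ses = np.array([g.se for g in groups])
    ns = np.array([g.n for g in groups])
    var = float(np.sum(ses**2)) / mu_v**2
    if vehicle_error_term:
        var += (contrast * vehicle.se / mu_v**2) ** 2
    se = 100.0 * math.sqrt(var)
    if se == 0.0:
        raise DegenerateInputError(
            "all four group standard errors are 0; t statistic undefined"
        )
    df = welch_satterthwaite_df(ses, ns)
    t = score / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    result = SynergyResult(
        score_percent=float(score),
        se=float(se),
        df=float(df),
        t_stat=float(t),
        p_value=p,
        label="additive",  # provisional; final label set below
        arms={
            "ab": ab.group,
            "a": a.group,
            "b": b.group,
            "control": control.group,
            "vehicle": vehicle.group,
        },
    )
    return replace(result, label=classify_combination(result, ab, a, b, alpha=alpha))


def classify_combination(
    syn: SynergyResult,
    ab: GroupGrowthSummary,
    a: GroupGrowthSummary,
    b: GroupGrowthSummary,
    alpha: float = 0.05,
) -> CombinationLabel:
    """Label a combination from its synergy score and significance.

    additive if p >= alpha; synergistic if significant and score < 0;
    for a significant positive score, sub-additive when the combination
    still has the lowest mean growth rate of the three treated arms,
    antagonistic otherwise.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if syn.p_value >= alpha:
        return "additive"
    if syn.score_percent < 0:
        return "synergistic"
    if ab.mean_rate < min(a.mean_rate, b.mean_rate):
        return "sub-additive"
    return "antagonistic"


# --------------------------------------------------------- volume-based aids

def tc_ratio(treatment: pd.DataFrame, control: pd.DataFrame, day: int) -> float:
    """Treated-over-control mean tumor volume at a fixed day, in percent.

    The conventional preclinical T/C: ``100 * mean(V_treatment at day) /
    mean(V_control at day)``.  Both inputs are canonical long-format
    slices (one arm each).
    """
    means = []
    for name, arm in (("treatment", treatment), ("control", control)):
        at_day = arm[(arm["day"] == day) & arm["volume"].notna()]
        if len(at_day) == 0:
            raise ValidationError(f"{name} arm has no volume measurement at day {day}")
        means.append(float(at_day["volume"].mean()))
    t_mean, c_mean = means
    if c_mean == 0:
        raise DegenerateInputError(f"control mean volume at day {day} is 0")
    return 100.0 * t_mean / c_mean


def body_weight_loss(table: MeasurementTable) -> dict[str, BwlSummary]:
    """Per-arm mean percent body-weight change vs pre-dose Day-0 weights.

    For each animal and day, ``100 * (w_d - w_0) / w_0``; per arm and day
    the mean over animals; the maximal mean %BWL is the most negative
    arm-mean change over the study, reported as a positive loss magnitude
    with its day (0 on Day 0 if weights never drop below baseline on
    average).
    """
    df = table.data.dropna(subset=["body_weight"])
    day0 = df[df["day"] == 0].set_index("animal_id")["body_weight"]
    missing = [a for a in table.animals if a not in day0.index]
    if missing:
        raise ValidationError(
            "animal(s) missing a Day-0 body weight: " + ", ".join(missing)
        )
    pct = df.assign(
        bwl=100.0 * (df["body_weight"].to_numpy() - day0.loc[df["animal_id"]].to_numpy())
        / day0.loc[df["animal_id"]].to_numpy()
    )
    out: dict[str, BwlSummary] = {}
    for group, sub in pct.groupby("group", sort=False):
        by_day = sub.groupby("day")["bwl"].mean()
        worst_day = int(by_day.idxmin())
        worst = float(by_day.loc[worst_day])
        out[group] = BwlSummary(
            group=group,
            mean_bwl_percent_by_day={int(d): float(v) for d, v in by_day.items()},
            max_mean_bwl_percent=max(0.0, -worst),
            max_day=worst_day if worst < 0 else 0,
        )
    return out


def complete_responders(
    table: MeasurementTable,
    policy: Literal["zero-sustained", "final-day-zero"] = "zero-sustained",
) -> dict[str, CrSummary]:
    """Count complete responders per arm.

    Default policy ``zero-sustained``: an animal is a CR iff its recorded
    volume is 0 at its final assessment and at every measurement after it
    first reached 0 (no regrowth — "no tumor palpable" through study
    end).  ``final-day-zero`` only requires volume 0 at the last
    assessment.
    """
    if policy not in ("zero-sustained", "final-day-zero"):
        raise ValidationError(f"unknown CR policy: {policy!r}")
    df = table.data  # already sorted by (animal_id, day)
    animal_codes, animal_labels = pd.factorize(df["animal_id"])
    vols = df["volume"].to_numpy(dtype=float)
    group_of = dict(
        zip(df["animal_id"].to_numpy(), df["group"].to_numpy())
    )
    by_arm: dict[str, list[str]] = {}
    crs_by_arm: dict[str, list[str]] = {}
    for code, animal in enumerate(animal_labels):
        animal = str(animal)
        arm = str(group_of[animal])
        by_arm.setdefault(arm, []).append(animal)
        crs_by_arm.setdefault(arm, [])
        v = vols[animal_codes == code]
        v = v[~np.isnan(v)]
        if v.size == 0 or v[-1] != 0:
            continue
        if policy == "final-day-zero":
            crs_by_arm[arm].append(animal)
            continue
        first_zero = int(np.argmax(v == 0))
        if np.all(v[first_zero:] == 0):
            crs_by_arm[arm].append(animal)
    return {
        arm: CrSummary(
            group=arm,
            n=len(animals),
            cr_count=len(crs_by_arm[arm]),
            cr_animals=tuple(crs_by_arm[arm]),
        )
        for arm, animals in by_arm.items()
    }
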