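"""Per-animal exponential tumor-growth fitting and per-arm summaries.

Each animal's volume series V(t) is modeled as simple exponential growth,
``V(t) = V0 * exp(r * t)``, and r is estimated as the ordinary
least-squares slope of ln V against study day.  Volumes are floored at a
small positive value (default 1 mm^3) before the log transform so that
complete responders (recorded volume 0) contribute strongly negative,
finite rates; fits that touched the floor carry ``floored=True`` so
sensitivity analyses can exclude or re-floor them.

A "Day d" analysis window means all measurements with day in [0, d]
(cumulative from randomization), which is the only window consistent with
a single per-animal growth model.

Arm-level summaries carry the arithmetic mean rate, its between-animal
standard error (sample SD of the per-animal rates / sqrt(n)) and df = n-1.
Within-animal fit uncertainty (``rate_se``) is reported per animal but not
propagated into the arm SE: the downstream growth-rate-inhibition and
synergy tests compare arms through the between-animal dispersion of the
rates, treating each animal's fitted rate as that animal's datum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .io import MeasurementTable

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 1.0  # mm^3


@dataclass(frozen=True)
class GrowthFit:
    """OLS fit of ln(volume) vs day for one animal."""

    animal_id: str
    rate: float  # per day
    log_intercept: float  # ln(mm^3) at day 0
    rate_se: float  # per day; 0 when residuals are exactly 0
    n_points: int
    window: tuple[float, float]
    floored: bool
    group: str | None = None


@dataclass(frozen=True)
class GroupGrowthSummary:
    """Arm-level mean growth rate with between-animal SE."""

    group: str
    mean_rate: float  # per day
    se: float
    n: int
    df: int  # n - 1
    rates: tuple[float, ...]

    @classmethod
    def from_rates(cls, group: str, rates: Sequence[float]) -> "GroupGrowthSummary":
        """Summarize a vector of per-animal rates (n >= 2)."""
        r = np.asarray(rates, dtype=float)
        if r.size < 2:
            raise InsufficientDataError(
                f"group {group!r}: need >= 2 per-animal rates, got {r.size}"
            )
        return cls(
            group=group,
            mean_rate=float(r.mean()),
            se=float(r.std(ddof=1) / math.sqrt(r.size)),
            n=int(r.size),
            df=int(r.size - 1),
            rates=tuple(float(x) for x in r),
        )


def _ols_loglinear(days: np.ndarray, logv: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS slope, intercept and slope SE of logv ~ days."""
    n = days.size
    dbar = days.mean()
    sxx = float(np.sum((days - dbar) ** 2))
    if sxx == 0.0:
        raise InsufficientDataError("all measurement days identical; slope undefined")
    slope = float(np.sum((days - dbar) * (logv - logv.mean())) / sxx)
    intercept = float(logv.mean() - slope * dbar)
    resid = logv - (intercept + slope * days)
    ssr = float(np.sum(resid**2))
    if n <= 2 or ssr <= 0.0 or math.isclose(ssr, 0.0, abs_tol=1e-24):
        se = 0.0
    else:
        se = math.sqrt(ssr / (n - 2) / sxx)
    return slope, intercept, se


def fit_animal_growth(
    series: pd.DataFrame,
    window: tuple[float, float] | None = None,
    floor: float = DEFAULT_FLOOR,
) -> GrowthFit:
    """Fit one animal's volume series to the exponential growth model.

    Parameters
    ----------
    series
        Canonical rows for a single animal (columns ``animal_id``, ``day``,
        ``volume``; ``group`` carried through if present).
    window
        Inclusive ``(day_lo, day_hi)`` restriction; ``None`` uses all days.
        "Rate on Day d" corresponds to ``(0, d)``.
    floor
        Positive volume floor (mm^3) applied before the log transform.

    Returns
    -------
    GrowthFit
        ``rate`` is the OLS slope of ln(max(V, floor)) on day, ``rate_se``
        the standard OLS slope SE (0 when the fit is exact).

    Raises
    ------
    ValidationError
        ``floor <= 0``.
    InsufficientDataError
        Fewer than two usable measurements inside the window.
    """
    if floor <= 0:
        raise ValidationError(f"floor must be > 0 mm^3, got {floor}")
    animal = str(series["animal_id"].iloc[0]) if len(series) else "<empty>"
    group = str(series["group"].iloc[0]) if "group" in series.columns and len(series) else None
    all_days = series["day"].to_numpy(dtype=float)
    all_vol = series["volume"].to_numpy(dtype=float)
    return _fit_arrays(all_days, all_vol, animal, group, window, floor)


def _fit_arrays(
    all_days: np.ndarray,
    all_vol: np.ndarray,
    animal: str,
    group: str | None,
    window: tuple[float, float] | None,
    floor: float,
) -> GrowthFit:
    mask = ~np.isnan(all_vol)
    if window is not None:
        lo, hi = float(window[0]), float(window[1])
        mask &= (all_days >= lo) & (all_days <= hi)
    days = all_days[mask]
    vol = all_vol[mask]
    if window is None:
        lo = float(days.min()) if days.size else float("nan")
        hi = float(days.max()) if days.size else float("nan")
    if days.size < 2:
        raise InsufficientDataError(
            f"animal {animal}: {days.size} usable measurement(s) in window "
            f"[{lo}, {hi}]; need >= 2"
        )
    floored = bool(np.any(vol < floor))
    logv = np.log(np.maximum(vol, floor))
    slope, intercept, se = _ols_loglinear(days, logv)
    return GrowthFit(
        animal_id=animal,
        rate=slope,
        log_intercept=intercept,
        rate_se=se,
        n_points=int(days.size),
        window=(float(lo), float(hi)),
        floored=floored,
        group=group,
    )


def fit_study(
    table: MeasurementTable,
    window: tuple[float, float] | None = None,
    floor: float = DEFAULT_FLOOR,
) -> list[GrowthFit]:
    """Fit every animal in the table; skip (with a logged warning) animals
    with fewer than two usable points in the window."""
    fits: list[GrowthFit] = []
    df = table.data
    animal_codes, animal_labels = pd.factorize(df["animal_id"])
    days = df["day"].to_numpy(dtype=float)
    vols = df["volume"].to_numpy(dtype=float)
    groups = df["group"].to_numpy()
    for code, animal in enumerate(animal_labels):
        idx = animal_codes == code
        try:
            fits.append(
                _fit_arrays(
                    days[idx],
                    vols[idx],
                    str(animal),
                    str(groups[idx][0]),
                    window,
                    floor,
                )
            )
        except InsufficientDataError as exc:
            logger.warning("excluding animal %s from growth fits: %s", animal, exc)
    return fits


def summarize_group(fits: Iterable[GrowthFit], group: str) -> GroupGrowthSummary:
    """Arm summary (mean rate, between-animal SE, df = n-1) from fits.

    Fits whose ``group`` attribute is set are filtered to ``group``;
    fits without group information are assumed to belong to it.
    """
    rates = [f.rate for f in fits if f.group in (None, group)]
    return GroupGrowthSummary.from_rates(group, rates)


def summarize_study(fits: Iterable[GrowthFit]) -> dict[str, GroupGrowthSummary]:
    """Per-arm summaries keyed by arm label (arms with < 2 fits are
    dropped with a logged warning)."""
    by_group: dict[str, list[float]] = {}
    for f in fits:
        if f.group is None:
            raise ValidationError(
                f"fit for animal {f.animal_id} carries no group label"
            )
        by_group.setdefault(f.group, []).append(f.rate)
    out: dict[str, GroupGrowthSummary] = {}
    for g, rates in by_group.items():
        if len(rates) < 2:
            logger.warning("arm %s has %d fit(s); excluded from summary", g, len(rates))
            continue
        out[g] = GroupGrowthSummary.from_rates(g, rates)
    return out


def fits_to_frame(fits: Iterable[GrowthFit]) -> pd.DataFrame:
    """Per-animal fits as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "animal_id": f.animal_id,
                "group": f.group,
                "rate": f.rate,
                "rate_se": f.rate_se,
                "log_intercept": f.log_intercept,
                "n_points": f.n_points,
                "day_lo": f.window[0],
                "day_hi": f.window[1],
                "floored": f.floored,
            }
            for f in fits
        ]
    )


def summaries_to_frame(
    summaries: Mapping[str, GroupGrowthSummary]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": s.group,
                "n": s.n,
                "mean_rate": s.mean_rate,
                "se": s.se,
                "df": s.df,
            }
            for s in summaries.values()
        ]
    )
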