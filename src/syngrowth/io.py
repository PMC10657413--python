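"""Reading, validating and writing caliper-measurement tables.

The common currency of every analysis stage is the
:class:`MeasurementTable`: a long-format table with one row per animal per
measurement day carrying tumor length/width (mm) or a precomputed volume
(mm^3) and optionally a body weight (g).  Days are integer days since
randomization (Day 0 = randomization / first dose).  A recorded volume of
exactly 0 is legal and means "no palpable tumor" (the complete-response
convention).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import numbers
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical column names of the long format.
CANONICAL_COLUMNS = (
    "animal_id",
    "group",
    "day",
    "length",
    "width",
    "volume",
    "body_weight",
)

REQUIRED_COLUMNS = ("animal_id", "group", "day")


def caliper_volume(length, width):
    """Tumor volume (mm^3) from caliper length and width (mm).

    Uses the standard prolate-ellipsoid formula ``0.5 * length * width**2``
    with *width* the smaller of the two caliper axes.  If ``width > length``
    the caliper convention is likely swapped; a warning is emitted and the
    volume is computed with the values as given (silent swapping would hide
    data-entry errors).

    Parameters
    ----------
    length, width : float or array-like
        Caliper measurements in mm.  Must be nonnegative.

    Returns
    -------
    float or ndarray
        ``0.5 * length * width**2`` in mm^3.
    """
    length_a = np.asarray(length, dtype=float)
    width_a = np.asarray(width, dtype=float)
    if np.any(length_a < 0) or np.any(width_a < 0):
        raise ValidationError(
            f"caliper dimensions must be nonnegative, got length={length!r} "
            f"width={width!r}"
        )
    swapped = width_a > length_a
    if np.any(swapped):
        warnings.warn(
            "width > length in caliper measurement(s); the caliper "
            "convention may be swapped (computing with values as given)",
            UserWarning,
            stacklevel=2,
        )
    out = 0.5 * length_a * width_a**2
    if np.isscalar(length) and np.isscalar(width):
        return float(out)
    return out


@dataclass(frozen=True)
class Measurement:
    """A single animal-day caliper/weight record."""

    animal_id: str
    group: str
    day: int
    length: float | None = None
    width: float | None = None
    volume: float | None = None
    body_weight: float | None = None


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_table`."""

    code: str
    message: str
    animal_id: str | None = None
    day: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


class MeasurementTable:
    """Validated long-format animal x day measurement records.

    Wraps a :class:`pandas.DataFrame` with the canonical columns
    ``animal_id, group, day, length, width, volume, body_weight``; rows are
    sorted by (animal_id, day).  Construct with :meth:`from_dataframe`,
    :meth:`from_records` or :func:`read_measurements`.
    """

    def __init__(self, data: pd.DataFrame, metadata: Mapping[str, Any] | None = None):
        self._data = data
        self.metadata: dict[str, Any] = dict(metadata or {})

    # ------------------------------------------------------------------ build
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        metadata: Mapping[str, Any] | None = None,
        validate: bool = True,
    ) -> "MeasurementTable":
        """Build a table from a DataFrame already using canonical names.

        Missing optional columns are added as NaN; ``volume`` is derived
        via :func:`caliper_volume` wherever it is absent but length and
        width are present.
        """
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        out = df.copy()
        for col in CANONICAL_COLUMNS:
            if col not in out.columns:
                out[col] = np.nan
        out = out.loc[:, list(CANONICAL_COLUMNS)]
        out["animal_id"] = out["animal_id"].astype(str)
        out["group"] = out["group"].astype(str)
        try:
            day = pd.to_numeric(out["day"])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"non-numeric study day: {exc}") from exc
        if not np.allclose(day, np.round(day), atol=0, rtol=0):
            raise ValidationError("study days must be integers (days since randomization)")
        out["day"] = day.astype(int)
        for col in ("length", "width", "volume", "body_weight"):
            out[col] = pd.to_numeric(out[col], errors="coerce")
        needs_volume = out["volume"].isna() & out["length"].notna() & out["width"].notna()
        if needs_volume.any():
            out.loc[needs_volume, "volume"] = caliper_volume(
                out.loc[needs_volume, "length"].to_numpy(),
                out.loc[needs_volume, "width"].to_numpy(),
            )
        out = out.sort_values(["animal_id", "day"], kind="stable").reset_index(drop=True)
        table = cls(out, metadata)
        if validate:
            violations = validate_table(table)
            if violations:
                raise ValidationError(
                    "invalid measurement table:\n  "
                    + "\n  ".join(str(v) for v in violations)
                )
        return table

    @classmethod
    def from_records(
        cls, records: Iterable[Measurement], metadata: Mapping[str, Any] | None = None
    ) -> "MeasurementTable":
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        if df.empty:
            raise ValidationError("no measurement records supplied")
        return cls.from_dataframe(df, metadata)

    # ------------------------------------------------------------------ views
    def to_dataframe(self) -> pd.DataFrame:
        """A defensive copy of the underlying canonical DataFrame."""
        return self._data.copy()

    @property
    def data(self) -> pd.DataFrame:
        """The underlying DataFrame (do not mutate)."""
        return self._data

    @property
    def arms(self) -> list[str]:
        """Arm labels in first-appearance order."""
        return list(dict.fromkeys(self._data["group"]))

    @property
    def animals(self) -> list[str]:
        return list(dict.fromkeys(self._data["animal_id"]))

    @property
    def n_records(self) -> int:
        return len(self._data)

    def arm_table(self, group: str) -> pd.DataFrame:
        """Rows of one arm (copy)."""
        return self._data[self._data["group"] == group].copy()

    def animal_series(self, animal_id: str) -> pd.DataFrame:
        return self._data[self._data["animal_id"] == str(animal_id)].copy()

    def group_of(self) -> dict[str, str]:
        """animal_id -> arm label."""
        return dict(
            self._data.drop_duplicates("animal_id")[["animal_id", "group"]].itertuples(
                index=False, name=None
            )
        )

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        return self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MeasurementTable({len(self.animals)} animals, "
            f"{len(self.arms)} arms, {self.n_records} records)"
        )


def validate_table(table: MeasurementTable) -> list[Violation]:
    """Check every structural invariant; return the violations found.

    Reported: negative volumes, rows resolving no volume, duplicate or
    non-increasing days within an animal, animals assigned to more than
    one arm.  An empty list means the table is valid.  This never raises.
    (A width exceeding its length is a caliper-convention warning emitted
    at volume computation, not a structural violation.)
    """
    df = table.data
    out: list[Violation] = []
    neg = df[df["volume"] < 0]
    for row in neg.itertuples():
        out.append(
            Violation(
                "negative_volume",
                f"animal {row.animal_id} day {row.day}: volume {row.volume} < 0",
                row.animal_id,
                int(row.day),
            )
        )
    unresolved = df[df["volume"].isna()]
    for row in unresolved.itertuples():
        out.append(
            Violation(
                "missing_volume",
                f"animal {row.animal_id} day {row.day}: no volume and no "
                "length/width pair",
                row.animal_id,
                int(row.day),
            )
        )
    for animal, sub in df.groupby("animal_id", sort=False):
        days = sub["day"].to_numpy()
        if len(days) and np.any(np.diff(days) <= 0):
            dup = sorted(set(days[1:][np.diff(days) <= 0]))
            out.append(
                Violation(
                    "nonincreasing_days",
                    f"animal {animal}: duplicate or non-increasing days {dup}",
                    str(animal),
                )
            )
        groups = sub["group"].unique()
        if len(groups) > 1:
            out.append(
                Violation(
                    "multiple_arms",
                    f"animal {animal} appears in arms {sorted(groups)}",
                    str(animal),
                )
            )
    return out


def read_measurements(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    metadata: Mapping[str, Any] | None = None,
) -> MeasurementTable:
    """Read a long-format measurements CSV into a validated table.

    Parameters
    ----------
    path
        CSV file (UTF-8, comma-separated, header row required); one row
        per animal-day, empty cells for missing numerics.
    schema
        Optional mapping of canonical name -> file column name, e.g.
        ``{"animal_id": "Mouse", "day": "StudyDay"}``.  Unmapped canonical
        names are looked up verbatim.

    Raises
    ------
    SchemaError
        A required column is absent or a cell cannot be parsed (the error
        names the column and the 1-based file line).
    ValidationError
        The parsed table violates a structural invariant.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    rename = {v: k for k, v in (schema or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    for col in ("day", "length", "width", "volume", "body_weight"):
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise SchemaError(
                f"{path.name}: unparsable numeric in column '{col}' at line "
                f"{line}: {df[col][bad].iloc[0]!r}"
            )
        df[col] = parsed
    dup = df.duplicated(subset=["animal_id", "day"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            f"{path.name}: duplicate (animal, day) keys, e.g. animal "
            f"{first['animal_id']} day {first['day']}"
        )
    logger.info("read %d rows from %s", len(df), path)
    return MeasurementTable.from_dataframe(df, metadata)


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    """Write a table back to the canonical CSV dialect."""
    table.data.to_csv(path, index=False)


# --------------------------------------------------------------------- report

#: Column order of the delimited study report (one row per arm or arm-pair).
REPORT_COLUMNS = (
    "row_type",
    "group",
    "comparator",
    "n",
    "mean_growth_rate",
    "se",
    "gri_percent",
    "p_value",
    "synergy_score_percent",
    "classification",
    "cr_count",
    "max_mean_bwl_percent",
    "median_surrogate_survival",
)


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, numbers.Integral):
        return int(obj)
    if isinstance(obj, numbers.Real):
        v = float(obj)
        # NaN (missing) and inf (e.g. median survival never reached)
        # have no JSON representation; serialize both as null
        return v if math.isfinite(v) else None
    return obj


def write_study_report(results: Mapping[str, Any], path: str | Path) -> None:
    """Write the per-arm / per-pair summary CSV plus a JSON sidecar.

    ``results`` maps stage names to stage outputs; recognized keys are
    ``group_summaries`` (mapping arm -> GroupGrowthSummary), ``gri``
    (iterable of GriResult), ``synergy`` (iterable of SynergyResult),
    ``cr`` (mapping arm -> CrSummary), ``bwl`` (mapping arm -> BwlSummary)
    and ``survival_median`` (mapping arm -> median surrogate survival day).
    Unpopulated columns are left empty.  The sidecar (``<path>.json``)
    holds every supplied result at full precision and is the round-trip
    source of truth.
    """
    if not results or not any(v is not None and v != {} and v != [] for v in results.values()):
        raise ValidationError("write_study_report: no stage outputs supplied")
    path = Path(path)

    summaries = results.get("group_summaries") or {}
    cr = results.get("cr") or {}
    bwl = results.get("bwl") or {}
    median = results.get("survival_median") or {}
    arms: list[str] = list(
        dict.fromkeys([*summaries, *cr, *bwl, *median])
    )
    rows: list[dict[str, Any]] = []
    for arm in arms:
        s = summaries.get(arm)
        rows.append(
            {
                "row_type": "arm",
                "group": arm,
                "comparator": "",
                "n": getattr(s, "n", ""),
                "mean_growth_rate": getattr(s, "mean_rate", ""),
                "se": getattr(s, "se", ""),
                "cr_count": getattr(cr.get(arm), "cr_count", ""),
                "max_mean_bwl_percent": getattr(bwl.get(arm), "max_mean_bwl_percent", ""),
                "median_surrogate_survival": median.get(arm, ""),
            }
        )
    for g in results.get("gri") or []:
        rows.append(
            {
                "row_type": "gri",
                "group": g.treatment,
                "comparator": g.control,
                "gri_percent": g.gri_percent,
                "p_value": g.p_value,
            }
        )
    for s in results.get("synergy") or []:
        rows.append(
            {
                "row_type": "synergy",
                "group": s.arms.get("ab", ""),
                "comparator": "+".join(
                    filter(None, [s.arms.get("a", ""), s.arms.get("b", "")])
                ),
                "synergy_score_percent": s.score_percent,
                "se": s.se,
                "p_value": s.p_value,
                "classification": s.label,
            }
        )
    report = pd.DataFrame(rows, columns=list(REPORT_COLUMNS)).fillna("")
    report.to_csv(path, index=False)

    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps(_jsonify(results), indent=2, allow_nan=False))
    logger.info("wrote study report %s (+ sidecar %s)", path, sidecar.name)


def read_report_sidecar(path: str | Path) -> dict[str, Any]:
    """Load the full-precision JSON sidecar written by :func:`write_study_report`."""
    return json.loads(Path(path).read_text())
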