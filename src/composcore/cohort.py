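"""Domain types, CSV I/O and standardization for a clinical outcome battery.

A cohort is a long-format table with one row per (subject, condition)
record and one numeric column per outcome measure.  The default battery is
the eight-measure prosthetics assessment battery: Amputee Mobility
Predictor (AMP), Berg Balance Scale (BERG), 6-min walk test (6MWT),
Prosthesis Evaluation Questionnaire ambulation module (PEQ_amb), Modified
Falls Efficacy Scale (MFES), Four Square Step Test (FSST), 10-m walk test
(10MWT) and Timed Up and Go (TUG).  Each measure carries a direction of
improvement: +1 if a higher raw score means better function, -1 if lower
is better (the timed tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CohortFormatError,
    CohortValidationError,
    DegenerateScaleError,
)

__all__ = [
    "MeasureSpec",
    "CohortDataset",
    "ScalerParams",
    "StandardizedMatrix",
    "default_battery",
    "battery_from_yaml",
    "battery_to_yaml",
    "load_cohort",
    "write_cohort",
    "fit_scaler",
    "standardize",
    "inverse_standardize",
]

ID_COLUMNS = ("subject", "condition")


@dataclass(frozen=True)
class MeasureSpec:
    """One outcome measure: name, free-text units, direction of improvement."""

    name: str
    units: str = ""
    direction: int = 1

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise CohortValidationError(
                f"direction for measure {self.name!r} must be +1 or -1, "
                f"got {self.direction}"
            )


def default_battery() -> list[MeasureSpec]:
    """The eight-measure prosthetics battery with its improvement signs.

    Higher is better for AMP, BERG, 6MWT, PEQ_amb and MFES; lower is
    better for the timed FSST, 10MWT and TUG.
    """
    return [
        MeasureSpec("AMP", "points", +1),
        MeasureSpec("BERG", "points (0-56)", +1),
        MeasureSpec("6MWT", "m", +1),
        MeasureSpec("PEQ_amb", "points", +1),
        MeasureSpec("MFES", "points", +1),
        MeasureSpec("FSST", "s", -1),
        MeasureSpec("10MWT", "s", -1),
        MeasureSpec("TUG", "s", -1),
    ]


def battery_from_yaml(path: str | Path) -> list[MeasureSpec]:
    """Load battery metadata from a YAML list of {name, units, direction}."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise CohortFormatError(f"{path}: expected a non-empty YAML list")
    battery = [
        MeasureSpec(
            name=str(entry["name"]),
            units=str(entry.get("units", "")),
            direction=int(entry.get("direction", 1)),
        )
        for entry in raw
    ]
    _check_unique_names(battery)
    return battery


def battery_to_yaml(battery: Sequence[MeasureSpec], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            [
                {"name": m.name, "units": m.units, "direction": m.direction}
                for m in battery
            ],
            fh,
            sort_keys=False,
        )


def _check_unique_names(battery: Sequence[MeasureSpec]) -> None:
    names = [m.name for m in battery]
    if len(set(names)) != len(names):
        raise CohortValidationError("measure names must be unique within a battery")


@dataclass
class CohortDataset:
    """Long-format battery: one row per (subject, condition) record.

    ``table`` holds the identifier columns plus one float column per
    measure, in battery order.  ``condition_levels`` is the ordered pair
    of condition labels (first = reference, second = comparison).
    """

    table: pd.DataFrame
    battery: list[MeasureSpec]
    condition_levels: tuple[str, str]

    def __post_init__(self) -> None:
        _check_unique_names(self.battery)
        self.validate()

    # -- views ------------------------------------------------------------
    @property
    def measure_names(self) -> list[str]:
        return [m.name for m in self.battery]

    @property
    def directions(self) -> np.ndarray:
        """Signed direction-of-improvement vector d over the battery."""
        return np.array([m.direction for m in self.battery], dtype=float)

    @property
    def n_records(self) -> int:
        return len(self.table)

    @property
    def subjects(self) -> list:
        seen: dict = {}
        for s in self.table["subject"]:
            seen.setdefault(s, None)
        return list(seen)

    @property
    def record_keys(self) -> list[tuple]:
        return list(zip(self.table["subject"], self.table["condition"]))

    @property
    def values(self) -> np.ndarray:
        """records x measures float matrix in battery order."""
        return self.table[self.measure_names].to_numpy(dtype=float)

    def validate(self) -> None:
        missing = [c for c in (*ID_COLUMNS, *self.measure_names)
                   if c not in self.table.columns]
        if missing:
            raise CohortFormatError(f"cohort table lacks columns: {missing}")
        levels = list(dict.fromkeys(self.table["condition"]))
        if set(levels) != set(self.condition_levels) or len(levels) != 2:
            raise CohortValidationError(
                f"expected exactly the two condition levels "
                f"{self.condition_levels}, found {levels}"
            )
        dup = self.table.duplicated(subset=list(ID_COLUMNS))
        if dup.any():
            key = self.table.loc[dup.idxmax(), list(ID_COLUMNS)].tolist()
            raise CohortValidationError(f"duplicate record for {tuple(key)}")
        vals = self.table[self.measure_names]
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            bad = vals.isna() | ~np.isfinite(vals.to_numpy(dtype=float))
            row, col = np.argwhere(bad.to_numpy())[0]
            raise CohortValidationError(
                f"missing/non-finite value at row {row}, "
                f"measure {self.measure_names[col]!r}"
            )


@dataclass(frozen=True)
class ScalerParams:
    """Per-measure location/scale used for z-scoring (sample SD, n-1)."""

    measure_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(self.sd > 0):
            raise DegenerateScaleError("all scaler SDs must be strictly positive")


@dataclass
class StandardizedMatrix:
    """records x measures z-score matrix plus the scaler that produced it."""

    matrix: np.ndarray
    row_index: list[tuple]
    measure_names: list[str]
    scaler: ScalerParams
    fitted_on: frozenset


def load_cohort(
    path: str | Path,
    battery: Sequence[MeasureSpec] | None = None,
    condition_levels: tuple[str, str] | None = None,
) -> CohortDataset:
    """Read a long-format cohort CSV, validating columns and values.

    The file must have a header with ``subject``, ``condition`` and one
    column per battery measure; row order is preserved.  Condition levels
    default to first-appearance order in the file.
    """
    battery = list(battery) if battery is not None else default_battery()
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pragma: no cover - rare
        raise CohortFormatError(f"{path}: {exc}") from exc
    names = [m.name for m in battery]
    missing = [c for c in (*ID_COLUMNS, *names) if c not in table.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {missing}")
    for name in names:
        col = pd.to_numeric(table[name], errors="coerce")
        bad = col.isna()
        if bad.any():
            raise CohortValidationError(
                f"{path}: non-numeric or missing value for measure {name!r} "
                f"at row {int(bad.idxmax())}"
            )
        table[name] = col.astype(float)
    levels = list(dict.fromkeys(table["condition"]))
    if len(levels) != 2:
        raise CohortValidationError(
            f"{path}: expected exactly 2 condition levels, found {levels}"
        )
    if condition_levels is None:
        condition_levels = (levels[0], levels[1])
    return CohortDataset(
        table=table[list(ID_COLUMNS) + names].copy(),
        battery=battery,
        condition_levels=condition_levels,
    )


def write_cohort(data: CohortDataset, path: str | Path) -> None:
    """Write the cohort back to CSV (round-trips numeric content exactly)."""
    data.table.to_csv(path, index=False)


def fit_scaler(
    data: CohortDataset | np.ndarray,
    subset: Iterable[tuple] | None = None,
    measure_names: Sequence[str] | None = None,
) -> ScalerParams:
    """Per-measure mean and sample SD (n-1) over the given record subset.

    ``subset`` is a set of (subject, condition) keys; default all rows.
    A measure with undefined (n<2) or zero variance raises
    :class:`DegenerateScaleError`.
    """
    if isinstance(data, CohortDataset):
        values = data.values
        names = data.measure_names
        if subset is not None:
            keyset = set(subset)
            mask = np.array([k in keyset for k in data.record_keys])
            if not mask.any():
                raise DegenerateScaleError("scaling subset selects no rows")
            values = values[mask]
    else:
        values = np.asarray(data, dtype=float)
        names = list(measure_names) if measure_names is not None else [
            f"m{i}" for i in range(values.shape[1])
        ]
    if values.shape[0] < 2:
        raise DegenerateScaleError(
            "sample SD undefined on fewer than 2 rows"
        )
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if not s > 0:
            raise DegenerateScaleError(
                f"measure {names[j]!r} has zero variance on the scaling subset"
            )
    return ScalerParams(tuple(names), mean, sd)


def standardize(
    data: CohortDataset,
    scaler: ScalerParams | None = None,
    fitted_on: Iterable[tuple] | None = None,
) -> StandardizedMatrix:
    """z-score every record: (raw - mean) / SD per measure.

    If no scaler is given one is fitted on all rows.  The inverse
    transform (:func:`inverse_standardize`) recovers raw values exactly.
    """
    if scaler is None:
        scaler = fit_scaler(data)
        fitted_on = data.record_keys
    if tuple(data.measure_names) != scaler.measure_names:
        raise CohortFormatError(
            f"scaler covers {scaler.measure_names}, data has "
            f"{tuple(data.measure_names)}"
        )
    z = (data.values - scaler.mean) / scaler.sd
    keys = data.record_keys
    return StandardizedMatrix(
        matrix=z,
        row_index=keys,
        measure_names=list(data.measure_names),
        scaler=scaler,
        fitted_on=frozenset(fitted_on if fitted_on is not None else keys),
    )


def inverse_standardize(sm: StandardizedMatrix) -> np.ndarray:
    """Map a z-score matrix back to raw units."""
    return sm.matrix * sm.scaler.sd + sm.scaler.mean
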