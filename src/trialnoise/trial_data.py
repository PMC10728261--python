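"""Trial-level data model and I/O.

A :class:`TrialTable` holds long-format single-trial response times for a
battery of two-condition (congruent / incongruent) tasks.  The internal
time unit is milliseconds everywhere; readers accept a ``unit`` option and
convert on ingest so that files recorded in seconds do not silently mix
with millisecond data.

Trial order is file order.  This matters: split-half reliability is
defined on even/odd trial indices within each person-by-task-by-condition
cell, so readers and writers must preserve row order exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TrialTable",
    "CleaningRules",
    "CleaningReport",
    "TrialDataError",
    "FormatError",
    "ValidationError",
    "read_trials",
    "write_trials",
    "apply_cleaning",
]

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
CONDITIONS = (CONGRUENT, INCONGRUENT)

#: canonical column order of the long format
COLUMNS = ["person", "task", "condition", "rt"]


class TrialDataError(ValueError):
    """Base error for trial-table problems."""


class FormatError(TrialDataError):
    """The file or frame does not have the expected columns."""


class ValidationError(TrialDataError):
    """The data violate a trial-table invariant (e.g. non-positive RT)."""


def _normalize_condition(values: pd.Series) -> pd.Series:
    """Map condition labels case-insensitively onto the two-level enum.

    Unknown labels are an error, never a guess.  Works on the (few)
    unique labels rather than every row, so normalization is cheap even
    for very long tables.
    """
    if isinstance(values.dtype, pd.CategoricalDtype) and set(
        values.cat.categories
    ) <= set(CONDITIONS):
        return values
    uniques = pd.unique(values)
    mapping = {}
    for u in uniques:
        lowered = str(u).strip().lower()
        if lowered not in CONDITIONS:
            raise ValidationError(
                f"unknown condition label {u!r}; expected one of "
                f"{list(CONDITIONS)} (case-insensitive)"
            )
        mapping[u] = lowered
    return values.map(mapping).astype(pd.CategoricalDtype(list(CONDITIONS)))


@dataclass
class TrialTable:
    """Long-format table of single-trial response times.

    Parameters
    ----------
    data
        DataFrame with columns ``person``, ``task``, ``condition``, ``rt``.
        ``rt`` is in milliseconds; ``condition`` is ``"congruent"`` or
        ``"incongruent"`` (the design contrast code x is 0 for congruent,
        1 for incongruent).  Row order is meaningful and preserved.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        df = self.data.loc[:, COLUMNS].reset_index(drop=True).copy()
        df["condition"] = _normalize_condition(df["condition"])
        df["rt"] = pd.to_numeric(df["rt"], errors="coerce")
        self.data = df

    # -- basic properties -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def persons(self) -> list:
        return sorted(self.data["person"].unique().tolist())

    @property
    def tasks(self) -> list:
        return sorted(self.data["task"].unique().tolist())

    def condition_code(self) -> np.ndarray:
        """The contrast code x: 0 for congruent, 1 for incongruent."""
        return (self.data["condition"].to_numpy() == INCONGRUENT).astype(int)

    # -- validation -------------------------------------------------------
    def validate(self, strict: bool = True) -> list[str]:
        """Check the trial-table invariants.

        Returns a list of human-readable problem descriptions.  With
        ``strict=True`` (default), numeric problems (non-finite or
        non-positive RTs) raise :class:`ValidationError`; design problems
        (a person-by-task cell missing one condition) are always returned
        as flags rather than raised, since downstream estimators can drop
        such cells.  Validation never mutates the data.
        """
        problems: list[str] = []
        rt = self.data["rt"]
        bad = ~np.isfinite(rt.to_numpy(dtype=float)) | (rt.to_numpy(dtype=float) <= 0)
        if bad.any():
            rows = np.flatnonzero(bad)[:20].tolist()
            msg = (
                f"{int(bad.sum())} rows with non-positive, missing or non-numeric "
                f"rt (row indices {rows}{'...' if bad.sum() > 20 else ''})"
            )
            if strict:
                raise ValidationError(msg)
            problems.append(msg)
        counts = (
            self.data.groupby(["person", "task", "condition"], observed=True)
            .size()
            .unstack("condition", fill_value=0)
        )
        for cond in CONDITIONS:
            if cond not in counts.columns:
                counts[cond] = 0
        empty = counts[(counts[CONGRUENT] == 0) | (counts[INCONGRUENT] == 0)]
        for (person, task), row in empty.iterrows():
            problems.append(
                f"person {person!r}, task {task!r}: missing trials in "
                f"{CONGRUENT if row[CONGRUENT] == 0 else INCONGRUENT} condition"
            )
        return problems

    def equals(self, other: "TrialTable") -> bool:
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if len(a) != len(b):
            return False
        return (
            a["person"].astype(str).equals(b["person"].astype(str))
            and a["task"].astype(str).equals(b["task"].astype(str))
            and a["condition"].equals(b["condition"])
            and np.allclose(a["rt"].to_numpy(), b["rt"].to_numpy())
        )


@dataclass
class CleaningRules:
    """Keep trials with RT inside ``[min_rt, max_rt]`` (milliseconds)."""

    min_rt: float
    max_rt: float

    def __post_init__(self) -> None:
        if not (0 <= self.min_rt < self.max_rt):
            raise ValueError("cleaning rules require 0 <= min_rt < max_rt")


@dataclass
class CleaningReport:
    """What :func:`apply_cleaning` removed, per person-by-task-by-condition."""

    n_in: int
    n_out: int
    removed: pd.DataFrame = field(repr=False)  # person, task, condition, n_removed
    emptied_cells: list[tuple] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


def read_trials(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    unit: str = "ms",
) -> TrialTable:
    """Read a long-format trial CSV into a validated :class:`TrialTable`.

    Parameters
    ----------
    path
        CSV file with a header.  Expected columns are
        ``person,task,condition,rt`` unless remapped.
    column_map
        Optional mapping from canonical name to the file's column name,
        e.g. ``{"person": "subj", "rt": "RT_ms"}``.
    unit
        ``"ms"`` (default) or ``"s"``; seconds are converted to
        milliseconds on ingest.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required columns {missing} (have {list(df.columns)})"
        )
    if unit not in ("ms", "s"):
        raise ValueError(f"unit must be 'ms' or 's', got {unit!r}")
    df = df.loc[:, COLUMNS]
    rt = pd.to_numeric(df["rt"], errors="coerce")
    if rt.isna().any():
        rows = df.index[rt.isna()][:20].tolist()
        raise ValidationError(f"{path}: non-numeric rt values at rows {rows}")
    if unit == "s":
        rt = rt * 1000.0
    df = df.assign(rt=rt)
    table = TrialTable(df)
    table.validate(strict=True)
    return table


def write_trials(table: TrialTable, path: str | Path) -> None:
    """Write a trial table as ``person,task,condition,rt`` CSV.

    Round-trips exactly through :func:`read_trials` (row order preserved,
    full float precision).
    """
    table.data.to_csv(path, index=False)


def apply_cleaning(
    table: TrialTable, rules: CleaningRules
) -> tuple[TrialTable, CleaningReport]:
    """Remove trials with RT outside ``[rules.min_rt, rules.max_rt]``.

    Returns the cleaned table together with a report of removal counts per
    person-by-task-by-condition cell.  Cells left empty by cleaning are
    listed in the report and a warning is issued; the operation is
    idempotent.
    """
    df = table.data
    keep = (df["rt"] >= rules.min_rt) & (df["rt"] <= rules.max_rt)
    removed_rows = df.loc[~keep]
    removed = (
        removed_rows.groupby(["person", "task", "condition"], observed=True)
        .size()
        .rename("n_removed")
        .reset_index()
    )
    cleaned = TrialTable(df.loc[keep].reset_index(drop=True))
    before = set(map(tuple, df[["person", "task", "condition"]].drop_duplicates().itertuples(index=False)))
    after = set(map(tuple, cleaned.data[["person", "task", "condition"]].drop_duplicates().itertuples(index=False)))
    emptied = sorted(before - after)
    if emptied:
        warnings.warn(
            f"cleaning emptied {len(emptied)} person x task x condition cells",
            stacklevel=2,
        )
    report = CleaningReport(
        n_in=len(df), n_out=len(cleaned), removed=removed, emptied_cells=emptied
    )
    return cleaned, report
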