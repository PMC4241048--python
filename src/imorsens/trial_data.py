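"""Trial data containers, validation, CSV I/O and aggregation.

The analysis of a two-arm trial with one incomplete binary outcome needs
only the per-cell sufficient statistics: for every stratum defined by the
binary baseline covariate ``x`` (optional) and randomized arm ``z``, the
number of observed events, observed non-events, and participants whose
outcome is missing.  :class:`TrialTable` holds exactly those counts;
everything downstream (effect estimation, variances, imputation oracles)
is a function of a ``TrialTable``.

Coding convention (fixed, to avoid silent sign flips): ``y = 1`` is the
event (e.g. smoking at follow-up), ``z = 1`` the treatment arm, ``r = 1``
an observed outcome, ``x = 1`` the event state at baseline.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .errors import TrialDataError

#: Cell key: ``(x, z)`` with ``x`` in {0, 1}, or ``(None, z)`` when the
#: table carries no covariate.
CellKey = tuple[int | None, int]

WITH_X_KEYS: tuple[CellKey, ...] = ((0, 0), (1, 0), (0, 1), (1, 1))
NO_X_KEYS: tuple[CellKey, ...] = ((None, 0), (None, 1))


def _as_binary(value, name: str) -> int:
    try:
        iv = int(value)
    except (TypeError, ValueError):
        raise TrialDataError(f"{name} must be 0 or 1, got {value!r}") from None
    if iv not in (0, 1):
        raise TrialDataError(f"{name} must be 0 or 1, got {value!r}")
    return iv


@dataclass(frozen=True)
class ParticipantRecord:
    """One trial participant.

    ``y`` is present if and only if the outcome was observed (``r = 1``);
    ``x`` is either present for every record in a dataset or for none.
    """

    z: int
    r: int
    y: int | None = None
    x: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", _as_binary(self.z, "z"))
        object.__setattr__(self, "r", _as_binary(self.r, "r"))
        if self.x is not None:
            object.__setattr__(self, "x", _as_binary(self.x, "x"))
        if self.r == 1:
            if self.y is None:
                raise TrialDataError("outcome y missing although r = 1")
            object.__setattr__(self, "y", _as_binary(self.y, "y"))
        elif self.y is not None:
            raise TrialDataError("outcome y present although r = 0")


@dataclass(frozen=True)
class CellCounts:
    """Sufficient statistics for one ``(x, z)`` cell."""

    n_event_obs: int
    n_nonevent_obs: int
    n_miss: int

    def __post_init__(self) -> None:
        for name in ("n_event_obs", "n_nonevent_obs", "n_miss"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise TrialDataError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n_obs(self) -> int:
        return self.n_event_obs + self.n_nonevent_obs

    @property
    def n_total(self) -> int:
        return self.n_obs + self.n_miss

    def __add__(self, other: "CellCounts") -> "CellCounts":
        return CellCounts(
            self.n_event_obs + other.n_event_obs,
            self.n_nonevent_obs + other.n_nonevent_obs,
            self.n_miss + other.n_miss,
        )


@dataclass(frozen=True)
class TrialTable:
    """Per-cell counts for a two-arm trial, with or without a covariate.

    Every expected cell key is present, possibly with all-zero counts:
    empty cells receive weight zero downstream rather than being an error.
    """

    cells: Mapping[CellKey, CellCounts]
    has_x: bool

    def __post_init__(self) -> None:
        expected = WITH_X_KEYS if self.has_x else NO_X_KEYS
        got = tuple(sorted(self.cells.keys(), key=lambda k: (k[1], -1 if k[0] is None else k[0])))
        if set(self.cells.keys()) != set(expected):
            raise TrialDataError(
                f"table must have exactly the cells {expected}, got {got}"
            )
        object.__setattr__(self, "cells", dict(self.cells))

    # -- structure -------------------------------------------------------
    def arm_keys(self, z: int) -> list[CellKey]:
        return [k for k in (WITH_X_KEYS if self.has_x else NO_X_KEYS) if k[1] == z]

    def arm_total(self, z: int) -> int:
        return sum(self.cells[k].n_total for k in self.arm_keys(z))

    @property
    def n_total(self) -> int:
        return self.arm_total(0) + self.arm_total(1)

    # -- transforms ------------------------------------------------------
    def collapse_x(self) -> "TrialTable":
        """Sum the counts over the covariate strata (idempotent)."""
        if not self.has_x:
            return self
        cells = {
            (None, z): self.cells[(0, z)] + self.cells[(1, z)] for z in (0, 1)
        }
        return TrialTable(cells, has_x=False)

    def missingness_pattern(self) -> pd.DataFrame:
        """Known/missing counts and percentages per arm plus overall."""
        rows = []
        for z, name in ((0, "control"), (1, "treatment")):
            known = sum(self.cells[k].n_obs for k in self.arm_keys(z))
            miss = sum(self.cells[k].n_miss for k in self.arm_keys(z))
            rows.append({"arm": name, "known": known, "missing": miss})
        return missingness_summary(pd.DataFrame(rows))


def missingness_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Add a total row and known/missing percentages to an arm-level frame.

    ``counts`` must have columns ``arm``, ``known``, ``missing``; one row
    per arm.  Percentages are of each arm's total (the overall row uses the
    grand total).
    """
    required = {"arm", "known", "missing"}
    if not required.issubset(counts.columns):
        raise TrialDataError(f"frame must have columns {sorted(required)}")
    out = counts.loc[:, ["arm", "known", "missing"]].copy()
    total = pd.DataFrame(
        [{"arm": "total", "known": out["known"].sum(), "missing": out["missing"].sum()}]
    )
    out = pd.concat([out, total], ignore_index=True)
    denom = out["known"] + out["missing"]
    out["pct_known"] = 100.0 * out["known"] / denom
    out["pct_missing"] = 100.0 * out["missing"] / denom
    return out


# ---------------------------------------------------------------------------
# aggregation

def aggregate_records(records: Sequence[ParticipantRecord]) -> TrialTable:
    """Tally individual records into a :class:`TrialTable`.

    Requires a nonempty sequence with a consistent presence of ``x``.
    Each record lands in exactly one cell, so totals are conserved.
    """
    records = list(records)
    if not records:
        raise TrialDataError("no records to aggregate")
    has_x = records[0].x is not None
    if any((r.x is not None) != has_x for r in records):
        raise TrialDataError("covariate x must be present for all records or none")

    keys = WITH_X_KEYS if has_x else NO_X_KEYS
    tally = {k: [0, 0, 0] for k in keys}  # events, non-events, missing
    for rec in records:
        key = (rec.x, rec.z)
        if rec.r == 0:
            tally[key][2] += 1
        elif rec.y == 1:
            tally[key][0] += 1
        else:
            tally[key][1] += 1
    cells = {k: CellCounts(*v) for k, v in tally.items()}
    return TrialTable(cells, has_x=has_x)


def collapse_x(table: TrialTable) -> TrialTable:
    """Module-level alias for :meth:`TrialTable.collapse_x`."""
    return table.collapse_x()


# ---------------------------------------------------------------------------
# CSV I/O
#
# Records layout: header with (optionally) x, and z, r, y columns; the y
# field is blank or "NA" exactly when r = 0.  Counts layout: one row per
# cell with (optionally) x, and z, n_event_obs, n_nonevent_obs, n_miss.

_NA_TOKENS = {"", "NA", "na", "NaN", "nan"}


def read_records_csv(
    path,
    *,
    x_col: str = "x",
    z_col: str = "z",
    r_col: str = "r",
    y_col: str = "y",
) -> list[ParticipantRecord]:
    """Read individual participant records from a delimited text file."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (z_col, r_col, y_col):
        if col not in frame.columns:
            raise TrialDataError(f"records file lacks required column {col!r}")
    has_x = x_col in frame.columns
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        y_tok = str(row[y_col]).strip()
        y = None if y_tok in _NA_TOKENS else y_tok
        try:
            records.append(
                ParticipantRecord(
                    z=row[z_col],
                    r=row[r_col],
                    y=y,
                    x=row[x_col] if has_x else None,
                )
            )
        except TrialDataError as exc:
            raise TrialDataError(f"row {i + 2} of {path}: {exc}") from None
    if not records:
        raise TrialDataError(f"no data rows in {path}")
    return records


def write_records_csv(records: Iterable[ParticipantRecord], path) -> None:
    records = list(records)
    has_x = records[0].x is not None if records else False
    rows = []
    for rec in records:
        row = {}
        if has_x:
            row["x"] = rec.x
        row.update(z=rec.z, r=rec.r, y="" if rec.y is None else rec.y)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_counts_csv(path) -> TrialTable:
    """Read a per-cell counts file into a :class:`TrialTable`.

    Both arms must be present; cells absent from the file (within the
    layout implied by the presence of an ``x`` column) default to zero
    counts.  Duplicate cells and negative counts are rejected.
    """
    frame = pd.read_csv(path)
    required = {"z", "n_event_obs", "n_nonevent_obs", "n_miss"}
    if not required.issubset(frame.columns):
        raise TrialDataError(
            f"counts file must have columns {sorted(required)} (plus optional x)"
        )
    has_x = "x" in frame.columns
    keys = WITH_X_KEYS if has_x else NO_X_KEYS
    cells: dict[CellKey, CellCounts] = {k: CellCounts(0, 0, 0) for k in keys}
    seen: set[CellKey] = set()
    for _, row in frame.iterrows():
        z = _as_binary(row["z"], "z")
        x = _as_binary(row["x"], "x") if has_x else None
        key = (x, z)
        if key in seen:
            raise TrialDataError(f"duplicate cell {key} in {path}")
        seen.add(key)
        try:
            cells[key] = CellCounts(
                row["n_event_obs"], row["n_nonevent_obs"], row["n_miss"]
            )
        except TrialDataError as exc:
            raise TrialDataError(f"cell {key} in {path}: {exc}") from None
    for z in (0, 1):
        if not any(k[1] == z for k in seen):
            raise TrialDataError(
                f"counts file {path} has no rows for arm z={z}; both arms required"
            )
    return TrialTable(cells, has_x=has_x)


def write_counts_csv(table: TrialTable, path) -> None:
    rows = []
    for key, c in table.cells.items():
        row = {}
        if table.has_x:
            row["x"] = key[0]
        row.update(
            z=key[1],
            n_event_obs=c.n_event_obs,
            n_nonevent_obs=c.n_nonevent_obs,
            n_miss=c.n_miss,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
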