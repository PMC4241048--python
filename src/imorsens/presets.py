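"""Named missing-data assumptions and sensitivity-analysis grids.

The standard analyses — MAR, "missing = event" (the Russell Standard in
smoking-cessation trials), and last observation carried forward — are
special points in the log-IMOR parameter space.  A preset assigns those
values to a chosen scope of cells and leaves the rest *free*: free slots
must be filled explicitly before fitting, never defaulted silently.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from .errors import ImorsensError
from .sensitivity_model import (
    EffectEstimate,
    EffectScale,
    SensitivityParameters,
    fit,
)
from .trial_data import NO_X_KEYS, WITH_X_KEYS, CellKey, TrialTable

__all__ = [
    "AssumptionPreset",
    "preset",
    "finite_analogue",
    "GridEntry",
    "GridRow",
    "GridResult",
    "table5_entries",
    "run_grid",
]

PRESET_KINDS = ("mar", "locf", "missing_equals_event")
SCOPES = ("all", "treatment", "control")

INF = math.inf


@dataclass(frozen=True)
class AssumptionPreset:
    """A (possibly partial) log-IMOR assignment with a descriptive name."""

    name: str
    assignment: Mapping[CellKey, float | None]  # None = free slot

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))

    @property
    def free_cells(self) -> list[CellKey]:
        return [k for k, v in self.assignment.items() if v is None]

    def filled(self, values: Mapping[CellKey, float]) -> "AssumptionPreset":
        """Fill free slots from ``values``; assigned slots are untouched."""
        merged = {
            k: (values[k] if v is None and k in values else v)
            for k, v in self.assignment.items()
        }
        return AssumptionPreset(self.name, merged)

    def to_parameters(self) -> SensitivityParameters:
        if self.free_cells:
            raise ImorsensError(
                f"preset {self.name!r} has unfilled cells {self.free_cells}; "
                "assign a log IMOR to every cell before fitting"
            )
        return SensitivityParameters({k: float(v) for k, v in self.assignment.items()})


def _locf_value(x: int | None) -> float:
    # carrying the baseline state forward: x=0 -> non-event (-inf),
    # x=1 -> event (+inf); undefined without a baseline-outcome covariate
    if x is None:
        raise ImorsensError(
            "LOCF requires the baseline-outcome covariate x; it is undefined "
            "for a model without x"
        )
    return -INF if x == 0 else INF


def preset(
    kind: str,
    scope: str | CellKey = "all",
    *,
    has_x: bool = True,
) -> AssumptionPreset:
    """Build a named assumption for a scope of cells.

    ``kind``: ``"mar"`` (log IMOR 0), ``"locf"`` (-inf for x=0 cells,
    +inf for x=1 cells), or ``"missing_equals_event"`` (+inf).  ``scope``:
    ``"all"``, ``"treatment"``, ``"control"``, or a single ``(x, z)``
    cell.  Out-of-scope cells are left free.
    """
    if kind not in PRESET_KINDS:
        raise ImorsensError(f"unknown preset kind {kind!r}; choose from {PRESET_KINDS}")
    keys = WITH_X_KEYS if has_x else NO_X_KEYS

    if isinstance(scope, tuple):
        if scope not in keys:
            raise ImorsensError(f"scope cell {scope} not a cell of this model")
        in_scope = lambda k: k == scope  # noqa: E731
        scope_name = f"cell (x={scope[0]}, z={scope[1]})"
    elif scope in SCOPES:
        z_wanted = {"all": (0, 1), "treatment": (1,), "control": (0,)}[scope]
        in_scope = lambda k: k[1] in z_wanted  # noqa: E731
        scope_name = scope
    else:
        raise ImorsensError(f"unknown scope {scope!r}; choose from {SCOPES} or a cell")

    def value(k: CellKey) -> float:
        if kind == "mar":
            return 0.0
        if kind == "missing_equals_event":
            return INF
        return _locf_value(k[0])

    assignment = {k: (value(k) if in_scope(k) else None) for k in keys}
    label = {
        "mar": "MAR",
        "locf": "LOCF",
        "missing_equals_event": "Missing = event",
    }[kind]
    if scope != "all":
        label = f"{label} ({scope_name})"
    return AssumptionPreset(label, assignment)


def finite_analogue(
    source: AssumptionPreset, odds_ratio: float
) -> AssumptionPreset:
    """Replace infinite log IMORs by ``+/-log(odds_ratio)``.

    ``odds_ratio`` is given on the odds-ratio scale (2 means the missing
    have twice — or half, for carried-forward non-events — the odds of
    the event of their observed counterparts); 1 recovers MAR.  Zeros and
    free slots are unchanged.
    """
    if not odds_ratio > 0:
        raise ImorsensError(f"odds ratio must be positive, got {odds_ratio}")
    mag = math.log(odds_ratio)

    def convert(v: float | None) -> float | None:
        if v is None or not math.isinf(v):
            return v
        return mag if v > 0 else -mag

    name = f"{source.name} (OR {odds_ratio:g})"
    return AssumptionPreset(name, {k: convert(v) for k, v in source.assignment.items()})


# ---------------------------------------------------------------------------
# grids


@dataclass(frozen=True)
class GridEntry:
    """One labelled parameter set to be fitted in a grid."""

    label: str
    params: SensitivityParameters


def _entry(obj) -> GridEntry:
    if isinstance(obj, GridEntry):
        return obj
    if isinstance(obj, AssumptionPreset):
        return GridEntry(obj.name, obj.to_parameters())
    if isinstance(obj, SensitivityParameters):
        return GridEntry(obj.describe(), obj)
    if isinstance(obj, tuple) and len(obj) == 2:
        label, params = obj
        if isinstance(params, AssumptionPreset):
            params = params.to_parameters()
        return GridEntry(str(label), params)
    raise ImorsensError(f"cannot interpret grid entry {obj!r}")


def table5_entries(finite_or: float | None = None) -> list[GridEntry]:
    """The built-in ten-analysis grid.

    One complete-case-equivalent row that drops the covariate, then the
    nine combinations of MAR / LOCF / "missing = event" applied per arm
    (mixed rows labelled treatment/control).  With ``finite_or``, infinite
    log IMORs are softened to ``+/-log(finite_or)``.
    """
    sp = SensitivityParameters.with_x
    rows: list[tuple[str, SensitivityParameters]] = [
        ("MAR (ignoring x)", SensitivityParameters.without_x(0, 0)),
        ("MAR", sp(0, 0, 0, 0)),
        ("LOCF", sp(-INF, INF, -INF, INF)),
        ("Missing = event", sp(INF, INF, INF, INF)),
        ("MAR/LOCF", sp(0, 0, -INF, INF)),
        ("MAR/missing = event", sp(0, 0, INF, INF)),
        ("LOCF/MAR", sp(-INF, INF, 0, 0)),
        ("LOCF/missing = event", sp(-INF, INF, INF, INF)),
        ("Missing = event/MAR", sp(INF, INF, 0, 0)),
        ("Missing = event/LOCF", sp(INF, INF, -INF, INF)),
    ]
    entries = []
    for label, params in rows:
        if finite_or is not None:
            if not finite_or > 0:
                raise ImorsensError(f"odds ratio must be positive, got {finite_or}")
            mag = math.log(finite_or)
            params = SensitivityParameters(
                {
                    k: (math.copysign(mag, v) if math.isinf(v) else v)
                    for k, v in params.values.items()
                }
            )
            label = f"{label} (OR {finite_or:g})"
        entries.append(GridEntry(label, params))
    return entries


@dataclass(frozen=True)
class GridRow:
    label: str
    params: SensitivityParameters
    estimate: EffectEstimate | None
    error: str | None


@dataclass(frozen=True)
class GridResult:
    """Rows of a sensitivity-analysis grid; failed fits are carried as
    error rows rather than dropped."""

    rows: Sequence[GridRow]
    scale: EffectScale

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_failed(self) -> int:
        return sum(1 for r in self.rows if r.error is not None)

    def to_dataframe(self) -> pd.DataFrame:
        if not self.rows:  # header-only frame
            return pd.DataFrame(
                columns=[
                    "assumption",
                    "estimate",
                    "se",
                    "display_estimate",
                    "display_ci_lower",
                    "display_ci_upper",
                    "p_treatment",
                    "p_control",
                    "error",
                ]
            )
        records = []
        for row in self.rows:
            rec: dict = {"assumption": row.label}
            if row.params.has_x:
                rec.update(
                    log_imor_treatment_x0=row.params.values[(0, 1)],
                    log_imor_treatment_x1=row.params.values[(1, 1)],
                    log_imor_control_x0=row.params.values[(0, 0)],
                    log_imor_control_x1=row.params.values[(1, 0)],
                )
            else:
                rec.update(
                    log_imor_treatment=row.params.values[(None, 1)],
                    log_imor_control=row.params.values[(None, 0)],
                )
            if row.estimate is not None:
                est = row.estimate
                lo, hi = est.display_ci
                rec.update(
                    estimate=est.estimate,
                    se=est.se,
                    display_estimate=est.display_estimate,
                    display_ci_lower=lo,
                    display_ci_upper=hi,
                    p_treatment=est.p_treatment,
                    p_control=est.p_control,
                    error="",
                )
            else:
                rec["error"] = row.error
            records.append(rec)
        return pd.DataFrame(records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_grid(
    table: TrialTable,
    entries: Iterable,
    scale: EffectScale = EffectScale.LOG_ODDS_RATIO,
    *,
    ci_level: float = 0.95,
    continuity_correction: bool = False,
) -> GridResult:
    """Fit every labelled parameter set against one table.

    Rows keep the input order; a row whose fit fails records the error
    message instead of raising, so one inestimable assumption does not
    abort the rest of the grid.
    """
    scale = EffectScale(scale)
    rows: list[GridRow] = []
    for obj in entries:
        entry = _entry(obj)
        try:
            est = fit(
                table,
                entry.params,
                scale,
                ci_level=ci_level,
                continuity_correction=continuity_correction,
                label=entry.label,
            )
            rows.append(GridRow(entry.label, entry.params, est, None))
        except ImorsensError as exc:
            rows.append(GridRow(entry.label, entry.params, None, str(exc)))
    return GridResult(rows=tuple(rows), scale=scale)
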