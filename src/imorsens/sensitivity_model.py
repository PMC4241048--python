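"""Pattern-mixture estimator for a trial with one incomplete binary outcome.

The model stratifies participants by the optional binary baseline covariate
``x``, the randomized arm ``z``, and whether the outcome was observed.
Within each ``(x, z)`` cell the event probability among responders is a free,
identifiable parameter — the cell's observed log-odds, estimated as
``logit(events / observed)``.  The event probability among non-responders is
*not* identified by the data; it is tied to the responders' log-odds through
an analyst-supplied log odds ratio, the log **IMOR** (informatively missing
odds ratio) of that cell:

    P(event | responder)      = expit(observed log-odds)
    P(event | non-responder)  = expit(observed log-odds + log IMOR)

A log IMOR of 0 asserts the cell's data are missing at random; ``+inf``
forces every missing outcome to an event ("missing = event", the Russell
Standard in smoking trials); ``-inf`` forces a non-event.  With ``x`` equal
to the baseline outcome, ``-inf`` in ``x = 0`` cells plus ``+inf`` in
``x = 1`` cells is last observation carried forward.  Infinities are handled
symbolically (exact 0/1 probabilities, zero derivative), never as large
floats, so the imputation-based equivalences hold to machine precision.

Arm event probabilities combine the cells by the law of total probability
with the observed cell sizes as weights, and the intervention effect
compares the two arm probabilities on the log-odds-ratio, risk-difference,
or log-relative-risk scale.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass
from enum import Enum

from scipy.special import expit

from .errors import DegenerateEffectError, InestimableCellError, TrialDataError
from .trial_data import NO_X_KEYS, WITH_X_KEYS, CellCounts, CellKey, TrialTable

__all__ = [
    "EffectScale",
    "SensitivityParameters",
    "CellLogOdds",
    "EffectEstimate",
    "estimate_observed_log_odds",
    "cell_probability",
    "arm_probability",
    "intervention_effect",
    "fit",
]


class EffectScale(str, Enum):
    """Scale on which the intervention effect is reported."""

    LOG_ODDS_RATIO = "log_odds_ratio"
    RISK_DIFFERENCE = "risk_difference"
    LOG_RELATIVE_RISK = "log_relative_risk"

    @classmethod
    def from_string(cls, token: str) -> "EffectScale":
        aliases = {
            "log_odds_ratio": cls.LOG_ODDS_RATIO,
            "log-or": cls.LOG_ODDS_RATIO,
            "logor": cls.LOG_ODDS_RATIO,
            "or": cls.LOG_ODDS_RATIO,
            "risk_difference": cls.RISK_DIFFERENCE,
            "rd": cls.RISK_DIFFERENCE,
            "log_relative_risk": cls.LOG_RELATIVE_RISK,
            "log-rr": cls.LOG_RELATIVE_RISK,
            "logrr": cls.LOG_RELATIVE_RISK,
            "rr": cls.LOG_RELATIVE_RISK,
        }
        try:
            return aliases[token.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown effect scale {token!r}") from None


def _check_log_imor(value: float, name: str) -> float:
    value = float(value)
    if math.isnan(value):
        raise ValueError(f"{name} must be a real number or +/-inf, not NaN")
    return value


@dataclass(frozen=True)
class SensitivityParameters:
    """Analyst-supplied log IMOR for every cell of the model.

    With a covariate there are four values, one per ``(x, z)`` cell;
    without one, a single value per arm.  Values are extended reals:
    finite, ``+inf`` (missing = event) or ``-inf`` (missing = non-event).
    """

    values: Mapping[CellKey, float]

    def __post_init__(self) -> None:
        keys = set(self.values.keys())
        if keys not in (set(WITH_X_KEYS), set(NO_X_KEYS)):
            raise ValueError(
                "sensitivity parameters must cover the four (x, z) cells or "
                f"the two arms, got keys {sorted(keys, key=str)}"
            )
        cleaned = {
            k: _check_log_imor(v, f"log IMOR for cell {k}")
            for k, v in self.values.items()
        }
        object.__setattr__(self, "values", cleaned)

    # -- constructors ----------------------------------------------------
    @classmethod
    def with_x(
        cls,
        treatment_x0: float,
        treatment_x1: float,
        control_x0: float,
        control_x1: float,
    ) -> "SensitivityParameters":
        return cls(
            {
                (0, 1): treatment_x0,
                (1, 1): treatment_x1,
                (0, 0): control_x0,
                (1, 0): control_x1,
            }
        )

    @classmethod
    def without_x(cls, treatment: float, control: float) -> "SensitivityParameters":
        return cls({(None, 1): treatment, (None, 0): control})

    @classmethod
    def same_both_arms(cls, x0: float, x1: float) -> "SensitivityParameters":
        """Same assumption in both arms: one value per covariate stratum."""
        return cls.with_x(x0, x1, x0, x1)

    @classmethod
    def mar(cls, has_x: bool = True) -> "SensitivityParameters":
        return cls.with_x(0, 0, 0, 0) if has_x else cls.without_x(0, 0)

    # -- accessors -------------------------------------------------------
    @property
    def has_x(self) -> bool:
        return (None, 0) not in self.values

    def for_cell(self, x: int | None, z: int) -> float:
        try:
            return self.values[(x, z)]
        except KeyError:
            raise ValueError(f"no sensitivity parameter for cell {(x, z)}") from None

    def swap_arms(self) -> "SensitivityParameters":
        return SensitivityParameters({(x, 1 - z): v for (x, z), v in self.values.items()})

    def all_infinite(self) -> bool:
        return all(math.isinf(v) for v in self.values.values())

    def describe(self) -> str:
        def tok(v: float) -> str:
            if v == math.inf:
                return "inf"
            if v == -math.inf:
                return "-inf"
            return f"{v:g}"

        if self.has_x:
            parts = [
                f"t{x}={tok(self.values[(x, 1)])}" for x in (0, 1)
            ] + [f"c{x}={tok(self.values[(x, 0)])}" for x in (0, 1)]
        else:
            parts = [f"t={tok(self.values[(None, 1)])}", f"c={tok(self.values[(None, 0)])}"]
        return "log-IMOR " + ", ".join(parts)


@dataclass(frozen=True)
class CellLogOdds:
    """Estimated log-odds of the event among a cell's responders.

    ``events_eff``/``nonevents_eff`` are the counts actually used (equal
    to the raw counts, plus 0.5 each when a continuity correction was
    applied to a boundary cell); ``variance`` is ``1/events_eff +
    1/nonevents_eff``, the usual binomial log-odds variance.
    """

    cell: CellKey
    log_odds: float
    variance: float
    events_eff: float
    nonevents_eff: float

    @property
    def p_observed(self) -> float:
        return self.events_eff / (self.events_eff + self.nonevents_eff)


def estimate_observed_log_odds(
    cell: CellCounts,
    *,
    cell_id: CellKey | None = None,
    continuity_correction: bool = False,
) -> CellLogOdds:
    """Estimate a cell's observed log-odds ``logit(events / observed)``.

    Boundary cells (0 or 100% events among responders) have an infinite
    empirical log-odds; by default this raises
    :class:`~imorsens.errors.InestimableCellError` so the analyst decides
    explicitly.  With ``continuity_correction=True``, 0.5 is added to both
    outcome counts of the offending cell only.
    """
    s, f = cell.n_event_obs, cell.n_nonevent_obs
    if cell.n_obs == 0:
        raise InestimableCellError(
            f"cell {cell_id}: no observed outcomes, log-odds inestimable"
        )
    if s == 0 or f == 0:
        if not continuity_correction:
            raise InestimableCellError(
                f"cell {cell_id}: boundary cell ({s} events of {cell.n_obs} observed); "
                "enable the continuity correction, merge strata, or force the "
                "cell with an infinite sensitivity parameter"
            )
        s, f = s + 0.5, f + 0.5
    return CellLogOdds(
        cell=cell_id,
        log_odds=math.log(s / f),
        variance=1.0 / s + 1.0 / f,
        events_eff=float(s),
        nonevents_eff=float(f),
    )


def cell_probability(log_odds: float, log_imor: float, observed: bool) -> float:
    """Event probability in one (cell, response-status) group.

    Responders: ``expit(log_odds)``.  Non-responders: ``expit(log_odds +
    log_imor)``, with infinite log IMORs mapped symbolically to exactly 1
    (``+inf``) or 0 (``-inf``).
    """
    log_odds = float(log_odds)
    if not math.isfinite(log_odds):
        raise ValueError("observed log-odds must be finite")
    log_imor = _check_log_imor(log_imor, "log IMOR")
    if observed:
        return float(expit(log_odds))
    if log_imor == math.inf:
        return 1.0
    if log_imor == -math.inf:
        return 0.0
    return float(expit(log_odds + log_imor))


def _missing_probability(est: CellLogOdds, log_imor: float) -> float:
    """Non-responder event probability from effective counts.

    Algebraically ``expit(log_odds + log_imor)`` but computed as
    ``s*B / (s*B + f)`` with ``B = exp(log_imor)`` for numerical symmetry
    with the variance module's derivatives.
    """
    if log_imor == math.inf:
        return 1.0
    if log_imor == -math.inf:
        return 0.0
    b = math.exp(log_imor)
    return est.events_eff * b / (est.events_eff * b + est.nonevents_eff)


def arm_probability(
    table: TrialTable,
    z: int,
    estimates: Mapping[CellKey, CellLogOdds],
    params: SensitivityParameters,
) -> float:
    """Arm event probability by the law of total probability.

    ``p_z = sum_cells [n_obs * p_obs + n_miss * p_miss] / N_z`` with the
    table's counts as weights.  A cell with missing participants but no
    observed ones is admissible only under an infinite log IMOR, which
    fixes its probability regardless of the inestimable log-odds.
    """
    n_arm = table.arm_total(z)
    if n_arm == 0:
        raise InestimableCellError(f"arm z={z} is empty")
    total = 0.0
    for key in table.arm_keys(z):
        c = table.cells[key]
        if c.n_total == 0:
            continue
        log_imor = params.for_cell(*key)
        if c.n_obs > 0:
            est = estimates.get(key)
            if est is None:
                raise InestimableCellError(
                    f"cell {key}: observed log-odds estimate required but not supplied"
                )
            total += c.n_obs * est.p_observed
            if c.n_miss > 0:
                total += c.n_miss * _missing_probability(est, log_imor)
        else:  # n_miss > 0 only
            if not math.isinf(log_imor):
                raise InestimableCellError(
                    f"cell {key}: has missing participants but no observed outcomes; "
                    "only an infinite log IMOR identifies its probability"
                )
            total += c.n_miss * (1.0 if log_imor > 0 else 0.0)
    return total / n_arm


def intervention_effect(p1: float, p0: float, scale: EffectScale) -> float:
    """Contrast of the two arm probabilities on the requested scale."""
    scale = EffectScale(scale)
    for name, p in (("p1", p1), ("p0", p0)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    if scale is EffectScale.RISK_DIFFERENCE:
        return p1 - p0
    if scale is EffectScale.LOG_RELATIVE_RISK:
        if p0 <= 0.0 or p1 <= 0.0:
            raise DegenerateEffectError(
                f"log relative risk undefined for p1={p1}, p0={p0}"
            )
        return math.log(p1 / p0)
    # log odds ratio
    if not (0.0 < p0 < 1.0 and 0.0 < p1 < 1.0):
        raise DegenerateEffectError(
            f"log odds ratio undefined on the boundary (p1={p1}, p0={p0})"
        )
    return math.log(p1 / (1.0 - p1)) - math.log(p0 / (1.0 - p0))


@dataclass(frozen=True)
class EffectEstimate:
    """Intervention-effect estimate under one missing-data assumption."""

    scale: EffectScale
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    ci_level: float
    p_treatment: float
    p_control: float
    assumption: str

    @property
    def _exponentiated(self) -> bool:
        return self.scale in (EffectScale.LOG_ODDS_RATIO, EffectScale.LOG_RELATIVE_RISK)

    @property
    def display_estimate(self) -> float:
        """OR / RR for the log scales, the risk difference otherwise."""
        return math.exp(self.estimate) if self._exponentiated else self.estimate

    @property
    def display_ci(self) -> tuple[float, float]:
        if self._exponentiated:
            return (math.exp(self.ci_lower), math.exp(self.ci_upper))
        return (self.ci_lower, self.ci_upper)


def fit(
    table: TrialTable,
    params: SensitivityParameters,
    scale: EffectScale = EffectScale.LOG_ODDS_RATIO,
    *,
    ci_level: float = 0.95,
    continuity_correction: bool = False,
    label: str | None = None,
) -> EffectEstimate:
    """Estimate the intervention effect under one set of log IMORs.

    Orchestrates the full procedure: per-cell observed log-odds, missing-
    cell probabilities, law-of-total-probability arm probabilities, the
    effect on the requested scale, and a delta-method Wald interval.  When
    ``params`` carry no covariate but the table does, the table is
    collapsed over ``x`` first (dropping the covariate from the model).
    """
    from .variance import arm_variance, effect_se, wald_ci

    scale = EffectScale(scale)
    if not 0.0 < ci_level < 1.0:
        raise ValueError(f"ci_level must lie in (0, 1), got {ci_level}")
    if params.has_x and not table.has_x:
        raise TrialDataError(
            "sensitivity parameters are stratified by x but the table has no covariate"
        )
    if not params.has_x and table.has_x:
        table = table.collapse_x()

    estimates: dict[CellKey, CellLogOdds] = {}
    for key, c in table.cells.items():
        if c.n_obs > 0:
            estimates[key] = estimate_observed_log_odds(
                c, cell_id=key, continuity_correction=continuity_correction
            )

    p1 = arm_probability(table, 1, estimates, params)
    p0 = arm_probability(table, 0, estimates, params)
    point = intervention_effect(p1, p0, scale)

    av1 = arm_variance(table, 1, estimates, params)
    av0 = arm_variance(table, 0, estimates, params)
    se = effect_se(av1, av0, scale)
    lo, hi = wald_ci(point, se, ci_level)
    return EffectEstimate(
        scale=scale,
        estimate=point,
        se=se,
        ci_lower=lo,
        ci_upper=hi,
        ci_level=ci_level,
        p_treatment=p1,
        p_control=p0,
        assumption=label if label is not None else params.describe(),
    )
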