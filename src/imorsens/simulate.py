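"""Synthetic trial generation and independent validation oracles.

Generation follows the pattern-mixture factorization the estimator is
built on: draw the covariate from its arm-specific margin, the response
indicator given ``(x, z)``, and finally the outcome from the cell's
responder or non-responder probability — ``expit(log_odds)`` or
``expit(log_odds + log_imor)``.  Generation therefore requires finite log
IMORs.  The full outcome vector is retained alongside the masked records
so that tests can check identification properties against the truth.

The oracles here — single imputation, Rubin-pooled multiple imputation,
and a within-arm nonparametric bootstrap — deliberately take independent
computational routes from :func:`imorsens.sensitivity_model.fit` and
:func:`imorsens.variance.arm_variance`; they exist to validate those
routines, not to replace them.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .errors import DegenerateEffectError, ImorsensError, TrialDataError
from .sensitivity_model import (
    EffectScale,
    SensitivityParameters,
    estimate_observed_log_odds,
    fit,
    intervention_effect,
)
from .trial_data import (
    NO_X_KEYS,
    WITH_X_KEYS,
    CellCounts,
    CellKey,
    ParticipantRecord,
    TrialTable,
    aggregate_records,
)

__all__ = [
    "SimConfig",
    "SimulatedTrial",
    "generate_trial",
    "simulate_table",
    "single_impute",
    "log_odds_ratio_2x2",
    "complete_case_log_odds_ratio",
    "MIResult",
    "mi_oracle",
    "BootstrapResult",
    "bootstrap_se",
]


def _check_prob(p: float, name: str) -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ImorsensError(f"{name} must lie in [0, 1], got {p}")
    return p


@dataclass(frozen=True)
class SimConfig:
    """Full generative specification of a two-arm trial.

    ``p_x_control``/``p_x_treatment`` give P(x = 1) per arm (both ``None``
    for a model without the covariate); ``p_respond`` and
    ``observed_log_odds`` are keyed by cell; ``log_imors`` must be finite.

    The defaults mirror the treatment-arm margins of a published
    internet-based smoking-cessation trial used as this package's worked
    example (arm sizes 877/881, 85% with the baseline event, response
    rates 50%/38% by baseline state, responder log-odds 0.536/1.413), with
    control-arm responder log-odds chosen to give a beneficial effect of
    realistic size (log odds ratio about -0.35) and MAR missingness.
    """

    n_control: int = 881
    n_treatment: int = 877
    p_x_control: float | None = 0.85
    p_x_treatment: float | None = 0.85
    p_respond: Mapping[CellKey, float] = None  # type: ignore[assignment]
    observed_log_odds: Mapping[CellKey, float] = None  # type: ignore[assignment]
    log_imors: SensitivityParameters = None  # type: ignore[assignment]
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.p_x_control is None) != (self.p_x_treatment is None):
            raise ImorsensError("p_x must be given for both arms or neither")
        has_x = self.p_x_control is not None
        keys = WITH_X_KEYS if has_x else NO_X_KEYS
        if self.p_respond is None:
            object.__setattr__(
                self,
                "p_respond",
                {k: (0.50 if (k[0] in (0, None)) else 0.38) for k in keys},
            )
        if self.observed_log_odds is None:
            lo = {
                (0, 1): 0.536,
                (1, 1): 1.413,
                (0, 0): 0.9,
                (1, 0): 1.75,
            } if has_x else {(None, 1): 1.3, (None, 0): 1.6}
            object.__setattr__(self, "observed_log_odds", lo)
        if self.log_imors is None:
            object.__setattr__(self, "log_imors", SensitivityParameters.mar(has_x))

        if self.n_control <= 0 or self.n_treatment <= 0:
            raise ImorsensError("both arms must have at least one participant")
        if has_x:
            _check_prob(self.p_x_control, "p_x_control")
            _check_prob(self.p_x_treatment, "p_x_treatment")
        if set(self.p_respond.keys()) != set(keys) or set(
            self.observed_log_odds.keys()
        ) != set(keys):
            raise ImorsensError(f"p_respond and observed_log_odds must be keyed by {keys}")
        for k in keys:
            _check_prob(self.p_respond[k], f"p_respond{k}")
            if not math.isfinite(self.observed_log_odds[k]):
                raise ImorsensError(f"observed_log_odds{k} must be finite")
        if self.log_imors.has_x != has_x:
            raise ImorsensError("log_imors stratification must match the covariate")
        for k in keys:
            if math.isinf(self.log_imors.for_cell(*k)):
                raise ImorsensError("generation requires finite log IMORs")

    # -- derived truth ---------------------------------------------------
    @property
    def has_x(self) -> bool:
        return self.p_x_control is not None

    def p_x(self, z: int) -> float:
        return self.p_x_treatment if z == 1 else self.p_x_control  # type: ignore[return-value]

    def arm_size(self, z: int) -> int:
        return self.n_treatment if z == 1 else self.n_control

    def cell_event_prob(self, x: int | None, z: int, r: int) -> float:
        lo = self.observed_log_odds[(x, z)]
        if r == 1:
            return float(expit(lo))
        return float(expit(lo + self.log_imors.for_cell(x, z)))

    def true_arm_probability(self, z: int) -> float:
        total = 0.0
        for x, w in self._x_weights(z):
            pr = self.p_respond[(x, z)]
            total += w * (
                pr * self.cell_event_prob(x, z, 1)
                + (1 - pr) * self.cell_event_prob(x, z, 0)
            )
        return total

    def _x_weights(self, z: int):
        if not self.has_x:
            return [(None, 1.0)]
        px = self.p_x(z)
        return [(0, 1 - px), (1, px)]

    def true_effect(self, scale: EffectScale = EffectScale.LOG_ODDS_RATIO) -> float:
        return intervention_effect(
            self.true_arm_probability(1), self.true_arm_probability(0), scale
        )

    # -- plain-text config -----------------------------------------------
    @classmethod
    def from_file(cls, path) -> "SimConfig":
        """Read a ``key = value`` config file.

        Cell-keyed entries use flat names, e.g. ``p_respond_treatment_x0``
        or (without the covariate) ``p_respond_treatment``; similarly
        ``log_odds_*`` and ``log_imor_*``.  Omitted keys keep defaults.
        """
        raw: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise TrialDataError(f"{path}:{lineno}: expected 'key = value'")
                k, v = (part.strip() for part in line.split("=", 1))
                raw[k.lower()] = v

        def pop_float(key: str):
            return float(raw.pop(key)) if key in raw else None

        kwargs: dict = {}
        for key in ("n_control", "n_treatment", "seed"):
            if key in raw:
                kwargs[key] = int(raw.pop(key))
        px_c, px_t = pop_float("p_x_control"), pop_float("p_x_treatment")
        has_x = px_c is not None or px_t is not None
        if has_x:
            kwargs["p_x_control"] = px_c
            kwargs["p_x_treatment"] = px_t
        else:
            kwargs["p_x_control"] = kwargs["p_x_treatment"] = None

        def cell_map(prefix: str) -> dict | None:
            keys = WITH_X_KEYS if has_x else NO_X_KEYS
            out = {}
            for x, z in keys:
                arm = "treatment" if z == 1 else "control"
                name = f"{prefix}_{arm}" + (f"_x{x}" if x is not None else "")
                if name in raw:
                    out[(x, z)] = float(raw.pop(name))
            return out or None

        pr = cell_map("p_respond")
        lo = cell_map("log_odds")
        li = cell_map("log_imor")
        if pr is not None:
            kwargs["p_respond"] = pr
        if lo is not None:
            kwargs["observed_log_odds"] = lo
        if li is not None:
            kwargs["log_imors"] = SensitivityParameters(li)
        if raw:
            raise TrialDataError(f"unknown config keys in {path}: {sorted(raw)}")
        return cls(**kwargs)


@dataclass(frozen=True)
class SimulatedTrial:
    """Generated records (outcome masked where unobserved) plus the
    retained full truth, aligned index-for-index with ``records``."""

    records: list[ParticipantRecord]
    y_true: np.ndarray
    config: SimConfig


def generate_trial(config: SimConfig, seed: int | None = None) -> SimulatedTrial:
    """Draw one trial from the generative model; reproducible per seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[ParticipantRecord] = []
    truth: list[np.ndarray] = []
    for z in (0, 1):
        n = config.arm_size(z)
        if config.has_x:
            x = rng.binomial(1, config.p_x(z), size=n)
        else:
            x = np.full(n, -1)  # sentinel; never exposed
        pr = np.array(
            [config.p_respond[(int(xi) if xi >= 0 else None, z)] for xi in x]
        )
        r = rng.binomial(1, pr)
        py = np.array(
            [
                config.cell_event_prob(int(xi) if xi >= 0 else None, z, int(ri))
                for xi, ri in zip(x, r)
            ]
        )
        y = rng.binomial(1, py)
        truth.append(y)
        for xi, ri, yi in zip(x, r, y):
            records.append(
                ParticipantRecord(
                    z=z,
                    r=int(ri),
                    y=int(yi) if ri == 1 else None,
                    x=int(xi) if config.has_x else None,
                )
            )
    return SimulatedTrial(records=records, y_true=np.concatenate(truth), config=config)


def simulate_table(config: SimConfig, rng: np.random.Generator) -> TrialTable:
    """Draw the sufficient statistics directly (no record objects).

    Distributionally identical to tallying :func:`generate_trial` output;
    used for large simulation studies where only counts matter.
    """
    keys = WITH_X_KEYS if config.has_x else NO_X_KEYS
    cells: dict[CellKey, CellCounts] = {}
    for z in (0, 1):
        n = config.arm_size(z)
        if config.has_x:
            n_x1 = int(rng.binomial(n, config.p_x(z)))
            sizes = {0: n - n_x1, 1: n_x1}
        else:
            sizes = {None: n}
        for x, n_cell in sizes.items():
            n_obs = int(rng.binomial(n_cell, config.p_respond[(x, z)]))
            events = int(rng.binomial(n_obs, config.cell_event_prob(x, z, 1)))
            cells[(x, z)] = CellCounts(events, n_obs - events, n_cell - n_obs)
    return TrialTable({k: cells[k] for k in keys}, has_x=config.has_x)


# ---------------------------------------------------------------------------
# oracles


def single_impute(table: TrialTable, params: SensitivityParameters) -> TrialTable:
    """Deterministically complete the data under all-infinite log IMORs.

    Missing participants become events under ``+inf`` and non-events under
    ``-inf``; the result is collapsed over the covariate to the 2x2 table
    whose log odds ratio the fully-forced fit must reproduce exactly.
    Totals are preserved.
    """
    if params.has_x != table.has_x:
        if table.has_x and not params.has_x:
            table = table.collapse_x()
        else:
            raise TrialDataError("parameter stratification does not match the table")
    arm = {0: [0, 0], 1: [0, 0]}  # events, non-events
    for key, c in table.cells.items():
        li = params.for_cell(*key)
        if c.n_miss > 0 and not math.isinf(li):
            raise ImorsensError(
                f"single imputation needs an infinite log IMOR in cell {key}"
            )
        arm[key[1]][0] += c.n_event_obs + (c.n_miss if li > 0 else 0)
        arm[key[1]][1] += c.n_nonevent_obs + (c.n_miss if li < 0 else 0)
    cells = {(None, z): CellCounts(arm[z][0], arm[z][1], 0) for z in (0, 1)}
    return TrialTable(cells, has_x=False)


def log_odds_ratio_2x2(table: TrialTable) -> tuple[float, float]:
    """Log odds ratio and its textbook SE from a complete 2x2 table."""
    t = table.collapse_x()
    a, b = t.cells[(None, 1)].n_event_obs, t.cells[(None, 1)].n_nonevent_obs
    c, d = t.cells[(None, 0)].n_event_obs, t.cells[(None, 0)].n_nonevent_obs
    if t.cells[(None, 0)].n_miss or t.cells[(None, 1)].n_miss:
        raise ImorsensError("2x2 log odds ratio requires a completed table")
    if min(a, b, c, d) == 0:
        raise DegenerateEffectError("zero cell in the 2x2 table")
    est = math.log(a / b) - math.log(c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, se


def complete_case_log_odds_ratio(table: TrialTable) -> tuple[float, float]:
    """Complete-case 2x2 log odds ratio (missing participants dropped)."""
    t = table.collapse_x()
    cells = {
        (None, z): CellCounts(
            t.cells[(None, z)].n_event_obs, t.cells[(None, z)].n_nonevent_obs, 0
        )
        for z in (0, 1)
    }
    return log_odds_ratio_2x2(TrialTable(cells, has_x=False))


@dataclass(frozen=True)
class MIResult:
    estimate: float
    se: float
    m_used: int
    n_degenerate: int


def mi_oracle(
    records: Sequence[ParticipantRecord],
    params: SensitivityParameters,
    m: int = 50,
    seed: int | None = None,
) -> MIResult:
    """Multiple-imputation estimate of the log odds ratio, Rubin-pooled.

    Proper imputation: each completed dataset first draws every cell's
    responder log-odds from its asymptotic normal, shifts it by the cell's
    (finite) log IMOR, and then draws the missing outcomes, so that the
    pooled variance accounts for uncertainty in the identifiable
    parameters as well as imputation noise.  Completed datasets with a
    zero 2x2 cell are reported as degenerate, not silently dropped.
    """
    if m < 2:
        raise ImorsensError("multiple imputation needs m >= 2")
    for v in params.values.values():
        if math.isinf(v):
            raise ImorsensError("mi_oracle requires finite log IMORs")
    table = aggregate_records(records)
    if table.has_x and not params.has_x:
        table = table.collapse_x()
    elif params.has_x and not table.has_x:
        raise TrialDataError("parameter stratification does not match the records")
    estimates = {
        k: estimate_observed_log_odds(c, cell_id=k)
        for k, c in table.cells.items()
        if c.n_obs > 0
    }
    rng = np.random.default_rng(seed)
    ests, variances = [], []
    n_degenerate = 0
    for _ in range(m):
        arm = {0: [0, 0], 1: [0, 0]}
        for key, c in table.cells.items():
            arm[key[1]][0] += c.n_event_obs
            arm[key[1]][1] += c.n_nonevent_obs
            if c.n_miss == 0:
                continue
            est = estimates.get(key)
            if est is None:
                raise ImorsensError(
                    f"cell {key}: cannot impute with no observed outcomes and a "
                    "finite log IMOR"
                )
            draw = rng.normal(est.log_odds, math.sqrt(est.variance))
            q = float(expit(draw + params.for_cell(*key)))
            k_events = int(rng.binomial(c.n_miss, q))
            arm[key[1]][0] += k_events
            arm[key[1]][1] += c.n_miss - k_events
        a, b = arm[1]
        c0, d0 = arm[0]
        if min(a, b, c0, d0) == 0:
            n_degenerate += 1
            continue
        ests.append(math.log(a / b) - math.log(c0 / d0))
        variances.append(1 / a + 1 / b + 1 / c0 + 1 / d0)
    if len(ests) < 2:
        raise DegenerateEffectError(
            f"{n_degenerate} of {m} completed datasets degenerate; cannot pool"
        )
    m_used = len(ests)
    qbar = float(np.mean(ests))
    w = float(np.mean(variances))
    b_var = float(np.var(ests, ddof=1))
    total = w + (1 + 1 / m_used) * b_var
    return MIResult(estimate=qbar, se=math.sqrt(total), m_used=m_used, n_degenerate=n_degenerate)


@dataclass(frozen=True)
class BootstrapResult:
    se: float
    n_used: int
    n_failed: int

    def __float__(self) -> float:
        return self.se


def bootstrap_se(
    records: Sequence[ParticipantRecord],
    params: SensitivityParameters,
    b: int = 1000,
    seed: int | None = None,
    scale: EffectScale = EffectScale.LOG_ODDS_RATIO,
) -> BootstrapResult:
    """Nonparametric bootstrap SE of the effect estimate.

    Participants are resampled with replacement within each arm.  Because
    a participant is fully characterised by their cell category, the
    resample is drawn as a per-arm multinomial over category counts —
    identical in distribution to resampling record-by-record — and each
    resample is refit through the ordinary :func:`fit` path.  Resamples
    with inestimable cells or degenerate effects are counted and excluded.
    """
    if b < 2:
        raise ImorsensError("bootstrap needs b >= 2 resamples")
    table = aggregate_records(records)
    if table.has_x and not params.has_x:
        table = table.collapse_x()
    elif params.has_x and not table.has_x:
        raise TrialDataError("parameter stratification does not match the records")
    rng = np.random.default_rng(seed)
    keys_by_arm = {z: table.arm_keys(z) for z in (0, 1)}
    pvals = {}
    for z in (0, 1):
        n_arm = table.arm_total(z)
        flat = []
        for k in keys_by_arm[z]:
            c = table.cells[k]
            flat.extend([c.n_event_obs, c.n_nonevent_obs, c.n_miss])
        pvals[z] = (n_arm, np.asarray(flat, dtype=float) / n_arm)

    ests = []
    n_failed = 0
    for _ in range(b):
        cells: dict[CellKey, CellCounts] = {}
        for z in (0, 1):
            n_arm, p = pvals[z]
            draw = rng.multinomial(n_arm, p)
            for j, k in enumerate(keys_by_arm[z]):
                e, f, miss = draw[3 * j : 3 * j + 3]
                cells[k] = CellCounts(int(e), int(f), int(miss))
        boot = TrialTable(cells, has_x=table.has_x)
        try:
            ests.append(fit(boot, params, scale).estimate)
        except ImorsensError:
            n_failed += 1
    if len(ests) < 2:
        raise DegenerateEffectError("too few successful bootstrap resamples")
    return BootstrapResult(
        se=float(np.std(ests, ddof=1)), n_used=len(ests), n_failed=n_failed
    )
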