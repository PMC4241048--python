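"""Delta-method standard errors for the intervention effect.

Sampling model: within each arm the participants' cell-category labels —
(stratum, observed event), (stratum, observed non-event), (stratum,
missing) — form a single multinomial draw with the arm size fixed; the
two arms are independent; the log IMORs are analyst-supplied constants
carrying no uncertainty.  The arm event probability is a smooth function
of the category counts, so a first-order expansion gives

    var(p_hat_z) = [ sum_i pi_i d_i^2 - (sum_i pi_i d_i)^2 ] / N_z

with ``pi_i`` the category proportions and ``d_i = N_z * dh/dc_i`` the
count-gradient of the arm probability, evaluated at the observed counts.

This choice of sampling model is what makes the estimator's advertised
reductions *exact*: under all-infinite log IMORs the arm probability is a
binomial proportion of a composite category and the log-odds-ratio SE
collapses to the single-imputation ``sqrt(1/a + 1/b + 1/c + 1/d)``; with
no covariate and log IMORs of zero it collapses to the complete-case SE.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import DegenerateEffectError, InestimableCellError
from .sensitivity_model import CellLogOdds, EffectScale, SensitivityParameters
from .trial_data import CellKey, TrialTable

__all__ = ["ArmVariance", "arm_variance", "effect_se", "wald_ci"]


@dataclass(frozen=True)
class ArmVariance:
    """Arm event probability and its sampling variance."""

    z: int
    p_hat: float
    var_p: float

    def __post_init__(self) -> None:
        if self.var_p < 0:
            raise ValueError("variance cannot be negative")


def _cell_gradients(
    c, est: CellLogOdds | None, log_imor: float
) -> tuple[list[float], list[float], float]:
    """Category counts, count-gradients ``d_i`` and the cell's probability
    contribution for one cell.  Returns ``(counts, grads, contribution)``.
    """
    m = c.n_miss
    if c.n_obs == 0:
        if m == 0:
            return [], [], 0.0
        if not math.isinf(log_imor):
            raise InestimableCellError(
                f"cell {getattr(est, 'cell', None)}: missing participants but no "
                "observed outcomes under a finite log IMOR"
            )
        q = 1.0 if log_imor > 0 else 0.0
        return [m], [q], m * q

    if est is None:
        raise InestimableCellError("observed log-odds estimate missing for a cell")
    n = c.n_obs
    s_eff, f_eff = est.events_eff, est.nonevents_eff
    denom = s_eff + f_eff
    p = s_eff / denom
    # d/de and d/df of the observed contribution n * p(e, f), where the
    # continuity offset (if any) is a fixed constant of the correction.
    dp_de = f_eff / denom**2
    dp_df = -s_eff / denom**2
    if math.isinf(log_imor):
        q = 1.0 if log_imor > 0 else 0.0
        dq_de = dq_df = 0.0
    else:
        b = math.exp(log_imor)
        g = s_eff * b + f_eff
        q = s_eff * b / g
        dq_de = b * f_eff / g**2
        dq_df = -s_eff * b / g**2
    d_e = p + n * dp_de + m * dq_de
    d_f = p + n * dp_df + m * dq_df
    d_m = q
    counts = [c.n_event_obs, c.n_nonevent_obs, m]
    grads = [d_e, d_f, d_m]
    return counts, grads, n * p + m * q


def arm_variance(
    table: TrialTable,
    z: int,
    estimates: Mapping[CellKey, CellLogOdds],
    params: SensitivityParameters,
) -> ArmVariance:
    """Multinomial delta-method variance of the arm event probability.

    Cells whose probability is forced by an infinite log IMOR contribute
    zero derivative with respect to their observed log-odds; if the whole
    arm probability is a constant of the data the variance is exactly 0.
    """
    n_arm = table.arm_total(z)
    if n_arm == 0:
        raise InestimableCellError(f"arm z={z} is empty")
    counts: list[float] = []
    grads: list[float] = []
    total = 0.0
    for key in table.arm_keys(z):
        c = table.cells[key]
        if c.n_total == 0:
            continue
        cc, gg, contrib = _cell_gradients(c, estimates.get(key), params.for_cell(*key))
        counts.extend(cc)
        grads.extend(gg)
        total += contrib
    pi = np.asarray(counts, dtype=float) / n_arm
    d = np.asarray(grads, dtype=float)
    mean_d = float(pi @ d)
    var = (float(pi @ d**2) - mean_d**2) / n_arm
    return ArmVariance(z=z, p_hat=total / n_arm, var_p=max(var, 0.0))


def _arm_variance_fd(
    table: TrialTable,
    z: int,
    estimates: Mapping[CellKey, CellLogOdds],
    params: SensitivityParameters,
    step: float = 1e-6,
) -> ArmVariance:
    """Finite-difference check of :func:`arm_variance` (testing aid).

    Recomputes the count-gradient of the arm probability by central
    differences on each category count (arm size held at its observed
    value, continuity offsets frozen) and applies the same multinomial
    covariance.  Must agree with the analytic gradient to ~1e-6.
    """
    n_arm = table.arm_total(z)
    layout: list[tuple[CellKey, float, float]] = []  # (key, offset, log_imor)
    counts: list[float] = []
    for key in table.arm_keys(z):
        c = table.cells[key]
        if c.n_total == 0:
            continue
        log_imor = params.for_cell(*key)
        est = estimates.get(key)
        offset = (est.events_eff - c.n_event_obs) if est is not None else 0.0
        if c.n_obs > 0:
            layout.append((key, offset, log_imor))
            counts.extend([c.n_event_obs, c.n_nonevent_obs, c.n_miss])
        else:
            layout.append((key, math.nan, log_imor))
            counts.append(c.n_miss)

    def h(cvec: np.ndarray) -> float:
        total = 0.0
        i = 0
        for _, offset, log_imor in layout:
            if math.isnan(offset):  # missing-only cell, forced by +/-inf
                m = cvec[i]
                i += 1
                total += m * (1.0 if log_imor > 0 else 0.0)
                continue
            e, f, m = cvec[i : i + 3]
            i += 3
            s_eff, f_eff = e + offset, f + offset
            p = s_eff / (s_eff + f_eff)
            if math.isinf(log_imor):
                q = 1.0 if log_imor > 0 else 0.0
            else:
                b = math.exp(log_imor)
                q = s_eff * b / (s_eff * b + f_eff)
            total += (e + f) * p + m * q
        return total / n_arm

    c0 = np.asarray(counts, dtype=float)
    scale = max(1.0, float(np.max(c0)))
    eps = step * scale
    grad = np.empty_like(c0)
    for i in range(c0.size):
        up, dn = c0.copy(), c0.copy()
        up[i] += eps
        dn[i] -= eps
        grad[i] = (h(up) - h(dn)) / (2 * eps)
    d = grad * n_arm
    pi = c0 / n_arm
    mean_d = float(pi @ d)
    var = (float(pi @ d**2) - mean_d**2) / n_arm
    return ArmVariance(z=z, p_hat=h(c0), var_p=max(var, 0.0))


def effect_se(arm1: ArmVariance, arm0: ArmVariance, scale: EffectScale) -> float:
    """Propagate the two arm variances through the effect transform.

    ``se^2 = g'(p1)^2 var(p1) + g'(p0)^2 var(p0)`` with ``g`` the logit,
    identity, or log link for the log-odds-ratio, risk-difference and
    log-relative-risk scales respectively (arms independent).
    """
    scale = EffectScale(scale)

    def gprime(p: float) -> float:
        if scale is EffectScale.RISK_DIFFERENCE:
            return 1.0
        if scale is EffectScale.LOG_RELATIVE_RISK:
            if p <= 0.0:
                raise DegenerateEffectError("log-RR standard error undefined at p = 0")
            return 1.0 / p
        if not 0.0 < p < 1.0:
            raise DegenerateEffectError(
                "log-OR standard error undefined at a boundary probability"
            )
        return 1.0 / (p * (1.0 - p))

    return math.sqrt(
        gprime(arm1.p_hat) ** 2 * arm1.var_p + gprime(arm0.p_hat) ** 2 * arm0.var_p
    )


def wald_ci(point: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-quantile Wald interval; degenerate at the point when se = 0."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    if se < 0:
        raise ValueError("standard error cannot be negative")
    zq = float(norm.ppf(0.5 + level / 2.0))
    return (point - zq * se, point + zq * se)
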