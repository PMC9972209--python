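"""Cost-minimizing choice of alert sensitivities across diagnostic categories.

For each MDC ``i`` with average missed-case cost ``Cost_FN_i``, ``N_septic_i``
sepsis encounters and ``N_controls_i`` non-septic encounters, the expected
excess cost of operating the alert at sensitivity ``sens_i`` is

    FN_i = Cost_FN_i · N_septic_i · (1 − γ·sens_i)
    FP_i = (Cost_FN_i / α) · N_controls_i · γ_fp · f(sens_i)

where ``f`` is the AUC-constrained map from sensitivity to false-alarm rate,
``α`` converts the cost of a false alarm into missed-case units (one false
alarm costs ``Cost_FN_i / α``), and ``γ`` is physician adherence: ignored
alarms lower the effective detection rate to ``γ·sens_i``.  By default an
ignored alarm also triggers no overtreatment, so γ scales the false-positive
term as well (``gamma_scales_fp``); under that convention γ factors out of
the net benefit and leaves the optimal thresholds unchanged while scaling
savings linearly.

The objective is separable across MDCs, so each ``sens_i`` is found by a
deterministic grid search (default step 0.001) — exactly reproducible and
directly checkable against exhaustive enumeration.  Ties go to the lower
sensitivity (fewer alarms at equal cost).  Three deployment regimes are
compared: a fixed clinical default of 80% sensitivity everywhere, a single
cost-optimized uniform threshold, and fully heterogeneous per-MDC thresholds.

Savings are measured against the no-model baseline in which every sepsis
case incurs its excess cost and no false-alarm cost is paid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np

from .excess_cost import ExcessCostTable
from .roc_model import RocCurve, make_roc, pooled_dor

__all__ = [
    "REGIMES",
    "PolicyConfig",
    "CostBreakdown",
    "OptimizationResult",
    "expected_cost",
    "baseline_cost",
    "optimize_heterogeneous",
    "optimize_uniform",
    "evaluate_fixed",
    "optimize",
]

REGIMES = ("fixed_080", "uniform_optimized", "heterogeneous")

FIXED_SENSITIVITY = 0.80


@dataclass(frozen=True)
class PolicyConfig:
    """Policy-layer parameters of one optimization run.

    alpha : false-alarm conversion factor (>0); higher α = cheaper alarms.
    gamma : physician adherence in (0, 1].
    auc : discriminative performance of the alert model.
    regime : one of ``fixed_080``, ``uniform_optimized``, ``heterogeneous``.
    grid_step : sensitivity grid resolution in (0, 0.1].
    gamma_scales_fp : whether ignored alarms also avoid overtreatment cost.
    """

    alpha: float
    gamma: float
    auc: float
    regime: str = "heterogeneous"
    grid_step: float = 0.001
    gamma_scales_fp: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not (0 < self.gamma <= 1):
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if not (0 < self.grid_step <= 0.1):
            raise ValueError(f"grid_step must be in (0, 0.1], got {self.grid_step}")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")


class CostBreakdown(NamedTuple):
    fn_cost: float
    fp_cost: float
    total: float


@dataclass
class OptimizationResult:
    """Thresholds and cost components of one policy evaluation."""

    regime: str
    sens_by_mdc: dict[str, float]
    fpr_by_mdc: dict[str, float]
    fn_cost: float
    fp_cost: float
    total_cost: float
    baseline_cost: float
    savings: float
    pooled_dor: float
    alpha: float
    gamma: float
    auc: float
    grid_step: float | None = None
    gamma_scales_fp: bool = True

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        if math.isnan(out["pooled_dor"]):
            out["pooled_dor"] = None
        return out


def _sens_grid(step: float) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n + 1)


def _cost_curves(table, roc, grid, alpha, gamma, gamma_scales_fp):
    """Per-MDC FN and FP cost evaluated on the whole sensitivity grid.

    Returns arrays of shape (n_mdc, n_grid).
    """
    cost = table.data["cost_fn"].to_numpy()[:, None]
    n_sep = table.data["n_septic"].to_numpy()[:, None]
    n_ctl = table.data["n_controls"].to_numpy()[:, None]
    fpr = roc.fpr_at(grid)[None, :]
    gamma_fp = gamma if gamma_scales_fp else 1.0
    fn = cost * n_sep * (1.0 - gamma * grid[None, :])
    fp = (cost / alpha) * n_ctl * gamma_fp * fpr
    return fn, fp


def expected_cost(
    table: ExcessCostTable,
    roc,
    sens_by_mdc: Mapping[str, float],
    alpha: float,
    gamma: float,
    gamma_scales_fp: bool = True,
) -> CostBreakdown:
    """Expected FN, FP and total cost of a given sensitivity assignment."""
    missing = [m for m in sens_by_mdc if m not in set(table.mdcs)]
    if missing:
        raise ValueError(f"sensitivities given for unknown MDC(s): {missing}")
    absent = [m for m in table.mdcs if m not in sens_by_mdc]
    if absent:
        raise ValueError(f"no sensitivity for MDC(s): {absent}")

    gamma_fp = gamma if gamma_scales_fp else 1.0
    fn_cost = fp_cost = 0.0
    for row in table.data.itertuples(index=False):
        s = float(sens_by_mdc[row.mdc])
        if not (0 <= s <= 1):
            raise ValueError(f"sensitivity for {row.mdc} outside [0, 1]: {s}")
        fn_cost += row.cost_fn * row.n_septic * (1.0 - gamma * s)
        fp_cost += (row.cost_fn / alpha) * row.n_controls * gamma_fp * roc.fpr_at(s)
    return CostBreakdown(fn_cost, fp_cost, fn_cost + fp_cost)


def baseline_cost(table: ExcessCostTable) -> float:
    """Total excess cost with no predictive model deployed.

    Every sepsis case incurs its category's excess cost; no alarms, so no
    false-alarm cost: ``Σ_i Cost_FN_i · N_septic_i``.
    """
    return table.total_excess


def _package(table, roc, sens, alpha, gamma, regime, grid_step, gamma_scales_fp):
    sens_by_mdc = {m: float(s) for m, s in zip(table.mdcs, sens)}
    fpr_by_mdc = {m: float(roc.fpr_at(s)) for m, s in sens_by_mdc.items()}
    fn, fp, total = expected_cost(
        table, roc, sens_by_mdc, alpha, gamma, gamma_scales_fp
    )
    base = baseline_cost(table)
    result = OptimizationResult(
        regime=regime,
        sens_by_mdc=sens_by_mdc,
        fpr_by_mdc=fpr_by_mdc,
        fn_cost=float(fn),
        fp_cost=float(fp),
        total_cost=float(total),
        baseline_cost=float(base),
        savings=float(base - total),
        pooled_dor=float("nan"),
        alpha=alpha,
        gamma=gamma,
        auc=roc.auc,
        grid_step=grid_step,
        gamma_scales_fp=gamma_scales_fp,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        result.pooled_dor = pooled_dor(result, table)
    return result


def optimize_heterogeneous(
    table: ExcessCostTable,
    roc,
    alpha: float,
    gamma: float,
    grid_step: float = 0.001,
    gamma_scales_fp: bool = True,
) -> OptimizationResult:
    """Choose one sensitivity per MDC to minimize total expected cost.

    The objective is a sum of per-MDC terms, so each ``sens_i`` is the grid
    minimizer of its own term; ties resolve to the lowest sensitivity.
    """
    roc = _as_roc(roc)
    grid = _sens_grid(grid_step)
    fn, fp = _cost_curves(table, roc, grid, alpha, gamma, gamma_scales_fp)
    idx = np.argmin(fn + fp, axis=1)  # first minimum == lowest sensitivity
    return _package(
        table, roc, grid[idx], alpha, gamma, "heterogeneous", grid_step, gamma_scales_fp
    )


def optimize_uniform(
    table: ExcessCostTable,
    roc,
    alpha: float,
    gamma: float,
    grid_step: float = 0.001,
    gamma_scales_fp: bool = True,
) -> OptimizationResult:
    """Choose a single shared sensitivity minimizing total expected cost."""
    roc = _as_roc(roc)
    grid = _sens_grid(grid_step)
    fn, fp = _cost_curves(table, roc, grid, alpha, gamma, gamma_scales_fp)
    total = (fn + fp).sum(axis=0)
    j = int(np.argmin(total))
    sens = np.full(len(table.mdcs), grid[j])
    return _package(
        table, roc, sens, alpha, gamma, "uniform_optimized", grid_step, gamma_scales_fp
    )


def evaluate_fixed(
    table: ExcessCostTable,
    roc,
    alpha: float,
    gamma: float,
    sens: float = FIXED_SENSITIVITY,
    gamma_scales_fp: bool = True,
) -> OptimizationResult:
    """Evaluate (not optimize) a fixed uniform sensitivity, default 80%."""
    roc = _as_roc(roc)
    values = np.full(len(table.mdcs), float(sens))
    return _package(
        table, roc, values, alpha, gamma, "fixed_080", None, gamma_scales_fp
    )


def optimize(table: ExcessCostTable, config: PolicyConfig) -> OptimizationResult:
    """Dispatch on ``config.regime``."""
    roc = make_roc(config.auc)
    if config.regime == "heterogeneous":
        return optimize_heterogeneous(
            table, roc, config.alpha, config.gamma, config.grid_step,
            config.gamma_scales_fp,
        )
    if config.regime == "uniform_optimized":
        return optimize_uniform(
            table, roc, config.alpha, config.gamma, config.grid_step,
            config.gamma_scales_fp,
        )
    return evaluate_fixed(
        table, roc, config.alpha, config.gamma,
        gamma_scales_fp=config.gamma_scales_fp,
    )


def _as_roc(roc):
    if isinstance(roc, (int, float)):
        return make_roc(float(roc))
    return roc
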