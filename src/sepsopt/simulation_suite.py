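"""Parameter sweeps over α × γ × AUC × deployment regime.

Reproduces, on any :class:`~sepsopt.excess_cost.ExcessCostTable`, the policy
comparisons of interest: cost savings and pooled diagnostic odds ratio as a
function of false-alarm tolerance (α), physician adherence (γ) and model
discrimination (AUC), for the three deployment regimes (fixed 80%
sensitivity, cost-optimized uniform threshold, per-MDC heterogeneous
thresholds).  Everything downstream of the claims generator is
deterministic, so two sweeps over the same table are identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .excess_cost import ExcessCostTable
from .policy_optimizer import (
    REGIMES,
    evaluate_fixed,
    optimize_heterogeneous,
    optimize_uniform,
)
from .roc_model import make_roc

__all__ = [
    "ParameterGrid",
    "DEFAULT_GRID",
    "HEADLINE_POINT",
    "sweep",
    "compare_regimes",
    "adherence_curve",
    "render_report",
]

SWEEP_COLUMNS = [
    "alpha",
    "gamma",
    "auc",
    "regime",
    "fn_cost",
    "fp_cost",
    "total_cost",
    "baseline_cost",
    "savings",
    "pooled_dor",
    "sens_min",
    "sens_median",
    "sens_max",
]

#: Headline operating point for summary reporting: α=20 (the maximum
#: false-alarm penalty used in the PhysioNet sepsis challenge), full
#: adherence, and the most accurate of the three candidate models.
HEADLINE_POINT = (20.0, 1.0, 0.9)


@dataclass(frozen=True)
class ParameterGrid:
    """Default grid: integer α 17–27, γ 0.5–1.0 by 0.1, AUC {0.82, 0.87, 0.9}."""

    alphas: tuple[float, ...] = tuple(float(a) for a in range(17, 28))
    gammas: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.01, 0.1), 10))
    aucs: tuple[float, ...] = (0.82, 0.87, 0.9)

    def __post_init__(self) -> None:
        if not (self.alphas and self.gammas and self.aucs):
            raise ValueError("parameter grid must be non-empty on every axis")
        if any(a <= 0 for a in self.alphas):
            raise ValueError("alpha values must be > 0")
        if any(not (0 < g <= 1) for g in self.gammas):
            raise ValueError("gamma values must lie in (0, 1]")
        if any(not (0.5 < a <= 1) for a in self.aucs):
            raise ValueError("auc values must lie in (0.5, 1]")

    @property
    def n_points(self) -> int:
        return len(self.alphas) * len(self.gammas) * len(self.aucs)


DEFAULT_GRID = ParameterGrid()

_OPTIMIZERS = {
    "heterogeneous": optimize_heterogeneous,
    "uniform_optimized": optimize_uniform,
}


def sweep(
    table: ExcessCostTable,
    grid: ParameterGrid | None = None,
    regimes: Sequence[str] = REGIMES,
    grid_step: float = 0.001,
    gamma_scales_fp: bool = True,
) -> pd.DataFrame:
    """Exhaustive evaluation over the parameter grid; one row per point × regime."""
    grid = grid or DEFAULT_GRID
    unknown = [r for r in regimes if r not in REGIMES]
    if unknown:
        raise ValueError(f"unknown regime(s): {unknown}")
    if not regimes:
        raise ValueError("at least one regime is required")

    rows = []
    for auc in grid.aucs:
        roc = make_roc(auc)
        for alpha in grid.alphas:
            for gamma in grid.gammas:
                for regime in regimes:
                    if regime == "fixed_080":
                        res = evaluate_fixed(
                            table, roc, alpha, gamma, gamma_scales_fp=gamma_scales_fp
                        )
                    else:
                        res = _OPTIMIZERS[regime](
                            table, roc, alpha, gamma, grid_step, gamma_scales_fp
                        )
                    sens = np.fromiter(res.sens_by_mdc.values(), float)
                    rows.append(
                        (
                            alpha,
                            gamma,
                            auc,
                            regime,
                            res.fn_cost,
                            res.fp_cost,
                            res.total_cost,
                            res.baseline_cost,
                            res.savings,
                            res.pooled_dor,
                            sens.min(),
                            float(np.median(sens)),
                            sens.max(),
                        )
                    )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def compare_regimes(
    sweep_table: pd.DataFrame, at: tuple[float, float, float]
) -> dict[str, float]:
    """Pairwise savings and DOR deltas between regimes at one grid point.

    ``at`` is (alpha, gamma, auc).  By regime nesting the savings deltas are
    non-negative: heterogeneous ≥ uniform_optimized ≥ fixed_080.
    """
    alpha, gamma, auc = at
    point = sweep_table[
        np.isclose(sweep_table["alpha"], alpha)
        & np.isclose(sweep_table["gamma"], gamma)
        & np.isclose(sweep_table["auc"], auc)
    ]
    by_regime = {r: g.iloc[0] for r, g in point.groupby("regime")}
    missing = [r for r in REGIMES if r not in by_regime]
    if missing:
        raise ValueError(f"regime(s) {missing} absent at grid point {at}")

    het, uni, fix = (
        by_regime["heterogeneous"],
        by_regime["uniform_optimized"],
        by_regime["fixed_080"],
    )
    return {
        "savings_het_minus_uniform": float(het["savings"] - uni["savings"]),
        "savings_uniform_minus_fixed": float(uni["savings"] - fix["savings"]),
        "savings_het_minus_fixed": float(het["savings"] - fix["savings"]),
        "dor_het_minus_uniform": float(het["pooled_dor"] - uni["pooled_dor"]),
        "dor_uniform_minus_fixed": float(uni["pooled_dor"] - fix["pooled_dor"]),
        "dor_het_minus_fixed": float(het["pooled_dor"] - fix["pooled_dor"]),
    }


def adherence_curve(
    table: ExcessCostTable,
    alphas: Sequence[float] | None = None,
    auc: float = 0.87,
    gammas: Sequence[float] | None = None,
    regimes: Sequence[str] = REGIMES,
    grid_step: float = 0.001,
    gamma_scales_fp: bool = True,
) -> pd.DataFrame:
    """Savings as a function of adherence γ and α at a single fixed AUC."""
    grid = ParameterGrid(
        alphas=tuple(alphas) if alphas else DEFAULT_GRID.alphas,
        gammas=tuple(gammas) if gammas else DEFAULT_GRID.gammas,
        aucs=(auc,),
    )
    return sweep(table, grid, regimes, grid_step, gamma_scales_fp)


def render_report(
    sweep_table: pd.DataFrame,
    outdir,
    headline: tuple[float, float, float] = HEADLINE_POINT,
    make_figures: bool = True,
) -> dict[str, str]:
    """Write sweep CSV, a JSON summary at the headline point, and heat maps.

    Heat maps show savings and pooled DOR over (α, AUC) per regime at the
    headline γ.  Returns a manifest mapping artifact names to paths.
    """
    if not len(sweep_table):
        raise ValueError("sweep table is empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    csv_path = outdir / "sweep.csv"
    sweep_table.to_csv(csv_path, index=False)
    paths["sweep_csv"] = str(csv_path)

    alpha, gamma, auc = headline
    summary: dict = {"headline": {"alpha": alpha, "gamma": gamma, "auc": auc}}
    point = sweep_table[
        np.isclose(sweep_table["alpha"], alpha)
        & np.isclose(sweep_table["gamma"], gamma)
        & np.isclose(sweep_table["auc"], auc)
    ]
    for regime, g in point.groupby("regime"):
        row = g.iloc[0]
        summary[regime] = {
            "savings": float(row["savings"]),
            "pooled_dor": float(row["pooled_dor"]),
            "fn_cost": float(row["fn_cost"]),
            "fp_cost": float(row["fp_cost"]),
        }
    if all(r in summary for r in REGIMES):
        summary["deltas"] = compare_regimes(sweep_table, headline)
    json_path = outdir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2) + "\n")
    paths["summary_json"] = str(json_path)

    if make_figures:
        paths.update(_heatmaps(sweep_table, outdir, gamma))
    return paths


def _heatmaps(sweep_table: pd.DataFrame, outdir: Path, gamma: float) -> dict[str, str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, str] = {}
    at_gamma = sweep_table[np.isclose(sweep_table["gamma"], gamma)]
    for metric in ("savings", "pooled_dor"):
        regimes = sorted(at_gamma["regime"].unique())
        fig, axes = plt.subplots(
            1, len(regimes), figsize=(4.2 * len(regimes), 3.4), squeeze=False
        )
        for ax, regime in zip(axes[0], regimes):
            pivot = (
                at_gamma[at_gamma["regime"] == regime]
                .pivot_table(index="auc", columns="alpha", values=metric)
                .sort_index()
            )
            mesh = ax.pcolormesh(
                pivot.columns, pivot.index, pivot.to_numpy(), shading="nearest"
            )
            ax.set_title(regime)
            ax.set_xlabel("α (false-alarm tolerance)")
            ax.set_ylabel("AUC")
            fig.colorbar(mesh, ax=ax)
        fig.suptitle(f"{metric} at γ={gamma}")
        fig.tight_layout()
        path = outdir / f"heatmap_{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths[f"heatmap_{metric}"] = str(path)
    return paths
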