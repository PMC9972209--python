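"""AUC-constrained ROC curves and diagnostic-accuracy metrics.

The alert model itself (a sepsis risk score) is abstracted by its ROC
curve: a map ``f`` from a chosen sensitivity to the false-positive (false
alarm) rate the model must then accept.  The default family is the
equal-variance binormal ROC — scores for septic and non-septic patients are
unit-variance Gaussians separated by ``d`` — which has exactly one free
parameter and is therefore identified by the AUC alone:

    d   = sqrt(2) * Phi^{-1}(AUC)
    f(s) = Phi(Phi^{-1}(s) - d)

with ``Phi`` the standard normal CDF.  An empirical (sens, fpr) table read
from CSV can be substituted for the parametric family.

Diagnostic odds ratio (DOR): odds of a positive test in patients with
disease over the odds of a positive test in patients without disease,
``[sens/(1-sens)] / [fpr/(1-fpr)]``; pooled across categories by summing
confusion counts.  At boundary operating points the DOR is undefined and is
returned as NaN with a warning, never as a silently wrong number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "RocDomainError",
    "RocCurve",
    "EmpiricalRocCurve",
    "make_roc",
    "fpr_at",
    "auc_quadrature",
    "dor",
    "pooled_dor",
    "read_empirical_roc",
]

BINORMAL = "binormal_equal_variance"


class RocDomainError(ValueError):
    """AUC or sensitivity outside the admissible domain."""


@dataclass(frozen=True)
class RocCurve:
    """Equal-variance binormal ROC curve identified by its AUC."""

    auc: float
    family: str = BINORMAL
    separation: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.5 < self.auc <= 1.0):
            raise RocDomainError(f"auc must be in (0.5, 1], got {self.auc}")
        if self.family != BINORMAL:
            raise RocDomainError(
                f"unknown parametric ROC family {self.family!r}; "
                f"use {BINORMAL!r} or an EmpiricalRocCurve"
            )
        object.__setattr__(self, "separation", float(np.sqrt(2.0) * norm.ppf(self.auc)))

    def fpr_at(self, sens):
        """False-positive rate forced by choosing sensitivity ``sens``."""
        s = np.asarray(sens, dtype=float)
        if np.any((s < 0) | (s > 1)):
            raise RocDomainError("sensitivity must lie in [0, 1]")
        with np.errstate(invalid="ignore"):
            out = norm.cdf(norm.ppf(s) - self.separation)
        out = np.where(s <= 0.0, 0.0, np.where(s >= 1.0, 1.0, out))
        return float(out) if np.isscalar(sens) else out


@dataclass(frozen=True)
class EmpiricalRocCurve:
    """Piecewise-linear ROC curve from a monotone (sens, fpr) table."""

    sens: np.ndarray
    fpr: np.ndarray
    family: str = "empirical"

    def __post_init__(self) -> None:
        s, f = np.asarray(self.sens, float), np.asarray(self.fpr, float)
        if s.shape != f.shape or s.ndim != 1 or len(s) < 2:
            raise RocDomainError("empirical ROC needs two matched 1-d columns")
        if np.any(np.diff(s) <= 0) or np.any(np.diff(f) < 0):
            raise RocDomainError("empirical ROC must be monotone in sens and fpr")
        if s[0] != 0 or f[0] != 0 or s[-1] != 1 or f[-1] != 1:
            raise RocDomainError("empirical ROC must span (0,0) to (1,1)")
        object.__setattr__(self, "sens", s)
        object.__setattr__(self, "fpr", f)

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.sens, self.fpr))

    def fpr_at(self, sens):
        s = np.asarray(sens, dtype=float)
        if np.any((s < 0) | (s > 1)):
            raise RocDomainError("sensitivity must lie in [0, 1]")
        out = np.interp(s, self.sens, self.fpr)
        return float(out) if np.isscalar(sens) else out


def make_roc(auc: float, family: str = BINORMAL):
    """Construct an AUC-identified ROC curve of the given family."""
    return RocCurve(auc=auc, family=family)


def fpr_at(roc, sens):
    """Functional form of ``roc.fpr_at`` (convenience)."""
    return roc.fpr_at(sens)


def auc_quadrature(roc) -> float:
    """Recompute the AUC of a curve by numerical quadrature.

    Integrates sensitivity over the false-positive axis,
    ``∫0..1 TPR(u) du`` with ``u`` the FPR; for the binormal family
    ``TPR(u) = Phi(Phi^{-1}(u) + d)``.  Round-trip check for constructors.
    """
    if isinstance(roc, EmpiricalRocCurve):
        return roc.auc
    d = roc.separation
    value, _ = integrate.quad(
        lambda u: norm.cdf(norm.ppf(u) + d), 0.0, 1.0, limit=200, epsabs=1e-10
    )
    return float(value)


def _warn_undefined(context: str) -> float:
    warnings.warn(
        f"diagnostic odds ratio undefined ({context}); returning NaN",
        RuntimeWarning,
        stacklevel=3,
    )
    return float("nan")


def dor(sens: float, fpr: float) -> float:
    """Diagnostic odds ratio of a single operating point.

    Defined only for interior points; boundary operating points (perfect
    sensitivity, zero false alarms, ...) return NaN with a RuntimeWarning.
    """
    if not (0 <= sens <= 1 and 0 <= fpr <= 1):
        raise RocDomainError("sens and fpr must lie in [0, 1]")
    if sens in (0.0, 1.0) or fpr in (0.0, 1.0):
        return _warn_undefined(f"boundary point sens={sens}, fpr={fpr}")
    return (sens / (1.0 - sens)) / (fpr / (1.0 - fpr))


def pooled_dor(result, table, roc=None) -> float:
    """DOR from confusion counts pooled over the table's categories.

    ``result`` is either an optimizer result (anything exposing
    ``sens_by_mdc`` and ``fpr_by_mdc`` mappings) or a plain mapping
    MDC→sensitivity, in which case ``roc`` supplies the FPRs.  Pooled
    counts:

        TP = Σ sens_i·n_septic_i      FN = Σ (1-sens_i)·n_septic_i
        FP = Σ fpr_i·n_controls_i     TN = Σ (1-fpr_i)·n_controls_i

    and DOR = (TP·TN)/(FN·FP); any zero cell yields NaN with a warning.
    """
    if hasattr(result, "sens_by_mdc"):
        sens_map: Mapping[str, float] = result.sens_by_mdc
        fpr_map: Mapping[str, float] | None = getattr(result, "fpr_by_mdc", None)
    else:
        sens_map, fpr_map = result, None
    if fpr_map is None:
        if roc is None:
            raise ValueError("roc is required when result carries no fpr_by_mdc")
        fpr_map = {m: roc.fpr_at(s) for m, s in sens_map.items()}

    missing = [m for m in table.mdcs if m not in sens_map]
    if missing:
        raise ValueError(f"no sensitivity for MDC(s): {missing}")

    rows = table.data.set_index("mdc")
    tp = fn = fp = tn = 0.0
    for mdc in table.mdcs:
        s, f = float(sens_map[mdc]), float(fpr_map[mdc])
        n_sep, n_ctl = rows.at[mdc, "n_septic"], rows.at[mdc, "n_controls"]
        tp += s * n_sep
        fn += (1.0 - s) * n_sep
        fp += f * n_ctl
        tn += (1.0 - f) * n_ctl
    if min(tp, fn, fp, tn) <= 0.0:
        return _warn_undefined(
            f"pooled cell is zero (TP={tp:.3g}, FN={fn:.3g}, FP={fp:.3g}, TN={tn:.3g})"
        )
    return (tp * tn) / (fn * fp)


def read_empirical_roc(path) -> EmpiricalRocCurve:
    """Read a two-column (sens, fpr) CSV into an empirical ROC curve."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if "sens" not in cols or "fpr" not in cols:
        raise RocDomainError("empirical ROC CSV needs 'sens' and 'fpr' columns")
    df.columns = cols
    order = np.argsort(df["sens"].to_numpy())
    return EmpiricalRocCurve(
        sens=df["sens"].to_numpy()[order], fpr=df["fpr"].to_numpy()[order]
    )
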