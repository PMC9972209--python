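"""Matched-control estimation of the excess cost of secondary sepsis.

Each sepsis-flagged encounter is compared with the control in the same
(DRG code, DRG weight) stratum whose Charlson comorbidity index is closest;
the payment difference is the encounter's excess cost.  Pair excesses are
summarized per DRG, averaged per MDC into an :class:`ExcessCostTable`
(the optimizer's input: cost of a missed case, septic and control counts
per diagnostic category), and optionally scaled from a single site to the
national Medicare population.

Matching is with replacement: each sepsis case searches the full control
pool of its stratum, so its match never depends on other sepsis cases or on
row order.  Ties in comorbidity distance are broken by the lexicographically
smallest control encounter id.  Because identifiers are assigned
independently of payments, this tie-break is outcome-blind — it keeps the
estimator unbiased where a payment-based tie-break would systematically
select cheap (or similar-priced) controls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .synthetic_claims import ConfigurationError, validate_claims

__all__ = [
    "MatchResult",
    "ExcessCostTable",
    "ScalingFactors",
    "match_controls",
    "summarize_drg",
    "aggregate_mdc",
    "scale_national",
]

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["septic_id", "control_id", "drg_code", "drg_weight", "excess"]


@dataclass
class MatchResult:
    """Pairs produced by :func:`match_controls` plus any unmatched cases.

    ``pairs`` has one row per matched sepsis encounter with columns
    ``septic_id, control_id, drg_code, drg_weight, excess``;
    ``unmatched`` holds sepsis rows whose stratum had no control.
    """

    pairs: pd.DataFrame
    unmatched: pd.DataFrame

    def __len__(self) -> int:
        return len(self.pairs)


def match_controls(claims: pd.DataFrame) -> MatchResult:
    """Match every sepsis encounter to its nearest-comorbidity control.

    Within each (drg_code, drg_weight) stratum the chosen control minimizes
    ``|charlson_septic - charlson_control|``; remaining ties go to the
    smallest control ``encounter_id``.  Matching is with replacement.
    Sepsis rows with an empty control stratum are reported in
    ``result.unmatched`` (and logged), not raised.
    """
    validate_claims(claims)
    if not claims["sepsis_flag"].any():
        raise ValueError("claims must contain at least one sepsis-flagged row")

    pair_rows: list[tuple] = []
    unmatched_frames: list[pd.DataFrame] = []
    for (code, weight), stratum in claims.groupby(
        ["drg_code", "drg_weight"], sort=True
    ):
        septic = stratum[stratum["sepsis_flag"]]
        if septic.empty:
            continue
        controls = stratum[~stratum["sepsis_flag"]].sort_values("encounter_id")
        if controls.empty:
            logger.warning(
                "no controls in stratum (drg=%s, weight=%s): %d sepsis row(s) unmatched",
                code,
                weight,
                len(septic),
            )
            unmatched_frames.append(septic)
            continue
        ctl_charlson = controls["charlson"].to_numpy()
        ctl_payment = controls["payment"].to_numpy()
        ctl_ids = controls["encounter_id"].to_numpy()
        for row in septic.itertuples(index=False):
            # argmin returns the first minimum; controls are id-sorted, so
            # ties in |ΔCharlson| resolve to the smallest encounter_id
            j = int(np.argmin(np.abs(ctl_charlson - row.charlson)))
            pair_rows.append(
                (
                    row.encounter_id,
                    ctl_ids[j],
                    code,
                    weight,
                    float(row.payment - ctl_payment[j]),
                )
            )

    pairs = pd.DataFrame(pair_rows, columns=PAIR_COLUMNS)
    unmatched = (
        pd.concat(unmatched_frames, ignore_index=True)
        if unmatched_frames
        else claims.iloc[0:0]
    )
    return MatchResult(pairs=pairs, unmatched=unmatched)


def summarize_drg(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-DRG pair counts and mean/median excess (the excess distribution).

    Returns a frame with columns ``drg_code, n_pairs, mean_excess,
    median_excess``; empty input yields an empty frame.
    """
    if not len(pairs):
        return pd.DataFrame(
            columns=["drg_code", "n_pairs", "mean_excess", "median_excess"]
        )
    grouped = pairs.groupby("drg_code", sort=True)["excess"]
    out = pd.DataFrame(
        {
            "n_pairs": grouped.size(),
            "mean_excess": grouped.mean(),
            "median_excess": grouped.median(),
        }
    ).reset_index()
    return out


@dataclass
class ExcessCostTable:
    """Per-MDC cost of a missed sepsis case and cohort counts.

    ``data`` columns: ``mdc`` (category label), ``cost_fn`` (average excess
    cost of a false negative, USD, may be negative), ``n_septic`` and
    ``n_controls`` (encounter counts).  ``scope`` records whether the
    numbers describe the study site or the national Medicare population.
    This is also the hand-transcription format for published per-MDC
    aggregate tables, so the optimizer can run without patient-level data.
    """

    data: pd.DataFrame
    scope: Literal["site", "national"] = "site"

    COLUMNS = ["mdc", "cost_fn", "n_septic", "n_controls"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"ExcessCostTable missing columns: {missing}")
        self.data = self.data[self.COLUMNS].reset_index(drop=True)
        if self.data["mdc"].duplicated().any():
            raise ValueError("duplicate MDC rows in ExcessCostTable")
        if (self.data[["n_septic", "n_controls"]] < 0).any().any():
            raise ValueError("counts must be non-negative")
        if len(self.data) and not (self.data["n_septic"] > 0).any():
            raise ValueError("at least one MDC must have n_septic > 0")
        if self.scope not in ("site", "national"):
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def mdcs(self) -> list[str]:
        return list(self.data["mdc"])

    @property
    def total_excess(self) -> float:
        """Σ_i cost_fn_i · n_septic_i — the no-model excess cost."""
        return float((self.data["cost_fn"] * self.data["n_septic"]).sum())

    def to_csv(self, path) -> None:
        """Write the table plus a sidecar ``<path>.meta.json`` with scope."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps({"scope": self.scope}) + "\n"
        )

    @classmethod
    def from_csv(cls, path) -> "ExcessCostTable":
        path = Path(path)
        data = pd.read_csv(path)
        for col in ("cost_fn", "n_septic", "n_controls"):
            if col in data.columns and not np.issubdtype(data[col].dtype, np.number):
                bad = pd.to_numeric(data[col], errors="coerce").isna()
                row = int(data.index[bad][0]) + 2
                raise ValueError(
                    f"non-numeric {col!r} value {data.loc[bad, col].iloc[0]!r} "
                    f"at line {row} of {path}"
                )
        meta = path.with_suffix(path.suffix + ".meta.json")
        scope = "site"
        if meta.exists():
            scope = json.loads(meta.read_text()).get("scope", "site")
        data["mdc"] = data["mdc"].astype(str)
        return cls(data=data, scope=scope)

    @classmethod
    def from_records(cls, records, scope: str = "site") -> "ExcessCostTable":
        """Build from an iterable of (mdc, cost_fn, n_septic, n_controls)."""
        return cls(pd.DataFrame(records, columns=cls.COLUMNS), scope=scope)


def aggregate_mdc(
    pairs: pd.DataFrame,
    claims: pd.DataFrame,
    weighting: Literal["drg_mean", "pair_weighted"] = "drg_mean",
) -> ExcessCostTable:
    """Average DRG-level excesses into a per-MDC :class:`ExcessCostTable`.

    ``cost_fn`` is the unweighted mean of the MDC's DRG-level mean excesses
    (``weighting="drg_mean"``, the default) or the mean over all of the
    MDC's pair excesses (``"pair_weighted"``).  ``n_septic``/``n_controls``
    count all sepsis/control encounters of the MDC in ``claims``.
    """
    if weighting not in ("drg_mean", "pair_weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    drg_to_mdc = claims.drop_duplicates("drg_code").set_index("drg_code")["mdc"]
    missing = set(pairs["drg_code"]) - set(drg_to_mdc.index)
    if missing:
        raise ValueError(f"DRG(s) with no MDC assignment in claims: {sorted(missing)}")

    tagged = pairs.assign(mdc=pairs["drg_code"].map(drg_to_mdc))
    if weighting == "drg_mean":
        drg_means = tagged.groupby(["mdc", "drg_code"])["excess"].mean()
        cost = drg_means.groupby("mdc").mean()
    else:
        cost = tagged.groupby("mdc")["excess"].mean()

    counts = claims.groupby("mdc")["sepsis_flag"].agg(
        n_septic="sum", n_controls=lambda s: int((~s).sum())
    )
    data = (
        pd.DataFrame({"cost_fn": cost})
        .join(counts, how="left")
        .reset_index()
        .rename(columns={"index": "mdc"})
    )
    data["n_septic"] = data["n_septic"].astype(int)
    data["n_controls"] = data["n_controls"].astype(int)
    return ExcessCostTable(data=data, scope="site")


@dataclass
class ScalingFactors:
    """Site→national scaling inputs.

    ``payment_ratio`` maps a DRG code (``level="drg"``) or an MDC label
    (``level="mdc"``) to the ratio of national to site payments; site costs
    are multiplied by it.  ``site_share`` is the fraction of national
    Medicare patients treated at the site; counts are divided by it.
    """

    payment_ratio: Mapping[str, float]
    site_share: float
    level: Literal["drg", "mdc"] = "mdc"

    def __post_init__(self) -> None:
        if not (0 < self.site_share <= 1):
            raise ConfigurationError(
                f"site_share must be in (0, 1], got {self.site_share}"
            )
        if any(r <= 0 for r in self.payment_ratio.values()):
            raise ConfigurationError("all payment ratios must be > 0")
        if self.level not in ("drg", "mdc"):
            raise ConfigurationError(f"unknown scaling level {self.level!r}")


def scale_national(
    table: ExcessCostTable,
    factors: ScalingFactors,
    drg_to_mdc: Mapping[str, str] | None = None,
) -> ExcessCostTable:
    """Scale a site-scope table to the national Medicare population.

    DRG-level ratios are first aggregated to each MDC by an unweighted mean
    over the MDC's DRGs (requires ``drg_to_mdc``); MDC-level ratios apply
    directly.  Costs are multiplied by the ratio, counts divided by
    ``site_share``, and scope flips to ``"national"``.
    """
    if table.scope != "site":
        raise ValueError("scale_national expects a site-scope table")

    if factors.level == "mdc":
        ratio = pd.Series(dict(factors.payment_ratio), dtype=float)
    else:
        if drg_to_mdc is None:
            raise ConfigurationError(
                "drg_to_mdc mapping is required for DRG-level payment ratios"
            )
        per_drg = pd.Series(dict(factors.payment_ratio), dtype=float)
        mdc_of = pd.Series(dict(drg_to_mdc))
        ratio = per_drg.groupby(mdc_of.reindex(per_drg.index)).mean()

    missing = set(table.mdcs) - set(ratio.index)
    if missing:
        raise ConfigurationError(f"no payment ratio for MDC(s): {sorted(missing)}")

    data = table.data.copy()
    data["cost_fn"] = data["cost_fn"] * data["mdc"].map(ratio)
    data["n_septic"] = data["n_septic"] / factors.site_share
    data["n_controls"] = data["n_controls"] / factors.site_share
    return ExcessCostTable(data=data, scope="national")
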