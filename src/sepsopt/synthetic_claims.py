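"""Seeded generator for claims-style inpatient encounter tables.

Emulates a Medicare prospective-payment cohort: encounters are grouped into
DRGs (Diagnosis-Related Groups, each with a payment weight), DRGs are
partitioned into MDCs (Major Diagnostic Categories, roughly hospital
departments), and every encounter carries a Charlson comorbidity index, a
payer payment in USD and a flag for a secondary severe-sepsis/septic-shock
diagnosis.  Payments follow the prospective-payment logic: a base amount
proportional to the DRG weight, a comorbidity-dependent increment, a
heavy-tailed multiplicative "outlier payment" factor, and — for flagged
encounters — a known per-MDC excess cost that may be negative.

Because every injected excess is known, the generator gives downstream
estimators a ground truth to recover.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "ClaimsParseError",
    "GeneratorConfig",
    "CLAIM_COLUMNS",
    "SEPSIS_DRGS",
    "DEFAULT_TRUE_EXCESS_BY_MDC",
    "DEFAULT_SEPTIC_PER_DRG_BY_MDC",
    "default_drg_codes",
    "default_mdc_assignment",
    "generate_claims",
    "write_claims",
    "read_claims",
    "validate_claims",
]


class ConfigurationError(ValueError):
    """A generator or scaling configuration field is out of range."""


class ClaimsParseError(ValueError):
    """A claims CSV file violates the schema; the message cites the row."""


#: Canonical column order of a claim table (in memory and on disk).
CLAIM_COLUMNS = [
    "encounter_id",
    "drg_code",
    "drg_weight",
    "mdc",
    "charlson",
    "payment",
    "sepsis_flag",
]

#: Sepsis-specific DRGs; encounters in these groups are excluded upstream
#: because the target of estimation is the *excess* cost of a secondary
#: sepsis diagnosis in non-sepsis DRGs.
SEPSIS_DRGS = frozenset({"870", "871", "872"})

#: Default injected excess cost (USD) of a secondary sepsis diagnosis per
#: MDC.  The spread mimics what site-level claims show: a very expensive
#: pre-MDC group (transplants, ECMO), a broad midrange, and one *negative*
#: category — infectious-disease DRGs where the sepsis-flagged encounter can
#: be cheaper than its matched control (outlier payments for unrelated care,
#: or earlier discharge through death).
DEFAULT_TRUE_EXCESS_BY_MDC: Mapping[str, float] = {
    "PRE_MDC": 85_000.0,
    "NERVOUS": 18_000.0,
    "RESPIRATORY": 30_000.0,
    "CIRCULATORY": 28_000.0,
    "DIGESTIVE": 22_000.0,
    "HEPATOBILIARY": 26_000.0,
    "MUSCULOSKELETAL": 15_000.0,
    "SKIN": 12_000.0,
    "ENDOCRINE": 17_000.0,
    "KIDNEY_URINARY": 20_000.0,
    "BLOOD": 24_000.0,
    "MYELOPROLIFERATIVE": 35_000.0,
    "MENTAL": 8_000.0,
    "INJURY_TOXIC": 14_000.0,
    "MULTIPLE_TRAUMA": 40_000.0,
    "INFECTIOUS": -3_000.0,
}

#: Default sepsis-flagged encounters per DRG, by MDC.  Sepsis incidence
#: varies dramatically across diagnostic categories (respiratory,
#: infectious-disease and kidney DRGs see far more secondary sepsis than
#: psychiatric or musculoskeletal ones); this variation is what makes
#: category-specific alert thresholds worth choosing.  With the default
#: 131-DRG round-robin assignment these rates give 673 sepsis encounters.
DEFAULT_SEPTIC_PER_DRG_BY_MDC: Mapping[str, int] = {
    "PRE_MDC": 4,
    "NERVOUS": 3,
    "RESPIRATORY": 10,
    "CIRCULATORY": 8,
    "DIGESTIVE": 6,
    "HEPATOBILIARY": 5,
    "MUSCULOSKELETAL": 2,
    "SKIN": 3,
    "ENDOCRINE": 4,
    "KIDNEY_URINARY": 8,
    "BLOOD": 5,
    "MYELOPROLIFERATIVE": 6,
    "MENTAL": 1,
    "INJURY_TOXIC": 3,
    "MULTIPLE_TRAUMA": 4,
    "INFECTIOUS": 10,
}


def default_drg_codes(n_drgs: int) -> list[str]:
    """Zero-padded numeric DRG codes, skipping the sepsis DRGs 870-872."""
    codes: list[str] = []
    code = 100
    while len(codes) < n_drgs:
        label = f"{code:03d}"
        if label not in SEPSIS_DRGS:
            codes.append(label)
        code += 1
    return codes


def default_mdc_assignment(
    drg_codes: Sequence[str], mdcs: Sequence[str] | None = None
) -> dict[str, str]:
    """Round-robin partition of DRG codes over the MDC labels."""
    if mdcs is None:
        mdcs = list(DEFAULT_TRUE_EXCESS_BY_MDC)
    return {code: mdcs[i % len(mdcs)] for i, code in enumerate(drg_codes)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the scale of a single academic health system's Medicare
    claims over roughly four years: 131 non-sepsis DRGs across 16 MDCs,
    ~150 controls per DRG (19,519 in total) and an MDC-dependent sepsis
    incidence of 1-10 flagged encounters per DRG (673 in total), Charlson
    indices 0-15, and a log-normal outlier-payment factor with dispersion
    ``outlier_tail`` (0 disables payment noise entirely).

    ``n_controls_per_drg`` and ``n_septic_per_drg`` accept either a single
    count applied to every DRG or a mapping MDC→count.
    """

    n_drgs: int = 131
    mdc_assignment: Mapping[str, str] | None = None
    n_controls_per_drg: int | Mapping[str, int] = 149
    n_septic_per_drg: int | Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SEPTIC_PER_DRG_BY_MDC)
    )
    charlson_range: tuple[int, int] = (0, 15)
    baseline_payment_per_weight: float = 6_000.0
    charlson_payment_slope: float = 800.0
    drg_weight_range: tuple[float, float] = (0.7, 5.5)
    outlier_tail: float = 0.5
    true_excess_by_mdc: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_EXCESS_BY_MDC)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_drgs < 1:
            raise ConfigurationError("n_drgs must be >= 1")
        if not self.true_excess_by_mdc:
            raise ConfigurationError("true_excess_by_mdc must be non-empty")
        for name, value, floor in (
            ("n_controls_per_drg", self.n_controls_per_drg, 1),
            ("n_septic_per_drg", self.n_septic_per_drg, 0),
        ):
            counts = (
                dict(value).items()
                if isinstance(value, Mapping)
                else [(None, value)]
            )
            if isinstance(value, Mapping):
                uncovered = set(self.true_excess_by_mdc) - set(value)
                if uncovered:
                    raise ConfigurationError(
                        f"{name} mapping lacks MDC(s): {sorted(uncovered)}"
                    )
            for key, count in counts:
                if count < floor:
                    where = f" for MDC {key!r}" if key is not None else ""
                    reason = (
                        ": matching requires at least one candidate control "
                        "per DRG stratum"
                        if name == "n_controls_per_drg"
                        else ""
                    )
                    raise ConfigurationError(
                        f"{name} must be >= {floor}{where}{reason}"
                    )
        lo, hi = self.charlson_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("charlson_range must satisfy 0 <= lo <= hi")
        wlo, whi = self.drg_weight_range
        if wlo <= 0 or whi < wlo:
            raise ConfigurationError("drg_weight_range must be positive and ordered")
        if self.outlier_tail < 0:
            raise ConfigurationError("outlier_tail must be >= 0")
        if self.baseline_payment_per_weight <= 0:
            raise ConfigurationError("baseline_payment_per_weight must be > 0")
        if self.mdc_assignment is not None:
            unknown = set(self.mdc_assignment.values()) - set(self.true_excess_by_mdc)
            if unknown:
                raise ConfigurationError(
                    f"mdc_assignment maps to MDCs without a true excess: {sorted(unknown)}"
                )
            bad = SEPSIS_DRGS & set(self.mdc_assignment)
            if bad:
                raise ConfigurationError(
                    f"sepsis DRGs {sorted(bad)} may not appear in mdc_assignment"
                )

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def generate_claims(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a claim table from a :class:`GeneratorConfig`.

    All randomness derives from one ``numpy`` generator seeded with
    ``config.seed``, so a fixed config yields a byte-identical table.

    Per encounter, ``payment = baseline_payment_per_weight * drg_weight
    + charlson_payment_slope * charlson``, multiplied by a log-normal
    outlier factor with unit mean and log-scale ``outlier_tail``, plus the
    MDC's true excess if the encounter is sepsis-flagged.  Sepsis-flagged
    encounters draw their Charlson index by resampling from the control
    indices already present in the stratum, so an exact-comorbidity match
    always exists and the injected excess is recoverable without bias.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.mdc_assignment is None:
        drg_codes = default_drg_codes(config.n_drgs)
        assignment = default_mdc_assignment(drg_codes, list(config.true_excess_by_mdc))
    else:
        assignment = dict(config.mdc_assignment)
        drg_codes = sorted(assignment)
        if config.n_drgs != len(drg_codes):
            raise ConfigurationError(
                f"n_drgs={config.n_drgs} but mdc_assignment has {len(drg_codes)} DRGs"
            )

    lo, hi = config.charlson_range
    wlo, whi = config.drg_weight_range
    sigma = config.outlier_tail

    frames: list[pd.DataFrame] = []
    counter = 0
    for code in drg_codes:
        mdc = assignment[code]
        excess = float(config.true_excess_by_mdc[mdc])
        weight = float(np.round(rng.uniform(wlo, whi), 4))

        n_ctl = _count_for(config.n_controls_per_drg, mdc)
        n_sep = _count_for(config.n_septic_per_drg, mdc)
        ctl_charlson = rng.integers(lo, hi + 1, size=n_ctl)
        sep_charlson = rng.choice(ctl_charlson, size=n_sep, replace=True)

        charlson = np.concatenate([ctl_charlson, sep_charlson])
        flags = np.concatenate(
            [np.zeros(n_ctl, dtype=bool), np.ones(n_sep, dtype=bool)]
        )
        base = (
            config.baseline_payment_per_weight * weight
            + config.charlson_payment_slope * charlson
        )
        if sigma > 0:
            # unit-mean log-normal multiplicative outlier factor
            factor = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=base.size)
        else:
            factor = np.ones(base.size)
        payment = base * factor + np.where(flags, excess, 0.0)

        ids = [f"E{counter + k:07d}" for k in range(base.size)]
        counter += base.size
        frames.append(
            pd.DataFrame(
                {
                    "encounter_id": ids,
                    "drg_code": code,
                    "drg_weight": weight,
                    "mdc": mdc,
                    "charlson": charlson.astype(np.int64),
                    "payment": payment,
                    "sepsis_flag": flags,
                }
            )
        )

    table = pd.concat(frames, ignore_index=True)[CLAIM_COLUMNS]
    validate_claims(table)
    return table


def _count_for(value: int | Mapping[str, int], mdc: str) -> int:
    return int(value[mdc]) if isinstance(value, Mapping) else int(value)


def validate_claims(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants of a claim table; returns the table."""
    missing = [c for c in CLAIM_COLUMNS if c not in table.columns]
    if missing:
        raise ClaimsParseError(f"claim table is missing required columns: {missing}")
    if len(table):
        if (table["drg_weight"] <= 0).any():
            raise ClaimsParseError("drg_weight must be > 0 for every encounter")
        if (table["charlson"] < 0).any():
            raise ClaimsParseError("charlson must be a non-negative integer")
        bad = table["drg_code"].isin(SEPSIS_DRGS)
        if bad.any():
            raise ClaimsParseError(
                "sepsis DRGs 870-872 must be excluded before analysis; "
                f"found {sorted(table.loc[bad, 'drg_code'].unique())}"
            )
        # weight constant within a DRG stratum as used by matching
        if (table.groupby("drg_code")["drg_weight"].nunique() > 1).any():
            raise ClaimsParseError("drg_weight must be constant within a drg_code")
    return table


def write_claims(table: pd.DataFrame, path) -> None:
    """Write a claim table as UTF-8 CSV with sepsis_flag encoded as 0/1."""
    out = table[CLAIM_COLUMNS].copy()
    out["sepsis_flag"] = out["sepsis_flag"].astype(int)
    out.to_csv(path, index=False)


def read_claims(path, known_mdcs: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a claims CSV, validating schema row by row.

    Parameters
    ----------
    path : str, pathlib.Path or file-like
    known_mdcs : optional collection of admissible MDC labels; rows with any
        other label raise :class:`ClaimsParseError` naming the row.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLAIM_COLUMNS if c not in raw.columns]
    if missing:
        raise ClaimsParseError(f"missing required column(s): {missing}")
    raw = raw[CLAIM_COLUMNS]
    if not len(raw):
        empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in _DTYPES.items()})
        return empty[CLAIM_COLUMNS]

    def _numeric(col: str) -> pd.Series:
        values = pd.to_numeric(raw[col], errors="coerce")
        if values.isna().any():
            row = int(values.index[values.isna()][0]) + 2  # 1-based incl. header
            raise ClaimsParseError(
                f"non-numeric value {raw[col][values.isna()].iloc[0]!r} in "
                f"column {col!r} at line {row}"
            )
        return values

    table = pd.DataFrame(
        {
            "encounter_id": raw["encounter_id"],
            "drg_code": raw["drg_code"],
            "drg_weight": _numeric("drg_weight"),
            "mdc": raw["mdc"],
            "charlson": _numeric("charlson").astype(np.int64),
            "payment": _numeric("payment"),
        }
    )
    flag = raw["sepsis_flag"]
    bad_flag = ~flag.isin(["0", "1"])
    if bad_flag.any():
        row = int(flag.index[bad_flag][0]) + 2
        raise ClaimsParseError(
            f"sepsis_flag must be 0 or 1; got {flag[bad_flag].iloc[0]!r} at line {row}"
        )
    table["sepsis_flag"] = flag.astype(int).astype(bool)
    if known_mdcs is not None:
        bad = ~table["mdc"].isin(list(known_mdcs))
        if bad.any():
            row = int(table.index[bad][0]) + 2
            raise ClaimsParseError(
                f"unknown MDC label {table.loc[bad, 'mdc'].iloc[0]!r} at line {row}"
            )
    return validate_claims(table[CLAIM_COLUMNS])


_DTYPES = {
    "encounter_id": object,
    "drg_code": object,
    "drg_weight": float,
    "mdc": object,
    "charlson": np.int64,
    "payment": float,
    "sepsis_flag": bool,
}


def claims_to_csv_bytes(table: pd.DataFrame) -> bytes:
    """Serialize a claim table to CSV bytes (used for determinism checks)."""
    buf = io.StringIO()
    write_claims(table, buf)
    return buf.getvalue().encode("utf-8")
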