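"""Cohort CSV schema, validation, and report writing.

Cohorts are RFC-4180-style CSV with a header row and fixed lowercase
snake-case column names.  Leading ``#`` lines are treated as comments (the
generator records its seed there).  An optional header-mapping dict
supports alternate spellings.

Required columns:
    id, age, psa, tpv, tzv, pves, pabd, qmax, pvr,
    ipss_v, ipss_s, ipss_p, ipss_t, qol
Optional follow-up columns:
    ipss_t_post, qol_post, qmax_post

Validation is per record: a row violating an invariant is rejected with
exactly one reason code and reported, never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingDataError

REQUIRED_COLUMNS = (
    "id", "age", "psa", "tpv", "tzv", "pves", "pabd", "qmax", "pvr",
    "ipss_v", "ipss_s", "ipss_p", "ipss_t", "qol",
)
FOLLOWUP_COLUMNS = ("ipss_t_post", "qol_post", "qmax_post")

_NONNEG = ("psa", "pves", "pabd", "qmax", "pvr", "ipss_v", "ipss_s", "ipss_p", "ipss_t")


@dataclass(frozen=True)
class RowError:
    row_id: str
    reason: str


def _check_row(row: pd.Series, has_followup: bool) -> str | None:
    """First violated invariant for one parsed record, or None."""
    numeric_cols = [c for c in REQUIRED_COLUMNS if c != "id"]
    if has_followup:
        numeric_cols += [c for c in FOLLOWUP_COLUMNS if c in row.index]
    for c in numeric_cols:
        if pd.isna(row[c]):
            return f"unparseable or missing value in column '{c}'"
    if not 18 <= row["age"] <= 110:
        return "age outside 18..110"
    for c in _NONNEG:
        if row[c] < 0:
            return f"negative {c}"
    if row["tpv"] <= 0 or row["tzv"] <= 0:
        return "non-positive prostate volume"
    if row["tzv"] > row["tpv"]:
        return "tzv exceeds tpv"
    if not 0 <= row["qol"] <= 6:
        return "qol outside 0..6"
    if row["ipss_v"] > 20 or row["ipss_s"] > 15:
        return "IPSS subscore outside legal range"
    if row["ipss_t"] < max(row["ipss_v"], row["ipss_s"]):
        return "ipss_t below a subscore"
    if has_followup:
        if "qol_post" in row.index and not 0 <= row["qol_post"] <= 6:
            return "qol_post outside 0..6"
        if "ipss_t_post" in row.index and row["ipss_t_post"] < 0:
            return "negative ipss_t_post"
        if "qmax_post" in row.index and row["qmax_post"] < 0:
            return "negative qmax_post"
    return None


def read_cohort(
    path: str | Path, header_map: dict[str, str] | None = None
) -> tuple[pd.DataFrame, list[RowError]]:
    """Read and validate a cohort CSV.

    Returns ``(valid_records, errors)``.  A missing required column is
    fatal (:class:`MissingDataError`); an invalid row is excluded and
    reported with one reason.  Missing follow-up columns are tolerated —
    grading simply becomes unavailable.
    """
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    if header_map:
        df = df.rename(columns=header_map)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MissingDataError(f"cohort file lacks required column(s): {missing}")
    has_followup = any(c in df.columns for c in FOLLOWUP_COLUMNS)
    for c in df.columns:
        if c != "id":
            df[c] = pd.to_numeric(df[c], errors="coerce")

    errors: list[RowError] = []
    keep = np.ones(len(df), dtype=bool)
    seen: set[str] = set()
    for i, (_, row) in enumerate(df.iterrows()):
        rid = str(row["id"])
        if rid in seen:
            errors.append(RowError(rid, "duplicate id"))
            keep[i] = False
            continue
        seen.add(rid)
        reason = _check_row(row, has_followup)
        if reason is not None:
            errors.append(RowError(rid, reason))
            keep[i] = False
    return df.loc[keep].reset_index(drop=True), errors


def has_followup(cohort: pd.DataFrame) -> bool:
    """True when all three follow-up columns are present and non-null."""
    return all(c in cohort.columns and cohort[c].notna().all() for c in FOLLOWUP_COLUMNS)


def write_cohort(cohort: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a cohort CSV; the generating seed is recorded as a comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        cohort.to_csv(fh, index=False)


def write_results_json(results: dict, path: str | Path) -> None:
    """Deterministic machine-readable results: sorted keys, fixed float repr."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _clean(obj):
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            return float(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return obj

    with open(path, "w") as fh:
        json.dump(_clean(results), fh, indent=2, sort_keys=True)
        fh.write("\n")
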