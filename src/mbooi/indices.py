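"""Anatomical and urodynamic obstruction indices.

Pressure-flow studies record, at the moment of maximum flow, the total
intravesical pressure ``pves``, the abdominal pressure ``pabd`` (rectal
catheter), and the flow rate ``qmax``.  The detrusor pressure is the
difference ``pdet_qmax = pves - pabd``.  Two linear obstruction indices are
derived from these:

* ``BOOI  = pdet_qmax - 2 * qmax`` — the classical bladder outlet
  obstruction index, which ignores abdominal straining;
* ``MBOOI = pves - 2 * qmax`` — the modified index, which keeps the
  abdominal contribution, so that ``MBOOI - BOOI = pabd`` identically.

The BOOI bands the degree of obstruction: unobstructed (BOOI <= 20),
equivocal (20 < BOOI <= 40), obstructed (BOOI > 40).

Anatomically, prostate volumes are estimated from transrectal ultrasound
via the ellipsoid formula ``height * width * length * pi / 6`` and the
transitional-zone index is the per-patient ratio ``TZI = TZV / TPV``.

All pressures are in cmH2O, flows in mL/s, volumes in mL.  Units are fixed;
there is no conversion layer.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import MissingDataError, ValidationError

BOO_GRADES = ("unobstructed", "equivocal", "obstructed")

#: Columns a pressure-flow record must provide for index computation.
REQUIRED_PF_COLUMNS = ("pves", "pabd", "qmax")


def pdet_qmax(pves, pabd):
    """Detrusor pressure at maximum flow, ``pves - pabd`` (cmH2O).

    Accepts scalars or array-likes.  A negative result (abdominal pressure
    exceeding intravesical pressure, possible with transducer drift) is
    physiologically suspect but returned as-is; cohort-level code attaches a
    quality flag instead of discarding the value.
    """
    return np.asarray(pves) - np.asarray(pabd) if _is_arraylike(pves) else pves - pabd


def booi_index(pdet, qmax):
    """Bladder outlet obstruction index ``pdet - 2*qmax``."""
    return pdet - 2.0 * np.asarray(qmax) if _is_arraylike(qmax) else pdet - 2.0 * qmax


def mbooi_index(pves, qmax):
    """Modified obstruction index ``pves - 2*qmax`` (keeps straining)."""
    return pves - 2.0 * np.asarray(qmax) if _is_arraylike(qmax) else pves - 2.0 * qmax


def classify_boo(booi):
    """Assign the obstruction grade from the BOOI bands.

    ``booi <= 20`` -> ``"unobstructed"``; ``20 < booi <= 40`` ->
    ``"equivocal"``; ``booi > 40`` -> ``"obstructed"``.  Band edges are
    closed on the upper side.  Scalars return a string, array-likes an
    object array.  Non-finite input raises :class:`ValidationError`.
    """
    if _is_arraylike(booi):
        arr = np.asarray(booi, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("BOOI must be finite to be graded")
        out = np.where(arr <= 20, BOO_GRADES[0], np.where(arr <= 40, BOO_GRADES[1], BOO_GRADES[2]))
        return out
    if not math.isfinite(float(booi)):
        raise ValidationError("BOOI must be finite to be graded")
    if booi <= 20:
        return BOO_GRADES[0]
    if booi <= 40:
        return BOO_GRADES[1]
    return BOO_GRADES[2]


def ellipsoid_volume(height: float, width: float, length: float) -> float:
    """Prostate volume (mL) from TRUS axes (cm): ``h * w * l * pi/6``."""
    if height <= 0 or width <= 0 or length <= 0:
        raise ValidationError("ellipsoid axes must be positive")
    return height * width * length * math.pi / 6.0


def transitional_zone_index(tzv, tpv):
    """Per-patient transitional-zone index ``TZV / TPV`` in (0, 1].

    Cohort summaries must average these per-patient ratios, never take the
    ratio of cohort means — the two differ whenever TZI and TPV covary.
    """
    tzv_a, tpv_a = np.asarray(tzv, dtype=float), np.asarray(tpv, dtype=float)
    if np.any(tpv_a <= 0) or np.any(tzv_a <= 0):
        raise ValidationError("prostate volumes must be positive")
    if np.any(tzv_a > tpv_a):
        raise ValidationError("transitional-zone volume cannot exceed total volume")
    out = tzv_a / tpv_a
    return float(out) if out.ndim == 0 else out


def prostate_volumes(
    *,
    height: float | None = None,
    width: float | None = None,
    length: float | None = None,
    tpv: float | None = None,
    tzv: float | None = None,
) -> tuple[float | None, float | None, float | None]:
    """Resolve (tpv, tzv, tzi) from either ellipsoid axes or direct volumes.

    If the axis trio is given it overrides ``tpv``.  ``tzi`` is returned
    only when both volumes are available.
    """
    axes = (height, width, length)
    if any(a is not None for a in axes):
        if any(a is None for a in axes):
            raise MissingDataError("all three ellipsoid axes are required")
        tpv = ellipsoid_volume(height, width, length)
    if tpv is None:
        raise MissingDataError("either ellipsoid axes or tpv must be supplied")
    tzi = transitional_zone_index(tzv, tpv) if tzv is not None else None
    return tpv, tzv, tzi


def add_indices(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append derived index columns to a cohort table.

    Adds ``pdet_qmax``, ``booi``, ``mbooi``, ``boo_grade`` and a boolean
    quality flag ``flag_negative_pdet`` (pabd > pves).  Flagged records keep
    their values; downstream analyses may exclude them via the
    ``exclude_negative_pdet`` configuration switch.  If ``tzv``/``tpv`` are
    present a per-patient ``tzi`` column is added too.

    Raises
    ------
    MissingDataError
        If any of ``pves``, ``pabd``, ``qmax`` is absent or null.
    """
    missing = [c for c in REQUIRED_PF_COLUMNS if c not in cohort.columns]
    if missing:
        raise MissingDataError(f"cohort lacks required columns: {missing}")
    bad = cohort[list(REQUIRED_PF_COLUMNS)].isna().any(axis=1)
    if bad.any():
        raise MissingDataError(
            f"{int(bad.sum())} record(s) missing pves/pabd/qmax; "
            "validate or exclude them before computing indices"
        )
    out = cohort.copy()
    out["pdet_qmax"] = pdet_qmax(out["pves"].to_numpy(), out["pabd"].to_numpy())
    out["booi"] = booi_index(out["pdet_qmax"].to_numpy(), out["qmax"].to_numpy())
    out["mbooi"] = mbooi_index(out["pves"].to_numpy(), out["qmax"].to_numpy())
    out["boo_grade"] = classify_boo(out["booi"].to_numpy())
    out["flag_negative_pdet"] = out["pdet_qmax"].to_numpy() < 0
    if "tzv" in out.columns and "tpv" in out.columns and "tzi" not in out.columns:
        out["tzi"] = transitional_zone_index(out["tzv"].to_numpy(), out["tpv"].to_numpy())
    return out


def _is_arraylike(x) -> bool:
    return isinstance(x, (np.ndarray, pd.Series, list, tuple)) or (
        isinstance(x, Iterable) and not isinstance(x, (str, bytes))
    )
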