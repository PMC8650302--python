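"""Four-level efficacy grading of TURP outcome and its median combination.

Surgical efficacy is judged on three axes, each mapped to an ordinal grade
1 (poor) .. 4 (excellent):

========  ==========================  =======================================
axis      improvement statistic        bands (grade 4 / 3 / 2 / 1)
========  ==========================  =======================================
symptom   r = IPSS-t post / pre        r <= 0.25 / <= 0.50 / <= 0.75 / > 0.75
QoL       d = QoL pre - post           d >= 4 / d == 3 / d in {1, 2} / d <= 0
function  g = Qmax post - pre (mL/s)   g >= 10 / 5 <= g < 10 / 2.5 <= g < 5 /
                                       g < 2.5
========  ==========================  =======================================

The overall grade is the median (middle value) of the three axis grades;
grades 3–4 count as *effective*, 1–2 as *ineffective*.

Worsening (IPSS ratio > 1, negative QoL change, negative Qmax gain) falls
in the poor band: extending the lowest band downward is the only monotone
completion of the published cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import AnalysisError, UngradeableRecordError, ValidationError

GRADE_LABELS = {1: "poor", 2: "fair", 3: "good", 4: "excellent"}

#: Minimum overall grade that counts as an effective operation.
EFFECTIVE_THRESHOLD = 3


@dataclass(frozen=True)
class EfficacyResult:
    """Per-patient axis grades, their median, and the effective flag."""

    symptom_grade: int
    qol_grade: int
    function_grade: int
    overall_grade: int
    effective: bool


def grade_symptom(ipss_t_pre: float, ipss_t_post: float) -> int:
    """Grade symptomatic improvement from the post/pre IPSS-t ratio.

    Bands close on the right: a ratio of exactly 0.25 is still excellent.
    A baseline total of zero leaves the ratio undefined; such records are
    ungradeable and should be excluded with a reason code, not imputed
    (surgical candidates realistically score IPSS-t >= 8).
    """
    if ipss_t_pre < 1:
        raise UngradeableRecordError("baseline IPSS-t < 1: post/pre ratio undefined")
    if ipss_t_post < 0:
        raise ValidationError("IPSS-t cannot be negative")
    r = ipss_t_post / ipss_t_pre
    if r <= 0.25:
        return 4
    if r <= 0.50:
        return 3
    if r <= 0.75:
        return 2
    return 1


def grade_qol(qol_pre: int, qol_post: int) -> int:
    """Grade quality-of-life improvement from the pre - post score change."""
    for v in (qol_pre, qol_post):
        if not 0 <= v <= 6:
            raise ValidationError(f"QoL score {v} outside 0..6")
    d = qol_pre - qol_post
    if d >= 4:
        return 4
    if d == 3:
        return 3
    if d >= 1:
        return 2
    return 1


def grade_function(qmax_pre: float, qmax_post: float) -> int:
    """Grade voiding-function improvement from the Qmax gain (mL/s).

    Bands close on the left: a gain of exactly 10 mL/s is excellent,
    exactly 2.5 mL/s is fair.
    """
    if qmax_pre < 0 or qmax_post < 0:
        raise ValidationError("Qmax cannot be negative")
    g = qmax_post - qmax_pre
    if g >= 10:
        return 4
    if g >= 5:
        return 3
    if g >= 2.5:
        return 2
    return 1


def overall_efficacy(symptom: int, qol: int, function: int) -> EfficacyResult:
    """Combine the three axis grades: overall = median, effective = overall >= 3.

    With three values the median is always one of the attained grades, so
    the overall grade stays a valid ordinal level.
    """
    for g in (symptom, qol, function):
        if g not in GRADE_LABELS:
            raise ValidationError(f"grade {g} outside 1..4")
    overall = sorted((symptom, qol, function))[1]
    return EfficacyResult(symptom, qol, function, overall, overall >= EFFECTIVE_THRESHOLD)


FOLLOWUP_COLUMNS = ("ipss_t_post", "qol_post", "qmax_post")


def grade_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Grade every record of a cohort table with follow-up columns.

    Appends ``symptom_grade``, ``qol_grade``, ``function_grade``,
    ``overall_grade`` and ``effective``.  Records with baseline
    ``ipss_t < 1`` are ungradeable and raise; exclude them first (the I/O
    layer reports them with a reason code).
    """
    missing = [c for c in FOLLOWUP_COLUMNS if c not in cohort.columns]
    if missing:
        raise UngradeableRecordError(
            f"cohort lacks follow-up columns {missing}; grading requires post-operative data"
        )
    out = cohort.copy()
    graded = [
        overall_efficacy(
            grade_symptom(row.ipss_t, row.ipss_t_post),
            grade_qol(int(row.qol), int(row.qol_post)),
            grade_function(row.qmax, row.qmax_post),
        )
        for row in out.itertuples()
    ]
    out["symptom_grade"] = [g.symptom_grade for g in graded]
    out["qol_grade"] = [g.qol_grade for g in graded]
    out["function_grade"] = [g.function_grade for g in graded]
    out["overall_grade"] = [g.overall_grade for g in graded]
    out["effective"] = [g.effective for g in graded]
    return out


def _round2(x: float) -> float:
    # Table percentages are conventionally rounded half-up, not banker's.
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def grade_distribution(grades) -> dict:
    """Counts, half-up percentages and effective rate for one grade axis.

    Returns ``{"n": n, "counts": {4: .., 3: .., 2: .., 1: ..},
    "percentages": {...}, "effective_rate": ..}`` with percentages on the
    0–100 scale rounded to two decimals.
    """
    arr = np.asarray(list(grades), dtype=int)
    if arr.size == 0:
        raise AnalysisError("cannot summarise an empty cohort")
    if not np.isin(arr, (1, 2, 3, 4)).all():
        raise ValidationError("grades must be integers 1..4")
    n = arr.size
    counts = {g: int((arr == g).sum()) for g in (4, 3, 2, 1)}
    percentages = {g: _round2(100.0 * c / n) for g, c in counts.items()}
    effective_rate = _round2(100.0 * (counts[3] + counts[4]) / n)
    return {"n": n, "counts": counts, "percentages": percentages, "effective_rate": effective_rate}


def cohort_efficacy_summary(graded: pd.DataFrame) -> pd.DataFrame:
    """Tabulate grade counts/percentages per axis and overall.

    ``graded`` must carry the columns produced by :func:`grade_cohort`.
    Returns a tidy frame with one row per (axis, grade) plus the per-axis
    effective rates, shaped like the published efficacy table.
    """
    axes = {
        "symptom": "symptom_grade",
        "qol": "qol_grade",
        "function": "function_grade",
        "overall": "overall_grade",
    }
    rows = []
    for axis, col in axes.items():
        if col not in graded.columns:
            raise AnalysisError(f"column {col!r} missing; run grade_cohort first")
        dist = grade_distribution(graded[col])
        for g in (4, 3, 2, 1):
            rows.append(
                {
                    "axis": axis,
                    "grade": g,
                    "label": GRADE_LABELS[g],
                    "count": dist["counts"][g],
                    "percent": dist["percentages"][g],
                    "effective_rate": dist["effective_rate"],
                }
            )
    return pd.DataFrame(rows)
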