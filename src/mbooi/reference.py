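"""Published summary statistics of the 403-patient TURP cohort.

These are the printed baseline / effective / ineffective group moments
(mean, SD) and the efficacy-grade counts from the source study's summary
tables.  They serve two purposes:

* default distributional targets for the synthetic cohort generator
  (:mod:`mbooi.simulate`), and
* inputs for in-table consistency checks (the algebraic identities between
  MBOOI, BOOI and Pabd hold for cohort means by linearity).

The patient-level data behind them were never deposited; nothing here is a
computed result of this package.
"""

from __future__ import annotations

COHORT_N = 403
EFFECTIVE_N = 297
INEFFECTIVE_N = 106

#: (mean, sd) per variable, baseline column (n = 403).
BASELINE_MOMENTS: dict[str, tuple[float, float]] = {
    "age": (70.94, 7.50),
    "psa": (4.86, 4.98),
    "tpv": (52.84, 27.63),
    "tzv": (24.90, 19.45),
    "tzi": (0.43, 0.14),
    "pves": (102.72, 40.04),
    "pdet_qmax": (84.92, 35.23),
    "pabd": (17.79, 16.40),
    "qmax": (8.10, 3.37),
    "booi": (68.73, 35.66),
    "mbooi": (86.52, 40.59),
    "pvr": (74.36, 78.10),
    "ipss_t": (22.51, 5.22),
    "ipss_v": (8.72, 3.45),
    "ipss_s": (10.25, 2.71),
    "ipss_p": (3.51, 1.54),
    "qol": (4.73, 1.03),
}

#: (mean, sd) per variable for the effective (overall grade >= 3) group.
EFFECTIVE_MOMENTS: dict[str, tuple[float, float]] = {
    "age": (71.30, 7.44),
    "psa": (5.21, 5.30),
    "tpv": (54.19, 28.06),
    "tzv": (26.09, 19.92),
    "tzi": (0.44, 0.15),
    "pves": (110.38, 40.58),
    "pdet_qmax": (90.57, 36.07),
    "pabd": (19.81, 17.98),
    "qmax": (7.84, 3.31),
    "booi": (74.89, 36.41),
    "mbooi": (94.71, 41.04),
    "pvr": (79.54, 78.75),
    "ipss_t": (23.10, 5.17),
    "ipss_v": (8.99, 3.46),
    "ipss_s": (10.61, 2.65),
    "ipss_p": (3.48, 1.54),
    "qol": (4.77, 0.99),
}

#: (mean, sd) per variable for the ineffective (overall grade <= 2) group.
INEFFECTIVE_MOMENTS: dict[str, tuple[float, float]] = {
    "age": (69.94, 7.62),
    "psa": (3.88, 3.83),
    "tpv": (49.05, 26.12),
    "tzv": (21.59, 17.73),
    "tzi": (0.40, 0.12),
    "pves": (81.23, 29.38),
    "pdet_qmax": (69.10, 27.22),
    "pabd": (12.13, 8.65),
    "qmax": (8.82, 3.43),
    "booi": (51.47, 26.90),
    "mbooi": (63.59, 28.96),
    "pvr": (59.85, 74.73),
    "ipss_t": (20.84, 5.03),
    "ipss_v": (7.98, 3.34),
    "ipss_s": (9.24, 2.61),
    "ipss_p": (3.59, 1.54),
    "qol": (4.62, 1.14),
}

#: Published efficacy-grade counts, ordered (excellent, good, fair, poor),
#: i.e. grades (4, 3, 2, 1), per axis and for the overall median grade.
GRADE_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "symptom": (161, 146, 69, 27),
    "qol": (139, 125, 105, 34),
    "function": (116, 172, 77, 38),
    "overall": (136, 161, 84, 22),
}
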