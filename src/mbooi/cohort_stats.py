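"""Cohort-level statistical pipeline for predictor comparison.

The analysis mirrors standard practice for clinical two-group tables:

1. screen each continuous variable for normality (one-sample
   Kolmogorov–Smirnov against a normal law with estimated mean/SD,
   alpha = 0.05; a Lilliefors-corrected variant is available);
2. compare effective vs ineffective groups with Student's t-test when the
   screen accepts normality, otherwise the Mann–Whitney U test (exact for
   small tie-free samples, normal approximation with tie correction
   otherwise);
3. screen candidate predictors with simple linear regression against the
   ordinal overall grade and keep those with p < 0.05;
4. fit a forward stepwise binary logistic regression (likelihood-ratio
   entry at p_enter = 0.05, no removal step by default) reporting odds
   ratios with Wald 95% intervals;
5. compare predictors by ROC AUC with DeLong confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .errors import AnalysisError, SeparationError

ALPHA = 0.05

# ---------------------------------------------------------------------------
# normality screen and two-group comparison


@dataclass(frozen=True)
class NormalityResult:
    normal: bool
    p_value: float
    statistic: float
    degenerate: bool = False
    method: str = "ks"


def normality_screen(values, alpha: float = ALPHA, lilliefors: bool = False) -> NormalityResult:
    """Decide normal vs non-normal for one continuous variable.

    Kolmogorov–Smirnov against N(mean, sd) with moments estimated from the
    sample; ``normal`` iff p >= alpha.  Estimating the parameters from the
    same sample makes the plain KS p anti-conservative; set
    ``lilliefors=True`` for the corrected null distribution.
    A constant sample is reported non-normal with ``degenerate=True``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise AnalysisError(f"normality screen needs n >= 8, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        return NormalityResult(False, 0.0, 1.0, degenerate=True)
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        return NormalityResult(bool(p >= alpha), float(p), float(stat), method="lilliefors")
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return NormalityResult(bool(p >= alpha), float(p), float(stat))


@dataclass(frozen=True)
class GroupTestResult:
    test_used: str  # "t_test" | "mann_whitney"
    statistic: float
    p_value: float


def compare_groups(values_a, values_b, normal: bool) -> GroupTestResult:
    """Two-sided two-group comparison chosen by the normality screen."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("each group needs at least 2 observations")
    if normal:
        stat, p = stats.ttest_ind(a, b)
        return GroupTestResult("t_test", float(stat), float(p))
    # method="auto": exact enumeration for small tie-free samples, else the
    # tie-corrected normal approximation.
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return GroupTestResult("mann_whitney", float(stat), float(p))


def compare_table(
    cohort: pd.DataFrame,
    variables: list[str],
    group_col: str = "effective",
    alpha: float = ALPHA,
    lilliefors: bool = False,
) -> pd.DataFrame:
    """Two-group baseline comparison table (one row per variable).

    Reports mean/SD for the whole cohort and for each group, the test the
    normality screen selected, and its two-sided p-value.  Missing values
    are dropped per variable (complete-case per analysis).
    """
    if group_col not in cohort.columns:
        raise AnalysisError(f"grouping column {group_col!r} missing")
    grp = cohort[group_col].astype(bool)
    rows = []
    for var in variables:
        x = pd.to_numeric(cohort[var], errors="coerce")
        keep = x.notna()
        x, g = x[keep], grp[keep]
        screen = normality_screen(x, alpha=alpha, lilliefors=lilliefors)
        res = compare_groups(x[g], x[~g], screen.normal)
        rows.append(
            {
                "variable": var,
                "mean_all": x.mean(),
                "sd_all": x.std(ddof=1),
                "mean_effective": x[g].mean(),
                "sd_effective": x[g].std(ddof=1),
                "mean_ineffective": x[~g].mean(),
                "sd_ineffective": x[~g].std(ddof=1),
                "normal": screen.normal,
                "test_used": res.test_used,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# univariate linear screen


def univariate_screen(
    cohort: pd.DataFrame,
    candidates: list[str],
    outcome: str = "overall_grade",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Simple-linear-regression screen of candidate predictors.

    The ordinal overall grade (1..4) is treated as a numeric response; each
    candidate is regressed alone and kept when its slope's two-sided t-test
    gives p < alpha.  Zero-variance predictors are excluded with a reason.
    Returns a frame with ``slope``, ``p_value``, ``selected``, ``reason``.
    """
    y = pd.to_numeric(cohort[outcome], errors="coerce")
    rows = []
    for var in candidates:
        x = pd.to_numeric(cohort[var], errors="coerce")
        keep = x.notna() & y.notna()
        xi, yi = x[keep].to_numpy(), y[keep].to_numpy()
        if xi.size < 3 or np.ptp(xi) == 0:
            rows.append(
                {"variable": var, "slope": np.nan, "p_value": np.nan,
                 "selected": False, "reason": "zero-variance or too few observations"}
            )
            continue
        fit = stats.linregress(xi, yi)
        rows.append(
            {"variable": var, "slope": fit.slope, "p_value": fit.pvalue,
             "selected": bool(fit.pvalue < alpha), "reason": ""}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# forward stepwise logistic regression


@dataclass
class ModelReport:
    """Stepwise logistic fit: selected predictors with OR/CI/p."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    selection_order: list[str] = field(default_factory=list)
    log_likelihood: float = float("nan")
    n: int = 0
    skipped: dict[str, str] = field(default_factory=dict)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # separation is detected and raised as SeparationError below
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.Logit(y, X)
        res = model.fit(disp=0, maxiter=100, tol=1e-10)
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge")
    return res


def stepwise_forward_logistic(
    cohort: pd.DataFrame,
    candidates: list[str],
    outcome: str = "effective",
    p_enter: float = ALPHA,
    p_remove: float | None = None,
) -> ModelReport:
    """Forward stepwise binary logistic regression with LR entry tests.

    At each step the remaining candidate with the smallest likelihood-ratio
    p-value enters if that p is below ``p_enter``; the model is refit by
    maximum likelihood after every entry.  Pure forward selection by
    default; pass ``p_remove`` (e.g. 0.10) to also drop predictors whose
    removal LR p exceeds it, matching common stepwise software.

    Candidates that would make the design matrix rank-deficient (the cohort
    schema contains exact identities such as MBOOI = Pves - 2 Qmax) are
    skipped at that step and reported in ``skipped``.  Perfect separation
    raises :class:`SeparationError` with a diagnostic.
    """
    data = cohort[[outcome, *candidates]].dropna()
    y = data[outcome].astype(float).to_numpy()
    uniq = np.unique(y)
    if not np.isin(uniq, (0.0, 1.0)).all() or uniq.size != 2:
        raise AnalysisError("outcome must be binary with both classes present")
    n = y.size

    selected: list[str] = []
    skipped: dict[str, str] = {}
    # standardise nothing: ORs are reported per unit of the raw variable
    cur_res = _fit_logit(y, np.ones((n, 1)))

    def design(cols):
        X = np.column_stack([np.ones(n)] + [data[c].to_numpy(float) for c in cols])
        return X

    while True:
        remaining = [c for c in candidates if c not in selected and c not in skipped]
        if not remaining:
            break
        best = None
        for cand in remaining:
            X = design(selected + [cand])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                skipped[cand] = "collinear with selected predictors"
                continue
            try:
                res = _fit_logit(y, X)
            except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
                raise SeparationError(f"perfect separation adding {cand!r}: {exc}") from exc
            if np.abs(res.params).max() > 30:
                raise SeparationError(
                    f"diverging coefficients adding {cand!r}: quasi-separation suspected"
                )
            lr = 2.0 * (res.llf - cur_res.llf)
            p = stats.chi2.sf(max(lr, 0.0), df=1)
            if best is None or p < best[1]:
                best = (cand, p, res)
        if best is None or best[1] >= p_enter:
            break
        selected.append(best[0])
        cur_res = best[2]
        if p_remove is not None and len(selected) > 1:
            # backward look: drop any predictor whose removal LR p > p_remove
            dropped = True
            while dropped and len(selected) > 1:
                dropped = False
                for var in list(selected):
                    reduced = [v for v in selected if v != var]
                    red_res = _fit_logit(y, design(reduced))
                    p_out = stats.chi2.sf(2.0 * (cur_res.llf - red_res.llf), df=1)
                    if p_out > p_remove:
                        selected.remove(var)
                        cur_res = red_res
                        dropped = True
                        break

    rows = []
    if selected:
        params = cur_res.params[1:]
        ses = cur_res.bse[1:]
        pvals = cur_res.pvalues[1:]
        for i, var in enumerate(selected):
            coef, se = params[i], ses[i]
            rows.append(
                {
                    "variable": var,
                    "coef": coef,
                    "se": se,
                    "odds_ratio": float(np.exp(coef)),
                    "ci_low": float(np.exp(coef - 1.96 * se)),
                    "ci_high": float(np.exp(coef + 1.96 * se)),
                    "p_value": float(pvals[i]),
                    "step": i + 1,
                }
            )
    return ModelReport(
        table=pd.DataFrame(rows),
        selection_order=list(selected),
        log_likelihood=float(cur_res.llf),
        n=n,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocResult:
    predictor: str
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    ci_method: str = "delong"


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong variance of the empirical AUC (ties counted half).

    Uses the midrank formulation of the placement values, so the cost is
    O((m+n) log(m+n)) rather than O(m*n).
    """
    m, n = pos.size, neg.size
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    # placement of positive i among negatives / negative j among positives
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    scores,
    labels,
    predictor: str = "score",
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> RocResult:
    """AUC with a 95% confidence interval.

    AUC is the Mann–Whitney probability that a random positive outscores a
    random negative (ties half credit), identical to the trapezoidal area
    under the empirical ROC curve.  The CI is DeLong by default; a seeded
    percentile bootstrap over patients is available with
    ``ci_method="bootstrap"``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.size != y.size:
        raise AnalysisError("scores and labels differ in length")
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise AnalysisError("both outcome classes must be present for ROC analysis")
    # Mann-Whitney U / (m*n) == trapezoidal AUC
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").statistic
    auc = float(u / (pos.size * neg.size))
    if ci_method == "delong":
        var = _delong_variance(pos, neg, auc)
        half = 1.959963984540054 * np.sqrt(var)
        lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        idx = np.arange(s.size)
        for b in range(n_boot):
            take = rng.choice(idx, size=idx.size, replace=True)
            sb, yb = s[take], y[take]
            if yb.min() == yb.max():
                reps[b] = np.nan
                continue
            ub = stats.mannwhitneyu(
                sb[yb == 1], sb[yb == 0], alternative="two-sided", method="asymptotic"
            ).statistic
            reps[b] = ub / ((yb == 1).sum() * (yb == 0).sum())
        lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    else:
        raise AnalysisError(f"unknown ci_method {ci_method!r}")
    return RocResult(predictor, auc, float(lo), float(hi), pos.size, neg.size, ci_method)


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve points (fpr, tpr, threshold) for plotting."""
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), np.asarray(scores, float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


DEFAULT_PREDICTORS = ("mbooi", "booi", "tzv", "tzi")
OUTCOME_AXES = {
    "symptom": "symptom_grade",
    "qol": "qol_grade",
    "function": "function_grade",
    "overall": "overall_grade",
}


def compare_predictors(
    graded: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    axes: dict[str, str] | None = None,
    ci_method: str = "delong",
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-axis AUC comparison of candidate predictors.

    For each outcome axis the binary response is grade >= 3 (effective on
    that axis); predictors are ranked by AUC within each axis.  Shapes the
    ROC-comparison figure of a predictor study as a tidy table.
    """
    axes = OUTCOME_AXES if axes is None else axes
    rows = []
    for axis, col in axes.items():
        y = (pd.to_numeric(graded[col], errors="coerce") >= 3).astype(int)
        for pred in predictors:
            res = roc_auc(
                pd.to_numeric(graded[pred], errors="coerce"),
                y,
                predictor=pred,
                ci_method=ci_method,
                seed=seed,
            )
            rows.append(
                {
                    "axis": axis,
                    "predictor": pred,
                    "auc": res.auc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                }
            )
    out = pd.DataFrame(rows)
    out["rank"] = out.groupby("axis")["auc"].rank(ascending=False, method="first").astype(int)
    return out.sort_values(["axis", "rank"]).reset_index(drop=True)
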