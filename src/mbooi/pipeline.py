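"""End-to-end analysis pipeline: indices -> grading -> statistics -> reports."""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort_stats import compare_predictors, compare_table, roc_points, stepwise_forward_logistic, univariate_screen
from .errors import AnalysisError, MbooiError, ValidationError
from .grading import cohort_efficacy_summary, grade_cohort
from .indices import add_indices
from .io import has_followup, read_cohort, write_results_json

log = logging.getLogger("mbooi")

#: Baseline variables entering the two-group comparison and the screen.
ANALYSIS_VARIABLES = (
    "age", "psa", "tpv", "tzv", "tzi", "pves", "pdet_qmax", "pabd",
    "qmax", "pvr", "ipss_t", "ipss_v", "ipss_s", "ipss_p", "qol",
    "booi", "mbooi",
)


@dataclass
class RunConfig:
    """Pipeline run parameters."""

    input: str
    out_dir: str
    alpha: float = 0.05
    p_enter: float = 0.05
    p_remove: float | None = None
    auc_ci_method: str = "delong"
    exclude_negative_pdet: bool = False
    lilliefors: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.p_enter < 1:
            raise ValidationError("alpha and p_enter must lie in (0, 1)")


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    # no timestamps: identical runs must produce identical logs
    fmt = logging.Formatter("%(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log", mode="w")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Writes, under ``config.out_dir``: the cohort with derived index
    columns, the efficacy summary (grading table analogue), the two-group
    baseline comparison, the stepwise logistic model, per-predictor AUCs
    with ROC point files, and a deterministic ``results.json``.  Stages
    that need data the cohort cannot provide (no follow-up, or groups too
    small) are skipped with a logged diagnostic rather than failing the
    run.  Returns the results dictionary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    log.info("mbooi %s | seed=%d | input=%s", __version__, config.seed, config.input)

    cohort, errors = read_cohort(config.input)
    for err in errors:
        log.info("excluded record %s: %s", err.row_id, err.reason)
    results: dict = {
        "config": {
            "alpha": config.alpha,
            "p_enter": config.p_enter,
            "auc_ci_method": config.auc_ci_method,
            "exclude_negative_pdet": config.exclude_negative_pdet,
            "seed": config.seed,
        },
        "n_read": int(len(cohort) + len(errors)),
        "n_valid": int(len(cohort)),
        "exclusions": [{"id": e.row_id, "reason": e.reason} for e in errors],
    }

    cohort = add_indices(cohort)
    if config.exclude_negative_pdet:
        flagged = cohort["flag_negative_pdet"]
        for rid in cohort.loc[flagged, "id"]:
            log.info("excluded record %s: negative detrusor pressure", rid)
            results["exclusions"].append({"id": str(rid), "reason": "negative detrusor pressure"})
        cohort = cohort.loc[~flagged].reset_index(drop=True)
    results["n_analysed"] = int(len(cohort))
    cohort.to_csv(out / "cohort_with_indices.csv", index=False)

    ungradeable = cohort["ipss_t"] < 1
    if ungradeable.any():
        for rid in cohort.loc[ungradeable, "id"]:
            log.info("excluded record %s: baseline IPSS-t < 1 (ungradeable)", rid)
            results["exclusions"].append({"id": str(rid), "reason": "baseline IPSS-t < 1"})
        cohort = cohort.loc[~ungradeable].reset_index(drop=True)

    if not has_followup(cohort):
        msg = "no complete follow-up columns (ipss_t_post, qol_post, qmax_post): grading and efficacy analysis skipped"
        log.info(msg)
        results["grading"] = {"skipped": msg}
        write_results_json(results, out / "results.json")
        return results

    graded = grade_cohort(cohort)
    summary = cohort_efficacy_summary(graded)
    summary.to_csv(out / "efficacy_summary.csv", index=False)
    _write_efficacy_text(summary, out / "efficacy_summary.txt")
    results["grading"] = {
        "n": int(len(graded)),
        "effective_rate": float(100.0 * graded["effective"].mean()),
        "axis_effective_rates": {
            axis: float(summary.loc[summary["axis"] == axis, "effective_rate"].iloc[0])
            for axis in ("symptom", "qol", "function", "overall")
        },
    }

    try:
        _run_stats(graded, config, out, results)
    except (AnalysisError, MbooiError) as exc:
        msg = f"statistics stage refused: {exc}"
        log.info(msg)
        results["stats"] = {"skipped": msg}

    write_results_json(results, out / "results.json")
    log.info("report bundle written to %s", out)
    return results


def _run_stats(graded: pd.DataFrame, config: RunConfig, out: Path, results: dict) -> None:
    if len(graded) < 20 or graded["effective"].nunique() < 2:
        raise AnalysisError(
            f"n={len(graded)} with {graded['effective'].nunique()} outcome class(es): "
            "two-group comparison needs at least 20 records and both outcomes"
        )
    comparison = compare_table(
        graded, list(ANALYSIS_VARIABLES), alpha=config.alpha, lilliefors=config.lilliefors
    )
    comparison.to_csv(out / "group_comparison.csv", index=False)

    screen = univariate_screen(graded, list(ANALYSIS_VARIABLES), alpha=config.alpha)
    screen.to_csv(out / "univariate_screen.csv", index=False)
    kept = screen.loc[screen["selected"], "variable"].tolist()
    log.info("univariate screen kept %d/%d candidates", len(kept), len(ANALYSIS_VARIABLES))

    model_rows = {}
    if kept:
        model = stepwise_forward_logistic(
            graded, kept, outcome="effective", p_enter=config.p_enter, p_remove=config.p_remove
        )
        model.table.to_csv(out / "logistic_model.csv", index=False)
        model_rows = {
            "selection_order": model.selection_order,
            "log_likelihood": model.log_likelihood,
            "n": model.n,
            "skipped": model.skipped,
            "predictors": model.table.to_dict(orient="records"),
        }

    rocs = compare_predictors(graded, ci_method=config.auc_ci_method, seed=config.seed)
    rocs.to_csv(out / "roc_auc.csv", index=False)
    y = (graded["overall_grade"] >= 3).astype(int)
    for pred in ("mbooi", "booi", "tzv", "tzi"):
        roc_points(graded[pred], y).to_csv(out / f"roc_points_{pred}_overall.csv", index=False)

    results["stats"] = {
        "comparison": comparison.to_dict(orient="records"),
        "screen_selected": kept,
        "logistic": model_rows,
        "roc": rocs.to_dict(orient="records"),
    }


def _write_efficacy_text(summary: pd.DataFrame, path: Path) -> None:
    lines = ["Surgical efficacy by axis (grade: count, percent)", "=" * 50]
    for axis in ("symptom", "qol", "function", "overall"):
        sub = summary[summary["axis"] == axis]
        lines.append(f"{axis}  (effective rate {sub['effective_rate'].iloc[0]:.2f}%)")
        for _, r in sub.iterrows():
            lines.append(f"  {r['label']:<10} {int(r['count']):>5}  ({r['percent']:.2f}%)")
    path.write_text("\n".join(lines) + "\n")
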