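"""One-call reproduction of the complete collapse analysis on a cohort.

``run_full_analysis`` assembles, deterministically from the cohort alone:
univariate group comparisons (chi-square / pooled t-tests), the matrix-score
collapse table, the two logistic models (component factors and composite
score — fitted separately because score is a deterministic function of the
components), 1/3/5-year cumulative collapse by score with 2x4 chi-squares,
Kaplan-Meier curves overall and per score stratum with the log-rank test,
and the grouped ROC with AUC, Hanley-McNeil CI and Youden cut-off.

Covariate sections are skipped gracefully when the fields are absent (the
reconstructed fixture carries no age/sex/BMI/etiology); sections that are
undefined for the cohort (e.g. survival with zero events) are reported as
structured errors rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .cohort import Cohort
from .roc import grouped_roc
from .scoring import SCORE_LEVELS
from .stats import (
    SeparationError,
    build_contingency,
    fit_logistic,
    pearson_chi_square,
)
from .survival import km_estimate, log_rank

_HORIZONS = (1.0, 3.0, 5.0)


@dataclass
class AnalysisReport:
    sections: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return _jsonify(self.sections)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _score_event_counts(cohort: Cohort):
    """Per-score (collapse, non-collapse) counts over the whole follow-up."""
    scores = cohort.scores()
    pos = {s: 0 for s in SCORE_LEVELS}
    neg = {s: 0 for s in SCORE_LEVELS}
    for s, r in zip(scores, cohort):
        (pos if r.event else neg)[s] += 1
    return (
        np.array([pos[s] for s in SCORE_LEVELS]),
        np.array([neg[s] for s in SCORE_LEVELS]),
    )


def _univariate_section(cohort: Cohort) -> dict[str, Any]:
    from .stats import t_test_from_summary

    out: dict[str, Any] = {}
    df = cohort.to_dataframe()
    for col in ("age", "bmi"):
        if df[col].notna().all():
            g1 = df.loc[df["event"] == 1, col]
            g0 = df.loc[df["event"] == 0, col]
            if len(g1) >= 2 and len(g0) >= 2:
                res = t_test_from_summary(
                    g1.mean(), g1.std(ddof=1), len(g1),
                    g0.mean(), g0.std(ddof=1), len(g0),
                )
                out[col] = {
                    "collapse_mean": float(g1.mean()),
                    "collapse_sd": float(g1.std(ddof=1)),
                    "non_collapse_mean": float(g0.mean()),
                    "non_collapse_sd": float(g0.std(ddof=1)),
                    "t": res.statistic, "df": res.df, "p_value": res.p_value,
                }
    event_label = lambda r: "collapse" if r.event else "non_collapse"
    for factor in ("sex", "etiology", "arco_stage", "jic_type", "area_category"):
        if df[factor].notna().all() and df[factor].nunique() >= 2:
            table = build_contingency(
                cohort,
                lambda r, f=factor: getattr(r, f),
                event_label,
                col_order=["collapse", "non_collapse"],
            )
            entry: dict[str, Any] = {
                "levels": table.row_labels,
                "counts": table.counts,
            }
            try:
                chi = pearson_chi_square(table)
                entry.update(
                    chi_square=chi.statistic, df=chi.df, p_value=chi.p_value
                )
            except ValueError as exc:
                entry["chi_square_error"] = str(exc)
            out[factor] = entry
    return out


def _logistic_section(cohort: Cohort) -> dict[str, Any]:
    df = cohort.to_dataframe()
    df["score"] = [str(s) for s in cohort.scores()]
    refs = {"arco_stage": "I", "jic_type": "A", "area_category": "LT30",
            "score": "1"}
    has_age = df["age"].notna().all()
    out: dict[str, Any] = {
        "note": "component factors and the composite score are deterministically "
        "collinear, so two separate models are fitted",
    }
    specs = {
        "components_model": (["age"] if has_age else [])
        + ["arco_stage", "jic_type", "area_category"],
        "score_model": (["age"] if has_age else []) + ["score"],
    }
    for name, terms in specs.items():
        usable = [t for t in terms if df[t].nunique() > 1]
        if not usable:
            out[name] = {"error": "no usable terms (all constant)"}
            continue
        try:
            fit = fit_logistic(df, "event", usable, reference_levels=refs)
        except (SeparationError, ValueError) as exc:
            out[name] = {"error": str(exc)}
            continue
        out[name] = {
            "terms": fit.term_labels,
            "reference_levels": fit.reference_levels,
            "B": fit.coefficients,
            "SE": fit.standard_errors,
            "Wald": fit.wald_statistics,
            "p_value": fit.p_values,
            "OR": fit.odds_ratios,
            "ci_lower": fit.ci_lower,
            "ci_upper": fit.ci_upper,
            "converged": fit.converged,
        }
    return out


def _collapse_by_horizon_section(cohort: Cohort) -> dict[str, Any]:
    scores = np.array(cohort.scores())
    times = np.array(cohort.times())
    events = np.array(cohort.events())
    levels = [s for s in SCORE_LEVELS if (scores == s).any()]
    out: dict[str, Any] = {"score_levels": levels}
    strata_n = np.array([(scores == s).sum() for s in levels])
    out["n_per_score"] = strata_n
    from .stats import ContingencyTable

    for horizon in _HORIZONS:
        collapsed = events & (times <= horizon)
        counts = np.array(
            [[(collapsed & (scores == s)).sum() for s in levels],
             [(~collapsed & (scores == s)).sum() for s in levels]]
        )
        entry: dict[str, Any] = {
            "collapsed": counts[0],
            "rates": counts[0] / strata_n,
        }
        try:
            chi = pearson_chi_square(
                ContingencyTable(counts, ["collapsed", "not_collapsed"], levels)
            )
            entry.update(chi_square=chi.statistic, df=chi.df, p_value=chi.p_value)
        except ValueError as exc:
            entry["chi_square_error"] = str(exc)
        out[f"year_{horizon:g}"] = entry
    return out


def _km_summary(curve) -> dict[str, Any]:
    return {
        "event_times": curve.event_times,
        "at_risk": curve.at_risk,
        "events": curve.events,
        "survival": curve.survival,
        "greenwood_se": curve.greenwood_se,
        "survival_at_years": {
            f"{h:g}": curve.survival_at(h) for h in _HORIZONS
        },
        "median": curve.median if curve.median is not None else "not reached",
        "median_ci": list(curve.median_ci),
    }


def _survival_section(cohort: Cohort) -> dict[str, Any]:
    times = cohort.times()
    events = cohort.events()
    if not any(events):
        return {"error": "no collapse events in the cohort; survival analysis "
                "is degenerate (S(t) = 1 everywhere)"}
    scores = np.array(cohort.scores())
    out = {"overall": _km_summary(km_estimate(times, events))}
    groups = []
    for s in SCORE_LEVELS:
        mask = scores == s
        if mask.any():
            t = np.array(times)[mask]
            e = np.array(events)[mask]
            groups.append((t, e))
            out[f"score_{s}"] = _km_summary(km_estimate(t, e))
    if len(groups) >= 2:
        lr = log_rank(groups)
        out["log_rank"] = {
            "chi_square": lr.statistic, "df": lr.df, "p_value": lr.p_value,
        }
    return out


def _roc_section(cohort: Cohort) -> dict[str, Any]:
    pos, neg = _score_event_counts(cohort)
    if pos.sum() == 0 or neg.sum() == 0:
        return {"error": "ROC undefined: need at least one collapsed and one "
                "non-collapsed hip"}
    roc = grouped_roc(SCORE_LEVELS, pos, neg)
    return {
        "score_levels": roc.score_levels,
        "pos_counts": roc.pos_counts,
        "neg_counts": roc.neg_counts,
        "points": roc.points,
        "auc": roc.auc,
        "auc_se": roc.auc_se,
        "auc_ci": list(roc.auc_ci),
        "cutoff": roc.cutoff,
        "sensitivity": roc.cutoff_sensitivity,
        "specificity": roc.cutoff_specificity,
    }


def run_full_analysis(cohort: Cohort) -> AnalysisReport:
    """Run the complete analysis; a pure function of the cohort."""
    n = len(cohort)
    n_events = cohort.n_events
    sections: dict[str, Any] = {
        "cohort": {
            "n_hips": n,
            "n_collapsed": n_events,
            "collapse_rate": n_events / n,
            "provenance": cohort.provenance,
        },
        "univariate": _univariate_section(cohort),
        "logistic": _logistic_section(cohort),
        "collapse_by_horizon": _collapse_by_horizon_section(cohort),
        "survival": _survival_section(cohort),
        "roc": _roc_section(cohort),
    }
    return AnalysisReport(sections=sections)
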