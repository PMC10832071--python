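"""Association statistics: contingency tables, Pearson chi-square,
two-sample t-tests from summary statistics, and multivariate logistic
regression with reference (dummy) coding and Wald odds ratios.

Conventions follow the source analyses exactly: the chi-square carries no
continuity correction, the t-test pools variances (not Welch), confidence
intervals are z-based Wald (exp(B ± 1.96·SE)), and no multiple-testing
adjustment is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats as ss
import statsmodels.api as sm

from .cohort import Cohort, HipRecord

FactorSpec = Union[str, Callable[[HipRecord], object]]

Z_95 = 1.96  # conventional two-sided 95% normal quantile, as printed


class SeparationError(RuntimeError):
    """Logistic MLE diverged: a term (quasi-)perfectly predicts the outcome."""


@dataclass
class ContingencyTable:
    counts: np.ndarray  # r x c non-negative integers
    row_labels: list
    col_labels: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D grid")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("grand total must be positive")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class TTestResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class LogisticFit:
    """Reference-coded logistic ML fit with Wald inference.

    ``term_labels`` lists the fitted (non-reference) design columns;
    ``reference_levels`` records which level of each categorical term was
    absorbed into the intercept.
    """

    term_labels: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_statistics: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    reference_levels: dict[str, str]
    converged: bool
    iterations: int
    log_likelihood: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "B": self.coefficients,
                "SE": self.standard_errors,
                "Wald": self.wald_statistics,
                "p_value": self.p_values,
                "OR": self.odds_ratios,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            },
            index=self.term_labels,
        )


def _factor_values(cohort: Cohort, factor: FactorSpec, name: str) -> list:
    if callable(factor):
        values = [factor(r) for r in cohort]
    else:
        values = [getattr(r, factor) for r in cohort]
    for i, v in enumerate(values):
        if v is None:
            raise ValueError(f"{name} factor has a missing value at record {i}")
    return [v.value if hasattr(v, "value") and not isinstance(v, bool) else v
            for v in values]


def build_contingency(
    cohort: Cohort,
    row_factor: FactorSpec,
    col_factor: FactorSpec,
    row_order: Optional[Sequence] = None,
    col_order: Optional[Sequence] = None,
) -> ContingencyTable:
    """Cross-tabulate two categorical factors over a cohort.

    Factors are record field names or callables deriving a label per record
    (e.g. "collapsed within 3 years"). Level order defaults to sorted;
    booleans order True first so event columns read (collapse, no collapse).
    """
    rows = _factor_values(cohort, row_factor, "row")
    cols = _factor_values(cohort, col_factor, "col")

    def levels(values, order):
        if order is not None:
            return list(order)
        uniq = set(values)
        if all(isinstance(v, bool) for v in uniq):
            return [lv for lv in (True, False) if lv in uniq]
        return sorted(uniq)

    row_levels = levels(rows, row_order)
    col_levels = levels(cols, col_order)
    if len(row_levels) == 1 or len(col_levels) == 1:
        warnings.warn("a factor has a single observed level", stacklevel=2)
    r_idx = {lv: i for i, lv in enumerate(row_levels)}
    c_idx = {lv: j for j, lv in enumerate(col_levels)}
    counts = np.zeros((len(row_levels), len(col_levels)), dtype=np.int64)
    for rv, cv in zip(rows, cols):
        if rv not in r_idx or cv not in c_idx:
            raise ValueError(f"level pair ({rv!r}, {cv!r}) outside the given order")
        counts[r_idx[rv], c_idx[cv]] += 1
    return ContingencyTable(counts, row_levels, col_levels)


def pearson_chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Uncorrected Pearson chi-square with df = (r-1)(c-1)."""
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (table.row_totals == 0).any() or (table.col_totals == 0).any():
        raise ValueError("zero row/column margin: expected count zero")
    stat, p, df, _ = ss.chi2_contingency(counts, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))


def t_test_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TTestResult:
    """Pooled-variance two-sided Student's t from group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = ss.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return TTestResult(
        statistic=float(res.statistic), df=n1 + n2 - 2, p_value=float(res.pvalue)
    )


def _design_matrix(
    df: pd.DataFrame,
    terms: Sequence[str],
    reference_levels: Optional[dict[str, str]],
) -> tuple[pd.DataFrame, dict[str, str]]:
    reference_levels = dict(reference_levels or {})
    columns: dict[str, np.ndarray] = {}
    used_refs: dict[str, str] = {}
    for term in terms:
        col = df[term]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            columns[term] = col.to_numpy(dtype=float)
            continue
        values = col.astype(str)
        levels = sorted(values.unique(), key=lambda s: (len(s), s))
        ref = str(reference_levels.get(term, levels[0]))
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not observed for {term!r}")
        used_refs[term] = ref
        for lv in levels:
            if lv == ref:
                continue
            columns[f"{term}[{lv}]"] = (values == lv).to_numpy(dtype=float)
    X = pd.DataFrame(columns, index=df.index)
    X.insert(0, "intercept", 1.0)
    return X, used_refs


def fit_logistic(
    data: Union[Cohort, pd.DataFrame],
    outcome: str,
    terms: Sequence[str] = (),
    reference_levels: Optional[dict[str, str]] = None,
) -> LogisticFit:
    """Multivariate logistic regression of a binary outcome.

    Categorical terms are dummy-coded against a reference level (default:
    the first level in natural order); continuous terms enter linearly.
    The fit is by maximum likelihood; non-convergence or (quasi-)complete
    separation raises :class:`SeparationError` rather than returning
    meaningless coefficients.
    """
    df = data.to_dataframe() if isinstance(data, Cohort) else data.copy()
    y = df[outcome].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    X, used_refs = _design_matrix(df, terms, reference_levels)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient after reference coding")
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        # non-convergence is escalated to SeparationError below, so the
        # advisory warning would be redundant noise
        warnings.simplefilter("ignore", sm.tools.sm_exceptions.ConvergenceWarning)
        try:
            res = model.fit(disp=0, maxiter=50, tol=1e-10)
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError,
        ) as exc:
            raise SeparationError(
                f"logistic fit for {outcome!r} ~ {list(terms)} did not yield a "
                f"finite MLE: {exc}"
            ) from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if (not res.mle_retvals.get("converged", False)) or not np.all(
        np.isfinite(params) & np.isfinite(bse)
    ) or np.max(np.abs(params)) > 25:
        raise SeparationError(
            f"logistic fit for {outcome!r} ~ {list(terms)} did not converge to a "
            "finite MLE (possible separation)"
        )
    wald = (params / bse) ** 2
    p = ss.chi2.sf(wald, df=1)
    return LogisticFit(
        term_labels=list(X.columns),
        coefficients=params,
        standard_errors=bse,
        wald_statistics=wald,
        p_values=p,
        odds_ratios=np.exp(params),
        ci_lower=np.exp(params - Z_95 * bse),
        ci_upper=np.exp(params + Z_95 * bse),
        reference_levels=used_refs,
        converged=bool(res.mle_retvals.get("converged", False)),
        iterations=int(res.mle_retvals.get("iterations", 0)),
        log_likelihood=float(res.llf),
    )
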