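"""Inferential statistics: Pearson chi-square, McNemar, logistic risk-factor
regression and 1:1 greedy caliper propensity-score matching.

Conventions follow the study's analysis plan: the chi-square statistic is
uncorrected Pearson; McNemar uses the closed-form chi-square for b+c >= 25
and an exact two-sided binomial test below that; propensity scores are
estimated on the probability scale and matched greedily within a caliper of
0.01, traversing side A in descending score order with nearest-neighbour
tie-breaks on the lower candidate index, which makes the matching
deterministic for a fixed input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .model import StudyValidationError

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "chi_square_test",
    "McNemarResult",
    "mcnemar_test",
    "logistic_risk_factors",
    "MatchResult",
    "greedy_caliper_pairs",
    "propensity_match",
]


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        object.__setattr__(self, "counts", arr)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise StudyValidationError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise StudyValidationError("contingency table has negative counts")
        if len(self.row_labels) != arr.shape[0] or len(self.col_labels) != arr.shape[1]:
            raise StudyValidationError("contingency table labels do not match shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square_test(table: ContingencyTable | np.ndarray | Sequence) -> ChiSquareResult:
    """Pearson chi-square without continuity correction; df = (r-1)(c-1)."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise StudyValidationError("chi-square requires an r x c table, r,c >= 2")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise StudyValidationError("chi-square undefined: a marginal total is zero")
    stat, p, df, _ = scipy.stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p))


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

#: Discordant-pair total at and above which the closed-form chi-square is used.
MCNEMAR_EXACT_CUTOFF = 25


@dataclass(frozen=True)
class McNemarResult:
    statistic: float | None
    p_value: float
    method: str  # "chi2" | "exact" | "degenerate"


def mcnemar_test(b: int, c: int) -> McNemarResult:
    """McNemar test from the two discordant-pair counts.

    ``b`` counts pairs switching 0 -> 1, ``c`` pairs switching 1 -> 0.  For
    b + c >= 25 the uncorrected chi-square (b-c)^2/(b+c) on 1 df is used;
    below that, the exact two-sided binomial test at p = 1/2.
    """
    if b < 0 or c < 0:
        raise StudyValidationError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        warnings.warn("McNemar with no discordant pairs; p = 1", stacklevel=2)
        return McNemarResult(0.0, 1.0, "degenerate")
    if n >= MCNEMAR_EXACT_CUTOFF:
        stat = (b - c) ** 2 / n
        return McNemarResult(float(stat), float(scipy.stats.chi2.sf(stat, df=1)), "chi2")
    p = scipy.stats.binomtest(b, n, 0.5, alternative="two-sided").pvalue
    return McNemarResult(None, float(p), "exact")


# ---------------------------------------------------------------------------
# Logistic risk-factor regression
# ---------------------------------------------------------------------------

def logistic_risk_factors(
    outcome: Sequence[int] | np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Multivariate logistic regression of a binary outcome on categorical covariates.

    Categorical columns are dummy-coded against their first level; numeric
    columns enter as-is.  Returns one row per coefficient with the estimate,
    standard error, Wald p-value and a ``significant`` flag (p < ``alpha``).
    Rank-deficient or separated designs raise a diagnostic error.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise StudyValidationError("outcome must be binary 0/1")
    for col in covariates.columns:
        if covariates[col].nunique() < 2:
            raise StudyValidationError(
                f"covariate column {col!r} is constant (rank-deficient design)")
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise StudyValidationError("design matrix is rank-deficient after dummy coding")
    if len(y) <= X.shape[1]:
        raise StudyValidationError("fewer observations than parameters")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as e:
        raise StudyValidationError(f"logistic fit failed: perfect separation ({e})") from None
    except np.linalg.LinAlgError as e:
        raise StudyValidationError(f"logistic fit failed: singular design ({e})") from None
    out = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "p_value": fit.pvalues.to_numpy(),
        }
    )
    out["significant"] = out["p_value"] < alpha
    return out


# ---------------------------------------------------------------------------
# Propensity-score matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchResult:
    """1:1 matched pairs (positional indices into the two input frames)."""

    pairs: tuple[tuple[int, int], ...]
    ps_a: np.ndarray
    ps_b: np.ndarray
    caliper: float
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pair_id": k,
                "unit_a": ia,
                "unit_b": ib,
                "ps_a": float(self.ps_a[ia]),
                "ps_b": float(self.ps_b[ib]),
                "abs_delta_ps": abs(float(self.ps_a[ia]) - float(self.ps_b[ib])),
            }
            for k, (ia, ib) in enumerate(self.pairs)
        ]
        return pd.DataFrame(
            rows, columns=["pair_id", "unit_a", "unit_b", "ps_a", "ps_b", "abs_delta_ps"]
        )


def _estimate_ps(units_a: pd.DataFrame, units_b: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    pooled = pd.concat([units_a, units_b], ignore_index=True)
    membership = np.r_[np.ones(len(units_a)), np.zeros(len(units_b))]
    X = pd.get_dummies(pooled, drop_first=True, dtype=float)
    X = X.loc[:, X.nunique() > 1]
    X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(membership, X, family=sm.families.Binomial()).fit()
            ps = np.asarray(fit.predict(X))
        except (np.linalg.LinAlgError, ValueError):
            # quasi-separated stratum: a faint ridge still yields a balancing score
            fit = sm.Logit(membership, X).fit_regularized(alpha=1e-4, disp=0, maxiter=500)
            ps = np.asarray(fit.predict(X))
    return ps[: len(units_a)], ps[len(units_a):]


def greedy_caliper_pairs(
    ps_a: np.ndarray, ps_b: np.ndarray, caliper: float
) -> list[tuple[int, int]]:
    """Greedy 1:1 pairing on propensity scores.

    Side A is traversed in descending score order (ties: lower index first);
    each unit claims the unmatched side-B unit with the nearest score, ties
    going to the lower side-B index, and is left unmatched if the nearest
    available score lies outside the caliper.
    """
    order_a = sorted(range(len(ps_a)), key=lambda i: (-ps_a[i], i))
    available = np.ones(len(ps_b), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for ia in order_a:
        best_j, best_d = -1, np.inf
        for j in range(len(ps_b)):
            if not available[j]:
                continue
            d = abs(ps_a[ia] - ps_b[j])
            if d < best_d - 1e-15:
                best_j, best_d = j, d
        if best_j >= 0 and best_d <= caliper + 1e-12:
            pairs.append((ia, best_j))
            available[best_j] = False
    return pairs


def propensity_match(
    units_a: pd.DataFrame,
    units_b: pd.DataFrame,
    caliper: float = 0.01,
    seed: int | None = None,
) -> MatchResult:
    """1:1 greedy nearest-neighbour matching within a propensity-score caliper.

    The score is the logistic-regression probability of membership in side A
    given the covariate columns (all columns of the inputs are used).  Side A
    units are traversed in descending score order; each takes the unmatched
    side-B unit with the nearest score, provided |PS_a - PS_b| <= caliper;
    score ties go to the lower side-B index.  ``seed`` is accepted for
    interface stability; the procedure itself is deterministic given the
    input order.
    """
    if caliper <= 0:
        raise StudyValidationError("caliper must be positive")
    if len(units_a) == 0 or len(units_b) == 0:
        warnings.warn("propensity_match: an empty side; no pairs formed", stacklevel=2)
        return MatchResult(
            (), np.zeros(len(units_a)), np.zeros(len(units_b)), caliper,
            tuple(range(len(units_a))), tuple(range(len(units_b))),
        )
    if list(units_a.columns) != list(units_b.columns):
        raise StudyValidationError("both sides must share the same covariate columns")
    ps_a, ps_b = _estimate_ps(units_a, units_b)
    pairs = greedy_caliper_pairs(ps_a, ps_b, caliper)
    matched_a = {ia for ia, _ in pairs}
    matched_b = {jb for _, jb in pairs}
    return MatchResult(
        pairs=tuple(sorted(pairs)),
        ps_a=ps_a,
        ps_b=ps_b,
        caliper=caliper,
        unmatched_a=tuple(i for i in range(len(ps_a)) if i not in matched_a),
        unmatched_b=tuple(j for j in range(len(ps_b)) if j not in matched_b),
    )
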