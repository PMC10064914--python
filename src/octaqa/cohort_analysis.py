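"""Cohort-level statistics for quadrant-asymmetry analysis.

Implements the comparisons used to separate ischemic from non-ischemic
central retinal vein occlusion (CRVO):

* per-group QA summaries (n, mean, sample SD);
* two-group mean differences with a pooled two-sample standard error;
* Mann-Whitney U tests (exact permutation null, or a tie-corrected normal
  approximation with continuity correction);
* empirical CDFs of QA and a pointwise right-shift (stochastic dominance)
  check;
* per-quadrant Mann-Whitney comparisons of raw metric values, pooling
  control with non-ischemic eyes against ischemic eyes;
* an eye-fixed-effects OLS regression of quadrant values on quadrant
  dummies (superior as reference), identifying whether any particular
  quadrant is preferentially affected by ischemia.

The eye fixed effects absorb everything constant within an eye -- group
main effects included -- so the reported quadrant terms are purely
within-eye contrasts.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .etdrs_grid import QUADRANTS
from .qa_stats import GROUPS, METRICS, EyeRecord

__all__ = [
    "ALPHA",
    "GroupSummary",
    "MeanDifference",
    "ComparisonResult",
    "QuadrantRegressionResult",
    "group_summaries",
    "mean_difference",
    "mann_whitney",
    "ECDF",
    "ecdf",
    "ecdf_right_shifted",
    "compare_groups",
    "per_quadrant_comparison",
    "records_to_long",
    "quadrant_fixed_effects_regression",
    "holm_adjust",
]

log = logging.getLogger(__name__)

#: Two-sided significance threshold used throughout.
ALPHA = 0.05

NON_REFERENCE_QUADRANTS = ("inferior", "nasal", "temporal")


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and sample SD of one metric's QA within one group."""

    group: str
    metric: str
    n: int
    mean: float
    sd: float  # NaN when n < 2

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("a summary needs at least one eye")


class MeanDifference(NamedTuple):
    difference: float
    pooled_se: float


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group contrast: mean difference (a - b) +/- pooled SE, and
    Mann-Whitney U with a two-sided p-value."""

    group_a: str
    group_b: str
    metric: str
    n_a: int
    n_b: int
    mean_difference: float
    pooled_se: float
    u_statistic: float
    p_value: float
    mw_mode: str

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def group_summaries(qa_table: pd.DataFrame) -> list[GroupSummary]:
    """Per-group, per-metric n / mean / sample SD (n-1 denominator).

    Groups absent from the table are omitted with a warning.
    """
    out: list[GroupSummary] = []
    for metric in METRICS:
        sub = qa_table[qa_table["metric"] == metric]
        for group in GROUPS:
            vals = sub.loc[sub["group"] == group, "qa"].to_numpy(dtype=float)
            if vals.size == 0:
                log.warning("group %r has no eyes for metric %r; omitted", group, metric)
                continue
            sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else float("nan")
            out.append(
                GroupSummary(
                    group=group, metric=metric, n=int(vals.size),
                    mean=float(np.mean(vals)), sd=sd,
                )
            )
    return out


def mean_difference(summary_a: GroupSummary, summary_b: GroupSummary) -> MeanDifference:
    """Mean difference (a - b) with pooled two-sample standard error.

    ``sp^2 = ((n_a - 1) s_a^2 + (n_b - 1) s_b^2) / (n_a + n_b - 2)`` and
    ``SE = sp * sqrt(1/n_a + 1/n_b)``.
    """
    if summary_a.n < 2 or summary_b.n < 2:
        raise ValueError("pooled SE needs n >= 2 in both groups")
    if summary_a.metric != summary_b.metric:
        raise ValueError("summaries are for different metrics")
    sp2 = (
        (summary_a.n - 1) * summary_a.sd**2 + (summary_b.n - 1) * summary_b.sd**2
    ) / (summary_a.n + summary_b.n - 2)
    se = math.sqrt(sp2) * math.sqrt(1.0 / summary_a.n + 1.0 / summary_b.n)
    return MeanDifference(difference=summary_a.mean - summary_b.mean, pooled_se=se)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """U = #{(i, j): x_i > y_j} + half-ties, via midranks; also returns the
    pooled midranks (fixed under relabeling, so reusable for the null)."""
    n = x.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    return u, ranks


def _exact_u_distribution_no_ties(n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of U for tie-free samples via the classic
    rank-sum counting recursion.  Support is 0..n*m (integers)."""
    # dp[k, u] after processing pooled ranks 1..r = number of ways to have
    # assigned k of them to x with U = u; taking rank r as the k-th smallest
    # x adds (r - k) to U.
    nm = n * m
    dp = np.zeros((n + 1, nm + 1))
    dp[0, 0] = 1.0
    for r in range(1, n + m + 1):
        new = dp.copy()
        for k in range(min(r, n), 0, -1):
            # choosing rank r as the k-th smallest x adds (r - k) to U
            add = r - k
            if add <= nm:
                new[k, add:] += dp[k - 1, : nm + 1 - add]
        dp = new
    support = np.arange(nm + 1, dtype=float)
    return support, dp[n]


def _exact_u_distribution_ties(
    ranks: np.ndarray, n: int, max_combinations: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Permutation null of U conditional on the observed pooled midranks.
    Enumerates all C(n+m, n) assignments; None when that exceeds the cap."""
    total = math.comb(ranks.size, n)
    if total > max_combinations:
        return None
    offset = n * (n + 1) / 2.0
    us = np.fromiter(
        (sum(c) - offset for c in itertools.combinations(ranks, n)),
        dtype=float,
        count=total,
    )
    support, counts = np.unique(us, return_counts=True)
    return support, counts.astype(float)


def _two_sided_p(support: np.ndarray, counts: np.ndarray, u: float) -> float:
    total = counts.sum()
    lo = counts[support <= u + 1e-9].sum() / total
    hi = counts[support >= u - 1e-9].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "exact",
    *,
    max_combinations: int = 200_000,
) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    ``exact`` uses the permutation null: a counting recursion on tie-free
    data, or full enumeration of the C(n+m, n) labelings when ties are
    present (falling back, with a log message, to the normal approximation
    if enumeration would exceed ``max_combinations``).  ``normal_approx``
    uses the tie-corrected normal approximation with continuity correction.

    Returns ``(U, p)`` where U counts pairs with x > y plus half-ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    u, ranks = _u_statistic(x, y)

    if np.ptp(np.concatenate([x, y])) == 0:
        log.info("all values identical across both samples; p = 1")
        return u, 1.0

    if mode == "exact":
        has_ties = np.unique(ranks).size < ranks.size
        if not has_ties:
            support, counts = _exact_u_distribution_no_ties(n, m)
        else:
            dist = _exact_u_distribution_ties(ranks, n, max_combinations)
            if dist is None:
                log.info(
                    "tied data with C(%d, %d) > %d labelings: "
                    "falling back to normal approximation",
                    n + m, n, max_combinations,
                )
                return u, _normal_approx_p(u, n, m, ranks)
            support, counts = dist
        return u, _two_sided_p(support, counts, u)

    if mode == "normal_approx":
        return u, _normal_approx_p(u, n, m, ranks)

    raise ValueError(f"mode must be 'exact' or 'normal_approx', got {mode!r}")


def _normal_approx_p(u: float, n: int, m: int, ranks: np.ndarray) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    big_n = n + m
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (big_n * (big_n - 1))
    sigma2 = n * m / 12.0 * ((big_n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    mu = n * m / 2.0
    diff = u - mu
    z = (diff - math.copysign(0.5, diff)) / math.sqrt(sigma2) if diff != 0 else 0.0
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Empirical CDFs


@dataclass(frozen=True)
class ECDF:
    """Right-continuous empirical CDF with F(max) = 1."""

    support: np.ndarray  # sorted unique values
    cumulative: np.ndarray  # F evaluated at each support point

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        idx = np.searchsorted(self.support, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.cumulative])
        out = padded[idx]
        return float(out) if np.ndim(t) == 0 else out


def ecdf(values: Sequence[float]) -> ECDF:
    """ECDF of a sample; duplicated values accumulate on one support point."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("sample must be non-empty")
    support, counts = np.unique(values, return_counts=True)
    return ECDF(support=support, cumulative=np.cumsum(counts) / values.size)


def ecdf_right_shifted(high: Sequence[float], low: Sequence[float]) -> bool:
    """True when the ECDF of ``high`` lies at or below the ECDF of ``low``
    at every point of the joint support (``high`` stochastically >= ``low``)."""
    f_high, f_low = ecdf(high), ecdf(low)
    grid = np.union1d(f_high.support, f_low.support)
    return bool(np.all(f_high(grid) <= f_low(grid) + 1e-12))


# ---------------------------------------------------------------------------
# Group contrasts


def compare_groups(
    qa_table: pd.DataFrame,
    group_a: str,
    group_b: str,
    metric: str,
    mode: str = "exact",
) -> ComparisonResult:
    """Contrast QA between two groups: mean difference +/- pooled SE plus a
    Mann-Whitney test on the per-eye QA values."""
    sub = qa_table[qa_table["metric"] == metric]
    x = sub.loc[sub["group"] == group_a, "qa"].to_numpy(dtype=float)
    y = sub.loc[sub["group"] == group_b, "qa"].to_numpy(dtype=float)
    return _compare_samples(x, y, group_a, group_b, metric, mode)


def _compare_samples(
    x: np.ndarray, y: np.ndarray, name_a: str, name_b: str, metric: str, mode: str
) -> ComparisonResult:
    if x.size < 2 or y.size < 2:
        raise ValueError(
            f"insufficient eyes for contrast {name_a!r} vs {name_b!r}: "
            f"n = {x.size}, {y.size} (need >= 2 each)"
        )
    sa = GroupSummary(name_a, metric, x.size, float(np.mean(x)), float(np.std(x, ddof=1)))
    sb = GroupSummary(name_b, metric, y.size, float(np.mean(y)), float(np.std(y, ddof=1)))
    diff = mean_difference(sa, sb)
    u, p = mann_whitney(x, y, mode=mode)
    return ComparisonResult(
        group_a=name_a, group_b=name_b, metric=metric, n_a=x.size, n_b=y.size,
        mean_difference=diff.difference, pooled_se=diff.pooled_se,
        u_statistic=u, p_value=p, mw_mode=mode,
    )


def records_to_long(records: Iterable[EyeRecord]) -> pd.DataFrame:
    """Tidy long table: one row per eye x quadrant with vld and pd columns."""
    rows = []
    for rec in records:
        for q in QUADRANTS:
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "eye_id": rec.eye_id,
                    "laterality": rec.laterality,
                    "group": rec.group,
                    "quadrant": q,
                    "vld": rec.metrics.vld[q],
                    "pd": rec.metrics.pd[q],
                }
            )
    return pd.DataFrame(rows)


def per_quadrant_comparison(
    records: Sequence[EyeRecord], metric: str, mode: str = "normal_approx"
) -> dict[str, ComparisonResult]:
    """Mann-Whitney on raw quadrant metric values (not QA), one test per
    quadrant, pooling control + non-ischemic eyes against ischemic eyes."""
    long = records_to_long(records)
    out: dict[str, ComparisonResult] = {}
    for q in QUADRANTS:
        sub = long[long["quadrant"] == q]
        pooled = sub.loc[sub["group"].isin(["control", "non_ischemic"]), metric]
        isch = sub.loc[sub["group"] == "ischemic", metric]
        out[q] = _compare_samples(
            pooled.to_numpy(dtype=float),
            isch.to_numpy(dtype=float),
            "control+non_ischemic",
            "ischemic",
            metric,
            mode,
        )
    return out


# ---------------------------------------------------------------------------
# Eye-fixed-effects quadrant regression


@dataclass(frozen=True)
class CoefficientEstimate:
    coefficient: float
    standard_error: float
    p_value: float


@dataclass(frozen=True)
class QuadrantRegressionResult:
    """Quadrant terms (superior = reference) from an eye-fixed-effects OLS.

    In the default ``interaction`` variant, fitted on CRVO eyes only, each
    reported term is quadrant x ischemic: how much more the quadrant (vs
    superior) is depressed in ischemic than in non-ischemic eyes.  In the
    ``within_ischemic`` variant, fitted on ischemic eyes only, each term is
    the plain quadrant-vs-superior contrast.
    """

    metric: str
    variant: str
    coefficients: dict[str, CoefficientEstimate]
    eye_intercepts: dict[str, float]
    n_eyes: int
    n_obs: int
    residuals: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(NON_REFERENCE_QUADRANTS):
            raise ValueError("expected exactly the three non-reference quadrants")


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; the message names the term."""


def quadrant_fixed_effects_regression(
    records: Sequence[EyeRecord],
    metric: str,
    variant: str = "interaction",
) -> QuadrantRegressionResult:
    """OLS of quadrant metric values on quadrant dummies with one intercept
    per eye (fixed effects absorbing all eye-level variation).

    ``interaction`` (default): restricted to CRVO eyes; quadrant dummies plus
    quadrant x ischemic interactions; the interactions are the reported
    coefficients.  ``within_ischemic``: ischemic eyes only; plain quadrant
    dummies are reported.  Conventional OLS standard errors and t-test
    p-values.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if variant == "interaction":
        use_groups = ("non_ischemic", "ischemic")
    elif variant == "within_ischemic":
        use_groups = ("ischemic",)
    else:
        raise ValueError(f"variant must be 'interaction' or 'within_ischemic'")
    subset = [r for r in records if r.group in use_groups]
    if variant == "interaction":
        for g in use_groups:
            if not any(r.group == g for r in subset):
                raise RankDeficiencyError(
                    f"group {g!r} absent: the ischemic-indicator interaction "
                    "terms are not identified"
                )
    if len(subset) < 2:
        raise RankDeficiencyError("need at least two eyes to fit eye fixed effects")

    long = records_to_long(subset)
    eye_ids = long["eye_id"].unique().tolist()
    eye_dummies = pd.get_dummies(long["eye_id"], dtype=float)[eye_ids]
    eye_dummies.columns = [f"eye[{e}]" for e in eye_ids]
    parts = [eye_dummies]
    coef_cols: dict[str, str] = {}
    for q in NON_REFERENCE_QUADRANTS:
        quad = (long["quadrant"] == q).astype(float)
        parts.append(quad.rename(f"quadrant[{q}]"))
        if variant == "interaction":
            isch = (long["group"] == "ischemic").astype(float)
            name = f"quadrant[{q}]:ischemic"
            parts.append((quad * isch).rename(name))
            coef_cols[q] = name
        else:
            coef_cols[q] = f"quadrant[{q}]"
    X = pd.concat(parts, axis=1)
    y = long[metric].astype(float)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        zero = [c for c in X.columns if not X[c].any()]
        culprit = zero[0] if zero else "collinear eye/quadrant terms"
        raise RankDeficiencyError(f"design matrix rank deficient: {culprit}")

    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    by_name = dict(zip(X.columns, range(X.shape[1])))
    coefficients = {
        q: CoefficientEstimate(
            coefficient=float(fit.params[by_name[coef_cols[q]]]),
            standard_error=float(fit.bse[by_name[coef_cols[q]]]),
            p_value=float(fit.pvalues[by_name[coef_cols[q]]]),
        )
        for q in NON_REFERENCE_QUADRANTS
    }
    eye_intercepts = {
        e: float(fit.params[by_name[f"eye[{e}]"]]) for e in eye_ids
    }
    return QuadrantRegressionResult(
        metric=metric,
        variant=variant,
        coefficients=coefficients,
        eye_intercepts=eye_intercepts,
        n_eyes=len(eye_ids),
        n_obs=int(fit.nobs),
        residuals=np.asarray(fit.resid),
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; unadjusted by default)."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]
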