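"""Nonparametric group-level statistics and the participant-exclusion filter.

The analysis toolkit is deliberately nonparametric: Wilcoxon rank-sum and
signed-rank tests (z statistics with tie-corrected variance; exact
permutation p-values at small n), Spearman rank correlations, and
Spearman correlations computed after residualizing both variables on
covariates (sex, a binary university-degree indicator, and age) by
ordinary least squares.  All p-values are two-tailed; no multiple-testing
adjustment is applied anywhere.

Ties receive average ranks throughout, and the rank-test variances carry
the standard tie correction — which makes the reported z identical to the
moment-standardized statistic of the exact permutation distribution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "spearman",
    "residualized_spearman",
    "ranksum_test",
    "signedrank_test",
    "apply_exclusion",
    "EXACT_N_MAX",
    "ConstantInputError",
    "DegenerateInputError",
    "CollinearCovariatesError",
]

log = logging.getLogger(__name__)

#: largest per-sample n for which exact permutation p-values are used.
EXACT_N_MAX = 8


class ConstantInputError(ValueError):
    """Correlation is undefined for a constant input."""


class DegenerateInputError(ValueError):
    """The test statistic is undefined (e.g. all paired differences zero)."""


class CollinearCovariatesError(ValueError):
    """The covariate design matrix is rank deficient."""


@dataclass
class StatResult:
    """One test's outcome: estimate (ρ or z), two-tailed p, and context."""

    name: str
    estimate: float
    p: float
    n: int
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.p = float(min(max(self.p, 0.0), 1.0))


def spearman(x, y) -> StatResult:
    """Spearman rank correlation (average ranks for ties), two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return StatResult("spearman", float(rho), float(p), x.size)


def _residuals(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def residualized_spearman(x, y, covariates: pd.DataFrame) -> StatResult:
    """Spearman correlation of the OLS residuals of x and y on covariates.

    ``covariates`` is a DataFrame (one row per observation); an intercept
    is added automatically and boolean columns are cast to 0/1 (e.g. the
    university-degree indicator for education).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = pd.DataFrame(covariates)
    if len(cov) != x.size:
        raise ValueError("covariate table must have one row per observation")
    if cov.isna().any().any():
        raise ValueError("covariate table is incomplete (NaNs present)")
    C = cov.astype(float).to_numpy()
    design = np.column_stack([np.ones(len(cov)), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = []
        base = np.ones((len(cov), 1))
        for j, name in enumerate(cov.columns):
            cand = np.column_stack([base, C[:, j]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                collinear.append(str(name))
            else:
                base = cand
        raise CollinearCovariatesError(
            f"rank-deficient covariates; collinear columns: {collinear}"
        )
    res = spearman(_residuals(x, design), _residuals(y, design))
    return StatResult(
        "residualized_spearman",
        res.estimate,
        res.p,
        res.n,
        covariates=tuple(str(c) for c in cov.columns),
    )


def _tie_term(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts**3 - counts))


def ranksum_test(group_a, group_b) -> StatResult:
    """Wilcoxon rank-sum (Mann-Whitney) test via the z statistic.

    z standardizes group A's rank sum by the exact permutation mean and
    tie-corrected variance; p is two-tailed (normal approximation, or the
    exact permutation distribution when both groups have n ≤ 8).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one observation")
    n1, n2 = a.size, b.size
    N = n1 + n2
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())
    mu = n1 * (N + 1) / 2.0
    var = n1 * n2 / 12.0 * ((N + 1) - _tie_term(ranks) / (N * (N - 1)))
    z = 0.0 if var == 0 else (w - mu) / np.sqrt(var)
    if max(n1, n2) <= EXACT_N_MAX:
        dev = abs(w - mu)
        hits = total = 0
        for combo in itertools.combinations(range(N), n1):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= dev - 1e-12:
                hits += 1
        p = hits / total
    else:
        p = 2.0 * sps.norm.sf(abs(z))
    return StatResult("ranksum", float(z), float(p), N)


def signedrank_test(x, y=None) -> StatResult:
    """Wilcoxon signed-rank test on paired data (or differences directly).

    Zero differences are dropped; all-zero differences are degenerate.
    z standardizes the positive-rank sum by the permutation mean and
    tie-corrected variance; p is exact (sign-flip enumeration) for n ≤ 8.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    wpos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(ranks) / 48.0
    z = 0.0 if var == 0 else (wpos - mu) / np.sqrt(var)
    if n <= EXACT_N_MAX:
        dev = abs(wpos - mu)
        hits = 0
        for signs in itertools.product((0, 1), repeat=n):
            wp = float(np.dot(signs, ranks))
            if abs(wp - mu) >= dev - 1e-12:
                hits += 1
        p = hits / 2**n
    else:
        p = 2.0 * sps.norm.sf(abs(z))
    return StatResult("signedrank", float(z), float(p), n)


def apply_exclusion(participants, missed_observation_counts, threshold: int = 30):
    """Drop participants who missed the observation lottery on more than
    ``threshold`` trials (strict inequality: a count of exactly 30 stays).

    Returns the retained participants (same sequence type contract: a
    list) and logs the excluded ids.
    """
    counts = np.asarray(missed_observation_counts)
    parts = list(participants)
    if counts.size != len(parts):
        raise ValueError("one missed-trial count per participant required")
    if (counts < 0).any():
        raise ValueError("negative missed-trial counts")
    kept, dropped = [], []
    for p, c in zip(parts, counts):
        (kept if c <= threshold else dropped).append(p)
    if dropped:
        ids = [getattr(p, "id", repr(p)) for p in dropped]
        log.info(
            "excluded %d participant(s) with > %d missed observation trials: %s",
            len(dropped), threshold, ids,
        )
    return kept
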