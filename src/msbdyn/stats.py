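"""Hypothesis tests implemented from first principles.

The three tests used for the synapse comparisons — one-tailed two-sample t,
two-tailed Mann–Whitney U (exact for small samples), and χ² (goodness-of-fit
and contingency) — are computed here directly from their definitions so that
their small-sample behavior is inspectable and testable; only the reference
distributions (t, normal, χ²) come from scipy. Significance defaults to
α = 0.05 throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, DegenerateVarianceError, InsufficientDataError

DEFAULT_ALPHA = 0.05
ENUMERATION_BUDGET = 200_000  # max label assignments for exact ties handling

__all__ = [
    "TestResult",
    "t_test_one_tailed",
    "mann_whitney_two_tailed",
    "chi_square_gof",
    "chi_square_contingency",
    "exact_u_distribution",
    "DEFAULT_ALPHA",
]


@dataclass
class TestResult:
    """Outcome of a hypothesis test."""

    name: str
    statistic: float
    p_value: float
    tails: int
    df: float | None = None
    alpha: float = DEFAULT_ALPHA
    method: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ConfigError(f"p_value out of [0, 1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        d = asdict(self)
        d["significant"] = self.significant
        return d


def _as_sample(x, name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n or np.isnan(arr).any():
        raise InsufficientDataError(
            f"{name}: need >= {min_n} finite observations, got {arr.size}")
    return arr


def t_test_one_tailed(sample_a, sample_b, *, alternative: str,
                      equal_var: bool = True,
                      alpha: float = DEFAULT_ALPHA) -> TestResult:
    """One-tailed two-sample t test.

    ``alternative`` must be given explicitly: ``"greater"`` tests
    mean_a > mean_b, ``"less"`` tests mean_a < mean_b — the direction is
    never inferred from the data. ``equal_var=True`` uses the pooled-variance
    statistic (default); False uses Welch with Satterthwaite df.
    """
    if alternative not in ("greater", "less"):
        raise ConfigError(f"alternative: must be 'greater' or 'less', "
                          f"got {alternative!r}")
    a = _as_sample(sample_a, "sample_a", 2)
    b = _as_sample(sample_b, "sample_b", 2)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_var:
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if pooled == 0.0:
            raise DegenerateVarianceError(
                "pooled variance is zero: both samples are constant")
        se = math.sqrt(pooled * (1 / na + 1 / nb))
        df = float(na + nb - 2)
        method = "pooled"
    else:
        if va == 0.0 and vb == 0.0:
            raise DegenerateVarianceError("both sample variances are zero")
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        method = "welch"
    t = float((a.mean() - b.mean()) / se)
    p = float(sps.t.sf(t, df) if alternative == "greater" else sps.t.cdf(t, df))
    return TestResult(name="one-tailed t", statistic=t, p_value=p, tails=1,
                      df=df, alpha=alpha, method=f"{method}, H1 mean_a "
                      f"{'>' if alternative == 'greater' else '<'} mean_b")


@lru_cache(maxsize=128)
def exact_u_distribution(m: int, n: int) -> tuple[int, ...]:
    """Counts of label assignments yielding each U value, for tie-free data.

    ``dist[u]`` is the number of the C(m+n, m) equally likely group
    assignments with U = u, by the standard counting recurrence
    ``N(m, n, u) = N(m−1, n, u−n) + N(m, n−1, u)``.
    """
    prev = [np.zeros(m * n + 1, dtype=object) for _ in range(n + 1)]
    for j in range(n + 1):
        prev[j][0] = 1  # N(0, j, 0) = 1
    for i in range(1, m + 1):
        cur = [np.zeros(m * n + 1, dtype=object) for _ in range(n + 1)]
        cur[0][0] = 1
        for j in range(1, n + 1):
            shifted = np.zeros(m * n + 1, dtype=object)
            shifted[j:] = prev[j][:m * n + 1 - j]
            cur[j] = shifted + cur[j - 1]
        prev = cur
    return tuple(int(c) for c in prev[n])


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_two_tailed(sample_a, sample_b,
                            exact_max_n: int = 10,
                            exact_max_product: int = 400,
                            alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Two-tailed Mann–Whitney U test.

    The exact null distribution of U is used when both samples have at most
    ``exact_max_n`` observations or their size product is at most
    ``exact_max_product``: via the counting recurrence for tie-free data, or
    full enumeration of group assignments when ties are present (within a
    combinatorial budget). Otherwise the normal approximation with tie
    correction and continuity correction is used. ``method`` records which
    path ran. Reported statistic: U = min(U_a, U_b).
    """
    a = _as_sample(sample_a, "sample_a", 1)
    b = _as_sample(sample_b, "sample_b", 1)
    m, n = a.size, b.size
    u_a = _u_statistic(a, b)
    u = min(u_a, m * n - u_a)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        warnings.warn("all values tied across both samples; p = 1", stacklevel=2)
        return TestResult(name="Mann-Whitney U", statistic=u, p_value=1.0,
                          tails=2, alpha=alpha, method="degenerate (all tied)")
    has_ties = np.unique(pooled).size < pooled.size
    want_exact = (m <= exact_max_n and n <= exact_max_n) or m * n <= exact_max_product
    center = m * n / 2.0
    observed_dev = abs(u_a - center)
    if want_exact and not has_ties:
        dist = exact_u_distribution(m, n)
        total = sum(dist)
        extreme = sum(c for v, c in enumerate(dist)
                      if abs(v - center) >= observed_dev - 1e-9)
        return TestResult(name="Mann-Whitney U", statistic=u,
                          p_value=extreme / total, tails=2, alpha=alpha,
                          method="exact (counting recurrence)")
    if want_exact and has_ties and math.comb(m + n, m) <= ENUMERATION_BUDGET:
        extreme = 0
        total = 0
        idx = np.arange(m + n)
        for chosen in combinations(idx, m):
            mask = np.zeros(m + n, dtype=bool)
            mask[list(chosen)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - center) >= observed_dev - 1e-9:
                extreme += 1
        return TestResult(name="Mann-Whitney U", statistic=u,
                          p_value=extreme / total, tails=2, alpha=alpha,
                          method="exact (enumeration, ties)")
    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    big_n = m + n
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (big_n * (big_n - 1))
    var = m * n / 12.0 * ((big_n + 1) - tie_term)
    if var <= 0:
        warnings.warn("zero variance after tie correction; p = 1", stacklevel=2)
        return TestResult(name="Mann-Whitney U", statistic=u, p_value=1.0,
                          tails=2, alpha=alpha, method="degenerate (ties)")
    z = (observed_dev - 0.5) / math.sqrt(var)  # continuity-corrected
    p = min(2.0 * float(sps.norm.sf(z)), 1.0)
    return TestResult(name="Mann-Whitney U", statistic=u, p_value=p, tails=2,
                      alpha=alpha, method="normal approximation, tie-corrected")


def chi_square_gof(observed_counts, expected_counts_or_probs,
                   alpha: float = DEFAULT_ALPHA) -> TestResult:
    """χ² goodness-of-fit: observed counts against expected proportions.

    ``expected_counts_or_probs`` may be counts or probabilities; it is
    rescaled to the observed total. χ² = Σ (O−E)²/E with df = cells − 1 and
    an upper-tail p.
    """
    obs = np.asarray(observed_counts, dtype=float).ravel()
    exp = np.asarray(expected_counts_or_probs, dtype=float).ravel()
    if obs.size != exp.size or obs.size < 2:
        raise ConfigError("observed and expected need equal length >= 2")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ConfigError("observed counts must be non-negative integers")
    if (exp <= 0).any():
        raise ConfigError("expected values must be > 0 in every cell")
    exp = exp * (obs.sum() / exp.sum())
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    return TestResult(name="chi-square goodness-of-fit", statistic=chi2,
                      p_value=float(sps.chi2.sf(chi2, df)), tails=1,
                      df=float(df), alpha=alpha)


def chi_square_contingency(table, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Pearson χ² test of independence on an r×c count table.

    No continuity correction; df = (r−1)(c−1). All row and column totals
    must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ConfigError("table: expected a 2-D table with >= 2 rows and columns")
    if (t < 0).any():
        raise ConfigError("table: counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ConfigError("table: every row and column total must be > 0")
    expected = np.outer(rows, cols) / t.sum()
    chi2 = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return TestResult(name="chi-square contingency", statistic=chi2,
                      p_value=float(sps.chi2.sf(chi2, df)), tails=1,
                      df=float(df), alpha=alpha)
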