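"""Omnibus and post-hoc comparison of screening models from r x 2 counts.

Each model contributes a (correct, incorrect) pair on a shared class
denominator.  The omnibus test across all models is an uncorrected
Pearson chi-square, or an exact test (Fisher for 2 groups, its
Freeman-Halton extension for r >= 3) when expected counts are small or a
cell is empty.  If the omnibus rejects at ``alpha``, all pairwise 2 x 2
comparisons follow at the Bonferroni level ``alpha' = alpha / k``.

No continuity correction is applied anywhere: the uncorrected statistic
is what screening reports print for these table sizes.

Two-sided exact p-values use the point-probability ("Irwin") rule: sum
the null probabilities of all tables with fixed margins whose point
probability does not exceed that of the observed table (a 1e-7 relative
tolerance absorbs floating-point ties).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import lgamma

import numpy as np
from scipy import stats

PEARSON_CHI2 = "pearson_chi2"
FISHER_EXACT = "fisher_exact"

_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """r x 2 table of per-group (correct, incorrect) counts."""

    group_labels: tuple[str, ...]
    correct: tuple[int, ...]
    incorrect: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_labels", tuple(self.group_labels))
        object.__setattr__(self, "correct", tuple(int(c) for c in self.correct))
        object.__setattr__(self, "incorrect", tuple(int(c) for c in self.incorrect))
        if len(self.group_labels) < 2:
            raise ValueError("need at least 2 groups")
        if not len(self.group_labels) == len(self.correct) == len(self.incorrect):
            raise ValueError("labels, correct and incorrect must align")
        if any(c < 0 for c in self.correct + self.incorrect):
            raise ValueError("counts must be non-negative")
        if any(c + i == 0 for c, i in zip(self.correct, self.incorrect)):
            raise ValueError("every group total must be > 0")

    @classmethod
    def from_totals(cls, labels, correct, totals) -> "ContingencyTable":
        incorrect = tuple(t - c for c, t in zip(correct, totals))
        return cls(tuple(labels), tuple(correct), incorrect)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def as_array(self) -> np.ndarray:
        return np.column_stack([self.correct, self.incorrect])

    def expected(self) -> np.ndarray:
        """Expected counts under independence from row/column margins."""
        obs = self.as_array
        rows = obs.sum(axis=1, keepdims=True)
        cols = obs.sum(axis=0, keepdims=True)
        return rows * cols / obs.sum()

    def subset(self, i: int, j: int) -> "ContingencyTable":
        return ContingencyTable(
            (self.group_labels[i], self.group_labels[j]),
            (self.correct[i], self.correct[j]),
            (self.incorrect[i], self.incorrect[j]),
        )


@dataclass(frozen=True)
class ComparisonResult:
    """One hypothesis test: method, statistic (None for exact tests),
    degrees of freedom, p-value and the significance call at the level
    the test was run at (``alpha_prime``)."""

    method: str
    statistic: float | None
    df: int | None
    p_value: float
    alpha_prime: float
    significant: bool
    label: str = ""

    @property
    def statistic_2dp(self) -> float | None:
        if self.statistic is None:
            return None
        from .metrics import round_half_up

        return round_half_up(self.statistic, 2)


def pearson_chi2(
    t: ContingencyTable, alpha: float = 0.05, label: str = ""
) -> ComparisonResult:
    """Uncorrected Pearson chi-square on an r x 2 table, df = r - 1."""
    obs = t.as_array
    if (obs.sum(axis=0) == 0).any():
        raise ValueError(
            "a column margin is zero (all groups entirely correct or entirely "
            "incorrect); the chi-square statistic is undefined — use Fisher's "
            "exact test"
        )
    res = stats.chi2_contingency(obs, correction=False)
    return ComparisonResult(
        method=PEARSON_CHI2,
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        alpha_prime=alpha,
        significant=bool(res.pvalue < alpha),
        label=label,
    )


def fisher_exact_2x2(
    t: ContingencyTable, alpha: float = 0.05, label: str = ""
) -> ComparisonResult:
    """Two-sided Fisher exact test on a 2 x 2 table."""
    if t.n_groups != 2:
        raise ValueError("fisher_exact_2x2 needs exactly 2 groups")
    res = stats.fisher_exact(t.as_array, alternative="two-sided")
    return ComparisonResult(
        method=FISHER_EXACT,
        statistic=None,
        df=None,
        p_value=float(res.pvalue),
        alpha_prime=alpha,
        significant=bool(res.pvalue < alpha),
        label=label,
    )


def _log_binom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _rx2_log_prob(correct: tuple[int, ...], totals: tuple[int, ...],
                  col_total: int, log_denom: float) -> float:
    """Log multivariate-hypergeometric probability of one r x 2 table with
    the given first-column entries, conditional on all margins."""
    return sum(_log_binom(n, c) for n, c in zip(totals, correct)) - log_denom


def _iter_first_columns(totals: tuple[int, ...], col_total: int):
    """Yield every admissible first column of an r x 2 table with fixed
    row totals and first-column total."""
    r = len(totals)

    def rec(i: int, remaining: int, prefix: tuple[int, ...]):
        if i == r - 1:
            if 0 <= remaining <= totals[-1]:
                yield prefix + (remaining,)
            return
        tail_cap = sum(totals[i + 1:])
        lo = max(0, remaining - tail_cap)
        hi = min(totals[i], remaining)
        for c in range(lo, hi + 1):
            yield from rec(i + 1, remaining - c, prefix + (c,))

    yield from rec(0, col_total, ())


def count_admissible_tables(t: ContingencyTable) -> int:
    """Number of r x 2 tables sharing the observed margins."""
    totals = tuple(c + i for c, i in zip(t.correct, t.incorrect))
    col = sum(t.correct)
    # DP over groups: ways[s] = #prefixes with partial sum s
    ways = np.zeros(col + 1, dtype=np.int64)
    ways[0] = 1
    for n in totals:
        new = np.zeros_like(ways)
        for s in range(col + 1):
            if ways[s]:
                hi = min(n, col - s)
                new[s : s + hi + 1] += ways[s]
        ways = new
    return int(ways[col])


def fisher_freeman_halton(
    t: ContingencyTable,
    alpha: float = 0.05,
    label: str = "",
    max_tables: int = 10_000,
    monte_carlo: bool = False,
    n_resamples: int = 100_000,
    seed: int | None = None,
) -> ComparisonResult:
    """Freeman-Halton exact test on an r x 2 table (r >= 2).

    Exact route: enumerate every table with the observed margins and sum
    the multivariate-hypergeometric probabilities of those no more
    probable than the observed table.  If more than ``max_tables`` tables
    are admissible, a seeded Monte-Carlo estimate over
    ``n_resamples`` multivariate-hypergeometric draws is used instead when
    ``monte_carlo=True``; otherwise an error states the table size.
    """
    totals = tuple(c + i for c, i in zip(t.correct, t.incorrect))
    col = sum(t.correct)
    n = sum(totals)
    log_denom = _log_binom(n, col)
    log_p_obs = _rx2_log_prob(t.correct, totals, col, log_denom)
    cutoff = log_p_obs + np.log1p(_TIE_RTOL)

    n_tables = count_admissible_tables(t)
    if n_tables <= max_tables:
        p = 0.0
        for correct in _iter_first_columns(totals, col):
            lp = _rx2_log_prob(correct, totals, col, log_denom)
            if lp <= cutoff:
                p += np.exp(lp)
        p = min(1.0, p)
    elif monte_carlo:
        if seed is None:
            raise ValueError("Monte-Carlo fallback requires an explicit seed")
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_hypergeometric(totals, col, size=n_resamples)
        lps = np.array(
            [_rx2_log_prob(tuple(d), totals, col, log_denom) for d in draws]
        )
        # add-one estimator keeps p > 0, standard for resampling p-values
        p = (1 + int((lps <= cutoff).sum())) / (n_resamples + 1)
    else:
        raise ValueError(
            f"{n_tables} admissible tables exceed the enumeration guard of "
            f"{max_tables}; enable monte_carlo with a seed or raise max_tables"
        )
    return ComparisonResult(
        method=FISHER_EXACT,
        statistic=None,
        df=None,
        p_value=float(p),
        alpha_prime=alpha,
        significant=bool(p < alpha),
        label=label,
    )


def choose_method(t: ContingencyTable) -> str:
    """Test-selection rule: exact test when any expected count < 5 or any
    observed cell is 0, otherwise Pearson chi-square.  Inferred from the
    reference report's observed choices (Fisher exactly where a zero cell
    occurs); overridable by calling the tests directly."""
    obs = t.as_array
    if (obs == 0).any() or (t.expected() < 5).any():
        return FISHER_EXACT
    return PEARSON_CHI2


def _run_test(
    t: ContingencyTable, alpha: float, label: str, method: str | None, seed: int | None
) -> ComparisonResult:
    chosen = method or choose_method(t)
    if chosen == PEARSON_CHI2:
        return pearson_chi2(t, alpha=alpha, label=label)
    if t.n_groups == 2:
        return fisher_exact_2x2(t, alpha=alpha, label=label)
    return fisher_freeman_halton(t, alpha=alpha, label=label,
                                 monte_carlo=True, seed=seed or 0)


def compare_models(
    table: ContingencyTable,
    alpha: float = 0.05,
    k_pairwise: int | None = None,
    method: str | None = None,
    seed: int | None = None,
) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """Omnibus test plus Bonferroni-corrected post-hoc pairwise tests.

    The omnibus runs on the full r x 2 table at level ``alpha``.  Only if
    it rejects are all pairwise 2 x 2 comparisons run, each at
    ``alpha' = alpha / k_pairwise`` (default: the number of pairs, e.g.
    0.05 / 3 for three models).  Method selection per table follows
    :func:`choose_method` unless ``method`` overrides it.
    """
    r = table.n_groups
    if k_pairwise is None:
        k_pairwise = r * (r - 1) // 2
    omnibus = _run_test(table, alpha, " vs ".join(table.group_labels), method, seed)
    pairwise: list[ComparisonResult] = []
    if omnibus.p_value < alpha:
        alpha_prime = alpha / k_pairwise
        for i, j in itertools.combinations(range(r), 2):
            sub = table.subset(i, j)
            lbl = f"{table.group_labels[i]} vs {table.group_labels[j]}"
            pairwise.append(_run_test(sub, alpha_prime, lbl, method, seed))
    return omnibus, pairwise


def compare_models_from_counts(
    labels, correct, totals, **kwargs
) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """Convenience wrapper taking per-model correct counts over a shared
    class denominator; refuses mismatched denominators."""
    totals = tuple(int(t) for t in totals)
    if len(set(totals)) != 1:
        raise ValueError(
            f"models must share the class denominator; got totals {totals}"
        )
    return compare_models(ContingencyTable.from_totals(labels, correct, totals),
                          **kwargs)
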