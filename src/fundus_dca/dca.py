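"""Decision curve analysis for screening strategies.

Net benefit of a screen-and-refer strategy at probability threshold p_t:

    NB(p_t) = TP/n - (p_t / (1 - p_t)) * FP/n

where p_t is the disease risk at which referring and not referring break
even, so p_t/(1-p_t) is the exchange rate between a false positive and a
true positive.  A screening test with sensitivity s and specificity q in
a population of prevalence pi has expected TP = n*pi*s and
FP = n*(1-pi)*(1-q); the reference strategies are refer-everyone
("treat all", NB = pi - (1-pi)*p_t/(1-p_t)) and refer-no-one
("treat none", NB = 0).

Two computation routes are provided and cross-checked: the closed form
over expected (possibly fractional) counts, and the empirical form that
counts records of a simulated or observed cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import NORMAL, DataError

TEST = "test"
TREAT_ALL = "treat_all"
TREAT_NONE = "treat_none"


@dataclass(frozen=True)
class NetBenefitPoint:
    """Net benefit of one strategy at one threshold, with the counts
    behind it (expected counts may be fractional in the closed form)."""

    threshold: float
    true_positive_count: float
    false_positive_count: float
    n: float
    net_benefit: float


@dataclass(frozen=True)
class Strategy:
    """A screening strategy: a test with an operating point, or one of
    the treat-all / treat-none references (which carry no operating
    point)."""

    kind: str
    label: str
    sensitivity: float | None = None
    specificity: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (TEST, TREAT_ALL, TREAT_NONE):
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        has_perf = self.sensitivity is not None or self.specificity is not None
        if self.kind == TEST and (self.sensitivity is None or self.specificity is None):
            raise ValueError("a test strategy needs sensitivity and specificity")
        if self.kind != TEST and has_perf:
            raise ValueError(f"{self.kind} carries no operating point")


@dataclass(frozen=True)
class NetBenefitCurve:
    strategy: Strategy
    points: tuple[NetBenefitPoint, ...]
    setting_label: str = ""

    def __post_init__(self) -> None:
        thr = [p.threshold for p in self.points]
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if len({p.n for p in self.points}) > 1:
            raise ValueError("all points of a curve must share n")

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([p.threshold for p in self.points])

    @property
    def net_benefits(self) -> np.ndarray:
        return np.array([p.net_benefit for p in self.points])


@dataclass(frozen=True)
class DominanceInterval:
    """Maximal contiguous threshold interval on which one strategy's net
    benefit strictly exceeds every competitor's."""

    strategy_label: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0.0 < self.lower <= self.upper < 1.0:
            raise ValueError("interval must lie within (0,1) with lower <= upper")


def _check_pt(p_t: float) -> None:
    if not 0.0 < p_t < 1.0:
        raise ValueError(
            f"threshold must lie in (0,1), got {p_t} "
            "(the false-positive weight p_t/(1-p_t) is undefined at 1)"
        )


def _weight(p_t: float) -> float:
    return p_t / (1.0 - p_t)


def nb_test_closed(
    sens: float, spec: float, prevalence: float, p_t: float, n: float = 100_000
) -> NetBenefitPoint:
    """Closed-form net benefit of a test at one threshold.

    Expected counts: TP = n*prevalence*sens, FP = n*(1-prevalence)*(1-spec);
    counts are kept fractional rather than rounded to whole persons.
    """
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} out of [0,1]: {v}")
    _check_pt(p_t)
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    tp = n * prevalence * sens
    fp = n * (1.0 - prevalence) * (1.0 - spec)
    nb = tp / n - _weight(p_t) * fp / n
    return NetBenefitPoint(p_t, tp, fp, n, nb)


def nb_treat_all(prevalence: float, p_t: float, n: float = 100_000) -> NetBenefitPoint:
    """Net benefit of referring everyone: prevalence - (1-prevalence)*w."""
    return nb_test_closed(1.0, 0.0, prevalence, p_t, n)


def nb_treat_none(p_t: float, n: float = 100_000) -> NetBenefitPoint:
    """Net benefit of referring no one: identically zero."""
    _check_pt(p_t)
    return NetBenefitPoint(p_t, 0.0, 0.0, n, 0.0)


def nb_empirical(
    records: pd.DataFrame,
    p_t: float,
    positive_class: str = "any",
    positive_rule: str = "exact_class",
) -> NetBenefitPoint:
    """Empirical net benefit from a record table.

    ``positive_class`` names the condition being screened for: a disease
    name, or ``"any"`` for any targeted disease.  A record is screen-
    positive when its prediction matches the condition (``exact_class``)
    or names any disease (``any_disease`` — identical to ``exact_class``
    when ``positive_class="any"``).  TP are screen-positive records that
    truly carry the condition, FP are screen-positive records that do
    not; n is the full record count.
    """
    if records.empty:
        raise DataError("record table is empty")
    _check_pt(p_t)
    truth = records["true_class"].to_numpy(dtype=object)
    pred = records["predicted_class"].to_numpy(dtype=object)
    if positive_class == "any":
        cond = truth != NORMAL
        pos = pred != NORMAL
    else:
        cond = truth == positive_class
        if positive_rule == "any_disease":
            pos = pred != NORMAL
        else:
            pos = pred == positive_class
    n = len(records)
    tp = int((pos & cond).sum())
    fp = int((pos & ~cond).sum())
    nb = tp / n - _weight(p_t) * fp / n
    return NetBenefitPoint(p_t, tp, fp, n, nb)


def combined_screening(
    sens_by_disease: dict[str, float], prevalence_by_disease: dict[str, float],
    specificity: float,
) -> tuple[float, float, float]:
    """Effective (sensitivity, specificity, prevalence) for screening
    "any targeted disease" in a mutually-exclusive multi-disease cohort.

    Combined prevalence is the sum of the per-disease prevalences (the
    diseases being disjoint); combined sensitivity is the prevalence-
    weighted mean of the per-disease sensitivities (the chance a random
    diseased subject is flagged); combined specificity is the normal-
    fundus specificity unchanged.
    """
    diseases = list(sens_by_disease)
    if not diseases:
        raise ValueError("empty disease list")
    missing = set(diseases) - set(prevalence_by_disease)
    if missing:
        raise ValueError(f"no prevalence for: {sorted(missing)}")
    prev = sum(prevalence_by_disease[d] for d in diseases)
    if prev >= 1.0:
        raise ValueError(f"prevalences sum to {prev} >= 1")
    if prev == 0.0:
        raise ValueError("combined prevalence is zero; sensitivity undefined")
    sens = sum(prevalence_by_disease[d] * sens_by_disease[d] for d in diseases) / prev
    return sens, specificity, prev


def default_grid(start: float = 0.01, stop: float = 0.99, step: float = 0.01
                 ) -> np.ndarray:
    """Threshold grid over (0,1); default 1% steps from 1% to 99%."""
    grid = np.round(np.arange(start, stop + step / 2, step), 10)
    if grid[0] <= 0.0 or grid[-1] >= 1.0:
        raise ValueError("grid must lie strictly inside (0,1)")
    return grid


def build_curves(
    strategies: list[Strategy],
    prevalence: float,
    n: float = 100_000,
    grid: np.ndarray | None = None,
    setting_label: str = "",
) -> list[NetBenefitCurve]:
    """One closed-form curve per strategy over a shared threshold grid.

    Treat-all and treat-none references are appended automatically if the
    caller did not include them.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.min() <= 0.0 or grid.max() >= 1.0:
        raise ValueError("grid thresholds must lie strictly inside (0,1)")
    kinds = {s.kind for s in strategies}
    strategies = list(strategies)
    if TREAT_ALL not in kinds:
        strategies.append(Strategy(TREAT_ALL, "treat all"))
    if TREAT_NONE not in kinds:
        strategies.append(Strategy(TREAT_NONE, "treat none"))

    curves = []
    for s in strategies:
        if s.kind == TEST:
            pts = [nb_test_closed(s.sensitivity, s.specificity, prevalence, t, n)
                   for t in grid]
        elif s.kind == TREAT_ALL:
            pts = [nb_treat_all(prevalence, t, n) for t in grid]
        else:
            pts = [nb_treat_none(t, n) for t in grid]
        curves.append(NetBenefitCurve(s, tuple(pts), setting_label))
    return curves


def dominance_intervals(curves: list[NetBenefitCurve]) -> list[DominanceInterval]:
    """Maximal grid intervals on which a single strategy strictly beats
    all others; grid points where the maximum is tied yield no interval."""
    if len(curves) < 2:
        raise ValueError("need at least 2 curves")
    grids = [tuple(c.thresholds) for c in curves]
    if len(set(grids)) != 1:
        raise ValueError("curves must share the threshold grid")
    thr = curves[0].thresholds
    nb = np.vstack([c.net_benefits for c in curves])
    best = nb.argmax(axis=0)
    # a strict winner must exceed the runner-up
    sorted_nb = np.sort(nb, axis=0)
    strict = sorted_nb[-1] > sorted_nb[-2]
    winner = np.where(strict, best, -1)

    intervals: list[DominanceInterval] = []
    start = 0
    for k in range(1, len(thr) + 1):
        if k == len(thr) or winner[k] != winner[start]:
            if winner[start] >= 0:
                intervals.append(
                    DominanceInterval(
                        curves[winner[start]].strategy.label,
                        float(thr[start]),
                        float(thr[k - 1]),
                    )
                )
            start = k
    return intervals


def curves_to_frame(curves: list[NetBenefitCurve]) -> pd.DataFrame:
    """Long-format table: setting,strategy,threshold,tp,fp,n,net_benefit."""
    rows = []
    for c in curves:
        for p in c.points:
            rows.append(
                dict(setting=c.setting_label, strategy=c.strategy.label,
                     threshold=p.threshold, tp=p.true_positive_count,
                     fp=p.false_positive_count, n=p.n, net_benefit=p.net_benefit)
            )
    return pd.DataFrame(rows)
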