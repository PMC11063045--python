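"""Diagnostic-accuracy metrics for multi-class screening records.

Per-class sensitivity (disease images assigned their own class), normal-
fundus specificity, Youden's index J = sensitivity + specificity - 1, and
a rank-based AUC utility.  Display follows the reporting convention of
community screening studies: percentages half-up to 2 decimals with the
correct count in parentheses, J to 4 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .cohort import NORMAL, DataError

POSITIVE_RULES = ("exact_class", "any_disease")


def round_half_up(x: float, decimals: int) -> float:
    """Round half away from zero on the decimal representation.

    Table conventions round 0.005 up to 0.01; binary floating-point
    `round()` is half-even, hence the Decimal detour.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Correct count over a class denominator.

    For a disease class this is (TP, class total); for the normal class
    (TN, normal total).
    """

    positive_correct: int
    positive_total: int

    def __post_init__(self) -> None:
        if self.positive_total <= 0:
            raise ValueError(f"positive_total must be > 0, got {self.positive_total}")
        if not 0 <= self.positive_correct <= self.positive_total:
            raise ValueError(
                f"need 0 <= correct <= total, got "
                f"{self.positive_correct}/{self.positive_total}"
            )

    @property
    def fraction(self) -> float:
        return self.positive_correct / self.positive_total

    @property
    def incorrect(self) -> int:
        return self.positive_total - self.positive_correct


@dataclass(frozen=True)
class TestPerformance:
    """Operating point of one model: per-disease sensitivity plus
    normal-fundus specificity, with the defining counts."""

    sensitivity_counts: dict[str, ConfusionCounts]
    specificity_counts: ConfusionCounts
    model_name: str = "model"

    @property
    def sensitivity_by_disease(self) -> dict[str, float]:
        return {d: c.fraction for d, c in self.sensitivity_counts.items()}

    @property
    def specificity(self) -> float:
        return self.specificity_counts.fraction

    def sensitivity_pct(self, disease: str) -> float:
        return sensitivity_pct(self.sensitivity_counts[disease])

    def specificity_pct(self) -> float:
        return specificity_pct(self.specificity_counts)


def class_confusion(
    records: pd.DataFrame, class_name: str, positive_rule: str = "exact_class"
) -> ConfusionCounts:
    """Confusion counts for one class of a record table.

    For a disease class the denominator is the records with that
    ``true_class``; a record counts correct if predicted its own class
    (``exact_class``, default) or any disease (``any_disease``).  For the
    normal class, correct means predicted normal under either rule.
    """
    if records.empty:
        raise DataError("record table is empty")
    if positive_rule not in POSITIVE_RULES:
        raise ValueError(f"positive_rule must be in {POSITIVE_RULES}")
    in_class = records["true_class"] == class_name
    total = int(in_class.sum())
    if total == 0:
        raise DataError(f"class {class_name!r} absent from record table")
    preds = records.loc[in_class, "predicted_class"]
    if class_name == NORMAL:
        correct = int((preds == NORMAL).sum())
    elif positive_rule == "exact_class":
        correct = int((preds == class_name).sum())
    else:
        correct = int((preds != NORMAL).sum())
    return ConfusionCounts(correct, total)


def performance_from_records(
    records: pd.DataFrame,
    diseases: list[str] | tuple[str, ...],
    positive_rule: str = "exact_class",
    model_name: str = "model",
) -> TestPerformance:
    """Full operating point (all diseases + specificity) of one model."""
    sens = {d: class_confusion(records, d, positive_rule) for d in diseases}
    spec = class_confusion(records, NORMAL)
    return TestPerformance(sens, spec, model_name=model_name)


def sensitivity_pct(c: ConfusionCounts) -> float:
    """Sensitivity as a percentage, half-up to 2 decimals (display).

    The unrounded fraction stays available as ``c.fraction`` and is what
    every downstream computation consumes.
    """
    return round_half_up(100.0 * c.positive_correct / c.positive_total, 2)


def specificity_pct(c: ConfusionCounts) -> float:
    """Specificity as a percentage, half-up to 2 decimals (display)."""
    return sensitivity_pct(c)


def youden_index(sens_fraction: float, spec_fraction: float) -> float:
    """Youden's J = sensitivity + specificity - 1, half-up to 4 decimals.

    Computed from unrounded fractions; see :func:`youden_from_counts` for
    the table-reporting convention that sums pre-rounded percentages.
    """
    for name, v in (("sensitivity", sens_fraction), ("specificity", spec_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} out of [0,1]: {v}")
    return round_half_up(sens_fraction + spec_fraction - 1.0, 4)


def youden_from_counts(
    sens: ConfusionCounts, spec: ConfusionCounts, table_convention: bool = False
) -> float:
    """Youden's J from the defining counts.

    With ``table_convention=True``, sensitivity and specificity are first
    rounded half-up to 2-decimal percentages and then summed — the
    arithmetic screening reports actually print, which can differ from
    the unrounded value in the 4th decimal.
    """
    if table_convention:
        j = (sensitivity_pct(sens) + specificity_pct(spec)) / 100.0 - 1.0
        return round_half_up(j, 4)
    return youden_index(sens.fraction, spec.fraction)


def wilson_interval(c: ConfusionCounts, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for the underlying proportion (an extension;
    the reference tables print no interval estimates)."""
    lo, hi = proportion_confint(
        c.positive_correct, c.positive_total, alpha=alpha, method="wilson"
    )
    return float(lo), float(hi)


def auc_trapezoid(scores, binary_labels) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    Ties in score are handled by rank averaging, making the result equal
    to the Mann-Whitney U statistic scaled by ``n_pos * n_neg``.
    """
    labels = np.asarray(binary_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs at least one positive and one negative label")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def metrics_table(
    records: pd.DataFrame,
    diseases: list[str] | tuple[str, ...],
    positive_rule: str = "exact_class",
) -> pd.DataFrame:
    """Per-(model, class) metric table from a multi-model record table.

    Output columns: model, class, metric, correct, total, percentage;
    one ``youden`` row per (model, disease) pairs each disease's
    sensitivity with the shared normal-fundus specificity.
    """
    rows = []
    for model, sub in records.groupby("model_name", sort=True):
        perf = performance_from_records(sub, diseases, positive_rule, str(model))
        spec_c = perf.specificity_counts
        for d in diseases:
            c = perf.sensitivity_counts[d]
            rows.append(
                dict(model=model, **{"class": d}, metric="sensitivity",
                     correct=c.positive_correct, total=c.positive_total,
                     percentage=sensitivity_pct(c))
            )
        rows.append(
            dict(model=model, **{"class": NORMAL}, metric="specificity",
                 correct=spec_c.positive_correct, total=spec_c.positive_total,
                 percentage=specificity_pct(spec_c))
        )
        for d in diseases:
            rows.append(
                dict(model=model, **{"class": d}, metric="youden",
                     correct=np.nan, total=np.nan,
                     percentage=youden_from_counts(perf.sensitivity_counts[d], spec_c))
            )
    return pd.DataFrame(rows)
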