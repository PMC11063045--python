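"""Synthetic screening-cohort generator.

Emulates a mutually-exclusive multi-class fundus-disease cohort (each
subject carries at most one target disease; everyone else has a normal
fundus) screened by a classifier with a known per-disease sensitivity and
a normal-fundus specificity.  The generator is the record-level forward
model for every downstream stage: diagnostic metrics, model comparison
and decision curve analysis can all be exercised on its output without
any external data.

All randomness flows through an explicit ``numpy.random.Generator`` seeded
per call; there is no global RNG state, so identical ``(spec, seed)``
pairs yield byte-identical record tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NORMAL = "normal"

RECORD_COLUMNS = ["record_id", "true_class", "predicted_class", "model_name"]

_MISS_TARGETS = frozenset({"normal"})
_FP_TARGETS = frozenset({"uniform"})


class ConfigurationError(ValueError):
    """Raised when a cohort or classifier specification is invalid."""


class DataError(ValueError):
    """Raised when a record table violates the declared class vocabulary."""


@dataclass(frozen=True)
class CohortSpec:
    """Population structure of a screening cohort.

    Parameters
    ----------
    diseases:
        Ordered disease names (e.g. ``["AMD", "DR", "PM"]``).
    prevalence_by_disease:
        Fraction of the cohort carrying each disease, in ``[0, 1)``.
        The remainder (``1 - sum``) is the normal-fundus class.
    cohort_size:
        Number of subjects to draw.
    setting_label:
        Free-text label for the setting, e.g. ``"urban"`` or ``"rural"``.
    """

    diseases: tuple[str, ...]
    prevalence_by_disease: dict[str, float] = field(hash=False)
    cohort_size: int = 100_000
    setting_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "diseases", tuple(self.diseases))
        if self.cohort_size < 1:
            raise ConfigurationError(
                f"cohort_size must be >= 1, got {self.cohort_size}"
            )
        missing = set(self.diseases) - set(self.prevalence_by_disease)
        if missing:
            raise ConfigurationError(f"no prevalence given for: {sorted(missing)}")
        if NORMAL in self.diseases:
            raise ConfigurationError(f"{NORMAL!r} is reserved for the residual class")
        for d in self.diseases:
            p = self.prevalence_by_disease[d]
            if not 0.0 <= p < 1.0:
                raise ConfigurationError(f"prevalence of {d!r} out of [0,1): {p}")
        total = sum(self.prevalence_by_disease[d] for d in self.diseases)
        if total >= 1.0:
            detail = ", ".join(
                f"{d}={self.prevalence_by_disease[d]}" for d in self.diseases
            )
            raise ConfigurationError(
                f"disease prevalences sum to {total} >= 1 ({detail}); "
                "no probability mass left for the normal class"
            )

    @property
    def classes(self) -> tuple[str, ...]:
        """Full class vocabulary: diseases plus the normal residual."""
        return self.diseases + (NORMAL,)

    @property
    def normal_fraction(self) -> float:
        return 1.0 - sum(self.prevalence_by_disease[d] for d in self.diseases)


@dataclass(frozen=True)
class ClassifierSpec:
    """Operating characteristics of a screening classifier.

    ``sensitivity_by_disease`` gives, per disease, the probability that a
    subject with that disease is assigned its own class.  ``specificity``
    is the probability a normal fundus is called normal.  ``miss_target``
    says where a missed disease case goes (only ``"normal"``: cross-disease
    confusions are not modelled because the reference operating points
    report only per-class sensitivity and normal-fundus specificity).
    ``false_positive_target`` says which disease a misclassified normal is
    assigned (only ``"uniform"`` over the declared diseases).
    """

    sensitivity_by_disease: dict[str, float] = field(hash=False)
    specificity: float = 1.0
    miss_target: str = "normal"
    false_positive_target: str = "uniform"
    model_name: str = "model"

    def __post_init__(self) -> None:
        for d, s in self.sensitivity_by_disease.items():
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError(f"sensitivity of {d!r} out of [0,1]: {s}")
        if not 0.0 <= self.specificity <= 1.0:
            raise ConfigurationError(f"specificity out of [0,1]: {self.specificity}")
        if self.miss_target not in _MISS_TARGETS:
            raise ConfigurationError(
                f"miss_target must be one of {sorted(_MISS_TARGETS)}, "
                f"got {self.miss_target!r}"
            )
        if self.false_positive_target not in _FP_TARGETS:
            raise ConfigurationError(
                f"false_positive_target must be one of {sorted(_FP_TARGETS)}, "
                f"got {self.false_positive_target!r}"
            )


def draw_true_classes(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw the true class of every subject in the cohort.

    Each subject's class is drawn independently from the categorical
    distribution given by the prevalences, with the residual mass on
    ``normal``.  Returns a record table with ``predicted_class`` empty.
    """
    rng = np.random.default_rng(seed)
    probs = [spec.prevalence_by_disease[d] for d in spec.diseases]
    probs.append(spec.normal_fraction)
    idx = rng.choice(len(spec.classes), size=spec.cohort_size, p=probs)
    classes = np.asarray(spec.classes, dtype=object)
    width = len(str(spec.cohort_size - 1))
    record_ids = [f"S{i:0{width}d}" for i in range(spec.cohort_size)]
    return pd.DataFrame(
        {
            "record_id": record_ids,
            "true_class": classes[idx],
            "predicted_class": "",
            "model_name": "",
        },
        columns=RECORD_COLUMNS,
    )


def apply_classifier(
    records: pd.DataFrame, clf: ClassifierSpec, seed: int
) -> pd.DataFrame:
    """Fill ``predicted_class`` by forward-simulating the classifier.

    A subject with disease ``d`` is predicted ``d`` with probability
    ``sensitivity_by_disease[d]`` and otherwise sent to ``miss_target``.
    A normal subject is predicted normal with probability ``specificity``
    and otherwise assigned a disease per ``false_positive_target``.
    """
    truths = records["true_class"].to_numpy(dtype=object)
    diseases = sorted(clf.sensitivity_by_disease)
    known = set(diseases) | {NORMAL}
    unknown = set(truths) - known
    if unknown:
        raise DataError(
            f"records contain classes with no classifier behaviour: {sorted(unknown)}"
        )

    rng = np.random.default_rng(seed)
    u = rng.random(len(truths))
    predicted = np.empty(len(truths), dtype=object)

    for d in diseases:
        mask = truths == d
        hit = u[mask] < clf.sensitivity_by_disease[d]
        out = np.where(hit, d, NORMAL)  # miss_target == "normal"
        predicted[mask] = out

    mask = truths == NORMAL
    hit = u[mask] < clf.specificity
    # misclassified normals get a disease uniformly at random; the draw is
    # seeded so the choice is reproducible even though no implemented
    # statistic depends on which disease is picked
    fp_choice = rng.integers(0, len(diseases), size=int(mask.sum()))
    fp_labels = np.asarray(diseases, dtype=object)[fp_choice]
    predicted[mask] = np.where(hit, NORMAL, fp_labels)

    out = records.copy()
    out["predicted_class"] = predicted
    out["model_name"] = clf.model_name
    return out


def simulate_cohort(
    spec: CohortSpec, clf: ClassifierSpec, seed: int
) -> pd.DataFrame:
    """Draw truths and predictions in one call (truths use ``seed``,
    predictions ``seed + 1``, both below 2**31)."""
    records = draw_true_classes(spec, seed)
    return apply_classifier(records, clf, (seed + 1) % (2**31))


def write_records(records: pd.DataFrame, path) -> None:
    """Write a record table as comma-separated UTF-8 text with header."""
    records.to_csv(path, index=False, columns=RECORD_COLUMNS, encoding="utf-8")


def read_records(path, vocabulary: set[str] | None = None) -> pd.DataFrame:
    """Read a record table, validating structure and class vocabulary.

    ``vocabulary``, when given, is the allowed set of class tokens
    (diseases plus ``"normal"``); any other token raises :class:`DataError`
    naming the token and its line number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"record file {path} lacks columns {missing}")
    df = df[RECORD_COLUMNS]
    if df["record_id"].duplicated().any():
        dup = df.loc[df["record_id"].duplicated(), "record_id"].iloc[0]
        raise DataError(f"duplicate record_id {dup!r} in {path}")
    if vocabulary is not None:
        for col in ("true_class", "predicted_class"):
            bad = ~df[col].isin(vocabulary) & (df[col] != "")
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                tok = df[col].iloc[i]
                # +2: header line plus 1-based numbering
                raise DataError(
                    f"unknown class token {tok!r} in column {col!r} "
                    f"at line {i + 2} of {path}"
                )
    return df
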