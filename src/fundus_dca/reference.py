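"""Published operating points of the community fundus-screening study.

The study evaluated a foundation-model-based screener ("RETFound-enhanced")
against two anonymised commercial models ("Model S", "Model Y") on a
community test set of 1890 fundus images: 287 age-related macular
degeneration (AMD), 337 diabetic retinopathy (DR), 151 pathologic myopia
(PM) and 1115 normal fundus.  A companion DR-only comparison against two
supervised CNN baselines used an internal validation set (502 DR / 517
normal) and the community set as external validation.

These printed correct-counts are the inputs to the desk-scale
recomputation: every comparison statistic and index in the analysis
derives from them.  Prevalence figures for urban and rural China were not
published alongside the counts; the values in ``ILLUSTRATIVE_PREVALENCE``
are plausible stand-ins (urban above rural, as the study's qualitative
finding requires) and are clearly not the study's own parameters.
"""

from __future__ import annotations

from .comparison import ContingencyTable
from .metrics import ConfusionCounts, TestPerformance

DISEASES = ("AMD", "DR", "PM")

MODELS = ("RETFound-enhanced", "Model S", "Model Y")

# community test set: per-model correct counts over the class denominators
CLASS_TOTALS = {"AMD": 287, "DR": 337, "PM": 151, "normal": 1115}

SCREENING_CORRECT = {
    "RETFound-enhanced": {"AMD": 218, "DR": 321, "PM": 151, "normal": 1031},
    "Model S": {"AMD": 176, "DR": 266, "PM": 90, "normal": 866},
    "Model Y": {"AMD": 170, "DR": 240, "PM": 109, "normal": 821},
}

# DR classification study: (correct, total) per model and validation arm.
# The report's printed percentages are kept alongside because its Youden
# column sums them as printed: one cell (ResNet50 external specificity,
# printed 91.56) disagrees with half-up rounding of 1021/1115 (91.57), so
# the printed J of 0.5328 is reproducible only from the printed
# percentages; counts give 0.5329.
DR_VALIDATION = {
    "internal": {
        "totals": {"DR": 502, "normal": 517},
        "correct": {
            "RETFound": {"DR": 483, "normal": 430},
            "EfficientNetB3": {"DR": 455, "normal": 453},
            "ResNet50": {"DR": 466, "normal": 444},
        },
    },
    "external": {
        "totals": {"DR": 337, "normal": 1115},
        "correct": {
            "RETFound": {"DR": 279, "normal": 875},
            "EfficientNetB3": {"DR": 229, "normal": 921},
            "ResNet50": {"DR": 208, "normal": 1021},
        },
    },
}

DR_PRINTED_PERCENT = {
    "internal": {
        "RETFound": {"DR": 96.22, "normal": 83.17},
        "EfficientNetB3": {"DR": 90.64, "normal": 87.62},
        "ResNet50": {"DR": 92.83, "normal": 85.88},
    },
    "external": {
        "RETFound": {"DR": 82.79, "normal": 78.48},
        "EfficientNetB3": {"DR": 67.95, "normal": 82.60},
        "ResNet50": {"DR": 61.72, "normal": 91.56},
    },
}

DR_PRINTED_YOUDEN = {
    "internal": {"RETFound": 0.7939, "EfficientNetB3": 0.7826, "ResNet50": 0.7871},
    "external": {"RETFound": 0.6127, "EfficientNetB3": 0.5055, "ResNet50": 0.5328},
}

# illustrative per-disease prevalences for the hypothetical cohort of
# 100,000; chosen once as round figures with urban > rural
ILLUSTRATIVE_PREVALENCE = {
    "urban": {"AMD": 0.031, "DR": 0.024, "PM": 0.011},
    "rural": {"AMD": 0.022, "DR": 0.012, "PM": 0.006},
}

HYPOTHETICAL_COHORT_SIZE = 100_000


def screening_performance(model: str) -> TestPerformance:
    """Operating point of one screening model from the printed counts."""
    correct = SCREENING_CORRECT[model]
    sens = {
        d: ConfusionCounts(correct[d], CLASS_TOTALS[d]) for d in DISEASES
    }
    spec = ConfusionCounts(correct["normal"], CLASS_TOTALS["normal"])
    return TestPerformance(sens, spec, model_name=model)


def screening_contingency(class_name: str) -> ContingencyTable:
    """r x 2 (correct, incorrect) table across the three screening models
    for one class (a disease, or "normal" for specificity)."""
    total = CLASS_TOTALS[class_name]
    correct = [SCREENING_CORRECT[m][class_name] for m in MODELS]
    return ContingencyTable.from_totals(MODELS, correct, [total] * len(MODELS))
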