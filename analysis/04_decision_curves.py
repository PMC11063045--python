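"""Decision curve analysis of the screening strategies.

For each setting (urban/rural illustrative prevalences) builds closed-form
net benefit curves over thresholds 1%..99% for the three screening models
— single-disease screening per disease and combined any-disease screening
— against the treat-all and treat-none references, reports the threshold
intervals on which each strategy dominates, and cross-checks the closed
form against record-level counting on a simulated 100,000-subject cohort.

Run from the repository root:  python analysis/04_decision_curves.py [--seed 1]
"""

import argparse
import math
from pathlib import Path

import numpy as np
import pandas as pd

from fundus_dca import (
    ClassifierSpec,
    CohortSpec,
    Strategy,
    build_curves,
    combined_screening,
    default_grid,
    dominance_intervals,
    nb_empirical,
    nb_test_closed,
    simulate_cohort,
)
from fundus_dca import reference as ref
from fundus_dca.dca import TEST, curves_to_frame


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    results = Path("results")
    results.mkdir(exist_ok=True)
    grid = default_grid()
    n = ref.HYPOTHETICAL_COHORT_SIZE
    perfs = {m: ref.screening_performance(m) for m in ref.MODELS}

    all_curves, dom_rows = [], []
    for setting in ("urban", "rural"):
        prev_by = ref.ILLUSTRATIVE_PREVALENCE[setting]
        panels = [(d, prev_by[d],
                   {m: (p.sensitivity_by_disease[d], p.specificity)
                    for m, p in perfs.items()})
                  for d in ref.DISEASES]
        combined = {m: combined_screening(p.sensitivity_by_disease, prev_by,
                                          p.specificity)
                    for m, p in perfs.items()}
        panels.append(("combined", next(iter(combined.values()))[2],
                       {m: (s, q) for m, (s, q, _) in combined.items()}))
        for panel, prev, ops in panels:
            strategies = [Strategy(TEST, m, sensitivity=s, specificity=q)
                          for m, (s, q) in ops.items()]
            curves = build_curves(strategies, prev, n, grid,
                                  f"{setting}:{panel}")
            all_curves.extend(curves)
            for iv in dominance_intervals(curves):
                dom_rows.append(dict(setting=setting, panel=panel,
                                     strategy=iv.strategy_label,
                                     lower=iv.lower, upper=iv.upper))

    curves_to_frame(all_curves).to_csv(results / "net_benefit_curves.csv",
                                       index=False)
    dom = pd.DataFrame(dom_rows)
    dom.to_csv(results / "dominance_intervals.csv", index=False)

    # closed form vs record-level counting on a simulated cohort
    xrows = []
    for s_i, setting in enumerate(("urban", "rural")):
        prev_by = ref.ILLUSTRATIVE_PREVALENCE[setting]
        spec = CohortSpec(ref.DISEASES, prev_by, n, setting)
        perf = perfs["RETFound-enhanced"]
        clf = ClassifierSpec(perf.sensitivity_by_disease, perf.specificity,
                             model_name=perf.model_name)
        cohort = simulate_cohort(spec, clf, (args.seed + s_i) % 2**31)
        sens, q, prev = combined_screening(perf.sensitivity_by_disease,
                                           prev_by, perf.specificity)
        p_tp, p_fp = prev * sens, (1 - prev) * (1 - q)
        for p_t in grid:
            w = p_t / (1 - p_t)
            closed = nb_test_closed(sens, q, prev, float(p_t), n).net_benefit
            emp = nb_empirical(cohort, float(p_t), "any").net_benefit
            sd = math.sqrt((p_tp * (1 - p_tp) + w**2 * p_fp * (1 - p_fp)) / n)
            xrows.append(dict(setting=setting, threshold=float(p_t),
                              closed=closed, empirical=emp,
                              deviation_sd=(emp - closed) / sd))
    xtab = pd.DataFrame(xrows)
    xtab.to_csv(results / "dca_crosscheck.csv", index=False)

    print("dominance intervals (strategy strictly above all competitors):")
    print(dom.to_string(index=False))
    worst = xtab["deviation_sd"].abs().max()
    print(f"\nclosed-form vs empirical net benefit on simulated cohorts: "
          f"largest |deviation| {worst:.2f} propagated binomial SD "
          "(bound: < 4 at every threshold)")
    lead = dom[dom.strategy == "RETFound-enhanced"]
    urban = lead[(lead.setting == "urban") & (lead.panel == "combined")]
    rural = lead[(lead.setting == "rural") & (lead.panel == "combined")]
    print("\ncombined screening: the foundation-model screener dominates on "
          f"urban thresholds {urban.lower.min():.0%}-{urban.upper.max():.0%} "
          f"and rural {rural.lower.min():.0%}-{rural.upper.max():.0%} "
          "(under the illustrative prevalences; urban net benefit exceeds "
          "rural at equal thresholds because prevalence is higher).")
    print("wrote results/net_benefit_curves.csv, dominance_intervals.csv, "
          "dca_crosscheck.csv")


if __name__ == "__main__":
    main()
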