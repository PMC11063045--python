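"""End-to-end pipeline: simulate -> metrics -> compare -> dca.

A single YAML config drives every stage.  Outputs are CSV files whose
first line is a comment embedding the seed and a hash of the effective
config, so any result file can be traced to the exact run that produced
it; a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import comparison, dca, metrics
from .cohort import (
    ClassifierSpec,
    CohortSpec,
    ConfigurationError,
    apply_classifier,
    draw_true_classes,
)

log = logging.getLogger("fundus_dca")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``models`` maps a model name to ``{"sensitivity": {disease: fraction},
    "specificity": fraction}``.  ``seed`` feeds every random draw; each
    model's classifier gets a distinct sub-seed derived from it.
    """

    diseases: tuple[str, ...]
    prevalence: dict[str, float]
    cohort_size: int
    setting_label: str
    models: dict[str, dict]
    positive_rule: str = "exact_class"
    alpha: float = 0.05
    pairwise: int | None = None
    grid_start: float = 0.01
    grid_stop: float = 0.99
    grid_step: float = 0.01
    seed: int = 0
    out_dir: str = "results/pipeline"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            cohort = raw["cohort"]
            analysis = raw.get("analysis", {})
            grid = analysis.get("grid", {})
            cfg = cls(
                diseases=tuple(cohort["diseases"]),
                prevalence=dict(cohort["prevalence"]),
                cohort_size=int(cohort.get("size", 100_000)),
                setting_label=str(raw.get("setting_label", "")),
                models={str(k): dict(v) for k, v in raw["models"].items()},
                positive_rule=analysis.get("positive_rule", "exact_class"),
                alpha=float(analysis.get("alpha", 0.05)),
                pairwise=analysis.get("pairwise"),
                grid_start=float(grid.get("start", 0.01)),
                grid_stop=float(grid.get("stop", 0.99)),
                grid_step=float(grid.get("step", 0.01)),
                seed=int(raw.get("seed", 0)),
                out_dir=str(raw.get("out_dir", "results/pipeline")),
            )
        except KeyError as e:
            raise ConfigurationError(f"config missing required key: {e}") from None
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        """Construct every domain spec once, so bad values fail here,
        before any stage has run."""
        self.cohort_spec()
        for name in self.models:
            self.classifier_spec(name)
        if self.positive_rule not in metrics.POSITIVE_RULES:
            raise ConfigurationError(
                f"positive_rule must be in {metrics.POSITIVE_RULES}"
            )
        dca.default_grid(self.grid_start, self.grid_stop, self.grid_step)

    def cohort_spec(self) -> CohortSpec:
        missing = set(self.diseases) - set(self.prevalence)
        if missing:
            raise ConfigurationError(f"config missing prevalence for {sorted(missing)}")
        return CohortSpec(self.diseases, self.prevalence, self.cohort_size,
                          self.setting_label)

    def classifier_spec(self, model: str) -> ClassifierSpec:
        m = self.models[model]
        try:
            return ClassifierSpec(
                sensitivity_by_disease={d: float(m["sensitivity"][d])
                                        for d in self.diseases},
                specificity=float(m["specificity"]),
                model_name=model,
            )
        except KeyError as e:
            raise ConfigurationError(
                f"model {model!r} missing key {e} in config"
            ) from None

    def to_dict(self) -> dict:
        return {
            "setting_label": self.setting_label,
            "cohort": {"diseases": list(self.diseases),
                       "prevalence": dict(self.prevalence),
                       "size": self.cohort_size},
            "models": self.models,
            "analysis": {"positive_rule": self.positive_rule,
                         "alpha": self.alpha, "pairwise": self.pairwise,
                         "grid": {"start": self.grid_start,
                                  "stop": self.grid_stop,
                                  "step": self.grid_step}},
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # where outputs land does not identify the run
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    header = f"# seed={cfg.seed} config={cfg.config_hash()}\n"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_output_csv(path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the provenance comment line."""
    return pd.read_csv(path, comment="#")


def render_table1_style(
    performances: list[metrics.TestPerformance],
    diseases: tuple[str, ...],
) -> pd.DataFrame:
    """Operating points in the layout of a screening-report table: one
    row per model x metric, one column per class, cells
    "percentage (correct count)" with "/" where the metric does not apply."""
    rows = []
    for perf in performances:
        sens_row = {"model": perf.model_name, "metric": "Sensitivity"}
        spec_row = {"model": perf.model_name, "metric": "Specificity"}
        for d in diseases:
            c = perf.sensitivity_counts[d]
            pct = metrics.sensitivity_pct(c)
            sens_row[d] = f"{pct:.2f} ({c.positive_correct})"
            spec_row[d] = "/"
        sc = perf.specificity_counts
        sens_row["normal"] = "/"
        spec_row["normal"] = f"{metrics.specificity_pct(sc):.2f} ({sc.positive_correct})"
        rows.extend([sens_row, spec_row])
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run simulate -> metrics -> compare -> dca and write the bundle.

    Returns the paths of the written outputs.  A failure in any stage
    removes the partial outputs and re-raises with the stage named.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": out / "config.yaml",
        "records": out / "records.csv",
        "metrics": out / "metrics.csv",
        "comparison": out / "comparison.csv",
        "curves": out / "curves.csv",
        "dominance": out / "dominance.csv",
        "summary": out / "summary.txt",
    }
    written: list[Path] = []
    stage = "validate"
    try:
        cfg.validate()
        with open(paths["config"], "w", encoding="utf-8") as fh:
            fh.write(f"# seed={cfg.seed} config={cfg.config_hash()}\n")
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
        written.append(paths["config"])

        stage = "simulate"
        t0 = time.perf_counter()
        spec = cfg.cohort_spec()
        truths = draw_true_classes(spec, cfg.seed)
        frames = []
        for i, model in enumerate(sorted(cfg.models)):
            clf = cfg.classifier_spec(model)
            # shared truth draw across models, distinct prediction draws
            rec = apply_classifier(truths, clf, (cfg.seed + 1 + i) % (2**31))
            rec["record_id"] = [f"{model}:{r}" for r in rec["record_id"]]
            frames.append(rec)
        records = pd.concat(frames, ignore_index=True)
        _write_csv(records, paths["records"], cfg)
        written.append(paths["records"])
        log.info("simulate: %d records in %.2fs", len(records),
                 time.perf_counter() - t0)

        stage = "metrics"
        t0 = time.perf_counter()
        mtab = metrics.metrics_table(records, cfg.diseases, cfg.positive_rule)
        _write_csv(mtab, paths["metrics"], cfg)
        written.append(paths["metrics"])
        log.info("metrics: %d rows in %.2fs", len(mtab), time.perf_counter() - t0)

        stage = "compare"
        t0 = time.perf_counter()
        crows = []
        sens = mtab[mtab.metric.isin(["sensitivity", "specificity"])]
        for cls_name, sub in sens.groupby("class", sort=True):
            sub = sub.sort_values("model")
            omnibus, pairwise = comparison.compare_models_from_counts(
                sub["model"].tolist(),
                sub["correct"].astype(int).tolist(),
                sub["total"].astype(int).tolist(),
                alpha=cfg.alpha,
                k_pairwise=cfg.pairwise,
                seed=cfg.seed,
            )
            for scope, res in [("omnibus", omnibus)] + [
                ("pairwise", p) for p in pairwise
            ]:
                crows.append(
                    {"class": cls_name, "scope": scope, "comparison": res.label,
                     "method": res.method, "statistic": res.statistic_2dp,
                     "df": res.df, "p_value": res.p_value,
                     "alpha_prime": res.alpha_prime,
                     "significant": res.significant}
                )
        ctab = pd.DataFrame(crows)
        _write_csv(ctab, paths["comparison"], cfg)
        written.append(paths["comparison"])
        log.info("compare: %d tests in %.2fs", len(ctab), time.perf_counter() - t0)

        stage = "dca"
        t0 = time.perf_counter()
        grid = dca.default_grid(cfg.grid_start, cfg.grid_stop, cfg.grid_step)
        all_curves = []
        perfs = {
            model: metrics.performance_from_records(
                records[records.model_name == model], cfg.diseases,
                cfg.positive_rule, model)
            for model in sorted(cfg.models)
        }
        targets = [(d, cfg.prevalence[d]) for d in cfg.diseases]
        comb = [(model,
                 dca.combined_screening(p.sensitivity_by_disease,
                                        cfg.prevalence, p.specificity))
                for model, p in perfs.items()]
        for disease, prev in targets:
            strategies = [
                dca.Strategy(dca.TEST, model,
                             sensitivity=p.sensitivity_by_disease[disease],
                             specificity=p.specificity)
                for model, p in perfs.items()
            ]
            curves = dca.build_curves(strategies, prev, cfg.cohort_size, grid,
                                      f"{cfg.setting_label}:{disease}")
            all_curves.extend(curves)
        strategies = [
            dca.Strategy(dca.TEST, model, sensitivity=s, specificity=q)
            for model, (s, q, _) in comb
        ]
        prev_comb = comb[0][1][2]
        all_curves.extend(
            dca.build_curves(strategies, prev_comb, cfg.cohort_size, grid,
                             f"{cfg.setting_label}:combined")
        )
        _write_csv(dca.curves_to_frame(all_curves), paths["curves"], cfg)
        written.append(paths["curves"])

        drows = []
        for label in {c.setting_label for c in all_curves}:
            group = [c for c in all_curves if c.setting_label == label]
            for iv in dca.dominance_intervals(group):
                drows.append({"setting": label, "strategy": iv.strategy_label,
                              "lower": iv.lower, "upper": iv.upper})
        dtab = pd.DataFrame(drows, columns=["setting", "strategy", "lower", "upper"])
        dtab = dtab.sort_values(["setting", "strategy", "lower"]).reset_index(drop=True)
        _write_csv(dtab, paths["dominance"], cfg)
        written.append(paths["dominance"])
        log.info("dca: %d curves in %.2fs", len(all_curves),
                 time.perf_counter() - t0)

        stage = "summary"
        table1 = render_table1_style(list(perfs.values()), cfg.diseases)
        with open(paths["summary"], "w", encoding="utf-8") as fh:
            fh.write(f"# seed={cfg.seed} config={cfg.config_hash()}\n")
            fh.write(f"setting: {cfg.setting_label or '(unlabelled)'}\n")
            fh.write(f"cohort size: {cfg.cohort_size}\n\n")
            fh.write("Operating points (simulated cohort):\n")
            fh.write(table1.to_string(index=False))
            fh.write("\n\nComparisons:\n")
            fh.write(ctab.to_string(index=False))
            fh.write("\n\nDominance intervals:\n")
            fh.write(dtab.to_string(index=False) if len(dtab) else "(none)")
            fh.write("\n")
        written.append(paths["summary"])
    except Exception as e:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    return paths
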