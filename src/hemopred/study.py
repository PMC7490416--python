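"""End-to-end study orchestration shared by the CLI, the analysis scripts
and the acceptance machinery: dataset generation with a drop log, the
two-scenario multi-model nested-CV battery, and report assembly."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import StudyConfig
from .dataset import StudyDataset, assemble_dataset, corrupt
from .errors import HemopredError
from .evaluation import (
    COMPLIANCE_THRESHOLDS,
    bland_altman,
    feature_importance_summary,
    regression_report,
    threshold_compliance,
)
from .measurements import build_record
from .population import sample_population
from .regression import (
    PRESSURE_EF_FEATURES,
    PRESSURE_FEATURES,
    CVRunResult,
    ModelSpec,
    ScenarioSpec,
    ensemble_average,
    hyperparameter_frequency,
    run_nested_cv,
)
from .simulator import simulate_population

log = logging.getLogger("hemopred")

__all__ = ["GenerationReport", "generate_study_dataset", "study_scenarios",
           "run_study", "summarise_run"]


@dataclass
class GenerationReport:
    """Dataset plus the per-subject drop log."""

    dataset: StudyDataset           # noise-corrupted (or clean, per config)
    clean: StudyDataset             # pre-noise table
    dropped: list[tuple[str, str]]  # (subject_id, reason)
    n_requested: int

    @property
    def drop_fraction(self) -> float:
        return len(self.dropped) / max(self.n_requested, 1)


def generate_study_dataset(config: StudyConfig,
                           progress: bool = False) -> GenerationReport:
    """population -> simulate -> extract -> (noise): the Fig-1 style pipeline."""
    subjects = sample_population(config.sampling)
    results = simulate_population(subjects, config.solver,
                                  batch_size=config.batch_size,
                                  progress=progress)
    records, dropped = [], []
    for subj, res in zip(subjects, results):
        try:
            feats, targs = build_record(res, subj)
            records.append((subj.id, feats, targs))
        except HemopredError as exc:
            dropped.append((subj.id, str(exc)))
            log.info("dropped %s: %s", subj.id, exc)
    provenance = {
        "population_seed": config.sampling.seed,
        "n_requested": config.sampling.n,
        "n_retained": len(records),
        "simulator_version": __version__,
        "config_hash": config.config_hash(),
    }
    clean = assemble_dataset(records, provenance)
    dataset = corrupt(clean, config.noise) if config.apply_noise else clean
    if dropped and len(dropped) > 0.05 * config.sampling.n:
        log.warning("dropped %d/%d subjects (> 5%%)",
                    len(dropped), config.sampling.n)
    return GenerationReport(dataset=dataset, clean=clean, dropped=dropped,
                            n_requested=config.sampling.n)


def study_scenarios(targets=("aSBP", "CO", "E_es")) -> list[ScenarioSpec]:
    """Scenario (i): pressure features for every target; (ii): +EF for E_es."""
    scenarios = [ScenarioSpec(PRESSURE_FEATURES, t) for t in targets]
    if "E_es" in targets:
        scenarios.append(ScenarioSpec(PRESSURE_EF_FEATURES, "E_es"))
    return scenarios


def summarise_run(run: CVRunResult) -> dict:
    """Metrics block, Bland-Altman and compliance for one CV run."""
    report = regression_report(run.y_pred, run.y_true, run.fold_ids)
    ba = bland_altman(run.y_pred, run.y_true)
    thresholds = COMPLIANCE_THRESHOLDS[run.scenario.target]
    return {
        "model": run.model.family,
        "target": run.scenario.target,
        "features": "+".join(run.scenario.features),
        **report.to_dict(),
        "ba_bias": ba.bias, "ba_loa_low": ba.loa_low, "ba_loa_high": ba.loa_high,
        **{f"pct_within_{tau:g}": v
           for tau, v in threshold_compliance(run.y_pred, run.y_true,
                                              thresholds).items()},
    }


def run_study(dataset: StudyDataset, config: StudyConfig,
              families=("random_forest", "svr", "ridge", "gradient_boosting"),
              scenarios: list[ScenarioSpec] | None = None,
              progress: bool = False):
    """The full Tables-2-to-7 battery.

    Returns (runs, summary, hyper_freq, importances): nested-CV runs keyed by
    (family, features, target), a tidy summary table including the two
    ensemble rows per scenario, hyperparameter selection frequencies, and
    Random-Forest importances per scenario (when RF is among the families).
    """
    scenarios = scenarios or study_scenarios(config.targets)
    runs: dict[tuple, CVRunResult] = {}
    summary_rows, freq_rows, importance_rows = [], [], []
    for scen in scenarios:
        scen_runs = []
        for family in families:
            model = ModelSpec(family, dict(config.grids.get(family, {})))
            if progress:
                print(f"[{scen.target} | {'+'.join(scen.features)}] {family}",
                      flush=True)
            run = run_nested_cv(dataset, model, scen, config.cv,
                                progress=False)
            runs[(family, scen.features, scen.target)] = run
            scen_runs.append(run)
            summary_rows.append(summarise_run(run))
            freq = hyperparameter_frequency(run)
            freq.insert(0, "model", family)
            freq.insert(1, "target", scen.target)
            freq.insert(2, "features", "+".join(scen.features))
            freq_rows.append(freq)
            if family == "random_forest":
                imp = feature_importance_summary(run, dataset)
                imp.insert(0, "target", scen.target)
                imp.insert(1, "features", "+".join(scen.features))
                importance_rows.append(imp)
        # ensemble rows: all families, and RF+SVR+GB
        for label, members in (("ensemble_all", families),
                               ("ensemble_rf_svr_gb",
                                [f for f in families if f != "ridge"])):
            member_runs = [r for r in scen_runs if r.model.family in members]
            if len(member_runs) < 2:
                continue
            pred = ensemble_average(member_runs)
            proxy = CVRunResult(
                model=member_runs[0].model, scenario=scen,
                cv=member_runs[0].cv, y_true=member_runs[0].y_true,
                y_pred=pred, fold_ids=member_runs[0].fold_ids,
                fold_params=member_runs[0].fold_params,
                fold_inner_mse=member_runs[0].fold_inner_mse,
            )
            row = summarise_run(proxy)
            row["model"] = label
            summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    hyper = (pd.concat(freq_rows, ignore_index=True)
             if freq_rows else pd.DataFrame())
    importances = (pd.concat(importance_rows, ignore_index=True)
                   if importance_rows else pd.DataFrame())
    return runs, summary, hyper, importances
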