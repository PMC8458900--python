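"""Deterministic orchestration of the full pipeline and its file outputs.

Stage order follows the study design: sample a heterogeneous population,
stress every individual and classify the phenotypes, fit the phenotype
tree, scan random treatments separately over the low- and high-cortisol
cohorts, rank targets with the random forest, read the treatment direction
off the decision tree, and design and evaluate targeted protocols.

Every stage draws its randomness from a seed derived from the master seed
and the stage name, so stages are reproducible in isolation and growing
one stage never reshuffles another.
"""

from __future__ import annotations

import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .model_core import COMPONENTS
from .ml_analysis import (
    balance_classes,
    build_phenotype_features,
    build_treatment_features,
    fit_classification_tree,
    random_forest_importance,
    treatment_direction_tree,
)
from .population import PopulationSample, sample_population
from .protocols import (
    HIGH_CORTISOL,
    LOW_CORTISOL,
    PatientRecord,
    phenotype_fractions,
    random_treatment_scan,
    records_to_frame,
    run_cohort,
)
from .treatment_design import design_top_protocols, evaluate_protocol

__all__ = ["stage_seed", "run_pipeline", "simulate_population",
           "cohort_frame", "PHENOTYPE_CLASSES"]

logger = logging.getLogger(__name__)

PHENOTYPE_CLASSES = {"low": LOW_CORTISOL, "high": HIGH_CORTISOL}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from master seed + name."""
    return int(np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(zlib.crc32(stage.encode()),)).generate_state(1)[0]
        % (2 ** 31))


def simulate_population(config: RunConfig
                        ) -> tuple[PopulationSample, list[PatientRecord]]:
    """Sample the population and run the stress experiment on everyone."""
    pop = sample_population(config.basal_params(), config.fold, config.n,
                            stage_seed(config.seed, "population"))
    cohort = run_cohort(pop, config.pulse(), config.sim(),
                        checkpoint_times=(config.scan_t_on,
                                          config.targeted_t_on))
    return pop, cohort


def cohort_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Phenotype table: label, cortisol summaries, post-stress levels."""
    return pd.DataFrame([{
        "id": p.individual_id,
        "phenotype": p.phenotype.label,
        "baseline_cortisol": p.phenotype.baseline_cortisol,
        "post_cortisol": p.phenotype.post_cortisol,
        "oscillatory": p.phenotype.oscillatory,
        **dict(zip(COMPONENTS, p.post_state_mean)),
    } for p in cohort])


def run_pipeline(config: RunConfig, make_plots: bool = False
                 ) -> dict[str, str]:
    """Execute every stage and write CSV/text outputs; returns the manifest.

    Any stage failure propagates with the stage name attached; outputs of
    completed stages remain on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def write(key: str, name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest[key] = str(path)
        logger.info("pipeline: wrote %s", path)

    stage = "configuration"
    try:
        write("config", "effective_config.yaml", config.to_yaml)

        stage = "population"
        pop, cohort = simulate_population(config)
        write("population", "population.csv", pop.to_csv)
        write("phenotypes", "phenotypes.csv",
              lambda p: cohort_frame(cohort).to_csv(p, index=False))
        logger.info("phenotype fractions: %s", phenotype_fractions(cohort))

        stage = "phenotype tree"
        table = balance_classes(build_phenotype_features(cohort),
                                stage_seed(config.seed, "balance"))
        ptree = fit_classification_tree(table, config.tree_max_depth,
                                        config.tree_min_leaf,
                                        stage_seed(config.seed, "ptree"))
        write("phenotype_tree", "phenotype_tree.txt",
              lambda p: Path(p).write_text(ptree.render() + "\n"))
        write("phenotype_tree_csv", "phenotype_tree.csv", ptree.to_csv)

        for short, label in PHENOTYPE_CLASSES.items():
            patients = [p for p in cohort if p.phenotype.label == label]
            if not patients:
                logger.warning("no %s patients; skipping that arm", label)
                continue

            stage = f"treatment scan ({short})"
            records = random_treatment_scan(
                patients, config.n_treatments_per_patient,
                config.magnitude_max,
                stage_seed(config.seed, f"scan-{short}"),
                config.scan_t_on, config.scan_duration, config.sim())
            write(f"scan_{short}", f"scan_{short}.csv",
                  lambda p, r=records: records_to_frame(r).to_csv(
                      p, index=False))

            stage = f"ML analysis ({short})"
            ttable = build_treatment_features(records)
            report = random_forest_importance(
                ttable, config.n_trees, config.n_permutations,
                stage_seed(config.seed, f"forest-{short}"))
            write(f"importance_{short}", f"importance_{short}.csv",
                  report.to_csv)
            dtree = treatment_direction_tree(
                ttable, config.tree_max_depth, config.tree_min_leaf,
                stage_seed(config.seed, f"dtree-{short}"))
            write(f"direction_tree_{short}", f"direction_tree_{short}.csv",
                  dtree.to_csv)
            write(f"direction_tree_{short}_txt", f"direction_tree_{short}.txt",
                  lambda p, t=dtree: Path(p).write_text(t.render() + "\n"))

            stage = f"treatment design ({short})"
            try:
                protocols = design_top_protocols(
                    report, dtree, label,
                    (config.targeted_t_on, config.targeted_duration),
                    config.safety_factor, config.tie_points)
            except ValueError as exc:
                # an undetermined direction (top target never split on) is
                # a data condition, not a code failure: skip this arm
                logger.warning("no designable protocol for %s: %s",
                               label, exc)
                continue
            proto_rows = []
            eff_frames = []
            for k, proto in enumerate(protocols):
                eff = evaluate_protocol(proto, patients, config.sim())
                logger.info("%s protocol %s %s by %.3g: %d/%d effective",
                            label, proto.direction, proto.target,
                            proto.magnitude, eff.n_effective, eff.n_treated)
                proto_rows.append({
                    "phenotype": label, "target": proto.target,
                    "direction": proto.direction,
                    "magnitude": proto.magnitude,
                    "t_on": proto.window[0], "duration": proto.window[1],
                    "n_treated": eff.n_treated,
                    "n_effective": eff.n_effective,
                    "fraction_effective": eff.fraction_effective,
                })
                eff_frames.append(
                    eff.outcomes.assign(target=proto.target))
            write(f"protocols_{short}", f"protocols_{short}.csv",
                  lambda p, rows=proto_rows: pd.DataFrame(rows).to_csv(
                      p, index=False))
            write(f"efficacy_{short}", f"efficacy_{short}.csv",
                  lambda p, fr=eff_frames: pd.concat(
                      fr, ignore_index=True).to_csv(p, index=False))

        if make_plots:
            stage = "plots"
            from .plots import plot_phenotype_examples
            write("plots", "phenotype_examples.png",
                  lambda p: plot_phenotype_examples(config, cohort, p))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return manifest
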