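"""Rational design of targeted treatments from ML rankings.

The random forest ranks candidate target parameters; the direction tree
says on which side of a split threshold the effective treatments sit.  A
targeted protocol takes a top-ranked target, the direction of its
effective-majority side, and a magnitude slightly beyond the tree's
threshold (a safety factor covers the threshold's estimation error), and
applies the identical transient change to every patient of the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .model_core import SystemState
from .ml_analysis import ImportanceReport, TreeSummary
from .protocols import (
    EFFECTIVE,
    PatientRecord,
    SimConfig,
    TreatmentSpec,
    apply_treatment,
    classify_treatment_outcome,
)

__all__ = ["TargetedProtocol", "EfficacyReport", "design_protocol",
           "design_top_protocols", "evaluate_protocol"]

logger = logging.getLogger(__name__)

DECREASE = "decrease"
INCREASE = "increase"


@dataclass(frozen=True)
class TargetedProtocol:
    """One rationally designed transient treatment for a phenotype class."""

    phenotype_class: str
    target: str
    direction: str
    magnitude: float
    window: tuple[float, float]  # (t_on, duration)

    def __post_init__(self) -> None:
        if self.direction not in (DECREASE, INCREASE):
            raise ValueError(f"direction must be '{DECREASE}' or "
                             f"'{INCREASE}', got {self.direction!r}")
        if not self.magnitude > 0:
            raise ValueError(f"magnitude must be > 0, got {self.magnitude}")

    @property
    def delta(self) -> float:
        return -self.magnitude if self.direction == DECREASE \
            else self.magnitude

    def as_treatment(self, max_magnitude: float = 10.0) -> TreatmentSpec:
        return TreatmentSpec(self.target, self.delta, self.window[0],
                             self.window[1], max_magnitude=max_magnitude)


@dataclass(frozen=True)
class EfficacyReport:
    """Cohort-level outcome of one targeted protocol."""

    protocol: TargetedProtocol
    n_treated: int
    n_effective: int
    outcomes: pd.DataFrame  # individual_id, outcome

    @property
    def fraction_effective(self) -> float:
        return self.n_effective / self.n_treated

    def to_csv(self, path) -> None:
        self.outcomes.to_csv(path, index=False)


def _split_direction(tree: TreeSummary, feature: str) -> tuple[str, float]:
    """Direction and threshold from the feature's shallowest split.

    The effective-majority side of the split decides the direction: left
    (delta <= threshold) means the parameter must be decreased, right
    increased.  Sides are compared by their subtree fraction of effective
    outcomes.
    """
    splits = tree.splits_on(feature)
    if not splits:
        raise ValueError(
            f"feature {feature!r} is not used by any tree split; the "
            "required treatment direction is undetermined -- supply it "
            "manually or deepen the tree")
    node = splits[0]
    frac_left = tree.subtree_class_fraction(node.left, EFFECTIVE)
    frac_right = tree.subtree_class_fraction(node.right, EFFECTIVE)
    direction = DECREASE if frac_left >= frac_right else INCREASE
    return direction, float(node.threshold)


def design_protocol(report: ImportanceReport, tree: TreeSummary,
                    phenotype_class: str, rank: int = 1,
                    window: tuple[float, float] = (60.0, 10.0),
                    safety_factor: float = 1.5,
                    max_magnitude: float = 10.0) -> TargetedProtocol:
    """Turn the rank-th ranked target plus the direction tree into a protocol.

    The magnitude is |split threshold| * safety_factor (capped at the
    treatment magnitude limit): the threshold estimates where outcomes flip,
    and the overshoot buys robustness against its estimation error.
    """
    nonzero = [name for name in report.ranking if report.scaled(name) > 0]
    if rank < 1 or rank > len(nonzero):
        raise ValueError(f"rank {rank} out of range: only {len(nonzero)} "
                         "features have nonzero importance")
    target = nonzero[rank - 1]
    direction, threshold = _split_direction(tree, target)
    magnitude = min(abs(threshold) * safety_factor, max_magnitude)
    return TargetedProtocol(phenotype_class, target, direction, magnitude,
                            window)


def design_top_protocols(report: ImportanceReport, tree: TreeSummary,
                         phenotype_class: str,
                         window: tuple[float, float] = (60.0, 10.0),
                         safety_factor: float = 1.5,
                         tie_points: float = 10.0) -> list[TargetedProtocol]:
    """Protocols for the top target, plus the runner-up when near-tied.

    When the top two scaled importances are within ``tie_points`` of each
    other, both targets plausibly support effective treatments and both
    protocols are emitted.
    """
    protocols = [design_protocol(report, tree, phenotype_class, 1, window,
                                 safety_factor)]
    if len(report.ranking) > 1:
        first, second = report.ranking[0], report.ranking[1]
        if report.scaled(second) > 0 and \
                report.scaled(first) - report.scaled(second) <= tie_points:
            try:
                protocols.append(design_protocol(
                    report, tree, phenotype_class, 2, window, safety_factor))
            except ValueError as exc:
                logger.warning("skipping near-tied runner-up %s: %s",
                               second, exc)
    return protocols


def evaluate_protocol(protocol: TargetedProtocol,
                      cohort: list[PatientRecord],
                      sim: SimConfig = SimConfig()) -> EfficacyReport:
    """Apply one identical protocol to every cohort member and aggregate."""
    if not cohort:
        raise ValueError("cannot evaluate a protocol on an empty cohort")
    labels = {p.phenotype.label for p in cohort}
    if labels != {protocol.phenotype_class}:
        raise ValueError(f"cohort phenotype(s) {sorted(labels)} do not match "
                         f"the protocol class {protocol.phenotype_class!r}")
    t_on = protocol.window[0]
    treatment = protocol.as_treatment()
    rows = []
    n_eff = 0
    for patient in cohort:
        if t_on not in patient.checkpoints:
            raise ValueError(f"patient {patient.individual_id} lacks a "
                             f"checkpoint at t = {t_on}")
        state = SystemState(patient.checkpoints[t_on], t_on)
        traj = apply_treatment(patient.params, state, treatment, sim)
        outcome = classify_treatment_outcome(
            traj, patient.phenotype.baseline_cortisol, sim.tol)
        n_eff += outcome == EFFECTIVE
        rows.append({"individual_id": patient.individual_id,
                     "outcome": outcome})
    return EfficacyReport(protocol, len(cohort), int(n_eff),
                          pd.DataFrame(rows))
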