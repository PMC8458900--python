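"""Stress-pulse experiments, phenotype labels, and transient treatments.

The in-silico protocol mirrors a trauma-and-treatment timeline in arbitrary
time units: every individual is burnt in without stress to its physiological
attractor, receives a rectangular stress pulse (default on [20, 30)), and is
followed to the horizon (default 100).  Cortisol averaged over the last
quarter of the burn-in defines the individual's physiological baseline;
cortisol averaged over the last quarter of the horizon decides the
phenotype: restored within tolerance (control), sustained low, or sustained
high.  Treatments are transient additive changes of a single parameter over
a later window and are called effective when they bring the final-window
cortisol back into the baseline band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    COMPONENTS,
    PARAM_NAMES,
    IntegrationError,
    NetworkSpec,
    ParameterOverlay,
    ParameterSet,
    StepSignal,
    SystemState,
    Trajectory,
    integrate,
)

__all__ = [
    "CONTROL", "LOW_CORTISOL", "HIGH_CORTISOL", "EFFECTIVE", "NON_EFFECTIVE",
    "PulseProtocol", "TreatmentSpec", "PhenotypeLabel", "TreatmentRecord",
    "SimConfig", "PatientRecord",
    "stress_signal", "classify_phenotype", "run_stress_experiment",
    "run_cohort", "apply_treatment", "classify_treatment_outcome",
    "random_treatment_scan", "phenotype_fractions", "records_to_frame",
]

logger = logging.getLogger(__name__)

CONTROL = "control"
LOW_CORTISOL = "low_cortisol"
HIGH_CORTISOL = "high_cortisol"

EFFECTIVE = "effective"
NON_EFFECTIVE = "non_effective"


@dataclass(frozen=True)
class PulseProtocol:
    """Rectangular stress pulse: ``amplitude`` on [t_on, t_on + duration)."""

    t_on: float = 20.0
    duration: float = 10.0
    amplitude: float = 1.5

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")

    def as_signal(self) -> StepSignal:
        return StepSignal([self.t_on, self.t_on + self.duration],
                          [self.amplitude, 0.0])


@dataclass(frozen=True)
class TreatmentSpec:
    """One transient single-parameter treatment.

    ``delta`` is an additive change of the raw parameter value, applied on
    [t_on, t_on + duration) and fully withdrawn afterwards.
    """

    target: str
    delta: float
    t_on: float = 40.0
    duration: float = 10.0
    max_magnitude: float = 10.0

    def __post_init__(self) -> None:
        if self.target not in PARAM_NAMES:
            raise ValueError(f"unknown treatment target {self.target!r}")
        if abs(self.delta) > self.max_magnitude:
            raise ValueError(
                f"|delta| = {abs(self.delta)} exceeds the maximum magnitude "
                f"{self.max_magnitude}")
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class PhenotypeLabel:
    """Phenotype decided by final-window vs baseline cortisol."""

    label: str
    baseline_cortisol: float
    post_cortisol: float
    oscillatory: bool = False


@dataclass(frozen=True)
class TreatmentRecord:
    """One scanned treatment with its restoration outcome."""

    individual_id: int
    phenotype: PhenotypeLabel
    treatment: TreatmentSpec
    outcome: str


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation settings (time units are the model's arbitrary ones)."""

    spec: NetworkSpec = field(default_factory=NetworkSpec)
    horizon: float = 100.0
    dt_out: float = 0.1
    x0: tuple[float, float, float, float] = (0.1, 0.1, 0.1, 0.1)
    tol: float = 0.05            # cortisol classification band, activity units
    window_frac: float = 0.25    # averaging window: last quarter of each phase
    atol: float = 1e-9
    rtol: float = 1e-7


@dataclass(frozen=True)
class PatientRecord:
    """One simulated individual with restart states for later treatment."""

    individual_id: int
    params: ParameterSet
    phenotype: PhenotypeLabel
    checkpoints: dict  # time -> 4-vector state at that time
    post_state_mean: np.ndarray = None  # final-window mean of all 4 components


def stress_signal(t: float, pulse: PulseProtocol) -> float:
    """Pulse amplitude inside [t_on, t_on + duration), zero outside."""
    return pulse.amplitude if pulse.t_on <= t < pulse.t_on + pulse.duration \
        else 0.0


def classify_phenotype(baseline: float, post: float,
                       tol: float = 0.05, *,
                       oscillatory: bool = False) -> PhenotypeLabel:
    """Control if post-stress cortisol is within ``tol`` of baseline,
    otherwise low or high cortisol by the sign of the departure."""
    if not tol > 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    if not (np.isfinite(baseline) and np.isfinite(post)):
        raise ValueError(f"non-finite cortisol summary: {baseline}, {post}")
    if abs(post - baseline) <= tol:
        label = CONTROL
    elif post < baseline:
        label = LOW_CORTISOL
    else:
        label = HIGH_CORTISOL
    return PhenotypeLabel(label, float(baseline), float(post), oscillatory)


def run_stress_experiment(individual: ParameterSet,
                          pulse: PulseProtocol,
                          sim: SimConfig = SimConfig(),
                          ) -> tuple[Trajectory, PhenotypeLabel]:
    """Burn in, pulse, follow to the horizon, and label the phenotype.

    The burn-in runs stress-free from t = 0 to the pulse onset; baseline
    cortisol is the time-average over its last quarter.  Post-stress
    cortisol is the time-average over the last quarter of the horizon.
    Individuals with a non-decaying cortisol oscillation in that tail are
    flagged oscillatory and classified on the same windowed averages.
    """
    traj = integrate(individual, sim.spec, stress=pulse.as_signal(),
                     t_span=(0.0, sim.horizon), x0=np.array(sim.x0),
                     dt_out=sim.dt_out, atol=sim.atol, rtol=sim.rtol)
    baseline = traj.window_mean("COR", (1 - sim.window_frac) * pulse.t_on,
                                pulse.t_on)
    post = traj.window_mean("COR", (1 - sim.window_frac) * sim.horizon)
    label = classify_phenotype(baseline, post, sim.tol,
                               oscillatory=traj.is_oscillatory("COR"))
    return traj, label


def run_cohort(population, pulse: PulseProtocol,
               sim: SimConfig = SimConfig(),
               checkpoint_times: tuple[float, ...] = (40.0, 60.0),
               ) -> list[PatientRecord]:
    """Run the stress experiment for every individual of a population.

    Individuals whose integration fails are excluded with a warning (their
    parameters are in the log record).  Trajectories are not retained;
    instead the states at ``checkpoint_times`` are kept so treatments can
    restart from the moment of application.
    """
    records = []
    n_failed = 0
    for ind_id, params in population:
        try:
            traj, label = run_stress_experiment(params, pulse, sim)
        except IntegrationError:
            n_failed += 1
            logger.warning("excluding individual %d: integration failed "
                           "(params=%s)", ind_id, params.to_dict())
            continue
        cps = {t: traj.state_at(t).x.copy() for t in checkpoint_times}
        t_final = (1 - sim.window_frac) * sim.horizon
        post_means = np.array([traj.window_mean(c, t_final)
                               for c in COMPONENTS])
        records.append(PatientRecord(ind_id, params, label, cps, post_means))
    if n_failed:
        logger.warning("excluded %d/%d individuals with failed integrations",
                       n_failed, len(records) + n_failed)
    return records


def apply_treatment(individual: ParameterSet,
                    post_stress_state: SystemState,
                    treatment: TreatmentSpec,
                    sim: SimConfig = SimConfig()) -> Trajectory:
    """Continue an individual from the treatment onset with the transient
    parameter change applied.

    The target parameter equals (its sampled value + delta) inside the
    treatment window and reverts to the sampled value outside.  A delta that
    transiently flips an inhibition's sign is allowed but logged; a delta
    driving a relaxation rate below zero is clamped at zero by the
    integrator (rates are nonnegative).
    """
    if treatment.target in ("RCRH_GR", "RACTH_GR"):
        value = individual[treatment.target]
        if value * (value + treatment.delta) < 0:
            logger.debug("treatment transiently flips the sign of the "
                         "inhibition %s", treatment.target)
    overlay = ParameterOverlay([(treatment.target, treatment.delta,
                                 treatment.t_on,
                                 treatment.t_on + treatment.duration)])
    return integrate(individual, sim.spec, overlay=overlay,
                     t_span=(post_stress_state.t, sim.horizon),
                     x0=post_stress_state.x, dt_out=sim.dt_out,
                     atol=sim.atol, rtol=sim.rtol)


def classify_treatment_outcome(traj: Trajectory, baseline: float,
                               tol: float = 0.05) -> str:
    """Effective iff final-window cortisol is back in the baseline band.

    The average is taken over the last quarter of the horizon, after the
    treatment window, so the transient excursion during treatment does not
    enter the decision.
    """
    final = traj.window_mean("COR", (1 - 0.25) * traj.times[-1])
    return EFFECTIVE if abs(final - baseline) <= tol else NON_EFFECTIVE


def random_treatment_scan(patients: list[PatientRecord],
                          n_treatments_per_patient: int = 1,
                          magnitude_max: float = 10.0,
                          seed: int = 0,
                          t_on: float = 40.0,
                          duration: float = 10.0,
                          sim: SimConfig = SimConfig(),
                          ) -> list[TreatmentRecord]:
    """Scan random single-parameter transient treatments over one cohort.

    For every record a target is chosen uniformly among the 16 parameters,
    the direction uniformly up/down, and the magnitude uniformly on
    (0, magnitude_max].  All patients must share one phenotype class; the
    low- and high-cortisol cohorts are scanned separately.
    """
    if not patients:
        raise ValueError("cannot scan an empty patient list")
    labels = {p.phenotype.label for p in patients}
    if len(labels) > 1:
        raise ValueError(f"patients must share one phenotype class, got "
                         f"{sorted(labels)}")
    records = []
    for patient in patients:
        if t_on not in patient.checkpoints:
            raise ValueError(
                f"patient {patient.individual_id} has no checkpoint at "
                f"t = {t_on}; available: {sorted(patient.checkpoints)}")
        state = SystemState(patient.checkpoints[t_on], t_on)
        for j in range(n_treatments_per_patient):
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=seed, spawn_key=(patient.individual_id, j)))
            target = PARAM_NAMES[rng.integers(0, len(PARAM_NAMES))]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            magnitude = rng.uniform(0.0, magnitude_max)
            spec = TreatmentSpec(target, sign * magnitude, t_on, duration,
                                 max_magnitude=magnitude_max)
            traj = apply_treatment(patient.params, state, spec, sim)
            outcome = classify_treatment_outcome(
                traj, patient.phenotype.baseline_cortisol, sim.tol)
            records.append(TreatmentRecord(patient.individual_id,
                                           patient.phenotype, spec, outcome))
    return records


def phenotype_fractions(patients: list[PatientRecord]) -> dict[str, float]:
    """Fraction of each phenotype class in a cohort."""
    n = len(patients)
    out = {CONTROL: 0.0, LOW_CORTISOL: 0.0, HIGH_CORTISOL: 0.0}
    for p in patients:
        out[p.phenotype.label] += 1.0
    return {k: v / n for k, v in out.items()} if n else out


def records_to_frame(records: list[TreatmentRecord]) -> pd.DataFrame:
    """Scan results as a tidy table (one row per treatment)."""
    return pd.DataFrame({
        "individual_id": [r.individual_id for r in records],
        "phenotype": [r.phenotype.label for r in records],
        "target": [r.treatment.target for r in records],
        "delta": [r.treatment.delta for r in records],
        "t_on": [r.treatment.t_on for r in records],
        "duration": [r.treatment.duration for r in records],
        "outcome": [r.outcome for r in records],
    })
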