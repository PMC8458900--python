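"""Optional figure-style plots of exemplar trajectories (never required)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .config import RunConfig
from .protocols import (
    CONTROL,
    HIGH_CORTISOL,
    LOW_CORTISOL,
    PatientRecord,
    run_stress_experiment,
)

__all__ = ["plot_phenotype_examples"]


def plot_phenotype_examples(config: RunConfig, cohort: list[PatientRecord],
                            path, per_class: int = 5) -> None:
    """Stress signal plus exemplar cortisol traces for the three phenotypes."""
    fig, axes = plt.subplots(4, 1, figsize=(7, 9), sharex=True)
    pulse = config.pulse()
    ts = [0, pulse.t_on, pulse.t_on, pulse.t_on + pulse.duration,
          pulse.t_on + pulse.duration, config.horizon]
    ss = [0, 0, pulse.amplitude, pulse.amplitude, 0, 0]
    axes[0].plot(ts, ss, "k-")
    axes[0].set_ylabel("stress")

    for ax, label, title in zip(
            axes[1:], (CONTROL, LOW_CORTISOL, HIGH_CORTISOL),
            ("control", "low cortisol", "high cortisol")):
        shown = 0
        for p in cohort:
            if p.phenotype.label != label:
                continue
            traj, _ = run_stress_experiment(p.params, pulse, config.sim())
            ax.plot(traj.times, traj.component("COR"), lw=0.8)
            shown += 1
            if shown >= per_class:
                break
        ax.set_ylabel("cortisol")
        ax.set_title(f"{title} (n={shown})", fontsize=9)
    axes[-1].set_xlabel("time (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
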