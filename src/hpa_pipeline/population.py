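"""Virtual-patient population: independent 10-fold uniform parameter sampling.

Heterogeneous individuals share the network wiring and differ only in their
16 parameter values.  Each parameter is drawn independently and uniformly
(on the linear scale) between 1/fold and fold times its basal magnitude --
the default fold of 10 spans 10% to 1,000% of the basal value -- and the
basal sign is re-applied, so inhibitions stay inhibitions and the network
topology is preserved across the population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import PARAM_NAMES, ParameterSet

__all__ = ["PopulationSample", "sample_population"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PopulationSample:
    """A reproducible draw of ``n`` individuals around a basal parameter set."""

    individuals: tuple[tuple[int, ParameterSet], ...]
    basal: ParameterSet
    fold: float
    seed: int

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def parameter_matrix(self) -> np.ndarray:
        """(n, 16) array in canonical parameter order."""
        return np.array([ps.as_array() for _, ps in self.individuals])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.parameter_matrix(), columns=list(PARAM_NAMES))
        df.insert(0, "id", [i for i, _ in self.individuals])
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, basal: ParameterSet,
                   fold: float, seed: int) -> "PopulationSample":
        individuals = tuple(
            (int(row["id"]), ParameterSet.from_dict(
                {k: float(row[k]) for k in PARAM_NAMES}))
            for _, row in df.iterrows())
        return cls(individuals, basal, fold, seed)


def sample_population(basal: ParameterSet, fold: float = 10.0,
                      n: int = 1, seed: int = 0) -> PopulationSample:
    """Draw ``n`` independent individuals around ``basal``.

    Each parameter magnitude is uniform on [|basal|/fold, |basal|*fold] with
    the basal sign re-applied; a basal value of exactly zero stays zero (its
    range is degenerate) and is reported once via a warning.

    Per-individual random streams are spawned from a single seed with
    counter-based keys, so individual ``i`` is identical no matter how large
    ``n`` is -- growing a population never reshuffles earlier individuals.
    """
    if not fold > 1:
        raise ValueError(f"fold must be > 1, got {fold}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")

    base = basal.as_array()
    zero = base == 0.0
    if zero.any():
        logger.warning("basal parameters held at zero (degenerate range): %s",
                       [PARAM_NAMES[i] for i in np.flatnonzero(zero)])
    lo = np.abs(base) / fold
    hi = np.abs(base) * fold
    signs = np.sign(base)

    individuals = []
    for i in range(n):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        mags = rng.uniform(lo, hi)
        individuals.append(
            (i, ParameterSet.from_array(signs * mags)))
    return PopulationSample(tuple(individuals), basal, float(fold), int(seed))
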