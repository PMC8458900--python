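# hpa-pipeline

Simulation and machine-learning pipeline for studying stress-disorder
heterogeneity in the hypothalamic–pituitary–adrenal (HPA) axis and for
rationally designing transient treatments that restore cortisol
homeostasis in a heterogeneous virtual population.

The package is aimed at computational-biology and quantitative-systems-
pharmacology work where a mechanistic ODE model and ML analysis are
combined: the model generates heterogeneous patient behavior, the ML layer
extracts which parameters matter for effective treatment, and the model
then tests the resulting designed protocols.

## The model

Four activities — CRH, ACTH, cortisol (COR) and the activated
glucocorticoid receptor (GR) — evolve by the standard sigmoidal network
form

```
dX_i/dt = ts_i (F_i − X_i),    F_i = 1 / (1 + e^(−σ W_i)),
W_i     = R_i0 + Σ_j R_ij X_j
```

with net input `W_i` built from signed regulation weights `R_ij`, a
background input `R_i0`, a relaxation rate `ts_i`, and sigmoid gain `σ`
(default 10). The wiring is fixed: stress drives CRH; CRH → ACTH → COR →
GR; GR represses CRH and ACTH (the classic negative feedback); CRH and GR
each self-activate (two positive feedbacks that make bistable, sustained
disorder states possible). Sixteen parameters describe one individual; a
virtual population draws every parameter independently and uniformly
between 1/10× and 10× its basal magnitude, signs preserved.

The in-silico protocol: burn in without stress to t = 20, apply a
rectangular stress pulse on [20, 30), follow to t = 100. Comparing
time-averaged cortisol before and after the pulse (tolerance 0.05)
classifies each individual as **control** (recovered), **low-cortisol** or
**high-cortisol** patient. Random transient single-parameter treatments
(additive delta up to ±10 on [40, 50)) are scanned over each patient
class; a random forest ranks targets by out-of-bag permutation importance
(scaled so the top target reads 100%), a decision tree exposes the
required direction and rough dose, and the resulting targeted protocol
(applied on [60, 70)) is evaluated cohort-wide.

## Worked example

```python
from hpa_pipeline import PulseProtocol, SimConfig, sample_population
from hpa_pipeline.config import default_basal
from hpa_pipeline.protocols import run_cohort, phenotype_fractions

basal, sigma = default_basal()
pop = sample_population(basal, fold=10.0, n=2000, seed=42)
cohort = run_cohort(pop, PulseProtocol(), SimConfig())
print(phenotype_fractions(cohort))
```

prints

```
{'control': 0.828, 'low_cortisol': 0.03, 'high_cortisol': 0.142}
```

— 82% of stimulated individuals recover their cortisol baseline after the
strong pulse, ~3% settle into a sustained-low state (a latched GR positive
feedback represses the axis) and ~14% into a sustained-high state (a
latched CRH positive feedback keeps driving it).

The same run from the shell, end to end:

```
hpa-pipeline run-all --seed 5 --out results/
```

writes the population, phenotype table and tree, scan records, importance
rankings, direction trees, and designed-protocol efficacy as CSV. On the
default settings the low-cortisol arm ranks `RGR_GR` and `RGR_0` as top
treatment targets and the high-cortisol arm `RCRH_0` and `RCRH_CRH`, all
with direction *decrease*; the designed protocols cure 30–45% of their
cohort versus the 5–7% effective rate of random targeting.

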