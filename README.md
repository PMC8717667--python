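# prevmap

Bayesian spatio-temporal disease-prevalence mapping on areal lattices.

The package implements a full analysis pipeline for chronic-disease
prevalence from administrative health records:

1. **cohort** — a rolling-window case-definition algorithm over linked
   hospital / physician-claim / prescription event streams, with
   death / emigration / age-out censoring, tabulated into a
   region × year × age-sex-stratum prevalence cube.
2. **standardize** — indirect age-sex standardization against the internal
   (all-region) reference, pooled over a year window or year-by-year.
3. **covariates** — a one-factor deprivation score from four census
   variables (maximum-likelihood factor analysis, regression scores,
   deprivation-positive orientation) plus the Indigenous population
   proportion on a per-0.1 reporting scale.
4. **geography** — adjacency graphs from edge lists or GeoJSON polygons
   (queen contiguity), ICAR / random-walk-1 / Kronecker-interaction
   structure matrices, and a permutation Moran's I test.
5. **models** — three hierarchical Poisson models fitted by adaptive
   Metropolis-within-Gibbs MCMC: a spatial convolution (BYM) model with
   covariates, a spatio-temporal main-effects model, and a model with a
   Kronecker-structured space-time interaction field. Gamma(1, 0.0005)
   precision priors by default, uniform-on-standard-deviation sensitivity
   option, sum-to-zero constraints by post-sweep centering.
6. **diagnostics** — DIC, conditional predictive ordinates (harmonic-mean
   identity, validated against brute-force leave-one-out refits),
   randomized probability integral transforms, per-term variance shares,
   exceedance probabilities Pr(RR > 1), ranked credible-interval tables,
   and GeoJSON choropleth export.
7. **synthetic** — generators for every input (irregular lattice,
   stratified populations, correlated census covariates, model-generated
   counts, person-level records) with ground truth retained for recovery
   testing.
8. **pipeline / CLI** — a declarative YAML config drives
   simulate → cohort → standardize → covariates → fit → diagnose with
   content-hashed, reproducible artifacts.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end property checks
(standardization conservation, case-definition oracle equivalence, ICAR
sampler correctness, GLM limit, parameter recovery, interaction detection,
exceedance/PIT calibration, Moran null behavior, determinism); the full
suite runs in a few minutes on one CPU.

## CLI

```sh
prevmap run-all --config config.yaml --seed 7 --outdir out/
prevmap simulate --seed 1 --outdir out/
prevmap fit-spatial --hyperprior gamma --seed 2 --outdir out/
prevmap fit-st --interaction --seed 3 --outdir out/
```

A minimal `config.yaml`:

```yaml
seed: 7
outdir: out
n_rows: 12
n_cols: 8
years: [2000, 2001, 2002, 2003, 2004, 2005]
n_iterations: 2000
n_burnin: 1000
n_chains: 2
```

Every run echoes its config, writes a `manifest.json` with SHA-256 hashes
per artifact, and is bit-reproducible given the seed.

## Library example

```python
import numpy as np
from prevmap import synthetic as syn
from prevmap import standardize as stz
from prevmap.models import ModelConfig, fit_model
from prevmap.diagnostics import build_report

bundle = syn.make_bundle(12, 8, years=range(2000, 2006), seed=1)
expected = stz.expected_counts(bundle.cube, pool_time=False)
cfg = ModelConfig(model_form="st_interaction", n_iterations=2000,
                  n_burnin=1000, n_chains=2, seed=2)
fit = fit_model(bundle.cube.case_totals(), expected, None,
                bundle.graph, len(bundle.cube.years), cfg)
report = build_report(fit, pit_seed=3)
print(report.dic, report.variance_shares)
```
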