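# trajmix

Latent-class mixture modelling of longitudinal binary symptom panels in
birth cohorts. `trajmix` fits and compares three generative families over
per-child trajectories of eczema / wheeze / rhinitis indicators observed
at a discrete age grid (default ages 1, 3, 5, 8, 11 years), with missing
data handled by exact marginalization:

- **independent_markov** — per-symptom first-order Markov chains,
  independent given a shared latent class;
- **atopic_march_markov** — first-order chains with lagged cross-symptom
  parents (eczema at *t−1* conditions wheeze at *t*; wheeze at *t−1*
  conditions rhinitis at *t*), encoding the hypothesised eczema → wheeze
  → rhinitis progression;
- **latent_profile** — class-conditional independent Bernoulli emissions
  per symptom and age.

Emissions are parameterized on the probit scale with a standard-normal
prior; fitting is MAP-penalized EM with seeded multi-restart
initialization. Class-number and family selection use hold-out predictive
log-likelihood or a BIC penalty, with a stability-window convergence
rule and a Dirichlet-pseudocount sensitivity sweep. Downstream modules
produce class trajectory tables, cross-sectional prevalence summaries,
membership-quality matrices, cross-classification confusion matrices, and
2×2 odds ratios with Woolf (Wald log-OR) 95% confidence intervals against
a baseline class.

Because individual-level cohort data of this kind are not freely
distributable, the package ships a synthetic-cohort generator
(`trajmix.synthetic_cohort`) that reproduces the relevant statistical
structure: two cohorts of configurable size, an eight-class default truth
with realistic trajectory shapes, cohort-specific structural missingness
(rhinitis not collected at the first two ages in the larger cohort),
independent item missingness, optional attrition, and the derived-variable
rules (current asthma = any two of wheeze / medication / diagnosis;
sensitisation = wheal ≥ 3 mm over the negative control; the
minimum-timepoints and mild-eczema inclusion filters).

## Library quick start

```python
import numpy as np
from trajmix import synthetic_cohort as sc
from trajmix import ModelSpec, FitConfig, fit, sweep

truth = sc.default_truth(seed=0, cohort_sizes=(2000, 500), item_rate=0.05)
cohort, true_class = sc.generate_cohort(truth)

res = fit(cohort, ModelSpec("latent_profile", 8), FitConfig(seed=1))
print(res.params.weights, res.converged)

sel = sweep(cohort, ["latent_profile"], range(2, 13), [1.0],
            FitConfig(seed=1, restarts=4), evidence_method="bic")
print(sel.selected)
```

## Command line

```bash
trajmix simulate --seed 1 --n-a 2000 --n-b 500 --out cohort.csv --truth-out truth.csv
trajmix fit --cohort cohort.csv --family latent_profile --n 8 --seed 1 --out fitdir/
trajmix sweep --cohort cohort.csv --n 2:12 --pseudocounts 1/n,2/n,1,2 \
              --seed 1 --evidence-method bic --out sweep.csv
trajmix profiles --cohort cohort.csv --params fitdir/params.json \
                 --memberships fitdir/memberships.csv --out profdir/ --plot
trajmix assoc --cohort cohort.csv --params fitdir/params.json \
              --memberships fitdir/memberships.csv --trait sensitised --baseline 0 \
              --out assoc.csv
trajmix run --config config.yaml --out outdir/   # end-to-end with manifest
```

`run` writes a `manifest.json` with versions, the seed, and SHA-256 hashes
of every output; reruns with the same config and seed are bit-identical.

## Layout

- `src/trajmix/synthetic_cohort.py` — cohort container, generator, derived
  variables, inclusion filters, CSV dialect
- `src/trajmix/latent_models.py` — the three model families: parameter
  spaces, exact-marginalization likelihoods, sampling
- `src/trajmix/inference.py` — MAP-EM fitting, posterior memberships,
  hold-out / BIC evidence
- `src/trajmix/model_selection.py` — sweeps, stability rule, pseudocount
  sensitivity
- `src/trajmix/class_profiles.py` — trajectory/prevalence tables,
  membership quality, confusion matrices, plots
- `src/trajmix/assoc_stats.py` — Woolf odds ratios, Pearson chi-square
  class comparisons
- `src/trajmix/cli.py` — pipeline orchestration
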