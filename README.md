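# oslm — Bayesian operation-specific learning models

Hierarchical Bayesian item response modelling of **within-test practice
effects**: the LLTM / RWLLTM / OSLM / RWOSLM model family for binary
person × item data whose item difficulties decompose into component
(rule / figural-property) difficulties via a structure matrix **W**, and
whose component difficulties may change with accumulated practice via a
derived practice matrix **V**.

The package covers the full analysis workflow:

- **Design structures** (`oslm.design`) — component/weight matrices,
  cumulative-practice matrix construction, model-identification checks
  (full column rank of W, V⁺ = (V, 1), their concatenation, and the
  2M + 1 ≤ J effect-count condition).
- **Model family** (`oslm.models`) — the shared logit
  `theta_i − Σ_m w_jm·α_m + Σ_m v_jm·δ_im` with fixed or person-varying
  (multivariate-normal, LKJ-correlated) difficulty and practice effects,
  and the corresponding priors.
- **Inference** (`oslm.inference`) — posterior sampling with a built-in
  No-U-Turn sampler (analytic gradients, non-centered random effects,
  diagonal mass adaptation), EAP/SD/2.5–97.5 %/R̂ summaries, posterior sign
  probabilities, per-person practice-effect classification, and
  difficulty-vs-practice trajectories.
- **Model comparison** (`oslm.compare`) — WAIC, PSIS-LOO (Pareto-k
  diagnostics), and posterior predictive checks with a pairwise
  odds-ratio statistic.
- **Synthetic data** (`oslm.simulate`) — seed-deterministic generators for
  design matrices, person parameters, responses, response latencies (plus
  the sub-second exclusion filter), and external measures with target
  correlations.
- **Reporting** (`oslm.report`) — external-measure correlation tables,
  Rasch-difficulty variance-explained regression with an item-position
  check, and CSV/markdown exports.

No external MCMC backend is required; everything runs on
numpy / scipy / pandas / arviz.

## Quick start (Python)

```python
from oslm import SamplerConfig, build_practice_matrix, fit, summarize
from oslm.simulate import (
    generate_design, generate_persons, simulate_responses,
    table2_generating_parameters,
)

gen = table2_generating_parameters()          # packaged realistic magnitudes
design = generate_design(J=34, seed=7)        # ART-like 34-item, 8-component design
practice = build_practice_matrix(design)
persons = generate_persons(300, gen, seed=8)
data = simulate_responses(design, practice, persons, gen, seed=9)

draws = fit(gen.model_spec(), design, practice, data,
            SamplerConfig.fast(seed=1))       # 2 x 1000; default is 4 x 5000
print(summarize(draws))
```

## Command line

```bash
oslm simulate --n 765 --items 34 --seed 7 --out sim/
oslm fit --design sim/design.csv --responses sim/responses.csv \
         --latencies sim/latencies.csv --model rwoslm_const --seed 11 --out fit/
oslm compare --fits fit/ other_fit/ --ppmc --out comparison.csv
oslm report --fit fit/ --external sim/external_measures.csv --out report/
oslm run-all --config study.yaml
```

A `run-all` config looks like:

```yaml
out: study/
seed: 7
n: 765
items: 34
contamination: 0.065
models: [lltm, rwlltm, oslm, rwoslm, rwoslm_const]
sampler: {chains: 4, iterations: 5000}
ppmc: true
```

## Tests and acceptance

```bash
python -m pytest -q tests/                       # full suite (~10-15 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the acceptance criteria (algebraic
identities, brute-force oracles for the practice matrix and WAIC,
exact-refit leave-one-out validation of PSIS-LOO, parameter-recovery and
interval-coverage replications, model-selection and posterior-predictive
sanity checks, and a deterministic end-to-end demo). Replication-based
checks run at desk scale; see the module docstring for the scaling.

`scripts/acceptance.py` runs a full-pipeline smoke check and writes an
empty target report: the originating study's numeric results were computed
on a dataset that was never publicly deposited, so no paper-level numbers
can be recomputed offline — acceptance for this package is property-based.

## Notes

- Normal priors written N(a, b) are interpreted with b as a **variance**
  (the diffuse fixed-effect prior N(0, 100) has SD 10).
- Missing responses are rejected; persons with any response latency below
  1 s can be excluded with `latency_filter` (the default in the CLI when
  latencies are present).
- Random effects use a non-centered parameterization internally; reported
  draws are always on the natural scale.
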