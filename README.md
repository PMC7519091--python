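# isomix

Isotope incorporation kinetics, diet–tissue discrimination factors (DTDFs)
and Bayesian stable-isotope mixing models for diet-switch feeding trials,
as a tested, reusable pipeline.

The package covers the full analysis chain of a diet-switch experiment:

- **`isomix.kinetics`** — one- and two-compartment incorporation curves
  (`dXinf - (dXinf - dX0) * exp(-t*lambda)` and the two-pool mixture) and
  residence-time arithmetic (`tau = 1/lambda`, pool-weighted `tau_mean`).
- **`isomix.synthetic_data`** — seeded generators for every input: the
  formulated experimental diet sources, a hypothetical 4-source/5-consumer
  mixing scenario, and full feeding-trial datasets (5 groups x 2 tissues,
  sampling days 0–120, 3 fish per occasion, Gaussian noise).
- **`isomix.bayes_fit`** — Bayesian incorporation fits by adaptive
  random-walk Metropolis (informative normal priors, half-normal residual
  scale), Gelman–Rubin PSRF diagnostics, DIC model comparison with a
  one-compartment parsimony tie-break, and Levenberg–Marquardt NLS with
  AICc.
- **`isomix.dtdf`** — equilibrium-window (day ≥ 60) discrimination factors
  as plain averages and as Bayesian posteriors of the mean; literature
  defaults 1.0 ± 2.0 ‰ (C) and 3.4 ± 2.0 ‰ (N).
- **`isomix.mixing`** — a simmr/MixSIAR-style Bayesian mixing model:
  Dirichlet prior on dietary proportions sampled in log-ratio space, source
  and DTDF uncertainty propagated via p²-weighted variances with either an
  additive or a multiplicative residual term, per-source posterior means
  and 95% credibility ranges.
- **`isomix.niche_geometry`** — standard ellipse areas (SEA, SEA_c) and
  convex-hull areas in (δ¹³C, δ¹⁵N) space.
- **`isomix.cli_io`** — CSV/JSON/YAML I/O with schema validation and the
  two end-to-end workflows (hypothetical scenario; feeding-trial analysis).

## CLI

```sh
isomix simulate --seed 1 --out samples.csv                  # synthetic trial
isomix simulate --seed 1 --scenario mixture --out mix.csv   # mixing scenario
isomix fit-incorporation --samples samples.csv --group 1 --tissue muscle \
    --isotope c --model one --seed 1 --out fit.json
isomix dtdf --samples samples.csv --sources sources.csv --day-min 60 \
    --method average --out dtdf.csv
isomix mix --consumers samples.csv --sources sources.csv --dtdf literature \
    --group 1 --tissue muscle --seed 1 --out mix.json
isomix ellipse --samples samples.csv --tissue muscle
isomix run-hypothetical --seed 1 --out hypothetical.json
isomix run-trial --seed 1 --out trial.json
```

All MCMC subcommands accept `--iters/--burn/--thin/--chains/--seed`;
defaults follow the published chain settings (3 chains × 100,000
iterations, 50,000 burn-in; thinning 50 for incorporation fits, 3 for the
mixing model). Workflow outputs embed the seed, a config hash and the
package version.

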