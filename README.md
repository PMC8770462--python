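# evoselect

Evolutionary wrapper feature selection for case–control feature tables of
volumetric measurements (e.g. regional brain volumes, percentages and
asymmetry indices), built around:

- **NSGA-II** binary subset selection minimizing the two objectives
  *(classification error, number of selected features)*, plus four
  single-objective comparison metaheuristics (**GA, ACO, SA, PSO**) on a
  scalarized fitness;
- a **20-10-5 multilayer perceptron** fitness classifier trained with
  **Levenberg–Marquardt backpropagation** (damped Gauss–Newton on the
  network error vector, Jacobian assembled from backward-propagated layer
  sensitivities), evaluated on a stratified 80/20 split;
- a **statistical baseline**: per-feature Mann–Whitney rank-sum tests
  (exact by enumeration for small pooled samples), Benjamini–Hochberg FDR
  correction, and an accuracy curve over the top-k smallest-p features;
- a **synthetic cohort generator** (two groups, default 56/54 subjects,
  correlated right-skewed positive features, a planted informative subset
  with configurable standardized effects) so the whole pipeline can be
  exercised and validated without access-restricted clinical data;
- an **experiment harness**: replicated seeded runs, per-feature selection
  frequencies, top-k feature rankings, and cross-method mean (SD)
  accuracy/time comparison tables.

## CLI

Every subcommand takes `--config <yaml>`, `--seed`, `--out-dir` and
`--log-level`, and writes a `provenance.json` beside its outputs.

```sh
# generate a synthetic cohort (CSV + metadata JSON)
evoselect synth --seed 1 --out-dir out/synth

# rank-sum tests + FDR + p-ranked accuracy curve
evoselect stats --table out/synth/cohort.csv --k-max 30 --out-dir out/stats

# run one selector (nsga2 | ga | aco | sa | pso)
evoselect select --table out/synth/cohort.csv --method nsga2 --seed 1 --out-dir out/sel

# replicate a selector n times; selection counts + summary
evoselect replicate --table out/synth/cohort.csv --method nsga2 --n-runs 100 --out-dir out/rep

# compare replicate summaries; top-k feature report
evoselect compare out/rep/summary_nsga2.json out/rep2/summary_ga.json --out-dir out/cmp
evoselect report  out/rep/summary_nsga2.json out/rep2/summary_ga.json --out-dir out/report
```

A YAML config can override any component, e.g.:

```yaml
synth: {n_per_group: [56, 54], p: 142, k_informative: 8, effect_sizes: 1.0}
train: {max_iterations: 50}
eval: {n_restarts: 3}
nsga2: {population_size: 25, max_generations: 50, crossover_percentage: 0.14,
        mutation_percentage: 0.4, mutation_rate: 0.1}
metaheuristic: {population_size: 25, iterations: 50, lam: 0.01}
```

## Package layout

- `evoselect.data` — feature tables, labels, CSV/TSV IO, synthetic
  cohorts, train-split standardization, stratified splits.
- `evoselect.stats` — rank-sum tests, BH FDR, p-ranked accuracy curve.
- `evoselect.mlp` — the MLP, sensitivity-based Jacobian, LM training.
- `evoselect.fitness` — subset evaluation (split, standardize, train,
  score) with caching.
- `evoselect.nsga2` — nondominated sorting, crowding distance, the NSGA-II
  loop, operating-point choice.
- `evoselect.metaheuristics` — GA/ACO/SA/PSO on the scalarized fitness.
- `evoselect.harness` — replicated experiments, rankings, comparisons.
- `evoselect.cli` — the `evoselect` command.
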