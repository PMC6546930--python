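# liquidens

Ensemble liquid state machines (LSMs): a clock-driven spiking reservoir
simulator with excitatory/inhibitory conductance-based LIF neurons, an
ensemble partitioning scheme that splits one neuron budget into several
independent small liquids, trained linear readouts (single shared readout and
multiple per-liquid readouts), and the liquid-quality metric suite (pairwise
separation, rank-based separation/generalization, discriminant ratio) used to
analyze why splitting a large liquid improves class discrimination.

## What is in the box

| module | contents |
| --- | --- |
| `liquidens.liquid` | LIF neuron model, exact-exponential step loop, `run_liquid` / `run_ensemble` |
| `liquidens.topology` | 4:1 E/I split, Bernoulli connectivity masks, uniform(0,1) weights, ensembles, connection counting |
| `liquidens.encoders` | Poisson image encoder, channel-probability encoder, Gaussian-filtered spike distance, jitter operator |
| `liquidens.metrics` | exponentially filtered states, pairwise separation, numerical rank, scatter matrices, DR / Fisher ratio |
| `liquidens.readout` | liquid state extraction, softmax readout (SGD), random / clustered training-space division, max-vote fusion |
| `liquidens.synthetic` | seeded generators: spike-pair suites, clustered glyph images, channel-intensity signals |
| `liquidens.workbench` | experiment configs, result tables, the three trend drivers |
| `liquidens.io` | plain-text serialization (spike CSV + JSON sidecar, channel CSV, images) |

Neuron constants that the modeled formulation leaves open (membrane time
constants, reversal/reset potentials, refractory durations) default to the
standard conductance-LIF values of Diehl & Cook and are flagged as
assumptions; every experiment driver logs them at run start.

## CLI

```bash
liquidens gen-data  --seed 1 --out results/data      # write synthetic datasets
liquidens sp-run    --out results --n-ens 1,2,4      # pairwise separation + ranks
liquidens dr-sweep  --out results                    # discriminant-ratio sweep
liquidens acc-sweep --out results --mlmr             # MLSR / MLMR accuracy sweep
```

Each command accepts `--config <file.yaml>` (see
`liquidens.workbench.ExperimentConfig.to_dict()` for the schema), `--seed`,
`--out <dir>`, and `--n-ens <comma list>`. Results are written as a CSV table
plus a JSON metadata sidecar carrying the config hash, so any table is
reproducible from its own metadata. Tuned presets for the three trend
experiments are available as `ExperimentConfig.sp_preset()`,
`.dr_preset()`, and `.accuracy_preset()`.

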