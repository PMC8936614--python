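# actisense

Analysis pipeline linking active-sensing kinematics, EEG encoding of those
kinematics, drift-diffusion decision dynamics, and cross-modal
(redundant / unique / synergistic) information interactions — together with
a fully seeded synthetic-data generator that provides ground truth for every
recovery test.

## What's inside

| module | role |
| --- | --- |
| `actisense.synthdata` | seeded generators: scanning trajectories, EEG as a lagged linear mixture of finger velocity, drift-diffusion behavior; full datasets with stored ground truth |
| `actisense.kinematics` | velocity, movement parameters (mean speed, midline crossings, low-side dwell), RT quality filters, cumulative-Gaussian psychometrics |
| `actisense.trf_decoding` | lagged ridge decoding of velocity from multichannel EEG (λ on the standardized Gram), trial-wise cross-validated r², forward-model (encoding) inversion |
| `actisense.surrogate_stats` | phase-randomization surrogates and empirical nulls for decoding accuracy |
| `actisense.ddm_inference` | Wiener first-passage density (dual series expansion, numba), hierarchical Bayesian drift-diffusion model with trial-level regressors, adaptive MCMC, Gelman-Rubin, DIC, posterior contrasts |
| `actisense.pid_interactions` | Gaussian-copula mutual information, common-change-in-surprisal partial information decomposition per EEG channel, permutation + FDR significance |
| `actisense.pipeline_cli` | YAML-driven orchestration with manifests, seeding and resumability; EDF/BDF + CSV import |
| `actisense.edfio` | minimal EDF(16-bit)/BDF(24-bit) continuous-recording writer/reader |

## CLI

Four console scripts are installed (`synth`, `pipeline`, `ddm`, `pid`):

```bash
# generate a dataset from a simulation config
synth generate --config sim.yaml --out data.h5 --seed 1

# run the full pipeline (generate -> kinematics -> decode -> [surrogates]
# -> ddm -> pid) from one run config
pipeline run --config run.yaml --out out_dir --seed 1

# fit the hierarchical decision model to a behavior CSV
ddm fit --table out_dir/behavior_scored.csv --model drift_r2+ndt_mov --seed 1 --out ddm_out

# run only the decomposition branch
pid run --config run.yaml --out pid_dir --seed 1
```

A run config is plain YAML; unset keys fall back to defaults:

```yaml
seed: 1
out_dir: out
sim: {n_participants: 4, n_trials_per_cell: 10, n_channels: 16}
stages: {surrogates: false}
ddm: {chains: 3, n: 2000, burn: 500, thin: 5}
pid: {n_perm: 500}
```

Every stage writes a JSON manifest (parameters, seed, input hashes,
outputs); rerunning with an unchanged config and seed skips completed
stages, and all CSV outputs are byte-identical across reruns.

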