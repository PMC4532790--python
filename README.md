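# ndfkit

Latent linear-dynamical modelling of binned spike counts and neural-dynamical
cursor decoding, with the associated diagnostic statistics and a synthetic
session generator.

The package learns a latent-state linear dynamical system (LDS) from
channels × bins spike-count matrices by expectation maximization, estimates the
dynamical neural state with a (steady-state) Kalman filter, and decodes 2-D
cursor kinematics with a neural dynamical filter (NDF) plus comparison
decoders: optimal linear estimator (OLE) with causal Gaussian smoothing,
Wiener filter (WF) over spike history, kinematic-state Kalman filter (KKF),
and a PC-smooth control. Diagnostics include the dynamics-vs-innovations
contribution ratio, one-step-ahead captured variance under three predictors,
hold/reach speed ratios, condition averaging, and grid-task achieved bitrate.
Because no public recordings accompany the method, a synthetic
center-out-and-back session generator (`ndfkit.synth`) provides ground-truth
systems for every analysis.

## Layout

| module | contents |
| --- | --- |
| `ndfkit.lds` | `SpikeCounts`, `LDSParams`, Kalman filter/smoother, steady-state gain, EM (`em_fit`), FA initialization, eigen summaries, permuted-dynamics control |
| `ndfkit.decoders` | `fit_ndf` / `fit_ole` / `fit_wf` / `fit_kkf` / `fit_pcsmooth`, causal Gaussian smoothing, shared least-squares readout, position blending, causal `decode` |
| `ndfkit.metrics` | `dynamics_contribution`, `captured_variance`, `forward_prediction_study`, `condition_average`, `speed_ratio`, `grid_bitrate`, selection-log statistics |
| `ndfkit.synth` | ground-truth LDS construction, ancestral LDS sampling, center-out-and-back sessions, grid-task selection streams |
| `ndfkit.io` | delimited-text session files, JSON model/LDS serialization, selection logs |
| `ndfkit.cli` | `ndfkit simulate | fit | decode | metrics | bitrate` |

## CLI

```sh
ndfkit simulate --out sess/ --trials 50 --seed 7         # synthetic session
ndfkit fit --session sess/ --decoder ndf --latent-dim 8 --out ndf.json
ndfkit decode --session sess/ --model ndf.json --out decoded.tsv
ndfkit metrics --session sess/ --lds ndf.json            # rho, speed ratios, eigenvalues
ndfkit bitrate --log sess/grid_log.tsv
```

All stochastic entry points take explicit seeds; identical invocations produce
identical outputs.

## Quick example

```python
import ndfkit as nk

gt = nk.make_ground_truth_lds(d=8, n_channels=24, seed=0)
Y, X = nk.simulate_reach_session(gt, n_trials=100, seed=0)

ndf = nk.fit_ndf(Y, X, d=8, max_iter=30, steady_e_step=True)
decoded = nk.decode(ndf, Y, init_pos=X.pos[:, 0])

rho, _ = nk.dynamics_contribution(ndf.lds, Y)      # dynamics-process share
print(nk.eigen_summary(ndf.lds))                   # time constants, rotation Hz
```
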