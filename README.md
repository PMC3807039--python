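# cortexlimb

Non-invasive motor decoding for continuous arm reaching: joint angles of
the shoulder and elbow are reconstructed from scalp EEG *through* muscle
activity, in three stages.

1. **Cortical current estimation.** Currents `J(t)` over the cortical
   surface are estimated from 64-channel EEG by a hierarchical Bayesian
   inverse. With a lead field `G`, sensor-noise precision `β` and
   per-vertex current variances `Σ = diag(α⁻¹)`, the inverse filter is

       L = Σ G′ (G Σ G′ + β⁻¹ I)⁻¹,       J(t) = L E(t).

   The variances are unknown and estimated by variational Bayes under an
   automatic-relevance-determination (ARD) hierarchy: each `α_i` carries a
   Gamma prior with mean `1/v0_i` and confidence `r0`, where the prior
   variance is set from functional-MRI activation,
   `v0_i = vbase + (m0 − 1) · vbase · t̂_i²` (normalized T-values `t̂`,
   magnification `m0 = 100`, `r0 = 10`, and `vbase` estimated from the
   pre-movement baseline by Bayesian minimum norm). Artifact dipoles
   (heart, eyes, shoulder, wrist, carotids) are extra columns of `G`.

2. **Sparse EMG reconstruction.** Quasi-tension (rectified, smoothed,
   tension-filtered) EMG of nine arm muscles is regressed on the currents
   of the 33 primary-motor-cortex (M1) vertexes at a fixed 17-ms
   cortico-muscular delay,

       fEMG_i(t + δt) = Σ_j w_ij J_j(t) + bias_i,

   with per-weight ARD hyperpriors optimized by evidence maximization, so
   uninformative vertexes are pruned to exactly zero.

3. **Joint-angle decoding.** A mixture-of-experts network maps the nine
   filtered-EMG channels to the four joint angles: a posture expert, a
   movement expert, and a softmax gate driven by the summed-squared joint
   velocity (estimated from EMG at test time). Training maximizes the
   mixture log likelihood by backpropagation.

Because the recordings such a method is developed on are not public, the
package ships a forward simulator (`cortexlimb.synthetic_data`) that
generates complete sessions of the button-reaching task — joint
trajectories, muscle activations, surface EMG, cortical currents, EEG
through a three-sphere head model or a seeded random lead field, artifact
sources, fMRI priors — with ground truth at every stage, so each decoder
is verified by parameter recovery.

## Worked example

```python
import numpy as np
from cortexlimb.synthetic_data import SimulationConfig, generate_session
from cortexlimb.pipeline import RunConfig, train_decoder, decode_trial
from cortexlimb.pipeline import _trial_metrics  # per-trial CC/nRMSE helper

config = SimulationConfig.test_scale(trials_per_sequence=4)  # 16 trials/set
session, truth = generate_session(config, seed=11)

rc = RunConfig(seed=0)
bundle = train_decoder(session, train_sets=[1], config=rc)   # fit all stages
print("retained M1 vertexes per muscle:", bundle.emg_weights.n_retained)

emg_cc, ang_cc = [], []
for trial in session.trials_in_sets([2]):                    # held-out set
    femg_pred, ang_pred = decode_trial(bundle, trial, session.lead_field)
    ecc, _, acc, _ = _trial_metrics(femg_pred, ang_pred, trial, bundle, rc)
    emg_cc.append(np.mean(ecc)); ang_cc.append(np.mean(acc))
print(f"mean EMG CC {np.mean(emg_cc):.3f}, mean joint-angle CC {np.mean(ang_cc):.3f}")
```

Output:

```
retained M1 vertexes per muscle: [13 10 15 13 13 13 11 15 11]
mean EMG CC 0.847, mean joint-angle CC 0.865
```

The first line shows the sparse regression keeping a third to a half of the
33 candidate M1 vertexes per muscle; the second line is held-out decoding
accuracy on a desk-scale session (224 vertexes, 16 sensors, SNR 10): the
correlation between decoded and measured quasi-tension EMG, and between
decoded and marker-derived joint angles, averaged over muscles/joints and
trials.

A command-line interface covers the same workflow:

```bash
cortexlimb simulate --seed 7 --out session.h5
cortexlimb evaluate --in session.h5 --out report.json   # leave-one-out CV
cortexlimb regions  --in session.h5                     # M1/PMd/PP/All ranking
cortexlimb counts                                       # split sample arithmetic
```

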