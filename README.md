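# tsldmf — two-stage latent dynamics modeling and filtering for smartphone gait data

`tsldmf` characterises individual walking and running patterns from
smartphone inertial sensors. It is aimed at digital-health and
biomechanics researchers who record 30 Hz gyroscope + accelerometer logs
and want a compact, causal, per-subject representation of movement — for
visual gait signatures, subject comparison, or screening trajectories
against a learned "normal" region.

## The method

Each time step gives an 8-dim feature frame
x_t = (ω_x, ω_y, ω_z, ω_T, A_x, A_y, A_z, A_T) — three angular-velocity
channels, three acceleration channels and their Euclidean magnitudes.
After cohort-wide min–max scaling, observations stack three consecutive
frames, y_t = [x_t, x_{t−1}, x_{t−2}] ∈ [0,1]^24, and a latent Markov
model explains them:

    p_θ(y_0:T, z_0:T) = p(z_0) p(y_0|z_0) ∏_t p(y_t|z_t) p(z_t|z_{t−1}),

with z_t ∈ R² or R³, a mixture-density transition network and an MLP
emitter. Training proceeds in two stages:

1. **Latent dynamics modeling** — a backward-in-time GRU encoder
   q_φ(z_t|y_t:T) and the backbone θ are fitted jointly by maximising the
   ELBO (reconstruction minus KL terms) with reparameterized gradients.
2. **Causal filtering** — with θ frozen, a combiner network is trained in
   a Kalman-style predict–correct loop: predict through the transition,
   then correct the predicted mean using the current observation only.
   The result filters sequentially in real time.

Filtered latent trajectories are then pooled and their density is
estimated with a continuous normalizing flow (a neural ODE whose
log-density follows the instantaneous change of variables, with an exact
Jacobian trace at d ≤ 3); thresholding the density at a probability mass
yields the normal region. An incremental-PCA baseline at equal latent
dimension quantifies the reconstruction advantage via the ratio
MSE_IPCA / MSE_TS-LDMF.

No public recording accompanies the method, so the package ships a
synthetic cohort generator (per-subject harmonic gait signatures with
realistic amplitudes, gravity offset and sensor noise) that makes every
stage testable end to end.

## Worked example

Train both stages on four recordings of one synthetic subject, filter the
held-out fifth recording, and compare against incremental PCA:

```python
import numpy as np
from tsldmf import (generate_cohort, fit_minmax, build_observations,
                    train_stage1, train_stage2, filter_sequence, fit_ipca,
                    reconstruction_mse, fit_density, normal_region,
                    log_density)
from tsldmf.stage1 import Stage1Config
from tsldmf.stage2 import Stage2Config
from tsldmf.evaluate import TsldmfReconstructor
from tsldmf.density import DensityConfig

recordings, profiles = generate_cohort(1, 5, seed=7, motions=("walk",),
                                       duration_s=30.0)
print(f"subject {profiles[0].subject_id}: walk fundamental "
      f"{profiles[0].fundamental_hz['walk']:.2f} Hz, "
      f"{len(recordings)} recordings x {len(recordings[0])} frames")
scaling = fit_minmax(recordings)
obs = [build_observations(r, scaling) for r in recordings]
train, test = obs[1:], obs[0]

params, enc, log = train_stage1(train, Stage1Config(
    latent_dim=2, epochs=10, batch_size=8, lr=1e-2, subseq_len=25, seed=0))
print(f"stage 1 ELBO per subsequence: {log[0]['elbo']:.1f} -> {log[-1]['elbo']:.1f}")
comb, _ = train_stage2(train, params, Stage2Config(
    epochs=10, batch_size=8, lr=1e-2, subseq_len=25, seed=0), encoder=enc)

traj = filter_sequence(test, params, comb)
mse_ts = reconstruction_mse(test.matrix, TsldmfReconstructor(params, comb))
mse_pca = reconstruction_mse(test.matrix,
                             fit_ipca(np.vstack([o.matrix for o in train]), 2))
print(f"held-out reconstruction MSE: TS-LDMF {mse_ts:.3f}, "
      f"IPCA {mse_pca:.3f}, ratio {mse_pca / mse_ts:.2f}")

latents = np.vstack([filter_sequence(o, params, comb).means for o in train])
density = fit_density(latents, DensityConfig(iters=300, seed=0))
region = normal_region(density, mass=0.95, seed=0)
inside = np.mean(np.exp(log_density(density, traj.means)) >= region.threshold)
print(f"95% normal region: density threshold {region.threshold:.4f}; "
      f"{100 * inside:.1f}% of held-out trajectory inside")
```

Output:

```
subject S01: walk fundamental 2.00 Hz, 5 recordings x 900 frames
stage 1 ELBO per subsequence: -261.1 -> 767.6
held-out reconstruction MSE: TS-LDMF 0.148, IPCA 0.330, ratio 2.23
95% normal region: density threshold 0.0276; 98.8% of held-out trajectory inside
```

The rising ELBO shows the latent dynamics fitting the stride cycle; the
ratio 2.23 means the 2-dim nonlinear latent model reconstructs the
held-out recording with less than half the squared error of a rank-2
linear projection; and almost all of the held-out trajectory falls inside
the subject's 95% normal region — the recording looks like the training
gait.

The same workflow is available from the shell:

```bash
tsldmf simulate --subjects 2 --recordings 5 --out data/
tsldmf scale --data data/ --out scaling.yaml
tsldmf train-stage1 --data data/ --scaling scaling.yaml --out ckpt
tsldmf train-stage2 --data data/ --scaling scaling.yaml --checkpoint ckpt --out combiner.npz
tsldmf filter --checkpoint ckpt --combiner combiner.npz --scaling scaling.yaml \
       --input data/S01_walk_1.csv --output latents.csv
tsldmf density fit --latents latents.csv --out density.npz
tsldmf run --config pipeline.yaml     # everything above in one shot
```

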