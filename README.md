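# muforce

Unsupervised decomposition of **one-channel surface EMG** into motor-unit
action potentials (MUAPs), and muscle-force estimation from the decoded
motor-unit activity — for researchers in myoelectric control and
electrophysiology who need proportional force estimates without a force
sensor (e.g., for prosthetic-hand control, where the force of a lost limb
cannot be recorded for supervised training).

## The method

A surface EMG signal is a superposition of time-shifted MUAPs plus noise,
`x = As + ε`. Instead of mapping signal *amplitude* to force (which
saturates and fluctuates when MUAPs superimpose and cancel), the package:

1. band-passes (100–3000 Hz), standardizes and reshapes the signal into an
   `m×n` segment matrix `x` (120×800 at 16 kHz);
2. learns a spike-bearing near-orthogonal basis by **reconstruction ICA**,
   minimizing `J(W) = λ‖Wx‖₁ + ½‖WᵀWx − x‖²_F` (λ = 0.01, k = 100 basis
   vectors `b = Wx`);
3. detects spikes in basis vectors against a robust noise threshold
   `4σ`, `σ = median(|·|)/0.6745`, extracts aligned 100-sample (6.25 ms)
   MUAP waveforms, and clusters them by Fourier-magnitude shape features
   with K-means, the cluster count `L ∈ [5, 20]` chosen by a silhouette
   grid search;
4. builds a **sparse basis** `s` (each retained spike window replaced by
   its cluster's representative MUAP) and approximates `s⁻¹` with LSQR;
5. decodes new 0.05 s windows as `ā = x̄ s⁻¹` and estimates force as
   `F̌ = φ · (#{|āᵢ| > c} / k) · unique(active clusters)` (c = 0.34) —
   proportional to firing rate and to the number of recruited motor
   units — reported every 0.5 s and normalized to %MVC by a
   maximal-voluntary-contraction calibration.

Estimates are scored against measured force with
`R² = (1 − var(F̌−F)/var(F)) × 100 %`. A synthetic sEMG generator
(recruitment thresholds, 10–20 Hz rate coding, renewal spike trains,
template superposition, additive noise) provides ground truth for
validation; see `docs/methods.md` for modelling details and limitations.

## Worked example

```python
from muforce import MotorUnitDecomposition, benchmark_scene, r_squared
from muforce.simulate import TRAIN_CYCLES, CYCLE_S
import numpy as np

# simulate 8 contract/relax cycles (7 motor units, 10 dB SNR), with the
# true force known at 10 Hz
rec, force, truth = benchmark_scene("trapezoid", seed=1, G=7, snr_db=10.0)
train = rec.slice_time(0, TRAIN_CYCLES * CYCLE_S)   # first 3 cycles, 6 s
test = rec.slice_time(TRAIN_CYCLES * CYCLE_S, rec.duration_s)

results = MotorUnitDecomposition(train).fit(seed=1)
print(results.summary())

results = results.calibrate_mvc(train)              # peak force -> 100 %MVC
est = results.force_trace(test)                     # one value per 0.5 s
gt = truth.force_trace(t0=TRAIN_CYCLES * CYCLE_S, t1=rec.duration_s)
r2 = r_squared(np.interp(gt.times, est.times + TRAIN_CYCLES * CYCLE_S,
                         est.values), gt.values)
print(f"R^2 vs true force: {r2:.1f}%")
```

prints

```
          Motor-Unit Decomposition Results
====================================================
Segments (m x n)                120 x 800
Basis vectors (k)               100
Sparsity penalty (lambda)       0.01
Noise sigma (median/0.6745)     0.2814
Spike threshold                 4 sigma = 1.1254
Retained spikes (MUAPs)         86
Motor-unit clusters (L)         7
Activation constant (c)         0.34
Inverse residual max|s s+ - I|  0.5
Scale phi                       1
Final RICA cost J(W)            469.8989
Silhouette score (best L)       0.714
====================================================
R^2 vs true force: 80.4%
```

86 of the 100 basis vectors yielded a complete supra-threshold MUAP; the
grid search grouped them into 7 clusters — matching the 7 simulated motor
units — and the decoded activity explains ~80% of the held-out force
variance. (An inverse residual of 0.5 is normal here: basis vectors whose
spikes land at the same offset in the same cluster produce duplicate
sparse rows, and the minimum-norm inverse splits their coordinates.)

The same pipeline is scriptable from the shell:

```sh
muforce simulate --preset trapezoid --seed 1 \
    --out-signal sig.csv --out-force force.csv
muforce train sig.csv --seed 1 --model-out model.npz
muforce estimate sig.csv --model model.npz --out est.csv
muforce evaluate --estimated est.csv --measured force.csv --out report.csv
```

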