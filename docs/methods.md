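# Methods

## The model

A surface electromyogram (sEMG) recorded by one bipolar electrode is
modelled as a linear superposition of time-shifted motor-unit action
potentials (MUAPs) plus Gaussian noise,

    x(t) = sum_j sum_d a_j s_j(t - d) + eps(t),

where `s_j` is the firing pattern of motor unit (MU) j and `a_j` the
volume-conduction gain between that unit and the electrode. Two
physiological facts make unsupervised force estimation from this signal
possible: MUAP shape is stationary across force levels, and force is
modulated by recruiting more MUs and raising their firing rates. The
package therefore estimates force from *decoded MU activity* rather than
from the signal amplitude, which saturates and fluctuates under MUAP
superposition.

## Training pipeline

1. **Preprocessing.** Band-pass 100–3000 Hz (4th-order Butterworth,
   applied forward–backward so filtering is zero-phase and spike peaks
   stay put; "3 dB" is read as the usual Butterworth band-edge
   attenuation), standardize to zero mean / unit population variance, and
   reshape the first `m*n` samples into an `m x n` matrix `x` of
   consecutive segments. Defaults `m=120, n=800` make each row a 0.05 s
   analysis window at 16 kHz and require 6 s of training signal.

2. **Basis learning (reconstruction ICA).** Find the transform `W (k x m)`
   minimizing

       J(W) = lambda * ||W x||_1 + 1/2 * ||W^T W x - x||_F^2,

   with `k=100 <= m` and `lambda=0.01`. The L1 term drives each basis
   vector (row of `b = W x`, length `n`) toward isolated spikes; the
   reconstruction term is a soft orthogonality constraint. The L1 norm is
   smoothed as `sqrt(z^2 + eps^2)` (`eps = 1e-8`) so a quasi-Newton
   optimizer (L-BFGS) applies; the exact J(W) is reported alongside. W is
   initialized with seeded row-normalized Gaussian rows. The iteration cap
   defaults to 3000: at a few hundred iterations the objective is visibly
   unconverged and the leftover structure in the basis vectors blurs spike
   shapes enough to destabilize the downstream cluster-count search. A
   plain backtracking gradient-descent fallback (`method="gd"`) exists for
   reference.

3. **Spike extraction.** The noise scale is the robust estimate
   `sigma = median(|.|)/0.6745` (0.6745 = 0.75 normal quantile). Each
   basis vector's absolute peak is compared against `4*sigma`; by default
   sigma is re-estimated per basis vector, since basis learning leaves
   each row an arbitrary scale and a single global threshold
   systematically misses valid spikes in small-norm vectors (the global
   sigma of the standardized signal is still recorded as the bundle's
   noise diagnostic). Around a supra-threshold peak, 100 samples (6.25 ms)
   are cut with the peak at 0-based index 49; negative-peak spikes are
   flipped and the corresponding row of W is negated, which provably leaves
   `W^T W x` and J(W) unchanged. Windows truncated by either end of the
   basis vector are discarded as incomplete. At most one spike is taken
   per basis vector (an iterate-and-subtract multi-spike mode exists but
   measurably floods the shape space with superposition fragments, so it
   stays off).

4. **Shape clustering.** Each spike is summarized by the magnitudes of DFT
   bins 0–19 of its waveform after scaling to unit peak — magnitudes
   discard phase so alignment jitter is harmless, and peak normalization
   makes the feature a *shape*, not a basis-scale, descriptor (without it,
   clustering groups by the arbitrary per-vector scale). The cluster count
   L is searched over 5–20 with K-means (k-means++, 10 restarts, seeded)
   scored by the fraction of clusters whose mean silhouette strictly
   exceeds the overall mean; ties go to the smaller L. This count-above-
   mean score is kept exactly as the method defines it, with a caveat
   spelled out under Limitations. The representative MUAP `r_l` of each
   cluster is the time-domain mean of its member waveforms (members share
   a positive peak at index 49, so the mean provably inherits it; a medoid
   mode is available). The sparse basis `s` keeps one row per retained
   spike: zeros except the spike's 100-sample window, which holds `r_l`.
   Basis vectors without spikes would contribute all-zero rows that make
   the system singular, so they are dropped and the row-to-basis-vector
   map is stored.

5. **Inverse.** `pinv(s)` is approximated column-by-column with LSQR
   (minimum-norm least squares for `s v = e_j`); the residual
   `max|s pinv(s) - I|` is stored as a diagnostic. For disjoint spike
   windows this reduces to `s^T diag(1/||s_i||^2)` exactly.

## Force estimation

A new window `x_bar` (0.05 s), preprocessed with the *training* filter and
standardization constants (a causal system cannot re-standardize by data
it has not seen), is decoded as `a_bar = x_bar @ pinv(s)`. Components with
`|a_bar_i| > c` (default `c = 0.34`, calibrated for unit-variance input)
are active; the active MU count is the number of distinct cluster labels
among them. The window force is

    F = phi * (#active components / k_active) * (#unique active clusters),

proportional to firing rate and recruitment. Reported force is the mean of
the ten window forces in each 0.5 s block (the mean, rather than the sum,
only rescales phi and low-passes the trace toward the 10 Hz force-sensor
comparison). `phi` is set by maximal-voluntary-contraction (MVC)
calibration: the peak report-window force of an MVC recording becomes
100 %MVC. Evaluation resamples the 2 Hz estimate onto the 10 Hz measured
grid by linear interpolation and applies the variance-accounted-for
statistic R^2 = (1 - var(F_est - F)/var(F)) x 100 %, which is offset- but
not scale-invariant (population variance). The conventional baseline is
the mean absolute value of the band-passed signal per 0.5 s window (RMS
mode available), calibrated to %MVC the same way.

## The synthetic generator

No public recordings accompany the method, so validation runs on a
generator that implements the model above directly:

* **Templates** — mixtures of two differentiated-Gaussian components
  (orders 1–3) with randomized widths and asymmetry, zero-mean, <= 100
  samples, pairwise normalized cross-correlation < 0.9, spectral centroid
  kept in 100–400 Hz (real MUAP spectra are bell-shaped around ~200 Hz).
* **Recruitment and rate coding** — size-principle thresholds spread over
  [0, 0.8] of maximum drive; once recruited, a unit's rate interpolates
  10–20 Hz with the drive above threshold. Interpulse intervals are a
  jittered renewal process (CV 0.15, 20 ms refractory floor), which puts
  interval histogram modes in the physiological 50–100 ms band. Gains
  grow with threshold (1 + 1.5*theta): later-recruited units are larger.
* **Scenes** — eight cycles of 1 s contraction / 1 s rest with preset
  per-cycle amplitudes (the protocol is fixed; randomness enters through
  spike timing, template shape and noise). The `trapezoid` preset mixes
  levels 0.5–1.0 with full-MVC cycles in both splits so unsupervised MVC
  calibration is well-posed; `low_force` stays at 0.2–0.35;
  `high_superposition` holds 0.9–1.0 where amplitude cancellation is
  worst; `ramp` is a single triangular sweep. Noise is white Gaussian,
  scaled to a requested SNR (10 dB default) against the rendered clean
  signal. The first three cycles are the conventional training split.

What the generator does *not* emulate: volume-conductor filtering that
differs across units beyond a scalar gain, electrode shift, slow drift of
the mixing (the stationary regime only), fatigue, motor-unit
synchronization, and non-Gaussian artifacts. Passing the synthetic
benchmarks therefore shows the pipeline recovers structure generated by
its own model class under realistic firing statistics and noise — not
that it handles every pathology of clinical recordings.

## Benchmark protocol and typical numbers

`muforce.benchmark.run_benchmark` trains on the first three cycles of a
scene (exactly the 96 000 samples the 120x800 segment matrix consumes),
calibrates %MVC on that split, and scores the last five cycles. At the
default conditions (G=7 units, SNR 10 dB) across 20 seeds the cluster-count
search lands within 7±1 in roughly two-thirds to three-quarters of seeds,
median R^2 sits at ~80%, the reconstruction retains ~50–60% of the signal
energy, and under the high-superposition preset the decomposition estimate
beats the amplitude baseline in nearly every seed. These are the
quantities `scripts/acceptance.py` recomputes; problem sizes (20 trapezoid
seeds, 10 high-superposition seeds, 16 s scenes) were chosen so a full run
completes comfortably on one CPU.

## Numerical choices and edge cases

* Ties in peak detection resolve to the earliest index; spike windows are
  `[peak-49, peak+51)`.
* K-means that still yields an empty cluster after one re-seed raises; a
  set of byte-identical spikes short-circuits to a single effective
  cluster with a warning.
* Constant signals cannot be standardized (error), zero-variance measured
  force cannot be scored (error), and a claimed-MVC recording with no
  supra-threshold activation cannot calibrate phi (error).
* Model bundles serialize to a single `.npz` with a JSON metadata block;
  loading checks a format version and fails loudly on corruption. A bundle
  with zero retained spikes round-trips but is flagged degenerate.
* All randomness (basis init, K-means restarts, generator) flows from
  explicit integer seeds; two runs with the same seed are bit-identical.

## Known limitations

* **The cluster-count score.** The count-above-mean silhouette score is
  implemented exactly as the method defines it. On idealized,
  well-separated *balanced* feature clouds it provably prefers
  overclustering (at the true L all clusters are equally good, so only
  ~half exceed the mean), and it cannot recover a planted cluster count
  there. On the noisy, unbalanced features the pipeline actually produces
  it carries real signal (7±1 recovery far above chance), which is the
  regime the method was designed for. Selecting by mean silhouette would
  be more conventional but would change the published selection rule, so
  it is not the default.
* Decoding assumes spike positions in new windows overlap the training
  windows' positions; coverage comes from having ~80–100 spike windows
  spread over the 800-sample frame, not from shift invariance.
* One spike per basis vector caps the decomposition at k MUAP instances
  per training set; very high recruitment can exceed that.
* `c = 0.34` presumes unit-variance preprocessing; recordings decoded with
  a model trained at a very different activity level inherit that
  calibration.
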