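"""Model/Results interface tying the decomposition pipeline together.

``MotorUnitDecomposition`` is built from a raw one-channel recording;
``fit()`` runs the full training pipeline — band-pass, standardize,
segment, learn the basis by reconstruction ICA, detect and extract spikes,
cluster them, build the sparse basis and approximate its inverse — and
returns a ``DecompositionResults`` carrying the trained artifacts,
diagnostics, a ``summary()`` table, force estimation, reconstruction and
serialization.
"""

from __future__ import annotations

import numpy as np

from . import cluster as _cluster
from . import force as _force
from . import metrics as _metrics
from . import muap as _muap
from . import preprocess as _pre
from . import rica as _rica
from .io import ModelBundle, PipelineConfig, Recording, read_model, write_model

__all__ = ["MotorUnitDecomposition", "DecompositionResults"]


class MotorUnitDecomposition:
    """Unsupervised decomposition of a one-channel sEMG recording.

    Parameters
    ----------
    endog : Recording or array_like
        The training signal (raw voltage samples).
    rate_hz : float
        Sampling rate when ``endog`` is a plain array.
    config : PipelineConfig, optional
        Pipeline tunables; defaults follow the published operating point.
    """

    def __init__(self, endog, rate_hz: float = 16000.0, config: PipelineConfig | None = None):
        if isinstance(endog, Recording):
            self.recording = endog
        else:
            self.recording = Recording(np.asarray(endog, dtype=float), rate_hz)
        self.config = config if config is not None else PipelineConfig(rate_hz=self.recording.rate_hz)
        if abs(self.config.rate_hz - self.recording.rate_hz) > 1e-9:
            self.config = self.config.replace(rate_hz=self.recording.rate_hz)
        needed = self.config.m * self.config.n
        if self.recording.samples.size < needed:
            raise ValueError(
                f"training signal too short: need {needed} samples "
                f"(m={self.config.m} x n={self.config.n}), "
                f"have {self.recording.samples.size}"
            )

    @classmethod
    def from_recording(cls, rec: Recording, config: PipelineConfig | None = None):
        return cls(rec, config=config)

    def fit(self, seed: int = 0, method: str = "lbfgs") -> "DecompositionResults":
        """Run the full training pipeline; deterministic given ``seed``."""
        cfg = self.config
        filtered = _pre.bandpass(
            self.recording, cfg.band_low_hz, cfg.band_high_hz, cfg.filter_order
        )
        standardized, mean, scale = _pre.standardize(filtered, return_params=True)
        segments = _pre.segment(standardized, cfg.m, cfg.n)

        basis = _rica.learn_transform(
            segments,
            _rica.RicaConfig(
                k=cfg.k,
                lambda_penalty=cfg.lambda_penalty,
                max_iter=cfg.rica_max_iter,
                tol=cfg.rica_tol,
                seed=seed,
                method=method,
            ),
        )
        noise = _muap.estimate_noise(
            standardized.samples[: cfg.m * cfg.n], multiplier=cfg.threshold_multiplier
        )
        # per-basis-vector noise thresholding (scale-invariant detection);
        # sigma of the standardized signal is kept as the reported noise level
        spikes = _muap.extract_all_spikes(
            basis,
            None,
            spike_length=cfg.spike_length,
            multiplier=cfg.threshold_multiplier,
        )

        if len(spikes) == 0:
            bundle = ModelBundle(
                sparse_basis=np.zeros((0, cfg.n)),
                inverse_basis=np.zeros((cfg.n, 0)),
                transform=basis.W,
                row_cluster=np.zeros(0, dtype=int),
                spike_rows=np.zeros(0, dtype=int),
                spike_peaks=np.zeros(0, dtype=int),
                representatives=np.zeros((0, cfg.spike_length)),
                noise_sigma=noise.sigma,
                activation_threshold=cfg.activation_threshold,
                threshold_multiplier=cfg.threshold_multiplier,
                cluster_count=0,
                train_mean=mean,
                train_scale=scale,
                config=cfg,
            )
            return DecompositionResults(self, bundle, basis, spikes, None, None, segments)

        features = _cluster.feature_matrix(spikes, cfg.n_fourier_coeffs)
        L = _cluster.select_cluster_count(
            features, cfg.cluster_min, cfg.cluster_max, seed=seed
        )
        clusters = _cluster.cluster_muaps(spikes, features, L, seed=seed)
        sparse = _cluster.build_sparse_basis(basis, spikes, clusters)
        inverse = _cluster.invert_sparse_basis(sparse)
        residual = _cluster.inverse_residual(sparse.s, inverse)

        bundle = ModelBundle(
            sparse_basis=sparse.s,
            inverse_basis=inverse,
            transform=basis.W,
            row_cluster=sparse.row_cluster,
            spike_rows=sparse.spike_rows,
            spike_peaks=sparse.spike_peaks,
            representatives=clusters.representatives,
            noise_sigma=noise.sigma,
            activation_threshold=cfg.activation_threshold,
            threshold_multiplier=cfg.threshold_multiplier,
            cluster_count=L,
            train_mean=mean,
            train_scale=scale,
            inverse_residual=residual,
            config=cfg,
        )
        return DecompositionResults(self, bundle, basis, spikes, clusters, sparse, segments)


class DecompositionResults:
    """Trained decomposition: sparse basis, inverse, clusters, diagnostics."""

    def __init__(self, model, bundle, basis=None, spikes=None, clusters=None,
                 sparse=None, segments=None):
        self.model = model
        self.bundle: ModelBundle = bundle
        self.basis = basis
        self.spikes = spikes if spikes is not None else []
        self.clusters = clusters
        self.sparse = sparse
        self.segments = segments

    # -- scalar diagnostics -------------------------------------------------
    @property
    def n_spikes(self) -> int:
        return self.bundle.k_active

    @property
    def n_clusters(self) -> int:
        return int(self.bundle.cluster_count)

    @property
    def noise_sigma(self) -> float:
        return float(self.bundle.noise_sigma)

    @property
    def inverse_residual(self) -> float:
        return float(self.bundle.inverse_residual)

    @property
    def final_cost(self) -> float:
        return float(self.basis.final_cost) if self.basis is not None else np.nan

    # -- application --------------------------------------------------------
    def force_trace(self, rec: Recording, **kwargs) -> _force.ForceEstimate:
        """Estimate force on a new recording (see :func:`muforce.force.force_trace`)."""
        return _force.force_trace(rec, self.bundle, **kwargs)

    def calibrate_mvc(self, mvc_recording: Recording) -> "DecompositionResults":
        """Return results whose phi scales the MVC peak to 100 %MVC."""
        bundle = _force.calibrate_mvc(self.bundle, mvc_recording)
        return DecompositionResults(
            self.model, bundle, self.basis, self.spikes, self.clusters,
            self.sparse, self.segments,
        )

    def reconstruct(self) -> _pre.SegmentMatrix:
        """Signal implied by the sparse basis: pinv(W) @ s (zero rows restored)."""
        if self.basis is None or self.sparse is None:
            raise ValueError("reconstruction requires the in-memory training artifacts")
        return _metrics.reconstruct(self.basis, self.sparse)

    def energy_retained(self) -> float:
        """Energy fraction of the training segments kept by the reconstruction."""
        if self.segments is None:
            raise ValueError("training segments unavailable")
        return _metrics.energy_ratio(self.reconstruct(), self.segments)

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        b = self.bundle
        cfg = b.config
        lines = [
            "          Motor-Unit Decomposition Results",
            "=" * 52,
            f"{'Segments (m x n)':<32}{cfg.m} x {cfg.n}",
            f"{'Basis vectors (k)':<32}{cfg.k}",
            f"{'Sparsity penalty (lambda)':<32}{cfg.lambda_penalty:g}",
            f"{'Noise sigma (median/0.6745)':<32}{b.noise_sigma:.4f}",
            f"{'Spike threshold':<32}{b.threshold_multiplier:g} sigma = "
            f"{b.threshold_multiplier * b.noise_sigma:.4f}",
            f"{'Retained spikes (MUAPs)':<32}{b.k_active}",
            f"{'Motor-unit clusters (L)':<32}{b.cluster_count}",
            f"{'Activation constant (c)':<32}{b.activation_threshold:g}",
            f"{'Inverse residual max|s s+ - I|':<32}{b.inverse_residual:.3g}",
            f"{'Scale phi':<32}{b.scale_phi:.4g}"
            + ("  (%MVC calibrated)" if b.normalized else ""),
        ]
        if self.basis is not None:
            lines.append(f"{'Final RICA cost J(W)':<32}{self.basis.final_cost:.4f}")
        if self.clusters is not None:
            lines.append(
                f"{'Silhouette score (best L)':<32}{self.clusters.score:.3f}"
            )
        lines.append("=" * 52)
        return "\n".join(lines)

    def plot_muaps(self, ax=None):
        """Plot the representative waveform of each motor-unit cluster."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dt_ms = 1000.0 / self.bundle.config.rate_hz
        t = np.arange(self.bundle.representatives.shape[1]) * dt_ms
        for l, rep in enumerate(self.bundle.representatives):
            ax.plot(t, rep, label=f"MU{l + 1}")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("amplitude (standardized units)")
        ax.legend(fontsize="small")
        return ax

    def plot_force(self, estimate: _force.ForceEstimate, measured=None, ax=None):
        """Plot an estimated force trace, optionally against a measured one."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(estimate.times, estimate.values, label="estimated")
        if measured is not None:
            ax.plot(measured.times, measured.values, label="measured")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("force" + (" (%MVC)" if estimate.normalized else ""))
        ax.legend()
        return ax

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        write_model(self.bundle, path)

    @classmethod
    def load(cls, path) -> "DecompositionResults":
        """Load a saved bundle; in-memory training artifacts (spikes,
        segment matrix) are not stored, so reconstruction-from-training is
        unavailable on a loaded results object, but force estimation is."""
        bundle = read_model(path)
        basis = _rica.BasisModel(W=bundle.transform, b=np.zeros((bundle.transform.shape[0], bundle.config.n)))
        return cls(None, bundle, basis=basis)
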