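"""Evaluation metrics and diagnostics.

The accuracy statistic is the variance-accounted-for form of R-squared,

    R^2 = (1 - var(F_est - F) / var(F)) * 100 %,

which is invariant to adding a constant to either trace (population
variance throughout). The conventional baseline estimates force from the
amplitude envelope (mean absolute value per reporting window) of the
band-passed signal. Reconstruction of the signal from the sparse basis,
x_rec = pinv(W) @ s, the retained-energy fraction, interpulse-interval
histograms and Welch power spectra round out the diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .cluster import SparseBasis
from .io import ForceTrace, Recording
from .preprocess import SegmentMatrix, bandpass
from .rica import BasisModel

__all__ = [
    "r_squared",
    "resample_trace",
    "amplitude_baseline",
    "reconstruct",
    "energy_ratio",
    "ipi_histogram",
    "power_spectrum",
    "EvaluationReport",
]


@dataclass
class EvaluationReport:
    r_squared: float
    baseline_r_squared: float = np.nan
    energy_retained: float = np.nan


def r_squared(estimate: np.ndarray, measured: np.ndarray) -> float:
    """Percent of measured-force variance explained by the estimate."""
    estimate = np.asarray(estimate, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if estimate.shape != measured.shape:
        raise ValueError(
            f"length mismatch: estimate {estimate.shape}, measured {measured.shape}; "
            "resample to a common grid first"
        )
    var_f = measured.var(ddof=0)
    if var_f == 0:
        raise ValueError("measured force has zero variance; R^2 undefined")
    return float((1.0 - (estimate - measured).var(ddof=0) / var_f) * 100.0)


def resample_trace(trace: ForceTrace, target_times: np.ndarray) -> np.ndarray:
    """Linear interpolation of a force trace onto a target time grid."""
    return np.interp(np.asarray(target_times, float), trace.times, trace.values)


def amplitude_baseline(
    rec: Recording,
    window_s: float = 0.5,
    band: tuple[float, float] = (100.0, 3000.0),
    order: int = 4,
    mode: str = "mav",
    scale: float = 1.0,
) -> ForceTrace:
    """Conventional amplitude-envelope force proxy, one value per window.

    ``mode`` selects mean absolute value (default) or RMS. ``scale`` is the
    caller's calibration factor (e.g. 100 / training-peak for %MVC).
    """
    filtered = bandpass(rec, band[0], band[1], order).samples
    n = int(round(window_s * rec.rate_hz))
    num = filtered.size // n
    win = filtered[: num * n].reshape(num, n)
    if mode == "mav":
        env = np.abs(win).mean(axis=1)
    elif mode == "rms":
        env = np.sqrt((win**2).mean(axis=1))
    else:
        raise ValueError(f"unknown amplitude mode {mode!r}")
    times = (np.arange(num) + 0.5) * window_s
    return ForceTrace(times, scale * env, rate_hz=1.0 / window_s)


def _full_sparse(s: SparseBasis | np.ndarray, k: int, n: int) -> np.ndarray:
    """Re-insert zero rows so the sparse basis conforms to W (k x n)."""
    if isinstance(s, SparseBasis):
        full = np.zeros((k, n))
        full[s.spike_rows] = s.s
        return full
    return np.atleast_2d(np.asarray(s, dtype=float))


def reconstruct(basis: BasisModel, s: SparseBasis | np.ndarray) -> SegmentMatrix:
    """x_rec = pinv(W) @ s_full — the signal implied by the sparse basis."""
    W = basis.W
    k, m = W.shape
    rank = np.linalg.matrix_rank(W)
    if rank < k:
        raise ValueError(f"W is rank-deficient (rank {rank} < k={k}); cannot invert")
    s_full = _full_sparse(s, k, basis.b.shape[1])
    x_rec = np.linalg.pinv(W) @ s_full
    return SegmentMatrix(x_rec, rate_hz=np.nan)


def energy_ratio(x_hat: SegmentMatrix | np.ndarray, x: SegmentMatrix | np.ndarray) -> float:
    """Fraction of the original signal energy retained by x_hat."""
    a = x_hat.x if isinstance(x_hat, SegmentMatrix) else np.asarray(x_hat, float)
    b = x.x if isinstance(x, SegmentMatrix) else np.asarray(x, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = float(np.sum(b * b))
    if denom == 0:
        raise ValueError("original signal has zero energy")
    return float(np.sum(a * a) / denom)


def ipi_histogram(
    spike_times_ms: np.ndarray, bin_ms: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of successive interpulse intervals for one motor unit.

    Returns (counts, bin_edges_ms); empty arrays (with a warning) when
    fewer than two spikes exist.
    """
    t = np.sort(np.asarray(spike_times_ms, dtype=float))
    if t.size < 2:
        warnings.warn("fewer than 2 spikes: empty interpulse histogram", stacklevel=2)
        return np.array([], dtype=int), np.array([])
    ipi = np.diff(t)
    top = (np.floor(ipi.max() / bin_ms) + 1) * bin_ms
    edges = np.arange(0.0, top + bin_ms / 2, bin_ms)
    counts, edges = np.histogram(ipi, bins=edges)
    return counts, edges


def ipi_mode_ms(spike_times_ms: np.ndarray, bin_ms: float = 10.0) -> float:
    """Center of the most populated interpulse-interval bin."""
    counts, edges = ipi_histogram(spike_times_ms, bin_ms)
    if counts.size == 0:
        return np.nan
    i = int(np.argmax(counts))
    return float((edges[i] + edges[i + 1]) / 2)


def power_spectrum(
    signal: np.ndarray, rate_hz: float, nperseg: int = 1024
) -> tuple[np.ndarray, np.ndarray, float]:
    """Welch PSD and spectral centroid (Hz) of a signal."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < 256:
        raise ValueError("need at least 256 samples for a stable spectrum")
    freqs, psd = sps.welch(signal, fs=rate_hz, nperseg=min(nperseg, signal.size))
    centroid = float(np.sum(freqs * psd) / np.sum(psd))
    return freqs, psd, centroid
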