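"""Band-pass filtering, standardization and segmentation of raw sEMG.

The pipeline order is filter -> standardize -> reshape: the filtered signal
is brought to zero mean and unit variance, then cut into ``m`` consecutive
``n``-sample segments forming the matrix consumed by basis learning. At the
defaults (m=120, n=800 at 16 kHz) each segment spans the 0.05 s analysis
window used throughout force estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Recording

__all__ = ["SegmentMatrix", "bandpass", "standardize", "standardization_params", "segment"]


@dataclass
class SegmentMatrix:
    """The m x n matrix of consecutive standardized signal segments."""

    x: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))

    @property
    def m(self) -> int:
        return self.x.shape[0]

    @property
    def n(self) -> int:
        return self.x.shape[1]

    @property
    def window_s(self) -> float:
        return self.n / self.rate_hz


def design_bandpass(low_hz: float, high_hz: float, rate_hz: float, order: int = 4):
    """Second-order sections of the Butterworth band-pass used throughout.

    The 3 dB points sit at the band edges, the usual Butterworth reading of
    a "100-3000 Hz, 3 dB" specification.
    """
    nyq = rate_hz / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz ({high_hz} Hz) must be below the Nyquist rate ({nyq} Hz)"
        )
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rate_hz, output="sos")


def bandpass(
    rec: Recording,
    low_hz: float = 100.0,
    high_hz: float = 3000.0,
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-pass; preserves length and spike timing.

    Forward-backward filtering keeps MUAP peak alignment meaningful (no
    group delay), at the cost of doubling the effective attenuation.
    """
    sos = design_bandpass(low_hz, high_hz, rec.rate_hz, order)
    filtered = sps.sosfiltfilt(sos, rec.samples)
    return Recording(filtered, rec.rate_hz, rec.channel_label)


def standardization_params(samples: np.ndarray) -> tuple[float, float]:
    """Mean and population standard deviation used for standardization."""
    samples = np.asarray(samples, dtype=float)
    mean = float(samples.mean())
    scale = float(samples.std(ddof=0))
    if scale == 0.0:
        raise ValueError("zero variance: cannot standardize a constant signal")
    return mean, scale


def standardize(rec: Recording, return_params: bool = False):
    """Scale the signal to zero mean and unit (population) variance."""
    mean, scale = standardization_params(rec.samples)
    out = Recording((rec.samples - mean) / scale, rec.rate_hz, rec.channel_label)
    if return_params:
        return out, mean, scale
    return out


def segment(rec: Recording, m: int = 120, n: int = 800) -> SegmentMatrix:
    """Reshape the first ``m*n`` samples into an m x n matrix, row-major.

    Row ``t`` holds samples ``[t*n, (t+1)*n)``; trailing samples beyond
    ``m*n`` are discarded.
    """
    needed = m * n
    if rec.samples.size < needed:
        raise ValueError(
            f"signal too short to segment: need {needed} samples "
            f"(m={m} x n={n}), have {rec.samples.size}"
        )
    x = rec.samples[:needed].reshape(m, n).copy()
    return SegmentMatrix(x, rec.rate_hz)
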