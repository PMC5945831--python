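"""Spike (MUAP) detection and extraction from learned basis vectors.

The background-noise scale is the robust median estimate
``sigma = median(|x|) / 0.6745`` (0.6745 being the 0.75 quantile of the
standard normal, so that sigma is a consistent estimate of the noise
standard deviation under Gaussian noise). A basis-vector excursion whose
absolute peak exceeds ``4*sigma`` is taken to be a motor-unit action
potential; 100 samples (6.25 ms at 16 kHz) are cut out with the peak at
0-based index 49, negative-peak spikes are flipped, and spikes whose
100-sample window would run off either end of the basis vector are
discarded as incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rica import BasisModel

__all__ = [
    "NoiseLevel",
    "MuapSpike",
    "estimate_noise",
    "detect_peak",
    "extract_spike",
    "apply_flip_to_transform",
    "extract_all_spikes",
    "MAD_NORMAL_CONSTANT",
]

# 0.75 quantile of the standard normal distribution, to 4 decimals
MAD_NORMAL_CONSTANT = 0.6745


@dataclass
class NoiseLevel:
    sigma: float
    multiplier: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def threshold(self) -> float:
        return self.multiplier * self.sigma


@dataclass
class MuapSpike:
    """An extracted, aligned, positive-peak 100-sample waveform."""

    waveform: np.ndarray
    source_row: int
    peak_offset: int
    flipped: bool

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)


def estimate_noise(x, multiplier: float = 4.0) -> NoiseLevel:
    """Robust noise scale: median(|x|)/0.6745 (scale-equivariant)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot estimate noise from empty input")
    sigma = float(np.median(np.abs(x)) / MAD_NORMAL_CONSTANT)
    return NoiseLevel(sigma=sigma, multiplier=multiplier)


def detect_peak(b_i: np.ndarray, noise: NoiseLevel) -> int | None:
    """Location of the absolute peak if it clears the threshold, else None.

    Ties are broken by the earliest index (argmax convention).
    """
    b_i = np.asarray(b_i, dtype=float)
    loc = int(np.argmax(np.abs(b_i)))
    if np.abs(b_i[loc]) > noise.threshold:
        return loc
    return None


def extract_spike(
    b_i: np.ndarray, peak_loc: int, source_row: int = 0, spike_length: int = 100
) -> MuapSpike | None:
    """Cut ``spike_length`` samples with the peak at index spike_length//2-1.

    Returns None (discard) when the window would be truncated by either
    edge of the basis vector — incomplete spikes carry unreliable shape.
    Negative-peak spikes are sign-flipped so all waveforms align with a
    positive peak.
    """
    b_i = np.asarray(b_i, dtype=float)
    pre = spike_length // 2 - 1          # 49 samples before the peak
    start, stop = peak_loc - pre, peak_loc - pre + spike_length
    if start < 0 or stop > b_i.size:
        return None
    waveform = b_i[start:stop].copy()
    flipped = b_i[peak_loc] < 0
    if flipped:
        waveform = -waveform
    return MuapSpike(
        waveform=waveform, source_row=source_row, peak_offset=peak_loc, flipped=bool(flipped)
    )


def apply_flip_to_transform(model: BasisModel, spike: MuapSpike) -> BasisModel:
    """Negate the spike's row of W (and its basis vector) in place.

    Because the reconstruction W^T W x is invariant under negating any row
    of W, this re-orients the basis vector to a positive peak without
    changing the signal it reconstructs. Applying the same flip twice
    restores the original W exactly.
    """
    i = spike.source_row
    model.W[i] = -model.W[i]
    model.b[i] = -model.b[i]
    return model


def extract_all_spikes(
    model: BasisModel,
    noise: NoiseLevel | None = None,
    spike_length: int = 100,
    max_per_vector: int = 1,
    flip_transform: bool = True,
    multiplier: float = 4.0,
) -> list[MuapSpike]:
    """Detect and extract spikes across all basis vectors.

    When ``noise`` is None (default), the noise scale is re-estimated per
    basis vector — the spike-sorting convention of thresholding the trace
    on which detection runs, which also makes detection invariant to the
    arbitrary per-vector scale the basis learning leaves behind. Passing a
    fixed :class:`NoiseLevel` applies one global threshold instead.

    Default is the single global-peak rule (at most one spike per basis
    vector). ``max_per_vector > 1`` enables an iterate-and-subtract mode
    that zeroes each extracted window and searches again; only the first
    (largest) spike of a vector decides the sign flip applied to W.
    """
    spikes: list[MuapSpike] = []
    for i in range(model.k):
        work = model.b[i].copy()
        noise_i = noise if noise is not None else estimate_noise(work, multiplier)
        for rank in range(max_per_vector):
            loc = detect_peak(work, noise_i)
            if loc is None:
                break
            spike = extract_spike(work, loc, source_row=i, spike_length=spike_length)
            pre = spike_length // 2 - 1
            lo = max(0, loc - pre)
            hi = min(work.size, loc - pre + spike_length)
            work[lo:hi] = 0.0
            if spike is None:
                continue  # incomplete window near an edge; keep searching
            if rank == 0 and spike.flipped and flip_transform:
                apply_flip_to_transform(model, spike)
            spikes.append(spike)
    return spikes
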