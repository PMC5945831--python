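"""Force estimation from decomposed motor-unit activity.

A new signal window x_bar (0.05 s, preprocessed exactly like the training
data: band-passed, then shifted/scaled by the *training* standardization
constants) is decoded against the stored sparse basis:

    a_bar = x_bar @ s_inverse

Coordinates with |a_bar_i| > c (c = 0.34 at the unit-variance operating
point) mark active components; the motor units they belong to are the
distinct cluster labels among them. The window force is

    F = phi * (active components / k_active) * (# unique active clusters)

— proportional to the firing rate (fraction of spiking components per
0.05 s) and to the number of recruited motor units. Forces are reported as
the mean over consecutive 0.5 s blocks (ten analysis windows), giving a
2 Hz trace comparable to a 10 Hz tensiometer after interpolation. phi is
set by maximal-voluntary-contraction (MVC) calibration: the peak reported
force during an MVC recording defines 100 %MVC.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .io import ModelBundle, Recording
from .preprocess import bandpass

__all__ = [
    "WindowCoordinates",
    "ActivationSummary",
    "ForceEstimate",
    "preprocess_like_training",
    "window_coordinates",
    "summarize_activation",
    "window_force",
    "force_trace",
    "calibrate_mvc",
]


@dataclass
class WindowCoordinates:
    a_bar: np.ndarray
    window_index: int = 0


@dataclass
class ActivationSummary:
    active_components: int
    active_mus: int
    window_index: int = 0


@dataclass
class ForceEstimate:
    """Per-report-window force estimate (one value each ``report_s``)."""

    values: np.ndarray
    times: np.ndarray                     # report-window centers, seconds
    window_s: float = 0.05
    report_s: float = 0.5
    phi: float = 1.0
    normalized: bool = False
    window_forces: np.ndarray | None = None
    active_components: np.ndarray | None = None   # per analysis window
    active_mus: np.ndarray | None = None
    cluster_active: np.ndarray | None = None      # (num windows, L) booleans


def preprocess_like_training(rec: Recording, bundle: ModelBundle) -> np.ndarray:
    """Band-pass and apply the training standardization to a new signal.

    A live decoder cannot standardize by statistics of data it has not yet
    seen, so the affine transform stored at training time is reused.
    """
    cfg = bundle.config
    if abs(rec.rate_hz - cfg.rate_hz) > 1e-6 * cfg.rate_hz:
        raise ValueError(
            f"recording rate {rec.rate_hz} Hz does not match the model's "
            f"training rate {cfg.rate_hz} Hz"
        )
    filtered = bandpass(rec, cfg.band_low_hz, cfg.band_high_hz, cfg.filter_order)
    return (filtered.samples - bundle.train_mean) / bundle.train_scale


def window_coordinates(x_bar: np.ndarray, bundle: ModelBundle) -> WindowCoordinates:
    """Coordinates of one preprocessed n-sample window w.r.t. s."""
    x_bar = np.asarray(x_bar, dtype=float)
    n = bundle.inverse_basis.shape[0]
    if x_bar.size != n:
        raise ValueError(f"window length {x_bar.size} != basis length {n}")
    return WindowCoordinates(a_bar=x_bar @ bundle.inverse_basis)


def summarize_activation(
    coords: WindowCoordinates | np.ndarray,
    c: float = 0.34,
    row_cluster: np.ndarray | ModelBundle | None = None,
) -> ActivationSummary:
    """Count active components and the distinct motor units among them."""
    a = coords.a_bar if isinstance(coords, WindowCoordinates) else np.asarray(coords, float)
    if isinstance(row_cluster, ModelBundle):
        row_cluster = row_cluster.row_cluster
    if c <= 0:
        raise ValueError("activation threshold c must be positive")
    active = np.abs(a) > c
    n_active = int(active.sum())
    if row_cluster is None:
        n_mus = n_active
    else:
        row_cluster = np.asarray(row_cluster)
        n_mus = int(np.unique(row_cluster[active]).size)
    idx = coords.window_index if isinstance(coords, WindowCoordinates) else 0
    return ActivationSummary(
        active_components=n_active, active_mus=n_mus, window_index=idx
    )


def window_force(summary: ActivationSummary, phi: float, k_active: int) -> float:
    """phi * (active components / k_active) * (# unique active clusters)."""
    if phi <= 0 or k_active <= 0:
        raise ValueError("phi and k_active must be positive")
    return phi * (summary.active_components / k_active) * summary.active_mus


def force_trace(
    rec: Recording,
    bundle: ModelBundle,
    window_s: float | None = None,
    report_s: float | None = None,
) -> ForceEstimate:
    """Slide non-overlapping analysis windows and report block means."""
    cfg = bundle.config
    window_s = cfg.window_s if window_s is None else window_s
    report_s = cfg.report_s if report_s is None else report_s
    n = int(round(window_s * rec.rate_hz))
    per_report = int(round(report_s / window_s))
    if abs(per_report * window_s - report_s) > 1e-9:
        raise ValueError("report_s must be an integer multiple of window_s")
    if rec.samples.size < n:
        raise ValueError(
            f"recording shorter than one analysis window ({n} samples)"
        )
    z = preprocess_like_training(rec, bundle)
    num_windows = z.size // n
    if bundle.degenerate:
        coords = np.zeros((num_windows, 0))
    else:
        if n != bundle.inverse_basis.shape[0]:
            raise ValueError(
                f"analysis window of {n} samples does not match the model's "
                f"basis length {bundle.inverse_basis.shape[0]}"
            )
        windows = z[: num_windows * n].reshape(num_windows, n)
        coords = windows @ bundle.inverse_basis          # (num_windows, k_active)

    c = bundle.activation_threshold
    active = np.abs(coords) > c                          # (num_windows, k_active)
    n_active = active.sum(axis=1)
    L = max(int(bundle.cluster_count), 1)
    if bundle.k_active:
        onehot = np.zeros((bundle.k_active, L), dtype=bool)
        onehot[np.arange(bundle.k_active), bundle.row_cluster] = True
        cluster_active = active @ onehot                 # (num_windows, L)
        n_mus = cluster_active.sum(axis=1)
    else:
        cluster_active = np.zeros((num_windows, L), dtype=bool)
        n_mus = np.zeros(num_windows, dtype=int)

    k_active = max(bundle.k_active, 1)
    wf = bundle.scale_phi * (n_active / k_active) * n_mus

    num_reports = num_windows // per_report
    blocks = wf[: num_reports * per_report].reshape(num_reports, per_report)
    values = blocks.mean(axis=1)
    times = (np.arange(num_reports) + 0.5) * report_s
    return ForceEstimate(
        values=values,
        times=times,
        window_s=window_s,
        report_s=report_s,
        phi=bundle.scale_phi,
        normalized=bundle.normalized,
        window_forces=wf,
        active_components=n_active,
        active_mus=n_mus,
        cluster_active=cluster_active,
    )


def calibrate_mvc(bundle: ModelBundle, mvc_recording: Recording) -> ModelBundle:
    """Set phi so the peak report-window force during the MVC equals 100.

    Returns a new bundle with ``scale_phi`` set and ``normalized=True``;
    thereafter estimates are on the %MVC scale.
    """
    probe = dataclasses.replace(bundle, scale_phi=1.0)
    trace = force_trace(mvc_recording, probe)
    peak = float(trace.values.max()) if trace.values.size else 0.0
    if peak <= 0:
        raise ValueError(
            "no motor-unit activation detected in the claimed MVC recording; "
            "cannot calibrate"
        )
    return dataclasses.replace(bundle, scale_phi=100.0 / peak, normalized=True)
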