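"""Signal, force-trace and model-bundle I/O, plus run configuration.

File conventions
----------------
* signal CSV: comma-separated, '.' decimal, one numeric column (optional
  single header line) or two columns ``time, value`` with uniform spacing;
* force CSV: two columns ``time_s, force`` at a nominal 10 Hz;
* WAV: mono PCM or float, amplitudes treated as dimensionless (the training
  standardization removes any scale anyway);
* model bundle: a single ``.npz`` archive holding the named numeric arrays
  of the trained decomposition plus a JSON metadata block — one artifact,
  matching the deployment story of downloading the sparse inverse to an
  embedded controller.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Recording",
    "ForceTrace",
    "PipelineConfig",
    "ModelBundle",
    "read_recording",
    "write_recording",
    "read_force_csv",
    "write_force_csv",
    "read_model",
    "write_model",
    "load_config",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class Recording:
    """A single-channel voltage time series.

    Parameters
    ----------
    samples : ndarray
        Signal values in arbitrary voltage units.
    rate_hz : float
        Sampling rate; the portable acquisition setting modelled here is
        16 kHz.
    channel_label : str
        Free-text channel description.
    """

    samples: np.ndarray
    rate_hz: float = 16000.0
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError(
                f"Recording holds exactly one channel; got shape {self.samples.shape}"
            )
        if self.samples.size == 0:
            raise ValueError("Recording must contain at least one sample")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def slice_time(self, t0_s: float, t1_s: float) -> "Recording":
        """Return the sub-recording covering ``[t0_s, t1_s)``."""
        i0 = int(round(t0_s * self.rate_hz))
        i1 = int(round(t1_s * self.rate_hz))
        return Recording(self.samples[i0:i1], self.rate_hz, self.channel_label)


@dataclass
class ForceTrace:
    """A measured or estimated force time series (nominally 10 Hz)."""

    times: np.ndarray
    values: np.ndarray
    rate_hz: float = 10.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class PipelineConfig:
    """All tunables of the decomposition pipeline with their defaults.

    Defaults follow the published operating point: a 100–3000 Hz band-pass,
    a 120x800 segment matrix (0.05 s segments at 16 kHz), k=100 basis
    vectors, sparsity penalty 0.01, a 4-sigma spike threshold, 100-sample
    (6.25 ms) spikes, cluster counts searched over 5..20, activation
    constant c=0.34, and 0.05 s analysis / 0.5 s reporting windows.
    """

    rate_hz: float = 16000.0
    band_low_hz: float = 100.0
    band_high_hz: float = 3000.0
    filter_order: int = 4
    m: int = 120
    n: int = 800
    k: int = 100
    lambda_penalty: float = 0.01
    rica_max_iter: int = 3000
    rica_tol: float = 1e-6
    threshold_multiplier: float = 4.0
    spike_length: int = 100
    cluster_min: int = 5
    cluster_max: int = 20
    n_fourier_coeffs: int = 20
    activation_threshold: float = 0.34
    window_s: float = 0.05
    report_s: float = 0.5

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ModelBundle:
    """The serializable product of training: everything needed to decompose
    new signal windows and estimate force.

    ``sparse_basis`` is the sparse matrix *s* (one row per retained spike,
    the 100-sample spike window replaced by the cluster representative and
    zeros elsewhere); ``inverse_basis`` is its LSQR-approximated
    pseudo-inverse, the object an embedded controller would run.
    """

    sparse_basis: np.ndarray        # (k_active, n)
    inverse_basis: np.ndarray       # (n, k_active)
    transform: np.ndarray           # (k, m), the learned W
    row_cluster: np.ndarray         # (k_active,) cluster label per sparse row
    spike_rows: np.ndarray          # (k_active,) basis-vector index per row
    spike_peaks: np.ndarray         # (k_active,) peak sample within the basis vector
    representatives: np.ndarray     # (L, spike_length)
    noise_sigma: float
    activation_threshold: float = 0.34
    threshold_multiplier: float = 4.0
    scale_phi: float = 1.0
    cluster_count: int = 0
    train_mean: float = 0.0
    train_scale: float = 1.0
    inverse_residual: float = np.nan
    normalized: bool = False
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        self.sparse_basis = np.atleast_2d(np.asarray(self.sparse_basis, dtype=float))
        self.inverse_basis = np.atleast_2d(np.asarray(self.inverse_basis, dtype=float))
        self.row_cluster = np.asarray(self.row_cluster, dtype=int)
        self.spike_rows = np.asarray(self.spike_rows, dtype=int)
        self.spike_peaks = np.asarray(self.spike_peaks, dtype=int)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.k_active and self.inverse_basis.shape[1] != self.k_active:
            raise ValueError(
                "inverse_basis column count "
                f"({self.inverse_basis.shape[1]}) must equal the number of "
                f"active sparse-basis rows ({self.k_active})"
            )
        if self.degenerate:
            warnings.warn(
                "ModelBundle has zero active rows (no retained spikes); "
                "force estimates will be identically zero",
                stacklevel=2,
            )
        elif not 5 <= self.cluster_count <= 20:
            warnings.warn(
                f"cluster_count {self.cluster_count} lies outside the usual "
                "physiological search range 5..20",
                stacklevel=2,
            )

    @property
    def k_active(self) -> int:
        if self.sparse_basis.size == 0:
            return 0
        return self.sparse_basis.shape[0]

    @property
    def degenerate(self) -> bool:
        return self.k_active == 0 or self.sparse_basis.size == 0


# ---------------------------------------------------------------------------
# recordings


def _scan_csv_rows(path: Path) -> np.ndarray:
    """Slow fallback parse that pinpoints the first bad row."""
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for idx, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                if idx == 0:
                    continue  # single header line is allowed
                raise ValueError(
                    f"non-numeric value at row {idx} of {path}: {line!r}"
                ) from None
    if not rows:
        raise ValueError(f"{path} contains no numeric rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        bad = next(i for i, r in enumerate(rows) if len(r) != width)
        raise ValueError(f"inconsistent column count at data row {bad} of {path}")
    return np.asarray(rows, dtype=float)


def _load_csv(path: Path) -> np.ndarray:
    try:
        return np.atleast_2d(np.loadtxt(path, delimiter=",", ndmin=2))
    except ValueError:
        pass
    try:
        return np.atleast_2d(np.loadtxt(path, delimiter=",", ndmin=2, skiprows=1))
    except ValueError:
        pass
    return _scan_csv_rows(path)


def read_recording(path, format: str | None = None, rate_hz: float = 16000.0) -> Recording:
    """Read a one-channel recording from CSV or WAV.

    CSV may hold one numeric column (samples at ``rate_hz``) or two columns
    ``time, value`` whose spacing must match ``1/rate_hz``. WAV must be
    mono; its embedded sampling rate is used.
    """
    path = Path(path)
    if format is None:
        format = "wav" if path.suffix.lower() == ".wav" else "csv"
    if format == "wav":
        rate, data = wavfile.read(path)
        data = np.asarray(data)
        if data.ndim != 1:
            raise ValueError(
                f"multi-channel WAV not supported: {path} has "
                f"{data.shape[1]} channels"
            )
        return Recording(data.astype(float), float(rate), channel_label=path.stem)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'wav'")

    arr = _load_csv(path)
    if arr.shape[1] == 1:
        return Recording(arr[:, 0], rate_hz, channel_label=path.stem)
    if arr.shape[1] == 2:
        times, values = arr[:, 0], arr[:, 1]
        if times.size > 1:
            dt = np.diff(times)
            if not np.allclose(dt, 1.0 / rate_hz, rtol=1e-4, atol=1e-9):
                raise ValueError(
                    f"time column of {path} is not uniformly spaced at "
                    f"{rate_hz} Hz (observed mean step {dt.mean():.6g} s)"
                )
        return Recording(values, rate_hz, channel_label=path.stem)
    raise ValueError(
        f"multi-channel input rejected: {path} has {arr.shape[1]} columns, "
        "expected 1 (value) or 2 (time,value)"
    )


def write_recording(rec: Recording, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "wav" if path.suffix.lower() == ".wav" else "csv"
    if format == "wav":
        wavfile.write(path, int(round(rec.rate_hz)), rec.samples.astype(np.float32))
    elif format == "csv":
        np.savetxt(path, rec.samples, fmt="%.10g")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_force_csv(path) -> ForceTrace:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"force CSV {path} needs two columns (time_s, force)")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(times))) if times.size > 1 else 10.0
    return ForceTrace(times, df.iloc[:, 1].to_numpy(dtype=float), rate_hz=rate)


def write_force_csv(trace: ForceTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "force": trace.values}).to_csv(
        path, index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# model bundle


_BUNDLE_ARRAYS = (
    "sparse_basis",
    "inverse_basis",
    "transform",
    "row_cluster",
    "spike_rows",
    "spike_peaks",
    "representatives",
)
_BUNDLE_SCALARS = (
    "noise_sigma",
    "activation_threshold",
    "threshold_multiplier",
    "scale_phi",
    "cluster_count",
    "train_mean",
    "train_scale",
    "inverse_residual",
    "normalized",
)


def write_model(bundle: ModelBundle, path) -> None:
    """Serialize a trained bundle to a single ``.npz`` archive."""
    meta = {name: getattr(bundle, name) for name in _BUNDLE_SCALARS}
    meta["config"] = dataclasses.asdict(bundle.config)
    meta["format_version"] = MODEL_FORMAT_VERSION
    arrays = {name: getattr(bundle, name) for name in _BUNDLE_ARRAYS}
    np.savez(path, meta_json=np.array(json.dumps(meta)), **arrays)


def read_model(path) -> ModelBundle:
    """Load a bundle written by :func:`write_model`.

    Raises a descriptive error on container-version mismatch or a corrupt
    archive rather than returning silent garbage.
    """
    try:
        with np.load(path, allow_pickle=False) as npz:
            if "meta_json" not in npz:
                raise ValueError(f"{path} is not a muforce model archive")
            meta = json.loads(str(npz["meta_json"]))
            arrays = {name: npz[name] for name in _BUNDLE_ARRAYS}
    except (zipfile.BadZipFile, OSError, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupt or unreadable model archive {path}: {exc}") from exc
    found = meta.get("format_version")
    if found != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model archive version mismatch: expected {MODEL_FORMAT_VERSION}, "
            f"found {found}"
        )
    cfg = PipelineConfig(**meta.pop("config"))
    meta.pop("format_version")
    meta["normalized"] = bool(meta["normalized"])
    meta["cluster_count"] = int(meta["cluster_count"])
    return ModelBundle(config=cfg, **arrays, **meta)


# ---------------------------------------------------------------------------
# configuration


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a flat ``key = value`` file.

    Unknown keys raise an error listing the valid keys; missing keys keep
    their defaults. ``overrides`` apply after the file.
    """
    valid = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    values: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            for idx, raw in enumerate(fh):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed config line {idx}: {raw!r}")
                key, val = (part.strip() for part in line.split("=", 1))
                if key not in valid:
                    raise ValueError(
                        f"unknown config key {key!r}; valid keys: "
                        + ", ".join(sorted(valid))
                    )
                values[key] = val
    for key in overrides:
        if key not in valid:
            raise ValueError(
                f"unknown config key {key!r}; valid keys: " + ", ".join(sorted(valid))
            )
    cfg = PipelineConfig()
    typed: dict = {}
    for key, val in values.items():
        target = type(getattr(cfg, key))
        typed[key] = target(float(val)) if target in (int, float) else target(val)
    typed.update(overrides)
    return dataclasses.replace(cfg, **typed)
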