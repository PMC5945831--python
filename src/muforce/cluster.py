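"""MUAP shape clustering and construction of the sparse basis.

Spike shape is summarized by the magnitudes of the first DFT coefficients
of the 100-sample waveform (phase discarded, so small alignment jitter
does not dominate the distance). K-means groups the spikes; the cluster
count L is chosen over a physiological range (5..20 by default) by a grid
search on a silhouette-based score,

    score(L) = #{ l : mean silhouette of cluster l > overall mean } / L,

with ties broken toward the smaller L. The most representative waveform of
each cluster is the time-domain mean of its members. The sparse basis s
keeps, for every basis vector that yielded a retained spike, only the
100-sample spike window — filled with the cluster representative — and
zeros elsewhere. Rows without spikes would be identically zero and make
the system singular, so they are dropped (the row-to-basis-vector map is
kept). The pseudo-inverse of s is approximated column-by-column with LSQR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as spsparse
from scipy.sparse.linalg import lsqr
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .muap import MuapSpike
from .rica import BasisModel

__all__ = [
    "ClusterModel",
    "SparseBasis",
    "shape_features",
    "silhouette_grid_score",
    "select_cluster_count",
    "cluster_muaps",
    "build_sparse_basis",
    "invert_sparse_basis",
]


@dataclass
class ClusterModel:
    L: int
    labels: np.ndarray
    representatives: np.ndarray          # (L, spike_length)
    score: float
    silhouette_by_cluster: np.ndarray
    mean_silhouette: float


@dataclass
class SparseBasis:
    """Sparse form s of the basis plus bookkeeping for decoding."""

    s: np.ndarray                        # (k_active, n)
    row_cluster: np.ndarray              # (k_active,)
    spike_rows: np.ndarray               # basis-vector index per row
    spike_peaks: np.ndarray              # peak sample per row
    inverse: np.ndarray | None = field(default=None)

    @property
    def k_active(self) -> int:
        return self.s.shape[0]


def shape_features(
    spike: MuapSpike | np.ndarray, n_coeffs: int = 20, normalize: bool = True
) -> np.ndarray:
    """Magnitudes of DFT bins 0..n_coeffs-1 of the spike waveform.

    ``normalize`` scales the waveform to unit peak first: spikes from
    different basis vectors carry arbitrary scale, and shape — not basis
    scale — is what distinguishes motor units. Phase is discarded so small
    alignment jitter does not dominate the distance.
    """
    waveform = spike.waveform if isinstance(spike, MuapSpike) else np.asarray(spike, float)
    if n_coeffs > waveform.size // 2:
        raise ValueError(
            f"n_coeffs={n_coeffs} exceeds the Nyquist bin "
            f"({waveform.size // 2}) of a {waveform.size}-sample frame"
        )
    if normalize:
        peak = np.abs(waveform).max()
        if peak > 0:
            waveform = waveform / peak
    return np.abs(np.fft.rfft(waveform))[:n_coeffs]


def feature_matrix(spikes: list[MuapSpike], n_coeffs: int = 20) -> np.ndarray:
    return np.vstack([shape_features(sp, n_coeffs) for sp in spikes])


def _kmeans(features: np.ndarray, L: int, seed: int) -> KMeans:
    return KMeans(n_clusters=L, n_init=10, random_state=seed).fit(features)


def silhouette_grid_score(features: np.ndarray, L: int, seed: int = 0) -> float:
    """Fraction of clusters whose mean silhouette exceeds the overall mean."""
    features = np.asarray(features, dtype=float)
    if L < 2:
        raise ValueError("need at least 2 clusters to score")
    if features.shape[0] <= L:
        raise ValueError(
            f"need more spikes ({features.shape[0]}) than clusters ({L})"
        )
    labels = _kmeans(features, L, seed).labels_
    if len(np.unique(labels)) < 2:
        return 0.0
    sil = silhouette_samples(features, labels)
    overall = sil.mean()
    above = sum(sil[labels == l].mean() > overall for l in range(L))
    return above / L


def select_cluster_count(
    features: np.ndarray, L_min: int = 5, L_max: int = 20, seed: int = 0
) -> int:
    """Grid-search L maximizing the silhouette score; ties -> smaller L."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n <= L_max:
        L_max_eff = n - 1
        warnings.warn(
            f"only {n} spikes: truncating cluster search range to "
            f"[{L_min}, {L_max_eff}]",
            stacklevel=2,
        )
    else:
        L_max_eff = L_max
    if L_max_eff < max(2, L_min):
        raise ValueError(f"too few spikes ({n}) to search clusters >= {L_min}")
    best_L, best_score = None, -np.inf
    for L in range(max(2, L_min), L_max_eff + 1):
        score = silhouette_grid_score(features, L, seed=seed)
        if score > best_score:          # strict: ties keep the smaller L
            best_L, best_score = L, score
    if best_L is None:
        raise ValueError("no valid cluster count found")
    return best_L


def cluster_muaps(
    spikes: list[MuapSpike],
    features: np.ndarray,
    L: int,
    seed: int = 0,
    representative: str = "mean",
) -> ClusterModel:
    """K-means in feature space; representatives in the time domain.

    The representative r_l is the mean of the member waveforms (medoid mode
    available). Because every member has its positive absolute peak at
    index 49, the mean inherits a positive peak at index 49.
    """
    features = np.asarray(features, dtype=float)
    waveforms = np.vstack([sp.waveform for sp in spikes])
    if len(np.unique(waveforms, axis=0)) == 1:
        # single effective cluster: every representative is that waveform
        warnings.warn("all spikes identical: clustering is degenerate", stacklevel=2)
        reps = np.tile(waveforms[0], (L, 1))
        return ClusterModel(
            L=L,
            labels=np.zeros(len(spikes), dtype=int),
            representatives=reps,
            score=0.0,
            silhouette_by_cluster=np.zeros(L),
            mean_silhouette=0.0,
        )
    for attempt in range(2):
        km = _kmeans(features, L, seed + attempt)
        labels = km.labels_
        counts = np.bincount(labels, minlength=L)
        if counts.min() > 0:
            break
    else:
        raise RuntimeError("K-means produced an empty cluster after re-seeding")

    reps = np.empty((L, waveforms.shape[1]))
    for l in range(L):
        members = waveforms[labels == l]
        if representative == "mean":
            reps[l] = members.mean(axis=0)
        elif representative == "medoid":
            centroid = members.mean(axis=0)
            reps[l] = members[np.argmin(np.linalg.norm(members - centroid, axis=1))]
        else:
            raise ValueError(f"unknown representative mode {representative!r}")

    if len(np.unique(labels)) < 2 or features.shape[0] <= L:
        sil = np.zeros(len(labels))
    else:
        sil = silhouette_samples(features, labels)
    overall = float(sil.mean())
    by_cluster = np.array([sil[labels == l].mean() for l in range(L)])
    score = float(np.sum(by_cluster > overall) / L)
    return ClusterModel(
        L=L,
        labels=labels,
        representatives=reps,
        score=score,
        silhouette_by_cluster=by_cluster,
        mean_silhouette=overall,
    )


def build_sparse_basis(
    basis: BasisModel, spikes: list[MuapSpike], clusters: ClusterModel
) -> SparseBasis:
    """Replace each retained spike window with its cluster representative.

    One row per retained spike: zeros everywhere except the 100-sample
    window at the spike's detected location, which holds r_l of the
    spike's cluster.
    """
    n = basis.b.shape[1]
    spike_length = clusters.representatives.shape[1]
    pre = spike_length // 2 - 1
    k_active = len(spikes)
    s = np.zeros((k_active, n))
    row_cluster = np.empty(k_active, dtype=int)
    spike_rows = np.empty(k_active, dtype=int)
    spike_peaks = np.empty(k_active, dtype=int)
    for j, (sp, label) in enumerate(zip(spikes, clusters.labels)):
        start = sp.peak_offset - pre
        s[j, start : start + spike_length] = clusters.representatives[label]
        row_cluster[j] = label
        spike_rows[j] = sp.source_row
        spike_peaks[j] = sp.peak_offset
    return SparseBasis(
        s=s, row_cluster=row_cluster, spike_rows=spike_rows, spike_peaks=spike_peaks
    )


def invert_sparse_basis(
    s: SparseBasis | np.ndarray, tol: float = 1e-10, max_iter: int | None = None
) -> np.ndarray:
    """Approximate pseudo-inverse of s, column-by-column via LSQR.

    Column j is the minimum-norm least-squares solution of ``s v = e_j``,
    i.e. the j-th coordinate functional. For mutually orthogonal rows this
    reduces to s^T diag(1/||s_i||^2).
    """
    mat = s.s if isinstance(s, SparseBasis) else np.atleast_2d(np.asarray(s, float))
    k_active, n = mat.shape
    if k_active < 1:
        raise ValueError("sparse basis has no rows to invert")
    A = spsparse.csr_matrix(mat)
    iter_lim = max_iter if max_iter is not None else 8 * n
    inverse = np.empty((n, k_active))
    for j in range(k_active):
        e = np.zeros(k_active)
        e[j] = 1.0
        sol = lsqr(A, e, atol=tol, btol=tol, iter_lim=iter_lim)
        v, istop = sol[0], sol[1]
        if istop == 7:
            resid = np.linalg.norm(A @ v - e)
            raise RuntimeError(
                f"LSQR did not converge for column {j} within {iter_lim} "
                f"iterations (residual {resid:.3g})"
            )
        inverse[:, j] = v
    if isinstance(s, SparseBasis):
        s.inverse = inverse
    return inverse


def inverse_residual(s: np.ndarray, inverse: np.ndarray) -> float:
    """max |s @ inverse - I|, the decoding-consistency diagnostic."""
    k = s.shape[0]
    return float(np.abs(s @ inverse - np.eye(k)).max())
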