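import numpy as np
import pytest

from muforce.cluster import (
    build_sparse_basis,
    cluster_muaps,
    feature_matrix,
    invert_sparse_basis,
    inverse_residual,
    select_cluster_count,
    shape_features,
    silhouette_grid_score,
)
from muforce.muap import MuapSpike
from muforce.rica import BasisModel


def _naive_dft_magnitudes(w, n_coeffs):
    """O(N^2) direct-summation DFT oracle."""
    N = len(w)
    out = np.zeros(n_coeffs)
    for f in range(n_coeffs):
        re = sum(w[t] * np.cos(2 * np.pi * f * t / N) for t in range(N))
        im = -sum(w[t] * np.sin(2 * np.pi * f * t / N) for t in range(N))
        out[f] = np.hypot(re, im)
    return out


def _naive_silhouette(X, labels):
    """Brute-force per-sample silhouette coefficients."""
    n = len(X)
    out = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            out[i] = 0.0
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(n) if labels[j] == l])
            for l in set(labels) - {labels[i]}
        )
        out[i] = (b - a) / max(a, b)
    return out


def _spike(waveform):
    return MuapSpike(waveform=waveform, source_row=0, peak_offset=400, flipped=False)


class TestShapeFeatures:
    def test_zero_waveform(self):
        np.testing.assert_array_equal(shape_features(_spike(np.zeros(100))), 0)

    def test_pure_cosine_single_bin(self):
        t = np.arange(100)
        feats = shape_features(_spike(np.cos(2 * np.pi * 3 * t / 100)), normalize=False)
        assert np.argmax(feats) == 3
        others = np.delete(feats, 3)
        assert np.all(others < 1e-9 * feats[3] + 1e-9)

    def test_matches_naive_dft(self, rng):
        w = rng.standard_normal(100)
        feats = shape_features(_spike(w), n_coeffs=20, normalize=False)
        np.testing.assert_allclose(feats, _naive_dft_magnitudes(w, 20), atol=1e-9)

    def test_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            shape_features(_spike(np.zeros(100)), n_coeffs=51)


class TestSilhouetteScore:
    def test_score_matches_brute_force_on_planted_points(self):
        # two tight blobs and one diffuse blob in 2-D
        X = np.array(
            [
                [0.0, 0.0], [0.1, 0.0], [0.0, 0.1],
                [10.0, 0.0], [10.1, 0.0], [10.0, 0.1],
                [0.0, 30.0], [6.0, 36.0], [12.0, 30.0],
            ]
        )
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        sil = _naive_silhouette(X, labels)
        overall = sil.mean()
        expected = sum(sil[labels == l].mean() > overall for l in range(3)) / 3
        got = silhouette_grid_score(X, 3, seed=0)
        assert got == pytest.approx(expected)
        assert expected == pytest.approx(2 / 3)  # the diffuse blob falls below

    def test_score_bounded(self, rng):
        X = rng.standard_normal((30, 4))
        for L in (2, 5, 9):
            assert 0.0 <= silhouette_grid_score(X, L, seed=0) <= 1.0

    def test_more_clusters_than_spikes_rejected(self, rng):
        with pytest.raises(ValueError, match="more spikes"):
            silhouette_grid_score(rng.standard_normal((4, 3)), 5)


def _planted_features(G, per=12, d=20, sep=30.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = sep * rng.standard_normal((G, d))
    return np.vstack([c + rng.standard_normal((per, d)) for c in centers])


class TestSelectClusterCount:
    def test_argmax_contract_with_brute_force(self):
        """Selection is the argmax of the count-above-mean silhouette score
        over the grid, ties broken toward the smaller cluster count; checked
        against an independent brute-force recomputation of every score."""
        feats = _planted_features(6, per=8, seed=2)
        from muforce.cluster import _kmeans

        best_L, best = None, -np.inf
        for L in range(5, 21):
            labels = _kmeans(feats, L, seed=3).labels_
            sil = _naive_silhouette(feats, labels)
            score = sum(sil[labels == l].mean() > sil.mean() for l in range(L)) / L
            if score > best:
                best_L, best = L, score
        assert select_cluster_count(feats, seed=3) == best_L

    def test_selection_lands_inside_search_range(self):
        for seed in range(5):
            feats = _planted_features(5 + seed, seed=seed)
            assert 5 <= select_cluster_count(feats, seed=seed) <= 20

    def test_truncation_warns_with_few_spikes(self):
        feats = _planted_features(2, per=3, seed=1)  # 6 spikes
        with pytest.warns(UserWarning, match="truncating"):
            L = select_cluster_count(feats, seed=0)
        assert L <= 5


def _template_family_spikes(seed=0, per=15):
    """Two distinct waveform families with small jitter, peak at index 49."""
    rng = np.random.default_rng(seed)
    t = np.arange(100)
    base1 = np.exp(-0.5 * ((t - 49) / 3.0) ** 2)
    base2 = np.exp(-0.5 * ((t - 49) / 3.0) ** 2) * np.cos(2 * np.pi * (t - 49) / 25)
    spikes = []
    for i in range(per):
        for base in (base1, base2):
            w = base + 0.02 * rng.standard_normal(100)
            w[49] = max(w[49], np.abs(w).max() + 1e-6)  # keep peak at 49
            spikes.append(_spike(w))
    return spikes, (base1, base2)


class TestClusterMuaps:
    def test_planted_families_recovered(self):
        spikes, (b1, b2) = _template_family_spikes()
        feats = feature_matrix(spikes)
        cm = cluster_muaps(spikes, feats, L=2, seed=0)
        for rep in cm.representatives:
            best = max(
                abs(np.corrcoef(rep, b1)[0, 1]), abs(np.corrcoef(rep, b2)[0, 1])
            )
            assert best > 0.95
            assert rep.size == 100
            assert np.argmax(np.abs(rep)) == 49
            assert rep[49] > 0

    def test_identical_spikes_degenerate_warning(self):
        w = np.exp(-0.5 * ((np.arange(100) - 49) / 3.0) ** 2)
        spikes = [_spike(w.copy()) for _ in range(10)]
        feats = feature_matrix(spikes)
        with pytest.warns(UserWarning, match="identical"):
            cm = cluster_muaps(spikes, feats, L=2, seed=0)
        for rep in cm.representatives:
            np.testing.assert_allclose(rep, w, atol=1e-12)

    def test_representatives_permutation_stable(self):
        spikes, _ = _template_family_spikes()
        feats = feature_matrix(spikes)
        a = cluster_muaps(spikes, feats, L=2, seed=0)
        b = cluster_muaps(spikes, feats, L=2, seed=41)
        got = {tuple(np.round(r, 9)) for r in a.representatives}
        other = {tuple(np.round(r, 9)) for r in b.representatives}
        assert got == other


class TestSparseBasis:
    def _basis_and_spikes(self, peaks=(400,), n=800, seed=0):
        rng = np.random.default_rng(seed)
        k = len(peaks)
        basis = BasisModel(W=np.eye(k), b=rng.standard_normal((k, n)))
        spikes = [
            MuapSpike(
                waveform=np.exp(-0.5 * ((np.arange(100) - 49) / (2.0 + i)) ** 2),
                source_row=i,
                peak_offset=p,
                flipped=False,
            )
            for i, p in enumerate(peaks)
        ]
        return basis, spikes

    def test_window_placement(self):
        basis, spikes = self._basis_and_spikes(peaks=(400,))
        feats = feature_matrix(spikes + spikes)  # duplicate to allow L=1 k-means
        cm = cluster_muaps(spikes + spikes, feats, L=1, seed=0)
        sb = build_sparse_basis(basis, spikes, cm)
        row = sb.s[0]
        assert np.all(row[:351] == 0)
        assert np.all(row[451:] == 0)
        np.testing.assert_array_equal(row[351:451], cm.representatives[0])

    def test_row_count_matches_spikes(self):
        basis, spikes = self._basis_and_spikes(peaks=(100, 300, 500, 700))
        feats = feature_matrix(spikes)
        cm = cluster_muaps(spikes, feats, L=2, seed=0)
        sb = build_sparse_basis(basis, spikes, cm)
        assert sb.s.shape == (4, 800)
        assert np.all((sb.s != 0).sum(axis=1) <= 100)


class TestInverse:
    def test_orthogonal_rows_closed_form(self, rng):
        s = np.zeros((4, 800))
        for i, p in enumerate((100, 300, 500, 700)):
            s[i, p - 49 : p + 51] = rng.standard_normal(100)
        inv = invert_sparse_basis(s)
        closed = s.T / (s**2).sum(axis=1)
        np.testing.assert_allclose(inv, closed, atol=1e-8)
        assert inverse_residual(s, inv) < 1e-6

    def test_row_space_consistency(self, rng):
        s = np.zeros((3, 800))
        for i, p in enumerate((100, 400, 700)):
            s[i, p - 49 : p + 51] = rng.standard_normal(100)
        inv = invert_sparse_basis(s)
        coords = (2.0 * s[1]) @ inv
        np.testing.assert_allclose(coords, 2.0 * np.eye(3)[1], atol=1e-8)

    def test_matches_dense_pseudo_inverse(self, rng):
        s = rng.standard_normal((5, 800)) * (rng.random((5, 800)) < 0.1)
        inv = invert_sparse_basis(s, tol=1e-12)
        np.testing.assert_allclose(inv, np.linalg.pinv(s), atol=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no rows"):
            invert_sparse_basis(np.zeros((0, 800)))
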