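"""Spatial filter, windowed SVD, thresholding, end-to-end delineation."""

import numpy as np
import pytest

from sefmap.evoked import Evoked
from sefmap.geometry import Parcellation, SourceSpace
from sefmap.inverse import SourceEstimate, apply_sloreta
from sefmap.localize import (
    dominant_modes,
    localize_patient,
    peak_activation_time,
    spatial_filter,
    svd_window,
    threshold_region,
)


def _stc(values, times=None):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.shape[1], dtype=float) if times is None else times
    return SourceEstimate(values=values, times=t)


def _toy_space(positions):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return SourceSpace(
        positions=positions,
        orientations=np.tile([0.0, 0.0, 1.0], (n, 1)),
        hemispheres=np.full(n, "left", dtype=object),
        vertex_ids=np.arange(n),
    )


def _toy_parc(labels, names=None):
    labels = np.asarray(labels)
    table = {0: ("other", "both")}
    for lid in np.unique(labels):
        if lid != 0:
            name = names[lid] if names else "postcentral_gyrus"
            table[int(lid)] = (name, "left")
    return Parcellation(labels, table)


class TestSpatialFilter:
    def test_zero_radius_is_identity(self, wb3):
        rng = np.random.default_rng(0)
        stc = _stc(rng.normal(size=(wb3.model.source_space.n_sources, 4)))
        out = spatial_filter(stc, wb3.model.source_space, wb3.model.parcellation, radius=0.0)
        assert np.array_equal(out.values, stc.values)

    def test_spatially_constant_unchanged(self, wb3):
        n = wb3.model.source_space.n_sources
        stc = _stc(np.tile(np.sin(np.arange(5.0)), (n, 1)))
        out = spatial_filter(stc, wb3.model.source_space, wb3.model.parcellation)
        assert np.allclose(out.values, stc.values, atol=1e-12)

    def test_isolated_label_untouched(self):
        # one source with a unique label has no same-label neighbours in range
        pos = [[0, 0, 0], [2, 0, 0], [4, 0, 0]]
        ss = _toy_space(pos)
        parc = _toy_parc([1, 2, 2], names={1: "central_sulcus", 2: "postcentral_gyrus"})
        stc = _stc([[5.0, 1.0], [1.0, 1.0], [3.0, 1.0]])
        out = spatial_filter(stc, ss, parc, radius=5.0)
        assert np.allclose(out.values[0], [5.0, 1.0])  # label-isolated
        assert np.allclose(out.values[1], [2.0, 1.0])  # mean of sources 1 and 2

    def test_averaging_reduces_noise_variance(self, wb3):
        rng = np.random.default_rng(1)
        n = wb3.model.source_space.n_sources
        stc = _stc(rng.normal(size=(n, 3)))
        out = spatial_filter(stc, wb3.model.source_space, wb3.model.parcellation)
        assert out.values.std() < stc.values.std()


class TestSvdWindow:
    def test_rank_one_identity(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=60)
        a /= np.linalg.norm(a)
        b = rng.normal(size=46)
        b /= np.linalg.norm(b)
        X = 7.0 * np.outer(a, b)
        stc = _stc(X, times=15.0 + np.arange(46.0))
        svd = svd_window(stc, (15.0, 60.0))
        assert svd.S[0] == pytest.approx(7.0, rel=1e-12)
        assert np.allclose(svd.S[1:], 0.0, atol=1e-10)
        sign = np.sign(np.dot(svd.U[:, 0], a))
        assert np.allclose(sign * svd.U[:, 0], a, atol=1e-10)
        assert np.allclose(sign * svd.V[:, 0], b, atol=1e-10)

    def test_reconstruction_and_orthonormality(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 46))
        stc = _stc(X, times=15.0 + np.arange(46.0))
        svd = svd_window(stc, (15.0, 60.0))
        recon = svd.U @ np.diag(svd.S) @ svd.V.T
        assert np.linalg.norm(recon - X) / np.linalg.norm(X) < 1e-10
        assert np.allclose(svd.U.T @ svd.U, np.eye(46), atol=1e-10)
        assert np.allclose(svd.V.T @ svd.V, np.eye(46), atol=1e-10)
        assert (np.diff(svd.S) <= 1e-12).all()

    def test_sign_convention_temporal_peak_positive(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 10))
        svd = svd_window(_stc(X), (0.0, 9.0))
        for k in range(svd.V.shape[1]):
            i = np.argmax(np.abs(svd.V[:, k]))
            assert svd.V[i, k] > 0

    def test_variance_fractions_match_eigensolver(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            X = rng.normal(size=(40, 12))
            svd = svd_window(_stc(X), (0.0, 11.0))
            evals = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
            assert np.allclose(svd.variance_fractions(), evals / evals.sum(), atol=1e-10)

    def test_wide_matrix_rejected(self):
        with pytest.raises(ValueError):
            svd_window(_stc(np.zeros((5, 10))), (0.0, 9.0))


class TestDominantModes:
    def test_rank_one_variance_fraction_is_one(self):
        X = np.outer(np.ones(20), np.arange(1.0, 5.0))
        u1, v1, frac = dominant_modes(svd_window(_stc(X), (0.0, 3.0)))
        assert frac == pytest.approx(1.0, abs=1e-12)

    def test_equal_singular_values_split_half(self):
        X = np.zeros((10, 2))
        X[0, 0] = 3.0
        X[1, 1] = 3.0
        u1, v1, frac = dominant_modes(svd_window(_stc(X), (0.0, 1.0)))
        assert frac == pytest.approx(0.5, abs=1e-12)


class TestThresholdRegion:
    def test_rule_application(self):
        ss = _toy_space([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        parc = _toy_parc([0, 0, 0])
        region = threshold_region(np.array([1.0, 0.9, 0.79]), parc, ss, threshold=0.8)
        assert region.members.tolist() == [0, 1]

    def test_threshold_one_keeps_argmax_and_ties(self):
        ss = _toy_space([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        parc = _toy_parc([0, 0, 0, 0])
        region = threshold_region(np.array([0.5, -1.0, 1.0, 0.2]), parc, ss, threshold=1.0)
        assert region.members.tolist() == [1, 2]  # |.| ties included

    def test_tiny_threshold_keeps_all_nonzero(self):
        ss = _toy_space([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        parc = _toy_parc([0, 0, 0])
        region = threshold_region(np.array([0.4, 0.0, -0.2]), parc, ss, threshold=1e-9)
        assert region.members.tolist() == [0, 2]

    def test_all_zero_rejected(self):
        ss = _toy_space([[0, 0, 0]])
        with pytest.raises(ValueError):
            threshold_region(np.zeros(1), _toy_parc([0]), ss)

    def test_centroid_and_label(self):
        ss = _toy_space([[0, 0, 0], [2, 0, 0], [10, 0, 0]])
        parc = _toy_parc([1, 1, 0], names={1: "central_sulcus"})
        region = threshold_region(np.array([1.0, 1.0, 0.01]), parc, ss, threshold=0.5)
        assert np.allclose(region.centroid, [1.0, 0.0, 0.0])
        assert region.centroid_vertex == 0  # tie at distance 1 -> lowest index
        assert region.centroid_label == "central_sulcus"


class TestPeakActivationTime:
    def test_one_hot(self):
        times = 15.0 + np.arange(46.0)
        v1 = np.zeros(46)
        v1[18] = 1.0  # 33 ms
        assert peak_activation_time(v1, times) == 33.0

    def test_sign_invariant(self):
        times = 15.0 + np.arange(46.0)
        v1 = np.zeros(46)
        v1[10] = -2.0
        assert peak_activation_time(v1, times) == peak_activation_time(-v1, times) == 25.0

    def test_constant_ties_to_window_start(self):
        times = 15.0 + np.arange(46.0)
        assert peak_activation_time(np.ones(46), times) == 15.0


class TestLocalizePatient:
    def test_noiseless_recovery_within_truth_neighborhood(self, wb3, noiseless_patient):
        _, truth, evoked, inv = noiseless_patient
        region = localize_patient(evoked, inv, wb3.model)
        from scipy.spatial import cKDTree

        pos = wb3.model.source_space.positions
        d, _ = cKDTree(pos[truth.patch]).query(pos[region.members])
        assert d.max() <= 5.0
        inter = len(np.intersect1d(region.members, truth.patch))
        union = len(np.union1d(region.members, truth.patch))
        # the 80% threshold keeps the focal core of the patch: high precision,
        # modest Jaccard (bounded above by region size / patch size)
        assert inter / region.size >= 0.8
        assert inter / union >= 0.2
        assert 15.0 <= region.peak_time <= 60.0

    def test_deterministic(self, wb3, noiseless_patient):
        _, _, evoked, inv = noiseless_patient
        r1 = localize_patient(evoked, inv, wb3.model)
        r2 = localize_patient(evoked, inv, wb3.model)
        assert np.array_equal(r1.members, r2.members)
        assert r1.peak_time == r2.peak_time

    def test_scale_and_sign_invariance(self, wb3, noiseless_patient):
        _, _, evoked, inv = noiseless_patient
        base = localize_patient(evoked, inv, wb3.model)
        for factor in (10.0, -1.0):
            ev = Evoked(data=factor * evoked.data, times=evoked.times,
                        n_ave=evoked.n_ave, ch_kinds=evoked.ch_kinds)
            got = localize_patient(ev, inv, wb3.model)
            assert np.array_equal(got.members, base.members)
            assert got.peak_time == base.peak_time

    def test_member_count_monotone_in_threshold(self, wb3, noiseless_patient):
        _, _, evoked, inv = noiseless_patient
        sizes = [
            localize_patient(evoked, inv, wb3.model, threshold=th).size
            for th in np.arange(0.5, 1.01, 0.1)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_quantile_semantics_also_monotone(self, wb3, noiseless_patient):
        _, _, evoked, inv = noiseless_patient
        r_lo = localize_patient(evoked, inv, wb3.model, threshold=0.8, semantics="quantile")
        r_hi = localize_patient(evoked, inv, wb3.model, threshold=0.95, semantics="quantile")
        assert r_hi.size <= r_lo.size
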