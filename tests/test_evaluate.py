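"""Overlap metrics, permutation null, and cohort statistics."""

import numpy as np
import pytest
from scipy import stats

from sefmap import evaluate as ev
from sefmap.geometry import grow_patch
from sefmap.localize import ActivationRegion


def _region(members, centroid=(0.0, 0.0, 0.0)):
    members = np.asarray(members, dtype=np.int64)
    return ActivationRegion(
        members=members,
        loadings=np.ones(len(members)),
        centroid=np.asarray(centroid, dtype=float),
        centroid_vertex=int(members[0]),
        centroid_label="other",
        peak_time=20.0,
        threshold=0.8,
    )


class TestAtlasOverlap:
    def test_counting(self, wb3):
        parc = wb3.model.parcellation
        roi = np.flatnonzero(parc.roi_mask())
        non = np.flatnonzero(~parc.roi_mask())
        assert ev.atlas_overlap(roi[:5], parc) == 100.0
        assert ev.atlas_overlap(non[:5], parc) == 0.0
        mixed = np.concatenate([roi[:3], non[:1]])
        assert ev.atlas_overlap(mixed, parc) == 75.0

    def test_empty_region_rejected(self, wb3):
        with pytest.raises(ValueError):
            ev.atlas_overlap(np.array([], dtype=int), wb3.model.parcellation)


class TestSphereOverlap:
    def test_radius_law(self):
        r = ev.sphere_radius_mm(3.0)
        assert (4.0 / 3.0) * np.pi * r**3 == pytest.approx(3000.0, rel=1e-9)
        assert r == pytest.approx(8.947, abs=1e-3)

    def test_inclusion_and_boundary(self, wb3):
        ss = wb3.model.source_space
        center = ss.positions[100]
        d = np.linalg.norm(ss.positions - center, axis=1)
        r = ev.sphere_radius_mm()
        inside = np.flatnonzero(d <= r)[:3]
        outside = np.flatnonzero(d > 25.0)[: len(inside)]
        assert len(inside) == len(outside) > 0
        assert ev.sphere_overlap(inside, ss, center) == 100.0
        assert ev.sphere_overlap(outside, ss, center) == 0.0
        both = np.concatenate([inside, outside])
        assert ev.sphere_overlap(both, ss, center) == 50.0


class TestCentroidDistance:
    def test_hand_case_and_invariance(self):
        region = _region([0], centroid=(0.0, 0.0, 0.0))
        assert ev.centroid_distance(region, np.array([3.0, 4.0, 0.0])) == 5.0
        shift = np.array([10.0, -7.0, 2.0])
        shifted = _region([0], centroid=shift)
        assert ev.centroid_distance(shifted, np.array([3.0, 4.0, 0.0]) + shift) == 5.0
        assert ev.centroid_distance(region, region.centroid) == 0.0


class TestProjectToAtlas:
    def test_exact_vertex_and_oracle(self, wb3):
        ss = wb3.model.source_space
        parc = wb3.model.parcellation
        v, label = ev.project_to_atlas(ss.positions[321], ss, parc)
        assert v == 321
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.normal(scale=40.0, size=3)
            v, label = ev.project_to_atlas(p, ss, parc)
            d = np.linalg.norm(ss.positions - p, axis=1)
            assert v == int(np.argmin(d))
            assert label == parc.name_of(parc.labels[v])

    def test_tie_breaks_to_lower_index(self):
        from sefmap.geometry import Parcellation, SourceSpace

        ss = SourceSpace(
            positions=np.array([[1.0, 0, 0], [-1.0, 0, 0]]),
            orientations=np.tile([0.0, 0, 1], (2, 1)),
            hemispheres=np.array(["left", "left"], dtype=object),
            vertex_ids=np.arange(2),
        )
        parc = Parcellation(np.array([0, 0]), {0: ("other", "both")})
        v, _ = ev.project_to_atlas(np.zeros(3), ss, parc)
        assert v == 0


class TestPermutationNull:
    def test_patches_size_exact_and_reproducible(self, wb3):
        model = wb3.model
        sizes = []
        null1 = ev.permutation_null(25, lambda p: float(len(p)), model, n=50, seed=4)
        null2 = ev.permutation_null(25, lambda p: float(len(p)), model, n=50, seed=4)
        assert (null1.values == 25).all()
        assert np.array_equal(null1.values, null2.values)

    def test_full_cortex_roi_gives_total_overlap(self, wb3):
        from sefmap.geometry import Parcellation

        model = wb3.model
        n_src = model.source_space.n_sources
        all_roi = Parcellation(np.ones(n_src, dtype=np.int64), {1: ("postcentral_gyrus", "left")})
        null = ev.permutation_null(
            10, lambda p: ev.atlas_overlap(p, all_roi), model, n=20, seed=1
        )
        assert (null.values == 100.0).all()

    def test_mean_overlap_matches_roi_fraction(self, wb3):
        model = wb3.model
        null = ev.permutation_null(
            30, lambda p: ev.atlas_overlap(p, model.parcellation), model, n=1500, seed=2
        )
        roi_pct = 100.0 * model.parcellation.roi_mask().mean()
        se = null.values.std(ddof=1) / np.sqrt(null.n_permutations)
        assert abs(null.values.mean() - roi_pct) <= 3.0 * se + 0.5


class TestBeatsChance:
    def test_conventions(self):
        null = ev.NullDistribution(values=np.array([9.0, 9.0, 9.0]), seed=0, region_size=5)
        assert ev.beats_chance(97.6, null) is True
        assert ev.beats_chance(9.0, null) is False  # strict inequality
        assert ev.beats_chance(0.0, null) is False


class TestCohortBinomial:
    def test_all_success_mass_reproduces_printed_values(self):
        p58 = ev.cohort_binomial(57, 58, 0.05, mode="all_success_mass")
        assert p58 == pytest.approx(0.05**58, rel=1e-12)
        assert f"{p58:.1e}" == "3.5e-76"
        p50 = ev.cohort_binomial(49, 50, 0.05, mode="all_success_mass")
        assert p50 == pytest.approx(8.8e-66, rel=0.02)

    def test_tail_hand_case(self):
        # P(X >= 57 | n=58, p=1/2) = 59 * 2^-58
        p = ev.cohort_binomial(57, 58, 0.5, mode="tail")
        assert p == pytest.approx(59.0 * 0.5**58, rel=1e-10)

    def test_tail_zero_successes_is_one(self):
        assert ev.cohort_binomial(0, 20, 0.3, mode="tail") == pytest.approx(1.0, rel=1e-12)

    def test_tail_matches_big_rational_summation(self):
        from fractions import Fraction
        from math import comb

        for n in (10, 25, 60):
            for k in (0, 1, n // 2, n - 1, n):
                p0 = Fraction(1, 20)
                exact = sum(
                    Fraction(comb(n, j)) * p0**j * (1 - p0) ** (n - j)
                    for j in range(k, n + 1)
                )
                got = ev.cohort_binomial(k, n, 0.05, mode="tail")
                assert got == pytest.approx(float(exact), rel=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ev.cohort_binomial(5, 3, 0.05)
        with pytest.raises(ValueError):
            ev.cohort_binomial(1, 3, 1.5)


class TestWilcoxon:
    def test_all_positive_differences_exact(self):
        # five positive differences: two-sided p = 2/32
        p = ev.wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0], [0.0] * 5)
        assert p == pytest.approx(2.0 / 32.0, rel=1e-12)

    def test_symmetry_under_swap(self):
        a = [3.0, 1.0, 4.0, 1.5, 9.0]
        b = [2.0, 2.0, 3.0, 5.0, 4.0]
        assert ev.wilcoxon_signed_rank(a, b) == pytest.approx(ev.wilcoxon_signed_rank(b, a))

    def test_single_nonzero_difference(self):
        assert ev.wilcoxon_signed_rank([1.0], [0.0]) == pytest.approx(1.0)

    def test_matches_full_sign_enumeration(self):
        rng = np.random.default_rng(6)
        for n in (4, 6, 8, 10):
            d = rng.normal(size=n)
            d[np.abs(d) < 1e-3] = 0.5
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            # enumerate all 2^n sign assignments
            ws = []
            for m in range(2**n):
                signs = [(m >> i) & 1 for i in range(n)]
                ws.append(sum(r for r, s in zip(ranks, signs) if s))
            ws = np.array(ws)
            lo = (ws <= w_obs).mean()
            hi = (ws >= w_obs).mean()
            expect = min(1.0, 2.0 * min(lo, hi))
            got = ev.wilcoxon_signed_rank(d, np.zeros(n))
            assert got == pytest.approx(expect, rel=1e-12)

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        got = ev.wilcoxon_signed_rank(a, b)
        want = stats.wilcoxon(a, b, method="exact").pvalue
        assert got == pytest.approx(want, rel=1e-9)

    def test_large_sample_normal_approx_close_to_scipy(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        got = ev.wilcoxon_signed_rank(a, b)
        want = stats.wilcoxon(a, b, method="approx", correction=False).pvalue
        assert got == pytest.approx(want, rel=1e-6)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            ev.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestChi2:
    def test_identical_rows_statistic_zero(self):
        stat, p = ev.chi2_location_test(np.array([[10, 20, 5], [10, 20, 5]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_case_2x2(self):
        stat, p = ev.chi2_location_test(np.array([[20, 10], [10, 20]]))
        assert stat == pytest.approx(20.0 / 3.0, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(20.0 / 3.0, 1), rel=1e-9)

    def test_row_swap_invariant(self):
        t = np.array([[5, 9, 2], [7, 3, 8]])
        s1, _ = ev.chi2_location_test(t)
        s2, _ = ev.chi2_location_test(t[::-1])
        assert s1 == pytest.approx(s2)

    def test_zero_column_dropped(self):
        t = np.array([[5, 0, 9], [7, 0, 3]])
        stat, _ = ev.chi2_location_test(t)
        s2, _ = ev.chi2_location_test(np.array([[5, 9], [7, 3]]))
        assert stat == pytest.approx(s2)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            ev.chi2_location_test(np.array([[0, 0], [1, 2]]))


class TestNullCalibration:
    def test_random_region_beats_chance_about_half_the_time(self, wb3):
        # continuous metric: patch-centroid distance to a fixed reference point
        model = wb3.model
        ref = np.array([0.0, 0.0, 100.0])

        def metric(p):
            return float(np.linalg.norm(model.source_space.positions[p].mean(axis=0) - ref))

        rng = np.random.default_rng(9)
        m = 100
        hits = 0
        for _ in range(m):
            sv = int(rng.integers(model.source_space.n_sources))
            obs = metric(grow_patch(model.source_space, model.adjacency, sv, 30))
            null = ev.permutation_null(30, metric, model, n=101, seed=int(rng.integers(2**31)))
            hits += ev.beats_chance(obs, null)
        rate = hits / m
        assert abs(rate - 0.5) <= 3.0 * np.sqrt(0.25 / m)
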