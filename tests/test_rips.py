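import math

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from cohorttda.mixed_distance import DistanceMatrix
from cohorttda.rips import (
    BarcodeSet,
    FiltrationSizeError,
    build_filtration,
    cut_clusters,
    persistent_homology,
    projected_simplex_counts,
    representative_cycle,
)
from cohorttda.synthetic import sample_shapes

from _oracles import brute_force_ph

SQRT2 = math.sqrt(2.0)


def _dm(points: np.ndarray) -> DistanceMatrix:
    return DistanceMatrix(squareform(pdist(points)), tuple(range(len(points))))


def _finite_multiset(bars: BarcodeSet, dim: int):
    return sorted((round(p.birth, 12), round(p.death, 12)) for p in bars.finite(dim))


class TestFiltration:
    def test_three_point_complete_complex(self):
        D = np.ones((3, 3)) - np.eye(3)
        filt = build_filtration(DistanceMatrix(D, (0, 1, 2)), max_dim=1, max_scale=2)
        assert filt.count(0) == 3 and filt.count(1) == 3 and filt.count(2) == 1
        assert filt.count() == 7

    def test_simplices_sorted_by_diameter_then_dim(self):
        d = sample_shapes("square_corners")
        filt = build_filtration(d, max_dim=2)
        sims = list(filt.simplices())
        keys = [(s.diameter, s.dim, s.vertices) for s in sims]
        assert keys == sorted(keys)
        # faces never appear after a cosimplex of smaller diameter
        diam = {s.vertices: s.diameter for s in sims}
        for s in sims:
            if s.dim > 0:
                for omit in range(len(s.vertices)):
                    face = s.vertices[:omit] + s.vertices[omit + 1:]
                    assert diam[face] <= s.diameter

    def test_projected_counts_for_cll_sized_cohort(self):
        counts = projected_simplex_counts(266, max_dim=2)
        assert counts[1] == 35_245
        assert counts[2] == 3_101_560
        assert counts[3] == 203_927_570

    def test_resource_guard_trips_on_cohort_scale_voids(self):
        rng = np.random.default_rng(0)
        d = _dm(rng.normal(size=(266, 3)))
        with pytest.raises(FiltrationSizeError, match="choose"):
            build_filtration(d, max_dim=2)

    def test_invalid_parameters(self):
        d = sample_shapes("square_corners")
        with pytest.raises(ValueError):
            build_filtration(d, max_dim=3)
        with pytest.raises(ValueError):
            build_filtration(d, max_dim=1, max_scale=0.0)


class TestAnalyticFixtures:
    def test_square_corners_single_loop(self):
        bars = persistent_homology(sample_shapes("square_corners"), max_dim=2)
        d1 = bars.in_dim(1)
        assert len(d1) == 1
        assert d1[0].birth == 1.0 and d1[0].death == SQRT2
        assert bars.in_dim(2) == []
        # representative is exactly the four sides of the square
        assert sorted(d1[0].representative) == [(0, 1), (0, 3), (1, 2), (2, 3)]

    def test_octahedron_single_void(self):
        bars = persistent_homology(sample_shapes("octahedron"), max_dim=2)
        assert bars.in_dim(1) == []  # all 1-cycles fill instantly at sqrt(2)
        d2 = bars.in_dim(2)
        assert len(d2) == 1
        assert d2[0].birth == pytest.approx(SQRT2, abs=1e-15)
        assert d2[0].death == 2.0
        assert len(d2[0].representative) == 8  # the eight facets

    def test_equilateral_triangle_has_no_loop(self):
        D = np.ones((3, 3)) - np.eye(3)
        bars = persistent_homology(DistanceMatrix(D, (0, 1, 2)), max_dim=1)
        assert bars.in_dim(1) == []

    def test_single_infinite_component_at_full_scale(self):
        rng = np.random.default_rng(3)
        bars = persistent_homology(_dm(rng.normal(size=(15, 3))), max_dim=1)
        essential = [p for p in bars.in_dim(0) if p.is_infinite]
        assert len(essential) == 1
        assert len(essential[0].representative) == 15


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_reduction_on_random_spaces(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        # mix of geometric and purely random (tie-prone) metrics
        if seed % 2 == 0:
            D = squareform(pdist(rng.normal(size=(n, 3))))
        else:
            D = squareform(np.round(rng.uniform(0.2, 1.0, n * (n - 1) // 2), 1))
        d = DistanceMatrix(D, tuple(range(n)))
        got = persistent_homology(d, max_dim=2)
        expected = brute_force_ph(D, max_dim=2)
        ours = sorted(
            (p.dim, round(p.birth, 12), round(p.death, 12) if not p.is_infinite else math.inf)
            for p in got.pairs
        )
        theirs = sorted((d_, round(b, 12), dd if math.isinf(dd) else round(dd, 12))
                        for d_, b, dd in expected)
        assert ours == theirs

    def test_dim0_deaths_equal_mst_weights(self):
        rng = np.random.default_rng(11)
        D = squareform(pdist(rng.normal(size=(30, 4))))
        bars = persistent_homology(DistanceMatrix(D, tuple(range(30))), max_dim=1)
        deaths = sorted(p.death for p in bars.finite(0))
        mst = minimum_spanning_tree(D).toarray()
        weights = sorted(mst[mst > 0])
        np.testing.assert_allclose(deaths, weights, rtol=0, atol=1e-12)


class TestCircleRecovery:
    def test_dominant_loop_with_closed_representative(self):
        d = sample_shapes("circle", n=40)
        bars = persistent_homology(d, max_dim=1)
        d1 = sorted(bars.in_dim(1), key=lambda p: -p.duration)
        assert d1, "circle must produce a loop"
        if len(d1) > 1:
            assert d1[0].duration >= 3 * d1[1].duration
        rep = d1[0].representative
        # the representative is a single closed cycle visiting >= n/2 points
        degree: dict[int, int] = {}
        for a, b in rep:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        assert all(v % 2 == 0 for v in degree.values())  # boundary = 0 mod 2
        assert len(degree) >= 20

    def test_representative_max_diameter_equals_birth(self):
        d = sample_shapes("circle", n=25, noise=0.05, seed=4)
        bars = persistent_homology(d, max_dim=1)
        top = bars.most_persistent(1)
        diam = max(d.values[a, b] for a, b in top.representative)
        assert diam == pytest.approx(top.birth, abs=1e-12)


class TestStability:
    def test_duplicate_point_changes_no_positive_bar(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 2))
        base = persistent_homology(_dm(pts), max_dim=2)
        dup = persistent_homology(_dm(np.vstack([pts, pts[3]])), max_dim=2)
        for dim in (1, 2):
            assert _finite_multiset(base, dim) == _finite_multiset(dup, dim)

    def test_raising_max_scale_preserves_earlier_pairs(self):
        rng = np.random.default_rng(6)
        d = _dm(rng.normal(size=(14, 2)))
        lo = persistent_homology(d, max_dim=1, max_scale=1.0)
        hi = persistent_homology(d, max_dim=1)
        lo_pairs = {(round(p.birth, 12), round(p.death, 12))
                    for p in lo.finite(1) if p.death < 1.0}
        hi_pairs = {(round(p.birth, 12), round(p.death, 12)) for p in hi.finite(1)}
        assert lo_pairs <= hi_pairs


class TestRepresentativeContract:
    def test_infinite_dim1_class_has_no_representative(self):
        # two far-apart squares truncated before they connect
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = _dm(pts)
        bars = persistent_homology(d, max_dim=1, max_scale=1.2)
        inf1 = [p for p in bars.in_dim(1) if p.is_infinite]
        assert len(inf1) == 1  # the square loop never dies below 1.2 < sqrt(2)
        with pytest.raises(ValueError, match="no representative"):
            representative_cycle(inf1[0])

    def test_finite_pair_representative_roundtrip(self, tmp_path):
        d = sample_shapes("circle", n=20)
        bars = persistent_homology(d, max_dim=1)
        path = tmp_path / "bars.tsv"
        bars.to_tsv(path)
        back = BarcodeSet.from_tsv(path)
        top_a = bars.most_persistent(1)
        top_b = back.most_persistent(1)
        assert top_a.birth == top_b.birth and top_a.death == top_b.death
        assert top_a.representative == top_b.representative


class TestCutClusters:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (12, 2))])
        labels = cut_clusters(_dm(pts), 2)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[15]

    def test_boundary_cases(self):
        rng = np.random.default_rng(10)
        d = _dm(rng.normal(size=(6, 2)))
        assert len(set(cut_clusters(d, 1))) == 1
        assert len(set(cut_clusters(d, 6))) == 6
        with pytest.raises(ValueError):
            cut_clusters(d, 0)
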