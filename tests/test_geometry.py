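import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from cohorttda.cohort_io import FeatureSchema, MixedDataset
from cohorttda.geometry import (
    Embedding,
    assign_sectors,
    centroid_separation,
    circos_table,
    embed,
    export_off,
    fit_loop,
    fit_sinusoid,
    loop_centroid,
    sector_center_angles,
    sector_profile,
    sphere_projection,
    void_axes,
)
from cohorttda.mixed_distance import DistanceMatrix


def _dm(points: np.ndarray) -> DistanceMatrix:
    return DistanceMatrix(squareform(pdist(points)), tuple(range(len(points))))


class TestEmbed:
    def test_collinear_points_exact_1d(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        emb = embed(DistanceMatrix(D, (0, 1, 2)), method="mds", k=1)
        x = emb.coords[:, 0]
        gaps = np.abs(np.diff(np.sort(x)))
        np.testing.assert_allclose(gaps, [1.0, 1.0], atol=1e-10)

    def test_mds_recovers_planar_distances(self, rng):
        pts = rng.normal(size=(20, 2))
        emb = embed(_dm(pts), method="mds", k=2)
        np.testing.assert_allclose(
            squareform(pdist(emb.coords)), squareform(pdist(pts)), atol=1e-8
        )

    def test_k_too_large_rejected(self, rng):
        d = _dm(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="at most"):
            embed(d, k=5)

    def test_umap_deterministic_under_seed(self, rng):
        d = _dm(rng.normal(size=(30, 3)))
        a = embed(d, method="umap", k=2, seed=42)
        b = embed(d, method="umap", k=2, seed=42)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestLoopCentroid:
    def test_square_cycle_centroid_at_origin(self):
        emb = Embedding(np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]], float), "mds")
        rep = ((0, 1), (1, 2), (2, 3), (0, 3))
        np.testing.assert_allclose(loop_centroid(emb, rep), [0, 0], atol=1e-15)

    def test_twelve_gon_centroid(self):
        th = np.linspace(0, 2 * math.pi, 12, endpoint=False)
        emb = Embedding(np.c_[2 + np.cos(th), -1 + np.sin(th)], "mds")
        rep = tuple((i, (i + 1) % 12) for i in range(12))
        np.testing.assert_allclose(loop_centroid(emb, rep), [2, -1], atol=1e-12)

    def test_single_vertex_degenerate(self):
        emb = Embedding(np.array([[3.0, 4.0], [0.0, 0.0]]), "mds")
        np.testing.assert_allclose(loop_centroid(emb, ((0, 0),)), [3, 4])

    def test_empty_representative_rejected(self):
        emb = Embedding(np.zeros((3, 2)), "mds")
        with pytest.raises(ValueError, match="empty"):
            loop_centroid(emb, ())


class TestAssignSectors:
    def test_direct_binning(self):
        coords = np.array([[1.0, 0.0], [math.cos(math.radians(25)), math.sin(math.radians(25))]])
        s = assign_sectors(Embedding(coords, "mds"), np.zeros(2))
        assert s[0] == 0 and s[1] == 1

    def test_default_width_gives_18_sectors(self, rng):
        th = rng.uniform(0, 2 * math.pi, 2000)
        emb = Embedding(np.c_[np.cos(th), np.sin(th)], "mds")
        s = assign_sectors(emb, np.zeros(2))
        assert set(s) == set(range(18))

    def test_width_must_divide_360(self, rng):
        emb = Embedding(rng.normal(size=(5, 2)), "mds")
        with pytest.raises(ValueError, match="divide"):
            assign_sectors(emb, np.zeros(2), width=25)

    def test_partition_excludes_only_centroid_subjects(self, rng):
        coords = rng.normal(size=(50, 2))
        coords[7] = [0.25, -0.5]
        with pytest.warns(UserWarning, match="centroid"):
            s = assign_sectors(Embedding(coords, "mds"), np.array([0.25, -0.5]))
        assert s[7] == -1
        assert (s >= 0).sum() == 49

    def test_requires_2d(self, rng):
        emb = Embedding(rng.normal(size=(5, 3)), "mds")
        with pytest.raises(ValueError, match="2-D"):
            assign_sectors(emb, np.zeros(3))


class TestSectorProfile:
    def test_constant_feature(self):
        s = np.repeat(np.arange(18), 3)
        prof = sector_profile(np.ones(s.size), s, 18)
        np.testing.assert_allclose(prof, 1.0)

    def test_upper_half_plane_indicator(self, rng):
        th = rng.uniform(0, 2 * math.pi, 5000)
        emb = Embedding(np.c_[np.cos(th), np.sin(th)], "mds")
        s = assign_sectors(emb, np.zeros(2))
        prof = sector_profile((th < math.pi).astype(float), s, 18)
        np.testing.assert_allclose(prof[:9], 1.0)
        np.testing.assert_allclose(prof[9:], 0.0)

    def test_empty_sector_is_missing(self):
        s = np.array([0, 0, 5])
        prof = sector_profile(np.array([1.0, 2.0, 3.0]), s, 18)
        assert prof[0] == pytest.approx(1.5)
        assert np.isnan(prof[1])


class TestFitSinusoid:
    def test_exact_model_recovered(self):
        th = np.radians(sector_center_angles(18))
        fit = fit_sinusoid(2 + np.sin(th))
        assert (fit.beta0, fit.beta1, fit.beta2) == pytest.approx((2, 1, 0), abs=1e-12)
        assert fit.kappa == pytest.approx(0.0, abs=1e-12)
        assert fit.peak_angle_deg == pytest.approx(90.0, abs=1e-6)

    def test_constant_means_flagged(self):
        fit = fit_sinusoid(np.full(18, 3.0))
        assert fit.constant and math.isnan(fit.kappa)

    def test_white_noise_kappa_large(self, rng):
        kappas = []
        for _ in range(1000):
            kappas.append(fit_sinusoid(rng.normal(size=18)).kappa)
        assert np.median(kappas) >= 0.6

    def test_kappa_affine_invariant(self, rng):
        y = rng.normal(size=18)
        base = fit_sinusoid(y).kappa
        assert fit_sinusoid(3.7 * y - 11).kappa == pytest.approx(base, abs=1e-12)

    def test_agrees_with_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        y = rng.normal(size=18)
        th = np.radians(sector_center_angles(18))
        X = sm.add_constant(np.c_[np.sin(th), np.cos(th)])
        ref = sm.OLS(y, X).fit()
        fit = fit_sinusoid(y)
        np.testing.assert_allclose(
            [fit.beta0, fit.beta1, fit.beta2], ref.params, atol=1e-10
        )
        np.testing.assert_allclose(fit.mse * 18, ref.ssr, atol=1e-10)

    def test_needs_four_sectors(self):
        y = np.full(18, np.nan)
        y[:3] = [1, 2, 3]
        with pytest.raises(ValueError, match="at least 4"):
            fit_sinusoid(y)


def _binary_ds(values: np.ndarray, name: str = "grp") -> MixedDataset:
    schema = [FeatureSchema(name, "binary_symmetric", levels=("A", "B")),
              FeatureSchema("pad", "continuous")]
    df = pd.DataFrame(
        {name: np.where(values, "B", "A"), "pad": np.arange(len(values), dtype=float)},
        index=[f"P{i}" for i in range(len(values))],
    )
    df[name] = df[name].astype(object)
    return MixedDataset(schema=schema, values=df)


class TestCentroidSeparation:
    def test_constructed_groups(self, rng):
        n = 200
        flag = np.arange(n) < n // 2
        coords = np.where(flag[:, None], [0.0, 0.0], [1.0, 0.0]) + rng.normal(0, 0.01, (n, 2))
        sep = centroid_separation(_binary_ds(flag), coords, "grp")
        assert sep.distance == pytest.approx(1.0, abs=0.01)
        assert sep.n_low == sep.n_high == 100

    def test_random_labels_separation_vanishes(self, rng):
        n = 2000
        coords = rng.normal(size=(n, 2))
        flag = rng.random(n) < 0.5
        sep = centroid_separation(_binary_ds(flag), coords, "grp")
        assert sep.distance <= 0.05

    def test_non_binary_rejected(self, rng):
        ds = _binary_ds(rng.random(10) < 0.5)
        with pytest.raises(ValueError, match="not binary"):
            centroid_separation(ds, rng.normal(size=(10, 2)), "pad")


class TestVoidAxes:
    def _cube_ds(self, rng, n=160, sd=0.05):
        vert = rng.integers(0, 8, n)
        signs = np.c_[vert & 1, (vert >> 1) & 1, (vert >> 2) & 1].astype(float)
        coords = signs - 0.5 + rng.normal(0, sd, (n, 3))
        schema = [
            FeatureSchema(f"ax{i}", "binary_symmetric", levels=("Low", "High"))
            for i in range(3)
        ]
        df = pd.DataFrame(
            {f"ax{i}": np.where(signs[:, i] > 0, "High", "Low") for i in range(3)},
            index=[f"P{i}" for i in range(n)], dtype=object,
        )
        return MixedDataset(schema=schema, values=df), coords

    def test_cube_axes_orthogonal(self, rng):
        ds, coords = self._cube_ds(rng)
        axes = void_axes(ds, Embedding(coords, "mds"), ["ax0", "ax1", "ax2"])
        assert abs(axes.determinant) == pytest.approx(1.0, abs=0.05)
        assert not axes.collinear

    def test_duplicate_features_flagged_collinear(self, rng):
        ds, coords = self._cube_ds(rng)
        ds.values["ax1"] = ds.values["ax0"]
        with pytest.warns(UserWarning, match="collinear"):
            axes = void_axes(ds, Embedding(coords, "mds"), ["ax0", "ax1", "ax2"])
        assert axes.collinear and axes.determinant == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_features_and_3d(self, rng):
        ds, coords = self._cube_ds(rng)
        with pytest.raises(ValueError, match="three"):
            void_axes(ds, Embedding(coords, "mds"), ["ax0", "ax1"])
        with pytest.raises(ValueError, match="3-D"):
            void_axes(ds, Embedding(coords[:, :2], "mds"), ["ax0", "ax1", "ax2"])


class TestSphereProjection:
    def test_normalization(self):
        emb = Embedding(np.array([[2.0, 0, 0], [0, -3.0, 0], [0, 0, 0.5]]), "mds",
                        labels=("a", "b", "c"))
        proj = sphere_projection(emb, np.zeros(3), [1.0, 2.0, 3.0])
        np.testing.assert_allclose(
            np.linalg.norm(proj[["x", "y", "z"]].to_numpy(), axis=1), 1.0, atol=1e-12
        )
        np.testing.assert_allclose(proj.loc["a", ["x", "y", "z"]], [1, 0, 0])

    def test_antipodal_subjects(self):
        emb = Embedding(np.array([[0, 0, 2.0], [0, 0, -5.0]]), "mds")
        proj = sphere_projection(emb, np.zeros(3), [0.0, 1.0])
        np.testing.assert_allclose(
            proj.iloc[0][["x", "y", "z"]].astype(float),
            -proj.iloc[1][["x", "y", "z"]].astype(float),
            atol=1e-12,
        )

    def test_centroid_subject_excluded(self):
        emb = Embedding(np.array([[1.0, 1, 1], [0.5, 0.5, 0.5]]), "mds")
        with pytest.warns(UserWarning, match="centroid"):
            proj = sphere_projection(emb, np.array([0.5, 0.5, 0.5]), [1.0, 2.0])
        assert len(proj) == 1


class TestCircosTable:
    def _loopfit(self, rng, n=720):
        th = rng.uniform(0, 2 * math.pi, n)
        emb = Embedding(np.c_[np.cos(th), np.sin(th)], "mds")
        schema = [
            FeatureSchema("wave", "continuous"),
            FeatureSchema("flat", "continuous"),
        ]
        df = pd.DataFrame(
            {"wave": 5 + 2 * np.sin(th), "flat": np.full(n, 2.0)},
            index=[f"P{i}" for i in range(n)],
        )
        ds = MixedDataset(schema=schema, values=df)
        rep = tuple((i, (i + 1) % n) for i in range(n))
        return fit_loop(ds, emb, rep)

    def test_rows_ranked_by_kappa_and_scaled(self, rng):
        lf = self._loopfit(rng)
        table = circos_table(lf)
        assert list(table.index) == ["wave"]  # constant feature excluded from ranking
        assert table.loc["wave"].min() == pytest.approx(0.0)
        assert table.loc["wave"].max() == pytest.approx(1.0)

    def test_constant_feature_scales_to_zero(self, rng):
        lf = self._loopfit(rng)
        table = circos_table(lf, features=["wave", "flat"])
        np.testing.assert_allclose(table.loc["flat"], 0.0)

    def test_empty_feature_list(self, rng):
        lf = self._loopfit(rng)
        assert circos_table(lf, features=[]).empty


class TestExportOff:
    def test_mesh_structure(self, tmp_path, rng):
        coords = rng.normal(size=(6, 3))
        tris = [(0, 1, 2), (2, 3, 4)]
        export_off(tris, coords, tmp_path / "m.off")
        lines = (tmp_path / "m.off").read_text().splitlines()
        assert lines[0] == "OFF"
        nv, nf, _ = map(int, lines[1].split())
        assert nv == 5 and nf == 2
        assert lines[2 + nv].startswith("3 ")
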