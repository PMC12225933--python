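"""Volumetric segmentation against analytic fields and phantom truth."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from dermafold import segmentation as seg
from dermafold import synthetic as syn
from dermafold.surfaces import TriSurface


@pytest.fixture(scope="module")
def clean_phantom():
    return syn.make_image_phantom(n_cells=0, noise_sd=0.0, seed=0)


@pytest.fixture(scope="module")
def phantom_clouds(clean_phantom):
    edges = seg.canny_edges_3d(clean_phantom.stack)
    return seg.split_edge_surfaces(clean_phantom.stack, edges)


def _sphere_cloud(radius=20.0, n=2000, seed=0, outward=True):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    sign = 1.0 if outward else -1.0
    return seg.OrientedPointCloud(points=radius * v, normals=sign * v)


class TestCanny:
    def test_constant_stack_empty(self):
        assert seg.canny_edges_3d(np.full((20, 20, 20), 0.7)).sum() == 0

    def test_phantom_edges_near_truth_surfaces(self, clean_phantom):
        ph = clean_phantom
        edges = seg.canny_edges_3d(ph.stack)
        pts = np.argwhere(edges).astype(float)
        c = np.array(ph.truth_outer_surface["center"])
        r = np.linalg.norm(pts - c, axis=1)
        d_out = np.abs(r - ph.truth_outer_surface["radius"])
        d_in = np.abs(r - ph.truth_inner_surface["radius"])
        assert (np.minimum(d_out, d_in) <= 1.0 + 1e-9).mean() > 0.99
        assert (d_out < 1.5).sum() > 100 and (d_in < 1.5).sum() > 100

    def test_two_nested_surfaces_give_separate_components(self,
                                                          clean_phantom):
        from scipy import ndimage

        edges = seg.canny_edges_3d(clean_phantom.stack)
        _, n = ndimage.label(edges, structure=np.ones((3, 3, 3)))
        assert n >= 2

    def test_axis_permutation_equivariance(self, clean_phantom):
        stack = clean_phantom.stack
        edges = seg.canny_edges_3d(stack)
        perm = (2, 0, 1)
        edges_p = seg.canny_edges_3d(np.transpose(stack, perm))
        assert np.array_equal(edges_p, np.transpose(edges, perm))

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            seg.canny_edges_3d(np.zeros((5, 5, 5)), low=0.9, high=0.5)


class TestNormals:
    def test_radial_field_gives_radial_normals(self):
        zz, yy, xx = np.meshgrid(*(np.arange(40.0),) * 3, indexing="ij")
        c = 19.5
        r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
        stack = np.clip(1.0 - r / 15.0, 0, 1)     # bright sphere, dark out
        pts = np.argwhere((r > 9) & (r < 11))
        cloud = seg.estimate_normals(stack, pts, sigma=1.0)
        radial = cloud.points - c
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip(
            (cloud.normals * radial).sum(1), -1, 1)))
        assert np.quantile(ang, 0.95) < 2.0

    def test_sign_flip_negates_normals(self, clean_phantom):
        edges = seg.canny_edges_3d(clean_phantom.stack)
        pts = np.argwhere(edges)[:500]
        a = seg.estimate_normals(clean_phantom.stack, pts)
        b = seg.estimate_normals(-clean_phantom.stack, pts)
        assert np.allclose(a.normals, -b.normals)

    def test_flat_step_normals_along_z(self):
        stack = np.zeros((30, 20, 20))
        stack[:15] = 1.0                      # bright below, step at z=15
        pts = np.argwhere(np.zeros_like(stack, dtype=bool))
        pts = np.array([[14, y, x] for y in range(5, 15)
                        for x in range(5, 15)])
        cloud = seg.estimate_normals(stack, pts, sigma=1.0)
        assert np.allclose(cloud.normals, [1.0, 0.0, 0.0], atol=1e-9)

    def test_zero_gradient_points_dropped(self):
        stack = np.zeros((20, 20, 20))
        stack[10:] = 1.0
        pts = np.array([[10, 10, 10], [0, 0, 0]])   # second has no gradient
        cloud = seg.estimate_normals(stack, pts, sigma=0.8)
        assert len(cloud) == 1


class TestReconstruction:
    def test_sphere_area_within_5_percent(self):
        cloud = _sphere_cloud(radius=20.0, n=4000)
        surf = seg.reconstruct_surface(cloud, spacing=2.0)
        assert surf.area() == pytest.approx(4 * np.pi * 20**2, rel=0.05)

    def test_surface_to_cloud_hausdorff_below_one_voxel(self):
        cloud = _sphere_cloud(radius=20.0, n=20000)
        surf = seg.reconstruct_surface(cloud, spacing=2.0)
        d, _ = cKDTree(cloud.points).query(surf.vertices)
        assert d.max() < 1.0

    def test_plane_cloud_stays_planar(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 30, size=(3000, 2))
        pts = np.column_stack([np.full(len(xy), 10.0), xy])
        normals = np.tile([1.0, 0.0, 0.0], (len(pts), 1))
        surf = seg.reconstruct_surface(
            seg.OrientedPointCloud(pts, normals), spacing=2.0)
        interior = ((surf.vertices[:, 1] > 3) & (surf.vertices[:, 1] < 27)
                    & (surf.vertices[:, 2] > 3) & (surf.vertices[:, 2] < 27))
        assert np.abs(surf.vertices[interior, 0] - 10.0).max() < 0.5

    def test_lighter_format_contract(self, phantom_clouds):
        for cloud in phantom_clouds.values():
            surf = seg.reconstruct_surface(cloud)
            assert surf.n_vertices < len(cloud)

    def test_incoherent_normals_rejected(self):
        cloud = _sphere_cloud(radius=20.0, n=1000, seed=3)
        rng = np.random.default_rng(0)
        flip = rng.random(len(cloud)) < 0.5
        bad = seg.OrientedPointCloud(
            cloud.points, np.where(flip[:, None], -cloud.normals,
                                   cloud.normals))
        with pytest.raises(ValueError, match="re-orient"):
            seg.reconstruct_surface(bad)

    def test_too_few_points_rejected(self):
        cloud = _sphere_cloud(n=50)
        with pytest.raises(ValueError, match="100"):
            seg.reconstruct_surface(cloud)


class TestThickness:
    @staticmethod
    def _icosphere(radius, outward=True):
        import trimesh

        m = trimesh.creation.icosphere(subdivisions=3, radius=radius)
        faces = m.faces if outward else m.faces[:, [0, 2, 1]]
        return TriSurface(np.asarray(m.vertices), np.asarray(faces))

    def test_concentric_spheres(self):
        outer = self._icosphere(20.0)
        inner = self._icosphere(15.0)
        th = seg.thickness_map(outer, inner)
        assert np.all(np.abs(th - 5.0) < 0.5)

    def test_identical_surfaces_zero(self):
        s1 = self._icosphere(10.0)
        s2 = self._icosphere(10.0)
        th = seg.thickness_map(s1, s2)
        assert np.abs(th).max() < 1e-6

    def test_parallel_planes_exact_gap(self):
        xs = np.arange(0, 11, dtype=float)
        X, Y = np.meshgrid(xs, xs, indexing="ij")

        def plane(z, up):
            v = np.column_stack([X.ravel(), Y.ravel(),
                                 np.full(X.size, z)])
            f = []
            n = X.shape[0]
            for i in range(n - 1):
                for j in range(n - 1):
                    a = i * n + j
                    tri = ([a, a + n, a + n + 1], [a, a + n + 1, a + 1])
                    f.extend(tri if up else [t[::-1] for t in tri])
            return TriSurface(v, np.array(f))

        outer = plane(3.0, up=True)        # normals +z, inward ray -z
        inner = plane(0.0, up=True)
        th = seg.thickness_map(outer, inner)
        hit = ~np.isnan(th)
        assert np.allclose(th[hit], 3.0)


class TestCells:
    def test_exact_recovery_of_separated_cells(self):
        ph = syn.make_image_phantom(n_cells=20, noise_sd=0.0, seed=2)
        det = seg.detect_cells(ph.stack)
        assert len(det) == 20
        d, idx = cKDTree(ph.truth_cells).query(det.centroids)
        assert d.max() <= 1.0
        assert len(np.unique(idx)) == 20

    def test_zero_stack_zero_detections(self):
        det = seg.detect_cells(np.zeros((20, 20, 20)))
        assert len(det) == 0

    def test_two_touching_scale_cells_not_merged(self):
        from dermafold import config as C

        stack = np.zeros((40, 40, 40))
        sigma = C.PHANTOM_CELL_RADIUS / 2
        sep = 2.5 * C.PHANTOM_CELL_RADIUS
        centers = [(20.0, 20.0, 15.0), (20.0, 20.0, 15.0 + sep)]
        for c in centers:
            syn._add_blob(stack, c, sigma, 0.6)
        det = seg.detect_cells(stack)
        assert len(det) == 2
        d, _ = cKDTree(np.array(centers)).query(det.centroids)
        assert d.max() <= 1.0


class TestDensities:
    def test_disjoint_masks_required_and_respected(self):
        cells = seg.CellDetection(
            centroids=np.array([[5.0, 5, 5], [6.0, 6, 6]]),
            scores=np.ones(2))
        shape = (20, 20, 20)
        epi = np.zeros(shape, dtype=bool)
        epi[:10] = True
        der = np.zeros(shape, dtype=bool)
        der[10:] = True
        df = seg.proliferation_density(cells, {"epidermis": epi,
                                               "dermis": der})
        row = df.set_index("layer")
        assert row.loc["dermis", "density"] == 0.0
        assert row.loc["epidermis", "n_cells"] == 2
        with pytest.raises(ValueError, match="overlap"):
            seg.proliferation_density(cells, {"a": epi, "b": epi})

    def test_density_halves_when_volume_doubles(self):
        cells = seg.CellDetection(
            centroids=np.array([[2.0, 2, 2]]), scores=np.ones(1))
        shape = (20, 20, 20)
        small = np.zeros(shape, dtype=bool)
        small[:5] = True
        big = np.zeros(shape, dtype=bool)
        big[:10] = True
        d_small = seg.proliferation_density(
            cells, {"m": small}).loc[0, "density"]
        d_big = seg.proliferation_density(
            cells, {"m": big}).loc[0, "density"]
        assert d_big == pytest.approx(d_small / 2.0)

    def test_empty_mask_reported_missing(self):
        cells = seg.CellDetection(centroids=np.empty((0, 3)),
                                  scores=np.empty(0))
        df = seg.proliferation_density(
            cells, {"empty": np.zeros((10, 10, 10), dtype=bool)})
        assert bool(df.loc[0, "missing"])
        assert np.isnan(df.loc[0, "density"])

    def test_uniform_cells_cv_consistent_with_poisson(self):
        rng = np.random.default_rng(0)
        shape = (30, 60, 60)
        mask = np.ones(shape, dtype=bool)
        n = 600
        pts = rng.uniform([0, 0, 0], np.array(shape) - 1, size=(n, 3))
        cells = seg.CellDetection(centroids=pts, scores=np.ones(n))
        df = seg.proliferation_density(cells, {"m": mask}, n_bins=3)
        cv = df.loc[0, "cv"]
        mean_count = n / 27
        cv_poisson = 1 / np.sqrt(mean_count)
        # 3 sigma band for the CV of 27 Poisson counts
        sd_cv = cv_poisson / np.sqrt(2 * 26)
        assert abs(cv - cv_poisson) < 3 * np.sqrt(sd_cv**2
                                                  + (0.3 * cv_poisson)**2)


class TestSplitSurfaces:
    def test_outer_inner_classification(self, clean_phantom, phantom_clouds):
        c = np.array(clean_phantom.truth_outer_surface["center"])
        r_outer = np.linalg.norm(phantom_clouds["outer"].points - c,
                                 axis=1).mean()
        r_inner = np.linalg.norm(phantom_clouds["inner"].points - c,
                                 axis=1).mean()
        assert r_outer == pytest.approx(
            clean_phantom.truth_outer_surface["radius"], abs=1.0)
        assert r_inner == pytest.approx(
            clean_phantom.truth_inner_surface["radius"], abs=1.0)
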