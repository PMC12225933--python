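"""Fold-pattern quantification on constructed analytic surfaces."""

import numpy as np
import pytest
import trimesh

from dermafold import pattern as pat
from dermafold.surfaces import TriSurface


def grid_surface(X, Y, Z):
    n = X.shape
    vids = np.arange(X.size).reshape(n)
    v = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    f = []
    for i in range(n[0] - 1):
        for j in range(n[1] - 1):
            a, b = vids[i, j], vids[i + 1, j]
            c, d = vids[i + 1, j + 1], vids[i, j + 1]
            f += [[a, b, c], [a, c, d]]
    return TriSurface(v, np.array(f))


@pytest.fixture()
def flat_sheet():
    xs = np.linspace(0, 20, 41)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    return grid_surface(X, Y, np.zeros_like(X))


class TestCurvature:
    def test_sphere_positive_one_over_r(self):
        m = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        surf = TriSurface(np.asarray(m.vertices), np.asarray(m.faces))
        h = pat.surface_curvature(surf)
        assert np.median(h) == pytest.approx(0.1, rel=0.02)
        assert (h > 0).all()          # convex-outward positive convention

    def test_plane_zero(self, flat_sheet):
        h = pat.surface_curvature(flat_sheet)
        assert np.abs(h).max() < 1e-10

    def test_cylinder_half_over_r(self):
        r, nt, nz = 5.0, 96, 30
        theta = np.linspace(0, 2 * np.pi, nt, endpoint=False)
        z = np.linspace(0, 20, nz)
        T, Zg = np.meshgrid(theta, z, indexing="ij")
        v = np.stack([r * np.cos(T).ravel(), r * np.sin(T).ravel(),
                      Zg.ravel()], axis=1)
        vid = np.arange(nt * nz).reshape(nt, nz)
        f = []
        for i in range(nt):
            for j in range(nz - 1):
                a, b = vid[i, j], vid[(i + 1) % nt, j]
                c, d = vid[(i + 1) % nt, j + 1], vid[i, j + 1]
                f += [[a, b, c], [a, c, d]]
        surf = TriSurface(v, np.array(f))
        h = pat.surface_curvature(surf)
        interior = (v[:, 2] > 3) & (v[:, 2] < 17)
        assert np.median(h[interior]) == pytest.approx(1 / (2 * r),
                                                       rel=0.05)

    def test_nonmanifold_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                      [0, -1, 0.0]])
        f = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])  # 3 faces on an edge
        with pytest.raises(ValueError, match="non-manifold"):
            pat.surface_curvature(TriSurface(v, f))

    def test_rigid_motion_invariance(self):
        m = trimesh.creation.icosphere(subdivisions=2, radius=6.0)
        s1 = TriSurface(np.asarray(m.vertices), np.asarray(m.faces))
        rot = trimesh.transformations.rotation_matrix(0.7, [1, 2, 3])[:3, :3]
        s2 = TriSurface(np.asarray(m.vertices) @ rot.T + [5, -3, 2],
                        np.asarray(m.faces))
        assert np.allclose(pat.surface_curvature(s1),
                           pat.surface_curvature(s2), atol=1e-9)


class TestCreases:
    def test_smooth_surfaces_give_empty_network(self, flat_sheet):
        net = pat.extract_creases(flat_sheet)
        assert net.is_empty() and net.n_components == 0
        m = trimesh.creation.icosphere(subdivisions=3, radius=30.0)
        dome = TriSurface(np.asarray(m.vertices), np.asarray(m.faces))
        assert pat.extract_creases(dome).is_empty()

    def test_single_groove_one_open_component(self):
        xs = np.linspace(0, 20, 41)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        Z = -1.0 * np.exp(-((X - 10.0) ** 2) / (2 * 0.8**2))
        surf = grid_surface(X, Y, Z)
        net = pat.extract_creases(surf)
        assert net.n_components == 1
        assert net.component_closed == [False]
        # the groove spans most of the sheet in y
        ys = surf.vertices[net.crease_vertices, 1]
        assert ys.max() - ys.min() > 14.0

    def test_ring_grooves_closed_components(self):
        xs = np.linspace(0, 30, 61)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        Z = np.zeros_like(X)
        centers = [(8, 8), (8, 22), (22, 8), (22, 22)]
        for cx, cy in centers:
            r = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
            Z -= 1.0 * np.exp(-((r - 4.0) ** 2) / (2 * 0.7**2))
        surf = grid_surface(X, Y, Z)
        net = pat.extract_creases(surf)
        closed = [c for c in net.component_closed if c]
        assert len(closed) == len(centers)
        assert net.fraction_open == pytest.approx(
            1 - len(closed) / net.n_components)

    def test_explicit_threshold_must_be_negative(self, flat_sheet):
        with pytest.raises(ValueError):
            pat.extract_creases(flat_sheet, threshold=0.1)


class TestDomains:
    def test_empty_network_one_domain(self, flat_sheet):
        net = pat.extract_creases(flat_sheet)
        labels = pat.segment_domains(flat_sheet, net)
        assert set(labels.tolist()) == {0}

    def test_square_lattice_grooves_domain_count(self):
        xs = np.linspace(0, 30, 61)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        Z = np.zeros_like(X)
        for line in (10.0, 20.0):
            Z -= np.exp(-((X - line) ** 2) / (2 * 0.6**2))
            Z -= np.exp(-((Y - line) ** 2) / (2 * 0.6**2))
        surf = grid_surface(X, Y, Z)
        # explicit threshold: the groove network covers more vertices than
        # the adaptive quantile would admit
        net = pat.extract_creases(surf, threshold=-0.5)
        labels = pat.segment_domains(surf, net)
        stats = pat.pattern_statistics(surf, net, labels)
        assert stats.n_domains == 9           # 3 x 3 cells

    def test_partition_property(self):
        xs = np.linspace(0, 20, 41)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        Z = -np.exp(-((X - 10.0) ** 2) / (2 * 0.8**2))
        surf = grid_surface(X, Y, Z)
        net = pat.extract_creases(surf)
        labels = pat.segment_domains(surf, net)
        crease = set(net.crease_vertices.tolist())
        for v in range(surf.n_vertices):
            if v in crease:
                assert labels[v] == -1
            else:
                assert labels[v] >= 0
        # domain areas partition the non-crease area
        table = pat.domain_table(surf, labels)
        areas = surf.vertex_areas()
        assert table["area"].sum() == pytest.approx(
            areas[labels >= 0].sum())


class TestStatistics:
    def test_flat_plane_stats(self, flat_sheet):
        net = pat.extract_creases(flat_sheet)
        labels = pat.segment_domains(flat_sheet, net)
        stats = pat.pattern_statistics(flat_sheet, net, labels)
        assert stats.crease_length_density == 0.0
        assert stats.n_domains == 1
        assert stats.fraction_open_creases == 0.0

    @pytest.mark.parametrize("lam0", [5.0, 8.0])
    def test_sinusoid_wavelength(self, lam0):
        xs = np.linspace(0, 20, 41)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        Z = 0.3 * np.sin(2 * np.pi * X / lam0)
        surf = grid_surface(X, Y, Z)
        est = pat.dominant_wavelength(surf)
        assert est == pytest.approx(lam0, rel=0.10)

    def test_uniform_scaling_scales_lengths_linearly(self):
        xs = np.linspace(0, 20, 41)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        Z = 0.3 * np.sin(2 * np.pi * X / 5.0) - np.exp(
            -((Y - 10.0) ** 2) / (2 * 0.8**2))
        s1 = grid_surface(X, Y, Z)
        s2 = TriSurface(2.0 * s1.vertices, s1.faces)
        n1, d1, st1 = pat.analyze_surface(s1)
        n2, d2, st2 = pat.analyze_surface(s2)
        assert st2.dominant_wavelength == pytest.approx(
            2 * st1.dominant_wavelength, rel=0.05)
        assert st2.surface_area == pytest.approx(4 * st1.surface_area,
                                                 rel=1e-6)
        if n1.total_crease_length > 0:
            assert n2.total_crease_length == pytest.approx(
                2 * n1.total_crease_length, rel=0.05)


class TestCompareSpecies:
    @staticmethod
    def _stats(density):
        return pat.PatternStats(
            n_domains=1, mean_domain_area=1.0,
            crease_length_density=density, fraction_open_creases=1.0,
            dominant_wavelength=5.0)

    def test_identical_batches_report_tie(self):
        batch = [self._stats(1.0)] * 3
        report = pat.compare_species({"sulcata": list(batch),
                                      "graeca": list(batch),
                                      "marginata": list(batch)})
        assert report["tie"] and report["ranking"] is None
        assert report["matches_expected"] is False

    def test_forced_ordering_reproduced(self):
        stats = {
            "sulcata": [self._stats(3.0 + d) for d in (-0.1, 0, 0.1)],
            "graeca": [self._stats(2.0 + d) for d in (-0.1, 0, 0.1)],
            "marginata": [self._stats(1.0 + d) for d in (-0.1, 0, 0.1)],
        }
        report = pat.compare_species(stats)
        assert report["ranking"] == ["sulcata", "graeca", "marginata"]
        assert report["matches_expected"] is True
        assert report["confidence"] > 0.95

    def test_refuses_fewer_than_three_replicates(self):
        stats = {"a": [self._stats(1.0)] * 3, "b": [self._stats(2.0)] * 2}
        with pytest.raises(ValueError, match="3"):
            pat.compare_species(stats)
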