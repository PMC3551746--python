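"""Geometry, transmural depth, local frames, helix angles, region labels."""

import numpy as np
import pytest

from cdtikit.cardioframe import (
    LAYER_NAMES,
    WALL_NAMES,
    LVGeometryModel,
    assign_layers,
    assign_walls,
    build_labels,
    helix_angle_map,
    local_frame,
    transmural_depth,
)
from cdtikit.core import GeometryError
from cdtikit.phantom import build_geometry
from cdtikit.tensorfit import EigenSystemField


@pytest.fixture(scope="module")
def annulus(quiet_config):
    geom = build_geometry(quiet_config)
    return geom, transmural_depth(geom)


def _eig_from_e1(e1_field, mask):
    """Anisotropic eigensystem with a prescribed principal direction."""
    shape = mask.shape
    evals = np.zeros(shape + (3,))
    evals[mask] = [1.7e-3, 0.4e-3, 0.15e-3]
    vecs = np.broadcast_to(np.eye(3), shape + (3, 3)).copy()
    vecs[mask, :, 0] = e1_field[mask]
    return EigenSystemField(eigenvalues=evals, eigenvectors=vecs, mask=mask)


def _frames(geom):
    from cdtikit.cardioframe import _frame_fields

    return _frame_fields(geom)


class TestTransmuralDepth:
    def test_midwall_depth_is_half(self, annulus, quiet_config):
        geom, depth = annulus
        cfg = quiet_config
        n = cfg.grid_size
        center = (n - 1) / 2
        rows, cols = np.mgrid[0:n, 0:n]
        radius = np.hypot(rows - center, cols - center) * cfg.pixel_spacing
        mid_r = (cfg.endo_radius + cfg.epi_radius) / 2
        ring = geom.myocardium_mask[0] & (np.abs(radius - mid_r) < cfg.pixel_spacing / 2)
        assert ring.any()
        tol = cfg.pixel_spacing / (cfg.epi_radius - cfg.endo_radius)
        assert np.abs(depth[0][ring] - 0.5).max() < tol

    def test_depth_bounds_and_boundary(self, annulus, quiet_config):
        geom, depth = annulus
        m = geom.myocardium_mask
        d = depth[m]
        assert d.min() >= 0 and d.max() <= 1
        # voxels adjacent to the cavity sit within one pixel of the border
        cfg = quiet_config
        pixel_frac = cfg.pixel_spacing / (cfg.epi_radius - cfg.endo_radius)
        from scipy import ndimage

        inner_rim = geom.myocardium_mask[0] & ndimage.binary_dilation(geom.cavity_mask[0])
        assert depth[0][inner_rim].max() < pixel_frac

    def test_radial_symmetry_of_rings(self, annulus, quiet_config):
        geom, depth = annulus
        cfg = quiet_config
        n = cfg.grid_size
        center = (n - 1) / 2
        rows, cols = np.mgrid[0:n, 0:n]
        radius_px = np.hypot(rows - center, cols - center)
        m = geom.myocardium_mask[0]
        # voxels related by the grid's dihedral symmetry (same unordered
        # |offset| pair from the centre) must get identical depths
        classes = {}
        for r, c in np.argwhere(m):
            dr, dc = abs(r - center), abs(c - center)
            classes.setdefault((min(dr, dc), max(dr, dc)), []).append(depth[0][r, c])
        for vals in classes.values():
            assert np.ptp(vals) < 1e-12
        # and depths track the analytic annulus within a pixel width
        analytic = (radius_px[m] * cfg.pixel_spacing - cfg.endo_radius) / (
            cfg.epi_radius - cfg.endo_radius
        )
        pixel_frac = cfg.pixel_spacing / (cfg.epi_radius - cfg.endo_radius)
        assert np.abs(depth[0][m] - np.clip(analytic, 0, 1)).max() < pixel_frac

    def test_empty_myocardium_raises(self, quiet_config):
        geom = build_geometry(quiet_config)
        bad = LVGeometryModel.__new__(LVGeometryModel)  # bypass validation
        bad.cavity_mask = geom.epi_mask.copy()
        bad.epi_mask = geom.epi_mask.copy()
        bad.centroids = geom.centroids
        with pytest.raises(GeometryError):
            transmural_depth(bad)


class TestLocalFrame:
    def test_east_voxel_frame(self, quiet_config):
        # odd grid puts the centroid exactly on a voxel
        import dataclasses

        geom = build_geometry(dataclasses.replace(quiet_config, grid_size=33))
        s = 0
        cr, cc = geom.centroids[s]
        assert cr == int(cr)
        voxel = (s, int(cr), int(cc) + 8)
        c_hat, l_hat, r_hat = local_frame(geom, voxel)
        assert np.allclose(r_hat, [1, 0, 0])
        assert np.allclose(l_hat, [0, 0, 1])
        assert np.allclose(c_hat, np.cross(l_hat, r_hat))
        assert np.allclose(c_hat, [0, 1, 0])

    def test_orthonormal_right_handed_everywhere(self, annulus):
        geom, _ = annulus
        c_hat, l_hat, r_hat = _frames(geom)
        m = geom.myocardium_mask
        triad = np.stack([c_hat[m], np.asarray(l_hat)[m], r_hat[m]], axis=-1)
        gram = np.einsum("nij,nik->njk", triad, triad)
        assert np.allclose(gram, np.eye(3), atol=1e-12)
        assert np.allclose(np.linalg.det(triad), 1.0, atol=1e-12)

    def test_centroid_radial_undefined(self, quiet_config):
        import dataclasses

        geom = build_geometry(dataclasses.replace(quiet_config, grid_size=33))
        cr, cc = geom.centroids[0]
        with pytest.raises(GeometryError):
            local_frame(geom, (0, int(cr), int(cc)))


class TestHelixAngle:
    @pytest.mark.parametrize(
        "combo,expected",
        [((1.0, 0.0), 0.0), ((1.0, 1.0), 45.0), ((1.0, -1.0), -45.0), ((0.0, 1.0), 90.0)],
    )
    def test_convention_angles(self, annulus, combo, expected):
        """e1 = a*c_hat + b*l_hat maps to the conventional helix angle."""
        geom, _ = annulus
        c_hat, l_hat, _ = _frames(geom)
        a, b = combo
        e1 = a * c_hat + b * l_hat
        e1 /= np.maximum(np.linalg.norm(e1, axis=-1, keepdims=True), 1e-30)
        m = geom.myocardium_mask
        ha = helix_angle_map(_eig_from_e1(e1, m), geom)
        assert np.allclose(ha.values[ha.mask], expected, atol=1e-9)

    def test_sign_invariance_under_eigenvector_flip(self, annulus):
        geom, _ = annulus
        c_hat, l_hat, _ = _frames(geom)
        e1 = (0.8 * c_hat + 0.6 * l_hat)
        m = geom.myocardium_mask
        ha_pos = helix_angle_map(_eig_from_e1(e1, m), geom)
        ha_neg = helix_angle_map(_eig_from_e1(-e1, m), geom)
        assert np.allclose(ha_pos.values[m], ha_neg.values[m], atol=1e-12)

    def test_longitudinal_reflection_negates_ha(self, annulus):
        geom, _ = annulus
        c_hat, l_hat, _ = _frames(geom)
        e1 = 0.7 * c_hat + 0.714142842854285 * l_hat
        e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
        m = geom.myocardium_mask
        reflected = e1 - 2 * np.sum(e1 * l_hat, axis=-1, keepdims=True) * l_hat
        ha = helix_angle_map(_eig_from_e1(e1, m), geom)
        ha_ref = helix_angle_map(_eig_from_e1(reflected, m), geom)
        assert np.allclose(ha_ref.values[m], -ha.values[m], atol=1e-9)

    def test_degenerate_leading_eigenvalues_masked(self, annulus):
        geom, _ = annulus
        m = geom.myocardium_mask
        evals = np.zeros(m.shape + (3,))
        evals[m] = [1e-3, 1e-3, 0.5e-3]  # lambda1 == lambda2
        vecs = np.broadcast_to(np.eye(3), m.shape + (3, 3)).copy()
        eig = EigenSystemField(eigenvalues=evals, eigenvectors=vecs, mask=m)
        ha = helix_angle_map(eig, geom)
        assert not ha.mask.any()

    def test_phantom_roundtrip_voxelwise_and_layers(self, quiet_result):
        """Noiseless pipeline HA equals the truth ramp."""
        res = quiet_result
        truth = res.truth
        ha = res.maps["HA"]
        common = ha.mask & truth.mask
        assert common.sum() == truth.mask.sum()
        assert np.abs(ha.values[common] - truth.ha_truth[common]).max() < 2.0
        labels = res.labels
        for l, name in enumerate(LAYER_NAMES):
            sel = common & (labels.layer == l)
            err = ha.values[sel].mean() - truth.ha_truth[sel].mean()
            assert abs(err) < 1.0
        # endocardium right-handed (positive), epicardium left-handed (negative)
        endo = common & (labels.layer == 0)
        epi = common & (labels.layer == 2)
        assert ha.values[endo].mean() > 0 > ha.values[epi].mean()


class TestLabels:
    @pytest.mark.parametrize(
        "d,expected", [(0.2, 0), (0.5, 1), (0.9, 2), (1 / 3, 1), (2 / 3, 2), (0.0, 0)]
    )
    def test_layer_rule_and_tiebreaks(self, d, expected):
        depth = np.array([[[d]]])
        mask = np.ones((1, 1, 1), bool)
        assert assign_layers(depth, mask)[0, 0, 0] == expected

    def test_layer_assignment_matches_analytic_annulus(self, annulus, quiet_config):
        """Layers agree voxelwise with the analytic-radius thirds, and their
        areas converge to the analytic ring areas at fine resolution."""
        import dataclasses

        geom, depth = annulus
        cfg = quiet_config
        labels = assign_layers(depth, geom.myocardium_mask)
        n = cfg.grid_size
        rows, cols = np.mgrid[0:n, 0:n]
        r_mm = np.hypot(rows - (n - 1) / 2, cols - (n - 1) / 2) * cfg.pixel_spacing
        analytic_d = np.clip(
            (r_mm - cfg.endo_radius) / (cfg.epi_radius - cfg.endo_radius), 0, 1
        )
        analytic = assign_layers(
            np.repeat(analytic_d[None], cfg.n_slices, axis=0), geom.myocardium_mask
        )
        m = geom.myocardium_mask
        assert (labels[m] == analytic[m]).mean() > 0.9

        fine = dataclasses.replace(cfg, grid_size=96, pixel_spacing=1.35, n_slices=1)
        fgeom = build_geometry(fine)
        flabels = assign_layers(transmural_depth(fgeom), fgeom.myocardium_mask)
        counts = np.bincount(flabels[flabels >= 0], minlength=3).astype(float)
        edges = np.linspace(fine.endo_radius, fine.epi_radius, 4)
        areas = np.diff(edges**2)  # ring area ∝ r_out² - r_in²
        assert np.allclose(counts / counts.sum(), areas / areas.sum(), atol=0.02)

    def test_wall_anchoring(self, annulus, quiet_config):
        geom, _ = annulus
        wall = assign_walls(geom)
        s = 0
        cr, cc = geom.centroids[s]
        az = np.radians(quiet_config.rv_azimuth)
        r_px = (quiet_config.endo_radius + quiet_config.epi_radius) / 2 / quiet_config.pixel_spacing
        septal_voxel = (s, int(round(cr + r_px * np.sin(az))), int(round(cc + r_px * np.cos(az))))
        lateral_voxel = (s, int(round(cr - r_px * np.sin(az))), int(round(cc - r_px * np.cos(az))))
        assert WALL_NAMES[wall[septal_voxel]] == "septal"
        assert WALL_NAMES[wall[lateral_voxel]] == "lateral"

    def test_wall_sector_areas_equal(self, annulus):
        geom, _ = annulus
        wall = assign_walls(geom)
        counts = np.bincount(wall[wall >= 0], minlength=4)
        assert counts.max() / counts.min() < 1.02 / 0.98

    def test_labels_partition_mask(self, annulus):
        geom, _ = annulus
        labels = build_labels(geom)
        m = labels.mask
        assert (labels.wall[m] >= 0).all() and (labels.layer[m] >= 0).all()
        assert (labels.wall[~m] == -1).all() and (labels.layer[~m] == -1).all()
        n = m.sum()
        assert np.bincount(labels.wall[m]).sum() == n
        assert np.bincount(labels.layer[m]).sum() == n
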