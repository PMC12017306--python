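import numpy as np
import pytest

from retidend import morpho, synthetic


def _line_skeleton(n=13, step=10.0):
    """Unbranched straight dendrite along +x, tip at (n-1)*step um."""
    ids = np.arange(1, n + 1)
    xyz = np.zeros((n, 3))
    xyz[:, 0] = np.arange(n) * step
    parent = np.r_[-1, ids[:-1]]
    return morpho.MorphologySkeleton(ids, xyz, np.ones(n), parent)


def _y_skeleton():
    # soma -> (10,0) -> branch to (10,20) and (30,0)
    ids = np.array([1, 2, 3, 4, 5])
    xyz = np.array([[0, 0, 0], [10, 0, 0], [10, 20, 0], [20, 0, 0],
                    [30, 0, 0]], float)
    parent = np.array([-1, 1, 2, 2, 4])
    return morpho.MorphologySkeleton(ids, xyz, np.ones(5), parent)


class TestHullMetrics:
    def test_square_closed_form(self):
        L = 100.0
        pts = np.array([[0, 0, 0], [L, 0, 0], [L, L, 0], [0, L, 0]])
        skel = morpho.MorphologySkeleton(np.arange(1, 5), pts, np.ones(4),
                                         np.array([-1, 1, 2, 3]))
        area, diam = morpho.hull_metrics(skel)
        assert area == pytest.approx(L**2)
        assert diam == pytest.approx(2 * L / np.sqrt(np.pi))

    def test_sampled_circle(self):
        r = 120.0
        ang = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        pts = np.c_[r * np.cos(ang), r * np.sin(ang), np.zeros(200)]
        skel = morpho.MorphologySkeleton(
            np.arange(1, 201), pts, np.ones(200),
            np.r_[-1, np.arange(1, 200)])
        _, diam = morpho.hull_metrics(skel)
        assert diam == pytest.approx(2 * r, rel=0.01)

    def test_rotation_translation_invariance(self):
        skel = synthetic.gen_morphology("temporal", seed=2)
        _, d0 = morpho.hull_metrics(skel)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xyz = skel.xyz.copy()
        xyz[:, :2] = xyz[:, :2] @ R.T + [123.0, -40.0]
        moved = morpho.MorphologySkeleton(skel.ids, xyz, skel.radius,
                                         skel.parent)
        _, d1 = morpho.hull_metrics(moved)
        assert d1 == pytest.approx(d0)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            morpho.hull_metrics(_line_skeleton())


class TestDendriticDistance:
    def test_straight_dendrite_tip(self):
        skel = _line_skeleton(13, 10.0)
        assert morpho.dendritic_distance(skel, [120.0, 0, 0]) \
            == pytest.approx(120.0)

    def test_y_tree_matches_parent_walk_oracle(self):
        skel = _y_skeleton()
        # independent oracle: walk parents, summing edge lengths
        idx = {i: k for k, i in enumerate(skel.ids)}
        def walk(node):
            total = 0.0
            while skel.parent[idx[node]] != -1:
                p = skel.parent[idx[node]]
                total += np.linalg.norm(skel.xyz[idx[node]] - skel.xyz[idx[p]])
                node = p
            return total
        for node_id, point in [(3, [10, 20, 0]), (5, [30, 0, 0])]:
            assert morpho.dendritic_distance(skel, point) \
                == pytest.approx(walk(node_id))

    def test_at_least_euclidean(self):
        skel = synthetic.gen_morphology("temporal", seed=5)
        rng = np.random.default_rng(1)
        for i in rng.integers(0, len(skel.ids), 10):
            p = skel.xyz[i]
            dd = morpho.dendritic_distance(skel, p)
            assert dd >= np.linalg.norm(p - skel.xyz[0]) - 1e-9


class TestRegisterField:
    def test_field_cut_from_template_recovered(self):
        skel = synthetic.gen_morphology("temporal", seed=3)
        stack, origin = morpho.skeleton_template_stack(
            skel, np.zeros(3), pixel_um=1.0, crop_um=120.0)
        iz, y0, x0 = 3, 35, 40  # a dendrite-rich window near the soma
        field = stack[iz, y0:y0 + 40, x0:x0 + 40]
        assert field.max() > 0
        pos = morpho.register_field(field, skel, expected_pos=np.zeros(3),
                                    pixel_um=1.0, crop_um=120.0, penalty=1e-6)
        expected = origin + np.array([x0 * 1.0, y0 * 1.0, iz * 2.0])
        assert np.linalg.norm(pos - expected) <= 1.5

    def test_noisy_field_recovered_within_one_pixel(self, rng):
        skel = synthetic.gen_morphology("temporal", seed=3)
        stack, origin = morpho.skeleton_template_stack(
            skel, np.zeros(3), pixel_um=1.0, crop_um=120.0)
        iz, y0, x0 = 3, 35, 40
        field = stack[iz, y0:y0 + 40, x0:x0 + 40] \
            + rng.normal(0, 0.02, (40, 40))
        pos = morpho.register_field(field, skel, expected_pos=np.zeros(3),
                                    pixel_um=1.0, crop_um=120.0, penalty=1e-6)
        expected = origin + np.array([x0 * 1.0, y0 * 1.0, iz * 2.0])
        assert np.linalg.norm(pos[:2] - expected[:2]) <= 1.0

    def test_percentile_clipping_bounds(self, rng):
        img = rng.normal(size=(50, 50))
        clipped = morpho._clip01_percentile(img)
        assert clipped.min() == 0.0 and clipped.max() == 1.0
        lo, hi = np.percentile(img, [20, 90])
        assert np.all(clipped[img <= lo] == 0.0)
        assert np.all(clipped[img >= hi] == 1.0)


class TestHexDensity:
    def test_total_length_conserved(self):
        skel = synthetic.gen_morphology("temporal", seed=4)
        fit = morpho.hex_density_fit(skel)
        # exact polygon clipping up to floating-point effects on shared
        # hexagon boundaries
        assert fit.lengths.sum() == pytest.approx(skel.total_length, rel=1e-3)

    def test_central_hexagon_captures_compact_cell(self):
        # all dendrite within the central hexagon -> profile is a delta at 0
        ids = np.array([1, 2, 3])
        xyz = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0]], float)
        skel = morpho.MorphologySkeleton(ids, xyz, np.ones(3),
                                         np.array([-1, 1, 1]))
        fit = morpho.hex_density_fit(skel, hex_spacing=16.0)
        radii = np.linalg.norm(fit.centers, axis=1)
        assert fit.lengths[radii > 1].sum() == pytest.approx(0.0)
        assert fit.lengths[np.argmin(radii)] == pytest.approx(6.0)

    def test_radial_gaussian_profile_recovered(self, rng):
        # planted Gaussian radial profile, fit directly
        r = np.linspace(0, 200, 60)
        sigma = 55.0
        y = 40.0 * np.exp(-r**2 / (2 * sigma**2))
        y = np.where(r <= 160.0, y, 0.0) + rng.normal(0, 0.5, len(r))
        amp, scale, cutoff = morpho.fit_radial_profile(r, np.maximum(y, 0))
        assert scale == pytest.approx(sigma, rel=0.10)

    def test_fit_on_generated_morphology(self):
        skel = synthetic.gen_morphology("nasal", seed=6)
        fit = morpho.hex_density_fit(skel)
        assert fit.converged
        assert fit.scale > 0 and fit.cutoff > 0


def test_swc_roundtrip(tmp_path):
    skel = synthetic.gen_morphology("temporal", seed=8)
    path = str(tmp_path / "cell.swc")
    morpho.write_swc(path, skel)
    back = morpho.read_swc(path, region="temporal")
    assert np.allclose(back.xyz, skel.xyz, atol=1e-3)
    assert np.array_equal(back.parent, skel.parent)
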