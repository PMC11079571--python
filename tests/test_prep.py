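"""Resampling, smoothing, orientation, rasterization, rotation and dataset
assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemonet import prep, synthetic as sv
from hemonet.errors import IncompleteComponentError, OrientationError
from hemonet.prep import (Profile1D, orient_daughter, orient_to_global,
                          rasterize_cross_section, resample_profile,
                          rotate_augment, smooth_profile)


class TestResample:
    def test_constant_stays_constant(self):
        xi = np.linspace(0, 1, 10)
        p = resample_profile(xi, np.full(10, 3.3), n=56)
        assert np.allclose(p.values, 3.3, atol=1e-12)

    def test_output_length_is_56(self):
        xi = np.linspace(0, 1, 9)
        p = resample_profile(xi, np.sin(xi), n=56)
        assert p.n == 56

    def test_cubic_reproduced_exactly(self):
        # not-a-knot splines reproduce cubics; oracle = direct evaluation
        f = lambda x: x ** 3 - 0.5 * x
        xi = np.linspace(0, 1, 12)
        p = resample_profile(xi, f(xi), n=56)
        assert np.max(np.abs(p.values - f(p.xi))) < 1e-10

    @given(st.integers(0, 3))
    @settings(max_examples=8, deadline=None)
    def test_polynomials_up_to_cubic_exact(self, degree):
        coeffs = np.arange(1, degree + 2, dtype=float)
        f = np.polynomial.Polynomial(coeffs)
        xi = np.linspace(0, 1, 11)
        p = resample_profile(xi, f(xi), n=31)
        assert np.max(np.abs(p.values - f(p.xi))) < 1e-9

    def test_endpoints_preserved(self):
        xi = np.linspace(0, 1, 8)
        vals = np.array([0.0, 1, 2, 1, 2, 1, 2, 5.0])
        p = resample_profile(xi, vals, n=25)
        assert p.values[0] == 0.0 and p.values[-1] == 5.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            resample_profile([0.0, 0.5, 1.0], [1.0, 2.0, 3.0])

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            resample_profile([0.0, 0.6, 0.4, 1.0], [1, 2, 3, 4.0])


class TestSmooth:
    def test_zero_weight_is_identity(self):
        xi = np.linspace(0, 1, 56)
        p = Profile1D(xi, np.sin(3 * xi))
        out = smooth_profile(p, lambda_s=0)
        assert np.max(np.abs(out.values - p.values)) < 1e-12

    def test_constant_unchanged(self):
        xi = np.linspace(0, 1, 56)
        p = Profile1D(xi, np.full(56, 2.0))
        out = smooth_profile(p, lambda_s=5.0)
        assert np.max(np.abs(out.values - 2.0)) < 1e-10

    def test_gcv_denoises_parabola(self):
        rng = np.random.default_rng(3)
        xi = np.linspace(0, 1, 56)
        clean = 4 * xi * (1 - xi)
        noisy = clean + rng.normal(0, 0.05, 56)
        out = smooth_profile(Profile1D(xi, noisy), lambda_s=None)
        rms_out = np.sqrt(np.mean((out.values - clean) ** 2))
        rms_in = np.sqrt(np.mean((noisy - clean) ** 2))
        assert rms_out < rms_in


class TestOrientation:
    def test_left_apex_unchanged(self):
        p = Profile1D(np.linspace(0, 1, 5), np.arange(5.0))
        out = orient_daughter(p, "left")
        assert np.array_equal(out.values, p.values)
        assert out.orientation == "apex_first"

    def test_right_apex_reverses(self):
        p = Profile1D(np.linspace(0, 1, 5), np.arange(5.0))
        out = orient_daughter(p, "right")
        assert np.array_equal(out.values, p.values[::-1])

    @pytest.mark.parametrize("side", ["left", "right"])
    def test_involution(self, side):
        p = Profile1D(np.linspace(0, 1, 9), np.arange(9.0) ** 2)
        back = orient_to_global(orient_daughter(p, side), side)
        assert np.allclose(back.values, p.values)
        assert back.orientation == "global"

    def test_double_orientation_rejected(self):
        p = Profile1D(np.linspace(0, 1, 5), np.arange(5.0))
        once = orient_daughter(p, "left")
        with pytest.raises(OrientationError):
            orient_daughter(once, "left")

    def test_daughter_hematocrit_peaks_on_apex_side(self, small_network,
                                                    small_flow):
        # after orientation both daughters' H maxima lie in the first half
        for node in small_network.nodes:
            if node.kind != "bifurcation":
                continue
            (left, right), apex = sv.bifurcation_daughters(small_network,
                                                           node.id)
            for v in (left, right):
                gt = sv.render_fields(small_flow, v.id, 0.0, noise_sd=0.0)
                oriented = orient_daughter(gt.profile_h, apex[v.id])
                assert np.argmax(oriented.values) < oriented.n // 2


class TestRasterize:
    def test_uniform_field(self):
        f = rasterize_cross_section(lambda x, y: np.full_like(x, 1.7), ng=32)
        assert np.all(f.grid[f.mask] == 1.7)
        assert np.all(f.grid[~f.mask] == 0.0)

    def test_grid_shape(self):
        f = rasterize_cross_section(lambda x, y: x, ng=32)
        assert f.grid.shape == (32, 32)

    def test_parabola_exact_at_cell_centers(self):
        f = rasterize_cross_section(lambda x, y: 1 - (x * x + y * y), ng=32)
        c = (np.arange(32) + 0.5) / 32 * 2 - 1
        xx, yy = np.meshgrid(c, c)
        expected = np.where(f.mask, 1 - (xx ** 2 + yy ** 2), 0.0)
        assert np.max(np.abs(f.grid - expected)) < 1e-12


class TestRotate:
    def _smooth_field(self, ng=32):
        # vanishes at the lumen boundary, like physical no-slip data
        return rasterize_cross_section(
            lambda x, y: np.maximum(1 - x * x - y * y, 0.0) *
            np.exp(-((x - 0.2) ** 2 + y ** 2) / 0.3), ng=ng)

    def test_zero_rotation_identity(self):
        f = self._smooth_field()
        out = rotate_augment(f, 0.0)
        assert np.array_equal(out.grid, f.grid)
        assert out.delta_beta == f.delta_beta

    def test_180_degrees_is_index_reversal(self):
        f = self._smooth_field()
        out = rotate_augment(f, 180.0)
        expected = f.grid[::-1, ::-1]
        common = f.mask & f.mask[::-1, ::-1]
        assert np.max(np.abs(out.grid[common] - expected[common])) < 1e-7

    def test_near_involution(self):
        f = self._smooth_field()
        back = rotate_augment(rotate_augment(f, 37.0), -37.0)
        err = np.max(np.abs(back.grid[f.mask] - f.grid[f.mask]))
        assert err < 0.05 * f.grid.max()
        assert back.delta_beta == pytest.approx(0.0)

    def test_delta_beta_accumulates(self):
        f = self._smooth_field()
        out = rotate_augment(rotate_augment(f, 10.0), 15.0)
        assert out.delta_beta == pytest.approx(25.0)

    def test_in_mask_mean_preserved(self):
        f = self._smooth_field()
        out = rotate_augment(f, 33.0)
        m_in = f.grid[f.mask].mean()
        m_out = out.grid[out.mask].mean()
        assert abs(m_out - m_in) < 0.01 * abs(m_in)


class TestBuildDataset:
    def test_component_counts_no_augment(self, small_network, small_flow,
                                         small_fields, small_dataset_2d):
        kinds = [n.kind for n in small_network.nodes]
        assert len(small_dataset_2d["bifurcation"]) == \
            kinds.count("bifurcation")
        assert len(small_dataset_2d["merger"]) == kinds.count("merger")
        assert len(small_dataset_2d["vessel"]) == len(small_network.vessels)

    def test_augment_count_adds_samples(self, tiny_network):
        flow = sv.solve_flow(tiny_network, seed=1)
        fields = sv.render_network(flow, ng=32, seed=3)
        ds = prep.build_dataset(tiny_network, flow, fields, mode="3d",
                                augment_count=100, seed=4)
        # one base sample plus 100 rotated copies per component
        assert len(ds["bifurcation"]) == 101
        assert len(ds["vessel"]) == 4 * 101

    def test_area_ratios_match_geometry(self, small_network,
                                        small_dataset_2d):
        for s in small_dataset_2d["bifurcation"]:
            mother = small_network.in_vessels(s.component_id)[0]
            (left, right), _ = sv.bifurcation_daughters(small_network,
                                                        s.component_id)
            assert s.scalars["a1"] == pytest.approx(
                (left.d_um / mother.d_um) ** 2, abs=1e-12)
            assert s.scalars["a2"] == pytest.approx(
                (right.d_um / mother.d_um) ** 2, abs=1e-12)

    def test_missing_ground_truth_raises(self, small_network, small_flow,
                                         small_fields):
        partial = dict(small_fields)
        partial.pop((small_network.vessels[0].id, "end"))
        with pytest.raises(IncompleteComponentError):
            prep.build_dataset(small_network, small_flow, partial, mode="2d")

    def test_deterministic_per_seed(self, tiny_network):
        flow = sv.solve_flow(tiny_network, seed=1)
        fields = sv.render_network(flow, ng=32, seed=3)
        a = prep.build_dataset(tiny_network, flow, fields, mode="3d",
                               augment_count=5, seed=9)
        b = prep.build_dataset(tiny_network, flow, fields, mode="3d",
                               augment_count=5, seed=9)
        for kind in a:
            for sa, sb in zip(a[kind], b[kind]):
                assert sa.scalars == sb.scalars
                for key in sa.inputs:
                    assert np.array_equal(sa.inputs[key].grid,
                                          sb.inputs[key].grid)

    def test_extra_samples_mixed_into_training_pool(self, tiny_network,
                                                    small_dataset_2d):
        # a few components from another network can augment the pool
        flow = sv.solve_flow(tiny_network, seed=1)
        fields = sv.render_network(flow, ng=32, seed=3)
        extra = small_dataset_2d["bifurcation"][:2]
        ds = prep.build_dataset(tiny_network, flow, fields, mode="2d",
                                extra_samples=extra)
        assert len(ds["bifurcation"]) == 1 + 2
        assert ds["bifurcation"][-1] is extra[-1]
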