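"""Scattered-data gridding: exactness, bounds, masking, serialization."""

import numpy as np
import pytest

from conftest import make_events
from metalase import (GridSpec, ImageStack, grid_channels, load_ome_tiff,
                      save_ome_tiff)


@pytest.fixture(scope="module")
def scattered():
    rng = np.random.default_rng(123)
    n = 300
    return rng.uniform(0, 100, n), rng.uniform(0, 60, n)


class TestGridChannels:
    @pytest.mark.parametrize("method", ["natural_neighbor", "linear"])
    def test_affine_field_reproduced_exactly(self, scattered, method):
        x, y = scattered
        ev = make_events(x, y, value_fn=lambda x, y: 2 * x + 3 * y)
        grid = GridSpec(origin=(8.0, 6.0), spacing=(1.3, 0.9), shape=(50, 60))
        stack = grid_channels(ev, grid=grid, method=method)
        xx, yy = np.meshgrid(grid.x, grid.y)
        exact = 2 * xx + 3 * yy
        img = stack.channel("af_nadh")
        m = np.isfinite(img)
        assert m.mean() > 0.9
        rel = np.abs(img[m] - exact[m]) / np.abs(exact[m])
        assert rel.max() <= 1e-9

    @pytest.mark.parametrize("method", ["natural_neighbor", "linear"])
    def test_constant_field_reproduced(self, scattered, method):
        x, y = scattered
        ev = make_events(x, y, value_fn=lambda x, y: np.full_like(x, 5.5))
        stack = grid_channels(ev, method=method, spacing_fast=2.0, spacing_slow=2.0)
        img = stack.channel("pars")
        np.testing.assert_allclose(img[np.isfinite(img)], 5.5, rtol=1e-12)

    def test_pixels_outside_hull_masked(self):
        # events on a disk: grid corners fall outside the convex hull
        th = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        x = 50 + 20 * np.cos(th)
        y = 50 + 20 * np.sin(th)
        ev = make_events(x, y, value_fn=lambda x, y: x)
        grid = GridSpec(origin=(25.0, 25.0), spacing=(2.5, 2.5), shape=(21, 21))
        stack = grid_channels(ev, grid=grid)
        assert not stack.mask[0, 0]
        assert stack.mask[10, 10]
        assert np.isnan(stack.channel("pars")[0, 0])

    @pytest.mark.parametrize("method", ["natural_neighbor", "linear"])
    def test_values_bounded_by_input_range(self, scattered, method):
        rng = np.random.default_rng(7)
        x, y = scattered
        v = rng.uniform(-3, 9, x.size)
        ev = make_events(x, y, value_fn=lambda x, y: v)
        stack = grid_channels(ev, method=method, spacing_fast=1.5, spacing_slow=1.5)
        img = stack.channel("uv_refl")
        assert np.nanmin(img) >= v.min() - 1e-9
        assert np.nanmax(img) <= v.max() + 1e-9

    def test_row_permutation_leaves_output_bit_identical(self, scattered):
        x, y = scattered
        ev = make_events(x, y, value_fn=lambda x, y: np.sin(x) + y)
        grid = GridSpec(origin=(10.0, 10.0), spacing=(2.0, 2.0), shape=(20, 40))
        stack1 = grid_channels(ev, grid=grid)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ev))
        ev2 = make_events(x[perm], y[perm],
                          value_fn=lambda x, y: np.sin(x) + y)
        stack2 = grid_channels(ev2, grid=grid)
        np.testing.assert_array_equal(stack1.channel("pars"), stack2.channel("pars"))

    def test_duplicate_positions_averaged(self):
        x = np.array([0.0, 10.0, 0.0, 5.0])
        y = np.array([0.0, 0.0, 0.0, 10.0])
        v = np.array([1.0, 2.0, 3.0, 4.0])
        ev = make_events(x, y, value_fn=lambda x, y: v)
        grid = GridSpec(origin=(2.0, 2.0), spacing=(1.0, 1.0), shape=(3, 3))
        stack = grid_channels(ev, grid=grid)  # duplicate (0,0) -> mean 2.0
        assert stack.meta["n_events"] == 3
        assert np.isfinite(stack.channel("pars")).any()

    def test_degenerate_event_cloud_rejected(self):
        x = np.linspace(0, 10, 5)
        ev = make_events(x, np.zeros(5), value_fn=lambda x, y: x)
        with pytest.raises(ValueError, match="degenerate"):
            grid_channels(ev)

    def test_unknown_method_rejected(self, scattered):
        x, y = scattered
        ev = make_events(x, y, value_fn=lambda x, y: x)
        with pytest.raises(ValueError, match="method"):
            grid_channels(ev, method="kriging")


class TestGridSpec:
    def test_auto_grid_inside_bounding_box(self, scattered):
        x, y = scattered
        ev = make_events(x, y, value_fn=lambda x, y: x)
        g = GridSpec.from_events(ev, spacing_fast=1.0, spacing_slow=2.0)
        assert g.x.min() >= x.min() and g.x.max() <= x.max()
        assert g.y.min() >= y.min() and g.y.max() <= y.max()

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            GridSpec(origin=(0, 0), spacing=(0.0, 1.0), shape=(4, 4))


class TestOmeTiff:
    def test_round_trip_preserves_data_and_metadata(self, scattered, tmp_path):
        x, y = scattered
        ev = make_events(x, y, value_fn=lambda x, y: x * y / 100.0)
        grid = GridSpec(origin=(20.0, 15.0), spacing=(1.5, 3.0), shape=(12, 40))
        stack = grid_channels(ev, grid=grid)
        p = tmp_path / "stack.ome.tif"
        save_ome_tiff(stack, p)
        back = load_ome_tiff(p)
        assert list(back.channels) == list(stack.channels)
        assert back.grid.spacing == stack.grid.spacing
        assert back.grid.origin == pytest.approx(stack.grid.origin)
        np.testing.assert_allclose(back.channel("af_fad"),
                                   stack.channel("af_fad").astype(np.float32),
                                   rtol=1e-6, equal_nan=True)
        assert back.meta["method"] == "natural_neighbor"

    def test_write_is_deterministic(self, scattered, tmp_path):
        x, y = scattered
        ev = make_events(x, y, value_fn=lambda x, y: x)
        stack = grid_channels(ev, spacing_fast=2.0, spacing_slow=2.0)
        p1, p2 = tmp_path / "a.tif", tmp_path / "b.tif"
        save_ome_tiff(stack, p1)
        save_ome_tiff(stack, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_shape_mismatch_rejected(self):
        grid = GridSpec(origin=(0, 0), spacing=(1, 1), shape=(4, 4))
        with pytest.raises(ValueError, match="shape"):
            ImageStack(channels={"pars": np.zeros((3, 4))},
                       mask=np.ones((4, 4), dtype=bool), grid=grid)
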