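"""Stack quantification: preprocessing, counting, selection, projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from layerquant import (
    ConfigurationError,
    ImageStack,
    LayerProfile,
    count_channel_pixels,
    median_filter,
    quantify_stack,
    relative_intensity,
    select_layers,
    stack_thickness,
    subtract_background,
    z_projection,
)


def stack_from(marker, membrane=None, nuclei=None):
    marker = np.asarray(marker, dtype=float)
    if marker.ndim == 2:
        marker = marker[None]
    membrane = np.full_like(marker, 100.0) if membrane is None else np.asarray(membrane, float)
    nuclei = np.zeros_like(marker) if nuclei is None else np.asarray(nuclei, float)
    return ImageStack(np.stack([marker, membrane, nuclei]))


def profile_from(r, defined=None):
    r = np.asarray(r, dtype=float)
    defined = np.ones(r.size, dtype=bool) if defined is None else np.asarray(defined, bool)
    return LayerProfile(r=r, defined=defined)


class TestSubtractBackground:
    def test_zero_layer_stays_zero(self):
        out = subtract_background(stack_from(np.zeros((8, 8))), "percentile", 20)
        assert np.all(out.channel("marker") == 0)

    def test_constant_method_exact_cancellation(self):
        out = subtract_background(stack_from(np.full((8, 8), 10.0)), "constant", 10)
        assert np.all(out.channel("marker") == 0)

    def test_percentile_matches_direct_recomputation(self):
        rng = np.random.default_rng(0)
        layer = rng.integers(0, 256, (16, 16)).astype(float)
        out = subtract_background(stack_from(layer), "percentile", 50).channel("marker")[0]
        expected = np.clip(layer - np.percentile(layer, 50), 0, None)
        np.testing.assert_array_equal(out, expected)
        assert np.median(out) == pytest.approx(0.0, abs=0.5)

    def test_invalid_inputs_rejected(self):
        s = stack_from(np.zeros((8, 8)))
        with pytest.raises(ConfigurationError):
            subtract_background(s, "percentile", 150)
        with pytest.raises(ConfigurationError):
            subtract_background(s, "gaussian", 1)


class TestMedianFilter:
    def test_window_one_is_identity(self):
        s = stack_from(np.arange(64.0).reshape(8, 8))
        np.testing.assert_array_equal(median_filter(s, 1).voxels, s.voxels)

    def test_removes_single_bright_pixel(self):
        layer = np.zeros((9, 9))
        layer[4, 4] = 255
        out = median_filter(stack_from(layer), 3)
        assert np.all(out.channel("marker") == 0)

    def test_matches_per_pixel_brute_force(self):
        rng = np.random.default_rng(1)
        layer = rng.integers(0, 100, (5, 5)).astype(float)
        out = median_filter(stack_from(layer), 3).channel("marker")[0]
        # scipy's 'reflect' boundary duplicates the edge sample (numpy 'symmetric')
        padded = np.pad(layer, 1, mode="symmetric")
        expected = np.empty_like(layer)
        for i in range(5):
            for j in range(5):
                expected[i, j] = np.median(padded[i : i + 3, j : j + 3])
        np.testing.assert_array_equal(out, expected)

    def test_even_window_rejected(self):
        with pytest.raises(ConfigurationError):
            median_filter(stack_from(np.zeros((8, 8))), 4)


class TestCounting:
    def test_infinite_threshold_counts_nothing(self):
        counts = count_channel_pixels(stack_from(np.ones((8, 8))), np.inf)
        assert (counts == 0).all().all()

    def test_binary_mask_counted_exactly(self):
        layer = np.zeros((10, 10))
        layer.flat[:37] = 1.0
        counts = count_channel_pixels(stack_from(layer), 0.0)
        assert counts.loc[1, "marker"] == 37

    def test_raising_threshold_never_increases_counts(self):
        rng = np.random.default_rng(2)
        s = stack_from(rng.integers(0, 50, (4, 12, 12)).astype(float))
        low = count_channel_pixels(s, 5.0)
        high = count_channel_pixels(s, 20.0)
        assert (high["marker"] <= low["marker"]).all()


class TestRelativeIntensity:
    def test_basic_ratio(self):
        counts = pd.DataFrame({"marker": [50], "membrane": [5000], "nuclei": [0]})
        assert relative_intensity(counts).r[0] == pytest.approx(0.01)

    def test_zero_marker_everywhere(self):
        counts = pd.DataFrame({"marker": [0, 0], "membrane": [10, 20], "nuclei": [0, 0]})
        np.testing.assert_array_equal(relative_intensity(counts).r, [0.0, 0.0])

    def test_zero_membrane_flagged_undefined(self):
        counts = pd.DataFrame({"marker": [3], "membrane": [0], "nuclei": [0]})
        profile = relative_intensity(counts)
        assert not profile.defined[0]
        assert np.isnan(profile.r[0])


class TestSelectLayers:
    def make(self, first, last, n_layers):
        r = np.zeros(n_layers)
        r[first - 1 : last] = 0.2
        return profile_from(r)

    @pytest.mark.parametrize(
        "first,last,n_layers,n_sel,thickness",
        [(13, 60, 199, 48, 33.6), (1, 20, 215, 20, 14.0), (10, 118, 182, 109, 76.3)],
    )
    def test_contiguous_runs_and_thickness(self, first, last, n_layers, n_sel, thickness):
        sel = select_layers(self.make(first, last, n_layers), cutoff=0.01)
        assert (sel.first, sel.last, sel.n_selected) == (first, last, n_sel)
        assert sel.thickness == pytest.approx(thickness)

    def test_all_below_cutoff_gives_empty_selection(self):
        sel = select_layers(profile_from(np.full(50, 0.005)), cutoff=0.01)
        assert sel.empty and sel.thickness == 0.0 and sel.first is None

    def test_longest_run_wins_over_earlier_shorter_run(self):
        r = np.zeros(30)
        r[1:4] = 0.2   # run of 3
        r[10:20] = 0.2  # run of 10
        sel = select_layers(profile_from(r))
        assert (sel.first, sel.last) == (11, 20)

    def test_mode_all_counts_every_supra_cutoff_layer(self):
        r = np.zeros(30)
        r[1:4] = 0.2
        r[10:20] = 0.2
        sel = select_layers(profile_from(r), mode="all")
        assert sel.n_selected == 13
        assert (sel.first, sel.last) == (2, 20)

    def test_cutoff_is_strict_and_monotone(self):
        r = np.array([0.01, 0.02, 0.02, 0.005])
        assert select_layers(profile_from(r), cutoff=0.01).n_selected == 2
        rng = np.random.default_rng(4)
        prof = profile_from(rng.uniform(0, 0.1, 80))
        lengths = [select_layers(prof, cutoff=c).n_selected for c in (0.0, 0.02, 0.05, 0.1)]
        assert lengths == sorted(lengths, reverse=True)

    def test_undefined_layers_never_selected(self):
        prof = profile_from([np.nan, 0.5, 0.5], defined=[False, True, True])
        sel = select_layers(prof)
        assert (sel.first, sel.last) == (2, 3)


class TestGeometry:
    @pytest.mark.parametrize(
        "n,expected", [(199, 139.3), (182, 127.4), (190, 133.0), (215, 150.5), (0, 0.0)]
    )
    def test_thickness_of_scanned_stacks(self, n, expected):
        assert stack_thickness(n) == pytest.approx(expected)

    def test_negative_layer_count_rejected(self):
        with pytest.raises(ConfigurationError):
            stack_thickness(-1)


class TestZProjection:
    def test_single_layer_identity(self):
        layer = np.arange(64.0).reshape(8, 8)
        s = stack_from(layer)
        np.testing.assert_array_equal(z_projection(s)[0], layer)

    def test_two_constant_layers_sum(self):
        marker = np.stack([np.full((8, 8), 3.0), np.full((8, 8), 5.0)])
        assert np.all(z_projection(stack_from(marker))[0] == 8.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_sum_projection_conserves_total_intensity(self, seed):
        rng = np.random.default_rng(seed)
        voxels = rng.integers(0, 1000, (3, 4, 8, 8)).astype(np.int64)
        s = ImageStack(voxels)
        assert z_projection(s).sum() == voxels.sum()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            z_projection(stack_from(np.zeros((8, 8))), mode="max")


class TestStackValidation:
    def test_shape_and_negativity_checks(self):
        with pytest.raises(ConfigurationError):
            ImageStack(np.zeros((2, 4, 8, 8)))
        with pytest.raises(ConfigurationError):
            ImageStack(-np.ones((3, 4, 8, 8)))

    def test_channel_order_is_enforced(self):
        with pytest.raises(ConfigurationError):
            ImageStack(np.zeros((3, 1, 8, 8)), channel_names=("membrane", "marker", "nuclei"))


def test_quantify_stack_composes_the_stages():
    rng = np.random.default_rng(8)
    marker = (rng.random((5, 16, 16)) < 0.2) * 150.0
    s = stack_from(marker)
    profile = quantify_stack(s, background=None, median_window=1)
    expected = (marker > 0).sum(axis=(1, 2)) / 256
    np.testing.assert_allclose(profile.r, expected)
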