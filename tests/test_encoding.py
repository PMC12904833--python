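import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromoglyph import (
    EncodingError,
    Scene,
    apply_mask,
    categorical_palette,
    continuous_colormap,
    normalize_values,
    resolve_view_config,
    validate_view_config,
)
from chromoglyph.encoding import auto_base_size
from conftest import random_structure


class TestValidateViewConfig:
    def test_empty_config_is_valid_defaults(self):
        assert validate_view_config({}).is_valid

    def test_unknown_mark_lists_allowed(self):
        report = validate_view_config({"mark": "tetrahedron"})
        assert not report.is_valid
        assert "sphere" in report.errors[0][2]

    def test_constant_and_field_together_rejected(self):
        report = validate_view_config(
            {"color": {"constant": "#fff", "field": "v"}}
        )
        assert any(rule == "channel-form" for rule, _, _ in report.errors)

    def test_unknown_keys_are_errors_fail_fast(self):
        assert not validate_view_config({"colour": "#fff"}).is_valid
        assert not validate_view_config(
            {"color": {"field": "v", "fields": "w"}}
        ).is_valid

    def test_unknown_colormap_rejected(self):
        report = validate_view_config(
            {"color": {"field": "v", "range": "jet2000"}}
        )
        assert not report.is_valid


class TestNormalizeValues:
    @pytest.mark.parametrize(
        "values, domain, expected",
        [
            ([0, 5, 10], None, [0, 0.5, 1]),
            ([5], [0, 20], [0.25]),
            ([30], [0, 20], [1.0]),       # clipped
            ([-5], [0, 20], [0.0]),       # clipped low
            ([3, 3, 3], None, [0.5] * 3), # degenerate
        ],
    )
    def test_examples(self, values, domain, expected):
        np.testing.assert_allclose(normalize_values(values, domain), expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    def test_output_always_in_unit_interval(self, values):
        t = normalize_values(values)
        assert ((t >= 0) & (t <= 1)).all()


class TestColormaps:
    def test_bluered_endpoints_and_midpoint(self):
        np.testing.assert_array_equal(
            continuous_colormap("bluered", 0.0), [0, 0, 255, 255]
        )
        np.testing.assert_array_equal(
            continuous_colormap("bluered", 1.0), [255, 0, 0, 255]
        )
        np.testing.assert_array_equal(
            continuous_colormap("bluered", 0.5), [128, 0, 128, 255]
        )

    def test_viridis_endpoints_hit_first_and_last_anchor(self):
        from matplotlib import colormaps

        table = np.asarray(colormaps["viridis"].colors)
        np.testing.assert_array_equal(
            continuous_colormap("viridis", 0.0)[:3],
            np.floor(table[0] * 255 + 0.5),
        )
        np.testing.assert_array_equal(
            continuous_colormap("viridis", 1.0)[:3],
            np.floor(table[-1] * 255 + 0.5),
        )

    def test_unknown_name_lists_builtins(self):
        with pytest.raises(EncodingError, match="viridis"):
            continuous_colormap("turbo2", 0.5)

    def test_vectorized_lookup_matches_scalar(self):
        t = np.linspace(0, 1, 7)
        batch = continuous_colormap("viridis", t)
        for i, ti in enumerate(t):
            np.testing.assert_array_equal(
                batch[i], continuous_colormap("viridis", float(ti))
            )


class TestCategoricalPalette:
    def test_three_categories_distinct_and_deterministic(self):
        m1 = categorical_palette(["a", "b", "c"])
        m2 = categorical_palette(["a", "b", "c"])
        assert len({tuple(v) for v in m1.values()}) == 3
        for k in m1:
            np.testing.assert_array_equal(m1[k], m2[k])

    def test_color_follows_first_appearance_order(self):
        m1 = categorical_palette(["a", "b"])
        m2 = categorical_palette(["b", "a"])
        np.testing.assert_array_equal(m1["a"], m2["b"])
        np.testing.assert_array_equal(m1["b"], m2["a"])

    def test_thirteenth_category_cycles_with_warning(self):
        cats = [f"c{i}" for i in range(13)]
        with pytest.warns(UserWarning, match="repeat"):
            mapping = categorical_palette(cats)
        np.testing.assert_array_equal(mapping["c12"], mapping["c0"])


class TestResolveViewConfig:
    def test_categorical_chrom_color_one_color_per_chromosome(self):
        table = random_structure(seed=20)  # multiple chromosomes
        attrs = resolve_view_config(
            table, {"color": {"field": "chrom", "scale_type": "categorical"}}
        )
        chroms = np.asarray(table["chrom"], dtype=object)
        colors_by_chrom = {
            c: {tuple(rgba) for rgba in attrs.rgba[chroms == c]}
            for c in set(chroms)
        }
        assert all(len(s) == 1 for s in colors_by_chrom.values())
        distinct = {next(iter(s)) for s in colors_by_chrom.values()}
        assert len(distinct) == len(colors_by_chrom)

    def test_continuous_endpoints_hit_colormap_anchors(self, simple_table):
        simple_table["v"] = [2.0, 9.0, 5.0]
        attrs = resolve_view_config(
            simple_table,
            {"color": {"field": "v", "scale_type": "continuous",
                       "range": "bluered"}},
        )
        np.testing.assert_array_equal(attrs.rgba[0], [0, 0, 255, 255])
        np.testing.assert_array_equal(attrs.rgba[1], [255, 0, 0, 255])

    def test_constants_broadcast(self, simple_table):
        attrs = resolve_view_config(
            simple_table,
            {"color": {"constant": "#ff0000"}, "scale": {"constant": 2.0},
             "base_size": 1.0},
        )
        assert (attrs.rgba == [255, 0, 0, 255]).all()
        np.testing.assert_allclose(attrs.size, 2.0)
        assert set(attrs.mark) == {"sphere"}

    def test_rgba_hex_alpha_supported(self, simple_table):
        attrs = resolve_view_config(simple_table, {"color": "#11223380"})
        np.testing.assert_array_equal(attrs.rgba[0], [17, 34, 51, 128])

    def test_output_length_always_matches_and_is_deterministic(self):
        table = random_structure(seed=21)
        table["v"] = np.random.default_rng(0).random(len(table))
        config = {"color": {"field": "v"}, "scale": {"field": "v"}}
        a1 = resolve_view_config(table, config)
        a2 = resolve_view_config(table, config)
        assert len(a1) == len(table)
        np.testing.assert_array_equal(a1.rgba, a2.rgba)
        np.testing.assert_array_equal(a1.size, a2.size)

    def test_missing_field_error_names_available_columns(self, simple_table):
        with pytest.raises(EncodingError, match="chrom"):
            resolve_view_config(simple_table, {"color": {"field": "nope"}})

    def test_continuous_over_categorical_column_rejected(self, simple_table):
        with pytest.raises(EncodingError, match="categorical"):
            resolve_view_config(
                simple_table,
                {"color": {"field": "chrom", "scale_type": "continuous"}},
            )

    def test_zero_spread_domain_warns_and_maps_to_midpoint(self, simple_table):
        simple_table["v"] = [3.0, 3.0, 3.0]
        with pytest.warns(UserWarning, match="zero-spread"):
            attrs = resolve_view_config(
                simple_table,
                {"color": {"field": "v", "range": "bluered"}},
            )
        np.testing.assert_array_equal(attrs.rgba[0], [128, 0, 128, 255])

    def test_scale_maps_into_range_and_sizes_positive(self, simple_table):
        simple_table["v"] = [0.0, 1.0, 0.5]
        attrs = resolve_view_config(
            simple_table,
            {"scale": {"field": "v", "range": [0.5, 2.0]}, "base_size": 1.0},
        )
        np.testing.assert_allclose(attrs.size, [0.5, 2.0, 1.25])
        assert (attrs.size > 0).all()

    def test_auto_base_size_is_half_median_consecutive_gap(self, simple_table):
        # consecutive gaps: 1.0 and sqrt(2) -> median ~1.207
        expected = 0.5 * np.median([1.0, np.sqrt(2.0)])
        assert auto_base_size(simple_table) == pytest.approx(expected)

    def test_color_invariant_under_unrelated_column_append(self, simple_table):
        simple_table["v"] = [1.0, 2.0, 3.0]
        base = resolve_view_config(simple_table, {"color": {"field": "v"}})
        extended = simple_table.assign(unrelated=["p", "q", "r"])
        again = resolve_view_config(extended, {"color": {"field": "v"}})
        np.testing.assert_array_equal(base.rgba, again.rgba)

    def test_monotone_data_gives_monotone_interpolation_parameter(self):
        table = random_structure(seed=22)
        table["v"] = np.linspace(0, 1, len(table))
        attrs = resolve_view_config(
            table, {"scale": {"field": "v"}, "base_size": 1.0}
        )
        assert (np.diff(attrs.size) >= 0).all()

    def test_subset_resolution_matches_only_for_constant_channels(self):
        table = random_structure(seed=23)
        table["v"] = np.random.default_rng(5).random(len(table))
        mask = np.zeros(len(table), dtype=bool)
        mask[: len(table) // 2] = True
        subset = apply_mask(table, mask)

        const_cfg = {"color": {"constant": "#aabbcc"}, "base_size": 1.0}
        full = resolve_view_config(table, const_cfg)
        sub = resolve_view_config(subset, const_cfg)
        np.testing.assert_array_equal(full.rgba[mask], sub.rgba)

        # data-driven domains are recomputed on the subset: documented
        # as NOT equal in general (pin `domain` for comparability)
        data_cfg = {"color": {"field": "v", "range": "bluered"}}
        full = resolve_view_config(table, data_cfg)
        sub = resolve_view_config(subset, data_cfg)
        assert not np.array_equal(full.rgba[mask], sub.rgba)
        pinned = {"color": {"field": "v", "range": "bluered",
                            "domain": [0.0, 1.0]}}
        full = resolve_view_config(table, pinned)
        sub = resolve_view_config(subset, pinned)
        np.testing.assert_array_equal(full.rgba[mask], sub.rgba)


def test_scene_holds_ordered_entries(simple_table):
    scene = Scene().add(simple_table).add(simple_table, {"mark": "box"})
    assert len(scene) == 2
    assert scene.entries[1][1] == {"mark": "box"}
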