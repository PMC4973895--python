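"""Layout heuristics: coordinates, ticks, labels, stagger, radii."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import needleplot as nd
from needleplot import fixtures, layout_engine as le
from needleplot.errors import LayoutError
from needleplot.variant_parser import Variant

from conftest import assert_no_head_overlap, assert_tick_completeness


class TestAaToPx:
    def test_left_edge_closed_form(self):
        cfg = nd.DrawConfig(plot_width=700, pad=10)
        assert le.aa_to_px(1, 100, cfg) == pytest.approx(13.4)

    def test_right_edge_symmetric(self):
        cfg = nd.DrawConfig(plot_width=700, pad=10)
        assert le.aa_to_px(100, 100, cfg) == pytest.approx(686.6)
        # symmetric about the plot center
        assert le.aa_to_px(1, 100, cfg) + le.aa_to_px(100, 100, cfg) == pytest.approx(700)

    def test_out_of_range_is_layout_error(self):
        cfg = nd.DrawConfig()
        with pytest.raises(LayoutError):
            le.aa_to_px(0, 100, cfg)
        with pytest.raises(LayoutError):
            le.aa_to_px(101, 100, cfg)

    @given(
        st.integers(min_value=2, max_value=2000),
        st.floats(min_value=100, max_value=3000),
        st.floats(min_value=1, max_value=40),
    )
    def test_strictly_monotone_within_padded_area(self, length, width, pad):
        cfg = nd.DrawConfig(plot_width=width, pad=pad)
        step = max(1, length // 50)
        previous = None
        for position in range(1, length + 1, step):
            x = le.aa_to_px(position, length, cfg)
            assert cfg.pad <= x <= cfg.plot_width - cfg.pad
            if previous is not None:
                assert x > previous
            previous = x


class TestTextWidth:
    def test_empty_string_is_zero(self):
        assert le.estimate_text_width("", 12) == 0

    def test_appending_never_shrinks(self):
        for text in ["A", "P53", "..TAD", "Fibrinogen"]:
            for extra in "Wi.":
                assert le.estimate_text_width(text + extra, 12) >= le.estimate_text_width(
                    text, 12
                )

    def test_known_value_from_packaged_metrics(self):
        # frozen from the packaged DejaVu Sans advance table
        assert le.estimate_text_width("P53", 12) == pytest.approx(22.5, abs=0.01)

    def test_scales_linearly_with_font_size(self):
        assert le.estimate_text_width("P53", 24) == pytest.approx(
            2 * le.estimate_text_width("P53", 12)
        )

    def test_unknown_characters_use_average_advance(self):
        assert le.estimate_text_width("α", 12) > 0


class TestSelectTicks:
    def test_no_variants_full_candidate_set_survives(self, config):
        arch = nd.ProteinArchitecture(
            accession="", gene_symbol="", length=200,
            domains=(nd.DomainRegion("PF1", "D", "domain D", 50, 120, "#112233"),),
        )
        ticks = nd.select_ticks(arch, [], config)
        assert ticks.positions() == (1, 50, 120, 200)

    def test_variant_beats_colliding_domain_boundary(self, config):
        arch = nd.ProteinArchitecture(
            accession="", gene_symbol="", length=2000,
            domains=(nd.DomainRegion("PF1", "D", "domain D", 50, 1200, "#112233"),),
        )
        variants = [Variant(52, "R52H")]
        ticks = nd.select_ticks(arch, variants, config)
        positions = ticks.positions()
        assert 52 in positions
        assert 50 not in positions  # culled by the higher-priority variant label
        assert_tick_completeness(arch, variants, config, ticks)

    def test_equal_priority_keeps_leftmost(self, config):
        arch = nd.ProteinArchitecture(accession="", gene_symbol="", length=2000)
        variants = [Variant(1000, "A1000B"), Variant(1004, "A1004B")]
        ticks = nd.select_ticks(arch, variants, config)
        assert 1000 in ticks.positions()
        assert 1004 not in ticks.positions()

    def test_duplicate_positions_keep_max_priority(self, config):
        arch = nd.ProteinArchitecture(
            accession="", gene_symbol="", length=400,
            domains=(nd.DomainRegion("PF1", "D", "d", 100, 300, "#112233"),),
        )
        ticks = nd.select_ticks(arch, [Variant(100, "R100H")], config)
        by_pos = {t.position: t.priority for t in ticks.ticks}
        assert by_pos[100] == le.PRIORITY_VARIANT

    def test_variant_beyond_length_is_layout_error(self, config, tp53_arch):
        with pytest.raises(LayoutError, match="beyond"):
            nd.select_ticks(tp53_arch, [Variant(400, "R400H")], config)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_completeness_oracle_on_random_fixtures(self, seed):
        config = nd.DrawConfig()
        rng_doc = fixtures.generate_architecture(
            seed=seed, n_domains=seed % 5, n_motifs=seed % 3, length=120 + (seed % 900)
        )
        arch = nd.load_architecture_json(rng_doc)
        specs = fixtures.generate_variants(seed=seed, n=seed % 8, length=arch.length)
        variants = nd.parse_variants(specs)
        ticks = nd.select_ticks(arch, variants, config)
        assert_tick_completeness(arch, variants, config, ticks)


class TestChooseDomainLabel:
    def test_wide_box_gets_full_description(self, tp53_arch, config):
        p53 = tp53_arch.domains[1]
        choice = nd.choose_domain_label(p53, tp53_arch.domains, 350.0, config)
        assert choice.mode == "description"
        assert choice.text == "P53 DNA-binding domain"

    def test_narrow_box_abbreviates_shared_prefix(self, tp53_arch, config):
        tad = tp53_arch.domains[0]
        choice = nd.choose_domain_label(tad, tp53_arch.domains, 43.0, config)
        assert choice.mode == "abbreviated"
        assert choice.text == "..TAD"

    def test_fib_prefix_dropped_but_suffix_kept(self, fga_arch, config):
        aC = next(d for d in fga_arch.domains if d.short_name == "Fib_aC")
        choice = nd.choose_domain_label(aC, fga_arch.domains, 40.0, config)
        assert choice.mode == "abbreviated"
        assert choice.text == "..aC"

    def test_mid_box_falls_back_to_short_name(self, fga_arch, config):
        alpha = fga_arch.domains[0]
        choice = nd.choose_domain_label(alpha, fga_arch.domains, 80.0, config)
        assert choice.mode == "name"
        assert choice.text == "Fib_alpha"

    def test_hopeless_box_hides_label(self, tp53_arch, config):
        choice = nd.choose_domain_label(tp53_arch.domains[0], tp53_arch.domains, 6.0, config)
        assert choice.mode == "hidden" and choice.text is None

    def test_no_shared_prefix_means_no_abbreviation(self, config):
        lonely = nd.DomainRegion("PF1", "Unique_name", "a very long description", 1, 10, "#112233")
        other = nd.DomainRegion("PF2", "Other_tag", "x", 20, 30, "#112233")
        choice = nd.choose_domain_label(lonely, [lonely, other], 30.0, config)
        assert choice.mode == "hidden"


class TestScaleRadii:
    def test_equal_magnitudes_all_base_radius(self, config):
        variants = [Variant(i, f"A{i}B") for i in (10, 20, 30)]
        assert nd.scale_radii(variants, config) == [config.base_radius] * 3

    def test_extremes_hit_bounds(self, config):
        variants = [Variant(10, "A10B", None, 1.0), Variant(20, "A20B", None, 42.0)]
        radii = nd.scale_radii(variants, config)
        assert radii[0] == pytest.approx(config.min_radius)
        assert radii[1] == pytest.approx(config.max_radius)

    def test_sqrt_interpolation(self, config):
        variants = [
            Variant(10, "A10B", None, 1.0),
            Variant(20, "A20B", None, 5.0),
            Variant(30, "A30B", None, 9.0),
        ]
        radii = nd.scale_radii(variants, config)
        expected_mid = config.min_radius + (
            config.max_radius - config.min_radius
        ) * math.sqrt(0.5)
        assert radii[1] == pytest.approx(expected_mid)

    @given(st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=1, max_size=30))
    def test_rank_order_preserved_and_bounded(self, magnitudes):
        config = nd.DrawConfig()
        variants = [
            Variant(i + 1, f"A{i + 1}B", None, m) for i, m in enumerate(magnitudes)
        ]
        radii = nd.scale_radii(variants, config)
        for r in radii:
            assert config.min_radius - 1e-9 <= r <= config.max_radius + 1e-9
        for i in range(len(radii)):
            for j in range(len(radii)):
                if magnitudes[i] < magnitudes[j]:
                    assert radii[i] <= radii[j] + 1e-9

    def test_empty_input(self, config):
        assert nd.scale_radii([], config) == []


class TestStagger:
    def test_single_variant_slot_zero(self, config):
        layout = nd.stagger_lollipops([Variant(50, "A50B")], [5.0], 100, config)
        assert layout.slot == (0,)
        assert layout.stem_top == (config.stem_base_height,)

    def test_adjacent_variants_get_different_slots(self, config):
        variants = [Variant(50, "A50B"), Variant(51, "A51B")]
        layout = nd.stagger_lollipops(variants, [5.0, 5.0], 1000, config)
        assert layout.slot[0] == 0 and layout.slot[1] == 1
        assert_no_head_overlap(layout)

    def test_distant_variants_all_slot_zero(self, config):
        # > 2*max_radius apart in pixels: no horizontal overlap possible
        variants = [Variant(100, "A100B"), Variant(200, "A200B"), Variant(300, "A300B")]
        layout = nd.stagger_lollipops(variants, [5.0] * 3, 400, config)
        assert layout.slot == (0, 0, 0)

    def test_stem_x_matches_aa_to_px(self, config):
        variants = [Variant(10, "A10B"), Variant(17, "A17B")]
        layout = nd.stagger_lollipops(variants, [5.0, 5.0], 40, config)
        for v, x in zip(variants, layout.x):
            assert x == pytest.approx(le.aa_to_px(v.position, 40, config))

    def test_overflow_raises_helpful_error(self, config):
        variants = [Variant(50, f"A50B") for _ in range(40)]
        with pytest.raises(LayoutError, match="widen"):
            nd.stagger_lollipops(variants, [12.0] * 40, 100, config)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_soundness_on_random_inputs(self, seed):
        config = nd.DrawConfig()
        specs = fixtures.generate_variants(seed=seed, n=seed % 12, length=500, decorate=True)
        variants = nd.parse_variants(specs)
        radii = nd.scale_radii(variants, config)
        layout = nd.stagger_lollipops(variants, radii, 500, config)
        assert_no_head_overlap(layout)
        for v, x in zip(variants, layout.x):
            assert x == pytest.approx(le.aa_to_px(v.position, 500, config))


class TestDrawConfig:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            nd.DrawConfig(plot_width=20, pad=15)
        with pytest.raises(ValueError):
            nd.DrawConfig(min_radius=6, base_radius=5)
        with pytest.raises(ValueError):
            nd.DrawConfig(font_size=0)
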