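"""Star-notation parsing/rendering, scheme enumeration and break application."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import g4integrity as g4
from g4integrity.breaks import (DEFAULT_DOUBLE_PAIRS, DEFAULT_LOOP_POSITIONS,
                                DEFAULT_SINGLE_POSITIONS, HTELO_SEQUENCE,
                                ParseError, PositionError, site_class)

# the thirteen rows of the standard damage table over the h-telo 22-mer
TABLE_ROWS = [
    ("A GGG TTA GGG TTA GGG TTA GGG", ()),
    ("A G★GG TTA GGG TTA GGG TTA GGG", (2,)),
    ("A GG★G TTA GGG TTA GGG TTA GGG", (3,)),
    ("A GGG TTA GG★G TTA GGG TTA GGG", (9,)),
    ("A GGG TTA GGG TTA G★GG TTA GGG", (14,)),
    ("A GGG TTA GGG TTA GG★G TTA GGG", (15,)),
    ("A GGG TTA GGG TTA GGG TTA GG★G", (21,)),
    ("A G★G★G TTA GGG TTA GGG TTA GGG", (2, 3)),
    ("A G★GG TTA GGG TTA G★GG TTA GGG", (2, 14)),
    ("A GG★G TTA GG★G TTA GGG TTA GGG", (3, 9)),
    ("A GG★G TTA GGG TTA G★GG TTA GGG", (3, 14)),
    ("A GG★G TTA GGG TTA GG★G TTA GGG", (3, 15)),
    ("A GGG TTA GGG TTA G★G★G TTA GGG", (14, 15)),
]


@pytest.mark.parametrize("text,positions", TABLE_ROWS)
@pytest.mark.parametrize("chem", [g4.Chemistry.CA, g4.Chemistry.NC])
def test_parse_and_render_round_trip_table_rows(text, positions, chem):
    cfg = g4.parse_star_notation(text, chem)
    assert tuple(b.upstream_pos for b in cfg.breaks) == positions
    assert cfg.sequence == HTELO_SEQUENCE
    rendered = g4.render_star_notation(cfg)
    assert rendered == text
    assert g4.parse_star_notation(rendered, chem) == cfg


def test_parse_accepts_ascii_star_alias():
    a = g4.parse_star_notation("A G*GG TTA GGG TTA GGG TTA GGG", "CA")
    b = g4.parse_star_notation("A G★GG TTA GGG TTA GGG TTA GGG", "CA")
    assert a == b


def test_parse_no_star_is_native():
    cfg = g4.parse_star_notation("AGGG", "CA")
    assert cfg.breaks == () and cfg.label == "Native"


@pytest.mark.parametrize("bad", ["★AGGG", "AGGG★", "AG★★GG", "AXGG"])
def test_parse_rejects_malformed_text(bad):
    with pytest.raises((ParseError, PositionError)):
        g4.parse_star_notation(bad, "CA")


def test_labels_group_consecutive_positions():
    cfg = g4.parse_star_notation("A G★G★G TTA GGG TTA GGG TTA GGG", "NC")
    assert cfg.label == "NC 2-3-4"
    cfg = g4.parse_star_notation("A GG★G TTA GGG TTA G★GG TTA GGG", "CA")
    assert cfg.label == "CA 3-4/14-15"


@given(positions=st.sets(st.integers(min_value=1, max_value=21), max_size=5),
       chem=st.sampled_from([g4.Chemistry.CA, g4.Chemistry.NC]))
@settings(max_examples=60, deadline=None)
def test_round_trip_identity_random_break_sets(positions, chem):
    breaks = tuple(g4.StrandBreak(p, chem) for p in sorted(positions))
    cfg = g4.BreakConfig(HTELO_SEQUENCE, breaks, g4.make_label(breaks))
    assert g4.parse_star_notation(g4.render_star_notation(cfg), chem) == cfg


def test_site_class_distinguishes_tetrad_and_loop_breaks():
    assert site_class(HTELO_SEQUENCE, g4.StrandBreak(2)) == "tetrad"
    assert site_class(HTELO_SEQUENCE, g4.StrandBreak(5)) == "loop"
    assert site_class(HTELO_SEQUENCE, g4.StrandBreak(4)) == "loop"  # G-T junction


class TestEnumeration:
    def test_standard_scheme_counts(self):
        configs = g4.enumerate_damage_scheme()
        assert len(configs) == 27
        labels = [c.label for c in configs]
        assert len(set(labels)) == 27
        ca = [c for c in configs if all(b.chemistry == g4.Chemistry.CA
                                        for b in c.breaks)]
        nc = [c for c in configs if all(b.chemistry == g4.Chemistry.NC
                                        for b in c.breaks)]
        assert len(ca) == 15 and len(nc) == 12  # loop breaks are CA-only
        singles = [c for c in configs if len(c.breaks) == 1
                   and c.site_classes == ("tetrad",)]
        doubles = [c for c in configs if len(c.breaks) == 2]
        loops = [c for c in configs if c.site_classes == ("loop",)]
        assert len(singles) == 12 and len(doubles) == 12 and len(loops) == 3

    def test_count_formula(self):
        n_s, n_d, n_l = (len(DEFAULT_SINGLE_POSITIONS),
                         len(DEFAULT_DOUBLE_PAIRS), len(DEFAULT_LOOP_POSITIONS))
        assert len(g4.enumerate_damage_scheme()) == 2 * (n_s + n_d) + n_l

    def test_no_loop_positions_gives_24(self):
        assert len(g4.enumerate_damage_scheme(loop_positions=())) == 24

    def test_empty_lists_give_empty_scheme(self):
        assert g4.enumerate_damage_scheme(single_positions=(), double_pairs=(),
                                          loop_positions=()) == []

    def test_duplicate_positions_rejected(self):
        with pytest.raises(PositionError):
            g4.enumerate_damage_scheme(single_positions=(2, 2))
        with pytest.raises(PositionError):
            g4.enumerate_damage_scheme(double_pairs=((3, 3),))


class TestApplyBreaks:
    def test_native_config_is_identity(self, ideal_model):
        native = g4.BreakConfig(HTELO_SEQUENCE)
        out = g4.apply_breaks(ideal_model, native)
        assert out.bonds == ideal_model.bonds
        assert np.array_equal(out.coordinates, ideal_model.coordinates)

    @pytest.mark.parametrize("chem,up_label,down_label", [
        (g4.Chemistry.CA, "3'-OH", "5'-PO4"),
        (g4.Chemistry.NC, "3'-PO4", "5'-OH"),
    ])
    def test_terminal_chemistry_annotations(self, ideal_model, chem,
                                            up_label, down_label):
        cfg = g4.parse_star_notation("A G★GG TTA GGG TTA GGG TTA GGG", chem)
        out = g4.apply_breaks(ideal_model, cfg)
        assert len(ideal_model.bonds) - len(out.bonds) == 1
        assert out.termini[2] == (up_label,)
        assert out.termini[3] == (down_label,)
        owner = out.break_annotations[0]["phosphate_owner"]
        assert owner == (3 if chem == g4.Chemistry.CA else 2)

    def test_removes_exactly_one_bond_per_break_and_never_moves_atoms(
            self, ideal_model):
        for cfg in g4.enumerate_damage_scheme():
            out = g4.apply_breaks(ideal_model, cfg)
            assert len(ideal_model.bonds) - len(out.bonds) == len(cfg.breaks)
            assert np.abs(out.coordinates - ideal_model.coordinates).max() == 0.0

    def test_break_outside_model_rejected(self, ideal_model):
        cfg = g4.BreakConfig("A" * 40, (g4.StrandBreak(30),), "CA 30-31")
        with pytest.raises(PositionError):
            g4.apply_breaks(ideal_model, cfg)


def test_break_table_round_trips_bit_identically(tmp_path):
    configs = g4.enumerate_damage_scheme()
    p1 = tmp_path / "a.csv"
    p2 = tmp_path / "b.csv"
    g4.write_break_table(configs, p1)
    again = g4.read_break_table(p1)
    assert [c.breaks for c in again] == [c.breaks for c in configs]
    g4.write_break_table(again, p2)
    assert p1.read_bytes() == p2.read_bytes()
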