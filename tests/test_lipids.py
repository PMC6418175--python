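import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ndomics import (
    LipidomeConfig,
    classify_origin,
    class_change_calls,
    generate_lipidome,
    origin_fraction_of_increase,
    parse_lipid_name,
    pufa_sn2_profile,
    select_major_species,
    species_change_calls,
    trace_signatures,
)
from ndomics.lipids import DIACYL_CLASSES, MONOACYL_CLASSES

from conftest import lipid_frame

_chain = st.tuples(
    st.sampled_from([12, 14, 16, 18, 20, 22]),
    st.integers(0, 5),
    st.sampled_from([None, "n-3", "n-6", "n-9"]),
).map(lambda t: f"{t[0]}:{t[1]}{t[2] or ''}")


@st.composite
def lipid_names(draw):
    cls = draw(st.sampled_from(sorted(MONOACYL_CLASSES | DIACYL_CLASSES | {"TAG"})))
    arity = 1 if cls in MONOACYL_CLASSES else (3 if cls == "TAG" else 2)
    chains = draw(st.lists(_chain, min_size=arity, max_size=arity))
    return f"{cls}({'/'.join(chains)})"


class TestParsing:
    def test_diacyl_positions(self):
        sp = parse_lipid_name("DGDG(20:5/16:1)")
        assert sp.lipid_class == "DGDG"
        assert (sp.sn1.carbons, sp.sn1.double_bonds) == (20, 5)
        assert (sp.sn2.carbons, sp.sn2.double_bonds) == (16, 1)

    def test_tag_terminal_symmetry(self):
        a = parse_lipid_name("TAG(16:0/16:1/20:5)")
        b = parse_lipid_name("TAG(20:5/16:1/16:0)")
        assert a == b and a.name == b.name
        assert (a.sn2.carbons, a.sn2.double_bonds) == (16, 1)

    def test_omega_label_retained(self):
        sp = parse_lipid_name("PC(16:0/20:4n-6)")
        assert sp.sn2.omega == "n-6"
        assert sp.name == "PC(16:0/20:4n-6)"

    @pytest.mark.parametrize(
        "bad", ["DGDG(20:5)", "XYZ(16:0/16:1)", "DGDG(20:5/16:x)", "PC(16:0/15:0)",
                "LPC(16:0/18:1)", "TAG(16:0/16:1)", "DGDG 20:5/16:1"]
    )
    def test_malformed_names_rejected_with_position(self, bad):
        with pytest.raises(ValueError) as err:
            parse_lipid_name(bad)
        assert "position" in str(err.value)

    @settings(derandomize=True, max_examples=200)
    @given(name=lipid_names())
    def test_parse_format_roundtrip_is_identity(self, name):
        try:
            sp = parse_lipid_name(name)
        except ValueError:
            return  # invalid chain chemistry drawn; rejection is the contract
        again = parse_lipid_name(sp.name)
        assert again == sp and again.name == sp.name  # canonicalization idempotent


class TestOrigin:
    @pytest.mark.parametrize(
        "name,origin",
        [
            ("DGDG(20:5/16:1)", "prokaryotic"),
            ("PC(16:0/20:4)", "eukaryotic"),
            ("PE(16:0/18:1)", "eukaryotic"),
            ("TAG(16:0/16:1/20:5)", "prokaryotic"),
            ("TAG(16:0/22:5/16:0)", "eukaryotic"),
            ("LPC(18:1)", "undetermined"),
            ("FFA(20:5)", "undetermined"),
        ],
    )
    def test_sn2_rule(self, name, origin):
        assert classify_origin(name).origin == origin

    def test_short_sn2_flagged_undetermined(self):
        call = classify_origin("PC(16:0/14:0)")
        assert call.origin == "undetermined" and call.flagged

    @settings(derandomize=True, max_examples=200)
    @given(name=lipid_names())
    def test_partition_into_exactly_one_label(self, name):
        try:
            sp = parse_lipid_name(name)
        except ValueError:
            return
        assert classify_origin(sp).origin in {"prokaryotic", "eukaryotic", "undetermined"}


class TestChangeCalls:
    def test_identical_replicates_unchanged(self, make_lipids):
        table = make_lipids([("PC(16:0/18:1)", (3, 3, 3), (3, 3, 3))])
        calls = species_change_calls(table)
        assert calls["direction"].iloc[0] == "unchanged"

    def test_exact_threshold_not_significant(self, make_lipids):
        table = make_lipids([("PC(16:0/18:1)", (2.99, 3.0, 3.01), (1.99, 2.0, 2.01))])
        calls = species_change_calls(table, fold_threshold=1.5)
        row = calls.iloc[0]
        assert row["fold"] == pytest.approx(1.5, abs=0.01)
        assert not row["significant"]  # strict inequality at the boundary

    def test_planted_three_fold_called_up(self, make_lipids):
        rng = np.random.default_rng(8)
        nr = 5 * rng.lognormal(0, 0.1, 3)
        table = make_lipids([("TAG(16:0/16:1/18:1)", 3 * 5 * rng.lognormal(0, 0.1, 3), nr)])
        assert species_change_calls(table)["direction"].iloc[0] == "up"

    def test_single_species_class_call_equals_species_call(self, make_lipids):
        table = make_lipids([("MGMG(16:1)", (9.0, 10.0, 11.0), (2.0, 2.1, 1.9))])
        cls = class_change_calls(table, 1.5).iloc[0]
        sp = species_change_calls(table, 1.5).iloc[0]
        assert cls["fold"] == pytest.approx(sp["fold"])
        assert cls["direction"] == sp["direction"]

    def test_planted_tag_class_up_at_all_presets(self, synthetic_lipidome):
        table, _ = synthetic_lipidome
        for preset in (1.2, 1.25, 1.5):
            calls = class_change_calls(table, preset)
            row = calls[calls["lipid_class"] == "TAG"].iloc[0]
            assert row["direction"] == "up"

    def test_origin_stratified_calls_can_oppose_total(self, make_lipids):
        # prokaryotic MGDG falls, eukaryotic MGDG rises by the same amount:
        # the strata disagree while the whole class stays flat
        table = make_lipids(
            [
                ("MGDG(20:5/16:1)", (4.0, 4.1, 3.9), (8.0, 8.2, 7.8)),
                ("MGDG(16:0/18:2)", (8.0, 8.2, 7.8), (4.0, 4.1, 3.9)),
            ]
        )
        prok = class_change_calls(table, 1.25, origin="prokaryotic").iloc[0]
        euk = class_change_calls(table, 1.25, origin="eukaryotic").iloc[0]
        total = class_change_calls(table, 1.25).iloc[0]
        assert prok["direction"] == "down" and euk["direction"] == "up"
        assert total["direction"] == "unchanged"
        # strata partition the class sum exactly
        assert prok["mean_nd"] + euk["mean_nd"] == pytest.approx(total["mean_nd"])


class TestMajorSpecies:
    def _table(self, n, make):
        return make(
            [(f"TAG(16:0/16:1/{12 + 2 * i}:0)", float(n - i), float(n - i)) for i in range(n)]
        )

    def test_five_or_fewer_keeps_all(self, make_lipids):
        names, gap = select_major_species(self._table(4, make_lipids))
        assert len(names) == 4 and not gap

    def test_ten_keeps_top_half(self, make_lipids):
        table = self._table(10, make_lipids)
        names, gap = select_major_species(table)
        assert len(names) == 5 and not gap
        assert names == list(table["species"].iloc[:5])  # most abundant half

    def test_seven_flagged_rule_gap(self, make_lipids):
        names, gap = select_major_species(self._table(7, make_lipids))
        assert len(names) == 4 and gap

    def test_empty_class(self, make_lipids):
        names, gap = select_major_species(self._table(4, make_lipids).iloc[:0])
        assert names == [] and not gap


def _brute_force_trace(table, require_direction):
    """All-pairs positional oracle, independent of the library matcher."""
    calls = species_change_calls(table, 1.5, 0.05)
    direction = dict(zip(calls["species"], calls["direction"]))
    pairs = set()
    sources = []
    for cls in ("DGDG", "MGDG", "PG"):
        rows = table[table["lipid_class"] == cls]
        keep, _ = select_major_species(rows)
        sources.extend(keep)
    for src_name in sources:
        src = parse_lipid_name(src_name)
        for tgt_name in table.loc[table["lipid_class"].isin(["DAG", "TAG"]), "species"]:
            tgt = parse_lipid_name(tgt_name)
            s1, s2 = src.chains[0].signature, src.chains[1].signature
            if tgt.lipid_class == "DAG":
                ok = (tgt.chains[0].signature, tgt.chains[1].signature) == (s1, s2)
            else:
                t1, t2, t3 = (c.signature for c in tgt.chains)
                ok = t2 == s2 and s1 in (t1, t3)
            if ok and (
                not require_direction
                or (direction[src_name] == "down" and direction[tgt_name] == "up")
            ):
                pairs.add((src_name, tgt_name))
    return pairs


class TestTracing:
    def test_published_signature_examples(self, make_lipids):
        table = make_lipids(
            [
                ("DGDG(20:5/16:1)", (1.0, 1.1, 0.9), (4.0, 4.1, 3.9)),  # down
                ("DAG(20:5/16:1)", (6.0, 6.1, 5.9), (2.0, 2.1, 1.9)),  # up
                ("TAG(16:0/16:1/20:5)", (9.0, 9.1, 8.9), (3.0, 3.1, 2.9)),  # up
                ("PG(16:0/20:5)", (1.0, 1.1, 0.9), (3.0, 3.1, 2.9)),  # down, no home
            ]
        )
        matches = trace_signatures(table)
        pairs = {(m.source.name, m.target.name): m.match_kind for m in matches}
        assert pairs[("DGDG(20:5/16:1)", "DAG(20:5/16:1)")] == "exact-diacyl"
        assert pairs[("DGDG(20:5/16:1)", "TAG(16:0/16:1/20:5)")] == "embedded-in-TAG"
        assert not any(src == "PG(16:0/20:5)" for src, _ in pairs)

    def test_direction_filter_returns_subset(self, synthetic_lipidome):
        table, _ = synthetic_lipidome
        strict = {(m.source.name, m.target.name) for m in trace_signatures(table)}
        loose = {
            (m.source.name, m.target.name)
            for m in trace_signatures(table, require_direction=False)
        }
        assert strict <= loose

    @pytest.mark.parametrize("require_direction", [True, False])
    def test_matches_brute_force_oracle(self, synthetic_lipidome, require_direction):
        table, _ = synthetic_lipidome
        assert len(table) <= 100
        got = {
            (m.source.name, m.target.name)
            for m in trace_signatures(table, require_direction=require_direction)
        }
        assert got == _brute_force_trace(table, require_direction)

    def test_planted_pairs_recovered(self, synthetic_lipidome):
        table, truth = synthetic_lipidome
        found = {(m.source.name, m.target.name) for m in trace_signatures(table)}
        assert set(truth.planted_trace_pairs) <= found


class TestOriginFraction:
    def test_all_increasing_prokaryotic(self, make_lipids):
        table = make_lipids(
            [
                ("TAG(16:0/16:1/18:1)", 10.0, 2.0),
                ("TAG(14:0/18:1/18:1)", 1.0, 3.0),  # decreasing: excluded
            ]
        )
        assert origin_fraction_of_increase(table) == 1.0

    def test_equal_split(self, make_lipids):
        table = make_lipids(
            [("TAG(16:0/16:1/18:1)", 5.0, 1.0), ("TAG(16:0/18:1/18:1)", 5.0, 1.0)]
        )
        assert origin_fraction_of_increase(table) == pytest.approx(0.5)

    def test_no_increase_is_undefined(self, make_lipids):
        table = make_lipids([("TAG(16:0/16:1/18:1)", 1.0, 3.0)])
        assert origin_fraction_of_increase(table) is None

    def test_planted_fraction_recovered(self, synthetic_lipidome):
        table, truth = synthetic_lipidome
        assert truth.planted_f_prokaryotic == 0.7
        assert origin_fraction_of_increase(table) == pytest.approx(0.70, abs=0.05)


class TestPufaProfile:
    def test_absent_pufa_reports_zero_unchanged(self, make_lipids):
        table = make_lipids([("PC(16:0/18:1)", 3.0, 3.0)])
        profile = pufa_sn2_profile(table)
        row = profile[profile["pufa"] == "20:5n-3"].iloc[0]
        assert row["mean_nd"] == 0.0 and row["direction"] == "unchanged"

    def test_single_species_equals_aggregate(self, make_lipids):
        table = make_lipids([("PC(16:0/20:4n-6)", (2.0, 2.1, 1.9), (6.0, 6.1, 5.9))])
        profile = pufa_sn2_profile(table)
        row = profile[profile["pufa"] == "20:4n-6"].iloc[0]
        assert row["mean_nd"] == pytest.approx(2.0)
        assert row["direction"] == "down"

    def test_planted_sn2_pufa_decrease_all_called_down(self, make_lipids):
        rng = np.random.default_rng(6)
        rows = []
        for i, sn2 in enumerate(["18:3n-6", "20:4n-6", "20:4n-6", "20:5n-3"]):
            base = 10 * rng.lognormal(0, 0.1)
            rows.append(
                (f"PC({14 + 2 * i}:0/{sn2})",
                 base / 2 * rng.lognormal(0, 0.05, 3), base * rng.lognormal(0, 0.05, 3))
            )
        profile = pufa_sn2_profile(lipid_frame(rows))
        assert (profile["direction"] == "down").all()

    def test_empty_pufa_set_rejected(self, make_lipids):
        table = make_lipids([("PC(16:0/18:1)", 1.0, 1.0)])
        with pytest.raises(ValueError):
            pufa_sn2_profile(table, pufa_set=())
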