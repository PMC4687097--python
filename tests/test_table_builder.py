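import pytest

from proximal.alignment import max_common_subgraph
from proximal.atom_typing import type_map
from proximal.chem_io import canonical_key, from_smiles
from proximal.fixtures import fixture_graph, generate_synthetic_reactions, load_curated_reactions
from proximal.table_builder import (
    LookupKey,
    ReactionRecord,
    build_tables,
    extract_key,
    extract_rule,
    find_reaction_centers,
    load_tables,
    normalize_enzyme,
    save_tables,
)
from proximal.transformer import replay_rule


def _aligned(r, p):
    return max_common_subgraph(r, p), type_map(r), type_map(p)


class TestFindReactionCenters:
    def test_antipyrine_pair_center_is_atom_9(self):
        a, rt, pt = _aligned(fixture_graph("antipyrine"), fixture_graph("hydroxymethylantipyrine"))
        assert find_reaction_centers(a, rt, pt) == [9]

    def test_identity_reaction_has_no_centers(self, bpa):
        a, rt, pt = _aligned(bpa, bpa)
        assert find_reaction_centers(a, rt, pt) == []

    def test_benzene_to_phenol_center_is_the_hydroxylated_carbon(self):
        r, p = from_smiles("c1ccccc1"), from_smiles("Oc1ccccc1")
        a, rt, pt = _aligned(r, p)
        (center,) = find_reaction_centers(a, rt, pt)
        assert rt[center] == "C8x"
        assert pt[a.reactant_to_product()[center]] == "C8y"


class TestExtractKey:
    def test_antipyrine_center_9_key(self):
        g = fixture_graph("antipyrine")
        key = extract_key(g, type_map(g), 9)
        assert key == LookupKey("C1a", ("C8y",), tuple(sorted(["N4y", "C8x", "C1a"])))

    def test_acetaminophen_center_11_key(self, acetaminophen):
        key = extract_key(acetaminophen, type_map(acetaminophen), 11)
        assert key == LookupKey("O1a", ("C8y",), ("C8x", "C8x", "O1a"))

    def test_isolated_atom_key_is_self_only(self):
        g = from_smiles("C")  # methane: no neighbours, distant set is the center itself
        key = extract_key(g, type_map(g), 1)
        assert key == LookupKey("C1a", (), ("C1a",))


class TestExtractRule:
    def test_antipyrine_rule_adds_a_hydroxyl_to_the_center(self):
        r, p = fixture_graph("antipyrine"), fixture_graph("hydroxymethylantipyrine")
        rec = ReactionRecord("RX", ("1A2",), "I", r, p)
        a = max_common_subgraph(r, p)
        key, rule = extract_rule(rec, 9, a)
        assert rule.product_rc_type == "C1b"
        assert [el for _, el, _ in rule.added_atoms] == ["O"]
        assert rule.attachments == ((0, 0, 1),)  # single O bonded to the center
        assert rule.removed_positions == ()
        regenerated = replay_rule(r, 9, rule)
        assert canonical_key(regenerated) == canonical_key(p)

    def test_demethylation_rule_has_removed_atom_and_no_added_fragment(self):
        r = fixture_graph("dimethylaniline")
        p = fixture_graph("n_methylaniline")
        rec = ReactionRecord("RX", ("3A4",), "I", r, p)
        a = max_common_subgraph(r, p)
        rt, pt = type_map(r), type_map(p)
        (center,) = find_reaction_centers(a, rt, pt)
        assert r.atom(center).element == "N"
        key, rule = extract_rule(rec, center, a)
        assert rule.added_atoms == ()
        assert len(rule.removed_positions) == 1
        assert canonical_key(replay_rule(r, center, rule)) == canonical_key(p)

    def test_non_center_atom_is_rejected(self):
        r, p = fixture_graph("antipyrine"), fixture_graph("hydroxymethylantipyrine")
        rec = ReactionRecord("RX", ("1A2",), "I", r, p)
        with pytest.raises(ValueError, match="not a reaction center"):
            extract_rule(rec, 1, max_common_subgraph(r, p))


class TestBuildTables:
    def test_empty_record_list_is_an_error(self):
        with pytest.raises(ValueError):
            build_tables([])

    def test_curated_set_contains_the_antipyrine_key(self, curated_build):
        key = LookupKey("C1a", ("C8y",), tuple(sorted(["N4y", "C8x", "C1a"])))
        assert key in curated_build.phase_i.entries

    def test_phases_are_separated(self, curated_build):
        assert all(r.phase == "I" for rules in curated_build.phase_i.entries.values() for r in rules)
        assert all(r.phase == "II" for rules in curated_build.phase_ii.entries.values() for r in rules)

    def test_identity_reaction_yields_diagnostic_not_entries(self, bpa):
        rec = ReactionRecord("ID", ("1A2",), "I", bpa, bpa)
        build = build_tables([rec])
        assert build.phase_i.n_rules == 0
        assert any("no reaction center" in d for d in build.diagnostics)

    def test_multi_center_reactions_store_one_entry_per_valid_center(self):
        # epoxidation changes the type of every ring atom; each valid center
        # contributes its own (key, rule) entry
        recs = [r for r in generate_synthetic_reactions(3, 60) if r.metadata["kind"] == "epoxidation"]
        rec = recs[0]
        build = build_tables([rec])
        a = max_common_subgraph(rec.reactant, rec.product)
        centers = find_reaction_centers(a, type_map(rec.reactant), type_map(rec.product))
        rejected = len(build.diagnostics)
        assert build.phase_i.n_rules + rejected >= len(centers)
        assert build.phase_i.n_rules >= 1

    def test_structurally_identical_rules_merge_enzyme_sets(self, curated_build):
        # BPA and acetaminophen share the phenol-glucuronidation rule: one
        # structural rule with merged provenance
        for rules in curated_build.phase_ii.entries.values():
            for rule in rules:
                if {"R05", "R08"} <= set(rule.provenance):
                    return
        pytest.fail("glucuronidation rules from R05/R08 did not merge")


class TestSerialization:
    def test_round_trip_preserves_tables(self, curated_build, tmp_path):
        path = tmp_path / "tables.json"
        save_tables(curated_build.phase_i, curated_build.phase_ii, path)
        t1, t2 = load_tables(path)
        assert t1.entries == curated_build.phase_i.entries
        assert t2.entries == curated_build.phase_ii.entries

    def test_rebuilt_tables_serialize_byte_identically(self, tmp_path):
        recs = load_curated_reactions()
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        b1, b2 = build_tables(recs), build_tables(recs)
        save_tables(b1.phase_i, b1.phase_ii, p1)
        save_tables(b2.phase_i, b2.phase_ii, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_truncated_file_is_an_error(self, curated_build, tmp_path):
        path = tmp_path / "tables.json"
        save_tables(curated_build.phase_i, curated_build.phase_ii, path)
        path.write_text(path.read_text()[: path.stat().st_size // 2])
        with pytest.raises(Exception):
            load_tables(path)

    def test_schema_version_mismatch_is_an_error(self, tmp_path):
        path = tmp_path / "tables.json"
        path.write_text('{"schema_version": 99, "phase_i": {}, "phase_ii": {}}')
        with pytest.raises(ValueError, match="schema version"):
            load_tables(path)


@pytest.mark.parametrize(
    "name, phase, expected",
    [
        ("CYP3A4", "I", "3A4"),
        ("1a2", "I", "1A2"),
        ("UGT", "II", "2.4.1.17"),
        ("GST", "II", "2.5.1.18"),
        ("2.1.1.6", "II", "2.1.1.6"),
    ],
)
def test_enzyme_normalization(name, phase, expected):
    assert normalize_enzyme(name, phase) == expected
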