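from proximal.chem_io import canonical_key, from_smiles
from proximal.fixtures import fixture_graph
from proximal.table_builder import LookupKey, LookupTable, ReactionRecord, build_tables
from proximal.transformer import apply_rule, enumerate_sites, match_sites, predict

from .conftest import graphs_isomorphic


class TestEnumerateSites:
    def test_bpa_17_sites_7_unique_classes(self, bpa):
        sites = enumerate_sites(bpa)
        assert len(sites) == 17
        assert len({s.symmetry_class for s in sites}) == 7

    def test_pcb3_13_sites_8_unique_classes(self, pcb3):
        sites = enumerate_sites(pcb3)
        assert len(sites) == 13
        assert len({s.symmetry_class for s in sites}) == 8

    def test_benzene_is_one_class(self):
        sites = enumerate_sites(from_smiles("c1ccccc1"))
        assert len(sites) == 6
        assert len({s.symmetry_class for s in sites}) == 1
        assert [s.atom_index for s in sites if s.representative] == [1]

    def test_pcb3_biphenyl_link_carbons_share_a_class(self, pcb3):
        # type-equivalent but not automorphic: the two C8y link carbons have
        # identical key tuples, which is the uniqueness notion used here
        sites = {s.atom_index: s for s in enumerate_sites(pcb3)}
        assert sites[4].symmetry_class == sites[7].symmetry_class


class TestMatchSites:
    def test_acetaminophen_site_11_matches_curated_phase_i(self, acetaminophen, curated_build):
        matches = match_sites(enumerate_sites(acetaminophen), curated_build.phase_i)
        keys = {site.key for site, _ in matches}
        assert LookupKey("O1a", ("C8y",), ("C8x", "C8x", "O1a")) in keys

    def test_fallback_typed_sites_never_match(self):
        table = LookupTable("I")
        key = LookupKey("B?", (), ("B?",))
        assert table.lookup(key) == []

    def test_empty_table_matches_nothing(self, bpa):
        assert match_sites(enumerate_sites(bpa), LookupTable("I")) == []


class TestApplyRule:
    def test_benzene_hydroxylation_rule_yields_phenol(self):
        rec = ReactionRecord("B2P", ("2E1",), "I", from_smiles("c1ccccc1"), from_smiles("Oc1ccccc1"))
        build = build_tables([rec])
        sites = enumerate_sites(rec.reactant)
        ((site, rule),) = match_sites(sites, build.phase_i)
        product = apply_rule(rec.reactant, site, rule)
        assert graphs_isomorphic(product.graph, from_smiles("Oc1ccccc1"))

    def test_acetaminophen_products_match_published_structures(self, acetaminophen, curated_build):
        products = predict(acetaminophen, curated_build.phase_i, curated_build.phase_ii)
        got = {p.canonical for p in products}
        for name in ("napqi", "acetaminophen_glucuronide", "acetaminophen_sulfate"):
            assert canonical_key(fixture_graph(name)) in got, name


class TestPredict:
    def test_symmetric_sites_collapse_to_one_product(self, bpa, curated_build):
        products = predict(bpa, curated_build.phase_i, curated_build.phase_ii,
                           phases={"I"}, depth=1)
        hydroxylated = canonical_key(fixture_graph("bpa_hydroxy"))
        assert sum(1 for p in products if p.canonical == hydroxylated) == 1

    def test_every_product_differs_from_the_query(self, bpa, curated_build):
        ck = canonical_key(bpa)
        for p in predict(bpa, curated_build.phase_i, curated_build.phase_ii):
            assert p.canonical != ck

    def test_depth_1_phase_i_only_yields_no_conjugate_chains(self, bpa, curated_build):
        products = predict(bpa, curated_build.phase_i, curated_build.phase_ii,
                           phases={"I"}, depth=1)
        assert products
        assert all(p.phase_chain == ("I",) for p in products)

    def test_depth_2_chains_phase_ii_onto_phase_i_products(self, bpa, curated_build):
        products = predict(bpa, curated_build.phase_i, curated_build.phase_ii, depth=2)
        chains = {p.phase_chain for p in products}
        assert ("I", "II") in chains

    def test_no_matching_keys_gives_empty_list(self, curated_build):
        g = from_smiles("CCCC")  # plain butane: no curated key matches
        assert predict(g, curated_build.phase_i, curated_build.phase_ii) == []

    def test_output_order_is_stable(self, bpa, curated_build):
        p1 = predict(bpa, curated_build.phase_i, curated_build.phase_ii)
        p2 = predict(bpa, curated_build.phase_i, curated_build.phase_ii)
        assert [p.canonical for p in p1] == [p.canonical for p in p2]

    def test_napqi_rule_requires_the_acylamino_context(self, bpa, curated_build):
        """The quinone-imine rewrite needs a para nitrogen; on BPA its key
        matches but the template cannot embed, so no such product appears."""
        napqi_like = canonical_key(fixture_graph("napqi"))
        products = predict(bpa, curated_build.phase_i, curated_build.phase_ii)
        assert napqi_like not in {p.canonical for p in products}
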