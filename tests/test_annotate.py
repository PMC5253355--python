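"""Kingdom assignment decision tree, keyword dictionary, LCA, collation."""

import itertools

import numpy as np
import pytest

from virobench import annotate
from virobench.annotate import (
    DomainAnnotation,
    KeywordDictionary,
    LcaParams,
    ProteinHit,
    assign_kingdom,
    build_keyword_dictionary,
    collate_contig_taxonomy,
    contamination_fraction,
    lca_assign,
    metavir_viral_call,
    title_matches_keyword,
)
from virobench.taxonomy import TaxonomyTree


def hit(pid="p", source="nr", title="some protein", lineage=(), bit=100.0, ev=1e-10,
        taxon=None):
    return ProteinHit(pid, source, title, list(lineage), bit, ev, taxon)


BACT = ("cellular organisms", "Bacteria", "Proteobacteria")
EUK = ("cellular organisms", "Eukaryota", "Metazoa")
ARCH = ("cellular organisms", "Archaea", "Euryarchaeota")
VIR = ("Viruses", "Caudovirales", "Siphoviridae")


class TestMetavirCall:
    @pytest.mark.parametrize("bit,expected", [(51.0, True), (50.0, False), (49.0, False)])
    def test_strict_bitscore_boundary(self, bit, expected):
        assert metavir_viral_call(hit(source="viral-subset", bit=bit)) is expected

    def test_wrong_source_rejected(self):
        with pytest.raises(ValueError):
            metavir_viral_call(hit(source="nr"))


class TestKeywordDictionary:
    def test_tokenizer_rules(self):
        kw = build_keyword_dictionary(["phage portal protein"])
        assert "phage" in kw.keywords and "portal" in kw.keywords
        assert "protein" not in kw.keywords  # stoplisted

    def test_empty_input(self):
        assert build_keyword_dictionary([]).keywords == set()

    def test_duplicate_titles_set_semantics(self):
        once = build_keyword_dictionary(["major capsid protein vp1"])
        thrice = build_keyword_dictionary(["major capsid protein vp1"] * 3)
        assert once.keywords == thrice.keywords

    def test_recurring_bigram_kept_as_phrase(self):
        kw = build_keyword_dictionary(
            ["phage terminase large subunit", "phage terminase small subunit"]
        )
        assert "phage terminase" in kw.keywords

    def test_short_tokens_dropped(self):
        kw = build_keyword_dictionary(["gp 12 of phage T4"])
        assert "phage" in kw.keywords and "of" not in kw.keywords

    def test_whole_token_matching(self):
        kw = KeywordDictionary({"phage"})
        assert title_matches_keyword("unknown phage protein", kw)
        assert not title_matches_keyword("macrophage receptor", kw)


KW = KeywordDictionary({"phage", "terminase", "capsid"})


class TestAssignKingdom:
    def test_rule_a_viral_subset_highest(self):
        hits = [hit(source="viral-subset", bit=120), hit(source="nr", lineage=BACT, bit=100)]
        call = assign_kingdom("p", hits, keywords=KW)
        assert (call.klass, call.rule) == ("Viruses", "a")

    def test_rule_b_viral_lineage(self):
        hits = [hit(source="nr", lineage=VIR, bit=100, ev=1e-6)]
        call = assign_kingdom("p", hits, keywords=KW)
        assert (call.klass, call.rule) == ("Viruses", "b")

    def test_rule_c_keyword_title(self):
        hits = [hit(source="nr", title="putative terminase", lineage=BACT, bit=100, ev=1e-6)]
        call = assign_kingdom("p", hits, keywords=KW)
        assert (call.klass, call.rule) == ("Viruses", "c")

    def test_rule_d_viral_domain(self):
        hits = [hit(source="nr", lineage=BACT, bit=100, ev=1e-20)]
        domains = [DomainAnnotation("p", "PF04860", "phage portal", viral_flag=True)]
        call = assign_kingdom("p", hits, domains, keywords=KW)
        assert (call.klass, call.rule) == ("Viruses", "d")

    def test_putative_viruses_weak_evalue(self):
        hits = [hit(source="nr", title="putative phage terminase", lineage=BACT,
                    bit=100, ev=1e-3)]
        call = assign_kingdom("p", hits, keywords=KW)
        assert (call.klass, call.rule) == ("putative-Viruses", "putative")

    def test_cellular_kingdoms(self):
        for lineage, expected in ((BACT, "Bacteria"), (EUK, "Eukaryota"), (ARCH, "Archaea")):
            call = assign_kingdom("p", [hit(source="nr", lineage=lineage, ev=1e-9)],
                                  keywords=KW)
            assert (call.klass, call.rule) == (expected, "cellular")

    def test_unclassified_no_hits(self):
        call = assign_kingdom("p", [], keywords=KW)
        assert (call.klass, call.rule) == ("unclassified", "none")

    def test_score_tie_does_not_fire_rule_a(self):
        hits = [hit(source="viral-subset", bit=100), hit(source="nr", lineage=BACT, ev=1e-9, bit=100)]
        call = assign_kingdom("p", hits, keywords=KW)
        assert call.rule != "a"
        assert call.klass == "Bacteria"

    def test_evalue_boundary_is_strict(self):
        # e-value exactly 1e-4 is NOT below the threshold: rule b cannot fire
        at = assign_kingdom("p", [hit(source="nr", lineage=VIR, ev=1.0e-4)], keywords=KW)
        below = assign_kingdom("p", [hit(source="nr", lineage=VIR, ev=0.99e-4)], keywords=KW)
        assert (at.klass, at.rule) == ("putative-Viruses", "putative")
        assert (below.klass, below.rule) == ("Viruses", "b")

    def test_rule_a_dominance_property(self):
        """Raising the viral-subset bit above all others always gives Viruses."""
        others = [hit(source="nr", lineage=BACT, bit=200, ev=1e-30),
                  hit(source="refseq-p", lineage=EUK, bit=150, ev=1e-20)]
        call = assign_kingdom("p", others + [hit(source="viral-subset", bit=201)],
                              keywords=KW)
        assert (call.klass, call.rule) == ("Viruses", "a")

    def test_hit_order_permutation_invariance(self):
        hits = [
            hit(source="viral-subset", bit=90),
            hit(source="nr", title="phage tail fiber", lineage=BACT, bit=100, ev=1e-8),
            hit(source="refseq-p", lineage=VIR, bit=95, ev=1e-8),
        ]
        calls = {
            (assign_kingdom("p", list(perm), keywords=KW).klass,
             assign_kingdom("p", list(perm), keywords=KW).rule)
            for perm in itertools.permutations(hits)
        }
        assert len(calls) == 1

    def test_weakening_max_evalue_preserves_viral_calls(self):
        h = [hit(source="nr", lineage=VIR, ev=1e-6)]
        strict = assign_kingdom("p", h, keywords=KW, max_evalue=1e-4)
        loose = assign_kingdom("p", h, keywords=KW, max_evalue=1e-2)
        assert strict.klass == loose.klass == "Viruses"

    def test_twenty_protein_fixture_matches_hand_derived_truth(self):
        """Every decision branch, exercised by a hand-built 20-protein fixture."""
        fixture = [
            # (hits, domains, expected class, expected rule)
            ([hit(source="viral-subset", bit=120)], [], "Viruses", "a"),
            ([hit(source="viral-subset", bit=80), hit(source="nr", lineage=BACT, bit=60, ev=1e-9)],
             [], "Viruses", "a"),
            ([hit(source="nr", lineage=VIR, bit=90, ev=1e-9)], [], "Viruses", "b"),
            ([hit(source="refseq-p", lineage=VIR, bit=50, ev=1e-5)], [], "Viruses", "b"),
            ([hit(source="nr", title="phage integrase", lineage=BACT, bit=70, ev=1e-8)],
             [], "Viruses", "c"),
            ([hit(source="refseq-p", title="major capsid", lineage=EUK, bit=46, ev=1e-6)],
             [], "Viruses", "c"),
            ([hit(source="nr", lineage=BACT, bit=100, ev=1e-9)],
             [DomainAnnotation("p", "PF05133", "phage portal", True)], "Viruses", "d"),
            ([], [DomainAnnotation("p", "PF02407", "viral rep", True)], "Viruses", "d"),
            ([hit(source="nr", lineage=VIR, bit=90, ev=1e-3)], [], "putative-Viruses", "putative"),
            ([hit(source="nr", title="phage portal", lineage=BACT, bit=90, ev=0.5)],
             [], "putative-Viruses", "putative"),
            ([hit(source="nr", lineage=VIR, bit=90, ev=1e-4)], [], "putative-Viruses", "putative"),
            ([hit(source="nr", lineage=BACT, bit=90, ev=1e-9)], [], "Bacteria", "cellular"),
            ([hit(source="refseq-p", lineage=ARCH, bit=90, ev=1e-9)], [], "Archaea", "cellular"),
            ([hit(source="nr", lineage=EUK, bit=90, ev=1e-9)], [], "Eukaryota", "cellular"),
            ([hit(source="viral-subset", bit=90), hit(source="nr", lineage=BACT, bit=90, ev=1e-9)],
             [], "Bacteria", "cellular"),
            ([hit(source="nr", lineage=BACT, bit=90, ev=1e-3)], [], "unclassified", "none"),
            ([hit(source="nr", lineage=(), bit=90, ev=1e-9)], [], "unclassified", "none"),
            ([], [], "unclassified", "none"),
            ([hit(source="nr", lineage=VIR, bit=40, ev=1e-9)], [], "unclassified", "none"),
            # keyword hit below the min bit score: falls through to the lineage kingdom
            ([hit(source="nr", title="phage capsid", lineage=BACT, bit=40, ev=1e-9)],
             [], "Bacteria", "cellular"),
        ]
        assert len(fixture) == 20
        for i, (hits, domains, klass, rule) in enumerate(fixture):
            hits = [ProteinHit(f"p{i}", h.source, h.subject_title, h.lineage,
                               h.bitscore, h.evalue) for h in hits]
            domains = [DomainAnnotation(f"p{i}", d.accession, d.description, d.viral_flag)
                       for d in domains]
            call = assign_kingdom(f"p{i}", hits, domains, keywords=KW)
            assert (call.klass, call.rule) == (klass, rule), f"protein {i}"


class TestLca:
    def _tree(self):
        #        1 (root)
        #       /  \
        #      2    5
        #     / \
        #    3   4
        return TaxonomyTree({1: 1, 2: 1, 3: 2, 4: 2, 5: 1})

    def test_single_survivor(self):
        t = self._tree()
        assert lca_assign([hit(bit=100, ev=1e-9, taxon=3)], t) == 3

    def test_sibling_species_collapse_to_genus(self):
        t = self._tree()
        hits = [hit(bit=100, ev=1e-9, taxon=3), hit(bit=100, ev=1e-9, taxon=4)]
        assert lca_assign(hits, t) == 2

    def test_top_percent_cutoff_arithmetic(self):
        t = self._tree()
        hits = [hit(bit=100, ev=1e-9, taxon=3), hit(bit=85, ev=1e-9, taxon=4)]
        # cutoff = 90: only the first hit survives
        assert lca_assign(hits, t, LcaParams(top_percent=10)) == 3

    def test_top_percent_zero_is_best_hit(self):
        t = self._tree()
        hits = [hit(bit=100, ev=1e-9, taxon=3), hit(bit=99, ev=1e-9, taxon=5)]
        assert lca_assign(hits, t, LcaParams(top_percent=0)) == 3

    def test_filters_remove_everything(self):
        t = self._tree()
        assert lca_assign([hit(bit=40, ev=1e-9, taxon=3)], t) is None
        assert lca_assign([hit(bit=100, ev=1e-2, taxon=3)], t) is None

    def test_against_ancestor_intersection_oracle_on_random_trees(self):
        """LCA agrees with brute-force ancestor-set intersection on 200
        random taxonomies and hit sets."""
        rng = np.random.default_rng(99)
        for trial in range(200):
            n = int(rng.integers(2, 40))
            parent = {1: 1}
            for node in range(2, n + 1):
                parent[node] = int(rng.integers(1, node))
            t = TaxonomyTree(parent)
            n_hits = int(rng.integers(1, 8))
            hits = [
                hit(bit=float(rng.integers(45, 200)), ev=1e-9,
                    taxon=int(rng.integers(1, n + 1)))
                for _ in range(n_hits)
            ]
            result = lca_assign(hits, t, LcaParams(top_percent=100))
            # oracle: intersect full ancestor sets, take the deepest
            ancestor_sets = []
            for h in hits:
                path = set(t.path_to_root(h.taxon_id))
                ancestor_sets.append(path)
            common = set.intersection(*ancestor_sets)
            depth = {node: len(t.path_to_root(node)) for node in common}
            expected = max(common, key=lambda x: depth[x])
            assert result == expected, f"trial {trial}"


class TestTaxonomyTree:
    def test_cycle_detected(self):
        with pytest.raises(ValueError):
            TaxonomyTree({1: 2, 2: 1})

    def test_from_table_roundtrip(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("1\t1\troot\n2\t1\tViruses\n3\t2\tCaudovirales\n")
        t = TaxonomyTree.from_table(p)
        assert t.path_to_root(3) == [3, 2, 1]
        assert t.name[2] == "Viruses"

    def test_from_ncbi_dumps(self, tmp_path):
        nodes = tmp_path / "nodes.dmp"
        nodes.write_text("1\t|\t1\t|\tno rank\t|\n10239\t|\t1\t|\tsuperkingdom\t|\n")
        names = tmp_path / "names.dmp"
        names.write_text("10239\t|\tViruses\t|\t\t|\tscientific name\t|\n")
        t = TaxonomyTree.from_ncbi_dumps(nodes, names)
        assert t.path_to_root(10239) == [10239, 1]
        assert t.name[10239] == "Viruses"


class TestCollation:
    def _call(self, pid, klass):
        from virobench.annotate import KingdomCall

        return KingdomCall(pid, klass, "a" if klass == "Viruses" else "cellular")

    def test_majority_and_viral_flag(self):
        calls = {"c1": [self._call("p1", "Viruses"), self._call("p2", "Viruses"),
                        self._call("p3", "Bacteria")]}
        rows = collate_contig_taxonomy(calls, {"c1": "Viruses"})
        assert rows[0]["majority_class"] == "Viruses"
        assert rows[0]["viral_contig"] is True
        assert rows[0]["nucleotide_kingdom"] == "Viruses"

    def test_tie_gives_unclassified(self):
        calls = {"c1": [self._call("p1", "Bacteria"), self._call("p2", "Eukaryota")]}
        rows = collate_contig_taxonomy(calls)
        assert rows[0]["majority_class"] == "unclassified"
        assert rows[0]["viral_contig"] is False

    def test_contig_without_proteins(self):
        rows = collate_contig_taxonomy({"c1": []})
        assert rows[0]["n_proteins"] == 0
        assert rows[0]["majority_class"] == "unclassified"


class TestContamination:
    def test_ratio_arithmetic(self):
        hits = [(f"r{i}", 90.0) for i in range(6)]
        assert contamination_fraction(hits, 10_000) == 0.06

    def test_empty_hit_table(self):
        assert contamination_fraction([], 5000) == 0.0

    def test_duplicate_hits_counted_once(self):
        hits = [("r1", 90.0), ("r1", 120.0), ("r2", 85.0)]
        assert contamination_fraction(hits, 100) == 2.0

    def test_below_threshold_ignored(self):
        assert contamination_fraction([("r1", 79.9)], 100) == 0.0

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            contamination_fraction([], 0)
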