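"""Concordance factors: quadripartitions, gCF, sCF, and the branch report."""

import itertools

import dendropy
import numpy as np
import pytest

from concordscape import synthetic_data
from concordscape.concordance import (
    BranchQuadripartition,
    concordance_frame,
    concordance_table,
    annotate_tree,
    gene_concordance,
    internal_branches,
    quadripartition,
    site_concordance,
    site_support,
)
from concordscape.phylo_core import (
    MultipleAlignment,
    PhyloError,
    read_tree,
)


def dendropy_contains_split(gene_newick: str, side: set, other: set) -> bool:
    """Independent oracle: does the gene tree contain the induced split?

    Uses dendropy's bipartition machinery on the gene tree restricted to the
    taxa shared with the reference bipartition.
    """
    tree = dendropy.Tree.get(data=gene_newick, schema="newick",
                             preserve_underscores=True)
    taxa = {lf.taxon.label for lf in tree.leaf_node_iter()}
    a, b = side & taxa, other & taxa
    if len(a) < 2 or len(b) < 2:
        return False
    tree.retain_taxa_with_labels(list(a | b))
    tree.encode_bipartitions()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        leafset = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter())
        if leafset in (frozenset(a), frozenset(b)):
            comp = (a | b) - leafset
            if len(leafset) >= 2 and len(comp) >= 2:
                return True
    return False


class TestQuadripartition:
    def test_five_taxon_example(self):
        tree = read_tree("((A,B),(C,(D,E)));")
        node = next(n for n in tree.preorder()
                    if {c.label for c in n.children} == {"A", "B"})
        quad = quadripartition(tree, node)
        assert set(quad.sets) == {frozenset("A"), frozenset("B"),
                                  frozenset("C"), frozenset("DE")}

    def test_four_taxon_tree(self):
        tree = read_tree("((A,B),(C,D));")
        node = next(n for n in tree.preorder()
                    if {c.label for c in n.children} == {"A", "B"})
        quad = quadripartition(tree, node)
        assert set(quad.sets) == {frozenset(x) for x in "ABCD"}

    def test_sets_partition_leaf_set(self, default_bundle):
        tree = default_bundle.species_tree
        for _, quad in internal_branches(tree):
            assert quad.taxa == tree.taxon_set()
            assert sum(len(s) for s in quad.sets) == tree.n_leaves()

    def test_terminal_branch_rejected(self):
        tree = read_tree("((A,B),(C,D));")
        leaf = tree.leaves()[0]
        with pytest.raises(PhyloError):
            quadripartition(tree, leaf)

    def test_branch_count_is_n_minus_3(self, default_bundle):
        tree = default_bundle.species_tree
        assert len(internal_branches(tree)) == tree.n_leaves() - 3


class TestGeneConcordance:
    def test_all_identical_genes_give_100(self):
        ref = read_tree("((A,B),(C,(D,E)));")
        genes = [read_tree("((A,B),(C,(D,E)));") for _ in range(10)]
        for _, quad in internal_branches(ref):
            gcf, n_conc, n_dec = gene_concordance(quad, genes)
            assert gcf == 100.0 and n_conc == n_dec == 10

    def test_hand_enumerated_mixture(self):
        # third gene lacks the {D,E} subtree entirely -> not decisive
        ref = read_tree("((A,B),(C,(D,E)));")
        quad = next(q for _, q in internal_branches(ref)
                    if q.bipartition.normalized_side() == frozenset("AB"))
        genes = [read_tree("((A,B),(C,(D,E)));"),
                 read_tree("((A,C),(B,(D,E)));"),
                 read_tree("((A,B),C);")]
        gcf, n_conc, n_dec = gene_concordance(quad, genes)
        assert (gcf, n_conc, n_dec) == (50.0, 1, 2)

    def test_no_decisive_genes_is_undefined_not_zero(self):
        ref = read_tree("((A,B),(C,(D,E)));")
        quad = internal_branches(ref)[0][1]
        genes = [read_tree("((A,B),C);")] * 3  # all miss the {D,E} subtree
        gcf, n_conc, n_dec = gene_concordance(quad, genes)
        assert gcf is None and n_dec == 0

    def test_matches_dendropy_oracle_on_msc_genes(self):
        """Dual route: our restricted-split membership vs dendropy bipartitions."""
        sp = synthetic_data.build_species_tree({
            "clade_sizes": {"OUT": 1, "PNA": 2, "PRI": 1, "HAL": 2, "MM": 1,
                            "AMC": 1},
        })
        genes = synthetic_data.simulate_msc_gene_trees(sp, 50, seed=4)
        rng = np.random.default_rng(0)
        genes = synthetic_data.drop_taxa(genes, 0.85, rng)
        ref = sp
        for _, quad in internal_branches(ref):
            bip = quad.bipartition
            side, other = set(bip.side_a), set(bip.side_b)
            expected_conc = 0
            expected_dec = 0
            for g in genes:
                taxa = g.taxon_set()
                if not all(s & taxa for s in quad.sets):
                    continue
                expected_dec += 1
                if dendropy_contains_split(g.to_newick(), side, other):
                    expected_conc += 1
            gcf, n_conc, n_dec = gene_concordance(quad, genes)
            assert (n_conc, n_dec) == (expected_conc, expected_dec)


class TestSiteSupport:
    @pytest.mark.parametrize("site,expected", [
        ("AAGG", (1, 0, 0)),   # pairs taxa 1+2
        ("AGAG", (0, 1, 0)),   # pairs taxa 1+3
        ("AGGA", (0, 0, 1)),   # pairs taxa 1+4
        ("AAAA", (0, 0, 0)),   # constant: not decisive
        ("ACGT", (0, 0, 0)),   # all different: not decisive
        ("AAG-", (0, 0, 0)),   # gap: not decisive
        ("AAGN", (0, 0, 0)),   # missing: not decisive
    ])
    def test_single_site_classification(self, site, expected):
        aln = MultipleAlignment(list("abcd"), list(site))
        assert site_support(aln, list("abcd"))[:3] == expected

    def test_exactly_one_class_over_all_256_patterns(self):
        """Every clean 4-nucleotide pattern is s1, s2, s3, or not decisive."""
        for pattern in itertools.product("ACGT", repeat=4):
            aln = MultipleAlignment(list("abcd"), list(pattern))
            s1, s2, s3, total = site_support(aln, list("abcd"))
            assert total == s1 + s2 + s3
            assert sorted((s1, s2, s3)) in ([0, 0, 0], [0, 0, 1])

    def test_brute_force_counts_on_toy_alignment(self, rng):
        rows = ["".join(rng.choice(list("ACGT-N"), 12)) for _ in range(4)]
        aln = MultipleAlignment(list("abcd"), rows)
        s1, s2, s3, total = site_support(aln, list("abcd"))
        exp = [0, 0, 0]
        for col in zip(*rows):
            a, b, c, d = col
            if any(ch in "-N" for ch in col):
                continue
            if a == b and c == d and a != c:
                exp[0] += 1
            elif a == c and b == d and a != b:
                exp[1] += 1
            elif a == d and b == c and a != b:
                exp[2] += 1
        assert [s1, s2, s3] == exp

    def test_absent_taxon_rejected(self):
        aln = MultipleAlignment(list("abcd"), ["A", "C", "G", "T"])
        with pytest.raises(PhyloError):
            site_support(aln, ["a", "b", "c", "z"])


class TestSiteConcordance:
    def test_perfectly_supporting_alignment(self):
        quad = BranchQuadripartition((frozenset("a"), frozenset("b"),
                                      frozenset("c"), frozenset("d")))
        aln = MultipleAlignment(list("abcd"),
                                ["AACC", "AACC", "GGTT", "GGTT"])
        scf, s_n, n_q = site_concordance(quad, aln, n_quartets=10, rng=0)
        assert scf == 100.0 and s_n == 4.0 and n_q == 1

    def test_exhaustive_equals_brute_force_average(self, rng):
        taxa = list("abcde")
        rows = ["".join(rng.choice(list("ACGT"), 40)) for _ in taxa]
        aln = MultipleAlignment(taxa, rows)
        quad = BranchQuadripartition((frozenset("ab"), frozenset("c"),
                                      frozenset("d"), frozenset("e")))
        scf, _, n_q = site_concordance(quad, aln, n_quartets=100, rng=1)
        assert n_q == 2  # 2*1*1*1 combinations, enumerated exhaustively
        props = []
        for q in itertools.product("ab", "c", "d", "e"):
            s1, s2, s3, tot = site_support(aln, q)
            if tot:
                props.append(100.0 * s1 / tot)
        assert scf == pytest.approx(np.mean(props))

    def test_null_alignment_near_one_third(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        rows = ["".join(rng.choice(list("ACGT"), 20000)) for _ in taxa]
        aln = MultipleAlignment(taxa, rows)
        quad = BranchQuadripartition((
            frozenset(taxa[:2]), frozenset(taxa[2:4]),
            frozenset(taxa[4:6]), frozenset(taxa[6:]),
        ))
        scf, _, _ = site_concordance(quad, aln, n_quartets=100, rng=2)
        assert scf == pytest.approx(100.0 / 3.0, abs=1.5)

    def test_no_decisive_sites_flagged_undefined(self):
        quad = BranchQuadripartition((frozenset("a"), frozenset("b"),
                                      frozenset("c"), frozenset("d")))
        aln = MultipleAlignment(list("abcd"), ["AAAA"] * 4)
        scf, s_n, _ = site_concordance(quad, aln, n_quartets=5, rng=0)
        assert scf is None and s_n is None


class TestConcordanceTable:
    def test_record_count_and_planted_signal(self, rng):
        ref = read_tree("(((A,B),C),((D,E),F));")
        genes = [read_tree("(((A,B),C),((D,E),F));") for _ in range(20)]
        rows = ["".join(rng.choice(list("ACGT"), 3000)) for _ in "ABCDEF"]
        aln = MultipleAlignment(list("ABCDEF"), rows)
        records = concordance_table(ref, genes, aln, n_quartets=100, seed=7)
        assert len(records) == 3  # n - 3 internal branches
        assert all(r.gCF == 100.0 for r in records)
        for r in records:
            assert r.sCF == pytest.approx(100.0 / 3.0, abs=4.0)

    def test_fixed_seed_reproducible_report(self, rng, tmp_path):
        ref = read_tree("(((A,B),C),((D,E),F));")
        genes = [read_tree("(((A,B),C),((D,E),F));") for _ in range(5)]
        rows = ["".join(rng.choice(list("ACGT"), 500)) for _ in "ABCDEF"]
        aln = MultipleAlignment(list("ABCDEF"), rows)
        frames = []
        for _ in range(2):
            records = concordance_table(ref, genes, aln, n_quartets=10, seed=11)
            frames.append(concordance_frame(records).to_csv(sep="\t"))
        assert frames[0] == frames[1]

    def test_annotated_tree_carries_labels(self, rng):
        ref = read_tree("((A,B),(C,(D,E)));")
        genes = [read_tree("((A,B),(C,(D,E)));")] * 4
        records = concordance_table(ref, genes, None, seed=0)
        annotated = annotate_tree(ref, records)
        labels = [n.label for n in annotated.preorder()
                  if not n.is_leaf and n.label]
        assert labels and all(lab.startswith("100.0/") for lab in labels)


class TestCoalescentOracle:
    def test_gcf_tracks_closed_form(self):
        """Empirical gCF at internode T matches 100(1 - 2/3 e^-T) (3 SE)."""
        T = 1.0
        sp = read_tree(f"(((A:1,B:1):{T},C:{1 + T}):8,D:{9 + T});")
        genes = synthetic_data.simulate_msc_gene_trees(sp, 1500, seed=13)
        quad = next(q for _, q in internal_branches(sp)
                    if q.bipartition.normalized_side() == frozenset("AB"))
        gcf, _, n_dec = gene_concordance(quad, genes)
        expected = 100.0 * synthetic_data.expected_concordance(T)
        se = 100.0 * np.sqrt(expected / 100 * (1 - expected / 100) / n_dec)
        assert abs(gcf - expected) < 3 * se
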