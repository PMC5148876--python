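import io as _io

import numpy as np
import pytest
from Bio import Phylo

from endosig.errors import EndosigError, FormatError
from endosig.hgt import (
    Hit,
    HitTable,
    adaptive_cluster,
    call_candidate,
    filter_hits,
    greedy_cluster,
    nj_tree,
    pairwise_identity,
    rpb2_control_settings,
    screen_gene,
    sister_clade_call,
)
from endosig.simulate import SimulationConfig, simulate_hit_tables


def make_hit(i, kingdom="fungal", bit=100.0, identity=0.5, coverage=0.9):
    return Hit(hit_id=f"h{i:04d}", taxon_name=f"t{i}", kingdom=kingdom,
               bit_score=bit, identity=identity, query_coverage=coverage)


class TestFilterHits:
    def test_coverage_boundary(self):
        hits = [make_hit(0, coverage=0.39), make_hit(1, coverage=0.40)]
        table = filter_hits("g", hits)
        assert [h.hit_id for h in table.hits] == ["h0001"]

    def test_truncation_to_best_by_bit_score(self):
        hits = [make_hit(i, bit=float(i + 1)) for i in range(1500)]
        table = filter_hits("g", hits, max_hits=1000)
        assert len(table.hits) == 1000
        assert table.hits[0].bit_score == 1500.0
        assert min(h.bit_score for h in table.hits) == 501.0

    def test_matches_naive_filter(self, rng):
        hits = [
            make_hit(i, bit=float(rng.uniform(30, 500)),
                     identity=float(rng.uniform(0, 1)),
                     coverage=float(rng.uniform(0, 1)))
            for i in range(200)
        ]
        table = filter_hits("g", hits)
        naive = sorted(
            (h for h in hits if h.query_coverage >= 0.40 and h.identity >= 0.20),
            key=lambda h: (-h.bit_score, h.hit_id),
        )[:1000]
        assert table.hits == naive

    def test_empty_result_flagged(self):
        table = filter_hits("g", [make_hit(0, coverage=0.1)])
        assert table.hits == [] and table.filtered


class TestCallCandidate:
    def test_skew_only(self):
        hits = [make_hit(i, "fungal", bit=400.0) for i in range(10)]
        hits += [make_hit(100 + i, "non_fungal", bit=300.0) for i in range(90)]
        call = call_candidate(HitTable("g", hits))
        assert call.reasons == {"taxonomic_skew"}
        assert call.is_candidate

    def test_dominance_only(self):
        hits = [make_hit(i, "fungal", bit=200.0) for i in range(50)]
        hits += [make_hit(100 + i, "non_fungal", bit=250.0) for i in range(50)]
        call = call_candidate(HitTable("g", hits))
        assert call.reasons == {"bitscore_dominance"}

    def test_no_fungal_hits_triggers_both(self):
        hits = [make_hit(i, "non_fungal") for i in range(5)]
        call = call_candidate(HitTable("g", hits))
        assert call.reasons == {"taxonomic_skew", "bitscore_dominance"}

    def test_majority_fungal_dominant_not_candidate(self):
        hits = [make_hit(i, "fungal", bit=400.0) for i in range(80)]
        hits += [make_hit(100 + i, "non_fungal", bit=300.0) for i in range(20)]
        call = call_candidate(HitTable("g", hits))
        assert not call.is_candidate and call.reasons == frozenset()

    def test_empty_table_not_evaluable(self):
        call = call_candidate(HitTable("g", []))
        assert not call.evaluable and not call.is_candidate

    def test_scale_invariance_in_bit_scores(self, rng):
        hits = [
            make_hit(i, "fungal" if rng.random() < 0.5 else "non_fungal",
                     bit=float(rng.uniform(50, 500)))
            for i in range(60)
        ]
        call1 = call_candidate(HitTable("g", hits))
        scaled = [
            Hit(h.hit_id, h.taxon_name, h.kingdom, h.bit_score * 7.3,
                h.identity, h.query_coverage)
            for h in hits
        ]
        call2 = call_candidate(HitTable("g", scaled))
        assert call1.reasons == call2.reasons


def unrooted_bipartitions(tree):
    """Non-trivial leaf bipartitions of a Bio.Phylo tree, each as its
    canonical (lexicographically smaller) side."""
    all_leaves = frozenset(l.name for l in tree.get_terminals())
    parts = set()
    for clade in tree.get_nonterminals():
        side = frozenset(l.name for l in clade.get_terminals())
        if 1 < len(side) < len(all_leaves) - 1:
            parts.add(min(side, all_leaves - side, key=sorted))
    return parts


def nw_affine_score(a, b, match=1, mismatch=-1, open_=-2, extend=-1):
    """Independent affine-gap global alignment score (Gotoh DP)."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = open_ + extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend, X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_fully_mismatched(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(EndosigError):
            pairwise_identity("", "ACGT")

    def test_symmetry_and_score_against_gotoh_oracle(self, rng):
        from endosig.hgt import _aligner
        for _ in range(30):
            la, lb = int(rng.integers(3, 25)), int(rng.integers(3, 25))
            a = "".join(rng.choice(list("ACGT"), size=la))
            b = "".join(rng.choice(list("ACGT"), size=lb))
            assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))
            assert _aligner.score(a, b) == pytest.approx(nw_affine_score(a, b))

    def test_equal_length_high_similarity_matches_hamming(self, rng):
        base = rng.choice(list("ACGT"), size=60)
        mut = base.copy()
        mut[[3, 17, 40]] = ["T" if x != "T" else "A" for x in mut[[3, 17, 40]]]
        ident = pairwise_identity("".join(base), "".join(mut))
        hamming = float(np.mean(base == mut))
        assert ident == pytest.approx(hamming, abs=0.05)


class TestGreedyAndAdaptiveClustering:
    def test_all_identical_one_cluster(self):
        seqs = {f"s{i}": "ACGTACGTAC" for i in range(10)}
        cs = greedy_cluster(seqs, 0.95)
        assert cs.n_clusters == 1
        assert cs.threshold_used == 0.95

    def test_two_families_two_clusters(self):
        seqs = {"a1": "A" * 40, "a2": "A" * 40, "b1": "ACGT" * 10, "b2": "ACGT" * 10}
        cs = greedy_cluster(seqs, 0.95)
        assert cs.n_clusters == 2

    def test_matches_reference_greedy_order_for_order(self, rng):
        seqs = {}
        for i in range(12):
            seqs[f"s{i:02d}"] = "".join(
                rng.choice(list("ACGT"), size=int(rng.integers(20, 60)))
            )
        threshold = 0.6
        cs = greedy_cluster(seqs, threshold)
        order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
        clusters = []
        for sid in order:
            for rep, members in clusters:
                if pairwise_identity(seqs[sid], seqs[rep]) >= threshold:
                    members.append(sid)
                    break
            else:
                clusters.append((sid, [sid]))
        assert cs.clusters == clusters

    def test_adaptive_identical_sequences(self):
        seqs = {f"s{i}": "MKVLITAG" * 5 for i in range(10)}
        cs = adaptive_cluster(seqs)
        assert cs.threshold_used == 0.95 and cs.n_clusters == 1

    def test_adaptive_floor_reached(self, rng):
        seqs = {
            f"s{i:02d}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
            for i in range(60)
        }
        cs = adaptive_cluster(seqs)
        assert cs.threshold_used == pytest.approx(0.50)
        assert cs.n_clusters == 60

    def test_adaptive_steps_to_intermediate_threshold(self, rng):
        # 35 families; 15 carry a variant at identity between 0.90 and 0.95,
        # so 50 clusters form at 0.95 but only 35 at 0.90
        seqs = {}
        for i in range(35):
            base = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100)
            seqs[f"f{i:02d}a"] = "".join(base)
            if i < 15:
                var = base.copy()
                pos = rng.choice(100, size=7, replace=False)
                var[pos] = [chr(ord("A"))] * 7  # deterministic substitution
                seqs[f"f{i:02d}b"] = "".join(var)
        at95 = greedy_cluster(seqs, 0.95).n_clusters
        at90 = greedy_cluster(seqs, 0.90).n_clusters
        assert at95 > 40 >= at90  # constructed premise
        cs = adaptive_cluster(seqs)
        assert cs.threshold_used == pytest.approx(0.90)
        assert cs.n_clusters == at90

    def test_threshold_always_on_grid(self, rng):
        grid = {round(0.95 - 0.05 * k, 2) for k in range(10)}
        for n in (3, 10, 25):
            seqs = {
                f"s{i:02d}": "".join(rng.choice(list("ACDEFG"), size=30))
                for i in range(n)
            }
            cs = adaptive_cluster(seqs)
            assert round(cs.threshold_used, 2) in grid


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        newick = nj_tree(d, ["A", "B", "C"])
        tree = Phylo.read(_io.StringIO(newick), "newick")
        bl = {leaf.name: leaf.branch_length for leaf in tree.get_terminals()}
        # a + b = 5, a + c = 9, b + c = 10 -> a=2, b=3, c=7
        assert bl["A"] == pytest.approx(2.0)
        assert bl["B"] == pytest.approx(3.0)
        assert bl["C"] == pytest.approx(7.0)

    def test_four_taxon_additive_recovers_topology(self):
        d = np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float)
        newick = nj_tree(d, ["A", "B", "C", "D"])
        tree = Phylo.read(_io.StringIO(newick), "newick")
        # A and B must be siblings (share their immediate parent clade)
        clade_ab = tree.common_ancestor(["A", "B"])
        assert {l.name for l in clade_ab.get_terminals()} == {"A", "B"}
        # branch lengths reproduce the generating tree
        dist = {}
        for x in "ABCD":
            for y in "ABCD":
                if x < y:
                    dist[x + y] = tree.distance(x, y)
        assert dist["AB"] == pytest.approx(5.0)
        assert dist["CD"] == pytest.approx(9.0)
        assert dist["AC"] == pytest.approx(7.0)

    def test_label_permutation_topology_invariant(self):
        d = np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float)
        labels = ["A", "B", "C", "D"]
        perm = [2, 0, 3, 1]
        dp = d[np.ix_(perm, perm)]
        lp = [labels[i] for i in perm]
        t1 = Phylo.read(_io.StringIO(nj_tree(d, labels)), "newick")
        t2 = Phylo.read(_io.StringIO(nj_tree(dp, lp)), "newick")
        # same unrooted topology: the single internal edge splits AB | CD
        assert unrooted_bipartitions(t1) == unrooted_bipartitions(t2) == {
            frozenset({"A", "B"})
        }

    def test_against_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(5)
        raw = rng.uniform(0.2, 1.0, size=(6, 6))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"t{i}" for i in range(6)]
        ours = Phylo.read(_io.StringIO(nj_tree(d, labels)), "newick")
        theirs = skbio_nj(DistanceMatrix(d, labels))
        # compare unrooted topologies via leaf bipartitions
        def bipartitions_phylo(tree):
            all_leaves = frozenset(l.name for l in tree.get_terminals())
            parts = set()
            for clade in tree.get_nonterminals():
                side = frozenset(l.name for l in clade.get_terminals())
                if 1 < len(side) < len(all_leaves) - 1:
                    parts.add(min(side, all_leaves - side, key=sorted))
            return parts

        def bipartitions_skbio(tree):
            all_leaves = frozenset(t.name for t in tree.tips())
            parts = set()
            for node in tree.non_tips(include_self=True):
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < len(all_leaves) - 1:
                    parts.add(min(side, all_leaves - side, key=sorted))
            return parts

        assert bipartitions_phylo(ours) == bipartitions_skbio(theirs)

    def test_too_few_taxa(self):
        with pytest.raises(EndosigError):
            nj_tree(np.zeros((2, 2)), ["A", "B"])

    def test_invalid_matrix(self):
        with pytest.raises(FormatError):
            nj_tree(np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], float), list("ABC"))


class TestSisterCladeCall:
    def test_focal_beside_bacterium(self):
        newick = "((focal:0.05,bact1:0.05):0.5,fungus1:0.6);"
        call = sister_clade_call(newick, "focal",
                                 {"bact1": "non_fungal", "fungus1": "fungal"})
        assert call.origin == "non_fungal"
        assert call.supported_hgt
        assert call.sister_members == ["bact1"]

    def test_focal_nested_among_fungi(self):
        newick = "((focal:0.05,fun1:0.05):0.1,(fun2:0.1,bact1:0.9):0.2);"
        call = sister_clade_call(newick, "focal",
                                 {"fun1": "fungal", "fun2": "fungal", "bact1": "non_fungal"})
        assert call.origin == "fungal"
        assert not call.supported_hgt

    def test_unlabeled_leaf_rejected(self):
        with pytest.raises(EndosigError):
            sister_clade_call("((focal:1,x:1):1,y:1);", "focal", {"x": "fungal"})


def test_rpb2_control_settings_immutable():
    preset = rpb2_control_settings()
    assert preset["identity_floor"] == 0.75
    assert preset["cluster_threshold"] == 0.90
    with pytest.raises(TypeError):
        preset["identity_floor"] = 0.5


class TestEndToEnd:
    def test_planted_genes_supported_by_tree(self):
        cfg = SimulationConfig(seed=17, n_genes_hit_tables=12, n_planted_hgt=3,
                               hits_per_gene=20)
        tables, focal_seqs, truth = simulate_hit_tables(cfg, seq_length=80)
        planted = set(truth.planted_hgt_gene_ids)
        for table in tables:
            result = screen_gene(table, focal_seqs[table.gene_id], phylogeny=True)
            if table.gene_id in planted:
                assert result.call.is_candidate
                assert result.sister is not None and result.sister.supported_hgt
            else:
                assert not result.call.is_candidate

    def test_fungal_only_family_not_supported(self):
        # conserved-control behaviour: a gene whose neighbours are all fungal
        hits = [
            Hit(f"h{i}", f"fungus{i}", "fungal", 400.0, 0.9, 1.0, sequence="MKVLITAGHERT" * 5)
            for i in range(4)
        ]
        table = HitTable("ctrl_gene", hits)
        result = screen_gene(table, "MKVLITAGHERT" * 5, phylogeny=True)
        assert not result.call.is_candidate
        assert result.sister is None
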