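"""Classifier: domain search, clustering oracle, MSA filter, NJ trees,
family cuts and canonical names."""

import numpy as np
import pytest

from retromob import classify, synth
from retromob._util import random_seq, revcomp
from retromob.phylo import Node, bipartitions, neighbor_joining


@pytest.fixture(scope="module")
def domain_db():
    rng = np.random.default_rng(12)
    return synth.make_domain_db({"Ale": "Copia", "Athila": "Gypsy"}, rng)


class TestDetectDomains:
    def test_embedded_domains_found_with_lineage(self, domain_db):
        rng = np.random.default_rng(0)
        spec = synth.ElementSpec(name="e", ltr_len=300, internal_len=3500,
                                 lineage="Ale")
        elem, _, _ = synth.build_element(spec, rng, domain_db=domain_db)
        hits = classify.detect_domains("e", elem, domain_db)
        assert {h.domain for h in hits} == {"GAG", "PR", "INT", "RT", "RH"}
        assert all(h.lineage == "Ale" for h in hits)
        # Copia order along the element
        assert [h.domain for h in sorted(hits, key=lambda h: h.start)] == [
            "GAG", "PR", "INT", "RT", "RH"
        ]

    def test_minus_strand_hits_at_mirrored_coordinates(self, domain_db):
        rng = np.random.default_rng(1)
        spec = synth.ElementSpec(name="e", ltr_len=300, internal_len=3500,
                                 lineage="Ale")
        elem, _, _ = synth.build_element(spec, rng, domain_db=domain_db)
        fwd = classify.detect_domains("e", elem, domain_db)
        rev = classify.detect_domains("e", revcomp(elem), domain_db)
        n = len(elem)
        assert {(h.domain, n - h.end, n - h.start) for h in rev} == {
            (h.domain, h.start, h.end) for h in fwd
        }
        assert all(h.frame < 0 for h in rev)

    def test_element_without_domains_is_unclassified(self, domain_db):
        rng = np.random.default_rng(2)
        elem = random_seq(rng, 4000, 0.4)
        hits = classify.detect_domains("bare", elem, domain_db)
        assert hits == []
        assert classify.assign_lineage(hits) == ("unclassified", "unclassified")

    def test_malformed_header_rejected(self):
        with pytest.raises(ValueError, match="bad header"):
            classify.parse_domain_db([("bad header", "MKV")])


class TestAssignLineage:
    def _hit(self, lineage):
        return classify.DomainHit("c", "RT", 1, 0, 30, 100.0, lineage)

    def test_majority_vote(self):
        hits = [self._hit("Ale"), self._hit("Ale"), self._hit("Athila")]
        assert classify.assign_lineage(hits) == ("Ale", "Copia")

    def test_gypsy_superfamily_lookup(self):
        assert classify.assign_lineage([self._hit("Athila")]) == (
            "Athila", "Gypsy"
        )

    def test_tie_goes_unclassified(self):
        hits = [self._hit("Ale"), self._hit("Athila")]
        assert classify.assign_lineage(hits) == ("unclassified", "unclassified")


class TestClusterSubfamilies:
    def test_identical_sequences_one_subfamily(self):
        seqs = {f"c{i}": "TG" + "ACGT" * 60 + "CA" for i in range(5)}
        part = classify.cluster_subfamilies(seqs)
        assert set(part.assignment.values()) == {"s0001"}

    def test_transitive_chain_clusters_together(self):
        rng = np.random.default_rng(4)
        a = random_seq(rng, 400, 0.4)
        b = synth.substitute(a, 30, 10, rng)
        c = synth.substitute(b, 30, 10, rng)
        part = classify.cluster_subfamilies({"a": a, "b": b, "c": c})
        assert len(set(part.assignment.values())) == 1

    def test_low_overlap_pair_stays_separate(self):
        rng = np.random.default_rng(5)
        a = random_seq(rng, 400, 0.4)
        half = a[:200] + random_seq(rng, 220, 0.4)
        part = classify.cluster_subfamilies({"a": a, "h": half})
        assert part.assignment["a"] != part.assignment["h"]

    def test_matches_brute_force_components(self):
        """Single-linkage result equals connected components of the
        thresholded all-pairs graph, across many random sequence sets."""
        for trial in range(25):
            rng = np.random.default_rng(trial)
            seqs = {}
            n_fam = int(rng.integers(1, 4))
            ancestors = [random_seq(rng, 300, 0.4) for _ in range(n_fam)]
            for i in range(int(rng.integers(3, 8))):
                anc = ancestors[int(rng.integers(0, n_fam))]
                n_mut = int(rng.integers(0, 40))
                seqs[f"t{trial}_{i}"] = synth.substitute(
                    anc, n_mut * 2 // 3, n_mut - n_mut * 2 // 3, rng
                )
            part = classify.cluster_subfamilies(seqs)
            # brute force: thresholded pair graph + BFS, written out here
            ids = sorted(seqs)
            adj = {i: set() for i in ids}
            for x in range(len(ids)):
                for y in range(x + 1, len(ids)):
                    pid, pov = classify.ltr_pair_metrics(
                        seqs[ids[x]], seqs[ids[y]]
                    )
                    if pid >= 0.6 and pov >= 0.7:
                        adj[ids[x]].add(ids[y])
                        adj[ids[y]].add(ids[x])
            seen, comps = set(), []
            for start in ids:
                if start in seen:
                    continue
                stack, comp = [start], set()
                while stack:
                    node = stack.pop()
                    if node in comp:
                        continue
                    comp.add(node)
                    stack.extend(adj[node] - comp)
                seen |= comp
                comps.append(frozenset(comp))
            got = {}
            for cid, lab in part.assignment.items():
                got.setdefault(lab, set()).add(cid)
            assert {frozenset(v) for v in got.values()} == set(comps)


class TestAlignAndFilter:
    def test_identical_sequences_untouched(self):
        seqs = {f"s{i}": "ACGTACGTAA" * 10 for i in range(4)}
        aln = classify.align_and_filter(seqs)
        assert all(v == "ACGTACGTAA" * 10 for v in aln.values())

    def test_unique_insertion_columns_dropped(self):
        rng = np.random.default_rng(6)
        base = random_seq(rng, 300, 0.4)
        seqs = {f"s{i}": base for i in range(19)}
        seqs["ins"] = base[:150] + random_seq(rng, 50, 0.4) + base[150:]
        aln = classify.align_and_filter(seqs)
        width = len(next(iter(aln.values())))
        assert width == 300
        assert aln["s0"] == base

    def test_width_bounded_by_longest_input(self):
        rng = np.random.default_rng(7)
        seqs = {f"s{i}": random_seq(rng, 200 + 10 * i, 0.4) for i in range(4)}
        aln = classify.align_and_filter(seqs)
        assert len(next(iter(aln.values()))) <= 230 + 200  # generous bound

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            classify.align_and_filter({"only": "ACGT"})


class TestNeighborJoining:
    def test_additive_quartet_recovered_exactly(self):
        # unrooted quartet: A,B joined (1,2), C,D joined (3,4), inner 1
        labels = ["A", "B", "C", "D"]
        dm = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(dm, labels)
        splits = bipartitions(tree)
        assert frozenset({"C", "D"}) in splits
        node = splits[frozenset({"C", "D"})]
        assert node.length == pytest.approx(1.0)
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_matches_reference_nj_on_random_additive_matrices(self):
        """Cross-check against an independent NJ (scikit-bio) on
        additive matrices built from random cherry trees."""
        import skbio

        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 6
            # three cherries hanging off a central node, random lengths
            leaf = rng.uniform(0.1, 2.0, size=n)
            inner = rng.uniform(0.5, 2.0, size=3)
            dm = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    ci, cj = i // 2, j // 2
                    d = leaf[i] + leaf[j]
                    if ci != cj:
                        d += inner[ci] + inner[cj]
                    dm[i, j] = dm[j, i] = d
            labels = [f"t{i}" for i in range(n)]
            mine = neighbor_joining(dm, labels)
            ref = skbio.tree.nj(
                skbio.DistanceMatrix(dm, ids=labels), neg_as_zero=False
            )
            ref_splits = set()
            for node in ref.non_tips():
                side = frozenset(t.name for t in node.tips())
                allset = frozenset(labels)
                if 2 <= len(side) <= n - 2:
                    key = side if "t0" not in side else allset - side
                    ref_splits.add(key)
            assert set(bipartitions(mine)) == ref_splits

    def test_identical_sequences_star_tree(self):
        seqs = {f"s{i}": "ACGT" * 50 for i in range(5)}
        ft = classify.build_family_tree(seqs, n_bootstrap=10, seed=0)
        assert all(
            n.length == 0 for n in ft.tree.walk() if n is not ft.tree
        )

    def test_bootstrap_support_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        anc = random_seq(rng, 200, 0.4)
        seqs = {
            f"s{i}": synth.mutate_ltr_pair(anc, 0.1, rng, protect_ends=0)
            for i in range(5)
        }
        aln = classify.align_and_filter(seqs)
        t1 = classify.build_family_tree(aln, n_bootstrap=50, seed=5)
        t2 = classify.build_family_tree(aln, n_bootstrap=50, seed=5)
        assert t1.tree.newick() == t2.tree.newick()


class TestCutFamilies:
    def _leaf(self, name, length):
        return Node(name=name, length=length)

    def test_two_supported_clades_become_f1_f2(self):
        left = Node(length=0.5, support=95.0,
                    children=[self._leaf("a1", 0.01), self._leaf("a2", 0.01)])
        right = Node(length=0.5, support=95.0,
                     children=[self._leaf("b1", 0.01),
                               self._leaf("b2", 0.01),
                               self._leaf("b3", 0.01)])
        tree = Node(children=[left, right])
        ft = classify.FamilyTree(lineage="L", tree=tree, assignment={})
        fams = classify.cut_families(ft)
        assert fams["b1"] == fams["b2"] == fams["b3"] == "f1"  # larger clade
        assert fams["a1"] == fams["a2"] == "f2"

    def test_star_tree_single_family(self):
        tree = Node(children=[self._leaf(f"s{i}", 0.05) for i in range(6)])
        ft = classify.FamilyTree(lineage="L", tree=tree, assignment={})
        fams = classify.cut_families(ft)
        assert set(fams.values()) == {"f1"}

    def test_copies_without_rt_get_f0(self):
        tree = Node(children=[self._leaf("a", 0.05), self._leaf("b", 0.05)])
        ft = classify.FamilyTree(lineage="L", tree=tree, assignment={})
        fams = classify.cut_families(ft, no_rt=["trunc1"])
        assert fams["trunc1"] == "f0"

    def test_low_support_long_branch_not_cut(self):
        clade = Node(length=0.5, support=40.0,
                     children=[self._leaf("a", 0.01), self._leaf("b", 0.01)])
        tree = Node(children=[clade, self._leaf("c", 0.01)])
        ft = classify.FamilyTree(lineage="L", tree=tree, assignment={})
        fams = classify.cut_families(ft)
        assert len(set(fams.values())) == 1


class TestCanonicalName:
    def test_classified_name(self):
        name = classify.canonical_name("Copia", "Ale", "f2", "s0082",
                                       "chr3", 100, 5000)
        assert name == "Copia_DcAle_f2.s0082_chr3:100-5000"

    def test_unclassified_placeholder(self):
        name = classify.canonical_name("unclassified", "unclassified",
                                       "f0", "s0191", "chr1", 5, 10)
        assert name == "unclassified_f0.s0191_chr1:5-10"

    @pytest.mark.parametrize("args", [
        ("Copia", "Ale", "f2", "s0082", "chr3", 100, 5000),
        ("Gypsy", "Athila", "f11", "s1140", "chr9", 1, 99),
        ("unclassified", "unclassified", "f0", "s0003", "chrX", 7, 8),
    ])
    def test_round_trip(self, args):
        name = classify.canonical_name(*args)
        d = classify.parse_name(name)
        assert (d["lineage"], d["family"], d["subfamily"],
                d["chrom"], d["start"], d["end"]) == (
            args[1], args[2], args[3], args[4], args[5], args[6]
        )
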