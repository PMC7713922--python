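"""Genealogical-concordance delimitation: clade status, independent
lineages, provisional species, the divergence threshold, and rescue."""

import numpy as np
import pytest

from hostnet.alignment import DistanceMatrix, p_distance, trim_alignment
from hostnet.datamodel import ValidationError
from hostnet.delimitation import (
    CONTRADICTED,
    PRESENT,
    UNINFORMATIVE,
    CladeSet,
    assign_remaining,
    clade_status,
    delimit,
    divergence_threshold,
    independent_lineages,
    provisional_species,
)
from hostnet.io import read_newick
from hostnet.simulate import simulate_gene_trees


def dm(ids, entries):
    """DistanceMatrix from {(a, b): d} pairs."""
    n = len(ids)
    v = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(ids)}
    for (a, b), d in entries.items():
        v[idx[a], idx[b]] = v[idx[b], idx[a]] = d
    return DistanceMatrix(list(ids), v)


class TestCladeStatus:
    @pytest.mark.parametrize(
        "clade,newick,expected",
        [
            ({"a", "b"}, "((a,b),(c,d));", PRESENT),
            ({"a", "c"}, "((a,b),(c,d));", CONTRADICTED),
            ({"a", "b"}, "((a,x),y);", UNINFORMATIVE),  # b absent, |S|=1
            ({"a", "b", "c", "d"}, "((a,b),(c,d));", UNINFORMATIVE),  # S = all leaves
            ({"c", "d", "e"}, "((a,b),(c,(d,e)));", PRESENT),
        ],
    )
    def test_status(self, clade, newick, expected):
        assert clade_status(frozenset(clade), read_newick(newick)) == expected


class TestIndependentLineages:
    def test_full_concordance(self):
        trees = [read_newick("((a,b),(c,(d,e)));") for _ in range(3)]
        lin = independent_lineages(trees)
        assert set(lin.clades) == {
            frozenset("ab"),
            frozenset("de"),
            frozenset("cde"),
        }

    def test_contradicted_in_one_tree_excluded(self):
        t12 = read_newick("((a,b),(c,d));")
        t3 = read_newick("((a,c),(b,d));")  # contradicts {a,b}
        lin = independent_lineages([t12, read_newick("((a,b),(c,d));"), t3])
        assert frozenset("ab") not in set(lin.clades)

    def test_present_once_uninformative_twice_excluded(self):
        # {a,b} monophyletic only in tree 1; trees 2, 3 lack b entirely
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,c),d);")
        t3 = read_newick("((a,d),c);")
        lin = independent_lineages([t1, t2, t3])
        assert frozenset("ab") not in set(lin.clades)

    def test_fewer_than_two_trees_errors(self):
        with pytest.raises(ValidationError):
            independent_lineages([read_newick("((a,b),c);")])


class TestProvisionalSpecies:
    def make_cladeset(self, sets):
        return CladeSet(
            [frozenset(s) for s in sets], [(PRESENT, PRESENT, UNINFORMATIVE)] * len(sets)
        )

    def test_nested_qualifying_lineage_wins(self):
        cs = self.make_cladeset(["abc", "abcde", "de"])
        assert provisional_species(cs) == [frozenset("abc")]

    def test_single_lineage(self):
        cs = self.make_cladeset(["abc"])
        assert provisional_species(cs) == [frozenset("abc")]

    def test_all_lineages_too_small(self):
        cs = self.make_cladeset(["ab", "cd"])
        assert provisional_species(cs) == []

    def test_small_nested_lineage_does_not_disqualify(self):
        cs = self.make_cladeset(["abcd", "ab"])
        assert provisional_species(cs) == [frozenset("abcd")]


class TestThreshold:
    def test_min_cross_pair(self):
        ids = list("abcdef")
        entries = {(x, y): 0.2 for x in "abc" for y in "def"}
        entries[("c", "d")] = 0.07
        D = dm(ids, entries)
        thr = divergence_threshold([frozenset("abc"), frozenset("def")], D)
        assert thr == pytest.approx(0.07)

    def test_identical_duplicates_floor_zero(self):
        ids = list("abcdef")
        entries = {(x, y): 0.2 for x in "abc" for y in "def"}
        entries[("a", "d")] = 0.0
        D = dm(ids, entries)
        assert divergence_threshold([frozenset("abc"), frozenset("def")], D) == 0.0

    def test_single_species_undefined(self):
        D = dm(list("abc"), {})
        assert divergence_threshold([frozenset("abc")], D) is None


class TestAssignRemaining:
    def base(self):
        ids = list("abcx")
        entries = {(x, y): 0.01 for x in "abc" for y in "abc" if x < y}
        return ids, entries

    def test_distant_specimen_becomes_singleton(self):
        ids, entries = self.base()
        for m in "abc":
            entries[(m, "x")] = 0.15
        asg = assign_remaining(ids, [frozenset("abc")], 0.1, dm(ids, entries))
        assert asg.origin["x"] == "threshold_singleton"
        assert frozenset("x") in asg.partition()

    def test_zero_distance_specimen_joins(self):
        ids, entries = self.base()
        entries[("a", "x")] = 0.0
        entries[("b", "x")] = entries[("c", "x")] = 0.01
        asg = assign_remaining(ids, [frozenset("abc")], 0.1, dm(ids, entries))
        assert asg.assignment["x"] == asg.assignment["a"]
        assert asg.origin["x"] == "linked"

    def test_three_close_unplaced_form_new_cluster(self):
        ids = list("abcxyz")
        entries = {(p, q): 0.01 for p in "abc" for q in "abc" if p < q}
        entries.update({(p, q): 0.02 for p in "xyz" for q in "xyz" if p < q})
        entries.update({(p, q): 0.5 for p in "abc" for q in "xyz"})
        asg = assign_remaining(ids, [frozenset("abc")], 0.1, dm(ids, entries))
        assert frozenset("xyz") in asg.partition()

    def test_result_is_partition(self):
        ids, entries = self.base()
        for m in "abc":
            entries[(m, "x")] = 0.05
        asg = assign_remaining(ids, [frozenset("abc")], 0.1, dm(ids, entries))
        assigned = sorted(asg.assignment)
        assert assigned == sorted(ids)


class TestDelimit:
    def run_benchmark(self, seed, partition, concordance=1.0):
        rng = np.random.default_rng(seed)
        gts, sm, truth = simulate_gene_trees(partition, concordance, rng)
        D = p_distance(trim_alignment(sm))
        return delimit(gts, D), truth

    def test_three_cluster_benchmark_recovers_truth(self):
        part = [frozenset(f"sp{i}_{j}" for j in range(4)) for i in range(3)]
        asg, truth = self.run_benchmark(11, part)
        assert asg.partition() == set(truth.partition)

    def test_divergent_singleton_added(self):
        part = [frozenset(f"sp{i}_{j}" for j in range(4)) for i in range(3)]
        part.append(frozenset(["lone"]))
        asg, truth = self.run_benchmark(12, part)
        assert asg.partition() == set(truth.partition)
        assert len(asg.partition()) == 4
        assert asg.origin["lone"] == "threshold_singleton"

    def test_within_cluster_rearrangement_keeps_species_count(self):
        part = [frozenset(f"sp{i}_{j}" for j in range(4)) for i in range(3)]
        rng = np.random.default_rng(13)
        gts, sm, truth = simulate_gene_trees(part, 1.0, rng)
        # swap two specimens of one cluster in one gene tree only
        t = gts[0]
        leaves = {lf.taxon.label: lf for lf in t.leaf_node_iter()}
        a, b = leaves["sp0_0"], leaves["sp0_1"]
        c = leaves["sp0_2"]
        a.taxon, c.taxon = c.taxon, a.taxon
        D = p_distance(trim_alignment(sm))
        asg = delimit(gts, D)
        assert len(asg.partition()) == 3
        assert asg.partition() == set(truth.partition)

    def test_label_equivariance(self):
        part = [frozenset(f"sp{i}_{j}" for j in range(4)) for i in range(2)]
        rng = np.random.default_rng(14)
        gts, sm, truth = simulate_gene_trees(part, 1.0, rng)
        D = p_distance(trim_alignment(sm))
        asg1 = delimit(gts, D)
        relabel = {s: f"Q_{s}" for p in part for s in p}
        taxa = {id(lf.taxon): lf.taxon for t in gts for lf in t.leaf_node_iter()}
        for tx in taxa.values():
            tx.label = relabel[tx.label]
        D2 = DistanceMatrix([relabel[i] for i in D.ids], D.values)
        asg2 = delimit(gts, D2)
        mapped = {frozenset(relabel[s] for s in p) for p in asg1.partition()}
        assert mapped == asg2.partition()

    def test_threshold_monotonicity_in_singletons(self):
        # raising the threshold never increases singleton count
        part = [frozenset(f"sp{i}_{j}" for j in range(4)) for i in range(3)]
        part += [frozenset(["x1"]), frozenset(["x2"])]
        rng = np.random.default_rng(15)
        gts, sm, _ = simulate_gene_trees(part, 1.0, rng)
        D = p_distance(trim_alignment(sm))
        from hostnet.delimitation import (
            _midpoint_root_if_unrooted,
            independent_lineages,
            provisional_species,
        )

        trees = [_midpoint_root_if_unrooted(t) for t in gts]
        species = provisional_species(independent_lineages(trees))
        specimens = sorted({lf.taxon.label for t in trees for lf in t.leaf_node_iter()})
        counts = []
        for thr in (0.01, 0.05, 0.2, 0.8):
            asg = assign_remaining(specimens, species, thr, D)
            counts.append(len(asg.outlier_species))
        assert counts == sorted(counts, reverse=True)
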