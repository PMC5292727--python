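"""p-distances, NJ fallback tree, monophyly, problem-species flags and the
printed-percentage function."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampliqc.model import DistanceMatrix, ValidationError
from ampliqc.report import (
    PhyloTree,
    build_nj_tree,
    check_monophyly,
    divergent_groups,
    flag_problem_species,
    group_divergence,
    p_distance,
    percent,
    success_by_year_series,
)

from conftest import mutate, random_seq


class TestPDistance:
    def test_identical(self, rng):
        s = random_seq(rng, 100)
        assert p_distance(s, s) == 0.0

    def test_two_differences_over_hundred(self, rng):
        s = random_seq(rng, 100)
        assert p_distance(s, mutate(rng, s, 2)) == pytest.approx(0.02)

    def test_sites_with_n_are_pairwise_deleted(self, rng):
        s = random_seq(rng, 100)
        other = mutate(rng, s, 2)
        masked = "N" * 10 + other[10:]
        # the 2 mutated sites sit outside the mask with high prob.; place
        # them deterministically instead
        other = s[:50] + ("A" if s[50] != "A" else "C") + s[51:]
        masked = "N" * 10 + other[10:]
        assert p_distance(s, masked) == pytest.approx(1 / 90)

    def test_zero_comparable_sites_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance("NNNN", "ACGT")

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = random_seq(rng, 80)
        b = mutate(rng, a, int(rng.integers(0, 40)))
        d1, d2 = p_distance(a, b), p_distance(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0
        assert (d1 == 0.0) == (a == b)


class TestGroupDivergence:
    def test_singleton_groups_equal_pairwise(self, rng):
        a = random_seq(rng, 100)
        b = mutate(rng, a, 8)
        assert group_divergence([[a], [b]]) == pytest.approx(p_distance(a, b))

    def test_duplicate_members_do_not_change_value(self, rng):
        a = random_seq(rng, 100)
        b = mutate(rng, a, 8)
        assert group_divergence([[a, a], [b]]) == pytest.approx(p_distance(a, b))

    def test_matches_brute_force_average(self, rng):
        groups = [[random_seq(rng, 60) for _ in range(3)] for _ in range(3)]
        want = np.mean(
            [
                p_distance(x, y)
                for gi in range(3)
                for gj in range(gi + 1, 3)
                for x in groups[gi]
                for y in groups[gj]
            ]
        )
        assert group_divergence(groups) == pytest.approx(want)


def _additive_matrix():
    """4-taxon tree ((A:2,B:3):1,(C:4,D:5)); path-length (additive) matrix."""
    labels = ["A", "B", "C", "D"]
    m = np.array(
        [
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ],
        dtype=float,
    )
    return DistanceMatrix(labels, m)


class TestBuildNJTree:
    def test_recovers_additive_four_taxon_tree(self):
        tree = build_nj_tree(_additive_matrix())
        sk = tree.tree
        # topology: AB | CD split with the generating branch lengths
        tip = {t.name: t for t in sk.tips()}
        assert tip["A"].length == pytest.approx(2.0)
        assert tip["B"].length == pytest.approx(3.0)
        # A and B form a cherry
        a_parent = tip["A"].parent
        assert {t.name for t in a_parent.tips()} == {"A", "B"}
        # path lengths reproduce the input distances exactly
        for x, y, d in [("A", "B", 5), ("A", "C", 7), ("C", "D", 9)]:
            assert tip[x].distance(tip[y]) == pytest.approx(float(d))

    def test_three_taxa_star(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float),
        )
        tree = build_nj_tree(dm)
        assert sorted(t.name for t in tree.tree.tips()) == ["A", "B", "C"]

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], dtype=float))

    def test_deterministic(self):
        t1 = build_nj_tree(_additive_matrix()).to_newick()
        t2 = build_nj_tree(_additive_matrix()).to_newick()
        assert t1 == t2


# ------------------------------------------------------------- monophyly

def random_tree_newick(rng, n_leaves):
    """Random binary topology by sequential leaf attachment."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    parts = [nodes[0], nodes[1], nodes[2]] if n_leaves >= 3 else nodes[:]
    rest = nodes[3:]
    # represent as a nested list structure
    tree = parts
    for leaf in rest:
        # pick a random position: wrap a random existing element
        def collect(node, acc):
            acc.append(node)
            if isinstance(node, list):
                for c in node:
                    collect(c, acc)

        acc = []
        for c in tree:
            collect(c, acc)
        target = acc[int(rng.integers(len(acc)))]

        def replace(node, target, repl):
            if node is target:
                return repl
            if isinstance(node, list):
                return [replace(c, target, repl) for c in node]
            return node

        tree = [replace(c, target, [target, leaf]) for c in tree]

    def to_newick(node):
        if isinstance(node, list):
            return "(" + ",".join(to_newick(c) for c in node) + ")"
        return node

    return "(" + ",".join(to_newick(c) for c in tree) + ");"


def monophyly_oracle(newick, species_map):
    """Independent check via networkx: a species is monophyletic iff
    removing some edge separates exactly its leaves from the rest."""
    import io
    import networkx as nx
    from skbio import TreeNode

    t = TreeNode.read(io.StringIO(newick), format="newick")
    g = nx.Graph()
    counter = [0]
    names = {}

    def walk(node):
        if node.is_tip():
            names[id(node)] = node.name
            return node.name
        counter[0] += 1
        me = f"internal{counter[0]}"
        for child in node.children:
            g.add_edge(me, walk(child))
        return me

    root = walk(t)
    leaves = {x for x in g.nodes if not x.startswith("internal")}
    by_species = {}
    for leaf in leaves:
        by_species.setdefault(species_map[leaf], set()).add(leaf)
    out = {}
    for sp, members in by_species.items():
        if len(members) <= 1:
            out[sp] = True
            continue
        ok = False
        for e in list(g.edges):
            g.remove_edge(*e)
            comps = list(nx.connected_components(g))
            g.add_edge(*e)
            for comp in comps:
                if comp & leaves == members:
                    ok = True
        out[sp] = ok
    return out


class TestCheckMonophyly:
    def test_adjacent_cherries_all_monophyletic(self):
        tree = PhyloTree.from_newick("((a1,a2),(b1,b2),(c1,c2));")
        result = check_monophyly(
            tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
        )
        assert all(result.values())

    def test_interleaved_species_paraphyletic(self):
        tree = PhyloTree.from_newick("((a1,(b1,b2)),a2,c1);")
        result = check_monophyly(
            tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
        )
        assert result["B"] is True
        assert result["A"] is False

    def test_singleton_species_monophyletic(self):
        tree = PhyloTree.from_newick("((a1,b1),c1);")
        result = check_monophyly(tree, {"a1": "A", "b1": "B", "c1": "C"})
        assert all(result.values())

    def test_unmapped_leaf_raises(self):
        tree = PhyloTree.from_newick("((a1,b1),c1);")
        with pytest.raises(ValueError, match="without species"):
            check_monophyly(tree, {"a1": "A", "b1": "B"})

    @settings(max_examples=20, deadline=None)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.integers(min_value=4, max_value=12),
        st.integers(min_value=2, max_value=4),
    )
    def test_agrees_with_bipartition_enumeration(self, seed, n_leaves, n_species):
        rng = np.random.default_rng(seed)
        newick = random_tree_newick(rng, n_leaves)
        species_map = {
            f"L{i}": f"S{int(rng.integers(n_species))}" for i in range(n_leaves)
        }
        got = check_monophyly(PhyloTree.from_newick(newick), species_map)
        want = monophyly_oracle(newick, species_map)
        assert got == want


class TestProblemSpecies:
    def test_tight_monophyletic_species_not_flagged(self, rng):
        base = random_seq(rng, 300)
        seqs = {
            "x1": base,
            "x2": mutate(rng, base, 2),  # ~0.7% apart
            "y1": mutate(rng, base, 60),
        }
        species = {"x1": "X", "x2": "X", "y1": "Y"}
        problems = flag_problem_species(seqs, species, None, 0.07)
        assert problems == []

    def test_two_divergent_groups_flagged(self, rng):
        base = random_seq(rng, 300)
        far = mutate(rng, base, 24)  # 8% within one nominal species
        seqs = {"x1": base, "x2": base, "x3": far, "out": mutate(rng, base, 90)}
        species = {"x1": "X", "x2": "X", "x3": "X", "out": "O"}
        problems = flag_problem_species(seqs, species, None, 0.07)
        flagged = {p.species: p for p in problems}
        assert "X" in flagged
        assert flagged["X"].n_groups == 2
        assert flagged["X"].between_group_divergence == pytest.approx(0.08)

    def test_boundary_is_strictly_greater(self, rng):
        # a species whose two haplotype groups sit at exactly the threshold
        # chains into one group: flagging requires divergence STRICTLY > 7%
        base = random_seq(rng, 300)
        at_seven = mutate(rng, base, 21)  # exactly 0.07
        groups = divergent_groups(["a", "b"], [base, at_seven], 0.07)
        assert len(groups) == 1
        above = mutate(rng, base, 22)
        groups = divergent_groups(["a", "b"], [base, above], 0.07)
        assert len(groups) == 2

    def test_paraphyly_alone_flags(self, rng):
        # five leaves: with only four, B monophyletic would force A
        # monophyletic under the unrooted convention
        base = random_seq(rng, 300)
        seqs = {
            "a1": base,
            "b1": mutate(rng, base, 30),
            "b2": mutate(rng, base, 60),
            "a2": mutate(rng, base, 3),
            "c1": mutate(rng, base, 45),
        }
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
        tree = PhyloTree.from_newick("((a1,(b1,b2)),a2,c1);")
        problems = flag_problem_species(seqs, species, tree, 0.30)
        assert [p.species for p in problems] == ["A"]
        assert problems[0].paraphyletic


class TestPercent:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(272, 369, 73.7), (99, 115, 86.1), (0, 115, 0.0)],
    )
    def test_printed_rounding(self, num, den, expected):
        assert percent(num, den) == expected

    def test_half_up(self):
        assert percent(1, 8) == 12.5
        assert percent(5, 8) == 62.5
        assert percent(1, 16) == 6.3  # 6.25 rounds half-up

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)


class TestSuccessByYear:
    def test_rates_and_negative_age_trend(self):
        years = [2000] * 10 + [2005] * 10 + [2010] * 10
        success = [False] * 7 + [True] * 3 + [False] * 5 + [True] * 5 + [False] * 1 + [True] * 9
        df, corr = success_by_year_series(years, success)
        assert df.loc[df.year == 2000, "success_rate"].item() == pytest.approx(0.3)
        assert df.loc[df.year == 2010, "success_rate"].item() == pytest.approx(0.9)
        # success increases with collection year = decreases with age
        assert corr == pytest.approx(1.0)
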