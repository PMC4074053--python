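"""Parsimony-tree tests against brute-force oracles.

The oracles enumerate every unrooted topology (<= 6 taxa) and every
internal state assignment, entirely independently of the Fitch/Sankoff
implementation under test.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from endoscreen import tree as T


# ---------------------------------------------------------------------------
# brute-force oracles


def all_unrooted_topologies(n_taxa):
    """Enumerate unrooted binary trees by recursive edge insertion."""
    assert 4 <= n_taxa <= 6

    def edges_of(adj):
        return [(u, v) for u in adj for v in adj[u] if u < v]

    def clone(adj):
        return {k: set(v) for k, v in adj.items()}

    hub = n_taxa  # internal ids never collide with taxa 0..n-1
    base = {hub: {0, 1, 2}, 0: {hub}, 1: {hub}, 2: {hub}}
    trees = [base]
    next_leaf = 3
    while next_leaf < n_taxa:
        new_trees = []
        for adj in trees:
            for u, v in edges_of(adj):
                a = clone(adj)
                w = max(a) + 1
                a[u].discard(v)
                a[v].discard(u)
                a[u].add(w)
                a[v].add(w)
                a[w] = {u, v, next_leaf}
                a[next_leaf] = {w}
                new_trees.append(a)
        trees = new_trees
        next_leaf += 1
    return trees


def brute_force_char_score(adj, leaf_states, *, root_state=None):
    """Minimum changes for one binary character by trying every internal
    state assignment (optionally with the root forced)."""
    internal = sorted(n for n in adj if len(adj[n]) > 1)
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    best = math.inf
    for combo in itertools.product([0, 1], repeat=len(internal)):
        state = dict(zip(internal, combo))
        state.update(leaf_states)
        if root_state is not None and state[root_state[0]] != root_state[1]:
            continue
        changes = sum(state[u] != state[v] for u, v in edges)
        best = min(best, changes)
    return best


def brute_force_score(adj, matrix):
    total = 0
    for c in range(matrix.n_characters):
        leaf_states = {t: int(matrix.data[t, c]) for t in range(matrix.n_taxa)}
        changes = brute_force_char_score(adj, leaf_states)
        if changes == 0 and any(leaf_states.values()):
            changes = 1  # gain-rooting convention: ubiquitous characters originate once
        total += changes
    return total


def random_matrix(rng, n_taxa, n_chars):
    data = rng.random((n_taxa, n_chars)) < 0.4
    return T.CharacterMatrix(
        [f"t{i}" for i in range(n_taxa)],
        [f"c{j}" for j in range(n_chars)],
        data,
    )


# ---------------------------------------------------------------------------


class TestFilterNontrivial:
    def _fv(self, rows):
        cols = ["F1", "F2", "F3"]
        return pd.DataFrame(
            {c: [bool(r[i]) for r in rows.values()] for i, c in enumerate(cols)},
            index=list(rows),
        )

    def test_singletons_split_out(self):
        fv = self._fv({"gA": (1, 1, 0), "gB": (1, 0, 0), "gC": (0, 1, 1)})
        matrix, singles = T.filter_nontrivial(fv)
        assert matrix.characters == ["gA", "gC"]
        assert singles == ["gB"]

    def test_all_singletons_rejected(self):
        fv = self._fv({"gA": (1, 0, 0), "gB": (0, 1, 0)})
        with pytest.raises(ValueError):
            T.filter_nontrivial(fv)


class TestParsimonyScore:
    def test_four_taxon_example(self):
        taxa = ["A", "B", "C", "D"]
        data = np.array([[1, 1, 1, 0, 0, 0],
                         [1, 1, 1, 0, 0, 0],
                         [0, 0, 0, 1, 1, 1],
                         [0, 0, 0, 1, 1, 1]], dtype=bool)
        m = T.CharacterMatrix(taxa, [f"c{i}" for i in range(6)], data)
        assert T.parsimony_score("((A,B),(C,D));", m) == 6
        assert T.parsimony_score("((A,C),(B,D));", m) == 12

    def test_ubiquitous_character_costs_one_origin(self):
        m = T.CharacterMatrix(["A", "B", "C", "D"], ["c0"],
                              np.ones((4, 1), dtype=bool))
        assert T.parsimony_score("((A,B),(C,D));", m) == 1

    def test_all_zero_character_costs_nothing(self):
        m = T.CharacterMatrix(["A", "B", "C", "D"], ["c0"],
                              np.zeros((4, 1), dtype=bool))
        assert T.parsimony_score("((A,B),(C,D));", m) == 0

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_matches_brute_force_on_all_topologies(self, n_taxa, rng):
        m = random_matrix(rng, n_taxa, 8)
        for adj in all_unrooted_topologies(n_taxa):
            assert T.parsimony_score(adj, m) == brute_force_score(adj, m)

    def test_leaf_mismatch_rejected(self):
        m = T.CharacterMatrix(["A", "B", "C"], ["c0"], np.zeros((3, 1), dtype=bool))
        with pytest.raises(ValueError):
            T.parsimony_score("((A,B),(C,D));", m)


class TestSearchTree:
    def test_recovers_four_taxon_optimum(self, rng):
        taxa = ["A", "B", "C", "D"]
        data = np.array([[1, 1, 1, 0, 0, 0],
                         [1, 1, 1, 0, 0, 0],
                         [0, 0, 0, 1, 1, 1],
                         [0, 0, 0, 1, 1, 1]], dtype=bool)
        m = T.CharacterMatrix(taxa, [f"c{i}" for i in range(6)], data)
        adj, score = T.search_tree(m, n_restarts=5, seed=1)
        assert score == 6
        bips = {frozenset(taxa[i] for i in b) for b in T._bipartitions(adj, 4)}
        assert bips == {frozenset({"C", "D"})}  # the AB|CD split

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_finds_global_optimum_on_six_taxa(self, seed, rng):
        """Exhaustive 105-topology oracle gives the global minimum."""
        m = random_matrix(np.random.Generator(np.random.PCG64(seed + 50)), 6, 10)
        best = min(brute_force_score(adj, m) for adj in all_unrooted_topologies(6))
        _, score = T.search_tree(m, n_restarts=10, seed=seed)
        assert score == best

    def test_nested_characters_recover_nesting(self):
        taxa = list("ABCDEF")
        groups = ["AB", "ABCD", "EF"]
        cols = [[t in g for t in taxa] for g in groups for _ in range(3)]
        m = T.CharacterMatrix(taxa, [f"c{i}" for i in range(9)], np.array(cols).T)
        adj, score = T.search_tree(m, n_restarts=10, seed=3)
        assert score == 9  # one gain per character
        bips = {frozenset(taxa[i] for i in b) for b in T._bipartitions(adj, 6)}
        complement = lambda s: frozenset(taxa) - s
        for g in groups:
            fs = frozenset(g)
            assert fs in bips or complement(fs) in bips

    def test_deterministic_per_seed(self, rng):
        m = random_matrix(rng, 6, 12)
        a1, s1 = T.search_tree(m, n_restarts=5, seed=9)
        a2, s2 = T.search_tree(m, n_restarts=5, seed=9)
        assert s1 == s2 and a1 == a2

    def test_score_beats_caterpillar(self, rng):
        """Search never does worse than a fixed ladder topology."""
        m = random_matrix(rng, 6, 15)
        ladder = "((((( t0,t1),t2),t3),t4),t5);".replace(" ", "")
        _, score = T.search_tree(m, n_restarts=5, seed=4)
        assert score <= T.parsimony_score(ladder, m)


class TestJackknifeConsensus:
    def test_unanimous_bipartition_has_full_support(self):
        taxa = list("ABCDEF")
        cols = [[t in "ABC" for t in taxa] for _ in range(20)]
        m = T.CharacterMatrix(taxa, [f"c{i}" for i in range(20)], np.array(cols).T)
        cons = T.jackknife_consensus(m, n_reps=20, n_restarts=3, seed=1)
        clades = cons.clade_leafsets()
        supports = {frozenset(clades[n.node_id]): n.support
                    for n in cons.internal_nodes() if n.support is not None}
        target = frozenset("ABC")
        comp = frozenset(taxa) - target
        assert any(cl in (target, comp) and s == 100.0 for cl, s in supports.items())

    def test_conflicting_signal_collapses_to_polytomy(self):
        """50/50 conflicting characters leave no majority bipartition."""
        taxa = list("ABCD")
        half1 = [[t in "AB" for t in taxa]] * 10   # supports AB|CD
        half2 = [[t in "AC" for t in taxa]] * 10   # supports AC|BD
        m = T.CharacterMatrix(taxa, [f"c{i}" for i in range(20)],
                              np.array(half1 + half2).T)
        cons = T.jackknife_consensus(m, n_reps=40, n_restarts=3, seed=2)
        supported = [n for n in cons.internal_nodes()
                     if n.support is not None and n.support > 75]
        assert supported == []  # neither split reaches a stable majority

    def test_supports_within_bounds(self, rng):
        m = random_matrix(rng, 6, 15)
        cons = T.jackknife_consensus(m, n_reps=10, n_restarts=3, seed=3)
        for n in cons.internal_nodes():
            if n.support is not None:
                assert 50.0 < n.support <= 100.0


class TestAssignCharacters:
    def _consensus(self, matrix, seed=1):
        return T.jackknife_consensus(matrix, n_reps=10, n_restarts=5, seed=seed)

    def test_single_clade_character_gains_once(self):
        taxa = list("ABCDEF")
        # each character sits on exactly one clade of the true tree
        groups = ["AB", "CD", "EF"]
        cols = [[t in g for t in taxa] for g in groups for _ in range(5)]
        m = T.CharacterMatrix(taxa, [f"c{i}" for i in range(15)], np.array(cols).T)
        tree = T.assign_characters(self._consensus(m), m)
        ev = tree.events
        assert ev.losses == 0
        assert ev.gains == 15  # one gain per character
        assert ev.total_events == ev.gains + ev.losses
        assert ev.multi_gain_characters == 0

    def test_disjoint_clades_prefer_two_gains(self):
        taxa = list("ABCDEF")
        scaffold = [[t in g for t in taxa] for g in ("AB", "CD", "EF") for _ in range(5)]
        probe = [[t in "ABEF" for t in taxa]]  # on two disjoint clades
        m = T.CharacterMatrix(taxa, [f"c{i}" for i in range(16)],
                              np.array(scaffold + probe).T)
        tree = T.assign_characters(self._consensus(m), m)
        gains = sum("c15" in n.genes_added for n in tree.nodes())
        losses = sum("c15" in n.genes_lost for n in tree.nodes())
        # 2 gains vs 1 gain + 1 loss are equal cost; gains preferred
        assert (gains, losses) == (2, 0)

    def test_events_match_sankoff_minimum(self, rng):
        """Total events per character equal the brute-force minimum
        (with the root state forced to the chosen reconstruction's)."""
        m = random_matrix(rng, 6, 12)
        cons = self._consensus(m, seed=5)
        tree = T.assign_characters(cons, m)
        # rebuild adjacency of the final rooted tree for the oracle
        adj = {}
        ids = {}

        def walk(node):
            ids.setdefault(id(node), len(ids))
            for c in node.children:
                ids.setdefault(id(c), len(ids))
                adj.setdefault(ids[id(node)], set()).add(ids[id(c)])
                adj.setdefault(ids[id(c)], set()).add(ids[id(node)])
                walk(c)

        walk(tree.root)
        leaf_idx = {n.leaf_name: ids[id(n)] for n in tree.leaves()}
        taxon_of = {name: i for i, name in enumerate(m.taxa)}
        # model the origin event as a state-0 pseudo-leaf above the root
        pseudo = len(ids) + 1
        root_id = ids[id(tree.root)]
        adj.setdefault(root_id, set()).add(pseudo)
        adj[pseudo] = {root_id}
        for ci, cname in enumerate(m.characters):
            gains = sum(cname in n.genes_added for n in tree.nodes())
            losses = sum(cname in n.genes_lost for n in tree.nodes())
            leaf_states = {leaf_idx[t]: int(m.data[taxon_of[t], ci]) for t in m.taxa}
            leaf_states[pseudo] = 0
            oracle = brute_force_char_score(adj, leaf_states)
            assert gains + losses == oracle, cname

    def test_reconstruction_reproduces_leaf_patterns(self, rng):
        """Applying gains/losses down the rooted tree yields each leaf's state."""
        m = random_matrix(rng, 6, 10)
        tree = T.assign_characters(self._consensus(m, seed=8), m)
        taxon_of = {name: i for i, name in enumerate(m.taxa)}
        for ci, cname in enumerate(m.characters):
            def state_at(node, inherited):
                s = inherited
                if cname in node.genes_added:
                    s = 1
                if cname in node.genes_lost:
                    s = 0
                if node.is_leaf:
                    assert s == int(m.data[taxon_of[node.leaf_name], ci])
                for c in node.children:
                    state_at(c, s)
            state_at(tree.root, 0)

    def test_root_is_least_populated_internal_node(self, rng):
        m = random_matrix(rng, 6, 10)
        tree = T.assign_characters(self._consensus(m, seed=11), m)
        pops = {n.node_id: n.n_state1 for n in tree.internal_nodes()}
        assert pops[tree.root.node_id] == min(pops.values())


class TestLeafOverlap:
    def test_identical_sets_are_enriched(self, rng):
        bg = [f"g{i}" for i in range(1000)]
        s = bg[:50]
        res = T.leaf_overlap_test(s, s, bg, n_perm=200, seed=1)
        assert res["p_enrich"] < 0.01
        assert res["p_deplete"] == pytest.approx(1.0)

    def test_disjoint_sets_are_depleted(self):
        bg = [f"g{i}" for i in range(100)]
        res = T.leaf_overlap_test(bg[:50], bg[50:], bg, n_perm=200, seed=2)
        # expected overlap of 50/50 from 100 is 25; zero is extreme depletion
        assert res["p_deplete"] < 1e-6
        assert res["observed"] == 0

    def test_empty_set_gives_p_one(self):
        res = T.leaf_overlap_test([], ["g1"], ["g1", "g2"], n_perm=50)
        assert res["p_empirical"] == 1.0
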