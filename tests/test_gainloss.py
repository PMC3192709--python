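"""Dollo loss counting, independent-gain counting, and the exact test."""

import itertools
import random
from math import comb, inf

import pytest

from cctrace.gainloss import (
    ModelViolation,
    compare_scenarios,
    cooccurrence,
    count_resolutions,
    enumerate_resolutions,
    min_gains_no_loss,
    min_losses_single_gain,
    _loss_stats,
)
from cctrace.io import read_tree_string

# ---------------------------------------------------------------- oracles


def _struct_of(node):
    if node.is_leaf():
        return ("leaf", node.taxon.label)
    return ("node", [_struct_of(c) for c in node.child_nodes()])


def _tips(struct):
    if struct[0] == "leaf":
        return [struct[1]]
    return [t for c in struct[1] for t in _tips(c)]


def _subtrees(struct):
    yield struct
    if struct[0] == "node":
        for c in struct[1]:
            yield from _subtrees(c)


def _min_cover_losses(struct, states):
    """Independent oracle for one binary tree: smallest set of loss edges
    (each an all-absent-or-unknown subtree) covering every absent tip."""
    candidates = []
    for sub in _subtrees(struct):
        tips = _tips(sub)
        if all(states.get(t) is not True for t in tips):
            if any(states.get(t) is False for t in tips):
                candidates.append(frozenset(tips))
    absent = {t for t in _tips(struct) if states.get(t) is False}
    if not absent:
        return 0
    for k in range(1, len(absent) + 1):
        for combo in itertools.combinations(candidates, k):
            if absent <= frozenset().union(*combo):
                return k
    return inf  # pragma: no cover


def _oracle_loss_range(tree, states, gain_node_label):
    phylo = tree
    node = phylo.find_node(gain_node_label)
    struct = _struct_of(node)
    counts = [
        _min_cover_losses(resolved, states)
        for resolved in enumerate_resolutions(struct)
    ]
    return min(counts), max(counts)


def _random_polytomy_tree(rng, n_tips):
    """Random rooted tree with polychotomies (child counts 2-4)."""
    labels = [f"t{i}" for i in range(n_tips)]
    nodes = [("leaf", l) for l in labels]
    while len(nodes) > 1:
        k = min(rng.randint(2, 4), len(nodes))
        picked = [nodes.pop(rng.randrange(len(nodes))) for _ in range(k)]
        nodes.append(("node", picked))
    def to_newick(s):
        if s[0] == "leaf":
            return s[1]
        return "(" + ",".join(to_newick(c) for c in s[1]) + ")"
    return read_tree_string(to_newick(nodes[0]) + ";"), labels


def _fisher_two_sided(a, b, c, d):
    """Closed-form two-sided hypergeometric sum."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    def pr(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)
    p_obs = pr(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(pr(x) for x in range(lo, hi + 1) if pr(x) <= p_obs * (1 + 1e-9))


# ----------------------------------------------------------------- tests


class TestSingleGainLosses:
    def test_binary_tree_two_isolated_absences(self):
        tree = read_tree_string("((A,B),(C,D));")
        states = {"A": True, "B": False, "C": True, "D": False}
        lo, hi, placements, _ = min_losses_single_gain(tree, states, "A,B,C,D")
        assert (lo, hi) == (2, 2)
        assert sorted(sorted(p) for p in placements) == [["B"], ["D"]]

    def test_trichotomy_resolution_shrinks_or_splits_the_loss(self):
        tree = read_tree_string("(A,B,C);")
        states = {"A": True, "B": False, "C": False}
        lo, hi, _, n_res = min_losses_single_gain(tree, states, "A,B,C")
        assert (lo, hi) == (1, 2)
        assert n_res == 3

    def test_all_tips_present_needs_no_losses(self):
        tree = read_tree_string("((A,B),C);")
        states = {t: True for t in "ABC"}
        assert min_losses_single_gain(tree, states, "A,B,C")[:2] == (0, 0)

    def test_star_tree_one_present_tip(self):
        tree = read_tree_string("(A,B,C,D,E);")
        states = {"A": True, "B": False, "C": False, "D": False, "E": False}
        lo, hi, _, n_res = min_losses_single_gain(tree, states, "A,B,C,D,E")
        assert (lo, hi) == (1, 4)
        assert n_res == 105  # (2*5-3)!! rooted binary shapes on 5 children

    def test_present_tip_outside_gain_subtree_rejected(self):
        tree = read_tree_string("((A,B),(C,D));")
        states = {"A": True, "B": True, "C": True, "D": False}
        with pytest.raises(ModelViolation, match="C"):
            min_losses_single_gain(tree, states, "A,B")

    def test_unknown_tips_take_the_cheaper_state(self):
        # ((A-, u?), B-): losing the whole left pair plus B is 2 either way,
        # but u=absent lets one loss cover A and u together
        tree = read_tree_string("(((A,U),B),P);")
        states = {"A": False, "U": None, "B": False, "P": True}
        lo, hi, _, _ = min_losses_single_gain(tree, states, "A,U,B,P")
        assert lo == 1  # (A,U,B) clade groups into one lost subtree

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_cover_oracle_on_random_trees(self, seed):
        rng = random.Random(seed)
        tree, labels = _random_polytomy_tree(rng, rng.randint(4, 9))
        states = {l: rng.choice([True, False, None]) for l in labels}
        if not any(s is True for s in states.values()):
            states[labels[0]] = True
        gain = ",".join(labels)
        lo, hi, _, _ = min_losses_single_gain(tree, states, gain)
        assert (lo, hi) == _oracle_loss_range(tree, states, gain)

    def test_closed_form_agrees_with_enumeration_past_the_cap(self):
        rng = random.Random(99)
        for _ in range(10):
            tree, labels = _random_polytomy_tree(rng, 8)
            states = {l: rng.choice([True, False]) for l in labels}
            states[labels[0]] = True
            gain = ",".join(labels)
            enum = min_losses_single_gain(tree, states, gain)
            closed = min_losses_single_gain(tree, states, gain, resolution_cap=0)
            assert enum[:2] == closed[:2]

    def test_sandwich_property_over_resolutions(self):
        tree = read_tree_string("((A,B,C,D),(P,Q));")
        states = {"A": False, "B": False, "C": True, "D": False,
                  "P": True, "Q": False}
        gain = "A,B,C,D,P,Q"
        lo, hi, _, _ = min_losses_single_gain(tree, states, gain)
        node = tree.find_node(gain)
        for resolved in enumerate_resolutions(_struct_of(node)):
            st = _loss_stats(resolved, states)
            assert lo <= st.min_count <= hi


class TestFreeGains:
    def test_two_disjoint_present_clades_need_two_gains(self):
        tree = read_tree_string("(((A,B),(C,D)),((E,F),(G,H)));")
        states = {t: t in "ABEF" for t in "ABCDEFGH"}
        gains, placements = min_gains_no_loss(tree, states)
        assert gains == 2
        assert sorted(sorted(p) for p in placements) == [["A", "B"], ["E", "F"]]

    def test_single_present_tip_is_one_gain(self):
        tree = read_tree_string("((A,B),C);")
        states = {"A": True, "B": False, "C": False}
        assert min_gains_no_loss(tree, states)[0] == 1

    def test_polychotomy_present_children_can_unite(self):
        tree = read_tree_string("(A,B,C,D);")
        states = {"A": True, "B": True, "C": False, "D": False}
        assert min_gains_no_loss(tree, states)[0] == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_over_resolutions_and_subsets(self, seed):
        rng = random.Random(100 + seed)
        tree, labels = _random_polytomy_tree(rng, rng.randint(4, 8))
        states = {l: rng.choice([True, False]) for l in labels}
        gains, _ = min_gains_no_loss(tree, states)
        # oracle: min over resolutions of the number of maximal present clades
        struct = _struct_of(tree.tree.seed_node)
        def maximal_present(s, parent_all_present=False):
            tips = _tips(s)
            allp = all(states[t] for t in tips)
            if allp:
                return 0 if parent_all_present else (1 if tips else 0)
            if s[0] == "leaf":
                return 0
            return sum(maximal_present(c, False) for c in s[1])
        oracle = min(
            maximal_present(r) for r in enumerate_resolutions(struct)
        )
        assert gains == oracle


class TestCompareScenarios:
    def test_two_present_clades_with_trichotomy(self):
        # two present clades separated by two absent clades that no
        # resolution of the root trichotomy can unite into one lost subtree
        tree = read_tree_string("((A,B),(C,D),((E,F),(G,H)));")
        states = {t: t in "ABGH" for t in "ABCDEFGH"}
        rows = compare_scenarios(tree, states, ["A,B,C,D,E,F,G,H"])
        single = next(s for s in rows if s.model == "single_gain_at_node")
        free = next(s for s in rows if s.model == "free_gains_no_loss")
        assert single.gain_count == 1 and single.loss_count_min >= 2
        assert free.gain_count == 2 and free.loss_count_max == 0

    def test_all_absent_flags_single_gain_infeasible(self):
        tree = read_tree_string("((A,B),C);")
        states = {t: False for t in "ABC"}
        rows = compare_scenarios(tree, states, ["A,B,C"])
        single = next(s for s in rows if s.model == "single_gain_at_node")
        assert not single.feasible
        assert "infeasible" in single.note


class TestSankoffBracketing:
    """The two extreme models bracket the general-cost minimum."""

    def _sankoff(self, struct, states, gain_cost, loss_cost):
        def costs(node):
            if node[0] == "leaf":
                s = states[node[1]]
                return {0: 0 if s is not True else inf,
                        1: 0 if s is not False else inf}
            out = {}
            ch = [costs(c) for c in node[1]]
            for b in (0, 1):
                total = 0.0
                for cc in ch:
                    as_absent = cc[0] + (loss_cost if b == 1 else 0)
                    as_present = cc[1] + (gain_cost if b == 0 else 0)
                    total += min(as_absent, as_present)
                out[b] = total
            return out
        root = costs(struct)
        # ancestrally absent; a present root counts as one gain on its stem
        return min(root[0], root[1] + gain_cost)

    @pytest.mark.parametrize("seed", range(6))
    def test_extreme_cost_ratios_recover_each_model(self, seed):
        rng = random.Random(200 + seed)
        # binary trees: resolution ranges collapse, comparison is exact
        labels = [f"t{i}" for i in range(6)]
        nodes = [("leaf", l) for l in labels]
        while len(nodes) > 1:
            a = nodes.pop(rng.randrange(len(nodes)))
            b = nodes.pop(rng.randrange(len(nodes)))
            nodes.append(("node", [a, b]))
        struct = nodes[0]
        def to_newick(s):
            return s[1] if s[0] == "leaf" else (
                "(" + ",".join(to_newick(c) for c in s[1]) + ")"
            )
        tree = read_tree_string(to_newick(struct) + ";")
        states = {l: rng.choice([True, False]) for l in labels}
        states[labels[0]] = True
        gains, _ = min_gains_no_loss(tree, states)
        present = [l for l in labels if states[l]]
        # optimal single-gain placement is the MRCA of the present tips
        losses = min_losses_single_gain(tree, states, ",".join(present))[0]
        # loss cost prohibitive -> independent gains; gain cost prohibitive
        # -> single gain plus losses
        assert self._sankoff(struct, states, 1, 1000) == gains
        assert self._sankoff(struct, states, 1000, 1) == 1000 + losses
        # any intermediate ratio can only do as well or better
        for g, l in [(1, 1), (2, 1), (1, 2), (3, 5)]:
            general = self._sankoff(struct, states, g, l)
            assert general <= min(g * gains, g + l * losses)


class TestCooccurrence:
    def test_perfect_association_matches_hypergeometric_sum(self):
        intron = {f"p{i}": True for i in range(16)} | {
            f"a{i}": False for i in range(30)
        }
        cct = dict(intron)
        res = cooccurrence(intron, cct)
        assert res.table.values.tolist() == [[16, 0], [0, 30]]
        assert res.discordant == []
        assert res.p_value == pytest.approx(_fisher_two_sided(16, 0, 0, 30), rel=1e-9)

    def test_constant_state_is_degenerate_with_p_one(self):
        intron = {"a": True, "b": True, "c": True}
        cct = {"a": True, "b": False, "c": True}
        res = cooccurrence(intron, cct)
        assert res.degenerate and res.p_value == 1.0

    def test_discordant_loss_taxon_listed(self):
        intron = {"p1": True, "p2": True, "loss": False, "a1": False, "a2": False}
        cct = {"p1": True, "p2": True, "loss": True, "a1": False, "a2": False}
        res = cooccurrence(intron, cct)
        assert res.discordant == ["loss"]
        assert res.table.loc["intron_absent", "cct_present"] == 1
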