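import math

import numpy as np
import pytest

from ylinkage import (
    ContingencyTable2x2,
    CostModel,
    InfeasibleReconstructionError,
    LinkageMatrix,
    GeneClassLabels,
    UninformativeGeneError,
    brute_force_min_cost,
    classify_events,
    map_observations,
    reacquisition_table,
    sankoff_reconstruct,
)
from ylinkage.phylogeny import parse_newick

from conftest import random_binary_tree, random_cost_model, random_tip_states

INF = float("inf")


class TestSankoff:
    def test_fig2_dollo_two_losses(self, fig2, fig2_tip_states, dollo_y):
        rec = sankoff_reconstruct(fig2.tree, fig2_tip_states, dollo_y, gene="ORY")
        assert rec.min_cost == 2
        changed = {(c[1], c[2], c[3]) for c in rec.change_branches}
        assert changed == {("nannoptera", "Y", "AX"), ("Zaprionus", "Y", "AX")}
        # one independent event covers all three Zaprionus species
        assert rec.node_state["Zaprionus"] == "AX"
        assert rec.node_state[fig2.tree.root.id] == "Y"

    def test_uniform_tips_no_changes(self, fig2, dollo_y):
        states = {sp: "Y" for sp in fig2.tree.tip_names}
        for cost in (dollo_y, CostModel.fitch()):
            rec = sankoff_reconstruct(fig2.tree, states, cost)
            assert rec.min_cost == 0
            assert rec.n_changes == 0
            assert set(rec.node_state.values()) == {"Y"}

    def test_fig2_reverse_hypothesis_needs_four_gains(self, fig2, fig2_tip_states):
        # ancestrally A/X with only gains allowed: one gain per Y-linked tip
        gains_only = CostModel.sankoff(
            {
                ("AX", "Y"): 1.0,
                ("Y", "AX"): INF,
                ("Y", "absent"): INF,
                ("AX", "absent"): INF,
                ("absent", "Y"): INF,
                ("absent", "AX"): INF,
            },
            root_state="AX",
        )
        rec = sankoff_reconstruct(fig2.tree, fig2_tip_states, gains_only, gene="ORY")
        assert rec.min_cost == 4
        tips_changed = {c[1] for c in rec.change_branches}
        assert tips_changed == {"melanogaster", "virilis", "acanthoptera", "immigrans"}

    def test_all_na_is_uninformative(self, fig2, dollo_y):
        with pytest.raises(UninformativeGeneError):
            sankoff_reconstruct(fig2.tree, {sp: None for sp in fig2.tree.tip_names}, dollo_y)

    def test_infeasible_reported_not_relaxed(self, fig2, fig2_tip_states):
        impossible = CostModel.dollo(root_state="AX")  # AX root but M tips exist
        with pytest.raises(InfeasibleReconstructionError):
            sankoff_reconstruct(fig2.tree, fig2_tip_states, impossible)

    def test_na_tips_are_free(self, dollo_y):
        tree = parse_newick("((a,b),(c,d));")
        rec = sankoff_reconstruct(tree, {"a": "Y", "b": None, "c": "Y", "d": None}, dollo_y)
        assert rec.min_cost == 0


class TestBruteForceOracle:
    def test_fig2_symmetric_costs(self, fig2, fig2_tip_states):
        assert brute_force_min_cost(fig2.tree, fig2_tip_states, CostModel.fitch()) == 2

    def test_two_disjoint_losses(self):
        tree = parse_newick("((a,b),(c,d));")
        states = {"a": "AX", "b": "Y", "c": "AX", "d": "Y"}
        assert brute_force_min_cost(tree, states, CostModel.dollo("Y")) == 2

    def test_uniform_zero(self):
        tree = parse_newick("((a,b),(c,d));")
        assert brute_force_min_cost(tree, {t: "Y" for t in "abcd"}, CostModel.fitch()) == 0

    def test_refuses_large_trees(self):
        rng = np.random.default_rng(0)
        tree = random_binary_tree(rng, 15)
        with pytest.raises(ValueError):
            brute_force_min_cost(tree, {t: "Y" for t in tree.tip_names}, CostModel.fitch())

    def test_sankoff_equals_brute_force_random(self):
        """DP minimum equals exhaustive enumeration on random instances."""
        rng = np.random.default_rng(991)
        for _ in range(120):
            tree = random_binary_tree(rng, int(rng.integers(2, 10)))
            states = random_tip_states(rng, tree)
            cost = random_cost_model(rng)
            expected = brute_force_min_cost(tree, states, cost)
            if math.isinf(expected):
                with pytest.raises(InfeasibleReconstructionError):
                    sankoff_reconstruct(tree, states, cost)
            else:
                rec = sankoff_reconstruct(tree, states, cost)
                assert rec.min_cost == pytest.approx(expected)
                # assignment consistency: cost of changes sums to min_cost
                total = sum(cost.cost(c[2], c[3]) for c in rec.change_branches)
                assert total == pytest.approx(rec.min_cost)


def count_max_ax_subtrees(tree, states):
    all_ax = {}
    for node in tree.root_postorder():
        if node.is_leaf:
            all_ax[node.id] = states[node.name] == "AX"
        else:
            all_ax[node.id] = all(all_ax[c.id] for c in node.children)
    if all_ax[tree.root.id]:
        return len(tree.root.children)  # root constrained Y: one loss per child
    return sum(
        1 for p, c in tree.edges() if all_ax[c.id] and not all_ax[p.id]
    )


def test_dollo_loss_count_closed_form():
    """Under Dollo with root Y, losses = number of maximal all-AX subtrees."""
    rng = np.random.default_rng(4242)
    dollo = CostModel.dollo("Y")
    for _ in range(60):
        tree = random_binary_tree(rng, int(rng.integers(3, 14)))
        states = {t: ("AX" if rng.random() < 0.4 else "Y") for t in tree.tip_names}
        rec = sankoff_reconstruct(tree, states, dollo)
        assert rec.n_changes == count_max_ax_subtrees(tree, states)


def min_losses_over_optima(tree, states, gain_cost):
    """Oracle: among all min-cost assignments, the minimum number of Y->AX
    changes (two-state enumeration)."""
    import itertools

    internal = [n for n in tree.preorder() if not n.is_leaf]
    best_cost, best_losses = INF, None
    for assign in itertools.product(("Y", "AX"), repeat=len(internal)):
        if assign[internal.index(tree.root)] != "Y":
            continue
        state = {n.id: s for n, s in zip(internal, assign)}
        state.update({tree.tip(t).id: states[t] for t in tree.tip_names})
        cost = losses = 0
        for p, c in tree.edges():
            s, t = state[p.id], state[c.id]
            if s == "Y" and t == "AX":
                cost += 1
                losses += 1
            elif s == "AX" and t == "Y":
                cost += gain_cost
        if cost < best_cost - 1e-9:
            best_cost, best_losses = cost, losses
        elif abs(cost - best_cost) <= 1e-9:
            best_losses = min(best_losses, losses)
    return best_losses


def test_loss_count_monotone_in_gain_cost():
    """Raising cost(AX->Y) never decreases the optimal number of Y->AX events."""
    rng = np.random.default_rng(77)
    for _ in range(15):
        tree = random_binary_tree(rng, int(rng.integers(4, 9)))
        states = {t: ("AX" if rng.random() < 0.5 else "Y") for t in tree.tip_names}
        counts = [
            min_losses_over_optima(tree, states, gc) for gc in (0.5, 1.0, 2.0, 4.0, INF)
        ]
        assert counts == sorted(counts)


class TestClassifyEvents:
    def _recon(self, tree, gene, states, cost=None):
        return sankoff_reconstruct(tree, states, cost or CostModel.dollo("Y"), gene=gene)

    def test_full_incorporation_single_event(self):
        tree = parse_newick("((a,b)inc,(c,d));")
        genes = [f"g{i}" for i in range(6)]
        recs = [
            self._recon(tree, g, {"a": "AX", "b": "AX", "c": "Y", "d": "Y"})
            for g in genes
        ]
        events = classify_events(recs, min_genes=3, inc_fraction=1.0)
        assert len(events) == 1
        (ev,) = events
        assert ev.type == "incorporation"
        assert ev.genes == frozenset(genes)
        assert ev.branch[1] == "inc"

    def test_single_gene_transfer(self, fig2, fig2_tip_states, dollo_y):
        rec = sankoff_reconstruct(fig2.tree, fig2_tip_states, dollo_y, gene="ORY")
        events = classify_events([rec])
        assert [e.type for e in events] == ["transfer", "transfer"]

    def test_adjacency_group_merges_transfers(self):
        tree = parse_newick("((a,b),(c,d));")
        moved = {"a": "AX", "b": "AX", "c": "Y", "d": "Y"}
        stay = {"a": "Y", "b": "Y", "c": "Y", "d": "Y"}
        recs = [
            self._recon(tree, "PRY", moved),
            self._recon(tree, "JY-alpha", moved),
            self._recon(tree, "kl-2", stay),
        ]
        events = classify_events(recs, groups=[["PRY", "JY-alpha"]], min_genes=3)
        assert len(events) == 1
        assert events[0].type == "transfer"
        assert events[0].genes == frozenset({"PRY", "JY-alpha"})

    def test_systematic_failure_is_genomic_loss(self):
        tree = parse_newick("((a,b),(c,d));")
        matrix = LinkageMatrix.from_dict(
            {"a": {"g": "F"}, "b": {"g": "F"}, "c": {"g": "M"}, "d": {"g": "M"}}
        )
        states = map_observations(matrix, "g")
        assert states["a"] == "absent"  # F in >= 2 species: systematic
        rec = self._recon(tree, "g", states)
        events = classify_events([rec])
        assert [e.type for e in events] == ["genomic_loss"]

    def test_lone_failure_treated_as_na(self):
        matrix = LinkageMatrix.from_dict(
            {"a": {"g": "F"}, "b": {"g": "M"}, "c": {"g": "M"}, "d": {"g": "M"}}
        )
        states = map_observations(matrix, "g")
        assert states["a"] is None

    def test_partition_property(self):
        """Every state change lands in exactly one event."""
        rng = np.random.default_rng(5150)
        for _ in range(25):
            tree = random_binary_tree(rng, int(rng.integers(4, 12)))
            recs = []
            for gi in range(int(rng.integers(2, 6))):
                states = {
                    t: ("AX" if rng.random() < 0.3 else "Y") for t in tree.tip_names
                }
                recs.append(self._recon(tree, f"g{gi}", states))
            events = classify_events(recs, min_genes=3, inc_fraction=1.0)
            n_changes = sum(r.n_changes for r in recs)
            assert sum(len(e.genes) for e in events) == n_changes

    def test_inc_fraction_validation(self, fig2, fig2_tip_states, dollo_y):
        rec = sankoff_reconstruct(fig2.tree, fig2_tip_states, dollo_y, gene="ORY")
        with pytest.raises(ValueError):
            classify_events([rec], inc_fraction=0.0)


class TestReacquisitionTable:
    def _matrix_with_moved(self, n_anc_moved):
        anc = [f"y{i}" for i in range(11)]
        ctl = [f"c{i}" for i in range(4)]
        rows = {}
        for sp in ("s1", "s2", "s3"):
            rows[sp] = {g: "MF" for g in anc + ctl}
        for i in range(n_anc_moved):
            rows[f"s{(i % 3) + 1}"][anc[i]] = "M"
        labels = GeneClassLabels(frozenset(anc), frozenset(ctl))
        return LinkageMatrix.from_dict(rows), labels

    def test_montium_configuration(self):
        matrix, labels = self._matrix_with_moved(9)
        table = reacquisition_table(matrix, labels)
        assert table.as_tuple() == (9, 2, 0, 4)

    def test_no_gene_ever_m(self):
        matrix, labels = self._matrix_with_moved(0)
        assert reacquisition_table(matrix, labels).as_tuple() == (0, 11, 0, 4)

    def test_clade_restriction(self):
        matrix, labels = self._matrix_with_moved(9)
        sub = reacquisition_table(matrix, labels, clade_species=["s1"])
        assert sub.a <= 9 and sub.a + sub.b == 11

    def test_missing_labelled_gene_errors(self):
        matrix, _ = self._matrix_with_moved(3)
        labels = GeneClassLabels(frozenset({"nope"}), frozenset())
        with pytest.raises(ValueError, match="nope"):
            reacquisition_table(matrix, labels)


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 0, 0, 1)
    with pytest.raises(ValueError):
        ContingencyTable2x2(0, 0, 0, 0)
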