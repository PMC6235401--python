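"""Ancestral-state reconstruction and event classification.

Each gene is a three-state character on the tree:

* ``Y``      — the gene sits on the Y chromosome (males-only PCR signal, M),
* ``AX``     — the gene sits on an autosome or the X (both-sex signal, MF),
* ``absent`` — the gene was lost from the genome (systematic failure, F).

Reconstruction is generalized (Sankoff) parsimony over an arbitrary
transition-cost matrix, with three ready-made cost models:

* **Dollo** (the default for ancestrally Y-linked genes): Y-linkage is the
  ancestral condition and can never be regained, so ``AX -> Y`` and every
  transition out of ``absent`` cost infinity; losses (``Y -> AX``,
  ``Y -> absent``, ``AX -> absent``) cost 1.  Under this model the minimal
  solution counts the independent loss events directly.
* **Fitch**: all state changes cost 1 (symmetric parsimony, used for
  sensitivity analysis).
* **Sankoff**: user-supplied costs.

Among co-optimal ancestral assignments we use delayed transformation
(DELTRAN): states change as close to the tips as possible, with a fixed
canonical traversal order, so reconstructions are fully deterministic.

Changes are then aggregated into *independent events*: a branch on which all
(or, configurably, nearly all) genes still carried by the Y switch to ``AX``
at once is a whole-chromosome **incorporation**; physically adjacent genes
declared as a group and moving on the same branch merge into one
**transfer**; remaining ``Y -> AX`` changes are single-gene transfers,
``Y -> absent`` changes are genomic losses, and ``AX -> Y`` changes (only
possible outside Dollo mode) are gains.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .linkage_io import GeneClassLabels, LinkageMatrix
from .phylogeny import Phylogeny

STATES = ("Y", "AX", "absent")
_IDX = {s: i for i, s in enumerate(STATES)}

INF = math.inf


class UninformativeGeneError(ValueError):
    """All tips are NA for this gene: nothing to reconstruct."""


class InfeasibleReconstructionError(ValueError):
    """No ancestral assignment has finite cost under the given cost model.

    Typically raised in Dollo mode when the data require a forbidden gain
    under the fixed root state.  The constraint is reported, never silently
    relaxed.
    """


@dataclass(frozen=True)
class CostModel:
    """Transition costs for the three-state linkage character.

    ``costs[(s, t)]`` is the cost of an ``s -> t`` change along one branch;
    the diagonal must be zero and all costs non-negative (infinity marks a
    forbidden transition).  ``root_state`` constrains the state at the root
    ("Y", "AX", "absent" or "free").
    """

    costs: Mapping[tuple[str, str], float]
    root_state: str = "free"
    mode: str = "sankoff"

    def __post_init__(self):
        if self.root_state not in STATES + ("free",):
            raise ValueError(f"invalid root_state {self.root_state!r}")
        for s, t in itertools.product(STATES, repeat=2):
            c = self.costs.get((s, t), 0.0 if s == t else None)
            if c is None:
                raise ValueError(f"cost model missing transition ({s}, {t})")
            if s == t and c != 0.0:
                raise ValueError("cost(s -> s) must be 0")
            if c < 0 or math.isnan(c):
                raise ValueError(f"invalid cost {c!r} for ({s}, {t})")

    def cost(self, s: str, t: str) -> float:
        return 0.0 if s == t else float(self.costs[(s, t)])

    @property
    def matrix(self) -> np.ndarray:
        m = np.zeros((3, 3))
        for (s, t), c in self.costs.items():
            m[_IDX[s], _IDX[t]] = c
        return m

    @classmethod
    def fitch(cls, root_state: str = "free") -> "CostModel":
        costs = {
            (s, t): 1.0 for s, t in itertools.product(STATES, repeat=2) if s != t
        }
        return cls(costs=costs, root_state=root_state, mode="fitch")

    @classmethod
    def dollo(
        cls,
        root_state: str = "Y",
        loss_cost: float = 1.0,
        genomic_loss_cost: float = 1.0,
    ) -> "CostModel":
        """Y-linkage can only be lost: gains and resurrections are forbidden."""
        costs = {
            ("Y", "AX"): loss_cost,
            ("Y", "absent"): genomic_loss_cost,
            ("AX", "absent"): genomic_loss_cost,
            ("AX", "Y"): INF,
            ("absent", "Y"): INF,
            ("absent", "AX"): INF,
        }
        return cls(costs=costs, root_state=root_state, mode="dollo")

    @classmethod
    def sankoff(
        cls, costs: Mapping[tuple[str, str], float], root_state: str = "free"
    ) -> "CostModel":
        full = {
            (s, t): float(costs.get((s, t), 0.0 if s == t else 1.0))
            for s, t in itertools.product(STATES, repeat=2)
            if s != t
        }
        return cls(costs=full, root_state=root_state, mode="sankoff")


@dataclass
class Reconstruction:
    """One gene's optimal ancestral assignment on the tree."""

    gene: Optional[str]
    tree: Phylogeny
    node_state: dict[str, str]
    min_cost: float
    change_branches: list[tuple[str, str, str, str]]  # (parent_id, child_id, from, to)

    def state(self, node_id: str) -> str:
        return self.node_state[node_id]

    @property
    def n_changes(self) -> int:
        return len(self.change_branches)


def map_observations(
    matrix: LinkageMatrix,
    gene: str,
    f_min_species: int = 2,
    confirmed_absent: Iterable[str] = (),
) -> dict[str, Optional[str]]:
    """Translate a gene's PCR codes into character states.

    ``M -> Y``, ``MF -> AX``, ``NA -> None`` (free in the optimization).
    ``F`` maps to ``absent`` only when the failure looks systematic — at
    least ``f_min_species`` species fail for this gene, or the gene is in the
    ``confirmed_absent`` set — otherwise a lone failure is treated as an
    untested cell, since one failed PCR does not distinguish genomic loss
    from assay failure.
    """
    col = matrix.gene_column(gene)
    n_f = int((col == "F").sum())
    f_is_absent = n_f >= f_min_species or gene in set(confirmed_absent)
    out: dict[str, Optional[str]] = {}
    for sp, obs in col.items():
        if obs == "M":
            out[sp] = "Y"
        elif obs == "MF":
            out[sp] = "AX"
        elif obs == "F":
            out[sp] = "absent" if f_is_absent else None
        else:
            out[sp] = None
    return out


def _tip_cost_vector(state: Optional[str]) -> np.ndarray:
    v = np.full(3, INF)
    if state is None:
        v[:] = 0.0
    else:
        v[_IDX[state]] = 0.0
    return v


def sankoff_reconstruct(
    tree: Phylogeny,
    tip_states: Mapping[str, Optional[str]],
    cost: CostModel,
    gene: Optional[str] = None,
) -> Reconstruction:
    """Minimum-cost ancestral reconstruction of one gene.

    ``tip_states`` maps species name to "Y"/"AX"/"absent" or None (NA);
    tips absent from the mapping are treated as NA.  Ties among co-optimal
    assignments are broken by delayed transformation (prefer keeping the
    parent's state) and then by fixed state order, over the canonical
    traversal, so the result is deterministic.
    """
    known = {
        sp: st
        for sp, st in tip_states.items()
        if st is not None and sp in set(tree.tip_names)
    }
    if not known:
        raise UninformativeGeneError(
            f"gene {gene!r} uninformative: every tip is NA"
        )
    bad = {sp: st for sp, st in tip_states.items() if st is not None and st not in STATES}
    if bad:
        raise ValueError(f"invalid tip states: {bad}")

    cmat = cost.matrix
    # bottom-up: minimal cost of each subtree conditional on the node's state
    sub: dict[str, np.ndarray] = {}
    for node in tree.root_postorder():
        if node.is_leaf:
            sub[node.id] = _tip_cost_vector(tip_states.get(node.name))
        else:
            v = np.zeros(3)
            for child in node.children:
                child_v = sub[child.id]
                # min over child state t of cost(s -> t) + sub[child][t]
                v = v + np.min(cmat + child_v[None, :], axis=1)
            sub[node.id] = v

    root_v = sub[tree.root.id]
    if cost.root_state == "free":
        min_cost = float(np.min(root_v))
        root_idx = int(np.argmin(root_v))  # first minimum: state order Y, AX, absent
    else:
        root_idx = _IDX[cost.root_state]
        min_cost = float(root_v[root_idx])
    if not math.isfinite(min_cost):
        raise InfeasibleReconstructionError(
            f"gene {gene!r}: no finite-cost reconstruction under mode "
            f"{cost.mode!r} with root state {cost.root_state!r} "
            "(the data would require a forbidden transition)"
        )

    # top-down DELTRAN traceback
    node_state: dict[str, str] = {tree.root.id: STATES[root_idx]}
    changes: list[tuple[str, str, str, str]] = []
    for parent, child in tree.edges():
        p_idx = _IDX[node_state[parent.id]]
        child_v = cmat[p_idx] + sub[child.id]
        best = float(np.min(child_v))
        if math.isclose(child_v[p_idx], best, rel_tol=1e-12, abs_tol=1e-12):
            c_idx = p_idx  # delayed transformation: keep the parent's state
        else:
            c_idx = int(np.argmin(child_v))
        node_state[child.id] = STATES[c_idx]
        if c_idx != p_idx:
            changes.append((parent.id, child.id, STATES[p_idx], STATES[c_idx]))

    return Reconstruction(
        gene=gene,
        tree=tree,
        node_state=node_state,
        min_cost=min_cost,
        change_branches=changes,
    )


def brute_force_min_cost(
    tree: Phylogeny,
    tip_states: Mapping[str, Optional[str]],
    cost: CostModel,
) -> float:
    """Exhaustive minimum reconstruction cost (testing oracle).

    Enumerates every assignment of the three states to internal nodes.
    NA tips are free variables, but since cost(s -> s) = 0 an NA leaf can
    always copy its parent's state at zero cost, so such leaves (and their
    edges) are pruned rather than enumerated.  Refuses trees with more than
    14 tips.
    """
    if tree.n_tips > 14:
        raise ValueError("brute force limited to trees with <= 14 tips")
    nodes = list(tree.preorder())
    na_leaf = {
        n.id for n in nodes if n.is_leaf and tip_states.get(n.name) is None
    }
    if len(na_leaf) == tree.n_tips:
        raise UninformativeGeneError("every tip is NA")
    fixed_idx = {
        n.id: _IDX[tip_states[n.name]]
        for n in nodes
        if n.is_leaf and n.id not in na_leaf
    }
    free_ids = [n.id for n in nodes if not n.is_leaf]
    k = len(free_ids)
    if 3**k > 2_000_000:  # unreachable for binary trees of <= 14 tips
        raise ValueError("brute force state space too large")

    # all 3^k assignments as an array of state indices
    grids = np.meshgrid(*([np.arange(3)] * k), indexing="ij") if k else []
    assign = (
        np.stack([g.ravel() for g in grids], axis=1)
        if k
        else np.zeros((1, 0), dtype=int)
    )
    pos = {nid: j for j, nid in enumerate(free_ids)}

    def state_col(nid: str) -> np.ndarray:
        if nid in pos:
            return assign[:, pos[nid]]
        return np.full(assign.shape[0], fixed_idx[nid])

    cmat = cost.matrix
    total = np.zeros(assign.shape[0])
    for parent, child in tree.edges():
        if child.id in na_leaf:
            continue  # free leaf: copies the parent state at zero cost
        total += cmat[state_col(parent.id), state_col(child.id)]
    if cost.root_state != "free":
        root_col = state_col(tree.root.id)
        total = np.where(root_col == _IDX[cost.root_state], total, INF)
    return float(np.min(total))


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventRecord:
    """One independent evolutionary event inferred on a branch."""

    event_id: int
    branch: tuple[str, str]  # (parent node id, child node id)
    genes: frozenset[str]
    type: str  # transfer | genomic_loss | incorporation | gain

    def __post_init__(self):
        if not self.genes:
            raise ValueError("event with empty gene set")
        if self.type not in {"transfer", "genomic_loss", "incorporation", "gain"}:
            raise ValueError(f"unknown event type {self.type!r}")


def classify_events(
    reconstructions: Sequence[Reconstruction],
    groups: Optional[Iterable[Iterable[str]]] = None,
    min_genes: int = 3,
    inc_fraction: float = 1.0,
) -> list[EventRecord]:
    """Aggregate per-gene state changes into independent events.

    On each branch, ``Y -> AX`` changes collapse into a single incorporation
    event when the changed genes make up at least ``inc_fraction`` of the
    genes reconstructed as Y-linked in the parent node and number at least
    ``min_genes``; otherwise genes declared physically adjacent (``groups``)
    that move together on one branch merge into one transfer, and the rest
    are single-gene transfers.  ``Y -> absent`` changes are genomic losses
    and ``AX -> Y`` changes are gains.  Every state change belongs to
    exactly one event.
    """
    if not reconstructions:
        return []
    if not (0 < inc_fraction <= 1):
        raise ValueError("inc_fraction must be in (0, 1]")
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    tree = reconstructions[0].tree
    if any(r.tree is not tree for r in reconstructions):
        raise ValueError("all reconstructions must share one tree")
    group_of: dict[str, int] = {}
    for gi, group in enumerate(groups or ()):
        for gene in group:
            if gene in group_of:
                raise ValueError(f"gene {gene!r} in more than one adjacency group")
            group_of[gene] = gi

    by_branch: dict[tuple[str, str], list[tuple[str, str, str]]] = {}
    for rec in reconstructions:
        for parent_id, child_id, s_from, s_to in rec.change_branches:
            by_branch.setdefault((parent_id, child_id), []).append(
                (rec.gene or "?", s_from, s_to)
            )
    parent_y_count: dict[str, int] = {}
    for rec in reconstructions:
        for nid, st in rec.node_state.items():
            if st == "Y":
                parent_y_count[nid] = parent_y_count.get(nid, 0) + 1

    events: list[EventRecord] = []
    eid = 0
    for parent, child in tree.edges():  # canonical preorder: deterministic ids
        branch = (parent.id, child.id)
        changes = by_branch.get(branch)
        if not changes:
            continue
        to_ax = sorted(g for g, s, t in changes if s == "Y" and t == "AX")
        losses = sorted(g for g, s, t in changes if t == "absent")
        gains = sorted(g for g, s, t in changes if s != "Y" and t == "Y")
        n_parent_y = parent_y_count.get(parent.id, 0)
        if (
            to_ax
            and len(to_ax) >= min_genes
            and n_parent_y > 0
            and len(to_ax) >= inc_fraction * n_parent_y
        ):
            events.append(
                EventRecord(eid, branch, frozenset(to_ax), "incorporation")
            )
            eid += 1
        elif to_ax:
            grouped: dict[int, list[str]] = {}
            singles: list[str] = []
            for g in to_ax:
                if g in group_of:
                    grouped.setdefault(group_of[g], []).append(g)
                else:
                    singles.append(g)
            for gi in sorted(grouped):
                events.append(
                    EventRecord(eid, branch, frozenset(grouped[gi]), "transfer")
                )
                eid += 1
            for g in singles:
                events.append(EventRecord(eid, branch, frozenset([g]), "transfer"))
                eid += 1
        for g in losses:
            events.append(EventRecord(eid, branch, frozenset([g]), "genomic_loss"))
            eid += 1
        for g in gains:
            events.append(EventRecord(eid, branch, frozenset([g]), "gain"))
            eid += 1
    return events


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for the re-acquisition test.

    Rows are gene classes (ancestrally Y-linked vs. control), columns are
    "Y-linked in at least one clade species" vs. "never Y-linked".
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("table counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def reacquisition_table(
    matrix: LinkageMatrix,
    labels: GeneClassLabels,
    clade_species: Optional[Iterable[str]] = None,
) -> ContingencyTable2x2:
    """Build the 2x2 re-acquisition table for a focal clade.

    ``a`` counts ancestrally Y-linked genes with state M in at least one
    clade species, ``b`` those with none; ``c``/``d`` the same for control
    genes.  Restricting to ``clade_species`` (default: every species in the
    matrix) selects the focal clade.
    """
    if clade_species is not None:
        matrix = matrix.restrict_species(clade_species)
    stray = (labels.ancestral_Y | labels.control) - set(matrix.genes)
    if stray:
        raise ValueError(f"labelled genes missing from matrix: {sorted(stray)}")

    def moved(genes: frozenset[str]) -> tuple[int, int]:
        hits = sum(1 for g in sorted(genes) if (matrix.gene_column(g) == "M").any())
        return hits, len(genes) - hits

    a, b = moved(labels.ancestral_Y)
    c, d = moved(labels.control)
    return ContingencyTable2x2(a, b, c, d)
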