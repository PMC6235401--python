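import numpy as np
import pytest

from ylinkage import CostModel, load_fixture, map_observations
from ylinkage.phylogeny import Node, Phylogeny, parse_newick


@pytest.fixture(scope="session")
def fig2():
    return load_fixture("fig2_ory")


@pytest.fixture(scope="session")
def fig2_tip_states(fig2):
    return map_observations(fig2.matrix, "ORY")


@pytest.fixture
def dollo_y():
    return CostModel.dollo(root_state="Y")


def random_binary_tree(rng: np.random.Generator, n_tips: int, with_lengths: bool = False) -> Phylogeny:
    """Random topology by sequential pair joins; optional exponential lengths."""
    nodes = [Node(name=f"s{i}") for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    tree = Phylogeny(nodes[0])
    if with_lengths:
        for _, child in tree.edges():
            child.length = float(rng.exponential(5.0))
    return tree


def random_tip_states(rng: np.random.Generator, tree: Phylogeny, na_prob: float = 0.15,
                      states=("Y", "AX", "absent")):
    out = {}
    for name in tree.tip_names:
        if rng.random() < na_prob:
            out[name] = None
        else:
            out[name] = states[int(rng.integers(len(states)))]
    if all(v is None for v in out.values()):  # keep the gene informative
        out[tree.tip_names[0]] = states[0]
    return out


def random_cost_model(rng: np.random.Generator) -> CostModel:
    kind = int(rng.integers(3))
    if kind == 0:
        return CostModel.fitch(root_state=("free", "Y", "AX")[int(rng.integers(3))])
    if kind == 1:
        return CostModel.dollo(root_state="Y")
    costs = {}
    for s in ("Y", "AX", "absent"):
        for t in ("Y", "AX", "absent"):
            if s != t:
                # half-integer costs keep float sums exact; occasional infinities
                costs[(s, t)] = (
                    float("inf") if rng.random() < 0.1 else float(rng.integers(0, 9)) / 2.0
                )
    return CostModel.sankoff(costs, root_state="free")
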