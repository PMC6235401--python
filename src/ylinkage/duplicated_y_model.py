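"""Forward simulator of Y-linked gene-content evolution on trees.

The model tracks, for every gene in every lineage, which copies exist: a
Y-linked copy, an autosomal/X ("AX") copy, both, or neither.  Five kinds of
events occur as independent Poisson processes along branches (rates per
Myr):

* **transfer** (per Y-only gene): the gene moves off the Y; it becomes
  AX-only.
* **genomic loss** (per Y-only gene): the gene disappears entirely.
* **gain** (per AX-only gene, default rate 0): the gene moves onto the Y.
* **incorporation** (per lineage): the whole Y chromosome is incorporated
  into an autosome or the X.  Every currently Y-only gene becomes
  *redundant* — it now has both a Y-linked and an AX copy — because a free
  copy of the Y survives alongside the incorporated one.  The process is
  active only while at least one gene is Y-only (otherwise there is no
  gene-bearing free Y left to incorporate).
* **resolution** (per redundant gene): one of the two redundant copies is
  lost at random; the Y copy survives with probability ``pi_keep_Y``.

The resolution step is what makes formerly Y-linked genes appear to
"re-acquire" Y-linkage in some descendant lineages while sister lineages
lose the Y copy — the pattern the duplicated-Y model was built to explain.

The PCR observation layer maps the true copy state to the assay codes: a
redundant gene amplifies in both sexes (MF) exactly like an AX-only gene —
the surviving Y copy is invisible to the assay until the AX copy is lost —
while Y-only genes give M and absent genes give F.  Independent per-cell
assay failure masks cells to NA.

Simulation is exact (Gillespie): exponential waiting times along each
branch, pre-order branch traversal, genes scanned in input order, so one
seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .event_inference import (
    CostModel,
    classify_events,
    map_observations,
    sankoff_reconstruct,
)
from .linkage_io import LinkageMatrix
from .phylogeny import Node, Phylogeny
from .rate_stats import exposure, poisson_rate_ci


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run.  All rates are per Myr.

    ``forced_incorporations`` pins incorporation events to chosen branches
    for scenario studies: each entry is ``(tips, rel_time)`` where ``tips``
    is a tuple of tip names whose MRCA's stem branch carries the event, and
    ``rel_time`` in [0, 1] places it along that branch.
    """

    genes: tuple[str, ...]
    seed: int
    initial_location: Mapping[str, str] = field(default_factory=dict)
    lambda_transfer: float = 0.0
    lambda_genomic_loss: float = 0.0
    lambda_gain: float = 0.0
    mu_incorporation: float = 0.0
    rho_resolution: float = 0.0
    pi_keep_Y: float = 0.5
    pcr_fail_prob: float = 0.0
    n_tips: int = 0
    birth_rate: float = 0.0
    forced_incorporations: tuple[tuple[tuple[str, ...], float], ...] = ()

    def __post_init__(self):
        if not self.genes:
            raise ValueError("config needs at least one gene")
        if self.seed is None or int(self.seed) != self.seed:
            raise ValueError("an integer seed is mandatory")
        for name, rate in (
            ("lambda_transfer", self.lambda_transfer),
            ("lambda_genomic_loss", self.lambda_genomic_loss),
            ("lambda_gain", self.lambda_gain),
            ("mu_incorporation", self.mu_incorporation),
            ("rho_resolution", self.rho_resolution),
        ):
            if rate < 0 or not np.isfinite(rate):
                raise ValueError(f"{name} must be finite and >= 0")
        if not (0.0 <= self.pi_keep_Y <= 1.0):
            raise ValueError("pi_keep_Y must be in [0, 1]")
        if not (0.0 <= self.pcr_fail_prob < 1.0):
            raise ValueError("pcr_fail_prob must be in [0, 1)")
        for gene, loc in self.initial_location.items():
            if loc not in ("Y", "AX"):
                raise ValueError(f"initial location of {gene!r} must be Y or AX")
        for tips, rel in self.forced_incorporations:
            if not (0.0 <= rel <= 1.0):
                raise ValueError("forced incorporation rel_time must be in [0, 1]")

    def start_state(self, gene: str) -> str:
        return self.initial_location.get(gene, "Y")


@dataclass(frozen=True)
class SimEvent:
    """One true event in the simulation's ground-truth log."""

    branch: tuple[str, str]  # (parent id, child id)
    time: float  # Myr from the start of the branch
    genes: tuple[str, ...]
    type: str  # transfer | genomic_loss | gain | incorporation | resolution


@dataclass
class EventLog:
    events: list[SimEvent] = field(default_factory=list)

    def of_type(self, kind: str) -> list[SimEvent]:
        return [e for e in self.events if e.type == kind]

    def branches_of_type(self, kind: str) -> set[tuple[str, str]]:
        return {e.branch for e in self.events if e.type == kind}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parent": e.branch[0],
                "child": e.branch[1],
                "time_Myr": e.time,
                "genes": ",".join(e.genes),
                "type": e.type,
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows, columns=["parent", "child", "time_Myr", "genes", "type"]
        )


@dataclass
class GenotypeMatrix:
    """True copy flags per species x gene, before the PCR observation layer."""

    has_y: pd.DataFrame
    has_ax: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.has_y.index)

    @property
    def genes(self) -> list[str]:
        return list(self.has_y.columns)


def simulate_tree(n_tips: int, birth_rate: float, seed) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` tips, branch lengths in Myr.

    Lineages split at rate ``birth_rate``; after the n-th lineage appears
    the process runs one further exponential epoch and all tips are sampled
    at that time.  Identical ``seed`` gives an identical tree.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth_rate > 0:
        raise ValueError("birth_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = Node()
    birth_time: dict[int, float] = {}
    active: list[Node] = []
    for _ in range(2):
        child = root.add_child(Node())
        birth_time[id(child)] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        parent.length = t - birth_time[id(parent)]
        for _ in range(2):
            child = parent.add_child(Node())
            birth_time[id(child)] = t
            active.append(child)
    t_final = t + rng.exponential(1.0 / (birth_rate * n_tips))
    width = len(str(n_tips))
    for i, tip in enumerate(active, start=1):
        tip.length = t_final - birth_time[id(tip)]
        tip.name = f"t{i:0{width}d}"
    return Phylogeny(root)


# per-gene copy state encoding
_NONE, _Y_ONLY, _AX_ONLY, _BOTH = 0, 1, 2, 3


def simulate_gene_content(
    tree: Phylogeny, config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[GenotypeMatrix, EventLog]:
    """Run the continuous-time model down a dated tree.

    Returns the true genotype at every tip and the ground-truth event log.
    """
    if not tree.has_branch_lengths:
        raise ValueError("simulation requires branch lengths (Myr)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = list(config.genes)
    g_index = {g: i for i, g in enumerate(genes)}

    forced: dict[str, list[float]] = {}
    for tips, rel in config.forced_incorporations:
        node = tree.mrca(tips) if len(tips) > 1 else tree.tip(tips[0])
        if node is tree.root:
            raise ValueError("cannot force an incorporation on the root (no stem)")
        forced.setdefault(node.id, []).append(rel * node.length)
    for times in forced.values():
        times.sort()

    root_state = np.array(
        [_Y_ONLY if config.start_state(g) == "Y" else _AX_ONLY for g in genes],
        dtype=np.int8,
    )
    log = EventLog()
    tip_state: dict[str, np.ndarray] = {}
    node_state: dict[str, np.ndarray] = {tree.root.id: root_state}

    for parent, child in tree.edges():  # canonical pre-order
        state = node_state[parent.id].copy()
        branch = (parent.id, child.id)
        _evolve_branch(
            state, branch, child.length, forced.get(child.id, ()), config, rng, log, genes
        )
        node_state[child.id] = state
        if child.is_leaf:
            tip_state[child.name] = state

    species = tree.tip_names
    has_y = pd.DataFrame(
        [[tip_state[sp][g_index[g]] in (_Y_ONLY, _BOTH) for g in genes] for sp in species],
        index=species,
        columns=genes,
        dtype=bool,
    )
    has_ax = pd.DataFrame(
        [[tip_state[sp][g_index[g]] in (_AX_ONLY, _BOTH) for g in genes] for sp in species],
        index=species,
        columns=genes,
        dtype=bool,
    )
    return GenotypeMatrix(has_y=has_y, has_ax=has_ax), log


def _apply_incorporation(
    state: np.ndarray, branch, t: float, log: EventLog, genes: Sequence[str]
) -> None:
    affected = tuple(g for g, s in zip(genes, state) if s == _Y_ONLY)
    state[state == _Y_ONLY] = _BOTH
    log.events.append(SimEvent(branch=branch, time=t, genes=affected, type="incorporation"))


def _evolve_branch(
    state: np.ndarray,
    branch: tuple[str, str],
    length: float,
    forced_times: Sequence[float],
    config: SimulationConfig,
    rng: np.random.Generator,
    log: EventLog,
    genes: Sequence[str],
) -> None:
    """Gillespie simulation of one branch, mutating ``state`` in place."""
    t = 0.0
    pending = list(forced_times)
    while True:
        # per-gene rates in input order, incorporation last
        rates = np.zeros(len(state) + 1)
        for i, s in enumerate(state):
            if s == _Y_ONLY:
                rates[i] = config.lambda_transfer + config.lambda_genomic_loss
            elif s == _AX_ONLY:
                rates[i] = config.lambda_gain
            elif s == _BOTH:
                rates[i] = config.rho_resolution
        if (state == _Y_ONLY).any():
            rates[-1] = config.mu_incorporation
        total = float(rates.sum())
        horizon = pending[0] if pending else length
        if total <= 0.0:
            t = horizon
        else:
            t = t + rng.exponential(1.0 / total)
        if t >= horizon:
            if pending and horizon == pending[0]:
                _apply_incorporation(state, branch, horizon, log, genes)
                t = pending.pop(0)
                continue
            return  # beyond branch end: discard
        # choose the event deterministically from one uniform draw
        u = rng.random() * total
        cum = 0.0
        chosen = None
        for i, r in enumerate(rates):
            cum += r
            if u < cum:
                chosen = i
                break
        if chosen is None:  # numerical edge: fall back to the last active slot
            chosen = int(np.nonzero(rates)[0][-1])
        if chosen == len(state):
            _apply_incorporation(state, branch, t, log, genes)
            continue
        gene = genes[chosen]
        s = state[chosen]
        if s == _Y_ONLY:
            p_transfer = config.lambda_transfer / (
                config.lambda_transfer + config.lambda_genomic_loss
            )
            if rng.random() < p_transfer:
                state[chosen] = _AX_ONLY
                log.events.append(SimEvent(branch, t, (gene,), "transfer"))
            else:
                state[chosen] = _NONE
                log.events.append(SimEvent(branch, t, (gene,), "genomic_loss"))
        elif s == _AX_ONLY:
            state[chosen] = _Y_ONLY
            log.events.append(SimEvent(branch, t, (gene,), "gain"))
        elif s == _BOTH:
            keep_y = rng.random() < config.pi_keep_Y
            state[chosen] = _Y_ONLY if keep_y else _AX_ONLY
            log.events.append(SimEvent(branch, t, (gene,), "resolution"))


def observe_pcr(
    truth: GenotypeMatrix, pcr_fail_prob: float = 0.0, seed=None
) -> LinkageMatrix:
    """Apply the PCR observation model to a true genotype matrix.

    M when only the Y copy exists; MF whenever an AX copy exists (a
    redundant Y copy is invisible to the assay); F when no copy exists.
    Each cell is independently masked to NA with ``pcr_fail_prob``.
    """
    if not (0.0 <= pcr_fail_prob < 1.0):
        raise ValueError("pcr_fail_prob must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = {}
    for sp in truth.species:
        row = {}
        for g in truth.genes:
            y, ax = bool(truth.has_y.loc[sp, g]), bool(truth.has_ax.loc[sp, g])
            if ax:
                row[g] = "MF"
            elif y:
                row[g] = "M"
            else:
                row[g] = "F"
            if pcr_fail_prob > 0.0 and rng.random() < pcr_fail_prob:
                row[g] = "NA"
        states[sp] = row
    return LinkageMatrix.from_dict(states)


# ---------------------------------------------------------------------------
# Parameter-recovery harness
# ---------------------------------------------------------------------------


@dataclass
class RecoverySummary:
    """Aggregate results of a simulate -> infer -> estimate experiment.

    ``exact_event_match_fraction`` counts replicates whose inferred transfer
    (branch, gene) pairs equal the truth log exactly.  A replicate is
    *homoplasy-free* when, for every gene, no two true loss branches are
    mergeable by parsimony (no ancestral node subtends only lost-from-Y
    tips without itself being below a loss); among those replicates the
    match is expected to be exact, and
    ``exact_match_homoplasy_free`` reports that conditional fraction.
    """

    n_reps: int
    true_lambda_transfer: float
    ci_coverage: float
    mean_signed_error: float
    exact_event_match_fraction: float
    incorporation_sensitivity: float
    n_homoplasy_free: int = 0
    exact_match_homoplasy_free: float = float("nan")
    rates: list[float] = field(default_factory=list)


def _maximal_ax_stems(tree: Phylogeny, ax_tips: set[str]) -> set[tuple[str, str]]:
    """Stem branches of maximal subtrees whose tips are all off the Y.

    This is where Dollo parsimony with an ancestrally Y-linked root places
    the loss events; the truth log matches it exactly iff the true events
    are not mergeable (homoplasy-free).
    """
    all_ax: dict[str, bool] = {}
    for node in tree.root_postorder():
        if node.is_leaf:
            all_ax[node.id] = node.name in ax_tips
        else:
            all_ax[node.id] = all(all_ax[c.id] for c in node.children)
    if all_ax[tree.root.id]:
        return {(tree.root.id, c.id) for c in tree.root.children}
    return {
        (p.id, c.id)
        for p, c in tree.edges()
        if all_ax[c.id] and not all_ax[p.id]
    }


def recovery_experiment(
    config: SimulationConfig,
    n_reps: int,
    min_genes: int = 3,
    inc_fraction: float = 1.0,
    conf: float = 0.95,
) -> RecoverySummary:
    """Simulate, observe, re-infer, and score parameter recovery.

    Each replicate draws a fresh Yule tree (``config.n_tips`` /
    ``config.birth_rate``), simulates gene content, applies the observation
    layer, reconstructs every gene under Dollo parsimony with ancestral
    Y-linkage, classifies events and estimates the per-gene transfer rate
    with its Garwood CI.  Reported: the fraction of replicates whose CI
    covers the true rate, the mean signed rate error, the fraction of
    replicates in which the inferred transfer branches match the truth log
    exactly, and (when incorporations were simulated or forced) the fraction
    of true incorporation branches recovered as incorporation events.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if config.n_tips < 2 or not config.birth_rate > 0:
        raise ValueError("recovery_experiment needs n_tips and birth_rate in config")
    cover = 0
    errors = []
    exact = 0
    n_hfree = 0
    exact_hfree = 0
    inc_true_total = 0
    inc_found_total = 0
    rates = []
    cost = CostModel.dollo(root_state="Y")
    for rep in range(n_reps):
        rng = np.random.default_rng((int(config.seed) + rep) % (2**31))
        tree = simulate_tree(config.n_tips, config.birth_rate, rng)
        truth, log = simulate_gene_content(tree, config, rng=rng)
        obs = observe_pcr(truth, config.pcr_fail_prob, seed=rng)
        recons = []
        for gene in config.genes:
            tip_states = map_observations(obs, gene)
            recons.append(sankoff_reconstruct(tree, tip_states, cost, gene=gene))
        events = classify_events(recons, min_genes=min_genes, inc_fraction=inc_fraction)
        inferred_transfers = {
            (e.branch, g) for e in events if e.type == "transfer" for g in e.genes
        }
        true_transfers = {
            (e.branch, g) for e in log.of_type("transfer") for g in e.genes
        }
        matched = inferred_transfers == true_transfers
        if matched:
            exact += 1
        hfree = True
        for gene in config.genes:
            true_branches = {
                e.branch for e in log.of_type("transfer") if gene in e.genes
            }
            ax_tips = set(truth.has_ax.index[truth.has_ax[gene]])
            if ax_tips and _maximal_ax_stems(tree, ax_tips) != true_branches:
                hfree = False
                break
        if hfree:
            n_hfree += 1
            if matched:
                exact_hfree += 1
        n_events = len([e for e in events if e.type == "transfer"])
        total_exposure, _ = exposure(tree, recons)
        est = poisson_rate_ci(n_events, total_exposure, conf=conf)
        rates.append(est.rate)
        if est.ci_low <= config.lambda_transfer <= est.ci_high:
            cover += 1
        errors.append(est.rate - config.lambda_transfer)
        true_inc = log.branches_of_type("incorporation")
        found_inc = {e.branch for e in events if e.type == "incorporation"}
        inc_true_total += len(true_inc)
        inc_found_total += len(true_inc & found_inc)
    return RecoverySummary(
        n_reps=n_reps,
        true_lambda_transfer=config.lambda_transfer,
        ci_coverage=cover / n_reps,
        mean_signed_error=float(np.mean(errors)),
        exact_event_match_fraction=exact / n_reps,
        incorporation_sensitivity=(
            inc_found_total / inc_true_total if inc_true_total else float("nan")
        ),
        n_homoplasy_free=n_hfree,
        exact_match_homoplasy_free=(
            exact_hfree / n_hfree if n_hfree else float("nan")
        ),
        rates=rates,
    )
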