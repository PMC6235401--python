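"""End-to-end orchestration: read -> reconstruct -> classify -> rates -> tests.

``run_infer`` is the library entry point behind the ``ylinkage infer``
command.  Given a dated tree, a linkage matrix and optional gene-class
labels / adjacency groups it produces a deterministic
:class:`~ylinkage.report.AnalysisReport`.
"""

from __future__ import annotations

from importlib.metadata import PackageNotFoundError, version as pkg_version
from typing import Iterable, Optional

from . import report as rpt
from .event_inference import (
    CostModel,
    EventRecord,
    Reconstruction,
    UninformativeGeneError,
    classify_events,
    map_observations,
    reacquisition_table,
    sankoff_reconstruct,
)
from .linkage_io import GeneClassLabels, LinkageMatrix, validate_dataset
from .phylogeny import Phylogeny
from .rate_stats import (
    exposure,
    fisher_exact_2x2,
    incorporation_rate,
    poisson_rate_ci,
)


class PipelineError(ValueError):
    """Raised when inputs fail validation; carries the report's error list."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


def _version() -> str:
    try:
        return pkg_version("ylinkage")
    except PackageNotFoundError:  # pragma: no cover - source checkout
        return "0+unknown"


def _event_entries(events: Iterable[EventRecord]) -> list[rpt.EventEntry]:
    return [
        rpt.EventEntry(
            event_id=e.event_id,
            parent=e.branch[0],
            child=e.branch[1],
            type=e.type,
            genes=sorted(e.genes),
        )
        for e in events
    ]


def run_infer(
    tree: Phylogeny,
    matrix: LinkageMatrix,
    labels: Optional[GeneClassLabels] = None,
    groups: Optional[list[list[str]]] = None,
    mode: str = "dollo",
    min_genes: int = 3,
    inc_fraction: float = 1.0,
    nearly_all_fraction: Optional[float] = 0.9,
    f_min_species: int = 2,
    conf: float = 0.95,
    unit_branch_lengths: bool = False,
    timestamp: Optional[str] = None,
) -> rpt.AnalysisReport:
    """Run the full analysis and assemble a report.

    Ancestrally Y-linked genes (all genes, when no labels are given) are
    reconstructed under Dollo parsimony with the root fixed to Y-linked;
    control genes under symmetric (Fitch) parsimony with a free root.
    ``mode="fitch"`` switches every gene to symmetric parsimony for
    sensitivity analysis.  Rates are only reported when the tree carries
    branch lengths in Myr; with ``unit_branch_lengths`` every branch is set
    to 1 and rate estimation is disabled (event counts remain valid).
    """
    if mode not in {"dollo", "fitch"}:
        raise ValueError("mode must be 'dollo' or 'fitch'")
    validation = validate_dataset(tree, matrix, labels)
    if validation.errors:
        raise PipelineError(validation.errors)
    warnings = list(validation.warnings)

    rates_enabled = tree.has_branch_lengths
    if unit_branch_lengths and not rates_enabled:
        for _, child in tree.edges():
            child.length = 1.0
        warnings.append("unit branch lengths substituted: rate estimation disabled")

    control = labels.control if labels else frozenset()
    recons: list[Reconstruction] = []
    for gene in matrix.genes:
        tip_states = map_observations(matrix, gene, f_min_species=f_min_species)
        if mode == "fitch":
            cost = CostModel.fitch(root_state="free")
        elif gene in control:
            cost = CostModel.fitch(root_state="free")
        else:
            cost = CostModel.dollo(root_state="Y")
        try:
            recons.append(sankoff_reconstruct(tree, tip_states, cost, gene=gene))
        except UninformativeGeneError:
            warnings.append(f"gene {gene!r} skipped: no informative observation")

    events = classify_events(
        recons, groups=groups, min_genes=min_genes, inc_fraction=inc_fraction
    )
    nearly = None
    if nearly_all_fraction is not None and nearly_all_fraction != inc_fraction:
        nearly = classify_events(
            recons, groups=groups, min_genes=min_genes, inc_fraction=nearly_all_fraction
        )

    loss_rate_entry = inc_rate_entry = None
    if rates_enabled:
        total_exposure, _ = exposure(tree, recons)
        n_loss = sum(1 for e in events if e.type in {"transfer", "genomic_loss"})
        est = poisson_rate_ci(n_loss, total_exposure, conf=conf)
        loss_rate_entry = rpt.RateEntry(**est.as_dict())
        n_inc = sum(1 for e in events if e.type == "incorporation")
        inc_est = incorporation_rate(n_inc, tree.total_length, conf=conf)
        inc_rate_entry = rpt.RateEntry(**inc_est.as_dict())

    reacq_entry = None
    if labels is not None and labels.ancestral_Y and labels.control:
        table = reacquisition_table(matrix, labels)
        test = fisher_exact_2x2(table)
        reacq_entry = rpt.TestEntry(
            p=test.p_value,
            method=test.method,
            statistic=test.statistic,
            table=list(table.as_tuple()),
        )

    config = {
        "mode": mode,
        "min_genes": min_genes,
        "inc_fraction": inc_fraction,
        "nearly_all_fraction": nearly_all_fraction,
        "f_min_species": f_min_species,
        "conf": conf,
        "unit_branch_lengths": unit_branch_lengths,
        "groups": groups,
        "labels": {
            "ancestral_Y": sorted(labels.ancestral_Y),
            "control": sorted(labels.control),
        }
        if labels
        else None,
    }
    return rpt.AnalysisReport(
        dataset=rpt.DatasetSummary(
            n_species=len(matrix.species),
            n_genes=len(matrix.genes),
            na_fraction=matrix.na_fraction,
            has_branch_lengths=rates_enabled,
            warnings=warnings,
        ),
        mode=mode,
        reconstructions=[
            rpt.ReconstructionEntry(
                gene=r.gene or "?",
                min_cost=r.min_cost,
                node_states=r.node_state,
                changes=[list(c) for c in r.change_branches],
            )
            for r in recons
        ],
        events=_event_entries(events),
        events_nearly_all=_event_entries(nearly) if nearly is not None else None,
        n_independent_events=len(events),
        loss_rate=loss_rate_entry,
        incorporation_rate=inc_rate_entry,
        reacquisition=reacq_entry,
        provenance=rpt.Provenance(
            version=_version(), config=config, timestamp=timestamp
        ),
    )


def events_to_tsv(events: Iterable[rpt.EventEntry]) -> str:
    lines = ["event_id\tparent\tchild\ttype\tgenes"]
    for e in events:
        lines.append(f"{e.event_id}\t{e.parent}\t{e.child}\t{e.type}\t{','.join(e.genes)}")
    return "\n".join(lines) + "\n"


def reconstructions_to_tsv(entries: Iterable[rpt.ReconstructionEntry]) -> str:
    lines = ["gene\tnode\tstate"]
    for r in entries:
        for node_id, state in r.node_states.items():
            lines.append(f"{r.gene}\t{node_id}\t{state}")
    return "\n".join(lines) + "\n"
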