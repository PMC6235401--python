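"""Machine-readable analysis report.

The report is a versioned pydantic model; the JSON Schema shipped at
``docs/report_schema.json`` is generated from it and tests keep the two in
sync.  Every number in a report is produced by an operation of the library
(reconstruction, classification, rate estimation, exact tests) — the report
layer only assembles them.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field

SCHEMA_VERSION = "1.0"


class DatasetSummary(BaseModel):
    n_species: int
    n_genes: int
    na_fraction: float
    has_branch_lengths: bool
    warnings: list[str] = Field(default_factory=list)


class ReconstructionEntry(BaseModel):
    gene: str
    min_cost: float
    node_states: dict[str, str]
    changes: list[list[str]]  # [parent, child, from, to]


class EventEntry(BaseModel):
    event_id: int
    parent: str
    child: str
    type: str
    genes: list[str]


class RateEntry(BaseModel):
    n: int
    exposure: float
    rate: float
    ci: list[float]
    conf: float
    method: str


class TestEntry(BaseModel):
    p: float
    method: str
    statistic: Optional[float] = None
    table: Optional[list[int]] = None


class Provenance(BaseModel):
    package: str = "ylinkage"
    version: str
    schema_version: str = SCHEMA_VERSION
    config: dict
    timestamp: Optional[str] = None


class AnalysisReport(BaseModel):
    """Full output of one pipeline run."""

    dataset: DatasetSummary
    mode: str
    reconstructions: list[ReconstructionEntry]
    events: list[EventEntry]
    events_nearly_all: Optional[list[EventEntry]] = None
    n_independent_events: int
    loss_rate: Optional[RateEntry] = None
    incorporation_rate: Optional[RateEntry] = None
    reacquisition: Optional[TestEntry] = None
    poisson_ratio: Optional[TestEntry] = None
    provenance: Provenance

    def to_json(self, **kwargs) -> str:
        return self.model_dump_json(indent=2, **kwargs)
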