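"""Linkage matrices, gene class labels, dataset validation and packaged fixtures.

The central observation object is the :class:`LinkageMatrix`: a species x gene
table of PCR outcome codes,

* ``M``  — amplification in males only (the gene is Y-linked),
* ``MF`` — amplification in both sexes (the gene is autosomal or X-linked),
* ``F``  — systematic failure in both sexes (candidate genomic loss),
* ``NA`` — species x gene combination not tested (or assay failure).

Matrices are plain delimited text (tab-separated by default, comma accepted):
a header row of gene names, first column species names.  Common synonyms for
the four codes are normalized on read.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .phylogeny import Phylogeny, parse_newick

CANONICAL_STATES = ("M", "MF", "F", "NA")

#: Synonyms accepted on input (matched case-insensitively after trimming).
STATE_SYNONYMS = {
    "m": "M",
    "male": "M",
    "mf": "MF",
    "m+f": "MF",
    "male+female": "MF",
    "f": "F",
    "fail": "F",
    "failed": "F",
    "na": "NA",
    "n/a": "NA",
    "-": "NA",
    "": "NA",
}


class LinkageMatrixError(ValueError):
    """Raised for malformed linkage tables (unknown tokens, duplicates, ...)."""


class LinkageMatrix:
    """Species x gene matrix of canonical linkage states.

    Thin wrapper over a :class:`pandas.DataFrame` (index = species,
    columns = genes, values in ``{"M","MF","F","NA"}``).
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.empty:
            raise LinkageMatrixError("empty linkage matrix")
        if frame.index.duplicated().any():
            dup = sorted(frame.index[frame.index.duplicated()].unique())
            raise LinkageMatrixError(f"duplicated species rows: {dup}")
        if frame.columns.duplicated().any():
            dup = sorted(frame.columns[frame.columns.duplicated()].unique())
            raise LinkageMatrixError(f"duplicated gene columns: {dup}")
        norm = frame.copy()
        for sp in norm.index:
            for gene in norm.columns:
                norm.loc[sp, gene] = _normalize_state(norm.loc[sp, gene], sp, gene)
        self._frame = norm.astype(str)

    # -- accessors -----------------------------------------------------------

    @property
    def species(self) -> list[str]:
        return list(self._frame.index)

    @property
    def genes(self) -> list[str]:
        return list(self._frame.columns)

    def state(self, species: str, gene: str) -> str:
        return self._frame.loc[species, gene]

    def gene_column(self, gene: str) -> pd.Series:
        return self._frame[gene]

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def restrict_species(self, species: Iterable[str]) -> "LinkageMatrix":
        keep = [s for s in self.species if s in set(species)]
        if not keep:
            raise LinkageMatrixError("restriction leaves no species")
        return LinkageMatrix(self._frame.loc[keep])

    def count(self, state: str) -> int:
        return int((self._frame == state).sum().sum())

    @property
    def na_fraction(self) -> float:
        return self.count("NA") / (len(self.species) * len(self.genes))

    def __eq__(self, other) -> bool:
        return isinstance(other, LinkageMatrix) and self._frame.equals(other._frame)

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_dict(cls, states: Mapping[str, Mapping[str, str]]) -> "LinkageMatrix":
        """Build from ``{species: {gene: state}}`` (missing cells become NA)."""
        frame = pd.DataFrame.from_dict(states, orient="index")
        frame = frame.where(frame.notna(), "NA")
        return cls(frame)

    @classmethod
    def read(cls, source: Union[str, Path, io.TextIOBase], sep: str = "\t") -> "LinkageMatrix":
        """Read a delimited table: header of gene names, first column species."""
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
        else:
            text = source.read()
        if not text.strip():
            raise LinkageMatrixError("empty linkage table")
        try:
            frame = pd.read_csv(
                io.StringIO(text), sep=sep, index_col=0, dtype=str, keep_default_na=False
            )
        except Exception as exc:
            raise LinkageMatrixError(f"cannot parse linkage table: {exc}") from exc
        if frame.shape[1] == 0:
            raise LinkageMatrixError("linkage table has no gene columns")
        frame.index = frame.index.astype(str).str.strip()
        frame.columns = frame.columns.astype(str).str.strip()
        return cls(frame)

    def write(self, target: Union[str, Path, io.TextIOBase], sep: str = "\t") -> None:
        if isinstance(target, (str, Path)):
            self._frame.to_csv(target, sep=sep, index_label="species")
        else:
            self._frame.to_csv(target, sep=sep, index_label="species")


def read_linkage_matrix(source, sep: str = "\t") -> LinkageMatrix:
    """Module-level alias for :meth:`LinkageMatrix.read`."""
    return LinkageMatrix.read(source, sep=sep)


def _normalize_state(raw, species: str, gene: str) -> str:
    token = str(raw).strip()
    if token in CANONICAL_STATES:
        return token
    key = token.lower()
    if key in STATE_SYNONYMS:
        return STATE_SYNONYMS[key]
    raise LinkageMatrixError(
        f"unknown state token {token!r} at species {species!r}, gene {gene!r}"
    )


@dataclass(frozen=True)
class GeneClassLabels:
    """Partition of genes into ancestrally Y-linked vs. control (never-Y) sets."""

    ancestral_Y: frozenset[str]
    control: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "ancestral_Y", frozenset(self.ancestral_Y))
        object.__setattr__(self, "control", frozenset(self.control))
        overlap = self.ancestral_Y & self.control
        if overlap:
            raise ValueError(f"gene class labels overlap: {sorted(overlap)}")
        if not self.ancestral_Y and not self.control:
            raise ValueError("gene class labels are empty")

    @classmethod
    def read(cls, source: Union[str, Path, io.TextIOBase], sep: str = "\t") -> "GeneClassLabels":
        """Read a two-column table ``gene <sep> class`` with class in
        {ancestral_Y, control}."""
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
        else:
            text = source.read()
        anc, ctl = set(), set()
        for i, line in enumerate(text.splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) != 2:
                raise ValueError(f"labels line {i + 1}: expected 'gene{sep}class'")
            gene, klass = parts
            if i == 0 and klass.lower() in {"class", "label"}:
                continue
            if klass == "ancestral_Y":
                anc.add(gene)
            elif klass == "control":
                ctl.add(gene)
            else:
                raise ValueError(f"labels line {i + 1}: unknown class {klass!r}")
        return cls(frozenset(anc), frozenset(ctl))


@dataclass
class ValidationReport:
    """Problems found when pairing a tree with a linkage matrix."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_dataset(
    tree: Phylogeny,
    matrix: LinkageMatrix,
    labels: Optional[GeneClassLabels] = None,
) -> ValidationReport:
    """Cross-check a tree/matrix (and optionally labels) pairing.

    Species in the matrix that are not tips of the tree are errors (the
    parsimony step would silently drop data otherwise); all-NA gene columns
    and missing branch lengths are warnings.
    """
    report = ValidationReport()
    tips = set(tree.tip_names)
    for sp in matrix.species:
        if sp not in tips:
            report.errors.append(f"matrix species {sp!r} is not a tip of the tree")
    untested = tips - set(matrix.species)
    if untested:
        report.warnings.append(
            f"{len(untested)} tree tips absent from the matrix (treated as NA): "
            f"{sorted(untested)[:5]}..."
            if len(untested) > 5
            else f"tree tips absent from the matrix (treated as NA): {sorted(untested)}"
        )
    for gene in matrix.genes:
        if (matrix.gene_column(gene) == "NA").all():
            report.warnings.append(f"gene {gene!r} has no non-NA observation")
    if not tree.has_branch_lengths:
        report.warnings.append(
            "tree lacks branch lengths: exposure/rate estimation unavailable"
        )
    if labels is not None:
        stray = (labels.ancestral_Y | labels.control) - set(matrix.genes)
        if stray:
            report.errors.append(f"labelled genes missing from matrix: {sorted(stray)}")
    return report


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fixture:
    """A packaged worked-example dataset.

    Depending on the fixture, some fields are None (e.g. the 2x2 count table
    fixture carries no tree).
    """

    name: str
    tree: Optional[Phylogeny] = None
    matrix: Optional[LinkageMatrix] = None
    labels: Optional[GeneClassLabels] = None
    table: Optional[tuple[int, int, int, int]] = None


class FixtureIntegrityError(RuntimeError):
    """Raised when a packaged fixture file does not match its checksum."""


FIXTURE_NAMES = ("fig2_ory", "montium_partial", "table1_counts", "fig1_pairs")

_FIXTURE_FILES = {
    "fig2_ory": {"tree": "fig2_ory.nwk", "matrix": "fig2_ory.tsv"},
    "montium_partial": {
        "tree": "montium_partial.nwk",
        "matrix": "montium_partial.tsv",
        "labels": "montium_partial_labels.tsv",
    },
    "table1_counts": {"table": "table1_counts.tsv"},
    "fig1_pairs": {"matrix": "fig1_pairs.tsv"},
}


def _fixture_text(filename: str, verify: bool = True) -> str:
    pkg = resources.files("ylinkage.fixtures")
    text = (pkg / filename).read_text()
    if verify:
        sums = {}
        for line in (pkg / "CHECKSUMS.sha256").read_text().splitlines():
            if line.strip():
                digest, name = line.split()
                sums[name] = digest
        actual = hashlib.sha256(text.encode()).hexdigest()
        if sums.get(filename) != actual:
            raise FixtureIntegrityError(
                f"fixture {filename} checksum mismatch (file was edited?)"
            )
    return text


def fixture_path(filename: str) -> str:
    return str(resources.files("ylinkage.fixtures") / filename)


def load_fixture(name: str, verify: bool = True) -> Fixture:
    """Load a packaged worked-example dataset by name.

    Known names: ``fig2_ory`` (8 species, gene ORY), ``montium_partial``
    (montium subgroup facts stated in the running text), ``table1_counts``
    (the 2x2 re-acquisition counts), ``fig1_pairs`` (two species x four
    genes primary-data example).
    """
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    files = _FIXTURE_FILES[name]
    tree = matrix = labels = table = None
    if "tree" in files:
        tree = parse_newick(_fixture_text(files["tree"], verify))
    if "matrix" in files:
        matrix = LinkageMatrix.read(io.StringIO(_fixture_text(files["matrix"], verify)))
    if "labels" in files:
        labels = GeneClassLabels.read(io.StringIO(_fixture_text(files["labels"], verify)))
    if "table" in files:
        frame = pd.read_csv(
            io.StringIO(_fixture_text(files["table"], verify)), sep="\t", index_col=0
        )
        table = (
            int(frame.iloc[0, 0]),
            int(frame.iloc[0, 1]),
            int(frame.iloc[1, 0]),
            int(frame.iloc[1, 1]),
        )
    return Fixture(name=name, tree=tree, matrix=matrix, labels=labels, table=table)
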