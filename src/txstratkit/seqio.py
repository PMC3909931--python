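"""Readers and writers for the external formats the toolkit touches.

Formats: FASTA (contigs, proteins), tab-separated homology hit tables
(BLAST tabular style), minimal SAM (QNAME/FLAG/RNAME only), OBO 1.2
ontologies, and two-column TSV annotation tables.

SAM parsing is deliberately minimal: the coverage statistic downstream
needs only per-contig aligned-read counts, so CIGAR strings and positions
are never consumed. Secondary (0x100) and supplementary (0x800) records
are dropped so that one read contributes at most once.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import networkx as nx
import obonet
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger("txstratkit")

#: Sentinel reference for unaligned SAM records (FLAG bit 0x4).
UNALIGNED = None

_GO_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class FormatError(ValueError):
    """A malformed input file; message carries file context and line number."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    """An assembled transcript sequence.

    ``length`` always equals ``len(sequence)``; sequences are stored
    uppercase.
    """

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def _as_handle(source, mode: str = "r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def read_fasta(source) -> list[Contig]:
    """Read FASTA records into :class:`Contig` objects.

    The record id is the first whitespace-delimited header token; the
    sequence is uppercased. Duplicate ids and empty sequences are errors.
    """
    handle, close = _as_handle(source)
    try:
        contigs: list[Contig] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate FASTA id: {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"empty sequence for FASTA id {rec.id!r}")
            seen.add(rec.id)
            contigs.append(Contig(id=rec.id, sequence=seq))
        return contigs
    finally:
        if close:
            handle.close()


def write_fasta(contigs: Iterable[Contig], dest, width: int = 70) -> None:
    """Write contigs as multi-line FASTA (exact round trip with read_fasta)."""
    handle, close = _as_handle(dest, "w")
    try:
        records = [SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs]
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HitRecord:
    """One homology hit of a contig against a taxonomically binned database."""

    query_id: str
    subject_id: str
    bin: str
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class HitTableColumns:
    """Zero-based column positions in a tab-separated hit file.

    Defaults follow the standard 12-column BLAST tabular layout
    (qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore).
    """

    query: int = 0
    subject: int = 1
    evalue: int = 10
    bitscore: int = 11


def read_hits(
    source,
    bin_name: str,
    evalue_threshold: float = 1e-3,
    columns: HitTableColumns = HitTableColumns(),
) -> list[HitRecord]:
    """Read a tab-separated hit table, tagging records with ``bin_name``.

    Rows whose E-value exceeds ``evalue_threshold`` are dropped (the count
    is logged). The default threshold is the conventional 1e-3 cutoff for
    transcriptome-scale BLASTx annotation.
    """
    handle, close = _as_handle(source)
    kept: list[HitRecord] = []
    dropped = 0
    try:
        ncol = max(columns.query, columns.subject, columns.evalue, columns.bitscore) + 1
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < ncol:
                raise FormatError(
                    f"hit table line {lineno}: expected >= {ncol} fields, got {len(fields)}"
                )
            try:
                evalue = float(fields[columns.evalue])
                bitscore = float(fields[columns.bitscore])
            except ValueError as exc:
                raise FormatError(f"hit table line {lineno}: non-numeric field ({exc})") from None
            if evalue < 0:
                raise FormatError(f"hit table line {lineno}: negative E-value")
            if evalue > evalue_threshold:
                dropped += 1
                continue
            kept.append(
                HitRecord(
                    query_id=fields[columns.query],
                    subject_id=fields[columns.subject],
                    bin=bin_name,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
        if dropped:
            logger.info("read_hits[%s]: dropped %d rows above E-value %g", bin_name, dropped, evalue_threshold)
        return kept
    finally:
        if close:
            handle.close()


def write_hits(hits: Iterable[HitRecord], dest) -> None:
    """Write hits in 12-column BLAST tabular layout (unused columns zeroed)."""
    handle, close = _as_handle(dest, "w")
    try:
        for h in hits:
            row = [h.query_id, h.subject_id] + ["0"] * 8 + [repr(h.evalue), repr(h.bitscore)]
            handle.write("\t".join(row) + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentRecord:
    """One sequencing read's alignment outcome: aligned to a contig or not."""

    read_id: str
    flag: int
    reference_id: str | None  # UNALIGNED sentinel (None) when flag bit 0x4 set

    @property
    def is_aligned(self) -> bool:
        return self.reference_id is not None


def read_sam(source) -> list[AlignmentRecord]:
    """Read a SAM file, keeping primary records only.

    Header lines (``@``) are skipped. Records with the unmapped bit (0x4)
    carry the :data:`UNALIGNED` sentinel. Secondary (0x100) and
    supplementary (0x800) records are excluded so each read appears at
    most once; the exclusion count is logged.
    """
    handle, close = _as_handle(source)
    records: list[AlignmentRecord] = []
    excluded = 0
    try:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("@"):
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(f"SAM line {lineno}: expected >= 11 fields, got {len(fields)}")
            try:
                flag = int(fields[1])
            except ValueError:
                raise FormatError(f"SAM line {lineno}: non-integer FLAG {fields[1]!r}") from None
            if flag < 0:
                raise FormatError(f"SAM line {lineno}: negative FLAG")
            if flag & 0x100 or flag & 0x800:
                excluded += 1
                continue
            if flag & 0x4:
                records.append(AlignmentRecord(fields[0], flag, UNALIGNED))
            else:
                records.append(AlignmentRecord(fields[0], flag, fields[2]))
        if excluded:
            logger.info("read_sam: excluded %d secondary/supplementary records", excluded)
        return records
    finally:
        if close:
            handle.close()


def write_sam(records: Iterable[AlignmentRecord], dest) -> None:
    """Write minimal SAM records (placeholder values for unused fields).

    Output is reader-grade for :func:`read_sam`, not aligner-grade SAM.
    """
    handle, close = _as_handle(dest, "w")
    try:
        handle.write("@HD\tVN:1.6\tSO:unknown\n")
        for r in records:
            rname = r.reference_id if r.reference_id is not None else "*"
            handle.write(f"{r.read_id}\t{r.flag}\t{rname}\t0\t255\t*\t*\t0\t0\t*\t*\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# OBO ontologies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OntologyTerm:
    id: str
    name: str
    namespace: str | None
    parents: tuple[str, ...]
    obsolete: bool = False


class OntologyDag:
    """A parsed ontology: terms plus directed is_a edges (child -> parent).

    Multi-parent terms are first-class; acyclicity is verified at load.
    Obsolete terms are retained but flagged and excluded from traversals.
    """

    def __init__(self, terms: Mapping[str, OntologyTerm]):
        self._terms = dict(terms)
        g = nx.DiGraph()
        g.add_nodes_from(self._terms)
        for t in self._terms.values():
            for p in t.parents:
                if p not in self._terms:
                    raise FormatError(f"ontology: dangling parent ids: {p}")
                g.add_edge(t.id, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise FormatError(f"ontology: cycle detected: {' -> '.join(u for u, _ in cycle)}")
        self._graph = g

    # -- container protocol -------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self._terms)

    # -- accessors ----------------------------------------------------------
    @property
    def graph(self) -> nx.DiGraph:
        """Directed graph with child -> parent is_a edges."""
        return self._graph

    def term(self, term_id: str) -> OntologyTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise KeyError(f"unknown ontology term: {term_id}") from None

    def parents(self, term_id: str) -> set[str]:
        self.term(term_id)
        return set(self._graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        """Direct children (terms with an is_a edge to ``term_id``), obsolete excluded."""
        self.term(term_id)
        return {c for c in self._graph.predecessors(term_id) if not self._terms[c].obsolete}

    def roots(self, namespace: str | None = None) -> list[str]:
        """Parentless non-obsolete terms, optionally restricted to a namespace."""
        out = []
        for tid, t in self._terms.items():
            if t.obsolete or t.parents:
                continue
            if namespace is None or t.namespace == namespace:
                out.append(tid)
        return sorted(out)


def read_obo(source, relationships: Sequence[str] = ("is_a",)) -> OntologyDag:
    """Parse an OBO 1.2 file into an :class:`OntologyDag`.

    Only edges whose relationship type is in ``relationships`` are loaded
    (default: is_a only, matching ontology-coverage semantics downstream).
    Obsolete terms are retained, flagged, and carry no edges. Dangling
    parent references and cycles are errors.
    """
    handle, close = _as_handle(source)
    try:
        multigraph = obonet.read_obo(handle, ignore_obsolete=False)
    finally:
        if close:
            handle.close()

    dangling = sorted(n for n, d in multigraph.nodes(data=True) if "name" not in d)
    if dangling:
        raise FormatError(f"ontology: dangling parent ids: {', '.join(dangling)}")

    terms: dict[str, OntologyTerm] = {}
    for tid, data in multigraph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents: tuple[str, ...] = ()
        if not obsolete:
            parents = tuple(
                sorted(
                    {
                        v
                        for _, v, key in multigraph.out_edges(tid, keys=True)
                        if key in relationships
                    }
                )
            )
        terms[tid] = OntologyTerm(
            id=tid,
            name=data.get("name", ""),
            namespace=data.get("namespace"),
            parents=parents,
            obsolete=obsolete,
        )
    return OntologyDag(terms)


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

#: EC numbers: 1-4 dot-separated fields, each digits or "-" (partial).
EC_PATTERN = re.compile(r"^(?:EC:)?\d+(?:\.(?:\d+|-)){0,3}$")
GO_PATTERN = re.compile(r"^GO:\d{7}$")


@dataclass
class AnnotationTable:
    """Rows of (contig_id, label) where label is a GO term id or EC number."""

    pairs: list[tuple[str, str]]
    unresolved: set[str] = field(default_factory=set)

    @property
    def labels(self) -> set[str]:
        return {label for _, label in self.pairs}

    def by_contig(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for cid, label in self.pairs:
            out.setdefault(cid, set()).add(label)
        return out


def read_annotations(source, ontology: OntologyDag | None = None, kind: str = "go") -> AnnotationTable:
    """Read a ``contig_id<TAB>label`` annotation TSV (header row required).

    ``kind='go'``: labels not resolving in ``ontology`` (when given) are
    collected in ``unresolved`` and logged, not fatal. ``kind='ec'``:
    labels must match the dotted EC pattern; violations are errors naming
    the row.
    """
    if kind not in ("go", "ec"):
        raise ValueError(f"unknown annotation kind: {kind!r}")
    handle, close = _as_handle(source)
    pairs: list[tuple[str, str]] = []
    unresolved: set[str] = set()
    try:
        header = handle.readline()
        if not header.strip():
            return AnnotationTable(pairs=[])
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"annotation line {lineno}: expected 2 fields, got {len(fields)}")
            cid, label = fields
            if kind == "ec":
                if not EC_PATTERN.match(label):
                    raise FormatError(f"annotation line {lineno}: malformed EC number {label!r}")
            elif ontology is not None and label not in ontology:
                unresolved.add(label)
            pairs.append((cid, label))
        if unresolved:
            logger.info("read_annotations: %d labels unresolved in ontology", len(unresolved))
        return AnnotationTable(pairs=pairs, unresolved=unresolved)
    finally:
        if close:
            handle.close()


def write_annotations(table: AnnotationTable, dest) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        handle.write("contig_id\tlabel\n")
        for cid, label in table.pairs:
            handle.write(f"{cid}\t{label}\n")
    finally:
        if close:
            handle.close()
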