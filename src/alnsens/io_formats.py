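"""Readers and writers for the formats the pipeline touches.

FASTA (unaligned and aligned), Newick trees, and the tab-separated report
tables.  Sequences are held as :class:`SequenceRecord`; rectangular gapped
matrices as :class:`MultipleAlignment`.  Gaps are ``-`` internally ('.' in
input is normalized); ``X``/``N`` ambiguity codes are retained and treated
as missing data downstream.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
from Bio.SeqIO.FastaIO import SimpleFastaParser

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"
AMBIGUITY = {"aa": "X", "nt": "N"}
GAP = "-"


class FormatError(ValueError):
    """Malformed input file (FASTA, alignment, or table)."""


class NewickError(ValueError):
    """Malformed or invalid Newick input."""


def _alphabet(moltype: str) -> set[str]:
    if moltype == "aa":
        return set(AA_ALPHABET) | {AMBIGUITY["aa"]}
    if moltype == "nt":
        return set(NT_ALPHABET) | {AMBIGUITY["nt"]}
    raise ValueError(f"moltype must be 'aa' or 'nt', got {moltype!r}")


@dataclass(frozen=True)
class SequenceRecord:
    """A named residue string, the pipeline's atomic input.

    ``seq`` is uppercase and restricted to the declared alphabet plus the
    ambiguity symbol; a gapped row additionally allows ``-``.
    """

    id: str
    seq: str
    moltype: str = "aa"
    gapped: bool = False

    def __post_init__(self):
        if not self.id or re.search(r"\s", self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        allowed = _alphabet(self.moltype)
        if self.gapped:
            allowed = allowed | {GAP}
        seq = self.seq.upper().replace(".", GAP)
        object.__setattr__(self, "seq", seq)
        for pos, ch in enumerate(seq):
            if ch not in allowed:
                raise FormatError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos + 1}"
                )

    def ungapped(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.seq.replace(GAP, ""), self.moltype)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MultipleAlignment:
    """Rectangular gap-padded residue matrix with a method label.

    Columns are indexed 0-based internally; reports render sites 1-based.
    """

    records: tuple[SequenceRecord, ...]
    method_label: str = ""

    def __post_init__(self):
        records = tuple(self.records)
        if len(records) < 2:
            raise FormatError("an alignment needs at least 2 rows")
        ncol = len(records[0].seq)
        for rec in records:
            if len(rec.seq) != ncol:
                raise FormatError(
                    f"ragged alignment: row {rec.id!r} has length "
                    f"{len(rec.seq)}, expected {ncol}"
                )
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate row ids in alignment")
        object.__setattr__(self, "records", records)

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_cols(self) -> int:
        return len(self.records[0].seq)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, rid: str) -> str:
        for r in self.records:
            if r.id == rid:
                return r.seq
        raise KeyError(rid)

    def column(self, j: int) -> str:
        return "".join(r.seq[j] for r in self.records)

    def ungapped_records(self) -> list[SequenceRecord]:
        return [r.ungapped() for r in self.records]


def parse_fasta(text: str, moltype: str = "aa", gapped: bool = False) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for title, seq in SimpleFastaParser(io.StringIO(text)):
        rid = title.split()[0] if title.split() else ""
        if rid in seen:
            raise FormatError(f"duplicate sequence id {rid!r}")
        seen.add(rid)
        records.append(SequenceRecord(rid, seq, moltype, gapped=gapped))
    if not records:
        raise FormatError("no FASTA records found")
    return records


def read_fasta(path, moltype: str = "aa") -> list[SequenceRecord]:
    """Read unaligned FASTA; ids are the first whitespace token of the header."""
    with open(path) as fh:
        return parse_fasta(fh.read(), moltype)


def write_fasta(records, path=None, width: int = 70) -> str:
    chunks = []
    for rec in records:
        body = "\n".join(rec.seq[i : i + width] for i in range(0, len(rec.seq), width))
        chunks.append(f">{rec.id}\n{body}\n")
    text = "".join(chunks)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_alignment(path, moltype: str = "aa", method_label: str = "") -> MultipleAlignment:
    """Read aligned FASTA into a :class:`MultipleAlignment` with the given label."""
    with open(path) as fh:
        records = parse_fasta(fh.read(), moltype, gapped=True)
    return MultipleAlignment(tuple(records), method_label=method_label)


def write_alignment(aln: MultipleAlignment, path=None) -> str:
    return write_fasta(aln.records, path)


# ---------------------------------------------------------------------------
# Newick

def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise NewickError("duplicate leaf labels")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise NewickError(f"negative branch length {edge.length}")
    return tree


def read_newick(source) -> dendropy.Tree:
    """Parse Newick from a string or file path into a dendropy tree.

    Numeric internal-node labels are interpreted as support values in [0, 1]
    (left on ``node.label``; also mirrored to ``edge.support``).
    """
    text = source
    if not str(source).lstrip().startswith("("):
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"Newick parse error: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.is_internal() and node.label is not None:
            try:
                node.edge.support = float(node.label)
            except ValueError:
                pass
    return _validate_tree(tree)


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths at 10 significant digits."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )
    return s.strip() + "\n"


# ---------------------------------------------------------------------------
# Report tables

@dataclass
class ReportTable:
    """Rows of named cells with a declared column schema.

    Numeric cells are rendered at 6 significant digits, enough to round-trip
    the statistics the pipeline reports.
    """

    columns: list[str]
    rows: list[dict] = field(default_factory=list)

    def add_row(self, **cells) -> None:
        missing = [c for c in self.columns if c not in cells]
        if missing:
            raise FormatError(f"row is missing declared columns {missing}")
        self.rows.append({c: cells[c] for c in self.columns})

    @staticmethod
    def format_cell(value) -> str:
        if isinstance(value, bool) or value is None:
            return str(value)
        if isinstance(value, float):
            return f"{value:.6g}"
        return str(value)

    def to_tsv(self) -> str:
        lines = ["\t".join(self.columns)]
        for row in self.rows:
            lines.append("\t".join(self.format_cell(row[c]) for c in self.columns))
        return "\n".join(lines) + "\n"


def write_report(table: ReportTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(table.to_tsv())
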