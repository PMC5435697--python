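"""Readers, writers and shared sequence/coordinate conventions.

All coordinates are 0-based half-open on the forward strand of a contig;
GFF3 input (1-based inclusive) is converted at the boundary.  Genome
sequences are uppercase over the alphabet ``{A, C, G, T, N}``; ``U`` is
mapped to ``T`` on input.  CDS translation uses the bacterial code
(translation table 11) with initiator codons rendered as methionine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data import CodonTable

__all__ = [
    "GenomeRecord",
    "GeneRecord",
    "TaxonomyLabel",
    "StrainkitError",
    "EmptyFastaError",
    "DuplicateIdError",
    "IllegalCharacterError",
    "CoordinateError",
    "UnknownContigError",
    "ShapeMismatchError",
    "InternalStopWarning",
    "read_fasta",
    "write_fasta",
    "load_genome",
    "read_gene_table",
    "write_gene_table",
    "read_category_map",
    "read_taxonomy",
    "write_matrix",
    "read_matrix",
    "reverse_complement",
    "translate_cds",
]

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_START_CODONS_11 = set(_TABLE11.start_codons)
_STOP_CODONS_11 = set(_TABLE11.stop_codons)


class StrainkitError(Exception):
    """Base class for all errors raised by this package."""


class EmptyFastaError(StrainkitError):
    """FASTA file contained no records."""


class DuplicateIdError(StrainkitError):
    """Two records in one file share an identifier."""


class IllegalCharacterError(StrainkitError):
    """A sequence contained a character outside the accepted alphabet."""


class CoordinateError(StrainkitError):
    """Gene coordinates fall outside the contig or are inverted."""


class UnknownContigError(StrainkitError):
    """A gene refers to a contig absent from its genome."""


class ShapeMismatchError(StrainkitError):
    """Matrix labels do not match the value array shape."""


class InternalStopWarning(UserWarning):
    """A CDS translated with an internal stop codon; protein truncated."""


@dataclass
class GenomeRecord:
    """One strain's assembly: ordered contigs plus free-text metadata."""

    genome_id: str
    contigs: list[tuple[str, str]]
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, seq in self.contigs:
            if cid in seen:
                raise DuplicateIdError(f"duplicate contig id {cid!r} in genome {self.genome_id!r}")
            seen.add(cid)
            if not seq:
                raise IllegalCharacterError(f"empty sequence for contig {cid!r}")
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise IllegalCharacterError(
                    f"illegal characters {sorted(bad)} in contig {cid!r} of genome {self.genome_id!r}"
                )

    @property
    def contig_dict(self) -> dict[str, str]:
        return dict(self.contigs)

    @property
    def length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def sequence(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise UnknownContigError(f"contig {contig_id!r} not in genome {self.genome_id!r}")


@dataclass
class GeneRecord:
    """One annotated gene with its extracted CDS and translation.

    ``start``/``end`` are 0-based half-open on the contig's forward
    strand; ``cds`` is the forward-strand slice, reverse-complemented
    when ``strand`` is ``-``.  ``category`` is a single subsystem letter
    ``A``-``Z`` or ``"UNASSIGNED"``; ``feature_type`` distinguishes
    protein-coding genes (``"cds"``) from annotated 16S rRNA genes
    (``"rRNA_16S"``), which carry no translation.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    cds: str = ""
    protein: str = ""
    category: str = "UNASSIGNED"
    subcategory: str = ""
    feature_type: str = "cds"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise StrainkitError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class TaxonomyLabel:
    """Taxonomic assignment of one hit-database entry."""

    entry_id: str
    order: str
    phylum: str

    def __post_init__(self) -> None:
        if not self.order or not self.phylum:
            raise StrainkitError(f"empty order/phylum for entry {self.entry_id!r}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str, warn: bool = True, gene_id: str = "") -> str:
    """Translate a CDS with the bacterial code (table 11).

    Initiator codons are rendered as ``M``.  A trailing stop codon is
    dropped; an internal stop truncates the protein at the first stop
    (with :class:`InternalStopWarning` when ``warn``).  Codons
    containing ``N`` translate as ``X``.
    """
    aa: list[str] = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in _STOP_CODONS_11:
            if i < n_codons - 1 and warn:
                warnings.warn(
                    f"internal stop codon in CDS {gene_id or '<anonymous>'} at codon {i}; "
                    "protein truncated",
                    InternalStopWarning,
                    stacklevel=2,
                )
            break
        if i == 0 and codon in _START_CODONS_11:
            aa.append("M")
        elif "N" in codon:
            aa.append("X")
        else:
            aa.append(_TABLE11.forward_table[codon])
    return "".join(aa)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "nt") -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs.

    Ids are taken up to the first whitespace; sequences are uppercased.
    With the default nucleotide alphabet ``U`` is mapped to ``T``;
    ``alphabet="aa"`` accepts protein sequences instead.  Raises
    :class:`EmptyFastaError`, :class:`DuplicateIdError` or
    :class:`IllegalCharacterError`.
    """
    legal = NUCLEOTIDES if alphabet == "nt" else AMINO_ACIDS
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks).upper()
        if alphabet == "nt":
            seq = seq.replace("U", "T")
        bad = set(seq) - legal
        if bad:
            raise IllegalCharacterError(
                f"illegal characters {sorted(bad)} in record {current_id!r} of {path}"
            )
        records.append((current_id, seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if len(line) > 1 else ""
                if not current_id:
                    raise StrainkitError(f"record with empty id in {path}")
                if current_id in seen:
                    raise DuplicateIdError(f"duplicate id {current_id!r} in {path}")
                seen.add(current_id)
                chunks = []
            else:
                if current_id is None:
                    raise StrainkitError(f"sequence before first header in {path}")
                chunks.append(line)
    flush()
    if not records:
        raise EmptyFastaError(f"no records in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_genome(path: str | Path, genome_id: str | None = None, source: str = "") -> GenomeRecord:
    """Load a multi-FASTA assembly as a :class:`GenomeRecord`."""
    contigs = read_fasta(path)
    gid = genome_id if genome_id is not None else Path(path).stem
    return GenomeRecord(genome_id=gid, contigs=contigs, source=source or str(path))


# ---------------------------------------------------------------------------
# Gene tables (TSV and GFF3)

_GENE_TSV_COLUMNS = [
    "gene_id",
    "genome_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "category",
    "feature_type",
    "subcategory",
]


def _extract_cds(genome: GenomeRecord, contig_id: str, start: int, end: int, strand: str,
                 gene_id: str) -> str:
    seq = genome.sequence(contig_id)
    if end > len(seq):
        raise CoordinateError(
            f"gene {gene_id!r}: [{start}, {end}) exceeds contig {contig_id!r} length {len(seq)}"
        )
    sub = seq[start:end]
    return reverse_complement(sub) if strand == "-" else sub


def read_gene_table(path: str | Path, genomes: Sequence[GenomeRecord] | dict[str, GenomeRecord],
                    warn: bool = True) -> list[GeneRecord]:
    """Read gene annotations (TSV, or GFF3 as an alternate dialect).

    The TSV dialect has a header with at least ``gene_id, genome_id,
    contig_id, start, end, strand, category`` (0-based half-open).  GFF3
    is detected by a ``##gff-version`` pragma or a ``.gff``/``.gff3``
    suffix: CDS features are read (1-based inclusive, converted), the
    gene id from ``ID=`` and the category from a ``category=``
    attribute.  CDS and protein are extracted from the matching
    :class:`GenomeRecord` using translation table 11.
    """
    if not isinstance(genomes, dict):
        genomes = {g.genome_id: g for g in genomes}
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    is_gff = first.startswith("##gff-version") or path.suffix.lower() in {".gff", ".gff3"}
    rows = _read_gff3_rows(path, genomes) if is_gff else _read_tsv_rows(path)

    genes: list[GeneRecord] = []
    for row in rows:
        genome = genomes.get(row["genome_id"])
        if genome is None:
            raise StrainkitError(f"gene {row['gene_id']!r}: unknown genome {row['genome_id']!r}")
        feature_type = row.get("feature_type") or "cds"
        cds = _extract_cds(genome, row["contig_id"], row["start"], row["end"], row["strand"],
                           row["gene_id"])
        protein = ""
        if feature_type == "cds":
            protein = translate_cds(cds, warn=warn, gene_id=row["gene_id"])
        genes.append(GeneRecord(
            gene_id=row["gene_id"],
            genome_id=row["genome_id"],
            contig_id=row["contig_id"],
            start=row["start"],
            end=row["end"],
            strand=row["strand"],
            cds=cds,
            protein=protein,
            category=row.get("category") or "UNASSIGNED",
            subcategory=row.get("subcategory") or "",
            feature_type=feature_type,
        ))
    return genes


def _read_tsv_rows(path: Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"gene_id", "genome_id", "contig_id", "start", "end", "strand", "category"}
        missing = required - set(header)
        if missing:
            raise StrainkitError(f"gene table {path} missing columns {sorted(missing)}")
        idx = {name: header.index(name) for name in header}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            row = {name: fields[i] if i < len(fields) else "" for name, i in idx.items()}
            row["start"] = int(row["start"])
            row["end"] = int(row["end"])
            rows.append(row)
    return rows


def _read_gff3_rows(path: Path, genomes: dict[str, GenomeRecord]) -> list[dict]:
    # contig -> genome lookup so single-genome GFF3 files need no genome column
    contig_owner = {cid: g.genome_id for g in genomes.values() for cid, _ in g.contigs}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            contig, _, _, start1, end1, _, strand, _, attrs = fields[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr.get("ID") or attr.get("Name")
            if gene_id is None:
                raise StrainkitError(f"GFF3 CDS without ID attribute in {path}")
            if contig not in contig_owner:
                raise UnknownContigError(f"GFF3 contig {contig!r} not in any supplied genome")
            rows.append({
                "gene_id": gene_id,
                "genome_id": attr.get("genome_id", contig_owner[contig]),
                "contig_id": contig,
                "start": int(start1) - 1,   # 1-based inclusive -> 0-based half-open
                "end": int(end1),
                "strand": strand,
                "category": attr.get("category", "UNASSIGNED"),
                "subcategory": attr.get("subcategory", ""),
                "feature_type": attr.get("feature_type", "cds"),
            })
    return rows


def write_gene_table(path: str | Path, genes: Iterable[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_TSV_COLUMNS) + "\n")
        for g in genes:
            fh.write("\t".join([
                g.gene_id, g.genome_id, g.contig_id, str(g.start), str(g.end), g.strand,
                g.category, g.feature_type, g.subcategory,
            ]) + "\n")


def read_category_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping gene_id -> single category letter."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if i == 0 and fields[0] == "gene_id":
                continue
            if len(fields) < 2:
                raise StrainkitError(f"malformed category map line: {line!r}")
            mapping[fields[0]] = fields[1]
    return mapping


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyLabel]:
    """Read a TSV of entry_id, order, phylum into TaxonomyLabel objects."""
    out: dict[str, TaxonomyLabel] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if i == 0 and fields[0] == "entry_id":
                continue
            if len(fields) < 3:
                raise StrainkitError(f"malformed taxonomy line: {line!r}")
            out[fields[0]] = TaxonomyLabel(entry_id=fields[0], order=fields[1], phylum=fields[2])
    return out


# ---------------------------------------------------------------------------
# Matrices


def write_matrix(path: str | Path, row_labels: Sequence[str], col_labels: Sequence[str],
                 values) -> None:
    """Write a labelled numeric matrix as TSV, floats at 4 decimals.

    Row order is preserved as given; the first header cell is empty.
    """
    values = [list(row) for row in values]
    if len(values) != len(row_labels):
        raise ShapeMismatchError(
            f"{len(row_labels)} row labels but {len(values)} value rows"
        )
    for row in values:
        if len(row) != len(col_labels):
            raise ShapeMismatchError(
                f"{len(col_labels)} column labels but a row with {len(row)} values"
            )
    with open(path, "w") as fh:
        fh.write("\t".join([""] + list(col_labels)) + "\n")
        for label, row in zip(row_labels, values):
            fh.write("\t".join([label] + [f"{v:.4f}" for v in row]) + "\n")


def read_matrix(path: str | Path) -> tuple[list[str], list[str], list[list[float]]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col_labels = header[1:]
        row_labels: list[str] = []
        values: list[list[float]] = []
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            row_labels.append(fields[0])
            values.append([float(v) for v in fields[1:]])
    return row_labels, col_labels, values
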