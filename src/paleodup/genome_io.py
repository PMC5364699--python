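"""Readers, writers and validation for the four input artifacts.

The shared data model lives here: positioned gene models with per-chromosome
rank orders (:class:`Gene` / :class:`GeneIndex`), filtered protein-similarity
edges (:class:`HomologHit`), gene-to-annotation-term maps
(:class:`TermAnnotation`) and coding/protein sequence sets
(:class:`SequenceSet`).

Coordinates are 1-based inclusive on input (GFF3 convention); internal gene
ranks are 0-based per chromosome.  Strand is stored but ignored downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Gene",
    "GeneIndex",
    "HomologHit",
    "TermAnnotation",
    "SequenceSet",
    "ParseError",
    "ValidationError",
    "HIT_COLUMNS",
    "read_gff3",
    "write_gff3",
    "read_hit_table",
    "write_hit_table",
    "read_term_table",
    "write_term_table",
    "read_fasta",
    "write_fasta",
]


class ParseError(ValueError):
    """A file could not be parsed into the data model."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Standard 12 columns of tabular protein-search output.
HIT_COLUMNS = [
    "query_id", "subject_id", "pident", "aln_len", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_CDS_ALPHABET = frozenset("ACGTN")
# BLOSUM62 residue alphabet without the stop symbol.
_PROTEIN_ALPHABET = frozenset("ARNDCQEGHILKMFPSTWYVBZX")


@dataclass(frozen=True)
class Gene:
    """A positioned gene model; ``rank`` is its 0-based order on its chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GeneIndex:
    """Rank-ordered gene models of one genome.

    Parameters
    ----------
    genome_label:
        Free-text label ("reference", "descendant", a species name, ...).
    genes:
        Gene models; ranks are (re)assigned here per chromosome by ascending
        ``(start, end, gene_id)``.
    chrom_lengths:
        Optional assembled length per chromosome.  When absent each
        chromosome's extent is taken as the maximum gene ``end``.
    """

    def __init__(self, genome_label: str, genes: Iterable[Gene],
                 chrom_lengths: Mapping[str, int] | None = None) -> None:
        self.genome_label = genome_label
        by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        self.by_chromosome: dict[str, list[Gene]] = {}
        self.genes: dict[str, Gene] = {}
        for chrom in sorted(by_chrom):
            ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
            ranked = [
                Gene(g.gene_id, g.chromosome, g.start, g.end, g.strand, rank)
                for rank, g in enumerate(ordered)
            ]
            self.by_chromosome[chrom] = ranked
            for g in ranked:
                if g.gene_id in self.genes:
                    raise ValidationError(f"duplicate gene ID {g.gene_id!r}")
                self.genes[g.gene_id] = g
        self.chrom_lengths: dict[str, int] = (
            dict(chrom_lengths) if chrom_lengths is not None else
            {c: max(g.end for g in gl) for c, gl in self.by_chromosome.items()}
        )

    @property
    def total_length_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneIndex):
            return NotImplemented
        return (self.genome_label == other.genome_label
                and self.genes == other.genes
                and self.chrom_lengths == other.chrom_lengths)


@dataclass(frozen=True)
class HomologHit:
    """An undirected, filtered protein-similarity edge between two genes."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def key(self) -> tuple[str, str]:
        a, b = sorted((self.query_id, self.subject_id))
        return (a, b)


class TermAnnotation:
    """Mapping gene_id -> set of annotation-term identifiers.

    Genes absent from the mapping, or mapped to an empty set, are
    "unannotated".
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None) -> None:
        self._terms: dict[str, frozenset[str]] = {}
        if mapping:
            for gene_id, terms in mapping.items():
                fs = frozenset(terms)
                if fs:
                    self._terms[gene_id] = fs

    def terms_for(self, gene_id: str) -> frozenset[str]:
        return self._terms.get(gene_id, frozenset())

    def is_annotated(self, gene_id: str) -> bool:
        return bool(self._terms.get(gene_id))

    def genes(self) -> list[str]:
        return sorted(self._terms)

    def items(self):
        return self._terms.items()

    def __len__(self) -> int:
        return len(self._terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermAnnotation):
            return NotImplemented
        return self._terms == other._terms


class SequenceSet:
    """Gene sequences of one kind ('cds' or 'protein') with validation flags.

    Coding sequences have one terminal stop codon trimmed; sequences failing
    the frame/alphabet rules stay in the set but are flagged unusable for
    selection analyses (``valid_for_selection``).
    """

    def __init__(self, kind: str) -> None:
        if kind not in ("cds", "protein"):
            raise ValidationError(f"unknown sequence kind {kind!r}")
        self.kind = kind
        self.sequences: dict[str, str] = {}
        self.invalid: dict[str, str] = {}  # gene_id -> reason

    def add(self, gene_id: str, seq: str) -> None:
        seq = seq.upper()
        if self.kind == "cds":
            if len(seq) >= 3 and seq[-3:] in STOP_CODONS:
                seq = seq[:-3]
            if not set(seq) <= _CDS_ALPHABET:
                self.invalid[gene_id] = "bad_alphabet"
            elif len(seq) % 3 != 0:
                self.invalid[gene_id] = "length_not_multiple_of_3"
            elif any(seq[i:i + 3] in STOP_CODONS for i in range(0, len(seq), 3)):
                self.invalid[gene_id] = "internal_stop"
        else:
            if seq.endswith("*"):
                seq = seq[:-1]
            if not set(seq) <= _PROTEIN_ALPHABET:
                self.invalid[gene_id] = "bad_alphabet"
        self.sequences[gene_id] = seq

    def valid_for_selection(self, gene_id: str) -> bool:
        return gene_id in self.sequences and gene_id not in self.invalid

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)


# ---------------------------------------------------------------------------
# GFF3


def _parse_gff3_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k] = v
    return out


def read_gff3(path: str | Path, genome_label: str) -> GeneIndex:
    """Read gene features from a GFF3 file into a :class:`GeneIndex`.

    Only features of type ``gene`` are used; their ``ID`` attribute becomes
    the gene id.  ``##sequence-region`` directives, when present, supply
    chromosome lengths.
    """
    path = Path(path)
    genes: list[Gene] = []
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated "
                                 f"fields, found {len(fields)}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            attr_map = _parse_gff3_attributes(attrs)
            gene_id = attr_map.get("ID")
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: gene feature without ID attribute")
            genes.append(Gene(gene_id, chrom, start_i, end_i,
                              strand if strand in ("+", "-") else "."))
    return GeneIndex(genome_label, genes, chrom_lengths or None)


def write_gff3(index: GeneIndex, path: str | Path) -> None:
    """Write a :class:`GeneIndex` back to GFF3 (round-trips with read_gff3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(index.chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {index.chrom_lengths[chrom]}\n")
        for chrom in sorted(index.by_chromosome):
            for g in index.by_chromosome[chrom]:
                fh.write("\t".join([
                    chrom, "paleodup", "gene", str(g.start), str(g.end),
                    ".", g.strand, ".", f"ID={g.gene_id}",
                ]) + "\n")


# ---------------------------------------------------------------------------
# Homology hits


def read_hit_table(path: str | Path, max_evalue: float = 1e-20) -> list[HomologHit]:
    """Read a 12-column tabular hit file, filter, and collapse to undirected edges.

    Rows with ``evalue > max_evalue`` and self-hits are removed; reciprocal
    duplicates collapse to one undirected edge keeping the best bitscore.
    """
    try:
        df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, header=None,
                         comment="#",
                         dtype={"query_id": str, "subject_id": str})
        df["evalue"] = pd.to_numeric(df["evalue"], errors="raise")
        df["bitscore"] = pd.to_numeric(df["bitscore"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: malformed hit table: {exc}") from exc
    if (df["evalue"] < 0).any():
        raise ValidationError(f"{path}: negative e-value")
    df = df[df["evalue"] <= max_evalue]
    df = df[df["query_id"] != df["subject_id"]]
    best: dict[tuple[str, str], HomologHit] = {}
    for row in df.itertuples(index=False):
        hit = HomologHit(row.query_id, row.subject_id,
                         float(row.evalue), float(row.bitscore))
        key = hit.key()
        prev = best.get(key)
        if prev is None or hit.bitscore > prev.bitscore:
            best[key] = hit
    return [best[k] for k in sorted(best)]


def write_hit_table(hits: Iterable[HomologHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join([
                h.query_id, h.subject_id, "100.0", "0", "0", "0",
                "0", "0", "0", "0", f"{h.evalue:g}", f"{h.bitscore:g}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Term tables


def read_term_table(path: str | Path) -> TermAnnotation:
    """Read a 2-column (gene_id, term_id) TSV; header row optional."""
    mapping: dict[str, set[str]] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            gene_id, term_id = fields[0].strip(), fields[1].strip()
            if lineno == 1 and gene_id.lower() in ("gene", "gene_id") :
                continue  # header row
            mapping.setdefault(gene_id, set()).add(term_id)
            n_rows += 1
    if n_rows == 0:
        warnings.warn(f"{path}: empty term table", stacklevel=2)
    return TermAnnotation(mapping)


def write_term_table(annotation: TermAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for gene_id, terms in sorted(annotation.items()):
            for term in sorted(terms):
                fh.write(f"{gene_id}\t{term}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, kind: str) -> SequenceSet:
    """Read FASTA into a :class:`SequenceSet` with per-kind validation."""
    sset = SequenceSet(kind)
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sset:
            raise ValidationError(f"{path}: duplicate record id {record.id!r}")
        sset.add(record.id, str(record.seq))
    for gene_id, reason in sset.invalid.items():
        warnings.warn(f"{path}: {gene_id} excluded from selection analyses "
                      f"({reason})", stacklevel=2)
    return sset


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for gene_id in sequences:
            seq = sequences[gene_id]
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def translate_cds(cds: str) -> str:
    """Translate a frame-checked CDS (no terminal stop) to protein."""
    return str(Seq(cds).translate())
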