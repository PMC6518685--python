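"""Readers/writers for the standard formats the pipeline touches.

FASTA parsing is delegated to :mod:`Bio.SeqIO`; GFF3 parsing to
:mod:`gffutils`.  This module adds the domain types and the validation the
rest of the pipeline relies on: unique ids, alphabet checks, per-chromosome
gene ranks, exon-within-gene validation, and the tabular family report.

Coordinates are GFF3 1-based inclusive throughout and never converted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Malformed FASTA record (bad header, empty sequence, duplicate id)."""


class AlphabetError(ValueError):
    """Sequence contains characters outside the declared alphabet."""


class Gff3ValidationError(ValueError):
    """Structurally invalid gene model (e.g. exon outside the gene span)."""


class SchemaError(ValueError):
    """A tabular report is missing a mandatory column."""


class CdsMismatchError(ValueError):
    """CDS does not translate to its paired protein."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    seq: str


@dataclass(frozen=True)
class CodingSequenceRecord:
    id: str
    seq: str


@dataclass(frozen=True)
class GeneLocus:
    """A gene's genomic placement; ``rank`` is its ordinal among all genes
    on its chromosome sorted by ascending start (ties: end, then id)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    rank: int


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    mrna_id: str
    exons: tuple[tuple[int, int], ...]


def _validate_seq(rec_id: str, seq: str, alphabet: str) -> str:
    seq = seq.upper()
    if not seq:
        raise FastaParseError(f"record {rec_id!r}: empty sequence")
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
    bad = set(seq) - allowed
    if bad:
        raise AlphabetError(
            f"record {rec_id!r}: illegal {alphabet} characters {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path, alphabet: str = "protein"):
    """Read a FASTA file into :class:`ProteinRecord` or
    :class:`CodingSequenceRecord` objects.

    Sequences are upper-cased; duplicate ids and illegal characters are
    rejected.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    cls = ProteinRecord if alphabet == "protein" else CodingSequenceRecord
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(cls(id=rec.id, seq=_validate_seq(rec.id, str(rec.seq), alphabet)))
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_gff3(path: str | Path) -> tuple[list[GeneLocus], list[GeneModel]]:
    """Parse gene/mRNA/exon features from a GFF3 file.

    Returns loci with per-chromosome ranks assigned by ascending start
    (ties broken by ascending end, then lexicographic gene id), and one
    :class:`GeneModel` per gene using the first mRNA given in the input
    (recorded in ``mrna_id``).
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    raw: list[tuple[str, str, str, int, int]] = []
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        raw.append((gene.id, gene.seqid, gene.strand, gene.start, gene.end))
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            continue
        mrna = mrnas[0]
        exons = sorted(
            (e.start, e.end)
            for e in db.children(mrna, featuretype="exon", order_by="start")
        )
        for (s, e) in exons:
            if s < gene.start or e > gene.end:
                raise Gff3ValidationError(
                    f"gene {gene.id!r}: exon ({s},{e}) outside gene span "
                    f"({gene.start},{gene.end})"
                )
        if exons:
            models.append(GeneModel(gene_id=gene.id, mrna_id=mrna.id, exons=tuple(exons)))

    loci: list[GeneLocus] = []
    by_chrom: dict[str, list[tuple[str, str, str, int, int]]] = {}
    for row in raw:
        by_chrom.setdefault(row[1], []).append(row)
    for chrom in sorted(by_chrom):
        rows = sorted(by_chrom[chrom], key=lambda r: (r[3], r[4], r[0]))
        for rank, (gid, seqid, strand, start, end) in enumerate(rows, start=1):
            if start > end:
                raise Gff3ValidationError(f"gene {gid!r}: start > end")
            loci.append(GeneLocus(gid, seqid, strand, start, end, rank))
    return loci, models


def count_introns(model: GeneModel) -> int:
    """Number of introns = number of exons − 1."""
    return len(model.exons) - 1


def strip_terminal_stop(cds: str, code: dict[str, str] | None = None) -> str:
    """Remove one terminal stop codon, if present and in frame."""
    if code is None:
        from .kaks import GENETIC_CODE
        code = GENETIC_CODE
    if len(cds) % 3 == 0 and len(cds) >= 3 and code.get(cds[-3:]) == "*":
        return cds[:-3]
    return cds


def validate_cds_pairing(protein: ProteinRecord, cds: CodingSequenceRecord) -> str:
    """Check that ``cds`` translates to ``protein`` and return the CDS with
    any terminal stop removed.

    ``X`` in the protein is tolerated opposite N-containing codons; any other
    mismatch raises :class:`CdsMismatchError`.
    """
    seq = strip_terminal_stop(cds.seq)
    if len(seq) % 3 != 0:
        raise CdsMismatchError(
            f"{cds.id}: CDS length {len(seq)} not divisible by 3 after stop removal"
        )
    n_codons = len(seq) // 3
    if n_codons != len(protein.seq):
        raise CdsMismatchError(
            f"{cds.id}: {n_codons} codons vs protein length {len(protein.seq)}"
        )
    translated = str(Seq(seq).translate())
    for i, (aa_t, aa_p) in enumerate(zip(translated, protein.seq)):
        codon = seq[3 * i: 3 * i + 3]
        if aa_t == aa_p:
            continue
        if aa_p == "X" and ("N" in codon or aa_t == "X"):
            continue
        raise CdsMismatchError(
            f"{cds.id}: codon {i} ({codon}) translates to {aa_t!r}, protein has {aa_p!r}"
        )
    return seq


REPORT_COLUMNS = [
    "gene_id", "type", "ecm_spacing", "protein_length_aa", "cds_length_bp",
    "mw_kda", "pi", "intron_count", "chrom", "start", "end",
]


def write_family_report(rows: Sequence[dict], path: str | Path) -> pd.DataFrame:
    """Write the per-gene family report as TSV, stably sorted by type then
    gene id.  Missing mandatory columns raise :class:`SchemaError`."""
    for i, row in enumerate(rows):
        missing = [c for c in REPORT_COLUMNS if c not in row]
        if missing:
            raise SchemaError(f"row {i}: missing columns {missing}")
    df = pd.DataFrame(list(rows), columns=REPORT_COLUMNS)
    if len(df):
        df = df.sort_values(["type", "gene_id"], kind="stable").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n",
              quoting=csv.QUOTE_NONE)
    return df
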