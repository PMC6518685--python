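"""Promoter extraction and IUPAC cis-element scanning.

Motif sequences are user input (only the element-name → functional-category
mapping is bundled: A = hormone-related, B = stress-related, C =
growth/development-related).  Scanning is exact IUPAC matching on both
strands by default; overlapping matches are all reported.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

CATEGORIES = ("A", "B", "C")


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str       # IUPAC nucleotide codes
    category: str      # A | B | C

    def __post_init__(self):
        if not self.pattern:
            raise ValueError(f"motif {self.name!r}: empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name!r}: non-IUPAC codes {sorted(bad)}")
        if self.category not in CATEGORIES:
            raise ValueError(f"motif {self.name!r}: category must be one of {CATEGORIES}")


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    seq: str
    truncated: bool = False


@dataclass(frozen=True)
class PromoterHit:
    gene_id: str
    element: str
    strand: str
    start: int         # 1-based within the promoter (forward coordinates)


def load_category_map() -> dict[str, str]:
    """Bundled element-name → category mapping (endosperm elements excluded)."""
    src = importlib.resources.files("ltpscan.data") / "cis_element_categories.tsv"
    df = pd.read_csv(src.open(), sep="\t")
    return dict(zip(df["element"], df["category"]))


def read_motif_table(path: str | Path) -> list[MotifDef]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "pattern", "category"}
    if not required <= set(df.columns):
        raise ValueError(f"motif table missing columns {required - set(df.columns)}")
    return [MotifDef(r["name"], r["pattern"].upper(), r["category"])
            for _, r in df.iterrows()]


def extract_promoters(loci, genome: dict[str, str], length: int = 1500) -> list[Promoter]:
    """Per gene, the ``length``-bp window immediately 5' of the gene start on
    its strand (reverse-complemented for − strand genes); truncated at
    chromosome edges with a flag.
    """
    promoters = []
    for loc in loci:
        if loc.chrom not in genome:
            raise KeyError(f"gene {loc.gene_id!r}: chromosome {loc.chrom!r} "
                           "absent from the genome")
        chrom_seq = genome[loc.chrom].upper()
        if loc.strand == "+":
            lo = max(1, loc.start - length)
            hi = loc.start - 1
            window = chrom_seq[lo - 1: hi]
            truncated = loc.start - length < 1
        else:
            lo = loc.end + 1
            hi = min(len(chrom_seq), loc.end + length)
            window = str(Seq(chrom_seq[lo - 1: hi]).reverse_complement())
            truncated = loc.end + length > len(chrom_seq)
        promoters.append(Promoter(gene_id=loc.gene_id, seq=window, truncated=truncated))
    return promoters


def _iupac_match(window: str, pattern: str) -> bool:
    return all(base in IUPAC[code] for base, code in zip(window, pattern))


def _scan_strand(seq: str, pattern: str) -> list[int]:
    k = len(pattern)
    return [i for i in range(len(seq) - k + 1) if _iupac_match(seq[i:i + k], pattern)]


def scan_promoters(promoters: list[Promoter], motifs: list[MotifDef],
                   both_strands: bool = True) -> tuple[list[PromoterHit], pd.DataFrame]:
    """Exact IUPAC scan of every motif against every promoter.

    Returns all (overlapping) hits plus a per-gene table of hit counts per
    functional category.  Minus-strand hit starts are reported in forward
    promoter coordinates.
    """
    hits: list[PromoterHit] = []
    for prom in promoters:
        seq = prom.seq.upper()
        for motif in motifs:
            pattern = motif.pattern.upper()
            for i in _scan_strand(seq, pattern):
                hits.append(PromoterHit(prom.gene_id, motif.name, "+", i + 1))
            if both_strands:
                rc = str(Seq(pattern).reverse_complement())
                for i in _scan_strand(seq, rc):
                    hits.append(PromoterHit(prom.gene_id, motif.name, "-", i + 1))

    category_of = {m.name: m.category for m in motifs}
    rows = []
    for prom in promoters:
        counts = {c: 0 for c in CATEGORIES}
        for h in hits:
            if h.gene_id == prom.gene_id:
                counts[category_of[h.element]] += 1
        rows.append({"gene_id": prom.gene_id, **{f"category_{c}": counts[c]
                                                 for c in CATEGORIES},
                     "total": sum(counts.values())})
    return hits, pd.DataFrame(rows)
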