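"""Codon alignment and Nei–Gojobori (1986) Ka/Ks estimation.

Pipeline for a duplicated gene pair: global protein alignment
(Needleman–Wunsch, affine gaps, BLOSUM62) → back-translation to a codon
alignment → NG86 site/difference counting with path averaging → Jukes–Cantor
correction.  Codon columns containing gaps, stop codons, or ambiguity codes
are excluded from counting and their number reported.
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices


def _load_genetic_code() -> dict[str, str]:
    code = {}
    with (importlib.resources.files("ltpscan.data") / "genetic_code.tsv").open() as fh:
        next(fh)
        for line in fh:
            codon, aa = line.split()
            code[codon] = aa
    return code


GENETIC_CODE: dict[str, str] = _load_genetic_code()
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
_BASES = "TCAG"


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float


@dataclass(frozen=True)
class CodonAlignment:
    """Gapped codon strings; gaps come in whole-codon units."""

    codons_a: str
    codons_b: str

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon alignment rows differ in length")
        if len(self.codons_a) % 3 != 0:
            raise ValueError("codon alignment length not divisible by 3")


@dataclass(frozen=True)
class SiteCounts:
    S: float          # synonymous sites
    N: float          # nonsynonymous sites
    Sd: float         # synonymous differences
    Nd: float         # nonsynonymous differences
    skipped_codons: int = 0


@dataclass(frozen=True)
class KaKsEstimate:
    ka: float | None
    ks: float | None
    ratio: float | None
    saturated: bool = False


@dataclass(frozen=True)
class KaKsResult:
    """Full per-pair record: estimates plus selection call and dating."""

    gene_a: str
    gene_b: str
    mode: str                    # tandem | segmental
    ka: float | None
    ks: float | None
    ratio: float | None
    selection: str
    time_mya: float | None
    estimator: str = "NG86"


def _make_aligner(gap_open: float, gap_extend: float, matrix: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # gap of length L costs open + (L-1)*extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_proteins_global(a: str, b: str, matrix: str = "BLOSUM62",
                          gap_open: float = 10.0,
                          gap_extend: float = 0.5) -> PairwiseAlignment:
    """Needleman–Wunsch global alignment with affine gaps.

    Deterministic: the first optimal alignment in Biopython's fixed
    traceback order is returned.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(aligned_a=str(aln[0]), aligned_b=str(aln[1]),
                             score=aln.score)


def backtranslate_alignment(protein_aln: PairwiseAlignment,
                            cds_a: str, cds_b: str) -> CodonAlignment:
    """Map each protein alignment column to a codon column; protein gaps
    become ``---``.  CDS must translate to the de-gapped proteins."""
    def build(aligned_protein: str, cds: str) -> str:
        n_res = sum(1 for ch in aligned_protein if ch != "-")
        if len(cds) != 3 * n_res:
            raise ValueError(
                f"CDS length {len(cds)} != 3 × {n_res} aligned residues")
        out, i = [], 0
        for idx, ch in enumerate(aligned_protein):
            if ch == "-":
                out.append("---")
            else:
                codon = cds[3 * i: 3 * i + 3]
                aa = GENETIC_CODE.get(codon)
                if aa is not None and aa != "*" and ch not in ("X", aa):
                    raise ValueError(
                        f"codon {i} ({codon}→{aa}) does not match aligned residue "
                        f"{ch!r} at column {idx}")
                out.append(codon)
                i += 1
        return "".join(out)

    return CodonAlignment(build(protein_aln.aligned_a, cds_a),
                          build(protein_aln.aligned_b, cds_b))


def synonymous_site_fraction(codon: str) -> float:
    """NG86 synonymous sites of one codon: over the 3 positions, the fraction
    of one-step changes that preserve the amino acid (changes to stop codons
    count as nonsynonymous)."""
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if GENETIC_CODE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons,
    averaged over all orderings of single-nucleotide steps; paths through
    stop codons are excluded (all-path fallback if none survive)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[int, int]] = []       # (syn steps, nonsyn steps)
    stopless: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nsyn = 0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                hits_stop = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        paths.append((syn, nsyn))
        if not hits_stop:
            stopless.append((syn, nsyn))
    use = stopless if stopless else paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _codon_ok(codon: str) -> bool:
    return ("-" not in codon and codon in GENETIC_CODE
            and GENETIC_CODE[codon] != "*")


def ng86_counts(alignment: CodonAlignment) -> SiteCounts:
    """Nei–Gojobori site and difference counts over a codon alignment.

    Site totals are averaged between the two sequences; codon columns with
    gaps, stops, or ambiguity codes are skipped and counted.
    """
    S = N = Sd = Nd = 0.0
    skipped = 0
    for i in range(0, len(alignment.codons_a), 3):
        ca = alignment.codons_a[i:i + 3]
        cb = alignment.codons_b[i:i + 3]
        if not (_codon_ok(ca) and _codon_ok(cb)):
            skipped += 1
            continue
        s_a = synonymous_site_fraction(ca)
        s_b = synonymous_site_fraction(cb)
        S += 0.5 * (s_a + s_b)
        N += 3.0 - 0.5 * (s_a + s_b)
        sd, nd = _codon_pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    return SiteCounts(S=S, N=N, Sd=Sd, Nd=Nd, skipped_codons=skipped)


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None at saturation (p ≥ 3/4)."""
    if p < 0:
        raise ValueError("proportion cannot be negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks_estimate(counts: SiteCounts) -> KaKsEstimate:
    """Ka and Ks from NG86 counts with Jukes–Cantor correction."""
    if counts.S <= 0 or counts.N <= 0:
        raise ValueError("site counts must be positive")
    ka = jukes_cantor(counts.Nd / counts.N)
    ks = jukes_cantor(counts.Sd / counts.S)
    if ka is None or ks is None:
        return KaKsEstimate(ka=ka, ks=ks, ratio=None, saturated=True)
    ratio = ka / ks if ks > 0 else None
    return KaKsEstimate(ka=ka, ks=ks, ratio=ratio)


def analyze_pair(protein_a: str, protein_b: str, cds_a: str, cds_b: str) -> tuple[SiteCounts, KaKsEstimate]:
    """Align, back-translate, and estimate Ka/Ks for one gene pair."""
    aln = align_proteins_global(protein_a, protein_b)
    codon_aln = backtranslate_alignment(aln, cds_a, cds_b)
    counts = ng86_counts(codon_aln)
    return counts, kaks_estimate(counts)
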