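"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators: proteomes with planted eight-cysteine motifs plus decoys
probing each classifier failure mode; chromosome gene maps with planted
tandem clusters and decoy pairs that each violate exactly one clause of the
pair rule; and coding-sequence pairs with controlled synonymous and
nonsynonymous divergence.  All randomness flows from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecm_classifier import ScanConfig, TypeTemplate, load_templates
from .io_formats import CodingSequenceRecord, GeneLocus, ProteinRecord
from .kaks import GENETIC_CODE, STOP_CODONS, synonymous_site_fraction

NON_CYS_RESIDUES = "ADEFGHIKLMNPQRSTVWY"   # 19 letters, spacers stay Cys-free
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(GENETIC_CODE.items()):
    if _aa != "*":
        _CODONS_FOR.setdefault(_aa, []).append(_codon)

DECOY_CLASSES = ("missing_cys", "bad_spacer", "no_cys")


@dataclass
class TruthTable:
    """Per-record ground truth for one generated dataset."""

    rows: list[dict] = field(default_factory=list)
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NON_CYS_RESIDUES), size=length))


def _ecm_from_spacers(rng: np.random.Generator, spacers) -> str:
    s1, s2, s3, s4, s5 = spacers
    return ("C" + _random_protein(rng, s1)
            + "C" + _random_protein(rng, s2)
            + "CC" + _random_protein(rng, s3)
            + "C" + _random_protein(rng, 1)
            + "C" + _random_protein(rng, s4)
            + "C" + _random_protein(rng, s5)
            + "C")


def _cds_for_protein(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein)


def _out_of_range_value(slot: int, templates, config: ScanConfig,
                        rng: np.random.Generator) -> int:
    allowed_union = set()
    for t in templates:
        allowed_union |= t.allowed[slot]
    candidates = [v for v in range(config.min_spacer, config.max_spacer + 1)
                  if v not in allowed_union]
    if not candidates:
        raise ValueError(f"no out-of-range spacer value available for slot {slot + 1}")
    return int(rng.choice(candidates))


def generate_proteome(composition: dict[str, int], n_decoys: int, seed: int,
                      templates: list[TypeTemplate] | None = None,
                      config: ScanConfig = ScanConfig(),
                      ) -> tuple[list[ProteinRecord], list[CodingSequenceRecord], TruthTable]:
    """Generate a proteome of planted family proteins plus decoys.

    Family proteins get spacers drawn uniformly from their template's allowed
    sets, cysteine-free leaders (20–35 aa) and tails (0–20 aa).  Decoys cycle
    through three classes: a family-like protein with one motif cysteine
    mutated away; one with a spacer outside every template's range; and a
    cysteine-free random protein.  CDS are uniform random codon choices.
    """
    if templates is None:
        templates = load_templates()
    by_name = {t.type_name: t for t in templates}
    unknown = [k for k in composition if k not in by_name]
    if unknown:
        raise KeyError(f"composition names unknown types: {unknown}")

    rng = np.random.default_rng(seed)
    proteins: list[ProteinRecord] = []
    cds: list[CodingSequenceRecord] = []
    truth = TruthTable(seed=seed)

    def finish(rec_id: str, core: str, category: str, true_type, spacers):
        leader = _random_protein(rng, int(rng.integers(20, 36)))
        tail = _random_protein(rng, int(rng.integers(0, 21)))
        seq = leader + core + tail
        proteins.append(ProteinRecord(rec_id, seq))
        cds.append(CodingSequenceRecord(rec_id, _cds_for_protein(rng, seq)))
        truth.rows.append({
            "record_id": rec_id, "category": category,
            "true_type": true_type if true_type is not None else "",
            "spacers": ",".join(map(str, spacers)) if spacers else "",
        })

    counter = 0
    for type_name in sorted(composition):
        for _ in range(composition[type_name]):
            counter += 1
            template = by_name[type_name]
            spacers = tuple(int(rng.choice(sorted(a))) for a in template.allowed)
            finish(f"fam{counter:04d}", _ecm_from_spacers(rng, spacers),
                   "family", type_name, spacers)

    for i in range(n_decoys):
        decoy_class = DECOY_CLASSES[i % len(DECOY_CLASSES)]
        rec_id = f"decoy{i + 1:04d}"
        template = by_name[
            sorted(by_name)[int(rng.integers(0, len(by_name)))]]
        if decoy_class == "missing_cys":
            spacers = tuple(int(rng.choice(sorted(a))) for a in template.allowed)
            core = list(_ecm_from_spacers(rng, spacers))
            cys_idx = [j for j, ch in enumerate(core) if ch == "C"]
            core[int(rng.choice(cys_idx))] = str(rng.choice(list(NON_CYS_RESIDUES)))
            finish(rec_id, "".join(core), decoy_class, None, ())
        elif decoy_class == "bad_spacer":
            spacers = [int(rng.choice(sorted(a))) for a in template.allowed]
            slot = int(rng.integers(0, 5))
            spacers[slot] = _out_of_range_value(slot, templates, config, rng)
            finish(rec_id, _ecm_from_spacers(rng, spacers), decoy_class,
                   None, tuple(spacers))
        else:
            finish(rec_id, _random_protein(rng, int(rng.integers(60, 160))),
                   decoy_class, None, ())
    return proteins, cds, truth


@dataclass(frozen=True)
class ClusterSpec:
    """A planted tandem cluster: ``size`` family genes; every rank-adjacent
    pair separated by ``intervening`` background genes within ``pair_bp``."""

    size: int
    intervening: int = 0
    pair_bp: int = 20_000

    def validate(self, max_intervening: int = 5, max_distance: int = 100_000):
        if self.size < 2:
            raise ValueError("cluster size must be ≥ 2")
        if self.intervening > max_intervening or self.pair_bp > max_distance:
            raise ValueError(
                f"cluster spec ({self.intervening} intervening, {self.pair_bp} bp) "
                "violates the rule it claims to satisfy")


@dataclass(frozen=True)
class DecoyPairSpec:
    """Two family genes violating exactly one clause of the pair rule:
    ``intervening`` (too many genes between, but close) or ``distance``
    (adjacent ranks, but too far apart)."""

    violation: str
    intervening: int = 6
    pair_bp: int = 50_000

    def validate(self, max_intervening: int = 5, max_distance: int = 100_000):
        if self.violation == "intervening":
            if not (self.intervening > max_intervening and self.pair_bp <= max_distance):
                raise ValueError("intervening decoy must violate only the gene-count clause")
        elif self.violation == "distance":
            if not (self.intervening <= max_intervening and self.pair_bp > max_distance):
                raise ValueError("distance decoy must violate only the distance clause")
        else:
            raise ValueError(f"unknown violation {self.violation!r}")


GENE_LEN = 1000
UNIT_PAD_BP = 400_000      # distance between placed units: fails the bp clause
UNIT_PAD_GENES = 8         # background genes between units: fails the count clause


def generate_gene_map(n_chromosomes: int, cluster_specs: list[ClusterSpec],
                      decoy_specs: list[DecoyPairSpec], seed: int,
                      n_isolated_family: int = 0,
                      max_intervening: int = 5, max_distance: int = 100_000,
                      ) -> tuple[str, list[GeneLocus], TruthTable]:
    """Lay out family genes and background genes on chromosomes.

    Planted clusters obey the tandem pair rule between rank-adjacent members;
    decoy pairs violate exactly one clause; isolated family genes and unit
    padding are spaced so no accidental qualifying pair arises.  Returns the
    GFF3 text, the loci (with ranks), and the truth table.
    """
    for spec in cluster_specs:
        spec.validate(max_intervening, max_distance)
    for spec in decoy_specs:
        spec.validate(max_intervening, max_distance)

    rng = np.random.default_rng(seed)
    # chromosome -> list of (gene_id, start)
    chrom_genes: dict[str, list[tuple[str, int]]] = {
        f"chr{i + 1:02d}": [] for i in range(n_chromosomes)}
    chrom_cursor = {c: 50_000 for c in chrom_genes}
    truth = TruthTable(seed=seed)
    fam_counter = bg_counter = 0

    def next_chrom(unit_idx: int) -> str:
        return f"chr{(unit_idx % n_chromosomes) + 1:02d}"

    def place_background(chrom: str, pos: int) -> int:
        nonlocal bg_counter
        bg_counter += 1
        chrom_genes[chrom].append((f"bg{bg_counter:05d}", pos))
        return pos

    def place_family(chrom: str, pos: int, cluster_id: str | None,
                     truth_category: str) -> str:
        nonlocal fam_counter
        fam_counter += 1
        gid = f"fam{fam_counter:04d}"
        chrom_genes[chrom].append((gid, pos))
        truth.rows.append({"record_id": gid, "category": truth_category,
                           "cluster_id": cluster_id or "", "chrom": chrom})
        return gid

    def pad_unit(chrom: str):
        """Background-gene buffer so consecutive units can never pair."""
        pos = chrom_cursor[chrom]
        for _ in range(UNIT_PAD_GENES):
            pos += UNIT_PAD_BP // UNIT_PAD_GENES
            place_background(chrom, pos)
        chrom_cursor[chrom] = pos + UNIT_PAD_BP

    unit_idx = 0
    for ci, spec in enumerate(cluster_specs, start=1):
        chrom = next_chrom(unit_idx)
        unit_idx += 1
        cluster_id = f"cluster{ci:02d}"
        pos = chrom_cursor[chrom]
        place_family(chrom, pos, cluster_id, "cluster_member")
        for _ in range(spec.size - 1):
            step = spec.pair_bp // (spec.intervening + 1)
            for _ in range(spec.intervening):
                pos += step
                place_background(chrom, pos)
            pos += spec.pair_bp - spec.intervening * step
            place_family(chrom, pos, cluster_id, "cluster_member")
        chrom_cursor[chrom] = pos
        pad_unit(chrom)

    for di, spec in enumerate(decoy_specs, start=1):
        chrom = next_chrom(unit_idx)
        unit_idx += 1
        pos = chrom_cursor[chrom]
        place_family(chrom, pos, None, f"decoy_{spec.violation}")
        step = spec.pair_bp // (spec.intervening + 1)
        for _ in range(spec.intervening):
            pos += step
            place_background(chrom, pos)
        pos += spec.pair_bp - spec.intervening * step
        place_family(chrom, pos, None, f"decoy_{spec.violation}")
        chrom_cursor[chrom] = pos
        pad_unit(chrom)

    for _ in range(n_isolated_family):
        chrom = next_chrom(unit_idx)
        unit_idx += 1
        place_family(chrom, chrom_cursor[chrom], None, "isolated")
        pad_unit(chrom)

    loci: list[GeneLocus] = []
    gff_lines = ["##gff-version 3"]
    for chrom in sorted(chrom_genes):
        genes = sorted(chrom_genes[chrom], key=lambda g: g[1])
        for rank, (gid, start) in enumerate(genes, start=1):
            end = start + GENE_LEN - 1
            loci.append(GeneLocus(gid, chrom, "+", start, end, rank))
            gff_lines.append(
                f"{chrom}\tltpscan\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}")
            gff_lines.append(
                f"{chrom}\tltpscan\tmRNA\t{start}\t{end}\t.\t+\t.\t"
                f"ID={gid}.1;Parent={gid}")
            gff_lines.append(
                f"{chrom}\tltpscan\texon\t{start}\t{end}\t.\t+\t.\t"
                f"ID={gid}.1.exon1;Parent={gid}.1")
    return "\n".join(gff_lines) + "\n", loci, truth


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    sense = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
    return "".join(rng.choice(sense) for _ in range(n_codons))


def _single_step_changes(cds: str, synonymous: bool) -> list[tuple[int, str]]:
    """All (position, new_base) single-nucleotide changes of the requested
    kind that do not create a stop codon."""
    out = []
    for ci in range(0, len(cds), 3):
        codon = cds[ci:ci + 3]
        aa = GENETIC_CODE[codon]
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1:]
                alt_aa = GENETIC_CODE[alt]
                if alt_aa == "*":
                    continue
                if (alt_aa == aa) == synonymous:
                    out.append((ci + pos, base))
    return out


def _mutate_lineage(rng: np.random.Generator, cds: str,
                    n_syn: int, n_nonsyn: int) -> tuple[str, int, int]:
    """Apply the requested numbers of synonymous/nonsynonymous substitutions,
    choosing uniformly among currently available one-step changes; stops are
    never created (stop-creating proposals are excluded up front)."""
    seq = list(cds)
    applied_syn = applied_nonsyn = 0
    for kind, count in (("syn", n_syn), ("nonsyn", n_nonsyn)):
        for _ in range(count):
            options = _single_step_changes("".join(seq), kind == "syn")
            if not options:
                break
            pos, base = options[int(rng.integers(0, len(options)))]
            seq[pos] = base
            if kind == "syn":
                applied_syn += 1
            else:
                applied_nonsyn += 1
    return "".join(seq), applied_syn, applied_nonsyn


def simulate_codon_pair(n_codons: int, target_ks: float, target_ka: float,
                        seed: int) -> tuple[str, str, TruthTable]:
    """Evolve two descendants from a random ancestor CDS with Poisson numbers
    of synonymous/nonsynonymous substitutions (expected per-site totals
    ``target_ks``/``target_ka`` split evenly between lineages).

    The truth table records the ancestor's NG86 site counts and the realized
    per-site substitution loads.
    """
    if not (0 <= target_ks < 0.75 and 0 <= target_ka < 0.75):
        raise ValueError("targets must be below Jukes–Cantor saturation (3/4)")
    rng = np.random.default_rng(seed)
    ancestor = _random_cds(rng, n_codons)
    S = sum(synonymous_site_fraction(ancestor[i:i + 3])
            for i in range(0, len(ancestor), 3))
    N = 3 * n_codons - S

    descendants = []
    total_syn = total_nonsyn = 0
    for _ in range(2):
        n_syn = rng.poisson(target_ks / 2.0 * S)
        n_nonsyn = rng.poisson(target_ka / 2.0 * N)
        seq, a_syn, a_nonsyn = _mutate_lineage(rng, ancestor, n_syn, n_nonsyn)
        descendants.append(seq)
        total_syn += a_syn
        total_nonsyn += a_nonsyn

    truth = TruthTable(seed=seed)
    truth.rows.append({
        "n_codons": n_codons, "S_anc": S, "N_anc": N,
        "syn_events": total_syn, "nonsyn_events": total_nonsyn,
        "realized_ks": total_syn / S, "realized_ka": total_nonsyn / N,
        "target_ks": target_ks, "target_ka": target_ka,
        "ancestor": ancestor,
    })
    return descendants[0], descendants[1], truth
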