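"""End-to-end orchestration: classify → characterize → duplications → Ka/Ks
→ tree → promoters, driven by a flat key-value config file.

Every output is a plain-text table (TSV) or Newick; the log narrates each
filtering decision (no-ECM, unclassified, skipped codon columns) and the
seed is recorded in every report header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import duplication, ecm_classifier, kaks, physchem, phylo
from .io_formats import (read_fasta, read_gff3, count_introns,
                         validate_cds_pairing, write_family_report)

logger = logging.getLogger(__name__)

ALL_STAGES = ("classify", "characterize", "duplication", "kaks", "tree", "promoters")


@dataclass
class RunConfig:
    proteome: str = ""
    cds: str = ""
    gff: str = ""
    genome: str = ""
    motifs: str = ""
    anchors: str = ""
    templates: str = ""                 # empty -> bundled registry
    out_dir: str = "ltpscan_out"
    min_spacer: int = 3
    max_spacer: int = 40
    max_intervening: int = duplication.DEFAULT_MAX_INTERVENING
    max_distance: int = duplication.DEFAULT_MAX_DISTANCE
    neutral_rate: float = duplication.DEFAULT_NEUTRAL_RATE
    bootstrap: int = 1000
    promoter_length: int = 1500
    seed: int = 0
    stages: tuple = ALL_STAGES

    def __post_init__(self):
        if self.max_intervening < 0 or self.max_distance <= 0:
            raise ValueError("duplication thresholds must be positive")
        if self.neutral_rate <= 0 or self.bootstrap < 0:
            raise ValueError("neutral rate and bootstrap count must be positive")


_INT_KEYS = {"min_spacer", "max_spacer", "max_intervening", "max_distance",
             "bootstrap", "promoter_length", "seed"}
_FLOAT_KEYS = {"neutral_rate"}


def parse_config(path: str | Path, **overrides) -> RunConfig:
    """Flat ``key = value`` config file; unknown keys rejected; keyword
    overrides (CLI flags) win over file values."""
    valid = {f.name for f in fields(RunConfig)}
    kwargs: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key == "stages":
                kwargs[key] = tuple(s.strip() for s in value.split(",") if s.strip())
            elif key in _INT_KEYS:
                kwargs[key] = int(value)
            elif key in _FLOAT_KEYS:
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def filter_expressed(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop genes whose expression is zero across all conditions (rows of
    all-zero values); negative values are rejected; order preserved."""
    if (matrix.values < 0).any():
        raise ValueError("expression values cannot be negative")
    if matrix.empty:
        return matrix.copy()
    keep = (matrix != 0).any(axis=1)
    return matrix.loc[keep].copy()


def summarize_types(results: list) -> pd.DataFrame:
    """Member count, realized spacing-pattern string, and percentage share
    per assigned type (classified proteins only), in compact range syntax.
    """
    classified = [r for r in results
                  if r.assigned_type not in ("no_ecm", "unclassified")]
    by_type: dict[str, list] = {}
    for r in classified:
        by_type.setdefault(r.assigned_type, []).append(r)
    total = len(classified)
    rows = []
    for type_name in sorted(by_type, key=_type_sort_key):
        members = by_type[type_name]
        spacer_sets = [set() for _ in range(5)]
        for r in members:
            if r.best_match is not None:
                for k, s in enumerate(r.best_match.spacers):
                    spacer_sets[k].add(s)
        fmt = ecm_classifier.format_allowed
        pattern = (f"CX{fmt(spacer_sets[0])}CX{fmt(spacer_sets[1])}"
                   f"CCX{fmt(spacer_sets[2])}CXCX{fmt(spacer_sets[3])}"
                   f"CX{fmt(spacer_sets[4])}C") if members else ""
        rows.append({"type": type_name, "count": len(members),
                     "spacing_pattern": pattern,
                     "percent": round(100.0 * len(members) / total, 2)})
    return pd.DataFrame(rows, columns=["type", "count", "spacing_pattern", "percent"])


_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6, "VII": 7,
          "VIII": 8, "IX": 9, "X": 10, "XI": 11, "XII": 12, "XIII": 13}


def _type_sort_key(name: str):
    return (_ROMAN.get(name, 99), name)


def _check_stage_inputs(config: RunConfig) -> None:
    requirements = {
        "classify": ["proteome"],
        "characterize": ["proteome"],
        "duplication": ["gff"],
        "kaks": ["proteome", "cds", "gff"],
        "tree": ["proteome"],
        "promoters": ["gff", "genome", "motifs"],
    }
    problems = []
    for stage in config.stages:
        if stage not in ALL_STAGES:
            problems.append(f"unknown stage {stage!r}")
            continue
        for key in requirements[stage]:
            if not getattr(config, key):
                problems.append(f"stage {stage!r} requires config key {key!r}")
    if problems:
        raise ValueError("; ".join(problems))


def _header(config: RunConfig) -> str:
    return f"# ltpscan run; seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def run(config: RunConfig) -> dict:
    """Execute the enabled stages; returns a bundle of in-memory results and
    writes the report files under ``config.out_dir``."""
    _check_stage_inputs(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}

    scan_config = ecm_classifier.ScanConfig(
        min_spacer=config.min_spacer, max_spacer=config.max_spacer)
    templates = (ecm_classifier.load_templates(config.templates or None))

    results = None
    if "classify" in config.stages or "characterize" in config.stages \
            or "tree" in config.stages or "kaks" in config.stages:
        proteome = read_fasta(config.proteome, "protein")
        results, summary = ecm_classifier.classify_proteome(
            proteome, templates, config=scan_config)
        n_no_ecm = sum(1 for r in results if r.assigned_type == "no_ecm")
        n_uncls = sum(1 for r in results if r.assigned_type == "unclassified")
        logger.info("classified %d proteins: %d no-ECM, %d unclassified",
                    len(results), n_no_ecm, n_uncls)
        bundle["classifications"] = results
        bundle["type_summary"] = summarize_types(results)
        if "classify" in config.stages:
            _write_tsv(bundle["type_summary"], out_dir / "type_summary.tsv", config)
        by_id = {p.id: p for p in proteome}
        bundle["proteome"] = by_id

    family_ids = []
    if results is not None:
        family_ids = [r.protein_id for r in results
                      if r.assigned_type not in ("no_ecm", "unclassified")]
    bundle["family_ids"] = family_ids

    loci = models = None
    if "duplication" in config.stages or "kaks" in config.stages \
            or "promoters" in config.stages:
        loci, models = read_gff3(config.gff)
        bundle["loci"] = loci

    if "characterize" in config.stages:
        rows = []
        intron_by_gene = {m.gene_id: count_introns(m) for m in (models or [])}
        locus_by_gene = {l.gene_id: l for l in (loci or [])}
        for r in results:
            if r.assigned_type in ("no_ecm", "unclassified"):
                continue
            seq = bundle["proteome"][r.protein_id].seq
            try:
                pc = physchem.characterize(seq)
                mw, pi = round(pc.mw, 2), round(pc.pi, 2)
            except ValueError:
                mw = pi = float("nan")
            loc = locus_by_gene.get(r.protein_id)
            rows.append({
                "gene_id": r.protein_id, "type": r.assigned_type,
                "ecm_spacing": ",".join(map(str, r.best_match.spacers)),
                "protein_length_aa": len(seq),
                "cds_length_bp": 3 * len(seq),
                "mw_kda": mw, "pi": pi,
                "intron_count": intron_by_gene.get(r.protein_id, ""),
                "chrom": loc.chrom if loc else "",
                "start": loc.start if loc else "",
                "end": loc.end if loc else "",
            })
        bundle["family_report"] = write_family_report(
            rows, out_dir / "family_report.tsv")

    clusters = []
    if "duplication" in config.stages:
        known = {l.gene_id for l in loci}
        callable_ids = [g for g in family_ids if g in known]
        dropped = len(family_ids) - len(callable_ids)
        if dropped:
            logger.info("%d family genes absent from the annotation", dropped)
        clusters = duplication.find_tandem_clusters(
            callable_ids, loci, config.max_intervening, config.max_distance)
        bundle["tandem_clusters"] = clusters
        cluster_df = pd.DataFrame(
            [{"cluster": i + 1, "chrom": c.chrom, "members": ",".join(c.members)}
             for i, c in enumerate(clusters)])
        _write_tsv(cluster_df, out_dir / "tandem_clusters.tsv", config)
        logger.info("found %d tandem clusters covering %d genes",
                    len(clusters), sum(len(c.members) for c in clusters))

    if "kaks" in config.stages:
        cds_records = {c.id: c for c in read_fasta(config.cds, "nucleotide")}
        pairs: list[tuple[str, str, str]] = []
        for c in clusters:
            pairs.extend((a, b, "tandem") for a, b in duplication.cluster_pairs(c))
        if config.anchors:
            for p in duplication.load_segmental_anchors(config.anchors, family_ids):
                pairs.append((p.gene_a, p.gene_b, "segmental"))
        kaks_rows = []
        for gene_a, gene_b, mode in pairs:
            prot_a = bundle["proteome"][gene_a]
            prot_b = bundle["proteome"][gene_b]
            cds_a = validate_cds_pairing(prot_a, cds_records[gene_a])
            cds_b = validate_cds_pairing(prot_b, cds_records[gene_b])
            counts, est = kaks.analyze_pair(prot_a.seq, prot_b.seq, cds_a, cds_b)
            if counts.skipped_codons:
                logger.info("pair %s/%s: %d codon columns skipped",
                            gene_a, gene_b, counts.skipped_codons)
            selection = duplication.categorize_selection(est.ka, est.ks)
            time_mya = (duplication.divergence_time(est.ks, config.neutral_rate)
                        if est.ks is not None else None)
            kaks_rows.append({
                "gene_a": gene_a, "gene_b": gene_b, "mode": mode,
                "ka": _fmt(est.ka), "ks": _fmt(est.ks),
                "ka_ks": _fmt(est.ratio), "selection": selection,
                "time_mya": round(time_mya, 2) if time_mya is not None else "NA",
                "estimator": "NG86",
            })
        bundle["kaks_table"] = pd.DataFrame(kaks_rows)
        _write_tsv(bundle["kaks_table"], out_dir / "kaks_pairs.tsv", config)

    if "tree" in config.stages and len(family_ids) >= 3:
        matches = [(r.protein_id, r.best_match) for r in results
                   if r.protein_id in set(family_ids) and r.best_match is not None]
        aligned = phylo.anchored_ecm_alignment(matches)
        tree = phylo.bootstrap_support(aligned, n_replicates=config.bootstrap,
                                       seed=config.seed)
        bundle["tree"] = tree
        with open(out_dir / "tree.nwk", "w") as fh:
            fh.write(tree.to_newick() + "\n")

    if "promoters" in config.stages:
        from . import promoter_elements
        genome = {r.id: r.seq for r in read_fasta(config.genome, "nucleotide")}
        motifs = promoter_elements.read_motif_table(config.motifs)
        family_loci = [l for l in loci if not family_ids or l.gene_id in set(family_ids)]
        promoters = promoter_elements.extract_promoters(
            family_loci, genome, config.promoter_length)
        hits, counts = promoter_elements.scan_promoters(promoters, motifs)
        bundle["promoter_hits"] = hits
        bundle["promoter_counts"] = counts
        hits_df = pd.DataFrame([{"gene_id": h.gene_id, "element": h.element,
                                 "strand": h.strand, "start": h.start}
                                for h in hits])
        _write_tsv(hits_df, out_dir / "promoter_hits.tsv", config)
        _write_tsv(counts, out_dir / "promoter_counts.tsv", config)

    return bundle


def _fmt(x: float | None) -> str | float:
    return "NA" if x is None else round(x, 5)
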