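"""Eight-cysteine-motif (ECM) detection and type classification.

The ECM skeleton is ``C-Xn-C-Xn-CC-Xn-CXC-Xn-C-Xn-C``: eight cysteines with
five variable spacers (s1..s5).  A family type is a named set of allowed
lengths for each spacer; a protein is assigned the type whose template
admits the spacers of its motif.  Proteins whose motif fits no template can
optionally be rescued by percent-identity against reference ECM sequences
(the route by which novel types are erected).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

DEFAULT_TYPE_ORDER = ("I", "II", "IV", "V", "VII", "VIII", "XII", "XIII")


@dataclass(frozen=True)
class EcmMatch:
    """One positional assignment of the 8 motif cysteines.

    ``cys_positions`` are ascending 0-based indices (c1..c8); spacers are
    s1 = c2−c1−1, s2 = c3−c2−1, s3 = c5−c4−1, s4 = c7−c6−1, s5 = c8−c7−1
    (c3/c4 form the CC block, c5/c6 the CXC block).
    """

    cys_positions: tuple[int, int, int, int, int, int, int, int]
    spacers: tuple[int, int, int, int, int]
    ecm_seq: str


@dataclass(frozen=True)
class TypeTemplate:
    type_name: str
    allowed: tuple[frozenset, frozenset, frozenset, frozenset, frozenset]

    def admits(self, spacers: tuple[int, ...]) -> bool:
        return all(s in a for s, a in zip(spacers, self.allowed))


@dataclass(frozen=True)
class ClassificationResult:
    protein_id: str
    best_match: EcmMatch | None
    matched_types: tuple[str, ...]
    assigned_type: str            # a type name, "unclassified" or "no_ecm"
    method: str                   # "spacing" | "similarity" | "none"
    similarity_identity: float | None = None


@dataclass(frozen=True)
class ScanConfig:
    """Global per-spacer scan bounds applied before template matching."""

    min_spacer: int = 3
    max_spacer: int = 40
    allow_cys_in_spacers: bool = False
    similarity_threshold: float = 50.0

    @property
    def bounds(self) -> tuple[tuple[int, int], ...]:
        return tuple((self.min_spacer, self.max_spacer) for _ in range(5))


def _parse_allowed(spec: str) -> frozenset:
    """Parse an allowed-set spec like ``"6..10,13"`` or ``"3,13,14"``."""
    values: set[int] = set()
    for token in spec.split(","):
        token = token.strip()
        if ".." in token:
            lo, hi = token.split("..")
            values.update(range(int(lo), int(hi) + 1))
        else:
            values.add(int(token))
    if not values:
        raise ValueError(f"empty allowed set: {spec!r}")
    return frozenset(values)


def format_allowed(values: frozenset | set) -> str:
    """Inverse of :func:`_parse_allowed`: compact ``a–b`` range syntax with an
    en dash, as printed in family-survey summary tables."""
    out: list[str] = []
    run: list[int] = []
    for v in sorted(values):
        if run and v == run[-1] + 1:
            run.append(v)
        else:
            if run:
                out.append(_format_run(run))
            run = [v]
    if run:
        out.append(_format_run(run))
    return ",".join(out)


def _format_run(run: list[int]) -> str:
    if len(run) == 1:
        return str(run[0])
    return f"{run[0]}–{run[-1]}"


def load_templates(path: str | Path | None = None) -> list[TypeTemplate]:
    """Load the type-template registry (bundled potato defaults if no path)."""
    if path is None:
        source = importlib.resources.files("ltpscan.data") / "templates.tsv"
        df = pd.read_csv(source.open(), sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"type_name", "s1", "s2", "s3", "s4", "s5"}
    if not required <= set(df.columns):
        raise ValueError(f"template registry missing columns {required - set(df.columns)}")
    templates = []
    for _, row in df.iterrows():
        templates.append(TypeTemplate(
            type_name=row["type_name"],
            allowed=tuple(_parse_allowed(row[f"s{i}"]) for i in range(1, 6)),
        ))
    return templates


def find_ecm_matches(seq: str, config: ScanConfig = ScanConfig()) -> list[EcmMatch]:
    """Enumerate every 8-cysteine assignment satisfying the ECM structure.

    Constraints: c4 = c3+1 (CC), c6 = c5+2 with a non-cysteine between (CXC),
    spacers cysteine-free unless ``allow_cys_in_spacers``, and every spacer
    within the configured global bounds.  Matches are ordered by c1 then c8.
    """
    cys = [i for i, ch in enumerate(seq) if ch == "C"]
    if len(cys) < 8:
        return []
    b = config.bounds
    allow = config.allow_cys_in_spacers
    cys_set = set(cys)

    def spacer_ok(lo_pos: int, hi_pos: int, slot: int) -> bool:
        length = hi_pos - lo_pos - 1
        if not (b[slot][0] <= length <= b[slot][1]):
            return False
        if not allow and any(p in cys_set for p in range(lo_pos + 1, hi_pos)):
            return False
        return True

    matches: list[EcmMatch] = []
    n = len(cys)
    for i1 in range(n):
        c1 = cys[i1]
        for i2 in range(i1 + 1, n):
            c2 = cys[i2]
            if not spacer_ok(c1, c2, 0):
                continue
            for i3 in range(i2 + 1, n):
                c3 = cys[i3]
                if not spacer_ok(c2, c3, 1):
                    continue
                c4 = c3 + 1
                if c4 not in cys_set:
                    continue
                i4 = cys.index(c4)
                for i5 in range(i4 + 1, n):
                    c5 = cys[i5]
                    if not spacer_ok(c4, c5, 2):
                        continue
                    c6 = c5 + 2
                    if c6 not in cys_set or seq[c5 + 1] == "C":
                        continue
                    i6 = cys.index(c6)
                    for i7 in range(i6 + 1, n):
                        c7 = cys[i7]
                        if not spacer_ok(c6, c7, 3):
                            continue
                        for i8 in range(i7 + 1, n):
                            c8 = cys[i8]
                            if not spacer_ok(c7, c8, 4):
                                continue
                            positions = (c1, c2, c3, c4, c5, c6, c7, c8)
                            spacers = (c2 - c1 - 1, c3 - c2 - 1, c5 - c4 - 1,
                                       c7 - c6 - 1, c8 - c7 - 1)
                            matches.append(EcmMatch(
                                cys_positions=positions,
                                spacers=spacers,
                                ecm_seq=seq[c1:c8 + 1],
                            ))
    matches.sort(key=lambda m: (m.cys_positions[0], m.cys_positions[7]))
    return matches


def classify_by_spacing(match: EcmMatch, templates: list[TypeTemplate]) -> list[str]:
    """All template names admitting the match's spacers, in registry order."""
    return [t.type_name for t in templates if t.admits(match.spacers)]


def classify_by_similarity(
    ecm_seq: str,
    references: list[tuple[str, str]],
) -> tuple[str, float]:
    """Assign a type by best global-alignment percent identity against
    reference ECM sequences.

    Percent identity = matched columns / alignment columns (dual-gap columns
    excluded; none arise in pairwise alignment).  Ties go to the first
    registered reference.
    """
    if not references:
        raise ValueError("classify_by_similarity requires at least one reference")
    from .kaks import align_proteins_global

    best: tuple[float, int, str] | None = None
    for idx, (type_name, ref_seq) in enumerate(references):
        aln = align_proteins_global(ecm_seq, ref_seq)
        cols = len(aln.aligned_a)
        ident = sum(
            1 for a, b in zip(aln.aligned_a, aln.aligned_b) if a == b and a != "-"
        )
        pct = 100.0 * ident / cols
        if best is None or pct > best[0]:
            best = (pct, idx, type_name)
    return best[2], best[0]


def _select_best_match(
    matches: list[EcmMatch], templates: list[TypeTemplate]
) -> tuple[EcmMatch, list[str]]:
    """Pick the most specific, most N-terminal match: fewest (≥1) matched
    types, then smallest c1; falls back to smallest c1 if nothing matches."""
    scored = [(m, classify_by_spacing(m, templates)) for m in matches]
    positive = [(m, t) for m, t in scored if t]
    if positive:
        best = min(positive, key=lambda mt: (len(mt[1]), mt[0].cys_positions[0]))
    else:
        best = min(scored, key=lambda mt: mt[0].cys_positions[0])
    return best


def classify_proteome(
    records,
    templates: list[TypeTemplate] | None = None,
    references: list[tuple[str, str]] | None = None,
    config: ScanConfig = ScanConfig(),
) -> tuple[list[ClassificationResult], pd.DataFrame]:
    """Scan and classify every protein; returns per-protein results plus a
    per-type member-count summary (count and percentage of classified total).
    """
    if templates is None:
        templates = load_templates()
    results: list[ClassificationResult] = []
    for rec in records:
        matches = find_ecm_matches(rec.seq, config)
        if not matches:
            results.append(ClassificationResult(rec.id, None, (), "no_ecm", "none"))
            continue
        best, matched = _select_best_match(matches, templates)
        if matched:
            results.append(ClassificationResult(
                rec.id, best, tuple(matched), matched[0], "spacing"))
            continue
        if references:
            type_name, pct = classify_by_similarity(best.ecm_seq, references)
            if pct >= config.similarity_threshold:
                results.append(ClassificationResult(
                    rec.id, best, (), type_name, "similarity", pct))
                continue
        results.append(ClassificationResult(rec.id, best, (), "unclassified", "none"))

    classified = [r for r in results if r.assigned_type not in ("no_ecm", "unclassified")]
    order = [t.type_name for t in templates]
    counts = {name: 0 for name in order}
    for r in classified:
        counts.setdefault(r.assigned_type, 0)
        counts[r.assigned_type] += 1
    total = len(classified)
    summary = pd.DataFrame({
        "type": list(counts),
        "count": [counts[k] for k in counts],
    })
    summary["percent"] = [
        round(100.0 * c / total, 2) if total else 0.0 for c in summary["count"]
    ]
    return results, summary


def consensus_logo_counts(aligned_seqs: list[str]) -> pd.DataFrame:
    """Position × residue count matrix for a set of equal-length aligned ECM
    sequences; gaps are counted in a ``-`` row.  Column sums all equal n."""
    if not aligned_seqs:
        raise ValueError("no sequences")
    length = len(aligned_seqs[0])
    for s in aligned_seqs:
        if len(s) != length:
            raise ValueError("aligned sequences differ in length")
    residues = sorted({ch for s in aligned_seqs for ch in s})
    counts = pd.DataFrame(0, index=residues, columns=range(length))
    for s in aligned_seqs:
        for pos, ch in enumerate(s):
            counts.loc[ch, pos] += 1
    return counts
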