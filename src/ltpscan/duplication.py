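"""Tandem-duplication calling, segmental-anchor ingestion, selection
categories, and Ks-based divergence dating.

Two family genes form a tandem pair iff they lie on the same chromosome,
are separated by no more than ``max_intervening`` other annotated genes
(any genes, not only family members), and are within ``max_distance`` bp.
Clusters are connected components of the qualifying-pair graph; singletons
are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .io_formats import GeneLocus

logger = logging.getLogger(__name__)

DEFAULT_MAX_INTERVENING = 5
DEFAULT_MAX_DISTANCE = 100_000
DEFAULT_NEUTRAL_RATE = 2.6e-9   # substitutions / site / year


@dataclass(frozen=True)
class TandemCluster:
    chrom: str
    members: tuple[str, ...]     # gene ids ordered by rank


@dataclass(frozen=True)
class SegmentalPair:
    gene_a: str
    gene_b: str


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def pair_qualifies(a: GeneLocus, b: GeneLocus,
                   max_intervening: int = DEFAULT_MAX_INTERVENING,
                   max_distance: int = DEFAULT_MAX_DISTANCE,
                   distance_mode: str = "start") -> bool:
    """Apply the tandem-duplication pair rule to two loci."""
    if a.chrom != b.chrom:
        return False
    intervening = abs(a.rank - b.rank) - 1
    if intervening > max_intervening:
        return False
    if distance_mode == "start":
        distance = abs(a.start - b.start)
    elif distance_mode == "gap":
        first, second = (a, b) if a.start <= b.start else (b, a)
        distance = max(0, second.start - first.end)
    else:
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    return distance <= max_distance


def find_tandem_clusters(family_ids, all_loci: list[GeneLocus],
                         max_intervening: int = DEFAULT_MAX_INTERVENING,
                         max_distance: int = DEFAULT_MAX_DISTANCE,
                         distance_mode: str = "start") -> list[TandemCluster]:
    """Tandem clusters among ``family_ids`` by transitive closure of the
    pair rule.  Unknown family ids raise."""
    by_id = {loc.gene_id: loc for loc in all_loci}
    family = sorted(set(family_ids))
    unknown = [g for g in family if g not in by_id]
    if unknown:
        raise KeyError(f"family ids absent from the gene annotation: {unknown}")

    uf = _UnionFind(family)
    by_chrom: dict[str, list[str]] = {}
    for g in family:
        by_chrom.setdefault(by_id[g].chrom, []).append(g)
    for genes in by_chrom.values():
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if pair_qualifies(by_id[genes[i]], by_id[genes[j]],
                                  max_intervening, max_distance, distance_mode):
                    uf.union(genes[i], genes[j])

    components: dict[str, list[str]] = {}
    for g in family:
        components.setdefault(uf.find(g), []).append(g)
    clusters = []
    for members in components.values():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda g: by_id[g].rank)
        clusters.append(TandemCluster(chrom=by_id[members[0]].chrom,
                                      members=tuple(members)))
    clusters.sort(key=lambda c: (c.chrom, by_id[c.members[0]].rank))
    return clusters


def cluster_pairs(cluster: TandemCluster, mode: str = "all") -> list[tuple[str, str]]:
    """Gene pairs to score within a cluster: every unordered pair (``all``)
    or rank-adjacent members only (``adjacent``)."""
    m = cluster.members
    if mode == "adjacent":
        return [(m[i], m[i + 1]) for i in range(len(m) - 1)]
    if mode == "all":
        return [(m[i], m[j]) for i in range(len(m)) for j in range(i + 1, len(m))]
    raise ValueError(f"unknown pair mode {mode!r}")


def load_segmental_anchors(path: str | Path, family_ids) -> list[SegmentalPair]:
    """Read precomputed segmental-duplication anchor pairs (two-column TSV),
    keeping order-independently deduplicated pairs with both genes in the
    family; pairs touching non-family genes are dropped and logged."""
    family = set(family_ids)
    seen: set[frozenset] = set()
    pairs: list[SegmentalPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not all(fields):
                raise ValueError(f"{path}:{lineno}: expected two tab-separated "
                                 f"gene ids, got {line!r}")
            a, b = fields
            if a not in family or b not in family:
                logger.info("anchor line %d dropped (non-family gene): %s", lineno, line)
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            pairs.append(SegmentalPair(a, b))
    return pairs


def divergence_time(ks: float, r: float = DEFAULT_NEUTRAL_RATE) -> float:
    """Divergence time in million years: t = Ks / (2r)."""
    if ks < 0:
        raise ValueError("Ks cannot be negative")
    if r <= 0:
        raise ValueError("neutral rate must be positive")
    return ks / (2.0 * r) / 1e6


def categorize_selection(ka: float | None, ks: float | None,
                         eps: float = 1e-9) -> str:
    """Selection category from the Ka/Ks ratio: <1 purifying, >1 positive,
    =1 neutral; undetermined when Ks = 0 or either estimate is missing."""
    if ka is None or ks is None:
        return "undetermined"
    if ka < 0 or ks < 0:
        raise ValueError("ka and ks cannot be negative")
    if ks == 0:
        return "undetermined"
    ratio = ka / ks
    if ratio < 1.0 - eps:
        return "purifying"
    if ratio > 1.0 + eps:
        return "positive"
    return "neutral"
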