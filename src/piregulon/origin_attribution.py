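"""Genomic origin mapping, cis/trans classification, and regulon calling.

piRNAs are traced to perfect (full-length, 0-mismatch) genomic origins
on both strands. Read counts of multimapping species are apportioned
equally across their origins; each origin's share accrues to the piRNA
cluster containing it, or to "unassigned". A cluster->gene regulon is
called when a single cluster contributes at least half (configurable)
of the reads targeting a gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .sequence_io import (
    ClusterAnnotation,
    GenomicInterval,
    SmallRNALibrary,
    revcomp,
)
from .target_scan import MatchHit

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

_SEED_LEN = 16


@dataclass(frozen=True)
class GenomicHit:
    """A perfect full-length genomic occurrence of a piRNA.

    For a '-' hit the piRNA sequence equals the reverse complement of
    the genome slice.
    """

    pirna_seq: str
    interval: GenomicInterval

    @property
    def strand(self) -> str:
        return self.interval.strand


def _build_seed_index(genome: Mapping[str, str]) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom in sorted(genome):
        seq = genome[chrom]
        for p in range(len(seq) - _SEED_LEN + 1):
            index.setdefault(seq[p : p + _SEED_LEN], []).append((chrom, p))
    return index


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_genomic_origins(
    library: SmallRNALibrary,
    genome: Mapping[str, str],
    use_index: Optional[bool] = None,
) -> dict[str, list[GenomicHit]]:
    """All exact full-length genomic occurrences of every library species.

    Species with no perfect origin map to an empty list ("unplaced").
    Small queries use direct string search; large libraries amortize a
    16-mer seed index over the genome (identical results either way).
    """
    species = sorted(library.records)
    if use_index is None:
        use_index = len(species) > 2000
    index = _build_seed_index(genome) if use_index else None

    origins: dict[str, list[GenomicHit]] = {}
    for seq in species:
        hits: list[GenomicHit] = []
        seen: set[tuple[str, int, str]] = set()
        for pattern, strand in ((seq, "+"), (revcomp(seq), "-")):
            if index is not None:
                cands = index.get(pattern[:_SEED_LEN], ())
                for chrom, p in cands:
                    if genome[chrom][p : p + len(pattern)] == pattern:
                        key = (chrom, p, strand)
                        if key not in seen:
                            seen.add(key)
                            hits.append(
                                GenomicHit(
                                    seq,
                                    GenomicInterval(chrom, p, p + len(pattern), strand),
                                )
                            )
            else:
                for chrom in sorted(genome):
                    for p in _find_all(genome[chrom], pattern):
                        key = (chrom, p, strand)
                        if key not in seen:
                            seen.add(key)
                            hits.append(
                                GenomicHit(
                                    seq,
                                    GenomicInterval(chrom, p, p + len(pattern), strand),
                                )
                            )
        hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.strand))
        origins[seq] = hits
    n_unplaced = sum(1 for h in origins.values() if not h)
    if n_unplaced:
        logger.info("map_genomic_origins: %d species unplaced", n_unplaced)
    return origins


def classify_cis_trans(
    origins: Sequence[GenomicHit], gene_locus: GenomicInterval
) -> str:
    """cis / trans / unplaced for one piRNA relative to one target gene.

    cis iff any perfect origin overlaps the gene's genomic span (any
    strand); trans iff all origins lie elsewhere; unplaced iff none.
    """
    if not origins:
        return "unplaced"
    overlapping = [h for h in origins if h.interval.overlaps(gene_locus)]
    if overlapping:
        if len(overlapping) < len(origins):
            logger.debug(
                "piRNA with mixed cis/trans origins classified cis (any-overlap rule)"
            )
        return "cis"
    return "trans"


class ClusterIntervals:
    """Merged, disjoint cluster intervals with fast point/overlap lookup.

    Overlapping intervals of the same cluster are merged; overlap between
    different clusters is a configuration error. Bidirectional clusters
    are treated as one id spanning both strands.
    """

    def __init__(self, clusters: Sequence[ClusterAnnotation]):
        ids = [c.cluster_id for c in clusters]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cluster ids")
        self.clusters = list(clusters)
        self._trees: dict[str, IntervalTree] = {}
        merged: dict[str, list[tuple[int, int, str]]] = {}
        for c in clusters:
            spans: dict[str, list[tuple[int, int]]] = {}
            for iv in c.intervals:
                spans.setdefault(iv.chrom, []).append((iv.start, iv.end))
            for chrom, lst in spans.items():
                lst.sort()
                out = [lst[0]]
                for s, e in lst[1:]:
                    if s <= out[-1][1]:
                        out[-1] = (out[-1][0], max(out[-1][1], e))
                    else:
                        out.append((s, e))
                merged.setdefault(chrom, []).extend(
                    (s, e, c.cluster_id) for s, e in out
                )
        for chrom, lst in merged.items():
            lst.sort()
            for (s1, e1, id1), (s2, e2, id2) in zip(lst, lst[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"clusters {id1} and {id2} overlap on {chrom}: "
                        f"[{s1},{e1}) vs [{s2},{e2})"
                    )
            tree = IntervalTree()
            for s, e, cid in lst:
                tree[s:e] = cid
            self._trees[chrom] = tree

    def cluster_at(self, interval: GenomicInterval) -> Optional[str]:
        """Cluster whose span contains the interval's start, if any."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return None
        hits = tree[interval.start]
        if not hits:
            return None
        return next(iter(hits)).data


def attribute_to_clusters(
    origins: Mapping[str, Sequence[GenomicHit]],
    clusters: Sequence[ClusterAnnotation] | ClusterIntervals,
    library: SmallRNALibrary,
    unique_only: bool = False,
) -> dict[str, dict[str, float]]:
    """Apportion each species' read count across cluster origins.

    Each perfect origin receives an equal share of the species' count;
    shares of origins inside a cluster accrue to that cluster, the rest
    to ``unassigned``. ``unique_only`` keeps only uniquely-mapping
    species (multimappers become fully unassigned).
    """
    ci = clusters if isinstance(clusters, ClusterIntervals) else ClusterIntervals(clusters)
    weights: dict[str, dict[str, float]] = {}
    for seq in sorted(origins):
        hits = origins[seq]
        count = library.records.get(seq)
        if count is None:
            continue
        w: dict[str, float] = {}
        if not hits or (unique_only and len(hits) > 1):
            w[UNASSIGNED] = float(count)
        else:
            share = count / len(hits)
            for h in hits:
                cid = ci.cluster_at(h.interval) or UNASSIGNED
                w[cid] = w.get(cid, 0.0) + share
        weights[seq] = w
    return weights


@dataclass
class RegulonCall:
    """Per-gene attribution of targeting reads to source clusters."""

    gene_id: str
    cluster_reads: dict[str, float]
    dominant_cluster: Optional[str]
    dominant_fraction: float
    unassigned_fraction: float
    total_reads: float
    is_one_to_one: bool


def call_regulon(
    gene_id: str,
    targeting_species: Sequence[str],
    cluster_weights: Mapping[str, Mapping[str, float]],
    dominant_threshold: float = 0.5,
) -> RegulonCall:
    """Attribute one gene's targeting reads to clusters and call dominance.

    The dominant cluster is the argmax of cluster shares (lexicographic
    tie-break); the one-to-one regulon flag is set when its share of the
    gene's targeting reads reaches the threshold.
    """
    shares: dict[str, float] = {}
    for seq in targeting_species:
        for cid, w in cluster_weights.get(seq, {}).items():
            shares[cid] = shares.get(cid, 0.0) + w
    total = sum(shares.values())
    unassigned = shares.get(UNASSIGNED, 0.0)
    cluster_only = {c: w for c, w in shares.items() if c != UNASSIGNED}
    if total == 0 or not cluster_only:
        return RegulonCall(gene_id, shares, None, 0.0, 1.0 if total else 0.0, total, False)
    dominant = min(cluster_only, key=lambda c: (-cluster_only[c], c))
    frac = cluster_only[dominant] / total
    return RegulonCall(
        gene_id=gene_id,
        cluster_reads=shares,
        dominant_cluster=dominant,
        dominant_fraction=frac,
        unassigned_fraction=unassigned / total,
        total_reads=total,
        is_one_to_one=frac >= dominant_threshold,
    )


def call_all_regulons(
    hits_by_species: Mapping[str, Sequence[MatchHit]],
    cluster_weights: Mapping[str, Mapping[str, float]],
    dominant_threshold: float = 0.5,
    origins: Optional[Mapping[str, Sequence[GenomicHit]]] = None,
    gene_loci: Optional[Mapping[str, GenomicInterval]] = None,
    exclude_cis: bool = True,
) -> dict[str, RegulonCall]:
    """Regulon call for every targeted gene.

    When origins and gene loci are supplied and ``exclude_cis`` is set,
    species acting in cis on a gene (a perfect origin inside that gene's
    locus — typically genic antisense reads rather than cluster piRNAs)
    are excluded from that gene's attribution, so regulons quantify
    trans regulation only.
    """
    species_by_gene: dict[str, list[str]] = {}
    for seq, hits in hits_by_species.items():
        for gene in {h.gene_id for h in hits}:
            species_by_gene.setdefault(gene, []).append(seq)
    out = {}
    for gene, species in sorted(species_by_gene.items()):
        if exclude_cis and origins is not None and gene_loci is not None:
            locus = gene_loci.get(gene)
            if locus is not None:
                species = [
                    s
                    for s in species
                    if classify_cis_trans(origins.get(s, ()), locus) != "cis"
                ]
        out[gene] = call_regulon(gene, sorted(species), cluster_weights, dominant_threshold)
    return out


def cluster_origin_share(
    cluster_weights: Mapping[str, Mapping[str, float]],
    species: Optional[Sequence[str]] = None,
) -> float:
    """Fraction of (targeting) piRNA reads attributed to any cluster."""
    keys = sorted(cluster_weights) if species is None else species
    total = 0.0
    in_cluster = 0.0
    for seq in keys:
        for cid, w in cluster_weights.get(seq, {}).items():
            total += w
            if cid != UNASSIGNED:
                in_cluster += w
    return in_cluster / total if total else 0.0


def tiled_coverage(
    origins: Mapping[str, Sequence[GenomicHit]],
    library: SmallRNALibrary,
    chrom_lengths: Mapping[str, int],
    tile: int = 100,
) -> pd.DataFrame:
    """Genome-wide small-RNA coverage in rpm per fixed tile per strand.

    Each origin contributes its equal apportioned share of the species'
    reads to the tile containing its start; values are scaled to reads
    per million retained library reads.
    """
    if tile <= 0:
        raise ValueError(f"tile size must be positive, got {tile}")
    total = library.total_reads
    acc: dict[tuple[str, int, str], float] = {}
    for seq in sorted(origins):
        hits = origins[seq]
        if not hits:
            continue
        count = library.records.get(seq)
        if count is None:
            continue
        share = count / len(hits)
        for h in hits:
            key = (h.interval.chrom, h.interval.start // tile, h.strand)
            acc[key] = acc.get(key, 0.0) + share
    rows = []
    for (chrom, tile_idx, strand), reads in sorted(acc.items()):
        rows.append(
            {
                "chrom": chrom,
                "start": tile_idx * tile,
                "end": min((tile_idx + 1) * tile, chrom_lengths.get(chrom, (tile_idx + 1) * tile)),
                "strand": strand,
                "rpm": reads * 1e6 / total,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "rpm"])


def cluster_expression(
    cluster_weights: Mapping[str, Mapping[str, float]],
    library: SmallRNALibrary,
    percentile: float = 90.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cluster piRNA expression in rpm, plus the top-percentile subset.

    The subset holds clusters whose rpm is at or above the given
    percentile of nonzero cluster rpm values (ties included).
    """
    total = library.total_reads
    per_cluster: dict[str, float] = {}
    for seq in sorted(cluster_weights):
        for cid, w in cluster_weights[seq].items():
            if cid != UNASSIGNED:
                per_cluster[cid] = per_cluster.get(cid, 0.0) + w
    table = pd.DataFrame(
        sorted(per_cluster.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["cluster_id", "reads"],
    )
    if table.empty or table["reads"].sum() == 0:
        logger.warning("cluster_expression: no cluster-attributed reads")
        table["rpm"] = []
        return table, []
    table["rpm"] = table["reads"] * 1e6 / total
    cutoff = float(np.percentile(table["rpm"].to_numpy(), percentile))
    top = sorted(table.loc[table["rpm"] >= cutoff, "cluster_id"])
    return table, top
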