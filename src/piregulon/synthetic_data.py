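"""Synthetic genomes, piRNA libraries, and count matrices with ground truth.

The generator emulates the data regime the pipeline is built for:
multi-exon genes and discrete piRNA clusters on a random background
genome; processed pseudogene fragments (spliced, 5'-truncated,
divergence-mutated, TSD-flanked, antisense by default) planted inside
clusters; cluster-emitted piRNA species 26-31 nt long with a 1U bias
and power-law read counts plus a background of non-cluster piRNAs and
per-read sequencing errors; and negative-binomial KO/WT count matrices
with derepression on the true targets. Every planted fact is recorded
in a machine-readable truth manifest so recovery can be scored.

What it deliberately does not emulate: repeat/transposon landscapes,
ping-pong piRNA pairs, read quality strings, or isoform diversity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sequence_io import (
    ClusterAnnotation,
    GenomicInterval,
    SmallRNALibrary,
    TranscriptModel,
    revcomp,
    write_clusters_bed,
    write_collapsed_fasta,
)

BASES = np.array(list("ACGT"))


@dataclass
class PGFPlan:
    """One planted pseudogene-fragment insertion."""

    gene_index: int
    cluster_index: int
    exons: Optional[list[int]] = None  # 1-based, contiguous, in transcript order
    orientation: str = "antisense"  # relative to mRNA sense on the precursor
    divergence: float = 0.05
    truncation: int = 100  # nt removed from the fragment 5' end
    tsd_len: int = 12
    retained_intron: Optional[int] = None  # 1-based intron index to keep


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic regime (all tunable)."""

    seed: int = 0
    # genome
    genome_size: int = 500_000
    n_chroms: int = 2
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (2, 8)
    exon_len: tuple[int, int] = (80, 400)
    intron_len: tuple[int, int] = (100, 2000)
    n_clusters: int = 6
    cluster_span: tuple[int, int] = (5_000, 30_000)
    pgf_plans: Optional[list[PGFPlan]] = None  # None -> default three regulons
    # piRNA model
    n_species: int = 3000
    length_probs: dict[int, float] = field(
        default_factory=lambda: {26: 0.08, 27: 0.12, 28: 0.18, 29: 0.22, 30: 0.22, 31: 0.18}
    )
    one_u_bias: float = 0.8
    power_exponent: float = 1.5
    library_depth: int = 200_000
    background_fraction: float = 0.05
    error_rate: float = 0.001
    cluster_weights: Optional[list[float]] = None  # None -> equal
    #: piRNA start-position density over planted PGF spans relative to the
    #: rest of the cluster; >1 mimics the concentrated antisense coverage
    #: that cluster profiles show over their pseudogene fragments
    pgf_region_weight: float = 5.0
    # expression model
    nb_mean: float = 500.0
    nb_dispersion: float = 0.05
    derepression_fc: float = 3.0
    replicates: int = 3

    def resolved_pgf_plans(self) -> list[PGFPlan]:
        if self.pgf_plans is not None:
            return self.pgf_plans
        n = min(3, self.n_genes, self.n_clusters)
        return [PGFPlan(gene_index=i, cluster_index=i) for i in range(n)]


@dataclass
class SyntheticDataset:
    """In-memory view of one simulated dataset."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    clusters: list[ClusterAnnotation]
    library: Optional[SmallRNALibrary]
    counts: Optional[pd.DataFrame]
    conditions: Optional[dict[str, str]]
    manifest: dict


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _mutate(
    rng: np.random.Generator, seq: str, rate: float
) -> tuple[str, int]:
    """Substitute each position independently at the given rate."""
    chars = np.array(list(seq))
    mask = rng.random(len(chars)) < rate
    n_sub = int(mask.sum())
    for i in np.flatnonzero(mask):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars), n_sub


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------


@dataclass
class _GeneDraft:
    strand: str
    exon_seqs: list[str]
    intron_seqs: list[str]

    @property
    def segment(self) -> str:
        parts = [self.exon_seqs[0]]
        for intron, exon in zip(self.intron_seqs, self.exon_seqs[1:]):
            parts.append(intron)
            parts.append(exon)
        return "".join(parts)

    @property
    def mature_plus(self) -> str:
        """Spliced sequence in genomic plus orientation."""
        return "".join(self.exon_seqs)


def _draft_gene(rng: np.random.Generator, cfg: SimulationConfig) -> _GeneDraft:
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_seqs = [
        _random_seq(rng, int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1)))
        for _ in range(n_exons)
    ]
    intron_seqs = [
        _random_seq(rng, int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1)))
        for _ in range(n_exons - 1)
    ]
    strand = "+" if rng.random() < 0.5 else "-"
    return _GeneDraft(strand=strand, exon_seqs=exon_seqs, intron_seqs=intron_seqs)


def _build_fragment(
    draft: _GeneDraft, plan: PGFPlan, rng: np.random.Generator
) -> tuple[str, int, list[int]]:
    """mRNA-sense fragment for a PGF plan: exon subset (optionally with a
    retained intron), 5'-truncated, divergence-mutated.

    Returns (fragment, n_substitutions, exon_indices_used).
    """
    n_exons = len(draft.exon_seqs)
    # exon/intron sequences in transcript (5'->3') order
    if draft.strand == "+":
        exons_tx = draft.exon_seqs
        introns_tx = draft.intron_seqs
    else:
        exons_tx = [revcomp(s) for s in reversed(draft.exon_seqs)]
        introns_tx = [revcomp(s) for s in reversed(draft.intron_seqs)]
    if plan.exons is None:
        lo = max(1, n_exons // 3)
        hi = n_exons
        exon_idx = list(range(lo, hi + 1))
    else:
        exon_idx = sorted(plan.exons)
        if exon_idx != list(range(exon_idx[0], exon_idx[-1] + 1)):
            raise ValueError("PGF exon subset must be contiguous")
        if exon_idx[0] < 1 or exon_idx[-1] > n_exons:
            raise ValueError("PGF exon subset outside gene")
    parts = []
    spans: list[tuple[int, int, int]] = []  # (exon index, start, end) pre-truncation
    off = 0
    for i in exon_idx:
        parts.append(exons_tx[i - 1])
        spans.append((i, off, off + len(exons_tx[i - 1])))
        off += len(exons_tx[i - 1])
        if plan.retained_intron == i and i < exon_idx[-1]:
            parts.append(introns_tx[i - 1])
            off += len(introns_tx[i - 1])
    fragment = "".join(parts)
    if plan.truncation >= len(fragment):
        raise ValueError("truncation removes the whole fragment")
    fragment = fragment[plan.truncation :]
    # exons still represented after truncation (>=10 nt or the whole exon)
    covered = [
        i
        for i, s, e in spans
        if e - max(s, plan.truncation) >= min(10, e - s)
    ]
    fragment, n_sub = _mutate(rng, fragment, plan.divergence)
    return fragment, n_sub, covered


def simulate_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SyntheticDataset:
    """Assemble chromosomes with genes, clusters, and planted PGFs.

    Chromosomes are built left-to-right from random background, gene
    segments, and cluster segments, so no coordinate shifting is ever
    needed; the truth manifest records every planted feature.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    plans = config.resolved_pgf_plans()

    drafts = [_draft_gene(rng, config) for _ in range(config.n_genes)]

    # cluster drafts: background span + planted insertions
    cluster_strands = ["+" if i % 2 == 0 else "-" for i in range(config.n_clusters)]
    cluster_bg = [
        _random_seq(rng, int(rng.integers(config.cluster_span[0], config.cluster_span[1] + 1)))
        for _ in range(config.n_clusters)
    ]
    pgf_records: list[dict] = []
    cluster_seqs: list[str] = []
    # insertions per cluster, applied in ascending insert-point order
    plans_by_cluster: dict[int, list[PGFPlan]] = {}
    for plan in plans:
        if not 0 <= plan.cluster_index < config.n_clusters:
            raise ValueError("PGF plan references unknown cluster")
        if not 0 <= plan.gene_index < config.n_genes:
            raise ValueError("PGF plan references unknown gene")
        plans_by_cluster.setdefault(plan.cluster_index, []).append(plan)

    for ci in range(config.n_clusters):
        bg = cluster_bg[ci]
        strand = cluster_strands[ci]
        todo = plans_by_cluster.get(ci, [])
        prepared = []
        for plan in todo:
            draft = drafts[plan.gene_index]
            fragment, n_sub, exon_idx = _build_fragment(draft, plan, rng)
            # genomic plus-strand representation of the inserted fragment:
            # piRNAs are sense fragments of the precursor (cluster strand),
            # so an 'antisense' plan puts revcomp(mRNA) on the precursor.
            precursor_frag = (
                revcomp(fragment) if plan.orientation == "antisense" else fragment
            )
            inserted = precursor_frag if strand == "+" else revcomp(precursor_frag)
            # choose an insertion point whose boundary bases differ from the
            # fragment ends, so the planted TSD is the unique maximal
            # duplication flanking the insertion (identifiable ground truth)
            for _ in range(100):
                u0 = int(rng.integers(1000, len(bg) - 1000))
                if (
                    inserted[0] != bg[u0]
                    and inserted[-1] != bg[u0 - plan.tsd_len - 1]
                ):
                    break
            else:
                raise ValueError("could not place PGF with distinct boundaries")
            prepared.append((plan, u0, inserted, fragment, n_sub, exon_idx))
        prepared.sort(key=lambda x: x[1])
        seq = bg
        offset = 0  # accumulated length added upstream
        for plan, u0, inserted, fragment, n_sub, exon_idx in prepared:
            u = u0 + offset
            tsd = seq[u - plan.tsd_len : u]
            seq = seq[:u] + inserted + tsd + seq[u:]
            pgf_records.append(
                {
                    "cluster_index": ci,
                    "gene_index": plan.gene_index,
                    "insert_local": u,
                    "insert_len": len(inserted),
                    "orientation": plan.orientation,
                    "divergence": plan.divergence,
                    "n_substitutions": n_sub,
                    "fragment_len": len(fragment),
                    "exons": exon_idx,
                    "retained_intron": plan.retained_intron,
                    "truncation": plan.truncation,
                    "tsd_seq": tsd,
                    "tsd_len": plan.tsd_len,
                }
            )
            offset += len(inserted) + plan.tsd_len
        cluster_seqs.append(seq)

    # chromosome assembly
    features: list[tuple[str, int]] = [("gene", i) for i in range(config.n_genes)] + [
        ("cluster", i) for i in range(config.n_clusters)
    ]
    order = list(rng.permutation(len(features)))
    per_chrom: dict[str, list[tuple[str, int]]] = {
        f"chr{c + 1}": [] for c in range(config.n_chroms)
    }
    chrom_names = sorted(per_chrom)
    for k, fi in enumerate(order):
        per_chrom[chrom_names[k % config.n_chroms]].append(features[fi])

    genome: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    clusters: list[ClusterAnnotation] = []
    gene_manifest: list[dict] = []
    cluster_coords: dict[int, tuple[str, int, int]] = {}

    for chrom in chrom_names:
        parts: list[str] = []
        pos = 0
        for kind, idx in per_chrom[chrom]:
            gap = _random_seq(rng, int(rng.integers(200, 2000)))
            parts.append(gap)
            pos += len(gap)
            if kind == "gene":
                draft = drafts[idx]
                seg = draft.segment
                exon_ivs = []
                off = 0
                for j, ex in enumerate(draft.exon_seqs):
                    exon_ivs.append(
                        GenomicInterval(chrom, pos + off, pos + off + len(ex), draft.strand)
                    )
                    off += len(ex)
                    if j < len(draft.intron_seqs):
                        off += len(draft.intron_seqs[j])
                gene_id = f"gene{idx + 1:03d}"
                mature = draft.mature_plus
                if draft.strand == "-":
                    mature = revcomp(mature)
                L = len(mature)
                cds_lo = max(1, L // 10)
                cds_hi = max(cds_lo + 3, (3 * L) // 4)
                model = TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}.t1",
                    locus=GenomicInterval(chrom, pos, pos + len(seg), draft.strand),
                    exons=exon_ivs,
                    cds_span=(cds_lo, cds_hi),
                    mature_seq=mature,
                )
                transcripts.append(model)
                gene_manifest.append(
                    {
                        "gene_id": gene_id,
                        "chrom": chrom,
                        "start": pos,
                        "end": pos + len(seg),
                        "strand": draft.strand,
                        "mature_len": L,
                    }
                )
                parts.append(seg)
                pos += len(seg)
            else:
                seq = cluster_seqs[idx]
                cluster_coords[idx] = (chrom, pos, pos + len(seq))
                parts.append(seq)
                pos += len(seq)
        tail = _random_seq(rng, int(rng.integers(200, 2000)))
        parts.append(tail)
        genome[chrom] = "".join(parts)

    # pad with background so total genome length reaches the configured size
    deficit = config.genome_size - sum(len(s) for s in genome.values())
    if deficit > 0:
        per = deficit // config.n_chroms
        for chrom in chrom_names:
            genome[chrom] += _random_seq(rng, per)

    for ci in range(config.n_clusters):
        chrom, start, end = cluster_coords[ci]
        clusters.append(
            ClusterAnnotation(
                f"piC{ci + 1}",
                GenomicInterval(chrom, start, end, cluster_strands[ci]),
            )
        )

    gene_ids = sorted(t.gene_id for t in transcripts)
    for rec in pgf_records:
        chrom, cstart, _ = cluster_coords[rec["cluster_index"]]
        rec["cluster_id"] = f"piC{rec['cluster_index'] + 1}"
        rec["gene_id"] = f"gene{rec['gene_index'] + 1:03d}"
        rec["chrom"] = chrom
        rec["insertion_start"] = cstart + rec["insert_local"]
        rec["insertion_end"] = cstart + rec["insert_local"] + rec["insert_len"]
        rec["tsd_upstream"] = [rec["insertion_start"] - rec["tsd_len"], rec["insertion_start"]]
        rec["tsd_downstream"] = [rec["insertion_end"], rec["insertion_end"] + rec["tsd_len"]]
        rec["processed"] = rec["retained_intron"] is None

    transcripts.sort(key=lambda t: t.gene_id)
    manifest = {
        "seed": config.seed,
        "genes": gene_manifest,
        "gene_ids": gene_ids,
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "strand": c.interval.strand,
            }
            for c in clusters
        ],
        "pgfs": pgf_records,
    }
    return SyntheticDataset(
        genome=genome,
        transcripts=transcripts,
        clusters=clusters,
        library=None,
        counts=None,
        conditions=None,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# piRNA library simulation
# ---------------------------------------------------------------------------


def _draw_species(
    rng: np.random.Generator,
    precursor: str,
    lengths: np.ndarray,
    length_p: np.ndarray,
    one_u_bias: float,
    t_positions: np.ndarray,
    position_weight: Optional[np.ndarray] = None,
) -> tuple[int, int]:
    """One (start, length) draw from a precursor.

    With probability ``one_u_bias`` the start is drawn from T positions,
    otherwise from non-T positions, so the expected 1U fraction of the
    emitted pool equals the configured bias exactly. ``position_weight``
    biases start density along the precursor (e.g. over PGF spans).
    """
    L = int(lengths[rng.choice(len(lengths), p=length_p)])
    max_start = len(precursor) - L
    if max_start < 0:
        raise ValueError("precursor shorter than piRNA length")
    want_t = rng.random() < one_u_bias
    pool = t_positions[t_positions <= max_start]
    if not want_t:
        mask = np.ones(max_start + 1, dtype=bool)
        mask[pool] = False
        pool = np.flatnonzero(mask)
    if pool.size == 0:
        return int(rng.integers(0, max_start + 1)), L
    if position_weight is not None:
        w = position_weight[pool]
        return int(pool[rng.choice(pool.size, p=w / w.sum())]), L
    return int(pool[rng.integers(0, pool.size)]), L


def simulate_pirna_library(
    config: SimulationConfig,
    dataset: SyntheticDataset,
    rng: Optional[np.random.Generator] = None,
) -> SmallRNALibrary:
    """Emit a collapsed piRNA library from the simulated clusters.

    Species are substrings of cluster precursor transcripts with the
    configured length spectrum and 1U bias; read counts follow a
    power-law across species, partitioned binomially/multinomially so
    that cluster emission shares and the background fraction hold in
    expectation; per-read substitution errors are applied before
    collapsing. Updates ``dataset.manifest['emission']`` and
    ``dataset.library``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    genome = dataset.genome
    clusters = dataset.clusters

    lengths = np.array(sorted(config.length_probs))
    length_p = np.array([config.length_probs[l] for l in lengths], dtype=float)
    length_p = length_p / length_p.sum()

    n_bg = max(1, round(config.n_species * config.background_fraction))
    n_cluster_species = config.n_species - n_bg
    weights = config.cluster_weights or [1.0] * len(clusters)
    if len(weights) != len(clusters):
        raise ValueError("cluster_weights length mismatch")
    wsum = sum(weights)
    weights = [w / wsum for w in weights]
    per_cluster = [
        max(1, round(n_cluster_species * w)) if w > 0 else 0 for w in weights
    ]

    pgf_spans: dict[str, list[tuple[int, int, str]]] = {}
    for rec in dataset.manifest["pgfs"]:
        pgf_spans.setdefault(rec["cluster_id"], []).append(
            (rec["insertion_start"], rec["insertion_end"], rec["gene_id"])
        )

    species: list[dict] = []  # seq, source, chrom, start, end, strand, pgf_gene
    for c, n_sp in zip(clusters, per_cluster):
        iv = c.interval
        plus = genome[iv.chrom][iv.start : iv.end]
        precursor = plus if iv.strand == "+" else revcomp(plus)
        t_positions = np.flatnonzero(np.frombuffer(precursor.encode(), dtype=np.uint8) == ord("T"))
        pos_weight = np.ones(len(precursor))
        for s, e, _gid in pgf_spans.get(c.cluster_id, []):
            # genomic PGF span -> precursor coordinates
            if iv.strand == "+":
                p0, p1 = s - iv.start, e - iv.start
            else:
                p0, p1 = iv.end - e, iv.end - s
            pos_weight[max(0, p0) : max(0, p1)] = config.pgf_region_weight
        for _ in range(n_sp):
            p, L = _draw_species(
                rng, precursor, lengths, length_p, config.one_u_bias,
                t_positions, pos_weight,
            )
            seq = precursor[p : p + L]
            if iv.strand == "+":
                g0, g1 = iv.start + p, iv.start + p + L
            else:
                g0, g1 = iv.end - p - L, iv.end - p
            pgf_gene = None
            for s, e, gid in pgf_spans.get(c.cluster_id, []):
                if min(g1, e) - max(g0, s) >= 21:
                    pgf_gene = gid
                    break
            species.append(
                {
                    "seq": seq,
                    "source": c.cluster_id,
                    "chrom": iv.chrom,
                    "start": g0,
                    "end": g1,
                    "strand": iv.strand,
                    "pgf_gene": pgf_gene,
                }
            )

    # background species: random non-cluster loci, either strand
    cluster_ranges: dict[str, list[tuple[int, int]]] = {}
    for c in clusters:
        cluster_ranges.setdefault(c.interval.chrom, []).append(
            (c.interval.start, c.interval.end)
        )
    chrom_names = sorted(genome)
    chrom_lens = np.array([len(genome[c]) for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    for _ in range(n_bg):
        while True:
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
            L = int(lengths[rng.choice(len(lengths), p=length_p)])
            p = int(rng.integers(0, len(genome[chrom]) - L + 1))
            if any(
                p < e and s < p + L for s, e in cluster_ranges.get(chrom, [])
            ):
                continue
            break
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome[chrom][p : p + L]
        if strand == "-":
            seq = revcomp(seq)
        species.append(
            {
                "seq": seq,
                "source": "background",
                "chrom": chrom,
                "start": p,
                "end": p + L,
                "strand": strand,
                "pgf_gene": None,
            }
        )

    # read counts: background binomial split, clusters multinomial by
    # weight, species within each source by power-law weights
    n_bg_reads = int(rng.binomial(config.library_depth, config.background_fraction))
    n_cluster_reads = config.library_depth - n_bg_reads
    by_source: dict[str, list[int]] = {}
    for i, sp in enumerate(species):
        by_source.setdefault(sp["source"], []).append(i)
    cluster_read_alloc = rng.multinomial(n_cluster_reads, weights)

    counts = np.zeros(len(species), dtype=np.int64)
    for c, n_reads in zip(clusters, cluster_read_alloc):
        idx = by_source.get(c.cluster_id, [])
        if not idx or n_reads == 0:
            continue
        w = (1.0 - rng.random(len(idx))) ** (-1.0 / (config.power_exponent - 1.0) if config.power_exponent > 1 else -1.0)
        w = np.minimum(w, 1e4)
        counts[idx] += rng.multinomial(int(n_reads), w / w.sum())
    bg_idx = by_source.get("background", [])
    if bg_idx and n_bg_reads:
        w = (1.0 - rng.random(len(bg_idx))) ** (-1.0 / (config.power_exponent - 1.0) if config.power_exponent > 1 else -1.0)
        w = np.minimum(w, 1e4)
        counts[bg_idx] += rng.multinomial(int(n_bg_reads), w / w.sum())

    # sequencing errors: each read independently carries one substitution
    raw: dict[str, int] = {}
    for sp, c in zip(species, counts):
        c = int(c)
        if c == 0:
            continue
        n_err = int(rng.binomial(c, config.error_rate))
        if c - n_err:
            raw[sp["seq"]] = raw.get(sp["seq"], 0) + (c - n_err)
        for _ in range(n_err):
            pos = int(rng.integers(0, len(sp["seq"])))
            alt = "ACGT".replace(sp["seq"][pos], "")[rng.integers(0, 3)]
            err_seq = sp["seq"][:pos] + alt + sp["seq"][pos + 1 :]
            raw[err_seq] = raw.get(err_seq, 0) + 1

    library = SmallRNALibrary(records=raw)

    cluster_reads = {
        c.cluster_id: int(counts[by_source.get(c.cluster_id, [])].sum())
        for c in clusters
    }
    target_mass: dict[str, dict[str, int]] = {}
    for sp, c in zip(species, counts):
        if sp["pgf_gene"] is not None and c:
            target_mass.setdefault(sp["pgf_gene"], {}).setdefault(sp["source"], 0)
            target_mass[sp["pgf_gene"]][sp["source"]] += int(c)

    dataset.manifest["emission"] = {
        "library_depth": config.library_depth,
        "background_reads": int(counts[bg_idx].sum()) if bg_idx else 0,
        "cluster_reads": cluster_reads,
        "per_gene_targeting_reads": {
            g: sum(d.values()) for g, d in sorted(target_mass.items())
        },
        "per_gene_cluster_targeting_reads": {g: d for g, d in sorted(target_mass.items())},
        "species": [
            {**sp, "count": int(c)} for sp, c in zip(species, counts) if c
        ],
    }
    dataset.library = library
    return library


# ---------------------------------------------------------------------------
# count matrix simulation
# ---------------------------------------------------------------------------


def simulate_counts(
    config: SimulationConfig,
    dataset: SyntheticDataset,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Negative-binomial KO/WT counts with derepression on true targets.

    Per-gene baseline means are lognormal around ``nb_mean``; genes with
    an antisense planted PGF have their KO mean multiplied by the
    derepression fold change (the regulating piRNAs are gone, so the
    target rises). Updates ``dataset.counts`` / ``dataset.conditions``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    gene_ids = dataset.manifest["gene_ids"]
    true_targets = {
        rec["gene_id"]
        for rec in dataset.manifest["pgfs"]
        if rec["orientation"] == "antisense"
    }
    phi = config.nb_dispersion
    n_param = 1.0 / phi if phi > 0 else None

    samples = [f"WT_{i + 1}" for i in range(config.replicates)] + [
        f"KO_{i + 1}" for i in range(config.replicates)
    ]
    conditions = {s: s.split("_")[0] for s in samples}
    mat = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    for gi, gene in enumerate(gene_ids):
        if config.nb_mean <= 0:
            mu = 0.0
        else:
            mu = float(rng.lognormal(np.log(config.nb_mean), 0.5))
        for si, sample in enumerate(samples):
            m = mu * (
                config.derepression_fc
                if conditions[sample] == "KO" and gene in true_targets
                else 1.0
            )
            if m <= 0:
                mat[gi, si] = 0
            elif n_param is None:
                mat[gi, si] = rng.poisson(m)
            else:
                mat[gi, si] = rng.negative_binomial(n_param, n_param / (n_param + m))
    counts = pd.DataFrame(mat, index=gene_ids, columns=samples)
    dataset.counts = counts
    dataset.conditions = conditions
    dataset.manifest["expression"] = {
        "true_targets": sorted(true_targets),
        "derepression_fc": config.derepression_fc,
        "replicates": config.replicates,
    }
    return counts, conditions


# ---------------------------------------------------------------------------
# dataset writing and validation
# ---------------------------------------------------------------------------


def _tx_interval_to_genomic(
    model: TranscriptModel, lo: int, hi: int
) -> list[tuple[int, int]]:
    """Project a transcript-coordinate interval onto genomic intervals."""
    exons = model.exons if model.strand == "+" else list(reversed(model.exons))
    out = []
    off = 0
    for e in exons:
        s0, s1 = off, off + len(e)
        ov0, ov1 = max(lo, s0), min(hi, s1)
        if ov0 < ov1:
            if model.strand == "+":
                out.append((e.start + (ov0 - s0), e.start + (ov1 - s0)))
            else:
                out.append((e.end - (ov1 - s0), e.end - (ov0 - s0)))
        off = s1
    return sorted(out)


def write_gtf(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF (exon + CDS features)."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda t: (t.locus.chrom, t.locus.start)):
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for exon in m.exons:
                fh.write(
                    f"{exon.chrom}\tsim\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
            if m.cds_span is not None:
                for s, e in _tx_interval_to_genomic(m, *m.cds_span):
                    fh.write(
                        f"{m.locus.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{m.strand}\t0\t{attrs}\n"
                    )


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_dataset(
    config: SimulationConfig, outdir: Optional[str | Path] = None
) -> SyntheticDataset:
    """Run the full generator; optionally write all standard-format files.

    Files written: genome.fa, genes.gtf, clusters.bed, pirnas.fa
    (collapsed), counts.tsv, conditions.tsv, manifest.json.
    """
    rng = np.random.default_rng(config.seed)
    dataset = simulate_genome(config, rng)
    simulate_pirna_library(config, dataset, rng)
    simulate_counts(config, dataset, rng)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome_fasta(dataset.genome, outdir / "genome.fa")
        write_gtf(dataset.transcripts, outdir / "genes.gtf")
        write_clusters_bed(dataset.clusters, outdir / "clusters.bed")
        write_collapsed_fasta(dataset.library, outdir / "pirnas.fa")
        dataset.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
        with open(outdir / "conditions.tsv", "w") as fh:
            fh.write("sample\tcondition\n")
            for s in dataset.counts.columns:
                fh.write(f"{s}\t{dataset.conditions[s]}\n")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(dataset.manifest, fh, indent=1, sort_keys=True)
    return dataset


def validate_manifest(dataset: SyntheticDataset) -> list[str]:
    """Check manifest assertions against the emitted data; return problems."""
    problems: list[str] = []
    genome = dataset.genome
    man = dataset.manifest
    for rec in man["pgfs"]:
        chrom = genome[rec["chrom"]]
        u0, u1 = rec["tsd_upstream"]
        d0, d1 = rec["tsd_downstream"]
        if chrom[u0:u1] != rec["tsd_seq"] or chrom[d0:d1] != rec["tsd_seq"]:
            problems.append(f"TSD mismatch for PGF of {rec['gene_id']}")
    tx = {t.gene_id: t for t in dataset.transcripts}
    for g in man["genes"]:
        t = tx.get(g["gene_id"])
        if t is None:
            problems.append(f"gene {g['gene_id']} missing from transcripts")
            continue
        if (t.locus.start, t.locus.end, t.locus.strand) != (
            g["start"], g["end"], g["strand"]
        ):
            problems.append(f"locus mismatch for {g['gene_id']}")
        if t.length != g["mature_len"]:
            problems.append(f"mature length mismatch for {g['gene_id']}")
    if "emission" in man and dataset.library is not None:
        em = man["emission"]
        total_emitted = sum(sp["count"] for sp in em["species"])
        if total_emitted != em["library_depth"]:
            problems.append("emitted species counts do not sum to library depth")
        if dataset.library.total_reads != em["library_depth"]:
            problems.append("library total differs from configured depth")
        for sp in em["species"]:
            s = genome[sp["chrom"]][sp["start"] : sp["end"]]
            if sp["strand"] == "-":
                s = revcomp(s)
            if s != sp["seq"]:
                problems.append(f"origin sequence mismatch for species at {sp['chrom']}:{sp['start']}")
                break
    return problems
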