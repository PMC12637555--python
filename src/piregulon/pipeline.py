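"""End-to-end orchestration: scan -> origins -> regulons -> PGF ->
signatures -> (expression), with plain-TSV interchange between stages.

Every output table starts with a comment header carrying the tool
version, a hash of the effective parameters, and the seed, so a rerun
with the same configuration is byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .expression_response import (
    CountMatrix,
    compare_target_tiers,
    feature_volcano_table,
)
from .origin_attribution import (
    ClusterIntervals,
    GenomicHit,
    UNASSIGNED,
    attribute_to_clusters,
    call_all_regulons,
    cluster_expression,
    cluster_origin_share,
    map_genomic_origins,
    tiled_coverage,
)
from .pgf_discovery import PGFCall, call_pgf
from .seq_signatures import length_distribution, positional_base_frequency
from .sequence_io import (
    ClusterAnnotation,
    SmallRNALibrary,
    TranscriptModel,
    build_transcriptome,
    select_representative_transcripts,
)
from .target_scan import HalfSiteIndex, TargetRanking, rank_targets

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All stage parameters in one validated bundle."""

    max_mm: int = 1
    mass_threshold: float = 0.70
    count_mode: str = "reads"
    assign_mode: str = "all"
    dominant_threshold: float = 0.5
    min_identity: float = 0.80
    min_span: int = 200
    truncation_margin: int = 50
    tile: int = 100
    expression_percentile: float = 90.0
    alpha: float = 0.05
    min_len: int = 24
    max_len: int = 34
    seed: int = 0
    full_origins: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    transcripts: list[TranscriptModel]
    library: SmallRNALibrary
    hits_by_species: dict
    ranking: TargetRanking
    origins: dict[str, list[GenomicHit]]
    cluster_weights: dict[str, dict[str, float]]
    regulons: dict
    pgf_calls: list[PGFCall]
    signatures: dict
    cluster_table: pd.DataFrame
    top_clusters: list[str]
    tiled: Optional[pd.DataFrame]
    expression: Optional[dict]
    report: dict


def run_analysis(
    genome: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    clusters: Sequence[ClusterAnnotation],
    library: SmallRNALibrary,
    params: PipelineParams = PipelineParams(),
    counts: Optional[CountMatrix] = None,
    run_pgf: bool = True,
) -> PipelineResult:
    """Run the full target-centered analysis on in-memory inputs."""
    reps = select_representative_transcripts(transcripts)
    if any(not t.mature_seq for t in reps):
        reps = build_transcriptome(genome, reps)

    index = HalfSiteIndex(reps)
    hits_by_species = index.scan_library(library, max_mm=params.max_mm)
    ranking = rank_targets(
        hits_by_species,
        library,
        transcripts=reps,
        mass_threshold=params.mass_threshold,
        count_mode=params.count_mode,
        assign_mode=params.assign_mode,
    )

    targeting = sorted(hits_by_species)
    if params.full_origins:
        origins = map_genomic_origins(library, genome)
    else:
        sub = SmallRNALibrary(
            records={s: library.records[s] for s in targeting},
            length_range=library.length_range,
        ) if targeting else SmallRNALibrary(records={}, length_range=library.length_range)
        origins = map_genomic_origins(sub, genome)

    ci = ClusterIntervals(clusters)
    cluster_weights = attribute_to_clusters(origins, ci, library)
    gene_loci = {t.gene_id: t.locus for t in reps}
    regulons = call_all_regulons(
        hits_by_species,
        cluster_weights,
        params.dominant_threshold,
        origins=origins,
        gene_loci=gene_loci,
        exclude_cis=True,
    )
    cluster_table, top_clusters = cluster_expression(
        cluster_weights, library, params.expression_percentile
    )
    tiled = None
    if params.full_origins:
        tiled = tiled_coverage(
            origins, library, {c: len(s) for c, s in genome.items()}, params.tile
        )

    pgf_calls: list[PGFCall] = []
    if run_pgf:
        for cluster in clusters:
            pgf_calls.extend(
                call_pgf(
                    cluster,
                    genome,
                    reps,
                    min_identity=params.min_identity,
                    min_span=params.min_span,
                    truncation_margin=params.truncation_margin,
                )
            )

    pfm = positional_base_frequency(library)
    lengths = length_distribution(library)
    signatures = {
        "one_u": pfm.one_u,
        "ten_a": pfm.ten_a,
        "matrix": pfm.matrix,
        "length_distribution": lengths,
    }

    expression = None
    if counts is not None:
        volcano = feature_volcano_table(counts, "WT", "KO", alpha=params.alpha)
        ranked_genes = set(ranking.genes)
        tiers = {
            "top": [g for g in ranking.top_targets if g in volcano.index],
            "lower": [
                g for g in ranking.genes
                if g not in ranking.top_targets and g in volcano.index
            ],
            "nontarget": sorted(set(volcano.index) - ranked_genes),
        }
        comparison = compare_target_tiers(volcano["log2fc"], tiers)
        expression = {"volcano": volcano, "tiers": tiers, "comparison": comparison}

    targeting_reads = sum(library.records[s] for s in targeting)
    report = {
        "version": __version__,
        "config_hash": params.config_hash(),
        "seed": params.seed,
        "library_species": library.n_species,
        "library_reads": library.total_reads,
        "targeting_species": len(targeting),
        "targeting_reads": targeting_reads,
        "pct_reads_mrna_targeting": 100.0 * targeting_reads / library.total_reads
        if library.total_reads
        else 0.0,
        "n_targets": len(ranking.genes),
        "n_top_targets": len(ranking.top_targets),
        "top_target": ranking.genes[0] if ranking.genes else None,
        "top_target_fraction": float(ranking.table["fraction"].iloc[0])
        if len(ranking.table)
        else 0.0,
        "cluster_origin_share_targeting": cluster_origin_share(
            cluster_weights, targeting
        ),
        "n_one_to_one_regulons": sum(
            1 for r in regulons.values() if r.is_one_to_one
        ),
        "n_pgf_calls": len(pgf_calls),
        "one_u": signatures["one_u"],
        "ten_a": signatures["ten_a"],
    }
    if expression is not None and len(expression["comparison"].pairwise):
        pw = expression["comparison"].pairwise
        row = pw[(pw.group_a == "top") & (pw.group_b == "nontarget")]
        if len(row):
            report["ks_d_top_vs_nontarget"] = float(row["D"].iloc[0])
            report["ks_p_top_vs_nontarget"] = float(row["p"].iloc[0])

    return PipelineResult(
        transcripts=reps,
        library=library,
        hits_by_species=hits_by_species,
        ranking=ranking,
        origins=origins,
        cluster_weights=cluster_weights,
        regulons=regulons,
        pgf_calls=pgf_calls,
        signatures=signatures,
        cluster_table=cluster_table,
        top_clusters=top_clusters,
        tiled=tiled,
        expression=expression,
        report=report,
    )


# ---------------------------------------------------------------------------
# on-disk pipeline
# ---------------------------------------------------------------------------


def _header(params: PipelineParams) -> str:
    return (
        f"# piregulon {__version__}; config={params.config_hash()}; "
        f"seed={params.seed}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, params: PipelineParams, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(_header(params))
        df.to_csv(fh, sep="\t", index=kwargs.pop("index", False), **kwargs)


def write_outputs(result: PipelineResult, outdir: str | Path, params: PipelineParams) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    hit_rows = []
    for seq in sorted(result.hits_by_species):
        for h in result.hits_by_species[seq]:
            hit_rows.append(
                {
                    "pirna_seq": seq,
                    "gene_id": h.gene_id,
                    "window_start": h.window[0],
                    "window_end": h.window[1],
                    "mismatches": h.mismatches,
                    "cleavage_site": h.cleavage_site,
                }
            )
    _write_tsv(pd.DataFrame(hit_rows, columns=[
        "pirna_seq", "gene_id", "window_start", "window_end", "mismatches",
        "cleavage_site"]), outdir / "hits.tsv", params)
    _write_tsv(result.ranking.table, outdir / "ranking.tsv", params)

    origin_rows = []
    for seq in sorted(result.origins):
        for h in result.origins[seq]:
            origin_rows.append(
                {
                    "pirna_seq": seq,
                    "chrom": h.interval.chrom,
                    "start": h.interval.start,
                    "end": h.interval.end,
                    "strand": h.strand,
                }
            )
    _write_tsv(pd.DataFrame(origin_rows, columns=[
        "pirna_seq", "chrom", "start", "end", "strand"]),
        outdir / "origins.tsv", params)

    attr_rows = []
    for seq in sorted(result.cluster_weights):
        for cid, w in sorted(result.cluster_weights[seq].items()):
            attr_rows.append({"pirna_seq": seq, "cluster_id": cid, "reads": w})
    _write_tsv(pd.DataFrame(attr_rows, columns=["pirna_seq", "cluster_id", "reads"]),
               outdir / "cluster_attribution.tsv", params)

    reg_rows = [
        {
            "gene_id": r.gene_id,
            "dominant_cluster": r.dominant_cluster or "",
            "dominant_fraction": r.dominant_fraction,
            "unassigned_fraction": r.unassigned_fraction,
            "targeting_reads": r.total_reads,
            "one_to_one": r.is_one_to_one,
        }
        for _, r in sorted(result.regulons.items())
    ]
    _write_tsv(pd.DataFrame(reg_rows, columns=[
        "gene_id", "dominant_cluster", "dominant_fraction",
        "unassigned_fraction", "targeting_reads", "one_to_one"]),
        outdir / "regulons.tsv", params)

    pgf_rows = [
        {
            "cluster_id": c.cluster_id,
            "parental_gene": c.parental_gene,
            "chrom": c.insertion.chrom,
            "start": c.insertion.start,
            "end": c.insertion.end,
            "identity": c.identity,
            "orientation": c.orientation,
            "covered_exons": ",".join(map(str, c.covered_exons)),
            "processed": c.processed,
            "five_prime_truncated": c.five_prime_truncated,
            "pirna_antisense": c.pirna_antisense,
            "tsd_seq": c.tsd.sequence if c.tsd else "",
            "tsd_len": c.tsd.length if c.tsd else 0,
        }
        for c in result.pgf_calls
    ]
    _write_tsv(pd.DataFrame(pgf_rows, columns=[
        "cluster_id", "parental_gene", "chrom", "start", "end", "identity",
        "orientation", "covered_exons", "processed", "five_prime_truncated",
        "pirna_antisense", "tsd_seq", "tsd_len"]),
        outdir / "pgf_calls.tsv", params)
    with open(outdir / "pgf_calls.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for c in result.pgf_calls:
            attrs = (
                f"ID=PGF-{c.parental_gene}-{c.cluster_id};"
                f"parental_gene={c.parental_gene};identity={c.identity:.4f};"
                f"processed={str(c.processed).lower()};"
                f"tsd={c.tsd.sequence if c.tsd else '.'}"
            )
            fh.write(
                f"{c.insertion.chrom}\tpiregulon\tpseudogene_fragment\t"
                f"{c.insertion.start + 1}\t{c.insertion.end}\t.\t"
                f"{'-' if c.orientation == 'antisense' else '+'}\t.\t{attrs}\n"
            )

    _write_tsv(result.signatures["matrix"], outdir / "positional_frequencies.tsv",
               params, index=True, index_label="position")
    _write_tsv(result.signatures["length_distribution"].rename_axis("length").reset_index(),
               outdir / "length_distribution.tsv", params)
    _write_tsv(result.cluster_table, outdir / "cluster_expression.tsv", params)
    if result.tiled is not None:
        for strand, label in (("+", "plus"), ("-", "minus")):
            sub = result.tiled[result.tiled.strand == strand]
            with open(outdir / f"tiled_coverage.{label}.bedgraph", "w") as fh:
                fh.write(_header(params))
                for _, r in sub.iterrows():
                    fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t{r.rpm:.4f}\n")

    if result.expression is not None:
        _write_tsv(result.expression["volcano"], outdir / "volcano.tsv", params,
                   index=True, index_label="feature")
        _write_tsv(result.expression["comparison"].pairwise,
                   outdir / "tier_comparison.tsv", params)
        ecdf_rows = []
        for label, vals in result.expression["comparison"].groups.items():
            n = len(vals)
            for i, v in enumerate(vals, 1):
                ecdf_rows.append({"group": label, "log2fc": v, "ecdf": i / n})
        _write_tsv(pd.DataFrame(ecdf_rows, columns=["group", "log2fc", "ecdf"]),
                   outdir / "ecdf_points.tsv", params)

    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=1, sort_keys=True)


def run_pipeline(
    genome_path: str | Path,
    annotation_path: str | Path,
    clusters_path: str | Path,
    pirna_path: str | Path,
    outdir: str | Path,
    counts_path: Optional[str | Path] = None,
    conditions_path: Optional[str | Path] = None,
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """File-based front end: validate inputs, run all stages, write outputs."""
    from .expression_response import read_count_matrix
    from .sequence_io import (
        read_annotation,
        read_clusters_bed,
        read_collapsed_fasta,
        read_genome_fasta,
    )

    for p in (genome_path, annotation_path, clusters_path, pirna_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    if (counts_path is None) != (conditions_path is None):
        raise ValueError("counts and conditions must be supplied together")

    genome = read_genome_fasta(genome_path)
    transcripts = read_annotation(annotation_path)
    clusters = read_clusters_bed(clusters_path)
    library = read_collapsed_fasta(pirna_path, params.min_len, params.max_len)
    counts = (
        read_count_matrix(counts_path, conditions_path) if counts_path else None
    )
    result = run_analysis(genome, transcripts, clusters, library, params, counts)
    write_outputs(result, outdir, params)
    return result
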