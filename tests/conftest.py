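"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from piregulon.sequence_io import GenomicInterval, TranscriptModel, revcomp
from piregulon.synthetic_data import PGFPlan, SimulationConfig, simulate_dataset

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def make_transcript(seq: str, gene_id: str = "geneA", chrom: str = "chr1",
                    offset: int = 0, cds=None) -> TranscriptModel:
    """Single-exon plus-strand transcript wrapping a given mature sequence."""
    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        locus=GenomicInterval(chrom, offset, offset + len(seq), "+"),
        exons=[GenomicInterval(chrom, offset, offset + len(seq), "+")],
        cds_span=cds,
        mature_seq=seq,
    )


def hamming_scan_oracle(core: str, mrna_seq: str, max_mm: int = 1):
    """Exhaustive sliding-window oracle for the antisense core scan."""
    target = revcomp(core)
    out = []
    for p in range(len(mrna_seq) - len(target) + 1):
        mm = sum(1 for x, y in zip(target, mrna_seq[p : p + len(target)]) if x != y)
        if mm <= max_mm:
            out.append((p, mm))
    return out


def string_search_oracle(genome: dict[str, str], pattern: str):
    """All exact occurrences of pattern / revcomp(pattern), naive search."""
    hits = []
    for strand, pat in (("+", pattern), ("-", revcomp(pattern))):
        for chrom in sorted(genome):
            seq = genome[chrom]
            start = 0
            while True:
                i = seq.find(pat, start)
                if i == -1:
                    break
                hits.append((chrom, i, i + len(pat), strand))
                start = i + 1
    return sorted(set(hits))


def ks_sup_oracle(x, y) -> float:
    """Brute-force sup |ECDF_x - ECDF_y| over all sample points."""
    x = sorted(x)
    y = sorted(y)
    best = 0.0
    for v in x + y:
        fx = sum(1 for a in x if a <= v) / len(x)
        fy = sum(1 for b in y if b <= v) / len(y)
        best = max(best, abs(fx - fy))
    return best


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down study conditions used by pipeline-level tests."""
    return SimulationConfig(
        seed=7,
        genome_size=120_000,
        n_chroms=2,
        n_genes=8,
        n_clusters=3,
        cluster_span=(4_000, 9_000),
        n_species=600,
        library_depth=30_000,
        pgf_plans=[
            PGFPlan(gene_index=0, cluster_index=0, divergence=0.05),
            PGFPlan(gene_index=1, cluster_index=1, divergence=0.05),
        ],
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
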