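"""Antisense piRNA target scanning and read-weighted target ranking.

The targeting rule: a piRNA hits an mRNA wherever the reverse complement
of its 20-nt guide core (piRNA nt 2-21) matches the mRNA sense strand
with at most one mismatch (Hamming distance; Watson-Crick only, no G:U
wobble, no indels). Position 1 of the piRNA is unconstrained, matching
the known non-pairing of the 1U position in PIWI guides.

Scanning uses a pigeonhole half-site index: any 20-mer window within
Hamming distance 1 of the query shares at least one exact 10-mer half
with it, so exact lookups of the two query halves enumerate all
candidate windows, which are then verified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sequence_io import SmallRNALibrary, TranscriptModel, revcomp

logger = logging.getLogger(__name__)

CORE_START = 1  # 0-based: core is piRNA nt 2..21
CORE_LEN = 20
HALF = 10


class GuideTooShortError(ValueError):
    """piRNA shorter than 21 nt cannot provide a full nt 2-21 core."""


@dataclass(frozen=True)
class GuideCore:
    """A piRNA's 20-nt targeting core (nt 2-21) with its read count."""

    pirna_seq: str
    core: str
    count: int = 1

    def __post_init__(self) -> None:
        if len(self.pirna_seq) < CORE_START + CORE_LEN:
            raise GuideTooShortError(
                f"piRNA of length {len(self.pirna_seq)} < 21 nt"
            )
        if self.core != self.pirna_seq[CORE_START : CORE_START + CORE_LEN]:
            raise ValueError("core is not piRNA nt 2-21")


@dataclass(frozen=True)
class MatchHit:
    """One antisense match of a piRNA core to an mRNA window.

    ``window`` is the 20-nt mRNA interval (transcript coordinates,
    half-open) paired by the core. ``cleavage_site`` is the 0-based index
    of the mRNA nucleotide 5' of the scissile phosphate (the base paired
    to piRNA nt 11); slicer cuts between it and the next base.
    """

    pirna_seq: str
    gene_id: str
    window: tuple[int, int]
    mismatches: int
    mismatch_core_position: Optional[int] = None  # 1-based within nt 2-21

    @property
    def cleavage_site(self) -> int:
        return self.window[0] + HALF


def extract_guide_core(pirna_seq: str, count: int = 1) -> GuideCore:
    """Extract nt 2-21 of a piRNA as its guide core."""
    if len(pirna_seq) < CORE_START + CORE_LEN:
        raise GuideTooShortError(f"piRNA of length {len(pirna_seq)} < 21 nt")
    return GuideCore(
        pirna_seq=pirna_seq,
        core=pirna_seq[CORE_START : CORE_START + CORE_LEN],
        count=count,
    )


def _hamming_leq(a: str, b: str, max_mm: int) -> Optional[list[int]]:
    """Positions where a and b differ, or None if more than max_mm."""
    diffs = []
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            diffs.append(i)
            if len(diffs) > max_mm:
                return None
    return diffs


def _hits_for_target(
    pirna_seq: str,
    gene_id: str,
    target: str,
    mrna_seq: str,
    positions: Iterable[int],
    max_mm: int,
) -> list[MatchHit]:
    hits = []
    for p in positions:
        window = mrna_seq[p : p + CORE_LEN]
        diffs = _hamming_leq(target, window, max_mm)
        if diffs is None:
            continue
        mm_core_pos = None
        if diffs:
            # target index i pairs with core index 19 - i
            mm_core_pos = CORE_LEN - diffs[0]
        hits.append(
            MatchHit(
                pirna_seq=pirna_seq,
                gene_id=gene_id,
                window=(p, p + CORE_LEN),
                mismatches=len(diffs),
                mismatch_core_position=mm_core_pos,
            )
        )
    return hits


def scan_transcript(
    core: GuideCore, mrna: TranscriptModel, max_mm: int = 1
) -> list[MatchHit]:
    """All antisense hits of one guide core on one mRNA (exhaustive scan)."""
    target = revcomp(core.core)
    seq = mrna.mature_seq
    return _hits_for_target(
        core.pirna_seq,
        mrna.gene_id,
        target,
        seq,
        range(len(seq) - CORE_LEN + 1),
        max_mm,
    )


class HalfSiteIndex:
    """Exact-lookup index of all 20-mer mRNA windows keyed by 10-mer halves."""

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self.transcripts = list(transcripts)
        # half-sequence -> list of (transcript index, window start)
        self._left: dict[str, list[tuple[int, int]]] = {}
        self._right: dict[str, list[tuple[int, int]]] = {}
        for t_idx, t in enumerate(self.transcripts):
            seq = t.mature_seq
            for p in range(len(seq) - CORE_LEN + 1):
                self._left.setdefault(seq[p : p + HALF], []).append((t_idx, p))
                self._right.setdefault(seq[p + HALF : p + CORE_LEN], []).append(
                    (t_idx, p)
                )

    def scan(self, core: GuideCore, max_mm: int = 1) -> list[MatchHit]:
        """All hits of one guide core across the indexed transcriptome."""
        target = revcomp(core.core)
        if not set(target) <= set("ACGT"):
            logger.info("skipping guide with non-ACGT core: %s", core.pirna_seq)
            return []
        candidates = set(self._left.get(target[:HALF], ()))
        candidates.update(self._right.get(target[HALF:], ()))
        hits: list[MatchHit] = []
        for t_idx, p in sorted(candidates):
            t = self.transcripts[t_idx]
            hits.extend(
                _hits_for_target(
                    core.pirna_seq, t.gene_id, target, t.mature_seq, (p,), max_mm
                )
            )
        return hits

    def scan_library(
        self, library: SmallRNALibrary, max_mm: int = 1
    ) -> dict[str, list[MatchHit]]:
        """Map each library species (with >=1 hit) to its hits.

        Species shorter than 21 nt are excluded with a logged count.
        """
        out: dict[str, list[MatchHit]] = {}
        too_short = 0
        for seq, count in sorted(library.records.items()):
            if len(seq) < CORE_START + CORE_LEN:
                too_short += 1
                continue
            hits = self.scan(extract_guide_core(seq, count), max_mm=max_mm)
            if hits:
                out[seq] = hits
        if too_short:
            logger.info("scan_library: %d species shorter than 21 nt skipped", too_short)
        return out


@dataclass
class TargetRanking:
    """Read-weighted per-gene targeting ranking.

    ``table`` columns: gene_id, reads, fraction, cumulative, rank,
    target_space, cds_reads, utr3_reads, utr5_reads. ``top_targets`` is
    the minimal rank prefix whose cumulative fraction reaches the mass
    threshold.
    """

    table: pd.DataFrame
    top_targets: list[str]
    total_targeting_reads: float
    mass_threshold: float
    count_mode: str
    assign_mode: str

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene_id"])


def _best_gene_for_species(
    hits: list[MatchHit],
) -> str:
    """Single-best-gene assignment: fewest mismatches, then longest
    covered span on the gene, then lexicographic gene_id."""
    per_gene: dict[str, list[MatchHit]] = {}
    for h in hits:
        per_gene.setdefault(h.gene_id, []).append(h)
    scored = []
    for gene, ghits in per_gene.items():
        min_mm = min(h.mismatches for h in ghits)
        covered = len({i for h in ghits for i in range(*h.window)})
        scored.append((min_mm, -covered, gene))
    return min(scored)[2]


def rank_targets(
    hits_by_species: Mapping[str, list[MatchHit]],
    library: SmallRNALibrary,
    transcripts: Optional[Sequence[TranscriptModel]] = None,
    mass_threshold: float = 0.70,
    count_mode: str = "reads",
    assign_mode: str = "all",
) -> TargetRanking:
    """Rank genes by their share of mRNA-targeting piRNAs.

    A species is mRNA-targeting iff it has at least one hit. Under
    ``assign_mode='all'`` a species hitting k genes contributes its full
    weight to each; ``'best'`` assigns each species to a single gene so
    per-gene fractions sum to one. ``count_mode='reads'`` weights species
    by read count, ``'species'`` counts each species once.
    """
    if count_mode not in ("reads", "species"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    if assign_mode not in ("all", "best"):
        raise ValueError(f"unknown assign_mode {assign_mode!r}")

    weight = (
        (lambda s: library.records[s]) if count_mode == "reads" else (lambda s: 1)
    )
    per_gene_reads: dict[str, float] = {}
    total = 0.0
    for seq, hits in hits_by_species.items():
        if not hits:
            continue
        w = weight(seq)
        total += w
        if assign_mode == "best":
            per_gene_reads[_best_gene_for_species(hits)] = (
                per_gene_reads.get(_best_gene_for_species(hits), 0.0) + w
            )
        else:
            for gene in {h.gene_id for h in hits}:
                per_gene_reads[gene] = per_gene_reads.get(gene, 0.0) + w

    if total == 0:
        logger.warning("rank_targets: no mRNA-targeting piRNAs")
        empty = pd.DataFrame(
            columns=[
                "gene_id", "reads", "fraction", "cumulative", "rank",
                "target_space", "cds_reads", "utr3_reads", "utr5_reads",
            ]
        )
        return TargetRanking(empty, [], 0.0, mass_threshold, count_mode, assign_mode)

    rows = sorted(per_gene_reads.items(), key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in rows]
    reads = np.array([r for _, r in rows], dtype=float)
    fractions = reads / total
    cumulative = np.cumsum(fractions)

    # target-space and region breakdown per gene
    tx_by_gene = {t.gene_id: t for t in transcripts} if transcripts else {}
    hits_by_gene: dict[str, list[tuple[MatchHit, float]]] = {}
    for seq, hits in hits_by_species.items():
        w = weight(seq)
        for h in hits:
            hits_by_gene.setdefault(h.gene_id, []).append((h, w))

    target_space = []
    region_reads = {"CDS": [], "3UTR": [], "5UTR": []}
    for gene in genes:
        ghits = hits_by_gene.get(gene, [])
        covered: set[int] = set()
        by_region = {"CDS": 0.0, "3UTR": 0.0, "5UTR": 0.0}
        tx = tx_by_gene.get(gene)
        for h, w in ghits:
            covered.update(range(*h.window))
            if tx is not None:
                region = tx.region_of(h.cleavage_site)
                if region in by_region:
                    by_region[region] += w
        target_space.append(len(covered))
        for r in region_reads:
            region_reads[r].append(by_region[r])

    table = pd.DataFrame(
        {
            "gene_id": genes,
            "reads": reads,
            "fraction": fractions,
            "cumulative": cumulative,
            "rank": np.arange(1, len(genes) + 1),
            "target_space": target_space,
            "cds_reads": region_reads["CDS"],
            "utr3_reads": region_reads["3UTR"],
            "utr5_reads": region_reads["5UTR"],
        }
    )
    n_top = int(np.searchsorted(cumulative, mass_threshold - 1e-12) + 1)
    n_top = min(n_top, len(genes))
    return TargetRanking(
        table=table,
        top_targets=genes[:n_top],
        total_targeting_reads=total,
        mass_threshold=mass_threshold,
        count_mode=count_mode,
        assign_mode=assign_mode,
    )


@dataclass
class CoverageProfile:
    """Per-nucleotide read-weighted antisense coverage of one mRNA."""

    gene_id: str
    coverage: np.ndarray
    target_space: int
    region_reads: dict[str, float]


def coverage_profile(
    hits: Sequence[MatchHit],
    library: SmallRNALibrary,
    transcript: TranscriptModel,
    count_mode: str = "reads",
) -> CoverageProfile:
    """Read-weighted coverage across one gene's mature mRNA.

    coverage[i] sums the weights of all hits whose window contains i;
    target_space is the number of positions with coverage > 0; each hit
    is assigned to the region (5UTR/CDS/3UTR) containing its predicted
    cleavage site.
    """
    cov = np.zeros(transcript.length, dtype=float)
    region_reads: dict[str, float] = {}
    for h in hits:
        if h.gene_id != transcript.gene_id:
            raise ValueError(f"hit for {h.gene_id} on transcript of {transcript.gene_id}")
        w = library.records.get(h.pirna_seq, 1) if count_mode == "reads" else 1
        cov[h.window[0] : h.window[1]] += w
        region = transcript.region_of(h.cleavage_site)
        region_reads[region] = region_reads.get(region, 0.0) + w
    return CoverageProfile(
        gene_id=transcript.gene_id,
        coverage=cov,
        target_space=int(np.count_nonzero(cov)),
        region_reads=region_reads,
    )


def molecules_per_cell(fraction: float, pool_size_per_cell: float) -> float:
    """Convert a piRNA pool fraction into molecules per cell.

    The total piRNA pool size per cell is a user-supplied literature
    constant, not something this package estimates.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if pool_size_per_cell <= 0:
        raise ValueError("pool size must be positive")
    return fraction * pool_size_per_cell
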