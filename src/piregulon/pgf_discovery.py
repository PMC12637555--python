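"""Pseudogene-fragment (PGF) discovery inside piRNA clusters.

A PGF is a partial, usually spliced ("processed") copy of an mRNA
inserted into a piRNA cluster; in antisense orientation it supplies the
cluster with piRNAs complementary to the parental mRNA. This module
finds such fragments by local alignment of cluster sequence against
mature mRNAs (Smith-Waterman scoring +2/-3, gap -5/-2 by default),
chains collinear high-identity blocks, and annotates the anatomy of the
insertion: overall identity, covered exons, 5' truncation, retained
introns (partly processed), and flanking target-site duplications (TSD)
diagnostic of LINE-mediated retrotransposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio import Align

from .sequence_io import (
    ClusterAnnotation,
    GenomicInterval,
    TranscriptModel,
    revcomp,
)

logger = logging.getLogger(__name__)

SAME = "same"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass
class LocalAlignmentBlock:
    """One chained local-alignment block between cluster and mRNA.

    Intervals are half-open; ``mrna_interval`` is in mature-transcript
    coordinates regardless of orientation. ``alignment_length`` counts
    alignment columns (including internal gap columns within the block).
    """

    cluster_interval: tuple[int, int]
    mrna_interval: tuple[int, int]
    orientation: str
    matches: int
    alignment_length: int
    gaps: int

    @property
    def identity(self) -> float:
        return self.matches / self.alignment_length if self.alignment_length else 0.0


@dataclass
class TSD:
    """A target-site duplication flanking an insertion."""

    sequence: str
    upstream: tuple[int, int]
    downstream: tuple[int, int]
    mismatches: int

    @property
    def length(self) -> int:
        return self.upstream[1] - self.upstream[0]


@dataclass
class PGFCall:
    """A pseudogene fragment called inside a cluster."""

    cluster_id: str
    insertion: GenomicInterval
    parental_gene: str
    blocks: list[LocalAlignmentBlock]
    identity: float
    covered_exons: list[int]
    processed: bool
    five_prime_truncated: bool
    orientation: str
    pirna_antisense: bool
    tsd: Optional[TSD] = None

    @property
    def aligned_mrna_length(self) -> int:
        return sum(b.mrna_interval[1] - b.mrna_interval[0] for b in self.blocks)


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _alignment_to_blocks(
    alignment, seq_a: str, seq_b: str, gap_split: int = 30
) -> list[LocalAlignmentBlock]:
    """Decompose one local alignment into end-trimmed blocks.

    Ungapped aligned segments separated by a gap of fewer than
    ``gap_split`` positions in both sequences are merged into a single
    block (the gap columns count against identity); larger gaps —
    retained introns, diverged spacers — split the alignment into
    separate blocks whose gap columns are excluded. Each block is then
    trimmed to its maximal-scoring column range under an end-strict
    score (+1 match, -3 mismatch/gap): Smith-Waterman keeps any net
    positive extension (~25% matches continue into random flanks), and
    trimming removes those while keeping genuinely diverged interiors.
    """
    segs_a, segs_b = alignment.aligned
    raw: list[list[tuple[bool, int, int]]] = []  # per block: (match, da, db)
    starts: list[tuple[int, int]] = []
    cur_cols: Optional[list[tuple[bool, int, int]]] = None
    prev_a1 = prev_b1 = 0
    for (a0, a1), (b0, b1) in zip(segs_a, segs_b):
        if cur_cols is not None:
            gap_a = a0 - prev_a1
            gap_b = b0 - prev_b1
            if max(gap_a, gap_b) < gap_split:
                cur_cols.extend([(False, 1, 0)] * gap_a)
                cur_cols.extend([(False, 0, 1)] * gap_b)
            else:
                raw.append(cur_cols)
                cur_cols = None
        if cur_cols is None:
            cur_cols = []
            starts.append((int(a0), int(b0)))
        for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]):
            cur_cols.append((x == y, 1, 1))
        prev_a1, prev_b1 = a1, b1
    if cur_cols is not None:
        raw.append(cur_cols)

    blocks: list[LocalAlignmentBlock] = []
    for (a0, b0), cols in zip(starts, raw):
        lo, hi = _max_scoring_range(cols)
        if lo >= hi:
            continue
        da_pre = sum(c[1] for c in cols[:lo])
        db_pre = sum(c[2] for c in cols[:lo])
        kept = cols[lo:hi]
        da = sum(c[1] for c in kept)
        db = sum(c[2] for c in kept)
        matches = sum(c[0] for c in kept)
        gaps = sum(1 for c in kept if c[1] + c[2] == 1)
        blocks.append(
            LocalAlignmentBlock(
                cluster_interval=(a0 + da_pre, a0 + da_pre + da),
                mrna_interval=(b0 + db_pre, b0 + db_pre + db),
                orientation=SAME,  # orientation fixed by caller
                matches=matches,
                alignment_length=len(kept),
                gaps=gaps,
            )
        )
    return blocks


def _max_scoring_range(
    cols: list[tuple[bool, int, int]], match: float = 1.0, penalty: float = -3.0
) -> tuple[int, int]:
    """Column range maximizing sum(match/penalty) — Kadane with traceback."""
    best = (0.0, 0, 0)
    run = 0.0
    run_start = 0
    for i, (is_match, _, _) in enumerate(cols):
        run += match if is_match else penalty
        if run <= 0:
            run = 0.0
            run_start = i + 1
        elif run > best[0]:
            best = (run, run_start, i + 1)
    return best[1], best[2]


def _iterative_local_blocks(
    seq_a: str,
    seq_b: str,
    scoring: AlignmentScoring,
    min_score: float,
    max_rounds: int = 6,
) -> list[LocalAlignmentBlock]:
    """Repeated best-local-alignment with masking of aligned query regions."""
    aligner = _make_aligner(scoring)
    work = seq_a
    blocks: list[LocalAlignmentBlock] = []
    for _ in range(max_rounds):
        if not work or not seq_b:
            break
        result = aligner.align(work, seq_b)
        if result.score < min_score:
            break
        alignment = result[0]
        new = _alignment_to_blocks(alignment, work, seq_b)
        blocks.extend(new)
        segs_a = alignment.aligned[0]
        lo = int(segs_a[0][0])
        hi = int(segs_a[-1][1])
        if hi <= lo:
            break
        work = work[:lo] + "X" * (hi - lo) + work[hi:]
    return blocks


def _best_collinear_chain(
    blocks: list[LocalAlignmentBlock], overlap_slop: int = 20
) -> list[LocalAlignmentBlock]:
    """Highest-scoring collinear chain (weighted LIS on matches).

    Blocks must advance in both sequences; a small terminal overlap
    (``overlap_slop``) is tolerated because local-alignment edges can
    extend ambiguously a few bases past a splice or divergence boundary.
    """
    blocks = sorted(blocks, key=lambda b: (b.cluster_interval, b.mrna_interval))
    n = len(blocks)
    best_score = [0.0] * n
    prev = [-1] * n
    for i, b in enumerate(blocks):
        best_score[i] = float(b.matches)
        for j in range(i):
            a = blocks[j]
            if (
                a.cluster_interval[0] < b.cluster_interval[0]
                and a.mrna_interval[0] < b.mrna_interval[0]
                and a.cluster_interval[1] <= b.cluster_interval[0] + overlap_slop
                and a.mrna_interval[1] <= b.mrna_interval[0] + overlap_slop
            ):
                cand = best_score[j] + b.matches
                if cand > best_score[i]:
                    best_score[i] = cand
                    prev[i] = j
    if not blocks:
        return []
    i = max(range(n), key=lambda k: best_score[k])
    chain = []
    while i != -1:
        chain.append(blocks[i])
        i = prev[i]
    return chain[::-1]


def align_cluster_to_mrna(
    cluster_seq: str,
    mrna: TranscriptModel | str,
    min_block_identity: float = 0.80,
    min_block_len: int = 50,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> list[LocalAlignmentBlock]:
    """Best collinear chain of local-alignment blocks, both orientations.

    The cluster sequence (genomic plus strand) is aligned against the
    mature mRNA directly (orientation ``same``) and against its reverse
    complement (``antisense``); blocks below the identity/length
    thresholds are discarded before chaining and the higher-scoring
    orientation wins. mRNA coordinates in returned blocks are always in
    the mature-transcript frame.
    """
    if not cluster_seq or not (mrna if isinstance(mrna, str) else mrna.mature_seq):
        raise ValueError("empty sequence")
    mrna_seq = mrna if isinstance(mrna, str) else mrna.mature_seq
    min_score = min_block_len * (
        scoring.match * min_block_identity + scoring.mismatch * (1 - min_block_identity)
    )
    min_score = max(min_score, scoring.match * 20)

    best_chain: list[LocalAlignmentBlock] = []
    best_matches = 0
    for orientation in (SAME, ANTISENSE):
        target = mrna_seq if orientation == SAME else revcomp(mrna_seq)
        blocks = _iterative_local_blocks(cluster_seq, target, scoring, min_score)
        blocks = [
            b
            for b in blocks
            if b.identity >= min_block_identity
            and (b.cluster_interval[1] - b.cluster_interval[0]) >= min_block_len
        ]
        chain = _best_collinear_chain(blocks)
        matches = sum(b.matches for b in chain)
        if matches > best_matches:
            L = len(mrna_seq)
            if orientation == ANTISENSE:
                chain = [
                    LocalAlignmentBlock(
                        cluster_interval=b.cluster_interval,
                        mrna_interval=(L - b.mrna_interval[1], L - b.mrna_interval[0]),
                        orientation=ANTISENSE,
                        matches=b.matches,
                        alignment_length=b.alignment_length,
                        gaps=b.gaps,
                    )
                    for b in chain
                ]
            else:
                for b in chain:
                    b.orientation = SAME
            best_chain = chain
            best_matches = matches
    return best_chain


def chain_identity(chain: Sequence[LocalAlignmentBlock]) -> float:
    cols = sum(b.alignment_length for b in chain)
    return sum(b.matches for b in chain) / cols if cols else 0.0


# ---------------------------------------------------------------------------
# TSD detection
# ---------------------------------------------------------------------------


def detect_tsd(
    chrom_seq: str,
    insertion: tuple[int, int],
    min_len: int = 10,
    max_len: int = 25,
    max_mm: int = 1,
    search_window: int = 30,
) -> Optional[TSD]:
    """Find the target-site duplication flanking an insertion, if any.

    Searches for the longest pair of near-identical substrings, one
    ending within ``search_window`` of the insertion start (entirely
    upstream) and one beginning within ``search_window`` of the insertion
    end (entirely downstream). Ties break by fewer mismatches, then by
    proximity to the insertion boundaries.
    """
    start, end = insertion
    if start - search_window < 0 or end + search_window > len(chrom_seq):
        logger.warning("detect_tsd: insufficient flank around [%d,%d)", start, end)
        return None
    best: Optional[tuple[tuple[int, int, int], TSD]] = None
    for length in range(max_len, min_len - 1, -1):
        for u_end in range(start, max(start - search_window, length) - 1, -1):
            u = chrom_seq[u_end - length : u_end]
            for d_start in range(end, min(end + search_window, len(chrom_seq) - length) + 1):
                v = chrom_seq[d_start : d_start + length]
                mm = sum(1 for x, y in zip(u, v) if x != y)
                if mm <= max_mm:
                    proximity = (start - u_end) + (d_start - end)
                    key = (-length, mm, proximity)
                    if best is None or key < best[0]:
                        best = (
                            key,
                            TSD(
                                sequence=u,
                                upstream=(u_end - length, u_end),
                                downstream=(d_start, d_start + length),
                                mismatches=mm,
                            ),
                        )
        if best is not None:
            break  # longest length found; shorter ones cannot beat it
    return best[1] if best else None


def refine_tsd(
    chrom_seq: str,
    insertion: tuple[int, int],
    boundary_slack: int = 15,
    min_len: int = 10,
    max_len: int = 25,
    max_mm: int = 1,
    search_window: int = 30,
) -> tuple[Optional[TSD], tuple[int, int]]:
    """Jointly infer insertion boundaries and their flanking TSD.

    Alignment-derived insertion end points can over- or under-run the
    true boundary by a few bases when flanking bases coincide with the
    parental sequence. This search considers candidate boundaries a in
    [start - search_window, start + boundary_slack] and b in
    [end - boundary_slack, end + search_window], requires the duplicated
    pair to abut the candidate boundary exactly (upstream copy ends at
    a, downstream copy starts at b), and prefers fewest mismatches, then
    longest duplication, then boundaries closest to the alignment ends.
    Returns the TSD (or None) and the refined insertion interval.
    """
    start, end = insertion
    best: Optional[tuple[tuple, TSD, tuple[int, int]]] = None
    a_lo = max(max_len, start - search_window)
    a_hi = min(start + boundary_slack, end)
    b_lo = max(end - boundary_slack, start)
    b_hi = min(end + search_window, len(chrom_seq) - max_len)
    for a in range(a_lo, a_hi + 1):
        for b in range(b_lo, b_hi + 1):
            if a > b:
                continue
            for length in range(max_len, min_len - 1, -1):
                if a - length < 0 or b + length > len(chrom_seq):
                    continue
                u = chrom_seq[a - length : a]
                v = chrom_seq[b : b + length]
                mm = sum(1 for x, y in zip(u, v) if x != y)
                if mm <= max_mm:
                    key = (mm, -length, abs(a - start) + abs(b - end))
                    if best is None or key < best[0]:
                        best = (
                            key,
                            TSD(sequence=u, upstream=(a - length, a),
                                downstream=(b, b + length), mismatches=mm),
                            (a, b),
                        )
    if best is None:
        return None, insertion
    return best[1], best[2]


# ---------------------------------------------------------------------------
# PGF calling
# ---------------------------------------------------------------------------


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _exon_tx_spans(mrna: TranscriptModel) -> list[tuple[int, int]]:
    """Exon spans in transcript coordinates, in transcript (5'->3') order."""
    exons = mrna.exons if mrna.strand == "+" else list(reversed(mrna.exons))
    spans = []
    off = 0
    for e in exons:
        spans.append((off, off + len(e)))
        off += len(e)
    return spans


def _unspliced_gene_seq(genome: Mapping[str, str], mrna: TranscriptModel) -> tuple[str, list[tuple[int, int]]]:
    """Pre-mRNA sequence (gene sense strand) and intron spans within it."""
    chrom = genome[mrna.locus.chrom]
    seq = chrom[mrna.locus.start : mrna.locus.end]
    introns_genomic = []
    for a, b in zip(mrna.exons, mrna.exons[1:]):
        introns_genomic.append((a.end - mrna.locus.start, b.start - mrna.locus.start))
    if mrna.strand == "-":
        L = len(seq)
        seq = revcomp(seq)
        introns_genomic = [(L - e, L - s) for s, e in introns_genomic]
    return seq, sorted(introns_genomic)


def _is_processed(
    fragment_seq: str,
    genome: Mapping[str, str],
    mrna: TranscriptModel,
    scoring: AlignmentScoring,
    min_intron_overlap: int = 30,
) -> bool:
    """Processed iff the fragment has no substantial alignment to introns.

    The fragment is aligned against the unspliced parental pre-mRNA; if
    chained blocks cover at least ``min_intron_overlap`` intronic
    positions, the fragment retains intron sequence (partly processed).
    """
    unspliced, introns = _unspliced_gene_seq(genome, mrna)
    if not introns:
        return True
    chain = align_cluster_to_mrna(
        fragment_seq, unspliced, min_block_identity=0.7, min_block_len=25,
        scoring=scoring,
    )
    intronic = 0
    for b in chain:
        s, e = b.mrna_interval
        for i0, i1 in introns:
            intronic += max(0, min(e, i1) - max(s, i0))
    return intronic < min_intron_overlap


def call_pgf(
    cluster: ClusterAnnotation,
    genome: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    min_identity: float = 0.80,
    min_span: int = 200,
    truncation_margin: int = 50,
    min_block_identity: float = 0.80,
    min_block_len: int = 50,
    tsd_kwargs: Optional[dict] = None,
    tsd_boundary_slack: int = 15,
    scoring: AlignmentScoring = AlignmentScoring(),
    seed_k: int = 13,
    min_seed_hits: int = 4,
) -> list[PGFCall]:
    """Call pseudogene fragments in one cluster against a transcriptome.

    Candidate parental genes are pre-screened by shared ``seed_k``-mers
    (either orientation) before alignment; per gene the best collinear
    chain is promoted to a PGFCall when its overall identity and aligned
    mRNA span pass the thresholds.
    """
    iv = cluster.interval
    chrom_seq = genome[iv.chrom]
    cluster_seq = chrom_seq[iv.start : iv.end]
    kmers_fwd = _kmer_set(cluster_seq, seed_k)

    calls: list[PGFCall] = []
    for mrna in transcripts:
        mseq = mrna.mature_seq
        m_kmers = _kmer_set(mseq, seed_k)
        n_fwd = len(m_kmers & kmers_fwd)
        m_kmers_rc = _kmer_set(revcomp(mseq), seed_k)
        n_rev = len(m_kmers_rc & kmers_fwd)
        if max(n_fwd, n_rev) < min_seed_hits:
            continue
        # restrict to the seeded cluster neighbourhood to bound alignment cost
        positions = [
            i
            for i in range(len(cluster_seq) - seed_k + 1)
            if cluster_seq[i : i + seed_k] in (m_kmers | m_kmers_rc)
        ]
        margin = 300
        lo = max(0, min(positions) - margin)
        hi = min(len(cluster_seq), max(positions) + seed_k + margin)
        chain = align_cluster_to_mrna(
            cluster_seq[lo:hi],
            mrna,
            min_block_identity=min_block_identity,
            min_block_len=min_block_len,
            scoring=scoring,
        )
        if not chain:
            continue
        chain = [
            LocalAlignmentBlock(
                cluster_interval=(b.cluster_interval[0] + lo, b.cluster_interval[1] + lo),
                mrna_interval=b.mrna_interval,
                orientation=b.orientation,
                matches=b.matches,
                alignment_length=b.alignment_length,
                gaps=b.gaps,
            )
            for b in chain
        ]
        identity = chain_identity(chain)
        span = sum(b.mrna_interval[1] - b.mrna_interval[0] for b in chain)
        if identity < min_identity or span < min_span:
            continue

        orientation = chain[0].orientation
        c_lo = min(b.cluster_interval[0] for b in chain)
        c_hi = max(b.cluster_interval[1] for b in chain)
        insertion = GenomicInterval(iv.chrom, iv.start + c_lo, iv.start + c_hi, "+")
        fragment_seq = cluster_seq[c_lo:c_hi]

        exon_spans = _exon_tx_spans(mrna)
        covered = []
        for idx, (s0, s1) in enumerate(exon_spans, start=1):
            ov = sum(
                max(0, min(b.mrna_interval[1], s1) - max(b.mrna_interval[0], s0))
                for b in chain
            )
            if ov >= min(10, s1 - s0):
                covered.append(idx)

        m_start = min(b.mrna_interval[0] for b in chain)
        truncated = m_start > truncation_margin
        processed = _is_processed(fragment_seq, genome, mrna, scoring)
        tsd, refined = refine_tsd(
            chrom_seq,
            (insertion.start, insertion.end),
            boundary_slack=tsd_boundary_slack,
            **(tsd_kwargs or {}),
        )
        if tsd is not None:
            insertion = GenomicInterval(iv.chrom, refined[0], refined[1], "+")

        # is the fragment antisense to the cluster's piRNA-producing strand?
        strands = {i.strand for i in cluster.intervals}
        frag_mrna_sense_strand = "+" if orientation == SAME else "-"
        pirna_antisense = any(s != frag_mrna_sense_strand for s in strands)

        calls.append(
            PGFCall(
                cluster_id=cluster.cluster_id,
                insertion=insertion,
                parental_gene=mrna.gene_id,
                blocks=chain,
                identity=identity,
                covered_exons=covered,
                processed=processed,
                five_prime_truncated=truncated,
                orientation=orientation,
                pirna_antisense=pirna_antisense,
                tsd=tsd,
            )
        )
    calls.sort(key=lambda c: (-c.identity * c.aligned_mrna_length, c.parental_gene))
    return calls


def pairwise_cluster_identity(
    seq_a: str,
    seq_b: str,
    min_block_identity: float = 0.5,
    min_block_len: int = 50,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> dict:
    """Percent identity over the best collinear chain of local blocks.

    Returns identity (percent; None when no chain exists) together with
    the aligned-coverage fraction of each input so the identity is
    interpretable: high identity over 2% of a locus is not conservation.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    chain = align_cluster_to_mrna(
        seq_a, seq_b, min_block_identity=min_block_identity,
        min_block_len=min_block_len, scoring=scoring,
    )
    if not chain:
        return {"identity_pct": None, "coverage_a": 0.0, "coverage_b": 0.0, "blocks": []}
    ident = 100.0 * chain_identity(chain)
    cov_a = sum(b.cluster_interval[1] - b.cluster_interval[0] for b in chain) / len(seq_a)
    cov_b = sum(b.mrna_interval[1] - b.mrna_interval[0] for b in chain) / len(seq_b)
    return {"identity_pct": ident, "coverage_a": cov_a, "coverage_b": cov_b, "blocks": chain}
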