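"""Standard-format I/O and primary sequence containers.

This module owns the coordinate conventions for the whole package:
internally everything is 0-based, half-open, with explicit strand. GTF
input (1-based, inclusive) is converted at the boundary; BED is taken
as-is. Mature mRNA sequences are built by splicing exon sequences in
genomic order and reverse-complementing minus-strand transcripts as a
single unit, so transcript coordinate 0 is always the 5' end of the
mature mRNA.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import gffutils
import pyfaidx

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Default retained length window for small-RNA libraries. Pachytene
#: piRNAs are 26-31 nt; the margin tolerates imperfectly trimmed ends.
DEFAULT_MIN_LEN = 24
DEFAULT_MAX_LEN = 34


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


class CoordinateError(ValueError):
    """A feature lies outside its chromosome or violates interval rules."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Locus overlap, ignoring strand."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A transcript with spliced (mature) sequence and CDS segmentation.

    ``cds_span`` is a half-open interval in transcript coordinates
    (0 = mature 5' end).  The 3'UTR is ``[cds_end, length)``.
    """

    gene_id: str
    transcript_id: str
    locus: GenomicInterval
    exons: list[GenomicInterval]
    cds_span: Optional[tuple[int, int]] = None
    mature_seq: str = ""

    def __post_init__(self) -> None:
        exs = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exs, exs[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} / {b.start}-{b.end}"
                )
            if a.chrom != b.chrom or a.strand != b.strand:
                raise AnnotationError(
                    f"{self.transcript_id}: exons on mixed chrom/strand"
                )
        self.exons = exs

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def strand(self) -> str:
        return self.locus.strand

    @property
    def cds_length(self) -> int:
        return 0 if self.cds_span is None else self.cds_span[1] - self.cds_span[0]

    def region_of(self, pos: int) -> str:
        """Classify a transcript coordinate as 5UTR / CDS / 3UTR / noncoding."""
        if not 0 <= pos < self.length:
            raise CoordinateError(
                f"{self.transcript_id}: position {pos} outside [0, {self.length})"
            )
        if self.cds_span is None:
            return "noncoding"
        lo, hi = self.cds_span
        if pos < lo:
            return "5UTR"
        if pos < hi:
            return "CDS"
        return "3UTR"

    def to_genomic(self, pos: int) -> int:
        """Project a transcript coordinate onto the genome."""
        if not 0 <= pos < self.length:
            raise CoordinateError(f"transcript position {pos} out of bounds")
        if self.strand == "-":
            pos = self.length - 1 - pos
        for exon in self.exons:
            if pos < len(exon):
                return exon.start + pos
            pos -= len(exon)
        raise AssertionError("unreachable")


@dataclass
class SmallRNALibrary:
    """Collapsed small-RNA library: unique sequence -> read count.

    Sequences are DNA-alphabet (U normalized to T at ingest) and all fall
    within ``length_range``. ``total_reads`` is the retained read mass.
    """

    records: dict[str, int]
    length_range: tuple[int, int] = (DEFAULT_MIN_LEN, DEFAULT_MAX_LEN)
    dropped_n: int = 0
    dropped_length: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        for seq, count in self.records.items():
            if count <= 0:
                raise ValueError(f"non-positive count for {seq}")
            if not lo <= len(seq) <= hi:
                raise ValueError(
                    f"sequence of length {len(seq)} outside window [{lo},{hi}]"
                )

    @property
    def total_reads(self) -> int:
        return sum(self.records.values())

    @property
    def n_species(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.records.items())


@dataclass
class ClusterAnnotation:
    """A piRNA cluster locus; bidirectional loci carry a second interval."""

    cluster_id: str
    interval: GenomicInterval
    second_interval: Optional[GenomicInterval] = None

    @property
    def intervals(self) -> list[GenomicInterval]:
        out = [self.interval]
        if self.second_interval is not None:
            out.append(self.second_interval)
        return out


# ---------------------------------------------------------------------------
# FASTA / GTF / BED readers
# ---------------------------------------------------------------------------


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a (multi-record) genome FASTA into an uppercase chrom->seq map."""
    fa = pyfaidx.Fasta(str(path), rebuild=True, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def _transcript_cds_span(
    exons: Sequence[GenomicInterval], cds: Sequence[tuple[int, int]], strand: str
) -> Optional[tuple[int, int]]:
    """Project genomic CDS segments into transcript coordinates."""
    if not cds:
        return None
    length = sum(len(e) for e in exons)
    g_lo = min(s for s, _ in cds)
    g_hi = max(e for _, e in cds)

    def genome_to_tx(gpos: int) -> int:
        off = 0
        for exon in exons:
            if exon.start <= gpos < exon.end:
                t = off + (gpos - exon.start)
                return length - 1 - t if strand == "-" else t
            off += len(exon)
        raise AnnotationError(f"CDS coordinate {gpos} not inside any exon")

    a = genome_to_tx(g_lo)
    b = genome_to_tx(g_hi - 1)
    lo, hi = min(a, b), max(a, b)
    return (lo, hi + 1)


def read_annotation(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF/GFF3 into transcript models (without mature sequence).

    Requires exon features with gene_id/transcript_id attributes; CDS
    features, when present, define the coding span.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    genes: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{path}: {feat.featuretype} at {feat.seqid}:{feat.start} "
                f"missing {exc} attribute"
            ) from None
        genes[tid] = gid
        # GTF/GFF are 1-based inclusive
        iv = (feat.start - 1, feat.end)
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(
                GenomicInterval(feat.seqid, iv[0], iv[1], feat.strand)
            )
        else:
            cds.setdefault(tid, []).append(iv)

    models = []
    for tid, exon_list in exons.items():
        exon_list = sorted(exon_list, key=lambda e: e.start)
        strand = exon_list[0].strand
        locus = GenomicInterval(
            exon_list[0].chrom, exon_list[0].start, exon_list[-1].end, strand
        )
        models.append(
            TranscriptModel(
                gene_id=genes[tid],
                transcript_id=tid,
                locus=locus,
                exons=exon_list,
                cds_span=_transcript_cds_span(exon_list, cds.get(tid, []), strand),
            )
        )
    models.sort(key=lambda m: (m.gene_id, m.transcript_id))
    return models


def read_clusters_bed(path: str | Path) -> list[ClusterAnnotation]:
    """Read a BED6 cluster annotation; strand '.' marks a bidirectional locus.

    Two records sharing a name are merged into one bidirectional annotation.
    """
    raw: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise AnnotationError(
                    f"{path}:{lineno}: BED record needs >=4 columns, got {len(parts)}"
                )
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3]
            strand = parts[5] if len(parts) >= 6 else "."
            if strand == ".":
                # bidirectional locus: represent as both strands
                ivs = [
                    GenomicInterval(chrom, start, end, "+"),
                    GenomicInterval(chrom, start, end, "-"),
                ]
            else:
                ivs = [GenomicInterval(chrom, start, end, strand)]
            if name not in raw:
                order.append(name)
            raw.setdefault(name, []).extend(ivs)

    clusters = []
    for name in order:
        ivs = raw[name]
        if len(ivs) == 1:
            clusters.append(ClusterAnnotation(name, ivs[0]))
        elif len(ivs) == 2:
            clusters.append(ClusterAnnotation(name, ivs[0], ivs[1]))
        else:
            raise AnnotationError(f"cluster {name}: more than two intervals")
    return clusters


def write_clusters_bed(clusters: Sequence[ClusterAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            if c.second_interval is not None and (
                c.second_interval.start == c.interval.start
                and c.second_interval.end == c.interval.end
            ):
                ivs = [(c.interval, ".")]
            else:
                ivs = [(iv, iv.strand) for iv in c.intervals]
            for iv, strand in ivs:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.cluster_id}\t0\t{strand}\n"
                )


# ---------------------------------------------------------------------------
# Small-RNA library I/O
# ---------------------------------------------------------------------------


def collapse_reads(
    reads: Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> SmallRNALibrary:
    """Collapse raw reads into a counted library.

    U is normalized to T; reads containing N (or any non-ACGT character
    after normalization) are dropped, as are reads outside the length
    window. Dropped totals are kept on the returned library.
    """
    counts: Counter[str] = Counter()
    dropped_n = 0
    dropped_length = 0
    allowed = set("ACGT")
    for read in reads:
        seq = read.upper().replace("U", "T")
        if not set(seq) <= allowed:
            dropped_n += 1
            continue
        if not min_len <= len(seq) <= max_len:
            dropped_length += 1
            continue
        counts[seq] += 1
    if dropped_n or dropped_length:
        logger.info(
            "collapse_reads: dropped %d ambiguous and %d out-of-window reads",
            dropped_n,
            dropped_length,
        )
    return SmallRNALibrary(
        records=dict(counts),
        length_range=(min_len, max_len),
        dropped_n=dropped_n,
        dropped_length=dropped_length,
    )


def read_collapsed_fasta(
    path: str | Path,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> SmallRNALibrary:
    """Read a collapsed small-RNA FASTA with ``>seqNNN_xCOUNT`` headers."""
    records: dict[str, int] = {}
    dropped_n = 0
    dropped_length = 0
    header = None
    seqs: list[str] = []

    def flush() -> None:
        nonlocal dropped_n, dropped_length
        if header is None:
            return
        try:
            count = int(header.rsplit("_x", 1)[1])
        except (IndexError, ValueError):
            raise AnnotationError(
                f"{path}: header {header!r} lacks a _xCOUNT suffix"
            ) from None
        seq = "".join(seqs).upper().replace("U", "T")
        if not set(seq) <= set("ACGT"):
            dropped_n += count
        elif not min_len <= len(seq) <= max_len:
            dropped_length += count
        else:
            records[seq] = records.get(seq, 0) + count

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
                seqs = []
            else:
                if header is None:
                    raise AnnotationError(f"{path}: sequence before first header")
                seqs.append(line)
        flush()
    return SmallRNALibrary(
        records=records,
        length_range=(min_len, max_len),
        dropped_n=dropped_n,
        dropped_length=dropped_length,
    )


def write_collapsed_fasta(library: SmallRNALibrary, path: str | Path) -> None:
    """Write a library in the collapsed ``>seqNNN_xCOUNT`` dialect.

    Records are written in descending count then lexicographic order so
    output is deterministic.
    """
    items = sorted(library.records.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(items, 1):
            fh.write(f">seq{i}_x{count}\n{seq}\n")


def read_fastq_reads(path: str | Path) -> Iterator[str]:
    """Yield raw sequences from an (uncompressed) FASTQ file."""
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            if not head.startswith("@"):
                raise AnnotationError(f"{path}: malformed FASTQ header {head!r}")
            seq = fh.readline().strip()
            plus = fh.readline()
            qual = fh.readline()
            if not plus.startswith("+") or not qual:
                raise AnnotationError(f"{path}: truncated FASTQ record")
            yield seq


# ---------------------------------------------------------------------------
# Transcript construction and selection
# ---------------------------------------------------------------------------


def build_mature_transcript(
    genome: Mapping[str, str], model: TranscriptModel
) -> TranscriptModel:
    """Fill in ``mature_seq`` by splicing exons from the genome.

    Exon sequences are concatenated in genomic order and the concatenation
    is reverse-complemented as one unit for minus-strand transcripts.
    """
    chrom = model.locus.chrom
    if chrom not in genome:
        raise CoordinateError(f"{model.transcript_id}: unknown chromosome {chrom}")
    chrom_seq = genome[chrom]
    parts = []
    for exon in model.exons:
        if exon.end > len(chrom_seq):
            raise CoordinateError(
                f"{model.transcript_id}: exon {exon.start}-{exon.end} beyond "
                f"end of {chrom} (length {len(chrom_seq)})"
            )
        parts.append(chrom_seq[exon.start : exon.end])
    seq = "".join(parts)
    if model.strand == "-":
        seq = revcomp(seq)
    model.mature_seq = seq
    return model


def build_transcriptome(
    genome: Mapping[str, str], models: Iterable[TranscriptModel]
) -> list[TranscriptModel]:
    return [build_mature_transcript(genome, m) for m in models]


def select_representative_transcripts(
    models: Iterable[TranscriptModel],
) -> list[TranscriptModel]:
    """One transcript per gene: longest CDS, then longest mature sequence,
    then lexicographically smallest transcript_id."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None:
            best[m.gene_id] = m
            continue
        key_new = (-m.cds_length, -m.length, m.transcript_id)
        key_cur = (-cur.cds_length, -cur.length, cur.transcript_id)
        if key_new < key_cur:
            best[m.gene_id] = m
    return sorted(best.values(), key=lambda m: m.gene_id)
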