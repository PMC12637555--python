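# Methods

## The problem

Pachytene piRNAs are a meiosis-specific class of 26–31-nt small RNAs
produced from discrete genomic clusters and loaded onto PIWI-clade
Argonautes with slicer activity. Individually they show little obvious
complementarity to cellular transcripts, but viewed target-first, groups
of them converge on single mRNAs with near-perfect antisense
complementarity. The source of that complementarity is pseudogene
fragments (PGFs): partial, spliced copies of an mRNA inserted into a
cluster in antisense orientation, so the cluster's precursor transcript
yields thousands of piRNAs complementary to the parental gene. A single
cluster then acts as a discrete regulatory unit for a single gene — a
cluster→gene regulon — and deleting the cluster derepresses the target.

`piregulon` implements this target-centered analysis end to end:
targeting, ranking, origin tracing, regulon calling, PGF anatomy,
positional sequence signatures, and target-derepression statistics,
together with a synthetic-data generator that plants all of these
structures with a machine-readable truth manifest.

## Targeting model

A piRNA targets an mRNA wherever the reverse complement of its 20-nt
guide core — piRNA nucleotides 2–21 — matches the mRNA sense strand with
at most one mismatch. Matching is Watson–Crick only (G:U wobble counts
as a mismatch), ungapped, and position 1 of the piRNA is unconstrained,
reflecting the non-pairing 1U position of PIWI guides. The mismatch
budget (`max_mm`, default 1) applies uniformly across the core.

Scanning uses a pigeonhole half-site index: any 20-mer window within
Hamming distance 1 of a query shares at least one exact 10-mer half with
it, so two exact lookups enumerate all candidate windows, which are then
verified. The index is exact — the test suite checks equivalence with an
exhaustive sliding-window Hamming scan on seeded random instances.

The predicted cleavage site of a hit at mRNA window `[p, p+20)` is
recorded as coordinate `p+10`: the base 5′ of the scissile phosphate,
which lies between the mRNA bases paired to piRNA nt 11 and nt 10
(canonical slicer geometry).

Target ranking is read-weighted by default: a species' read count is the
natural weight when the question is how much silencing capacity
converges on a gene; a `species` counting mode is available. A species
hitting several genes contributes its full count to each (default) or to
a single best gene (`assign best`: fewest mismatches, longest covered
span, lexicographic id), under which per-gene fractions sum to exactly
one. The top-target set is the minimal rank prefix whose cumulative
share of mRNA-targeting reads reaches `mass_threshold` (default 0.70).

## Origins, attribution, and regulon calls

Origins are perfect, full-length genomic matches on either strand.
Multimapping species have their count apportioned equally across
origins; each origin's share accrues to the piRNA cluster containing its
start, or to `unassigned`. Cluster annotations are merged per id and
must be mutually disjoint; a bidirectional locus is one id spanning both
strands.

A species is *cis* for a gene when any perfect origin overlaps the
gene's genomic span (any strand), *trans* when all origins lie
elsewhere, *unplaced* with no perfect origin. Regulon calling
quantifies trans regulation: for each targeted gene, cis species are
excluded (configurable via `exclude_cis`) and the remaining targeting
reads are attributed to clusters; the dominant cluster is the argmax
share, and the one-to-one flag is set when that share reaches
`dominant_threshold` (default 0.5). Excluding cis species matters in
practice: antisense reads arising inside a gene's own locus match the
mRNA perfectly and can otherwise swamp the attribution of a weakly
targeted gene.

## PGF discovery

Cluster sequence is aligned against each mature mRNA in both
orientations with local (Smith–Waterman) alignment, scoring +2 match,
−3 mismatch, −5 gap open, −2 gap extend — parameters chosen for
high-identity fragment detection and all configurable. Candidate
parental genes are pre-screened by shared 13-mers, and alignment is
restricted to the seeded cluster neighbourhood, which bounds cost
without changing results on real candidates.

Alignments are decomposed into blocks at gaps of ≥30 nt (a retained
intron appears as such a gap); each block is trimmed to its
maximal-scoring column range under an end-strict score (+1 match, −3
mismatch/gap), because a maximal-scoring local alignment happily extends
a few net-positive columns into random flanking sequence, which would
otherwise dilute identity and blur the insertion boundary. Blocks above
`min_block_identity`/`min_block_len` are chained collinearly (weighted
longest-increasing-subsequence on matches; a ≤20-nt terminal overlap
between consecutive blocks is tolerated because block edges are
ambiguous at splice and divergence boundaries). Overall identity is
Σ matches / Σ alignment columns over the chain — gap columns inside
blocks count against identity, the large inter-block gaps do not; the
reports pair identity with aligned coverage so that a high identity over
a tiny aligned span is not mistaken for conservation.

A chain is promoted to a PGF call when identity ≥ `min_identity` (0.80)
and aligned mRNA span ≥ `min_span` (200 nt). Exon composition projects
the chain onto exon boundaries (an exon counts as covered at ≥10 aligned
nt or its full length if shorter). The fragment is *processed* when
realignment against the unspliced parental locus covers <30 intronic nt,
and *5′ truncated* when the chain starts more than `truncation_margin`
(50 nt) into the mRNA.

### Target-site duplications

`detect_tsd` searches for the longest pair of near-identical substrings
(defaults: 10–25 bp, ≤1 mismatch) with one copy ending within 30 nt
upstream of the insertion start and one beginning within 30 nt
downstream of the end; ties break by fewer mismatches, then proximity.
The minimum length default is 10 bp because at 8 bp with one mismatch
allowed, chance duplications qualify in roughly a quarter of TSD-free
loci (measured over 200 seeded trials); at 10 bp the chance rate is ~1%.

Within `call_pgf` the insertion boundary itself is uncertain by a few
bases (alignment ends over- or under-run the true boundary when flanking
bases coincide with parental sequence), so the boundary and TSD are
inferred jointly (`refine_tsd`): candidate boundaries range 15 nt inward
and 30 nt outward of the alignment ends, the duplication must abut the
boundary exactly, and candidates are ranked by fewest mismatches, then
length, then distance from the alignment ends. Mismatch-first ranking is
deliberate here: with length-first, a one-mismatch extension of the true
duplication into coincidentally matching bases would win.

## Expression response

Counts are normalized by median-of-ratios size factors (per sample, the
median over features with a nonzero geometric mean of count /
geometric-mean). Fold changes are `log2((mean_b + 1) / (mean_a + 1))` on
normalized counts. Target tiers (top / lower-ranked / non-target) are
compared by ECDFs and the two-sample Kolmogorov–Smirnov test (asymptotic
p, effective n = nm/(n+m)); a signed D is reported, positive when the
first tier is shifted toward up-regulation. Per-feature testing is a
two-sided Welch t-test on log2(normalized count + 1) with
Benjamini–Hochberg step-up correction at α = 0.05.

This stack is transparent and fully specified, but deliberately simple:
with three replicates per condition a Welch t-test has ~2–4 degrees of
freedom, so its p-values rarely fall below ~10⁻³–10⁻⁵ and BH across
~1,000 features has little power for any single feature, however large
its fold change. The tier-level KS comparison, not the per-feature
rejection, is the primary readout; the volcano table is descriptive.
Count-model engines with dispersion shrinkage would be more powerful and
are intentionally out of scope.

## Sequence signatures

Positional base frequencies are computed per position over sequences
long enough to cover it, read-weighted by default (a logo should reflect
the molecular pool) with a species mode. The scalar summaries are the 1U
fraction (T at position 1) and the 10A fraction; a strong 1U with
background-level 10A is the signature of primary biogenesis without
ping-pong amplification. A ping-pong 5′-overlap statistic is not
implemented; the absence of 10A enrichment carries that inference.

## Synthetic data and its truth manifest

The generator assembles chromosomes left-to-right from random uniform
background, multi-exon genes (defaults: 40 genes, 2–8 exons of
80–400 nt, introns 100–2,000 nt), and clusters (6 clusters, 5–30 kb),
so no coordinate shifting is ever needed. Each planted PGF is built from
the parental mature mRNA (contiguous exon subset; optionally one
retained intron), 5′-truncated (default 100 nt), mutated at the planted
divergence, oriented (antisense by default, relative to the cluster's
precursor), inserted into the cluster, and flanked by an exact TSD
copied from the insertion site (default 12 bp). Insertion points are
chosen so the first and last inserted bases differ from the adjacent
background base; without this the planted TSD is not identifiable — a
one-base-shifted description of the same locus is an equally valid exact
duplication whenever a boundary base coincides.

piRNA species are substrings of cluster precursors: lengths follow a
peaked 26–31 distribution; with probability β (default 0.8) a species
starts on a T, otherwise on a non-T, so the per-species 1U bias equals β
exactly. Start density over planted PGF spans is 5× the rest of the
cluster, mimicking the concentrated antisense coverage clusters show
over their fragments and guaranteeing each planted regulon measurable
read mass; with that default the mRNA-targeting share of the library
lands in the few-percent range typical of real pools. Read counts follow
a power law (Pareto tail, exponent 1.5, capped) partitioned so that the
background fraction (5% of reads, drawn from random non-cluster loci on
either strand) and equal cluster emission shares hold in expectation at
a fixed depth of 200,000 reads. Each read independently carries one
substitution error with probability 0.001 before collapsing. KO/WT
counts are negative binomial (lognormal per-gene means around 500,
dispersion 0.05, 3 replicates each) with the KO mean of true target
genes multiplied by the derepression fold change (default 3).

The truth manifest records every planted structure: PGF coordinates,
exact substitution counts, TSD sequences and positions, post-truncation
exon content, per-species origins and counts, per-gene targeting read
mass by source cluster, and the derepressed gene set.
`validate_manifest` re-checks the manifest against the emitted files.

What the generator does not emulate: repeat and transposon landscapes,
ping-pong piRNA pairs, non-uniform genome composition, isoform
diversity, adapter/quality artefacts, and batch structure in the count
matrix. Passing tests therefore demonstrate correctness of the
machinery on data with the assumed structure, not performance on real
libraries, where cluster annotation quality and multimapping are the
dominant practical difficulties.

All randomness flows through one `numpy` generator seeded from the
configuration; identical seeds give byte-identical output trees (no
hash-iteration or dict-order dependence).

## Numerical and design choices

- Coordinates are 0-based half-open internally; GTF converts at the
  boundary, BED is native. Minus-strand mature sequences are spliced in
  genomic order then reverse-complemented as one unit.
- One representative transcript per gene: longest CDS, then longest
  mature sequence, then lexicographic id.
- Small-RNA ingest normalizes U→T, drops reads with ambiguous bases,
  and keeps a 24–34-nt window by default (pachytene piRNAs are
  26–31 nt; the margin tolerates imperfect trimming).
- Ties anywhere (dominant clusters, representative transcripts, best
  gene assignment) break lexicographically, keeping runs deterministic.
- The per-gene pool-size conversion (`molecules_per_cell`) is a plain
  product with a user-supplied total pool size; no literature constant
  is baked in.
- Tests and the acceptance script run on scaled problem sizes — genomes
  of 60–500 kb, libraries of 10⁴–2×10⁵ reads, 50-seed recovery loops —
  chosen so the planted effects are comfortably measurable at those
  scales.

## Known limitations

- Origin mapping is exact-match only; a sequencing error makes a
  species "unplaced" rather than soft-matching its source.
- PGF discovery reports one call per (cluster, parental gene); two
  independent insertions of the same gene in one cluster in the same
  orientation would be chained or the better one reported, not both.
- The DE stack is intentionally simple (see above); its per-feature
  calls at n=3 are conservative.
- Chain identity is block-local; genes with highly diverged segments
  below the block threshold report identity over the surviving blocks
  and coverage makes that visible, but no global alignment identity is
  offered.
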