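"""Perfect-origin mapping, cis/trans, cluster attribution, regulon calls."""

import numpy as np
import pytest

from piregulon.origin_attribution import (
    ClusterIntervals,
    UNASSIGNED,
    attribute_to_clusters,
    call_regulon,
    classify_cis_trans,
    cluster_expression,
    cluster_origin_share,
    map_genomic_origins,
    tiled_coverage,
)
from piregulon.sequence_io import (
    ClusterAnnotation,
    GenomicInterval,
    SmallRNALibrary,
    revcomp,
)

from conftest import random_seq, string_search_oracle


def lib_of(*seqs, counts=None):
    counts = counts or [1] * len(seqs)
    return SmallRNALibrary(dict(zip(seqs, counts)))


class TestMapGenomicOrigins:
    def test_planted_forward_copy_found_on_plus_strand(self):
        rng = np.random.default_rng(0)
        pirna = random_seq(rng, 30)
        genome = {"chr1": random_seq(rng, 500) + pirna + random_seq(rng, 500)}
        hits = map_genomic_origins(lib_of(pirna), genome)[pirna]
        assert [(h.interval.start, h.strand) for h in hits] == [(500, "+")]

    def test_planted_revcomp_copy_found_on_minus_strand(self):
        rng = np.random.default_rng(1)
        pirna = random_seq(rng, 28)
        genome = {"chr1": random_seq(rng, 300) + revcomp(pirna) + random_seq(rng, 300)}
        hits = map_genomic_origins(lib_of(pirna), genome)[pirna]
        assert [(h.interval.start, h.strand) for h in hits] == [(300, "-")]

    @pytest.mark.parametrize("use_index", [False, True])
    def test_matches_naive_string_search_oracle(self, use_index):
        rng = np.random.default_rng(2)
        genome = {"chr1": random_seq(rng, 60_000), "chr2": random_seq(rng, 40_000)}
        species = []
        for _ in range(100):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            L = int(rng.integers(26, 32))
            p = int(rng.integers(0, len(genome[chrom]) - L))
            s = genome[chrom][p : p + L]
            species.append(s if rng.random() < 0.5 else revcomp(s))
        library = lib_of(*set(species))
        origins = map_genomic_origins(library, genome, use_index=use_index)
        for seq in library.records:
            got = sorted(
                (h.interval.chrom, h.interval.start, h.interval.end, h.strand)
                for h in origins[seq]
            )
            assert got == string_search_oracle(genome, seq)

    def test_unplaced_species_get_empty_list(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": random_seq(rng, 1000)}
        stranger = "ACGT" * 7
        assert map_genomic_origins(lib_of(stranger), genome)[stranger] == []


class TestClassifyCisTrans:
    gene = GenomicInterval("chr1", 1000, 5000, "+")

    def _hit(self, chrom, start, length=30, strand="+"):
        from piregulon.origin_attribution import GenomicHit

        return GenomicHit("x", GenomicInterval(chrom, start, start + length, strand))

    def test_origin_inside_gene_span_is_cis_any_strand(self):
        assert classify_cis_trans([self._hit("chr1", 2000, strand="-")], self.gene) == "cis"

    def test_distant_origin_is_trans(self):
        assert classify_cis_trans([self._hit("chr1", 2_000_000)], self.gene) == "trans"
        assert classify_cis_trans([self._hit("chr2", 2000)], self.gene) == "trans"

    def test_mixed_origins_follow_any_overlap_rule(self):
        hits = [self._hit("chr1", 2000), self._hit("chr1", 900_000)]
        assert classify_cis_trans(hits, self.gene) == "cis"

    def test_no_origin_is_unplaced(self):
        assert classify_cis_trans([], self.gene) == "unplaced"

    def test_invariant_under_renaming_and_translation(self):
        shift = 10_000
        gene2 = GenomicInterval("chrZ", 1000 + shift, 5000 + shift, "+")
        for start, expected in ((2000, "cis"), (800_000, "trans")):
            assert classify_cis_trans([self._hit("chr1", start)], self.gene) == expected
            assert (
                classify_cis_trans([self._hit("chrZ", start + shift)], gene2) == expected
            )


class TestAttribution:
    clusters = [
        ClusterAnnotation("piC1", GenomicInterval("chr1", 0, 10_000, "+")),
        ClusterAnnotation("piC2", GenomicInterval("chr1", 20_000, 30_000, "-")),
    ]

    def _origins(self, seq, *starts):
        from piregulon.origin_attribution import GenomicHit

        return {
            seq: [
                GenomicHit(seq, GenomicInterval("chr1", s, s + len(seq), "+"))
                for s in starts
            ]
        }

    def test_unique_origin_in_cluster_gets_full_weight(self):
        seq = "A" * 30
        w = attribute_to_clusters(self._origins(seq, 500), self.clusters, lib_of(seq, counts=[8]))
        assert w[seq] == {"piC1": 8.0}

    def test_equal_apportionment_across_origins(self):
        seq = "C" * 30
        w = attribute_to_clusters(
            self._origins(seq, 500, 15_000), self.clusters, lib_of(seq, counts=[10])
        )
        assert w[seq] == {"piC1": 5.0, UNASSIGNED: 5.0}

    def test_unique_only_mode_discards_multimappers(self):
        seq = "C" * 30
        w = attribute_to_clusters(
            self._origins(seq, 500, 25_000), self.clusters, lib_of(seq, counts=[10]),
            unique_only=True,
        )
        assert w[seq] == {UNASSIGNED: 10.0}

    def test_overlapping_clusters_rejected(self):
        bad = [
            ClusterAnnotation("a", GenomicInterval("chr1", 0, 100, "+")),
            ClusterAnnotation("b", GenomicInterval("chr1", 50, 200, "+")),
        ]
        with pytest.raises(ValueError, match="overlap"):
            ClusterIntervals(bad)

    def test_apportionment_conserves_read_mass(self):
        rng = np.random.default_rng(4)
        from piregulon.origin_attribution import GenomicHit

        origins, records = {}, {}
        for i in range(50):
            seq = random_seq(rng, 28) + str(i)  # force uniqueness
            seq = random_seq(rng, 30)
            records[seq] = records.get(seq, 0) + int(rng.integers(1, 50))
            n_origins = int(rng.integers(0, 4))
            starts = [int(rng.integers(0, 40_000)) for _ in range(n_origins)]
            origins[seq] = [
                GenomicHit(seq, GenomicInterval("chr1", s0, s0 + 30, "+"))
                for s0 in starts
            ]
        library = SmallRNALibrary(records)
        w = attribute_to_clusters(origins, self.clusters, library)
        total = sum(v for d in w.values() for v in d.values())
        assert total == pytest.approx(library.total_reads, rel=1e-9)


class TestCallRegulon:
    def test_direct_arithmetic_and_flag(self):
        weights = {
            "s1": {"piC1": 81.0}, "s2": {"piC2": 10.0}, "s3": {UNASSIGNED: 9.0},
        }
        call = call_regulon("geneA", ["s1", "s2", "s3"], weights)
        assert call.dominant_cluster == "piC1"
        assert call.dominant_fraction == pytest.approx(0.81)
        assert call.is_one_to_one

    def test_tie_breaks_lexicographically_and_flag_unset(self):
        weights = {"s": {"piC2": 40.0, "piC1": 40.0, UNASSIGNED: 20.0}}
        call = call_regulon("geneA", ["s"], weights)
        assert call.dominant_cluster == "piC1"
        assert call.dominant_fraction == pytest.approx(0.40)
        assert not call.is_one_to_one

    def test_no_cluster_mass_gives_no_dominant(self):
        call = call_regulon("geneA", ["s"], {"s": {UNASSIGNED: 5.0}})
        assert call.dominant_cluster is None
        assert not call.is_one_to_one


class TestTiledCoverage:
    def test_single_origin_rpm_arithmetic(self):
        from piregulon.origin_attribution import GenomicHit

        seq = "G" * 30
        origins = {seq: [GenomicHit(seq, GenomicInterval("chr1", 150, 180, "+"))]}
        filler = "A" * 30
        library = SmallRNALibrary({seq: 10, filler: 990})
        table = tiled_coverage(origins, library, {"chr1": 1000})
        row = table.iloc[0]
        assert (row.chrom, row.start, row.end, row.strand) == ("chr1", 100, 200, "+")
        assert row.rpm == pytest.approx(10 * 1e6 / 1000)

    def test_tile_must_be_positive(self):
        with pytest.raises(ValueError):
            tiled_coverage({}, SmallRNALibrary({"A" * 30: 1}), {}, tile=0)

    def test_tile_sums_match_bruteforce_tally(self):
        rng = np.random.default_rng(5)
        from piregulon.origin_attribution import GenomicHit

        records, origins = {}, {}
        for _ in range(60):
            seq = random_seq(rng, 29)
            records[seq] = int(rng.integers(1, 40))
            starts = [int(rng.integers(0, 5000)) for _ in range(int(rng.integers(1, 3)))]
            origins[seq] = [
                GenomicHit(seq, GenomicInterval("chr1", s0, s0 + 29,
                                                "+" if rng.random() < 0.5 else "-"))
                for s0 in starts
            ]
        library = SmallRNALibrary(records)
        table = tiled_coverage(origins, library, {"chr1": 5100})
        tally = {}
        for seq, hits in origins.items():
            for h in hits:
                key = (h.interval.start // 100, h.strand)
                tally[key] = tally.get(key, 0.0) + records[seq] / len(hits)
        for _, row in table.iterrows():
            assert row.rpm == pytest.approx(
                tally[(row.start // 100, row.strand)] * 1e6 / library.total_reads
            )
        assert len(table) == len(tally)


class TestClusterExpression:
    def test_percentile_subset_takes_top_cluster(self):
        weights = {f"s{i}": {f"piC{i}": float(i + 1)} for i in range(10)}
        library = SmallRNALibrary({("A" * 29 + "T"): 100})
        table, top = cluster_expression(weights, library, percentile=90)
        assert top == ["piC9"]
        assert table.iloc[0].cluster_id == "piC9"

    def test_all_zero_clusters_give_empty_subset(self):
        library = SmallRNALibrary({"A" * 30: 10})
        table, top = cluster_expression({"s": {UNASSIGNED: 10.0}}, library)
        assert top == []

    def test_cluster_origin_share_fraction(self):
        weights = {"a": {"piC1": 86.0}, "b": {UNASSIGNED: 14.0}}
        assert cluster_origin_share(weights) == pytest.approx(0.86)
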