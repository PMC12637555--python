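"""Guide-core extraction, antisense scanning, ranking, coverage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from piregulon.sequence_io import SmallRNALibrary, revcomp
from piregulon.target_scan import (
    CORE_LEN,
    GuideTooShortError,
    HalfSiteIndex,
    coverage_profile,
    extract_guide_core,
    molecules_per_cell,
    rank_targets,
    scan_transcript,
)

from conftest import hamming_scan_oracle, make_transcript, random_seq


def make_pirna_for(mrna_seq: str, p: int, flank5: str = "T", flank3: str = "CGA") -> str:
    """A piRNA whose nt 2-21 core is the perfect antisense of mrna[p:p+20]."""
    return flank5 + revcomp(mrna_seq[p : p + CORE_LEN]) + flank3


class TestExtractGuideCore:
    def test_core_is_positions_2_to_21(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 nt
        core = extract_guide_core(seq)
        assert core.core == seq[1:21]
        assert len(core.core) == 20

    def test_21mer_core_is_last_20(self):
        seq = "G" + "ACGTACGTACGTACGTACGT"
        assert extract_guide_core(seq).core == seq[1:]

    def test_20mer_is_too_short(self):
        with pytest.raises(GuideTooShortError):
            extract_guide_core("A" * 20)


class TestScanTranscript:
    def test_constructed_perfect_complement_hits_once(self):
        mrna = make_transcript("AAAACCCCGGGGTTTTACGTACGT")
        pirna = make_pirna_for(mrna.mature_seq, 2)
        hits = scan_transcript(extract_guide_core(pirna), mrna)
        assert len(hits) == 1
        assert hits[0].window == (2, 22)
        assert hits[0].mismatches == 0
        assert hits[0].cleavage_site == 12  # window start + 10

    def test_one_substitution_counts_one_mismatch_two_kill_the_hit(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 60)
        mrna = make_transcript(seq)
        pirna = make_pirna_for(seq, 10)

        def mutate(s, idx):
            alt = "ACGT"[("ACGT".index(s[idx]) + 1) % 4]
            return s[:idx] + alt + s[idx + 1 :]

        one = mutate(pirna, 5)  # inside core (positions 1..20 of string)
        hits = scan_transcript(extract_guide_core(one), mrna)
        assert [h.mismatches for h in hits if h.window == (10, 30)] == [1]
        two = mutate(one, 12)
        hits = scan_transcript(extract_guide_core(two), mrna)
        assert all(h.window != (10, 30) for h in hits)

    def test_first_position_is_unconstrained(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 40)
        mrna = make_transcript(seq)
        for base in "ACGT":
            pirna = make_pirna_for(seq, 3, flank5=base)
            hits = scan_transcript(extract_guide_core(pirna), mrna)
            assert any(h.window == (3, 23) and h.mismatches == 0 for h in hits)

    def test_mm0_hits_subset_of_mm1_hits(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 500)
        mrna = make_transcript(seq)
        for _ in range(20):
            pirna = random_seq(rng, 28)
            core = extract_guide_core(pirna)
            h0 = {h.window for h in scan_transcript(core, mrna, max_mm=0)}
            h1 = {h.window for h in scan_transcript(core, mrna, max_mm=1)}
            assert h0 <= h1


class TestHalfSiteIndex:
    def test_single_window_mrna_found_via_either_half(self):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 20)
        mrna = make_transcript(seq)
        index = HalfSiteIndex([mrna])
        pirna = "T" + revcomp(seq) + "AAA"
        hits = index.scan(extract_guide_core(pirna))
        assert [(h.window, h.mismatches) for h in hits] == [((0, 20), 0)]

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_indexed_scan_equals_bruteforce_oracle(self, seed):
        """Pigeonhole index reproduces the exhaustive Hamming scan."""
        rng = np.random.default_rng(seed)
        mrna = make_transcript(random_seq(rng, 1000))
        index = HalfSiteIndex([mrna])
        n_with_hits = 0
        for _ in range(200):
            if rng.random() < 0.3:  # plant matches so the test is non-vacuous
                p = int(rng.integers(0, 980))
                pirna = make_pirna_for(mrna.mature_seq, p)
                if rng.random() < 0.5:
                    i = int(rng.integers(1, 21))
                    alt = "ACGT"[("ACGT".index(pirna[i]) + 1) % 4]
                    pirna = pirna[:i] + alt + pirna[i + 1 :]
            else:
                pirna = random_seq(rng, 28)
            core = extract_guide_core(pirna)
            got = sorted((h.window[0], h.mismatches) for h in index.scan(core))
            expected = hamming_scan_oracle(core.core, mrna.mature_seq)
            assert got == expected
            n_with_hits += bool(got)
        assert n_with_hits > 30

    def test_multi_transcript_scan_equals_per_transcript_bruteforce(self):
        rng = np.random.default_rng(9)
        transcripts = [
            make_transcript(random_seq(rng, 300), gene_id=f"g{i}") for i in range(50)
        ]
        index = HalfSiteIndex(transcripts)
        for _ in range(50):
            pirna = make_pirna_for(transcripts[int(rng.integers(0, 50))].mature_seq,
                                   int(rng.integers(0, 280)))
            core = extract_guide_core(pirna)
            got = sorted((h.gene_id, h.window[0], h.mismatches) for h in index.scan(core))
            expected = sorted(
                (t.gene_id, p, mm)
                for t in transcripts
                for p, mm in hamming_scan_oracle(core.core, t.mature_seq)
            )
            assert got == expected


class TestRankTargets:
    def _lib(self, records):
        return SmallRNALibrary(records={k: v for k, v in records.items()})

    def _hits(self, index, lib):
        return index.scan_library(lib)

    def test_fractions_and_top_set_direct_arithmetic(self):
        rng = np.random.default_rng(4)
        g1 = make_transcript(random_seq(rng, 200), gene_id="gene1")
        g2 = make_transcript(random_seq(rng, 200), gene_id="gene2")
        index = HalfSiteIndex([g1, g2])
        a = make_pirna_for(g1.mature_seq, 10)
        b = make_pirna_for(g2.mature_seq, 50)
        c = make_pirna_for(g1.mature_seq, 100)
        lib = self._lib({a: 70, b: 20, c: 10})
        ranking = rank_targets(self._hits(index, lib), lib, [g1, g2])
        tab = ranking.table.set_index("gene_id")
        assert tab.loc["gene1", "fraction"] == pytest.approx(0.8)
        assert tab.loc["gene2", "fraction"] == pytest.approx(0.2)
        assert ranking.top_targets == ["gene1"]

    def test_multi_gene_species_contributes_full_count_to_each(self):
        rng = np.random.default_rng(6)
        shared = random_seq(rng, 40)
        g1 = make_transcript(shared + random_seq(rng, 60), gene_id="gene1")
        g2 = make_transcript(shared + random_seq(rng, 80), gene_id="gene2")
        index = HalfSiteIndex([g1, g2])
        pirna = make_pirna_for(shared, 5)
        lib = self._lib({pirna: 10})
        ranking = rank_targets(index.scan_library(lib), lib, [g1, g2])
        tab = ranking.table.set_index("gene_id")
        assert tab.loc["gene1", "reads"] == 10
        assert tab.loc["gene2", "reads"] == 10
        assert tab.loc["gene1", "fraction"] == pytest.approx(1.0)

    def test_best_assignment_fractions_sum_to_one(self):
        rng = np.random.default_rng(7)
        transcripts = [make_transcript(random_seq(rng, 400), gene_id=f"g{i}") for i in range(5)]
        index = HalfSiteIndex(transcripts)
        records = {}
        for _ in range(30):
            t = transcripts[int(rng.integers(0, 5))]
            records[make_pirna_for(t.mature_seq, int(rng.integers(0, 380)))] = int(
                rng.integers(1, 100)
            )
        lib = self._lib(records)
        ranking = rank_targets(index.scan_library(lib), lib, transcripts, assign_mode="best")
        assert ranking.table["fraction"].sum() == pytest.approx(1.0)

    def test_empty_library_gives_empty_ranking(self):
        rng = np.random.default_rng(8)
        index = HalfSiteIndex([make_transcript(random_seq(rng, 100))])
        lib = self._lib({random_seq(rng, 30): 5})
        ranking = rank_targets(index.scan_library(lib), lib)
        # random 30-mer almost surely has no hit
        if ranking.total_targeting_reads == 0:
            assert ranking.top_targets == []
            assert len(ranking.table) == 0


class TestCoverageProfile:
    def test_single_hit_coverage_and_target_space(self):
        rng = np.random.default_rng(10)
        mrna = make_transcript(random_seq(rng, 30), cds=(0, 25))
        pirna = "GG" + make_pirna_for(mrna.mature_seq, 2, flank5="")[0:]
        # build explicitly: nt1 pad + antisense core of window [2,22)
        pirna = "G" + revcomp(mrna.mature_seq[2:22]) + "AAACC"
        lib = SmallRNALibrary({pirna: 5})
        index = HalfSiteIndex([mrna])
        hits = index.scan(extract_guide_core(pirna))
        prof = coverage_profile(hits, lib, mrna)
        assert prof.coverage[2:22].tolist() == [5.0] * 20
        assert prof.coverage[:2].tolist() == [0.0, 0.0]
        assert prof.target_space == 20

    def test_overlapping_hits_are_additive(self):
        rng = np.random.default_rng(12)
        mrna = make_transcript(random_seq(rng, 30), cds=(0, 30))
        p1 = "G" + revcomp(mrna.mature_seq[0:20]) + "AAACC"
        p2 = "G" + revcomp(mrna.mature_seq[10:30]) + "AAACC"
        lib = SmallRNALibrary({p1: 1, p2: 2})
        index = HalfSiteIndex([mrna])
        hits = index.scan(extract_guide_core(p1)) + index.scan(extract_guide_core(p2))
        hits = [h for h in hits if h.mismatches == 0 and h.window in ((0, 20), (10, 30))]
        prof = coverage_profile(hits, lib, mrna)
        assert prof.coverage[:10].tolist() == [1.0] * 10
        assert prof.coverage[10:20].tolist() == [3.0] * 10
        assert prof.coverage[20:30].tolist() == [2.0] * 10
        assert prof.target_space == 30

    def test_target_space_equals_interval_union_oracle(self):
        rng = np.random.default_rng(13)
        mrna = make_transcript(random_seq(rng, 500), gene_id="gX", cds=(50, 400))
        index = HalfSiteIndex([mrna])
        records, all_hits = {}, []
        for _ in range(40):
            p = int(rng.integers(0, 480))
            pirna = "C" + revcomp(mrna.mature_seq[p : p + 20]) + random_seq(rng, 5)
            records[pirna] = records.get(pirna, 0) + int(rng.integers(1, 20))
            all_hits.extend(index.scan(extract_guide_core(pirna)))
        lib = SmallRNALibrary(records)
        prof = coverage_profile(all_hits, lib, mrna)
        union = set()
        for h in all_hits:
            union.update(range(*h.window))
        assert prof.target_space == len(union)


class TestMoleculesPerCell:
    @pytest.mark.parametrize(
        "fraction,pool,expected",
        [(0.016, 1e7, 160_000), (0.0, 1e7, 0.0), (0.12, 160_000, 19_200)],
    )
    def test_product_is_reported_unrounded(self, fraction, pool, expected):
        assert molecules_per_cell(fraction, pool) == pytest.approx(expected)

    def test_rejects_fraction_outside_unit_interval(self):
        with pytest.raises(ValueError):
            molecules_per_cell(1.2, 1e6)
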