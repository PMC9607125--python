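"""Length normalization, promoter detection, location taxonomy, feature table."""

import math

import numpy as np
import pytest

from lncsift.errors import LncSiftError
from lncsift.feature_extraction import (
    FEATURE_ORDER,
    PromoterScorer,
    build_feature_vectors,
    classify_location,
    detect_promoter,
    fit_length_normalizer,
    summed_exon_length,
)
from lncsift.genomics_io import GenomicInterval, PeakSet, five_prime_end

from conftest import make_annotation, make_transcript


class TestSummedExonLength:
    def test_multi_exon_sum(self):
        t = make_transcript("t", "+", [(100, 200), (300, 450)])
        assert summed_exon_length(t) == 250

    def test_single_exon_equals_span(self):
        t = make_transcript("t", "+", [(0, 201)])
        assert summed_exon_length(t) == 201 == len(t.interval)


class TestLengthNormalizer:
    def test_minmax_endpoints_and_midpoint(self):
        lengths = [math.exp(1), math.exp(2), math.exp(3)]
        norm = fit_length_normalizer(lengths)
        out = norm.transform(lengths)
        assert out == pytest.approx([0.0, 0.5, 1.0])

    def test_degenerate_range_maps_to_half(self):
        norm = fit_length_normalizer([500.0] * 8)
        assert norm.transform([500.0, 123.0]) == pytest.approx([0.5, 0.5])

    def test_outlier_clips_to_one_against_hand_recomputation(self):
        # ten log-lengths with one extreme outlier; expected values recomputed
        # here with plain spreadsheet-style arithmetic, independent of the
        # implementation's vector path
        logs = [1.0, 2.0, 2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.4, 20.0]
        lengths = [math.exp(x) for x in logs]
        mean = sum(logs) / len(logs)
        var = sum((x - mean) ** 2 for x in logs) / len(logs)
        sd = math.sqrt(var)
        lo_lim, hi_lim = mean - 3 * sd, mean + 3 * sd
        clipped = [min(max(x, lo_lim), hi_lim) for x in logs]
        lo, hi = min(clipped), max(clipped)
        expected = [(x - lo) / (hi - lo) for x in clipped]

        norm = fit_length_normalizer(lengths)
        assert norm.transform(lengths) == pytest.approx(expected)
        # the outlier itself lands exactly on the clip boundary -> exactly 1.0
        assert norm.transform([lengths[-1]])[0] == 1.0

    def test_unseen_values_clip_into_unit_interval(self):
        norm = fit_length_normalizer([100.0, 1000.0, 10_000.0])
        assert norm.transform_one(1.0) == 0.0
        assert norm.transform_one(1e9) == 1.0

    def test_order_preserving(self):
        rng = np.random.default_rng(2)
        lengths = rng.integers(200, 100_000, size=500).astype(float)
        norm = fit_length_normalizer(lengths)
        ordered = np.sort(lengths)
        out = norm.transform(ordered)
        assert (np.diff(out) >= 0).all()

    def test_empty_and_invalid_inputs_rejected(self):
        with pytest.raises(LncSiftError):
            fit_length_normalizer([])
        with pytest.raises(LncSiftError):
            fit_length_normalizer([0.5, 100.0])


class TestDetectPromoter:
    def promoters(self, intervals):
        return PeakSet(GenomicInterval("chr1", s, e, ".") for s, e in intervals)

    def test_call_within_upstream_window(self):
        t = make_transcript("t", "+", [(5000, 6000)])
        assert detect_promoter(t, self.promoters([(4700, 4750)])) == 1

    def test_call_outside_window(self):
        t = make_transcript("t", "+", [(5000, 6000)])
        assert detect_promoter(t, self.promoters([(3400, 3500)])) == 0

    def test_no_evidence_is_zero(self):
        t = make_transcript("t", "+", [(5000, 6000)])
        assert detect_promoter(t) == 0

    def test_symmetric_window_sees_downstream_upstream_mode_does_not(self):
        t = make_transcript("t", "+", [(5000, 6000)])
        downstream = self.promoters([(5400, 5450)])
        assert detect_promoter(t, downstream, mode="symmetric") == 1
        assert detect_promoter(t, downstream, mode="upstream") == 0

    def test_upstream_mode_is_strand_aware(self):
        t = make_transcript("t", "-", [(5000, 6000)])  # 5' end at 5999
        right_of_end = self.promoters([(6300, 6350)])
        assert detect_promoter(t, right_of_end, mode="upstream") == 1

    def test_sequence_mode_tata_and_background(self):
        t = make_transcript("t", "+", [(1000, 1600)])
        n = 3000
        background = ("ATAACCATTG" * (n // 10))[:n]
        with_tata = background[:900] + "TATATAAG" + background[908:]
        assert detect_promoter(t, genome={"chr1": with_tata}) == 1
        assert detect_promoter(t, genome={"chr1": background}) == 0

    def test_scorer_cpg_island_detection(self):
        scorer = PromoterScorer()
        assert scorer.scan("GCGCGCGC" * 40) == 1
        assert scorer.scan("ATATTTAA" * 40) == 0
        assert scorer.scan("") == 0


class TestClassifyLocation:
    @pytest.fixture
    def annotation(self):
        return make_annotation(
            [
                ("pc_plus", "protein_coding", "chr1", 10_000, 15_000, "+"),
                ("pc_minus", "protein_coding", "chr1", 30_000, 36_000, "-"),
                ("lnc", "lncRNA", "chr1", 50_000, 52_000, "+"),
            ]
        )

    def test_divergent_near_opposite_tss(self, annotation):
        # 5' end at 10_500 on -, protein-coding TSS 10_000 on +: distance 500
        t = make_transcript("t", "-", [(9_000, 10_501)])
        assert five_prime_end(t) == 10_500
        assert classify_location(t, annotation) == "divergent"

    def test_antisense_needs_one_base_of_opposite_overlap(self, annotation):
        # overlaps the - strand gene body by 1 bp; TSS (35_999) is > 2 kb away
        t = make_transcript("t", "+", [(29_500, 30_001)])
        assert classify_location(t, annotation) == "antisense"
        not_touching = make_transcript("t2", "+", [(29_400, 30_000)])
        assert classify_location(not_touching, annotation) == "intergenic"

    def test_divergent_takes_precedence_over_antisense(self, annotation):
        # overlaps pc_minus and sits within 2 kb of its TSS on the opposite strand
        t = make_transcript("t", "+", [(35_000, 36_500)])
        assert classify_location(t, annotation) == "divergent"

    def test_far_transcript_is_intergenic(self, annotation):
        t = make_transcript("t", "+", [(500_000, 501_000)])
        assert classify_location(t, annotation) == "intergenic"

    def test_non_coding_genes_are_invisible_to_the_taxonomy(self, annotation):
        t = make_transcript("t", "-", [(50_500, 51_500)])
        assert classify_location(t, annotation) == "intergenic"

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(21)
        genes = []
        for i in range(60):
            s = int(rng.integers(0, 500_000))
            e = s + int(rng.integers(500, 20_000))
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = rng.choice(["protein_coding", "pseudogene", "lncRNA"], p=[0.6, 0.2, 0.2])
            genes.append((f"g{i}", str(biotype), "chr1", s, e, strand))
        ann = make_annotation(genes)
        for i in range(400):
            s = int(rng.integers(0, 510_000))
            t = make_transcript(
                f"t{i}", "+" if rng.random() < 0.5 else "-",
                [(s, s + int(rng.integers(200, 8000)))],
            )
            p = five_prime_end(t)
            opp = "-" if t.strand == "+" else "+"
            pc = [
                (gs, ge, strand, gs if strand == "+" else ge - 1)
                for _, b, _, gs, ge, strand in genes
                if b == "protein_coding"
            ]
            if any(strand == opp and abs(p - tss) <= 2000 for _, _, strand, tss in pc):
                expected = "divergent"
            elif any(
                strand == opp
                and min(t.interval.end, ge) - max(t.interval.start, gs) > 0
                for gs, ge, strand, _ in pc
            ):
                expected = "antisense"
            else:
                expected = "intergenic"
            assert classify_location(t, ann) == expected


class TestBuildFeatureVectors:
    def test_planted_fixture_vectors(self, toy_transcripts, toy_annotation, toy_promoters):
        retained = [
            t for t in toy_transcripts
            if t.transcript_id in ("t_divergent", "t_antisense", "t_intergenic")
        ]
        table, norm = build_feature_vectors(
            retained, toy_annotation, promoter_calls=toy_promoters
        )
        assert list(table.columns) == list(FEATURE_ORDER)
        div = table.loc["t_divergent"]
        assert (div.promoter, div.multiexon, div.divergent, div.antisense, div.intergenic) == (1, 1, 1, 0, 0)
        anti = table.loc["t_antisense"]
        assert (anti.promoter, anti.multiexon, anti.antisense) == (0, 0, 1)
        inter = table.loc["t_intergenic"]
        assert (inter.multiexon, inter.intergenic) == (0, 1)
        assert table["length_scaled"].between(0, 1).all()

    def test_one_hot_partition_on_random_fixture(self):
        rng = np.random.default_rng(33)
        genes = [
            (f"g{i}", "protein_coding", "chr1",
             int(s := rng.integers(0, 900_000)), int(s) + int(rng.integers(1000, 30_000)),
             "+" if rng.random() < 0.5 else "-")
            for i in range(40)
        ]
        ann = make_annotation(genes)
        ts = []
        for i in range(1000):
            s = int(rng.integers(0, 950_000))
            n_ex = int(rng.integers(1, 4))
            exons, pos = [], s
            for _ in range(n_ex):
                ln = int(rng.integers(100, 2000))
                exons.append((pos, pos + ln))
                pos += ln + int(rng.integers(50, 500))
            ts.append(make_transcript(f"t{i}", "+" if rng.random() < 0.5 else "-", exons))
        table, _ = build_feature_vectors(ts, ann)
        onehot = table[["divergent", "antisense", "intergenic"]].sum(axis=1)
        assert (onehot == 1).all()
        counts = table[["divergent", "antisense", "intergenic"]].sum()
        assert counts.sum() == len(ts)
        assert (table["multiexon"] == [int(len(t.exons) >= 2) for t in ts]).all()
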