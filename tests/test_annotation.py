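import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_gene, make_peak
from grnexpress.annotation import (
    build_regulatory_window,
    candidate_window,
    ctcf_bounded_window,
    intronic_regions,
    longest_transcript,
    partition_peaks,
    promoter_region,
)
from grnexpress.intervals import GenomicInterval


class TestLongestTranscript:
    def test_single_transcript_identity(self):
        gene = make_gene(tx_specs=[("T1", 100_000, 110_000, None)])
        assert longest_transcript(gene).tx_id == "T1"

    def test_max_by_length(self):
        gene = make_gene(
            tx_specs=[("T1", 100_000, 101_000, None), ("T2", 100_000, 102_000, None)]
        )
        assert longest_transcript(gene).tx_id == "T2"

    def test_tie_broken_by_id(self):
        # oracle: sort by (-length, tx_id), take first -> Ta
        gene = make_gene(
            tx_specs=[("Tb", 100_000, 100_500, None), ("Ta", 100_200, 100_700, None)]
        )
        assert longest_transcript(gene).tx_id == "Ta"


class TestCandidateWindow:
    def test_plus_strand(self):
        gene = make_gene(strand="+", body=(100_000, 110_000))
        assert candidate_window(gene, 50_000) == GenomicInterval("chr1", 50_000, 160_000, "+")

    def test_minus_strand_mirrored(self):
        # hand oracle: TSS = 110000 on '-', flank upstream extends right
        gene = make_gene(strand="-", body=(100_000, 110_000))
        assert candidate_window(gene, 50_000) == GenomicInterval("chr1", 50_000, 160_000, "-")

    def test_clip_at_zero(self):
        gene = make_gene(strand="+", body=(10_000, 20_000))
        assert candidate_window(gene, 50_000).start == 0

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            candidate_window(make_gene(), -1)


class TestCtcfBoundedWindow:
    candidate = GenomicInterval("chr1", 50_000, 160_000)
    body = GenomicInterval("chr1", 100_000, 110_000)

    def test_no_peaks_returns_candidate(self):
        assert ctcf_bounded_window(self.candidate, self.body, []) == self.candidate

    def test_most_distant_upstream_peak_wins(self):
        # brute-force oracle: most distant from the body = midpoint 60000
        peaks = [
            GenomicInterval("chr1", 59_900, 60_100),
            GenomicInterval("chr1", 79_900, 80_100),
        ]
        bounded = ctcf_bounded_window(self.candidate, self.body, peaks)
        assert bounded.start == 60_000
        assert bounded.end == self.candidate.end

    def test_in_body_peaks_ignored(self):
        peaks = [GenomicInterval("chr1", 104_000, 105_000)]
        assert ctcf_bounded_window(self.candidate, self.body, peaks) == self.candidate

    def test_always_contains_gene_body(self):
        peaks = [
            GenomicInterval("chr1", 59_900, 60_100),
            GenomicInterval("chr1", 130_000, 130_200),
        ]
        bounded = ctcf_bounded_window(self.candidate, self.body, peaks)
        assert bounded.contains(self.body)
        assert self.candidate.contains(bounded)


class TestPromoterRegion:
    def test_plus_strand(self):
        gene = make_gene(strand="+", body=(100_000, 110_000))
        assert promoter_region(gene) == GenomicInterval("chr1", 95_000, 100_000, "+")

    def test_minus_strand(self):
        gene = make_gene(strand="-", body=(100_000, 110_000))
        assert promoter_region(gene) == GenomicInterval("chr1", 110_000, 115_000, "-")

    def test_clip_at_zero(self):
        gene = make_gene(strand="+", body=(2_000, 12_000))
        assert promoter_region(gene) == GenomicInterval("chr1", 0, 2_000, "+")


class TestIntronicRegions:
    def test_single_exon_transcript_empty(self):
        gene = make_gene(tx_specs=[("T1", 0, 100, None)], body=(0, 100))
        assert intronic_regions(gene) == []

    def test_span_minus_exons(self):
        gene = make_gene(
            tx_specs=[("T1", 0, 100, [(0, 20), (80, 100)])], body=(0, 100)
        )
        assert intronic_regions(gene) == [GenomicInterval("chr1", 20, 80, "+")]

    def test_union_across_transcripts(self):
        # brute-force base-set oracle: a base is intronic iff it lies in some
        # transcript span and in no exon of any transcript
        gene = make_gene(
            tx_specs=[
                ("T1", 0, 100, [(0, 20), (80, 100)]),
                ("T2", 0, 140, [(0, 50), (120, 140)]),
            ],
            body=(0, 140),
        )
        span_bases = set(range(0, 100)) | set(range(0, 140))
        exon_bases = (
            set(range(0, 20)) | set(range(80, 100)) | set(range(0, 50)) | set(range(120, 140))
        )
        expected = span_bases - exon_bases
        result = intronic_regions(gene)
        assert {b for iv in result for b in range(iv.start, iv.end)} == expected
        assert result == [
            GenomicInterval("chr1", 50, 80, "+"),
            GenomicInterval("chr1", 100, 120, "+"),
        ]

    def test_never_overlaps_exons(self, small_sim):
        _, ann, _, _ = small_sim
        for gene in ann.genes[:10]:
            introns = intronic_regions(gene)
            for tx in gene.transcripts:
                for exon in tx.exons:
                    assert not any(iv.overlaps(exon) for iv in introns)


class TestPartitionPeaks:
    def window(self):
        gene = make_gene(
            strand="+",
            body=(100_000, 110_000),
            tx_specs=[("T1", 100_000, 110_000, [(100_000, 102_000), (108_000, 110_000)])],
        )
        return build_regulatory_window(gene)

    def test_promoter_peak(self):
        w = self.window()
        parts = partition_peaks([make_peak("A", 96_000, 96_200)], w)
        assert [p.tf for p in parts["promoter"]] == ["A"]

    def test_precedence_promoter_over_other(self):
        # straddles the promoter/gene-start boundary -> promoter by precedence
        w = self.window()
        parts = partition_peaks([make_peak("A", 99_900, 100_100)], w)
        assert len(parts["promoter"]) == 1
        assert not parts["intronic"] and not parts["distal"]

    def test_intronic_and_distal(self):
        w = self.window()
        parts = partition_peaks(
            [make_peak("A", 103_000, 103_200), make_peak("B", 130_000, 130_200)], w
        )
        assert [p.tf for p in parts["intronic"]] == ["A"]
        assert [p.tf for p in parts["distal"]] == ["B"]

    def test_out_of_window_excluded(self):
        w = self.window()
        parts = partition_peaks([make_peak("A", 10, 200)], w)
        assert all(not v for v in parts.values())

    def test_disjoint_cover(self, small_sim):
        """Every in-window peak lands in exactly one category."""
        _, _, reg, _ = small_sim
        for gene_id, w in list(reg.windows.items())[:10]:
            parts = partition_peaks(reg.peaks, w)
            labeled = [p for plist in parts.values() for p in plist]
            in_window = [p for p in reg.peaks if p.interval.overlaps(w.bounded)]
            assert len(labeled) == len(in_window)
            assert {id(p) for p in labeled} == {id(p) for p in in_window}


@given(offset=st.integers(200_000, 400_000))
def test_strand_symmetry(offset):
    """Reflecting coordinates and flipping strand mirrors windows and promoters."""
    reflect = 1_000_000
    plus = make_gene(strand="+", body=(offset, offset + 10_000))
    minus = make_gene(strand="-", body=(reflect - offset - 10_000, reflect - offset))
    wp = candidate_window(plus)
    wm = candidate_window(minus)
    assert (wp.start, wp.end) == (reflect - wm.end, reflect - wm.start)
    pp = promoter_region(plus)
    pm = promoter_region(minus)
    assert (pp.start, pp.end) == (reflect - pm.end, reflect - pm.start)
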