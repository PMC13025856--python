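"""Midpoint annotation vs an exhaustive oracle; enrichment and TSS profiles."""

import numpy as np
import pytest

from rloopscape.genome_annotation import (
    AnnotationConfig,
    Annotator,
    GeneModel,
    INTERGENIC,
    feature_enrichment,
    read_gtf,
    tss_distance_profile,
)
from rloopscape.intervals import GenomeInfo, GenomicInterval


def _gene(gid, tss, tes, strand="+", chrom="chr1", exons=(), utr5=(), utr3=()):
    mk = lambda pairs: tuple(GenomicInterval(chrom, s, e) for s, e in pairs)
    return GeneModel(gid, chrom, strand, tss, tes, mk(exons), mk(utr5), mk(utr3))


class TestAnnotateRegion:
    def test_promoter_upstream_of_plus_strand_tss(self):
        g = _gene("g1", 10_000, 15_000, "+", exons=[(10_000, 15_001)])
        ann = Annotator([g]).annotate(GenomicInterval("chr1", 9940, 9960))
        assert ann.category == "promoter-TSS"
        assert ann.nearest_gene_id == "g1" and ann.tss_distance == -50

    def test_exon_outside_promoter_and_tts_windows(self):
        g = _gene("g1", 10_000, 20_000, "+", exons=[(12_000, 13_000)])
        ann = Annotator([g]).annotate(GenomicInterval("chr1", 12_400, 12_600))
        assert ann.category == "exon"

    def test_minus_strand_distance_sign(self):
        # midpoint 50 bp right of a minus-strand TSS is upstream => negative
        g = _gene("g1", 10_000, 5_000, "-")
        ann = Annotator([g]).annotate(GenomicInterval("chr1", 10_040, 10_060))
        assert ann.tss_distance == -50

    def test_unknown_chromosome_flagged_intergenic(self):
        g = _gene("g1", 100, 500)
        ann = Annotator([g]).annotate(GenomicInterval("chr9", 0, 100))
        assert ann.category == INTERGENIC and ann.flagged and ann.nearest_gene_id is None

    def test_equidistant_tss_tie_breaks_to_smaller_gene_id(self):
        genes = [_gene("gB", 1000, 2000), _gene("gA", 3000, 4000)]
        ann = Annotator(genes).annotate(GenomicInterval("chr1", 1990, 2010))
        assert ann.nearest_gene_id == "gA"  # both 1000 bp away

    def test_matches_exhaustive_midpoint_oracle(self, rng):
        """Random regions vs random genes: category and nearest TSS by loops."""
        cfg = AnnotationConfig()
        genes = []
        for i in range(10):
            strand = "+" if rng.random() < 0.5 else "-"
            a = int(rng.integers(0, 90_000))
            b = a + int(rng.integers(2000, 8000))
            tss, tes = (a, b) if strand == "+" else (b, a)
            ex = [(a + 100, a + 600), (b - 600, b - 100)]
            genes.append(_gene(f"g{i:02d}", tss, tes, strand, exons=ex))
        annot = Annotator(genes, cfg)
        for _ in range(200):
            start = int(rng.integers(0, 99_000))
            region = GenomicInterval("chr1", start, start + int(rng.integers(10, 800)))
            got = annot.annotate(region)
            mid = region.midpoint
            # oracle: test membership per category by direct looping
            def in_promoter(g):
                d = g.signed_distance(mid)
                return -cfg.promoter_window[0] <= d <= cfg.promoter_window[1]

            def in_tts(g):
                return abs(mid - g.tes) <= cfg.tts_window

            def in_exon(g):
                return any(e.start <= mid < e.end for e in g.exons)

            def in_body(g):
                lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
                return lo <= mid <= hi

            if any(in_promoter(g) for g in genes):
                expected = "promoter-TSS"
            elif any(in_exon(g) for g in genes):
                expected = "exon"
            elif any(in_tts(g) for g in genes):
                expected = "TTS"
            elif any(in_body(g) for g in genes):
                expected = "intron"
            else:
                expected = INTERGENIC
            assert got.category == expected
            best = min(genes, key=lambda g: (abs(mid - g.tss), g.gene_id))
            assert got.nearest_gene_id == best.gene_id
            assert got.tss_distance == best.signed_distance(mid)


class TestFeatureEnrichment:
    def test_log2_arithmetic(self):
        # observed fraction 0.20 in a category covering 2% of the genome
        g = _gene("g1", 1000, 2000)
        annot = Annotator([g], AnnotationConfig(promoter_window=(1000, 999)))
        genome = GenomeInfo({"chr1": 100_000})
        regions = [GenomicInterval("chr1", 500, 700)] * 20 + [
            GenomicInterval("chr1", 50_000, 50_100)
        ] * 80
        df = feature_enrichment(annot.annotate_all(regions), genome, annot).set_index("category")
        assert df.loc["promoter-TSS", "observed_fraction"] == pytest.approx(0.20)
        assert df.loc["promoter-TSS", "expected_fraction"] == pytest.approx(0.02)
        assert df.loc["promoter-TSS", "log2_enrichment"] == pytest.approx(np.log2(10))

    def test_category_fractions_sum_to_one(self, rng):
        genes = [_gene(f"g{i}", 10_000 * i + 2000, 10_000 * i + 6000) for i in range(5)]
        annot = Annotator(genes)
        genome = GenomeInfo({"chr1": 60_000})
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 100)
            for s in rng.integers(0, 59_000, size=300)
        ]
        df = feature_enrichment(annot.annotate_all(regions), genome, annot)
        assert df["observed_fraction"].sum() == pytest.approx(1.0)
        assert df["expected_fraction"].sum() == pytest.approx(1.0)

    def test_uniform_regions_give_near_zero_enrichment(self, rng):
        """Uniformly placed regions show no category preference."""
        genes = [
            _gene(f"g{i:02d}", 20_000 * i + 5000, 20_000 * i + 15_000)
            for i in range(10)
        ]
        annot = Annotator(genes)
        genome = GenomeInfo({"chr1": 200_000})
        mids = rng.integers(5, 199_990, size=50_000)
        regions = [GenomicInterval("chr1", int(m) - 5, int(m) + 5) for m in mids]
        df = feature_enrichment(annot.annotate_all(regions), genome, annot)
        assert (df["log2_enrichment"].abs() < 0.1).all()


class TestTssDistanceProfile:
    def test_identical_subsets_identical_histograms(self):
        g = _gene("g1", 1000, 5000)
        annot = Annotator([g])
        anns = annot.annotate_all(
            [GenomicInterval("chr1", 900 + i * 40, 1100 + i * 40) for i in range(5)]
        )
        df = tss_distance_profile(
            anns, {"s1": {"g1"}, "s2": {"g1"}}, [-2000, 0, 2000]
        )
        assert (df.loc["s1"] == df.loc["s2"]).all()
        assert df.loc["s1"].sum() == 5

    def test_all_regions_at_tss_fall_in_zero_bin(self):
        g = _gene("g1", 1000, 5000)
        annot = Annotator([g])
        anns = annot.annotate_all([GenomicInterval("chr1", 990, 1010)] * 4)
        df = tss_distance_profile(anns, {"s": {"g1"}}, [-100, 100])
        assert df.loc["s"].sum() == 4 and df.loc["s"].iloc[0] == 4

    def test_unknown_gene_id_warns(self):
        g = _gene("g1", 1000, 5000)
        annot = Annotator([g])
        anns = annot.annotate_all([GenomicInterval("chr1", 990, 1010)])
        with pytest.warns(UserWarning):
            tss_distance_profile(anns, {"s": {"nope"}}, [-100, 100])


class TestGtfRoundTrip:
    def test_simulated_gtf_reads_back_consistent_models(self, tmp_path, default_sim):
        from rloopscape.synthetic_data import write_all

        paths = write_all(default_sim, tmp_path / "sim")
        genes = read_gtf(paths["gtf"])
        by_id = {g.gene_id: g for g in genes}
        assert len(genes) == len(default_sim.expression.genes)
        for g in default_sim.expression.genes[:50]:
            r = by_id[g.gene_id]
            assert (r.chrom, r.strand, r.tss, r.tes) == (g.chrom, g.strand, g.tss, g.tes)
            assert r.exons == g.exons
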