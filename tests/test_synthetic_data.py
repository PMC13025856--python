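"""Generator determinism, planted-signal guarantees, round-trip contracts."""

import numpy as np
import pytest

from rloopscape.consensus import call_common_regions
from rloopscape.intervals import pairwise_overlaps, read_narrowpeak
from rloopscape.sequence_features import gc_at_skew
from rloopscape.synthetic_data import (
    SimulationConfig,
    simulate_all,
    simulate_genome,
    simulate_peaks,
    write_all,
)


def _small_cfg(seed, **kw):
    defaults = dict(
        seed=seed, n_chroms=1, chrom_length=400_000, n_true_loci=60,
        n_genes=120, noise_per_mb=5.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateGenome:
    def test_same_seed_identical_output(self):
        a = simulate_genome(_small_cfg(3))
        b = simulate_genome(_small_cfg(3))
        assert a.sequences == b.sequences
        assert a.true_loci == b.true_loci
        assert [s.name for s in a.segmentation.segments] == [
            s.name for s in b.segmentation.segments
        ]

    def test_different_seed_differs(self):
        a = simulate_genome(_small_cfg(3))
        b = simulate_genome(_small_cfg(4))
        assert a.sequences != b.sequences

    def test_segments_tile_chromosomes(self):
        sim = simulate_genome(_small_cfg(5))
        pos = 0
        for seg in sim.segmentation.segments:
            assert seg.start == pos
            pos = seg.end
        assert pos == 400_000

    def test_planted_skew_zero_matches_binomial_null(self):
        """No planted skew: locus windows look like the genomic background."""
        sim = simulate_genome(_small_cfg(6, planted_gc_skew=0.0, planted_g4_per_kb=0.0))
        locus_skews = [
            gc_at_skew(sim.sequences[l.chrom][l.start:l.end])[0]
            for l in sim.true_loci
            if len(l) >= 150
        ]
        # E|skew| for binomial(n~0.45*len, 1/2) is small; planted 0 must stay small
        assert np.mean(locus_skews) < 0.12

    def test_planted_skew_elevates_locus_windows(self):
        sim = simulate_genome(_small_cfg(7))  # default planted skew 0.4
        locus_skews = [
            gc_at_skew(sim.sequences[l.chrom][l.start:l.end])[0] for l in sim.true_loci
        ]
        bg = [
            gc_at_skew(sim.sequences["chr1"][s:s + 200])[0]
            for s in range(0, 100_000, 5000)
        ]
        assert np.mean(locus_skews) > np.mean(bg) + 0.2

    def test_locus_longer_than_chromosome_rejected(self):
        with pytest.raises((ValueError, RuntimeError)):
            simulate_genome(
                SimulationConfig(
                    seed=1, n_chroms=1, chrom_length=1000, n_true_loci=2,
                    locus_min_length=2000, locus_max_length=3000,
                )
            )


class TestSimulatePeaks:
    def test_noiseless_perfect_sensitivity_reproduces_loci(self):
        cfg = _small_cfg(8, sensitivity=1.0, jitter_sd=0.0, noise_per_mb=0.0)
        sim = simulate_genome(cfg)
        peaks = simulate_peaks(cfg, sim)
        loci = {(l.chrom, l.start, l.end) for l in sim.true_loci}
        for _, _, ivs in peaks.collection.datasets:
            assert {(p.chrom, p.start, p.end) for p in ivs} == loci

    def test_zero_sensitivity_group_kills_consensus(self):
        cfg = _small_cfg(9, sensitivity=0.0, noise_per_mb=0.0)
        sim = simulate_genome(cfg)
        peaks = simulate_peaks(cfg, sim)
        # all datasets empty -> base_partition has nothing; consensus empty
        assert all(len(ivs) == 0 for _, _, ivs in peaks.collection.datasets)

    def test_group_detection_rate_matches_binomial_bound(self, default_sim):
        """Defaults (sens .9, >=3 datasets/group): consensus recovers >=90%."""
        sim = default_sim
        res = call_common_regions(sim.peaks.collection, genome=sim.genome.genome)
        hit = {i for i, _, _ in pairwise_overlaps(sim.genome.true_loci, res.regions)}
        assert len(hit) / len(sim.genome.true_loci) >= 0.90

    def test_provenance_aligns_with_peaks(self):
        cfg = _small_cfg(10)
        sim = simulate_genome(cfg)
        peaks = simulate_peaks(cfg, sim)
        loci_by_name = {l.name: l for l in sim.true_loci}
        for did, _, ivs in peaks.collection.datasets:
            prov = peaks.provenance[did]
            assert len(prov) == len(ivs)
            for iv, src in zip(ivs, prov):
                if src is not None:
                    assert iv.overlaps(loci_by_name[src])


class TestSimulateCountsGenes:
    def test_same_seed_identical_counts(self):
        a = simulate_all(_small_cfg(11))
        b = simulate_all(_small_cfg(11))
        assert a.expression.counts.equals(b.expression.counts)

    def test_dispersion_to_zero_approaches_poisson_cv(self):
        """NB with phi -> 0 collapses to Poisson: CV ~ 1/sqrt(mean)."""
        cfg = _small_cfg(
            12,
            nb_dispersion_associated=1e-6,
            nb_dispersion_other=1e-6,
            library_size_range=(1e6, 1e6),
        )
        sim = simulate_all(cfg)
        counts = sim.expression.counts.to_numpy(float)
        mean = counts.mean(axis=1)
        cv = counts.std(axis=1, ddof=1) / np.maximum(mean, 1e-12)
        keep = mean > 50
        ratio = cv[keep] * np.sqrt(mean[keep])  # ~1 under Poisson
        assert 0.6 < np.median(ratio) < 1.5
        # and far below the dispersed default
        dispersed = simulate_all(_small_cfg(12, library_size_range=(1e6, 1e6)))
        dc = dispersed.expression.counts.to_numpy(float)
        dcv = dc.std(axis=1, ddof=1) / np.maximum(dc.mean(axis=1), 1e-12)
        assert np.median(cv[keep]) < 0.5 * np.median(dcv[dc.mean(axis=1) > 50])

    def test_associated_genes_have_tss_near_a_locus(self):
        sim = simulate_all(_small_cfg(13))
        loci = sim.genome.true_loci
        by_id = {g.gene_id: g for g in sim.expression.genes}
        for gid in sim.expression.associated_genes:
            g = by_id[gid]
            assert any(
                l.chrom == g.chrom and abs(g.tss - l.midpoint) <= 1000 for l in loci
            )

    def test_enriched_gene_set_is_biased_to_associated(self):
        sim = simulate_all(_small_cfg(14))
        enriched = sim.expression.gene_sets["set_enriched"]
        frac = len(enriched & sim.expression.associated_genes) / len(enriched)
        assert frac >= 0.5


class TestRoundTrip:
    def test_emitted_files_parse_through_package_readers(self, tmp_path):
        from rloopscape.chromatin_states import read_segmentation
        from rloopscape.enrichment_stats import read_gmt
        from rloopscape.expression import read_counts
        from rloopscape.genome_annotation import read_gtf
        from rloopscape.intervals import read_bed, read_chrom_sizes
        from rloopscape.sequence_features import read_motif_table

        sim = simulate_all(_small_cfg(15))
        paths = write_all(sim, tmp_path / "sim")
        genome = read_chrom_sizes(paths["chrom_sizes"])
        assert genome.total_size == sim.genome.genome.total_size
        seg = read_segmentation(paths["segmentation"], genome=genome)
        assert len(seg.segments) == len(sim.genome.segmentation.segments)
        loci = read_bed(paths["true_loci"], genome=genome)
        assert [(l.start, l.end) for l in loci] == [
            (l.start, l.end) for l in sim.genome.true_loci
        ]
        counts = read_counts(paths["counts"])
        assert counts.equals(sim.expression.counts)
        assert read_gmt(paths["gmt"]).keys() == sim.expression.gene_sets.keys()
        assert len(read_gtf(paths["gtf"])) == len(sim.expression.genes)
        assert [m.name for m in read_motif_table(paths["motifs"])] == [
            n for n, _ in sim.cfg.motifs
        ]
        for did, _, ivs in sim.peaks.collection.datasets:
            back = read_narrowpeak(tmp_path / "sim" / "peaks" / f"{did}.narrowPeak")
            assert [(p.start, p.end) for p in back] == [(p.start, p.end) for p in ivs]

    def test_fasta_bytes_deterministic(self, tmp_path):
        a = simulate_all(_small_cfg(16))
        b = simulate_all(_small_cfg(16))
        write_all(a, tmp_path / "a")
        write_all(b, tmp_path / "b")
        assert (tmp_path / "a" / "genome.fa").read_bytes() == (
            tmp_path / "b" / "genome.fa"
        ).read_bytes()
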