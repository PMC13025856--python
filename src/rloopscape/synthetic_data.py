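"""Synthetic inputs with planted ground truth for the whole pipeline.

Emulates, at desk scale, every input the analysis consumes: a small
genome with a chromatin-state segmentation and state-dependent base
composition; R-loop peak sets from four method groups with controlled
per-dataset detection of planted true loci; planted GC skew, canonical G4
motifs and degenerate motifs inside true loci; gene models whose
"associated" members sit with their TSS next to a true locus; negative-
binomial RNA-seq counts with higher, more stable expression at associated
genes; and gene sets including one drawn preferentially from the
associated genes.

Everything is deterministic under ``SimulationConfig.seed``; independent
substreams are spawned per stage so adding a stage never perturbs
another's draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chromatin_states import StateSegmentation
from .genome_annotation import GeneModel
from .intervals import GenomeInfo, GenomicInterval, PeakCollection, write_bed
from .sequence_features import IUPACMotif

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "SimulatedPeaks",
    "SimulatedExpression",
    "simulate_genome",
    "simulate_peaks",
    "simulate_counts_genes",
    "simulate_all",
    "write_all",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the reference conditions.

    Scale (2 chromosomes x 2 Mb, 500 true loci, 2,000 genes) keeps a full
    pipeline run within minutes on one CPU while leaving every state with
    enough windows for the permutation tests.
    """

    seed: int
    n_chroms: int = 2
    chrom_length: int = 2_000_000

    # chromatin-state chain: pick-next weights and geometric mean lengths
    state_labels: tuple[str, ...] = ("TSS", "PromF", "Tx", "TxEx", "EnhA", "Quies")
    state_weights: tuple[float, ...] = (0.10, 0.10, 0.20, 0.10, 0.10, 0.40)
    state_mean_lengths: tuple[int, ...] = (2000, 2000, 8000, 3000, 2000, 12000)
    state_gc: tuple[float, ...] = (0.60, 0.55, 0.45, 0.50, 0.50, 0.40)

    # planted true loci
    n_true_loci: int = 500
    locus_length_log_mean: float = 5.0  # ln bp; median ~148 bp
    locus_length_log_sd: float = 0.6
    locus_min_length: int = 50
    locus_max_length: int = 1500
    locus_min_separation: int = 4000
    planted_gc_skew: float = 0.4  # expected |(G-C)/(G+C)| inside loci
    planted_g4_per_kb: float = 1.0
    motifs: tuple[tuple[str, str], ...] = (
        ("motifA", "TTAGCWGABT"),  # planted
        ("motifB", "CRCGTGAYCA"),  # unplanted control
    )
    #: motif -> state -> probability a locus midpointed in that state gets one copy
    motif_plant_rate: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = (
        ("motifA", (("Tx", 0.8), ("TSS", 0.8))),
    )

    # peak simulation: datasets per method group, detection, noise
    datasets_per_group: tuple[tuple[str, int], ...] = (
        ("DRIP", 4), ("CUT&Tag", 3), ("HBD", 3), ("MapR", 3),
    )
    sensitivity: float = 0.9
    jitter_sd: float = 20.0
    noise_per_mb: float = 5.0

    # expression simulation
    n_genes: int = 1000
    associated_fraction: float = 0.25  # of genes; capped at one gene per locus
    gene_length_range: tuple[int, int] = (1000, 2500)
    n_samples: int = 6
    nb_mean_associated: float = 300.0
    nb_mean_other: float = 60.0
    nb_dispersion_associated: float = 0.05
    nb_dispersion_other: float = 0.4
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    n_gene_sets: int = 10
    gene_set_size: int = 50
    enriched_set_bias: float = 0.8  # fraction of the enriched set from associated genes

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.sensitivity <= 1):
            raise ValueError("sensitivity must be in [0,1]")
        if not (0 <= self.planted_gc_skew <= 1):
            raise ValueError("planted_gc_skew must be in [0,1]")

    def motif_objects(self) -> list[IUPACMotif]:
        return [IUPACMotif(n, p) for n, p in self.motifs]


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    genome: GenomeInfo
    segmentation: StateSegmentation
    true_loci: list[GenomicInterval]  # name = locus id; each carries its midpoint state
    locus_states: dict[str, str]

    def fasta_like(self) -> dict[str, str]:
        """Mapping usable wherever an indexed FASTA is expected."""
        return self.sequences


@dataclass
class SimulatedPeaks:
    collection: PeakCollection
    #: dataset id -> list aligned with its peaks: locus id or None (noise)
    provenance: dict[str, list[str | None]]


@dataclass
class SimulatedExpression:
    genes: list[GeneModel]
    counts: pd.DataFrame
    gene_sets: dict[str, set[str]]
    associated_genes: set[str]
    enriched_set_name: str = "set_enriched"


def _rng_for(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(stage + 1)[stage])


def _random_bases(rng: np.random.Generator, n: int, p_acgt: Sequence[float]) -> np.ndarray:
    return _BASES[rng.choice(4, size=n, p=np.asarray(p_acgt) / np.sum(p_acgt))]


def simulate_genome(cfg: SimulationConfig) -> SimulatedGenome:
    """Simulate sequence, state segmentation, and planted true loci.

    States are drawn from a first-order chain (pick-next weights,
    geometric segment lengths); sequence composition is state-dependent.
    Inside true loci the G/C balance is tilted so the expected absolute
    GC skew matches ``planted_gc_skew``, and canonical G4 motifs
    (G3 N1-7 x4) are overwritten at the planted density.  Loci are placed
    uniformly with a minimum separation so distinct loci stay distinct
    after peak-span merging.
    """
    rng = _rng_for(cfg, 0)
    labels = list(cfg.state_labels)
    weights = np.asarray(cfg.state_weights, float)
    weights = weights / weights.sum()
    mean_len = dict(zip(labels, cfg.state_mean_lengths))
    gc = dict(zip(labels, cfg.state_gc))

    sequences: dict[str, bytearray] = {}
    segments: list[GenomicInterval] = []
    sizes: dict[str, int] = {}
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        sizes[chrom] = cfg.chrom_length
        seq = bytearray(cfg.chrom_length)
        pos = 0
        prev_state = None
        while pos < cfg.chrom_length:
            state = labels[int(rng.choice(len(labels), p=weights))]
            if state == prev_state:  # keep segments maximal runs of distinct states
                continue
            length = max(200, int(rng.geometric(1.0 / mean_len[state])))
            end = min(pos + length, cfg.chrom_length)
            c = gc[state]
            comp = ((1 - c) / 2, c / 2, c / 2, (1 - c) / 2)  # A C G T
            seq[pos:end] = _random_bases(rng, end - pos, comp).tobytes()
            segments.append(GenomicInterval(chrom, pos, end, name=state))
            pos = end
            prev_state = state
        sequences[chrom] = seq

    segmentation = StateSegmentation(segments)
    genome = GenomeInfo(sizes)

    # place true loci uniformly, enforcing separation
    loci: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
    attempts = 0
    while len(loci) < cfg.n_true_loci:
        attempts += 1
        if attempts > cfg.n_true_loci * 200:
            raise RuntimeError("could not place all loci; lower n_true_loci or separation")
        length = int(
            np.clip(
                rng.lognormal(cfg.locus_length_log_mean, cfg.locus_length_log_sd),
                cfg.locus_min_length,
                cfg.locus_max_length,
            )
        )
        if length >= cfg.chrom_length:
            raise ValueError("locus longer than chromosome")
        chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
        start = int(rng.integers(0, cfg.chrom_length - length))
        lo, hi = start - cfg.locus_min_separation, start + length + cfg.locus_min_separation
        if any(s < hi and lo < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, start + length))
        loci.append(GenomicInterval(chrom, start, start + length, name=f"locus_{len(loci):04d}"))
    loci.sort(key=GenomicInterval.sort_key)
    loci = [
        GenomicInterval(l.chrom, l.start, l.end, name=f"locus_{i:04d}")
        for i, l in enumerate(loci)
    ]

    # state at each locus midpoint (for state-stratified ground truth)
    locus_states: dict[str, str] = {}
    seg_by_chrom: dict[str, list[GenomicInterval]] = {}
    for s in segmentation.segments:
        seg_by_chrom.setdefault(s.chrom, []).append(s)
    for locus in loci:
        mid = locus.midpoint
        state = next(
            (s.name for s in seg_by_chrom[locus.chrom] if s.start <= mid < s.end),
            "Quies",
        )
        locus_states[locus.name] = state

    # plant GC skew inside loci: tilt G vs C keeping state GC content
    s_level = cfg.planted_gc_skew
    for locus in loci:
        seq = sequences[locus.chrom]
        c = gc[locus_states[locus.name]]
        comp = (
            (1 - c) / 2,
            c * (1 - s_level) / 2,
            c * (1 + s_level) / 2,
            (1 - c) / 2,
        )  # A C G T, G-rich tilt
        seq[locus.start:locus.end] = _random_bases(rng, len(locus), comp).tobytes()

    # plant canonical G4 motifs at the configured density
    for locus in loci:
        n_g4 = rng.poisson(cfg.planted_g4_per_kb * len(locus) / 1000.0)
        for _ in range(n_g4):
            motif = _random_g4(rng)
            if len(motif) >= len(locus):
                continue
            offset = int(rng.integers(0, len(locus) - len(motif)))
            start = locus.start + offset
            sequences[locus.chrom][start:start + len(motif)] = motif.encode()

    # plant degenerate motifs per state
    motif_by_name = {m.name: m for m in cfg.motif_objects()}
    for motif_name, state_rates in cfg.motif_plant_rate:
        motif = motif_by_name[motif_name]
        rates = dict(state_rates)
        for locus in loci:
            rate = rates.get(locus_states[locus.name], 0.0)
            if rate and rng.random() < rate and len(motif.pattern) < len(locus):
                inst = _instantiate_iupac(rng, motif.pattern)
                offset = int(rng.integers(0, len(locus) - len(inst)))
                start = locus.start + offset
                sequences[locus.chrom][start:start + len(inst)] = inst.encode()

    return SimulatedGenome(
        {c: bytes(b).decode() for c, b in sequences.items()},
        genome,
        segmentation,
        loci,
        locus_states,
    )


def _random_g4(rng: np.random.Generator) -> str:
    parts = []
    for i in range(4):
        parts.append("G" * int(rng.integers(3, 5)))
        if i < 3:
            loop_len = int(rng.integers(1, 4))
            parts.append("".join(rng.choice(list("ACT"), size=loop_len)))
    return "".join(parts)


def _instantiate_iupac(rng: np.random.Generator, pattern: str) -> str:
    from .sequence_features import IUPAC_CLASSES

    return "".join(rng.choice(list(IUPAC_CLASSES[ch])) for ch in pattern.upper())


def simulate_peaks(cfg: SimulationConfig, sim: SimulatedGenome) -> SimulatedPeaks:
    """Simulate per-dataset narrowPeak-like detections of the true loci.

    Each dataset detects each locus independently with ``sensitivity``;
    a detected peak is the locus with Gaussian boundary jitter (clipped
    to the chromosome, kept non-empty).  Noise peaks are placed uniformly
    at ``noise_per_mb`` per megabase per dataset with locus-like lengths.
    """
    rng = _rng_for(cfg, 1)
    collection = PeakCollection()
    provenance: dict[str, list[str | None]] = {}
    for group, n_datasets in cfg.datasets_per_group:
        for di in range(n_datasets):
            dataset_id = f"{group.replace('&', '')}_{di + 1}"
            peaks: list[GenomicInterval] = []
            prov: list[str | None] = []
            for locus in sim.true_loci:
                if rng.random() >= cfg.sensitivity:
                    continue
                start = locus.start + int(round(rng.normal(0, cfg.jitter_sd)))
                end = locus.end + int(round(rng.normal(0, cfg.jitter_sd)))
                # a detection always keeps >= 1 bp on its source locus
                start = max(0, min(start, locus.end - 1))
                end = max(end, locus.start + 1, start + 1)
                end = min(end, sim.genome[locus.chrom])
                start = min(start, end - 1)
                peaks.append(
                    GenomicInterval(
                        locus.chrom, start, end,
                        name=f"{dataset_id}_p{len(peaks)}",
                        score=float(rng.integers(100, 1000)),
                        extra=(float(rng.uniform(2, 20)), -1.0, -1.0, (end - start) // 2),
                    )
                )
                prov.append(locus.name)
            n_noise = rng.poisson(cfg.noise_per_mb * sim.genome.total_size / 1e6)
            for _ in range(n_noise):
                chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
                length = int(
                    np.clip(
                        rng.lognormal(cfg.locus_length_log_mean, cfg.locus_length_log_sd),
                        cfg.locus_min_length,
                        cfg.locus_max_length,
                    )
                )
                start = int(rng.integers(0, sim.genome[chrom] - length))
                peaks.append(
                    GenomicInterval(
                        chrom, start, start + length,
                        name=f"{dataset_id}_p{len(peaks)}",
                        score=float(rng.integers(100, 1000)),
                        extra=(float(rng.uniform(2, 20)), -1.0, -1.0, length // 2),
                    )
                )
                prov.append(None)
            order = sorted(range(len(peaks)), key=lambda i: peaks[i].sort_key())
            collection.add(dataset_id, group, [peaks[i] for i in order])
            provenance[dataset_id] = [prov[i] for i in order]
    return SimulatedPeaks(collection, provenance)


def simulate_counts_genes(
    cfg: SimulationConfig, sim: SimulatedGenome
) -> SimulatedExpression:
    """Place genes, designate associated ones next to loci, draw NB counts.

    One associated gene per selected true locus, its TSS within 1 kb of
    the locus midpoint; other genes are placed >= 5 kb from any locus.
    Counts are negative binomial with higher mean and lower dispersion
    for associated genes; library sizes vary per sample.  Gene sets: one
    set drawn preferentially from associated genes plus random sets.
    """
    rng = _rng_for(cfg, 2)
    n_assoc = min(int(cfg.n_genes * cfg.associated_fraction), len(sim.true_loci))
    chosen_loci = rng.choice(len(sim.true_loci), size=n_assoc, replace=False)

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in sim.genome}
    genes: list[GeneModel] = []

    def _try_place(chrom: str, start: int, length: int) -> bool:
        if start < 0 or start + length > sim.genome[chrom]:
            return False
        if any(s < start + length and start < e for s, e in occupied[chrom]):
            return False
        occupied[chrom].append((start, start + length))
        return True

    def _make_gene(gid: str, chrom: str, start: int, length: int, strand: str) -> GeneModel:
        end = start + length
        tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
        # 2-4 exons: first and last anchored at the gene ends
        n_ex = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(200, length - 200), size=2 * (n_ex - 1), replace=False))
        bounds = [start] + [start + int(c) for c in cuts] + [end]
        exons = tuple(
            GenomicInterval(chrom, bounds[2 * i], bounds[2 * i + 1])
            for i in range(n_ex)
        )
        return GeneModel(gid, chrom, strand, tss, tes, exons)

    # one associated gene per selected locus; a locus where no placement
    # fits (crowded neighbourhood) is skipped and another locus is tried
    associated: set[str] = set()
    locus_order = list(rng.permutation(len(sim.true_loci)))
    preferred = [int(i) for i in chosen_loci]
    rest = [i for i in locus_order if i not in set(preferred)]
    gi = 0
    for li in preferred + rest:
        if len(associated) >= n_assoc:
            break
        locus = sim.true_loci[li]
        for _ in range(50):
            length = int(rng.integers(*cfg.gene_length_range))
            strand = "+" if rng.random() < 0.5 else "-"
            tss_pos = locus.midpoint + int(rng.integers(-1000, 1001))
            start = tss_pos if strand == "+" else tss_pos - length + 1
            if _try_place(locus.chrom, start, length):
                gid = f"gene_{gi:04d}"
                genes.append(_make_gene(gid, locus.chrom, start, length, strand))
                associated.add(gid)
                gi += 1
                break
    if len(associated) < n_assoc:
        raise RuntimeError("could not place the associated genes; lower n_genes")

    guard = 0
    while gi < cfg.n_genes:
        guard += 1
        if guard > cfg.n_genes * 500:
            raise RuntimeError("could not place all genes; reduce n_genes")
        chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
        length = int(rng.integers(*cfg.gene_length_range))
        start = int(rng.integers(0, sim.genome[chrom] - length))
        if _try_place(chrom, start, length):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_make_gene(f"gene_{gi:04d}", chrom, start, length, strand))
            gi += 1

    genes.sort(key=lambda g: (g.chrom, min(g.tss, g.tes), g.gene_id))

    # negative-binomial counts
    libsizes = rng.uniform(*cfg.library_size_range, size=cfg.n_samples)
    base_mean = np.array(
        [
            cfg.nb_mean_associated if g.gene_id in associated else cfg.nb_mean_other
            for g in genes
        ]
    )
    # per-gene multiplicative variation so expression isn't flat within class
    base_mean = base_mean * rng.lognormal(0, 0.4, size=len(genes))
    disp = np.array(
        [
            cfg.nb_dispersion_associated if g.gene_id in associated else cfg.nb_dispersion_other
            for g in genes
        ]
    )
    counts = np.empty((len(genes), cfg.n_samples), dtype=np.int64)
    mean_lib = np.mean(libsizes)
    for j in range(cfg.n_samples):
        mu = base_mean * (libsizes[j] / mean_lib)
        r = 1.0 / disp
        p = r / (r + mu)
        counts[:, j] = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(
        counts,
        index=[g.gene_id for g in genes],
        columns=[f"sample_{j + 1}" for j in range(cfg.n_samples)],
    )

    # gene sets: one enriched in associated genes, the rest random
    all_ids = [g.gene_id for g in genes]
    assoc_list = sorted(associated)
    other_list = sorted(set(all_ids) - associated)
    n_from_assoc = min(int(cfg.gene_set_size * cfg.enriched_set_bias), len(assoc_list))
    enriched = set(rng.choice(assoc_list, size=n_from_assoc, replace=False)) | set(
        rng.choice(other_list, size=cfg.gene_set_size - n_from_assoc, replace=False)
    )
    gene_sets: dict[str, set[str]] = {"set_enriched": enriched}
    for k in range(cfg.n_gene_sets - 1):
        gene_sets[f"set_random_{k:02d}"] = set(
            rng.choice(all_ids, size=cfg.gene_set_size, replace=False)
        )
    return SimulatedExpression(genes, counts_df, gene_sets, associated)


@dataclass
class Simulation:
    cfg: SimulationConfig
    genome: SimulatedGenome
    peaks: SimulatedPeaks
    expression: SimulatedExpression


def simulate_all(cfg: SimulationConfig) -> Simulation:
    sim = simulate_genome(cfg)
    return Simulation(cfg, sim, simulate_peaks(cfg, sim), simulate_counts_genes(cfg, sim))


# ---------------------------------------------------------------------------
# file emission (round-trips through the package's own readers)
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_all(sim: Simulation, outdir: str | Path) -> dict[str, str]:
    """Write every pipeline input plus the ground-truth manifest; returns paths."""
    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    write_fasta(sim.genome.sequences, out / "genome.fa")
    paths["fasta"] = str(out / "genome.fa")

    with open(out / "genome.chrom.sizes", "w") as fh:
        for chrom, n in sim.genome.genome.items():
            fh.write(f"{chrom}\t{n}\n")
    paths["chrom_sizes"] = str(out / "genome.chrom.sizes")

    write_bed(sim.genome.segmentation.segments, out / "segmentation.bed")
    paths["segmentation"] = str(out / "segmentation.bed")

    peak_paths = {}
    for dataset_id, group, ivs in sim.peaks.collection.datasets:
        p = out / "peaks" / f"{dataset_id}.narrowPeak"
        write_bed(ivs, p)
        peak_paths[dataset_id] = {"group": group, "path": str(p)}
    paths["peaks_dir"] = str(out / "peaks")

    with open(out / "genes.gtf", "w") as fh:
        for g in sim.expression.genes:
            lo, hi = min(g.tss, g.tes), max(g.tss, g.tes) + 1
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{g.chrom}\tsim\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
    paths["gtf"] = str(out / "genes.gtf")

    sim.expression.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
    paths["counts"] = str(out / "counts.tsv")

    with open(out / "gene_sets.gmt", "w") as fh:
        for term, members in sim.expression.gene_sets.items():
            fh.write("\t".join([term, "synthetic"] + sorted(members)) + "\n")
    paths["gmt"] = str(out / "gene_sets.gmt")

    with open(out / "motifs.tsv", "w") as fh:
        for name, pattern in sim.cfg.motifs:
            fh.write(f"{name}\t{pattern}\n")
    paths["motifs"] = str(out / "motifs.tsv")

    write_bed(sim.genome.true_loci, out / "true_loci.bed")
    paths["true_loci"] = str(out / "true_loci.bed")

    manifest = {
        "seed": sim.cfg.seed,
        "datasets": peak_paths,
        "locus_states": sim.genome.locus_states,
        "associated_genes": sorted(sim.expression.associated_genes),
        "enriched_gene_set": sim.expression.enriched_set_name,
        "planted_gc_skew": sim.cfg.planted_gc_skew,
        "planted_g4_per_kb": sim.cfg.planted_g4_per_kb,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    paths["truth"] = str(out / "truth.json")
    return paths
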