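"""End-to-end orchestration: consensus -> annotation -> expression ->
ORA -> chromatin-state enrichment -> windows -> sequence features ->
permutation tests -> motif enrichment -> feature importance.

Every stage communicates through files in the output directory, so the
pipeline is restartable and each stage is independently inspectable. A
manifest records the config hash, seeds, per-stage row counts and output
file hashes; re-running with an identical config reproduces identical
hashes.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import ConsensusConfig, call_common_regions, fraction_in_range
from .chromatin_states import (
    classify_windows,
    partition_windows,
    read_segmentation,
    state_fold_enrichment,
)
from .enrichment_stats import (
    motif_enrichment_table,
    ora,
    permutation_importance,
    read_gmt,
    state_feature_enrichment,
)
from .expression import (
    associate_genes,
    expression_summary,
    filter_expressed,
    read_counts,
    tmm_factors,
)
from .genome_annotation import (
    AnnotationConfig,
    Annotator,
    annotations_to_frame,
    feature_enrichment,
    read_gtf,
)
from .intervals import (
    GenomicInterval,
    PeakCollection,
    read_bed,
    read_chrom_sizes,
    read_narrowpeak,
    write_bed,
)
from .sequence_features import (
    FEATURE_COLUMNS,
    featurize_windows,
    read_external_scores,
    read_motif_table,
)

__all__ = ["RunConfig", "run_all"]

STAGES = [
    "consensus",
    "annotation",
    "expression",
    "ora",
    "state_enrichment",
    "windows",
    "sequence_features",
    "permutation_tests",
    "motif_enrichment",
    "importance",
]


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    ``peaks`` maps dataset id -> (method group, narrowPeak path).  Every
    stochastic stage derives its stream from ``seed``.  Defaults follow
    the reference analysis: merge gap 0, promoter window (1000, 100),
    association window +/-3 kb, 200-bp windows with f = 0.5, 10,000
    permutations, G4Hunter threshold 1.2, ORA rule p < 0.01 & q < 0.05.
    """

    peaks: dict[str, tuple[str, str]]
    chrom_sizes: str
    fasta: str
    segmentation: str
    gtf: str
    counts: str
    gmt: str
    motifs: str
    out_dir: str
    cpg: str | None = None
    external_scores: str | None = None
    seed: int = 0
    merge_gap: int = 0
    min_per_group: int = 1
    promoter_window: tuple[int, int] = (1000, 100)
    max_assoc_distance: int = 3000
    window_length: int = 200
    overlap_f: float = 0.5
    n_perm: int = 10_000
    g4hunter_window: int = 25
    g4hunter_threshold: float = 1.2
    cpm_threshold: float = 1.0
    ora_p_cut: float = 0.01
    ora_q_cut: float = 0.05
    rf_folds: int = 5
    rf_repeats: int = 10

    def validate(self) -> None:
        missing = [
            p
            for p in [self.chrom_sizes, self.fasta, self.segmentation, self.gtf,
                      self.counts, self.gmt, self.motifs]
            + [path for _, path in self.peaks.values()]
            + ([self.cpg] if self.cpg else [])
            + ([self.external_scores] if self.external_scores else [])
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        if not self.peaks:
            raise ValueError("no peak datasets configured")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # the destination must not change the science
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }

    def _record(stage: str, rows: int, *paths: Path) -> None:
        manifest["stages"][stage] = {
            "rows": int(rows),
            "outputs": {p.name: _file_hash(p) for p in paths},
        }

    genome = read_chrom_sizes(cfg.chrom_sizes)

    # 1. consensus
    collection = PeakCollection()
    for dataset_id, (group, path) in sorted(cfg.peaks.items()):
        collection.add(dataset_id, group, read_narrowpeak(path, genome=genome))
    regions = call_common_regions(
        collection,
        ConsensusConfig(min_datasets_per_group=cfg.min_per_group, merge_gap=cfg.merge_gap),
        genome=genome,
    )
    regions_bed = out / "common_regions.bed"
    write_bed(regions.regions, regions_bed)
    prov_tsv = out / "common_regions_provenance.tsv"
    with open(prov_tsv, "w") as fh:
        for region, ids in zip(regions.regions, regions.provenance):
            fh.write(
                f"{region.chrom}\t{region.start}\t{region.end}\t{','.join(sorted(ids))}\n"
            )
    _record("consensus", len(regions), regions_bed, prov_tsv)

    # 2. annotation
    genes = read_gtf(cfg.gtf)
    cpg = read_bed(cfg.cpg, genome=genome) if cfg.cpg else []
    annotator = Annotator(
        genes, AnnotationConfig(promoter_window=cfg.promoter_window), cpg_islands=cpg
    )
    annotations = annotator.annotate_all(regions.regions)
    ann_df = annotations_to_frame(annotations)
    ann_tsv = out / "region_annotation.tsv"
    ann_df.to_csv(ann_tsv, sep="\t", index=False)
    enr_df = feature_enrichment(annotations, genome, annotator)
    enr_tsv = out / "feature_enrichment.tsv"
    enr_df.to_csv(enr_tsv, sep="\t", index=False)
    _record("annotation", len(ann_df), ann_tsv, enr_tsv)

    # 3. expression + association
    counts = read_counts(cfg.counts)
    expressed = filter_expressed(counts, threshold=cfg.cpm_threshold)
    expr_counts = counts.loc[expressed]
    factors = tmm_factors(expr_counts)
    associated = associate_genes(regions, annotator, cfg.max_assoc_distance)
    summary = expression_summary(expr_counts, factors, associated & set(expressed))
    expr_tsv = out / "expression_summary.tsv"
    summary.to_csv(expr_tsv, sep="\t", index_label="gene_id")
    _record("expression", len(summary), expr_tsv)

    # 4. gene-set over-representation
    gene_sets = read_gmt(cfg.gmt)
    ora_df = ora(
        sorted(associated & set(expressed)), gene_sets, expressed,
        p_cut=cfg.ora_p_cut, q_cut=cfg.ora_q_cut,
    )
    ora_tsv = out / "ora.tsv"
    ora_df.to_csv(ora_tsv, sep="\t", index=False)
    _record("ora", len(ora_df), ora_tsv)

    # 5. chromatin-state fold enrichment
    seg = read_segmentation(cfg.segmentation, genome=genome)
    fold_df = state_fold_enrichment(seg, regions, genome)
    fold_tsv = out / "state_fold_enrichment.tsv"
    fold_df.to_csv(fold_tsv, sep="\t", index=False)
    _record("state_enrichment", len(fold_df), fold_tsv)

    # 6. windows
    windows = partition_windows(seg, cfg.window_length)
    windows = classify_windows(windows, regions, f=cfg.overlap_f)
    win_tsv = out / "windows.tsv"
    windows.to_csv(win_tsv, sep="\t", index=False)
    _record("windows", len(windows), win_tsv)

    # 7. sequence features
    from pyfaidx import Fasta

    fasta = Fasta(cfg.fasta)
    motifs = read_motif_table(cfg.motifs)
    ext = read_external_scores(cfg.external_scores) if cfg.external_scores else None
    feats = featurize_windows(
        windows, fasta, motifs,
        g4hunter_window=cfg.g4hunter_window,
        g4hunter_threshold=cfg.g4hunter_threshold,
        external_scores=ext,
    )
    feat_tsv = out / "window_features.tsv"
    feats.to_csv(feat_tsv, sep="\t", index=False)
    _record("sequence_features", len(feats), feat_tsv)

    # 8. permutation tests per state x feature
    perm_features = ["gc_skew_abs", "at_skew_abs", "quadparser_count",
                     "g4hunter_max_abs", "g4hunter_hits"]
    if ext is not None:
        perm_features.append("external_score")
    perm_df = state_feature_enrichment(
        feats, perm_features, n_perm=cfg.n_perm, seed=cfg.seed
    )
    perm_tsv = out / "permutation_enrichment.tsv"
    header = (
        f"# seed={cfg.seed} n_perm={cfg.n_perm} config={cfg.config_hash()}\n"
    )
    with open(perm_tsv, "w") as fh:
        fh.write(header)
        perm_df.to_csv(fh, sep="\t", index=False)
    _record("permutation_tests", len(perm_df), perm_tsv)

    # 9. motif enrichment (rloop vs background windows per state)
    per_state: dict[str, dict[str, tuple]] = {}
    for state, sub in feats.groupby("state", sort=True):
        fg, bg = sub[sub["rloop"]], sub[~sub["rloop"]]
        if len(fg) < 10 or len(bg) < 10:
            continue
        per_state[state] = {
            m.name: ((fg[f"motif_{m.name}"] > 0).to_numpy(),
                     (bg[f"motif_{m.name}"] > 0).to_numpy())
            for m in motifs
        }
    motif_df = motif_enrichment_table(per_state)
    motif_tsv = out / "motif_enrichment.tsv"
    motif_df.to_csv(motif_tsv, sep="\t", index=False)
    _record("motif_enrichment", len(motif_df), motif_tsv)

    # 10. random-forest permutation importance on a class-balanced sample
    rng = np.random.default_rng(cfg.seed)
    fg = feats[feats["rloop"]]
    bg = feats[~feats["rloop"]]
    imp_df = pd.DataFrame()
    if len(fg) >= 20 and len(bg) >= len(fg):
        bg_sample = bg.iloc[
            np.sort(rng.choice(len(bg), size=len(fg), replace=False))
        ]
        both = pd.concat([fg, bg_sample], ignore_index=True)
        imp_features = [c for c in perm_features if c in both.columns]
        imp_df = permutation_importance(
            both[imp_features],
            both["rloop"].to_numpy(),
            k_folds=cfg.rf_folds,
            n_repeats=cfg.rf_repeats,
            seed=cfg.seed,
        )
    imp_tsv = out / "feature_importance.tsv"
    imp_df.to_csv(imp_tsv, sep="\t", index=False)
    _record("importance", len(imp_df), imp_tsv)

    manifest["summary"] = {
        "n_common_regions": len(regions),
        "genome_fraction": regions.genome_fraction,
        "fraction_length_10_1000": fraction_in_range(regions, 10, 1000),
        "n_expressed_genes": len(expressed),
        "n_associated_genes": len(associated & set(expressed)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
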