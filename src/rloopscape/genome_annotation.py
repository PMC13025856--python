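"""Region annotation against gene models and genomic elements.

Each region is assigned exactly one category by its midpoint, tested
against a priority-ordered list of element sets (HOMER-style single-label
annotation).  A broader, promoter-centric annotation (ChIPseeker-style
+/-3 kb promoters) is obtained from the same annotator by widening
``promoter_window`` — tool differences become two configurations of one
annotator.  CpG-island overlap is reported as an independent boolean,
since CpG islands are not gene features.
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeInfo, GenomicInterval, sort_and_merge, subtract

__all__ = [
    "GeneModel",
    "AnnotationConfig",
    "RegionAnnotation",
    "Annotator",
    "read_gtf",
    "feature_enrichment",
    "tss_distance_profile",
]

#: single-label priority, highest first; intergenic is the fallback
CATEGORY_PRIORITY = ["promoter-TSS", "5'UTR", "3'UTR", "exon", "TTS", "intron"]
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class GeneModel:
    """Minimal strand-aware gene model.

    ``tss``/``tes`` are 0-based positions of the first/last transcribed
    base; for a ``-`` strand gene the TSS is the rightmost position.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def body(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo, hi + 1)

    def signed_distance(self, position: int) -> int:
        """Signed distance of a genomic position to this gene's TSS.

        Negative means upstream of the TSS in gene orientation.
        """
        d = position - self.tss
        return d if self.strand == "+" else -d


@dataclass
class AnnotationConfig:
    promoter_window: tuple[int, int] = (1000, 100)  # (upstream, downstream) bp
    tts_window: int = 1000
    priority: tuple[str, ...] = tuple(CATEGORY_PRIORITY)

    def __post_init__(self) -> None:
        if min(self.promoter_window) < 0 or self.tts_window < 0:
            raise ValueError("windows must be >= 0")


@dataclass
class RegionAnnotation:
    region: GenomicInterval
    category: str
    nearest_gene_id: str | None
    tss_distance: int | None  # signed, gene orientation; negative = upstream
    cpg_overlap: bool = False
    flagged: bool = False  # chromosome absent from gene annotation


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF file via gffutils.

    Uses ``gene``, ``exon``, ``five_prime_utr``/``5UTR`` and
    ``three_prime_utr``/``3UTR`` feature rows keyed by ``gene_id``; a gene
    without a ``gene`` row gets its span inferred from its exons.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    utr_kinds = {"five_prime_utr": "utr5", "5UTR": "utr5",
                 "three_prime_utr": "utr3", "3UTR": "utr3"}
    for feat in db.all_features():
        gid_vals = feat.attributes.get("gene_id")
        if not gid_vals:
            continue
        gid = gid_vals[0]
        rec = per_gene.setdefault(
            gid,
            {"chrom": feat.seqid, "strand": feat.strand,
             "exons": [], "utr5": [], "utr3": []},
        )
        start, end = feat.start - 1, feat.end  # gffutils is 1-based inclusive
        if feat.featuretype == "gene":
            rec["start"], rec["end"] = start, end
        elif feat.featuretype == "exon":
            rec["exons"].append(GenomicInterval(feat.seqid, start, end))
        elif feat.featuretype in utr_kinds:
            rec[utr_kinds[feat.featuretype]].append(GenomicInterval(feat.seqid, start, end))
    genes = []
    for gid, rec in per_gene.items():
        if "start" not in rec:
            if not rec["exons"]:
                continue
            rec["start"] = min(e.start for e in rec["exons"])
            rec["end"] = max(e.end for e in rec["exons"])
        start, end = rec["start"], rec["end"]
        if rec["strand"] == "+":
            tss, tes = start, end - 1
        else:
            tss, tes = end - 1, start
        genes.append(
            GeneModel(
                gid, rec["chrom"], rec["strand"], tss, tes,
                tuple(sort_and_merge(rec["exons"])) if rec["exons"] else (),
                tuple(rec["utr5"]), tuple(rec["utr3"]),
            )
        )
    return sorted(genes, key=lambda g: (g.chrom, min(g.tss, g.tes), g.gene_id))


class Annotator:
    """Midpoint-based single-category region annotator."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        cfg: AnnotationConfig | None = None,
        cpg_islands: Sequence[GenomicInterval] = (),
    ):
        if not genes:
            raise ValueError("gene list must be non-empty")
        self.genes = list(genes)
        self.cfg = cfg or AnnotationConfig()
        self.cpg = sort_and_merge(cpg_islands) if cpg_islands else []
        self._category_sets = self._build_category_sets()
        # nearest-TSS index: per chromosome, sorted (tss, gene_id ...) arrays
        by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
        for g in self.genes:
            by_chrom[g.chrom].append(g)
        self._tss_index: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        for chrom, gs in by_chrom.items():
            gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self._tss_index[chrom] = (np.array([g.tss for g in gs]), gs)

    # -- category geometry ---------------------------------------------------

    def _promoter_interval(self, g: GeneModel) -> GenomicInterval:
        up, down = self.cfg.promoter_window
        # positions p with signed distance in [-up, +down], inclusive
        if g.strand == "+":
            lo, hi = g.tss - up, g.tss + down + 1
        else:
            lo, hi = g.tss - down, g.tss + up + 1
        return GenomicInterval(g.chrom, max(0, lo), hi)

    def _tts_interval(self, g: GeneModel) -> GenomicInterval:
        w = self.cfg.tts_window
        return GenomicInterval(g.chrom, max(0, g.tes - w), g.tes + w + 1)

    def _build_category_sets(self) -> dict[str, list[GenomicInterval]]:
        raw: dict[str, list[GenomicInterval]] = {c: [] for c in CATEGORY_PRIORITY}
        for g in self.genes:
            raw["promoter-TSS"].append(self._promoter_interval(g))
            raw["TTS"].append(self._tts_interval(g))
            raw["5'UTR"].extend(g.utr5)
            raw["3'UTR"].extend(g.utr3)
            raw["exon"].extend(g.exons)
            raw["intron"].append(g.body)  # refined below by priority
        return {c: sort_and_merge(ivs) if ivs else [] for c, ivs in raw.items()}

    def category_partition(self, genome: GenomeInfo) -> dict[str, list[GenomicInterval]]:
        """Disjoint genome partition: each base gets its highest-priority category."""
        taken: list[GenomicInterval] = []
        out: dict[str, list[GenomicInterval]] = {}
        for cat in self.cfg.priority:
            ivs = self._category_sets.get(cat, [])
            remaining = subtract(ivs, taken) if taken else list(ivs)
            out[cat] = remaining
            taken = sort_and_merge(taken + remaining)
        whole = [GenomicInterval(c, 0, n) for c, n in genome.items()]
        out[INTERGENIC] = subtract(whole, taken)
        return out

    def category_genome_bp(self, genome: GenomeInfo) -> dict[str, int]:
        return {
            cat: sum(len(iv) for iv in ivs)
            for cat, ivs in self.category_partition(genome).items()
        }

    # -- per-region annotation ----------------------------------------------

    def _midpoint_category(self, chrom: str, pos: int) -> str:
        for cat in self.cfg.priority:
            if _point_in(self._category_sets.get(cat, []), chrom, pos):
                return cat
        return INTERGENIC

    def nearest_tss(self, chrom: str, pos: int) -> tuple[GeneModel, int] | None:
        """Nearest-TSS gene and signed distance; ties go to smaller gene_id."""
        if chrom not in self._tss_index:
            return None
        tss_arr, gs = self._tss_index[chrom]
        i = int(np.searchsorted(tss_arr, pos))
        best: GeneModel | None = None
        best_abs = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(gs):
                g = gs[j]
                d_abs = abs(pos - g.tss)
                if (
                    best is None
                    or d_abs < best_abs
                    or (d_abs == best_abs and g.gene_id < best.gene_id)
                ):
                    best, best_abs = g, d_abs
        assert best is not None
        return best, best.signed_distance(pos)

    def annotate(self, region: GenomicInterval) -> RegionAnnotation:
        mid = region.midpoint
        cpg_hit = _point_in(self.cpg, region.chrom, mid) or any(
            region.overlaps(iv) for iv in self.cpg
        )
        near = self.nearest_tss(region.chrom, mid)
        if near is None:
            return RegionAnnotation(region, INTERGENIC, None, None, cpg_hit, flagged=True)
        gene, dist = near
        return RegionAnnotation(
            region, self._midpoint_category(region.chrom, mid), gene.gene_id, dist, cpg_hit
        )

    def annotate_all(self, regions: Iterable[GenomicInterval]) -> list[RegionAnnotation]:
        return [self.annotate(r) for r in regions]


def _point_in(sorted_merged: Sequence[GenomicInterval], chrom: str, pos: int) -> bool:
    # sorted_merged is disjoint and (chrom,start)-sorted
    keys = [(iv.chrom, iv.start) for iv in sorted_merged]
    i = bisect_left(keys, (chrom, pos + 1)) - 1
    if i < 0:
        return False
    iv = sorted_merged[i]
    return iv.chrom == chrom and iv.start <= pos < iv.end


def annotations_to_frame(annotations: Sequence[RegionAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [a.region.chrom for a in annotations],
            "start": [a.region.start for a in annotations],
            "end": [a.region.end for a in annotations],
            "category": [a.category for a in annotations],
            "nearest_gene": [a.nearest_gene_id for a in annotations],
            "tss_distance": [a.tss_distance for a in annotations],
            "cpg_overlap": [a.cpg_overlap for a in annotations],
        }
    )


def feature_enrichment(
    annotations: Sequence[RegionAnnotation],
    genome: GenomeInfo,
    annotator: Annotator,
) -> pd.DataFrame:
    """Per-category log2(observed fraction / expected genomic fraction).

    Expected fractions come from the same priority partition the annotator
    assigns with, so observed and expected fractions both sum to 1.
    Categories with zero genomic bp are excluded with a warning.
    """
    cat_bp = annotator.category_genome_bp(genome)
    total_bp = sum(cat_bp.values())
    obs = pd.Series([a.category for a in annotations]).value_counts()
    rows = []
    for cat in list(annotator.cfg.priority) + [INTERGENIC]:
        bp = cat_bp.get(cat, 0)
        if bp == 0:
            if obs.get(cat, 0):
                warnings.warn(f"category {cat!r} has zero genomic bp; excluded")
            continue
        expected = bp / total_bp
        observed = obs.get(cat, 0) / len(annotations) if annotations else math.nan
        log2 = (
            math.log2(observed / expected) if observed and observed > 0 else -math.inf
        )
        if observed == expected:
            log2 = 0.0
        rows.append(
            {
                "category": cat,
                "observed_fraction": observed,
                "expected_fraction": expected,
                "log2_enrichment": log2,
            }
        )
    return pd.DataFrame(rows)


def tss_distance_profile(
    annotations: Sequence[RegionAnnotation],
    gene_subsets: Mapping[str, set[str]],
    breaks: Sequence[float],
) -> pd.DataFrame:
    """Per-subset histogram of signed nearest-TSS distances.

    Rows are subsets, columns are ``[breaks[i], breaks[i+1])`` bins; each
    row sums to the number of regions whose nearest gene is in the subset.
    Unknown gene ids in a subset draw a warning and are ignored.
    """
    edges = np.asarray(breaks, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("breaks must be strictly increasing")
    known = {a.nearest_gene_id for a in annotations if a.nearest_gene_id}
    rows = {}
    for name, subset in gene_subsets.items():
        if not subset:
            raise ValueError(f"subset {name!r} is empty")
        unknown = subset - known
        if unknown == subset:
            warnings.warn(f"subset {name!r}: no member is a nearest gene of any region")
        dists = [
            a.tss_distance
            for a in annotations
            if a.nearest_gene_id in subset and a.tss_distance is not None
        ]
        counts = np.zeros(len(edges) - 1, dtype=int)
        for d in dists:
            i = int(np.searchsorted(edges, d, side="right")) - 1
            if 0 <= i < len(counts):
                counts[i] += 1
        rows[name] = counts
    cols = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 1)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
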