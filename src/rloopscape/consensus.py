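"""Consensus ("Common R-loop") region calling across method-grouped peak sets.

A genomic base is *supported* when, for every required profiling-method
group (e.g. DRIP, CUT&Tag, HBD, MapR), at least ``min_datasets_per_group``
datasets of that group have a peak covering it.  Supported segments are
then flooded out to the full span of every original peak that overlaps
them, and the collected spans are merged.  This reproduces the
multi-intersection + full-span-recovery + merge strategy used to define
method-independent R-loop regions.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import (
    GenomeInfo,
    GenomicInterval,
    PeakCollection,
    base_partition,
    pairwise_overlaps,
    sort_and_merge,
    total_bases,
)

__all__ = [
    "ConsensusConfig",
    "CommonRegionSet",
    "call_common_regions",
    "length_histogram",
    "element_overlap_fraction",
]


@dataclass
class ConsensusConfig:
    """Parameters of the group-constrained consensus rule.

    ``required_groups=None`` means every group present in the collection.
    """

    required_groups: set[str] | None = None
    min_datasets_per_group: int = 1
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.min_datasets_per_group < 1:
            raise ValueError("min_datasets_per_group must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.required_groups is not None and not self.required_groups:
            raise ValueError("required_groups must be non-empty")


@dataclass
class CommonRegionSet:
    """Disjoint, sorted consensus regions plus per-region peak provenance."""

    regions: list[GenomicInterval]
    provenance: list[frozenset[str]]  # dataset ids contributing to each region
    genome: GenomeInfo | None = None

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.provenance):
            raise ValueError("regions and provenance must align")

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def covered_bases(self) -> int:
        return sum(len(r) for r in self.regions)

    @property
    def genome_fraction(self) -> float:
        if self.genome is None:
            raise ValueError("no genome bound")
        return self.covered_bases / self.genome.total_size

    def summary(self) -> dict:
        lengths = [len(r) for r in self.regions]
        out = {
            "n_regions": len(self.regions),
            "covered_bases": self.covered_bases,
            "median_length": float(np.median(lengths)) if lengths else math.nan,
        }
        if self.genome is not None:
            out["genome_fraction"] = self.genome_fraction
        return out


def call_common_regions(
    collection: PeakCollection,
    cfg: ConsensusConfig | None = None,
    genome: GenomeInfo | None = None,
) -> CommonRegionSet:
    """Call consensus regions supported by every required method group.

    Algorithm: (1) base-level multi-dataset partition; (2) keep segments
    whose covering set contains >= ``min_datasets_per_group`` datasets from
    every required group; (3) collect the full original coordinates of every
    peak (any dataset) overlapping a kept segment; (4) merge the collected
    peaks with ``merge_gap``.
    """
    cfg = cfg or ConsensusConfig()
    required = cfg.required_groups if cfg.required_groups is not None else collection.groups
    if not required:
        raise ValueError("no groups in collection")
    for group in sorted(required):
        n = len(collection.datasets_in_group(group))
        if n < cfg.min_datasets_per_group:
            raise ValueError(
                f"required group {group!r} has {n} dataset(s), "
                f"needs >= {cfg.min_datasets_per_group}"
            )

    group_of = {d: g for d, g, _ in collection.datasets}
    kept_segments: list[GenomicInterval] = []
    for seg, covering in base_partition(collection):
        per_group = Counter(group_of[d] for d in covering)
        if all(per_group.get(g, 0) >= cfg.min_datasets_per_group for g in required):
            kept_segments.append(seg)

    if not kept_segments:
        return CommonRegionSet([], [], genome)

    # flood kept segments out to the full spans of all overlapping peaks
    contributing: list[GenomicInterval] = []
    contrib_ids: list[str] = []
    for dataset_id, _, ivs in collection.datasets:
        for _, j, _ in pairwise_overlaps(kept_segments, ivs):
            contributing.append(ivs[j])
            contrib_ids.append(dataset_id)

    regions = sort_and_merge(contributing, gap=cfg.merge_gap)

    prov_sets: list[set[str]] = [set() for _ in regions]
    for i, j, _ in pairwise_overlaps(regions, contributing):
        prov_sets[i].add(contrib_ids[j])
    return CommonRegionSet(regions, [frozenset(s) for s in prov_sets], genome)


def length_histogram(
    regions: CommonRegionSet | Sequence[GenomicInterval],
    bin_edges: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of region lengths over half-open bins ``[e_i, e_{i+1})``.

    The last edge may be ``inf``. Returns (counts, fractions); fractions are
    NaN for an empty region set.
    """
    ivs = regions.regions if isinstance(regions, CommonRegionSet) else list(regions)
    edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    lengths = np.array([len(iv) for iv in ivs], dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for i in range(len(edges) - 1):
        counts[i] = int(np.sum((lengths >= edges[i]) & (lengths < edges[i + 1])))
    if len(lengths) == 0:
        return counts, np.full(len(counts), np.nan)
    return counts, counts / len(lengths)


def fraction_in_range(
    regions: CommonRegionSet | Sequence[GenomicInterval], lo: int, hi: int
) -> float:
    """Fraction of regions with length in ``[lo, hi]`` (inclusive)."""
    ivs = regions.regions if isinstance(regions, CommonRegionSet) else list(regions)
    if not ivs:
        return math.nan
    return sum(1 for iv in ivs if lo <= len(iv) <= hi) / len(ivs)


def element_overlap_fraction(
    regions: CommonRegionSet | Sequence[GenomicInterval],
    elements: Sequence[GenomicInterval],
) -> float:
    """Fraction of ``elements`` overlapping >= 1 bp of the region union.

    Each element is counted at most once, however many regions it touches.
    """
    if not elements:
        raise ValueError("empty element list")
    ivs = regions.regions if isinstance(regions, CommonRegionSet) else list(regions)
    hit = {j for _, j, _ in pairwise_overlaps(list(ivs), list(elements))}
    return len(hit) / len(elements)
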