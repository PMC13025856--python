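"""Chromatin-state fold enrichment and fixed-width window stratification.

Fold enrichment of consensus regions in a chromatin state follows the
classical (C/A)/(B/D) ratio: C = overlap bp between state and regions,
A = state bp, B = region bp, D = genome bp.  For sequence-feature work
the segmentation is tiled into uniform windows (default 200 bp), each
window classified as ``rloop`` when its overlap with the region union
reaches a fraction f of its length (default 0.5), else ``background`` —
the state-matched "ex-R-loop" null population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .consensus import CommonRegionSet
from .intervals import (
    GenomeInfo,
    GenomicInterval,
    pairwise_overlaps,
    sort_and_merge,
)

__all__ = [
    "StateSegmentation",
    "read_segmentation",
    "state_fold_enrichment",
    "partition_windows",
    "classify_windows",
]


@dataclass
class StateSegmentation:
    """Disjoint, labeled segments tiling (part of) the genome."""

    segments: list[GenomicInterval]  # label carried in .name

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=GenomicInterval.sort_key)
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"overlapping segments at {b.chrom}:{b.start}")
        self.segments = segs

    @property
    def states(self) -> list[str]:
        return sorted({s.name for s in self.segments if s.name})

    def by_state(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for s in self.segments:
            out.setdefault(s.name, []).append(s)
        return out


def read_segmentation(path: str | Path, genome: GenomeInfo | None = None) -> StateSegmentation:
    """Read a 4-column BED segmentation (state label in column 4)."""
    from .intervals import read_bed

    ivs = read_bed(path, genome=genome)
    for iv in ivs:
        if iv.name is None:
            raise ValueError(f"segment {iv.chrom}:{iv.start}-{iv.end} lacks a state label")
    return StateSegmentation(ivs)


def state_fold_enrichment(
    seg: StateSegmentation,
    regions: CommonRegionSet | Sequence[GenomicInterval],
    genome: GenomeInfo,
) -> pd.DataFrame:
    """Per-state fold enrichment (C/A)/(B/D), sorted by fold descending.

    Raises when the region set is empty (B = 0); states with A = 0 are
    omitted with a warning.
    """
    region_ivs = regions.regions if isinstance(regions, CommonRegionSet) else list(regions)
    region_ivs = sort_and_merge(region_ivs)
    b = sum(len(r) for r in region_ivs)
    if b == 0:
        raise ValueError("empty region set (B = 0)")
    d = genome.total_size
    rows = []
    for state, segs in seg.by_state().items():
        a = sum(len(s) for s in segs)
        if a == 0:
            warnings.warn(f"state {state!r} has zero bp; omitted")
            continue
        c = sum(bp for _, _, bp in pairwise_overlaps(segs, region_ivs))
        rows.append(
            {"state": state, "A": a, "B": b, "C": c, "D": d,
             "fold": (c / a) / (b / d)}
        )
    return (
        pd.DataFrame(rows)
        .sort_values("fold", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


def partition_windows(seg: StateSegmentation, window: int = 200) -> pd.DataFrame:
    """Tile each maximal same-state run with non-overlapping L-bp windows.

    Runs of consecutive same-state segments are tiled left to right; a
    trailing remainder shorter than L bp is discarded, so every window is
    exactly L bp and lies within a single state run.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    # coalesce book-ended same-state segments into maximal runs
    runs: list[GenomicInterval] = []
    for s in seg.segments:
        if (
            runs
            and runs[-1].chrom == s.chrom
            and runs[-1].end == s.start
            and runs[-1].name == s.name
        ):
            runs[-1] = GenomicInterval(s.chrom, runs[-1].start, s.end, name=s.name)
        else:
            runs.append(s)
    chroms, starts, states = [], [], []
    for run in runs:
        n = (run.end - run.start) // window
        for k in range(n):
            chroms.append(run.chrom)
            starts.append(run.start + k * window)
            states.append(run.name)
    return pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": pd.Series(starts, dtype=np.int64),
            "end": pd.Series(starts, dtype=np.int64) + window,
            "state": pd.Series(states, dtype=str),
        }
    )


def classify_windows(
    windows: pd.DataFrame,
    regions: CommonRegionSet | Sequence[GenomicInterval],
    f: float | str = 0.5,
) -> pd.DataFrame:
    """Label windows ``rloop``/``background`` by overlap with the region union.

    A window is ``rloop`` iff its bp overlap with the merged region union
    is >= f * L (inclusive). ``f="any"`` means >= 1 bp, the no-threshold
    variant. Adds ``overlap_bp`` and ``rloop`` columns; attaches per-state
    counts and the fraction of region bp captured by rloop windows (the
    coverage diagnostic used to pick f) in ``DataFrame.attrs``.
    """
    if isinstance(f, str):
        if f != "any":
            raise ValueError("f must be a fraction in (0,1] or 'any'")
        min_bp = None
    else:
        if not (0 < f <= 1):
            raise ValueError("f must be in (0,1] or 'any'")
        min_bp = None  # computed per-window below from its length
    region_ivs = regions.regions if isinstance(regions, CommonRegionSet) else list(regions)
    region_ivs = sort_and_merge(region_ivs)
    win_ivs = [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(windows["chrom"], windows["start"], windows["end"])
    ]
    overlap = np.zeros(len(win_ivs), dtype=np.int64)
    for i, _, bp in pairwise_overlaps(win_ivs, region_ivs):
        overlap[i] += bp
    lengths = (windows["end"] - windows["start"]).to_numpy()
    if f == "any":
        is_rloop = overlap >= 1
    else:
        is_rloop = overlap >= f * lengths
    out = windows.copy()
    out["overlap_bp"] = overlap
    out["rloop"] = is_rloop
    region_bp = sum(len(r) for r in region_ivs)
    captured = int(overlap[is_rloop].sum())
    out.attrs["region_bp_captured_fraction"] = (
        captured / region_bp if region_bp else float("nan")
    )
    out.attrs["per_state_counts"] = (
        out.groupby("state")["rloop"].agg(["sum", "count"]).to_dict("index")
    )
    return out
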