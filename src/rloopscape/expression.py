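"""RNA-seq count-matrix processing and consensus-region/gene association.

Implements counts-per-million scaling, the CPM >= 1-in-any-sample
expressed-gene filter, trimmed-mean-of-M-values (TMM, Robinson & Oshlack
2010) between-sample normalization, per-gene mean/CV summaries, and the
nearest-TSS rule that classifies genes as consensus-R-loop-associated.

The expressed-gene set returned by :func:`filter_expressed` is the
background universe for all downstream over-representation analysis.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .consensus import CommonRegionSet
from .genome_annotation import Annotator, GeneModel
from .intervals import GenomicInterval

__all__ = [
    "read_counts",
    "cpm",
    "filter_expressed",
    "tmm_factors",
    "expression_summary",
    "associate_genes",
]


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples count TSV (first column = gene id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return df


def cpm(counts: pd.DataFrame, lib_sizes: Sequence[float] | None = None) -> pd.DataFrame:
    """Counts per million: ``count / library_size * 1e6`` per sample.

    Samples with zero library size are dropped with a warning. Column sums
    of the result equal 1e6 (up to float rounding).
    """
    libs = pd.Series(
        counts.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, float),
        index=counts.columns,
    )
    zero = libs[libs <= 0].index
    if len(zero):
        warnings.warn(f"dropping zero-library samples: {list(zero)}")
        counts = counts.drop(columns=zero)
        libs = libs.drop(zero)
    return counts / libs * 1e6


def filter_expressed(
    counts: pd.DataFrame, threshold: float = 1.0, min_samples: int = 1
) -> list[str]:
    """Genes with CPM >= ``threshold`` in at least ``min_samples`` samples.

    The comparison is inclusive: a gene hitting exactly 1 CPM is retained.
    """
    c = cpm(counts)
    keep = (c >= threshold).sum(axis=1) >= min_samples
    return list(counts.index[keep])


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    Reference sample: the one whose upper-quartile CPM is closest to the
    mean upper quartile (edgeR's rule).  For each sample, M (log2 CPM
    ratio vs reference) and A (mean log2 abundance) are computed on genes
    positive in both; the upper and lower ``trim_m`` of M and ``trim_a``
    of A are discarded; the factor is 2 to the precision-weighted mean of
    the surviving M values, using binomial delta-method weights.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    x = counts.to_numpy(dtype=float)
    libs = x.sum(axis=0)
    if (libs <= 0).any():
        raise ValueError("zero library size")
    p = x / libs  # proportions

    if ref_sample is None:
        uq = np.quantile(p, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_sample)

    log_factors = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            continue
        both = (x[:, j] > 0) & (x[:, ref_idx] > 0)
        if not both.any():
            warnings.warn(
                f"sample {counts.columns[j]!r} shares no expressed gene with the "
                "reference; factor set to 1"
            )
            continue
        obs, ref = p[both, j], p[both, ref_idx]
        m = np.log2(obs / ref)
        a = 0.5 * np.log2(obs * ref)
        # asymptotic (delta-method) variance of M for weighting
        w = (libs[j] - x[both, j]) / (libs[j] * x[both, j]) + (
            libs[ref_idx] - x[both, ref_idx]
        ) / (libs[ref_idx] * x[both, ref_idx])

        keep = _double_trim_mask(m, a, trim_m, trim_a)
        if not keep.any():
            continue
        log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])

    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _double_trim_mask(m: np.ndarray, a: np.ndarray, trim_m: float, trim_a: float) -> np.ndarray:
    """Two-sided rank trimming of M and A (edgeR's trimming rule)."""
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = _rank(m)
    rank_a = _rank(a)
    return (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)


def _rank(v: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(v)


def expression_summary(
    counts: pd.DataFrame,
    factors: pd.Series,
    associated_genes: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-gene expression summary on TMM-normalized CPM.

    ``mean_log10`` is the mean of log10(TMM-CPM + 1) across samples;
    ``cv`` is sd/mean on the linear TMM-CPM scale (0 for an all-zero
    gene). ``associated`` flags consensus-region-associated genes.
    """
    libs = counts.sum(axis=0)
    norm_cpm = counts / (libs * factors.reindex(counts.columns)) * 1e6
    arr = norm_cpm.to_numpy(float)
    mean_lin = arr.mean(axis=1)
    sd_lin = arr.std(axis=1, ddof=1) if arr.shape[1] > 1 else np.zeros(len(arr))
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean_lin > 0, sd_lin / mean_lin, 0.0)
    assoc = set(associated_genes)
    missing = assoc - set(counts.index)
    if missing:
        warnings.warn(f"{len(missing)} associated gene(s) absent from matrix; ignored")
    return pd.DataFrame(
        {
            "mean_log10": np.log10(arr + 1).mean(axis=1),
            "mean_tmm_cpm": mean_lin,
            "cv": cv,
            "associated": [g in assoc for g in counts.index],
        },
        index=counts.index,
    )


def associate_genes(
    regions: CommonRegionSet | Sequence[GenomicInterval],
    annotator: Annotator,
    max_abs_distance: int = 3000,
) -> set[str]:
    """Genes associated with consensus regions by nearest-TSS proximity.

    A gene is associated iff it is the nearest-TSS gene of at least one
    region whose |signed TSS distance| <= ``max_abs_distance`` (default
    +/-3 kb, the broad-promoter convention).
    """
    ivs = regions.regions if isinstance(regions, CommonRegionSet) else list(regions)
    out: set[str] = set()
    for region in ivs:
        near = annotator.nearest_tss(region.chrom, region.midpoint)
        if near is None:
            continue
        gene, dist = near
        if abs(dist) <= max_abs_distance:
            out.add(gene.gene_id)
    return out
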