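"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — per-base boolean bitmaps, explicit
loops, backtracking matchers — and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# per-base bitmap interval operations (single small genome)
# ---------------------------------------------------------------------------

def coverage_bitmap(intervals, genome_size: int, chrom: str = "chr1") -> np.ndarray:
    cov = np.zeros(genome_size, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            cov[iv.start:iv.end] = True
    return cov


def bitmap_to_intervals(cov: np.ndarray, chrom: str = "chr1"):
    """Maximal True runs of a bitmap as (start, end) pairs."""
    out = []
    in_run, start = False, 0
    for i, v in enumerate(cov):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(cov)))
    return out


def bitmap_merge_with_gap(intervals, genome_size: int, gap: int, chrom: str = "chr1"):
    """Merge semantics via bitmap: close gaps <= gap between covered runs."""
    cov = coverage_bitmap(intervals, genome_size, chrom)
    runs = bitmap_to_intervals(cov, chrom)
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def bitmap_intersect_bases(a, b, genome_size: int, chrom: str = "chr1") -> int:
    return int(
        np.sum(coverage_bitmap(a, genome_size, chrom) & coverage_bitmap(b, genome_size, chrom))
    )


def per_base_covering_sets(datasets, genome_size: int, chrom: str = "chr1"):
    """List over bases of frozenset of dataset ids covering that base."""
    out = [set() for _ in range(genome_size)]
    for dataset_id, ivs in datasets:
        for iv in ivs:
            if iv.chrom == chrom:
                for p in range(iv.start, iv.end):
                    out[p].add(dataset_id)
    return [frozenset(s) for s in out]


def brute_force_consensus(datasets_with_groups, genome_size: int, required_groups,
                          min_per_group: int = 1, merge_gap: int = 0, chrom: str = "chr1"):
    """Per-base group rule, flood to overlapping peak spans, bitmap merge.

    datasets_with_groups: list of (dataset_id, group, interval list).
    Returns merged (start, end) pairs.
    """
    support = np.zeros(genome_size, dtype=bool)
    for p in range(genome_size):
        per_group: dict[str, set[str]] = {}
        for dataset_id, group, ivs in datasets_with_groups:
            if any(iv.chrom == chrom and iv.start <= p < iv.end for iv in ivs):
                per_group.setdefault(group, set()).add(dataset_id)
        support[p] = all(
            len(per_group.get(g, ())) >= min_per_group for g in required_groups
        )
    spans = []
    for _, _, ivs in datasets_with_groups:
        for iv in ivs:
            if iv.chrom == chrom and support[iv.start:iv.end].any():
                spans.append((iv.start, iv.end))
    cov = np.zeros(genome_size, dtype=bool)
    for s, e in spans:
        cov[s:e] = True
    runs = bitmap_to_intervals(cov, chrom)
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# naive TMM (independent of the package implementation)
# ---------------------------------------------------------------------------

def naive_tmm(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed mean of M-values, written with explicit sorting-based trims."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    lib = counts.sum(axis=0)
    rate = counts / lib
    uq = np.array([sorted(rate[:, j])[int(np.floor(0.75 * (n_genes - 1)))] for j in range(n_samples)])
    # quantile per numpy's default linear interpolation, to mirror the rule
    uq = np.quantile(rate, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - np.mean(uq))))
    log_f = np.zeros(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        m_vals, a_vals, w_vals = [], [], []
        for g in range(n_genes):
            if counts[g, j] > 0 and counts[g, ref] > 0:
                m = np.log2(rate[g, j] / rate[g, ref])
                a = 0.5 * np.log2(rate[g, j] * rate[g, ref])
                w = (lib[j] - counts[g, j]) / (lib[j] * counts[g, j]) + (
                    lib[ref] - counts[g, ref]
                ) / (lib[ref] * counts[g, ref])
                m_vals.append(m)
                a_vals.append(a)
                w_vals.append(w)
        if not m_vals:
            continue
        m_arr, a_arr, w_arr = map(np.array, (m_vals, a_vals, w_vals))
        n = len(m_arr)
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        from scipy.stats import rankdata

        rm, ra = rankdata(m_arr), rankdata(a_arr)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any():
            log_f[j] = np.sum(m_arr[keep] / w_arr[keep]) / np.sum(1.0 / w_arr[keep])
    f = 2.0 ** log_f
    return f / np.exp(np.mean(np.log(f)))


# ---------------------------------------------------------------------------
# naive sequence scanners
# ---------------------------------------------------------------------------

def naive_skews(seq: str) -> tuple[float, float]:
    g = c = a = t = 0
    for ch in seq.upper():
        if ch == "G":
            g += 1
        elif ch == "C":
            c += 1
        elif ch == "A":
            a += 1
        elif ch == "T":
            t += 1
    gc = abs(g - c) / (g + c) if g + c else 0.0
    at = abs(a - t) / (a + t) if a + t else 0.0
    return gc, at


def _match_quad_at(seq: str, pos: int, run_char: str) -> int | None:
    """Backtracking match of RUN{3,}(LOOP{1,7}RUN{3,}){3} at pos.

    Mirrors a leftmost greedy regex engine: maximal run first, then loop
    lengths 7..1, recursing; returns the match end or None.
    """
    n = len(seq)

    def run_len(p: int) -> int:
        q = p
        while q < n and seq[q] == run_char:
            q += 1
        return q - p

    def rec(p: int, repeats_left: int) -> int | None:
        r = run_len(p)
        if r < 3:
            return None
        for take in range(r, 2, -1):  # greedy run
            q = p + take
            if repeats_left == 0:
                return q
            for loop in range(7, 0, -1):  # greedy loop
                if q + loop > n:
                    continue
                got = rec(q + loop, repeats_left - 1)
                if got is not None:
                    return got
        return None

    return rec(pos, 3)


def naive_quadparser(seq: str) -> int:
    s = seq.upper()
    total = 0
    for run_char in "GC":
        p = 0
        while p < len(s):
            end = _match_quad_at(s, p, run_char)
            if end is not None:
                total += 1
                p = end
            else:
                p += 1
    return total


def naive_g4hunter(seq: str, window: int = 25, threshold: float = 1.2):
    s = seq.upper()
    scores = []
    i = 0
    while i < len(s):
        if s[i] in "GC":
            j = i
            while j < len(s) and s[j] == s[i]:
                j += 1
            v = min(j - i, 4) * (1 if s[i] == "G" else -1)
            scores.extend([v] * (j - i))
            i = j
        else:
            scores.append(0)
            i += 1
    if len(scores) < window:
        means = [sum(scores) / len(scores)]
    else:
        means = [
            sum(scores[k:k + window]) / window for k in range(len(scores) - window + 1)
        ]
    hits = 0
    in_hit = False
    for m in means:
        if abs(m) >= threshold:
            if not in_hit:
                hits += 1
            in_hit = True
        else:
            in_hit = False
    return max(abs(m) for m in means), hits


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_iupac_scan(seq: str, pattern: str) -> tuple[bool, int]:
    def count_on(s: str) -> int:
        c = 0
        for i in range(len(s) - len(pattern) + 1):
            if all(s[i + k] in IUPAC[pattern[k].upper()] for k in range(len(pattern))):
                c += 1
        return c

    s = seq.upper()
    rc = "".join(_RC[ch] for ch in reversed(s))
    n = count_on(s) + count_on(rc)
    return n > 0, n


# ---------------------------------------------------------------------------
# exact hypergeometric tail via factorials
# ---------------------------------------------------------------------------

def exact_hypergeom_upper(k: int, n_universe: int, n_success: int, n_draw: int) -> float:
    """P[X >= k] computed with exact rational arithmetic."""
    from fractions import Fraction
    from math import comb

    total = comb(n_universe, n_draw)
    acc = Fraction(0)
    for x in range(k, min(n_success, n_draw) + 1):
        acc += Fraction(comb(n_success, x) * comb(n_universe - n_success, n_draw - x), total)
    return float(acc)
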