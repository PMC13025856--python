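"""Per-window sequence features relevant to R-loop formation.

Implements strand-agnostic nucleotide skews, the Quadparser canonical
G-quadruplex regular expression, the G4Hunter G/C-run sliding score, and
degenerate (IUPAC) motif scanning.  Because peak-derived regions carry no
strand information, skews are reported as absolute values and all motif
scanners search both strands.

An ``external_score`` column accepts any per-window numeric predictor
(e.g. a trained G4-propensity model), so motif counts, structure scores
and skew can be compared on equal footing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "gc_at_skew",
    "quadparser_count",
    "g4hunter",
    "IUPACMotif",
    "read_motif_table",
    "iupac_scan",
    "featurize_windows",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "gc_skew_abs",
    "at_skew_abs",
    "quadparser_count",
    "g4hunter_max_abs",
    "g4hunter_hits",
    "n_fraction",
]

#: canonical quadruplex motif: four G-runs (>=3) spaced by 1-7 nt loops
_QUADPARSER_G = re.compile(r"G{3,}(?:[ACGTN]{1,7}G{3,}){3}")
_QUADPARSER_C = re.compile(r"C{3,}(?:[ACGTN]{1,7}C{3,}){3}")

IUPAC_CLASSES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def gc_at_skew(sequence: str) -> tuple[float, float]:
    """Absolute GC and AT skew: |(G-C)/(G+C)| and |(A-T)/(A+T)|.

    N bases are excluded from the counts; a zero denominator yields a
    skew of 0 by convention. Invariant under reverse complement.
    """
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    g, c, a, t = s.count("G"), s.count("C"), s.count("A"), s.count("T")
    gc = abs(g - c) / (g + c) if g + c else 0.0
    at = abs(a - t) / (a + t) if a + t else 0.0
    return gc, at


def quadparser_count(sequence: str) -> int:
    """Count canonical G4 motifs on both strands.

    Matches G{3,}(N{1,7}G{3,}){3} left-to-right without overlap on the
    given strand, plus the C-run mirror (the reverse-strand motif); the
    two counts are summed.
    """
    s = sequence.upper()
    return sum(1 for _ in _QUADPARSER_G.finditer(s)) + sum(
        1 for _ in _QUADPARSER_C.finditer(s)
    )


def g4hunter_base_scores(sequence: str) -> np.ndarray:
    """Per-base G4Hunter scores: +min(run,4) in G-runs, -min(run,4) in C-runs."""
    s = sequence.upper()
    scores = np.zeros(len(s), dtype=np.int64)
    i = 0
    while i < len(s):
        ch = s[i]
        if ch in "GC":
            j = i
            while j < len(s) and s[j] == ch:
                j += 1
            val = min(j - i, 4)
            scores[i:j] = val if ch == "G" else -val
            i = j
        else:
            i += 1
    return scores


def g4hunter(
    sequence: str, window: int = 25, threshold: float = 1.2
) -> tuple[float, int, np.ndarray]:
    """G4Hunter sliding-mean score of G/C-run density.

    Returns (max |windowed mean|, number of merged threshold-exceeding
    runs, per-window mean scores).  A hit is a maximal run of consecutive
    windows whose |mean| >= ``threshold``; a sequence shorter than the
    window is scored as one whole-sequence mean.  The absolute value
    makes the score strand-agnostic.
    """
    if not sequence:
        raise ValueError("empty sequence")
    base = g4hunter_base_scores(sequence)
    if len(base) < window:
        sums = np.array([base.sum()])
        width = len(base)
    else:
        # exact integer sliding sums keep the threshold comparison crisp
        csum = np.concatenate(([0], np.cumsum(base)))
        sums = csum[window:] - csum[:-window]
        width = window
    means = sums / width
    above = np.abs(sums) >= threshold * width
    # count maximal runs of consecutive above-threshold windows
    hits = int(np.sum(above[1:] & ~above[:-1]) + (1 if above.size and above[0] else 0))
    max_abs = float(np.max(np.abs(means))) if means.size else 0.0
    return max_abs, hits, means


@dataclass(frozen=True)
class IUPACMotif:
    """A named degenerate-nucleotide motif."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(IUPAC_CLASSES)
        if bad:
            raise ValueError(f"invalid IUPAC symbol(s) {sorted(bad)} in {self.name!r}")

    def regex(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all counted
        body = "".join(f"[{IUPAC_CLASSES[ch]}]" for ch in self.pattern.upper())
        return re.compile(f"(?=({body}))")


def read_motif_table(path: str | Path) -> list[IUPACMotif]:
    """Read a 2-column TSV of (name, IUPAC pattern); '#' lines are comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"motif line needs 2 columns: {line!r}")
            out.append(IUPACMotif(fields[0], fields[1]))
    return out


def iupac_scan(sequence: str, motif: IUPACMotif) -> tuple[bool, int]:
    """Scan both strands for a degenerate motif.

    Returns (any match, total count); overlapping occurrences all count.
    N in the sequence matches only motif positions whose class is N.
    """
    s = sequence.upper()
    rx = motif.regex()
    n = sum(1 for _ in rx.finditer(s)) + sum(1 for _ in rx.finditer(reverse_complement(s)))
    return n > 0, n


def featurize_windows(
    windows: pd.DataFrame,
    fasta,
    motifs: Sequence[IUPACMotif] = (),
    g4hunter_window: int = 25,
    g4hunter_threshold: float = 1.2,
    max_n_fraction: float = 0.5,
    external_scores: Mapping[tuple[str, int], float] | None = None,
) -> pd.DataFrame:
    """Fill per-window sequence-feature columns from an indexed FASTA.

    ``fasta`` is a ``pyfaidx.Fasta`` (or any mapping of chrom -> sliceable
    sequence).  Windows with more than ``max_n_fraction`` N bases are
    dropped; the number dropped is recorded in ``DataFrame.attrs``.  A
    window extending past its contig raises, since that indicates a
    genome/annotation mismatch.  Adds one ``motif_<name>`` count column
    per motif and an ``external_score`` column when scores are supplied.
    """
    rows = {col: np.empty(len(windows)) for col in FEATURE_COLUMNS}
    motif_counts = {m.name: np.zeros(len(windows), dtype=int) for m in motifs}
    keep = np.ones(len(windows), dtype=bool)
    for k, (chrom, start, end) in enumerate(
        zip(windows["chrom"], windows["start"], windows["end"])
    ):
        contig = fasta[chrom]
        if end > len(contig):
            raise ValueError(
                f"window {chrom}:{start}-{end} beyond contig end {len(contig)} "
                "(genome mismatch?)"
            )
        seq = str(contig[int(start):int(end)]).upper()
        n_frac = seq.count("N") / len(seq)
        if n_frac > max_n_fraction:
            keep[k] = False
            continue
        gc, at = gc_at_skew(seq)
        g4max, g4hits, _ = g4hunter(seq, g4hunter_window, g4hunter_threshold)
        rows["gc_skew_abs"][k] = gc
        rows["at_skew_abs"][k] = at
        rows["quadparser_count"][k] = quadparser_count(seq)
        rows["g4hunter_max_abs"][k] = g4max
        rows["g4hunter_hits"][k] = g4hits
        rows["n_fraction"][k] = n_frac
        for m in motifs:
            motif_counts[m.name][k] = iupac_scan(seq, m)[1]
    out = windows.copy()
    for col, vals in rows.items():
        out[col] = vals
    for name, vals in motif_counts.items():
        out[f"motif_{name}"] = vals
    if external_scores is not None:
        out["external_score"] = [
            external_scores.get((c, int(s)), np.nan)
            for c, s in zip(windows["chrom"], windows["start"])
        ]
    dropped = int((~keep).sum())
    out = out[keep].reset_index(drop=True)
    out.attrs["n_windows_dropped_for_n"] = dropped
    out.attrs["g4hunter_window"] = g4hunter_window
    out.attrs["g4hunter_threshold"] = g4hunter_threshold
    return out


def read_external_scores(path: str | Path) -> dict[tuple[str, int], float]:
    """Read a per-window score TSV: chrom, start, score."""
    out: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, score = line.split("\t")[:3]
            out[(chrom, int(start))] = float(score)
    return out
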