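"""Core genomic-interval arithmetic and BED-family readers/writers.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.
Chromosome names are matched exactly; an optional ``chr``-prefix
normalisation switch exists on the readers but is off by default, because
silent renaming hides data errors.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "GenomeInfo",
    "PeakCollection",
    "read_bed",
    "read_narrowpeak",
    "read_chrom_sizes",
    "write_bed",
    "sort_and_merge",
    "intersect_bases",
    "pairwise_overlaps",
    "base_partition",
    "subtract",
    "total_bases",
]

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region with optional BED metadata.

    ``extra`` holds auxiliary narrowPeak columns (signalValue, pValue,
    qValue, summit offset) or anything else a reader wants to preserve.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."
    extra: tuple = ()

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


class GenomeInfo:
    """Ordered map of chromosome name -> length in bp."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        self._sizes: dict[str, int] = dict(sizes)
        for chrom, length in self._sizes.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {chrom}: {length}")

    @property
    def total_size(self) -> int:
        return sum(self._sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    def validate(self, intervals: Iterable[GenomicInterval]) -> None:
        """Raise if any interval lies on an unknown chromosome or past its end."""
        for iv in intervals:
            if iv.chrom not in self._sizes:
                raise ValueError(f"unknown chromosome {iv.chrom!r}")
            if iv.end > self._sizes[iv.chrom]:
                raise ValueError(
                    f"{iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {self._sizes[iv.chrom]}"
                )


@dataclass
class PeakCollection:
    """Peak datasets, each tagged with the profiling-method group it came from."""

    datasets: list[tuple[str, str, list[GenomicInterval]]] = field(default_factory=list)

    def add(self, dataset_id: str, group: str, intervals: Sequence[GenomicInterval]) -> None:
        if dataset_id in {d for d, _, _ in self.datasets}:
            raise ValueError(f"duplicate dataset id {dataset_id!r}")
        self.datasets.append((dataset_id, group, list(intervals)))

    @property
    def groups(self) -> set[str]:
        return {g for _, g, _ in self.datasets}

    def group_of(self, dataset_id: str) -> str:
        for d, g, _ in self.datasets:
            if d == dataset_id:
                return g
        raise KeyError(dataset_id)

    def datasets_in_group(self, group: str) -> list[str]:
        return [d for d, g, _ in self.datasets if g == group]

    def __len__(self) -> int:
        return len(self.datasets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _normalize_chrom(chrom: str, add_chr_prefix: bool) -> str:
    if add_chr_prefix and not chrom.startswith("chr"):
        return "chr" + chrom
    return chrom


def _parse_bed_line(
    line: str, lineno: int, path: str, narrowpeak: bool, add_chr_prefix: bool
) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
    chrom = _normalize_chrom(fields[0], add_chr_prefix)
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if end <= start or start < 0:
        raise ValueError(f"{path}:{lineno}: bad coordinates {start}-{end}")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        score = float(fields[4])
    strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
    extra: tuple = ()
    if narrowpeak and len(fields) >= 10:
        extra = (float(fields[6]), float(fields[7]), float(fields[8]), int(fields[9]))
    elif len(fields) > 6:
        extra = tuple(fields[6:])
    return GenomicInterval(chrom, start, end, name, score, strand, extra)


def _read_intervals(
    path: str | Path,
    narrowpeak: bool,
    genome: GenomeInfo | None,
    add_chr_prefix: bool,
) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_bed_line(line, lineno, str(path), narrowpeak, add_chr_prefix)
            if genome is not None and iv.chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {iv.chrom!r}")
            out.append(iv)
    return out


def read_bed(
    path: str | Path,
    genome: GenomeInfo | None = None,
    add_chr_prefix: bool = False,
) -> list[GenomicInterval]:
    """Read BED3/BED6(+); extra columns beyond 6 are preserved as strings."""
    return _read_intervals(path, narrowpeak=False, genome=genome, add_chr_prefix=add_chr_prefix)


def read_narrowpeak(
    path: str | Path,
    genome: GenomeInfo | None = None,
    add_chr_prefix: bool = False,
) -> list[GenomicInterval]:
    """Read an ENCODE narrowPeak (10-column BED6+4) file.

    Columns 4-6 map to name/score/strand; 7-10 (signalValue, pValue,
    qValue, summit) are kept in ``extra``. Malformed lines raise with the
    file and line number. Unknown chromosomes are rejected only when a
    :class:`GenomeInfo` is supplied.
    """
    return _read_intervals(path, narrowpeak=True, genome=genome, add_chr_prefix=add_chr_prefix)


def read_chrom_sizes(path: str | Path) -> GenomeInfo:
    """Read a 2-column ``chrom.sizes`` TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return GenomeInfo(sizes)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write sorted, tab-separated BED; emits as many columns as are populated."""
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    with open(path, "w") as fh:
        for iv in ivs:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            has_meta = iv.name is not None or iv.score is not None or iv.strand != "." or iv.extra
            if has_meta:
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(_fmt_score(iv.score) if iv.score is not None else ".")
                fields.append(iv.strand)
                fields.extend(_fmt_score(x) if isinstance(x, float) else str(x) for x in iv.extra)
            fh.write("\t".join(fields) + "\n")


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def sort_and_merge(intervals: Iterable[GenomicInterval], gap: int = 0) -> list[GenomicInterval]:
    """Sort and merge overlapping or near-book-ended intervals.

    Two intervals merge iff they overlap or are within ``gap`` bp of each
    other; the default ``gap=0`` merges touching intervals, the bedtools
    merge default. Metadata is dropped from merged output.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def total_bases(intervals: Iterable[GenomicInterval]) -> int:
    """Bases covered by the union of ``intervals``."""
    return sum(len(iv) for iv in sort_and_merge(intervals))


def pairwise_overlaps(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int, int]]:
    """All overlapping (index_a, index_b, bp) pairs, by sorted sweep."""
    order_a = sorted(range(len(a)), key=lambda i: a[i].sort_key())
    order_b = sorted(range(len(b)), key=lambda j: b[j].sort_key())
    out: list[tuple[int, int, int]] = []
    by_chrom_b: dict[str, list[int]] = defaultdict(list)
    for j in order_b:
        by_chrom_b[b[j].chrom].append(j)
    lo: dict[str, int] = defaultdict(int)  # per-chrom dead-prefix pointer
    for i in order_a:
        iv = a[i]
        js = by_chrom_b.get(iv.chrom, ())
        k = lo[iv.chrom]
        # b[j] ending at or before iv.start can never overlap a later query
        while k < len(js) and b[js[k]].end <= iv.start:
            k += 1
        lo[iv.chrom] = k
        for j in js[k:]:
            bj = b[j]
            if bj.start >= iv.end:
                break
            bp = min(iv.end, bj.end) - max(iv.start, bj.start)
            if bp > 0:
                out.append((i, j, bp))
    return out


def intersect_bases(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> int:
    """Bases in the intersection of the unions of ``a`` and ``b``.

    Equals the per-base AND of the two coverage bitmaps, hence symmetric.
    """
    ma, mb = sort_and_merge(a), sort_and_merge(b)
    total = 0
    for _, _, bp in pairwise_overlaps(ma, mb):
        total += bp
    return total


def subtract(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Portions of the union of ``a`` not covered by ``b`` (bedtools subtract)."""
    ma, mb = sort_and_merge(a), sort_and_merge(b)
    by_chrom_b: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in mb:
        by_chrom_b[iv.chrom].append(iv)
    out: list[GenomicInterval] = []
    for iv in ma:
        cursor = iv.start
        for blocker in by_chrom_b.get(iv.chrom, ()):
            if blocker.end <= cursor:
                continue
            if blocker.start >= iv.end:
                break
            if blocker.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, blocker.start))
            cursor = max(cursor, blocker.end)
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return out


def base_partition(
    collection: PeakCollection,
) -> list[tuple[GenomicInterval, frozenset[str]]]:
    """Multi-dataset base-level partition (bedtools multiinter semantics).

    Returns disjoint segments tiling exactly the union of all peaks; each
    segment carries the set of dataset ids covering every base of it, and
    adjacent segments differ in covering set.
    """
    if not collection.datasets:
        raise ValueError("empty collection")
    events: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for dataset_id, _, ivs in collection.datasets:
        for iv in sort_and_merge(ivs):  # within-dataset coverage is boolean
            events[iv.chrom].append((iv.start, +1, dataset_id))
            events[iv.chrom].append((iv.end, -1, dataset_id))
    out: list[tuple[GenomicInterval, frozenset[str]]] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom], key=lambda e: (e[0], e[1]))
        active: set[str] = set()
        prev_pos: int | None = None
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            if prev_pos is not None and active and pos > prev_pos:
                seg = (GenomicInterval(chrom, prev_pos, pos), frozenset(active))
                if out and out[-1][0].chrom == chrom and out[-1][0].end == prev_pos and out[-1][1] == seg[1]:
                    out[-1] = (
                        GenomicInterval(chrom, out[-1][0].start, pos),
                        seg[1],
                    )
                else:
                    out.append(seg)
            while i < len(evs) and evs[i][0] == pos:
                _, delta, ds = evs[i]
                if delta < 0:
                    active.discard(ds)
                else:
                    active.add(ds)
                i += 1
            prev_pos = pos
    return out
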