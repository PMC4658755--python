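"""Genomic interval / cut-count data model and I/O.

All coordinates are 0-based half-open (BED convention).  The central data
structure is :class:`CutProfile`, holding per-base counts of 5' DNase cut
events on the positive and negative strand over a genomic interval.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

__all__ = [
    "GenomicInterval",
    "CutProfile",
    "ReadSource",
    "extract_cuts",
    "read_intervals",
    "write_intervals",
    "intersect_counts",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def expand(self, pad: int) -> "GenomicInterval":
        """Extend by ``pad`` bp on both sides, floored at 0."""
        return GenomicInterval(
            self.chrom,
            max(0, self.start - pad),
            self.end + pad,
            self.strand,
            self.name,
            self.score,
        )

    def to_bed_fields(self) -> list[str]:
        fields = [self.chrom, str(self.start), str(self.end)]
        if self.name is not None or self.score is not None or self.strand != ".":
            fields.append(self.name if self.name is not None else ".")
            fields.append(
                format(self.score, "g") if self.score is not None else "0"
            )
            fields.append(self.strand)
        return fields


@dataclass
class CutProfile:
    """Per-base 5' cut counts on both strands over an interval.

    ``fwd[i]`` / ``rev[i]`` count reads whose 5' end falls at genomic
    position ``interval.start + i`` on the respective strand.
    """

    interval: GenomicInterval
    fwd: np.ndarray
    rev: np.ndarray

    def __post_init__(self) -> None:
        self.fwd = np.asarray(self.fwd)
        self.rev = np.asarray(self.rev)
        n = len(self.interval)
        if self.fwd.shape != (n,) or self.rev.shape != (n,):
            raise ValueError(
                f"count vectors must have length {n}, got "
                f"{self.fwd.shape} and {self.rev.shape}"
            )
        if (self.fwd < 0).any() or (self.rev < 0).any():
            raise ValueError("cut counts must be non-negative")

    def __len__(self) -> int:
        return len(self.interval)

    @property
    def total_fwd(self) -> int:
        return int(self.fwd.sum())

    @property
    def total_rev(self) -> int:
        return int(self.rev.sum())

    @property
    def total(self) -> int:
        return self.total_fwd + self.total_rev

    def slice(self, start: int, end: int) -> "CutProfile":
        """Sub-profile over ``[interval.start + start, interval.start + end)``."""
        sub = GenomicInterval(
            self.interval.chrom,
            self.interval.start + start,
            self.interval.start + end,
            self.interval.strand,
        )
        return CutProfile(sub, self.fwd[start:end].copy(), self.rev[start:end].copy())

    @staticmethod
    def zeros(interval: GenomicInterval) -> "CutProfile":
        n = len(interval)
        return CutProfile(interval, np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64))


class ReadSource:
    """Random-access handle to coordinate-sorted, indexed aligned reads.

    Wraps a :class:`pysam.AlignmentFile`.  Plain-text SAM inputs are
    transparently converted to a sorted, indexed BAM in a scratch
    directory, since random access needs an index.
    """

    def __init__(self, path: str | os.PathLike):
        path = os.fspath(path)
        if path.endswith(".sam") or _looks_like_sam_text(path):
            path = self._prepare_sam(path)
        self._path = path
        self._af = pysam.AlignmentFile(path, "rb")
        if not self._af.has_index():
            try:
                pysam.index(path)
                self._af = pysam.AlignmentFile(path, "rb")
            except Exception as exc:  # pragma: no cover
                raise ValueError(f"alignment file {path} is not indexed: {exc}")
        self.total_reads = self._af.mapped

    @staticmethod
    def _prepare_sam(sam_path: str) -> str:
        tmpdir = tempfile.mkdtemp(prefix="dfprint_bam_")
        bam = os.path.join(tmpdir, "reads.bam")
        pysam.sort("-o", bam, sam_path)
        pysam.index(bam)
        return bam

    @property
    def references(self) -> tuple[str, ...]:
        return tuple(self._af.references)

    def fetch(self, interval: GenomicInterval):
        if interval.chrom not in self._af.references:
            raise KeyError(
                f"chromosome {interval.chrom!r} not present in alignment file "
                f"(has {list(self._af.references)})"
            )
        return self._af.fetch(interval.chrom, interval.start, interval.end)

    def close(self) -> None:
        self._af.close()

    def __enter__(self) -> "ReadSource":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def _looks_like_sam_text(path: str) -> bool:
    try:
        with open(path, "rb") as fh:
            head = fh.read(4)
    except OSError:
        return False
    return head[:1] == b"@" or head[:3] not in (b"BAM", b"\x1f\x8b\x08")


def extract_cuts(source: ReadSource, interval: GenomicInterval) -> CutProfile:
    """Count 5' cut events per base within ``interval``.

    The 5' end of a +-strand read is its leftmost aligned base; for a
    −-strand read it is its rightmost aligned base (no offset applied).
    Unmapped, secondary and supplementary alignments are skipped;
    duplicates are retained.
    """
    n = len(interval)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for read in source.fetch(interval):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.is_reverse:
            pos = read.reference_end - 1
            if interval.start <= pos < interval.end:
                rev[pos - interval.start] += 1
        else:
            pos = read.reference_start
            if interval.start <= pos < interval.end:
                fwd[pos - interval.start] += 1
    return CutProfile(interval, fwd, rev)


def read_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Parse a BED3+ file into a list of intervals (order preserved)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates: {exc}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad score: {exc}")
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}")
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals as BED (BED3 or BED6 depending on populated fields)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(iv.to_bed_fields()) + "\n")


def intersect_counts(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> tuple[int, list[bool]]:
    """For each interval of ``a``, does it overlap >=1 bp of some interval of ``b``?

    Returns ``(shared_count, membership)`` where ``membership[i]`` is True
    iff ``a[i]`` is shared.  Sweep over per-chromosome sorted ``b`` starts.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    # collapse to sorted, merged spans per chromosome for O(log n) lookup
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        ms, me = [], []
        for s, e in spans:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[chrom] = (np.array(ms), np.array(me))

    membership: list[bool] = []
    for iv in a:
        hit = False
        if iv.chrom in merged:
            starts, ends = merged[iv.chrom]
            j = int(np.searchsorted(starts, iv.end, side="left"))
            # candidate merged span is the last one starting before iv.end
            if j > 0 and ends[j - 1] > iv.start:
                hit = True
        membership.append(hit)
    return sum(membership), membership
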