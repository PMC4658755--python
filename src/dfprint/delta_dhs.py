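"""Read-count-based differential DHS scoring (library-normalised cut
count difference per interval) plus top/bottom selection and the
single-nearby-TSS promoter filter."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .genomic_core import GenomicInterval

__all__ = [
    "DhsCount",
    "delta_dhs_score",
    "select_top_bottom",
    "filter_near_single_tss",
]


@dataclass(frozen=True)
class DhsCount:
    """Cut counts for one DHS interval in two libraries."""

    interval: GenomicInterval
    c_a: int
    c_b: int
    t_a: int  # library total for A
    t_b: int  # library total for B

    def __post_init__(self) -> None:
        if self.c_a < 0 or self.c_b < 0:
            raise ValueError("counts must be non-negative")
        if self.t_a <= 0 or self.t_b <= 0:
            raise ValueError("library totals must be positive")


def delta_dhs_score(
    d: DhsCount,
    normalize: Callable[[int, int], float] | None = None,
) -> float:
    """Difference of normalised counts, A minus B.

    Default normalisation is reads-per-million: ``1e6 * (c_a/t_a - c_b/t_b)``.
    A custom ``normalize(count, total)`` hook may be supplied.
    Antisymmetric under swapping A and B.
    """
    if normalize is None:
        normalize = lambda c, t: 1e6 * c / t
    return normalize(d.c_a, d.t_a) - normalize(d.c_b, d.t_b)


def select_top_bottom(
    scores: Sequence[tuple[GenomicInterval, float]], n: int = 1000
) -> tuple[list[tuple[GenomicInterval, float]], list[tuple[GenomicInterval, float]]]:
    """Top n by descending score and bottom n by ascending score.

    Ties broken deterministically by coordinate (chrom, start, end).
    """
    if n > len(scores):
        raise ValueError(
            f"requested n={n} exceeds number of scored intervals ({len(scores)})"
        )
    key_coord = lambda t: (t[0].chrom, t[0].start, t[0].end)
    top = sorted(scores, key=lambda t: (-t[1],) + key_coord(t))[:n]
    bottom = sorted(scores, key=lambda t: (t[1],) + key_coord(t))[:n]
    return top, bottom


def filter_near_single_tss(
    intervals: Sequence[GenomicInterval],
    tss: Sequence[tuple[str, str, int]],
    max_dist: int = 2000,
) -> list[tuple[GenomicInterval, str]]:
    """Keep intervals whose midpoint lies within ``max_dist`` of exactly
    one TSS; annotate each with that gene.

    ``tss`` entries are (gene, chrom, position).  Intervals near zero or
    two-plus TSSs are dropped.
    """
    if not tss:
        raise ValueError("TSS table must be non-empty")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene, chrom, pos in tss:
        by_chrom.setdefault(chrom, []).append((pos, gene))
    out: list[tuple[GenomicInterval, str]] = []
    for iv in intervals:
        mid = iv.midpoint
        near = [
            gene
            for pos, gene in by_chrom.get(iv.chrom, [])
            if abs(mid - pos) <= max_dist
        ]
        if len(near) == 1:
            out.append((iv, near[0]))
    return out
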