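"""Relative motif-frequency matrix over differential-footprint sets,
hierarchical clustering of its rows/columns, a minimal PWM scanner, and a
rank-sum expression-shift test."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu

from .genomic_core import GenomicInterval, intersect_counts

logger = logging.getLogger(__name__)

__all__ = [
    "MotifHitSet",
    "MotifFrequencyMatrix",
    "extend_intervals",
    "count_motif_occupancy",
    "relative_frequency_matrix",
    "cluster_matrix",
    "pwm_scan",
    "expression_shift_test",
]


@dataclass
class MotifHitSet:
    motif_id: str
    hits: list[GenomicInterval]


@dataclass
class MotifFrequencyMatrix:
    """Motifs x comparisons relative frequencies.

    ``values[i, j] = (n[i, j] / M[j]) * (C * sum_j M[j] / sum_j n[i, j])``
    where n[i, j] counts differential footprints of set j occupied by motif
    i, M[j] is the size of set j, and C is a scaling constant.
    """

    values: np.ndarray
    n: np.ndarray
    M: np.ndarray
    C: float
    motif_ids: list[str]
    comparison_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != self.n.shape:
            raise ValueError("values and n must have identical shapes")
        if self.values.shape[1] != self.M.shape[0]:
            raise ValueError("column count must match len(M)")
        if (self.n > self.M[None, :]).any():
            raise ValueError("occupancy counts cannot exceed set sizes")


def extend_intervals(
    dfps: Sequence[GenomicInterval], pad: int = 10
) -> list[GenomicInterval]:
    """Extend each interval by ``pad`` bp on both sides, floored at 0."""
    return [iv.expand(pad) for iv in dfps]


def count_motif_occupancy(
    dfps_extended: Sequence[GenomicInterval], hits: MotifHitSet
) -> int:
    """Number of footprints overlapped >=1 bp by >=1 hit of the motif.

    A footprint with several hits of the same motif counts once; hit
    strand is ignored (occupancy is strand-agnostic).
    """
    count, _ = intersect_counts(list(dfps_extended), hits.hits)
    return count


def relative_frequency_matrix(
    n: np.ndarray,
    M: np.ndarray,
    C: float = 1.0,
    motif_ids: list[str] | None = None,
    comparison_ids: list[str] | None = None,
) -> MotifFrequencyMatrix:
    """Build the relative-frequency matrix from occupancy counts.

    Motifs with an all-zero count row are dropped (with a warning) since
    their normaliser sum_j n_ij is zero.  Each retained row i satisfies
    ``sum_j values[i, j] * M[j] == C * sum_j M[j]`` exactly.
    """
    n = np.asarray(n, dtype=float)
    M = np.asarray(M, dtype=float)
    if (M <= 0).any():
        raise ValueError("every comparison set must be non-empty (M_j > 0)")
    I, J = n.shape
    if motif_ids is None:
        motif_ids = [f"motif_{i}" for i in range(I)]
    if comparison_ids is None:
        comparison_ids = [f"cmp_{j}" for j in range(J)]

    row_sums = n.sum(axis=1)
    keep = row_sums > 0
    if not keep.all():
        dropped = [motif_ids[i] for i in np.flatnonzero(~keep)]
        logger.warning("dropping all-zero motif rows: %s", ", ".join(dropped))
    n = n[keep]
    motif_ids = [m for m, k in zip(motif_ids, keep) if k]
    row_sums = row_sums[keep]

    values = (n / M[None, :]) * (C * M.sum() / row_sums[:, None])
    return MotifFrequencyMatrix(
        values=values,
        n=n.astype(int),
        M=M.astype(int),
        C=C,
        motif_ids=motif_ids,
        comparison_ids=comparison_ids,
    )


def cluster_matrix(
    m: MotifFrequencyMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Hierarchical clustering of rows and columns independently
    (Euclidean distance, complete linkage).

    Returns (row_order, col_order, row_linkage, col_linkage); orders are
    leaf index sequences.  Deterministic given a fixed input order.
    """
    v = m.values
    if v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    row_z = linkage(pdist(v, metric="euclidean"), method="complete")
    col_z = linkage(pdist(v.T, metric="euclidean"), method="complete")
    return leaves_list(row_z), leaves_list(col_z), row_z, col_z


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def pwm_scan(
    seq: str,
    pwm: np.ndarray,
    threshold: float = 0.8,
    pseudocount: float = 0.01,
    background: float = 0.25,
) -> list[tuple[int, str, float]]:
    """Scan both strands of ``seq`` with a 4xL probability matrix.

    Scores are log-odds against a uniform background; a window is a hit
    iff its score >= threshold x the maximum achievable score.  Returns
    (start, strand, score) tuples, 0-based starts on the forward sequence.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[0] != 4 or pwm.shape[1] < 4:
        raise ValueError("PWM must be 4 x L with L >= 4")
    L = pwm.shape[1]
    seq = seq.upper()
    if len(seq) < L:
        return []
    logodds = np.log2((pwm + pseudocount) / (background + pseudocount))
    max_score = logodds.max(axis=0).sum()
    cutoff = threshold * max_score

    hits: list[tuple[int, str, float]] = []
    rc = seq.translate(_COMPLEMENT)[::-1]
    for strand, s in (("+", seq), ("-", rc)):
        for i in range(len(s) - L + 1):
            window = s[i : i + L]
            try:
                score = sum(logodds[_BASE_INDEX[b], k] for k, b in enumerate(window))
            except KeyError:
                continue  # ambiguous base in window
            if score >= cutoff - 1e-12:
                start = i if strand == "+" else len(seq) - L - i
                hits.append((start, strand, float(score)))
    hits.sort()
    return hits


def expression_shift_test(
    fpkm_a: Mapping[str, float],
    fpkm_b: Mapping[str, float],
    gene_set: Sequence[str],
) -> tuple[float | None, float | None]:
    """Two-sided Mann-Whitney U comparison of A vs B expression over a
    gene set.

    Genes missing from either table are ignored; with fewer than 3 usable
    genes the result is (None, None) with a warning.
    """
    genes = [g for g in gene_set if g in fpkm_a and g in fpkm_b]
    if len(genes) < 3:
        logger.warning(
            "expression shift test needs >= 3 genes present in both tables, got %d",
            len(genes),
        )
        return None, None
    a = np.array([fpkm_a[g] for g in genes], dtype=float)
    b = np.array([fpkm_b[g] for g in genes], dtype=float)
    # exact null enumeration whenever it is well-defined (no ties, desk-scale n)
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == combined.size
    method = "exact" if (no_ties and combined.size <= 50) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
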