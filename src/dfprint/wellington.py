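"""Single-dataset footprint scoring from strand-specific cut imbalance.

A candidate footprint is a short window flanked by two fixed-width
"shoulders".  Protection is evidenced by positive-strand cuts piling up in
the upstream shoulder and negative-strand cuts in the downstream shoulder,
relative to the depleted footprint interior.  Each strand contributes an
upper binomial tail p-value; the score is minus the sum of their log10s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .genomic_core import CutProfile, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = ["FootprintParams", "Footprint", "wellington_score", "scan_footprints"]

DEFAULT_FOOTPRINT_SIZES = tuple(range(11, 26, 2))  # 11, 13, ..., 25


@dataclass(frozen=True)
class FootprintParams:
    footprint_sizes: tuple[int, ...] = DEFAULT_FOOTPRINT_SIZES
    shoulder_size: int = 35
    score_threshold: float = 10.0

    def __post_init__(self) -> None:
        if not self.footprint_sizes or min(self.footprint_sizes) < 1:
            raise ValueError("footprint sizes must be >= 1")
        if self.shoulder_size < 1:
            raise ValueError("shoulder_size must be >= 1")
        if self.score_threshold < 0:
            raise ValueError("score_threshold must be >= 0")


@dataclass(frozen=True)
class Footprint:
    interval: GenomicInterval
    score: float
    best_size: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("footprint score must be >= 0")


def _binom_sf_ge(x: np.ndarray | int, n: np.ndarray | int, q: float) -> np.ndarray:
    """P[Binomial(n, q) >= x]; exact, vectorised."""
    return binom.sf(np.asarray(x) - 1, np.asarray(n), q)


def wellington_score(
    profile: CutProfile, center: int, fp_size: int, shoulder: int
) -> float:
    """Footprint score at ``center`` (offset into the profile).

    The footprint window of width ``fp_size`` is centred at ``center``;
    shoulders of width ``shoulder`` flank it.  With q = shoulder /
    (shoulder + fp_size), the score is
    ``-(log10 P[Bin(N_f,q) >= X_f] + log10 P[Bin(N_r,q) >= X_r])``
    where X_f / N_f count positive-strand cuts in the upstream shoulder /
    shoulder-plus-footprint, and X_r / N_r the mirror on the negative
    strand downstream.
    """
    half = fp_size // 2
    fp_start = center - half
    fp_end = fp_start + fp_size
    u_start = fp_start - shoulder
    d_end = fp_end + shoulder
    if u_start < 0 or d_end > len(profile):
        raise ValueError(
            f"scoring window [{u_start}, {d_end}) out of profile bounds "
            f"[0, {len(profile)})"
        )
    x_f = int(profile.fwd[u_start:fp_start].sum())
    n_f = int(profile.fwd[u_start:fp_end].sum())
    x_r = int(profile.rev[fp_end:d_end].sum())
    n_r = int(profile.rev[fp_start:d_end].sum())
    q = shoulder / (shoulder + fp_size)
    p_f = float(_binom_sf_ge(x_f, n_f, q))
    p_r = float(_binom_sf_ge(x_r, n_r, q))
    # p in (0, 1]; guard log of underflowed tails
    tiny = np.finfo(float).tiny
    return float(-(np.log10(max(p_f, tiny)) + np.log10(max(p_r, tiny))))


def _score_all_centers(
    profile: CutProfile, fp_size: int, shoulder: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised wellington_score over every valid center for one size.

    Returns (centers, scores).
    """
    n = len(profile)
    half = fp_size // 2
    lo = shoulder + half
    hi = n - shoulder - (fp_size - half)
    if hi <= lo:
        return np.array([], dtype=int), np.array([])
    centers = np.arange(lo, hi)
    cf = np.concatenate([[0], np.cumsum(profile.fwd)])
    cr = np.concatenate([[0], np.cumsum(profile.rev)])
    fp_start = centers - half
    fp_end = fp_start + fp_size
    u_start = fp_start - shoulder
    d_end = fp_end + shoulder
    x_f = cf[fp_start] - cf[u_start]
    n_f = cf[fp_end] - cf[u_start]
    x_r = cr[d_end] - cr[fp_end]
    n_r = cr[d_end] - cr[fp_start]
    q = shoulder / (shoulder + fp_size)
    tiny = np.finfo(float).tiny
    p_f = np.maximum(_binom_sf_ge(x_f, n_f, q), tiny)
    p_r = np.maximum(_binom_sf_ge(x_r, n_r, q), tiny)
    return centers, -(np.log10(p_f) + np.log10(p_r))


def scan_footprints(
    profile: CutProfile, params: FootprintParams = FootprintParams()
) -> list[Footprint]:
    """Detect non-overlapping footprints in a profile.

    At each candidate center the score is maximised over the configured
    footprint sizes; candidates at or above the threshold are reduced to a
    non-overlapping set greedily in decreasing score order (ties broken by
    leftmost coordinate), then returned sorted by coordinate.
    """
    max_size = max(params.footprint_sizes)
    if len(profile) <= max_size + 2 * params.shoulder_size:
        logger.warning(
            "profile of length %d too short for footprint scan (needs > %d)",
            len(profile),
            max_size + 2 * params.shoulder_size,
        )
        return []

    n = len(profile)
    best_score = np.full(n, -np.inf)
    best_size = np.zeros(n, dtype=int)
    for fp_size in params.footprint_sizes:
        centers, scores = _score_all_centers(profile, fp_size, params.shoulder_size)
        if centers.size == 0:
            continue
        improved = scores > best_score[centers]
        idx = centers[improved]
        best_score[idx] = scores[improved]
        best_size[idx] = fp_size

    candidates = np.flatnonzero(best_score >= params.score_threshold)
    if candidates.size == 0:
        return []
    # greedy: decreasing score, ties by leftmost center
    order = sorted(candidates.tolist(), key=lambda c: (-best_score[c], c))
    taken: list[tuple[int, int, int]] = []  # (start, end, center) in profile coords
    for c in order:
        size = int(best_size[c])
        s = c - size // 2
        e = s + size
        if any(s < te and ts < e for ts, te, _ in taken):
            continue
        taken.append((s, e, c))

    taken.sort()
    out = []
    base = profile.interval.start
    for s, e, c in taken:
        iv = GenomicInterval(profile.interval.chrom, base + s, base + e)
        out.append(
            Footprint(interval=iv, score=float(best_score[c]), best_size=int(best_size[c]))
        )
    return out
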