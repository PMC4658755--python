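"""Differential footprint scoring by pooling and comparator shuffling.

Footprints are detected in a primary dataset.  At each locus the
comparator dataset's per-base cut counts are pooled in and the footprint
score of the pooled data is compared against a bootstrap distribution
obtained by shuffling the comparator counts (independently per strand)
within the scored window.  The percentile of the unshuffled score within
that distribution is the differential footprinting (DFP) score: low means
the comparator genuinely contributes footprint structure
(non-differential), high means it does not (differential).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .genomic_core import (
    CutProfile,
    GenomicInterval,
    ReadSource,
    extract_cuts,
    intersect_counts,
)
from .wellington import Footprint, FootprintParams, scan_footprints, wellington_score

logger = logging.getLogger(__name__)

__all__ = [
    "ShuffleConfig",
    "DfpScore",
    "DfpCallSet",
    "pool_profiles",
    "shuffle_profile",
    "bootstrap_score",
    "differential_footprints",
    "differential_from_profiles",
    "shared_dhs_summary",
    "shared_percentage",
    "SharedDhsSummary",
]


@dataclass(frozen=True)
class ShuffleConfig:
    n_shuffles: int = 1000
    seed: int = 0
    min_comparator_cuts: int = 10  # below this the call is flagged low-coverage

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


@dataclass(frozen=True)
class DfpScore:
    locus: Footprint
    score: float  # percentile in [0, 100]
    direction: str  # "over_in_A" | "over_in_B"
    low_coverage: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 100.0):
            raise ValueError(f"DFP score must be in [0, 100], got {self.score}")
        if self.direction not in ("over_in_A", "over_in_B"):
            raise ValueError(f"invalid direction {self.direction!r}")


@dataclass
class DfpCallSet:
    over_in_A: list[DfpScore] = field(default_factory=list)
    over_in_B: list[DfpScore] = field(default_factory=list)
    threshold: float = 10.0


def pool_profiles(a: CutProfile, b: CutProfile) -> CutProfile:
    """Elementwise per-strand sum of two profiles over the same interval."""
    if (
        a.interval.chrom != b.interval.chrom
        or a.interval.start != b.interval.start
        or a.interval.end != b.interval.end
    ):
        raise ValueError(
            f"cannot pool profiles over mismatched intervals "
            f"{a.interval} vs {b.interval}"
        )
    return CutProfile(a.interval, a.fwd + b.fwd, a.rev + b.rev)


def shuffle_profile(p: CutProfile, rng: np.random.Generator) -> CutProfile:
    """Independently permute the positions of each strand's counts."""
    return CutProfile(
        p.interval, rng.permutation(p.fwd), rng.permutation(p.rev)
    )


def _window_bounds(locus_center: int, fp_size: int, shoulder: int) -> tuple[int, int, int, int]:
    half = fp_size // 2
    fp_start = locus_center - half
    fp_end = fp_start + fp_size
    return fp_start - shoulder, fp_start, fp_end, fp_end + shoulder


def bootstrap_score(
    locus: Footprint,
    a: CutProfile,
    b: CutProfile,
    params: FootprintParams,
    cfg: ShuffleConfig,
    rng: np.random.Generator | None = None,
    direction: str = "over_in_A",
) -> DfpScore:
    """DFP score for one locus: percentile of the real pooled score within
    the shuffled-comparator score distribution.

    ``a`` and ``b`` must cover the locus window plus shoulders; shuffling
    is confined to the scored window (permutations outside it cannot change
    the statistic).  Ties count as >= (conservative toward differential in
    degenerate cases); near-zero comparator coverage flags the call.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    shoulder = params.shoulder_size
    fp_size = locus.best_size
    center = locus.interval.start + fp_size // 2 - a.interval.start
    w_lo, fp_start, fp_end, w_hi = _window_bounds(center, fp_size, shoulder)
    if w_lo < 0 or w_hi > len(a) or len(a) != len(b):
        raise ValueError("profiles do not cover the locus window plus shoulders")

    pooled = pool_profiles(a, b)
    s_real = wellington_score(pooled, center, fp_size, shoulder)

    a_fwd = a.fwd[w_lo:w_hi].astype(np.int64)
    a_rev = a.rev[w_lo:w_hi].astype(np.int64)
    b_fwd = b.fwd[w_lo:w_hi].astype(np.int64)
    b_rev = b.rev[w_lo:w_hi].astype(np.int64)
    low_coverage = int(b_fwd.sum() + b_rev.sum()) < cfg.min_comparator_cuts

    k = cfg.n_shuffles
    perm_fwd = rng.permuted(np.broadcast_to(b_fwd, (k, b_fwd.size)), axis=1)
    perm_rev = rng.permuted(np.broadcast_to(b_rev, (k, b_rev.size)), axis=1)
    pooled_fwd = perm_fwd + a_fwd
    pooled_rev = perm_rev + a_rev

    # window-local slice offsets
    us, fs, fe, de = 0, shoulder, shoulder + fp_size, shoulder + fp_size + shoulder
    x_f = pooled_fwd[:, us:fs].sum(axis=1)
    n_f = pooled_fwd[:, us:fe].sum(axis=1)
    x_r = pooled_rev[:, fe:de].sum(axis=1)
    n_r = pooled_rev[:, fs:de].sum(axis=1)
    q = shoulder / (shoulder + fp_size)
    tiny = np.finfo(float).tiny
    p_f = np.maximum(binom.sf(x_f - 1, n_f, q), tiny)
    p_r = np.maximum(binom.sf(x_r - 1, n_r, q), tiny)
    s_shuf = -(np.log10(p_f) + np.log10(p_r))

    # tolerate float jitter when comparing against the scalar-path score
    score = 100.0 * np.count_nonzero(s_shuf >= s_real - 1e-9) / k
    return DfpScore(locus=locus, score=score, direction=direction, low_coverage=low_coverage)


def _score_direction(
    primary: list[CutProfile],
    comparator: list[CutProfile],
    direction: str,
    params: FootprintParams,
    cfg: ShuffleConfig,
    threshold: float,
) -> list[DfpScore]:
    """Detect footprints in the primary profiles, bootstrap-score each
    against the matched comparator profile, keep calls at/above threshold.

    Per-locus RNG substreams are derived from (seed, direction, index) so
    serial and parallel evaluation orders agree.
    """
    tag = 0 if direction == "over_in_A" else 1
    out: list[DfpScore] = []
    locus_index = 0
    for p, c in zip(primary, comparator, strict=True):
        for fp in scan_footprints(p, params):
            rng = np.random.default_rng([cfg.seed, tag, locus_index])
            locus_index += 1
            d = bootstrap_score(fp, p, c, params, cfg, rng=rng, direction=direction)
            if d.score >= threshold:
                out.append(d)
    return out


def differential_from_profiles(
    profiles_a: list[CutProfile],
    profiles_b: list[CutProfile],
    params: FootprintParams = FootprintParams(),
    cfg: ShuffleConfig = ShuffleConfig(),
    threshold: float = 10.0,
) -> DfpCallSet:
    """Differential footprints from paired per-region cut profiles.

    ``profiles_a[i]`` and ``profiles_b[i]`` must cover identical intervals.
    Runs detection in A scored against B, then the reverse.
    """
    calls = DfpCallSet(threshold=threshold)
    calls.over_in_A = _score_direction(
        profiles_a, profiles_b, "over_in_A", params, cfg, threshold
    )
    calls.over_in_B = _score_direction(
        profiles_b, profiles_a, "over_in_B", params, cfg, threshold
    )
    if not calls.over_in_A and not calls.over_in_B:
        logger.warning("no differential footprints called")
    return calls


def differential_footprints(
    a: ReadSource,
    b: ReadSource,
    dhs_a: list[GenomicInterval],
    dhs_b: list[GenomicInterval],
    params: FootprintParams = FootprintParams(),
    cfg: ShuffleConfig = ShuffleConfig(),
    threshold: float = 10.0,
) -> DfpCallSet:
    """Two-directional differential footprint calling from read sources.

    Footprints detected in ``a`` within ``dhs_a`` are bootstrap-scored
    against ``b`` (-> over_in_A), and symmetrically for ``b`` within
    ``dhs_b``.  Deterministic given ``cfg.seed``.
    """
    if not dhs_a or not dhs_b:
        raise ValueError("DHS interval lists must be non-empty")
    calls = DfpCallSet(threshold=threshold)
    calls.over_in_A = _score_direction(
        [extract_cuts(a, iv) for iv in dhs_a],
        [extract_cuts(b, iv) for iv in dhs_a],
        "over_in_A",
        params,
        cfg,
        threshold,
    )
    calls.over_in_B = _score_direction(
        [extract_cuts(b, iv) for iv in dhs_b],
        [extract_cuts(a, iv) for iv in dhs_b],
        "over_in_B",
        params,
        cfg,
        threshold,
    )
    if not calls.over_in_A and not calls.over_in_B:
        logger.warning("no differential footprints called")
    return calls


def shared_percentage(in_shared: int, total: int) -> float | None:
    """100 x in_shared / total, one decimal; None when total is zero."""
    if total == 0:
        return None
    return round(100.0 * in_shared / total, 1)


@dataclass(frozen=True)
class SharedDhsSummary:
    n_dhs_a: int
    n_dhs_b: int
    n_shared: int
    n_over_a: int
    n_over_a_shared: int
    pct_over_a_shared: float | None
    n_over_b: int
    n_over_b_shared: int
    pct_over_b_shared: float | None


def shared_dhs_summary(
    dhs_a: list[GenomicInterval],
    dhs_b: list[GenomicInterval],
    calls: DfpCallSet,
) -> SharedDhsSummary:
    """Summarise how many differential footprints fall in shared DHSs.

    A DHS of A is shared iff it overlaps >=1 bp of some DHS of B (and
    symmetrically); a call is "in shared" iff its locus overlaps a shared
    DHS of its own direction's primary set.
    """
    n_shared_a, member_a = intersect_counts(dhs_a, dhs_b)
    _, member_b = intersect_counts(dhs_b, dhs_a)
    shared_a = [iv for iv, m in zip(dhs_a, member_a) if m]
    shared_b = [iv for iv, m in zip(dhs_b, member_b) if m]

    loci_a = [d.locus.interval for d in calls.over_in_A]
    loci_b = [d.locus.interval for d in calls.over_in_B]
    n_over_a_shared, _ = intersect_counts(loci_a, shared_a)
    n_over_b_shared, _ = intersect_counts(loci_b, shared_b)

    return SharedDhsSummary(
        n_dhs_a=len(dhs_a),
        n_dhs_b=len(dhs_b),
        n_shared=n_shared_a,
        n_over_a=len(loci_a),
        n_over_a_shared=n_over_a_shared,
        pct_over_a_shared=shared_percentage(n_over_a_shared, len(loci_a)),
        n_over_b=len(loci_b),
        n_over_b_shared=n_over_b_shared,
        pct_over_b_shared=shared_percentage(n_over_b_shared, len(loci_b)),
    )
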