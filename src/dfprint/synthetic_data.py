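"""Synthetic DNase-seq cut profiles with planted footprints.

Emulates the strand-imbalance signature of the double-hit protocol:
positive-strand cuts enriched in the shoulder immediately upstream of an
occupied site, negative-strand cuts immediately downstream, and a depleted
interior.  Also emits SAM text fixtures (one read per cut) and toy genome
sequence so the whole pipeline is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bias_profiles import BiasModel, _position_weights
from .genomic_core import CutProfile, GenomicInterval

__all__ = [
    "SimSpec",
    "simulate_profile",
    "simulate_pair",
    "emit_sam",
    "toy_genome",
    "write_fasta",
    "simulate_biased_cuts",
]


@dataclass(frozen=True)
class SimSpec:
    region_length: int = 5000
    depth: float = 100.0  # expected signal cuts per occupied site
    footprints: tuple[tuple[int, int, float], ...] = ()  # (center, width, occupancy)
    imbalance: float = 5.0  # signal-strand vs opposite-strand shoulder enrichment
    background: float = 0.05  # per-bp per-strand background cut rate
    shoulder: int = 35
    interior_depletion: float = 0.05  # background multiplier inside footprints
    chrom: str = "chrSim"
    region_start: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for center, width, occ in self.footprints:
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"occupancy must be in [0,1], got {occ}")
            if width < 5:
                raise ValueError(f"footprint width must be >= 5, got {width}")
            if not 0 <= center < self.region_length:
                raise ValueError(f"center {center} outside region")


def simulate_profile(
    spec: SimSpec,
) -> tuple[CutProfile, list[tuple[GenomicInterval, float, bool]]]:
    """Draw one profile; returns (profile, truth) where truth rows are
    (planted interval, occupancy parameter, realised occupied flag).

    Background cuts are independent Poisson per position and strand.  Each
    occupied plant adds Poisson(depth) signal cuts split between the two
    shoulders, with the signal strand (fwd upstream / rev downstream)
    ``imbalance`` times more likely than the opposite strand; the interior
    background is thinned to ``interior_depletion``.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.region_length
    interval = GenomicInterval(spec.chrom, spec.region_start, spec.region_start + L)
    fwd = rng.poisson(spec.background, size=L).astype(np.int64)
    rev = rng.poisson(spec.background, size=L).astype(np.int64)

    truth = []
    for center, width, occupancy in spec.footprints:
        half = width // 2
        fp_lo, fp_hi = center - half, center - half + width
        occupied = bool(rng.random() < occupancy)
        if occupied:
            # thin interior background
            fwd[fp_lo:fp_hi] = rng.binomial(fwd[fp_lo:fp_hi], spec.interior_depletion)
            rev[fp_lo:fp_hi] = rng.binomial(rev[fp_lo:fp_hi], spec.interior_depletion)
            u_lo, u_hi = max(0, fp_lo - spec.shoulder), fp_lo
            d_lo, d_hi = fp_hi, min(L, fp_hi + spec.shoulder)
            n_sig = rng.poisson(spec.depth)
            share = spec.imbalance / (spec.imbalance + 1.0)
            for (lo, hi), strand_main, strand_opp in (
                ((u_lo, u_hi), fwd, rev),
                ((d_lo, d_hi), rev, fwd),
            ):
                if hi <= lo:
                    continue
                n_half = rng.binomial(n_sig, 0.5)
                n_main = rng.binomial(n_half, share)
                pos_main = rng.integers(lo, hi, size=n_main)
                pos_opp = rng.integers(lo, hi, size=n_half - n_main)
                np.add.at(strand_main, pos_main, 1)
                np.add.at(strand_opp, pos_opp, 1)
        truth.append(
            (
                GenomicInterval(
                    spec.chrom, spec.region_start + fp_lo, spec.region_start + fp_hi
                ),
                occupancy,
                occupied,
            )
        )
    return CutProfile(interval, fwd, rev), truth


def simulate_pair(
    spec_a: SimSpec,
    spec_b: SimSpec,
    shared_footprints: list[tuple[int, int]],
    a_only: list[tuple[int, int]],
    b_only: list[tuple[int, int]],
    occupancy: float = 1.0,
) -> tuple[CutProfile, CutProfile, list[tuple[GenomicInterval, str]]]:
    """Two-condition profiles with shared and condition-specific plants.

    Footprint lists hold (center, width) in region coordinates and must be
    pairwise disjoint.  Returns (profile_a, profile_b, labels) with labels
    in {"shared", "A-only", "B-only"} on genomic intervals.
    """
    plants = (
        [(c, w, "shared") for c, w in shared_footprints]
        + [(c, w, "A-only") for c, w in a_only]
        + [(c, w, "B-only") for c, w in b_only]
    )
    spans = sorted((c - w // 2, c - w // 2 + w) for c, w, _ in plants)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"planted footprints overlap: [{s1},{e1}) and [{s2},{e2})")

    fps_a = tuple((c, w, occupancy) for c, w, lab in plants if lab in ("shared", "A-only"))
    fps_b = tuple((c, w, occupancy) for c, w, lab in plants if lab in ("shared", "B-only"))
    prof_a, _ = simulate_profile(replace(spec_a, footprints=fps_a))
    prof_b, _ = simulate_profile(replace(spec_b, footprints=fps_b))

    labels = [
        (
            GenomicInterval(
                spec_a.chrom,
                spec_a.region_start + c - w // 2,
                spec_a.region_start + c - w // 2 + w,
            ),
            lab,
        )
        for c, w, lab in plants
    ]
    return prof_a, prof_b, labels


def emit_sam(profile: CutProfile, read_length: int = 36) -> str:
    """Render a profile as SAM text, one aligned read per cut.

    +-strand reads start at the cut position; −-strand reads end at it
    (reads reaching past the chromosome start are clipped in length so the
    5' end stays put).  Round-trips through cut extraction.
    """
    iv = profile.interval
    chrom_len = iv.end + read_length + 10
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{iv.chrom}\tLN:{chrom_len}",
    ]
    ridx = 0
    for i in range(len(profile)):
        pos = iv.start + i
        for _ in range(int(profile.fwd[i])):
            lines.append(
                f"r{ridx}\t0\t{iv.chrom}\t{pos + 1}\t60\t{read_length}M\t*\t0\t0\t*\t*"
            )
            ridx += 1
        for _ in range(int(profile.rev[i])):
            length = min(read_length, pos + 1)
            start1 = pos - length + 2  # 1-based leftmost
            lines.append(
                f"r{ridx}\t16\t{iv.chrom}\t{start1}\t60\t{length}M\t*\t0\t0\t*\t*"
            )
            ridx += 1
    return "\n".join(lines) + "\n"


def toy_genome(seed: int = 0, length: int = 50000, chrom: str = "chrSim") -> dict[str, str]:
    """Reproducible pseudo-random single-chromosome genome."""
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return {chrom: seq}


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_biased_cuts(
    seq: str,
    total: int,
    model: BiasModel,
    rng: np.random.Generator,
    strand: str = "+",
) -> np.ndarray:
    """Place ``total`` cuts along a region with probability proportional
    to the hexamer bias weight at each position.

    ``seq`` covers the region plus 3 bp of context each side (same
    convention as the expected-count computation).
    """
    w = _position_weights(seq, model, strand)
    w = np.nan_to_num(w, nan=0.0)
    if w.sum() <= 0:
        raise ValueError("no valid positions to place cuts")
    counts = rng.multinomial(total, w / w.sum())
    return counts.astype(np.int64)
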