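"""Hexamer cleavage-bias model, expected-count correction, strand-oriented
average cleavage profiles, and the score-sorted strand-imbalance matrix.

DNaseI cuts DNA with a strong sequence preference.  The bias model maps
each 6-mer to a relative cleavage propensity; a region's observed total
cut count is redistributed along the region in proportion to the per-base
weights ("expected counts") and observed counts are divided by expected
to correct for the bias.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genomic_core import CutProfile, GenomicInterval, ReadSource, extract_cuts

__all__ = [
    "BiasModel",
    "AverageProfile",
    "expected_cuts",
    "bias_correct",
    "apply_variants",
    "average_profile",
    "strand_imbalance_matrix",
]

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class BiasModel:
    """Map from 6-mer to relative cleavage propensity (> 0)."""

    weights: dict[str, float]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for kmer, w in self.weights.items():
            if len(kmer) != 6 or any(b not in "ACGT" for b in kmer):
                raise ValueError(f"invalid 6-mer {kmer!r}")
            if w <= 0:
                raise ValueError(f"weight for {kmer} must be > 0, got {w}")

    def __getitem__(self, kmer: str) -> float:
        try:
            return self.weights[kmer]
        except KeyError:
            raise KeyError(f"bias model has no weight for 6-mer {kmer!r}")

    @classmethod
    def uniform(cls) -> "BiasModel":
        """Flat model: every 6-mer weight 1 (no bias)."""
        kmers = ("".join(p) for p in itertools.product("ACGT", repeat=6))
        return cls({k: 1.0 for k in kmers}, provenance="uniform")

    @classmethod
    def load(cls, path: str) -> "BiasModel":
        """Two-column text file: 6-mer <tab-or-space> weight."""
        weights = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected '6mer weight'")
                weights[parts[0].upper()] = float(parts[1])
        return cls(weights, provenance=path)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            for kmer in sorted(self.weights):
                fh.write(f"{kmer}\t{self.weights[kmer]:.10g}\n")


@dataclass
class AverageProfile:
    offsets: np.ndarray  # -flank .. +flank relative to locus center
    fwd_mean: np.ndarray
    rev_mean: np.ndarray
    corrected: bool

    def __post_init__(self) -> None:
        if not (len(self.offsets) == len(self.fwd_mean) == len(self.rev_mean)):
            raise ValueError("offset and mean vectors must have equal length")


def _position_weights(seq: str, model: BiasModel, strand: str) -> np.ndarray:
    """Per-base weight from the 6-mer spanning i-3..i+2 around each cut
    position; negative-strand lookups use the reverse complement.  The
    sequence must cover the region plus 3 bp of context each side, so
    region position i reads seq[i:i+6].  Positions whose hexamer contains
    a non-ACGT base get NaN (missing).
    """
    L = len(seq) - 6
    if L < 0:
        raise ValueError("sequence shorter than required 6 bp of context")
    seq = seq.upper()
    w = np.empty(L)
    for i in range(L):
        hexamer = seq[i : i + 6]
        if any(b not in "ACGT" for b in hexamer):
            w[i] = np.nan
            continue
        if strand == "-":
            hexamer = reverse_complement(hexamer)
        w[i] = model[hexamer]
    return w


def expected_cuts(
    seq: str, total_observed: int, model: BiasModel, strand: str = "+"
) -> np.ndarray:
    """Redistribute ``total_observed`` cuts along the region in proportion
    to the per-base hexamer weights.

    ``seq`` covers the region plus 3 bp of flanking context each side.
    Positions with ambiguous hexamers are NaN and excluded from the
    normalising sum; the non-missing expectations sum to total_observed.
    """
    w = _position_weights(seq, model, strand)
    valid = ~np.isnan(w)
    denom = np.nansum(w)
    out = np.full(w.shape, np.nan)
    if denom > 0:
        out[valid] = total_observed * w[valid] / denom
    elif total_observed == 0:
        out[valid] = 0.0
    return out


def bias_correct(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Elementwise observed / expected; NaN where expected is missing or 0."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have matching lengths")
    out = np.full(observed.shape, np.nan)
    ok = ~np.isnan(expected) & (expected > 0)
    out[ok] = observed[ok] / expected[ok]
    return out


def apply_variants(
    seq: str, region_start: int, variants: Sequence[tuple[int, str, str]]
) -> str:
    """Substitute SNVs into a reference sequence before hexamer lookup.

    ``variants`` are (pos0, ref, alt) with 0-based genomic positions;
    indels (len(ref) != 1 or len(alt) != 1) are skipped with a warning.
    """
    import logging

    chars = list(seq)
    for pos, ref, alt in variants:
        if len(ref) != 1 or len(alt) != 1:
            logging.getLogger(__name__).warning(
                "skipping non-SNV variant at position %d (%s->%s)", pos, ref, alt
            )
            continue
        i = pos - region_start
        if 0 <= i < len(chars):
            chars[i] = alt
    return "".join(chars)


def load_vcf_snvs(path: str, chrom: str, start: int, end: int) -> list[tuple[int, str, str]]:
    """Read SNV records overlapping [start, end) from an uncompressed VCF."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] != chrom:
                continue
            pos0 = int(f[1]) - 1
            if start <= pos0 < end:
                out.append((pos0, f[3], f[4].split(",")[0]))
    return out


def _oriented_corrected_profile(
    locus: GenomicInterval,
    source: ReadSource,
    flank: int,
    model: BiasModel | None,
    genome,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (fwd, rev) values over the flanked window, bias-corrected
    when a model is given, mirrored with strands swapped for − loci."""
    center = int(locus.midpoint)
    win = GenomicInterval(locus.chrom, center - flank, center + flank + 1)
    prof = extract_cuts(source, win)
    fwd = prof.fwd.astype(float)
    rev = prof.rev.astype(float)
    if model is not None:
        if genome is None:
            raise ValueError("bias correction requires a genome sequence")
        seq = str(genome[locus.chrom][win.start - 3 : win.end + 3])
        exp_f = expected_cuts(seq, prof.total_fwd, model, strand="+")
        exp_r = expected_cuts(seq, prof.total_rev, model, strand="-")
        fwd = bias_correct(fwd, exp_f)
        rev = bias_correct(rev, exp_r)
    if locus.strand == "-":
        fwd, rev = rev[::-1].copy(), fwd[::-1].copy()
    return fwd, rev


def average_profile(
    loci: Sequence[GenomicInterval],
    source: ReadSource,
    flank: int = 100,
    model: BiasModel | None = None,
    genome=None,
) -> AverageProfile:
    """Strand-oriented per-offset mean cleavage over motif-centred loci.

    Each locus is expanded to ±flank around its midpoint; −-strand loci
    are mirrored with fwd/rev swapped before averaging.  When a bias model
    (plus genome FASTA handle) is given, each locus is corrected before
    averaging; missing positions are excluded per offset (nanmean).
    """
    if not loci:
        raise ValueError("loci list must be non-empty")
    fwd_stack, rev_stack = [], []
    for locus in loci:
        fwd, rev = _oriented_corrected_profile(locus, source, flank, model, genome)
        fwd_stack.append(fwd)
        rev_stack.append(rev)
    fwd_mat = np.vstack(fwd_stack)
    rev_mat = np.vstack(rev_stack)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        fwd_mean = np.nanmean(fwd_mat, axis=0)
        rev_mean = np.nanmean(rev_mat, axis=0)
    return AverageProfile(
        offsets=np.arange(-flank, flank + 1),
        fwd_mean=fwd_mean,
        rev_mean=rev_mean,
        corrected=model is not None,
    )


def strand_imbalance_matrix(
    calls,
    a: ReadSource,
    b: ReadSource,
    flank: int = 100,
) -> tuple[np.ndarray, list]:
    """Per-locus, per-position cut imbalance (fwd − rev) for both datasets.

    Rows are call loci sorted by ascending differential score; each row is
    the dataset-A block followed by the dataset-B block.  Returns the
    matrix and the sorted calls.
    """
    all_calls = list(calls.over_in_A) + list(calls.over_in_B)
    if not all_calls:
        raise ValueError("call set is empty")
    all_calls.sort(key=lambda d: (d.score, d.locus.interval.chrom, d.locus.interval.start))
    rows = []
    for d in all_calls:
        iv = d.locus.interval
        center = int(iv.midpoint)
        win = GenomicInterval(iv.chrom, center - flank, center + flank + 1)
        pa = extract_cuts(a, win)
        pb = extract_cuts(b, win)
        rows.append(
            np.concatenate(
                [pa.fwd.astype(float) - pa.rev, pb.fwd.astype(float) - pb.rev]
            )
        )
    return np.vstack(rows), all_calls
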