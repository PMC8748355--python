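"""Coverage summaries, per-cycle base composition and SP-G misassignment.

These are the QC views used to show that nuclease treatment removes SS
artifacts without distorting the library: genome coverage statistics
(binned histogram, covered rate, CV of per-position depth), the base
composition of the first sequencing cycles (nuclease cut-site
preference shows up as enrichment at cycle 1), and the rate at which an
SP-G accidentally mixes read pairs from different source molecules.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dna import N, seq_to_codes, revcomp_codes
from .consensus import DuplexConsensusPair, SPGroup


@dataclass
class CoverageSummary:
    n_bins: int
    bin_width: int
    bin_means: np.ndarray
    covered_rate: float
    mean: float
    sd: float
    cv: float  # NaN when mean == 0

    def histogram_frame(self) -> pd.DataFrame:
        starts = np.arange(self.n_bins) * self.bin_width
        return pd.DataFrame(
            {"bin_start": starts, "bin_end": starts + self.bin_width, "mean_depth": self.bin_means}
        )

    def to_dict(self) -> dict:
        return dict(covered_rate=self.covered_rate, mean=self.mean, sd=self.sd,
                    cv=None if math.isnan(self.cv) else self.cv)


def depth_from_pairs(pairs: list[DuplexConsensusPair], genome_length: int) -> np.ndarray:
    """Per-position count of non-N dsDCS bases."""
    depth = np.zeros(genome_length, dtype=np.int64)
    for p in pairs:
        depth[p.start:p.end] += (p.bases != N).astype(np.int64)
    return depth


def summarize_depth(depth: np.ndarray, n_bins: int = 50000, per_bin_stats: bool = False) -> CoverageSummary:
    """Coverage statistics from a per-position depth vector.

    mean/sd/cv are computed over per-position depth (population sd,
    ddof=0); ``per_bin_stats=True`` computes them over the binned means
    instead. Bins only ever drive the histogram by default.
    """
    L = depth.size
    if L == 0:
        return CoverageSummary(0, 0, np.array([]), 0.0, 0.0, 0.0, math.nan)
    n_bins = min(n_bins, L)
    width = math.ceil(L / n_bins)
    n_bins = math.ceil(L / width)
    padded = np.pad(depth.astype(float), (0, n_bins * width - L), constant_values=np.nan)
    with np.errstate(invalid="ignore"):
        bin_means = np.nanmean(padded.reshape(n_bins, width), axis=1)
    basis = bin_means if per_bin_stats else depth
    mean = float(np.mean(basis))
    sd = float(np.std(basis))
    cv = sd / mean if mean > 0 else math.nan
    return CoverageSummary(
        n_bins=n_bins, bin_width=width, bin_means=bin_means,
        covered_rate=float((depth > 0).mean()), mean=mean, sd=sd, cv=cv,
    )


def coverage_summary(
    pairs: list[DuplexConsensusPair], genome_length: int, n_bins: int = 50000,
    per_bin_stats: bool = False,
) -> CoverageSummary:
    if genome_length < n_bins:
        import warnings

        warnings.warn("genome shorter than n_bins; bins collapse to width 1", stacklevel=2)
    return summarize_depth(depth_from_pairs(pairs, genome_length), n_bins, per_bin_stats)


@dataclass
class CompositionMatrix:
    """proportion[cycle][base] for forward and reverse reads, base order
    A/C/G/T; rows renormalised over non-N observations."""

    forward: np.ndarray
    reverse: np.ndarray
    n_forward: int
    n_reverse: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for direction, mat in (("forward", self.forward), ("reverse", self.reverse)):
            for cyc in range(mat.shape[0]):
                rows.append(
                    dict(direction=direction, cycle=cyc + 1,
                         **{b: mat[cyc, i] for i, b in enumerate("ACGT")})
                )
        return pd.DataFrame(rows)


def _tally(seqs, n_cycles: int) -> tuple[np.ndarray, int]:
    counts = np.zeros((n_cycles, 4), dtype=np.int64)
    n = 0
    codes = b"ACGT"
    for seq in seqs:
        n += 1
        m = min(len(seq), n_cycles)
        arr = seq[:m]
        for i, c in enumerate(codes):
            hits = np.nonzero(arr == c)[0]
            counts[hits, i] += 1
    tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(tot > 0, counts / tot, np.nan)
    return props, n


def cycle_composition_fastq(fastq_r1: str, fastq_r2: str, n_cycles: int) -> CompositionMatrix:
    """Per-cycle base proportions from as-sequenced paired FASTQ (R1 =
    forward direction, R2 = reverse)."""

    def fastq_seqs(path):
        with open(path) as fh:
            for i, line in enumerate(fh):
                if i % 4 == 1:
                    yield seq_to_codes(line.strip())

    fwd, n_f = _tally(fastq_seqs(fastq_r1), n_cycles)
    rev, n_r = _tally(fastq_seqs(fastq_r2), n_cycles)
    return CompositionMatrix(forward=fwd, reverse=rev, n_forward=n_f, n_reverse=n_r)


def cycle_composition_sam(sam_path: str, n_cycles: int) -> CompositionMatrix:
    """Per-cycle proportions from a SAM/BAM, reads restored to their
    as-sequenced orientation (stored sequence reverse-complemented for
    reverse-flagged reads); read 1 = forward direction, read 2 = reverse."""
    import pysam

    fwd_seqs, rev_seqs = [], []
    with pysam.AlignmentFile(sam_path, "r") as fh:
        for read in fh:
            if read.is_secondary or read.is_supplementary or read.query_sequence is None:
                continue
            codes = seq_to_codes(read.query_sequence)
            if read.is_reverse:
                codes = revcomp_codes(codes)
            (rev_seqs if read.is_read2 else fwd_seqs).append(codes)
    fwd, n_f = _tally(fwd_seqs, n_cycles)
    rev, n_r = _tally(rev_seqs, n_cycles)
    return CompositionMatrix(forward=fwd, reverse=rev, n_forward=n_f, n_reverse=n_r)


def cycle_composition_library(lib, n_cycles: int) -> CompositionMatrix:
    """Same computation straight from in-memory simulated reads."""

    def seqs(read2: bool):
        for p in lib.pairs:
            seq, rev = ((p.r2_seq, p.r2_reverse) if read2 else (p.r1_seq, p.r1_reverse))
            yield revcomp_codes(seq) if rev else seq

    fwd, n_f = _tally(seqs(False), n_cycles)
    rev, n_r = _tally(seqs(True), n_cycles)
    return CompositionMatrix(forward=fwd, reverse=rev, n_forward=n_f, n_reverse=n_r)


@dataclass
class MisassignmentReport:
    n_spg: int
    n_spg_multi_molecule: int
    rate: float
    analytic_estimate: float | None = None

    def to_dict(self) -> dict:
        return dict(n_spg=self.n_spg, n_spg_multi_molecule=self.n_spg_multi_molecule,
                    rate=self.rate, analytic_estimate=self.analytic_estimate)


def collision_rate_estimate(k: int, n_coords: float) -> float:
    """Expected fraction of occupied fragment coordinates hit by >= 2 of
    the k sampled molecules (Poisson occupancy / birthday approximation
    over ``n_coords`` distinguishable (start, end) pairs)."""
    if k < 2 or n_coords <= 0:
        return 0.0
    lam = k / n_coords
    occupied = -np.expm1(-lam)
    multi = occupied - lam * math.exp(-lam)
    return float(multi / occupied) if occupied > 0 else 0.0


def effective_coordinate_space(
    genome_length: int, size_mean: float, size_sd: float, min_length: int = 50
) -> float:
    """Number of distinguishable (start, end) coordinate pairs implied by
    the shearing model: uniform starts times a collision-equivalent count
    of fragment lengths, 1 / sum(p_len^2) for the discretised normal."""
    lo = max(min_length, int(size_mean - 8 * size_sd))
    hi = int(size_mean + 8 * size_sd)
    lens = np.arange(lo, hi + 1)
    p = norm.pdf(lens, loc=size_mean, scale=size_sd)
    p = p / p.sum()
    n_lengths = 1.0 / float((p ** 2).sum())
    n_starts = max(1, genome_length - int(size_mean) + 1)
    return n_starts * n_lengths


def misassignment_report(
    spgroups: list[SPGroup] | None = None,
    k: int | None = None,
    n_coords: float | None = None,
) -> MisassignmentReport:
    """Truth-based SP-G misassignment rate and/or its analytic estimate.

    Truth mode needs records carrying molecule ids (simulator data): an
    SP-G is misassigned when its members descend from >= 2 distinct
    source molecules. Analytic mode uses the birthday approximation with
    ``k`` sampled molecules over ``n_coords`` distinguishable coordinates.
    """
    analytic = None
    if k is not None and n_coords is not None:
        analytic = collision_rate_estimate(k, n_coords)
    if spgroups is None:
        if analytic is None:
            raise ValueError("need SP-Gs with molecule ids and/or (k, n_coords)")
        return MisassignmentReport(n_spg=0, n_spg_multi_molecule=0, rate=analytic, analytic_estimate=analytic)
    n_spg = 0
    n_multi = 0
    for g in spgroups:
        ids = g.molecule_ids()
        if not ids:
            raise ValueError(f"SP-G {g.key} has no molecule ids; truth mode needs simulator input")
        n_spg += 1
        if len(ids) >= 2:
            n_multi += 1
    rate = n_multi / n_spg if n_spg else 0.0
    return MisassignmentReport(n_spg=n_spg, n_spg_multi_molecule=n_multi, rate=rate, analytic_estimate=analytic)
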