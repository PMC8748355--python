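"""Strand-resolved mutation spectra from dsDCS vs the reference.

Substitutions are counted in one of two strand frames:

* ``reference`` — plus-strand reference base → plus-strand observed base;
* ``fragment`` (default) — each consensus position is classified in the
  orientation of the inward-sequencing read from the NEARER fragment end
  (left half as-is, right half reverse-complemented). This is the frame
  in which end-repair artifacts are strand-asymmetric: 8-oxoG filled in
  from a 5' overhang always reads G>T from its own fragment end,
  whichever genome strand carried the lesion.

Frequencies are reported per 10^6 counted bases, strand-resolved
(12-type) and pooled over complementary pairs (6-type). The 6-type
pooling is frame-invariant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .dna import COMPLEMENT, N, complement_codes
from .consensus import DuplexConsensusPair, FLAG_CLIPPED

MUT12 = ["G>T", "G>C", "G>A", "C>A", "C>G", "C>T",
         "A>T", "A>C", "A>G", "T>A", "T>C", "T>G"]
MUT6 = ["G:C>T:A", "G:C>C:G", "G:C>A:T", "A:T>T:A", "A:T>C:G", "A:T>G:C"]
# each 6-type class pools a substitution with its complement
POOL6 = {
    "G:C>T:A": ("G>T", "C>A"), "G:C>C:G": ("G>C", "C>G"), "G:C>A:T": ("G>A", "C>T"),
    "A:T>T:A": ("A>T", "T>A"), "A:T>C:G": ("A>C", "T>G"), "A:T>G:C": ("A>G", "T>C"),
}
PER_MB = 1e6


@dataclass
class SubstitutionCounts:
    counts: dict[str, int] = field(default_factory=lambda: {m: 0 for m in MUT12})
    denominators: dict[str, int] = field(default_factory=lambda: {b: 0 for b in "GCAT"})

    def add(self, other: "SubstitutionCounts") -> "SubstitutionCounts":
        for m in MUT12:
            self.counts[m] += other.counts[m]
        for b in "GCAT":
            self.denominators[b] += other.denominators[b]
        return self

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def total_denominator(self) -> int:
        return sum(self.denominators.values())


@dataclass
class SpectrumTable:
    """12-type and 6-type frequencies per 10^6 counted bases.

    Classes with zero denominator are missing (NaN), never reported as 0.
    """

    freq12: dict[str, float]
    freq6: dict[str, float]
    counts: SubstitutionCounts | None = None
    label: str = ""
    replicate: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(label=self.label, replicate=self.replicate, basis="12-type",
                     mutation_type=m, freq_per_mb=self.freq12.get(m, math.nan)) for m in MUT12]
        rows += [dict(label=self.label, replicate=self.replicate, basis="6-type",
                      mutation_type=m, freq_per_mb=self.freq6.get(m, math.nan)) for m in MUT6]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str) -> str:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path


@dataclass
class GroupComparison:
    table: pd.DataFrame  # mutation_type, means, sds, log2_fold_change, p_value, neg_log10_p
    test_name: str

    def to_tsv(self, path: str) -> str:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path


def clip_ends(pair: DuplexConsensusPair, k: int) -> DuplexConsensusPair:
    """Mask the k consensus positions adjacent to each fragment end.

    Clipped positions become N with a dedicated flag, so they count in
    neither numerators nor denominators; ``k=0`` is the identity and
    2k >= length blanks the whole pair.
    """
    if k < 0:
        raise ValueError("clip length must be >= 0")
    if k == 0:
        return pair
    bases = pair.bases.copy()
    flags = pair.flags.copy()
    bases[:k] = N
    bases[bases.size - k:] = N
    flags[:k] = FLAG_CLIPPED
    flags[flags.size - k:] = FLAG_CLIPPED
    return DuplexConsensusPair(key=pair.key, bases=bases, flags=flags)


def load_bed_mask(path: str) -> dict[str, IntervalTree]:
    """Known-variant mask from 0-based half-open BED3."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 tab-separated fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def mask_positions(pair: DuplexConsensusPair, mask: dict[str, IntervalTree]) -> DuplexConsensusPair:
    """N-out masked positions so they leave both numerator and denominator."""
    tree = mask.get(pair.chrom)
    if tree is None:
        return pair
    hits = tree.overlap(pair.start, pair.end)
    if not hits:
        return pair
    bases = pair.bases.copy()
    for iv in hits:
        a = max(iv.begin, pair.start) - pair.start
        b = min(iv.end, pair.end) - pair.start
        bases[a:b] = N
    return DuplexConsensusPair(key=pair.key, bases=bases, flags=pair.flags)


def mask_known_variants(pairs, mask: dict[str, IntervalTree]):
    """Stream filter applying the known-variant mask to each dsDCS pair."""
    for pair in pairs:
        yield mask_positions(pair, mask)


_CODE2BASE = {65: "A", 67: "C", 71: "G", 84: "T"}


def count_substitutions(
    pairs,
    genome,
    frame: str = "fragment",
    clip: int = 0,
    mask: dict[str, IntervalTree] | None = None,
) -> SubstitutionCounts:
    """Tally non-N consensus mismatches and countable bases by class.

    ``frame='fragment'`` complements both the reference and the observed
    base over the right half of each fragment (positions nearer the right
    end than the left; the exact middle of odd-length fragments counts
    with the left half).
    """
    if frame not in ("reference", "fragment"):
        raise ValueError(f"unknown frame {frame!r}")
    out = SubstitutionCounts()
    gcodes = genome.codes
    glen = genome.length
    for pair in pairs:
        if pair.start < 0 or pair.end > glen:
            raise ValueError(f"dsDCS interval {pair.key} outside the reference")
        if clip:
            pair = clip_ends(pair, clip)
        if mask:
            pair = mask_positions(pair, mask)
        obs = pair.bases
        ref = gcodes[pair.start:pair.end]
        if frame == "fragment":
            L = obs.size
            idx = np.arange(L)
            right = idx * 2 > (L - 1)
            if right.any():
                obs = obs.copy()
                ref = ref.copy()
                obs[right] = complement_codes(obs[right])
                ref[right] = complement_codes(ref[right])
        valid = obs != N
        if not valid.any():
            continue
        refv, obsv = ref[valid], obs[valid]
        for b in b"GCAT":
            out.denominators[chr(b)] += int((refv == b).sum())
        mism = refv != obsv
        if mism.any():
            for r, o in zip(refv[mism], obsv[mism]):
                key = f"{_CODE2BASE[int(r)]}>{_CODE2BASE[int(o)]}"
                if key in out.counts:
                    out.counts[key] += 1
    return out


def frequencies(counts: SubstitutionCounts, label: str = "", replicate: int = 0) -> SpectrumTable:
    """Frequencies per 10^6 bases from raw counts.

    freq12[b>x] = counts[b>x] / denominators[b] * 1e6; a 6-type class
    pools the two complementary 12-type classes over the summed
    denominators of both reference bases.
    """
    if counts.total_denominator == 0:
        raise ValueError("all denominators are zero; nothing was counted")
    freq12 = {}
    for m in MUT12:
        den = counts.denominators[m[0]]
        freq12[m] = counts.counts[m] / den * PER_MB if den > 0 else math.nan
    freq6 = {}
    for m6, (a, b) in POOL6.items():
        den = counts.denominators[a[0]] + counts.denominators[b[0]]
        num = counts.counts[a] + counts.counts[b]
        freq6[m6] = num / den * PER_MB if den > 0 else math.nan
    return SpectrumTable(freq12=freq12, freq6=freq6, counts=counts, label=label, replicate=replicate)


def read_spectrum_tsv(path: str) -> SpectrumTable:
    """Load a table written by :meth:`SpectrumTable.to_tsv`."""
    df = pd.read_csv(path, sep="\t")
    freq12 = dict(zip(df[df.basis == "12-type"].mutation_type, df[df.basis == "12-type"].freq_per_mb))
    freq6 = dict(zip(df[df.basis == "6-type"].mutation_type, df[df.basis == "6-type"].freq_per_mb))
    label = str(df.label.iloc[0]) if len(df) else ""
    rep = int(df.replicate.iloc[0]) if len(df) else 0
    return SpectrumTable(freq12=freq12, freq6=freq6, label=label, replicate=rep)


def _freq_matrix(tables: list[SpectrumTable], which: str) -> tuple[list[str], np.ndarray]:
    types = MUT6 if which == "freq6" else MUT12
    mat = np.array([[getattr(t, which)[m] for m in types] for t in tables], dtype=float)
    return types, mat


def compare_groups(
    treat,
    ctrl: list[SpectrumTable],
    test: str = "ttest",
    pseudocount_freq: float = 0.001,
    which: str = "freq6",
    welch: bool = False,
) -> GroupComparison:
    """Per-mutation-type group comparison on per-replicate frequencies.

    ``treat`` is one treatment group (list of tables) or several (list of
    lists; Dunnett then adjusts jointly against the shared control).
    log2 fold changes use a frequency floor ``pseudocount_freq`` (per
    10^6) so they stay finite at zero observed frequency. A zero mean
    difference is reported as p = 1 even when both groups are constant.
    """
    if test not in ("ttest", "dunnett"):
        raise ValueError(f"unknown test {test!r}")
    groups = treat if treat and isinstance(treat[0], list) else [treat]
    if len(ctrl) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 replicates per group")
    if test == "dunnett" and len({len(g) for g in groups}) > 1:
        raise ValueError("Dunnett requires equal replicate structure across treatment groups")
    types, cmat = _freq_matrix(ctrl, which)
    gmats = [_freq_matrix(g, which)[1] for g in groups]
    rows = []
    for j, mtype in enumerate(types):
        cvals = cmat[:, j]
        tvals_by_group = [m[:, j] for m in gmats]
        if test == "dunnett":
            res = stats.dunnett(*tvals_by_group, control=cvals,
                                random_state=np.random.default_rng(20210916))
            pvals = np.atleast_1d(res.pvalue)
        else:
            pvals = [stats.ttest_ind(tv, cvals, equal_var=not welch).pvalue
                     for tv in tvals_by_group]
        for gi, (tvals, p) in enumerate(zip(tvals_by_group, pvals)):
            mean_t, mean_c = float(np.mean(tvals)), float(np.mean(cvals))
            p = 1.0 if mean_t == mean_c else float(p)
            if math.isnan(p):
                p = 1.0
            lfc = math.log2((mean_t + pseudocount_freq) / (mean_c + pseudocount_freq))
            rows.append(
                dict(
                    group=gi, mutation_type=mtype,
                    mean_treat=mean_t, sd_treat=float(np.std(tvals, ddof=1)),
                    mean_ctrl=mean_c, sd_ctrl=float(np.std(cvals, ddof=1)),
                    log2_fold_change=lfc, p_value=p,
                    neg_log10_p=-math.log10(p) if p > 0 else math.inf,
                )
            )
    name = "dunnett" if test == "dunnett" else ("welch_t" if welch else "student_t")
    return GroupComparison(table=pd.DataFrame(rows), test_name=name)
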