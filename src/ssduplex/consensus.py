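"""UMI-free duplex consensus calling.

Aligned read pairs are grouped by exact fragment coordinates into
same-position groups (SP-Gs) and split into their two orientation
families (F1R2 / F2R1), the coordinate-based proxy for the two strands
of one source molecule. A double-strand consensus sequence (dsDCS) is
emitted only for SP-Gs with read pairs in both directions, and a base is
reported only where the two strand consensuses agree; everything else
becomes N. Indels are out of scope: read bases inserted or deleted
relative to the reference do not contribute.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pysam

from .dna import N, codes_to_str, seq_to_codes
from .library import F1R2, F2R1, LibraryOutput, SimReadPair

FLAG_RESOLVED = 0
FLAG_STRAND_CONFLICT = 1
FLAG_INSUFFICIENT = 2
FLAG_CLIPPED = 3


@dataclass
class ReadPairRecord:
    """One mated read pair collapsed onto its fragment interval.

    ``bases`` covers [frag_start, frag_end) in reference-forward
    orientation with N where neither mate aligned a base (or the mates
    disagreed in their overlap).
    """

    qname: str
    chrom: str
    frag_start: int
    frag_end: int
    orientation: str
    bases: np.ndarray
    molecule_id: str | None = None

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.frag_start, self.frag_end)


@dataclass
class SPGroup:
    key: tuple[str, int, int]
    family_f1r2: list[ReadPairRecord] = field(default_factory=list)
    family_f2r1: list[ReadPairRecord] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.family_f1r2) + len(self.family_f2r1)

    def molecule_ids(self) -> set[str]:
        return {
            r.molecule_id.split(".")[0]
            for r in self.family_f1r2 + self.family_f2r1
            if r.molecule_id is not None
        }


@dataclass
class StrandConsensus:
    key: tuple[str, int, int]
    bases: np.ndarray
    depth: np.ndarray


@dataclass
class DuplexConsensusPair:
    """dsDCS: per-position consensus over {A,C,G,T,N} plus flags."""

    key: tuple[str, int, int]
    bases: np.ndarray
    flags: np.ndarray

    @property
    def chrom(self) -> str:
        return self.key[0]

    @property
    def start(self) -> int:
        return self.key[1]

    @property
    def end(self) -> int:
        return self.key[2]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def sequence(self) -> str:
        return codes_to_str(self.bases)


def _pair_bases(start: int, end: int, placements: list[tuple[int, np.ndarray]]) -> np.ndarray:
    """Merge mate alignments onto the fragment interval; intra-pair
    disagreements in the mate overlap become N."""
    arr = np.zeros(end - start, dtype=np.uint8)  # 0 = uncovered
    for pos, seq in placements:
        a = pos - start
        b = a + seq.size
        window = arr[a:b]
        fresh = window == 0
        window[fresh] = seq[fresh]
        clash = (~fresh) & (window != seq)
        window[clash] = N
    arr[arr == 0] = N
    return arr


def records_from_library(lib: LibraryOutput, chrom: str | None = None) -> list[ReadPairRecord]:
    """Fast path from the simulator's in-memory reads."""
    chrom = chrom or lib.genome_name
    records = []
    for p in lib.pairs:
        bases = _pair_bases(p.frag_start, p.frag_end, [(p.r1_pos, p.r1_seq), (p.r2_pos, p.r2_seq)])
        records.append(
            ReadPairRecord(
                qname=p.qname, chrom=chrom, frag_start=p.frag_start, frag_end=p.frag_end,
                orientation=p.orientation, bases=bases, molecule_id=p.molecule_id,
            )
        )
    return records


def _aligned_placement(read: pysam.AlignedSegment) -> tuple[int, np.ndarray] | list[tuple[int, np.ndarray]]:
    seq = seq_to_codes(read.query_sequence)
    cig = read.cigartuples
    if cig is not None and len(cig) == 1 and cig[0][0] == 0:
        return [(read.reference_start, seq)]
    # general CIGAR: place aligned (match) runs only; indel bases dropped
    placements = []
    qpos, rpos = 0, read.reference_start
    for op, ln in cig or []:
        if op in (0, 7, 8):  # M, =, X
            placements.append((rpos, seq[qpos:qpos + ln]))
            qpos += ln
            rpos += ln
        elif op in (1, 4):  # I, S consume query
            qpos += ln
        elif op in (2, 3):  # D, N consume reference
            rpos += ln
    return placements


def _parse_molecule_id(qname: str) -> str | None:
    if qname.startswith("m") and ";" in qname:
        return qname.split(";", 1)[0][1:]
    return None


def load_alignments(
    sam_path: str, min_mapq: int = 0
) -> tuple[list[ReadPairRecord], Counter]:
    """Read a SAM/BAM into mated :class:`ReadPairRecord` objects.

    Pairs are mated by query name; secondary/supplementary alignments are
    ignored. Discordant pairs (unmapped mate, mates on different
    chromosomes or on the same strand, sub-threshold MAPQ, unmated reads)
    are excluded and tallied in the returned counter.
    """
    discards: Counter = Counter()
    pending: dict[str, pysam.AlignedSegment] = {}
    records: list[ReadPairRecord] = []
    try:
        fh = pysam.AlignmentFile(sam_path, "r")
    except ValueError as exc:
        raise ValueError(
            f"{sam_path}: SAM header must declare reference sequences (@SQ lines) ({exc})"
        ) from exc
    with fh:
        if fh.header.nreferences == 0:
            raise ValueError(f"{sam_path}: SAM header has no @SQ lines; an indexed reference header is required")
        for read in fh:
            if read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired:
                discards["unpaired"] += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r1, r2 = (read, mate) if read.is_read1 else (mate, read)
            if r1.is_unmapped or r2.is_unmapped:
                discards["unmapped_mate"] += 1
                continue
            if r1.reference_name != r2.reference_name:
                discards["different_chrom"] += 1
                continue
            if r1.is_reverse == r2.is_reverse:
                discards["same_strand"] += 1
                continue
            if min(r1.mapping_quality, r2.mapping_quality) < min_mapq:
                discards["low_mapq"] += 1
                continue
            start = min(r1.reference_start, r2.reference_start)
            end = max(r1.reference_end, r2.reference_end)
            placements = []
            for r in (r1, r2):
                placements.extend(_aligned_placement(r))
            records.append(
                ReadPairRecord(
                    qname=r1.query_name,
                    chrom=r1.reference_name,
                    frag_start=start,
                    frag_end=end,
                    orientation=F1R2 if not r1.is_reverse else F2R1,
                    bases=_pair_bases(start, end, placements),
                    molecule_id=_parse_molecule_id(r1.query_name),
                )
            )
    discards["unmated"] += len(pending)
    return records, discards


def group_spg(records: list[ReadPairRecord]) -> list[SPGroup]:
    """Group read pairs by exact (chrom, frag_start, frag_end) equality."""
    groups: dict[tuple, SPGroup] = {}
    for rec in records:
        g = groups.get(rec.key)
        if g is None:
            g = groups[rec.key] = SPGroup(key=rec.key)
        (g.family_f1r2 if rec.orientation == F1R2 else g.family_f2r1).append(rec)
    return [groups[k] for k in sorted(groups)]


def consensus_base(bases: list[str], threshold: float) -> str:
    """Reference (scalar) per-position consensus rule.

    Among non-N covering bases, the most frequent base is called when its
    agreement fraction reaches ``threshold`` (ties at exactly the
    threshold are accepted; a tie for the top base yields N). Zero
    coverage yields N.
    """
    counts = Counter(b for b in bases if b != "N")
    if not counts:
        return "N"
    total = sum(counts.values())
    (top, cnt), *rest = counts.most_common()
    if rest and rest[0][1] == cnt:
        return "N"
    return top if cnt / total >= threshold - 1e-9 else "N"


def default_agreement_threshold(family_size: int) -> float:
    """Unanimity for 1-2 member families, 80% majority for larger ones."""
    return 1.0 if family_size <= 2 else 0.8


def strand_consensus(
    family: list[ReadPairRecord], agreement_threshold: float | None = None
) -> StrandConsensus:
    if not family:
        raise ValueError("family must be non-empty")
    thr = agreement_threshold if agreement_threshold is not None else default_agreement_threshold(len(family))
    mat = np.stack([r.bases for r in family])
    length = mat.shape[1]
    counts = np.zeros((4, length), dtype=np.int32)
    for i, code in enumerate(b"ACGT"):
        counts[i] = (mat == code).sum(axis=0)
    cov = counts.sum(axis=0)
    top_idx = counts.argmax(axis=0)
    top_cnt = counts.max(axis=0)
    n_at_top = (counts == top_cnt).sum(axis=0)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    bases = lut[top_idx]
    ok = (cov > 0) & (n_at_top == 1) & (top_cnt >= thr * cov - 1e-9)
    bases[~ok] = N
    return StrandConsensus(key=family[0].key, bases=bases, depth=cov)


def duplex_consensus(
    spg: SPGroup,
    min_family_size: int = 1,
    agreement_threshold: float | None = None,
) -> DuplexConsensusPair | None:
    """Build the dsDCS for one SP-G, or None without both orientations.

    A position is resolved only when both strand-family consensuses are
    non-N and identical; disagreement is flagged as a strand conflict.
    """
    if len(spg.family_f1r2) < min_family_size or len(spg.family_f2r1) < min_family_size:
        return None
    c1 = strand_consensus(spg.family_f1r2, agreement_threshold)
    c2 = strand_consensus(spg.family_f2r1, agreement_threshold)
    agree = (c1.bases == c2.bases) & (c1.bases != N)
    conflict = (c1.bases != c2.bases) & (c1.bases != N) & (c2.bases != N)
    bases = np.where(agree, c1.bases, np.uint8(N))
    flags = np.full(bases.size, FLAG_INSUFFICIENT, dtype=np.uint8)
    flags[agree] = FLAG_RESOLVED
    flags[conflict] = FLAG_STRAND_CONFLICT
    return DuplexConsensusPair(key=spg.key, bases=bases, flags=flags)


def call_consensus(
    records: list[ReadPairRecord],
    min_family_size: int = 1,
    agreement_threshold: float | None = None,
) -> list[DuplexConsensusPair]:
    pairs = []
    for spg in group_spg(records):
        dcs = duplex_consensus(spg, min_family_size, agreement_threshold)
        if dcs is not None:
            pairs.append(dcs)
    return pairs


def write_dcs(pairs: list[DuplexConsensusPair], path: str, chrom: str, chrom_length: int) -> str:
    """dsDCS as unpaired SAM records at their SP-G coordinates (no
    re-mapping; coordinates are retained from the grouping key)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": chrom_length}]}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for p in sorted(pairs, key=lambda x: x.key):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"dcs_{p.start}_{p.end}"
            a.flag = 0
            a.reference_id = 0
            a.reference_start = p.start
            a.mapping_quality = 60
            a.cigarstring = f"{p.length}M"
            a.query_sequence = p.sequence
            a.query_qualities = pysam.qualitystring_to_array("?" * p.length)
            out.write(a)
    return path


def read_dcs(path: str) -> list[DuplexConsensusPair]:
    """Round-trip loader; N positions are flagged as insufficient (the
    conflict/insufficient distinction is not serialized)."""
    pairs = []
    with pysam.AlignmentFile(path, "r") as fh:
        for read in fh:
            bases = seq_to_codes(read.query_sequence)
            flags = np.where(bases == N, np.uint8(FLAG_INSUFFICIENT), np.uint8(FLAG_RESOLVED))
            pairs.append(
                DuplexConsensusPair(
                    key=(read.reference_name, read.reference_start, read.reference_start + bases.size),
                    bases=bases,
                    flags=flags,
                )
            )
    return pairs


def export_dcs_fastq(pairs: list[DuplexConsensusPair], path: str) -> str:
    """dsDCS as single-end FASTQ for users who want to re-map externally."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"@dcs_{p.chrom}_{p.start}_{p.end}\n{p.sequence}\n+\n{'?' * p.length}\n")
    return path
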