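"""Library sampling, PCR duplication and paired-end sequencing.

Each repaired duplex molecule yields two strand families — reads that
sequenced the genome-plus strand (orientation F1R2: read 1 maps forward
at the left fragment end) and reads from the minus strand (F2R1). PCR
duplicates within a family share the family's template, so a concordant
end-repair substitution is seen by BOTH families while discordant damage,
like most PCR/sequencing noise, is not.

Dilution is modelled through ``ligated_amount``: the number of distinct
molecules entering PCR scales with the amount of ligated product, which
controls how often two unrelated molecules collide on identical fragment
coordinates (SP-G misassignment).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .dna import COMPLEMENT, N, revcomp_codes, codes_to_str
from .fragments import DuplexFragment

F1R2 = "F1R2"
F2R1 = "F2R1"

# SAM flag values for a proper pair: (read1, read2)
_FLAGS = {F1R2: (99, 147), F2R1: (83, 163)}


@dataclass
class LibraryParams:
    """Sequencing-library knobs.

    ``duplicate_dist`` is ``("ztgeom", mean)`` (zero-truncated geometric)
    or ``("constant", k)`` read pairs per strand family.
    ``ligated_amount`` is a relative scale (the experiment's amol units);
    ``molecules_per_unit`` converts it to a sampled-molecule count;
    ``None`` sequences every fragment.
    """

    read_length: int = 100
    seq_error_rate: float = 1e-3
    pcr_error_rate: float = 1e-4
    duplicate_dist: tuple = ("ztgeom", 3.0)
    ligated_amount: float | None = None
    molecules_per_unit: float = 100.0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        kind, param = self.duplicate_dist
        if kind not in ("ztgeom", "constant") or param < 1:
            raise ValueError("duplicate_dist must be ('ztgeom'|'constant', value >= 1)")


@dataclass
class SimReadPair:
    """One sequenced read pair; mate sequences stored reference-forward."""

    qname: str
    molecule_id: str
    frag_start: int
    frag_end: int
    orientation: str
    r1_pos: int
    r1_seq: np.ndarray
    r2_pos: int
    r2_seq: np.ndarray

    @property
    def r1_reverse(self) -> bool:
        return self.orientation == F2R1

    @property
    def r2_reverse(self) -> bool:
        return self.orientation == F1R2


@dataclass
class LibraryOutput:
    genome_name: str
    genome_length: int
    read_length: int
    pairs: list[SimReadPair]
    truth_variants: pd.DataFrame
    truth_molecules: pd.DataFrame

    def write_fastq(self, prefix: str) -> tuple[str, str]:
        """Paired 4-line FASTQ, reads in as-sequenced orientation."""
        p1, p2 = f"{prefix}_R1.fastq", f"{prefix}_R2.fastq"
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for pair in self.pairs:
                s1 = pair.r1_seq if not pair.r1_reverse else revcomp_codes(pair.r1_seq)
                s2 = pair.r2_seq if not pair.r2_reverse else revcomp_codes(pair.r2_seq)
                for fh, seq in ((f1, s1), (f2, s2)):
                    fh.write(f"@{pair.qname}\n{codes_to_str(seq)}\n+\n{'?' * len(seq)}\n")
        return p1, p2

    def sam_header(self) -> dict:
        return {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": self.genome_name, "LN": self.genome_length}],
        }

    def write_sam(self, path: str) -> str:
        """Truth alignments: perfect coordinates, all-match CIGAR."""
        records = []
        for pair in self.pairs:
            f1, f2 = _FLAGS[pair.orientation]
            tlen = pair.frag_end - pair.frag_start
            records.append((pair.r1_pos, pair.qname, f1, pair.r1_seq, pair.r2_pos, tlen if f1 == 99 else -tlen))
            records.append((pair.r2_pos, pair.qname, f2, pair.r2_seq, pair.r1_pos, tlen if f2 == 163 else -tlen))
        records.sort(key=lambda r: (r[0], r[1], r[2]))
        with pysam.AlignmentFile(path, "w", header=self.sam_header(), add_sam_header=True) as out:
            for pos, qname, flag, seq, mpos, tlen in records:
                a = pysam.AlignedSegment(out.header)
                a.query_name = qname
                a.flag = flag
                a.reference_id = 0
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = f"{len(seq)}M"
                a.query_sequence = codes_to_str(seq)
                a.query_qualities = pysam.qualitystring_to_array("?" * len(seq))
                a.next_reference_id = 0
                a.next_reference_start = mpos
                a.template_length = tlen
                out.write(a)
        return path

    def write_truth(self, prefix: str) -> tuple[str, str]:
        pv, pm = f"{prefix}.truth_variants.tsv", f"{prefix}.truth_molecules.tsv"
        self.truth_variants.to_csv(pv, sep="\t", index=False)
        self.truth_molecules.to_csv(pm, sep="\t", index=False)
        return pv, pm


def _draw_duplicates(rng: np.random.Generator, dist: tuple) -> int:
    kind, param = dist
    if kind == "constant":
        return int(param)
    # zero-truncated geometric with the given mean: support >= 1
    return int(rng.geometric(1.0 / float(param)))


def _mutate(rng, codes: np.ndarray, rate: float) -> np.ndarray:
    """Independent per-base substitution errors at ``rate``."""
    if rate <= 0:
        return codes
    hits = np.nonzero(rng.random(codes.size) < rate)[0]
    if hits.size == 0:
        return codes
    out = codes.copy()
    base_idx = {65: 0, 67: 1, 71: 2, 84: 3}
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        cur = base_idx.get(int(out[i]), 0)
        out[i] = lut[(cur + 1 + rng.integers(3)) % 4]
    return out


def molecule_strand_sequences(frag: DuplexFragment, genome) -> tuple[np.ndarray, np.ndarray]:
    """Plus-frame base sequences observed when sequencing the plus strand
    (F1R2 template) and the minus strand (F2R1 template) of the molecule.

    Concordant end-repair substitutions appear in both; strand-discordant
    damage only in its own strand's template.
    """
    base = genome.codes[frag.genome_start:frag.genome_end].copy()
    for sub in frag.concordant_subs:
        alt_plus = sub.alt if sub.strand == "+" else COMPLEMENT[sub.alt]
        base[sub.position - frag.genome_start] = ord(alt_plus)
    top = base.copy()
    bottom = base
    for dam in frag.ds_damage:
        alt_plus = dam.alt if dam.strand == "+" else COMPLEMENT[dam.alt]
        (top if dam.strand == "+" else bottom)[dam.position - frag.genome_start] = ord(alt_plus)
    return top, bottom


def sample_and_sequence(
    fragments: list[DuplexFragment],
    genome,
    lib: LibraryParams,
    seed: int,
) -> LibraryOutput:
    """Sample molecules, amplify, sequence; emit reads plus truth tables.

    Reads are truncated (and flagged in the molecule truth table) when the
    fragment is shorter than the configured read length. Fully
    deterministic for a fixed seed.
    """
    for f in fragments:
        if not f.repaired:
            raise ValueError("fragments must be end-repaired before sequencing")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x11B]))
    n = len(fragments)
    if lib.ligated_amount is None:
        chosen = np.arange(n)
    else:
        k = min(n, int(round(lib.ligated_amount * lib.molecules_per_unit)))
        chosen = np.sort(rng.choice(n, size=k, replace=False))

    pairs: list[SimReadPair] = []
    var_rows: list[dict] = []
    mol_rows: list[dict] = []
    for idx in chosen:
        frag = fragments[idx]
        start, end = frag.genome_start, frag.genome_end
        flen = end - start
        rl = min(lib.read_length, flen)
        truncated = lib.read_length > flen
        top, bottom = molecule_strand_sequences(frag, genome)
        ndup = {}
        for orientation, template in ((F1R2, top), (F2R1, bottom)):
            ndup[orientation] = _draw_duplicates(rng, lib.duplicate_dist)
            for d in range(ndup[orientation]):
                tmpl = _mutate(rng, template, lib.pcr_error_rate)
                left = _mutate(rng, tmpl[:rl].copy(), lib.seq_error_rate)
                right = _mutate(rng, tmpl[flen - rl:].copy(), lib.seq_error_rate)
                if orientation == F1R2:
                    r1_pos, r1_seq, r2_pos, r2_seq = start, left, end - rl, right
                else:
                    r1_pos, r1_seq, r2_pos, r2_seq = end - rl, right, start, left
                pairs.append(
                    SimReadPair(
                        qname=f"m{frag.molecule_id};{orientation};{d}",
                        molecule_id=frag.molecule_id,
                        frag_start=start,
                        frag_end=end,
                        orientation=orientation,
                        r1_pos=r1_pos,
                        r1_seq=r1_seq,
                        r2_pos=r2_pos,
                        r2_seq=r2_seq,
                    )
                )
        for sub in frag.concordant_subs:
            var_rows.append(
                dict(
                    molecule_id=frag.molecule_id, chrom=genome.name, pos=sub.position,
                    strand=sub.strand, ref=sub.ref, alt=sub.alt, provenance=sub.provenance,
                    frag_start=start, frag_end=end,
                )
            )
        for dam in frag.ds_damage:
            var_rows.append(
                dict(
                    molecule_id=frag.molecule_id, chrom=genome.name, pos=dam.position,
                    strand=dam.strand, ref=dam.ref, alt=dam.alt, provenance="ds_discordant",
                    frag_start=start, frag_end=end,
                )
            )
        mol_rows.append(
            dict(
                molecule_id=frag.molecule_id, chrom=genome.name, frag_start=start,
                frag_end=end, n_dup_f1r2=ndup[F1R2], n_dup_f2r1=ndup[F2R1],
                truncated=truncated,
            )
        )
    var_cols = ["molecule_id", "chrom", "pos", "strand", "ref", "alt", "provenance", "frag_start", "frag_end"]
    mol_cols = ["molecule_id", "chrom", "frag_start", "frag_end", "n_dup_f1r2", "n_dup_f2r1", "truncated"]
    return LibraryOutput(
        genome_name=genome.name,
        genome_length=genome.length,
        read_length=lib.read_length,
        pairs=pairs,
        truth_variants=pd.DataFrame(var_rows, columns=var_cols),
        truth_molecules=pd.DataFrame(mol_rows, columns=mol_cols),
    )
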