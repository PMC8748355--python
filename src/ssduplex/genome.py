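"""Synthetic reference genomes and FASTA round-tripping.

A :class:`ReferenceGenome` stands in for the bacterial reference a real
run would align against; simulations only need a sequence long enough to
shear and a controllable GC content.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import BASE_CODES, codes_to_str, seq_to_codes


@dataclass
class ReferenceGenome:
    """A named DNA sequence over {A,C,G,T}.

    Parameters
    ----------
    name : reference/contig name used in SAM headers and truth tables.
    sequence : upper-case DNA string.
    gc_target : the GC fraction requested at generation time, if any;
        the realized value is :attr:`gc_content`.
    """

    name: str
    sequence: str
    gc_target: float | None = None
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        """Sequence as ASCII uint8 codes (cached)."""
        if self._codes is None:
            self._codes = seq_to_codes(self.sequence)
        return self._codes

    @property
    def gc_content(self) -> float:
        codes = self.codes
        return float(((codes == ord("G")) | (codes == ord("C"))).mean())

    def base(self, position: int, strand: str = "+") -> str:
        b = self.sequence[position]
        if strand == "-":
            from .dna import COMPLEMENT

            return COMPLEMENT[b]
        return b


def make_genome(length: int, gc: float, seed: int, name: str = "chrSim") -> ReferenceGenome:
    """Draw a random genome with the requested GC fraction.

    Bases are i.i.d. with P(G) = P(C) = gc/2, so the realized GC content
    concentrates around ``gc`` as length grows.
    """
    if length < 1000:
        raise ValueError(f"genome length must be >= 1000, got {length}")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFA57A]))
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]  # A, C, G, T
    codes = rng.choice(BASE_CODES, size=length, p=probs)
    return ReferenceGenome(name=name, sequence=codes_to_str(codes), gc_target=gc)


def write_fasta(genome: ReferenceGenome, path: str) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], path, "fasta")


def read_fasta(path: str) -> ReferenceGenome:
    rec = next(SeqIO.parse(path, "fasta"))
    return ReferenceGenome(name=rec.id, sequence=str(rec.seq).upper())
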