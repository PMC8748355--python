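import numpy as np
import pytest

from ssduplex import DamageParams, make_genome
from ssduplex.consensus import ReadPairRecord
from ssduplex.dna import seq_to_codes
from ssduplex.fragments import DuplexFragment, OverhangSpec, blunt


@pytest.fixture(scope="session")
def genome():
    return make_genome(20_000, 0.5, seed=42)


@pytest.fixture()
def damage_params():
    return DamageParams()


def make_fragment(start, end, mol="0", left=None, right=None, **kw):
    """Bare fragment with optional OverhangSpec ends."""
    return DuplexFragment(
        genome_start=start,
        genome_end=end,
        molecule_id=mol,
        overhang_left=left or blunt("left"),
        overhang_right=right or blunt("right"),
        **kw,
    )


def overhang(end, kind, length):
    return OverhangSpec(end=end, kind=kind, length=length)


def make_record(chrom, start, seq, orientation="F1R2", qname="r", molecule_id=None):
    """Read-pair record fully covering [start, start+len(seq))."""
    return ReadPairRecord(
        qname=qname,
        chrom=chrom,
        frag_start=start,
        frag_end=start + len(seq),
        orientation=orientation,
        bases=seq_to_codes(seq),
        molecule_id=molecule_id,
    )
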