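"""Truth-table bookkeeping for simulated runs.

Links planted events (concordant end-repair substitutions, discordant
damage) to what the consensus caller actually reported, and measures raw
read error rates as the baseline duplex correction is compared against.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dna import COMPLEMENT, N
from .consensus import DuplexConsensusPair
from .library import LibraryOutput


@dataclass
class ArtifactRecovery:
    n_planted: int          # concordant SS-artifact substitutions sequenced
    n_called: int           # reported in the dsDCS as the planted alt
    n_conflict_or_n: int    # position emitted as N instead

    @property
    def call_rate(self) -> float:
        return self.n_called / self.n_planted if self.n_planted else float("nan")


def _alt_plus(row) -> str:
    return row.alt if row.strand == "+" else COMPLEMENT[row.alt]


def artifact_recovery(
    pairs: list[DuplexConsensusPair],
    truth_variants: pd.DataFrame,
    provenance_prefix: str = "ss_",
    clip: int = 0,
) -> ArtifactRecovery:
    """How many planted SS artifacts the dsDCS reports as confident calls.

    Concordant artifacts are expected to SURVIVE duplex consensus (the
    failure mode the method's simulator exists to reproduce); discordant
    damage is expected to be suppressed. With ``clip`` > 0, calls within
    ``clip`` bases of either fragment end are treated as masked.
    """
    by_key = {p.key: p for p in pairs}
    planted = called = as_n = 0
    sel = truth_variants[truth_variants.provenance.str.startswith(provenance_prefix)]
    for row in sel.itertuples():
        planted += 1
        pair = by_key.get((row.chrom, row.frag_start, row.frag_end))
        if pair is None:
            as_n += 1
            continue
        clipped = not (pair.start + clip <= row.pos < pair.end - clip)
        if not clipped and pair.bases[row.pos - pair.start] == ord(_alt_plus(row)):
            called += 1
        else:
            as_n += 1
    return ArtifactRecovery(n_planted=planted, n_called=called, n_conflict_or_n=as_n)


def discordant_suppression(
    pairs: list[DuplexConsensusPair], truth_variants: pd.DataFrame
) -> tuple[int, int]:
    """(n_planted, n_leaked): discordant damage events that still surfaced
    as their alt base in the dsDCS (should be ~0)."""
    by_key = {p.key: p for p in pairs}
    sel = truth_variants[truth_variants.provenance == "ds_discordant"]
    planted = leaked = 0
    for row in sel.itertuples():
        planted += 1
        pair = by_key.get((row.chrom, row.frag_start, row.frag_end))
        if pair is not None and pair.bases[row.pos - pair.start] == ord(_alt_plus(row)):
            leaked += 1
    return planted, leaked


def raw_read_mismatch_rate(lib: LibraryOutput, genome) -> float:
    """Per-base mismatch rate of the raw reads against the reference."""
    mism = 0
    total = 0
    g = genome.codes
    for p in lib.pairs:
        for pos, seq in ((p.r1_pos, p.r1_seq), (p.r2_pos, p.r2_seq)):
            ref = g[pos:pos + seq.size]
            mism += int((seq != ref).sum())
            total += seq.size
    return mism / total if total else float("nan")


def dcs_mismatch_stats(
    pairs: list[DuplexConsensusPair], genome, exclude: pd.DataFrame | None = None
) -> tuple[int, int]:
    """(mismatch_count, counted_bases) of dsDCS vs reference, optionally
    excluding planted truth positions."""
    excluded: set[tuple[int, int, int]] = set()
    if exclude is not None:
        excluded = {(r.frag_start, r.frag_end, r.pos) for r in exclude.itertuples()}
    mism = 0
    total = 0
    g = genome.codes
    for p in pairs:
        obs = p.bases
        ref = g[p.start:p.end]
        valid = obs != N
        if excluded:
            for i in np.nonzero(valid)[0]:
                if (p.start, p.end, p.start + int(i)) in excluded:
                    valid[i] = False
        mism += int(((obs != ref) & valid).sum())
        total += int(valid.sum())
    return mism, total
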