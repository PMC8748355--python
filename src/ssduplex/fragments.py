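"""Sheared dsDNA fragments with single-strand structure.

Acoustic shearing leaves fragment ends that are blunt or carry 5'/3'
single-strand (SS) overhangs, and can nick or gap the duplex internally.
These SS regions are where guanine damage accumulates before library
preparation; their geometry is what this module models.

Coordinates are 0-based half-open genome intervals throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Strand = Literal["+", "-"]
END_LEFT = "left"
END_RIGHT = "right"


def opposite(strand: str) -> str:
    return "-" if strand == "+" else "+"


@dataclass(frozen=True)
class OverhangSpec:
    """One fragment end: blunt, or a 5'/3' SS overhang of a given length."""

    end: Literal["left", "right"]
    kind: Literal["blunt", "five_prime", "three_prime"]
    length: int

    def __post_init__(self) -> None:
        if (self.kind == "blunt") != (self.length == 0):
            raise ValueError("blunt end <=> zero overhang length")
        if self.length < 0:
            raise ValueError("overhang length must be >= 0")

    @property
    def protruding_strand(self) -> str | None:
        """Genome strand carrying the SS bases of this overhang.

        At the left end the plus strand's 5' terminus protrudes for a 5'
        overhang and the minus strand's 3' terminus for a 3' overhang;
        the right end is the mirror image.
        """
        if self.kind == "blunt":
            return None
        if self.end == END_LEFT:
            return "+" if self.kind == "five_prime" else "-"
        return "-" if self.kind == "five_prime" else "+"


def blunt(end: str) -> OverhangSpec:
    return OverhangSpec(end=end, kind="blunt", length=0)


@dataclass(frozen=True)
class Nick:
    """Backbone break on one strand; no bases missing."""

    strand: Strand
    position: int


@dataclass(frozen=True)
class Gap:
    """Missing stretch [start, end) on one strand; the other strand is the
    exposed SS template across the gap."""

    strand: Strand
    start: int
    end: int


@dataclass(frozen=True)
class SSLesion:
    """A damaged base inside an SS region.

    ``original_base`` is the base on the damaged strand (G for oxoG/Iz,
    C for deaminated C).
    """

    position: int
    strand: Strand
    original_base: str
    lesion: Literal["oxoG", "iz", "deamC"]
    region_kind: Literal["overhang", "gap", "nick_adjacent"]


@dataclass(frozen=True)
class ConcordantSub:
    """A substitution fixed into BOTH strands by end repair.

    ``ref``/``alt`` are expressed on ``strand`` (the damaged strand under
    the default ``damaged_strand`` frame rule).
    """

    position: int
    strand: Strand
    ref: str
    alt: str
    provenance: str


@dataclass(frozen=True)
class StrandDamage:
    """Strand-discordant damage in the double-stranded core; visible only
    in reads derived from ``strand``."""

    position: int
    strand: Strand
    ref: str
    alt: str


@dataclass
class DuplexFragment:
    genome_start: int
    genome_end: int
    molecule_id: str
    source_strand_top: Strand = "+"
    overhang_left: OverhangSpec = field(default_factory=lambda: blunt(END_LEFT))
    overhang_right: OverhangSpec = field(default_factory=lambda: blunt(END_RIGHT))
    nicks: list[Nick] = field(default_factory=list)
    gaps: list[Gap] = field(default_factory=list)
    lesions: list[SSLesion] = field(default_factory=list)
    ds_damage: list[StrandDamage] = field(default_factory=list)
    concordant_subs: list[ConcordantSub] = field(default_factory=list)
    repaired: bool = False

    @property
    def length(self) -> int:
        return self.genome_end - self.genome_start

    @property
    def core_start(self) -> int:
        return self.genome_start + self.overhang_left.length

    @property
    def core_end(self) -> int:
        return self.genome_end - self.overhang_right.length

    @property
    def root_id(self) -> str:
        return self.molecule_id.split(".")[0]

    def is_blunt(self) -> bool:
        return (
            self.overhang_left.kind == "blunt"
            and self.overhang_right.kind == "blunt"
            and not self.nicks
            and not self.gaps
        )

    def ss_regions(self, nick_window: int = 0) -> list[tuple[str, int, int, str]]:
        """All SS regions as (damaged_strand, start, end, kind) tuples.

        * overhangs: the protruding strand over the overhang span;
        * gaps: the strand OPPOSITE the gapped strand (it is the strand
          still present, exposed as SS template);
        * nicks: a breathing window of ``nick_window`` bases downstream
          (3' direction of the nicked strand), template on the intact
          strand — the stretch nick translation will resynthesise.
        """
        regions: list[tuple[str, int, int, str]] = []
        ol, orr = self.overhang_left, self.overhang_right
        if ol.kind != "blunt":
            regions.append((ol.protruding_strand, self.genome_start, self.genome_start + ol.length, "overhang"))
        if orr.kind != "blunt":
            regions.append((orr.protruding_strand, self.genome_end - orr.length, self.genome_end, "overhang"))
        for gap in self.gaps:
            regions.append((opposite(gap.strand), gap.start, gap.end, "gap"))
        if nick_window > 0:
            for nick in self.nicks:
                if nick.strand == "+":
                    a, b = nick.position, min(nick.position + nick_window, self.core_end)
                else:
                    a, b = max(nick.position - nick_window, self.core_start), nick.position
                if b > a:
                    regions.append((opposite(nick.strand), a, b, "nick_adjacent"))
        return regions


def _draw_overhang_length(rng: np.random.Generator, dist) -> int:
    if isinstance(dist, (int, np.integer)):
        return int(dist)
    kind, param = dist
    if kind == "constant":
        return int(param)
    if kind == "geometric":
        # support >= 1, mean == param
        return int(rng.geometric(1.0 / float(param)))
    raise ValueError(f"unknown overhang length distribution {dist!r}")


def shear_fragments(
    genome,
    n: int,
    *,
    size_mean: float = 350.0,
    size_sd: float = 50.0,
    overhang_len_dist=("geometric", 8.0),
    end_kind_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    nick_rate: float = 0.0,
    gap_rate: float = 0.0,
    gap_len_mean: float = 5.0,
    min_length: int = 50,
    seed: int = 0,
) -> list[DuplexFragment]:
    """Simulate sonication: fragment intervals plus per-end SS structure.

    Each end is independently blunt / 5' overhang / 3' overhang with
    ``end_kind_probs``; overhang lengths follow ``overhang_len_dist``
    (capped at a quarter of the fragment so a double-stranded core always
    remains). Nick and gap counts are Poisson in the core length. Fragments
    that would leave the genome are resampled, never truncated.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not np.isclose(sum(end_kind_probs), 1.0):
        raise ValueError("end_kind_probs must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EA2]))
    L = genome.length
    frags: list[DuplexFragment] = []
    kinds = np.array(["blunt", "five_prime", "three_prime"])
    for i in range(n):
        while True:
            flen = int(round(rng.normal(size_mean, size_sd)))
            if min_length <= flen <= L:
                break
        start = int(rng.integers(0, L - flen + 1))
        end = start + flen
        ends = []
        for which in (END_LEFT, END_RIGHT):
            kind = str(kinds[rng.choice(3, p=end_kind_probs)])
            if kind == "blunt":
                ends.append(blunt(which))
                continue
            olen = min(_draw_overhang_length(rng, overhang_len_dist), flen // 4)
            if olen == 0:
                ends.append(blunt(which))
            else:
                ends.append(OverhangSpec(end=which, kind=kind, length=olen))
        ol, orr = ends
        core_start = start + ol.length
        core_end = end - orr.length
        core_len = core_end - core_start
        nicks: list[Nick] = []
        gaps: list[Gap] = []
        if nick_rate > 0 and core_len > 2:
            for _ in range(rng.poisson(nick_rate * core_len)):
                pos = int(rng.integers(core_start + 1, core_end - 1))
                nicks.append(Nick(strand="+" if rng.random() < 0.5 else "-", position=pos))
        if gap_rate > 0 and core_len > 6:
            for _ in range(rng.poisson(gap_rate * core_len)):
                glen = max(1, min(int(rng.geometric(1.0 / gap_len_mean)), core_len // 3))
                if core_end - 1 - glen <= core_start + 1:
                    continue
                gstart = int(rng.integers(core_start + 1, core_end - 1 - glen))
                gaps.append(Gap(strand="+" if rng.random() < 0.5 else "-", start=gstart, end=gstart + glen))
        frags.append(
            DuplexFragment(
                genome_start=start,
                genome_end=end,
                molecule_id=str(i),
                overhang_left=ol,
                overhang_right=orr,
                nicks=nicks,
                gaps=gaps,
            )
        )
    return frags


def copy_fragment(frag: DuplexFragment, **changes) -> DuplexFragment:
    return replace(frag, **changes)
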