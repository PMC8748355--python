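"""Guanine damage confined to single-strand regions.

Exposed SS DNA is vulnerable to oxidation and deamination: 8-oxoG (reads
as A-pairing, hence G>T after copying), 2-aminoimidazolone (Iz, G>C) and
deaminated cytosine (C>T). Double-stranded DNA also picks up damage, but
there it stays on one strand and is later rejected by duplex consensus;
here it is modelled as explicit strand-discordant damage.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dna import COMPLEMENT
from .fragments import DuplexFragment, SSLesion, StrandDamage

LESION_KINDS = ("oxoG", "iz", "deamC")
DEFAULT_MANIFESTATION = {"oxoG": "T", "iz": "C", "deamC": "T"}


@dataclass
class DamageParams:
    """Per-base lesion probabilities and how lesions manifest.

    Probabilities apply per eligible base inside an SS region (G for
    oxoG/Iz, C for deamC). Realistic artifact regimes live at or below
    ~0.05 per base; values up to 1 are accepted so certainty cases
    (every exposed G damaged) remain expressible.

    ``frame_rule`` fixes the strand frame in which planted concordant
    substitutions are recorded in truth tables: ``damaged_strand`` keeps
    the mechanism explicit (G>T on whichever strand carried the 8-oxoG),
    ``reference`` projects onto the genome plus strand.
    """

    p_oxog_ss: float = 0.02
    p_iz_ss: float = 0.02
    p_deamc_ss: float = 0.01
    p_ds_damage: float = 0.0
    nick_window: int = 2
    frame_rule: str = "damaged_strand"
    manifestation: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MANIFESTATION))

    def __post_init__(self) -> None:
        for name in ("p_oxog_ss", "p_iz_ss", "p_deamc_ss", "p_ds_damage"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_oxog_ss + self.p_iz_ss > 1.0:
            raise ValueError("p_oxog_ss + p_iz_ss must not exceed 1")
        missing = set(LESION_KINDS) - set(self.manifestation)
        if missing:
            raise ValueError(f"manifestation map missing lesion kinds: {sorted(missing)}")
        if self.frame_rule not in ("reference", "damaged_strand"):
            raise ValueError(f"unknown frame_rule {self.frame_rule!r}")


def _fragment_rng(seed: int, frag: DuplexFragment, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(frag.root_id), stream]))


def apply_ss_damage(
    fragment: DuplexFragment, genome, params: DamageParams, seed: int
) -> DuplexFragment:
    """Place lesions in the fragment's SS regions (and optional discordant
    damage in its double-stranded core). Returns a new fragment.

    Lesions land only on eligible bases of the exposed strand: G for
    oxoG/Iz, C for deamC. One uniform draw per eligible base partitions
    the lesion kinds, so a base carries at most one lesion.
    """
    if fragment.repaired:
        raise ValueError("damage must be applied before end repair")
    rng = _fragment_rng(seed, fragment, 1)
    codes = genome.sequence
    lesions: list[SSLesion] = list(fragment.lesions)
    seen: set[tuple[str, int]] = {(l.strand, l.position) for l in lesions}
    ss_cover: set[int] = set()
    for strand, a, b, kind in fragment.ss_regions(nick_window=params.nick_window):
        ss_cover.update(range(a, b))
        us = rng.random(b - a)
        for offset, pos in enumerate(range(a, b)):
            base = codes[pos] if strand == "+" else COMPLEMENT[codes[pos]]
            if (strand, pos) in seen:
                continue
            u = us[offset]
            lesion = None
            if base == "G":
                if u < params.p_oxog_ss:
                    lesion = "oxoG"
                elif u < params.p_oxog_ss + params.p_iz_ss:
                    lesion = "iz"
            elif base == "C":
                if u < params.p_deamc_ss:
                    lesion = "deamC"
            if lesion is not None:
                lesions.append(
                    SSLesion(position=pos, strand=strand, original_base=base, lesion=lesion, region_kind=kind)
                )
                seen.add((strand, pos))
    ds_damage: list[StrandDamage] = list(fragment.ds_damage)
    if params.p_ds_damage > 0:
        core = [p for p in range(fragment.core_start, fragment.core_end) if p not in ss_cover]
        us = rng.random(len(core))
        hits = [p for p, u in zip(core, us) if u < params.p_ds_damage]
        for pos in hits:
            strand = "+" if rng.random() < 0.5 else "-"
            ref = codes[pos] if strand == "+" else COMPLEMENT[codes[pos]]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            ds_damage.append(StrandDamage(position=pos, strand=strand, ref=ref, alt=str(alt)))
    return replace(fragment, lesions=lesions, ds_damage=ds_damage)


def apply_ss_damage_all(fragments, genome, params: DamageParams, seed: int):
    return [apply_ss_damage(f, genome, params, seed) for f in fragments]
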