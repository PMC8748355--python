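"""In-silico single-strand-specific nuclease (SSN) digestion.

Three enzyme archetypes are modelled before end repair:

* ``s1`` — SS endonuclease: excises overhangs, cleaves the duplex at gaps
  and (efficiently) at nicks;
* ``mbn`` — mung-bean-like SS endonuclease: like S1 but with weak
  activity at nicks;
* ``recjf`` — 5'→3' SS exonuclease: degrades 5' overhangs only, no
  internal (gap/nick) activity, so gap-borne damage survives it;
* ``none`` — mock treatment.

Enzyme "units" map to probabilities through a saturating dose-response
``p_max * (1 - exp(-units/units_scale))`` — monotone non-decreasing and
bounded by 1; no biochemical kinetics are implied.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dna import COMPLEMENT
from .fragments import (
    END_LEFT,
    END_RIGHT,
    DuplexFragment,
    OverhangSpec,
    blunt,
)


@dataclass(frozen=True)
class NucleaseModel:
    name: str
    p_overhang_max: float = 0.0
    p_gap_max: float = 0.0
    p_nick_max: float = 0.0
    units_scale: float = 5.0
    directionality: str = "endo"  # "endo" | "exo5to3"
    end_bias: dict[str, float] | None = None
    end_bias_window: int = 3

    def __post_init__(self) -> None:
        for p in (self.p_overhang_max, self.p_gap_max, self.p_nick_max):
            if not 0.0 <= p <= 1.0:
                raise ValueError("activity maxima must be in [0, 1]")
        if self.directionality == "exo5to3" and (self.p_gap_max > 0 or self.p_nick_max > 0):
            raise ValueError("a 5'->3' SS exonuclease has no gap/nick activity")

    def _activity(self, p_max: float, units: float) -> float:
        if units <= 0 or p_max <= 0:
            return 0.0
        return p_max * (1.0 - math.exp(-units / self.units_scale))

    def p_overhang(self, units: float) -> float:
        return self._activity(self.p_overhang_max, units)

    def p_gap(self, units: float) -> float:
        return self._activity(self.p_gap_max, units)

    def p_nick(self, units: float) -> float:
        return self._activity(self.p_nick_max, units)


S1 = NucleaseModel(
    "s1", p_overhang_max=1.0, p_gap_max=1.0, p_nick_max=0.9,
    end_bias={"A": 1.0, "C": 1.0, "G": 3.0, "T": 1.0},
)
MBN = NucleaseModel(
    "mbn", p_overhang_max=1.0, p_gap_max=1.0, p_nick_max=0.2,
    end_bias={"A": 1.0, "C": 2.0, "G": 2.0, "T": 1.0},
)
RECJF = NucleaseModel("recjf", p_overhang_max=1.0, directionality="exo5to3")
NONE = NucleaseModel("none")

MODELS = {"s1": S1, "mbn": MBN, "recjf": RECJF, "none": NONE}


def get_model(name: str) -> NucleaseModel:
    try:
        return MODELS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown nuclease model {name!r}; choose from {sorted(MODELS)}") from None


def _bias_trim(model: NucleaseModel, genome, seed: int, boundary: int, left_end: bool) -> int:
    """Extra bases trimmed at a cut end so the new 5' terminal base follows
    the enzyme's sequence preference.

    Seeded per cut location so that, under common random numbers, the same
    cut trims identically regardless of what happened elsewhere.
    """
    if not model.end_bias:
        return 0
    w = model.end_bias_window
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), boundary, 2 if left_end else 3, 0x61A5])
    )
    weights = []
    for t in range(w + 1):
        if left_end:
            base = genome.sequence[boundary + t] if boundary + t < genome.length else "A"
        else:
            pos = boundary - 1 - t
            base = COMPLEMENT[genome.sequence[pos]] if pos >= 0 else "A"
        weights.append(model.end_bias.get(base, 1.0))
    probs = np.asarray(weights) / sum(weights)
    return int(rng.choice(w + 1, p=probs))


def digest_nuclease(
    fragment: DuplexFragment,
    model: NucleaseModel,
    units: float,
    genome,
    seed: int,
    *,
    min_length: int = 50,
    nick_window: int = 2,
) -> list[DuplexFragment]:
    """Digest one fragment; returns 0..k product fragments.

    Overhang excision discards the overhang (and its lesions); gap
    cleavage removes the gap span and splits the molecule; nick cleavage
    (endonucleases only) splits at the nick and excises its breathing
    window. Products shorter than ``min_length`` are dropped. Decisions
    are driven by per-fragment seeded uniforms drawn in a fixed order, so
    survival is monotone non-increasing in ``units`` at fixed seed.
    """
    if fragment.repaired:
        raise ValueError("digestion must precede end repair")
    if model.name == "none" or units <= 0:
        return [fragment]
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), int(fragment.root_id), 0xD16])
    )
    p_oh, p_gap, p_nick = model.p_overhang(units), model.p_gap(units), model.p_nick(units)
    endo = model.directionality == "endo"

    def cuttable(oh: OverhangSpec) -> bool:
        if oh.kind == "blunt":
            return False
        return endo or oh.kind == "five_prime"

    # fixed draw order: left overhang, right overhang, gaps, nicks
    cut_left = cuttable(fragment.overhang_left) and rng.random() < p_oh
    cut_right = cuttable(fragment.overhang_right) and rng.random() < p_oh
    removed: list[tuple[int, int]] = []  # spans whose bases/lesions are destroyed
    cut_nick_spans: list[tuple[int, int]] = []
    for gap in fragment.gaps:
        if endo and rng.random() < p_gap:
            removed.append((gap.start, gap.end))
    for nick in fragment.nicks:
        if endo and rng.random() < p_nick:
            if nick.strand == "+":
                span = (nick.position, min(nick.position + nick_window, fragment.core_end))
            else:
                span = (max(nick.position - nick_window, fragment.core_start), nick.position)
            removed.append(span if span[1] > span[0] else (nick.position, nick.position))
            cut_nick_spans.append((nick.position, nick.position))

    left_bound = fragment.genome_start
    new_left_oh = fragment.overhang_left
    if cut_left:
        left_bound = fragment.core_start + _bias_trim(model, genome, seed, fragment.core_start, True)
        new_left_oh = blunt(END_LEFT)
    right_bound = fragment.genome_end
    new_right_oh = fragment.overhang_right
    if cut_right:
        right_bound = fragment.core_end - _bias_trim(model, genome, seed, fragment.core_end, False)
        new_right_oh = blunt(END_RIGHT)

    # merge removed spans and build segments between them
    spans = sorted(s for s in removed if s[0] < right_bound and s[1] > left_bound)
    merged: list[list[int]] = []
    for a, b in spans:
        a, b = max(a, left_bound), min(b, right_bound)
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    boundaries: list[tuple[int, int]] = []
    cur = left_bound
    for a, b in merged:
        boundaries.append((cur, a))
        cur = b
    boundaries.append((cur, right_bound))
    n_seg = len(boundaries)

    destroyed = merged

    def destroyed_at(pos: int) -> bool:
        return any(a <= pos < b or (a == b == pos) for a, b in destroyed)

    products: list[DuplexFragment] = []
    emitted = 0
    for i, (a, b) in enumerate(boundaries):
        if b - a < min_length:
            continue
        is_first, is_last = i == 0, i == n_seg - 1
        oh_l = new_left_oh if is_first else blunt(END_LEFT)
        oh_r = new_right_oh if is_last else blunt(END_RIGHT)
        # interior cut ends get the enzyme's terminal-base preference too
        seg_a, seg_b = a, b
        if not is_first and model.end_bias:
            seg_a = a + _bias_trim(model, genome, seed, a, True)
        if not is_last and model.end_bias:
            seg_b = b - _bias_trim(model, genome, seed, b, False)
        if seg_b - seg_a < min_length:
            continue
        core_a, core_b = seg_a + oh_l.length, seg_b - oh_r.length
        nicks = [n for n in fragment.nicks
                 if core_a < n.position < core_b and not any(x == n.position for x, _ in cut_nick_spans)
                 and not destroyed_at(n.position)]
        gaps = [g for g in fragment.gaps if core_a < g.start and g.end < core_b
                and not destroyed_at(g.start)]
        lesions = [l for l in fragment.lesions if seg_a <= l.position < seg_b
                   and not destroyed_at(l.position)
                   and _lesion_survives(l, oh_l, oh_r, seg_a, seg_b, fragment)]
        ds_dam = [d for d in fragment.ds_damage if seg_a <= d.position < seg_b
                  and not destroyed_at(d.position)]
        mol_id = fragment.molecule_id if n_seg == 1 else f"{fragment.molecule_id}.{emitted}"
        products.append(
            replace(
                fragment,
                genome_start=seg_a,
                genome_end=seg_b,
                molecule_id=mol_id,
                overhang_left=oh_l,
                overhang_right=oh_r,
                nicks=nicks,
                gaps=gaps,
                lesions=lesions,
                ds_damage=ds_dam,
            )
        )
        emitted += 1
    return products


def _lesion_survives(lesion, oh_l, oh_r, seg_a, seg_b, original: DuplexFragment) -> bool:
    """Overhang lesions survive only if their overhang still exists on the
    product fragment (same end, position still within the overhang span)."""
    if lesion.region_kind != "overhang":
        return True
    if oh_l.kind != "blunt" and seg_a <= lesion.position < seg_a + oh_l.length:
        return True
    if oh_r.kind != "blunt" and seg_b - oh_r.length <= lesion.position < seg_b:
        return True
    return False
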