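"""End repair: the step that fixes SS damage into both strands.

Library preparation blunts every fragment: 5' overhangs and gaps are
filled in by a polymerase using the existing (possibly damaged) strand
as template, nicks are sealed after nick translation, and 3' overhangs
are chewed back. A lesion that served as template is thereby converted
into a CONCORDANT duplex substitution — both strands now agree on the
wrong base, which duplex consensus can no longer reject. Lesions on 3'
overhangs are simply removed with the overhang.

Strand-discordant damage in the double-stranded core is untouched and
stays discordant.
"""
from __future__ import annotations

from dataclasses import replace

from .dna import COMPLEMENT
from .fragments import END_LEFT, END_RIGHT, ConcordantSub, DuplexFragment, blunt
from .damage import DamageParams


def end_repair(fragment: DuplexFragment, genome, params: DamageParams) -> DuplexFragment:
    """Return the blunt, nick-free repaired duplex.

    The output fragment has empty overhang/nick/gap/lesion lists; every
    surviving 5'-overhang, gap or nick-window lesion reappears in
    ``concordant_subs`` with the substitution given by the manifestation
    map (oxoG→T, Iz→C, deamC→T on the damaged strand).
    """
    if fragment.repaired:
        return fragment
    new_start, new_end = fragment.genome_start, fragment.genome_end
    if fragment.overhang_left.kind == "three_prime":
        new_start += fragment.overhang_left.length
    if fragment.overhang_right.kind == "three_prime":
        new_end -= fragment.overhang_right.length

    subs: list[ConcordantSub] = list(fragment.concordant_subs)
    for lesion in fragment.lesions:
        if not new_start <= lesion.position < new_end:
            continue  # chewed back with a 3' overhang
        if lesion.region_kind == "overhang":
            # 3'-overhang lesions sit outside [new_start, new_end) by
            # construction; anything still inside was on a 5' overhang.
            oh_l, oh_r = fragment.overhang_left, fragment.overhang_right
            on_left = oh_l.kind == "five_prime" and lesion.position < fragment.genome_start + oh_l.length
            on_right = oh_r.kind == "five_prime" and lesion.position >= fragment.genome_end - oh_r.length
            if not (on_left or on_right):
                continue
        alt = params.manifestation[lesion.lesion]
        strand, ref = lesion.strand, lesion.original_base
        if params.frame_rule == "reference" and strand == "-":
            strand, ref, alt = "+", COMPLEMENT[ref], COMPLEMENT[alt]
        subs.append(
            ConcordantSub(
                position=lesion.position,
                strand=strand,
                ref=ref,
                alt=alt,
                provenance=f"ss_{lesion.region_kind}:{lesion.lesion}",
            )
        )
    ds_damage = [d for d in fragment.ds_damage if new_start <= d.position < new_end]
    return replace(
        fragment,
        genome_start=new_start,
        genome_end=new_end,
        overhang_left=blunt(END_LEFT),
        overhang_right=blunt(END_RIGHT),
        nicks=[],
        gaps=[],
        lesions=[],
        ds_damage=ds_damage,
        concordant_subs=subs,
        repaired=True,
    )


def end_repair_all(fragments, genome, params: DamageParams):
    return [end_repair(f, genome, params) for f in fragments]
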