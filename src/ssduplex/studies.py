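"""Canned desk-scale study designs mirroring the wet-lab comparisons.

Each function runs one self-contained simulation experiment at its
standard conditions and returns plain numbers. The conditions — 10^4
fragments with a 350 bp peak, geometric mean-8 bp overhangs, a 2% per-G
lesion rate in SS regions, 2 x 100 bp reads with zero-truncated
geometric (mean 3) duplicates — are the package defaults; experiment
functions only override what their design requires.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .config import SimConfig
from .consensus import call_consensus, group_spg, records_from_library
from .covqc import coverage_summary, effective_coordinate_space, misassignment_report
from .pipeline import simulate
from .spectrum import count_substitutions, frequencies
from .truth import artifact_recovery, dcs_mismatch_stats, raw_read_mismatch_rate


def mechanism_study(seed: int) -> dict:
    """End-repair artifact mechanism and the read-clipping counter-measure.

    One untreated library at default conditions; the fragment-frame
    G>T / C>A asymmetry is measured at clip 0, and planted-artifact
    yield at clip 0/10/20.
    """
    res = simulate(SimConfig(), seed)
    dcs = call_consensus(records_from_library(res.library))
    out: dict = {"n_fragments": len(res.fragments)}
    tv = res.library.truth_variants
    for clip in (0, 10, 20):
        c = count_substitutions(dcs, res.genome, frame="fragment", clip=clip)
        f = frequencies(c)
        out[f"freq_gt_clip{clip}"] = f.freq12["G>T"]
        out[f"freq_ca_clip{clip}"] = f.freq12["C>A"]
        out[f"artifact_calls_clip{clip}"] = artifact_recovery(dcs, tv, clip=clip).n_called
        out[f"gap_artifact_calls_clip{clip}"] = artifact_recovery(
            dcs, tv, provenance_prefix="ss_gap", clip=clip
        ).n_called
    out["gt_ca_ratio_clip0"] = out["freq_gt_clip0"] / max(out["freq_ca_clip0"], 1e-12)
    ov = artifact_recovery(dcs, tv, provenance_prefix="ss_overhang")
    out["overhang_call_rate"] = ov.call_rate
    out["overhang_planted"] = ov.n_planted
    return out


def nuclease_study(seed: int, saturating_units: float = 1000.0) -> dict:
    """SSN digestion head-to-head: untreated vs saturating S1-model vs
    RecJf-model, on the same fragment pool (common random numbers).

    Also reports genome-coverage robustness between the digested and
    undigested libraries at matched molecule sampling.
    """
    out: dict = {}
    per_model: dict[str, dict] = {}
    for model, units in (("none", 0.0), ("s1", saturating_units), ("recjf", saturating_units)):
        cfg = SimConfig()
        cfg.nuclease.model = model
        cfg.nuclease.units = units
        res = simulate(cfg, seed)
        dcs = call_consensus(records_from_library(res.library))
        counts = count_substitutions(dcs, res.genome, frame="fragment")
        cov = coverage_summary(dcs, res.genome.length, n_bins=1000)
        per_model[model] = dict(
            artifact_calls=artifact_recovery(dcs, res.library.truth_variants).n_called,
            gt=counts.counts["G>T"], ca=counts.counts["C>A"],
            den_g=counts.denominators["G"], den_c=counts.denominators["C"],
            covered_rate=cov.covered_rate, cv=cov.cv,
        )
    base = per_model["none"]["artifact_calls"]
    out["artifact_calls_untreated"] = base
    out["artifact_calls_s1"] = per_model["s1"]["artifact_calls"]
    out["artifact_calls_recjf"] = per_model["recjf"]["artifact_calls"]
    out["s1_removal_fraction"] = 1.0 - per_model["s1"]["artifact_calls"] / max(base, 1)
    out["recjf_removal_fraction"] = 1.0 - per_model["recjf"]["artifact_calls"] / max(base, 1)
    # are G>T and C>A equal after S1 digestion, within a 95% binomial CI?
    s1 = per_model["s1"]
    n, p = s1["gt"] + s1["ca"], s1["den_g"] / (s1["den_g"] + s1["den_c"])
    lo, hi = (0, 0) if n == 0 else binom.interval(0.95, n, p)
    out["s1_gt_count"], out["s1_ca_count"] = s1["gt"], s1["ca"]
    out["s1_gt_within_binomial_ci"] = bool(lo <= s1["gt"] <= hi)
    out["delta_covered_rate"] = abs(per_model["s1"]["covered_rate"] - per_model["none"]["covered_rate"])
    out["delta_cv"] = abs(per_model["s1"]["cv"] - per_model["none"]["cv"])
    return out


def suppression_study(seed: int) -> dict:
    """Duplex error suppression under strand-discordant noise only.

    Sequencing errors at 1e-2/base, PCR errors at 1e-3/base/copy, family
    mean 3, no SS damage; fragments average 160 bp so 100 bp mates tile
    them. The dsDCS mismatch rate is compared against the raw reads.
    """
    cfg = SimConfig()
    cfg.shear.size_mean, cfg.shear.size_sd = 160.0, 15.0
    cfg.shear.overhang_len_dist = "constant"
    cfg.shear.overhang_len_mean = 0
    cfg.shear.nick_rate = cfg.shear.gap_rate = 0.0
    cfg.damage.p_oxog_ss = cfg.damage.p_iz_ss = cfg.damage.p_deamc_ss = 0.0
    cfg.library.seq_error_rate = 1e-2
    cfg.library.pcr_error_rate = 1e-3
    res = simulate(cfg, seed)
    raw = raw_read_mismatch_rate(res.library, res.genome)
    dcs = call_consensus(records_from_library(res.library))
    mism, total = dcs_mismatch_stats(dcs, res.genome)
    rate = mism / total if total else float("nan")
    return dict(
        raw_mismatch_rate=raw,
        dcs_mismatch_rate=rate,
        dcs_mismatches=mism,
        dcs_bases=total,
        fold_reduction=raw / rate if rate > 0 else float("inf"),
    )


MISASSIGNMENT_AMOUNTS = (20.0, 39.0, 78.0, 156.0)


def misassignment_study(seed: int) -> dict:
    """SP-G multi-molecule rate vs amount of ligated product.

    A deliberately small coordinate space (4 kb genome, 120 +- 15 bp
    fragments, 100 molecules per relative amount unit) makes collisions
    countable at desk scale; the truth-based rate is compared with the
    birthday-style closed form over the same coordinate space.
    """
    out: dict = {"amounts": list(MISASSIGNMENT_AMOUNTS)}
    rates, analytic = [], []
    n_coords = effective_coordinate_space(4000, 120.0, 15.0)
    for amount in MISASSIGNMENT_AMOUNTS:
        cfg = SimConfig()
        cfg.genome.length = 4000
        cfg.shear.n_fragments = 16_000
        cfg.shear.size_mean, cfg.shear.size_sd = 120.0, 15.0
        cfg.shear.overhang_len_dist = "constant"
        cfg.shear.overhang_len_mean = 0
        cfg.shear.nick_rate = cfg.shear.gap_rate = 0.0
        cfg.damage.p_oxog_ss = cfg.damage.p_iz_ss = cfg.damage.p_deamc_ss = 0.0
        cfg.library.seq_error_rate = cfg.library.pcr_error_rate = 0.0
        cfg.library.duplicate_dist = "constant"
        cfg.library.duplicate_mean = 1
        cfg.library.ligated_amount = amount
        res = simulate(cfg, seed)
        groups = group_spg(records_from_library(res.library))
        rep = misassignment_report(groups, k=len(res.library.truth_molecules), n_coords=n_coords)
        rates.append(rep.rate)
        analytic.append(rep.analytic_estimate)
    out["rates"] = rates
    out["analytic"] = analytic
    out["n_coords"] = n_coords
    return out
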