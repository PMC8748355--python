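"""Duplex consensus: what it removes and what it cannot remove.

Runs two simulations — one with only strand-discordant noise (sequencing
and PCR errors), one with SS end-repair damage — and shows that duplex
consensus crushes the former but passes the latter through as confident
mutation calls.
"""
import ssduplex as sx
from ssduplex.truth import artifact_recovery, dcs_mismatch_stats, raw_read_mismatch_rate

# --- discordant noise only -------------------------------------------------
cfg = sx.SimConfig()
cfg.genome.length = 50_000
cfg.shear.n_fragments = 3000
cfg.shear.size_mean, cfg.shear.size_sd = 160, 15
cfg.shear.overhang_len_dist = "constant"
cfg.shear.overhang_len_mean = 0
cfg.shear.nick_rate = cfg.shear.gap_rate = 0.0
cfg.damage.p_oxog_ss = cfg.damage.p_iz_ss = cfg.damage.p_deamc_ss = 0.0
cfg.library.seq_error_rate = 1e-2
cfg.library.pcr_error_rate = 1e-3
res = sx.simulate(cfg, seed=2)
dcs = sx.call_consensus(sx.records_from_library(res.library))
raw = raw_read_mismatch_rate(res.library, res.genome)
mism, total = dcs_mismatch_stats(dcs, res.genome)
print(f"discordant noise: raw reads {raw:.2%} mismatches "
      f"-> dsDCS {mism}/{total} = {mism / total:.2e} ({raw / (mism / total + 1e-12):.0f}x lower)")

# --- SS end-repair damage --------------------------------------------------
cfg2 = sx.SimConfig()
cfg2.genome.length = 50_000
cfg2.shear.n_fragments = 3000
res2 = sx.simulate(cfg2, seed=2)
dcs2 = sx.call_consensus(sx.records_from_library(res2.library))
ar = artifact_recovery(dcs2, res2.library.truth_variants, provenance_prefix="ss_overhang")
print(f"SS overhang artifacts: {ar.n_planted} planted, {ar.n_called} called "
      f"({ar.call_rate:.0%}) — end repair made them concordant, so duplex "
      "consensus cannot reject them")
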