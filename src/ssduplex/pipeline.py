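"""End-to-end orchestration: simulate → consensus → spectrum → covqc.

`run_experiment` sweeps a condition grid (nuclease model × units ×
ligated amount × replicate) the way the wet-lab comparison was laid out:
every condition within a replicate shares the same sheared, damaged
fragment pool (common random numbers), so differences between grid cells
are attributable to the treatment, not to resampling noise.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, SimConfig
from .consensus import DuplexConsensusPair, call_consensus, records_from_library
from .covqc import CoverageSummary, coverage_summary
from .damage import apply_ss_damage_all
from .genome import ReferenceGenome, make_genome, write_fasta
from .library import LibraryOutput, sample_and_sequence
from .nuclease import digest_nuclease, get_model
from .repair import end_repair_all
from .fragments import shear_fragments
from .spectrum import SpectrumTable, compare_groups, count_substitutions, frequencies, load_bed_mask

log = logging.getLogger("ssduplex")


def derive_seed(global_seed: int, *path: int) -> int:
    """Stable per-stage/per-cell seed below 2^31."""
    ss = np.random.SeedSequence([int(global_seed), *[int(p) for p in path]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def atomic_write_df(df: pd.DataFrame, path: str, **kwargs) -> str:
    tmp = path + ".tmp"
    df.to_csv(tmp, sep="\t", index=False, **kwargs)
    os.replace(tmp, path)
    return path


def atomic_write_text(text: str, path: str) -> str:
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)
    return path


@dataclass
class SimResult:
    genome: ReferenceGenome
    fragments: list  # end-repaired molecules entering the library
    library: LibraryOutput


def simulate(cfg: SimConfig, seed: int) -> SimResult:
    """Run the full molecule-level simulation for one condition."""
    genome = make_genome(cfg.genome.length, cfg.genome.gc, seed, name=cfg.genome.name)
    frags = shear_fragments(
        genome,
        cfg.shear.n_fragments,
        size_mean=cfg.shear.size_mean,
        size_sd=cfg.shear.size_sd,
        overhang_len_dist=cfg.shear.overhang_dist(),
        end_kind_probs=cfg.shear.end_kind_probs,
        nick_rate=cfg.shear.nick_rate,
        gap_rate=cfg.shear.gap_rate,
        gap_len_mean=cfg.shear.gap_len_mean,
        min_length=cfg.shear.min_length,
        seed=seed,
    )
    damage_params = cfg.damage.to_params()
    frags = apply_ss_damage_all(frags, genome, damage_params, seed)
    model = get_model(cfg.nuclease.model)
    digested = []
    for f in frags:
        digested.extend(
            digest_nuclease(
                f, model, cfg.nuclease.units, genome, seed,
                min_length=cfg.shear.min_length, nick_window=cfg.damage.nick_window,
            )
        )
    repaired = end_repair_all(digested, genome, damage_params)
    library = sample_and_sequence(repaired, genome, cfg.library.to_params(), seed)
    return SimResult(genome=genome, fragments=repaired, library=library)


@dataclass
class CellResult:
    label: str
    sim: SimResult
    dcs: list[DuplexConsensusPair]
    spectrum: SpectrumTable
    coverage: CoverageSummary


def run_cell(config: RunConfig, sim_cfg: SimConfig, seed: int, label: str, replicate: int = 0) -> CellResult:
    sim = simulate(sim_cfg, seed)
    records = records_from_library(sim.library)
    dcs = call_consensus(
        records,
        min_family_size=config.consensus.min_family_size,
        agreement_threshold=config.consensus.agreement_threshold,
    )
    mask = load_bed_mask(config.spectrum.mask_bed) if config.spectrum.mask_bed else None
    counts = count_substitutions(
        dcs, sim.genome, frame=config.spectrum.frame, clip=config.spectrum.clip, mask=mask
    )
    spec = frequencies(counts, label=label, replicate=replicate)
    cov = coverage_summary(dcs, sim.genome.length, n_bins=min(config.covqc.n_bins, sim.genome.length))
    return CellResult(label=label, sim=sim, dcs=dcs, spectrum=spec, coverage=cov)


def run_experiment(config: RunConfig, outdir: str | None = None) -> dict:
    """Sweep the experiment grid; returns (and optionally writes) a long
    frequency table plus per-condition comparisons against the untreated
    control at matching ligated amount."""
    outdir = outdir or config.outdir
    os.makedirs(outdir, exist_ok=True)
    cfg_yaml = config.to_yaml()
    log.info(
        "experiment start: config_sha256=%s seed=%d version=%s",
        hashlib.sha256(cfg_yaml.encode()).hexdigest()[:12], config.seed, __version__,
    )
    grid = []
    exp = config.experiment
    for model in exp.nucleases:
        for units in exp.units:
            if model == "none" and units > 0:
                continue
            for amount in exp.ligated_amounts:
                grid.append((model, units, amount))
    spectra: dict[tuple, list[SpectrumTable]] = {}
    freq_rows = []
    cov_rows = []
    for ci, (model, units, amount) in enumerate(grid):
        for rep in range(exp.replicates):
            sim_cfg = config.sim.model_copy(deep=True)
            sim_cfg.nuclease.model = model
            sim_cfg.nuclease.units = units
            sim_cfg.library.ligated_amount = amount
            # the seed depends on the replicate only: conditions within a
            # replicate share fragments and differ only by treatment
            seed = derive_seed(config.seed, rep)
            label = f"{model}_u{units:g}_a{'all' if amount is None else amount:}"
            cell = run_cell(config, sim_cfg, seed, label, replicate=rep)
            spectra.setdefault((model, units, amount), []).append(cell.spectrum)
            df = cell.spectrum.to_frame()
            df.insert(0, "nuclease", model)
            df.insert(1, "units", units)
            df.insert(2, "ligated_amount", np.nan if amount is None else amount)
            freq_rows.append(df)
            cov_rows.append(
                dict(nuclease=model, units=units,
                     ligated_amount=np.nan if amount is None else amount, replicate=rep,
                     **cell.coverage.to_dict())
            )
    freq_table = pd.concat(freq_rows, ignore_index=True)
    cov_table = pd.DataFrame(cov_rows)
    comparisons = []
    controls = {key: tabs for key, tabs in spectra.items() if key[1] == 0}
    for key, tabs in spectra.items():
        if key[1] == 0 or len(tabs) < 2:
            continue
        ctrl = None
        for (cm, cu, ca), ctabs in controls.items():
            if ca == key[2] and len(ctabs) >= 2:
                ctrl = ctabs
                break
        if ctrl is None:
            continue
        comp = compare_groups(
            tabs, ctrl, test="ttest",
            pseudocount_freq=config.spectrum.pseudocount_freq, which=config.spectrum.which,
        )
        df = comp.table.drop(columns=["group"])
        df.insert(0, "nuclease", key[0])
        df.insert(1, "units", key[1])
        df.insert(2, "ligated_amount", np.nan if key[2] is None else key[2])
        comparisons.append(df)
    comp_table = pd.concat(comparisons, ignore_index=True) if comparisons else pd.DataFrame()
    atomic_write_df(freq_table, os.path.join(outdir, "frequencies.tsv"), float_format="%.6g")
    atomic_write_df(cov_table, os.path.join(outdir, "coverage.tsv"), float_format="%.6g")
    if len(comp_table):
        atomic_write_df(comp_table, os.path.join(outdir, "comparisons.tsv"), float_format="%.6g")
    atomic_write_text(cfg_yaml, os.path.join(outdir, "config_echo.yaml"))
    return {"frequencies": freq_table, "coverage": cov_table, "comparisons": comp_table}


def write_simulation(sim: SimResult, outdir: str, prefix: str = "sim") -> dict:
    """Materialise a simulation on disk: FASTA genome, paired FASTQ,
    truth SAM and truth tables."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    paths["genome"] = os.path.join(outdir, f"{prefix}.genome.fa")
    write_fasta(sim.genome, paths["genome"])
    r1, r2 = sim.library.write_fastq(os.path.join(outdir, prefix))
    paths["fastq_r1"], paths["fastq_r2"] = r1, r2
    paths["sam"] = sim.library.write_sam(os.path.join(outdir, f"{prefix}.truth.sam"))
    tv, tm = sim.library.write_truth(os.path.join(outdir, prefix))
    paths["truth_variants"], paths["truth_molecules"] = tv, tm
    return paths
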