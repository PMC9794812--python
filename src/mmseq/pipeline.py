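"""End-to-end orchestration: simulate -> count -> call -> annotate.

Each run writes its outputs plus a JSON manifest recording the parameters,
the seed, SHA-256 checksums of inputs and outputs, and the package version,
so a run is reproducible and verifiable byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Dict

from . import __version__
from .core import MethylationTruth, MotifRule
from .io_formats import (
    read_fasta,
    read_regions_bed,
    read_tss,
    write_alignments,
    write_fasta,
    write_truth_bed,
)
from .simdata import (
    SimConfig,
    plant_methylation,
    simulate_fragments_endo,
    simulate_fragments_exo,
    simulate_genome,
    simulate_wga,
)
from .site_caller import (
    CallerConfig,
    call_sites,
    filter_blacklist,
    write_calls_bed,
    write_calls_tsv,
)
from .terminal_model import count_terminals, dedup_alignments, estimate_background
from .annotate import motif_summary, sites_in_regions, tss_profile

__all__ = ["PipelineConfig", "run_pipeline", "sha256_of"]

# fixed per-stage seed derivation from the single run seed
_STAGE_OFFSETS = {"genome": 0, "truth": 1, "fragments": 2}
_SEED_MOD = 2**31


def stage_seed(seed: int, stage: str) -> int:
    return (seed + _STAGE_OFFSETS[stage]) % _SEED_MOD


def sha256_of(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineConfig(dict):
    """Dict-backed pipeline configuration with defaults.

    Recognized keys: mode, seed, out_dir, genome (path or None), n_contigs,
    contig_length, gc, motif, methyl_offset, both_strands, fraction,
    n_fragments, capture_prob, frag_len_mean, frag_len_sd, endo_cut_offset,
    coverage_cutoff, alpha, correction, require_A, blacklist, peaks, tss,
    tss_format, flank.
    """

    DEFAULTS = dict(
        mode="endo",
        seed=0,
        genome=None,
        n_contigs=1,
        contig_length=100_000,
        gc=0.5,
        motif="GATC",
        methyl_offset=1,
        both_strands=True,
        fraction=1.0,
        n_fragments=20_000,
        capture_prob=0.3,
        frag_len_mean=150,
        frag_len_sd=30,
        endo_cut_offset=0,
        coverage_cutoff=5,
        alpha=0.01,
        correction="bonferroni",
        require_A=True,
        blacklist=None,
        peaks=None,
        tss=None,
        tss_format="tsv",
        flank=5,
    )

    def __init__(self, **kwargs):
        merged = dict(self.DEFAULTS)
        unknown = set(kwargs) - set(self.DEFAULTS) - {"out_dir"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged.update({k: v for k, v in kwargs.items() if v is not None})
        super().__init__(**merged)


def run_pipeline(cfg: PipelineConfig, out_dir: str, force: bool = False) -> Dict:
    """Run simulate -> dedup -> count -> call -> annotate; return the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "seed": cfg["seed"],
        "parameters": {k: v for k, v in cfg.items()},
        "inputs": {},
        "outputs": {},
    }

    def out_path(name: str) -> str:
        path = os.path.join(out_dir, name)
        if os.path.exists(path) and not force:
            raise FileExistsError(f"{path} exists; use force to overwrite")
        return path

    # --- simulate -----------------------------------------------------------
    if cfg["genome"]:
        genome = read_fasta(cfg["genome"])
        manifest["inputs"][cfg["genome"]] = sha256_of(cfg["genome"])
    else:
        genome = simulate_genome(
            cfg["n_contigs"], cfg["contig_length"], cfg["gc"], stage_seed(cfg["seed"], "genome")
        )
    rule = MotifRule(cfg["motif"], cfg["motif"], cfg["methyl_offset"], cfg["both_strands"])
    mode = cfg["mode"]
    if mode == "wga":
        truth = MethylationTruth()
    else:
        truth = plant_methylation(
            genome, rule, cfg["fraction"], stage_seed(cfg["seed"], "truth")
        )
    sim = SimConfig(
        n_fragments=cfg["n_fragments"],
        capture_prob=cfg["capture_prob"],
        frag_len_mean=cfg["frag_len_mean"],
        frag_len_sd=cfg["frag_len_sd"],
        endo_cut_offset=cfg["endo_cut_offset"],
        seed=stage_seed(cfg["seed"], "fragments"),
    )
    if mode == "endo":
        alignments = simulate_fragments_endo(genome, truth, sim)
    elif mode == "exo":
        alignments = simulate_fragments_exo(genome, truth, sim)
    elif mode == "wga":
        alignments = simulate_wga(genome, sim)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    genome_path = out_path("genome.fasta")
    write_fasta(genome, genome_path)
    truth_path = out_path("truth.bed")
    write_truth_bed(truth, truth_path, motif_name=rule.name)
    aln_path = out_path("alignments.tsv")
    write_alignments(alignments, aln_path)

    # --- count + call -------------------------------------------------------
    count_mode = "endo" if mode == "wga" else mode
    deduped = dedup_alignments(alignments)
    counts = count_terminals(deduped, count_mode, genome)
    counts_path = out_path("counts.tsv")
    counts.write_tsv(counts_path)
    bg = estimate_background(counts)
    caller = CallerConfig(
        coverage_cutoff=cfg["coverage_cutoff"],
        alpha=cfg["alpha"],
        correction=cfg["correction"],
        require_A=cfg["require_A"],
    )
    calls = call_sites(counts, bg, genome, caller)
    if cfg["blacklist"]:
        manifest["inputs"][cfg["blacklist"]] = sha256_of(cfg["blacklist"])
        calls = filter_blacklist(calls, read_regions_bed(cfg["blacklist"]))
    calls_tsv = out_path("calls.tsv")
    write_calls_tsv(calls, calls_tsv)
    calls_bed = out_path("calls.bed")
    write_calls_bed(calls, calls_bed)
    manifest["background_p0"] = bg.p0
    manifest["n_passed"] = sum(c.passed for c in calls)

    # --- annotate -----------------------------------------------------------
    summary = motif_summary(calls, genome, [rule], flank=cfg["flank"])
    annot: Dict = {
        "motif_fraction_matching": summary.fraction_matching,
        "motif_total_sites": summary.total_sites,
        "base_freq": summary.base_freq.tolist(),
    }
    if cfg["peaks"]:
        manifest["inputs"][cfg["peaks"]] = sha256_of(cfg["peaks"])
        ov = sites_in_regions(calls, read_regions_bed(cfg["peaks"]))
        annot["fraction_in_peaks"] = ov.jaccard
    if cfg["tss"]:
        manifest["inputs"][cfg["tss"]] = sha256_of(cfg["tss"])
        profile = tss_profile(calls, read_tss(cfg["tss"], cfg["tss_format"]))
        annot["tss_dominant_period"] = profile.dominant_period
        annot["tss_period_score"] = profile.period_score
    annot_path = out_path("annotation.json")
    with open(annot_path, "w") as fh:
        json.dump(annot, fh, indent=2)

    for path in (genome_path, truth_path, aln_path, counts_path, calls_tsv, calls_bed, annot_path):
        manifest["outputs"][os.path.basename(path)] = sha256_of(path)
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
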