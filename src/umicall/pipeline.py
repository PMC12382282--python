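"""End-to-end monitoring pipeline on simulated or loaded data.

Chains the stages: simulate (or load) reads -> UMI consensus collapsing ->
per-stratum pileups -> background error calibration -> monitored-variant
calling -> panel-aggregate MRD test -> benchmark against truth.  All
artefacts can be written with stable names for the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io
from .calling import CallerConfig, VariantCall, call_monitored
from .consensus import ConsensusParams, ConsensusRead, collapse_all
from .error_model import ErrorModel, Pileups, build_pileups, estimate_background
from .evaluation import BenchmarkReport, build_benchmark
from .mrd import DEFAULT_FLANK_BP, MrdResult, mrd_from_calls
from .simulator import SimConfig, SimResult, simulate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """One self-contained simulated monitoring experiment."""

    sim: SimConfig = SimConfig()
    consensus: ConsensusParams = ConsensusParams()
    caller: CallerConfig = CallerConfig()
    flank_bp: int = DEFAULT_FLANK_BP
    mrd_alpha: float = 0.05
    outlier_k_sd: float = 3.0
    min_base_quality: int = 0
    run_benchmark: bool = True


@dataclass
class PipelineResult:
    params: PipelineParams
    sim: SimResult
    consensus_reads: list
    consensus_summary: pd.DataFrame
    pileups: Pileups
    model: ErrorModel
    calls: list
    call_summary: dict
    mrd: MrdResult
    benchmark: Optional[BenchmarkReport]


def run_simulated_pipeline(params: PipelineParams = PipelineParams()
                           ) -> PipelineResult:
    """Simulate a sample and push it through every analysis stage."""
    sim = simulate(params.sim)
    logger.info("stage consensus: collapsing %d reads", len(sim.reads))
    consensus_reads, summary = collapse_all(sim.reads, params.consensus)
    reference = {params.sim.chrom: sim.reference}
    regions = [(params.sim.chrom, s, e) for s, e in sim.targets]
    logger.info("stage pileup: %d consensus reads", len(consensus_reads))
    pileups = build_pileups(consensus_reads, reference, regions,
                            min_base_quality=params.min_base_quality,
                            flank_bp=params.flank_bp)
    monitored = [(s.chrom, s.pos) for s in sim.sites]
    model = estimate_background(pileups, exclude_positions=monitored)
    calls, call_summary = call_monitored(sim.sites, pileups, model,
                                         params.caller)
    mrd = mrd_from_calls(calls, pileups, flank_bp=params.flank_bp,
                         alpha=params.mrd_alpha, k_sd=params.outlier_k_sd,
                         included_strata=params.caller.included_strata)
    benchmark = None
    if params.run_benchmark:
        benchmark = build_benchmark(
            consensus_reads, reference, sim.sites, calls,
            input_molecules_per_site=params.sim.input_genome_equivalents)
    return PipelineResult(params, sim, consensus_reads, summary, pileups,
                          model, calls, call_summary, mrd, benchmark)


def write_artifacts(result: PipelineResult, outdir) -> dict[str, Path]:
    """Write every stage output with stable file names; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = result.sim
    chrom = result.params.sim.chrom
    ref_lengths = {chrom: len(sim.reference)}
    paths = {
        "reference": outdir / "reference.fa",
        "targets": outdir / "targets.bed",
        "sites_vcf": outdir / "monitored.vcf",
        "truth": outdir / "truth.tsv",
        "reads": outdir / "reads.sam",
        "consensus": outdir / "consensus.sam",
        "consensus_summary": outdir / "consensus_summary.tsv",
        "error_model": outdir / "error_model.tsv",
        "calls_tsv": outdir / "calls.tsv",
        "calls_vcf": outdir / "calls.vcf",
        "mrd": outdir / "mrd.tsv",
    }
    io.write_fasta(paths["reference"], {chrom: sim.reference})
    io.write_bed(paths["targets"], [(chrom, s, e) for s, e in sim.targets])
    io.write_sites_vcf(paths["sites_vcf"], sim.sites, ref_lengths)
    io.write_truth_tsv(paths["truth"], sim.molecules)
    io.write_reads_sam(paths["reads"], sim.reads, ref_lengths)
    io.write_consensus_sam(paths["consensus"], result.consensus_reads,
                           ref_lengths)
    result.consensus_summary.rename_axis("stratum").to_csv(
        paths["consensus_summary"], sep="\t")
    io.write_error_model_tsv(paths["error_model"], result.model)
    io.write_calls_tsv(paths["calls_tsv"], result.calls)
    io.write_calls_vcf(paths["calls_vcf"], result.calls, ref_lengths)
    io.write_mrd_tsv(paths["mrd"], result.mrd)
    if result.benchmark is not None:
        paths["benchmark_tsv"] = outdir / "benchmark.tsv"
        paths["benchmark_json"] = outdir / "benchmark.json"
        result.benchmark.error_table.to_csv(paths["benchmark_tsv"], sep="\t",
                                            index=False, float_format="%.6g")
        paths["benchmark_json"].write_text(result.benchmark.to_json())
    logger.info("wrote %d artefacts to %s", len(paths), outdir)
    return paths
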