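"""Benchmarking against simulator ground truth.

Everything the read simulator knows (which molecules exist, which carry a
spiked variant, the error-free sequence of each) lets the consensus and
calling stages be scored exactly: consensus error rates by family-size
stratum and duplex mode, coverage by minimum family size, call sensitivity
and specificity at the monitored sites, and the template-recovery fraction
(deduplicated coverage per nanogram over haploid genome equivalents per
nanogram).

Error rates are evaluated only at truth-wildtype positions: a true
alternate base at a spiked site is not an error, so monitored variant
columns are excluded from numerator and denominator, as are 'N'-masked
consensus bases.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calling import VariantCall
from .consensus import ConsensusRead
from .simulator import BASE_TO_CODE, Site

logger = logging.getLogger(__name__)

GENOME_EQUIVALENTS_PER_NG = 303.0

_MODES = ("SC", "DC", "MC")


@dataclass(slots=True)
class ErrorRateResult:
    """Consensus error rate with its underlying integer base counts."""

    error_bases: int
    total_bases: int

    @property
    def rate(self) -> float:
        return self.error_bases / self.total_bases if self.total_bases else float("nan")

    @property
    def defined(self) -> bool:
        return self.total_bases > 0


def consensus_error_rate(consensus_reads: Iterable[ConsensusRead],
                         reference: Mapping[str, bytes],
                         variant_positions: Iterable[tuple[str, int]] = (),
                         mode: str = "MC",
                         min_family_size: int = 1,
                         max_family_size: Optional[int] = None,
                         ) -> ErrorRateResult:
    """Mismatch rate of consensus bases against the reference.

    ``mode`` selects simplex-only ("SC"), duplex-only ("DC") or all ("MC")
    consensus reads; ``min_family_size`` is a floor on the family size and
    ``max_family_size`` an optional cap (``min=max=1`` isolates the
    uncorrected single-read families).  Truth-variant positions and 'N'
    bases are excluded entirely.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    exclude: dict[str, set[int]] = {}
    for chrom, pos in variant_positions:
        exclude.setdefault(chrom, set()).add(pos)
    ref_codes = {c: BASE_TO_CODE[np.frombuffer(seq, np.uint8)]
                 for c, seq in reference.items()}
    excl_mask = {}
    for chrom, codes in ref_codes.items():
        m = np.zeros(len(codes), bool)
        for pos in exclude.get(chrom, ()):
            m[pos] = True
        excl_mask[chrom] = m

    errors = total = 0
    for read in consensus_reads:
        if read.family_size < min_family_size:
            continue
        if max_family_size is not None and read.family_size > max_family_size:
            continue
        if mode == "SC" and read.duplex_flag != 0:
            continue
        if mode == "DC" and read.duplex_flag != 1:
            continue
        codes = BASE_TO_CODE[np.frombuffer(read.bases, np.uint8)]
        span = slice(read.fragment_start, read.fragment_end)
        refc = ref_codes[read.chrom][span]
        keep = (codes < 4) & ~excl_mask[read.chrom][span]
        total += int(keep.sum())
        errors += int((codes[keep] != refc[keep]).sum())
    if total == 0:
        logger.warning("no consensus bases selected for mode=%s, min size %d",
                       mode, min_family_size)
    return ErrorRateResult(errors, total)


def mean_site_depth(consensus_reads: Iterable[ConsensusRead],
                    sites: Sequence[Site],
                    mode: str = "MC",
                    min_family_size: int = 1) -> float:
    """Mean consensus depth over the monitored sites for one selection."""
    if not sites:
        return float("nan")
    spans: dict[str, list[tuple[int, int]]] = {}
    for read in consensus_reads:
        if read.family_size < min_family_size:
            continue
        if mode == "SC" and read.duplex_flag != 0:
            continue
        if mode == "DC" and read.duplex_flag != 1:
            continue
        spans.setdefault(read.chrom, []).append(
            (read.fragment_start, read.fragment_end))
    depths = []
    arrays = {c: (np.array([s for s, _ in v]), np.array([e for _, e in v]))
              for c, v in spans.items()}
    for site in sites:
        if site.chrom not in arrays:
            depths.append(0)
            continue
        starts, ends = arrays[site.chrom]
        depths.append(int(((starts <= site.pos) & (ends > site.pos)).sum()))
    return float(np.mean(depths))


def sensitivity_specificity(calls: Sequence[VariantCall],
                            sites: Sequence[Site],
                            ) -> tuple[float, float, pd.DataFrame]:
    """Confusion counts of the monitored panel against simulator truth.

    Sensitivity = called true variants / true variants; specificity =
    1 - false calls / monitored wild-type sites.  Undefined ratios (no
    positives, or no wild-type sites) come back as NaN.
    """
    truth = {(s.chrom, s.pos, s.ref, s.alt): s.true_vaf for s in sites}
    rows = []
    tp = fn = fp = tn = 0
    for call in calls:
        vid = (call.chrom, call.pos, call.ref, call.alt)
        if vid not in truth:
            raise ValueError(f"call at {vid} is not a monitored site")
        true_vaf = truth[vid]
        positive = true_vaf > 0
        if positive and call.called:
            cat = "TP"; tp += 1
        elif positive:
            cat = "FN"; fn += 1
        elif call.called:
            cat = "FP"; fp += 1
        else:
            cat = "TN"; tn += 1
        rows.append({"chrom": call.chrom, "pos": call.pos + 1,
                     "ref": call.ref, "alt": call.alt,
                     "true_vaf": true_vaf, "vaf": call.vaf,
                     "p_value": call.p_value, "called": bool(call.called),
                     "category": cat})
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 1.0 - fp / (fp + tn) if (fp + tn) else float("nan")
    return sens, spec, pd.DataFrame(rows)


def template_recovery(coverage_per_ng: float,
                      genome_equivalents_per_ng: float = GENOME_EQUIVALENTS_PER_NG,
                      ) -> float:
    """Fraction of input template molecules recovered in the library.

    Deduplicated (consensus) coverage per nanogram of input divided by the
    haploid genome equivalents one nanogram represents (303 for human DNA).
    """
    if coverage_per_ng <= 0 or genome_equivalents_per_ng <= 0:
        raise ValueError("inputs must be positive")
    return coverage_per_ng / genome_equivalents_per_ng


@dataclass
class BenchmarkReport:
    """Error/coverage table per (mode, min family size) plus call metrics."""

    error_table: pd.DataFrame
    sensitivity: float
    specificity: float
    per_variant: pd.DataFrame
    template_recovery_fraction: float

    def to_json(self) -> str:
        return json.dumps({
            "error_table": self.error_table.to_dict(orient="records"),
            "sensitivity": None if np.isnan(self.sensitivity) else self.sensitivity,
            "specificity": None if np.isnan(self.specificity) else self.specificity,
            "template_recovery_fraction": self.template_recovery_fraction,
        }, indent=2)


def build_benchmark(consensus_reads: Sequence[ConsensusRead],
                    reference: Mapping[str, bytes],
                    sites: Sequence[Site],
                    calls: Sequence[VariantCall],
                    input_ng: Optional[float] = None,
                    input_molecules_per_site: Optional[int] = None,
                    ) -> BenchmarkReport:
    """Assemble the full benchmark report for one simulated run."""
    variant_positions = [(s.chrom, s.pos) for s in sites]
    rows = []
    for mode in _MODES:
        for min_size in (1, 2, 3, 4):
            res = consensus_error_rate(consensus_reads, reference,
                                       variant_positions, mode, min_size)
            rows.append({"mode": mode, "min_family_size": min_size,
                         "error_bases": res.error_bases,
                         "total_bases": res.total_bases,
                         "error_rate": res.rate if res.defined else np.nan,
                         "mean_site_depth": mean_site_depth(
                             consensus_reads, sites, mode, min_size)})
    sens, spec, table = sensitivity_specificity(calls, sites)
    mc_depth = mean_site_depth(consensus_reads, sites, "MC", 1)
    if input_ng:
        recovery = template_recovery(mc_depth / input_ng)
    elif input_molecules_per_site:
        recovery = mc_depth / input_molecules_per_site
    else:
        recovery = float("nan")
    return BenchmarkReport(pd.DataFrame(rows), sens, spec, table, recovery)
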