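"""Monitored-variant calling against the stratified background error model.

Each monitored site is tested with a one-sided Fisher's exact test on a
single 2x2 table pooling the included family-size strata:

    [[alt_count,        depth - alt_count      ],
     [bg_error_bases,   bg_total_bases - bg_error_bases]]

where the background cell comes from the matching nucleotide-change group
when change-group models are enabled.  The test asks only whether the site
is enriched for the alternate allele relative to noise.  A variant counts
as called when it is supported by at least ``min_alt_reads`` consensus
reads (default 3) and reaches p <= alpha (default 0.05).  A proportion-Z
statistic, the fold change over background and the limit of detection
(smallest VAF whose expected alt count both meets the read-support floor
and reaches significance) are reported alongside.

No multiple-testing correction is applied: the monitored panel is small and
pre-specified.  Users testing large panels should correct downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .error_model import ErrorModel, Pileups, change_group

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerConfig:
    """Filters and pooling behaviour of the monitored-variant caller.

    Small-family strata carry higher error rates; by default only family
    sizes >= 2 enter the test (``included_strata`` uses 4 to mean the
    ">= 4" stratum).  ``combination`` selects between pooling counts into
    one table ("pooled", default) and combining per-stratum one-sided
    Fisher p-values with Fisher's method ("fisher_method").
    """

    included_strata: tuple[int, ...] = (2, 3, 4)
    alpha: float = 0.05
    min_alt_reads: int = 3
    use_change_groups: bool = False
    min_depth: int = 1
    combination: str = "pooled"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be >= 1")
        if self.combination not in ("pooled", "fisher_method"):
            raise ValueError(f"unknown combination {self.combination!r}")
        if not self.included_strata:
            raise ValueError("included_strata must be non-empty")


@dataclass(slots=True)
class VariantCall:
    """Per-site statistics; ``pos`` is 0-based internally, 1-based in reports."""

    chrom: str
    pos: int
    ref: str
    alt: str
    strata_counts: dict  # stratum -> (alt_count, depth)
    alt_count: int
    depth: int
    vaf: float
    p_value: float
    z_score: float
    fold_change: float
    lod: float
    called: bool
    filter_reasons: list


def site_p_value(alt: int, depth: int, bg_errors: int, bg_total: int) -> float:
    """One-sided Fisher exact p for alt enrichment at the site.

    Computed as the hypergeometric upper tail with the table's margins
    fixed, identical to ``fisher_exact(..., alternative="greater")``.
    """
    if depth < 0 or alt < 0 or alt > depth or bg_errors > bg_total:
        raise ValueError("inconsistent contingency counts")
    if depth == 0 or alt == 0:
        return 1.0
    p = float(stats.hypergeom.sf(alt - 1, depth + bg_total, alt + bg_errors, depth))
    return min(max(p, math.ulp(0.0)), 1.0)


def proportion_z(vaf: float, error_rate: float, depth: int,
                 bg_total: int) -> float:
    """Z statistic of the observed VAF against the background proportion.

    A zero background rate is floored at one error in ``bg_total`` bases so
    the statistic stays finite.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    e = error_rate if error_rate > 0 else 1.0 / max(bg_total, 1)
    return (vaf - e) / math.sqrt(e * (1.0 - e) / depth)


def fold_change(vaf: float, error_rate: float, bg_total: int) -> float:
    """VAF over the background rate, with the same zero-rate floor."""
    return vaf / max(error_rate, 1.0 / max(bg_total, 1))


def _pooled_background(model: ErrorModel, strata: Sequence[int],
                       group: Optional[int]) -> tuple[int, int]:
    usable = [st for st in strata if model.usable(st)]
    dropped = set(strata) - set(usable)
    if dropped:
        logger.warning("dropping strata without background coverage: %s",
                       sorted(dropped))
    return model.pooled_counts(usable, group)


def test_site(strata_counts: Mapping[int, tuple[int, int]],
              ref: str, alt: str,
              model: ErrorModel,
              config: CallerConfig = CallerConfig(),
              chrom: str = ".", pos: int = 0,
              lod: float = float("nan")) -> VariantCall:
    """Test one site's per-stratum (alt, depth) counts against background."""
    group = change_group(ref, alt) if config.use_change_groups else None
    included = {st: strata_counts.get(st, (0, 0))
                for st in config.included_strata}
    alt_count = sum(a for a, _ in included.values())
    depth = sum(d for _, d in included.values())
    bg_err, bg_tot = _pooled_background(model, config.included_strata, group)

    reasons: list[str] = []
    if depth == 0:
        reasons.append("no_coverage")
        call = VariantCall(chrom, pos, ref, alt, dict(included), 0, 0, 0.0,
                           1.0, 0.0, 0.0, lod, False, reasons)
        return call
    vaf = alt_count / depth
    if config.combination == "pooled" or len(config.included_strata) == 1:
        p = site_p_value(alt_count, depth, bg_err, bg_tot)
    else:
        p = _fisher_method(included, model, config, group)
    if bg_tot > 0:
        rate = bg_err / bg_tot
        z = proportion_z(vaf, rate, depth, bg_tot)
        fc = fold_change(vaf, rate, bg_tot)
    else:
        z = fc = 0.0

    if depth < config.min_depth:
        reasons.append("low_depth")
    if alt_count < config.min_alt_reads:
        reasons.append("min_alt_reads")
    if p > config.alpha:
        reasons.append("p_value")
    called = not reasons
    return VariantCall(chrom, pos, ref, alt, dict(included), alt_count, depth,
                       vaf, p, z, fc, lod, called, reasons)


def _fisher_method(included: Mapping[int, tuple[int, int]], model: ErrorModel,
                   config: CallerConfig, group: Optional[int]) -> float:
    """Combine per-stratum one-sided p-values with Fisher's method."""
    ps = []
    for st, (a, d) in included.items():
        if d == 0 or not model.usable(st):
            continue
        e, t = model.counts(st, group)
        ps.append(site_p_value(a, d, e, t))
    if not ps:
        return 1.0
    stat = -2.0 * sum(math.log(p) for p in ps)
    return float(stats.chi2.sf(stat, 2 * len(ps)))


def compute_lod(strata_depths: Mapping[int, int],
                model: ErrorModel,
                config: CallerConfig = CallerConfig(),
                group: Optional[int] = None) -> tuple[float, Optional[str]]:
    """Minimum detectable VAF at the site's current depth.

    The LOD is the smallest VAF v whose (conservatively rounded-up)
    expected alt count k = ceil(v * D) both meets the read-support floor
    and reaches p <= alpha against the pooled background; since p is
    monotone non-increasing in k at fixed margins, the smallest such k is
    found by binary search and LOD = k / D.  Returns (1.0, "undetectable")
    when even k = D fails.
    """
    depth = sum(strata_depths.get(st, 0) for st in config.included_strata)
    if depth <= 0:
        raise ValueError("pooled depth must be positive")
    bg_err, bg_tot = _pooled_background(model, config.included_strata, group)
    lo = config.min_alt_reads
    if lo > depth:
        return 1.0, "undetectable"
    if site_p_value(depth, depth, bg_err, bg_tot) > config.alpha:
        return 1.0, "undetectable"
    hi = depth
    while lo < hi:
        mid = (lo + hi) // 2
        if site_p_value(mid, depth, bg_err, bg_tot) <= config.alpha:
            hi = mid
        else:
            lo = mid + 1
    return lo / depth, None


def call_monitored(sites, pileups: Pileups, model: ErrorModel,
                   config: CallerConfig = CallerConfig(),
                   ) -> tuple[list[VariantCall], dict]:
    """Test every monitored site; returns calls plus a panel summary.

    ``sites`` is a sequence of objects with ``chrom``, ``pos`` (0-based),
    ``ref`` and ``alt`` attributes (e.g. :class:`umicall.simulator.Site`).
    """
    calls: list[VariantCall] = []
    for site in sites:
        strata_counts = {}
        strata_depths = {}
        for st, pile in pileups.items():
            if site.chrom not in pile.counts:
                continue
            a, d = pile.site_counts(site.chrom, site.pos, site.alt)
            strata_counts[st] = (a, d)
            strata_depths[st] = d
        pooled_depth = sum(strata_depths.get(st, 0)
                           for st in config.included_strata)
        if pooled_depth > 0:
            group = change_group(site.ref, site.alt) \
                if config.use_change_groups else None
            lod, _flag = compute_lod(strata_depths, model, config, group)
        else:
            lod = 1.0
        calls.append(test_site(strata_counts, site.ref, site.alt, model,
                               config, chrom=site.chrom, pos=site.pos, lod=lod))
    called_vafs = [c.vaf for c in calls if c.called]
    summary = {
        "n_sites": len(calls),
        "n_called": len(called_vafs),
        "median_vaf_called": float(np.median(called_vafs)) if called_vafs
        else float("nan"),
        "lod": [c.lod for c in calls],
    }
    return calls, summary


def normalize_indel(reference: bytes, pos: int, ref: str,
                    alt: str) -> tuple[int, str, str]:
    """Left-align and trim an indel allele pair on ``reference``.

    Standard VCF-style normalization: shared trailing bases are trimmed
    (extending left when an allele would empty), then shared leading bases
    are trimmed.  Idempotent; a right-aligned representation of the same
    indel normalizes to the identical left-aligned one.
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise ValueError("alleles must be non-empty (anchored VCF style)")
    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 0:
                    raise ValueError("cannot left-extend past contig start")
                anchor = chr(reference[pos - 1])
                ref, alt = anchor + ref, anchor + alt
                pos -= 1
        elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        else:
            return pos, ref, alt


def call_indel(strata_counts: Mapping[int, tuple[int, int]],
               indel_background: tuple[int, int],
               config: CallerConfig = CallerConfig(),
               chrom: str = ".", pos: int = 0,
               ref: str = "N", alt: str = "N") -> VariantCall:
    """Test a monitored indel with the same 2x2 construction as SNVs.

    ``indel_background`` is (indel_bases, total_bases) of the background
    indel model pooled over the included strata; alleles are expected
    left-aligned (see :func:`normalize_indel`).
    """
    included = {st: strata_counts.get(st, (0, 0))
                for st in config.included_strata}
    alt_count = sum(a for a, _ in included.values())
    depth = sum(d for _, d in included.values())
    bg_err, bg_tot = indel_background
    reasons: list[str] = []
    if depth == 0:
        return VariantCall(chrom, pos, ref, alt, dict(included), 0, 0, 0.0,
                           1.0, 0.0, 0.0, float("nan"), False, ["no_coverage"])
    vaf = alt_count / depth
    p = site_p_value(alt_count, depth, bg_err, bg_tot)
    if bg_tot > 0:
        rate = bg_err / bg_tot
        z = proportion_z(vaf, rate, depth, bg_tot)
        fc = fold_change(vaf, rate, bg_tot)
    else:
        z = fc = 0.0
    if depth < config.min_depth:
        reasons.append("low_depth")
    if alt_count < config.min_alt_reads:
        reasons.append("min_alt_reads")
    if p > config.alpha:
        reasons.append("p_value")
    return VariantCall(chrom, pos, ref, alt, dict(included), alt_count, depth,
                       vaf, p, z, fc, float("nan"), not reasons, reasons)
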