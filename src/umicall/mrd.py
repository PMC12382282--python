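"""Panel-aggregate molecular-residual-disease testing and VAF kinetics.

A single monitored variant at very low allele fraction rarely reaches
significance on its own; pooling evidence across the whole tumour-informed
panel does.  The MRD test first drops monitored variants whose VAF deviates
by more than three standard deviations from the panel mean (a germline
contaminant or artefact would otherwise dominate), then aggregates mutant
and wild-type consensus bases over all remaining target loci and compares
that ratio to the non-reference/reference ratio in the +-60 bp flanking
windows with a one-sided Fisher's exact test.  The flanks have no
designated alternate allele, so total non-reference bases serve as the
error proxy there; overlapping flank windows are merged and monitored
positions are excluded from them.

Two positivity rules are reported: the default p <= alpha rule and a
strict mode that additionally requires at least three individually called
variants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .calling import VariantCall, site_p_value
from .error_model import Pileups

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 60
MIN_CALLED_STRICT = 3


class MrdError(ValueError):
    """Raised for empty inputs or missing background windows."""


@dataclass(slots=True)
class MrdResult:
    included_variants: list
    excluded_outliers: list  # (call, reason) pairs
    target_alt: int
    target_ref: int
    flank_nonref: int
    flank_ref: int
    p_value: float
    mrd_positive: bool  # default rule: p <= alpha
    mrd_positive_strict: bool  # additionally >= 3 called variants
    n_called_variants: int


def exclude_outliers(calls: Sequence[VariantCall],
                     k_sd: float = 3.0) -> tuple[list[VariantCall],
                                                 list[tuple[VariantCall, str]]]:
    """Split calls into (included, excluded) by the k-SD VAF outlier rule.

    With two or fewer variants, or when all VAFs are identical (zero SD),
    nothing is excluded.
    """
    if not calls:
        raise MrdError("no monitored variants")
    if len(calls) <= 2:
        return list(calls), []
    vafs = np.array([c.vaf for c in calls])
    mu = float(vafs.mean())
    sd = float(vafs.std(ddof=1))
    if sd == 0 or not math.isfinite(k_sd * sd):
        return list(calls), []
    included, excluded = [], []
    for call in calls:
        if abs(call.vaf - mu) > k_sd * sd:
            excluded.append((call, f"vaf_outlier(|{call.vaf:.4g}-{mu:.4g}|"
                                   f">{k_sd:g}*{sd:.4g})"))
        else:
            included.append(call)
    return included, excluded


def mrd_contingency_p(target_alt: int, target_ref: int,
                      flank_nonref: int, flank_ref: int) -> float:
    """One-sided Fisher p for alt enrichment at targets over flanks."""
    if min(target_alt, target_ref, flank_nonref, flank_ref) < 0:
        raise MrdError("negative contingency counts")
    if flank_nonref + flank_ref == 0:
        raise MrdError("no_background_window")
    return site_p_value(target_alt, target_alt + target_ref,
                        flank_nonref, flank_nonref + flank_ref)


def _flank_windows(positions: Sequence[tuple[str, int]],
                   flank_bp: int) -> dict[str, list[tuple[int, int]]]:
    """Merged +-flank windows per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append((pos - flank_bp, pos + flank_bp + 1))
    merged = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for lo, hi in spans[1:]:
            if lo <= out[-1][1]:
                out[-1][1] = max(out[-1][1], hi)
            else:
                out.append([lo, hi])
        merged[chrom] = [(lo, hi) for lo, hi in out]
    return merged


def mrd_test(included_calls: Sequence[VariantCall],
             pileups: Pileups,
             monitored_positions: Iterable[tuple[str, int]],
             flank_bp: int = DEFAULT_FLANK_BP,
             alpha: float = 0.05,
             included_strata: Sequence[int] = (2, 3, 4),
             excluded_outliers: Optional[list] = None) -> MrdResult:
    """Aggregate MRD significance test over the included monitored variants.

    Target counts come from the calls themselves (pooled over the caller's
    included strata); flank counts are taken from the pileups over the
    merged +-``flank_bp`` windows around the included sites, with every
    monitored position excluded from the flanks.
    """
    if not included_calls:
        raise MrdError("no monitored variants")
    target_alt = sum(c.alt_count for c in included_calls)
    target_ref = sum(c.depth - c.alt_count for c in included_calls)

    monitored = set(monitored_positions)
    windows = _flank_windows([(c.chrom, c.pos) for c in included_calls], flank_bp)
    flank_nonref = flank_ref = 0
    strata = [st for st in included_strata if st in pileups]
    for chrom, spans in windows.items():
        any_pile = pileups[strata[0]]
        if chrom not in any_pile.counts:
            continue
        length = len(any_pile.mask[chrom])
        sel = np.zeros(length, bool)
        for lo, hi in spans:
            sel[max(lo, 0):min(hi, length)] = True
        for c, p in monitored:
            if c == chrom and 0 <= p < length:
                sel[p] = False
        idx = np.nonzero(sel)[0]
        if len(idx) == 0:
            continue
        refc = any_pile.ref_codes[chrom][idx]
        ok = refc < 4
        idx, refc = idx[ok], refc[ok]
        for st in strata:
            cnt = pileups[st].counts[chrom][idx]
            depth = cnt[:, :4].sum(axis=1)
            ref_match = cnt[np.arange(len(idx)), refc]
            flank_ref += int(ref_match.sum())
            flank_nonref += int(depth.sum() - ref_match.sum())

    if flank_nonref + flank_ref == 0:
        raise MrdError("no_background_window")
    p = mrd_contingency_p(target_alt, target_ref, flank_nonref, flank_ref)
    n_called = sum(1 for c in included_calls if c.called)
    return MrdResult(
        included_variants=list(included_calls),
        excluded_outliers=excluded_outliers or [],
        target_alt=target_alt, target_ref=target_ref,
        flank_nonref=flank_nonref, flank_ref=flank_ref,
        p_value=p,
        mrd_positive=p <= alpha,
        mrd_positive_strict=p <= alpha and n_called >= MIN_CALLED_STRICT,
        n_called_variants=n_called)


def mrd_from_calls(calls: Sequence[VariantCall], pileups: Pileups,
                   flank_bp: int = DEFAULT_FLANK_BP, alpha: float = 0.05,
                   k_sd: float = 3.0,
                   included_strata: Sequence[int] = (2, 3, 4)) -> MrdResult:
    """Outlier exclusion followed by the aggregate MRD test."""
    included, excluded = exclude_outliers(calls, k_sd)
    monitored = [(c.chrom, c.pos) for c in calls]
    return mrd_test(included, pileups, monitored, flank_bp, alpha,
                    included_strata, excluded_outliers=excluded)


@dataclass
class KineticsTable:
    """Longitudinal VAF trajectories plus per-timepoint panel summaries.

    ``variants`` is long-format (one row per timepoint x variant, outlier
    exclusions flagged but never dropped); ``timepoints`` carries the
    median VAF, called-variant count (the plot's significance asterisks)
    and MRD classification per timepoint.
    """

    variants: pd.DataFrame
    timepoints: pd.DataFrame


def build_kinetics(timepoints: Sequence[tuple[str, Sequence[VariantCall],
                                              Optional[MrdResult]]]
                   ) -> KineticsTable:
    """Assemble per-variant VAF kinetics across ordered timepoints.

    ``timepoints`` are (label, calls, mrd_result) triples in chronological
    order; labels must be unique.  Every variant appears at every timepoint
    (uncalled/uncovered rows are kept with ``called=False``).
    """
    if not timepoints:
        raise MrdError("no timepoints")
    labels = [label for label, _, _ in timepoints]
    if len(set(labels)) != len(labels):
        raise MrdError("duplicated timepoint labels")

    variant_ids: list[tuple] = []
    for _, calls, _ in timepoints:
        for c in calls:
            vid = (c.chrom, c.pos, c.ref, c.alt)
            if vid not in variant_ids:
                variant_ids.append(vid)

    rows = []
    tp_rows = []
    for label, calls, mrd in timepoints:
        by_id = {(c.chrom, c.pos, c.ref, c.alt): c for c in calls}
        outliers = {(c.chrom, c.pos, c.ref, c.alt)
                    for c, _ in (mrd.excluded_outliers if mrd else [])}
        vafs = []
        n_called = 0
        for vid in variant_ids:
            call = by_id.get(vid)
            chrom, pos, ref, alt = vid
            if call is None:
                rows.append({"timepoint": label, "chrom": chrom, "pos": pos + 1,
                             "ref": ref, "alt": alt, "vaf": np.nan,
                             "p_value": np.nan, "called": False,
                             "mrd_outlier": False})
                continue
            vafs.append(call.vaf)
            n_called += call.called
            rows.append({"timepoint": label, "chrom": chrom, "pos": pos + 1,
                         "ref": ref, "alt": alt, "vaf": call.vaf,
                         "p_value": call.p_value, "called": bool(call.called),
                         "mrd_outlier": vid in outliers})
        tp_rows.append({
            "timepoint": label,
            "median_vaf": float(np.median(vafs)) if vafs else np.nan,
            "n_called": n_called,
            "mrd_p": mrd.p_value if mrd else np.nan,
            "mrd_class": ("MRD+" if mrd and mrd.mrd_positive else
                          "MRD-" if mrd else "NA")})
    return KineticsTable(pd.DataFrame(rows), pd.DataFrame(tp_rows))
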