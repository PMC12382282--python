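"""Per-stratum pileups and stratified background error models.

The caller's null hypothesis is "this site looks like background noise".
Background is estimated separately for each consensus quality level
(UMI-family sizes 1, 2, 3, >= 4), and optionally for each of the six
unordered nucleotide-change groups (A-C, A-G, A-T, C-G, C-T, G-T), by
summing non-reference substitution bases over all covered positions that
are (i) on autosomes, (ii) not known germline or monitored somatic sites,
and (iii) free of likely real variants (every alternate allele below the
allele-frequency exclusion threshold, default 20%, judged against the
depth pooled over all strata).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusRead, STRATA, STRATUM_LABELS

logger = logging.getLogger(__name__)

_BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i

_NON_AUTOSOME_RE = re.compile(r"^(chr)?(x|y|m|mt)$", re.IGNORECASE)

#: the six unordered substitution groups; every substitution falls in exactly one
CHANGE_GROUPS: tuple[tuple[str, str], ...] = (
    ("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))
_GROUP_INDEX = {frozenset(g): i for i, g in enumerate(CHANGE_GROUPS)}


class PileupError(ValueError):
    """Raised for invalid pileup regions or inputs."""


def is_autosome(chrom: str) -> bool:
    """Contigs are autosomal unless named with an X/Y/M(T)-style suffix."""
    return _NON_AUTOSOME_RE.match(chrom) is None


def change_group(ref: str, alt: str) -> int:
    """Index of the unordered nucleotide-change group of ``ref -> alt``."""
    try:
        return _GROUP_INDEX[frozenset((ref.upper(), alt.upper()))]
    except KeyError:
        raise ValueError(f"not a substitution: {ref}>{alt}") from None


@dataclass
class PileupStratum:
    """Per-position, per-allele counts restricted to one family-size level.

    ``counts[chrom]`` is an ``(L, 5)`` integer array over the full contig
    (columns A, C, G, T, N); only positions where ``mask[chrom]`` is set
    were piled.  Depth excludes the N column.  ``indel_counts`` maps
    ``(chrom, pos)`` to left-aligned allele-string counts; the bundled
    simulator spikes no indels, so it is populated only by external input.
    """

    stratum: int
    counts: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]
    ref_codes: dict[str, np.ndarray]
    indel_counts: dict[tuple[str, int], dict[str, int]] = field(default_factory=dict)

    def depth(self, chrom: str) -> np.ndarray:
        return self.counts[chrom][:, :4].sum(axis=1)

    def site_counts(self, chrom: str, pos: int, alt: str) -> tuple[int, int]:
        """(alt count, depth) at one position."""
        row = self.counts[chrom][pos]
        return int(row[_BASE_TO_CODE[ord(alt)]]), int(row[:4].sum())


Pileups = dict[int, PileupStratum]

_FLUSH = 4_000_000


def build_pileups(consensus_reads: Iterable[ConsensusRead],
                  reference: Mapping[str, bytes],
                  regions: Sequence[tuple[str, int, int]],
                  min_base_quality: int = 0,
                  flank_bp: int = 0,
                  strata: Sequence[int] = STRATA) -> Pileups:
    """Stack consensus reads into one pileup per family-size stratum.

    Masked ('N') consensus bases and bases below ``min_base_quality``
    contribute nothing.  Counting is restricted to ``regions`` extended by
    ``flank_bp`` on both sides (the flank is what the MRD test uses as its
    background window).
    """
    ref_codes = {c: _BASE_TO_CODE[np.frombuffer(seq, np.uint8)]
                 for c, seq in reference.items()}
    mask = {c: np.zeros(len(seq), bool) for c, seq in reference.items()}
    for chrom, start, end in regions:
        if chrom not in mask:
            raise PileupError(f"region contig {chrom!r} not in reference")
        if not 0 <= start < end <= len(mask[chrom]):
            raise PileupError(f"region {chrom}:{start}-{end} outside reference")
        lo = max(0, start - flank_bp)
        hi = min(len(mask[chrom]), end + flank_bp)
        mask[chrom][lo:hi] = True

    flat = {st: {c: np.zeros(len(seq) * 5, np.int64)
                 for c, seq in reference.items()}
            for st in strata}
    pending: dict[tuple[int, str], list[np.ndarray]] = {}
    pending_size: dict[tuple[int, str], int] = {}

    def _flush(key: tuple[int, str]) -> None:
        chunks = pending.pop(key, None)
        if not chunks:
            return
        idx = np.concatenate(chunks)
        flat[key[0]][key[1]] += np.bincount(idx, minlength=flat[key[0]][key[1]].size)
        pending_size[key] = 0

    for read in consensus_reads:
        if read.stratum not in flat:
            continue
        codes = _BASE_TO_CODE[np.frombuffer(read.bases, np.uint8)]
        quals = np.frombuffer(read.joint_qualities, np.uint8)
        pos = np.arange(read.fragment_start, read.fragment_end)
        valid = (codes < 4) & (quals >= min_base_quality) & mask[read.chrom][pos]
        if not valid.any():
            continue
        key = (read.stratum, read.chrom)
        pending.setdefault(key, []).append(pos[valid] * 5 + codes[valid])
        pending_size[key] = pending_size.get(key, 0) + int(valid.sum())
        if pending_size[key] >= _FLUSH:
            _flush(key)
    for key in list(pending):
        _flush(key)

    return {st: PileupStratum(
        stratum=st,
        counts={c: arr.reshape(-1, 5) for c, arr in flat[st].items()},
        mask=mask, ref_codes=ref_codes) for st in strata}


@dataclass
class ErrorModel:
    """Background error rates per stratum (optionally per change group).

    Integer base counts are retained so the caller can build exact Fisher
    tables.  ``group_total_bases[(stratum, g)]`` is the depth at kept
    positions whose reference base belongs to group ``g``'s pair (each
    position therefore contributes to three of the six groups), while the
    group error counts partition the stratum's overall error count exactly.
    """

    error_bases: dict[int, int]
    total_bases: dict[int, int]
    group_error_bases: Optional[dict[tuple[int, int], int]]
    group_total_bases: Optional[dict[tuple[int, int], int]]
    indel_error_bases: dict[int, int]
    excluded_positions: int
    af_exclusion_threshold: float

    def usable(self, stratum: int) -> bool:
        return self.total_bases.get(stratum, 0) > 0

    def rate(self, stratum: int, group: Optional[int] = None) -> float:
        """Errors per sequenced base; raises if the stratum has no coverage."""
        err, tot = self.counts(stratum, group)
        if tot == 0:
            raise ValueError(f"stratum {stratum} has no background coverage")
        return err / tot

    def counts(self, stratum: int, group: Optional[int] = None) -> tuple[int, int]:
        if group is None:
            return self.error_bases.get(stratum, 0), self.total_bases.get(stratum, 0)
        if self.group_error_bases is None:
            raise ValueError("model was built without change groups")
        return (self.group_error_bases.get((stratum, group), 0),
                self.group_total_bases.get((stratum, group), 0))

    def pooled_counts(self, strata: Iterable[int],
                      group: Optional[int] = None) -> tuple[int, int]:
        err = tot = 0
        for st in strata:
            e, t = self.counts(st, group)
            err += e
            tot += t
        return err, tot

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for st in sorted(self.total_bases):
            tot = self.total_bases[st]
            rows.append({
                "stratum": STRATUM_LABELS.get(st, str(st)),
                "group": "all",
                "error_bases": self.error_bases[st],
                "total_bases": tot,
                "error_rate": self.error_bases[st] / tot if tot else np.nan})
            if self.group_error_bases is not None:
                for g, (b1, b2) in enumerate(CHANGE_GROUPS):
                    gt = self.group_total_bases[(st, g)]
                    rows.append({
                        "stratum": STRATUM_LABELS.get(st, str(st)),
                        "group": f"{b1}-{b2}",
                        "error_bases": self.group_error_bases[(st, g)],
                        "total_bases": gt,
                        "error_rate": (self.group_error_bases[(st, g)] / gt
                                       if gt else np.nan)})
        return pd.DataFrame(rows)


def estimate_background(pileups: Pileups,
                        exclude_positions: Iterable[tuple[str, int]] = (),
                        af_exclusion_threshold: float = 0.20,
                        per_change_group: bool = False) -> ErrorModel:
    """Estimate the stratified substitution background from pileups.

    Positions on non-autosomal contigs, positions in ``exclude_positions``
    (known germline plus monitored somatic sites) and positions where any
    alternate allele reaches ``af_exclusion_threshold`` of the all-strata
    pooled depth are excluded before counting.
    """
    if not pileups:
        raise PileupError("no pileups")
    if not 0.0 < af_exclusion_threshold <= 1.0:
        raise ValueError("af_exclusion_threshold must be in (0, 1]")
    strata = sorted(pileups)
    any_stratum = pileups[strata[0]]
    excluded = set(exclude_positions)

    error_bases = {st: 0 for st in strata}
    total_bases = {st: 0 for st in strata}
    group_err = {(st, g): 0 for st in strata for g in range(6)} \
        if per_change_group else None
    group_tot = {(st, g): 0 for st in strata for g in range(6)} \
        if per_change_group else None
    n_excluded = 0

    for chrom, mask in any_stratum.mask.items():
        if not mask.any():
            continue
        refc = any_stratum.ref_codes[chrom]
        keep = mask & (refc < 4)
        if not is_autosome(chrom):
            n_excluded += int(keep.sum())
            continue
        pooled = sum(pileups[st].counts[chrom] for st in strata)
        pooled_depth = pooled[:, :4].sum(axis=1)
        af_bad = np.zeros(len(mask), bool)
        covered = pooled_depth > 0
        for b in range(4):
            frac = np.zeros(len(mask))
            frac[covered] = pooled[covered, b] / pooled_depth[covered]
            af_bad |= (refc != b) & (frac >= af_exclusion_threshold)
        excl = np.zeros(len(mask), bool)
        for c, p in excluded:
            if c == chrom and 0 <= p < len(excl):
                excl[p] = True
        drop = keep & (af_bad | excl)
        n_excluded += int(drop.sum())
        keep &= ~(af_bad | excl)
        if not keep.any():
            continue
        idx = np.nonzero(keep)[0]
        ref_kept = refc[idx]
        for st in strata:
            cnt = pileups[st].counts[chrom][idx]
            depth = cnt[:, :4].sum(axis=1)
            ref_match = cnt[np.arange(len(idx)), ref_kept]
            total_bases[st] += int(depth.sum())
            error_bases[st] += int(depth.sum() - ref_match.sum())
            if per_change_group:
                for g, (b1, b2) in enumerate(CHANGE_GROUPS):
                    c1, c2 = _BASE_TO_CODE[ord(b1)], _BASE_TO_CODE[ord(b2)]
                    at1 = ref_kept == c1
                    at2 = ref_kept == c2
                    group_err[(st, g)] += int(cnt[at1, c2].sum()
                                              + cnt[at2, c1].sum())
                    group_tot[(st, g)] += int(depth[at1].sum()
                                              + depth[at2].sum())

    for st in strata:
        if total_bases[st] == 0:
            logger.warning("stratum %s has no usable background coverage",
                           STRATUM_LABELS.get(st, st))
    return ErrorModel(error_bases, total_bases, group_err, group_tot,
                      indel_error_bases={st: 0 for st in strata},
                      excluded_positions=n_excluded,
                      af_exclusion_threshold=af_exclusion_threshold)
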