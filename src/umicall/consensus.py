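"""UMI read-family grouping and simplex/duplex consensus collapsing.

Reads that share fragment endpoints and carry matching (edit-distance
tolerant) UMI pairs are PCR duplicates of one template molecule.  Reads from
the two strands of that molecule observe the UMI pair in swapped order
("reciprocal UMIs"), which is what lets a duplex consensus require
independent confirmation from both strands.

Consensus rules: per column, the majority base is emitted when its voter
fraction reaches the concordance threshold (default 75%, the boundary value
is kept); otherwise the column is masked with 'N'.  Joint quality is the
arithmetic mean of the base qualities that agree with the consensus.  A
duplex family first builds one consensus per strand and emits a base only
where the two strand consensuses agree.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

#: consensus quality-level strata: family sizes 1, 2, 3 and >= 4
STRATA = (1, 2, 3, 4)
STRATUM_LABELS = {1: "1", 2: "2", 3: "3", 4: "4+"}
MASK_QUALITY = 2
MAX_QUALITY = 93


class GroupingError(ValueError):
    """Raised on unsorted input or incompatible family members."""


@dataclass(slots=True)
class UmiRead:
    """One aligned read pair, reduced to its fragment span.

    ``fragment_start``/``fragment_end`` are 0-based half-open reference
    coordinates of the sequenced template fragment; ``bases`` covers that
    span.  ``orientation`` records which strand of the template the read
    observed ('+' reads report the UMI pair as (umi_a, umi_b), '-' reads see
    it swapped).  ``base_qualities`` are raw phred values, one per base.
    """

    read_id: str
    chrom: str
    fragment_start: int
    fragment_end: int
    orientation: str
    umi_a: str
    umi_b: str
    bases: bytes
    base_qualities: bytes

    def __post_init__(self) -> None:
        if self.fragment_end <= self.fragment_start:
            raise ValueError(f"{self.read_id}: empty fragment")
        if len(self.bases) != len(self.base_qualities):
            raise ValueError(f"{self.read_id}: bases/qualities length mismatch")


@dataclass(slots=True)
class ReadFamily:
    """All duplicates of one template molecule, split by strand."""

    family_key: tuple
    forward_members: list
    reverse_members: list

    @property
    def family_size(self) -> int:
        return len(self.forward_members) + len(self.reverse_members)


@dataclass(slots=True)
class ConsensusRead:
    """Collapsed family: bases (possibly 'N'-masked), duplex flag, stratum."""

    bases: bytes
    joint_qualities: bytes
    duplex_flag: int  # 0 = simplex, 1 = duplex
    family_size: int
    stratum: int  # min(family_size, 4); 4 means the ">= 4" stratum
    chrom: str
    fragment_start: int
    fragment_end: int
    family_key: tuple


@dataclass(frozen=True)
class ConsensusParams:
    max_edit_distance: int = 3
    min_concordance: float = 0.75
    max_discordant_fraction: float = 0.05
    mode: str = "MC"  # "MC": keep simplex and duplex; "DC": duplex only

    def __post_init__(self) -> None:
        if self.max_edit_distance < 0:
            raise ValueError("max_edit_distance must be >= 0")
        if not 0.0 < self.min_concordance <= 1.0:
            raise ValueError("min_concordance must be in (0, 1]")
        if self.mode not in ("MC", "DC"):
            raise ValueError(f"unknown consensus mode {self.mode!r}")


def canonical_umi_key(umi_a: str, umi_b: str, orientation: str) -> tuple[str, str]:
    """Molecule-level UMI key plus the inferred template strand.

    Reads from opposite strands of one molecule observe the UMI pair in
    swapped order, so the key is built in template-plus order: it is
    invariant under swapping the two UMIs together with flipping the
    orientation, and the returned strand is the orientation itself.
    """
    if not umi_a or not umi_b:
        raise ValueError("UMIs must be non-empty")
    if orientation == "+":
        return f"{umi_a}-{umi_b}", "+"
    return f"{umi_b}-{umi_a}", "-"


def group_duplicates(reads: Iterable[UmiRead],
                     max_edit_distance: int = 3) -> list[ReadFamily]:
    """Cluster coordinate-sorted reads into UMI families.

    Reads with identical ``(chrom, fragment_start, fragment_end)`` are
    clustered on their canonical UMI key.  Keys are processed in descending
    read-count order (ties broken lexicographically) as greedy cluster
    seeds; a key joins the first seed within ``max_edit_distance``.  With
    distance 0 this is exactly exact-key hashing.  Reads without both UMIs
    are skipped (counted, logged).
    """
    if max_edit_distance < 0:
        raise GroupingError("max_edit_distance must be >= 0")
    buckets: dict[tuple, dict[str, list[tuple[str, UmiRead]]]] = {}
    last: Optional[tuple[str, int]] = None
    skipped = 0
    for read in reads:
        if last is not None and read.chrom == last[0] \
                and read.fragment_start < last[1]:
            raise GroupingError("input reads are not coordinate-sorted")
        last = (read.chrom, read.fragment_start)
        if not read.umi_a or not read.umi_b:
            skipped += 1
            continue
        key, strand = canonical_umi_key(read.umi_a, read.umi_b, read.orientation)
        endpoint = (read.chrom, read.fragment_start, read.fragment_end)
        buckets.setdefault(endpoint, {}).setdefault(key, []).append((strand, read))
    if skipped:
        logger.warning("skipped %d reads with missing UMIs", skipped)

    families: list[ReadFamily] = []
    for endpoint in sorted(buckets):
        by_key = buckets[endpoint]
        assignment: dict[str, str] = {}
        if max_edit_distance == 0 or len(by_key) == 1:
            for key in by_key:
                assignment[key] = key
        else:
            seeds: list[str] = []
            for key in sorted(by_key, key=lambda k: (-len(by_key[k]), k)):
                for seed in seeds:
                    hit = edlib.align(key, seed, task="distance",
                                      k=max_edit_distance)
                    if hit["editDistance"] != -1:
                        assignment[key] = seed
                        break
                else:
                    seeds.append(key)
                    assignment[key] = key
        grouped: dict[str, ReadFamily] = {}
        for key, members in by_key.items():
            seed = assignment[key]
            fam = grouped.get(seed)
            if fam is None:
                fam = grouped[seed] = ReadFamily(endpoint + (seed,), [], [])
            for strand, read in members:
                (fam.forward_members if strand == "+"
                 else fam.reverse_members).append(read)
        families.extend(grouped[s] for s in sorted(grouped))
    return families


def _codes_matrix(members: list[UmiRead]) -> tuple[np.ndarray, np.ndarray]:
    length = len(members[0].bases)
    for m in members:
        if len(m.bases) != length:
            raise GroupingError(
                f"family members of unequal length ({m.read_id}); "
                "upstream grouping bug")
    raw = np.frombuffer(b"".join(m.bases for m in members),
                        dtype=np.uint8).reshape(len(members), length)
    quals = np.frombuffer(b"".join(m.base_qualities for m in members),
                          dtype=np.uint8).reshape(len(members), length)
    return _BASE_TO_CODE[raw], quals


def _vote(codes: np.ndarray, quals: np.ndarray,
          min_concordance: float) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise majority vote; returns (consensus codes, mean quality)."""
    counts = np.empty((4, codes.shape[1]), np.int32)
    for b in range(4):
        counts[b] = (codes == b).sum(axis=0)
    voters = counts.sum(axis=0)
    majority = counts.argmax(axis=0)
    top = counts.max(axis=0)
    frac = top / np.maximum(voters, 1)
    cons = np.where((voters > 0) & (frac >= min_concordance),
                    majority, 4).astype(np.uint8)
    match = codes == cons[None, :]
    n_match = match.sum(axis=0)
    qual = np.where(n_match > 0,
                    (quals * match).sum(axis=0) / np.maximum(n_match, 1),
                    float(MASK_QUALITY))
    return cons, qual


def build_consensus(family: ReadFamily,
                    min_concordance: float = 0.75,
                    max_discordant_fraction: float = 0.05) -> Optional[ConsensusRead]:
    """Collapse one family into a consensus read, or None if all members
    fail the discordance filter.

    Members whose fraction of positions disagreeing with the family-wide
    column majority exceeds ``max_discordant_fraction`` are removed and the
    vote repeated.  Duplex families (members on both strands) build one
    consensus per strand and emit 'N' wherever the strands disagree or
    either strand is masked.
    """
    n_fwd = len(family.forward_members)
    members = family.forward_members + family.reverse_members
    if not members:
        raise GroupingError("empty family")
    codes, quals = _codes_matrix(members)
    is_fwd = np.arange(len(members)) < n_fwd

    if len(members) > 1 and max_discordant_fraction < 1.0:
        counts = np.empty((4, codes.shape[1]), np.int32)
        for b in range(4):
            counts[b] = (codes == b).sum(axis=0)
        majority = counts.argmax(axis=0)
        disagree = ((codes != majority[None, :]) & (codes < 4)).mean(axis=1)
        keep = disagree <= max_discordant_fraction
        if not keep.any():
            return None
        if not keep.all():
            codes, quals, is_fwd = codes[keep], quals[keep], is_fwd[keep]

    duplex = bool(is_fwd.any() and (~is_fwd).any())
    if duplex:
        cons_f, qual_f = _vote(codes[is_fwd], quals[is_fwd], min_concordance)
        cons_r, qual_r = _vote(codes[~is_fwd], quals[~is_fwd], min_concordance)
        agree = (cons_f == cons_r) & (cons_f < 4)
        cons = np.where(agree, cons_f, 4).astype(np.uint8)
        qual = np.where(agree, (qual_f + qual_r) / 2.0, float(MASK_QUALITY))
    else:
        cons, qual = _vote(codes, quals, min_concordance)
        qual = np.where(cons < 4, qual, float(MASK_QUALITY))

    joint = np.clip(np.rint(qual), MASK_QUALITY, MAX_QUALITY).astype(np.uint8)
    size = int(codes.shape[0])
    chrom, start, end = family.family_key[:3]
    return ConsensusRead(
        bases=_CODE_TO_BASE[cons].tobytes(),
        joint_qualities=joint.tobytes(),
        duplex_flag=int(duplex),
        family_size=size,
        stratum=min(size, 4),
        chrom=chrom, fragment_start=start, fragment_end=end,
        family_key=family.family_key)


def collapse_all(reads: Iterable[UmiRead],
                 params: ConsensusParams = ConsensusParams(),
                 ) -> tuple[list[ConsensusRead], pd.DataFrame]:
    """Group, collapse and summarise a read stream.

    Returns the consensus stream (duplex-only if ``params.mode == "DC"``)
    and a per-stratum coverage summary counting simplex/duplex consensus
    reads.
    """
    reads = list(reads)
    if not reads:
        logger.warning("collapse_all: empty input")
        empty = pd.DataFrame(0, index=[STRATUM_LABELS[s] for s in STRATA],
                             columns=["simplex", "duplex", "total"])
        return [], empty
    families = group_duplicates(reads, params.max_edit_distance)
    consensuses: list[ConsensusRead] = []
    tally = Counter()
    for family in families:
        cons = build_consensus(family, params.min_concordance,
                               params.max_discordant_fraction)
        if cons is None:
            continue
        tally[(cons.stratum, cons.duplex_flag)] += 1
        if params.mode == "DC" and cons.duplex_flag == 0:
            continue
        consensuses.append(cons)
    summary = pd.DataFrame(
        {"simplex": [tally[(s, 0)] for s in STRATA],
         "duplex": [tally[(s, 1)] for s in STRATA]},
        index=[STRATUM_LABELS[s] for s in STRATA])
    summary["total"] = summary["simplex"] + summary["duplex"]
    return consensuses, summary
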