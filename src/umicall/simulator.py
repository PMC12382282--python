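"""Synthetic cfDNA read simulator with UMI tagging and PCR amplification.

Generates everything the rest of the toolkit consumes: a random reference
sequence with non-overlapping target regions, template cfDNA molecules drawn
from a fragment-size model (wild-type peak at 167 bp, tumour-derived
fragments shorter, concentrated around 100-150 bp), spike-in variants at
configured allele fractions, PCR amplification with heritable polymerase
errors, and UMI-tagged sequenced reads with independent sequencing errors.

The amplification model matters for downstream error structure: polymerase
errors are introduced per duplication event and are inherited by every
descendant copy of that PCR product, so an early error can dominate a
single-strand (simplex) read family, while a duplex consensus -- which
requires agreement between the two template strands -- suppresses it.

All randomness flows from a single integer seed; identical configurations
reproduce identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .consensus import UmiRead

logger = logging.getLogger(__name__)

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Mapping from ASCII nucleotide codes to integer codes 0..3 (A,C,G,T); 4 = N/other.
BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_TO_CODE[_b] = _i
CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

DEFAULT_QUALITY = 30
_EDGE_MARGIN = 150
_TARGET_GAP = 50


class SimulationError(ValueError):
    """Raised for infeasible or invalid simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cfDNA sequencing experiment.

    ``input_genome_equivalents`` is the number of haploid template molecules
    sampled per target locus (303 corresponds to roughly 1 ng of human DNA).
    ``variant_specs`` maps target indices to true variant allele fractions;
    every target carries one monitored site at its centre, wild-type unless
    listed here.  ``duplication_mean`` is the mean number of sequenced reads
    per emitted template strand (geometric, support >= 1);
    ``duplex_probability`` is the chance that both strands of a molecule
    yield reads (otherwise one strand is chosen at random).
    """

    reference_length: int = 50_000
    n_targets: int = 50
    target_length: int = 300
    input_genome_equivalents: int = 303
    variant_specs: tuple[tuple[int, float], ...] = ()
    wt_fragment_mean: float = 167.0
    wt_fragment_sd: float = 10.0
    ct_fragment_mean: float = 145.0
    ct_fragment_sd: float = 12.0
    duplication_mean: float = 3.0
    duplex_probability: float = 0.5
    seq_error_rate: float = 1.0e-3
    polymerase_error_rate: float = 3.0e-5
    umi_error_rate: float = 1.0e-3
    umi_scheme: str = "fixed"  # "fixed": pool of 32 x 8 bp; "random": 5 bp
    rng_seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant_specs",
                           tuple((int(i), float(v)) for i, v in self.variant_specs))
        for name in ("seq_error_rate", "polymerase_error_rate", "umi_error_rate",
                     "duplex_probability"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise SimulationError(f"{name}={rate!r} outside [0, 1]")
        for idx, vaf in self.variant_specs:
            if not 0.0 <= vaf <= 1.0:
                raise SimulationError(f"true VAF {vaf!r} outside [0, 1]")
            if not 0 <= idx < self.n_targets:
                raise SimulationError(f"variant site index {idx} outside targets")
        for name in ("reference_length", "n_targets", "target_length",
                     "input_genome_equivalents"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be positive")
        for name in ("wt_fragment_mean", "wt_fragment_sd", "ct_fragment_mean",
                     "ct_fragment_sd"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.duplication_mean < 1.0:
            raise SimulationError("duplication_mean must be >= 1 read per strand")
        if self.umi_scheme not in ("fixed", "random"):
            raise SimulationError(f"unknown umi_scheme {self.umi_scheme!r}")

    @property
    def umi_length(self) -> int:
        return 8 if self.umi_scheme == "fixed" else 5


@dataclass(slots=True)
class TruthRecord:
    """Ground truth for one template cfDNA molecule."""

    molecule_id: int
    target_index: int
    origin_strand: str  # '+' or '-': strand whose reads report the UMI pair in order
    fragment_start: int  # 0-based half-open reference coordinates
    fragment_end: int
    carries_variant: Optional[int]  # target index of the carried variant, or None
    true_sequence: bytes


@dataclass(slots=True)
class Site:
    """One monitored position (always the centre of a target region)."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    true_vaf: float


@dataclass
class SimResult:
    """All artefacts of one simulation run."""

    config: SimConfig
    reference: bytes
    targets: list[tuple[int, int]]
    sites: list[Site]
    molecules: list[TruthRecord]
    reads: list[UmiRead]
    emissions: dict[tuple[int, str], int]  # (molecule_id, strand) -> reads emitted


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    seq = np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(stage,))
    return np.random.default_rng(seq)


def simulate_reference(config: SimConfig) -> tuple[bytes, list[tuple[int, int]]]:
    """Random reference sequence plus ``n_targets`` disjoint target intervals.

    Each interval keeps at least 150 bp clearance from the sequence edges so
    fragments and MRD flanks never run off the reference.  Raises
    :class:`SimulationError` if the targets cannot fit.
    """
    rng = _rng(config, 0)
    reference = _ACGT[rng.integers(0, 4, config.reference_length)].tobytes()
    tl = config.target_length
    usable = config.reference_length - 2 * _EDGE_MARGIN
    needed = config.n_targets * (tl + _TARGET_GAP) - _TARGET_GAP
    if needed > usable:
        raise SimulationError(
            f"{config.n_targets} targets of {tl} bp do not fit in a "
            f"{config.reference_length} bp reference")
    slack = usable - needed
    jitter = rng.multinomial(slack, np.full(config.n_targets + 1,
                                            1.0 / (config.n_targets + 1)))
    targets: list[tuple[int, int]] = []
    cursor = _EDGE_MARGIN
    for i in range(config.n_targets):
        cursor += int(jitter[i])
        targets.append((cursor, cursor + tl))
        cursor += tl + _TARGET_GAP
    return reference, targets


def monitored_sites(config: SimConfig, reference: bytes,
                    targets: list[tuple[int, int]]) -> list[Site]:
    """The monitored panel: one site per target, spiked per ``variant_specs``.

    The alternate allele is the reference base shifted by one in ACGT order,
    making truth deterministic for a given reference.
    """
    vaf = dict(config.variant_specs)
    sites = []
    for idx, (start, end) in enumerate(targets):
        pos = (start + end) // 2
        ref_code = BASE_TO_CODE[reference[pos]]
        alt_code = (int(ref_code) + 1) % 4
        sites.append(Site(config.chrom, pos, chr(CODE_TO_BASE[ref_code]),
                          chr(CODE_TO_BASE[alt_code]), vaf.get(idx, 0.0)))
    return sites


def simulate_molecules(config: SimConfig, reference: bytes,
                       targets: list[tuple[int, int]]) -> list[TruthRecord]:
    """Draw template molecules covering each target's monitored site.

    Each of the ``input_genome_equivalents`` molecules per target carries the
    alternate allele independently with the configured true VAF; carriers are
    drawn from the shorter tumour-fragment length model, non-carriers from
    the wild-type 167 bp model.  Fragment start positions are uniform among
    placements that cover the monitored site.
    """
    rng = _rng(config, 1)
    sites = monitored_sites(config, reference, targets)
    records: list[TruthRecord] = []
    mol_id = 0
    ref_len = len(reference)
    for t_idx, site in enumerate(sites):
        n = config.input_genome_equivalents
        carrier = rng.random(n) < site.true_vaf
        mean = np.where(carrier, config.ct_fragment_mean, config.wt_fragment_mean)
        sd = np.where(carrier, config.ct_fragment_sd, config.wt_fragment_sd)
        lengths = np.rint(rng.normal(mean, sd)).astype(np.int64)
        lengths = np.clip(lengths, 60, 400)
        offsets = rng.integers(0, lengths)  # site - start
        starts = site.pos - offsets
        starts = np.maximum(starts, 0)
        starts = np.minimum(starts, site.pos)  # still cover the site
        ends = starts + lengths
        over = ends > ref_len
        starts[over] = np.maximum(ref_len - lengths[over], 0)
        ends = starts + lengths
        strands = rng.integers(0, 2, n)
        alt_byte = ord(site.alt)
        site_pos = site.pos
        for i in range(n):
            s, e = int(starts[i]), int(ends[i])
            seq = reference[s:e]
            carries = None
            if carrier[i]:
                mutated = bytearray(seq)
                mutated[site_pos - s] = alt_byte
                seq = bytes(mutated)
                carries = t_idx
            records.append(TruthRecord(mol_id, t_idx,
                                       "+" if strands[i] == 0 else "-",
                                       s, e, carries, seq))
            mol_id += 1
    return records


def _draw_umis(rng: np.random.Generator, config: SimConfig,
               n: int) -> np.ndarray:
    """UMI pairs as an (n, 2, umi_length) array of base codes."""
    k = config.umi_length
    if config.umi_scheme == "fixed":
        pool = rng.integers(0, 4, (32, k))
        idx = rng.integers(0, 32, (n, 2))
        return pool[idx]
    return rng.integers(0, 4, (n, 2, k))


def _pcr_product_errors(rng: np.random.Generator, n_products: int, length: int,
                        n_errors: int, true_codes: np.ndarray) -> list[dict]:
    """Per-product substitution maps for one strand's PCR genealogy.

    Product 0 is the founder copy of the template strand; each later product
    copies a uniformly chosen earlier product and inherits its accumulated
    errors.  ``n_errors`` total polymerase errors are placed uniformly over
    (product, position) and propagate to descendants.
    """
    own: list[dict[int, int]] = [{} for _ in range(n_products)]
    products = rng.integers(0, n_products, n_errors)
    positions = rng.integers(0, length, n_errors)
    shifts = rng.integers(1, 4, n_errors)
    for p, pos, sh in zip(products, positions, shifts):
        own[int(p)][int(pos)] = (int(true_codes[pos]) + int(sh)) % 4
    acc: list[dict[int, int]] = [own[0]]
    for i in range(1, n_products):
        parent = int(rng.integers(0, i))
        merged = dict(acc[parent])
        merged.update(own[i])
        acc.append(merged)
    return acc


def amplify_and_sequence(
    molecules: list[TruthRecord], config: SimConfig,
) -> tuple[list[UmiRead], dict[tuple[int, str], int]]:
    """PCR-amplify and sequence template molecules into UMI-tagged reads.

    Returns the read stream and an emission table mapping
    ``(molecule_id, strand)`` to the number of reads drawn for that strand,
    which downstream tests use as conservation ground truth.
    """
    if not molecules:
        raise SimulationError("no molecules to amplify")
    rng = _rng(config, 2)
    n = len(molecules)
    umi_codes = _draw_umis(rng, config, n)
    umi_cache: list[Optional[tuple[str, str]]] = [None] * n

    duplex = rng.random(n) < config.duplex_probability
    solo = rng.integers(0, 2, n)  # strand choice when not duplex: 0 -> '+', 1 -> '-'
    emit_plus = duplex | (solo == 0)
    emit_minus = duplex | (solo == 1)
    plus_idx = np.nonzero(emit_plus)[0]
    minus_idx = np.nonzero(emit_minus)[0]
    strand_mol = np.concatenate([plus_idx, minus_idx])
    strand_sign = np.concatenate([np.zeros(len(plus_idx), np.int8),
                                  np.ones(len(minus_idx), np.int8)])
    order = np.argsort(strand_mol, kind="stable")
    strand_mol = strand_mol[order]
    strand_sign = strand_sign[order]

    lengths = np.fromiter((m.fragment_end - m.fragment_start for m in molecules),
                          np.int64, n)
    strand_len = lengths[strand_mol]
    n_reads = rng.geometric(1.0 / config.duplication_mean, len(strand_mol))
    pol_counts = (rng.binomial(n_reads * strand_len, config.polymerase_error_rate)
                  if config.polymerase_error_rate > 0
                  else np.zeros(len(strand_mol), np.int64))
    read_len = np.repeat(strand_len, n_reads)
    total_reads = int(n_reads.sum())
    seq_err = (rng.binomial(read_len, config.seq_error_rate)
               if config.seq_error_rate > 0 else np.zeros(total_reads, np.int64))
    umi_err = (rng.binomial(2 * config.umi_length, config.umi_error_rate, total_reads)
               if config.umi_error_rate > 0 else np.zeros(total_reads, np.int64))

    qual_cache: dict[int, bytes] = {}
    reads: list[UmiRead] = []
    emissions: dict[tuple[int, str], int] = {}
    ridx = 0
    for s_i in range(len(strand_mol)):
        mol = molecules[int(strand_mol[s_i])]
        sign = "+" if strand_sign[s_i] == 0 else "-"
        r = int(n_reads[s_i])
        emissions[(mol.molecule_id, sign)] = r
        length = mol.fragment_end - mol.fragment_start
        true_seq = mol.true_sequence
        if umi_cache[mol.molecule_id] is None:
            codes = umi_codes[mol.molecule_id]
            umi_cache[mol.molecule_id] = (
                CODE_TO_BASE[codes[0]].tobytes().decode(),
                CODE_TO_BASE[codes[1]].tobytes().decode())
        umi_a, umi_b = umi_cache[mol.molecule_id]
        # the UMI pair is reported in (A, B) order on the origin strand and
        # swapped on the opposite strand (reciprocal UMIs)
        swap = sign != mol.origin_strand
        prod_errors = None
        if pol_counts[s_i]:
            true_codes = BASE_TO_CODE[np.frombuffer(true_seq, np.uint8)]
            prod_errors = _pcr_product_errors(rng, r, length,
                                              int(pol_counts[s_i]), true_codes)
        qual = qual_cache.get(length)
        if qual is None:
            qual = qual_cache[length] = bytes([DEFAULT_QUALITY]) * length
        for j in range(r):
            muts: dict[int, int] = {}
            if prod_errors is not None and prod_errors[j]:
                muts.update(prod_errors[j])
            k = int(seq_err[ridx])
            if k:
                for pos in rng.integers(0, length, k):
                    base = muts.get(int(pos), int(BASE_TO_CODE[true_seq[pos]]))
                    muts[int(pos)] = (base + int(rng.integers(1, 4))) % 4
            if muts:
                seq = bytearray(true_seq)
                for pos, code in muts.items():
                    seq[pos] = CODE_TO_BASE[code]
                bases = bytes(seq)
            else:
                bases = true_seq
            ua, ub = (umi_b, umi_a) if swap else (umi_a, umi_b)
            ue = int(umi_err[ridx])
            if ue:
                combined = bytearray((ua + ub).encode())
                for pos in rng.integers(0, len(combined), ue):
                    code = int(BASE_TO_CODE[combined[pos]])
                    combined[pos] = CODE_TO_BASE[(code + int(rng.integers(1, 4))) % 4]
                half = len(ua)
                ua = combined[:half].decode()
                ub = combined[half:].decode()
            reads.append(UmiRead(
                read_id=f"m{mol.molecule_id}{'p' if sign == '+' else 'n'}r{j}",
                chrom=config.chrom,
                fragment_start=mol.fragment_start,
                fragment_end=mol.fragment_end,
                orientation="+" if sign == mol.origin_strand else "-",
                umi_a=ua, umi_b=ub,
                bases=bases, base_qualities=qual))
            ridx += 1
    reads.sort(key=lambda rd: (rd.chrom, rd.fragment_start, rd.fragment_end,
                               rd.read_id))
    return reads, emissions


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: reference, molecules, amplified reads."""
    reference, targets = simulate_reference(config)
    sites = monitored_sites(config, reference, targets)
    molecules = simulate_molecules(config, reference, targets)
    reads, emissions = amplify_and_sequence(molecules, config)
    logger.info("simulated %d molecules -> %d reads over %d targets",
                len(molecules), len(reads), len(targets))
    return SimResult(config, reference, targets, sites, molecules, reads, emissions)
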