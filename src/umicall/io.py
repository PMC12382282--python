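"""Readers and writers for the toolkit's on-disk formats.

Conventions: internal coordinates are 0-based half-open everywhere;
conversions happen only here.  SAM/BAM records carry the UMI pair in the
``RX`` tag ("UMIA-UMIB"), consensus records additionally carry ``YD``
(0 = simplex, 1 = duplex) and ``XF`` (family size).  BED output is 0-based
half-open; VCF and report TSVs are 1-based.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import VariantCall
from .consensus import ConsensusRead, UmiRead
from .error_model import ErrorModel
from .mrd import MrdResult
from .simulator import Site, TruthRecord

logger = logging.getLogger(__name__)

FAMILY_SIZE_TAG = "XF"
DUPLEX_TAG = "YD"
UMI_TAG = "RX"


# --- FASTA -----------------------------------------------------------------

def write_fasta(path, reference: Mapping[str, bytes]) -> None:
    records = [SeqRecord(Seq(seq.decode()), id=name, description="")
               for name, seq in reference.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, bytes]:
    return {rec.id: str(rec.seq).upper().encode()
            for rec in SeqIO.parse(str(path), "fasta")}


# --- SAM -------------------------------------------------------------------

def _sam_header(reference_lengths: Mapping[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": int(length)}
               for name, length in reference_lengths.items()],
    })


def write_reads_sam(path, reads: Sequence[UmiRead],
                    reference_lengths: Mapping[str, int]) -> None:
    """Coordinate-sorted SAM; one record per read spanning its fragment."""
    header = _sam_header(reference_lengths)
    ordered = sorted(reads, key=lambda r: (r.chrom, r.fragment_start,
                                           r.fragment_end, r.read_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in ordered:
            a = pysam.AlignedSegment(header)
            a.query_name = read.read_id
            a.query_sequence = read.bases.decode()
            a.flag = 0 if read.orientation == "+" else 16
            a.reference_id = header.get_tid(read.chrom)
            a.reference_start = read.fragment_start
            a.mapping_quality = 60
            a.cigarstring = f"{len(read.bases)}M"
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.base_qualities))
            a.set_tag(UMI_TAG, f"{read.umi_a}-{read.umi_b}")
            out.write(a)


def read_reads_sam(path) -> list[UmiRead]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped:
                continue
            umi = a.get_tag(UMI_TAG) if a.has_tag(UMI_TAG) else "-"
            umi_a, _, umi_b = umi.partition("-")
            reads.append(UmiRead(
                read_id=a.query_name,
                chrom=a.reference_name,
                fragment_start=a.reference_start,
                fragment_end=a.reference_start + a.query_length,
                orientation="-" if a.is_reverse else "+",
                umi_a=umi_a, umi_b=umi_b,
                bases=a.query_sequence.encode(),
                base_qualities=bytes(a.query_qualities)))
    return reads


def write_consensus_sam(path, consensus_reads: Sequence[ConsensusRead],
                        reference_lengths: Mapping[str, int]) -> None:
    header = _sam_header(reference_lengths)
    ordered = sorted(consensus_reads,
                     key=lambda r: (r.chrom, r.fragment_start, r.fragment_end,
                                    str(r.family_key)))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, read in enumerate(ordered):
            a = pysam.AlignedSegment(header)
            a.query_name = f"consensus_{i}"
            a.query_sequence = read.bases.decode()
            a.flag = 0
            a.reference_id = header.get_tid(read.chrom)
            a.reference_start = read.fragment_start
            a.mapping_quality = 60
            a.cigarstring = f"{len(read.bases)}M"
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.joint_qualities))
            a.set_tag(UMI_TAG, str(read.family_key[3])
                      if len(read.family_key) > 3 else "")
            a.set_tag(DUPLEX_TAG, int(read.duplex_flag))
            a.set_tag(FAMILY_SIZE_TAG, int(read.family_size))
            out.write(a)


def read_consensus_sam(path) -> list[ConsensusRead]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped:
                continue
            size = int(a.get_tag(FAMILY_SIZE_TAG)) if a.has_tag(FAMILY_SIZE_TAG) else 1
            reads.append(ConsensusRead(
                bases=a.query_sequence.encode(),
                joint_qualities=bytes(a.query_qualities),
                duplex_flag=int(a.get_tag(DUPLEX_TAG)) if a.has_tag(DUPLEX_TAG) else 0,
                family_size=size,
                stratum=min(size, 4),
                chrom=a.reference_name,
                fragment_start=a.reference_start,
                fragment_end=a.reference_start + a.query_length,
                family_key=(a.reference_name, a.reference_start,
                            a.reference_start + a.query_length,
                            a.get_tag(UMI_TAG) if a.has_tag(UMI_TAG) else "")))
    return reads


# --- BED / regions ---------------------------------------------------------

def write_bed(path, regions: Sequence[tuple[str, int, int]]) -> None:
    pd.DataFrame(regions, columns=["chrom", "start", "end"]).to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return [(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]


# --- VCF (monitored sites) -------------------------------------------------

def _vcf_header(reference_lengths: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in reference_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("TVAF", 1, "Float", "True (simulated) variant allele fraction")
    return header


def write_sites_vcf(path, sites: Sequence[Site],
                    reference_lengths: Mapping[str, int]) -> None:
    header = _vcf_header(reference_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sites:
            rec = out.new_record(contig=site.chrom, start=site.pos,
                                 stop=site.pos + 1,
                                 alleles=(site.ref, site.alt))
            rec.info["TVAF"] = float(site.true_vaf)
            out.write(rec)


def read_sites_vcf(path) -> list[Site]:
    sites = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            tvaf = float(rec.info.get("TVAF", 0.0)) if "TVAF" in rec.info else 0.0
            sites.append(Site(rec.contig, rec.start, rec.ref,
                              rec.alts[0] if rec.alts else ".", tvaf))
    return sites


def read_sites_tsv(path) -> list[Site]:
    df = pd.read_csv(path, sep="\t")
    return [Site(str(r.chrom), int(r.pos) - 1, str(r.ref), str(r.alt),
                 float(getattr(r, "true_vaf", 0.0)))
            for r in df.itertuples()]


def write_sites_tsv(path, sites: Sequence[Site]) -> None:
    pd.DataFrame([{"chrom": s.chrom, "pos": s.pos + 1, "ref": s.ref,
                   "alt": s.alt, "true_vaf": s.true_vaf}
                  for s in sites]).to_csv(path, sep="\t", index=False)


# --- truth -----------------------------------------------------------------

def write_truth_tsv(path, molecules: Sequence[TruthRecord],
                    include_sequence: bool = False) -> None:
    rows = []
    for m in molecules:
        row = {"molecule_id": m.molecule_id, "target_index": m.target_index,
               "origin_strand": m.origin_strand,
               "fragment_start": m.fragment_start,
               "fragment_end": m.fragment_end,
               "carries_variant": -1 if m.carries_variant is None
               else m.carries_variant}
        if include_sequence:
            row["true_sequence"] = m.true_sequence.decode()
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- error model / calls / MRD --------------------------------------------

def write_error_model_tsv(path, model: ErrorModel) -> None:
    model.to_frame().to_csv(path, sep="\t", index=False)


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"chrom": c.chrom, "pos": c.pos + 1, "ref": c.ref, "alt": c.alt,
               "alt_count": c.alt_count, "depth": c.depth,
               "vaf": c.vaf, "p_value": c.p_value, "z_score": c.z_score,
               "fold_change": c.fold_change, "lod": c.lod,
               "called": bool(c.called),
               "filters": ";".join(c.filter_reasons) or "PASS"}
        for st, (a, d) in sorted(c.strata_counts.items()):
            row[f"alt_{st}x"] = a
            row[f"depth_{st}x"] = d
        rows.append(row)
    return pd.DataFrame(rows)


def write_calls_tsv(path, calls: Sequence[VariantCall]) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False,
                                 float_format="%.6g")


def read_calls_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls_vcf(path, calls: Sequence[VariantCall],
                    reference_lengths: Mapping[str, int]) -> None:
    header = pysam.VariantHeader()
    for name, length in reference_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Pooled consensus depth")
    header.info.add("AC", 1, "Integer", "Alt-supporting consensus reads")
    header.info.add("AF", 1, "Float", "Variant allele fraction")
    header.info.add("PV", 1, "Float", "One-sided Fisher exact p-value")
    header.info.add("ZS", 1, "Float", "Proportion Z score")
    header.info.add("FC", 1, "Float", "Fold change over background")
    header.info.add("LOD", 1, "Float", "Limit of detection (VAF fraction)")
    header.filters.add("not_called", None, None, "Failed calling filters")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            rec = out.new_record(contig=c.chrom, start=c.pos, stop=c.pos + 1,
                                 alleles=(c.ref, c.alt))
            rec.info["DP"] = c.depth
            rec.info["AC"] = c.alt_count
            rec.info["AF"] = c.vaf
            rec.info["PV"] = c.p_value
            rec.info["ZS"] = c.z_score
            rec.info["FC"] = c.fold_change
            if np.isfinite(c.lod):
                rec.info["LOD"] = c.lod
            if c.called:
                rec.filter.add("PASS")
            else:
                rec.filter.add("not_called")
            out.write(rec)


def write_mrd_tsv(path, result: MrdResult) -> None:
    pd.DataFrame([{
        "n_variants": len(result.included_variants) + len(result.excluded_outliers),
        "n_included": len(result.included_variants),
        "n_excluded_outliers": len(result.excluded_outliers),
        "n_called_variants": result.n_called_variants,
        "target_alt": result.target_alt, "target_ref": result.target_ref,
        "flank_nonref": result.flank_nonref, "flank_ref": result.flank_ref,
        "p_value": result.p_value,
        "mrd_positive": result.mrd_positive,
        "mrd_positive_strict": result.mrd_positive_strict,
    }]).to_csv(path, sep="\t", index=False, float_format="%.6g")
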