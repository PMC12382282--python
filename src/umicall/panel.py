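"""Rule-based selection of monitoring variants for tumour-informed panels.

Candidates arrive annotated (exonic flag, repeat/low-complexity proximity,
distance to the nearest known SNP); selection hard-excludes variants near
repetitive elements or in low-complexity regions, penalizes variants close
to another candidate or a known SNP, prefers exonic variants, and emits a
target BED (site +- padding) alongside the monitored-variant table.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("chrom", "pos", "ref", "alt", "exonic",
                    "repeat_proximal", "low_complexity")
MIN_PANEL = 20
MAX_PANEL = 100


def select_monitoring_variants(candidates: pd.DataFrame,
                               n_variants: int = 30,
                               cluster_bp: int = 50,
                               padding: int = 120,
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank and select up to ``n_variants`` monitoring variants.

    ``candidates`` needs columns chrom, pos (1-based), ref, alt, exonic,
    repeat_proximal, low_complexity, and optionally snp_distance (bp to the
    nearest known SNP).  Returns (selected variants, target BED frame with
    0-based half-open ``pos-1 +- padding`` intervals).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in candidates.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    if not MIN_PANEL <= n_variants <= MAX_PANEL:
        raise ValueError(f"n_variants must be in [{MIN_PANEL}, {MAX_PANEL}]")

    df = candidates.copy()
    df = df[~(df["repeat_proximal"].astype(bool)
              | df["low_complexity"].astype(bool))]
    snp_dist = (df["snp_distance"] if "snp_distance" in df.columns
                else pd.Series(np.inf, index=df.index))
    df = df.assign(
        _snp_penalty=(snp_dist.fillna(np.inf) < cluster_bp).astype(int),
        _rank=lambda d: (~d["exonic"].astype(bool)).astype(int))
    df = df.sort_values(["_rank", "_snp_penalty", "chrom", "pos"],
                        kind="stable")

    selected_rows = []
    chosen: dict[str, list[int]] = {}
    for row in df.itertuples():
        near = any(abs(row.pos - p) < cluster_bp
                   for p in chosen.get(row.chrom, ()))
        if near:
            continue
        selected_rows.append(row.Index)
        chosen.setdefault(row.chrom, []).append(row.pos)
        if len(selected_rows) == n_variants:
            break
    selected = df.loc[selected_rows].drop(
        columns=["_rank", "_snp_penalty"]).reset_index(drop=True)
    if len(selected) < n_variants:
        logger.warning("only %d of %d requested variants survive selection",
                       len(selected), n_variants)
    bed = pd.DataFrame({
        "chrom": selected["chrom"],
        "start": (selected["pos"] - 1 - padding).clip(lower=0),
        "end": selected["pos"] - 1 + padding + 1,
    })
    return selected, bed
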