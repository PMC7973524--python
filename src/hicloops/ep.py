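"""Enhancer–promoter interaction annotation from significant contacts.

Significant pixels are collected without clustering or loop filters, mapped
to genomic anchor pairs, and intersected with promoter intervals.  A
promoter is the 1 kb window upstream of a gene's transcription start site
(strand-aware, clipped at the chromosome start).  A contact with exactly one
anchor on a promoter is an enhancer–promoter interaction — the other anchor
is the putative enhancer; a contact whose both anchors hit promoters yields
one record per direction, flagged bidirectional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .background import significant_pixel_mask
from .matrix import ContactMatrix, GenomicInterval
from .presets import Preset

__all__ = [
    "Promoter",
    "PROMOTER_LENGTH",
    "significant_contacts",
    "define_promoters",
    "read_tss_table",
    "annotate_ep",
]

PROMOTER_LENGTH = 1_000  # bp upstream of the TSS


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    interval: GenomicInterval
    strand: str

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def significant_contacts(
    cm: ContactMatrix,
    preset: Preset | None = None,
    max_distance: int = 2_000_000,
) -> pd.DataFrame:
    """All significant pixels with genomic anchors, up to ``max_distance``.

    No clustering and no loop filters are applied.  Columns: chrom, start1,
    end1, start2, end2, i, j, value, q_adj, distance (anchor-midpoint
    separation, bp).
    """
    preset = preset or Preset()
    if max_distance < cm.resolution:
        raise ValueError("max_distance must be at least one bin")
    result = significant_pixel_mask(
        cm,
        fit_quantile=preset.q,
        q_threshold=preset.q_value_trhd,
        scaling_threshold=preset.scaling_q_value_trhd,
        adjust=preset.adjust_by_scale,
        max_distance=max_distance,
        include_zeros=preset.include_zeros,
        bh_scope=preset.bh_scope,
    )
    df = result.calls.copy()
    res = cm.resolution
    df["chrom"] = cm.chrom
    df["start1"] = df["i"] * res
    df["end1"] = df["start1"] + res
    df["start2"] = df["j"] * res
    df["end2"] = df["start2"] + res
    df["distance"] = (df["j"] - df["i"]) * res
    cols = ["chrom", "start1", "end1", "start2", "end2",
            "i", "j", "value", "q_adj", "distance"]
    return df[cols].reset_index(drop=True)


def define_promoters(genes: pd.DataFrame) -> list[Promoter]:
    """Promoter windows from a TSS table (columns chrom, tss, gene_id, strand).

    ``+`` strand: ``[TSS - 1000, TSS)``; ``-`` strand: ``[TSS, TSS + 1000)``;
    clipped at position 0.  Unknown strands raise, naming the record.
    """
    promoters = []
    for rec in genes.itertuples():
        tss = int(rec.tss)
        if rec.strand == "+":
            start, end = max(0, tss - PROMOTER_LENGTH), tss
        elif rec.strand == "-":
            start, end = tss, tss + PROMOTER_LENGTH
        else:
            raise ValueError(
                f"gene {rec.gene_id!r}: unknown strand {rec.strand!r}"
            )
        if end <= start:  # TSS at the chromosome start on + strand
            continue
        promoters.append(
            Promoter(
                gene_id=str(rec.gene_id),
                interval=GenomicInterval(str(rec.chrom), start, end),
                strand=rec.strand,
            )
        )
    return promoters


def read_tss_table(path: str) -> pd.DataFrame:
    """Read a BED-like TSS table.

    Accepts either a 4-column table ``chrom  tss  gene_id  strand`` or BED6
    (``chrom start end name score strand``, TSS = start on ``+`` / end on
    ``-``).  ``#`` comment lines are skipped.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "tss", "gene_id", "strand"])
    if df.shape[1] >= 6:
        tss = np.where(df[5] == "+", df[1], df[2])
        return pd.DataFrame(
            {"chrom": df[0], "tss": tss, "gene_id": df[3], "strand": df[5]}
        )
    if df.shape[1] == 4:
        df.columns = ["chrom", "tss", "gene_id", "strand"]
        return df
    raise ValueError(f"{path}: expected 4 or >= 6 columns, got {df.shape[1]}")


def _hits(start: np.ndarray, end: np.ndarray, promoters: list[Promoter], chrom: str):
    """For each interval, list of promoter indices overlapping by >= 1 bp."""
    ps = np.array([p.interval.start for p in promoters])
    pe = np.array([p.interval.end for p in promoters])
    pc = np.array([p.chrom for p in promoters])
    out = []
    for s, e in zip(start, end):
        m = (pc == chrom) & (ps < e) & (s < pe)
        out.append(np.flatnonzero(m))
    return out


def annotate_ep(
    contacts: pd.DataFrame, promoters: list[Promoter]
) -> pd.DataFrame:
    """Intersect contact anchors with promoters.

    Keeps contacts with at least one promoter-overlapping anchor; the other
    anchor is labelled the enhancer.  When both anchors hit promoters, two
    records are emitted (one per direction) with ``bidirectional=True``.

    Columns of the result: gene_id, chrom, promoter_start, promoter_end,
    enhancer_start, enhancer_end, q_adj, distance, bidirectional.
    """
    if len(contacts) == 0 or not promoters:
        return pd.DataFrame(
            columns=["gene_id", "chrom", "promoter_start", "promoter_end",
                     "enhancer_start", "enhancer_end", "q_adj", "distance",
                     "bidirectional"]
        )
    chrom = contacts["chrom"].iloc[0]
    s1 = contacts["start1"].to_numpy()
    e1 = contacts["end1"].to_numpy()
    s2 = contacts["start2"].to_numpy()
    e2 = contacts["end2"].to_numpy()
    hits1 = _hits(s1, e1, promoters, chrom)
    hits2 = _hits(s2, e2, promoters, chrom)
    rows = []
    for k in range(len(contacts)):
        rec = contacts.iloc[k]
        both = len(hits1[k]) > 0 and len(hits2[k]) > 0
        for pix in hits1[k]:
            rows.append(_ep_row(rec, promoters[pix], s2[k], e2[k], both))
        for pix in hits2[k]:
            rows.append(_ep_row(rec, promoters[pix], s1[k], e1[k], both))
    return pd.DataFrame(rows)


def _ep_row(rec, promoter: Promoter, enh_start: int, enh_end: int, both: bool):
    return {
        "gene_id": promoter.gene_id,
        "chrom": promoter.chrom,
        "promoter_start": int(rec.start1) if enh_start == rec.start2 else int(rec.start2),
        "promoter_end": int(rec.end1) if enh_start == rec.start2 else int(rec.end2),
        "enhancer_start": int(enh_start),
        "enhancer_end": int(enh_end),
        "q_adj": float(rec.q_adj),
        "distance": int(rec.distance),
        "bidirectional": bool(both),
    }
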