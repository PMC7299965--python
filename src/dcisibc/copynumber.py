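"""Segment-based copy-number summaries: gene-level copy number by maximal
overlap, genomic instability index (GII), and cohort aberration frequencies.

Segments are 1-based inclusive (sample, chrom, start, end, cn) with integer
copy number; segmentation itself happens upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GIIRecord",
    "gene_copy_number",
    "genomic_instability_index",
    "aberration_frequency",
]


@dataclass(frozen=True)
class GIIRecord:
    sample_id: str
    gii: float
    covered_bp: int
    aberrant_bp: int
    baseline: int


def _overlap_bp(seg_start, seg_end, gene_start, gene_end) -> int:
    return max(0, min(seg_end, gene_end) - max(seg_start, gene_start) + 1)


def gene_copy_number(segments: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per gene and sample, the copy number of the segment overlapping the
    gene the most (in bp). Equal overlap is broken in favour of the segment
    with the smaller start. Genes with no overlapping segment get NaN.

    ``genes`` columns: gene_id (or name), chrom, start, end.
    """
    gene_col = "gene_id" if "gene_id" in genes.columns else "name"
    samples = list(dict.fromkeys(segments["sample"]))
    table = pd.DataFrame(
        np.nan, index=list(genes[gene_col]), columns=samples, dtype=float
    )
    by_sample_chrom = {k: g for k, g in segments.groupby(["sample", "chrom"])}
    n_uncovered = 0
    for _, gene in genes.iterrows():
        gid, chrom, gstart, gend = (
            gene[gene_col], gene["chrom"], int(gene["start"]), int(gene["end"]),
        )
        for sample in samples:
            grp = by_sample_chrom.get((sample, chrom))
            if grp is None:
                n_uncovered += 1
                continue
            best_cn, best_ov, best_start = np.nan, 0, None
            for start, end, cn in zip(grp["start"], grp["end"], grp["cn"]):
                ov = _overlap_bp(start, end, gstart, gend)
                if ov > best_ov or (
                    ov == best_ov and ov > 0 and start < best_start
                ):
                    best_cn, best_ov, best_start = cn, ov, start
            if best_ov == 0:
                n_uncovered += 1
            else:
                table.at[gid, sample] = float(best_cn)
    if n_uncovered:
        logger.info("%d gene/sample pairs without segment coverage", n_uncovered)
    table.index.name = "gene_id"
    return table


def genomic_instability_index(
    segments: pd.DataFrame,
    baseline: int = 2,
    *,
    ploidy: pd.Series | dict | None = None,
) -> list[GIIRecord]:
    """Fraction of the covered genome with copy number different from the
    baseline, per sample.

    By default the baseline is the diploid cn=2. Alternatively, supply a
    per-sample ``ploidy``; each sample's baseline is then the nearest
    integer to its ploidy. The denominator is the summed segment length
    (uncovered genome carries no information).
    """
    records = []
    for sample, grp in segments.groupby("sample", sort=False):
        if ploidy is not None:
            base = int(round(float(pd.Series(ploidy)[sample])))
        else:
            base = int(baseline)
        lengths = (grp["end"] - grp["start"] + 1).to_numpy()
        covered = int(lengths.sum())
        if covered == 0:
            raise ValueError(f"sample {sample} has zero covered genome")
        aberrant = int(lengths[(grp["cn"] != base).to_numpy()].sum())
        records.append(
            GIIRecord(
                sample_id=str(sample),
                gii=aberrant / covered,
                covered_bp=covered,
                aberrant_bp=aberrant,
                baseline=base,
            )
        )
    return records


def gii_to_series(records: list[GIIRecord]) -> pd.Series:
    return pd.Series({r.sample_id: r.gii for r in records}, name="gii")


def aberration_frequency(
    gene_cn: pd.DataFrame, groups: pd.Series | dict, baseline: int = 2
) -> pd.DataFrame:
    """Per locus (row of ``gene_cn``) and group: fraction of samples with a
    gain (cn > baseline) and with a loss (cn < baseline). A sample counts
    toward at most one of the two per locus; missing values are excluded
    from the denominator."""
    groups = pd.Series(groups)
    rows = []
    for gname in pd.unique(groups):
        members = groups.index[groups == gname].intersection(gene_cn.columns)
        if len(members) == 0:
            raise ValueError(f"group {gname} has no samples in the table")
        sub = gene_cn[members]
        n = sub.notna().sum(axis=1)
        if (n == 0).all():
            raise ValueError(f"group {gname} has no observed copy numbers")
        gain = (sub > baseline).sum(axis=1) / n.replace(0, np.nan)
        loss = (sub < baseline).sum(axis=1) / n.replace(0, np.nan)
        for locus in gene_cn.index:
            rows.append(
                {
                    "locus": locus,
                    "group": gname,
                    "gain_freq": float(gain[locus]) if n[locus] else np.nan,
                    "loss_freq": float(loss[locus]) if n[locus] else np.nan,
                    "n": int(n[locus]),
                }
            )
    return pd.DataFrame(rows)
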