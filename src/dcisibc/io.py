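"""Tab-separated readers and writers for every on-disk format the pipeline
consumes or emits.

Coordinate convention: genomic intervals are 1-based inclusive everywhere in
memory. BED-like files are 0-based half-open on disk and converted by these
readers/writers; SEG-like files are written and read as 1-based inclusive.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_segments",
    "write_segments",
    "read_bed",
    "write_bed",
    "read_sample_annotations",
    "write_sample_annotations",
    "read_signature_defs",
    "write_signature_defs",
]

SEG_COLUMNS = ["sample", "chrom", "start", "end", "cn"]


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a feature x sample matrix (first column = feature id, header row
    of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dupes[:5]}")
    return df


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "id") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def read_segments(path) -> pd.DataFrame:
    """Read a SEG-like TSV (sample, chrom, start, end, cn; 1-based inclusive)
    and validate the per-sample/per-chromosome non-overlap invariant."""
    seg = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in seg.columns]
    if missing:
        raise ValueError(f"segment file {path} missing columns: {missing}")
    seg = seg[SEG_COLUMNS].copy()
    validate_segments(seg)
    return seg


def validate_segments(seg: pd.DataFrame) -> None:
    if (seg["end"] < seg["start"]).any():
        raise ValueError("segment with end < start")
    if (seg["cn"] < 0).any():
        raise ValueError("negative copy number in segments")
    for (sample, chrom), grp in seg.groupby(["sample", "chrom"], sort=False):
        g = grp.sort_values("start")
        if (g["start"].values[1:] <= g["end"].values[:-1]).any():
            raise ValueError(f"overlapping segments for {sample} on {chrom}")


def write_segments(seg: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    seg[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed(path, name_col: str = "name") -> pd.DataFrame:
    """Read a BED-like file (chrom, start, end, name; 0-based half-open on
    disk) into 1-based inclusive coordinates."""
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", name_col]
    )
    bed["start"] = bed["start"].astype(int) + 1
    bed["end"] = bed["end"].astype(int)
    if (bed["end"] < bed["start"]).any():
        raise ValueError(f"empty or inverted interval in {path}")
    return bed


def write_bed(df: pd.DataFrame, path, name_col: str = "name") -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = df[["chrom", "start", "end", name_col]].copy()
    out["start"] = out["start"].astype(int) - 1
    out.to_csv(path, sep="\t", header=False, index=False)


def read_sample_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    if ann.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return ann


def write_sample_annotations(ann: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ann.to_csv(path, sep="\t", index_label="sample")


def read_signature_defs(path) -> dict[str, list[tuple[str, float]]]:
    """Read signature definitions (columns: signature, gene_id, weight)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("signature", "gene_id", "weight"):
        if col not in df.columns:
            raise ValueError(f"signature file {path} missing column {col}")
    out: dict[str, list[tuple[str, float]]] = {}
    for name, grp in df.groupby("signature", sort=False):
        out[name] = list(zip(grp["gene_id"], grp["weight"].astype(float)))
    return out


def write_signature_defs(defs: dict[str, list[tuple[str, float]]], path) -> None:
    rows = [
        {"signature": name, "gene_id": g, "weight": w}
        for name, entries in defs.items()
        for g, w in entries
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["signature", "gene_id", "weight"]).to_csv(
        path, sep="\t", index=False
    )
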