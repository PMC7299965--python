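#!/usr/bin/env python
"""Copy-number summaries from the segment layer: per-sample genomic
instability index (fraction of covered genome with copy number != 2),
gene-level copy number by maximal segment overlap (including the ERBB2
locus used as the HER2 copy-number readout), and per-group gain/loss
frequencies at the modelled genes.
"""

import argparse
from pathlib import Path

import pandas as pd

from dcisibc import io as dio
from dcisibc.copynumber import (
    aberration_frequency, gene_copy_number, genomic_instability_index, gii_to_series,
)
from dcisibc.synthetic import read_cohort

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()
    data = read_cohort(args.cohort)
    ann = data["samples"]

    gii = gii_to_series(genomic_instability_index(data["segments"]))
    gii.to_frame().to_csv(ROOT / "results" / "gii.tsv", sep="\t", index_label="sample")
    cn = gene_copy_number(data["segments"], data["gene_models"])
    dio.write_matrix_tsv(cn, ROOT / "results" / "gene_copy_number.tsv", "gene_id")

    tumors = ann.index[ann["tumor_type"] != "NORMAL"]
    freq = aberration_frequency(cn[list(tumors)], ann.loc[tumors, "tumor_type"])
    freq.to_csv(ROOT / "results" / "aberration_frequency.tsv", sep="\t", index=False)

    for st in ("Basal", "Her2", "LumA", "LumB"):
        sel = ann.index[(ann["subtype"] == st)]
        parts = []
        for tt in ("DCIS", "IBC"):
            grp = gii[[s for s in sel if ann.at[s, "tumor_type"] == tt]]
            parts.append(f"{tt} median GII {grp.median():.3f}")
        print(f"{st}: " + ", ".join(parts))
    erbb2 = cn.loc["ERBB2"]
    her2 = ann.index[ann["subtype"] == "Her2"]
    print(f"ERBB2 copy number in HER2-enriched tumors: median {erbb2[her2].median():.0f}")


if __name__ == "__main__":
    main()
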