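#!/usr/bin/env python
"""Assemble the per-sample summary table (annotations, subtype calls,
receptor status, signature scores, GII, HER2 copy number, window score) and
run the subtype-stratified DCIS-vs-IBC Mann-Whitney comparisons.
"""

import argparse
from pathlib import Path

import pandas as pd

from dcisibc import io as dio
from dcisibc.compare import (
    build_sample_summary, group_tests_to_frame, stratified_group_tests,
)
from dcisibc.synthetic import read_cohort

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=RESULTS / "cohort")
    args = ap.parse_args()
    data = read_cohort(args.cohort)
    ann = data["samples"]

    calls = dio.read_matrix_tsv(RESULTS / "subtype_calls.tsv")
    scores = dio.read_matrix_tsv(RESULTS / "signature_scores.tsv")
    gii = pd.read_csv(RESULTS / "gii.tsv", sep="\t", index_col=0)["gii"]
    cn = dio.read_matrix_tsv(RESULTS / "gene_copy_number.tsv")
    window = pd.read_csv(RESULTS / "window_scores.tsv", sep="\t", index_col=0)[
        "window_mean_z"
    ]
    summary = build_sample_summary(
        ann.drop(columns=["subtype"]),
        calls,
        scores=scores,
        gii=gii,
        her2_cn=cn.loc["ERBB2"],
        window_score=window,
    )
    dio.write_matrix_tsv(summary, RESULTS / "sample_summary.tsv", "sample")

    tumors = summary[summary["tumor_type"].isin(["DCIS", "IBC"])]
    tests = stratified_group_tests(
        tumors, ["purity", "gii", "proliferation", "emt", "window_mean_z"]
    )
    frame = group_tests_to_frame(tests)
    frame.to_csv(RESULTS / "group_tests.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
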