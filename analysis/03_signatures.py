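#!/usr/bin/env python
"""Score the proliferation and EMT signatures (mean of per-gene standard
scores, adhesion genes weighted negatively in the EMT score) and compare
them between DCIS and IBC within each called subtype.
"""

import argparse
from pathlib import Path

import pandas as pd

from dcisibc import io as dio
from dcisibc.compare import group_tests_to_frame, stratified_group_tests
from dcisibc.signatures import SignatureDef, score_signatures
from dcisibc.synthetic import read_cohort

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()
    data = read_cohort(args.cohort)
    sigs = [
        SignatureDef(name, tuple(entries))
        for name, entries in data["signatures"].items()
    ]
    scores, found = score_signatures(data["expression"], sigs)
    dio.write_matrix_tsv(scores, ROOT / "results" / "signature_scores.tsv", "sample")
    print({name: f"{n} genes" for name, n in found.items()})

    calls = dio.read_matrix_tsv(ROOT / "results" / "subtype_calls.tsv")
    table = scores.join(data["samples"][["tumor_type"]]).join(calls[["subtype"]])
    results = stratified_group_tests(table, list(scores.columns))
    frame = group_tests_to_frame(results)
    frame.to_csv(ROOT / "results" / "signature_tests.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
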