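"""Subtype-stratified DCIS-vs-IBC statistics, the per-sample summary table,
and pipeline orchestration.

The comparison layer mirrors the study design: categorical compositions
(subtype, receptor status) are compared between tumor types with Fisher-type
exact tests, and continuous per-sample features (purity, GII, signature
scores, window methylation) with two-sided Mann-Whitney U tests run
separately within each subtype. No multiplicity correction is applied across
these few stratified comparisons; FDR control lives in the differential-
methylation stage only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .copynumber import gene_copy_number, genomic_instability_index, gii_to_series
from .expression import call_receptor_status, receptor_calls_to_series
from .methylation import (
    diffmeth_to_frame,
    differential_methylation,
    gene_methylation_profile,
    knn_impute,
    qc_filter_cpgs,
    qc_mask,
    window_mean_z,
    window_purity_association,
    window_scores_to_series,
)
from .signatures import SignatureDef, score_signatures
from .stats import fisher_exact_table, mann_whitney_u
from .subtyping import (
    CentroidSet,
    assign_subtype,
    balanced_center,
    call_core_basal,
    calls_to_frame,
)
from . import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTestResult",
    "fisher_exact_distribution",
    "stratified_group_tests",
    "build_sample_summary",
    "run_pipeline",
]

SUBTYPE_DISPLAY_ORDER = ("Basal", "Her2", "LumA", "LumB")


@dataclass(frozen=True)
class GroupTestResult:
    feature: str
    subtype: str  # a subtype name or "all"
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    direction: str  # "DCIS", "IBC" or "none" — group with the larger median


def fisher_exact_distribution(
    labels: pd.Series, groups: pd.Series, *, seed: int = 0
) -> GroupTestResult:
    """Fisher-type exact test that a categorical label (subtype, ER status)
    is distributed identically across two groups (tumor types)."""
    labels = pd.Series(labels)
    groups = pd.Series(groups)
    shared = labels.index.intersection(groups.index)
    tab = pd.crosstab(groups[shared], labels[shared])
    if tab.shape[0] != 2:
        raise ValueError(f"need exactly 2 groups, got {list(tab.index)}")
    if tab.shape[1] < 2:
        raise ValueError("label margin has fewer than 2 categories")
    p, method = fisher_exact_table(tab.to_numpy(), seed=seed)
    return GroupTestResult(
        feature=str(labels.name or "label"),
        subtype="all",
        test=method,
        statistic=float("nan"),
        p_value=p,
        n_a=int(tab.iloc[0].sum()),
        n_b=int(tab.iloc[1].sum()),
        direction="none",
    )


def stratified_group_tests(
    summary: pd.DataFrame,
    features: list[str],
    *,
    group_col: str = "tumor_type",
    subtype_col: str = "subtype",
    group_a: str = "DCIS",
    group_b: str = "IBC",
    min_group_size: int = 2,
) -> list[GroupTestResult]:
    """Two-sided Mann-Whitney U per subtype and feature between the two
    tumor types. Subtype cells with fewer than ``min_group_size`` non-missing
    values in either group are skipped with a notice."""
    unknown = [f for f in features if f not in summary.columns]
    if unknown:
        raise ValueError(
            f"unknown features {unknown}; available: {sorted(summary.columns)}"
        )
    results = []
    for st in pd.unique(summary[subtype_col].dropna()):
        if st == syn.NORMAL:
            continue
        cell = summary[summary[subtype_col] == st]
        for feat in features:
            a = cell.loc[cell[group_col] == group_a, feat].dropna().to_numpy(float)
            b = cell.loc[cell[group_col] == group_b, feat].dropna().to_numpy(float)
            if len(a) < min_group_size or len(b) < min_group_size:
                logger.info(
                    "skipping %s in %s: group sizes %d vs %d", feat, st, len(a), len(b)
                )
                continue
            res = mann_whitney_u(a, b)
            med_a, med_b = float(np.median(a)), float(np.median(b))
            if med_a > med_b:
                direction = group_a
            elif med_b > med_a:
                direction = group_b
            else:
                direction = "none"
            results.append(
                GroupTestResult(
                    feature=feat,
                    subtype=str(st),
                    test=f"mann-whitney-{res.method}",
                    statistic=res.u_statistic,
                    p_value=res.p_value,
                    n_a=res.n_x,
                    n_b=res.n_y,
                    direction=direction,
                )
            )
    return results


def group_tests_to_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature, "subtype": r.subtype, "test": r.test,
                "statistic": r.statistic, "p_value": r.p_value,
                "n_dcis": r.n_a, "n_ibc": r.n_b, "direction": r.direction,
            }
            for r in results
        ]
    )


def build_sample_summary(
    annotations: pd.DataFrame,
    subtype_calls: pd.DataFrame,
    *,
    receptor_status: pd.DataFrame | None = None,
    scores: pd.DataFrame | None = None,
    gii: pd.Series | None = None,
    her2_cn: pd.Series | None = None,
    window_score: pd.Series | None = None,
    subtype_order=SUBTYPE_DISPLAY_ORDER,
) -> pd.DataFrame:
    """Outer-join all per-sample layers into one table, sorted by subtype
    (fixed display order) and then by descending correlation to the sample's
    own subtype. Missing layers leave missing fields; conflicting duplicate
    annotations raise."""
    parts = [annotations, subtype_calls]
    for extra in (receptor_status, scores):
        if extra is not None:
            parts.append(extra)
    for name, series in (
        ("gii", gii), ("her2_cn", her2_cn), ("window_mean_z", window_score)
    ):
        if series is not None:
            parts.append(series.rename(name).to_frame())
    all_ids = parts[0].index
    for p in parts[1:]:
        if p.index.has_duplicates:
            raise ValueError("duplicate sample ids in a summary layer")
        all_ids = all_ids.union(p.index)
    missing_any = [p for p in parts if not all_ids.isin(p.index).all()]
    if missing_any:
        logger.warning("sample ids are not identical across layers; outer join used")
    summary = pd.concat([p.reindex(all_ids) for p in parts], axis=1)
    summary = summary.loc[:, ~summary.columns.duplicated()]
    own_cor = pd.Series(np.nan, index=summary.index)
    for sid in summary.index:
        st = summary.at[sid, "subtype"]
        col = f"cor_{st}"
        if isinstance(st, str) and col in summary.columns:
            own_cor[sid] = summary.at[sid, col]
    summary["own_correlation"] = own_cor
    order = {s: i for i, s in enumerate(subtype_order)}
    summary["_k"] = summary["subtype"].map(lambda s: order.get(s, len(order)))
    summary = summary.sort_values(
        ["_k", "own_correlation"], ascending=[True, False], kind="stable"
    ).drop(columns="_k")
    summary.index.name = "sample"
    return summary


DEFAULT_FEATURES = ["purity", "gii", "proliferation", "emt", "window_mean_z"]


def _stage(report: dict, name: str, status: str, **info) -> None:
    report["stages"][name] = {"status": status, **info}


def run_pipeline(config_path, outdir=None, seed=None) -> Path:
    """Run the full analysis from a YAML config; returns the output
    directory.

    The config either names input files (``inputs:`` with keys expression,
    centroids, samples, segments, betas, detection_p, cpg_positions,
    gene_models, signatures) or requests synthetic data (``synthetic:`` with
    generator fields). Stages whose inputs are absent are reported as
    skipped. Identical config + seed reproduce byte-identical outputs.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text()) or {}
    if seed is None:
        seed = int(cfg.get("seed", 0))
    outdir = Path(outdir or cfg.get("outdir", "pipeline_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed, "config": str(config_path), "stages": {}}

    data: dict = {}
    window = None
    if "synthetic" in cfg:
        syn_cfg = dict(cfg["synthetic"] or {})
        syn_cfg["seed"] = seed
        config = syn.CohortConfig(**syn_cfg)
        cohort = syn.generate_cohort(config)
        syn.write_cohort(cohort, outdir / "cohort")
        data = syn.read_cohort(outdir / "cohort")
        window = tuple(data["truth"]["window"])
        _stage(report, "simulate", "ok", n_samples=int(data["samples"].shape[0]))
    elif "inputs" in cfg:
        inputs = cfg["inputs"]
        readers = {
            "expression": dio.read_matrix_tsv, "centroids": dio.read_matrix_tsv,
            "betas": dio.read_matrix_tsv, "detection_p": dio.read_matrix_tsv,
            "segments": dio.read_segments, "samples": dio.read_sample_annotations,
            "cpg_positions": dio.read_bed, "gene_models": dio.read_bed,
            "signatures": dio.read_signature_defs,
        }
        for key, reader in readers.items():
            if key in inputs:
                data[key] = reader(inputs[key])
        if "window" in cfg:
            w = cfg["window"]
            window = (w["chrom"], int(w["start"]), int(w["end"]))
        _stage(report, "load", "ok", layers=sorted(data))
    else:
        raise ValueError("config must contain either 'synthetic' or 'inputs'")

    if "expression" not in data or "samples" not in data:
        raise ValueError("pipeline requires at least expression and samples layers")
    expr = data["expression"]
    samples = data["samples"]

    # --- receptor status and subtyping ---------------------------------
    sub_cfg = cfg.get("subtyping", {})
    receptor = {}
    for gene in ("ESR1", "PGR"):
        if gene in expr.index:
            calls = call_receptor_status(
                expr.loc[gene], gene,
                fallback_cutoff=sub_cfg.get("fallback_cutoff"),
                random_state=seed,
            )
            receptor[gene] = receptor_calls_to_series(calls)
    receptor_df = pd.DataFrame(receptor).rename(
        columns={"ESR1": "er_status", "PGR": "pgr_status"}
    )
    if "centroids" in data:
        er = receptor_df["er_status"]
        tumor_cols = samples.index[samples["tumor_type"] != syn.NORMAL]
        tumor_expr = expr[[c for c in expr.columns if c in set(tumor_cols)]]
        centered, _ = balanced_center(
            tumor_expr, er, w_pos=float(sub_cfg.get("w_pos", 0.6))
        )
        calls = assign_subtype(centered, CentroidSet(data["centroids"]))
        calls = call_core_basal(
            calls, threshold=float(sub_cfg.get("core_basal_threshold", 0.6))
        )
        calls_df = calls_to_frame(calls)
        dio.write_matrix_tsv(calls_df, outdir / "subtype_calls.tsv", "sample")
        _stage(report, "subtype", "ok", n_samples=len(calls))
    else:
        calls_df = pd.DataFrame(
            index=pd.Index([], name="sample"),
            columns=["subtype", "second_subtype", "core_basal", "n_genes_used"],
        )
        _stage(report, "subtype", "skipped", reason="no centroids input")

    # --- signature scores ----------------------------------------------
    if "signatures" in data:
        sigs = [
            SignatureDef(name, tuple(entries))
            for name, entries in data["signatures"].items()
        ]
        scores, found = score_signatures(expr, sigs)
        dio.write_matrix_tsv(scores, outdir / "signature_scores.tsv", "sample")
        _stage(report, "scores", "ok", genes_found=found)
    else:
        scores = None
        _stage(report, "scores", "skipped", reason="no signature definitions")

    # --- copy number ----------------------------------------------------
    gii = her2_cn = None
    if "segments" in data:
        cn_cfg = cfg.get("copy_number", {})
        baseline = int(cn_cfg.get("baseline", 2))
        gii_records = genomic_instability_index(data["segments"], baseline=baseline)
        gii = gii_to_series(gii_records)
        gii.to_frame().to_csv(outdir / "gii.tsv", sep="\t", index_label="sample")
        if "gene_models" in data:
            cn_table = gene_copy_number(data["segments"], data["gene_models"])
            dio.write_matrix_tsv(cn_table, outdir / "gene_copy_number.tsv", "gene_id")
            if "ERBB2" in cn_table.index:
                her2_cn = cn_table.loc["ERBB2"]
        _stage(report, "cnv", "ok", baseline=baseline, n_samples=int(gii.size))
    else:
        _stage(report, "cnv", "skipped", reason="no segments input")

    # --- methylation ----------------------------------------------------
    window_score = None
    meth_cfg = cfg.get("methylation", {})
    if "betas" in data and "detection_p" in data:
        masked, n_masked = qc_mask(
            data["betas"], data["detection_p"],
            p_threshold=float(meth_cfg.get("detection_p_threshold", 0.05)),
        )
        filtered, dropped = qc_filter_cpgs(
            masked, fail_fraction=float(meth_cfg.get("max_fail_fraction", 0.25))
        )
        imputed = knn_impute(filtered, k=int(meth_cfg.get("knn_k", 10)))
        masked_fraction = n_masked / masked.size
        profiles = None
        if "cpg_positions" in data and "gene_models" in data:
            profiles, prof_info = gene_methylation_profile(
                imputed, data["cpg_positions"], data["gene_models"],
                flank_bp=int(meth_cfg.get("flank_bp", 50_000)),
            )
            dio.write_matrix_tsv(profiles, outdir / "methylation_profiles.tsv", "gene_id")
            diff = differential_methylation(
                profiles,
                samples["tumor_type"],
                calls_df["subtype"] if len(calls_df) else samples["subtype"],
                fdr_alpha=float(meth_cfg.get("fdr_alpha", 0.05)),
                effect_top_fraction=float(meth_cfg.get("effect_top_fraction", 0.20)),
            )
            diff_df = diffmeth_to_frame(diff)
            diff_df.to_csv(outdir / "differential_methylation.tsv", sep="\t", index=False)
        if window is not None and "cpg_positions" in data:
            wscores = window_mean_z(imputed, data["cpg_positions"], window)
            window_score = window_scores_to_series(wscores)
            window_score.to_frame().to_csv(
                outdir / "window_scores.tsv", sep="\t", index_label="sample"
            )
            if "purity" in samples.columns:
                tumor_scores = [
                    s for s in wscores
                    if samples.at[s.sample_id, "tumor_type"] != syn.NORMAL
                ]
                assoc = window_purity_association(
                    tumor_scores, samples["purity"]
                )
                report["window_purity_association"] = assoc
        _stage(
            report, "methylation", "ok",
            masked_fraction=masked_fraction,
            n_cpgs_dropped=len(dropped),
            n_cpgs_retained=int(imputed.shape[0]),
        )
    else:
        _stage(report, "methylation", "skipped", reason="no beta/detection-p input")

    # --- comparisons and summary ---------------------------------------
    summary = build_sample_summary(
        samples.drop(columns=[c for c in ("subtype",) if c in samples.columns]),
        calls_df,
        receptor_status=receptor_df if len(receptor_df) else None,
        scores=scores,
        gii=gii,
        her2_cn=her2_cn,
        window_score=window_score,
    )
    dio.write_matrix_tsv(summary, outdir / "sample_summary.tsv", "sample")

    tumors = summary[summary["tumor_type"].isin(["DCIS", "IBC"])]
    tests = []
    if "subtype" in tumors.columns and tumors["subtype"].notna().any():
        tests.append(
            fisher_exact_distribution(
                tumors["subtype"].rename("subtype_distribution"),
                tumors["tumor_type"], seed=seed,
            )
        )
    if "er_status" in tumors.columns:
        tests.append(
            fisher_exact_distribution(
                tumors["er_status"].rename("er_distribution"),
                tumors["tumor_type"], seed=seed,
            )
        )
    features = [
        f for f in cfg.get("compare", {}).get("features", DEFAULT_FEATURES)
        if f in tumors.columns
    ]
    tests.extend(stratified_group_tests(tumors, features))
    tests_df = group_tests_to_frame(tests)
    tests_df.to_csv(outdir / "group_tests.tsv", sep="\t", index=False)
    _stage(report, "compare", "ok", n_tests=len(tests))

    report["ok"] = all(
        s["status"] in ("ok", "skipped") for s in report["stages"].values()
    )
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return outdir
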