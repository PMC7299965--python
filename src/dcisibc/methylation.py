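"""450K-style methylation analysis: QC masking and filtering of beta-values,
kNN imputation, per-gene first-principal-component methylation profiles,
subtype-stratified differential methylation with a joint FDR + effect-size
criterion, and windowed mean-Z scores for long-range epigenetic silencing.

A beta-value is the fraction of methylated molecules at a CpG, in [0, 1].
The per-gene "methylation profile" compresses all CpGs within the gene body
plus a 50 kb flank into one value per sample: the sample scores on the first
principal component of the local CpG submatrix, oriented so that
hypermethylated samples receive higher profile values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_fdr, mann_whitney_u, spearman

logger = logging.getLogger(__name__)

__all__ = [
    "DiffMethResult",
    "WindowScore",
    "qc_mask",
    "qc_filter_cpgs",
    "knn_impute",
    "gene_methylation_profile",
    "differential_methylation",
    "window_mean_z",
    "window_purity_association",
]


@dataclass(frozen=True)
class DiffMethResult:
    gene_id: str
    subtype: str
    u_statistic: float
    p_value: float
    fdr_q: float
    effect_size: float
    significant: bool


@dataclass(frozen=True)
class WindowScore:
    sample_id: str
    mean_z: float
    n_cpgs: int
    window: tuple[str, int, int]


def qc_mask(
    betas: pd.DataFrame, detection_p: pd.DataFrame, p_threshold: float = 0.05
) -> tuple[pd.DataFrame, int]:
    """Mask beta-values whose detection p-value is strictly above the
    threshold (unreliable probe signal). Returns the masked matrix and the
    number of newly masked entries."""
    if betas.shape != detection_p.shape:
        raise ValueError("beta and detection-p matrices must have the same shape")
    mask = detection_p.to_numpy() > p_threshold
    out = betas.copy()
    values = out.to_numpy(dtype=float)
    n_masked = int((mask & ~np.isnan(values)).sum())
    values[mask] = np.nan
    out.iloc[:, :] = values
    logger.info("masked %d beta-values at detection p > %s", n_masked, p_threshold)
    return out, n_masked


def qc_filter_cpgs(
    betas: pd.DataFrame, fail_fraction: float = 0.25
) -> tuple[pd.DataFrame, list[str]]:
    """Drop CpG rows whose missing fraction is strictly above
    ``fail_fraction``. Returns the filtered matrix and the dropped ids."""
    frac_missing = betas.isna().mean(axis=1)
    dropped = betas.index[frac_missing > fail_fraction]
    kept = betas.drop(index=dropped)
    if kept.shape[0] == 0:
        raise ValueError("all CpGs failed the missing-fraction filter")
    return kept, list(dropped)


def knn_impute(betas: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing beta-values from the k nearest CpG rows.

    Distance between CpG rows is Euclidean over jointly observed samples,
    scaled by the fraction observed (so rows with few shared samples are not
    spuriously close). A missing entry is replaced by the mean of the target
    sample's values over the k nearest rows observed at that sample; rows
    with no eligible neighbour fall back to the row mean. Imputed values are
    clipped to [0, 1].
    """
    values = betas.to_numpy(dtype=float).copy()
    missing = np.isnan(values)
    if not missing.any():
        return betas.copy()
    all_missing = missing.all(axis=1)
    if all_missing.any():
        bad = list(betas.index[all_missing])
        raise ValueError(f"CpG rows entirely missing, cannot impute: {bad[:10]}")
    rows_with_na = np.flatnonzero(missing.any(axis=1))
    n_rows, n_cols = values.shape
    row_means = np.nanmean(values, axis=1)
    filled = values.copy()
    for i in rows_with_na:
        xi = values[i]
        obs_i = ~missing[i]
        # scaled Euclidean distance to every other row over shared samples
        diff = values - xi  # nan wherever either is missing
        shared = ~np.isnan(diff)
        shared[i, :] = False
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d2 = np.nansum(diff**2, axis=1) / n_shared
        d2[n_shared == 0] = np.inf
        d2[i] = np.inf
        for j in np.flatnonzero(missing[i]):
            donors = np.flatnonzero(~missing[:, j] & np.isfinite(d2))
            if donors.size == 0:
                filled[i, j] = row_means[i]
                continue
            take = donors[np.argsort(d2[donors], kind="stable")[:k]]
            if take.size < k:
                logger.debug(
                    "CpG %s sample %s: only %d neighbours available",
                    betas.index[i], betas.columns[j], take.size,
                )
            filled[i, j] = values[take, j].mean()
    filled = np.clip(filled, 0.0, 1.0)
    return pd.DataFrame(filled, index=betas.index, columns=betas.columns)


def _first_pc_scores(submatrix: np.ndarray) -> np.ndarray:
    """Sample scores on PC1 of a samples x CpGs matrix of centered betas
    (covariance PCA via SVD)."""
    u, s, _ = np.linalg.svd(submatrix, full_matrices=False)
    return u[:, 0] * s[0]


def gene_methylation_profile(
    betas: pd.DataFrame,
    cpg_positions: pd.DataFrame,
    gene_models: pd.DataFrame,
    flank_bp: int = 50_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene methylation profile: sample scores on the first principal
    component of the CpGs within the gene body +/- ``flank_bp``.

    The matrix must be imputed (no missing values). CpGs are centered across
    samples; PCA is on the covariance (betas share a scale, so no per-CpG
    standardization). The PC1 sign is fixed so the profile correlates
    non-negatively with the per-sample mean beta over the gene's CpGs, making
    "hypermethylated => higher profile" hold. Genes with a single CpG return
    that CpG's centered beta; genes with no CpG are absent from the output.
    CpGs in overlapping gene neighbourhoods contribute to every such gene.

    ``cpg_positions`` columns: cpg_id (or name), chrom, start (1-based CpG
    position); ``gene_models``: gene_id (or name), chrom, start, end.

    Returns (profile table: gene x sample, info table: n_cpgs and
    orientation sign per gene).
    """
    if betas.isna().any().any():
        raise ValueError("beta matrix contains missing values; impute first")
    cpg_col = "cpg_id" if "cpg_id" in cpg_positions.columns else "name"
    gene_col = "gene_id" if "gene_id" in gene_models.columns else "name"
    pos = cpg_positions.set_index(cpg_col).loc[betas.index]
    values = betas.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    chrom_arr = pos["chrom"].to_numpy()
    pos_arr = pos["start"].to_numpy(dtype=int)
    profiles, info = {}, {}
    for _, gene in gene_models.iterrows():
        gid = gene[gene_col]
        lo, hi = int(gene["start"]) - flank_bp, int(gene["end"]) + flank_bp
        sel = np.flatnonzero((chrom_arr == gene["chrom"]) & (pos_arr >= lo) & (pos_arr <= hi))
        if sel.size == 0:
            continue
        sub = centered[sel, :].T  # samples x CpGs
        if sel.size == 1:
            scores = sub[:, 0]
            sign = 1
        elif np.allclose(sub, 0.0):
            warnings.warn(f"gene {gid}: zero-variance CpG neighbourhood", stacklevel=2)
            scores = np.zeros(sub.shape[0])
            sign = 1
        else:
            scores = _first_pc_scores(sub)
            mean_beta = values[sel, :].mean(axis=0)
            r = np.corrcoef(scores, mean_beta)[0, 1] if np.std(scores) > 0 else 0.0
            sign = -1 if r < 0 else 1
            scores = sign * scores
        profiles[gid] = scores
        info[gid] = {"n_cpgs": int(sel.size), "orientation": sign}
    profile_table = pd.DataFrame(profiles, index=betas.columns).T
    profile_table.index.name = "gene_id"
    info_table = pd.DataFrame(info).T
    return profile_table, info_table


def differential_methylation(
    profiles: pd.DataFrame,
    tumor_type: pd.Series,
    subtype: pd.Series,
    *,
    fdr_alpha: float = 0.05,
    effect_top_fraction: float = 0.20,
    group_a: str = "DCIS",
    group_b: str = "IBC",
    min_group_size: int = 2,
) -> list[DiffMethResult]:
    """Subtype-stratified differential methylation of per-gene profiles.

    Within each subtype, every gene's profile values are compared between
    the two tumor types with a two-sided Mann-Whitney U test; p-values are
    BH-adjusted across genes within the subtype. The effect size is the
    absolute difference of group medians. A gene is significant when
    FDR q < ``fdr_alpha`` AND its effect size is strictly above the
    (1 - effect_top_fraction) empirical quantile of effect sizes among the
    subtype's tested genes. Subtypes where either group has fewer than
    ``min_group_size`` samples are skipped with a notice.
    """
    tumor_type = pd.Series(tumor_type)
    subtype = pd.Series(subtype)
    results: list[DiffMethResult] = []
    for st in pd.unique(subtype):
        members = subtype.index[subtype == st]
        a = [s for s in members if s in profiles.columns and tumor_type.get(s) == group_a]
        b = [s for s in members if s in profiles.columns and tumor_type.get(s) == group_b]
        if len(a) < min_group_size or len(b) < min_group_size:
            logger.info(
                "subtype %s skipped: group sizes %d vs %d below floor %d",
                st, len(a), len(b), min_group_size,
            )
            continue
        stats_rows = []
        for gene in profiles.index:
            xa = profiles.loc[gene, a].to_numpy(dtype=float)
            xb = profiles.loc[gene, b].to_numpy(dtype=float)
            res = mann_whitney_u(xa, xb)
            effect = abs(float(np.median(xa)) - float(np.median(xb)))
            stats_rows.append((gene, res.u_statistic, res.p_value, effect))
        pvals = np.array([r[2] for r in stats_rows])
        qvals = bh_fdr(pvals)
        effects = np.array([r[3] for r in stats_rows])
        cutoff = float(np.quantile(effects, 1.0 - effect_top_fraction))
        for (gene, u, p, eff), q in zip(stats_rows, qvals):
            results.append(
                DiffMethResult(
                    gene_id=str(gene),
                    subtype=str(st),
                    u_statistic=u,
                    p_value=p,
                    fdr_q=float(q),
                    effect_size=eff,
                    significant=bool(q < fdr_alpha and eff > cutoff),
                )
            )
    return results


def diffmeth_to_frame(results: list[DiffMethResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "subtype": r.subtype,
                "u_statistic": r.u_statistic,
                "p_value": r.p_value,
                "fdr_q": r.fdr_q,
                "effect_size": r.effect_size,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def window_mean_z(
    betas: pd.DataFrame,
    cpg_positions: pd.DataFrame,
    window: tuple[str, int, int],
    *,
    ddof: int = 1,
) -> list[WindowScore]:
    """Mean standard score over a genomic window's CpGs, per sample.

    Each CpG in the window is z-scored across all supplied samples (tumors
    and normals together); a sample's window score is the mean z over the
    window CpGs. This is the long-range-epigenetic-silencing readout: a
    coordinated beta shift across the window moves the whole mean.
    """
    if betas.isna().any().any():
        raise ValueError("beta matrix contains missing values; impute first")
    chrom, start, end = window
    cpg_col = "cpg_id" if "cpg_id" in cpg_positions.columns else "name"
    pos = cpg_positions.set_index(cpg_col).loc[betas.index]
    in_window = (
        (pos["chrom"] == chrom) & (pos["start"] >= start) & (pos["start"] <= end)
    ).to_numpy()
    if not in_window.any():
        raise ValueError(f"no CpGs in window {chrom}:{start}-{end}")
    sub = betas.to_numpy(dtype=float)[in_window, :]
    sd = sub.std(axis=1, ddof=ddof, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    mean_z = z.mean(axis=0)
    return [
        WindowScore(
            sample_id=str(s),
            mean_z=float(m),
            n_cpgs=int(in_window.sum()),
            window=(chrom, int(start), int(end)),
        )
        for s, m in zip(betas.columns, mean_z)
    ]


def window_scores_to_series(scores: list[WindowScore]) -> pd.Series:
    return pd.Series({s.sample_id: s.mean_z for s in scores}, name="window_mean_z")


def window_purity_association(
    scores: list[WindowScore], purity: pd.Series | dict
) -> dict:
    """Spearman association between window mean-Z and tumor purity, to check
    that window methylation is not a normal-cell-content artifact."""
    s = window_scores_to_series(scores)
    purity = pd.Series(purity)
    shared = s.index.intersection(purity.index)
    pairs = pd.DataFrame({"score": s[shared], "purity": purity[shared]}).dropna()
    if len(pairs) < 3:
        raise ValueError("need >= 3 samples with both window score and purity")
    rho, p = spearman(pairs["score"], pairs["purity"])
    return {"rho": rho, "p_value": p, "n": int(len(pairs))}
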