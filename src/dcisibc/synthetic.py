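"""Synthetic multi-omic cohort generator.

Emulates the statistical structure of a DCIS / invasive breast cancer study
cohort across three omic layers plus annotations, so the whole pipeline is
exercisable without access-restricted patient data:

* expression — subtype-structured values on a set of synthetic centroid
  genes, a bimodal ESR1/PGR marker pair tied to ER/PR truth, and planted
  signature programs (proliferation up in aggressive subtypes and invasive
  basal tumors, EMT up / adhesion down in invasive tumors);
* methylation — beta-values with a plantable hypermethylated window
  (long-range epigenetic silencing in a designated subtype x tumor-type
  cell) and plantable per-gene DCIS-vs-IBC differences, plus detection
  p-values and missingness;
* copy number — per-sample genome-tiling integer segments realising
  recurrent subtype events (5q loss, 17q12 gain, 16q loss) and a target
  aberrant genome fraction;
* annotations — tumor type, true subtype, ER/PR truth, purity, CpG
  positions and gene models on a single synthetic coordinate system
  (1-based inclusive in memory).

Every planted effect is recorded in a truth record sufficient to score its
recovery. A fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "mean_intercentroid_gap",
    "default_aberration_profiles",
]

NORMAL = "NORMAL"


def _chrom_lengths(genome_length_bp: int) -> dict[str, int]:
    """Four named chromosomes with fixed genome-fraction splits."""
    fracs = {"chr1": 0.40, "chr5": 0.25, "chr16": 0.15, "chr17": 0.20}
    lengths = {c: int(round(f * genome_length_bp)) for c, f in fracs.items()}
    lengths["chr1"] += genome_length_bp - sum(lengths.values())  # exact total
    return lengths


def default_aberration_profiles(
    subtypes, tumor_types, genome_length_bp: int
) -> dict[tuple[str, str], dict]:
    """Recurrent events and target aberrant fractions per cohort cell.

    Events echo the canonical subtype lesions: 5q loss in invasive
    basal-like (covering the silencing window), 17q12 gain in HER2-enriched,
    16q loss in luminal tumors. DCIS cells carry fewer aberrations than
    their invasive counterparts.
    """
    L = _chrom_lengths(genome_length_bp)
    off5 = int(0.40 * genome_length_bp)  # not used: coordinates are per-chrom
    del off5
    ev_5q_loss = ("chr5", int(0.50 * L["chr5"]) + 1, L["chr5"], 1)
    ev_17q12_gain = ("chr17", int(0.33 * L["chr17"]) + 1, int(0.43 * L["chr17"]), 4)
    ev_16q_loss = ("chr16", int(0.47 * L["chr16"]) + 1, L["chr16"], 1)
    base = {
        ("Basal", "IBC"): {"events": [ev_5q_loss], "target_fraction": 0.35},
        ("Basal", "DCIS"): {"events": [], "target_fraction": 0.08},
        ("Her2", "IBC"): {"events": [ev_17q12_gain], "target_fraction": 0.25},
        ("Her2", "DCIS"): {"events": [ev_17q12_gain], "target_fraction": 0.15},
        ("LumA", "IBC"): {"events": [ev_16q_loss], "target_fraction": 0.15},
        ("LumA", "DCIS"): {"events": [ev_16q_loss], "target_fraction": 0.10},
        ("LumB", "IBC"): {"events": [ev_16q_loss], "target_fraction": 0.30},
        ("LumB", "DCIS"): {"events": [], "target_fraction": 0.12},
    }
    out = {}
    for st in subtypes:
        for tt in tumor_types:
            out[(st, tt)] = base.get(
                (st, tt), {"events": [], "target_fraction": 0.10 if tt == "IBC" else 0.05}
            )
    return out


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort. All genomic coordinates
    are 1-based inclusive; expression is on the log2 scale; beta shifts are
    fractions applied with clipping to [0, 1]."""

    n_per_group: int = 25                 # samples per (subtype x tumor type)
    subtypes: tuple[str, ...] = ("Basal", "Her2", "LumA", "LumB")
    tumor_types: tuple[str, ...] = ("DCIS", "IBC")
    n_normal: int = 10                    # normal-tissue samples (methylation context)
    n_genes: int = 1000                   # total expression genes
    n_centroid_genes: int = 50
    n_signature_genes: int = 11           # genes per signature block
    centroid_sd: float = 0.5              # within-subtype noise on centroid genes (log2)
    background_sd: float = 0.5            # noise on non-centroid genes (log2)
    esr1_modes: tuple[float, float, float] = (6.0, 10.0, 0.8)  # low mean, high mean, sd
    luminal_er_pos_prob: float = 0.9
    nonluminal_er_pos_prob: float = 0.15
    proliferation_shift: float = 1.0      # log2 shift in aggressive subtypes
    invasion_proliferation_shift: float = 0.8  # extra shift in invasive basal
    emt_shift: float = 0.6                # EMT up / adhesion down in invasive tumors
    n_cpgs: int = 5000
    n_meth_genes: int = 60                # genes with local CpGs, outside the window
    cpgs_per_gene: int = 5
    window_span_bp: int = 800_000
    n_window_cpgs: int = 698
    lres_delta: float = 0.3               # beta shift planted on window CpGs
    lres_subtype: str = "Basal"
    lres_tumor_type: str = "IBC"
    n_diff_genes: int = 10   # kept below the top-20% effect filter's capacity
    diff_delta: float = 0.2               # planted per-gene beta shift (DCIS vs IBC)
    diff_subtype: str = "Basal"
    beta_model: str = "truncated_gaussian"  # or "beta"
    beta_noise_sd: float = 0.05
    beta_concentration: float = 30.0      # used by the "beta" model
    missing_rate: float = 0.005
    detection_fail_rate: float = 0.00225
    genome_length_bp: int = 100_000_000
    aberration_profiles: dict | None = None   # default: default_aberration_profiles
    purity_range: tuple[float, float] = (0.3, 0.9)
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_per_group": self.n_per_group, "n_normal": self.n_normal,
            "n_genes": self.n_genes, "n_centroid_genes": self.n_centroid_genes,
            "n_signature_genes": self.n_signature_genes, "n_cpgs": self.n_cpgs,
            "n_meth_genes": self.n_meth_genes, "cpgs_per_gene": self.cpgs_per_gene,
            "n_window_cpgs": self.n_window_cpgs, "n_diff_genes": self.n_diff_genes,
            "genome_length_bp": self.genome_length_bp,
            "window_span_bp": self.window_span_bp,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name, v in {
            "lres_delta": self.lres_delta, "diff_delta": self.diff_delta,
            "missing_rate": self.missing_rate,
            "detection_fail_rate": self.detection_fail_rate,
        }.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.subtypes) < 1:
            raise ValueError("subtypes must be non-empty")
        if self.window_span_bp > self.genome_length_bp:
            raise ValueError("window_span_bp exceeds genome_length_bp")
        n_reserved = (
            self.n_centroid_genes + 3 * self.n_signature_genes + 2  # ESR1, PGR
        )
        if self.n_genes < n_reserved:
            raise ValueError(
                f"n_genes={self.n_genes} below the {n_reserved} reserved "
                "centroid/marker/signature genes"
            )
        if self.n_window_cpgs + self.n_meth_genes * self.cpgs_per_gene > self.n_cpgs:
            raise ValueError(
                "n_window_cpgs + n_meth_genes * cpgs_per_gene exceeds n_cpgs"
            )
        if self.n_diff_genes > self.n_meth_genes:
            raise ValueError("n_diff_genes exceeds n_meth_genes")
        if self.beta_model not in ("truncated_gaussian", "beta"):
            raise ValueError(f"unknown beta_model {self.beta_model!r}")
        L = _chrom_lengths(self.genome_length_bp)
        if self.window_span_bp > L["chr5"] // 2:
            raise ValueError("window_span_bp does not fit in chr5")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if d["aberration_profiles"] is not None:
            d["aberration_profiles"] = {
                f"{k[0]}|{k[1]}": v for k, v in d["aberration_profiles"].items()
            }
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame          # genes x samples (log2)
    centroids: pd.DataFrame           # centroid genes x subtypes (centered scale)
    betas: pd.DataFrame               # CpGs x samples, may contain NaN
    detection_p: pd.DataFrame         # CpGs x samples
    segments: pd.DataFrame            # sample, chrom, start, end, cn
    sample_annotations: pd.DataFrame  # tumor_type, subtype, er_truth, pgr_truth, purity
    cpg_positions: pd.DataFrame       # chrom, start, end, name (1-based inclusive)
    gene_models: pd.DataFrame         # chrom, start, end, name
    signatures: dict[str, list[tuple[str, float]]]
    window: tuple[str, int, int]
    truth: dict
    config: CohortConfig


def mean_intercentroid_gap(centroids: pd.DataFrame) -> float:
    """Mean absolute pairwise difference between subtype centroid values,
    averaged over genes and subtype pairs."""
    vals = centroids.to_numpy(dtype=float)
    k = vals.shape[1]
    diffs = [
        np.abs(vals[:, i] - vals[:, j]) for i in range(k) for j in range(i + 1, k)
    ]
    return float(np.mean(diffs))


def _sample_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    lo_p, hi_p = config.purity_range
    for st in config.subtypes:
        for tt in config.tumor_types:
            for i in range(config.n_per_group):
                sid = f"{st}_{tt}_{i + 1:03d}"
                luminal = st.lower().startswith("lum")
                p_er = config.luminal_er_pos_prob if luminal else config.nonluminal_er_pos_prob
                er = bool(rng.random() < p_er)
                pgr = er if rng.random() >= 0.2 else (not er)
                rows.append(
                    {
                        "sample": sid, "tumor_type": tt, "subtype": st,
                        "er_truth": "positive" if er else "negative",
                        "pgr_truth": "positive" if pgr else "negative",
                        "purity": float(rng.uniform(lo_p, hi_p)),
                    }
                )
    for i in range(config.n_normal):
        er = bool(rng.random() < 0.9)
        rows.append(
            {
                "sample": f"{NORMAL}_{i + 1:03d}", "tumor_type": NORMAL,
                "subtype": NORMAL,
                "er_truth": "positive" if er else "negative",
                "pgr_truth": "positive" if er else "negative",
                "purity": 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def _gene_ids(config: CohortConfig) -> dict[str, list[str]]:
    ids = {
        "centroid": [f"CG{i + 1:03d}" for i in range(config.n_centroid_genes)],
        "marker": ["ESR1", "PGR"],
        "proliferation": [f"PROLIF{i + 1:02d}" for i in range(config.n_signature_genes)],
        "emt": [f"EMT{i + 1:02d}" for i in range(config.n_signature_genes)],
        "adhesion": [f"ADH{i + 1:02d}" for i in range(config.n_signature_genes)],
    }
    n_used = sum(len(v) for v in ids.values())
    ids["filler"] = [f"G{i + 1:04d}" for i in range(config.n_genes - n_used)]
    return ids


def _expression_layer(config, rng, samples: pd.DataFrame, ids):
    n_samples = len(samples)
    st = samples["subtype"]
    tt = samples["tumor_type"]
    # centered synthetic centroids: per gene, subtype deviations with zero row mean
    delta = rng.normal(0.0, 1.0, size=(config.n_centroid_genes, len(config.subtypes)))
    delta -= delta.mean(axis=1, keepdims=True)
    centroids = pd.DataFrame(
        delta, index=ids["centroid"], columns=list(config.subtypes)
    )
    rows = {}
    noise = rng.normal(0.0, 1.0, size=(config.n_centroid_genes, n_samples))
    for gi, g in enumerate(ids["centroid"]):
        base = np.where(
            st == NORMAL, 0.0,
            centroids.loc[g].reindex(st.where(st != NORMAL, config.subtypes[0])).to_numpy(),
        )
        rows[g] = base + config.centroid_sd * noise[gi]
    lo, hi, sd = config.esr1_modes
    for g, truth_col in (("ESR1", "er_truth"), ("PGR", "pgr_truth")):
        modes = np.where(samples[truth_col] == "positive", hi, lo)
        rows[g] = modes + sd * rng.normal(0.0, 1.0, size=n_samples)
    aggressive = {"Basal": config.proliferation_shift,
                  "Her2": 0.7 * config.proliferation_shift,
                  "LumB": 0.5 * config.proliferation_shift}
    prolif_shift = st.map(lambda s: aggressive.get(s, 0.0)).to_numpy(dtype=float)
    extra = ((st == config.lres_subtype) & (tt == "IBC")).to_numpy()
    prolif_shift = prolif_shift + np.where(extra, config.invasion_proliferation_shift, 0.0)
    invasive = (tt == "IBC").to_numpy()
    for g in ids["proliferation"]:
        mu = rng.normal(7.0, 1.0)
        rows[g] = mu + prolif_shift + config.background_sd * rng.normal(0.0, 1.0, n_samples)
    for g in ids["emt"]:
        mu = rng.normal(7.0, 1.0)
        rows[g] = mu + np.where(invasive, config.emt_shift, 0.0) \
            + config.background_sd * rng.normal(0.0, 1.0, n_samples)
    for g in ids["adhesion"]:
        mu = rng.normal(7.0, 1.0)
        rows[g] = mu - np.where(invasive, config.emt_shift, 0.0) \
            + config.background_sd * rng.normal(0.0, 1.0, n_samples)
    for g in ids["filler"]:
        mu = rng.normal(8.0, 1.0)
        rows[g] = mu + config.background_sd * rng.normal(0.0, 1.0, n_samples)
    expr = pd.DataFrame(rows, index=samples.index).T
    expr.index.name = "gene_id"
    return expr, centroids


def _genome_features(config, rng):
    """CpG positions, methylation gene models, window and CN marker genes."""
    L = _chrom_lengths(config.genome_length_bp)
    window_start = int(0.53 * L["chr5"]) + 1  # inside the default 5q-loss event
    window = ("chr5", window_start, window_start + config.window_span_bp - 1)
    # overlapping protocadherin-like cluster genes spanning the window
    span = config.window_span_bp
    cluster = [
        ("PCDH_A", "chr5", window_start + int(0.10 * span), window_start + int(0.45 * span)),
        ("PCDH_B", "chr5", window_start + int(0.35 * span), window_start + int(0.70 * span)),
        ("PCDH_C", "chr5", window_start + int(0.60 * span), window_start + int(0.92 * span)),
    ]
    # ERBB2-like gene inside the default 17q12 gain
    erbb2 = ("ERBB2", "chr17", int(0.36 * L["chr17"]) + 1, int(0.37 * L["chr17"]))
    # regularly spaced methylation genes on chr1/chr16, clear of flank overlap
    meth_genes = []
    gene_len, spacing = 20_000, 200_000
    host_chroms = ["chr1", "chr16"]
    per_chrom = int(np.ceil(config.n_meth_genes / len(host_chroms)))
    gi = 0
    for chrom in host_chroms:
        start = 1_000_001
        for _ in range(per_chrom):
            if gi >= config.n_meth_genes:
                break
            if start + gene_len - 1 > L[chrom] - 1_000_000:
                break
            gi += 1
            meth_genes.append((f"MG{gi:03d}", chrom, start, start + gene_len - 1))
            start += spacing
    if gi < config.n_meth_genes:
        raise ValueError("n_meth_genes does not fit on the synthetic genome")
    gene_models = pd.DataFrame(
        cluster + [erbb2] + meth_genes, columns=["name", "chrom", "start", "end"]
    )[["chrom", "start", "end", "name"]]
    # CpGs: window block, per-gene blocks, then random background
    cpg_rows = []
    wpos = np.sort(
        rng.choice(np.arange(window[1], window[2] + 1), size=config.n_window_cpgs, replace=False)
    )
    for p in wpos:
        cpg_rows.append(("chr5", int(p)))
    for name, chrom, gstart, gend in meth_genes:
        pos = np.sort(rng.choice(np.arange(gstart, gend + 1), size=config.cpgs_per_gene, replace=False))
        cpg_rows.extend((chrom, int(p)) for p in pos)
    n_bg = config.n_cpgs - len(cpg_rows)
    chrom_names = list(L)
    probs = np.array([L[c] for c in chrom_names], dtype=float)
    probs /= probs.sum()
    bg_chroms = rng.choice(chrom_names, size=n_bg, p=probs)
    for c in bg_chroms:
        cpg_rows.append((str(c), int(rng.integers(1, L[str(c)] + 1))))
    cpgs = pd.DataFrame(cpg_rows, columns=["chrom", "start"])
    cpgs["end"] = cpgs["start"]
    cpgs["name"] = [f"cg{i + 1:07d}" for i in range(len(cpgs))]
    cpgs = cpgs[["chrom", "start", "end", "name"]]
    window_cpgs = list(cpgs["name"][: config.n_window_cpgs])
    gene_cpgs = {}
    offset = config.n_window_cpgs
    for name, *_ in meth_genes:
        gene_cpgs[name] = list(
            cpgs["name"][offset: offset + config.cpgs_per_gene]
        )
        offset += config.cpgs_per_gene
    return cpgs, gene_models, window, window_cpgs, gene_cpgs


def _beta_draw(config, rng, mean: np.ndarray) -> np.ndarray:
    if config.beta_model == "beta":
        nu = config.beta_concentration
        a = np.clip(mean, 1e-3, 1 - 1e-3) * nu
        b = nu - a
        return rng.beta(a, b)
    return np.clip(mean + rng.normal(0.0, config.beta_noise_sd, size=mean.shape), 0.0, 1.0)


def _methylation_layer(config, rng, samples, cpgs, window_cpgs, gene_cpgs):
    n_cpgs, n_samples = len(cpgs), len(samples)
    cpg_index = pd.Index(cpgs["name"])
    is_window = cpg_index.isin(window_cpgs)
    # baseline per-CpG means: bimodal genome-wide, low across the window
    low = rng.beta(2.0, 10.0, size=n_cpgs)
    high = rng.beta(10.0, 2.0, size=n_cpgs)
    baseline = np.where(rng.random(n_cpgs) < 0.6, low, high)
    baseline[is_window] = rng.beta(2.0, 10.0, size=int(is_window.sum()))
    mean = np.repeat(baseline[:, None], n_samples, axis=1)
    st = samples["subtype"].to_numpy()
    tt = samples["tumor_type"].to_numpy()
    lres_samples = list(
        samples.index[(st == config.lres_subtype) & (tt == config.lres_tumor_type)]
    )
    mean[np.ix_(is_window, samples.index.isin(lres_samples))] += config.lres_delta
    diff_genes = sorted(gene_cpgs)[: config.n_diff_genes]
    diff_target = samples.index.isin(
        samples.index[(st == config.diff_subtype) & (tt == "IBC")]
    )
    for g in diff_genes:
        rows = cpg_index.isin(gene_cpgs[g])
        mean[np.ix_(rows, diff_target)] += config.diff_delta
    mean = np.clip(mean, 0.0, 1.0)
    betas = _beta_draw(config, rng, mean)
    # detection p-values: mostly tiny, a configured fraction failing (> 0.05)
    detp = rng.uniform(0.0, 0.01, size=(n_cpgs, n_samples))
    fail = rng.random((n_cpgs, n_samples)) < config.detection_fail_rate
    detp[fail] = 0.05 + 0.95 * rng.random(int(fail.sum()))
    # independent missingness on top
    miss = rng.random((n_cpgs, n_samples)) < config.missing_rate
    betas = betas.astype(float)
    betas[miss] = np.nan
    beta_df = pd.DataFrame(betas, index=cpg_index, columns=samples.index)
    detp_df = pd.DataFrame(detp, index=cpg_index, columns=samples.index)
    beta_df.index.name = detp_df.index.name = "cpg_id"
    return beta_df, detp_df, lres_samples, diff_genes


def _segments_layer(config, rng, samples, profiles):
    L = _chrom_lengths(config.genome_length_bp)
    genome = config.genome_length_bp
    rows = []
    realized = {}
    for sid, ann in samples.iterrows():
        key = (ann["subtype"], ann["tumor_type"])
        prof = profiles.get(key, {"events": [], "target_fraction": 0.0})
        events = [tuple(e) for e in prof["events"]]
        target = float(prof["target_fraction"])
        event_bp = sum(e[2] - e[1] + 1 for e in events)
        filler_bp = int(round(target * genome)) - event_bp
        if filler_bp < -0.01 * genome:
            raise ValueError(
                f"aberration_profiles[{key}]: events exceed target_fraction"
            )
        per_chrom_events: dict[str, list] = {c: [] for c in L}
        for chrom, start, end, cn in events:
            per_chrom_events[chrom].append((int(start), int(end), int(cn)))
        if filler_bp > 0:
            free = L["chr1"]
            if filler_bp > free - 2:
                raise ValueError(
                    f"aberration_profiles[{key}]: target_fraction filler does not fit chr1"
                )
            fstart = int(rng.integers(1, free - filler_bp + 2))
            per_chrom_events["chr1"].append((fstart, fstart + filler_bp - 1, 3))
        aberrant = 0
        for chrom, length in L.items():
            evs = sorted(per_chrom_events[chrom])
            cursor = 1
            for start, end, cn in evs:
                if start > cursor:
                    rows.append((sid, chrom, cursor, start - 1, 2))
                rows.append((sid, chrom, start, end, cn))
                if cn != 2:
                    aberrant += end - start + 1
                cursor = end + 1
            if cursor <= length:
                rows.append((sid, chrom, cursor, length, 2))
        realized[sid] = aberrant / genome
    seg = pd.DataFrame(rows, columns=dio.SEG_COLUMNS)
    return seg, realized


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``; deterministic in
    ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _sample_table(config, rng)
    ids = _gene_ids(config)
    expression, centroids = _expression_layer(config, rng, samples, ids)
    cpgs, gene_models, window, window_cpgs, gene_cpgs = _genome_features(config, rng)
    betas, detp, lres_samples, diff_genes = _methylation_layer(
        config, rng, samples, cpgs, window_cpgs, gene_cpgs
    )
    profiles = config.aberration_profiles or default_aberration_profiles(
        config.subtypes, config.tumor_types, config.genome_length_bp
    )
    segments, realized = _segments_layer(config, rng, samples, profiles)
    signatures = {
        "proliferation": [(g, 1.0) for g in ids["proliferation"]],
        "emt": [(g, 1.0) for g in ids["emt"]] + [(g, -1.0) for g in ids["adhesion"]],
    }
    truth = {
        "seed": config.seed,
        "subtype": samples["subtype"].to_dict(),
        "tumor_type": samples["tumor_type"].to_dict(),
        "er_truth": samples["er_truth"].to_dict(),
        "pgr_truth": samples["pgr_truth"].to_dict(),
        "lres_samples": lres_samples,
        "lres_delta": config.lres_delta,
        "window": list(window),
        "window_cpgs": window_cpgs,
        "diff_genes": diff_genes,
        "diff_delta": config.diff_delta,
        "diff_subtype": config.diff_subtype,
        "aberrant_fraction": realized,
        "signature_genes": {k: [g for g, _ in v] for k, v in signatures.items()},
    }
    return SyntheticCohort(
        expression=expression,
        centroids=centroids,
        betas=betas,
        detection_p=detp,
        segments=segments,
        sample_annotations=samples,
        cpg_positions=cpgs,
        gene_models=gene_models,
        signatures=signatures,
        window=window,
        truth=truth,
        config=config,
    )


_FILES = {
    "expression": "expression.tsv",
    "centroids": "centroids.tsv",
    "betas": "betas.tsv",
    "detection_p": "detection_p.tsv",
    "segments": "segments.tsv",
    "samples": "samples.tsv",
    "cpg_positions": "cpg_positions.bed",
    "gene_models": "gene_models.bed",
    "signatures": "signatures.tsv",
    "truth": "truth.json",
}


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write every layer in the pipeline's input formats; returns (and
    writes) a manifest with per-file content hashes, the seed and the
    config hash."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dio.write_matrix_tsv(cohort.expression, directory / _FILES["expression"], "gene_id")
    dio.write_matrix_tsv(cohort.centroids, directory / _FILES["centroids"], "gene_id")
    dio.write_matrix_tsv(cohort.betas, directory / _FILES["betas"], "cpg_id")
    dio.write_matrix_tsv(cohort.detection_p, directory / _FILES["detection_p"], "cpg_id")
    dio.write_segments(cohort.segments, directory / _FILES["segments"])
    dio.write_sample_annotations(cohort.sample_annotations, directory / _FILES["samples"])
    dio.write_bed(cohort.cpg_positions, directory / _FILES["cpg_positions"])
    dio.write_bed(cohort.gene_models, directory / _FILES["gene_models"])
    dio.write_signature_defs(cohort.signatures, directory / _FILES["signatures"])
    truth = dict(cohort.truth)
    truth["window"] = list(cohort.window)
    (directory / _FILES["truth"]).write_text(json.dumps(truth, indent=1, sort_keys=True))
    manifest = {
        "seed": cohort.config.seed,
        "config_hash": cohort.config.content_hash(),
        "config": cohort.config.to_jsonable(),
        "files": {},
    }
    for key, fname in _FILES.items():
        digest = hashlib.sha256((directory / fname).read_bytes()).hexdigest()
        manifest["files"][fname] = digest
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_cohort(directory) -> dict:
    """Read a written cohort back into in-memory objects (matrices exactly
    round-trip; truth and manifest as dicts)."""
    directory = Path(directory)
    out = {
        "expression": dio.read_matrix_tsv(directory / _FILES["expression"]),
        "centroids": dio.read_matrix_tsv(directory / _FILES["centroids"]),
        "betas": dio.read_matrix_tsv(directory / _FILES["betas"]),
        "detection_p": dio.read_matrix_tsv(directory / _FILES["detection_p"]),
        "segments": dio.read_segments(directory / _FILES["segments"]),
        "samples": dio.read_sample_annotations(directory / _FILES["samples"]),
        "cpg_positions": dio.read_bed(directory / _FILES["cpg_positions"]),
        "gene_models": dio.read_bed(directory / _FILES["gene_models"]),
        "signatures": dio.read_signature_defs(directory / _FILES["signatures"]),
        "truth": json.loads((directory / _FILES["truth"]).read_text()),
        "manifest": json.loads((directory / "manifest.json").read_text()),
    }
    return out
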