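"""Methylation QC, imputation, per-gene PC1 profiles, differential testing,
window scores."""

import math

import numpy as np
import pandas as pd
import pytest

from dcisibc.methylation import (
    differential_methylation,
    gene_methylation_profile,
    knn_impute,
    qc_filter_cpgs,
    qc_mask,
    window_mean_z,
    window_purity_association,
    window_scores_to_series,
)


def beta_frame(values, cpgs=None, samples=None):
    arr = np.asarray(values, dtype=float)
    cpgs = cpgs or [f"cg{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=cpgs, columns=samples)


def positions_frame(rows):
    return pd.DataFrame(rows, columns=["cpg_id", "chrom", "start"])


class TestQCMask:
    def test_strict_threshold_boundaries(self):
        betas = beta_frame([[0.5, 0.5, 0.5]])
        detp = beta_frame([[0.06, 0.05, 0.0]])
        masked, n = qc_mask(betas, detp)
        assert n == 1
        assert np.isnan(masked.iloc[0, 0])     # 0.06 > 0.05 masked
        assert masked.iloc[0, 1] == 0.5        # 0.05 kept (strict >)
        assert masked.iloc[0, 2] == 0.5

    def test_null_mask_identity(self):
        betas = beta_frame([[0.2, 0.8], [0.4, 0.6]])
        masked, n = qc_mask(betas, beta_frame(np.zeros((2, 2))))
        assert n == 0
        assert masked.equals(betas)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            qc_mask(beta_frame([[0.5]]), beta_frame([[0.1, 0.2]]))


class TestQCFilter:
    def test_strict_fraction_boundaries(self):
        row_30 = [np.nan, np.nan, np.nan] + [0.5] * 7   # 30% missing of 10
        row_25 = [np.nan, np.nan] + [0.5] * 6           # 25% of 8 -> kept
        betas_a = beta_frame(
            [row_30, [0.5] * 10],
            cpgs=["drop", "full"],
            samples=[f"s{i}" for i in range(10)],
        )
        kept_a, dropped_a = qc_filter_cpgs(betas_a)
        assert "drop" in dropped_a
        betas_b = beta_frame([row_25], cpgs=["keep"], samples=[f"s{i}" for i in range(8)])
        kept_b, dropped_b = qc_filter_cpgs(betas_b)
        assert dropped_b == [] and "keep" in kept_b.index

    def test_no_missing_identity(self):
        betas = beta_frame([[0.1, 0.9], [0.5, 0.5]])
        kept, dropped = qc_filter_cpgs(betas)
        assert dropped == [] and kept.equals(betas)

    def test_all_dropped_rejected(self):
        betas = beta_frame([[np.nan, np.nan, 0.5]])
        with pytest.raises(ValueError):
            qc_filter_cpgs(betas)


class TestKNNImpute:
    def test_no_missing_identity(self):
        betas = beta_frame([[0.1, 0.2], [0.3, 0.4]])
        assert knn_impute(betas).equals(betas)

    def test_constant_neighbourhood(self):
        rows = [[0.5, 0.5, np.nan]] + [[0.5, 0.5, 0.5]] * 10
        filled = knn_impute(beta_frame(rows), k=10)
        assert filled.iloc[0, 2] == pytest.approx(0.5)
        assert not filled.isna().any().any()

    def test_hand_computed_two_neighbours(self):
        # 5x4 toy, one missing at (cg0, s3); k=2.
        vals = [
            [0.10, 0.20, 0.30, np.nan],
            [0.10, 0.20, 0.30, 0.40],   # distance 0 on shared samples
            [0.12, 0.22, 0.32, 0.50],   # distance 0.02 per shared sample
            [0.90, 0.80, 0.70, 0.60],
            [0.50, 0.55, 0.60, 0.90],
        ]
        filled = knn_impute(beta_frame(vals), k=2)
        # nearest two rows over jointly observed samples: cg1 then cg2
        assert filled.iloc[0, 3] == pytest.approx((0.40 + 0.50) / 2)

    def test_entirely_missing_row_rejected(self):
        betas = beta_frame([[np.nan, np.nan], [0.5, 0.5]], cpgs=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            knn_impute(betas)

    def test_imputed_values_clipped(self):
        rows = [[0.0, 0.0, np.nan]] + [[0.0, 0.0, 0.0]] * 3
        filled = knn_impute(beta_frame(rows), k=3)
        assert (filled.to_numpy() >= 0).all() and (filled.to_numpy() <= 1).all()

    def test_filter_then_impute_equals_impute_of_survivors(self, rng):
        for _ in range(5):
            vals = rng.uniform(size=(12, 6))
            mask = rng.random((12, 6)) < 0.2
            vals[mask] = np.nan
            betas = beta_frame(vals.copy())
            betas = betas[betas.notna().any(axis=1)]
            try:
                kept, _ = qc_filter_cpgs(betas, fail_fraction=0.4)
            except ValueError:
                continue
            a = knn_impute(kept, k=3)
            b = knn_impute(betas.loc[kept.index], k=3)
            assert np.allclose(a, b)


class TestGeneProfile:
    def simple_annotation(self, n_cpgs, chrom="c1", start=1000, step=100):
        return positions_frame(
            [(f"cg{i}", chrom, start + i * step) for i in range(n_cpgs)]
        )

    def gene(self, name="g", chrom="c1", start=900, end=2000):
        return pd.DataFrame(
            [(name, chrom, start, end)], columns=["gene_id", "chrom", "start", "end"]
        )

    def test_single_cpg_centered_beta(self):
        betas = beta_frame([[0.2, 0.5, 0.8]])
        prof, info = gene_methylation_profile(
            betas, self.simple_annotation(1), self.gene(), flank_bp=0
        )
        assert np.allclose(prof.loc["g"], [-0.3, 0.0, 0.3])
        assert info.loc["g", "n_cpgs"] == 1

    def test_two_correlated_cpgs_match_eigen_oracle(self):
        base = np.array([0.1, 0.4, 0.7, 0.9])
        betas = beta_frame([base, base])
        prof, _ = gene_methylation_profile(
            betas, self.simple_annotation(2), self.gene(), flank_bp=0
        )
        centered = np.vstack([base - base.mean()] * 2).T
        cov = centered.T @ centered / (4 - 1)
        w, v = np.linalg.eigh(cov)
        scores = centered @ v[:, -1]
        if np.corrcoef(scores, base)[0, 1] < 0:
            scores = -scores
        assert np.allclose(np.abs(prof.loc["g"]), np.abs(scores), atol=1e-8)
        assert np.allclose(prof.loc["g"], scores, atol=1e-8)

    def test_orientation_hypermethylated_highest(self, rng):
        vals = rng.uniform(0.1, 0.4, size=(5, 6))
        vals[:, 0] = 0.95  # one clearly hypermethylated sample
        prof, info = gene_methylation_profile(
            beta_frame(vals), self.simple_annotation(5), self.gene(), flank_bp=0
        )
        assert prof.loc["g"].idxmax() == "s0"

    def test_profiles_centered(self, rng):
        vals = rng.uniform(size=(8, 10))
        prof, _ = gene_methylation_profile(
            beta_frame(vals), self.simple_annotation(8), self.gene(), flank_bp=0
        )
        assert prof.loc["g"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_neighbourhood_warns(self):
        betas = beta_frame(np.full((3, 4), 0.5))
        with pytest.warns(UserWarning, match="zero-variance"):
            prof, _ = gene_methylation_profile(
                betas, self.simple_annotation(3), self.gene(), flank_bp=0
            )
        assert np.allclose(prof.loc["g"], 0.0)

    def test_gene_without_cpgs_absent(self):
        betas = beta_frame([[0.2, 0.4]])
        genes = pd.concat([self.gene("near"), self.gene("far", chrom="c9")])
        prof, _ = gene_methylation_profile(
            betas, self.simple_annotation(1), genes, flank_bp=0
        )
        assert list(prof.index) == ["near"]

    def test_flank_widens_selection(self):
        betas = beta_frame([[0.2, 0.4], [0.9, 0.1]])
        ann = positions_frame([("cg0", "c1", 1500), ("cg1", "c1", 5000)])
        gene = self.gene(start=1000, end=2000)
        prof0, info0 = gene_methylation_profile(betas, ann, gene, flank_bp=0)
        prof1, info1 = gene_methylation_profile(betas, ann, gene, flank_bp=4000)
        assert info0.loc["g", "n_cpgs"] == 1
        assert info1.loc["g", "n_cpgs"] == 2

    def test_missing_values_rejected(self):
        betas = beta_frame([[np.nan, 0.4]])
        with pytest.raises(ValueError, match="impute"):
            gene_methylation_profile(betas, self.simple_annotation(1), self.gene())


class TestDifferentialMethylation:
    def make_profiles(self, rows, samples):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))], columns=samples)

    def test_identical_groups_null(self):
        samples = [f"s{i}" for i in range(8)]
        prof = self.make_profiles([[1.0, 2.0, 3.0, 4.0] * 2], samples)
        tt = pd.Series(["DCIS"] * 4 + ["IBC"] * 4, index=samples)
        st = pd.Series(["Basal"] * 8, index=samples)
        res = differential_methylation(prof, tt, st)
        assert res[0].p_value == pytest.approx(1.0)
        assert not res[0].significant

    def test_small_subtype_skipped(self):
        samples = ["a", "b", "c"]
        prof = self.make_profiles([[0.1, 0.2, 0.3]], samples)
        tt = pd.Series(["DCIS", "IBC", "IBC"], index=samples)
        st = pd.Series(["LumB"] * 3, index=samples)
        assert differential_methylation(prof, tt, st) == []

    def test_effect_size_is_median_difference(self, rng):
        samples = [f"s{i}" for i in range(10)]
        a = [0.0, 0.1, 0.2, 0.3, 0.4]
        b = [1.0, 1.1, 1.2, 1.3, 1.4]
        prof = self.make_profiles([a + b], samples)
        tt = pd.Series(["DCIS"] * 5 + ["IBC"] * 5, index=samples)
        st = pd.Series(["Basal"] * 10, index=samples)
        res = differential_methylation(prof, tt, st)
        assert res[0].effect_size == pytest.approx(1.0)

    def test_power_on_planted_shifts(self, rng):
        # 20 genes of 200 carry a 1.5-sd group shift: the joint FDR +
        # effect-size criterion flags >= 90% of them across 50 replicates
        n, m, shifted = 40, 200, 20
        samples = [f"s{i}" for i in range(n)]
        tt = pd.Series(["DCIS"] * 20 + ["IBC"] * 20, index=samples)
        st = pd.Series(["Basal"] * n, index=samples)
        flagged = total = 0
        for _ in range(50):
            vals = rng.normal(size=(m, n))
            vals[:shifted, 20:] += 1.5
            prof = self.make_profiles(vals, samples)
            res = differential_methylation(prof, tt, st)
            hits = {r.gene_id for r in res if r.significant}
            flagged += sum(f"g{i}" in hits for i in range(shifted))
            total += shifted
        assert flagged / total >= 0.90

    def test_strict_top_fraction_bound(self, rng):
        m, n = 50, 20
        samples = [f"s{i}" for i in range(n)]
        prof = self.make_profiles(rng.normal(size=(m, n)), samples)
        tt = pd.Series(["DCIS"] * 10 + ["IBC"] * 10, index=samples)
        st = pd.Series(["Basal"] * n, index=samples)
        res = differential_methylation(prof, tt, st, fdr_alpha=1.1)
        n_pass = sum(r.significant for r in res)
        assert n_pass <= math.ceil(0.2 * m)


class TestWindowScore:
    def annotation(self):
        return positions_frame([("cg0", "c5", 100), ("cg1", "c5", 200), ("cg2", "c9", 100)])

    def test_two_samples_one_cpg(self):
        betas = beta_frame([[0.2, 0.8]], cpgs=["cg0"])
        ann = positions_frame([("cg0", "c5", 100)])
        scores = window_mean_z(betas, ann, ("c5", 1, 1000))
        vals = window_scores_to_series(scores)
        assert vals["s0"] == pytest.approx(-1 / np.sqrt(2), abs=1e-6)
        assert vals["s1"] == pytest.approx(+1 / np.sqrt(2), abs=1e-6)

    def test_sample_at_cohort_mean_scores_zero(self, rng):
        # x = mean([x, rest]) iff x = mean(rest): set sample 0 to the mean of
        # the others so it sits exactly at the per-CpG cohort mean
        vals = rng.uniform(0.2, 0.8, size=(2, 4))
        vals[:, 0] = vals[:, 1:].mean(axis=1)
        betas = beta_frame(vals, cpgs=["cg0", "cg1"])
        scores = window_scores_to_series(
            window_mean_z(betas, self.annotation(), ("c5", 1, 1000))
        )
        assert scores["s0"] == pytest.approx(0.0, abs=1e-10)

    def test_location_invariance(self, rng):
        vals = rng.uniform(0.1, 0.5, size=(2, 5))
        betas = beta_frame(vals, cpgs=["cg0", "cg1"])
        shifted = beta_frame(vals + 0.3, cpgs=["cg0", "cg1"])
        a = window_scores_to_series(window_mean_z(betas, self.annotation(), ("c5", 1, 1000)))
        b = window_scores_to_series(window_mean_z(shifted, self.annotation(), ("c5", 1, 1000)))
        assert np.allclose(a, b)

    def test_only_window_cpgs_used(self, rng):
        vals = rng.uniform(size=(3, 4))
        betas = beta_frame(vals, cpgs=["cg0", "cg1", "cg2"])
        scores = window_mean_z(betas, self.annotation(), ("c5", 1, 1000))
        assert scores[0].n_cpgs == 2

    def test_empty_window_rejected(self):
        betas = beta_frame([[0.5, 0.6]], cpgs=["cg0"])
        ann = positions_frame([("cg0", "c5", 100)])
        with pytest.raises(ValueError, match="window"):
            window_mean_z(betas, ann, ("c9", 1, 1000))


class TestWindowPurity:
    def scores(self, values):
        from dcisibc.methylation import WindowScore

        return [
            WindowScore(f"s{i}", v, 10, ("c5", 1, 2)) for i, v in enumerate(values)
        ]

    def test_monotone_identity(self):
        purity = pd.Series({f"s{i}": 0.1 * (i + 1) for i in range(5)})
        res = window_purity_association(self.scores([1, 2, 3, 4, 5]), purity)
        assert res["rho"] == pytest.approx(1.0)

    def test_rank_difference_formula(self):
        purity = pd.Series({"s0": 3.0, "s1": 1.0, "s2": 2.0})
        res = window_purity_association(self.scores([1.0, 2.0, 3.0]), purity)
        assert res["rho"] == pytest.approx(-0.5)

    def test_constant_purity_rejected(self):
        purity = pd.Series({f"s{i}": 0.5 for i in range(4)})
        with pytest.raises(ValueError, match="constant"):
            window_purity_association(self.scores([1, 2, 3, 4]), purity)

    def test_too_few_pairs_rejected(self):
        purity = pd.Series({"s0": 0.5, "s1": 0.6})
        with pytest.raises(ValueError):
            window_purity_association(self.scores([1, 2]), purity)
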