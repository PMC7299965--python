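"""Synthetic cohort generator: bookkeeping, planted effects, determinism,
round-trips."""

import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from dcisibc.synthetic import (
    CohortConfig,
    default_aberration_profiles,
    generate_cohort,
    mean_intercentroid_gap,
    read_cohort,
    write_cohort,
)


def tiny_config(**overrides):
    base = dict(
        n_per_group=4, n_normal=2, n_genes=150, n_cpgs=400,
        n_window_cpgs=60, n_meth_genes=15, n_diff_genes=5, seed=11,
    )
    base.update(overrides)
    return CohortConfig(**base)


class TestBookkeeping:
    def test_sample_counts_in_every_layer(self):
        cohort = generate_cohort(CohortConfig(
            n_per_group=10, n_normal=0, n_genes=150, n_cpgs=400,
            n_window_cpgs=60, n_meth_genes=15, n_diff_genes=5, seed=3,
        ))
        # 4 subtypes x 2 tumor types x 10
        assert cohort.expression.shape[1] == 80
        assert cohort.betas.shape[1] == 80
        assert cohort.detection_p.shape[1] == 80
        assert cohort.sample_annotations.shape[0] == 80
        assert cohort.segments["sample"].nunique() == 80

    def test_layer_shapes_follow_config(self, small_cohort, small_config):
        assert small_cohort.expression.shape[0] == small_config.n_genes
        assert small_cohort.betas.shape[0] == small_config.n_cpgs
        assert len(small_cohort.truth["window_cpgs"]) == small_config.n_window_cpgs
        assert len(small_cohort.truth["diff_genes"]) == small_config.n_diff_genes

    def test_beta_and_detection_ranges(self, small_cohort):
        b = small_cohort.betas.to_numpy()
        assert np.nanmin(b) >= 0.0 and np.nanmax(b) <= 1.0
        p = small_cohort.detection_p.to_numpy()
        assert p.min() >= 0.0 and p.max() <= 1.0


class TestPlantedEffects:
    def test_zero_noise_expression_equals_centroid(self):
        cohort = generate_cohort(tiny_config(centroid_sd=0.0))
        ann = cohort.sample_annotations
        for sid in ann.index[ann["tumor_type"] == "IBC"][:5]:
            st = ann.at[sid, "subtype"]
            got = cohort.expression.loc[cohort.centroids.index, sid]
            assert np.allclose(got, cohort.centroids[st])

    def test_lres_shift_planted_in_designated_samples(self):
        cohort = generate_cohort(tiny_config(lres_delta=0.4))
        wcpgs = cohort.truth["window_cpgs"]
        lres = cohort.truth["lres_samples"]
        ann = cohort.sample_annotations
        others = [s for s in ann.index if s not in lres and ann.at[s, "tumor_type"] != "NORMAL"]
        mean_lres = cohort.betas.loc[wcpgs, lres].mean().mean()
        mean_other = cohort.betas.loc[wcpgs, others].mean().mean()
        assert mean_lres - mean_other > 0.2

    def test_null_lres_rejects_at_nominal_rate(self):
        # with lres_delta=0 a rank test on window means across tumor types
        # should reject at roughly the nominal level over 20 seeds
        rejections = 0
        for seed in range(20):
            cohort = generate_cohort(tiny_config(seed=seed, lres_delta=0.0, n_per_group=6))
            wcpgs = cohort.truth["window_cpgs"]
            ann = cohort.sample_annotations
            basal = ann.index[ann["subtype"] == "Basal"]
            dcis = [s for s in basal if ann.at[s, "tumor_type"] == "DCIS"]
            ibc = [s for s in basal if ann.at[s, "tumor_type"] == "IBC"]
            a = cohort.betas.loc[wcpgs, dcis].mean().to_numpy()
            b = cohort.betas.loc[wcpgs, ibc].mean().to_numpy()
            p = mannwhitneyu(a, b, alternative="two-sided").pvalue
            rejections += p < 0.05
        assert rejections <= 4  # nominal 1 of 20, generous MC slack

    def test_aberrant_fraction_within_tolerance(self, small_cohort):
        genome = small_cohort.config.genome_length_bp
        targets = {
            key: prof["target_fraction"]
            for key, prof in default_aberration_profiles(
                small_cohort.config.subtypes, small_cohort.config.tumor_types, genome
            ).items()
        }
        ann = small_cohort.sample_annotations
        for sid, frac in small_cohort.truth["aberrant_fraction"].items():
            st, tt = ann.at[sid, "subtype"], ann.at[sid, "tumor_type"]
            if tt == "NORMAL":
                assert frac == 0.0
            else:
                assert abs(frac - targets[(st, tt)]) <= 0.01

    def test_segments_tile_genome_without_overlap(self, small_cohort):
        from dcisibc.io import validate_segments

        validate_segments(small_cohort.segments)
        genome = small_cohort.config.genome_length_bp
        lengths = small_cohort.segments.assign(
            length=lambda d: d["end"] - d["start"] + 1
        ).groupby("sample")["length"].sum()
        assert (lengths == genome).all()

    def test_esr1_bimodal_consistent_with_er_truth(self, small_cohort):
        ann = small_cohort.sample_annotations
        esr1 = small_cohort.expression.loc["ESR1"]
        lo, hi, sd = small_cohort.config.esr1_modes
        pos = esr1[ann["er_truth"] == "positive"]
        neg = esr1[ann["er_truth"] == "negative"]
        assert pos.mean() > (lo + hi) / 2 > neg.mean()

    def test_beta_model_alternative(self):
        cohort = generate_cohort(tiny_config(beta_model="beta"))
        b = cohort.betas.to_numpy()
        assert np.nanmin(b) >= 0.0 and np.nanmax(b) <= 1.0


class TestValidation:
    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("n_per_group", -1, "n_per_group"),
            ("lres_delta", 1.5, "lres_delta"),
            ("missing_rate", -0.1, "missing_rate"),
            ("n_window_cpgs", 10_000, "n_window_cpgs"),
            ("n_diff_genes", 100, "n_diff_genes"),
            ("beta_model", "gamma", "beta_model"),
        ],
    )
    def test_invalid_config_names_field(self, field, value, match):
        with pytest.raises(ValueError, match=match):
            generate_cohort(tiny_config(**{field: value}))


class TestDeterminismAndRoundTrip:
    def test_same_seed_identical_cohorts(self):
        a = generate_cohort(tiny_config())
        b = generate_cohort(tiny_config())
        assert a.expression.equals(b.expression)
        assert a.betas.equals(b.betas)
        assert a.segments.equals(b.segments)
        assert a.truth == b.truth

    def test_write_read_round_trip(self, tmp_path, small_cohort):
        write_cohort(small_cohort, tmp_path / "c")
        back = read_cohort(tmp_path / "c")
        assert np.allclose(back["expression"], small_cohort.expression)
        assert list(back["expression"].index) == list(small_cohort.expression.index)
        got = back["betas"].to_numpy()
        want = small_cohort.betas.to_numpy()
        assert ((got == want) | (np.isnan(got) & np.isnan(want))).all()
        assert back["segments"].equals(small_cohort.segments)
        # BED round trip preserves 1-based inclusive coordinates
        assert back["cpg_positions"]["start"].tolist() == \
            small_cohort.cpg_positions["start"].tolist()

    def test_same_seed_identical_manifests(self, tmp_path):
        cohort = generate_cohort(tiny_config())
        m1 = write_cohort(cohort, tmp_path / "a")
        m2 = write_cohort(generate_cohort(tiny_config()), tmp_path / "b")
        assert m1["files"] == m2["files"]
        assert m1["config_hash"] == m2["config_hash"]

    def test_different_seeds_differ(self, tmp_path):
        for offset in range(5):
            m1 = write_cohort(
                generate_cohort(tiny_config(seed=100 + offset)), tmp_path / f"x{offset}"
            )
            m2 = write_cohort(
                generate_cohort(tiny_config(seed=200 + offset)), tmp_path / f"y{offset}"
            )
            assert m1["files"] != m2["files"]

    def test_centroids_stable_under_noise_scale(self):
        # changing only the noise scale must not move the centroids, so the
        # gap can be measured first and the cohort regenerated
        a = generate_cohort(tiny_config(centroid_sd=0.1))
        b = generate_cohort(tiny_config(centroid_sd=2.0))
        assert a.centroids.equals(b.centroids)
        assert mean_intercentroid_gap(a.centroids) > 0
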