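"""Filtering, age transform, imputation, batch correction, outlier flags."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiclock import (
    AgeTransform,
    SimConfig,
    correct_batches,
    filter_adults,
    flag_distribution_outliers,
    generate_cohort,
    inject_missingness,
    inverse_transform_age,
    knn_impute,
    transform_age,
)
from epiclock.preprocess import _combat_parametric
from oracles import knn_impute_bruteforce


class TestFilterAdults:
    def test_under_25_excluded_boundary_kept(self):
        samples = pd.DataFrame(
            {"age": [10.0, 24.9, 25.0, 80.0]},
            index=[f"s{i}" for i in range(4)],
        )
        kept = filter_adults(samples)
        assert list(kept["age"]) == [25.0, 80.0]

    def test_identity_when_all_adult(self):
        samples = pd.DataFrame({"age": [30.0, 40.0]}, index=["a", "b"])
        pd.testing.assert_frame_equal(filter_adults(samples), samples)

    def test_empty_result_is_error(self):
        samples = pd.DataFrame({"age": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="no samples remain"):
            filter_adults(samples)


class TestAgeTransform:
    def test_anchor_and_known_values(self):
        assert transform_age(20.0) == pytest.approx(0.0)
        assert transform_age(41.0) == pytest.approx(1.0)  # (41-20)/21

    @pytest.mark.parametrize("age", [0.0, 5.0, 20.0, 37.0, 100.0])
    def test_round_trip(self, age):
        assert inverse_transform_age(transform_age(age)) == pytest.approx(
            age, abs=1e-9
        )

    def test_strictly_increasing_on_dense_grid(self):
        grid = np.arange(0, 120.001, 0.5)
        y = transform_age(grid)
        assert np.all(np.diff(y) > 0)
        back = inverse_transform_age(y)
        assert np.max(np.abs(back - grid)) < 1e-9

    @given(st.floats(min_value=0, max_value=120), st.floats(min_value=1, max_value=60))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_any_adult_age(self, age, adult_age):
        t = AgeTransform(adult_age)
        assert inverse_transform_age(transform_age(age, t), t) == pytest.approx(
            age, abs=1e-8
        )

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            transform_age(-1.0)


class TestKnnImpute:
    def test_no_missing_is_identity(self, linear_cohort):
        matrix, _, _ = linear_cohort
        pd.testing.assert_frame_equal(knn_impute(matrix), matrix)

    def test_constant_neighbourhood_gives_constant(self):
        rng = np.random.default_rng(0)
        values = np.full((30, 10), 0.5) + rng.normal(0, 1e-6, (30, 10))
        values[0, 0] = np.nan
        matrix = pd.DataFrame(values)
        out = knn_impute(matrix, k=10)
        assert out.iloc[0, 0] == pytest.approx(0.5, abs=1e-4)

    def test_matches_bruteforce_oracle_unchunked(self):
        cfg = SimConfig(n_samples=20, n_loci=50, seed=33)
        matrix, _, _ = generate_cohort(cfg)
        holey, _ = inject_missingness(matrix, 0.05, seed=34)
        ours = knn_impute(holey, k=10, chunk_size=10_000)
        oracle = knn_impute_bruteforce(holey.to_numpy(), k=10)
        assert np.allclose(ours.to_numpy(), oracle, atol=1e-10)

    def test_chunking_changes_only_co_considered_loci(self):
        cfg = SimConfig(n_samples=30, n_loci=80, seed=35)
        matrix, _, _ = generate_cohort(cfg)
        holey, _ = inject_missingness(matrix, 0.03, seed=36)
        whole = knn_impute(holey, k=5, chunk_size=10_000)
        chunked = knn_impute(holey, k=5, chunk_size=40)
        assert not whole.isna().any().any()
        assert not chunked.isna().any().any()
        # same entries imputed; values may differ only at imputed entries
        mask = holey.isna()
        assert np.allclose(whole.to_numpy()[~mask], chunked.to_numpy()[~mask])


class TestCorrectBatches:
    def test_single_batch_unchanged(self, linear_cohort):
        matrix, samples, _ = linear_cohort
        with pytest.warns(UserWarning, match="single batch"):
            out = correct_batches(matrix, samples)
        pd.testing.assert_frame_equal(out, matrix)

    def test_planted_shift_removed_and_age_signal_kept(self):
        cfg = SimConfig(
            n_samples=200,
            n_loci=200,
            locus_class_counts={"age_linear": 50, "null": 150},
            noise_sd=0.02,
            batch_count=2,
            seed=13,
        )
        matrix, samples, truth = generate_cohort(cfg)
        b1 = samples.index[samples["batch"] == "B1"]
        b0 = samples.index[samples["batch"] == "B0"]
        shifted = matrix.copy()
        shifted[b1] = (shifted[b1] + 0.05).clip(0, 1)
        corrected = correct_batches(shifted, samples, covariates=["age"])

        nulls = truth.loci_of_class("null")
        post = (
            corrected.loc[nulls, b1].mean(axis=1)
            - corrected.loc[nulls, b0].mean(axis=1)
        ).abs()
        assert post.mean() < 0.005  # >=90% of the 0.05 shift removed

        ages = samples["age"].to_numpy()
        x = ages - ages.mean()
        lins = truth.loci_of_class("age_linear")

        def slopes(mat):
            y = mat.loc[lins].to_numpy()
            return (y @ x) / (x @ x)

        retention = slopes(corrected).sum() / slopes(shifted).sum()
        assert retention > 0.8

    def test_confounded_covariate_rejected(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(
            rng.uniform(0.2, 0.8, (20, 8)), columns=[f"s{i}" for i in range(8)]
        )
        samples = pd.DataFrame(
            {
                "age": [30.0] * 4 + [70.0] * 4,  # age constant within batch
                "batch": ["A"] * 4 + ["B"] * 4,
            },
            index=matrix.columns,
        )
        with pytest.raises(ValueError, match="confounded"):
            correct_batches(matrix, samples, covariates=["age"])

    def test_matches_sva_combat_oracle(self, tmp_path):
        """Independent check against Bioconductor's parametric ComBat."""
        rng = np.random.default_rng(0)
        n_genes, n = 30, 40
        batch = np.array([0] * 20 + [1] * 20)
        age = rng.uniform(25, 95, n)
        data = rng.normal(0, 1, (n_genes, n)) + 0.01 * age[None, :]
        data[:, batch == 1] += rng.normal(0.5, 0.3, n_genes)[:, None]
        np.savetxt(tmp_path / "d.tsv", data, delimiter="\t")
        np.savetxt(tmp_path / "meta.tsv", np.column_stack([batch, age]), delimiter="\t")
        script = f"""
suppressMessages(library(sva))
d <- as.matrix(read.table("{tmp_path}/d.tsv", sep="\t"))
meta <- read.table("{tmp_path}/meta.tsv", sep="\t")
out <- ComBat(dat=d, batch=factor(meta$V1), mod=model.matrix(~ V2, data=meta),
              par.prior=TRUE)
write.table(out, "{tmp_path}/out.tsv", sep="\t", row.names=FALSE, col.names=FALSE)
"""
        (tmp_path / "combat.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "combat.R")], check=True, capture_output=True
        )
        reference = np.loadtxt(tmp_path / "out.tsv", delimiter="\t")
        mine = _combat_parametric(data, batch, (age - age.mean())[:, None])
        assert np.max(np.abs(mine - reference)) < 1e-4


class TestOutlierFlags:
    def test_homogeneous_cohort_unflagged_and_injected_outlier_caught(self):
        cfg = SimConfig(n_samples=60, n_loci=800, seed=44)
        matrix, _, _ = generate_cohort(cfg)
        flags = flag_distribution_outliers(matrix)
        assert not flags.any()
        rng = np.random.default_rng(45)
        spoiled = matrix.copy()
        spoiled.iloc[:, 0] = rng.uniform(0, 1, len(matrix))
        flags = flag_distribution_outliers(spoiled)
        assert flags.iloc[0]
        assert flags.iloc[1:].sum() == 0

    def test_infinite_threshold_flags_nothing(self, linear_cohort):
        matrix, _, _ = linear_cohort
        assert not flag_distribution_outliers(matrix, threshold=np.inf).any()
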