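"""The simulator must realise exactly the structure it claims to plant."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from epiclock import (
    SimConfig,
    generate_cohort,
    generate_feature_tracks,
    generate_locus_map,
    inject_batch_effects,
    inject_missingness,
)


def test_planted_lifespan_delta_matches_young_aged_contrast():
    cfg = SimConfig(
        n_samples=2000,
        n_loci=300,
        locus_class_counts={"age_linear": 100, "null": 200},
        lifespan_delta=0.015,
        seed=11,
    )
    matrix, samples, truth = generate_cohort(cfg)
    ages = samples["age"].to_numpy()
    lin = truth.loci_of_class("age_linear")
    sub = matrix.loc[lin].to_numpy()
    delta = sub[:, ages >= 65].mean() - sub[:, ages <= 35].mean()
    assert delta == pytest.approx(0.015, abs=0.003)


def test_null_loci_uncorrelated_with_age():
    cfg = SimConfig(n_samples=500, n_loci=1000, seed=12)  # all-null default
    matrix, samples, truth = generate_cohort(cfg)
    ages = samples["age"].to_numpy()
    x = matrix.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    ac = ages - ages.mean()
    r = (xc @ ac) / (np.sqrt((xc**2).sum(axis=1) * (ac**2).sum()))
    assert abs(r.mean()) < 0.02


def test_parabolic_loci_flat_overall_but_rising_to_peak():
    cfg = SimConfig(
        n_samples=2000,
        n_loci=100,
        locus_class_counts={"age_parabolic": 100},
        parabola_peak_age=62.5,
        noise_sd=0.005,
        seed=13,
    )
    matrix, samples, truth = generate_cohort(cfg)
    ages = samples["age"].to_numpy()
    y = matrix.to_numpy().mean(axis=0)

    def ols_slope(mask):
        a = ages[mask] - ages[mask].mean()
        return (a @ (y[mask] - y[mask].mean())) / (a @ a)

    full = ols_slope(np.ones_like(ages, dtype=bool))
    rising = ols_slope(ages <= 62.5)
    # planted quadratic: expected full-range slope ~0, clearly positive below peak
    assert abs(full) < 0.2 * rising
    assert rising > 0


def test_variance_loci_have_age_increasing_spread_constant_mean():
    cfg = SimConfig(
        n_samples=3000,
        n_loci=60,
        locus_class_counts={"age_variance": 60},
        noise_sd=0.01,
        seed=14,
    )
    matrix, samples, truth = generate_cohort(cfg)
    ages = samples["age"].to_numpy()
    young, aged = ages <= 45, ages >= 80
    x = matrix.to_numpy()
    var_ratio = x[:, aged].var(axis=1) / x[:, young].var(axis=1)
    assert np.median(var_ratio) > 2.0
    mean_diff = np.abs(x[:, aged].mean(axis=1) - x[:, young].mean(axis=1))
    assert np.median(mean_diff) < 0.01


def test_tissue_identity_offset_recovered(mixed_cohort):
    matrix, samples, truth = mixed_cohort
    recovered = []
    for locus in truth.loci_of_class("tissue_identity"):
        dev = truth.loci.loc[locus, "deviant_tissue"]
        in_dev = (samples["tissue"] == dev).to_numpy()
        vals = matrix.loc[locus].to_numpy()
        recovered.append(vals[in_dev].mean() - vals[~in_dev].mean())
    planted = truth.loci.loc[truth.loci["class"] == "tissue_identity", "tissue_offset"]
    assert np.allclose(recovered, planted, atol=0.05)
    assert np.mean(np.abs(np.abs(recovered) - 0.40)) < 0.04  # |bias| < 10% of delta


def test_values_in_range_and_deterministic(mixed_cohort):
    matrix, samples, truth = mixed_cohort
    assert matrix.to_numpy().min() >= 0 and matrix.to_numpy().max() <= 1
    cfg = SimConfig(
        n_samples=300,
        n_loci=400,
        locus_class_counts={
            "age_linear": 60,
            "age_parabolic": 40,
            "age_variance": 40,
            "tissue_identity": 60,
            "interaction": 40,
            "null": 160,
        },
        noise_sd=0.02,
        seed=202,
    )
    again, samples2, _ = generate_cohort(cfg)
    pd.testing.assert_frame_equal(matrix, again)
    pd.testing.assert_frame_equal(samples, samples2)


@pytest.mark.parametrize(
    "bad",
    [
        dict(locus_class_counts={"age_linear": 999}),  # counts != n_loci
        dict(tissues=[]),
        dict(age_range=(90.0, 30.0)),
        dict(missing_rate=1.0),
    ],
)
def test_invalid_configs_rejected(bad):
    cfg = SimConfig(n_samples=50, n_loci=100, **bad)
    with pytest.raises(ValueError):
        generate_cohort(cfg)


def test_missingness_rate_and_determinism():
    cfg = SimConfig(n_samples=100, n_loci=1000, seed=5)
    matrix, _, _ = generate_cohort(cfg)
    out0, mask0 = inject_missingness(matrix, 0.0, seed=9)
    pd.testing.assert_frame_equal(out0, matrix)
    out, mask = inject_missingness(matrix, 0.05, seed=9)
    n_missing = out.isna().to_numpy().sum()
    n = matrix.size
    sd = np.sqrt(n * 0.05 * 0.95)
    assert abs(n_missing - 0.05 * n) <= 3 * sd
    out2, mask2 = inject_missingness(matrix, 0.05, seed=9)
    assert np.array_equal(mask, mask2)
    # original values recoverable via the mask
    assert np.allclose(matrix.to_numpy()[~mask], out.to_numpy()[~mask])
    with pytest.raises(ValueError):
        inject_missingness(matrix, 1.0, seed=1)


def test_batch_shifts_match_recorded_truth():
    cfg = SimConfig(n_samples=300, n_loci=200, batch_count=2, seed=6)
    matrix, samples, _ = generate_cohort(cfg)
    shifted, truth_shifts = inject_batch_effects(matrix, samples, 0.05, seed=3)
    delta = shifted - matrix
    for batch in ("B0", "B1"):
        cols = samples.index[samples["batch"] == batch]
        observed = delta[cols].mean(axis=1)
        # mean realised shift per locus tracks the recorded truth (clipping aside)
        r = pearsonr(observed, truth_shifts[batch]).statistic
        assert r > 0.95
    zero, _ = inject_batch_effects(matrix, samples, 0.0, seed=3)
    pd.testing.assert_frame_equal(zero, matrix)


def test_feature_track_planted_odds_ratio():
    cfg = SimConfig(
        n_samples=10,
        n_loci=1000,
        locus_class_counts={"age_linear": 500, "null": 500},
        seed=8,
    )
    matrix, _, truth = generate_cohort(cfg)
    lmap = generate_locus_map(list(matrix.index), seed=9)
    from epiclock import annotate_loci, derive_features

    tracks = generate_feature_tracks(
        lmap, truth, {"age_linear": ("intergenic", 3.0)}, seed=10
    )
    members = annotate_loci(lmap, derive_features(tracks, lmap.chrom_sizes))
    lin = truth.loci_of_class("age_linear")
    null = truth.loci_of_class("null")
    p1 = members.loc[lin, "intergenic"].mean()
    p0 = members.loc[null, "intergenic"].mean()
    odds_ratio = (p1 / (1 - p1)) / (p0 / (1 - p0))
    assert odds_ratio == pytest.approx(3.0, abs=0.5)


def test_feature_tracks_uniform_without_spec():
    cfg = SimConfig(
        n_samples=10,
        n_loci=1500,
        locus_class_counts={"age_linear": 750, "null": 750},
        seed=18,
    )
    matrix, _, truth = generate_cohort(cfg)
    lmap = generate_locus_map(list(matrix.index), seed=19)
    from epiclock import annotate_loci, derive_features, enrich

    tracks = generate_feature_tracks(lmap, truth, {}, seed=20)
    members = annotate_loci(lmap, derive_features(tracks, lmap.chrom_sizes))
    rows = enrich(truth.loci_of_class("age_linear"), list(matrix.index), members)
    assert (rows["log_odds_ratio"].abs() < 0.3).all()


def test_feature_track_errors():
    cfg = SimConfig(n_samples=10, n_loci=50, seed=1)
    matrix, _, truth = generate_cohort(cfg)
    lmap = generate_locus_map(list(matrix.index), seed=2)
    with pytest.raises(ValueError, match="positive"):
        generate_feature_tracks(lmap, truth, {"null": ("intergenic", -1.0)}, seed=3)
    with pytest.raises(ValueError, match="unknown feature"):
        generate_feature_tracks(lmap, truth, {"null": ("nosuch", 2.0)}, seed=3)
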