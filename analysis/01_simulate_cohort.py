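#!/usr/bin/env python
"""Simulate the reference multi-tissue methylome cohort used downstream.

Writes the beta matrix, sample table, planted truth, locus coordinates and
synthetic genomic feature tracks under results/cohort/.  The cohort mixes
every planted locus class: small age-linear drifts (~1.5% of the beta
scale between young and aged samples), large tissue-identity offsets,
parabolic trajectories peaking at 62.5 years, variance-increasing loci,
tissue x age interactions and pure-noise nulls.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import epiclock as ec
from epiclock.io import (
    write_beta_matrix,
    write_locus_map,
    write_sample_table,
    write_tracks_bed,
    write_truth,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 20260927

config = ec.SimConfig(
    n_samples=800,
    n_loci=2000,
    locus_class_counts={
        "age_linear": 300,
        "age_parabolic": 150,
        "age_variance": 100,
        "tissue_identity": 250,
        "interaction": 100,
        "null": 1100,
    },
    tissues=[("blood", 0.4), ("brain", 0.3), ("liver", 0.3)],
    noise_sd=0.01,
    batch_count=3,
    batch_shift_sd=0.02,
    seed=SEED,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix, samples, truth = ec.generate_cohort(config)
    lmap = ec.generate_locus_map(list(matrix.index), seed=SEED + 1)
    tracks = ec.generate_feature_tracks(
        lmap,
        truth,
        {"age_linear": ("intergenic", 3.0), "tissue_identity": ("cpg_island", 2.0)},
        seed=SEED + 2,
    )
    write_beta_matrix(matrix, OUT / "beta.tsv")
    write_sample_table(samples, OUT / "samples.tsv")
    write_truth(truth, OUT / "truth.json")
    write_locus_map(lmap, OUT / "locus_map.tsv")
    write_tracks_bed(tracks, OUT / "tracks.bed")
    print(f"cohort: {matrix.shape[0]} loci x {matrix.shape[1]} samples -> {OUT}")
    print(samples["tissue"].value_counts().to_string())
    print(f"planted classes:\n{truth.loci['class'].value_counts().to_string()}")


if __name__ == "__main__":
    main()
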