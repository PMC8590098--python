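"""End-to-end pipeline orchestration with seed and artifact provenance.

A pipeline run is described by a config (YAML or dict): a global seed, an
output directory, and per-stage parameters for the fixed stage order
simulate -> preprocess -> select -> train -> evaluate.  Each stage reads
the previous stage's files, and a manifest records package version, seeds,
stage parameters and SHA-256 hashes of every artifact, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from .clock import TrainingConfig, evaluate, predict_ages, train_clock
from .io import (
    read_beta_matrix,
    read_sample_table,
    write_beta_matrix,
    write_sample_table,
    write_truth,
)
from .preprocess import filter_adults, knn_impute
from .select import score_table, top_fraction
from .synthetic import SimConfig, generate_cohort

STAGES = ("simulate", "preprocess", "select", "train", "evaluate")

DEFAULTS = {
    "min_age": 25.0,
    "l1_ratio": 0.5,
    "cv_folds": 10,
    "top_fraction": 0.20,
    "fdr_q": 0.10,
    "select_method": "mutual_information",
    "test_fraction": 0.25,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(source) -> dict:
    if isinstance(source, (str, Path)):
        config = yaml.safe_load(Path(source).read_text())
    else:
        config = dict(source)
    known = set(DEFAULTS) | {"seed", "out_dir", "stages", "sim"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stage names: {bad}")
    resolved = {**DEFAULTS, **config}
    resolved.setdefault("seed", 0)
    resolved["stages"] = stages
    return resolved


def run_pipeline(config) -> Path:
    """Run the configured stages; returns the run directory."""
    cfg = load_config(config)
    out_dir = Path(cfg.get("out_dir", "pipeline_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "resolved_config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))
    manifest = {"version": __version__, "seed": cfg["seed"], "stages": []}
    seed = int(cfg["seed"])

    matrix = samples = None
    for stage in cfg["stages"]:
        artifacts = []
        if stage == "simulate":
            sim = SimConfig(**{**cfg.get("sim", {}), "seed": seed})
            matrix, samples, truth = generate_cohort(sim)
            write_beta_matrix(matrix, out_dir / "beta.tsv")
            write_sample_table(samples, out_dir / "samples.tsv")
            write_truth(truth, out_dir / "truth.json")
            artifacts = ["beta.tsv", "samples.tsv", "truth.json"]
        elif stage == "preprocess":
            if matrix is None:
                matrix = read_beta_matrix(out_dir / "beta.tsv")
                samples = read_sample_table(out_dir / "samples.tsv")
            samples = filter_adults(samples, cfg["min_age"])
            matrix = matrix[samples.index]
            if matrix.isna().any().any():
                matrix = knn_impute(matrix)
            write_beta_matrix(matrix, out_dir / "beta.clean.tsv")
            write_sample_table(samples, out_dir / "samples.clean.tsv")
            artifacts = ["beta.clean.tsv", "samples.clean.tsv"]
        elif stage == "select":
            ages = samples.loc[matrix.columns, "age"].to_numpy()
            scores = score_table(matrix, ages, methods=[cfg["select_method"]], seed=seed)
            scores.to_csv(out_dir / "scores.tsv", sep="\t", index=False)
            series = scores.set_index("locus_id")["score"]
            selected = top_fraction(series, cfg["top_fraction"])
            (out_dir / "selected_loci.txt").write_text("\n".join(selected) + "\n")
            matrix = matrix.loc[selected]
            artifacts = ["scores.tsv", "selected_loci.txt"]
        elif stage == "train":
            import numpy as np

            rng = np.random.default_rng(seed)
            ids = np.array(matrix.columns)
            rng.shuffle(ids)
            n_test = max(1, int(round(cfg["test_fraction"] * len(ids))))
            test_ids, train_ids = list(ids[:n_test]), list(ids[n_test:])
            tc = TrainingConfig(
                l1_ratio=cfg["l1_ratio"], cv_folds=cfg["cv_folds"], seed=seed
            )
            model = train_clock(matrix[train_ids], samples.loc[train_ids], tc)
            (out_dir / "clock.json").write_text(model.to_json())
            (out_dir / "test_samples.txt").write_text("\n".join(test_ids) + "\n")
            artifacts = ["clock.json", "test_samples.txt"]
        elif stage == "evaluate":
            from .clock import ClockModel

            model = ClockModel.from_json((out_dir / "clock.json").read_text())
            test_ids = (out_dir / "test_samples.txt").read_text().split()
            pred = predict_ages(model, matrix[test_ids])
            actual = samples.loc[test_ids, "age"].to_numpy()
            metrics = evaluate(pred.to_numpy(), actual)
            (out_dir / "metrics.json").write_text(
                json.dumps(
                    {
                        "pearson_r": metrics.pearson_r,
                        "rmse": metrics.rmse,
                        "mad": metrics.mad,
                        "n_test": metrics.n,
                        "n_clock_loci": len(model.loci),
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
            artifacts = ["metrics.json"]
        manifest["stages"].append(
            {
                "name": stage,
                "artifacts": {a: _sha256(out_dir / a) for a in artifacts},
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out_dir
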