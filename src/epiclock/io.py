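"""TSV/BED/JSON readers and writers for every pipeline artifact.

All tabular artifacts are TSV with a header (diffable, versionable);
missing betas use the token "NA"; genomic tracks are BED3+name or BED6.
Readers validate ranges and identifiers and report the offending
row/column on failure.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import FeatureTrack, LocusMap, SyntheticTruth

NA_TOKEN = "NA"
FORMAT_VERSION = "1"


def write_beta_matrix(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "locus_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.10g")


def read_beta_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    if df.empty or df.shape[0] == 0:
        raise ValueError(f"{path}: no loci")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate locus id {dup!r}")
    if pd.Index(df.columns).duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    values = df.to_numpy(dtype=float)
    bad = np.argwhere((values < 0) | (values > 1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: value {values[i, j]} out of [0, 1] at locus "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return df


def write_sample_table(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    if "age" in df.columns:
        df["age"] = df["age"].astype(float)
        if (df["age"] < 0).any():
            raise ValueError(f"{path}: negative age")
    return df


def write_tracks_bed(tracks: list[FeatureTrack], path) -> None:
    """All tracks in one BED file: chrom, start, end, track name [, ., strand]."""
    rows = []
    for t in tracks:
        for _, r in t.intervals.iterrows():
            row = [r["chrom"], int(r["start"]), int(r["end"]), t.name]
            if "strand" in t.intervals.columns:
                row += [".", r["strand"]]
            rows.append("\t".join(map(str, row)))
    Path(path).write_text("\n".join(rows) + "\n")


def read_tracks_bed(path) -> list[FeatureTrack]:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        rows.append(parts)
    by_name: dict[str, list] = {}
    for parts in rows:
        chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        rec = {"chrom": chrom, "start": start, "end": end}
        if len(parts) >= 6:
            rec["strand"] = parts[5]
        by_name.setdefault(name, []).append(rec)
    tracks = []
    for name, recs in by_name.items():
        df = pd.DataFrame(recs).sort_values(["chrom", "start"]).reset_index(drop=True)
        tracks.append(FeatureTrack(name, df))
    return tracks


def write_locus_map(locus_map: LocusMap, path) -> None:
    df = locus_map.positions.copy()
    df.index.name = "locus_id"
    df.to_csv(path, sep="\t")
    Path(str(path) + ".sizes.json").write_text(json.dumps(locus_map.chrom_sizes))


def read_locus_map(path) -> LocusMap:
    df = pd.read_csv(path, sep="\t", index_col=0)
    sizes = json.loads(Path(str(path) + ".sizes.json").read_text())
    lm = LocusMap(positions=df, chrom_sizes=sizes)
    lm.validate()
    return lm


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "clip_fraction": truth.clip_fraction,
        "loci": truth.loci.reset_index().to_dict(orient="list"),
        "samples": truth.samples.reset_index().to_dict(orient="list"),
    }
    if truth.batch_shifts is not None:
        payload["batch_shifts"] = truth.batch_shifts.reset_index().to_dict(orient="list")
    Path(path).write_text(json.dumps(payload))


def read_truth(path) -> SyntheticTruth:
    d = json.loads(Path(path).read_text())
    loci = pd.DataFrame(d["loci"]).set_index("locus_id")
    samples = pd.DataFrame(d["samples"]).set_index("sample_id")
    shifts = None
    if "batch_shifts" in d:
        shifts = pd.DataFrame(d["batch_shifts"]).set_index("index")
    return SyntheticTruth(
        loci=loci,
        samples=samples,
        batch_shifts=shifts,
        clip_fraction=d.get("clip_fraction", 0.0),
    )
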