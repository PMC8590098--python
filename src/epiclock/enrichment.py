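"""Genomic-feature annotation and hypergeometric enrichment of locus sets.

Coordinates are BED-style throughout: 0-based, half-open intervals; CpG
loci are single cytosine positions.  Derived features follow the usual
array-annotation conventions: promoters are the 2 kb strand-aware window
upstream of the TSS, CpG-island shores the 2 kb flanks of island bodies,
shelves the next 2 kb beyond the shores, intergenic the complement of
genes plus promoters.  Enrichment of a locus set against the array
background uses the hypergeometric distribution (both tails, so depletion
is the under-representation tail with a negative log odds ratio), with
Benjamini-Hochberg correction across features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .synthetic import FeatureTrack, LocusMap

# ---------------------------------------------------------------------------
# Interval arithmetic on sorted half-open intervals, per chromosome
# ---------------------------------------------------------------------------


def merge_intervals(iv: pd.DataFrame) -> pd.DataFrame:
    """Union of half-open intervals, sorted, per chromosome."""
    if iv.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    for chrom, sub in iv.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Set difference a \\ b of half-open intervals (both merged first)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    rows = []
    b_by_chrom = {c: sub for c, sub in b.groupby("chrom")} if not b.empty else {}
    for chrom, sub_a in a.groupby("chrom", sort=True):
        cuts = b_by_chrom.get(chrom)
        starts_a = sub_a["start"].to_numpy()
        ends_a = sub_a["end"].to_numpy()
        if cuts is None:
            rows.extend((chrom, s, e) for s, e in zip(starts_a, ends_a))
            continue
        cs = cuts["start"].to_numpy()
        ce = cuts["end"].to_numpy()
        for s, e in zip(starts_a, ends_a):
            lo = int(np.searchsorted(ce, s, side="right"))
            hi = int(np.searchsorted(cs, e, side="left"))
            pos = s
            for j in range(lo, hi):  # only cuts overlapping [s, e)
                if cs[j] > pos:
                    rows.append((chrom, pos, cs[j]))
                pos = max(pos, ce[j])
            if pos < e:
                rows.append((chrom, pos, e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _flanks(iv: pd.DataFrame, width: int, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    if iv.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    sizes = iv["chrom"].map(chrom_sizes).fillna(np.inf)
    left = pd.DataFrame(
        {
            "chrom": iv["chrom"],
            "start": np.maximum(iv["start"] - width, 0),
            "end": iv["start"],
        }
    )
    right = pd.DataFrame(
        {
            "chrom": iv["chrom"],
            "start": iv["end"],
            "end": np.minimum(iv["end"] + width, sizes).astype(int),
        }
    )
    out = pd.concat([left, right], ignore_index=True)
    return out[out["start"] < out["end"]].reset_index(drop=True)


def _clip(iv: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    if iv.empty:
        return iv
    out = iv.copy()
    sizes = out["chrom"].map(chrom_sizes)
    out["start"] = np.maximum(out["start"], 0)
    out["end"] = np.minimum(out["end"], sizes)
    return out[out["start"] < out["end"]].reset_index(drop=True)


@dataclass
class DerivedFeatureSet:
    """Interval features derived from raw tracks, plus point features."""

    intervals: dict[str, pd.DataFrame]  # feature name -> merged BED3 intervals
    points: dict[str, pd.DataFrame]  # feature name -> chrom/pos point table
    point_window: int = 500

    @property
    def names(self) -> list[str]:
        return list(self.intervals) + list(self.points)


def derive_features(
    tracks: list[FeatureTrack],
    chrom_sizes: dict[str, int],
    promoter_width: int = 2000,
    flank_width: int = 2000,
    point_window: int = 500,
) -> DerivedFeatureSet:
    """Derive island/shore/shelf, gene/promoter/intergenic and point features.

    Expects tracks named cpg_island, gene, tss (BED6, strand required),
    and optionally point tracks (enhancer, eqtl).  Shores exclude island
    bodies; shelves exclude shores and bodies; intergenic is the
    complement of genes plus promoters, clipped to contig bounds.
    """
    by_name = {t.name: t for t in tracks}
    for required in ("cpg_island", "gene", "tss"):
        if required not in by_name:
            raise ValueError(f"missing required track {required!r}")
    tss = by_name["tss"].intervals
    if "strand" not in tss.columns or tss["strand"].isin(["+", "-"]).all() is False:
        raise ValueError("tss track requires a strand column with +/- values")

    islands = merge_intervals(by_name["cpg_island"].intervals)
    genes = merge_intervals(by_name["gene"].intervals)

    shores = subtract_intervals(_flanks(islands, flank_width, chrom_sizes), islands)
    shores = _clip(shores, chrom_sizes)
    bodies_and_shores = merge_intervals(pd.concat([islands, shores]))
    shelves = subtract_intervals(
        _flanks(bodies_and_shores, flank_width, chrom_sizes), bodies_and_shores
    )
    shelves = _clip(shelves, chrom_sizes)

    plus = tss["strand"].to_numpy() == "+"
    prom = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": np.where(plus, tss["start"] - promoter_width, tss["end"]),
            "end": np.where(plus, tss["start"], tss["end"] + promoter_width),
        }
    )
    promoters = merge_intervals(_clip(prom, chrom_sizes))

    genic = merge_intervals(pd.concat([genes, promoters]))
    whole = pd.DataFrame(
        [(c, 0, s) for c, s in chrom_sizes.items()], columns=["chrom", "start", "end"]
    )
    intergenic = subtract_intervals(whole, genic)

    intervals = {
        "cpg_island": islands,
        "shore": shores,
        "shelf": shelves,
        "gene": genes,
        "promoter": promoters,
        "intergenic": intergenic,
    }
    points = {}
    for name, track in by_name.items():
        if name in ("cpg_island", "gene", "tss"):
            continue
        iv = track.intervals
        mid = ((iv["start"] + iv["end"] - 1) // 2) if len(iv) else pd.Series(dtype=int)
        points[name] = pd.DataFrame({"chrom": iv.get("chrom", []), "pos": mid})
    return DerivedFeatureSet(intervals=intervals, points=points, point_window=point_window)


def _member_of(
    chrom: np.ndarray, pos: np.ndarray, intervals: pd.DataFrame
) -> np.ndarray:
    """Point-in-interval membership against merged, sorted intervals."""
    out = np.zeros(len(pos), dtype=bool)
    if intervals.empty:
        return out
    for c, sub in intervals.groupby("chrom"):
        mask = chrom == c
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, pos[mask], side="right") - 1
        ok = idx >= 0
        hit = np.zeros(mask.sum(), dtype=bool)
        hit[ok] = pos[mask][ok] < ends[idx[ok]]
        out[mask] = hit
    return out


def annotate_loci(locus_map: LocusMap, features: DerivedFeatureSet) -> pd.DataFrame:
    """Boolean membership table: loci x features (plus open_sea)."""
    df = locus_map.positions
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    known = np.isin(chrom, list(locus_map.chrom_sizes))
    if not known.all():
        import warnings

        warnings.warn(f"{int((~known).sum())} loci on unknown contigs left unannotated")
    table = {}
    for name, iv in features.intervals.items():
        table[name] = _member_of(chrom, pos, iv) & known
    w = features.point_window
    for name, pts in features.points.items():
        member = np.zeros(len(pos), dtype=bool)
        for c, sub in pts.groupby("chrom") if len(pts) else []:
            mask = chrom == c
            if not mask.any():
                continue
            p = np.sort(sub["pos"].to_numpy())
            lo = np.searchsorted(p, pos[mask] - w, side="left")
            hi = np.searchsorted(p, pos[mask] + w, side="right")
            member[mask] = hi > lo
        table[name] = member & known
    out = pd.DataFrame(table, index=df.index)
    out["open_sea"] = ~(out["cpg_island"] | out["shore"] | out["shelf"]) & known
    return out


def enrich(
    set_ids: list[str],
    background_ids: list[str],
    membership: pd.DataFrame,
    fdr_q: float = 0.10,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a locus set against the array background.

    Per feature: k = set members in feature, K = set size, m = background
    members in feature, N = background size.  Reports both tails, a
    two-sided p (2 x smaller tail, capped at 1), the log odds ratio with
    Haldane-Anscombe 0.5 correction, and BH q across features.
    """
    set_ids = list(set_ids)
    background_ids = list(background_ids)
    if not set_ids:
        raise ValueError("empty locus set")
    extra = set(set_ids) - set(background_ids)
    if extra:
        raise ValueError(f"{len(extra)} set loci absent from background")
    bg = membership.loc[background_ids]
    sub = membership.loc[set_ids]
    n_bg = len(bg)
    n_set = len(sub)
    rows = []
    for feature in membership.columns:
        m = int(bg[feature].sum())
        k = int(sub[feature].sum())
        p_over = float(hypergeom.sf(k - 1, n_bg, m, n_set))
        p_under = float(hypergeom.cdf(k, n_bg, m, n_set))
        p_two = min(1.0, 2.0 * min(p_over, p_under))
        # odds of the feature in the set vs in the background, 0.5-corrected
        log_or = float(
            np.log((k + 0.5) / (n_set - k + 0.5))
            - np.log((m + 0.5) / (n_bg - m + 0.5))
        )
        rows.append(
            {
                "feature": feature,
                "k": k,
                "K": n_set,
                "m": m,
                "N": n_bg,
                "log_odds_ratio": log_or,
                "p_over": p_over,
                "p_under": p_under,
                "p_two_sided": p_two,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = multipletests(out["p_two_sided"].to_numpy(), alpha=fdr_q, method="fdr_bh")[1]
    return out
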