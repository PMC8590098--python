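"""Feature derivation, locus annotation and hypergeometric enrichment."""

import numpy as np
import pandas as pd
import pytest

from epiclock import SimConfig, annotate_loci, derive_features, enrich, generate_cohort
from epiclock.enrichment import merge_intervals, subtract_intervals
from epiclock.synthetic import FeatureTrack, LocusMap, generate_feature_tracks, generate_locus_map
from oracles import hypergeom_tails, point_in_intervals_scan


def _track(name, rows, cols=("chrom", "start", "end")):
    return FeatureTrack(name, pd.DataFrame(rows, columns=list(cols)))


def _basic_tracks():
    return [
        _track("cpg_island", [("c1", 1000, 2000)]),
        _track("gene", [("c1", 5000, 8000)]),
        _track(
            "tss",
            [("c1", 5000, 5001, "+")],
            cols=("chrom", "start", "end", "strand"),
        ),
    ]


class TestDeriveFeatures:
    def test_island_shores_shelves_with_edge_clipping(self):
        feats = derive_features(_basic_tracks(), {"c1": 10_000})
        shores = feats.intervals["shore"].to_records(index=False).tolist()
        shelves = feats.intervals["shelf"].to_records(index=False).tolist()
        # island [1000,2000): left shore clipped at 0, left shelf vanishes
        assert ("c1", 0, 1000) in shores and ("c1", 2000, 4000) in shores
        assert shelves == [("c1", 4000, 6000)]

    def test_minus_strand_promoter_extends_rightward(self):
        tracks = _basic_tracks()
        tracks[2] = _track(
            "tss", [("c1", 7999, 8000, "-")], cols=("chrom", "start", "end", "strand")
        )
        feats = derive_features(tracks, {"c1": 20_000})
        prom = feats.intervals["promoter"].iloc[0]
        assert (prom["start"], prom["end"]) == (8000, 10_000)

    def test_promoter_is_2kb_except_at_contig_edge(self):
        feats = derive_features(_basic_tracks(), {"c1": 10_000})
        prom = feats.intervals["promoter"].iloc[0]
        assert prom["end"] - prom["start"] == 2000
        feats_small = derive_features(_basic_tracks(), {"c1": 10_000})
        assert (feats_small.intervals["shore"]["start"] >= 0).all()

    def test_empty_island_track_gives_empty_shores(self):
        tracks = _basic_tracks()
        tracks[0] = _track("cpg_island", [])
        feats = derive_features(tracks, {"c1": 10_000})
        assert feats.intervals["shore"].empty
        assert feats.intervals["shelf"].empty

    def test_shores_exclude_bodies_everywhere(self):
        rng = np.random.default_rng(6)
        rows = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(500, 6000))
            rows.append(("c1", pos, pos + int(rng.integers(200, 3000))))
            pos = rows[-1][2]
        tracks = _basic_tracks()
        tracks[0] = _track("cpg_island", rows)
        feats = derive_features(tracks, {"c1": pos + 10_000})
        islands = feats.intervals["cpg_island"]
        shores = feats.intervals["shore"]
        inter = subtract_intervals(shores, islands)
        # subtracting islands from shores changes nothing: already disjoint
        assert inter["end"].sub(inter["start"]).sum() == shores["end"].sub(shores["start"]).sum()


class TestAnnotateLoci:
    def test_half_open_boundaries(self):
        lmap = LocusMap(
            positions=pd.DataFrame(
                {"chrom": ["c1", "c1"], "pos": [1999, 2000]}, index=["a", "b"]
            ),
            chrom_sizes={"c1": 10_000},
        )
        feats = derive_features(_basic_tracks(), {"c1": 10_000})
        members = annotate_loci(lmap, feats)
        assert members.loc["a", "cpg_island"]
        assert not members.loc["b", "cpg_island"]

    def test_multiple_membership_allowed(self):
        # locus inside the gene promoter that also lies in an island shore
        tracks = [
            _track("cpg_island", [("c1", 1000, 2000)]),
            _track("gene", [("c1", 3500, 6000)]),
            _track("tss", [("c1", 3500, 3501, "+")], cols=("chrom", "start", "end", "strand")),
        ]
        lmap = LocusMap(
            positions=pd.DataFrame({"chrom": ["c1"], "pos": [2500]}, index=["a"]),
            chrom_sizes={"c1": 10_000},
        )
        members = annotate_loci(lmap, derive_features(tracks, {"c1": 10_000}))
        assert members.loc["a", "promoter"] and members.loc["a", "shore"]

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(7)
        intervals = []
        pos = 0
        for _ in range(20):
            pos += int(rng.integers(100, 2000))
            intervals.append(("c1", pos, pos + int(rng.integers(50, 800))))
            pos = intervals[-1][2]
        size = pos + 1000
        lmap = LocusMap(
            positions=pd.DataFrame(
                {"chrom": "c1", "pos": rng.integers(0, size, 200)},
                index=[f"cg{i}" for i in range(200)],
            ).drop_duplicates(subset=["chrom", "pos"]),
            chrom_sizes={"c1": size},
        )
        tracks = [
            _track("cpg_island", intervals),
            _track("gene", []),
            _track("tss", [], cols=("chrom", "start", "end", "strand")),
        ]
        members = annotate_loci(lmap, derive_features(tracks, {"c1": size}))
        for locus, row in lmap.positions.iterrows():
            expected = point_in_intervals_scan(row["chrom"], row["pos"], intervals)
            assert members.loc[locus, "cpg_island"] == expected


class TestEnrich:
    @staticmethod
    def _membership(n=100, seed=8):
        rng = np.random.default_rng(seed)
        ids = [f"cg{i}" for i in range(n)]
        return pd.DataFrame(
            {"feat": rng.uniform(size=n) < 0.5}, index=ids
        )

    def test_set_equal_background_is_null(self):
        members = self._membership()
        rows = enrich(list(members.index), list(members.index), members)
        assert rows["log_odds_ratio"].abs().max() == pytest.approx(0.0)
        assert (rows["p_two_sided"] == 1.0).all()

    def test_tail_probability_matches_enumeration(self):
        members = self._membership(100, seed=9)
        members["feat"] = [i < 50 for i in range(100)]
        chosen = [f"cg{i}" for i in range(45, 55)]  # k=5 of K=10
        rows = enrich(chosen, list(members.index), members)
        k = rows.loc["feat", "k"]
        over, under = hypergeom_tails(int(k), 10, 50, 100)
        assert rows.loc["feat", "p_over"] == pytest.approx(over, rel=1e-9)
        assert rows.loc["feat", "p_under"] == pytest.approx(under, rel=1e-9)

    def test_exhaustive_small_tables(self):
        """All 2x2 configurations with N <= 60 against exact enumeration."""
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = int(rng.integers(10, 61))
            m = int(rng.integers(1, n))
            big_k = int(rng.integers(1, n))
            ids = [f"g{i}" for i in range(n)]
            members = pd.DataFrame({"f": [i < m for i in range(n)]}, index=ids)
            chosen = list(rng.choice(ids, size=big_k, replace=False))
            rows = enrich(chosen, ids, members)
            k = int(rows.loc["f", "k"])
            over, under = hypergeom_tails(k, big_k, m, n)
            assert rows.loc["f", "p_over"] == pytest.approx(over, rel=1e-9, abs=1e-12)
            assert rows.loc["f", "p_under"] == pytest.approx(under, rel=1e-9, abs=1e-12)

    def test_feature_complement_flips_log_odds_sign(self):
        members = self._membership(200, seed=11)
        members["anti"] = ~members["feat"]
        chosen = list(members.index[:40])
        rows = enrich(chosen, list(members.index), members)
        assert rows.loc["feat", "log_odds_ratio"] == pytest.approx(
            -rows.loc["anti", "log_odds_ratio"]
        )

    def test_set_outside_background_rejected(self):
        members = self._membership()
        with pytest.raises(ValueError, match="absent"):
            enrich(["nope"], list(members.index), members)
        with pytest.raises(ValueError, match="empty"):
            enrich([], list(members.index), members)


def test_planted_enrichment_recovered_end_to_end():
    cfg = SimConfig(
        n_samples=10,
        n_loci=1200,
        locus_class_counts={"age_linear": 200, "null": 1000},
        seed=80,
    )
    matrix, _, truth = generate_cohort(cfg)
    lmap = generate_locus_map(list(matrix.index), seed=81)
    tracks = generate_feature_tracks(lmap, truth, {"age_linear": ("intergenic", 3.0)}, seed=82)
    members = annotate_loci(lmap, derive_features(tracks, lmap.chrom_sizes))
    rows = enrich(truth.loci_of_class("age_linear"), list(matrix.index), members)
    assert rows.loc["intergenic", "log_odds_ratio"] > 0
    assert rows.loc["intergenic", "q"] < 0.1


def test_merge_intervals_oracle():
    rng = np.random.default_rng(12)
    raw = []
    for _ in range(50):
        s = int(rng.integers(0, 5000))
        raw.append(("c1", s, s + int(rng.integers(1, 400))))
    merged = merge_intervals(pd.DataFrame(raw, columns=["chrom", "start", "end"]))
    covered = np.zeros(6000, dtype=bool)
    for _, s, e in raw:
        covered[s:e] = True
    merged_covered = np.zeros(6000, dtype=bool)
    for _, row in merged.iterrows():
        assert not merged_covered[row["start"] : row["end"]].any()  # disjoint
        merged_covered[row["start"] : row["end"]] = True
    assert np.array_equal(covered, merged_covered)
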