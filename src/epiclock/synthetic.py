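"""Synthetic methylome cohorts with planted aging structure.

Generates beta-value matrices (loci x samples, values in [0, 1]) whose
statistical structure mimics large multi-tissue 450k-array compendia:
age-linear loci whose lifetime change is small (~1.5% of the beta scale),
tissue-identity loci with large between-tissue offsets, parabolic
(rise-then-fall) trajectories, variance-increasing loci, tissue-by-age
interaction loci, and pure-noise null loci.  Every planted effect is
recorded in a :class:`SyntheticTruth` so downstream recovery can be tested
against ground truth.

Noise is added on the logit scale and inverse-transformed, which respects
the [0, 1] range and reproduces the bimodal marginal distribution of array
betas without heavy clipping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

LOCUS_CLASSES = (
    "age_linear",
    "age_parabolic",
    "age_variance",
    "tissue_identity",
    "interaction",
    "null",
)

# Windows of the young/aged group contrast used to calibrate the planted
# age-linear slope so that the expected young-vs-aged beta difference equals
# lifespan_delta (the "delta" metric convention).
YOUNG_WINDOW = (25.0, 35.0)
AGED_WINDOW = (65.0, 100.0)

_MU_EPS = 1e-3  # mean values are kept inside [eps, 1-eps] before logit


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    ``lifespan_delta`` is the expected beta difference between the aged
    (65-100) and young (25-35) sample groups at an age-linear locus;
    ``tissue_delta`` the expected between-tissue mean difference at a
    tissue-identity locus; ``noise_sd`` the residual beta-scale standard
    deviation around the planted mean; ``interaction_slope`` the extra
    beta-per-year slope a deviant tissue gets at interaction loci.
    """

    n_samples: int = 500
    n_loci: int = 1000
    age_range: tuple[float, float] = (25.0, 100.0)
    tissues: list[tuple[str, float]] = field(
        default_factory=lambda: [("blood", 0.5), ("brain", 0.5)]
    )
    locus_class_counts: dict[str, int] | None = None
    lifespan_delta: float = 0.015
    tissue_delta: float = 0.40
    interaction_slope: float = 0.001
    parabola_peak_age: float = 62.5
    parabola_amplitude: float = 0.02
    variance_slope: float = 8.0  # variance multiplier at max age = 1 + variance_slope
    noise_sd: float = 0.01
    batch_count: int = 1
    batch_shift_sd: float = 0.0
    missing_rate: float = 0.0
    hyper_fraction: float = 1.0  # fraction of age_linear loci gaining methylation
    ages: list[float] | None = None  # explicit age design; default uniform sampling
    disease_groups: list[tuple[str, int, float]] = field(default_factory=list)
    seed: int = 0

    def class_counts(self) -> dict[str, int]:
        if self.locus_class_counts is None:
            return {"null": self.n_loci}
        counts = {c: 0 for c in LOCUS_CLASSES}
        counts.update(self.locus_class_counts)
        return counts

    def validate(self) -> None:
        lo, hi = self.age_range
        if hi <= lo:
            raise ValueError(f"age_range inverted: {self.age_range}")
        if not self.tissues:
            raise ValueError("empty tissue list")
        props = [p for _, p in self.tissues]
        if abs(sum(props) - 1.0) > 1e-8:
            raise ValueError(f"tissue proportions sum to {sum(props)}, expected 1")
        counts = self.class_counts()
        unknown = set(counts) - set(LOCUS_CLASSES)
        if unknown:
            raise ValueError(f"unknown locus classes: {sorted(unknown)}")
        if sum(counts.values()) != self.n_loci:
            raise ValueError(
                f"locus_class_counts sums to {sum(counts.values())}, "
                f"but n_loci = {self.n_loci}"
            )
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0, 1): {self.missing_rate}")
        if self.ages is not None:
            if len(self.ages) != self.n_samples:
                raise ValueError(
                    f"explicit ages length {len(self.ages)} != n_samples {self.n_samples}"
                )
            if self.disease_groups:
                raise ValueError("explicit ages cannot be combined with disease_groups")
        for name, value in [
            ("lifespan_delta", self.lifespan_delta),
            ("tissue_delta", self.tissue_delta),
            ("noise_sd", self.noise_sd),
        ]:
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1]: {value}")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated cohort.

    ``loci`` has one row per locus: class label, signed slope (beta/year),
    parabola peak age, variance slope, deviant tissue and its offset, and
    the interaction slope.  ``samples`` records each sample's true batch,
    condition, and planted age-acceleration shift in years.  ``batch_shifts``
    (loci x batches) holds additive planted batch effects, when any.
    """

    loci: pd.DataFrame
    samples: pd.DataFrame
    batch_shifts: pd.DataFrame | None = None
    clip_fraction: float = 0.0

    def loci_of_class(self, cls: str) -> list[str]:
        return list(self.loci.index[self.loci["class"] == cls])


def _window_gap(age_range: tuple[float, float]) -> float:
    """Expected aged-window minus young-window mean age under uniform sampling."""
    lo, hi = age_range

    def mid(w):
        a, b = max(w[0], lo), min(w[1], hi)
        return (a + b) / 2.0 if b > a else None

    young, aged = mid(YOUNG_WINDOW), mid(AGED_WINDOW)
    if young is None or aged is None or aged <= young:
        return hi - lo  # windows outside range: fall back to full span
    return aged - young


def _sample_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    labels = [t for t, _ in config.tissues]
    props = np.array([p for _, p in config.tissues])
    rows = []
    n_total = config.n_samples + sum(n for _, n, _ in config.disease_groups)
    lo, hi = config.age_range
    if config.ages is not None:
        ages = np.asarray(config.ages, dtype=float)
    else:
        ages = rng.uniform(lo, hi, size=n_total)
    tissue = rng.choice(labels, size=n_total, p=props)
    batch = rng.integers(config.batch_count, size=n_total)
    conditions = ["control"] * config.n_samples
    shifts = [0.0] * config.n_samples
    for label, n, shift in config.disease_groups:
        conditions += [label] * n
        shifts += [float(shift)] * n
    for i in range(n_total):
        rows.append(
            {
                "sample_id": f"S{i:05d}",
                "age": ages[i],
                "tissue": tissue[i],
                "batch": f"B{batch[i]}",
                "condition": conditions[i],
                "shift_years": shifts[i],
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a cohort: returns (beta matrix, sample table, truth).

    The beta matrix is loci x samples.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = _sample_table(config, rng)
    n = len(samples)
    ages = samples["age"].to_numpy()
    eff_age = ages + samples["shift_years"].to_numpy()
    lo, hi = config.age_range
    mean_age = (lo + hi) / 2.0
    tissue_labels = [t for t, _ in config.tissues]

    counts = config.class_counts()
    classes = np.concatenate(
        [np.full(counts.get(c, 0), c) for c in LOCUS_CLASSES]
    ).astype(object)
    rng.shuffle(classes)
    n_loci = config.n_loci
    locus_ids = [f"cg{i:06d}" for i in range(n_loci)]

    # Per-locus baseline from a low/intermediate/high methylation mixture;
    # classes with large planted offsets get mid-range baselines so the
    # offset fits inside [0, 1].
    state = rng.choice(3, size=n_loci, p=[0.35, 0.30, 0.35])
    m0 = np.where(
        state == 0,
        rng.uniform(0.05, 0.20, n_loci),
        np.where(
            state == 1,
            rng.uniform(0.35, 0.65, n_loci),
            rng.uniform(0.80, 0.95, n_loci),
        ),
    )
    wide = np.isin(classes, ["tissue_identity"])
    m0[wide] = rng.uniform(0.25, 0.45, wide.sum())
    bumped = np.isin(classes, ["age_parabolic"])
    m0[bumped] = rng.uniform(0.20, 0.70, bumped.sum())

    gap = _window_gap(config.age_range)
    slope = np.zeros(n_loci)
    is_lin = classes == "age_linear"
    sign = np.where(
        rng.uniform(size=n_loci) < config.hyper_fraction, 1.0, -1.0
    )
    slope[is_lin] = sign[is_lin] * config.lifespan_delta / gap

    peak = np.full(n_loci, np.nan)
    peak[classes == "age_parabolic"] = config.parabola_peak_age
    var_slope = np.zeros(n_loci)
    var_slope[classes == "age_variance"] = config.variance_slope

    deviant_tissue = np.array([None] * n_loci, dtype=object)
    tissue_offset = np.zeros(n_loci)
    inter_slope = np.zeros(n_loci)
    multi_tissue = len(tissue_labels) > 1
    for name, amount in [
        ("tissue_identity", config.tissue_delta),
        ("interaction", config.interaction_slope),
    ]:
        idx = np.where(classes == name)[0]
        if len(idx) and not multi_tissue:
            raise ValueError(f"{name} loci require at least two tissues")
        for i in idx:
            deviant_tissue[i] = tissue_labels[rng.integers(len(tissue_labels))]
            if name == "tissue_identity":
                s = 1.0 if m0[i] + amount <= 0.97 else -1.0
                tissue_offset[i] = s * amount
            else:
                inter_slope[i] = amount

    # Mean structure, loci x samples.
    mu = np.tile(m0[:, None], (1, n))
    mu[is_lin] += slope[is_lin, None] * (eff_age - mean_age)[None, :]
    is_par = classes == "age_parabolic"
    if is_par.any():
        w = max(abs(lo - config.parabola_peak_age), abs(hi - config.parabola_peak_age))
        bump = 1.0 - ((eff_age - config.parabola_peak_age) / w) ** 2
        mu[is_par] += config.parabola_amplitude * bump[None, :]
    in_dev = np.zeros((n_loci, n), dtype=bool)
    sample_tissue = samples["tissue"].to_numpy()
    for i in np.where(deviant_tissue != None)[0]:  # noqa: E711
        in_dev[i] = sample_tissue == deviant_tissue[i]
    is_tis = classes == "tissue_identity"
    mu[is_tis] += tissue_offset[is_tis, None] * in_dev[is_tis]
    is_int = classes == "interaction"
    mu[is_int] += (
        inter_slope[is_int, None] * in_dev[is_int] * (eff_age - mean_age)[None, :]
    )

    clipped = (mu < _MU_EPS) | (mu > 1 - _MU_EPS)
    clip_fraction = float(clipped.mean())
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)

    # Logit-scale noise calibrated so the beta-scale residual sd ~ noise_sd
    # near the baseline; variance loci get an age-increasing multiplier.
    m0c = np.clip(m0, 0.05, 0.95)
    sigma = config.noise_sd / (m0c * (1 - m0c))
    scale = sigma[:, None] * np.ones((1, n))
    is_var = classes == "age_variance"
    if is_var.any():
        age_frac = (ages - lo) / (hi - lo)
        mult = np.sqrt(1.0 + config.variance_slope * age_frac)
        scale[is_var] = scale[is_var] * mult[None, :]
    values = expit(logit(mu) + rng.standard_normal((n_loci, n)) * scale)

    matrix = pd.DataFrame(values, index=locus_ids, columns=samples.index)

    loci_truth = pd.DataFrame(
        {
            "class": classes,
            "baseline": m0,
            "slope": slope,
            "peak_age": peak,
            "variance_slope": var_slope,
            "deviant_tissue": deviant_tissue,
            "tissue_offset": tissue_offset,
            "interaction_slope": inter_slope,
        },
        index=pd.Index(locus_ids, name="locus_id"),
    )
    truth = SyntheticTruth(
        loci=loci_truth,
        samples=samples[["batch", "condition", "shift_years"]].copy(),
        clip_fraction=clip_fraction,
    )

    if config.batch_count > 1 and config.batch_shift_sd > 0:
        matrix, shifts = inject_batch_effects(
            matrix, samples, config.batch_shift_sd, seed=int(rng.integers(2**31))
        )
        truth.batch_shifts = shifts
    if config.missing_rate > 0:
        matrix, _ = inject_missingness(
            matrix, config.missing_rate, seed=int(rng.integers(2**31))
        )

    return matrix, samples.drop(columns="shift_years"), truth


def inject_missingness(
    matrix: pd.DataFrame, rate: float, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Set a Bernoulli(rate) subset of entries to NaN.

    Returns the masked matrix and the boolean mask of removed entries so
    oracle tests can recover the original values.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"missing rate must be in [0, 1): {rate}")
    if rate == 0:
        return matrix.copy(), np.zeros(matrix.shape, dtype=bool)
    rng = np.random.default_rng(seed)
    mask = rng.uniform(size=matrix.shape) < rate
    out = matrix.copy()
    out.values[mask] = np.nan
    return out, mask


def inject_batch_effects(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    shift_sd: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add per-batch, per-locus additive shifts drawn N(0, shift_sd).

    Values are clipped back to [0, 1].  Returns the shifted matrix and the
    planted shift table (loci x batches).
    """
    if "batch" not in samples.columns:
        raise ValueError("sample table has no batch column")
    batches = sorted(samples["batch"].unique())
    if len(batches) < 2 and shift_sd > 0:
        warnings.warn("only one batch present; batch shifts are unidentifiable")
    rng = np.random.default_rng(seed)
    shifts = pd.DataFrame(
        rng.normal(0.0, shift_sd, size=(len(matrix), len(batches))),
        index=matrix.index,
        columns=batches,
    )
    out = matrix.copy()
    if shift_sd > 0:
        batch_of = samples.loc[matrix.columns, "batch"].to_numpy()
        add = shifts.to_numpy()[:, [batches.index(b) for b in batch_of]]
        shifted = out.to_numpy() + add
        n_clip = np.sum((shifted < 0) | (shifted > 1))
        if n_clip:
            warnings.warn(
                f"batch shifts clipped {n_clip} values "
                f"({n_clip / shifted.size:.2%}) at the [0, 1] boundary"
            )
        out = pd.DataFrame(
            np.clip(shifted, 0.0, 1.0), index=out.index, columns=out.columns
        )
    return out, shifts


# ---------------------------------------------------------------------------
# Genomic coordinates and feature tracks with planted enrichments
# ---------------------------------------------------------------------------

#: spacing between adjacent loci; structures planted around one locus extend
#: at most ~7 kb, so 20 kb guarantees independence between neighbours.
_LOCUS_SPACING = 20_000

_GENIC_BASE = {"gene": 0.30, "promoter": 0.20, "intergenic": 0.50}
_ISLAND_BASE = {"cpg_island": 0.25, "shore": 0.10, "shelf": 0.05, "open_sea": 0.60}
_POINT_BASE = {"enhancer": 0.10, "eqtl": 0.10}

_AXES = {
    "gene": "genic",
    "promoter": "genic",
    "intergenic": "genic",
    "cpg_island": "island",
    "shore": "island",
    "shelf": "island",
    "open_sea": "island",
    "enhancer": "point",
    "eqtl": "point",
}


@dataclass
class LocusMap:
    """Single-cytosine coordinates (0-based) for every matrix locus."""

    positions: pd.DataFrame  # index locus_id, columns chrom, pos
    chrom_sizes: dict[str, int]

    def validate(self) -> None:
        dup = self.positions.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos) in locus map")
        if (self.positions["pos"] < 0).any():
            raise ValueError("negative position in locus map")


@dataclass
class FeatureTrack:
    """A named set of half-open, 0-based genomic intervals (BED3 semantics)."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end [, strand]

    def validate(self) -> None:
        iv = self.intervals
        if (iv["start"] >= iv["end"]).any():
            raise ValueError(f"track {self.name}: start >= end")
        if (iv["start"] < 0).any():
            raise ValueError(f"track {self.name}: negative coordinate")
        for _, sub in iv.groupby("chrom", sort=False):
            if not sub["start"].is_monotonic_increasing:
                raise ValueError(f"track {self.name}: intervals not sorted")


def generate_locus_map(locus_ids: list[str], seed: int) -> LocusMap:
    """Place loci on one synthetic chromosome, 20 kb apart with jitter."""
    rng = np.random.default_rng(seed)
    n = len(locus_ids)
    base = np.arange(n) * _LOCUS_SPACING + _LOCUS_SPACING // 2
    pos = base + rng.integers(-2000, 2001, size=n)
    df = pd.DataFrame(
        {"chrom": "chrS", "pos": pos}, index=pd.Index(locus_ids, name="locus_id")
    )
    return LocusMap(positions=df, chrom_sizes={"chrS": int(n * _LOCUS_SPACING + 10_000)})


def _tilt(base: dict[str, float], feature: str, odds_multiplier: float) -> dict[str, float]:
    """Multiply one category's odds by odds_multiplier, renormalising the rest."""
    p = base[feature]
    odds = odds_multiplier * p / (1 - p)
    p_new = odds / (1 + odds)
    rest = 1 - p
    out = {k: (p_new if k == feature else v * (1 - p_new) / rest) for k, v in base.items()}
    return out


def generate_feature_tracks(
    locus_map: LocusMap,
    truth: SyntheticTruth,
    enrichment_spec: dict[str, tuple[str, float]] | None = None,
    seed: int = 0,
) -> list[FeatureTrack]:
    """Emit CpG-island, gene, TSS, enhancer and eQTL tracks around the loci.

    Each locus is assigned a genic context (gene body / promoter /
    intergenic), an island context (island / shore / shelf / open sea) and
    point-feature memberships, drawn from base probabilities optionally
    tilted per planted locus class: ``enrichment_spec`` maps a truth class
    to ``(feature_name, odds_multiplier)``, and the realised membership odds
    of that class relative to null loci match the multiplier.  Structures
    (gene + TSS, island) are then laid down around each locus so that
    re-deriving features from the emitted tracks reproduces the planted
    memberships.
    """
    enrichment_spec = enrichment_spec or {}
    for cls, (feature, mult) in enrichment_spec.items():
        if mult <= 0:
            raise ValueError(f"odds_multiplier must be positive: {cls} -> {mult}")
        if feature not in _AXES:
            raise ValueError(f"unknown feature {feature!r}")
    missing = set(truth.loci.index) - set(locus_map.positions.index)
    if missing:
        raise ValueError(f"{len(missing)} loci missing from locus map")

    rng = np.random.default_rng(seed)
    genes, tss, islands, enhancers, eqtls = [], [], [], [], []

    # per-class tilted probability tables, computed once
    tables: dict[str, tuple[dict, dict, dict]] = {}
    for cls in truth.loci["class"].unique():
        genic = dict(_GENIC_BASE)
        island = dict(_ISLAND_BASE)
        point = dict(_POINT_BASE)
        if cls in enrichment_spec:
            feature, mult = enrichment_spec[cls]
            axis = _AXES[feature]
            if axis == "genic":
                genic = _tilt(genic, feature, mult)
            elif axis == "island":
                island = _tilt(island, feature, mult)
            else:
                point = {**point, feature: _tilt(point, feature, mult)[feature]}
        tables[cls] = (genic, island, point)

    classes = truth.loci["class"].reindex(locus_map.positions.index).to_numpy()
    positions = locus_map.positions["pos"].to_numpy()
    chroms = locus_map.positions["chrom"].to_numpy()

    for i in range(len(positions)):
        genic, island, point = tables[classes[i]]
        pos = int(positions[i])
        chrom = chroms[i]
        g = rng.choice(list(genic), p=list(genic.values()))
        if g == "gene":
            start = pos - int(rng.integers(200, 2500))
            length = int(rng.integers(3000, 5000))
            strand = "+" if rng.uniform() < 0.5 else "-"
            genes.append((chrom, max(0, start), start + length, strand))
        elif g == "promoter":
            # place the TSS 1-1999 bp downstream so the locus sits in the
            # 2 kb strand-aware upstream promoter window
            offset = int(rng.integers(1, 2000))
            strand = "+" if rng.uniform() < 0.5 else "-"
            if strand == "+":
                tss_pos = pos + offset
                genes.append((chrom, tss_pos, tss_pos + 3000, strand))
            else:
                tss_pos = pos - offset
                genes.append((chrom, max(0, tss_pos - 3000), tss_pos, strand))

        isl = rng.choice(list(island), p=list(island.values()))
        if isl == "cpg_island":
            start = pos - int(rng.integers(100, 700))
            islands.append((chrom, max(0, start), start + int(rng.integers(800, 1500))))
        elif isl == "shore":
            # island body ends 1-1999 bp away from the locus
            gap = int(rng.integers(1, 2000))
            body = int(rng.integers(800, 1500))
            islands.append((chrom, pos + gap, pos + gap + body))
        elif isl == "shelf":
            gap = int(rng.integers(2001, 4000))
            body = int(rng.integers(800, 1500))
            islands.append((chrom, pos + gap, pos + gap + body))

        for feat, store in [("enhancer", enhancers), ("eqtl", eqtls)]:
            if rng.uniform() < point[feat]:
                store.append((chrom, pos + int(rng.integers(-400, 401))))

    def _interval_df(rows, cols=("chrom", "start", "end")):
        df = pd.DataFrame(rows, columns=list(cols))
        return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    gene_df = _interval_df(genes, ("chrom", "start", "end", "strand"))
    tss_rows = [
        (c, (s if strand == "+" else e - 1), (s + 1 if strand == "+" else e), strand)
        for c, s, e, strand in genes
    ]
    tss_df = _interval_df(tss_rows, ("chrom", "start", "end", "strand"))
    point_df = lambda rows: _interval_df([(c, p, p + 1) for c, p in rows])  # noqa: E731

    tracks = [
        FeatureTrack("cpg_island", _interval_df(islands)),
        FeatureTrack("gene", gene_df),
        FeatureTrack("tss", tss_df),
        FeatureTrack("enhancer", point_df(enhancers)),
        FeatureTrack("eqtl", point_df(eqtls)),
    ]
    names = [t.name for t in tracks]
    if len(set(names)) != len(names):
        raise ValueError("feature name collision")
    for t in tracks:
        if len(t.intervals):
            t.validate()
    return tracks
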