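"""Training-set assembly: p300-anchored positives, TSS + background negatives.

The enhancer class is the set of p300 binding sites that overlap a DNase-I
hypersensitive site and lie distal to every annotated TSS. The non-enhancer
class pools an equal number of DHS-overlapping TSS with ``x`` times as many
random background bins distal to both p300 sites and TSS (default x = 7,
i.e. a 1:8 positive:negative ratio overall). Each training sample is an
M-mark block of 20 bin values spanning -1 kb to +1 kb around the locus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._intervals import intervals_overlap, nearest_distance, points_in_intervals
from .layout import GenomeLayout
from .signal import BinnedTrack

__all__ = [
    "Locus",
    "TrainingConfig",
    "FeatureBlockMatrix",
    "read_bed_intervals",
    "interval_centers",
    "select_positive_sites",
    "select_tss_negatives",
    "sample_background",
    "extract_features",
    "assemble_training_set",
]

log = logging.getLogger(__name__)

WINDOW_BINS = 20  # -1 kb .. +1 kb at 100 bp
HALF_WINDOW = 1000

ENHANCER = 1
NON_ENHANCER = 0


@dataclass(frozen=True)
class Locus:
    """A labelled training anchor point on the genome."""

    chrom: str
    center: int
    label: int  # ENHANCER / NON_ENHANCER
    provenance: str  # "p300" | "tss" | "background"


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of training-set assembly.

    background_multiplier
        x: background negatives per positive (7 reproduces the 1:7
        p300:non-p300 ratio once the equal-count TSS are included).
    distal_threshold
        Minimum distance in bp from a positive to any TSS, and from a
        background bin to any p300/TSS exclusion (2.5 kb, matching the
        evaluation window).
    """

    background_multiplier: int = 7
    distal_threshold: int = 2500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_multiplier < 1:
            raise ValueError("background_multiplier must be >= 1")
        if self.distal_threshold <= 0:
            raise ValueError("distal_threshold must be positive")


@dataclass
class FeatureBlockMatrix:
    """N samples x M marks x 20 bins of RPKM values plus class labels."""

    values: np.ndarray  # (N, M, 20) float64, non-negative
    mark_names: tuple[str, ...]
    labels: np.ndarray  # (N,) int, ENHANCER / NON_ENHANCER
    loci: tuple[Locus, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n, m, w = self.values.shape
        if w != WINDOW_BINS:
            raise ValueError(f"feature window must have {WINDOW_BINS} bins, got {w}")
        if m != len(self.mark_names):
            raise ValueError("mark_names length mismatch")
        if n != len(self.labels):
            raise ValueError("labels length mismatch")
        if self.loci and len(self.loci) != n:
            raise ValueError("loci length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_marks(self) -> int:
        return self.values.shape[1]

    def save(self, path: str) -> None:
        loci = [
            {"chrom": l.chrom, "center": l.center, "label": l.label, "provenance": l.provenance}
            for l in self.loci
        ]
        meta = {"mark_names": list(self.mark_names), "loci": loci}
        np.savez_compressed(
            path,
            values=self.values,
            labels=self.labels,
            __meta__=np.array(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path: str) -> "FeatureBlockMatrix":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["__meta__"]))
            loci = tuple(Locus(**d) for d in meta["loci"])
            return cls(npz["values"], tuple(meta["mark_names"]), npz["labels"], loci)


def read_bed_intervals(path: str) -> pd.DataFrame:
    """Read a BED file of intervals into a DataFrame (chrom, start, end, extras)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            rows.append([fields[0], int(fields[1]), int(fields[2])] + fields[3:])
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    width = max(len(r) for r in rows)
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(4, width + 1)]
    return pd.DataFrame([r + [None] * (width - len(r)) for r in rows], columns=cols)


def interval_centers(df: pd.DataFrame) -> np.ndarray:
    """Peak anchor per interval: summit position when an integer summit-offset
    column (col 5) within the interval width is present, else the midpoint."""
    mid = ((df["start"] + df["end"]) // 2).to_numpy(np.int64)
    if "col5" not in df.columns:
        return mid
    centers = mid.copy()
    widths = (df["end"] - df["start"]).to_numpy(np.int64)
    raw = df["col5"].to_numpy()
    for i, v in enumerate(raw):
        try:
            off = int(v)
        except (TypeError, ValueError):
            continue
        if 0 <= off < widths[i]:
            centers[i] = int(df["start"].iloc[i]) + off
    return centers


def _window_fits(layout: GenomeLayout, chrom: str, center: int) -> bool:
    return HALF_WINDOW <= center <= layout.length(chrom) - HALF_WINDOW


def select_positive_sites(
    p300: pd.DataFrame,
    dhs: pd.DataFrame,
    tss: pd.DataFrame,
    layout: GenomeLayout,
    cfg: TrainingConfig,
) -> list[Locus]:
    """Enhancer-class loci: p300 peaks overlapping DHS and distal to all TSS."""
    n_total = n_dhs = n_distal = 0
    loci: list[Locus] = []
    tss_pos = {c: interval_centers(g) for c, g in tss.groupby("chrom")}
    for chrom, peaks in p300.groupby("chrom"):
        if chrom not in layout:
            continue
        n_total += len(peaks)
        d = dhs[dhs["chrom"] == chrom]
        has_dhs = intervals_overlap(
            peaks["start"].to_numpy(), peaks["end"].to_numpy(),
            d["start"].to_numpy(), d["end"].to_numpy(),
        )
        n_dhs += int(has_dhs.sum())
        centers = interval_centers(peaks)
        dist, _ = nearest_distance(centers, tss_pos.get(chrom, np.empty(0)))
        distal = dist > cfg.distal_threshold
        n_distal += int((has_dhs & distal).sum())
        for center in centers[has_dhs & distal]:
            if _window_fits(layout, chrom, int(center)):
                loci.append(Locus(chrom, int(center), ENHANCER, "p300"))
    if not loci:
        raise ValueError(
            f"no positive sites survive filtering: {n_total} p300 peaks, "
            f"{n_dhs} overlap DHS, {n_distal} also distal to TSS, "
            f"0 with a full +/-1 kb window"
        )
    return loci


def select_tss_negatives(
    tss: pd.DataFrame,
    dhs: pd.DataFrame,
    layout: GenomeLayout,
    n: int,
    seed: int,
) -> list[Locus]:
    """Sample *n* DHS-overlapping TSS (without replacement) as negatives."""
    eligible: list[Locus] = []
    for chrom, group in tss.groupby("chrom"):
        if chrom not in layout:
            continue
        pos = interval_centers(group)
        d = dhs[dhs["chrom"] == chrom]
        open_chromatin = points_in_intervals(
            pos, d["start"].to_numpy(), d["end"].to_numpy()
        )
        for center in pos[open_chromatin]:
            if _window_fits(layout, chrom, int(center)):
                eligible.append(Locus(chrom, int(center), NON_ENHANCER, "tss"))
    if len(eligible) < n:
        raise ValueError(
            f"need {n} DHS-overlapping TSS but only {len(eligible)} qualify"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(picked)]


def sample_background(
    layout: GenomeLayout,
    exclusions: pd.DataFrame,
    n: int,
    cfg: TrainingConfig,
) -> list[Locus]:
    """Draw *n* uniform-random bin centers distal to every exclusion interval.

    Eligible bins lie > ``distal_threshold`` bp from the nearest exclusion
    (p300 or TSS interval) and far enough from chromosome ends for a full
    window. Sampling is uniform over the genome-wide eligible pool.
    """
    bw = layout.bin_width
    pools: list[tuple[str, np.ndarray]] = []
    total = 0
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        ok = np.ones(nb, dtype=bool)
        centers = np.arange(nb, dtype=np.int64) * bw + bw // 2
        ok &= (centers >= HALF_WINDOW) & (centers <= layout.length(chrom) - HALF_WINDOW)
        excl = exclusions[exclusions["chrom"] == chrom]
        for s, e in zip(excl["start"].to_numpy(np.int64), excl["end"].to_numpy(np.int64)):
            lo = (s - cfg.distal_threshold) // bw
            hi = (e + cfg.distal_threshold) // bw + 1
            ok[max(lo, 0):min(hi, nb)] = False
        idx = np.nonzero(ok)[0]
        pools.append((chrom, centers[idx]))
        total += len(idx)
    if total < n:
        raise ValueError(f"only {total} eligible background bins for {n} requested")
    rng = np.random.default_rng(cfg.seed)
    flat = rng.choice(total, size=n, replace=False)
    flat.sort()
    loci: list[Locus] = []
    offset = 0
    for chrom, centers in pools:
        local = flat[(flat >= offset) & (flat < offset + len(centers))] - offset
        loci.extend(
            Locus(chrom, int(centers[i]), NON_ENHANCER, "background") for i in local
        )
        offset += len(centers)
    return loci


def extract_features(
    loci: list[Locus], tracks: list[BinnedTrack]
) -> FeatureBlockMatrix:
    """Extract the M x 20 block around each locus from the mark tracks.

    The locus center is snapped to the nearest bin boundary; feature bin j
    covers ``[center + (j - 10) * 100, center + (j - 9) * 100)``, so index 10
    is the bin starting at the center. Loci whose window does not fit on the
    chromosome are excluded with a warning.
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    layout = tracks[0].layout
    for t in tracks[1:]:
        if t.layout != layout:
            raise ValueError("tracks have mismatched layouts")
    bw = layout.bin_width
    half = WINDOW_BINS // 2
    kept: list[Locus] = []
    rows: list[np.ndarray] = []
    n_excluded = 0
    for locus in loci:
        nb = layout.n_bins(locus.chrom)
        c_bin = int(round(locus.center / bw))
        lo, hi = c_bin - half, c_bin + half
        if lo < 0 or hi > nb:
            n_excluded += 1
            continue
        block = np.stack([t.values[locus.chrom][lo:hi] for t in tracks])
        kept.append(locus)
        rows.append(block)
    if n_excluded:
        log.warning("excluded %d loci too close to chromosome edges", n_excluded)
    values = (
        np.stack(rows)
        if rows
        else np.empty((0, len(tracks), WINDOW_BINS))
    )
    labels = np.array([l.label for l in kept], dtype=np.int64)
    return FeatureBlockMatrix(values, tuple(t.mark_name for t in tracks), labels, tuple(kept))


def assemble_training_set(
    p300: pd.DataFrame,
    dhs: pd.DataFrame,
    tss: pd.DataFrame,
    tracks: list[BinnedTrack],
    cfg: TrainingConfig,
) -> FeatureBlockMatrix:
    """Full training-set path: positives, TSS negatives, background, features."""
    layout = tracks[0].layout
    positives = select_positive_sites(p300, dhs, tss, layout, cfg)
    n_pos = len(positives)
    tss_neg = select_tss_negatives(tss, dhs, layout, n_pos, cfg.seed)
    exclusions = pd.concat(
        [p300[["chrom", "start", "end"]], tss[["chrom", "start", "end"]]],
        ignore_index=True,
    )
    background = sample_background(
        layout, exclusions, cfg.background_multiplier * n_pos, cfg
    )
    return extract_features(positives + tss_neg + background, tracks)
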