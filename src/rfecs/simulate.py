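"""Synthetic ChIP-seq datasets with planted enhancers and promoters.

The generator emulates the chromatin signature the classifier exploits:
planted enhancers carry bimodal H3K4me1 (and, at a random half of sites,
H3K27ac) flanking a nucleosome-depleted center, while planted promoters
carry strong unimodal H3K4me3; three flat marks contribute pure noise.
Read counts are drawn per 100 bp bin as independent Poissons whose rates
integrate Gaussian site profiles plus a uniform background — enough
structure to exercise binning, RPKM normalization, training, scanning and
peak calling, without fragment-level realism (no GC, mappability or
fragment-length model).

Truth BED sets mirror the real inputs: p300 = enhancer centers, DHS =
enhancers ∪ promoters, TSS = promoter centers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .layout import GenomeLayout
from .signal import BinnedTrack, ReadSet, average_replicates, bin_reads, rpkm_normalize
from .training import FeatureBlockMatrix, TrainingConfig, assemble_training_set

__all__ = [
    "MarkProfile",
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "default_marks",
    "simulate_dataset",
    "make_training_fixture",
]


@dataclass(frozen=True)
class MarkProfile:
    """Signal shape of one mark at planted sites.

    ``*_shape`` is one of ``bimodal`` (two Gaussian modes at ±offset),
    ``unimodal`` (single Gaussian at the center) or ``flat`` (no site
    signal); ``*_reads`` is the expected number of reads emitted per site.
    ``enhancer_fraction`` < 1 restricts the enhancer-site signal to a random
    subset of enhancers (e.g. H3K27ac at active enhancers only).
    """

    enhancer_shape: str = "flat"
    enhancer_reads: float = 0.0
    promoter_shape: str = "flat"
    promoter_reads: float = 0.0
    offset: int = 300
    width: int = 150
    enhancer_fraction: float = 1.0


def default_marks() -> dict[str, MarkProfile]:
    """The six-mark default panel (three informative, three flat noise)."""
    return {
        "H3K4me1": MarkProfile("bimodal", 200.0, "bimodal", 30.0, offset=300, width=150),
        "H3K4me3": MarkProfile("unimodal", 20.0, "unimodal", 250.0, offset=0, width=300),
        "H3K27ac": MarkProfile(
            "bimodal", 150.0, "unimodal", 60.0, offset=300, width=150, enhancer_fraction=0.5
        ),
        "noise_1": MarkProfile(),
        "noise_2": MarkProfile(),
        "noise_3": MarkProfile(),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic genome.

    Defaults: 2 chromosomes × 2 Mb, 60 enhancers and 60 promoters genome-wide
    placed ≥5 kb apart and ≥5 kb from chromosome ends, background 0.1 reads
    per 100 bp bin per track (≈ sparse real ChIP-seq depth at this scale).
    """

    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_enhancers: int = 60
    n_promoters: int = 60
    marks: dict[str, MarkProfile] = field(default_factory=default_marks)
    background_rate: float = 0.1
    bin_width: int = 100
    read_length: int = 36
    min_site_spacing: int = 5000
    edge_margin: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_site_spacing <= 0 or self.edge_margin < 1000:
            raise ValueError("sites must be spaced out and >= 1 kb from chromosome ends")
        for name, p in self.marks.items():
            if p.enhancer_reads < 0 or p.promoter_reads < 0:
                raise ValueError(f"negative amplitude for mark {name!r}")

    def layout(self) -> GenomeLayout:
        names = tuple(f"chr{i + 1}" for i in range(self.n_chroms))
        return GenomeLayout(names, (self.chrom_length,) * self.n_chroms, self.bin_width)


@dataclass
class SyntheticTruth:
    """Planted site coordinates and realized per-site read counts."""

    enhancers: dict[str, np.ndarray]  # chrom -> centers (bp)
    promoters: dict[str, np.ndarray]
    site_read_counts: dict[str, pd.DataFrame]  # mark -> (chrom, center, kind, n_reads)
    active_enhancer_mask: dict[str, dict[str, np.ndarray]]  # mark -> chrom -> bool

    def enhancer_list(self) -> list[tuple[str, int]]:
        return [(c, int(p)) for c, arr in self.enhancers.items() for p in arr]

    def promoter_list(self) -> list[tuple[str, int]]:
        return [(c, int(p)) for c, arr in self.promoters.items() for p in arr]


@dataclass
class SyntheticDataset:
    """In-memory simulated dataset plus writers for the on-disk BED layout."""

    cfg: SimulationConfig
    layout: GenomeLayout
    truth: SyntheticTruth
    mark_reads: dict[str, dict[str, np.ndarray]]  # mark -> chrom -> 5' positions
    input_reads: dict[str, np.ndarray]

    def read_set(self, mark: str | None = None) -> ReadSet:
        src = self.input_reads if mark is None else self.mark_reads[mark]
        return ReadSet(self.layout, {c: np.sort(v) for c, v in src.items()})

    def make_tracks(self) -> list[BinnedTrack]:
        """Run the binning/RPKM pipeline in memory, one track per mark."""
        inp = self.read_set()
        input_counts = bin_reads(inp, self.layout)
        tracks = []
        for mark in self.cfg.marks:
            rs = self.read_set(mark)
            counts = bin_reads(rs, self.layout)
            tracks.append(
                average_replicates(
                    [
                        rpkm_normalize(
                            counts,
                            rs.total_mapped_reads,
                            input_counts,
                            inp.total_mapped_reads,
                            self.layout,
                            mark,
                        )
                    ]
                )
            )
        return tracks

    def truth_frames(self) -> dict[str, pd.DataFrame]:
        """p300/DHS/TSS DataFrames in BED-interval form (midpoint = center)."""
        def frame(sites: list[tuple[str, int]], half: int) -> pd.DataFrame:
            rows = [
                {"chrom": c, "start": p - half, "end": p + half} for c, p in sites
            ]
            return pd.DataFrame(rows, columns=["chrom", "start", "end"])

        enh = self.truth.enhancer_list()
        prom = self.truth.promoter_list()
        return {
            "p300": frame(enh, 100),
            "dhs": frame(enh + prom, 150),
            "tss": frame(prom, 50),
        }

    def write(self, outdir: str) -> dict[str, str]:
        """Write per-mark read BEDs, input BED, truth BEDs and chrom.sizes."""
        os.makedirs(outdir, exist_ok=True)
        paths: dict[str, str] = {}

        def write_reads(name: str, reads: dict[str, np.ndarray]) -> None:
            path = os.path.join(outdir, f"{name}.bed")
            with open(path, "w") as fh:
                for chrom in self.layout.chrom_names:
                    for pos in np.sort(reads.get(chrom, np.empty(0, dtype=np.int64))):
                        end = min(int(pos) + self.cfg.read_length, self.layout.length(chrom))
                        fh.write(f"{chrom}\t{int(pos)}\t{end}\treads\t0\t+\n")
            paths[name] = path

        for mark, reads in self.mark_reads.items():
            write_reads(mark, reads)
        write_reads("input", self.input_reads)

        for name, df in self.truth_frames().items():
            path = os.path.join(outdir, f"{name}.bed")
            df.sort_values(["chrom", "start"]).to_csv(
                path, sep="\t", header=False, index=False
            )
            paths[name] = path

        cs = os.path.join(outdir, "chrom.sizes")
        with open(cs, "w") as fh:
            for name, length in zip(self.layout.chrom_names, self.layout.chrom_lengths):
                fh.write(f"{name}\t{length}\n")
        paths["chrom_sizes"] = cs
        return paths


def _place_sites(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Place enhancers and promoters on the bin grid, >= min_site_spacing
    apart and >= edge_margin from chromosome ends, uniformly at random."""
    layout = cfg.layout()
    n_sites = cfg.n_enhancers + cfg.n_promoters
    per_chrom = np.full(cfg.n_chroms, n_sites // cfg.n_chroms)
    per_chrom[: n_sites % cfg.n_chroms] += 1
    # guard the spacing against the <= bin_width/2 shift introduced by snapping
    gap = cfg.min_site_spacing + cfg.bin_width
    enh: dict[str, np.ndarray] = {}
    prom: dict[str, np.ndarray] = {}
    n_enh_left = cfg.n_enhancers
    for ci, chrom in enumerate(layout.chrom_names):
        k = int(per_chrom[ci])
        lo = cfg.edge_margin
        hi = cfg.chrom_length - cfg.edge_margin
        span = hi - lo - (k - 1) * gap
        if span <= 0:
            raise ValueError(
                f"cannot place {k} sites {cfg.min_site_spacing} bp apart on {chrom}"
            )
        base = np.sort(rng.uniform(0, span, size=k))
        centers = lo + base + np.arange(k) * gap
        centers = (np.round(centers / cfg.bin_width) * cfg.bin_width).astype(np.int64)
        # split into enhancers/promoters proportionally, assignment randomized
        k_enh = min(n_enh_left, int(round(k * cfg.n_enhancers / n_sites)))
        if ci == cfg.n_chroms - 1:
            k_enh = n_enh_left
        n_enh_left -= k_enh
        is_enh = np.zeros(k, dtype=bool)
        is_enh[rng.choice(k, size=k_enh, replace=False)] = True
        enh[chrom] = centers[is_enh]
        prom[chrom] = centers[~is_enh]
    return enh, prom


def _site_bin_rates(
    center: int, shape: str, reads: float, offset: int, width: int, nb: int, bw: int
) -> tuple[np.ndarray, int]:
    """Expected read count per bin contributed by one site (local window)."""
    if shape == "flat" or reads <= 0:
        return np.empty(0), 0
    reach = abs(offset) + 5 * width
    lo_bin = max(0, (center - reach) // bw)
    hi_bin = min(nb, (center + reach) // bw + 1)
    edges = np.arange(lo_bin, hi_bin + 1) * bw
    if shape == "bimodal":
        mass = 0.5 * (
            np.diff(norm.cdf(edges, loc=center - offset, scale=width))
            + np.diff(norm.cdf(edges, loc=center + offset, scale=width))
        )
    elif shape == "unimodal":
        mass = np.diff(norm.cdf(edges, loc=center, scale=width))
    else:
        raise ValueError(f"unknown profile shape {shape!r}")
    return reads * mass, int(lo_bin)


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Draw a complete dataset; byte-identical outputs under the same seed."""
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout()
    enh, prom = _place_sites(cfg, rng)

    active: dict[str, dict[str, np.ndarray]] = {}
    for mark, profile in cfg.marks.items():
        active[mark] = {}
        for chrom in layout.chrom_names:
            k = len(enh[chrom])
            mask = np.ones(k, dtype=bool)
            if profile.enhancer_fraction < 1.0:
                n_on = int(round(profile.enhancer_fraction * k))
                mask = np.zeros(k, dtype=bool)
                mask[rng.choice(k, size=n_on, replace=False)] = True
            active[mark][chrom] = mask

    mark_reads: dict[str, dict[str, np.ndarray]] = {}
    site_counts: dict[str, pd.DataFrame] = {}
    bw = cfg.bin_width
    for mark, profile in cfg.marks.items():
        per_chrom: dict[str, np.ndarray] = {}
        count_rows = []
        for chrom in layout.chrom_names:
            nb = layout.n_bins(chrom)
            counts = rng.poisson(cfg.background_rate, size=nb)
            sites = [
                (int(c), "enhancer", profile.enhancer_shape, profile.enhancer_reads, on)
                for c, on in zip(enh[chrom], active[mark][chrom])
            ] + [
                (int(c), "promoter", profile.promoter_shape, profile.promoter_reads, True)
                for c in prom[chrom]
            ]
            for center, kind, shape, reads, on in sites:
                if not on:
                    count_rows.append((chrom, center, kind, 0))
                    continue
                rates, lo_bin = _site_bin_rates(
                    center, shape, reads, profile.offset, profile.width, nb, bw
                )
                drawn = rng.poisson(rates) if rates.size else np.empty(0, dtype=np.int64)
                counts[lo_bin : lo_bin + len(drawn)] += drawn
                count_rows.append((chrom, center, kind, int(drawn.sum())))
            nz = np.nonzero(counts)[0]
            per_chrom[chrom] = np.repeat(nz * bw, counts[nz]).astype(np.int64)
        mark_reads[mark] = per_chrom
        site_counts[mark] = pd.DataFrame(
            count_rows, columns=["chrom", "center", "kind", "n_reads"]
        )

    input_reads: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        counts = rng.poisson(cfg.background_rate, size=nb)
        nz = np.nonzero(counts)[0]
        input_reads[chrom] = np.repeat(nz * bw, counts[nz]).astype(np.int64)

    truth = SyntheticTruth(enh, prom, site_counts, active)
    return SyntheticDataset(cfg, layout, truth, mark_reads, input_reads)


def make_training_fixture(
    cfg: SimulationConfig, training: TrainingConfig | None = None
) -> tuple[FeatureBlockMatrix, SyntheticDataset, list[BinnedTrack]]:
    """Full simulate → binarize → training-set path in memory.

    Positives are planted enhancers (via their p300 truth peaks); negatives
    follow the standard equal-TSS + x-fold-background recipe.
    """
    if training is None:
        training = TrainingConfig(seed=cfg.seed)
    ds = simulate_dataset(cfg)
    tracks = ds.make_tracks()
    frames = ds.truth_frames()
    fbm = assemble_training_set(
        frames["p300"], frames["dhs"], frames["tss"], tracks, training
    )
    return fbm, ds, tracks
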