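"""ChIP-seq signal I/O: read binning, RPKM input-normalization, track storage.

The normalization pipeline follows the standard practice for chromatin-mark
tracks: reads from each mark and its matched input (whole-cell extract
control) are binned into fixed 100 bp intervals, both are converted to RPKM
(reads per kilobase per million mapped reads), and the track value is the
input-subtracted RPKM clamped at zero. Replicates are normalized
individually and then averaged per bin.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .layout import GenomeLayout

__all__ = [
    "ReadSet",
    "BinnedTrack",
    "read_intervals",
    "bin_reads",
    "rpkm_normalize",
    "average_replicates",
    "write_track",
    "read_track",
    "binarize_mark",
]

log = logging.getLogger(__name__)

TRACK_FORMAT_VERSION = 1


@dataclass
class ReadSet:
    """Aligned reads reduced to their 5'-most genomic coordinate.

    ``positions[chrom]`` holds one entry per read; reads on chromosomes
    absent from the layout were skipped at parse time and are not counted.
    """

    layout: GenomeLayout
    positions: dict[str, np.ndarray]
    n_malformed: int = 0
    n_skipped_chrom: int = 0

    @property
    def total_mapped_reads(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))


@dataclass
class BinnedTrack:
    """Per-chromosome 100 bp-bin signal values (RPKM units) for one mark."""

    layout: GenomeLayout
    values: dict[str, np.ndarray]
    mark_name: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.layout.chrom_names:
            v = np.asarray(self.values.get(chrom), dtype=np.float64)
            if v.ndim != 1 or len(v) != self.layout.n_bins(chrom):
                raise ValueError(
                    f"track {self.mark_name!r}: {chrom} has {v.size} bins, "
                    f"layout expects {self.layout.n_bins(chrom)}"
                )
            self.values[chrom] = v


def read_intervals(path: str, layout: GenomeLayout, extend: int = 0) -> ReadSet:
    """Parse a BED-like file of aligned reads into 5'-end positions.

    Coordinates are 0-based half-open. The 5'-most coordinate is the interval
    start for ``+`` (or unstranded) reads and ``end - 1`` for ``-`` reads;
    strand is column 6 when present. ``extend`` optionally shifts each
    position ``extend // 2`` bp in the 3' direction to approximate fragment
    centers (off by default). Malformed lines are skipped and counted;
    reads on chromosomes not in *layout* are skipped and counted.
    """
    per_chrom: dict[str, list[int]] = {c: [] for c in layout.chrom_names}
    n_malformed = 0
    n_skipped = 0
    shift = extend // 2
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                n_malformed += 1
                continue
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                n_malformed += 1
                continue
            if chrom not in layout:
                n_skipped += 1
                continue
            if start < 0 or end > layout.length(chrom) or end <= start:
                n_malformed += 1
                continue
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand == "-":
                pos = end - 1 - shift
            else:
                pos = start + shift
            pos = min(max(pos, 0), layout.length(chrom) - 1)
            per_chrom[chrom].append(pos)
    if n_malformed:
        log.warning("%s: skipped %d malformed lines", path, n_malformed)
    if n_skipped:
        log.warning("%s: skipped %d reads on chromosomes absent from layout", path, n_skipped)
    positions = {c: np.array(v, dtype=np.int64) for c, v in per_chrom.items()}
    return ReadSet(layout, positions, n_malformed, n_skipped)


def bin_reads(reads: ReadSet, layout: GenomeLayout) -> dict[str, np.ndarray]:
    """Count reads per bin by the bin containing each read's 5' coordinate.

    The sum of all bin counts equals the number of in-bounds reads whose
    5' position falls inside a complete bin (positions in a dropped trailing
    partial bin do not count).
    """
    counts: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        n = layout.n_bins(chrom)
        pos = reads.positions.get(chrom, np.empty(0, dtype=np.int64))
        idx = pos // layout.bin_width
        idx = idx[idx < n]
        counts[chrom] = np.bincount(idx, minlength=n).astype(np.float64)
    return counts


def _rpkm(counts: dict[str, np.ndarray], total: int, bin_width: int) -> dict[str, np.ndarray]:
    scale = (bin_width / 1000.0) * (total / 1e6)
    return {c: v / scale for c, v in counts.items()}


def rpkm_normalize(
    chip_counts: dict[str, np.ndarray],
    chip_total: int,
    input_counts: dict[str, np.ndarray],
    input_total: int,
    layout: GenomeLayout,
    mark_name: str,
    chip_label: str = "chip",
    input_label: str = "input",
) -> BinnedTrack:
    """Input-normalized RPKM track: ``max(0, RPKM_chip - RPKM_input)`` per bin.

    RPKM(x) = count / ((bin_width/1000) * (total/1e6)). Subtraction is
    clamped at zero so downstream features stay non-negative; the choice is
    recorded in the track metadata.
    """
    if chip_total <= 0:
        raise ValueError(f"zero mapped reads in ChIP file {chip_label!r}")
    if input_total <= 0:
        raise ValueError(f"zero mapped reads in input file {input_label!r}")
    chip = _rpkm(chip_counts, chip_total, layout.bin_width)
    inp = _rpkm(input_counts, input_total, layout.bin_width)
    values = {c: np.maximum(0.0, chip[c] - inp[c]) for c in layout.chrom_names}
    meta = {
        "normalization": "rpkm_clamped_subtraction",
        "chip_total": int(chip_total),
        "input_total": int(input_total),
    }
    return BinnedTrack(layout, values, mark_name, meta)


def average_replicates(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Per-bin arithmetic mean of replicate tracks (same layout and mark)."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if t.layout != first.layout:
            raise ValueError("replicate tracks have mismatched layouts")
        if t.mark_name != first.mark_name:
            raise ValueError(
                f"replicate mark names differ: {t.mark_name!r} vs {first.mark_name!r}"
            )
    values = {
        c: np.mean([t.values[c] for t in tracks], axis=0)
        for c in first.layout.chrom_names
    }
    meta = {"n_replicates": len(tracks), **first.metadata}
    return BinnedTrack(first.layout, values, first.mark_name, meta)


def write_track(track: BinnedTrack, path: str) -> None:
    """Persist a track to a self-describing ``.npz`` container.

    Keys: ``__meta__`` (JSON: format version, mark, bin width, chromosome
    names/lengths, normalization metadata) and one float64 array per
    chromosome under ``values/<chrom>``. NaN values are rejected.
    """
    for chrom, v in track.values.items():
        if np.isnan(v).any():
            raise ValueError(f"NaN in track {track.mark_name!r} on {chrom}")
    meta = {
        "format_version": TRACK_FORMAT_VERSION,
        "mark_name": track.mark_name,
        "bin_width": track.layout.bin_width,
        "chrom_names": list(track.layout.chrom_names),
        "chrom_lengths": list(track.layout.chrom_lengths),
        "metadata": track.metadata,
    }
    arrays = {f"values/{c}": track.values[c] for c in track.layout.chrom_names}
    np.savez_compressed(path, __meta__=np.array(json.dumps(meta)), **arrays)


def read_track(path: str) -> BinnedTrack:
    """Load a track written by :func:`write_track` (lossless round-trip)."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        if meta.get("format_version") != TRACK_FORMAT_VERSION:
            raise ValueError(f"unsupported track format in {path}")
        layout = GenomeLayout(
            tuple(meta["chrom_names"]), tuple(meta["chrom_lengths"]), meta["bin_width"]
        )
        values = {c: npz[f"values/{c}"] for c in layout.chrom_names}
    return BinnedTrack(layout, values, meta["mark_name"], meta.get("metadata", {}))


def binarize_mark(
    chip_paths: list[str],
    input_path: str,
    layout: GenomeLayout,
    mark_name: str,
    extend: int = 0,
) -> BinnedTrack:
    """Full per-mark pipeline: parse, bin, RPKM-normalize, average replicates."""
    input_reads = read_intervals(input_path, layout, extend=extend)
    input_counts = bin_reads(input_reads, layout)
    replicates = []
    for chip_path in chip_paths:
        chip_reads = read_intervals(chip_path, layout, extend=extend)
        chip_counts = bin_reads(chip_reads, layout)
        replicates.append(
            rpkm_normalize(
                chip_counts,
                chip_reads.total_mapped_reads,
                input_counts,
                input_reads.total_mapped_reads,
                layout,
                mark_name,
                chip_label=chip_path,
                input_label=input_path,
            )
        )
    return average_replicates(replicates)
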