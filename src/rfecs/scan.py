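"""Genome-wide scanning of the trained forest and enhancer peak calling.

Every 100 bp bin is scored by extracting the ±1 kb feature block centered on
it and taking the forest's enhancer-vote fraction. Because the voting
percentage decays symmetrically on either side of a true site, peaks are
called greedily: candidate bins above the voting cutoff are visited in
descending vote order and accepted unless an already-accepted call on the
same chromosome lies within the peak-filtering distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forest import VectorForest, predict_votes
from .layout import GenomeLayout
from .signal import BinnedTrack
from .training import WINDOW_BINS

__all__ = ["VoteTrack", "EnhancerCall", "scan_genome", "call_peaks", "calls_to_bed"]


@dataclass
class VoteTrack:
    """Per-bin enhancer-vote fraction in [0, 1] on the shared bin grid."""

    layout: GenomeLayout
    votes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.layout.chrom_names:
            v = np.asarray(self.votes[chrom], dtype=np.float64)
            if len(v) != self.layout.n_bins(chrom):
                raise ValueError(f"vote array length mismatch on {chrom}")
            if ((v < 0) | (v > 1)).any():
                raise ValueError("votes must lie in [0, 1]")
            self.votes[chrom] = v


@dataclass(frozen=True)
class EnhancerCall:
    """A called enhancer peak: one 100 bp bin plus its voting fraction."""

    chrom: str
    start: int
    end: int
    vote: float
    rank: int = 0

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def _window_features(track_values: list[np.ndarray]) -> np.ndarray:
    """(n_windows, M, 20) sliding feature blocks over one chromosome."""
    views = [
        np.lib.stride_tricks.sliding_window_view(v, WINDOW_BINS) for v in track_values
    ]
    return np.stack(views, axis=1).astype(np.float64)


def scan_genome(forest: VectorForest, tracks: list[BinnedTrack]) -> VoteTrack:
    """Score every bin of the genome; deterministic given the forest.

    Bins whose ±1 kb window does not fit on the chromosome receive vote 0
    rather than padded features (padding would fabricate signal). Tracks are
    reordered to the forest's training mark order; a missing mark is fatal.
    """
    by_name = {t.mark_name: t for t in tracks}
    missing = [m for m in forest.mark_names if m not in by_name]
    if missing:
        raise ValueError(f"tracks missing marks required by the forest: {missing}")
    ordered = [by_name[m] for m in forest.mark_names]
    layout = ordered[0].layout
    half = WINDOW_BINS // 2
    votes: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        v = np.zeros(nb)
        if nb >= WINDOW_BINS:
            X = _window_features([t.values[chrom] for t in ordered])
            # window starting at bin i-half is centered on bin i
            v[half : half + X.shape[0]] = predict_votes(forest, X)
        votes[chrom] = v
    return VoteTrack(layout, votes)


def call_peaks(
    votes: VoteTrack, cutoff: float = 0.5, filter_distance: int = 1000
) -> list[EnhancerCall]:
    """Greedy max-vote peak selection with a minimum-separation constraint.

    Bins with vote > *cutoff* are candidates; sorted by vote descending
    (ties: chromosome order, then leftmost bin), a candidate is accepted iff
    no accepted call on the same chromosome is closer than *filter_distance*
    (bin-start to bin-start). Calls are returned sorted by genomic position
    with 1-based ranks assigned in descending vote order.
    """
    if not 0.5 <= cutoff < 1.0:
        raise ValueError("cutoff must lie in [0.5, 1)")
    bw = votes.layout.bin_width
    records: list[tuple[float, int, int]] = []  # (-vote, chrom_idx, bin)
    for ci, chrom in enumerate(votes.layout.chrom_names):
        idx = np.nonzero(votes.votes[chrom] > cutoff)[0]
        v = votes.votes[chrom][idx]
        records.extend(zip(-v, [ci] * len(idx), idx.tolist()))
    records.sort()
    accepted: dict[int, list[int]] = {}
    out: list[EnhancerCall] = []
    for neg_vote, ci, b in records:
        starts = accepted.setdefault(ci, [])
        pos = b * bw
        if any(abs(pos - s) < filter_distance for s in starts):
            continue
        starts.append(pos)
        chrom = votes.layout.chrom_names[ci]
        out.append(EnhancerCall(chrom, pos, pos + bw, -neg_vote, rank=len(out) + 1))
    out.sort(key=lambda c: (votes.layout.chrom_names.index(c.chrom), c.start))
    return out


def calls_to_bed(calls: list[EnhancerCall], path: str) -> None:
    """Write calls as 5-column BED (name = rank, score = 1000 * vote)."""
    ordered = sorted(calls, key=lambda c: (c.chrom, c.start))
    with open(path, "w") as fh:
        for c in ordered:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\tenhancer_{c.rank}\t{round(1000 * c.vote)}\n"
            )
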