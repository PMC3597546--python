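"""Evaluation of enhancer calls: validation taxonomy, rate curves, resolution,
permutation FDR, and mark-correlation clustering.

Each call is labelled against two point sets — true-positive markers (TPM:
DNase-I hypersensitive sites, p300/CBP/TF binding sites) and annotated TSS:

* **validated** — nearest TPM within 2.5 kb of the call and the TPM's own
  nearest TSS more than 1 kb away from it;
* **misclassified** — a TSS within 2.5 kb of the call, and the call's
  nearest TPM either beyond 2.5 kb or within 1 kb of that TSS;
* **unknown** — neither a TPM nor a TSS within 2.5 kb.

The rules are evaluated in that order; the rare geometries matched by none
fall through to *unknown* so the taxonomy always partitions the calls.
Distances are measured call-center to feature midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from ._intervals import nearest_distance
from .forest import VectorForest
from .scan import EnhancerCall, VoteTrack, call_peaks, scan_genome
from .signal import BinnedTrack
from .training import FeatureBlockMatrix

__all__ = [
    "VALIDATED",
    "MISCLASSIFIED",
    "UNKNOWN",
    "ValidationSummary",
    "classify_prediction",
    "classify_predictions",
    "rate_curves",
    "distance_resolution",
    "empirical_fdr",
    "FdrTable",
    "mark_correlation",
    "MarkCorrelation",
]

VALIDATED = "validated"
MISCLASSIFIED = "misclassified"
UNKNOWN = "unknown"

PROXIMAL = 2500  # bp window for validation / misclassification
TPM_TSS_GUARD = 1000  # bp: a TPM this close to a TSS cannot validate


def _by_chrom(positions: pd.DataFrame | dict) -> dict[str, np.ndarray]:
    if isinstance(positions, dict):
        return {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()}
    out: dict[str, np.ndarray] = {}
    for chrom, group in positions.groupby("chrom"):
        out[chrom] = ((group["start"] + group["end"]) // 2).to_numpy(np.int64)
    return out


def classify_prediction(
    call: EnhancerCall,
    tpm: dict[str, np.ndarray],
    tss: dict[str, np.ndarray],
) -> str:
    """Label a single call validated / misclassified / unknown."""
    c = call.center
    chrom_tpm = tpm.get(call.chrom, np.empty(0, dtype=np.int64))
    chrom_tss = tss.get(call.chrom, np.empty(0, dtype=np.int64))
    d_tpm, tpm_pos = nearest_distance(np.array([c]), chrom_tpm)
    d_tss, tss_pos = nearest_distance(np.array([c]), chrom_tss)
    d_tpm, d_tss = float(d_tpm[0]), float(d_tss[0])

    if d_tpm <= PROXIMAL:
        d_tss_from_tpm, _ = nearest_distance(np.array([tpm_pos[0]]), chrom_tss)
        if float(d_tss_from_tpm[0]) > TPM_TSS_GUARD:
            return VALIDATED
    if d_tss <= PROXIMAL:
        if d_tpm > PROXIMAL or (tpm_pos[0] >= 0 and abs(int(tpm_pos[0]) - int(tss_pos[0])) <= TPM_TSS_GUARD):
            return MISCLASSIFIED
    return UNKNOWN


def classify_predictions(
    calls: list[EnhancerCall],
    tpm: pd.DataFrame | dict,
    tss: pd.DataFrame | dict,
) -> list[str]:
    tpm_pos = _by_chrom(tpm)
    tss_pos = _by_chrom(tss)
    return [classify_prediction(c, tpm_pos, tss_pos) for c in calls]


@dataclass
class ValidationSummary:
    """Per-cutoff validation/misclassification rates plus resolution and FDR."""

    curves: pd.DataFrame  # columns: cutoff, n_calls, n_validated, n_misclassified, validation_rate, misclassification_rate
    labels: list[str] = field(default_factory=list)
    resolution: pd.DataFrame | None = None
    fdr: "FdrTable | None" = None


def rate_curves(
    calls: list[EnhancerCall],
    tpm: pd.DataFrame | dict,
    tss: pd.DataFrame | dict,
    cutoffs: np.ndarray | list[float],
) -> ValidationSummary:
    """VR/MR versus voting cutoff among calls with vote >= cutoff.

    A cutoff with zero surviving calls yields NaN rates (recorded, not an
    error). The per-call labels are computed once; counts at each cutoff are
    exact because greedy peak calls at a higher cutoff are the subset of
    base-cutoff calls above it.
    """
    labels = classify_predictions(calls, tpm, tss)
    votes = np.array([c.vote for c in calls])
    lab = np.array(labels)
    rows = []
    for c in np.asarray(cutoffs, dtype=float):
        sel = votes >= c
        n = int(sel.sum())
        nv = int((lab[sel] == VALIDATED).sum())
        nm = int((lab[sel] == MISCLASSIFIED).sum())
        rows.append(
            {
                "cutoff": c,
                "n_calls": n,
                "n_validated": nv,
                "n_misclassified": nm,
                "validation_rate": nv / n if n else math.nan,
                "misclassification_rate": nm / n if n else math.nan,
            }
        )
    return ValidationSummary(pd.DataFrame(rows), labels)


def distance_resolution(
    calls: list[EnhancerCall],
    markers: pd.DataFrame | dict,
    radius: int = 200,
    hist_bins: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of calls within *radius* bp of their nearest marker.

    A call on a chromosome with no markers counts as beyond the radius.
    Returns (fraction, histogram DataFrame of nearest distances).
    """
    pos = _by_chrom(markers)
    if all(len(p) == 0 for p in pos.values()):
        raise ValueError("marker set is empty")
    dists = []
    for c in calls:
        d, _ = nearest_distance(
            np.array([c.center]), pos.get(c.chrom, np.empty(0, dtype=np.int64))
        )
        dists.append(float(d[0]))
    dists = np.array(dists)
    frac = float(np.mean(dists <= radius)) if len(dists) else math.nan
    if hist_bins is None:
        hist_bins = np.arange(0, 2100, 100)
    finite = np.clip(dists, 0, hist_bins[-1])
    counts, edges = np.histogram(finite, bins=hist_bins)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    return frac, hist


@dataclass
class FdrTable:
    """Empirical FDR per voting cutoff, averaged over chromosomes/permutations."""

    cutoffs: np.ndarray
    fdr: np.ndarray  # NaN where no real calls at that cutoff

    def find_cutoff(self, target: float) -> float | None:
        """Smallest cutoff on the grid whose FDR is defined and <= target."""
        for c, f in zip(self.cutoffs, self.fdr):
            if not math.isnan(f) and f <= target:
                return float(c)
        return None


def _count_at_cutoffs(calls: list[EnhancerCall], chrom: str, cutoffs: np.ndarray) -> np.ndarray:
    votes = np.array([c.vote for c in calls if c.chrom == chrom])
    return np.array([(votes >= c).sum() for c in cutoffs], dtype=float)


def permute_tracks(
    tracks: list[BinnedTrack],
    rng: np.random.Generator,
    independent_marks: bool = False,
) -> list[BinnedTrack]:
    """Shuffle 100 bp bins within each chromosome; by default the same
    permutation is applied to every mark, preserving cross-mark structure."""
    layout = tracks[0].layout
    perms = {c: rng.permutation(layout.n_bins(c)) for c in layout.chrom_names}
    out = []
    for t in tracks:
        values = {}
        for chrom in layout.chrom_names:
            p = rng.permutation(layout.n_bins(chrom)) if independent_marks else perms[chrom]
            values[chrom] = t.values[chrom][p]
        out.append(BinnedTrack(layout, values, t.mark_name, dict(t.metadata)))
    return out


def empirical_fdr(
    forest: VectorForest,
    tracks: list[BinnedTrack],
    cutoffs: np.ndarray | list[float],
    seed: int = 0,
    n_perms: int = 1,
    independent_marks: bool = False,
    filter_distance: int = 1000,
    real_votes: VoteTrack | None = None,
) -> FdrTable:
    """Empirical FDR by permuting genome bins and re-running the predictor.

    FDR(c) = #calls(permuted, c) / #calls(real, c), clipped to [0, 1],
    computed per chromosome and averaged over chromosomes with at least one
    real call (NaN where no chromosome qualifies), then averaged over
    permutation replicates.
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    base = float(cutoffs.min())
    if real_votes is None:
        real_votes = scan_genome(forest, tracks)
    real_calls = call_peaks(real_votes, cutoff=base, filter_distance=filter_distance)
    layout = tracks[0].layout
    real_counts = {c: _count_at_cutoffs(real_calls, c, cutoffs) for c in layout.chrom_names}

    rng = np.random.default_rng(seed)
    ratios = np.zeros((len(cutoffs),))
    weights = np.zeros((len(cutoffs),))
    for _ in range(n_perms):
        perm_tracks = permute_tracks(tracks, rng, independent_marks)
        perm_votes = scan_genome(forest, perm_tracks)
        perm_calls = call_peaks(perm_votes, cutoff=base, filter_distance=filter_distance)
        for chrom in layout.chrom_names:
            rc = real_counts[chrom]
            pc = _count_at_cutoffs(perm_calls, chrom, cutoffs)
            defined = rc > 0
            ratios[defined] += np.clip(pc[defined] / rc[defined], 0.0, 1.0)
            weights[defined] += 1
    fdr = np.full(len(cutoffs), np.nan)
    ok = weights > 0
    fdr[ok] = ratios[ok] / weights[ok]
    return FdrTable(cutoffs, fdr)


@dataclass
class MarkCorrelation:
    """Pairwise Pearson correlation of marks over the ±1 kb training windows."""

    mark_names: tuple[str, ...]
    matrix: np.ndarray  # (M, M), symmetric, unit diagonal
    leaf_order: np.ndarray  # display ordering from average-linkage clustering
    zero_variance_marks: tuple[str, ...] = ()


def mark_correlation(ts: FeatureBlockMatrix) -> MarkCorrelation:
    """Pearson r between per-mark signal vectors flattened over all training
    loci and the 20 window bins; hierarchical clustering (average linkage on
    1 - r) supplies the display ordering. Zero-variance marks correlate 0
    with everything and are flagged."""
    if ts.n_samples < 2:
        raise ValueError("need at least 2 samples for correlations")
    m = ts.n_marks
    flat = ts.values.transpose(1, 0, 2).reshape(m, -1)
    sd = flat.std(axis=1)
    degenerate = sd == 0
    corr = np.eye(m)
    good = np.nonzero(~degenerate)[0]
    if len(good) >= 2:
        sub = np.corrcoef(flat[good])
        corr[np.ix_(good, good)] = sub
    np.fill_diagonal(corr, 1.0)
    if m > 1:
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        order = leaves_list(average(squareform(dist, checks=False)))
    else:
        order = np.array([0])
    flagged = tuple(ts.mark_names[i] for i in np.nonzero(degenerate)[0])
    return MarkCorrelation(ts.mark_names, corr, order, flagged)
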