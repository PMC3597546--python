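# Methods

## Signal preparation

Aligned reads (BED intervals, 0-based half-open) are reduced to their 5′-most
coordinate — interval start on the `+` strand, `end − 1` on `-` — and counted
into 100 bp bins; a trailing partial bin at a chromosome end is dropped. No
fragment extension or shift is applied by default (an `--extend N` option
moves each 5′ end N/2 bp 3′-ward for users who want approximate fragment
centers); starts keep the operation deterministic and make strand handling
trivial. Each mark is converted to RPKM, `count / ((bin_width/1000) ·
(total/10⁶))`, and normalized against its matched input by **clamped
subtraction**, `max(0, RPKM_chip − RPKM_input)`. Subtraction rather than a
ratio was chosen because the ratio is unstable where input coverage is near
zero, and clamping keeps features non-negative; the choice is recorded in
each track's metadata. Replicates are normalized individually and then
averaged per bin, which keeps a bad replicate's depth from dominating the
pooled estimate.

## Training design

The enhancer class comprises p300 binding sites that (a) overlap a DNase-I
hypersensitive site by ≥1 bp and (b) lie more than `distal_threshold` from
every annotated TSS. `distal_threshold` defaults to 2500 bp so that the
training-time notion of "distal" matches the ±2.5 kb window used at
evaluation time. Peak anchors use the summit-offset column when a peak file
carries a valid one, else the interval midpoint. The non-enhancer class pools
an equal number of DNase-open TSS with `x` times as many random background
bins distal to all p300/TSS intervals (`x = 7` by default; 9 is appropriate
for sparser binding-site sets). TSS and background are sampled once per run
under the configured seed.

Features are the M-mark × 20-bin blocks spanning −1 kb..+1 kb; locus centers
snap to the nearest 100 bp bin boundary so that training extraction and the
genome scan share one code path, and loci whose window does not fit on the
chromosome are dropped with a warning rather than zero-padded.

## The vector forest

Nodes hold `(mark, w, t)` where `w = (S_W + λI)⁻¹(μ_enh − μ_non)` is the
Fisher discriminant of the node's samples restricted to one mark and `t`
minimizes weighted Gini impurity over all midpoints of consecutive sorted
projections (exact, O(n log n) via prefix sums). Numerical choices:

* λ = 10⁻⁶·trace(S_W)/20, floored at 10⁻¹²: sparse tracks produce
  zero-variance bins and singular scatter; the trace scaling keeps the
  regularizer proportionate to the data scale.
* `w` is normalized to unit length (the split is scale-invariant; this keeps
  serialized thresholds comparable).
* Ties in impurity break to the lower mark index, then the lower threshold
  (first minimum in the ascending scan); leaf-class ties break to
  non-enhancer, the conservative call for a screening tool.
* A node splits only when the best candidate yields a strictly positive
  impurity decrease; nodes of ≤ `min_node` samples (default 5) or pure nodes
  become leaves, so `min_node = N` yields a single-leaf tree.

Trees (default 65 — vote-fraction variance shrinks with ensemble size and is
stable well below that) are grown on bootstrap resamples of size N; `mtry =
ceil(√M)` candidate marks are drawn per node. Every tree gets an independent
generator spawned from the forest seed, so fits are exactly reproducible and
tree growth is order-independent. The classifier is strictly two-class
(enhancer vs pooled TSS + background).

Out-of-bag (OOB) error classifies each sample by majority vote of the trees
for which it is out-of-bag (samples with no OOB tree are excluded and
counted). Mark importance permutes the mark's **entire 20-bin block** among a
tree's OOB samples — permuting bins independently would break the
within-block shape that the discriminant uses — and averages the tree-level
OOB error increase over trees and permutation replicates (default 5).
Importance can be ≤ 0 for uninformative marks; ranks break ties by mark
order.

## Genome scan and peak calling

Every bin's vote is the forest output for the ±1 kb block centered on it;
bins within 1 kb of a chromosome end get vote 0 rather than padded features,
because padding would fabricate signal. Peak calling visits candidate bins
(vote > cutoff, cutoff ∈ [0.5, 1)) in descending vote order and accepts a
bin iff no accepted bin on the same chromosome is closer than the
peak-filtering distance (default 1000 bp, bin-start to bin-start); vote ties
break to the leftmost bin. Because candidates are processed in descending
order, the call set at a higher cutoff is exactly the subset of base-cutoff
calls above it — call counts are monotone in the cutoff and rate curves can
be computed from a single base call set.

## Evaluation

Calls are labelled against true-positive markers (TPM: DNase-I, p300/CBP/TF
sites) and TSS, with distances measured call-center to feature midpoint:
validated if the nearest TPM is within 2.5 kb and that TPM's nearest TSS is
more than 1 kb from it; misclassified if a TSS is within 2.5 kb and the
call's nearest TPM is either beyond 2.5 kb or within 1 kb of that TSS;
unknown when neither is within 2.5 kb. The rules are applied in that order,
and the rare geometries none of them matches also fall to "unknown" so the
three labels always partition the calls. Resolution is the fraction of calls
within 200 bp (configurable) of the nearest marker; a call on a chromosome
with no marker counts as beyond the radius.

The empirical FDR permutes the genome's 100 bp bins within each chromosome —
the same permutation applied to every mark, preserving cross-mark structure
(an `independent_marks` option shuffles marks separately) — re-runs the scan
and peak caller, and reports `#permuted calls / #real calls` clipped to
[0, 1], per chromosome, averaged over chromosomes with at least one real
call and over permutation replicates (default 1). `find_cutoff(target)`
returns the smallest grid cutoff whose FDR meets the target.

Mark correlation flattens each mark's N×20 training-window signal, computes
Pearson r between marks (zero-variance marks are flagged and correlate 0),
and orders marks by average-linkage clustering on 1 − r for display.

## The synthetic genome

The generator plants the signature the method assumes: H3K4me1 bimodal
(modes ±300 bp, σ = 150 bp, ~200 reads/site) at enhancers and weak at
promoters; H3K4me3 strongly unimodal (σ = 300 bp, ~250 reads/site) at
promoters and weak at enhancers; H3K27ac bimodal at a random half of
enhancers; three flat noise marks. Read counts are independent Poissons per
bin whose rates integrate the Gaussian site profiles plus a uniform
background of 0.1 reads/bin (sparse realistic depth at this genome size);
the matched input is background-only. Sites sit ≥5 kb apart and ≥5 kb from
chromosome ends on a default genome of 2 chromosomes × 2 Mb with 60
enhancers and 60 promoters. Truth sets double as the pipeline inputs: p300 =
enhancer centers, DHS = all sites, TSS = promoter centers.

Per-bin Poisson sampling deliberately omits fragment-length, GC and
mappability structure, duplicated reads, and the heterogeneous enhancer
subclasses of real chromatin. Tests passing on this generator therefore
demonstrate that the algorithm recovers the signature it models —
end-to-end recovery of ≥90 % of planted enhancers within 200 bp with ≤5 %
of calls near promoters, correct importance ordering, calibrated FDR — not
that real-genome validation rates will match; on real data the unknown
fraction is expected to be much larger.

## Problem sizes

The default synthetic study (4 Mb, 40 000 scanned bins, 540 training
samples, 65 trees) completes the whole pipeline in a few seconds; the
reported quantities in `scripts/acceptance.py` use exactly these defaults,
with ten independent replicates for the importance-recovery rate.

## Known limitations

* Binary classification only; promoters and enhancers are not separated
  into distinct output classes.
* No probability calibration beyond raw vote fractions.
* Peak calls are single 100 bp bins, not enhancer extents.
* The scan scores every bin; no minimum-signal prefilter is applied, which
  trades compute for the guarantee that no region is silently skipped.
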