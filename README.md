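# rfecs

Random-forest enhancer calling from histone-modification ChIP-seq.

Enhancers are distal cis-regulatory elements that carry a characteristic
chromatin signature — high H3K4me1 and H3K27ac flanking a nucleosome-depleted
center, low H3K4me3 — while promoters show the reverse. `rfecs` turns that
signature into genome-wide enhancer predictions for any cell type with mapped
histone modifications: it classifies every 100 bp genomic bin as enhancer vs
non-enhancer with a *vector* random forest, calls enhancer peaks from the
resulting voting track, ranks marks by out-of-bag importance, and evaluates
predictions against open-chromatin and TSS annotations. It is aimed at
regulatory-genomics analysts working from BED files of aligned ChIP-seq reads.

## The model

Each candidate position is represented by one feature block per histone mark:
the 20-dimensional vector of input-normalized RPKM values in 100 bp bins from
−1 kb to +1 kb. A forest of binary trees is grown on bootstrap resamples of a
training set containing p300 binding sites (distal, DNase-I-open; the
enhancer class) against an equal number of DNase-I-open TSS plus *x*-fold
random background bins (default *x* = 7, i.e. a 1:7 positive:negative ratio).

Unlike an axis-parallel forest, every internal node chooses one mark *m* and
splits on a Fisher linear discriminant over that mark's whole 20-bin vector
v:

    w = (S_W + λI)⁻¹ (μ_enh − μ_non),    go left ⟺ w·v ≤ t

where S_W is the node's pooled within-class scatter and the threshold *t*
minimizes the weighted Gini impurity over all projection midpoints. The node
therefore sees signal *shape* (the bimodal H3K4me1 profile) as well as
abundance. A genome scan assigns each bin the fraction of trees voting
"enhancer"; since that voting fraction decays symmetrically around a true
site, peaks are the local vote maxima separated by at least the
peak-filtering distance (default 1 kb) among bins with votes above the 0.5
cutoff. Out-of-bag permutation of one mark's whole 20-bin block measures that
mark's importance, and an empirical FDR is obtained by shuffling the genome's
100 bp bins (jointly across marks) and re-running the predictor.

## Worked example

Everything below runs from scratch in seconds on a simulated genome
(2 chromosomes × 2 Mb, 60 planted enhancers, 60 planted promoters, 6 marks):

```python
import rfecs

cfg = rfecs.SimulationConfig(seed=1)
training, dataset, tracks = rfecs.make_training_fixture(cfg)

results = rfecs.EnhancerForest(training).fit(n_trees=65, seed=1)
print(results.summary())
calls = results.call_enhancers(tracks, cutoff=0.5, filter_distance=1000)
print(len(calls), "enhancer calls")
```

```
Vector Random Forest — enhancer classification
======================================================
Samples:            540 (60 enhancer, 480 non-enhancer)
Marks:              6 × 20 bins (±1 kb at 100 bp)
Trees:              65
mtry / min_node:    3 / 5
Seed:               1
OOB error:          0.0000 (0 samples without OOB trees)

OOB permutation importance (error increase):
   mark  importance  rank
H3K4me1     0.16816     1
H3K27ac     0.01941     2
H3K4me3     0.00059     3
noise_1    -0.00003     4
noise_2    -0.00016     5
noise_3    -0.00017     6
60 enhancer calls
```

The summary reads like any ensemble-model fit report: a 540-sample design at
the 1:7(+TSS) class ratio, zero out-of-bag error (the planted signature is
strong), and the informative marks — H3K4me1 first — ranked above the flat
noise marks. All 60 calls land within 200 bp of a planted enhancer and none
near a promoter.

The same pipeline is available from the shell:

```bash
rfecs simulate --seed 1 --out fixture/
rfecs binarize --mark H3K4me1 --chip fixture/H3K4me1.bed \
      --input fixture/input.bed --chrom-sizes fixture/chrom.sizes --out tracks/
# ... one binarize per mark ...
rfecs make-training --p300 fixture/p300.bed --dhs fixture/dhs.bed \
      --tss fixture/tss.bed --tracks tracks/ --ratio 7 --seed 1 --out train.npz
rfecs train --training train.npz --trees 65 --seed 1 --out model.json
rfecs predict --model model.json --tracks tracks/ --out enhancers.bed
rfecs evaluate --calls enhancers.bed --tpm fixture/dhs.bed,fixture/p300.bed \
      --tss fixture/tss.bed --out report.tsv
rfecs fdr --model model.json --tracks tracks/ --target 0.05 --out fdr.tsv
```

Every subcommand writes a JSON manifest (version, parameters, seed, input
checksums) so runs are exactly reproducible.

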