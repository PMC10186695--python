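# chromoscale

Two-condition, multiscale comparison of Hi-C chromatin architecture:
A/B compartments, topologically associating domains (TADs), chromatin
loops, and the enrichment statistics that link architectural changes to
differential gene expression. The package is aimed at researchers who
have binned contact matrices (or raw contact-pair lists) for two
conditions — e.g. a control and a stress treatment — plus gene
expression, histone-mark and chromatin-accessibility tracks, and want a
reproducible, fully scripted account of what changed at each scale of
genome folding.

A first-class synthetic-data generator plants known compartments, TADs,
loops and matched gene/mark/DHS annotations, so every stage of the
pipeline can be verified against ground truth without downloading any
sequencing data.

## What it computes

**Matrix level.** Contact matrices are depth-normalised to the smaller
library, low-coverage bins are masked, and each chromosome is balanced
with Knight–Ruiz (KR) matrix scaling, i.e. a positive vector *x* with
diag(*x*)·*M*·diag(*x*) having equal row sums. Observed/expected (O/E)
maps divide each diagonal by its mean. Comparisons include the distance
decay *P(s)*, log2 differential maps, the stratum-adjusted correlation
coefficient (SCC) for reproducibility, and sliding-window structural
similarity z-scores (lower z = more different).

**Compartments** (50 kb). PC1 is the leading eigenvector of the Pearson
correlation matrix of the O/E map, oriented per chromosome so it
correlates positively with H3K27ac signal; PC1 > 0 marks the active A
compartment. Saddle plots bin the O/E map by PC1 percentile; compartment
strength is ln(AA·BB/AB²) over the 20 % corner classes. Per-bin joint
labels between conditions give the A-to-B / B-to-A switch table.

**TADs** (5 kb). The insulation score of bin *i* is the mean contact in
the square [i−w, i) × [i, i+w) for windows of 20–300 kb; local minima of
the combined z-scaled score, filtered on a delta statistic and a
Poisson depletion test with Benjamini–Hochberg (BH) correction, are
boundaries. A shift-tolerant consensus (± 2 bins) splits boundaries into
conserved and condition-specific; histone-mark-enriched TADs intersect a
peak and carry top-quartile mean signal.

**Loops** (pair level). Density clustering of contact pairs in
(pos1, pos2) space under the Chebyshev metric, run over an
(eps, minPts) grid and gated on local contrast, yields candidate
anchors; candidates pass when their count exceeds twice a
donut-style local background with BH-corrected Poisson significance.
Aggregate peak analysis (APA) averages O/E submatrices over loops;
differential loops are called on depth-matched (subsampled) pair lists
with an exact two-sided rate test per union loop.

**Integration.** Fisher exact enrichment of differentially expressed
genes (DEGs; |log2 FC| > 1) at condition-specific boundaries and
differential-loop anchors; permutation tests relocating intervals within
chromosomes (DHS–anchor overlap); and a genome-reorganisation summary —
the deduplicated union of DEGs in switched compartments, at specific
boundaries, or with promoters at differential loop anchors.

## Worked example

Simulate a paired-condition study (10 Mb genome, 5 kb bins, 5×10⁶
contact pairs; 15.5 % of bins switch compartment, ~29 % of boundaries
change, 30 % of loops are lost) and run the whole comparison:

```python
from chromoscale import (ArchitectureConfig, simulate_study,
                         CompareParams, compare_study)
from chromoscale.pipeline import simulated_inputs

config = ArchitectureConfig(seed=1)
study = simulate_study(config, return_pairs=True)
report = compare_study(params=CompareParams(seed=1, n_perm=200),
                       **simulated_inputs(study))
```

Printing a few entries of the report gives:

```
A fraction (cond 1):   51.5%
switched genome:       16.5%
compartment strength:  1.46 vs 1.54
TAD boundaries:        98 vs 95 (72.4% conserved)
loops:                 42 vs 39 (15 lost, 15 gained)
APA score (cond 1):    4.45
anchor-DHS overlap:    91.7% (perm p = 0.00498)
```

Reading: about half this synthetic genome is in the A compartment and
16.5 % of assessed bins switched state between conditions (15.5 % was
planted); compartment strength is the saddle statistic ln(AA·BB/AB²);
72 % of condition-1 TAD boundaries are found again in condition 2 within
± 2 bins; 42 loops are called in condition 1 (40 were planted) with an
APA score well above the no-enrichment value of 1; and 92 % of loop
anchors fall in DNase hypersensitive sites, far above the permutation
background.

The same pipeline runs from files (`chromoscale run --config run.yaml`)
on chrom.sizes + pair lists + gene/peak/DHS tables; see
`chromoscale simulate` to write a complete synthetic input set to disk.

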