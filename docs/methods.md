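# Methods

This note records the models, parameter choices and numerical decisions
behind chromoscale, in the package's own words. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The synthetic model

The generator produces per-chromosome contact-rate matrices of the form

    rate(i, j) = (|i − j| · bin_size)^(−α) · c(i, j) · t(i, j) · l(i, j)

with a power-law distance decay of exponent α (default 1.0, a typical
value for plant chromatin at the sub-megabase scale), a compartment
checkerboard factor c = (1 + A) for same-label bin pairs and 1/(1 + A)
otherwise (amplitude A, default 0.5), an intra-TAD fold t (default 3),
and a loop factor l applied to the 3 × 3 bin neighbourhood of each
planted anchor pair (default 5). Counts are independent Poisson draws of
the upper triangle, scaled so the expected total equals the stated
sequencing depth, then mirrored; pair lists place each count uniformly
within its bin pair.

Default study conditions: a 10 Mb genome (two 5 Mb chromosomes) at 5 kb
bins sampled to 5 × 10⁶ pairs. Compartment blocks alternate with
geometric lengths of mean 100 bins (500 kb); TAD boundaries are drawn
with near-exponential gaps of mean 24 bins (120 kb, the genome-wide mean
domain size implied by roughly 2,300 domains on a 271 Mb genome);
40 loops are placed with log-uniform separations of 120–750 kb. The
upper separation bound is a detectability choice: at this depth a 5-fold
focal peak beyond ~1 Mb carries only ~10 pairs in total, below any
density threshold, so planting such loops would only dilute recovery
scores without testing anything.

The paired condition flips whole compartment blocks until 15.5 % of bins
have switched (90 % of flipped blocks A→B), removes 29 % of boundaries
and gains the same number at new positions, and deletes 30 % of loops
while adding 0.8 × that number of new ones — fractions chosen to mirror
a cold-stress-scale reorganisation. Differential expression is planted
by re-drawing condition-2 FPKMs: a ~9.5 % background DEG rate
(down-biased), raised to ~23 % near changed boundaries (up-biased at
gains, down-biased at losses) and ~20 % for genes whose promoters sit at
lost-loop anchors. DEG labels always follow |log2 FC| > 1 applied to the
planted FPKM pair, so labels and expression values cannot disagree.
Tracks are generated consistently: 70 % of genes sit in A bins with
higher expression, H3K27ac peaks mark TSSs of the top-30 % expressed
genes, H3K27me3 covers B blocks, and DHSs sit at every loop anchor plus
random background sites.

What the generator does **not** emulate: restriction-fragment structure,
mappability and GC biases, translocations or copy-number effects,
trans-chromosomal contacts, nested/hierarchical domains, and realistic
correlated noise between conditions. Passing recovery tests therefore
demonstrates that each algorithm recovers the structure it models from
Poisson-sampled data at realistic depth — not that it is robust to every
artefact of real Hi-C libraries.

## Matrix processing

Depth normalisation scales both matrices to the smaller total pair
count. Low-coverage masking removes bins whose marginal is below 10 % of
the median positive marginal (scale-free). KR balancing uses the
standard inner-outer Newton iteration on each chromosome's unmasked
submatrix (masked bins are excluded, never zero-imputed), with relative
row-sum tolerance 1e−6 and at most 1000 outer iterations; the balanced
matrix is rescaled to preserve the chromosome total so depth
comparability survives. O/E divides each diagonal by its unmasked mean.

SCC combines per-distance-stratum Pearson correlations (strata up to
5 Mb, after a radius-1 mean filter) with weights
n·sd₁·sd₂ — the stratum pair count times the geometric mean of the two
stratum variances — so flat, uninformative strata contribute little.

Window similarity uses the standard SSIM form
(luminance·contrast·structure) on log2 O/E submatrices with stabilising
constants c₁ = (0.01 L)², c₂ = (0.03 L)², L being the joint dynamic
range of the window pair; z-scores are per chromosome (the natural scope
when chromosomes differ in coverage), recorded in the output metadata.
Degenerate windows (zero SSIM variance) get z = 0.

Distance classes for promoter–distal contact changes default to
20–50 kb, 50–100 kb, 100–500 kb, 500 kb–1 Mb and >1 Mb, half-open; the
promoter is the 2 kb region upstream of the TSS, strand-aware, assigned
to the bin of its midpoint.

## Compartments

PC1 is the leading eigenvector of the Pearson-correlation matrix of the
per-chromosome O/E map (correlation, not covariance, to suppress
marginal effects), unit-normalised and scaled by √eigenvalue, then
oriented by its correlation with an H3K27ac coverage track (gene density
as fallback). Saddle classes are PC1 percentiles computed **per
chromosome**: PC1 magnitudes are chromosome-scaled, and genome-wide
ranking can place an entire extreme class on one chromosome, leaving the
AB cross-corner without intra-chromosomal pairs. Corners pool the 10
extreme classes (20 % of bins) per side; bin pairs closer than 2 bins
are excluded to avoid self/adjacent inflation. Compartment intervals are
maximal same-label runs with no smoothing — single-bin islands are
reported as-is.

## TADs

The insulation score for window w is the mean unmasked contact in
[i−w, i) × [i, i+w); the combined score averages z-scaled
log2(raw/chromosome-mean) over windows of 20–300 kb in 5 kb steps. Near
chromosome ends, only the windows that fit contribute (bins where fewer
than two fit are undefined): clamping the full 300 kb exclusion zone
would make every boundary in the first and last 60 bins of a chromosome
structurally uncallable.

Boundary candidates are strict local minima of the combined score. The
delta filter (mean of 10 flanking bins each side minus the minimum,
threshold 0.01) removes shallow dips. Significance is a one-sided
Poisson test of the boundary-crossing square's summed count against the
chromosome's distance-decay expectation over the same bin pairs,
BH-corrected over all candidates before thresholding (q ≤ 0.01), which
makes the call count monotone in both thresholds. A rank-based
comparison of the crossing square against the flanking triangles was
considered and rejected: the square spans genomic distances up to 2w
while the triangles stop at w, so distance-dependent count levels and
discreteness dominate the ranks and the test rejects massively on
structureless data. The Poisson construction is calibrated under the
null (0 calls on structureless simulations at q ≤ 0.01) while retaining
full recall on planted domains; it assumes raw (or depth-scaled) counts,
so the caller takes the count matrix, not the balanced one.

Consensus matching is greedy nearest-first (leftmost on ties) within
± 2 bins, each boundary matched at most once; the conserved count is
symmetric in the input order. Differential TADs compare
condition-1 vs condition-2 value distributions over the intra-TAD
triangle and both flanking rectangles by rank-sum; mode "all" (default)
requires all three at p < 0.05. Mark-enriched TADs must intersect at
least one peak **and** carry top-25 % mean signal across TADs; when many
TADs are fully covered by broad domains their mean signals tie, and all
tied TADs at the threshold are labelled (no arbitrary tie-break).

## Loops

Clustering operates on raw pair coordinates under the Chebyshev (box)
metric, which makes axis-aligned anchor boxes natural. For each
(eps, minPts) combination — defaults eps ∈ {2, 5, 10} kb,
minPts ∈ {20, 50} — points are binned into eps-cells; a cell is dense
when its 3 × 3-cell neighbourhood holds ≥ minPts points **and** at least
twice the local background (the surrounding 9 × 9-cell ring). The local
gate is essential at realistic depth: near the diagonal the background
alone exceeds any absolute threshold over megabase-scale regions, and
compartment/domain structure shifts the local level both ways. Clusters
are 8-connected dense-cell components; components wider than 5·eps per
side are background blobs and are dropped. Runs are merged smallest-eps
first; overlapping boxes grow to their union so the underlying peak
stays inside. Candidates with anchor separation ≤ 2·max(eps) are
discarded as self-ligation range.

Significance re-centres a fixed 15 kb scoring window on the local count
maximum inside each candidate box (a merged box can be much wider than
the focal peak it contains), then compares the observed window count to
the larger of (a) the donut-style ring background — the mean of the 8
surrounding same-size boxes at ± 2 widths, reduced to the boxes that fit
— and (b) the genome-wide distance-decay expectation. The Poisson upper
tail is Šidák-corrected for the number of window positions searched
(choosing the maximum is a selection the raw tail ignores), de-duplicated
per site, BH-corrected, and thresholded at q ≤ 0.01 with
observed/expected ≥ 2. Diagonal-shifted backgrounds alone were rejected:
for a candidate inside a contact domain they leave the domain and
underestimate its level, passing domain-interior noise.

APA averages O/E submatrices (± 10 bins) over loops with separation
> 2·flank; the score is the centre pixel over the mean of the 3 × 3
lower-left (short-distance) corner. Differential loops subsample both
pair lists to the smaller total (seeded), then test each union loop's
two counts with an exact conditional binomial against the ratio of the
two conditions' local backgrounds (diagonal-shifted boxes — their
domain-level bias cancels between conditions); labels use BH-adjusted
q < 0.01 within the union, because the union contains condition-specific
calls whose counts differ by the very selection that called them, and
raw-p labelling over-calls gains.

## Enrichment statistics

Fisher tests are two-sided; the background includes the foreground by
default (the control is the overall prevalence), with a
foreground-excluded variant behind a flag. The permutation test
relocates each query interval uniformly within its own chromosome,
preserving length, with no non-overlap constraint; chromosome
preservation controls for chromosome-level composition. Because the
overlap fraction is discrete, the empirical p-value uses the mid-p tie
correction (half the tied permutations count), which keeps the null
distribution approximately uniform where the plain ≥ rule is
conservative; a fully degenerate statistic (all permutations tied, e.g.
saturating targets) returns p = 1.

Gene assignment: gene bodies for boundary regions (boundary bin
± 2 bins — the flank is configurable), strand-aware 2 kb promoters for
loop anchors, midpoint bins for compartment summaries. The
reorganisation summary is the deduplicated union of DEGs in switched
compartment bins, in condition-specific boundary regions, or with
promoters at differential-loop anchors, as a fraction of all DEGs.

## Benchmark design

Recovery benchmarks isolate the architectural layer under test where the
layers confound each other. Boundary recall/precision runs on a TAD-only
configuration: planted compartment block edges are genuine insulation
transitions and are (correctly) called as boundaries, which would be
scored as false positives against the TAD-only truth. Differential-loop
recovery runs on a loop-only perturbation: planted boundary and
compartment changes genuinely change contact rates at union-loop
positions and register as gained/lost rate calls that are not loop-layer
errors. Compartment metrics, APA and the end-to-end pipeline run on the
full configuration. Problem sizes (10 Mb, 5 × 10⁶ pairs, 200 calibration
runs at 199 permutations) were chosen so the whole acceptance run
completes in minutes on a single core while every planted feature stays
comfortably above the detection floor.

## Known limitations

* Intra-chromosomal analysis only; no `.cool`/`.hic` binary readers
  (text COO and pair lists are the exchange formats).
* Dense per-chromosome matrices: memory grows quadratically with bins
  per chromosome; comfortable to ~10⁴ bins per chromosome.
* The loop caller's density gates assume a roughly monotone distance
  decay; highly irregular backgrounds (e.g. assembly artefacts) are not
  modelled.
* No nested-TAD or sub-compartment calling, no CTCF-motif orientation
  analysis, no loop-extrusion modelling.
* The synthetic generator's simplifications listed above bound what the
  green test suite can certify about real libraries.
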