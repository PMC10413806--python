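# Methods

## The model

`burstkit` analyses single-cell UMI counts under the two-state (telegraph)
model of transcription. A promoter switches OFF → ON at rate K_on and
ON → OFF at rate K_off; mRNA is synthesised at rate K_syn only while ON and
degrades at rate d. All rates are expressed in units of d, which is fixed to
1 for every gene (the universal-degradation convention: per-gene variation in
degradation rates contributes little to the estimated bursting parameters,
and absolute time units are not identifiable from a snapshot). At steady
state the copy-number distribution is Poisson-Beta:

    P(X = x) = ∫₀¹ Pois(x; K_syn·b) · Beta(b; K_on, K_off) db,

i.e. a Poisson mixed over the stationary distribution of the ON-fraction.
Derived quantities: burst frequency = K_on (bursts per mRNA lifetime) and
burst size = K_syn/K_off (transcripts per burst, conventional definition).
Because the alternative ratio K_syn/K_on also circulates in the literature,
both are computed and reported side by side (`burst_size_conventional`,
`burst_size_alt`); all group statistics in this package use burst
frequency, where the two conventions do not interfere.

Measurement is modelled as binomial capture: a cell with n molecules of a
transcript yields X ~ Binomial(n, p) UMIs, with single-molecule capture
efficiency p (default assumption 0.35). Binomial thinning of a Poisson-Beta
law is again Poisson-Beta with K_syn → p·K_syn, so capture noise biases the
synthesis rate but, to first order, not K_on or K_off. The technical-noise
floor implied by capture alone is CV = sqrt((1−p)/m) at mean observed level
m = n·p.

## PMF evaluation

The mixing integral is evaluated by Gauss-Jacobi quadrature whose weight
function is exactly the Beta kernel (nodes/weights from
`scipy.special.roots_jacobi` with α = K_off−1, β = K_on−1), so endpoint
singularities for shape parameters < 1 are handled exactly and convergence
in the smooth Poisson factor is spectral. Sixty nodes are used for reported
probabilities and fifty inside the likelihood; `pb_pmf` verifies convergence
by doubling the node count (relative tolerance 1e-8) and falls back to dense
midpoint integration in the angle variable b = sin²θ on 2×10⁵ points if the
check fails. Accumulation is done in log space with a max-shift
log-sum-exp, so probabilities down to ~1e-300 are representable.

## Per-gene maximum likelihood

`fit_gene` maximises the Poisson-Beta log-likelihood over
(K_on, K_off, K_syn) with L-BFGS-B in log10-parameter space, box bounds
10⁻³–10³ (degradation units; spans published mammalian estimates while
preventing overflow). Initialisation is the classical factorial-moment
estimator — with r₁ = f₁, r₂ = f₂/f₁, r₃ = f₃/f₂ the three rates follow in
closed form — clipped into the box; a coarse log-grid over (K_on, K_off)
with K_syn matched to the sample mean serves as fallback and as a guard
against a poor local optimum from the moment start. Fitting is a
deterministic function of (counts, options).

Status flags:

* `failed` — all-zero counts (no information).
* `boundary` — the optimum sits at a box bound, or the fit fails a
  likelihood-ratio identifiability screen against the nested plain-Poisson
  limit (2·ΔLL ≤ 5.99, the χ²₂ 0.95 quantile). The Poisson law is the
  fast-switching limit of the telegraph model; when the data cannot reject
  it the likelihood is flat along a ridge and the individual rates are
  meaningless even though the fitted mean is correct. The screen is needed
  because a flat ridge can leave the optimiser stranded far from the box
  bounds with an arbitrary K_on.

`filter_fits` then marks fits as kept for downstream group statistics when
(a) status is `ok`; (b) mean observed expression is ≥ 1 UMI/cell — in
simulation diagnostics the K_on/K_off likelihood ridge leaves the burst
frequency uncertain by an order of magnitude below roughly one detected
transcript per cell, so such genes are not "reliably estimated" in the sense
group analyses require; and (c) a binned χ² goodness-of-fit test of the
counts against the fitted law does not reject at α = 0.01 (bins pooled from
the tail to expected ≥ 5, degrees of freedom reduced by the 3 estimated
parameters). The χ² filter is a stand-in for an unspecified
"deviates from the curve fit" criterion and its α and binning are exposed.

`half_sample_stability` refits on two disjoint random halves of the cells
and reports the Spearman correlation of burst-frequency estimates across
genes kept in both halves — the package's stability diagnostic in place of
per-gene confidence intervals.

Cell-level QC precedes fitting when per-cell metrics are available: wells
with < 50,000 exon reads (empty) or < 50% exon mapping rate (contamination)
are eliminated; values exactly at a threshold pass.

## TAD-contextual statistics

TADs are ordered non-overlapping intervals (BED, 0-based half-open). The
boundary of adjacent TADs A, B is [A.end − 0.05·len(A), B.start +
0.05·len(B)) — the 5% flanks around the breakpoint; non-abutting neighbours
still define one boundary spanning the gap (TAD callers can emit gaps). A
gene belongs to a feature only if fully contained in it. A gene contained in
a boundary region counts as a boundary gene even when it also lies inside
one TAD's flank ("within-TAD" means TAD-but-not-boundary), making the two
classes a partition — the contrast between them is the point of the
analysis.

For every TAD with ≥ 8 kept genes and boundary with ≥ 4 kept genes the CV
(sample sd / mean, ddof = 1) of the member genes' burst frequencies is
computed; inside the class comparison the standard small-sample correction
CV·(1 + 1/(4n)) is applied, because the sample CV is downward-biased more
strongly for the ~5-gene boundary groups than for the ~10-gene TAD groups
and the classes are compared directly (`group_cv` itself defaults to the
uncorrected textbook definition). Random control groups are drawn uniformly from all kept genes,
matched in number to each class and in size to the class's median group
size. Classes are compared by two-sided Wilcoxon rank-sum tests
(`scipy.stats.mannwhitneyu`, equivalent to R's unpaired `wilcox.test`) and
by bootstrap: 10,000 resamples of the groups (the group, not the gene, is
the exchangeable unit — the summary is a median over groups) recording the
median CV per class. Because bootstrap medians of the same groups are not
independent observations, the Wilcoxon comparison is reported both on the
raw per-group CVs (the honest test) and on the bootstrap medians.

A caveat worth knowing when reading results: for heavy-tailed frequency
distributions the size bias of the sample CV exceeds the first-order
1/(4n) correction, so a small structural residue can remain in
tad-vs-boundary comparisons under the null; the size-matched random
controls quantify it.

A/B compartment contrasts compare the distributions of burst frequency and
burst size between compartments with two-sided two-sample KS tests;
compartment labels come from the sign of a bedgraph eigenvector track (the
A = positive convention is a config switch, since deposited tracks differ).

## Gene-pair co-expression

Genes averaging < 2 raw transcripts/cell are excluded (rank correlations on
near-constant vectors are noise); each cell's counts are then divided by its
total UMI count, removing depth and residual global extrinsic variation
(fraction scale — no ×10⁴ factor, which would not change ranks). Spearman's
rank correlation (midrank ties) is computed across cells for all unordered
pairs within each TAD and each boundary region holding ≥ 2 kept genes, and
for a random control of pairs drawn uniformly from all kept genes
(configurable count, or exhaustive; controls falling in the same feature are
kept by default, matching a transcriptome-wide draw, with an exclusion
flag). Context distributions are compared by two-sided two-sample KS.

## The synthetic-data generator

The generator produces exactly the structures the analysis assumes, with
full ground truth and bit-reproducibility from (config, seed):

* counts per gene: Beta-mixture sampling of the stationary law (not
  trajectory simulation — the inference assumes stationarity, and the exact
  Gillespie simulator is retained solely as the distributional test oracle;
  its burn-in default is 10 mean promoter cycles plus 10 degradation times);
* binomial capture thinning at p (default 0.35);
* a single-chromosome genome of abutting TADs (default 200 kb) with genes
  (2 kb) packed without overlap into TAD interiors and 5%-flank boundary
  regions;
* spike-in wells: detected UMIs ~ Binomial(input copies, efficiency) over a
  two-fold input ladder.

Per-gene rates are drawn log-uniformly. Two regimes are provided:

* default (recovery studies): K_on ∈ [0.05, 5], K_off ∈ [0.5, 20],
  K_syn ∈ [5, 100] — a wide span of published mammalian estimates with
  K_off > K_on for most genes, deliberately including weakly identifiable
  corners so that the fit filters are exercised;
* `DatasetConfig.well_expressed()` (TAD/co-expression studies): K_on ∈
  [0.2, 2], K_off ∈ [1, 10], K_syn ∈ [20, 100]. Group-level analyses only
  ever see genes that survive fit filtering, which in real data are the
  adequately expressed ones; a genome in which most planted genes are
  unfittable cannot sustain groups at the ≥ 8/≥ 4 thresholds, so the
  group-analysis genome generates the fittable population directly.

Planted effects:

* within-TAD burst-frequency sharing: all genes of a TAD take a common
  TAD-level K_on times lognormal jitter (σ configurable; 0.1 in the planted
  studies → true within-TAD CV ≈ 0.1; 0 = identical). The paper-level
  readout (smaller within-TAD CV) is thereby an explicit effect size rather
  than an emergent property.
* cross-boundary co-expression: genes of one boundary region share a
  per-cell lognormal factor (unit mean, σ configurable; 0.6 in the planted
  studies) multiplying K_syn, inducing positive rank correlation
  (≈ 0.2–0.35 at 300 cells in the well-expressed regime) with little effect
  on marginal burst parameters.

With sharing off and σ = 0 the dataset is an exchangeable null. What the
generator does **not** emulate: read-level artefacts (no FASTQ, UMI errors,
barcodes), extrinsic cell-state noise beyond the optional shared factor
(the real cells' extrinsic-noise law is unknown; the lognormal factor is a
stand-in, not a claim), batch effects, or gene-length/GC biases. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to the full messiness of real data.

## Problem sizes and numerical choices

Verification runs use: 3×3×3 parameter grids for PMF checks (dense-grid
comparison restricted to shape parameters ≥ 0.5, where the angle-variable
midpoint rule attains 1e-5 accuracy); 5,000-draw KS comparisons between the
Gillespie and mixture samplers; 300 genes × 150 cells for parameter
recovery; a 50-TAD × 10-gene genome with 49 boundaries × 5 genes at 150
cells for the planted TAD contrast (20 replicates for the null arm); 20
replicates of a 25-TAD genome at 300 cells for the co-expression power
study; 150 genes × 300 cells for half-sample stability. Sizes were chosen so
each property is decided by a comfortable statistical margin on a single
CPU.

Ties, degenerate inputs and tie-breaks: zero-mean genes are dropped from
noise profiles (logged); zero-variance genes make a pair's SCC undefined
(pair dropped, logged); zero-total cells are an error in normalization;
boundary construction with fraction ≥ 0.5 is rejected (regions would cross
TAD midpoints); duplicate gene/cell ids and negative or fractional counts
are read errors, not coercions.

## Known limitations

* No allele-resolved fitting (the motivating application is haploid);
  diploid data would mix two independent allelic processes.
* No per-gene degradation rates; estimates are interpretable only relative
  to each gene's mRNA lifetime.
* No confidence intervals beyond the half-sample diagnostic.
* The χ² goodness-of-fit filter has limited power at low expression, where
  the reliability threshold does most of the work.
* Burst-size group statistics inherit whichever convention is chosen;
  cross-study comparisons must check which ratio is reported.
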