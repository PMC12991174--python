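# Methods

This note documents the statistical models implemented in `striazone`,
the synthetic study conditions used by the test suite and the acceptance
script, the numerical choices made where the design was genuinely open,
and the known limitations.  No number stated here is asserted anywhere
the code does not compute it.

## Micro-compartment point-pattern statistics

**Estimator.** For a cell type's point pattern inside the MSN window (the
convex hull of all MSN cells shrunk by a 50 μm inward buffer), the
inhomogeneous pair correlation function is estimated as

    ĝ(r) = Σ_{i≠j} κ_h(r − d_ij) / (2πr · λ̂(x_i) λ̂(x_j) · C(x_j − x_i)),

with an Epanechnikov kernel κ_h (bandwidth 0.15/√λ̄, the classic
intensity-scaled rule), a leave-one-out Gaussian kernel intensity
estimate λ̂ at a per-type bandwidth σ (defaults 500/570/720 μm by type),
and translation edge correction through the window's set covariance
C(v) = |W ∩ (W+v)|.  The set covariance is evaluated once by FFT
autocorrelation of the window indicator on a 256² grid and bilinearly
interpolated; intensity edge effects are corrected analytically against
the window's bounding box.  The r grid runs 0–1000 μm in 10 μm steps with
a 25 μm inner exclusion; donors with fewer than 30 cells of a type are
skipped.  The vectorized estimator agrees with a direct O(n²) pair-count
implementation to better than 1e-6 (tested).

**Envelopes and the compartmental call.** Null patterns are drawn from an
inhomogeneous Poisson process whose intensity is fit to *all* cells of
the pattern at a fixed 1500 μm bandwidth (capturing tissue-level
gradients only); each simulation is re-analysed exactly like the observed
pattern, and pointwise min/max envelopes are reported.  Because pointwise
envelopes over ~100 grid values have family-wise error near one, the
*compartmentalized* call is gated on a global studentized max-statistic
Monte-Carlo test: curves are standardized per radius by the pooled
(observed + simulated) mean and SD, and the observed curve's largest
standardized deviation must exceed every simulation's — an exchangeable,
(approximately) exact level-1/(n_sims+1) test that is not dominated by
the noisy smallest radii.  On homogeneous Poisson input this leaves the
radius undefined in ≈ 96–99% of runs (measured).

**Radius.** The compartment radius is the first downward crossing of
ĝ(r) = 1 beyond the inner exclusion, linearly interpolated between grid
points (the 10 μm grid makes the interpolation choice sub-resolution).
The crossing location depends on the intensity bandwidth: structure at
scales ≳ σ is absorbed into λ̂ and deflates ĝ.  The package therefore
keeps σ a per-type configuration value; the fixed per-type defaults sit
at ≈ 1.6× the compartment radii they target, and the radius-recovery
study uses that same ratio.  Under those conditions the median estimate
is within ±10% of truth for planted radii of 100–450 μm (measured;
the acceptance bound is ±20%).

**Compartment maps.** DBSCAN is implemented from its published definition
(core points have ≥ minPts neighbors within eps, the point itself
included; clusters are density-connected components; border points join
the first core cluster reached in deterministic index order).  Per donor
and compartment class, eps is swept from 20 μm to 2× the radius estimate
in 10 μm steps; at each eps, convex hulls around clusters of ≥ 3 cells
are scored by purity (fraction of all MSNs inside the hulls that are
target-type, point-in-polygon), and the largest eps with purity ≥ 0.90 is
kept (fallback: smallest eps producing any cluster).  Hull membership
uses covers-semantics (a hull includes its own vertex points).  Cells in
overlapping hulls take the smallest-area hull; remaining cells are Matrix
iff ≥ 1 matrix MSN lies within 150 μm and > 2 within 250 μm, else
unassigned.  Composition enrichment uses log2(compartment proportion /
matrix proportion) with a 0.5-cell pseudocount (keeps ratios finite and
symmetric), paired Wilcoxon across donors, BH across cell types.

## Zones

**Clustering.** Counts are library-size normalized (10⁴ per cell),
log1p-transformed, reduced to the most variable genes, standardized per
gene *within each donor* (the default batch handling; an external
corrected embedding can be supplied through a hook), and projected onto
up to 30 PCs whose scores are weighted by explained variance.  A shared
nearest-neighbor graph (k = 20, Jaccard weights, 1/15 prune) feeds Leiden
clustering; the resolution is bisected until the partition has exactly
the requested k.  Labels are renumbered dorsal → ventral by mean y.

**HDR.** Zone territories are 50% highest-density regions of a bivariate
Gaussian KDE on a 151×151 grid.  The bandwidth matrix is the multivariate
normal-reference rule (data covariance, factor n^(−1/6)) with its
Cholesky factor scaled by 0.9; zone fields are smooth unimodal blobs,
where the normal-reference and plug-in selectors agree closely, so the
simpler rule is used and the scale stays exposed.  The HDR threshold is
the descending-cumulative rule (sort grid densities, threshold where
cumulative mass reaches p); at p ≥ 1 the mask is all cells of nonzero
density.  Overlap is the percentage of one mask's cells inside the other
(asymmetric).  Enclosed mass is tight: removing the least dense included
cell drops it below p (tested).

**Granularity.** The selected zone count is the largest k in 3..9 whose
per-donor HDRs are (i) contiguous — largest connected component ≥ 90% of
the mask, (ii) non-overlapping — pairwise same-donor overlap ≤ 25%, and
(iii) represented — every cluster ≥ 1% of every donor's cells.  The
thresholds quantify qualitative criteria and are exposed as
configuration.

**Axes and transfer.** After removing spatial outliers (median distance
to k = 10 neighbors > mean + 3 SD), the D-V axis is the unit vector from
the zone-1 to the zone-4 centroid and the C-P axis its 90° rotation
signed so zone 2 projects positive; projected coordinates are invariant
to rigid rotations of the input (tested).  Zone transfer is two-stage:
a GM/WM call by majority among the k = 5 nearest cells carrying a GM/WM
hint (MSNs count as GM, glial *_GM/*_WM subtypes as labeled), then a
majority-zone vote among the k = 15 nearest reference cells within
750 μm; ties break by summed inverse distance, then lowest zone index.
Placement accuracy uses k = 50 neighborhoods: > 40 concordant neighbors
define a high-confidence territory, others are edge cells and excluded.

## Pseudobulk differential expression and blocks

**Engine.** Raw counts are summed per donor × zone (exact integer sums;
genes under 50 total counts are dropped).  Each gene gets a
negative-binomial GLM with log link, median-of-ratios size factors as
offsets, and design intercept + zone indicator + donor dummies, fit by
IRLS vectorized across genes.  Dispersion is method-of-moments from a
Poisson pre-fit with per-observation hat-leverage correction of the
squared residuals, then shrunk halfway (arithmetic scale — a log-scale
blend would bias α low by Jensen) toward an α ~ a₀ + a₁/μ trend.  Wald
p-values, BH FDR.  The engine is deliberately pluggable: the scientific
content downstream is the block algorithm and TWI, not the GLM fitter.
On null simulations the per-gene LFC is unbiased and the FDR holds
(tested); a residual few-percent optimism of Wald SEs at very small
sample counts is visible in the TWI bias measurement below.

**Block assignment.** Candidate blocks are single zones and contiguous
runs in the dorsoventral order 1..6, by default also treating zones 6
and 1 as spatial neighbors (configurable).  A gene is a candidate for a
block when every member zone passes the zone-vs-rest significance filter
(padj < 0.05, log2FC > 0.5).  Detection filters: pooled within-block
detection ≥ 20%; outside detection ≤ 15% and ≤ half the inside rate.  The
outside cap is enforced uniformly — as a maximum over non-block zones —
because a pooled mean would let a block member orphaned by the
significance filter hide among silent zones; the edge-validation rule
(edge-zone detection ≥ 2× outside) uses the pooled outside mean, which is
how that rule is stated.  Genes take their highest-mean-FC candidate,
ties broken by fewer zones then lower adjusted p; multi-zone blocks also
require a 20% per-zone floor and edge validation, with failures falling
back to the next qualifying candidate.  Multi-zone genes with any
BH-significant within-block pairwise contrast are *gradient*, the
partition into high and low subsets being read off the ordering of
pseudobulk means; genes with none are *discrete*.  The assignment is a
deterministic function of the DE table (tested).

**TWI.** Transcriptome-wide impact is the method-of-moments
deconvolution TWI = mean over genes of (LFC² − SE²), truncated at zero —
an estimate of the variance of true log2 fold changes.  The full
likelihood deconvolution of the effect-size distribution is out of
scope; the jackknife quantifies the difference empirically.  Confidence
intervals come from a leave-one-donor-out jackknife
(SE = √(((n−1)/n) Σ(TWIᵢ − T̄)²)), the 95% CI constructed around the
leave-one-out mean.  On simulated cohorts (600 genes, 12 donors,
pseudobulk depth 1.5×10⁶, planted Var(LFC) = 0.09) the CI covers the
realized planted variance in ~92% of seeds with a small (+2–3%) positive
bias from residual Wald-SE optimism.  The dorsoventral test permutes the
dorsal/ventral zone labels within each donor with 50% probability,
recomputing both DE fits and ΔTWI per iteration; the two-tailed empirical
p has resolution 1/n_iter (1,000 iterations at full scale; tests use
reduced counts via the argument).  The permutation null assumes the two
zone labels are exchangeable — "no difference" means the zones carry
identical true contrast vectors, not merely equal effect variances.

## Enrichment

Preranked GSEA uses the weighted running-sum statistic (hit steps
proportional to |statistic|), with gene-label permutation nulls shared
across sets of equal size, NES as the score over the mean same-signed
null magnitude, and the leading edge as the member genes up to the
running-sum extremum.  The adaptive multilevel p-value scheme of the
reference implementation is approximated by plain permutation; at the
default 500–1,000 permutations the p floor is 1/(n+1).  Redundancy
consolidation builds a leading-edge overlap graph over significant sets
(|NES| ≥ 1, FDR < 0.05, strictly > 0.21 overlap fraction of the smaller
edge), separately per NES sign; nodes with degree > 12 are iteratively
removed (highest current degree first, ties by name — a deterministic
order, since the removal order is otherwise unspecified), then one winner
per connected component is kept by highest degree, lowest adjusted p,
highest |NES|.  The greedy Jaccard prune scans terms by ascending
adjusted p and drops any term whose leading edge exceeds 0.7 Jaccard
similarity with a kept term.

## Spatial signaling

Signature scores rank each cell's genes by decreasing expression (average
ties, ranks clamped at max_rank + 1; max_rank defaults to 1500, the
convention of the rank-based scoring literature) and map the Mann-Whitney
U statistic to [0, 1], normalized so a signature filling the top ranks
scores exactly 1 and a fully undetected signature exactly 0; scores are
invariant to monotone transforms of expression (tested).  High/low flags
split at each donor's median.  Neighborhoods are 200 μm fixed-radius
balls; neighborhood deltas z-score pooled neighbor expression against the
donor-level pool of the same cell type and test the high-minus-low delta
with a one-sample t across donors.

Ligand-receptor scores multiply the sender's ligand expression
(log-normalized by default; exposed as configuration) by the 10%-trimmed
mean (floor(0.1 n) dropped from each tail — the symmetric convention) of
receptor complex expression among receiver-type cells within 200 μm;
complexes are geometric means of subunits with a hard zero if any subunit
is zero.  Senders are restricted to the contrast zones, receivers
contribute from all zones, senders without receivers in range are
excluded, and sender cells weigh equally in zone means.  Zone 1 − zone 4
donor deltas get paired t-tests with BH across all (sender, receiver,
pair) triples.  Robustness: per donor, sender zone labels are shuffled
(default 1,000 times; tests use 200), and the donor is robust iff its
|delta| exceeds the 99th percentile of the absolute null *and* matches
the cross-donor consensus sign; an interaction is retained at ≥ 65%
robust donors (12 of 18 at the reference cohort size).  On
label-symmetric data the percentile check fires at ≈ 1–2% of donor tests
and no pair passes FDR (measured).

## Aging

**Label transfer.** The reference hierarchy merges the two closest
cluster centroids in the embedding space per step (recorded as a merge
trace).  Each internal node stores a 30–100 gene panel ranked by the
product of detection-rate-difference and mean-difference ranks, with
branch profiles standardized per gene over the node's cells so
low-expressed discriminative genes are not drowned out by
housekeeping-scale genes.  Query cells descend the tree; at each node,
1,000 bootstrap draws of 90% of the panel vote via a matched filter
(projection on the branch-profile contrast, split at the midpoint of the
branch projections), and the vote fraction is the confidence.  Noiseless
centroid profiles map back to their own leaves exactly; held-out-donor
cells map at ≈ 91% zone accuracy under a realistic marker panel (~30
zone markers per zone), which is the regime of real zonal signatures —
per-cell mapping from a handful of weak markers is noise-limited.

**Age × zone model.** Donor × zone pseudobulk log2 CPM is fit per gene by
OLS with zone, age/10 (per-decade effects) and age × zone interactions,
plus optional user covariates.  Donor dependence is handled by
cluster-robust (CR1, by donor) sandwich standard errors with t reference
(donors − 1 df) rather than REML random intercepts: age is a donor-level
variable and pseudobulk rows are donor × zone, so clustered SEs give
valid inference at this scale; a random-intercept engine is a documented
extension point.  The reference zone's absolute aging effect equals the
baseline age coefficient exactly; other zones add their interaction,
with the delta-method SE from the coefficient covariance.

**Consensus ICA.** The genes × zones matrix of per-zone aging fold
changes is decomposed by FastICA with random initialization, 100 runs per
component count k = 2..6 (k capped at the numerical rank; non-converged
runs and spurious single-iteration fixed points are discarded).  The
pooled unit-normalized mixing columns are clustered by PAM (classic
build/swap on the 1 − |Pearson r| matrix, deterministic); per-cluster
stability is the mean pairwise |r|, and k* is the largest k with all
stabilities > 0.99 (if none, the best k is returned flagged).  Consensus
mixing vectors are cluster medoids; the source matrix comes from
Moore-Penrose pseudoinverse refactorization, with SEs across sign-aligned
member runs.  Signed Proportions divide each loading by the gene's sum of
absolute loadings (Σ|SP| = 1 for genes with any signal).  ICA requires
non-Gaussian sources; the recovery study plants Laplace-distributed gene
loadings on two orthogonal zone patterns.

**Erosion.** Between-zone variance per gene and donor is the sample
variance of pseudobulk logCPM across the six zones.  Genes are filtered
to mean young-quartile expression > 3 logCPM; delta_var is the
old-quartile minus young-quartile mean, and the statistic is the fraction
of genes with delta_var < 0, tested by shuffling quartile membership
(10,000 permutations at full scale), two-sided with floor 1/n_perm.
Zone-pair correlation trends use the same gene filter: per donor, the
Pearson correlation between two zones' expression vectors, then the
correlation of that similarity with donor age.

## Synthetic study conditions

The generator's defaults define the study conditions and are fixed:

- **Geometry**: 7 × 10 mm rectangle, vertical WM band (12% of width)
  between a caudate-like and a putamen-like lobe; six isotropic Gaussian
  zone fields (σ = 950 μm) ordered dorsal → ventral with zone 2 off-axis.
  Ground-truth zone is the *territory* (dominant field at the cell's
  position), not the generating mixture component — zones are regions of
  tissue, and adjacent fields overlap.
- **Compartments**: Thomas processes with offspring σ = radius/√6, so the
  stated radius is the 95% offspring-containment radius; defaults
  striosome-like 380 μm (0.45 parents/mm², 20 points), NUDAP-like 300 μm
  and KCNJ6-like 250 μm (0.3/mm²).  Parents of different classes keep
  0.6 × (Rᵢ+Rⱼ) separation, diffuse matrix MSNs are displaced from patch
  cores (compartments are mutually exclusive tissue), and intensities
  scale with the per-donor cell budget (calibrated at 5,000 cells).
  The standalone Thomas generator for estimator studies uses a scale
  family (parent intensity ∝ 1/R²) so clustering strength is comparable
  across radii.
- **Counts**: NB (Γ-Poisson) with dispersion 0.15, log-normal library
  sizes (mean 3,000), per-donor log2 shifts (SD 0.1).  Zonal markers are
  near-silent outside their block (0.08 expected counts/cell) as real
  zonal markers are; discrete markers default to log2FC 2, gradient
  markers span two adjacent zones ramping from half to full effect
  (default 4), so adjacent gradient zones differ by a 2× step.  All genes
  additionally carry weak pervasive zonation (log2 SD 0.15) — broad
  low-amplitude zonal structure is what the erosion statistics measure
  transcriptome-wide.
- **Aging**: a donor of age a retains 1 − erosion_rate·(a − min age)/10
  of every zonal contrast (floored at 0; applied to markers and the
  pervasive background), with optional per-zone-vulnerable aging gene
  programs.  Acceptance cohorts use 16 donors spanning ages 25–85.
- **Problem sizes** (chosen for single-CPU runs of a few minutes):
  pipeline default 3 donors × 5,000 cells × 1,000 genes; block recovery
  18 donors × 1,500 cells × 300 genes; TWI 600 genes × 12 donors at
  pseudobulk depth 1.5×10⁶; CSR calibration 100 patterns of 800 points
  with 39-simulation envelopes; LR null 8 donors × 1,200 cells × 30
  pairs at 200 permutations.

**What passing tests do and do not show.** The generator emulates the
geometry, count statistics, batch structure and planted effects of
zonated tissue, but not ambient RNA, doublets, segmentation error,
anisotropic anatomy, cross-section registration, or 3D structure.
Recovery results certify that the estimators are correctly implemented
and calibrated under their stated assumptions — not that real tissue
satisfies those assumptions.

## Known limitations

- The NB-GLM Wald SEs retain a few percent optimism at very small sample
  counts, visible as a ~+2–3% TWI bias; a quasi-likelihood or
  resampling-based SE would remove it.
- The dorsoventral TWI permutation tests label exchangeability; any true
  asymmetry of the zonal contrast vectors — not only a variance
  difference — rejects.
- Consensus-ICA stability across random restarts of the *same* data can
  saturate for k above the true signal rank when the residual structure
  is deterministic; the rank cap and convergence filters mitigate but do
  not remove this.
- Label transfer accuracy is bounded by the per-cell information in the
  marker panel; sparse panels of weak markers map near the Bayes floor.
- The GM/WM vote requires glial subtype hints or MSN presence; donors
  lacking both fall back to calling everything GM.
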