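# Methods

`etg3d` pairs enhancers with target-gene promoters genome-wide by combining
three orthogonal signals: spatial co-localization in the 3D genome,
synchronization of regulatory activity across cell types, and adaptive
multiple-testing control that lets the spatial signal inform the
statistical one. This note describes each component, its assumptions, the
tunable parameters, and the numerical and design choices a maintainer
should know about.

## Reference regions

The enhancer catalogue is constructed per cell type as the base-pair
intersection (≥1 bp overlap) of significant H3K27ac ChIP-seq and DNase-seq
narrow peaks — significance meaning −log10(adjusted p) ≥ 5 (`min_qscore`).
Exonic portions (coding and non-coding genes) are subtracted — an exon
strictly inside an interval splits it in two — and fragments shorter than
10 bp or longer than 2.5 kb are dropped; both boundary lengths are kept,
reading "shorter than" and "larger than" strictly. Per-cell-type enhancers
are merged (union) across cell types, so the catalogue is a disjoint set of
intervals, and only elements distal to every TSS window (3.5 kb upstream to
1.5 kb downstream, strand-aware, ≥1 bp overlap rule) are retained.
Intersection rather than "keep the DNase peak" was chosen deliberately: the
catalogue's elements should carry both accessibility and acetylation
evidence at every base, and intersection yields elements smaller than
either input peak set, which matches the intent of a conservative
reference.

Promoters are strand-aware windows of 1.5 kb upstream and 0.5 kb downstream
around each gene's most upstream TSS (minimum coordinate on `+`, maximum on
`-`, selected before window construction). TSSes within ±0.5 kb merge into
one promoter carrying every member's gene symbol; merging is transitive, so
a chain of close TSSes collapses into a single element spanning the union
of member windows. Chromosome Y and non-canonical contigs are excluded.

All coordinates are 0-based half-open (BED convention) and "overlap" always
means at least one shared base. Interval arithmetic is delegated to
pyranges; the test suite checks every operation against a per-base
bit-vector oracle on a toy genome.

Two Jaccard variants quantify agreement between region sets: coverage
(intersected bases over union bases) and overlap (elements of either set
hitting the other, over total element count). Because the element-wise
variant has no single canonical denominator, the asymmetric per-row form
(fraction of one set's elements hitting the other) is also exposed via the
`reference` argument.

## Hierarchical Contact score

TAD calls are consumed as BED intervals, one ensemble per (Hi-C dataset,
resolution window). The default window set is W = [5, 10, 20, 50]
(directionality-index windows in 10 kb bins); larger windows yield fewer,
larger domains. For an enhancer i and promoter j, the per-dataset score is

    S^(D)_ij = Σ_{w∈W} λ(w) · 1[i and j share a TAD in ensemble (D, w)]

with λ(w) = √(max(W)/w) by default, so the coarsest level has weight 1 and
finer levels — where co-occurrence is more specific — weigh more. The full
score sums over datasets: S = Σ_D S^(D). Under the defaults the per-dataset
maximum is √10+√5+√2.5+1 ≈ 7.98, and with 11 datasets max(S) ≈ 87.8.
Alternative weightings (unit, linear, log10, inverse) are provided; any
affine transform of the weights preserves the ranking of pairs whose
support patterns are nested.

An element belongs to a TAD iff its midpoint lies inside it. The midpoint
rule avoids ambiguity for 2 kb promoters straddling bin-aligned
boundaries; a strict full-containment mode is available
(`rule="containment"`). Scores are stored sparsely: a pair absent from the
table has S = 0. Candidate pairs for testing are those with S strictly
greater than 11, which discards pairs supported in only a small fraction of
the dataset × hierarchy combinations and bounds the number of hypotheses;
an optional midpoint-distance cutoff (e.g. 1 Mb, matching the reach of
cis-eQTL references) can be applied at the same step.

## Activity features and normalization

Activity of a region in a cell type is the maximum signal of a mark's
fold-change track over the region (uncovered bases count as 0). Values are
log2(x+1) transformed and quantile-normalized across cell types within
each chromosome's row block, per mark. The normalization reference is the
mean of column-sorted values — the standard construction — with ties
assigned the average of their target quantiles; within a block all
cell-type columns end up with identical value multisets while the overall
value range is preserved. Enhancer features are DNase + H3K27ac (p = 2);
promoter features add H3K4me3 (q = 3). The production design uses k = 44
cell types.

## Canonical-correlation test

For each candidate pair the k cell types give k joint observations of the
enhancer block X (k×p) and promoter block Y (k×q). Sample canonical
correlations are the singular values of the whitened cross-covariance
Σxx^{-1/2} Σxy Σyy^{-1/2}; whitening uses symmetric inverse square roots
with an eigenvalue floor of 1e-12, and singular values are clipped to
[0, 1] (floating point can exceed 1 by ~1e-15). Independence of X and Y
(all population canonical correlations zero) is tested via Wilks'
Λ = Π(1−r_l²), transformed by Rao's F-approximation:

    s = √((p²q²−4)/(p²+q²−5))  (s = 1 when pq ≤ 2),
    m = k − (p+q+3)/2,  df1 = pq,  df2 = m·s − pq/2 + 1,
    F = ((1−Λ^{1/s})/Λ^{1/s}) · df2/df1,

with the p-value from the upper F tail. The approximation is exact under
normality when min(p, q) ≤ 2, which covers both the production case
(p=2, q=3: s=2, df1=6, df2=2k−10) and the p=q=1 case, where the procedure
reduces algebraically to the classical two-sided Pearson correlation
F-test — the suite checks this identity to 1e-10 and null calibration at
k=44 empirically. The sample-size convention (m uses the number of
observations k) is fixed by that reduction. Pairs with a constant feature
column are degenerate: they are reported with p-value 1 and a flag rather
than dropped, a deliberately conservative choice.

## FDR control with side information

Three corrections are provided: Bonferroni, Benjamini–Hochberg (both via
statsmodels, verified against enumeration oracles), and an adaptive
p-value thresholding procedure that uses the HC score s_ij as a covariate,
run independently per chromosome (chromosomes with fewer than 50
hypotheses fall back to BH with a warning).

The adaptive procedure follows the masking argument: each p-value is
initially known to the fitting model only through min(p, 1−p), so the
model can learn where small p-values concentrate in covariate space
without knowing which tail any masked p-value is in. With a per-hypothesis
threshold s_t(x) (initialized to the constant min(45th percentile of p,
0.45)), the false discovery proportion is estimated by the mirror
statistic

    fdp̂ = (1 + #{p_i ≥ 1 − s_t(x_i)}) / max(1, #{p_i ≤ s_t(x_i)})

and hypotheses are "peeled" (their p-values revealed and their threshold
dropped to zero) until fdp̂ ≤ α. Because the peeling decision uses masked
information only, the procedure controls FDR in finite samples regardless
of model quality; the model affects only power, and with uninformative
side scores behaviour approaches BH.

The working model is a logistic-Gamma two-groups family: non-null
probability π(x) by logistic regression on a natural cubic spline basis of
the side score, and the non-null transform y = −log p by a Gamma GLM with
log link and a global (intercept-only) mean, fitted jointly by EM over the
masked labels (tolerance 1e-6 on the relative log-likelihood, 50
iterations maximum, multi-started from a moderate and a strong
signal-mean initialization). Five candidate bases with spline df ∈
{2,…,6} are compared by BIC at the first fit. Refits happen after every
5% of initially-masked hypotheses has been revealed, and a refit replaces
the incumbent model only when it explains the current masked data better
— late-path fitting, on a small signal-pure masked remainder, is
ill-posed, and gating refits on the likelihood keeps a sound early model
in charge when a refit degenerates. Peeling removes the masked hypothesis
with the highest estimated local fdr at its masked value, in batches of
⌈1% of remaining⌉, switching to one-at-a-time near the stopping boundary
so a batch cannot overshoot the first admissible state (an exact
one-at-a-time mode exists for tests). The GLM fits are small
self-contained IRLS routines: the loop refits the model many times per
chromosome, and a ridge-stabilized few-column solve is the right tool at
that granularity.

The masked likelihood deserves care: because masking hides which tail a
p-value is in, it admits degenerate modes that plain maximum likelihood
cannot reject — a "signal at p ≈ 1" component (the mirror image of real
signal), a narrow spike on the few most extreme p-values with the mixture
weight collapsing to zero, and an "everything non-null" fixpoint in which
every posterior saturates regardless of the densities. The fitting
routines therefore constrain the alternative to be one-sided and
identifiable: the Gamma mean is floored at twice the null mean of
−log p, the shape is confined to [1, 2] (below 1 the density spikes at
p ≈ 1, well above it the component can spike on extremes), the mean is
global rather than covariate-dependent (a spline mean lets
sparsely-populated covariate regions drag the fitted mean to its floor
and veto overwhelming per-hypothesis evidence there), EM posterior labels
are capped at 0.95, and a mixture weight that still collapses is
restarted. Each constraint was added against an observed failure mode in
simulation; none of them affects the FDR guarantee, which rests on the
masking argument alone.

Ties in peeling are broken deterministically by (min(p, 1−p), side score,
index) — masked quantities only. This matters: breaking ties on the raw
p-value leaks which tail a masked hypothesis is in whenever the estimated
local fdr saturates, and in simulation that leak visibly inflated the
realized FDR; with masked-only tie-breaks the mirror guarantee holds.

Adjusted values are defined over an α grid (0.01–0.30 in steps of 0.01):
a hypothesis's adjusted value is the smallest grid α at which it is
rejected. A single peeling path serves the whole grid — the candidate
rejection set only shrinks as peeling proceeds, so rejection sets are
nested and adjusted values monotone by construction.

## Benchmarking

Predicted pairs are annotated against four reference kinds. eQTL: a pair
is supported iff at least one SNP falls inside the enhancer interval and
is associated with a gene of the promoter; redundant SNPs (same enhancer,
same gene, or the same eQTL across tissues) count once. Capture Hi-C: the
promoter must overlap (≥1 bp) the bait fragment and the enhancer the other
end, or vice versa; pairs sharing one interaction are all retained.
CRISPR screens: study-specific filters produce candidate/validated flags —
for the FlowFISH-style table, non-promoter elements with adjusted p < 0.05
and ≥0.8 power to detect a 25% effect; for the at-scale gRNA screen,
DHS-associated gRNAs passing the top-two quality filter with a present
adjusted empirical p-value, validated at ≤ 0.1. Curated benchmark lists
are treated as generic labelled pairs (flag = 1 is true), with truths
counted only inside the candidate universe.

Performance uses the counts Z (candidates), V (truths among candidates),
z (predictions), v (true predictions): precision v/z, recall v/V, F1, and
relative improvement RI = (v/z)/(V/Z), the precision over the base rate
(1 = random). Precision-recall curves evaluate every cutoff of a ranked
candidate list (ascending distance or p-value, descending score or
correlation); ties keep the caller's stable order, which is documented
because precision at a cutoff depends on it. A fold-enrichment utility
compares the validated fraction among TAD-based candidates against a
fixed-distance-window candidate set on the same universe. External tools'
pair lists are harmonized before comparison: exon subtraction with pair
duplication per fragment, and removal of pairs with enhancer-midpoint to
TSS distance under 3 kb.

## Synthetic data

The generator emulates the statistical structure the method assumes, at
toy scale, and is first-class tested code. TAD hierarchies: a shared
finest-level boundary template per chromosome (Gamma-distributed domain
sizes, mean 183 kb), jittered ±20 kb per dataset; coarser levels keep a
random subset of the finer level's boundaries sized so mean domain size
grows toward 525 kb at the coarsest window — within a dataset, coarse
boundaries are an exact subset of fine ones. Mean TAD sizes per level
(183/250/350/525 kb) follow the range reported for directionality-index
callers on 10 kb-binned data. Activity: signals are drawn on the
log2(x+1) scale as Gaussians (mean 3, sd 1, floored at 0) and
inverse-mapped to raw enrichments, so the transform and normalization are
exercised nontrivially; each promoter in a true pair gets a latent
k-vector factor, and both it and all its truly-paired enhancers load on it
with √ρ (population first canonical correlation ρ, default 0.9) on their
first (DNase) feature column. Truth sets place one SNP uniformly inside
each true enhancer and one bait/other-end interaction per true pair.
Study-scale defaults (k = 44 cell types, 11 datasets, W = [5,10,20,50])
match the production design; the toy genome is 2 chromosomes × 10 Mb with
500 enhancers and 60 promoters, a 10% planted-pair fraction, small enough
for second-scale runs.

A separate two-groups generator drives the multiple-testing simulations:
N hypotheses, 10% non-null with Beta(0.1, 1) p-values, and HC-scale side
scores (null Beta(2,5)·88 vs non-null Beta(5,2)·88 — predictive but
overlapping, as the contact score is for real pairs).

What the generator does not emulate: correlated peaks across cell types,
sequence composition, distance-dependent contact decay within TADs,
confounding between activity and proximity, and gene-density variation.
Passing tests therefore demonstrate correctness of the machinery and its
statistical guarantees under the assumed model, not performance on real
epigenomes.

## Problem sizes in the test suite

The suite runs the pair test's null calibration at 5,000 pairs × k = 44,
the Pearson-reduction identity at 1,000 random instances, the
multiple-testing simulation at 200 replicates of N = 2,000 hypotheses
(the permuted-side-score convergence check on 100 of them), and the
brute-force BH/Bonferroni oracle at 1,000 vectors of size ≤ 12. These
sizes give Monte-Carlo standard errors a factor of a few below the margins
being asserted.

## Known limitations

- The CCA test assumes joint normality of the (transformed, normalized)
  features; heavy-tailed real tracks may mis-calibrate it.
- The adaptive procedure's power depends on the spline working model;
  severely multimodal side-score relationships would need a richer basis.
- TAD calls are consumed as given; no attempt is made to propagate caller
  uncertainty into the score.
- Gene-symbol matching in benchmarking is exact (case-insensitive);
  aliases are out of scope.
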