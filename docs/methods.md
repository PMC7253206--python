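# Methods

## The question the pipeline answers

When a wild and a cultivated accession diverge in gene expression, the
change can be *cis*-acting (a variant linked to the gene itself, shifting
only its own allele) or *trans*-acting (a change in diffusible regulators
affecting both alleles). In an F1 hybrid both parental alleles share one
cellular environment, so:

* allelic imbalance **within the hybrid** indicates *cis* divergence, and
* a **difference between the parental expression ratio and the hybrid
  allelic ratio** (an allele x generation interaction) indicates *trans*
  divergence.

The pipeline takes allele-resolved read counts for the two parents (F0) and
the hybrid (F1), runs three nested negative-binomial GLM likelihood-ratio
tests per gene, and sorts genes into seven categories: conserved, cis-only,
trans-only, cis+trans (concordant), cis-by-trans (opposing), compensatory
(cis and trans cancel so the parents express equally), and an ambiguous
catch-all for significance patterns with no regulatory interpretation.

## Statistical model

Counts are NB2: `Var(Y) = mu + phi*mu^2`, log link, library size factors as
fixed offsets (median-of-ratios normalization). The three tests per gene:

| test | data | full model | reduced model |
|---|---|---|---|
| parental | F0 | `~ allele` | `~ 1` |
| cis | F1 | `~ allele` | `~ 1` |
| trans | F0+F1 | `~ allele + generation + allele:generation` | `~ allele + generation` |

The two allele channels of one hybrid library share that library's size
factor (they come from a single sequencing library). Gene-wise dispersion is
estimated under each test's full design by maximizing the Cox-Reid adjusted
profile likelihood (the adjustment `-0.5*log|X'WX|` removes most of the
downward bias of the plain profile MLE at small replicate numbers) and is
held fixed for both nested fits, so the LRT statistic is nonnegative by
construction. Coefficients are fitted by IRLS with step-halving and a
Nelder-Mead polish as fallback; fitted log-likelihoods agree with dense-grid
brute-force maximization to well below 1e-3 (checked in the test suite).

**Reference distribution.** With dispersion estimated per gene from three
replicates, referring the LRT directly to chi-squared is anti-conservative
(~12% rejections at nominal 5% in our null simulations). The default
p-value therefore uses a quasi-likelihood F reference: `(LRT/df) / s2`
against `F(df, n-p)`, where `s2` is the full model's residual deviance per
residual degree of freedom. This absorbs dispersion-estimation noise gene
by gene, needs no information sharing across genes, and restores
calibration (4-6% empirical type-I error at nominal 5%). The asymptotic
chi-squared p-value remains available (`p_method="chisq"`). Deliberately
out of scope: empirical-Bayes dispersion shrinkage, Cook's distance
filtering, and independent filtering as done by dedicated DE packages.

**Multiple testing.** Benjamini-Hochberg step-up within each test family
(parental, cis, trans) separately, at FDR 5% by default. p-values are
floored at 1e-300; all-zero genes return p = 1 with a degenerate flag.

**Effect decomposition.** The cis component is the hybrid allelic log2
ratio; the trans component is the parental log2 ratio minus the hybrid
ratio, so `cis + trans = parental log2FC` holds exactly. Components are
computed from normalized mean counts with a pseudocount of 0.5 per cell
(configurable) to keep silenced alleles finite. The cis percentage
`100*|cis|/(|cis|+|trans|)` is undefined (not zero) when both components
vanish.

**Category decision table.** With P/H/T the FDR-significance of the
parental/cis/trans tests: conserved = none; cis-only = P,H; trans-only =
P,T; cis+trans / cis-by-trans = P,H,T with equal / opposite component
signs; compensatory = H,T without P; everything else ambiguous. A zero
component where a sign is needed falls to ambiguous (logged).

## Allele-specific count extraction

SNPs come from aligning the same F1 libraries to two parental
pseudoreferences. A site is usable when it is biallelic, heterozygous in
both alignment views, *reciprocal* (the ordered genotype in one view is the
reversal of the other, e.g. A/G vs G/A — each pseudoreference carries its
own parent's allele as REF), with QUAL > 30 and DP > 20, both strict, and
optionally present in every replicate's call set. Per-allele depths must
mirror between views; the default demands exact equality, and a relative
tolerance mode (default 10%, measured against the larger depth) is provided
because alignments to two different references rarely give identical depths.
Surviving depths are summed over SNPs of the same gene model; the C-view
orientation is canonical (REF depth = cultivated allele, ALT = wild).
Multi-gene SNPs go to the gene with the longest overlapping interval, ties
broken lexicographically. Genes with no surviving SNP are absent, not
zero-filled. BED intervals are treated as 0-based half-open, GFF3 as
1-based inclusive; VCF positions are 1-based.

## Synthetic data generator

The generator emulates the study design: three replicates per genotype,
NB2 counts with dispersion `phi` (default 0.05, a typical within-genotype
biological dispersion for plant RNA-seq; the real data's dispersion is not
published), baseline log2 mean 8 (~256 counts), and per-library size
factors. For a gene with cis effect `c` and trans effect `t` (log2):

    F0 wild        mu = s * 2^(m0 + (c+t)/2)
    F0 cultivated  mu = s * 2^(m0 - (c+t)/2)
    F1 wild allele        mu = s * 2^(m0 - 1 + c/2 + k_t*t/4)
    F1 cultivated allele  mu = s * 2^(m0 - 1 - c/2 + k_t*t/4)

so the expected parental log2 ratio is `c + t` and the hybrid allelic ratio
is `c`. `k_t` (`trans_dominance`, default 0 = additive on the log scale)
shifts the hybrid's shared trans environment toward one parent; it is a
parameter because dominance is something the analysis measures, not
assumes. Under this model a pure cis effect leaves the hybrid total exactly
at the arithmetic midparent (degree of dominance k = 0), reproducing the
expectation that cis-regulated genes inherit additively.

Per-category effects (sign random per gene): conserved (0,0); cis-only
(±c,0); trans-only (0,±t); cis+trans (±c,±t) concordant; compensatory
(±c,∓c) — exact cancellation is the *definition* of this category;
cis-by-trans (±c,∓2t) — opposing signs must differ in magnitude or the pair
would be compensatory, and doubling the trans magnitude keeps the parental
difference (|c+t| = |c|) and the interaction both well detectable. The
category mix defaults to the proportions of the study's classified genes
(~70% conserved, 27% trans-only, 1.4% cis-only, <1% each for the
interaction classes); counts per category are apportioned exactly
(largest remainder) and shuffled. One master seed spawns per-gene
substreams, so draws are independent of gene order and fixed seeds give
bit-identical tables.

The SNP-pair generator emits reciprocal heterozygous records with mirrored
depths (QUAL in 35-95, per-allele depths 11-30 so DP >= 22), and corrupts a
configurable fraction with exactly one violation each (non-reciprocal,
homozygous, QUAL <= 30, or DP <= 20) to exercise the filter. The fruit
generator draws lognormal multiplicative noise with unit mean around
genotype trait means, with the hybrid at `midparent + k*a`; defaults are
realistic 40-days-post-anthesis dimensions for an elongate cultivated
pepper (~85 x 16 mm) and a small round wild one (~11 x 9 mm).

What the simulations do **not** model: read-mapping bias between
pseudoreferences, positional SNP coverage structure within genes,
gene-specific dispersion variation, correlated counts between alleles of a
library beyond the shared size factor, and GO/annotation structure. Passing
recovery tests therefore demonstrates the statistical machinery under the
assumed generative model, not robustness to alignment artifacts.

## Dominance of expression and morphometrics

For per-genotype medians W, C, F1 of a trait or of normalized expression:
`a = (W-C)/2`, `d = F1 - (W+C)/2`, `k = d/a`. k is computed only where
|a| >= 1e-9 (undefined otherwise, so no infinities); the inheritance bins
are additive on the open interval (-0.25, 0.25), C-partially-recessive on
[0.25, 1.25], C-partially-dominant on [-1.25, -0.25] (closed ends on the
dominance side since the additivity interval is printed open), and
transgressive strictly beyond |1.25|. For expression, k is reported for
parental DEGs only.

Fruit descriptors follow ImageJ: AR = MaA/MiA, Ro = 4A/(pi*MaA^2),
Ci = 4*pi*A/perimeter^2; all equal 1 for a circle. A printed variant of the
circularity formula with AR in the numerator is kept behind a
`literal_circularity` flag for audit; it is dimensionally inconsistent and
treated as a typo for the standard descriptor. Size traits and AR are
log10-transformed; the bounded ratios Ro and Ci are arcsine-square-root
transformed with values clipped to [0,1] under a warning (measurement noise
can push a near-circular fruit slightly above 1). PCA runs on the
correlation matrix (traits mix units after transformation); each component
is oriented so its largest-magnitude loading is positive, making score
signs reproducible; constant columns are dropped with a warning.

## Network statistics

The coexpression graph is consumed as a mutual-information edge list with a
TF flag per node (inference itself is out of scope). "Closest neighbors"
are direct first neighbors (induced subgraph, optionally thresholded on
MI). Betweenness uses unweighted shortest paths by default — the MI weight
expresses coexpression strength, not path cost — normalized per connected
component by (n-1)(n-2)/2; a weighted option with length 1/MI is exposed.
TF enrichment of a neighborhood is the one-sided hypergeometric upper tail
against the whole-network background.

## Numerical choices and problem sizes

* IRLS convergence: relative log-likelihood change < 1e-10, max 60
  iterations, step-halving; linear predictor clipped to ±30.
* Dispersion search: bounded maximization over log(phi) in [log 1e-6,
  log 10], tolerance 5e-3; method-of-moments fallback on failure.
* Size factors require at least one gene positive in all samples and error
  with advice to relax filtering otherwise.
* Low-expression rule: a gene is kept when its median raw count is >= 5 in
  *at least one* genotype (preserving genes silenced in one parent — the
  biologically interesting allele-specific cases); a strict all-genotype
  rule is available via `rule="all"`. A median equal to the threshold
  passes.
* Simulation sizes used by the test suite and the acceptance script —
  chosen as the smallest sizes at which the Monte-Carlo checks are stable:
  3,000 genes (500 per category) for classifier recovery, 2,000 null genes
  for type-I calibration, 500 genes for inheritance recovery, 20 fruits
  per genotype for trait dominance, 50 random graphs (<= 8 nodes) for the
  betweenness oracle.

## Known limitations

* No empirical-Bayes moderation: per-gene dispersion is noisier than what
  shrinkage-based DE tools report; the QL-F reference compensates for
  calibration but power at n = 3 is below what moderated tests achieve.
* Depth "reciprocity" between alignment views is implemented both as exact
  equality and as a relative tolerance because the original criterion's
  strictness is underdetermined; results on real data can differ between
  modes (both are tested).
* The percentage printed for the divergent fraction of ASE transcripts in
  the source study (31% of 5,077) does not equal 1,007/5,077 (19.8%); the
  package reports raw counts and leaves derived percentages to the caller.
* Betweenness on graphs with multiple equal-length paths follows the
  standard fractional-count definition; figures produced with other tools
  may use different normalizations.
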