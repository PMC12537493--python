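# Methods

This note documents the models implemented in `epivar`, the defaults
they ship with, and the reasoning behind the design choices that were
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Site calling and gene states (`epivar.methylome`)

Each cytosine is called from its methylated/total read counts against a
per-sample error rate (in real data, the apparent methylation of the
unmethylated chloroplast genome — i.e. the bisulfite non-conversion
rate; synthetic runs pass the known simulation rate; default 0.005).

**Coverage sufficiency.** A site is informative only if its depth could,
in principle, distinguish a fully unmethylated site with error rate *e*
from a fully methylated site with the symmetric error 1−*e*.  We
implement this as a Fisher's exact test on the 2×2 table of rounded
expected methylated/unmethylated read counts under the two models at
the observed depth (two-sided).  For small *e* this reduces to the table
[[0, n], [n, 0]], whose two-sided p is 2/C(2n, n): depths below 4 are
never informative at alpha = 0.05.  Among the constructions consistent
with a "Fisher's exact test for sufficient coverage" description, this
one is the only one we found that makes a depth-2 site uninformative
while keeping depth-10 sites informative, which matches how the rest of
the calling rules behave; it is isolated in `min_sufficient_coverage`
and easy to swap.

**Status.** At sufficient coverage, a one-sided binomial test of the
methylated read count against *e* decides significance (default site
alpha 0.05, configurable — the upstream convention does not pin it
down).  Significant sites with methylated-read fraction ≥ 0.45 are
`methylated`; significant sites below 0.45 are `partial` and treated as
missing data everywhere downstream; non-significant sites are
`unmethylated`.  Raising alpha can only move calls toward
methylated/partial (tail tests are monotone), a property the suite
checks.

**Segmentation.** Runs of `methylated` sites separated by at most
`max_gap` bp (default 200, configurable) form segments; a segment
containing any methylated non-CG site is teM-like, otherwise gbM-like.
The published segmentation this emulates is a separate algorithm whose
details live in other work; gap-merging preserves the downstream
classification rules exactly, which is what matters here, and the
segmentation policy is an interchangeable preprocessing step behind
`segment_gene`.

**Classification.** Applied in order per gene-accession pair:

1. gbM: a gbM-like segment spanning ≥ 3 CG sites with ≥ 1 CG called
   methylated — demoted to `both` when a teM segment at least 25% of the
   gbM segment's length (bp, not CG count; the convention is ambiguous
   and bp is assumed) also overlaps the gene;
2. teM: a teM-like segment spanning ≥ 3 CG sites — symmetrically demoted
   to `both`;
3. UM: no segments and ≥ 3 sites called unmethylated;
4. otherwise `indeterminate`.

`both` and `indeterminate` genes are carried in the state matrix but
excluded from association analyses.  Mean mCG is methylated CG sites
over (methylated + unmethylated) CG sites; partial and insufficient
sites enter neither numerator nor denominator, and a gene with no
called CG site gets a missing value, not zero.

Coordinates are 0-based half-open internally; allc tables (1-based) and
GFF3 (1-based closed) are converted at the I/O boundary.

## Epimutation simulator (`epivar.simulate`)

Per gene, each of `n_sites` CG sites evolves per generation:
an unmethylated site gains methylation with probability
`gain_base + gain_coop * m/n_sites` (clamped to [0, 1], `m` = currently
methylated sites in the gene), a methylated site loses it with
probability `loss_rate`.  The cooperative term is the essential
ingredient: with `gain_base` small the unmethylated state is metastable,
while the reinforced state fluctuates around occupancy
`1 − loss_rate/gain_coop`, so independent lineages settle into a bimodal
population distribution of gene methylation — the qualitative signature
of natural gbM variation.  Defaults (`n_sites=10, gain_base=5e-4,
gain_coop=0.25, loss_rate=0.10`) were chosen once to sit in this
bistable regime with the high mode near 0.6, a realistic within-gene
mCG level for methylated epialleles; they are not fitted to any dataset.
The exact parameterization of the published epimutation model this
stands in for is not recoverable from the source analysis, so a
configurable cooperative model is used instead (see limitations).

For small systems the chain is exactly solvable:
`epimutation_transition_matrix` enumerates all 2^n site configurations
and `epimutation_stationary_distribution` extracts the stationary
vector, giving an oracle against which the Monte-Carlo simulator is
validated (total-variation distance < 0.02 at 5,000 lineages for a
3-site gene).

## Read counts, genotypes, expression, traits

* **Reads**: depth is Poisson (`mean_depth`, default 30); a read from an
  unmethylated cytosine is methylated with probability
  `nonconversion_rate`, from a methylated cytosine unmethylated with
  probability `overconversion_rate` (defaults 0.005 each — typical
  bisulfite error magnitudes).
* **Genotypes**: haploid 0/1 coding by default, mirroring essentially
  homozygous inbred accessions (diploid dosage available at the VCF
  reader).  Subpopulation allele frequencies follow a Balding–Nichols
  Beta model with divergence parameter F; within blocks of
  `ld_block_size` markers, each marker copies its left neighbour with
  probability `ld_rho`, so LD decays geometrically with distance and
  vanishes at block boundaries.
* **Expression**: for a simulated gene, sparse causal effects are drawn
  per marker group and each group's linear predictor is rescaled so its
  in-sample variance hits the target fraction exactly; residual noise
  makes the fractions sum to one.  Realized fractions (recorded in the
  truth object) differ from targets only through between-group sample
  covariance, which shrinks as 1/sqrt(n).
* **Traits**: causal epiallele effects at a target variance fraction,
  an optional dense polygenic SNP background, an optional
  per-subpopulation mean shift (stratification), and unit residual
  noise.

What the generators do **not** emulate: linkage between a gene's
epiallele and genuinely causal nearby SNPs arising from shared
demography (the confound panel imposes it explicitly instead),
recombination/selection, sequence context effects on epimutation rates,
count-distributed expression (expression is Gaussian on a log-like
scale), and missing-data patterns of real bisulfite libraries.  Passing
tests therefore demonstrate statistical correctness of the machinery
under the assumed generative structure, not robustness to every
pathology of real data.

## Grouped variance partition (`epivar.variance`)

Per gene, `y = X_gbm b_gbm + X_tem b_tem + X_snp b_snp + e` with every
coefficient drawn from its group's mixture of a point mass at zero and
normal slabs with variances {1e-4, 1e-3, 1e-2} × the group's effect
variance (BayesR-style; the external software this mirrors does not
print its constants, so the conventional ones are used and are
configurable).  Group effect variances and the residual variance carry
scaled inverse-chi-squared priors (nu = 4, scale set from Var(y));
mixture proportions carry a spike-weighted Dirichlet prior (spike weight
95, the remaining 5 split across slabs).  The spike weighting encodes
the expectation that the vast majority of markers have no effect on any
one gene; with a flat prior the near-zero slabs are likelihood-neutral
for null markers and can absorb several percent of variance spuriously
at desk scale (n of a few hundred), which the weighted prior prevents
while leaving genuine effects untouched — the suite checks both null
calibration (each null group < 5% attributed variance, spike occupancy
≥ 90%) and recovery of simulated fractions.

Sampling is single-site Gibbs over all marker effects, memberships,
variances and proportions (numba-compiled inner loop with a pure-Python
fallback; fixed seed ⇒ identical chains).  Defaults: 7,000 iterations,
2,000 burn-in, 5,000 kept samples.  Per kept sample the variance shares
are `Var(X_g b_g)` and `Var(e)` normalized by their sum, so the
reported fractions form an exact decomposition adding to one; without
the normalization the cross-covariance between sampled predictors and
residuals adds a few percent of per-sample slack at these sample sizes.
Columns are standardized (constant columns dropped and recorded);
missing marker values are mean-imputed before standardization.

Conjugate special cases can be pinned (`update_pi`, `update_group_var`,
`update_resid_var` flags) — used to verify the sampler against the
closed-form ridge posterior mean.  `convergence_filter` retains a gene
when between-run PVE discrepancy and within-chain split-half drift stay
below thresholds (default 0.1 each); with a single chain the split-half
diagnostic decides and is flagged as such.

Recommended marker filters mirror the population analysis: genes
expressed in ≥ 50% of accessions; gbM/teM genes methylated in > 20% of
accessions for partitioning (> 10% for eQTL mapping); SNPs at ≥ 15%
frequency.

## eQTL mapping (`epivar.eqtl`)

Per gene, Pearson R between mCG and expression with the t-distribution
p-value; slope on original scales `beta = R sigma_P/sigma_mCG`; and
`PVE = 100 beta^2 V_mCG / V_P`, which is algebraically `100 R^2` — the
identity is asserted to 1e-12 for every record.  Missing pairs are
dropped listwise.  Tiers: Bonferroni at `0.05/m` (m = eligible genes per
context, computed not hard-coded), then Benjamini–Hochberg at 0.05 and
0.10; the sign class (+eQTL/−eQTL) follows sign(R) for tiered records.

## Genetic-confound accounting (`epivar.confound`)

A single window convention — gene span ± 4 kb — is used for cis scans,
haplogroups and SV accounting (stated for haplotypes/SVs upstream,
unified here for coherence), and a single smallest-analysable-group
size `min_n = 15` applies to haplogroups (where it is stated: groups of
fewer than 15 accessions are discarded), nested populations and
SV-invariant subpopulations (where it is our reuse of the same policy).

The per-gene verdict: a Bonferroni cis scan of window SNPs against the
phenotype; if no SNP colocalizes the association cannot be locally
genetic and the gene is `retained`.  Otherwise the methylation
association is re-tested within the two nested populations fixed for
the top SNP; `retained` iff significant in ≥ 1 valid nested population,
`lost` if testable but nowhere significant, `untestable` if no nested
population has enough accessions and mCG variance.  `untestable` is
reported as its own class, with `collapse_untestable=True` folding it
into `lost` for strict two-class replication.  Nested-population alpha
defaults to 0.05 and can be set to the gene's original tier threshold.

LD between a binary epiallele and a SNP: r is the indicator
correlation, D = p_AB − p_A p_B, D′ = D/D_max with the sign-dependent
D_max, p from the chi-square of n r².  Trans-PVE: genome-wide
Bonferroni scan against the focal gene's mCG, joint OLS fit of the
significant SNPs, percent = model SS / total SS; `subsample` re-runs
the estimate on a subset of accessions, exposing the Beavis effect
(conditioning on significance inflates variance-explained estimates in
small samples).

## epiGWA (`epivar.epigwa`)

Markers are binary epialleles (gbM = 1 / UM = 0, or teM = 1 / UM = 0;
`both`/`indeterminate` are missing) filtered at MAF ≥ 5% and methylated
class carried by > 10% of called accessions.  Quantitative-mCG scans
are supported but linear-model epiGWA on structured traits is exactly
the case the lambda diagnostics flag as confounded.

* LM: marker-only regression.  GLM: adds Q, the leading principal
  components of the (mean-imputed, centred) epiallelic state matrix —
  default 3 components, configurable; the appropriate number is
  population-dependent and no canonical value exists.
* MLM: `Y = Xb + Qa + u + e`, `u ~ N(0, sigma_u^2 K)`, K = pairwise
  fraction of identically-stated markers among mutually observed ones
  (diagonal 1; negative eigenvalues clipped at 0 and counted).  Variance
  components are estimated once by REML under the null model — a
  bounded scalar optimization over log(sigma_e^2/sigma_u^2) in the
  eigenbasis of K — and reused for every marker, which is the
  EMMAX/P3D convention: orders of magnitude faster than per-marker
  REML, and exactly equal to OLS when K = I (asserted in the suite).
  Each marker is then tested by GLS after whitening.

Genomic control: p-values → 1-df chi-square quantiles;
`lambda = median(observed)/median(null)` (null median 0.4549).  All
tested markers enter the median by default with an optional thinning
stride — the appropriate "unlinked" subset is data-dependent and the
median is insensitive to moderate local correlation.  Correction
divides each chi-square by lambda; lambdas below 1 are applied as
computed by default, with `apply_if_deflated=False` restricting
correction to inflation only (the upstream convention corrected
inflated statistics and is silent about deflation).  Significance is
Benjamini–Hochberg FDR (default 0.05) on corrected p-values.

## Perturbation contrasts (`epivar.perturb`)

Methylation-change classes use the stated thresholds: eligible genes
have wild-type mCG > 10%; `demethylated` requires additionally a loss
> 5% and mutant mCG < 5%; genes gaining mCHG or mCHH above 1% are
`excluded_noncg`; eligible genes that are neither are `kept` (the
"keeps methylation" class has no printed threshold; loss ≤ 5% is the
documented, configurable complement).  Genes with promoter mCG > 5% in
the strand-aware −100..+250 bp TSS window are excluded from expression
contrasts; genes with no CG site in the window are kept and flagged
(missing-window handling is unstated upstream).  Interreplicate CV is
sample sd/mean, computed only when every replicate has detected
expression.  eQTL-class contrasts use Welch's two-sided t-test by
default (pooled-variance optional; the upstream variant is unstated).
Differential-expression log2 fold changes are inputs; no shrinkage
estimation is re-implemented.

## Numerical conventions

* One integer seed per entry point; child streams derived
  deterministically (`numpy` Generator seeding); identical seeds give
  bit-identical outputs.
* Degenerate inputs are flagged, not silently zeroed: zero-variance
  vectors give undefined (NaN) records, genes with no called CG sites
  get missing mCG, monomorphic markers are excluded.
* Collinear covariate columns are dropped by QR with a relative 1e-10
  pivot threshold.
* BH/FDR and multiple-testing corrections delegate to
  `statsmodels.stats.multitest`.

## Problem sizes

The test suite and acceptance script run the pipeline at desk scale,
chosen to make the statistical claims sharp while keeping runs short:
state calling at 200 genes × 600 accessions (30× depth), variance
partitioning at n = 500 with 1,400 markers and 5,000 kept samples,
epiGWA calibration at n = 600 with 2,000 (null) or 500/300 (structured)
markers over 100 seeds, confound verdicts over 200 genes at n = 600,
LD validated exhaustively over all 2×2 tables with n ≤ 30, and
trans-PVE at n = 625 vs 133 over 50 seeds.  Full-population scale
(hundreds of thousands of SNPs) is supported by the same code paths but
is not exercised in the suite.

## Known limitations

* The cooperative epimutation model is a stand-in with configurable
  rates, not a re-parameterization of the published model it emulates;
  region refinement of "methylatable" sequence (e.g. H2A.Z exclusion)
  is not modelled.
* The Fisher's-exact coverage construction is one defensible reading of
  an ambiguous description; alternatives shift the minimum informative
  depth by 1–2 reads.
* The sampler's mixture constants and Dirichlet weights are
  conventional defaults, not verified equivalents of the external
  software they mirror.
* IBS kinship matrices are generally not PSD; clipping negative
  eigenvalues at zero is standard but slightly biases variance
  components when many eigenvalues are clipped.
* Haplogroup analysis excludes accessions with any missing window
  genotype rather than imputing.
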