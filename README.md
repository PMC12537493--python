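# epivar

Population epigenomics of gene-body DNA methylation.

Plant genomes carry heritable methylation variants — epialleles — that
segregate across natural accessions much like sequence variants.
Gene-body CG methylation (gbM) is the puzzling case: CG-only methylation
inside constitutively expressed genes, stable over thousands of
generations, with long-debated functional consequences.  `epivar`
implements, as a tested and reusable pipeline, the statistical machinery
needed to ask whether natural gbM (and its repressive cousin, TE-like
methylation, teM) affects gene expression and phenotypes:

* **State calling** — per-cytosine binomial tests against the bisulfite
  conversion-error rate, segmentation of methylated runs, and per-gene
  classification into UM / gbM / teM / both / indeterminate with mean
  mCG levels (`epivar.methylome`).
* **Variance partitioning** — a grouped spike-and-slab (BayesR-style)
  Gibbs sampler for `y = X_gbM b_gbM + X_teM b_teM + X_snp b_snp + e`,
  attributing expression variance jointly to gbM, teM and SNP marker
  groups (`epivar.variance`).
* **eQTL mapping** — per-gene regression of expression on the gene's own
  mCG level; `PVE = beta^2 V_mCG / V_P` with `beta = R sigma_P/sigma_mCG`
  (so PVE = 100 R^2), Bonferroni/FDR tiers and +/− eQTL sign classes
  (`epivar.eqtl`).
* **Genetic-confound accounting** — cis-SNP scans, nested populations
  fixed for an associated SNP, SNP-invariant haplogroups, SV-invariant
  subpopulations, epiallele–SNP LD (r, D′) and trans-PVE with
  Beavis-effect diagnostics (`epivar.confound`).
* **epiGWA** — epiallele-trait association under LM, GLM (Q covariates
  from PCA of epiallelic states) and an EMMAX-style MLM
  `Y = Xb + Qa + u + e` with `u ~ N(0, sigma_u^2 K)`, K from
  identity-by-state; genomic-control lambda and FDR (`epivar.epigwa`).
* **Perturbation contrasts** — methylation-change classification in
  methyltransferase mutants (met1-style), promoter filters,
  interreplicate CV and eQTL-class expression shifts (`epivar.perturb`).
* **Synthetic data** — a cooperative epimutation simulator with an
  exactly solvable Markov-chain limit, structured genotypes, bisulfite
  read counts and sparse-effect expression/traits, so the entire
  pipeline is testable without downloads (`epivar.simulate`).

## Worked example

```python
import numpy as np
from epivar import (EpimutationConfig, simulate_epimutation_population,
                    PopulationSimConfig, simulate_genotypes,
                    ExpressionSimTruth, simulate_expression,
                    GroupedVariancePartition)

# 1. steady-state epimutation: bimodal population gbM
levels = simulate_epimutation_population(
    EpimutationConfig(n_generations=30000, n_lineages=740, seed=3))["levels"]
print(f"population gbM levels: {np.mean(levels < 0.2):.0%} low (<0.2), "
      f"{np.mean(levels > 0.4):.0%} high (>0.4)")

# 2. partition one gene's expression variance among gbM/teM/SNP groups
rng = np.random.default_rng(0)
n = 500
G = simulate_genotypes(PopulationSimConfig(n_accessions=n, n_snps=1000,
                                           seed=1))["genotypes"].astype(float)
gbm = ((rng.random((n, 300)) < rng.uniform(0.2, 0.8, 300)).astype(float)
       * rng.uniform(0.3, 0.9, 300))
tem = ((rng.random((n, 100)) < rng.uniform(0.2, 0.8, 100)).astype(float)
       * rng.uniform(0.3, 0.9, 100))
truth = ExpressionSimTruth(target_pve_gbm=0.15, target_pve_tem=0.25,
                           target_pve_snp=0.25, seed=2)
sim = simulate_expression(gbm, tem, G, truth)
res = GroupedVariancePartition(
    sim["expression"], {"gbm": gbm, "tem": tem, "snp": G}).fit(seed=4)
print(res.summary())
```

prints

```
population gbM levels: 53% low (<0.2), 32% high (>0.4)
Grouped spike-and-slab variance partition
  kept posterior samples: 5000
       group  PVE mean    2.5%   97.5%  spike
         gbm    0.1593  0.1197  0.2014  0.941
         tem    0.2684  0.2222  0.3139  0.893
         snp    0.2592  0.2090  0.3094  0.961
    residual    0.3131  0.2725  0.3573
```

The cooperative epimutation process produces the characteristic bimodal
population distribution of gene methylation (most lineages nearly
unmethylated or solidly methylated, few in between), and the sampler
recovers the generative variance fractions (0.15 / 0.25 / 0.25) with the
spike absorbing ~90–96% of the null markers.  The `spike` column is the
posterior fraction of markers assigned zero effect in each group.

A command-line interface mirrors the library
(`epivar simulate | call-states | partition-variance | eqtl | confound |
epigwa | perturb`); every run writes a JSON manifest with its
configuration and seed.

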