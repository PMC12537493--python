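"""Genetic-confound accounting for methylation-phenotype associations.

A methylation-expression (or methylation-trait) association is only
evidence for an epiallelic effect if it survives accounting for linked
genetic variation.  This module implements the battery of checks used
for that decision:

* cis scan for SNPs in the gene window associated with the phenotype;
* nested populations — re-testing the association within subpopulations
  fixed for the top associated SNP;
* haplogroups — accessions identical at every window SNP, within which
  methylation effects are free of local genetic variation;
* SV-invariant subpopulations, removing transposon presence/absence
  polymorphism;
* epiallele-SNP linkage disequilibrium statistics (r, D');
* trans-PVE — percent of a gene's mCG variance explained by unlinked
  genome-wide SNPs, with subsampled re-estimation exposing the Beavis
  effect (small-sample inflation of variance-explained among
  significant hits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Haplogroup",
    "ConfoundVerdict",
    "LDStat",
    "TransPveEstimate",
    "cis_scan",
    "nested_population_test",
    "define_haplogroups",
    "within_haplogroup_association",
    "sv_invariant_test",
    "ld_epiallele_snp",
    "trans_pve",
    "confound_pipeline",
]

DEFAULT_FLANK = 4000  # bp flank for cis windows, haplogroups, SV accounting
DEFAULT_MIN_N = 15  # smallest analysable subpopulation / haplogroup


@dataclass
class Haplogroup:
    gene_id: str
    signature: tuple
    members: np.ndarray  # accession indices
    kept: bool

    @property
    def size(self) -> int:
        return self.members.size


@dataclass
class LDStat:
    r: float
    d: float
    d_prime: float
    p_value: float
    defined: bool = True


@dataclass
class TransPveEstimate:
    gene_id: str
    n: int
    n_significant_snps: int
    percent: float
    flagged_no_hit: bool = False


@dataclass
class ConfoundVerdict:
    gene_id: str
    colocalized_snp: bool
    top_snp: int | None
    nested_results: list = field(default_factory=list)
    final_class: str = "untestable"  # retained / lost / untestable


# ---------------------------------------------------------------------------


def _assoc(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation test (slope sign equals correlation sign)."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cis_scan(
    expr: np.ndarray, genotypes: np.ndarray, alpha_bonf: float = 0.05
) -> pd.DataFrame:
    """Associate a phenotype with every polymorphic SNP in the window.

    Returns a per-SNP table with slope/r/p and a Bonferroni significance
    flag over the scan (alpha / number of polymorphic SNPs)."""
    expr = np.asarray(expr, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    rows = []
    poly = [j for j in range(G.shape[1]) if np.nanstd(G[:, j]) > 0]
    thr = alpha_bonf / max(len(poly), 1)
    for j in range(G.shape[1]):
        if j not in poly:
            rows.append((j, np.nan, np.nan, False, True))
            continue
        r, p = _assoc(G[:, j], expr)
        rows.append((j, r, p, bool(np.isfinite(p) and p < thr), False))
    return pd.DataFrame(
        rows, columns=["snp", "r", "p_value", "significant", "monomorphic"]
    )


def nested_population_test(
    mcg: np.ndarray,
    phenotype: np.ndarray,
    split_snp: np.ndarray,
    alpha: float = 0.05,
    min_n: int = DEFAULT_MIN_N,
) -> dict:
    """Re-test the methylation association within the two subpopulations
    fixed for each allele of the top associated SNP.

    Retained iff the association is significant in at least one valid
    nested population (size >= min_n with mCG variance); untestable when
    no nested population is valid."""
    mcg = np.asarray(mcg, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    snp = np.asarray(split_snp, dtype=float)
    alleles = np.unique(snp[~np.isnan(snp)])
    if alleles.size != 2:
        raise ValueError("split SNP must be biallelic")
    results = []
    any_valid = False
    any_sig = False
    for a in alleles:
        idx = snp == a
        n = int(idx.sum())
        valid = n >= min_n and np.nanstd(mcg[idx]) > 0
        r = p = np.nan
        if valid:
            any_valid = True
            r, p = _assoc(mcg[idx], phenotype[idx])
            if np.isfinite(p) and p < alpha:
                any_sig = True
        results.append(
            {"allele": float(a), "n": n, "valid": valid, "r": r, "p_value": p}
        )
    status = "retained" if any_sig else ("lost" if any_valid else "untestable")
    return {"nested": results, "status": status}


def define_haplogroups(
    genotypes: np.ndarray,
    gene_id: str = "",
    min_size: int = DEFAULT_MIN_N,
) -> list[Haplogroup]:
    """Partition accessions into window-SNP-identical haplogroups.

    ``genotypes`` holds the window SNPs (accessions x SNPs); accessions
    with any missing window genotype are excluded.  Groups smaller than
    ``min_size`` are kept in the list but flagged not analysable."""
    G = np.asarray(genotypes, dtype=float)
    complete = ~np.isnan(G).any(axis=1)
    sig_map: dict[tuple, list[int]] = {}
    for i in np.where(complete)[0]:
        key = tuple(G[i].astype(int))
        sig_map.setdefault(key, []).append(i)
    groups = [
        Haplogroup(
            gene_id=gene_id,
            signature=sig,
            members=np.array(members),
            kept=len(members) >= min_size,
        )
        for sig, members in sig_map.items()
    ]
    groups.sort(key=lambda h: -h.size)
    return groups


def within_haplogroup_association(
    haplogroups: list[Haplogroup],
    meth: np.ndarray,
    phenotype: np.ndarray,
    binary_state: bool = False,
) -> pd.DataFrame:
    """Test the methylation-phenotype association inside each kept
    haplogroup.

    For a binary epiallelic state a two-sided Welch t-test compares the
    phenotype between the two state classes; for quantitative mCG a
    Pearson correlation test is used.  Single-class haplogroups are
    reported untestable."""
    meth = np.asarray(meth, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    rows = []
    for h in haplogroups:
        if not h.kept:
            continue
        m = meth[h.members]
        y = phenotype[h.members]
        ok = ~(np.isnan(m) | np.isnan(y))
        m, y = m[ok], y[ok]
        if binary_state:
            g0, g1 = y[m == 0], y[m == 1]
            if g0.size < 2 or g1.size < 2:
                rows.append((h.signature, h.size, np.nan, np.nan, False))
                continue
            t, p = stats.ttest_ind(g1, g0, equal_var=False)
            rows.append((h.signature, h.size, float(g1.mean() - g0.mean()), float(p), True))
        else:
            if m.size < 3 or m.std() == 0 or y.std() == 0:
                rows.append((h.signature, h.size, np.nan, np.nan, False))
                continue
            r, p = _assoc(m, y)
            rows.append((h.signature, h.size, r, p, True))
    return pd.DataFrame(
        rows, columns=["signature", "n", "effect", "p_value", "testable"]
    )


def sv_invariant_test(
    mcg: np.ndarray,
    phenotype: np.ndarray,
    sv_genotypes: np.ndarray | None,
    alpha: float = 0.05,
    min_n: int = DEFAULT_MIN_N,
) -> dict:
    """Re-test the association in the largest subpopulation invariant for
    every structural variant (TE presence/absence) in the window."""
    mcg = np.asarray(mcg, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    if sv_genotypes is None or np.asarray(sv_genotypes).size == 0:
        r, p = _assoc(mcg, phenotype)
        return {
            "n": mcg.size,
            "r": r,
            "p_value": p,
            "status": "retained" if np.isfinite(p) and p < alpha else "lost",
            "sv_polymorphic": False,
        }
    S = np.asarray(sv_genotypes, dtype=float)
    groups = define_haplogroups(S, min_size=1)
    largest = groups[0]
    idx = largest.members
    if idx.size < min_n or np.nanstd(mcg[idx]) == 0:
        return {
            "n": int(idx.size),
            "r": np.nan,
            "p_value": np.nan,
            "status": "untestable",
            "sv_polymorphic": True,
        }
    r, p = _assoc(mcg[idx], phenotype[idx])
    return {
        "n": int(idx.size),
        "r": r,
        "p_value": p,
        "status": "retained" if np.isfinite(p) and p < alpha else "lost",
        "sv_polymorphic": len(groups) > 1,
    }


def ld_epiallele_snp(epiallele: np.ndarray, snp: np.ndarray) -> LDStat:
    """Linkage disequilibrium between a binary epiallele and a SNP allele.

    r is the Pearson correlation of the indicators, D = p_AB - p_A p_B,
    D' = D / D_max with the standard sign-dependent D_max, and the
    p-value comes from the chi-square of n r^2 (1 df)."""
    a = np.asarray(epiallele, dtype=float)
    b = np.asarray(snp, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size == 0 or len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return LDStat(np.nan, np.nan, np.nan, np.nan, defined=False)
    if not (set(np.unique(a)) <= {0.0, 1.0} and set(np.unique(b)) <= {0.0, 1.0}):
        raise ValueError("both vectors must be binary 0/1")
    n = a.size
    pA = a.mean()
    pB = b.mean()
    pAB = float((a * b).mean())
    D = pAB - pA * pB
    if D >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = D / d_max if d_max > 0 else np.nan
    r = D / np.sqrt(pA * (1 - pA) * pB * (1 - pB))
    p = float(stats.chi2.sf(n * r * r, df=1))
    return LDStat(float(r), float(D), float(d_prime), p)


def trans_pve(
    focal_mcg: np.ndarray,
    genotypes: np.ndarray,
    gene_id: str = "",
    alpha_bonf: float = 0.05,
    subsample: np.ndarray | None = None,
) -> TransPveEstimate:
    """Percent of focal mCG variance explained by trans genetic QTLs.

    Every genome-wide SNP is scanned against the focal gene's mCG;
    Bonferroni-significant SNPs are then fitted jointly and the estimate
    is the ratio of the SNP-marker sum of squares (after fitting the
    intercept) to the total sum of squares.  ``subsample`` restricts the
    analysis to the given accession indices (Beavis-effect runs)."""
    y = np.asarray(focal_mcg, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    if subsample is not None:
        y = y[subsample]
        G = G[subsample]
    if y.std() == 0:
        raise ValueError("focal gene has no mCG variance")
    scan = cis_scan(y, G, alpha_bonf=alpha_bonf)
    hits = scan.index[scan["significant"]].to_numpy()
    if hits.size == 0:
        return TransPveEstimate(gene_id, y.size, 0, 0.0, flagged_no_hit=True)
    X = G[:, hits]
    # drop duplicate/collinear hit columns via QR pivoting on centred X
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    fitted = Xc @ beta
    ss_model = float(fitted @ fitted)
    ss_total = float(yc @ yc)
    return TransPveEstimate(
        gene_id, y.size, int(hits.size), 100.0 * ss_model / ss_total
    )


def confound_pipeline(
    mcg: np.ndarray,
    phenotype: np.ndarray,
    window_genotypes: np.ndarray,
    alpha: float = 0.05,
    min_n: int = DEFAULT_MIN_N,
    gene_id: str = "",
    collapse_untestable: bool = False,
) -> ConfoundVerdict:
    """End-to-end verdict for one gene's methylation association.

    A cis scan looks for window SNPs associated with the phenotype; if
    none is found the association cannot be explained by local genetic
    variation and the gene is retained.  Otherwise the association is
    re-tested within nested populations fixed for the top SNP; the gene
    is retained iff significant in at least one valid nested population.
    ``collapse_untestable`` folds the untestable class into "lost" for
    strict replication of two-class reporting."""
    scan = cis_scan(phenotype, window_genotypes, alpha_bonf=alpha)
    sig = scan[scan["significant"]]
    if sig.empty:
        verdict = ConfoundVerdict(
            gene_id=gene_id, colocalized_snp=False, top_snp=None,
            final_class="retained",
        )
        return verdict
    top = int(sig.sort_values("p_value").iloc[0]["snp"])
    nested = nested_population_test(
        mcg, phenotype, window_genotypes[:, top], alpha=alpha, min_n=min_n
    )
    final = nested["status"]
    if collapse_untestable and final == "untestable":
        final = "lost"
    return ConfoundVerdict(
        gene_id=gene_id,
        colocalized_snp=True,
        top_snp=top,
        nested_results=nested["nested"],
        final_class=final,
    )
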