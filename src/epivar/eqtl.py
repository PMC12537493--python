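"""Per-gene methylation-expression association (eQTL mapping).

For every eligible gene, expression across accessions is regressed on
the gene's own mean mCG level.  The record carries Pearson's R with its
two-sided p-value, the slope on the original scales
``beta = R * sigma_expr / sigma_mcg``, and the percent expression
variance explained ``PVE = beta^2 * V_mcg / V_expr`` (algebraically
identical to ``100 * R^2``).  Significance tiers combine a Bonferroni
threshold with Benjamini-Hochberg FDR levels, and significant genes are
classed +eQTL or -eQTL by the sign of R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationRecord",
    "associate_gene",
    "eligibility_filter",
    "tier_and_classify",
    "stratified_summary",
    "EQTLScan",
]


@dataclass
class AssociationRecord:
    gene_id: str
    context: str  # "gbm" or "tem"
    n: int
    r: float
    p_value: float
    beta: float
    pve: float  # percent
    sign_class: str = "NA"  # "+eQTL" / "-eQTL" / "NA"
    tier: str = "none"  # "bonferroni" / "fdr05" / "fdr10" / "none"
    defined: bool = True


def associate_gene(
    mcg, expr, gene_id: str = "", context: str = "gbm"
) -> AssociationRecord:
    """Correlate one gene's mCG levels with its expression.

    Missing pairs are dropped listwise; with <3 complete pairs or a
    zero-variance vector the record is returned flagged undefined.
    """
    mcg = np.asarray(mcg, dtype=float)
    expr = np.asarray(expr, dtype=float)
    ok = ~(np.isnan(mcg) | np.isnan(expr))
    x, y = mcg[ok], expr[ok]
    n = x.size
    if n < 3 or x.std() == 0 or y.std() == 0 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationRecord(
            gene_id, context, n, np.nan, np.nan, np.nan, np.nan, defined=False
        )
    r, p = stats.pearsonr(x, y)
    beta = r * (y.std() / x.std())
    pve = 100.0 * beta**2 * x.var() / y.var()
    return AssociationRecord(gene_id, context, n, float(r), float(p), float(beta), float(pve))


def eligibility_filter(
    states: pd.DataFrame, context: str = "gbm", min_freq: float = 0.10
) -> list[str]:
    """Genes whose methylated epiallele is carried by more than
    ``min_freq`` of accessions with available calls (default 10% for
    eQTL mapping; the variance partition uses 20%)."""
    eligible = []
    for gid, row in states.iterrows():
        avail = row.isin(["gbm", "tem", "um"])
        n_avail = int(avail.sum())
        if n_avail == 0:
            continue
        f = (row == context).sum() / n_avail
        if f > min_freq:
            eligible.append(gid)
    return eligible


def tier_and_classify(
    records: list[AssociationRecord],
    m_tests: int | None = None,
    alpha_bonf: float = 0.05,
    fdr_levels: tuple[float, ...] = (0.05, 0.10),
) -> list[AssociationRecord]:
    """Assign the strictest passed significance tier and the eQTL sign.

    ``m_tests`` defaults to the number of defined records.  Tiers:
    Bonferroni at ``alpha_bonf / m_tests``, then Benjamini-Hochberg at
    each FDR level in order.
    """
    defined = [r for r in records if r.defined and np.isfinite(r.p_value)]
    if not defined:
        return records
    m = m_tests if m_tests is not None else len(defined)
    bonf_thr = alpha_bonf / m
    pvals = np.array([r.p_value for r in defined])
    bh = {}
    for q in sorted(fdr_levels):
        bh[q] = _bh_reject(pvals, q)
    for i, rec in enumerate(defined):
        if rec.p_value < bonf_thr:
            rec.tier = "bonferroni"
        else:
            rec.tier = "none"
            for q in sorted(fdr_levels):
                if bh[q][i]:
                    rec.tier = f"fdr{int(round(q * 100)):02d}"
                    break
        rec.sign_class = (
            ("+eQTL" if rec.r > 0 else "-eQTL") if rec.tier != "none" else "NA"
        )
    return records


def _bh_reject(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, alpha=q, method="fdr_bh")[0]


def stratified_summary(
    records: list[AssociationRecord],
    covariate: dict[str, float],
    breaks: tuple[float, ...],
    value: str = "pve",
) -> dict:
    """Distribution of an association statistic stratified by a per-gene
    covariate (e.g. expression Shannon entropy).

    Bins are defined by ``breaks``; a Kruskal-Wallis test across bins is
    followed by pairwise two-sided Mann-Whitney tests with Bonferroni
    correction.  Bins with fewer than 2 genes are reported but excluded
    from testing.
    """
    vals = {r.gene_id: getattr(r, value) for r in records if r.defined}
    edges = [-np.inf, *breaks, np.inf]
    bins: list[list[float]] = [[] for _ in range(len(edges) - 1)]
    for gid, v in vals.items():
        if gid not in covariate:
            continue
        c = covariate[gid]
        for i in range(len(edges) - 1):
            if edges[i] <= c < edges[i + 1]:
                bins[i].append(v)
                break
    testable = [i for i, b in enumerate(bins) if len(b) >= 2]
    kw_p = np.nan
    if len(testable) >= 2:
        kw_p = float(stats.kruskal(*[bins[i] for i in testable]).pvalue)
    pairwise = {}
    n_pairs = len(testable) * (len(testable) - 1) // 2
    for a in range(len(testable)):
        for b in range(a + 1, len(testable)):
            i, j = testable[a], testable[b]
            p = float(stats.mannwhitneyu(bins[i], bins[j], alternative="two-sided").pvalue)
            pairwise[(i, j)] = min(1.0, p * max(n_pairs, 1))
    return {
        "bin_sizes": [len(b) for b in bins],
        "bin_means": [float(np.mean(b)) if b else np.nan for b in bins],
        "kruskal_p": kw_p,
        "pairwise_bonferroni_p": pairwise,
        "excluded_bins": [i for i, b in enumerate(bins) if len(b) < 2],
    }


class EQTLScan:
    """Scan all eligible genes for mCG-expression associations.

    Parameters
    ----------
    mcg : DataFrame, genes x accessions mean-mCG levels
    expression : DataFrame, genes x accessions expression
    states : DataFrame, optional genes x accessions state strings used by
        the eligibility filter.
    """

    def __init__(self, mcg: pd.DataFrame, expression: pd.DataFrame, states=None):
        self.mcg = mcg
        self.expression = expression
        self.states = states

    def fit(
        self,
        context: str = "gbm",
        min_freq: float = 0.10,
        alpha_bonf: float = 0.05,
        fdr_levels: tuple[float, ...] = (0.05, 0.10),
    ) -> pd.DataFrame:
        if self.states is not None:
            genes = eligibility_filter(self.states, context, min_freq)
        else:
            genes = [g for g in self.mcg.index if g in self.expression.index]
        common = [c for c in self.mcg.columns if c in self.expression.columns]
        records = []
        for gid in genes:
            if gid not in self.expression.index:
                continue
            records.append(
                associate_gene(
                    self.mcg.loc[gid, common].to_numpy(dtype=float),
                    self.expression.loc[gid, common].to_numpy(dtype=float),
                    gene_id=gid,
                    context=context,
                )
            )
        tier_and_classify(records, alpha_bonf=alpha_bonf, fdr_levels=fdr_levels)
        return pd.DataFrame([r.__dict__ for r in records])
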