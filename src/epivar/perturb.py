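"""Methylation-perturbation contrasts (met1-style mutants vs wild type).

Genes are classified by how a methyltransferase mutant changed their
gene-body CG methylation (demethylated / kept / ineligible, with a
non-CG-gain exclusion), promoter-methylated genes are filtered out of
expression contrasts, interreplicate variability is summarised as the
coefficient of variation, and expression shifts are compared between
eQTL sign classes and across wild-type gbM-level bins.  Differential-
expression log2 fold changes are consumed as input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethChangeCall",
    "VariabilityRecord",
    "classify_meth_change",
    "promoter_filter",
    "interreplicate_cv",
    "eqtl_class_contrast",
    "mcg_binned_response",
]

WT_MCG_MIN = 0.10  # eligible genes are methylated (>10% mCG) in wild type
LOSS_MIN = 0.05  # demethylated genes lose >5% mCG ...
MUT_MCG_MAX = 0.05  # ... and end below 5% mCG in the mutant
NONCG_GAIN_MAX = 0.01  # genes gaining mCHG/mCHH above 1% are excluded


@dataclass
class MethChangeCall:
    gene_id: str
    wt_mcg: float
    mut_mcg: float
    change_class: str  # demethylated / kept / ineligible / excluded_noncg


@dataclass
class VariabilityRecord:
    gene_id: str
    cv_wt: float
    cv_mut: float

    @property
    def log2_cv_change(self) -> float:
        if self.cv_wt > 0 and self.cv_mut > 0:
            return float(np.log2(self.cv_mut / self.cv_wt))
        return float("nan")


def classify_meth_change(
    wt_mcg: float,
    mut_mcg: float,
    mut_mchg: float = 0.0,
    mut_mchh: float = 0.0,
    gene_id: str = "",
    wt_min: float = WT_MCG_MIN,
    loss_min: float = LOSS_MIN,
    mut_max: float = MUT_MCG_MAX,
    noncg_max: float = NONCG_GAIN_MAX,
) -> MethChangeCall:
    """Classify a gene's CG-methylation change in the mutant.

    demethylated: wild-type mCG > 10%, loss > 5% and mutant mCG < 5%;
    kept: eligible (wild-type mCG > 10%) but loss <= 5%;
    ineligible: wild-type mCG <= 10%;
    excluded_noncg: mutant gains mCHG or mCHH above 1%.
    """
    for name, v in (
        ("wt_mcg", wt_mcg), ("mut_mcg", mut_mcg),
        ("mut_mchg", mut_mchg), ("mut_mchh", mut_mchh),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    if mut_mchg > noncg_max or mut_mchh > noncg_max:
        cls = "excluded_noncg"
    elif wt_mcg <= wt_min:
        cls = "ineligible"
    elif (wt_mcg - mut_mcg) > loss_min and mut_mcg < mut_max:
        cls = "demethylated"
    else:
        cls = "kept"
    return MethChangeCall(gene_id, wt_mcg, mut_mcg, cls)


def promoter_filter(
    tss_window_mcg: float | None, threshold: float = 0.05
) -> dict:
    """Exclude genes whose strand-aware TSS window (-100 bp .. +250 bp)
    carries mCG above the threshold; genes with no CG site in the window
    are kept but flagged."""
    if tss_window_mcg is None or (
        isinstance(tss_window_mcg, float) and np.isnan(tss_window_mcg)
    ):
        return {"keep": True, "missing_window": True}
    return {"keep": tss_window_mcg <= threshold, "missing_window": False}


def tss_window_mcg(
    site_calls: pd.DataFrame,
    tss: int,
    strand: str = "+",
    upstream: int = 100,
    downstream: int = 250,
) -> float:
    """Mean mCG over the promoter window around the TSS (strand-aware:
    the window runs from ``-upstream`` to ``+downstream`` in the gene's
    reading direction)."""
    pos = site_calls["pos"].to_numpy()
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
    else:
        lo, hi = tss - downstream, tss + upstream
    w = site_calls[(pos >= lo) & (pos < hi) & (site_calls["context"] == "CG")]
    n_meth = int((w["status"] == "methylated").sum())
    n_unmeth = int((w["status"] == "unmethylated").sum())
    if n_meth + n_unmeth == 0:
        return float("nan")
    return n_meth / (n_meth + n_unmeth)


def interreplicate_cv(
    wt_reps, mut_reps, gene_id: str = ""
) -> VariabilityRecord | None:
    """Coefficient of variation (sample sd / mean) across biological
    replicates, separately for wild type and mutant.

    Returns None (gene skipped) when any replicate has no detected
    expression or a mean is zero."""
    wt = np.asarray(wt_reps, dtype=float)
    mut = np.asarray(mut_reps, dtype=float)
    if wt.size < 2 or mut.size < 2:
        raise ValueError("need >= 2 replicates per genotype")
    if np.any(wt <= 0) or np.any(mut <= 0):
        return None
    cv_wt = wt.std(ddof=1) / wt.mean()
    cv_mut = mut.std(ddof=1) / mut.mean()
    return VariabilityRecord(gene_id, float(cv_wt), float(cv_mut))


def eqtl_class_contrast(
    log2fc: pd.Series | dict,
    classes: pd.Series | dict,
    reference: str = "NA",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Mean log2 fold change per eQTL class with a two-sided two-sample
    t-test of each class against the non-associated reference group
    (Welch by default)."""
    fc = pd.Series(log2fc, dtype=float)
    cl = pd.Series(classes).reindex(fc.index)
    ref = fc[cl == reference].dropna()
    rows = []
    for name, grp in fc.groupby(cl):
        grp = grp.dropna()
        if name == reference:
            rows.append((name, len(grp), float(grp.mean()), np.nan, True))
            continue
        if len(grp) < 2 or len(ref) < 2:
            rows.append((name, len(grp), float(grp.mean()) if len(grp) else np.nan,
                         np.nan, False))
            continue
        t, p = stats.ttest_ind(grp, ref, equal_var=equal_var)
        rows.append((name, len(grp), float(grp.mean()), float(p), True))
    return pd.DataFrame(
        rows, columns=["class", "n", "mean_log2fc", "p_vs_reference", "tested"]
    ).set_index("class")


def mcg_binned_response(
    wt_gbm: np.ndarray,
    log2fc: np.ndarray,
    n_bins: int = 5,
    quantile_bins: bool = False,
) -> dict:
    """Bin genes by wild-type gbM level and correlate per-bin mean log2
    fold change with the bin centres (Pearson).

    Empty bins are dropped; with fewer than 3 populated bins the
    correlation is still computed but flagged low-resolution."""
    x = np.asarray(wt_gbm, dtype=float)
    y = np.asarray(log2fc, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if quantile_bins:
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    else:
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, len(edges) - 2)
    centers, means, sizes = [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum() == 0:
            continue
        centers.append(float(x[sel].mean()))
        means.append(float(y[sel].mean()))
        sizes.append(int(sel.sum()))
    if len(centers) < 2:
        return {"bin_centers": centers, "bin_means": means, "bin_sizes": sizes,
                "r": np.nan, "p_value": np.nan, "low_resolution": True}
    r, p = stats.pearsonr(centers, means)
    return {
        "bin_centers": centers,
        "bin_means": means,
        "bin_sizes": sizes,
        "r": float(r),
        "p_value": float(p),
        "low_resolution": len(centers) < 3,
    }
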