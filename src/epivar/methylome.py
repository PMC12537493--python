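"""Gene epigenetic-state calling from bisulfite read counts.

Workflow per accession: call each cytosine's methylation status from its
methylated/total read counts against the sample's bisulfite-conversion
error rate; merge runs of methylated sites into segments; classify each
gene as UM / gbM / teM / both / indeterminate from the segments
overlapping it; compute the gene's mean CG methylation (mCG); and
summarise state conservation across the population.

gbM (gene-body methylation) is CG-only methylation; teM (transposon-like
methylation) also carries CHG/CHH methylation.  Ambiguous genes ("both",
"indeterminate") are carried in the matrix but excluded from association
analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STATUS_CODES",
    "min_sufficient_coverage",
    "call_site",
    "call_sites",
    "MethSegment",
    "segment_gene",
    "classify_gene",
    "gene_mean_mcg",
    "call_epistate_matrix",
    "conservation_summary",
    "state_count_correlation",
]

# site status codes
INSUFFICIENT = "insufficient"
UNMETHYLATED = "unmethylated"
PARTIAL = "partial"
METHYLATED = "methylated"
STATUS_CODES = (INSUFFICIENT, UNMETHYLATED, PARTIAL, METHYLATED)

PARTIAL_FRACTION = 0.45  # below this methylated-read fraction a significant
# site is only partially methylated and treated as missing data


def min_sufficient_coverage(error_rate: float, alpha: float = 0.05, max_n: int = 1000) -> int:
    """Smallest read depth at which a site is informative.

    Coverage is sufficient when a Fisher's exact test can distinguish the
    expected read profile of a fully unmethylated site (methylated-read
    probability ``error_rate``, the conversion error) from a fully
    methylated site with the symmetric error: the 2x2 table holds the
    rounded expected methylated/unmethylated read counts of the two
    models at depth n, and the two-sided Fisher p must fall below alpha.
    """
    if not (0.0 < error_rate < 0.5):
        raise ValueError("error_rate must be in (0, 0.5)")
    for n in range(1, max_n + 1):
        if _coverage_sufficient(n, error_rate, alpha):
            return n
    raise ValueError("no sufficient coverage found below max_n")


def _coverage_sufficient(n: int, error_rate: float, alpha: float) -> bool:
    m_un = int(round(n * error_rate))
    m_me = int(round(n * (1.0 - error_rate)))
    table = [[m_un, n - m_un], [m_me, n - m_me]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return p < alpha


def call_site(
    reads_meth: int,
    reads_total: int,
    error_rate: float = 0.005,
    alpha: float = 0.05,
) -> str:
    """Call one cytosine's methylation status.

    Returns ``insufficient`` when the coverage cannot distinguish the
    fully-unmethylated and fully-methylated error models; otherwise a
    one-sided binomial test of the methylated read count against the
    error rate decides ``methylated`` (significant, fraction >= 0.45),
    ``partial`` (significant, fraction < 0.45) or ``unmethylated``.
    """
    if reads_meth < 0 or reads_total < 0 or reads_meth > reads_total:
        raise ValueError("require 0 <= reads_meth <= reads_total")
    return call_sites(
        np.array([reads_meth]), np.array([reads_total]), error_rate, alpha
    )[0]


def call_sites(
    reads_meth: np.ndarray,
    reads_total: np.ndarray,
    error_rate: float = 0.005,
    alpha: float = 0.05,
) -> np.ndarray:
    """Vectorized site calling; returns an object array of status strings."""
    meth = np.asarray(reads_meth)
    total = np.asarray(reads_total)
    if np.any(meth > total) or np.any(meth < 0):
        raise ValueError("require 0 <= reads_meth <= reads_total")
    n_min = min_sufficient_coverage(error_rate, alpha)
    status = np.full(meth.shape, INSUFFICIENT, dtype=object)
    ok = total >= n_min
    # upper binomial tail P(X >= meth | total, error_rate)
    p_up = stats.binom.sf(meth[ok] - 1, total[ok], error_rate)
    with np.errstate(invalid="ignore"):
        frac = np.where(total[ok] > 0, meth[ok] / np.maximum(total[ok], 1), 0.0)
    sig = p_up < alpha
    st = np.where(sig & (frac >= PARTIAL_FRACTION), METHYLATED,
                  np.where(sig, PARTIAL, UNMETHYLATED))
    status[ok] = st
    return status


# ---------------------------------------------------------------------------
# Segmentation and gene classification
# ---------------------------------------------------------------------------


@dataclass
class MethSegment:
    """A maximal run of methylated sites (half-open genomic interval)."""

    start: int
    end: int
    seg_class: str  # "gbm" (CG-only) or "tem" (contains non-CG methylation)
    n_cg_sites: int  # CG sites spanned by the interval
    n_cg_methylated: int

    @property
    def length(self) -> int:
        return self.end - self.start


def segment_gene(site_calls: pd.DataFrame, max_gap: int = 200) -> list[MethSegment]:
    """Merge called-methylated sites into segments.

    ``site_calls`` needs columns pos, context, status, sorted by pos.
    Consecutive methylated sites no more than ``max_gap`` bp apart join
    one segment; a segment containing any methylated non-CG site is
    teM-like, otherwise gbM-like.  Segment intervals are half-open,
    extending one bp past the last methylated site.
    """
    pos = site_calls["pos"].to_numpy()
    if np.any(np.diff(pos) < 0):
        raise ValueError("site calls must be sorted by position")
    is_meth = (site_calls["status"] == METHYLATED).to_numpy()
    is_cg = (site_calls["context"] == "CG").to_numpy()
    mpos = pos[is_meth]
    mcg = is_cg[is_meth]
    if mpos.size == 0:
        return []
    breaks = np.where(np.diff(mpos) > max_gap)[0] + 1
    segments = []
    for chunk_idx in np.split(np.arange(mpos.size), breaks):
        start = int(mpos[chunk_idx[0]])
        end = int(mpos[chunk_idx[-1]]) + 1
        span = (pos >= start) & (pos < end)
        n_cg = int((span & is_cg).sum())
        n_cg_meth = int((span & is_cg & is_meth).sum())
        has_noncg_meth = bool(np.any(~mcg[chunk_idx]))
        segments.append(
            MethSegment(
                start=start,
                end=end,
                seg_class="tem" if has_noncg_meth else "gbm",
                n_cg_sites=n_cg,
                n_cg_methylated=n_cg_meth,
            )
        )
    return segments


def classify_gene(segments: list[MethSegment], site_calls: pd.DataFrame) -> str:
    """Classify one gene-accession pair as gbm/tem/um/both/indeterminate.

    A gene with a gbM-like segment spanning >= 3 CG sites (>= 1 called
    methylated) is gbM, demoted to "both" when a teM segment at least 25%
    of the gbM segment's length also overlaps it; symmetrically for teM.
    A gene with no segments and >= 3 sites called unmethylated is UM;
    anything else is indeterminate.
    """
    gbm_segs = [s for s in segments if s.seg_class == "gbm"]
    tem_segs = [s for s in segments if s.seg_class == "tem"]
    gbm_q = [s for s in gbm_segs if s.n_cg_sites >= 3 and s.n_cg_methylated >= 1]
    tem_q = [s for s in tem_segs if s.n_cg_sites >= 3]
    if gbm_q:
        ref = max(s.length for s in gbm_q)
        if tem_segs and max(s.length for s in tem_segs) >= 0.25 * ref:
            return "both"
        return "gbm"
    if tem_q:
        ref = max(s.length for s in tem_q)
        if gbm_segs and max(s.length for s in gbm_segs) >= 0.25 * ref:
            return "both"
        return "tem"
    if not segments:
        n_unmeth = int((site_calls["status"] == UNMETHYLATED).sum())
        if n_unmeth >= 3:
            return "um"
    return "indeterminate"


def gene_mean_mcg(site_calls: pd.DataFrame) -> float:
    """Mean mCG: methylated CG sites / (methylated + unmethylated CG sites).

    Partial and insufficient sites are excluded from both numerator and
    denominator; returns NaN when no CG site is called either way.
    """
    cg = site_calls[site_calls["context"] == "CG"]
    n_meth = int((cg["status"] == METHYLATED).sum())
    n_unmeth = int((cg["status"] == UNMETHYLATED).sum())
    denom = n_meth + n_unmeth
    if denom == 0:
        return float("nan")
    return n_meth / denom


# ---------------------------------------------------------------------------
# Population-level matrix
# ---------------------------------------------------------------------------


def call_epistate_matrix(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    error_rate: float = 0.005,
    alpha: float = 0.05,
    max_gap: int = 200,
) -> dict:
    """Call gene states and mean mCG for every gene x accession pair.

    ``sites`` columns: gene_id, accession, pos, context, reads_meth,
    reads_total (positions 0-based).  ``genes`` is the annotation frame
    (gene_id at minimum).  Returns dict with ``states`` and ``mcg``
    DataFrames (genes x accessions).
    """
    sites = sites.copy()
    sites["status"] = call_sites(
        sites["reads_meth"].to_numpy(),
        sites["reads_total"].to_numpy(),
        error_rate,
        alpha,
    )
    gene_ids = list(genes["gene_id"])
    accessions = sorted(sites["accession"].unique())
    states = pd.DataFrame("indeterminate", index=gene_ids, columns=accessions)
    mcg = pd.DataFrame(np.nan, index=gene_ids, columns=accessions)
    for (gid, acc), grp in sites.groupby(["gene_id", "accession"], sort=False):
        grp = grp.sort_values("pos")
        segs = segment_gene(grp, max_gap=max_gap)
        state = classify_gene(segs, grp)
        states.loc[gid, acc] = state
        if state in ("gbm", "tem", "both"):
            mcg.loc[gid, acc] = gene_mean_mcg(grp)
    return {"states": states, "mcg": mcg}


def assign_sites_to_genes(sites: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach a gene_id column to a site table by interval lookup.

    Gene spans are assumed non-overlapping per chromosome (half-open);
    sites outside every gene are dropped."""
    out = []
    for chrom, grp in sites.groupby("chrom"):
        g = genes[genes["chrom"] == chrom].sort_values("start")
        if g.empty:
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        pos = grp["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        hit = grp.loc[ok].copy()
        hit["gene_id"] = g["gene_id"].to_numpy()[idx[ok]]
        out.append(hit)
    if not out:
        return sites.iloc[0:0].assign(gene_id=pd.Series(dtype=str))
    return pd.concat(out, ignore_index=True)


FREQ_BINS = ("<10%", "[10,90)", "[90,100)", "100%")


def _freq_bin(f: float) -> str:
    if np.isnan(f):
        return "missing"
    if f < 0.10:
        return FREQ_BINS[0]
    if f < 0.90:
        return FREQ_BINS[1]
    if f < 1.0:
        return FREQ_BINS[2]
    return FREQ_BINS[3]


def conservation_summary(
    states: pd.DataFrame, min_call_fraction: float = 0.7
) -> pd.DataFrame:
    """Per-gene gbM/teM population frequencies over available (non-ambiguous)
    calls, with conservation-class bins and a low-call flag."""
    out = []
    n_acc = states.shape[1]
    for gid, row in states.iterrows():
        available = row.isin(["gbm", "tem", "um"])
        n_avail = int(available.sum())
        gbm_f = float((row == "gbm").sum() / n_avail) if n_avail else np.nan
        tem_f = float((row == "tem").sum() / n_avail) if n_avail else np.nan
        out.append(
            {
                "gene_id": gid,
                "n_available": n_avail,
                "gbm_freq": gbm_f,
                "tem_freq": tem_f,
                "gbm_bin": _freq_bin(gbm_f),
                "tem_bin": _freq_bin(tem_f),
                "low_call": n_avail < min_call_fraction * n_acc,
            }
        )
    return pd.DataFrame(out).set_index("gene_id")


def state_count_correlation(states: pd.DataFrame) -> dict:
    """Per-accession gbM and teM gene counts and their Pearson correlation."""
    if states.shape[1] < 3:
        raise ValueError("need >= 3 accessions")
    gbm_counts = (states == "gbm").sum(axis=0)
    tem_counts = (states == "tem").sum(axis=0)
    if gbm_counts.nunique() == 1 or tem_counts.nunique() == 1:
        return {
            "gbm_counts": gbm_counts,
            "tem_counts": tem_counts,
            "r": float("nan"),
            "p_value": float("nan"),
            "defined": False,
        }
    r, p = stats.pearsonr(gbm_counts, tem_counts)
    return {
        "gbm_counts": gbm_counts,
        "tem_counts": tem_counts,
        "r": float(r),
        "p_value": float(p),
        "defined": True,
    }
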