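"""Synthetic population-epigenomics data generators.

Every downstream stage of the package (state calling, variance
partitioning, eQTL mapping, confound accounting, epiGWA, perturbation
contrasts) can be exercised end-to-end on data produced here.  The
generators emulate the statistical structure of a natural *Arabidopsis*
accession panel:

* a cooperative epimutation process that produces bimodal population
  distributions of gene-body CG methylation (gbM),
* bisulfite read counts with conversion-error noise,
* structured populations of essentially homozygous (haploid-coded)
  genotypes with block LD,
* sparse-effect expression driven by gbM / teM / SNP marker groups at
  configurable variance fractions, and
* traits with epiallelic, polygenic and stratification components.

All generators take a single integer seed and derive child streams
deterministically, so identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpimutationConfig",
    "ReadSimConfig",
    "PopulationSimConfig",
    "ExpressionSimTruth",
    "simulate_epimutation_population",
    "epimutation_transition_matrix",
    "epimutation_stationary_distribution",
    "simulate_genotypes",
    "simulate_reads",
    "simulate_expression",
    "simulate_traits",
    "simulate_methylomes",
    "simulate_confound_panel",
]


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


# ---------------------------------------------------------------------------
# Epimutation simulator
# ---------------------------------------------------------------------------


@dataclass
class EpimutationConfig:
    """Cooperative gain/loss epimutation model for the CG sites of one gene.

    Each generation, every unmethylated site gains methylation with
    probability ``gain_base + gain_coop * m / n_sites`` (clamped to [0, 1]),
    where ``m`` is the number of currently methylated sites in the gene;
    every methylated site loses methylation with probability ``loss_rate``.
    The positive feedback through ``gain_coop`` is what produces bimodal
    steady-state methylation across independent lineages.
    """

    n_sites: int = 10
    gain_base: float = 5e-4
    gain_coop: float = 0.25
    loss_rate: float = 0.10
    n_generations: int = 100_000
    n_lineages: int = 740
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob("gain_base", self.gain_base)
        if self.gain_coop < 0:
            raise ValueError("gain_coop must be >= 0")
        _check_prob("loss_rate", self.loss_rate)
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")

    def gain_probability(self, n_methylated: np.ndarray | int) -> np.ndarray:
        frac = np.asarray(n_methylated, dtype=float) / self.n_sites
        return np.clip(self.gain_base + self.gain_coop * frac, 0.0, 1.0)


def simulate_epimutation_population(cfg: EpimutationConfig) -> dict:
    """Run independent epimutation lineages from an unmethylated start.

    Returns a dict with ``states`` (n_lineages x n_sites boolean array of
    final-generation site states) and ``levels`` (per-lineage methylated
    fraction at the final generation).
    """
    rng = np.random.default_rng(cfg.seed)
    states = np.zeros((cfg.n_lineages, cfg.n_sites), dtype=bool)
    for _ in range(cfg.n_generations):
        m = states.sum(axis=1)
        p_gain = cfg.gain_probability(m)[:, None]
        u = rng.random(states.shape)
        gains = (~states) & (u < p_gain)
        losses = states & (u < cfg.loss_rate)
        states = (states | gains) & ~losses
    return {"states": states, "levels": states.mean(axis=1)}


def epimutation_transition_matrix(cfg: EpimutationConfig) -> np.ndarray:
    """Exact 2**n_sites transition matrix of the per-gene site-state chain.

    Rows/columns index site configurations as tuples of bits in
    ``itertools.product((0, 1), repeat=n_sites)`` order.  Intended for
    small systems (n_sites <= ~12).
    """
    n = cfg.n_sites
    configs = list(product((0, 1), repeat=n))
    size = len(configs)
    T = np.empty((size, size))
    for i, src in enumerate(configs):
        m = sum(src)
        pg = float(cfg.gain_probability(m))
        pl = cfg.loss_rate
        for j, dst in enumerate(configs):
            p = 1.0
            for s, d in zip(src, dst):
                if s == 0:
                    p *= pg if d else (1.0 - pg)
                else:
                    p *= pl if not d else (1.0 - pl)
            T[i, j] = p
    return T


def epimutation_stationary_distribution(cfg: EpimutationConfig) -> np.ndarray:
    """Stationary distribution of the exact chain (left eigenvector)."""
    T = epimutation_transition_matrix(cfg)
    w, v = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class PopulationSimConfig:
    """Structured haploid population with block LD.

    ``divergence`` is the Balding–Nichols F parameter controlling
    between-subpopulation allele-frequency drift; ``ld_block_size`` is the
    number of adjacent markers per LD block and ``ld_rho`` the per-adjacent-
    marker haplotype copy probability within a block.
    """

    n_accessions: int = 600
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_subpopulations: int = 1
    divergence: float = 0.0
    ld_block_size: int = 10
    ld_rho: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_subpopulations < 1:
            raise ValueError("n_subpopulations must be >= 1")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")


def simulate_genotypes(cfg: PopulationSimConfig) -> dict:
    """Simulate a haploid 0/1 genotype matrix with subpopulation labels.

    Returns dict with ``genotypes`` (n_accessions x n_snps int8 array),
    ``subpop`` (labels), ``ancestral_freq`` and ``subpop_freq``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.maf_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_snps)
    if cfg.divergence > 0 and cfg.n_subpopulations > 1:
        F = cfg.divergence
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        subpop_freq = rng.beta(a, b, size=(cfg.n_subpopulations, cfg.n_snps))
    else:
        subpop_freq = np.tile(p_anc, (cfg.n_subpopulations, 1))
    labels = np.repeat(
        np.arange(cfg.n_subpopulations),
        -(-cfg.n_accessions // cfg.n_subpopulations),
    )[: cfg.n_accessions]

    G = np.empty((cfg.n_accessions, cfg.n_snps), dtype=np.int8)
    freqs = subpop_freq[labels]  # n_accessions x n_snps
    u = rng.random((cfg.n_accessions, cfg.n_snps))
    fresh = (u < freqs).astype(np.int8)
    G[:, 0] = fresh[:, 0]
    copy = rng.random((cfg.n_accessions, cfg.n_snps)) < cfg.ld_rho
    for j in range(1, cfg.n_snps):
        if j % cfg.ld_block_size == 0:  # block boundary: no copying
            G[:, j] = fresh[:, j]
        else:
            G[:, j] = np.where(copy[:, j], G[:, j - 1], fresh[:, j])
    return {
        "genotypes": G,
        "subpop": labels,
        "ancestral_freq": p_anc,
        "subpop_freq": subpop_freq,
    }


# ---------------------------------------------------------------------------
# Bisulfite read counts
# ---------------------------------------------------------------------------


@dataclass
class ReadSimConfig:
    """Bisulfite read-count error model.

    ``nonconversion_rate`` — probability an unmethylated cytosine reads as
    methylated (failed conversion); ``overconversion_rate`` — probability a
    methylated cytosine reads as unmethylated.  Depth is Poisson with mean
    ``mean_depth``.
    """

    mean_depth: float = 30.0
    nonconversion_rate: float = 0.005
    overconversion_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        for name in ("nonconversion_rate", "overconversion_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 0.5):
                raise ValueError(f"{name} must be in [0, 0.5), got {v!r}")


def simulate_reads(true_states: np.ndarray, cfg: ReadSimConfig) -> pd.DataFrame:
    """Draw per-site read counts from true binary methylation states.

    ``true_states`` is a boolean array of any shape; the result is a flat
    table with columns ``site`` (flat index), ``reads_total``,
    ``reads_meth``.
    """
    rng = np.random.default_rng(cfg.seed)
    states = np.asarray(true_states, dtype=bool).ravel()
    total = rng.poisson(cfg.mean_depth, size=states.size)
    p_meth = np.where(states, 1.0 - cfg.overconversion_rate, cfg.nonconversion_rate)
    meth = rng.binomial(total, p_meth)
    return pd.DataFrame(
        {"site": np.arange(states.size), "reads_total": total, "reads_meth": meth}
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSimTruth:
    """Recorded generative truth for one simulated expression trait."""

    target_pve_gbm: float
    target_pve_tem: float
    target_pve_snp: float
    realized_pve: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    residual_variance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_pve_gbm", "target_pve_tem", "target_pve_snp"):
            _check_prob(name, getattr(self, name))
        total = self.target_pve_gbm + self.target_pve_tem + self.target_pve_snp
        if total > 1.0 + 1e-12:
            raise ValueError("target PVE fractions must sum to <= 1")


def _group_component(
    X: np.ndarray, n_causal: int, target_var: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse causal effects for one marker group, rescaled so the in-sample
    variance of the group linear predictor equals ``target_var`` exactly."""
    p = X.shape[1]
    b = np.zeros(p)
    if target_var <= 0 or p == 0:
        return b, np.zeros(X.shape[0])
    n_causal = min(max(1, n_causal), p)
    idx = rng.choice(p, size=n_causal, replace=False)
    b[idx] = rng.normal(size=n_causal)
    u = X @ b
    v = u.var()
    if v <= 0:
        raise ValueError("causal markers have zero variance; cannot hit target PVE")
    scale = np.sqrt(target_var / v)
    return b * scale, u * scale


def simulate_expression(
    mcg_gbm: np.ndarray,
    mcg_tem: np.ndarray,
    genotypes: np.ndarray,
    truth: ExpressionSimTruth,
    n_causal: tuple[int, int, int] = (10, 5, 10),
) -> dict:
    """Simulate one gene's expression from gbM, teM and SNP marker groups.

    All marker matrices are accessions x markers and are standardized
    internally.  Group linear predictors are rescaled so realized
    variance fractions hit the targets exactly up to between-group
    covariance; ``truth.realized_pve`` records the realized fractions.
    """
    mats = {"gbm": mcg_gbm, "tem": mcg_tem, "snp": genotypes}
    n = None
    for name, X in mats.items():
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"{name} matrix must be 2-D")
        if n is None:
            n = X.shape[0]
        elif X.shape[0] != n:
            raise ValueError("marker matrices must share the accession axis")
        mats[name] = standardize_columns(X)
    rng = np.random.default_rng(truth.seed)

    total_var = 1.0
    targets = {
        "gbm": truth.target_pve_gbm,
        "tem": truth.target_pve_tem,
        "snp": truth.target_pve_snp,
    }
    predictors = {}
    for (name, X), nc in zip(mats.items(), n_causal):
        b, u = _group_component(X, nc, targets[name] * total_var, rng)
        truth.effects[name] = b
        predictors[name] = u
    resid_var = total_var * (1.0 - sum(targets.values()))
    truth.residual_variance = resid_var
    eps = rng.normal(scale=np.sqrt(resid_var), size=n) if resid_var > 0 else np.zeros(n)
    y = predictors["gbm"] + predictors["tem"] + predictors["snp"] + eps
    vy = y.var()
    truth.realized_pve = {
        name: float(u.var() / vy) if vy > 0 else np.nan
        for name, u in predictors.items()
    }
    return {"expression": y, "predictors": predictors, "noise": eps, "truth": truth}


def standardize_columns(X: np.ndarray, drop_constant: bool = False) -> np.ndarray:
    """Column-standardize to mean 0, sd 1; constant columns become zeros
    (or are dropped when ``drop_constant``)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    if drop_constant:
        return Z[:, ok]
    return Z


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def simulate_traits(
    epistates: np.ndarray,
    genotypes: np.ndarray | None = None,
    subpop: np.ndarray | None = None,
    causal_genes: Sequence[int] = (),
    causal_pve: float = 0.0,
    polygenic_pve: float = 0.0,
    subpop_shift: float = 0.0,
    seed: int = 0,
) -> dict:
    """Simulate a quantitative trait from binary epiallelic states.

    ``epistates`` is accessions x genes 0/1 (NaN allowed, mean-imputed for
    the causal predictor).  ``causal_pve`` is the trait-variance fraction
    jointly explained by the causal epialleles; ``polygenic_pve`` adds a
    dense SNP background; ``subpop_shift`` adds a per-subpopulation mean
    offset in residual-sd units (population stratification).
    """
    rng = np.random.default_rng(seed)
    E = np.asarray(epistates, dtype=float)
    n = E.shape[0]
    y = np.zeros(n)
    if causal_genes and causal_pve > 0:
        Z = E[:, list(causal_genes)].copy()
        col_mean = np.nanmean(Z, axis=0)
        inds = np.where(np.isnan(Z))
        Z[inds] = np.take(col_mean, inds[1])
        Z = standardize_columns(Z)
        b = rng.normal(size=Z.shape[1])
        u = Z @ b
        if u.var() <= 0:
            raise ValueError("causal epialleles are monomorphic")
        y += u * np.sqrt(causal_pve / u.var())
    if genotypes is not None and polygenic_pve > 0:
        G = standardize_columns(np.asarray(genotypes, dtype=float))
        g = G @ rng.normal(size=G.shape[1])
        y += g * np.sqrt(polygenic_pve / g.var())
    noise_var = max(1.0 - causal_pve - polygenic_pve, 1e-12)
    y += rng.normal(scale=np.sqrt(noise_var), size=n)
    if subpop is not None and subpop_shift != 0.0:
        y += subpop_shift * np.asarray(subpop, dtype=float)
    return {"trait": y, "causal_genes": list(causal_genes)}


# ---------------------------------------------------------------------------
# Whole-methylome generator (genes x accessions with site-level read counts)
# ---------------------------------------------------------------------------


def simulate_methylomes(
    n_genes: int = 50,
    n_accessions: int = 20,
    n_cg_sites: int = 15,
    n_noncg_sites: int = 10,
    site_spacing: int = 50,
    class_probs: tuple[float, float, float] = (0.35, 0.15, 0.50),
    gbm_site_prob: float = 0.7,
    tem_cg_prob: float = 0.85,
    tem_noncg_prob: float = 0.6,
    conservation_beta: tuple[float, float] = (0.6, 0.6),
    read_cfg: ReadSimConfig | None = None,
    seed: int = 0,
) -> dict:
    """Simulate a panel of gene methylomes with known epiallelic truth.

    Each gene draws a class (gbM-variable, teM-variable, UM) with
    ``class_probs`` and, for variable genes, a population epiallele
    frequency from a Beta(``conservation_beta``) distribution — mimicking
    the U-shaped conservation spectrum of natural panels.  Each accession
    then carries the methylated epiallele with that frequency.  Site-level
    binary truth is drawn per accession and converted to allc-style read
    counts with the bisulfite error model.

    Returns dict with:
      ``sites`` — DataFrame: gene_id, accession, chrom, pos, strand,
         context, reads_meth, reads_total, true_methylated
      ``truth_states`` — DataFrame genes x accessions of true state strings
      ``truth_mcg`` — DataFrame genes x accessions of true mean mCG
      ``genes`` — annotation DataFrame (gene_id, chrom, start, end, strand)
    """
    if read_cfg is None:
        read_cfg = ReadSimConfig(seed=seed + 1)
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    accessions = [f"A{i:04d}" for i in range(n_accessions)]
    gene_class = rng.choice(["gbm", "tem", "um"], size=n_genes, p=class_probs)
    freq = rng.beta(*conservation_beta, size=n_genes)

    n_sites = n_cg_sites + n_noncg_sites
    gene_len = (n_sites + 1) * site_spacing
    rows = []
    truth_states = np.full((n_genes, n_accessions), "um", dtype=object)
    truth_mcg = np.full((n_genes, n_accessions), 0.0)
    contexts = np.array(["CG"] * n_cg_sites + ["CHH"] * n_noncg_sites)
    order = rng.permutation(n_sites)
    contexts = contexts[order]  # interleave CG and non-CG sites
    offsets = (np.arange(n_sites) + 1) * site_spacing

    true_meth = np.zeros((n_genes, n_accessions, n_sites), dtype=bool)
    is_cg = contexts == "CG"
    for g in range(n_genes):
        if gene_class[g] == "um":
            continue
        carrier = rng.random(n_accessions) < freq[g]
        for a in np.where(carrier)[0]:
            if gene_class[g] == "gbm":
                # redraw until the epiallele is callable (>=3 methylated CGs)
                while True:
                    pat = rng.random(n_cg_sites) < gbm_site_prob
                    if pat.sum() >= 3:
                        break
                true_meth[g, a, is_cg] = pat
                truth_states[g, a] = "gbm"
            else:
                while True:
                    pat_cg = rng.random(n_cg_sites) < tem_cg_prob
                    pat_nc = rng.random(n_noncg_sites) < tem_noncg_prob
                    if pat_cg.sum() >= 3 and pat_nc.sum() >= 1:
                        break
                true_meth[g, a, is_cg] = pat_cg
                true_meth[g, a, ~is_cg] = pat_nc
                truth_states[g, a] = "tem"
            truth_mcg[g, a] = true_meth[g, a, is_cg].mean()

    reads = simulate_reads(true_meth, read_cfg)
    total = reads["reads_total"].to_numpy().reshape(true_meth.shape)
    meth = reads["reads_meth"].to_numpy().reshape(true_meth.shape)

    gene_idx = np.repeat(np.arange(n_genes), n_accessions * n_sites)
    acc_idx = np.tile(np.repeat(np.arange(n_accessions), n_sites), n_genes)
    site_idx = np.tile(np.arange(n_sites), n_genes * n_accessions)
    starts = np.arange(n_genes) * (gene_len + site_spacing)
    sites = pd.DataFrame(
        {
            "gene_id": np.array(gene_ids)[gene_idx],
            "accession": np.array(accessions)[acc_idx],
            "chrom": "Chr1",
            "pos": starts[gene_idx] + offsets[site_idx],
            "strand": "+",
            "context": contexts[site_idx],
            "reads_meth": meth.ravel(),
            "reads_total": total.ravel(),
            "true_methylated": true_meth.ravel(),
        }
    )
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": "Chr1",
            "start": starts,
            "end": starts + gene_len,
            "strand": "+",
        }
    )
    return {
        "sites": sites,
        "truth_states": pd.DataFrame(truth_states, index=gene_ids, columns=accessions),
        "truth_mcg": pd.DataFrame(truth_mcg, index=gene_ids, columns=accessions),
        "genes": genes,
        "read_cfg": read_cfg,
    }


# ---------------------------------------------------------------------------
# Confound panel: genes with genuinely epigenetic vs SNP-confounded effects
# ---------------------------------------------------------------------------


def simulate_confound_panel(
    n_genes: int = 200,
    n_accessions: int = 600,
    n_window_snps: int = 20,
    frac_confounded: float = 0.5,
    effect_pve: float = 0.15,
    ld_with_snp: float = 0.8,
    seed: int = 0,
) -> list[dict]:
    """Per-gene datasets for the genetic-confound pipeline, with truth.

    For a *confounded* gene, expression is driven by a cis SNP and the
    gene's mCG level is in LD with that SNP (correlation ``ld_with_snp``)
    but has no direct effect.  For an *epigenetic* gene, expression is
    driven by mCG, which is independent of every window SNP.
    """
    rng = np.random.default_rng(seed)
    out = []
    n_conf = int(round(n_genes * frac_confounded))
    for g in range(n_genes):
        confounded = g < n_conf
        gcfg = PopulationSimConfig(
            n_accessions=n_accessions,
            n_snps=n_window_snps,
            seed=int(rng.integers(2**31 - 1)),
        )
        G = simulate_genotypes(gcfg)["genotypes"].astype(float)
        s = int(rng.integers(n_window_snps))
        snp = G[:, s]
        noise = rng.normal(size=n_accessions)
        if confounded:
            zs = (snp - snp.mean()) / snp.std()
            mcg_lat = ld_with_snp * zs + np.sqrt(1 - ld_with_snp**2) * noise
            mcg = (mcg_lat > np.quantile(mcg_lat, 0.5)).astype(float) * rng.uniform(
                0.4, 0.9
            )
            driver = zs
        else:
            mcg = (noise > 0).astype(float) * rng.uniform(0.4, 0.9)
            driver = (mcg - mcg.mean()) / mcg.std()
        expr = np.sqrt(effect_pve) * driver + np.sqrt(1 - effect_pve) * rng.normal(
            size=n_accessions
        )
        out.append(
            {
                "gene_id": f"G{g:05d}",
                "genotypes": G,
                "mcg": mcg,
                "expression": expr,
                "causal_snp": s if confounded else None,
                "truth": "confounded" if confounded else "epigenetic",
            }
        )
    return out
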