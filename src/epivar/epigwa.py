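"""Epigenome-wide association (epiGWA) with population-structure correction.

Gene epiallelic states (binary gbM/UM or teM/UM codes) or quantitative
mCG levels serve as markers against quantitative traits, under three
models:

* LM  — simple regression, no structure correction;
* GLM — fixed-effects regression with structure covariates Q (leading
  principal components of the epiallelic state matrix);
* MLM — mixed model ``Y = X b + Q a + u + e`` with a polygenic random
  effect ``u ~ N(0, sigma_u^2 K)`` where K is identity-by-state kinship.
  Variance components are estimated once by REML under the null model
  and reused for every marker (EMMAX/P3D-style), each marker then tested
  by generalized least squares after whitening.

Genomic-control inflation ``lambda = median(observed chi2) / median
(expected chi2)`` diagnoses residual confounding; statistics can be
lambda-corrected and thresholded by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "binary_epiallele_matrix",
    "maf_conservation_filter",
    "pca_structure",
    "ibs_kinship",
    "EpiGWA",
    "EpiGWAResults",
    "InflationReport",
    "genomic_inflation",
    "lambda_correct",
    "fdr_qtls",
]

CHI2_NULL_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549...


def binary_epiallele_matrix(states: pd.DataFrame, context: str = "gbm") -> pd.DataFrame:
    """Code a genes x accessions state matrix as binary epialleles.

    The methylated class (``context``) codes 1, UM codes 0; "both",
    "indeterminate" and anything else is missing (NaN).  Returns an
    accessions x genes frame ready for marker use."""
    E = pd.DataFrame(np.nan, index=states.index, columns=states.columns)
    E[states == context] = 1.0
    E[states == "um"] = 0.0
    return E.T


def maf_conservation_filter(
    epistates: pd.DataFrame | np.ndarray,
    maf_min: float = 0.05,
    conservation_min: float = 0.10,
) -> np.ndarray:
    """Eligibility mask over epiallelic markers.

    ``epistates`` is accessions x markers binary coding (NaN = missing).
    A marker is kept when its minor epiallele frequency is at least
    ``maf_min``, the methylated epiallele is carried by more than
    ``conservation_min`` of accessions with calls, and it is polymorphic.
    """
    E = np.asarray(epistates, dtype=float)
    keep = np.zeros(E.shape[1], dtype=bool)
    for j in range(E.shape[1]):
        col = E[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        f = col.mean()
        maf = min(f, 1 - f)
        if maf == 0:
            continue
        if maf < maf_min:
            continue
        if f <= conservation_min:
            continue
        keep[j] = True
    return keep


def pca_structure(epistates: pd.DataFrame | np.ndarray, k: int = 3) -> np.ndarray:
    """Structure covariates Q: top-k principal component scores of the
    (mean-imputed, centred) epiallelic state matrix."""
    E = np.asarray(epistates, dtype=float)
    if E.shape[0] < 2 or E.shape[1] < 2:
        raise ValueError("need >= 2 accessions and >= 2 markers")
    mu = np.nanmean(E, axis=0)
    inds = np.where(np.isnan(E))
    E = E.copy()
    E[inds] = np.take(mu, inds[1])
    E = E - E.mean(axis=0)
    if k == 0:
        return np.empty((E.shape[0], 0))
    rank = np.linalg.matrix_rank(E)
    if k >= max(rank, 1) and k >= min(E.shape):
        raise ValueError(f"k={k} >= rank of the state matrix")
    U, s, _ = np.linalg.svd(E, full_matrices=False)
    return U[:, :k] * s[:k]


def ibs_kinship(epistates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Identity-by-state kinship: K_ij = fraction of markers with the same
    state among markers non-missing in both accessions.  Diagonal is 1;
    pairs with zero overlap get NaN."""
    E = np.asarray(epistates, dtype=float)
    n = E.shape[0]
    obs = ~np.isnan(E)
    Ez = np.where(obs, E, 0.0)
    # pairwise counts of shared observed markers and of agreements
    overlap = obs.astype(float) @ obs.T.astype(float)
    # agreement = sum over observed of 1 - |e_i - e_j| (binary states)
    same11 = Ez @ Ez.T
    zeros = (obs & (Ez == 0)).astype(float)
    agree = same11 + zeros @ zeros.T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(overlap > 0, agree / overlap, np.nan)
    np.fill_diagonal(K, 1.0)
    return K


# ---------------------------------------------------------------------------
# Inflation
# ---------------------------------------------------------------------------


@dataclass
class InflationReport:
    lam: float
    observed_median_chi2: float
    expected_median_chi2: float
    raw_p: np.ndarray
    corrected_p: np.ndarray


def genomic_inflation(p_values, thin: int = 1) -> InflationReport:
    """Genomic-control inflation factor from association p-values.

    p-values are converted to 1-df chi-square quantiles; lambda is the
    ratio of their median to the null median (0.455).  ``thin`` keeps
    every thin-th marker as a crude unlinked subset.
    """
    p = np.asarray(p_values, dtype=float)[::thin]
    if p.size < 10:
        raise ValueError("need >= 10 p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / CHI2_NULL_MEDIAN)
    corrected = lambda_correct(p, lam)
    return InflationReport(
        lam=lam,
        observed_median_chi2=float(np.median(chi2)),
        expected_median_chi2=float(CHI2_NULL_MEDIAN),
        raw_p=p,
        corrected_p=corrected,
    )


def lambda_correct(p_values, lam: float, apply_if_deflated: bool = True) -> np.ndarray:
    """Divide each 1-df chi-square statistic by lambda and recompute p.

    With ``apply_if_deflated=False`` a lambda below 1 leaves p-values
    unchanged (only inflation is corrected)."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    p = np.asarray(p_values, dtype=float)
    if lam < 1 and not apply_if_deflated:
        return p.copy()
    chi2 = stats.chi2.isf(p, df=1)
    return stats.chi2.sf(chi2 / lam, df=1)


def fdr_qtls(results: pd.DataFrame, q: float = 0.05, p_col: str = "p_corrected") -> pd.DataFrame:
    """Benjamini-Hochberg significance over (corrected) p-values; adds
    ``q_value`` and ``significant`` columns."""
    from statsmodels.stats.multitest import multipletests

    out = results.copy()
    p = out[p_col].to_numpy(dtype=float)
    ok = np.isfinite(p)
    sig = np.zeros(len(out), dtype=bool)
    qv = np.full(len(out), np.nan)
    if ok.sum() > 0:
        rej, qvals, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        sig[ok] = rej
        qv[ok] = qvals
    out["q_value"] = qv
    out["significant"] = sig
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class EpiGWA:
    """Epigenome-wide association model.

    Parameters
    ----------
    trait : array, length n
    markers : accessions x markers array/DataFrame (binary epiallelic
        coding or quantitative mCG levels; NaN = missing, mean-imputed
        per marker at test time)
    Q : optional structure covariates (n x k)
    K : optional IBS kinship (n x n); required for the MLM
    marker_names : optional sequence of identifiers
    """

    def __init__(self, trait, markers, Q=None, K=None, marker_names=None):
        self.trait = np.asarray(trait, dtype=float)
        if isinstance(markers, pd.DataFrame):
            if marker_names is None:
                marker_names = list(markers.columns)
            markers = markers.to_numpy(dtype=float)
        self.markers = np.asarray(markers, dtype=float)
        if self.markers.shape[0] != self.trait.size:
            raise ValueError("trait and markers must share the accession axis")
        self.Q = None if Q is None else np.asarray(Q, dtype=float)
        self.K = None if K is None else np.asarray(K, dtype=float)
        self.marker_names = (
            list(marker_names)
            if marker_names is not None
            else [f"m{j}" for j in range(self.markers.shape[1])]
        )

    # -- fixed-effect models -------------------------------------------------

    def _design_base(self) -> np.ndarray:
        n = self.trait.size
        cols = [np.ones(n)]
        if self.Q is not None and self.Q.shape[1] > 0:
            cols.append(self.Q)
        X0 = np.column_stack(cols)
        # drop collinear covariate columns
        q, r = np.linalg.qr(X0)
        keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1)
        return X0[:, keep]

    def _imputed_marker(self, j: int) -> np.ndarray:
        x = self.markers[:, j].copy()
        nan = np.isnan(x)
        if nan.all():
            return x
        if nan.any():
            x[nan] = x[~nan].mean()
        return x

    def fit(self, model: str = "mlm", reml: bool = True) -> "EpiGWAResults":
        model = model.lower()
        if model == "lm":
            table = self._fit_fixed(use_Q=False)
            vc = None
        elif model == "glm":
            table = self._fit_fixed(use_Q=True)
            vc = None
        elif model == "mlm":
            table, vc = self._fit_mlm(reml=reml)
        else:
            raise ValueError(f"unknown model {model!r}")
        return EpiGWAResults(self, model, table, variance_components=vc)

    def _fit_fixed(self, use_Q: bool) -> pd.DataFrame:
        y = self.trait
        n = y.size
        Q = self.Q if use_Q else None
        base = [np.ones(n)] + ([Q] if Q is not None and Q.shape[1] else [])
        X0 = np.column_stack(base) if len(base) > 1 else np.ones((n, 1))
        rows = []
        for j in range(self.markers.shape[1]):
            x = self._imputed_marker(j)
            if np.nanstd(x) == 0 or np.isnan(x).all():
                rows.append((self.marker_names[j], np.nan, np.nan, np.nan))
                continue
            X = np.column_stack([X0, x])
            beta, se, p = _ols_last_coef(X, y)
            rows.append((self.marker_names[j], beta, se, p))
        return pd.DataFrame(rows, columns=["marker", "beta", "se", "p_value"])

    # -- mixed model ---------------------------------------------------------

    def _fit_mlm(self, reml: bool = True):
        if self.K is None:
            raise ValueError("MLM requires a kinship matrix K")
        y = self.trait
        n = y.size
        K = 0.5 * (self.K + self.K.T)
        w, V = np.linalg.eigh(K)
        clipped = int((w < 0).sum())
        w = np.clip(w, 0.0, None)
        X0 = self._design_base()
        # REML profile over delta = sigma2_e / sigma2_u on rotated data
        yr = V.T @ y
        X0r = V.T @ X0

        def neg_reml(log_delta: float) -> float:
            delta = np.exp(log_delta)
            d = w + delta
            Xw = X0r / d[:, None]
            XtX = X0r.T @ Xw
            Xty = Xw.T @ yr
            try:
                beta = np.linalg.solve(XtX, Xty)
            except np.linalg.LinAlgError:
                return np.inf
            r = yr - X0r @ beta
            rss = float(np.sum(r * r / d))
            q = X0.shape[1]
            dof = n - q if reml else n
            sigma2 = rss / dof
            ll = -0.5 * (dof * np.log(2 * np.pi * sigma2) + np.sum(np.log(d)) + dof)
            if reml:
                sign, logdet = np.linalg.slogdet(XtX)
                if sign <= 0:
                    return np.inf
                ll -= 0.5 * logdet
                sign0, logdet0 = np.linalg.slogdet(X0.T @ X0)
                ll += 0.5 * logdet0
            return -ll

        res = optimize.minimize_scalar(
            neg_reml, bounds=(-10.0, 10.0), method="bounded"
        )
        delta = float(np.exp(res.x))
        d = w + delta
        # null variance components
        Xw = X0r / d[:, None]
        beta0 = np.linalg.solve(X0r.T @ Xw, Xw.T @ yr)
        r0 = yr - X0r @ beta0
        sigma2_u = float(np.sum(r0 * r0 / d) / (n - X0.shape[1]))
        sigma2_e = sigma2_u * delta
        # whitening transform: multiply rotated data by d^{-1/2}
        scale = 1.0 / np.sqrt(d)
        yw = yr * scale
        X0w = X0r * scale[:, None]
        rows = []
        for j in range(self.markers.shape[1]):
            x = self._imputed_marker(j)
            if np.nanstd(x) == 0 or np.isnan(x).all():
                rows.append((self.marker_names[j], np.nan, np.nan, np.nan))
                continue
            xw = (V.T @ x) * scale
            X = np.column_stack([X0w, xw])
            beta, se, p = _ols_last_coef(X, yw)
            rows.append((self.marker_names[j], beta, se, p))
        table = pd.DataFrame(rows, columns=["marker", "beta", "se", "p_value"])
        vc = {
            "sigma2_u": sigma2_u,
            "sigma2_e": sigma2_e,
            "delta": delta,
            "clipped_eigenvalues": clipped,
        }
        return table, vc


def _ols_last_coef(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, SE and two-sided t-test p for the last column of X."""
    n, q = X.shape
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - rank
    if dof <= 0:
        return float(beta[-1]), np.nan, np.nan
    s2 = float(resid @ resid) / dof
    XtX = X.T @ X
    try:
        cov = np.linalg.pinv(XtX) * s2
    except np.linalg.LinAlgError:
        return float(beta[-1]), np.nan, np.nan
    se = float(np.sqrt(max(cov[-1, -1], 0.0)))
    if se == 0:
        return float(beta[-1]), 0.0, 0.0
    t = beta[-1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(beta[-1]), se, float(p)


class EpiGWAResults:
    """Association table plus inflation diagnostics for one epiGWA fit."""

    def __init__(self, model, model_name, table, variance_components=None):
        self.model = model
        self.model_name = model_name
        self.table = table
        self.variance_components = variance_components
        self._inflation = None

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy(dtype=float)

    def inflation(self, thin: int = 1) -> InflationReport:
        if self._inflation is None:
            p = self.p_values
            p = p[np.isfinite(p)]
            p = np.clip(p, 1e-300, 1.0)
            self._inflation = genomic_inflation(p, thin=thin)
        return self._inflation

    @property
    def lambda_gc(self) -> float:
        return self.inflation().lam

    def corrected_table(self, apply_if_deflated: bool = True) -> pd.DataFrame:
        lam = self.lambda_gc
        out = self.table.copy()
        p = np.clip(out["p_value"].to_numpy(dtype=float), 1e-300, 1.0)
        out["p_corrected"] = lambda_correct(p, lam, apply_if_deflated)
        return out

    def significant(self, q: float = 0.05, correct: bool = True) -> pd.DataFrame:
        table = self.corrected_table() if correct else self.table.assign(
            p_corrected=self.table["p_value"]
        )
        return fdr_qtls(table, q=q)

    def qq_data(self) -> pd.DataFrame:
        p = np.sort(self.p_values[np.isfinite(self.p_values)])
        exp = (np.arange(1, p.size + 1) - 0.5) / p.size
        return pd.DataFrame(
            {"expected_neglog10": -np.log10(exp), "observed_neglog10": -np.log10(p)}
        )

    def plot_qq(self, ax=None):
        """Quantile-quantile plot of observed vs expected -log10 p."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        qq = self.qq_data()
        ax.scatter(qq["expected_neglog10"], qq["observed_neglog10"], s=8)
        lim = float(qq["expected_neglog10"].max())
        ax.plot([0, lim], [0, lim], color="grey", lw=1)
        ax.set_xlabel("expected $-\\log_{10} p$")
        ax.set_ylabel("observed $-\\log_{10} p$")
        ax.set_title(
            f"{self.model_name.upper()} epiGWA, $\\lambda$ = {self.lambda_gc:.2f}"
        )
        return ax

    def summary(self) -> str:
        ntest = int(np.isfinite(self.p_values).sum())
        lines = [
            f"epiGWA {self.model_name.upper()} fit",
            f"  markers tested: {ntest} of {len(self.table)}",
            f"  genomic inflation lambda: {self.lambda_gc:.3f}",
        ]
        if self.variance_components:
            vc = self.variance_components
            lines.append(
                f"  variance components: sigma2_u={vc['sigma2_u']:.4f} "
                f"sigma2_e={vc['sigma2_e']:.4f} (delta={vc['delta']:.3f})"
            )
        top = self.table.dropna(subset=["p_value"]).nsmallest(5, "p_value")
        lines.append("  top associations:")
        for _, row in top.iterrows():
            lines.append(
                f"    {row['marker']:>12s} beta={row['beta']:+.4f} p={row['p_value']:.3e}"
            )
        return "\n".join(lines)
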