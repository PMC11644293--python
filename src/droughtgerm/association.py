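"""Kinship-corrected single-marker association on the composite D value.

The scan follows the EMMAX approximation to the linear mixed model

    y = X b + g s + u + e,   u ~ N(0, sg2 K),  e ~ N(0, se2 I)

where K is a genomic relationship matrix.  The variance ratio
delta = se2 / sg2 is estimated once under the null (no marker) by REML via
the spectral decomposition of K, and every marker is then tested by
generalized least squares on the rotated data — the standard trade of a
little exactness for a per-marker cost of one weighted regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import GenotypePanel

logger = logging.getLogger(__name__)

LOG10 = np.log(10.0)


class AssociationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

def qc_filter(
    panel: GenotypePanel, maf_min: float = 0.05, miss_max: float = 0.5
) -> tuple[GenotypePanel, dict]:
    """Keep SNPs with MAF strictly above ``maf_min`` and missing rate
    strictly below ``miss_max``.

    Returns the filtered panel and a report dict with the counts removed
    per criterion (a SNP failing both is counted under both).
    """
    if panel.n_snps == 0:
        raise AssociationError("empty genotype panel")
    maf = panel.maf()
    miss = panel.missing_rate()
    maf_ok = maf > maf_min
    miss_ok = miss < miss_max
    keep = maf_ok & miss_ok
    if not keep.any():
        raise AssociationError("QC removed every SNP")
    report = {
        "n_input": panel.n_snps,
        "n_kept": int(keep.sum()),
        "n_removed_maf": int((~maf_ok).sum()),
        "n_removed_missing": int((~miss_ok).sum()),
    }
    filtered = GenotypePanel(
        accessions=panel.accessions,
        sites=panel.sites.loc[keep].reset_index(drop=True),
        genotypes=panel.genotypes[:, keep],
    )
    return filtered, report


def _imputed_dosage(genotypes: np.ndarray) -> np.ndarray:
    """Per-SNP mean imputation of missing 0/1/2 dosages."""
    g = genotypes.astype(float, copy=True)
    col_mean = np.nanmean(g, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(g))
    g[nan_r, nan_c] = col_mean[nan_c]
    return g


def kinship(panel: GenotypePanel, method: str = "vanraden") -> np.ndarray:
    """Genomic relationship matrix.

    ``vanraden``: K = Z Z' / (2 sum p_j (1 - p_j)) with Z the
    allele-frequency-centered dosage matrix (missing calls mean-imputed),
    the centered GRM standard in mixed-model association.  ``ibs``: mean
    identity-by-state similarity, 1 - |g_i - g_j| / 2 averaged over SNPs.
    """
    g = _imputed_dosage(panel.genotypes)
    p = g.mean(axis=0) / 2.0
    if method == "vanraden":
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom <= 0:
            raise AssociationError("all SNPs monomorphic; kinship undefined")
        z = g - 2.0 * p
        return (z @ z.T) / denom
    if method == "ibs":
        n = g.shape[0]
        k = np.empty((n, n))
        for i in range(n):
            k[i] = 1.0 - np.abs(g - g[i]).mean(axis=1) / 2.0
        return k
    raise AssociationError(f"unknown kinship method: {method!r}")


# ---------------------------------------------------------------------------
# EMMAX scan
# ---------------------------------------------------------------------------

@dataclass
class AssocResult:
    table: pd.DataFrame          # per-SNP effect, se, p, neglog10p, significant
    sigma_g2: float
    sigma_e2: float
    delta: float                 # se2 / sg2
    threshold: float             # -log10(p) significance cut-off
    lambda_gc: float | None = None


def _reml_delta(s: np.ndarray, ystar: np.ndarray, xstar: np.ndarray) -> float:
    """One-dimensional REML for delta = se2/sg2 on the rotated data.

    Brent search on log(delta) in [-10, 10]; ``s`` are the eigenvalues of
    K, ``ystar``/``xstar`` the eigenvector-rotated phenotype and fixed
    effects.
    """
    n, p = xstar.shape

    def neg_restricted_ll(log_delta: float) -> float:
        w = s + np.exp(log_delta)
        xw = xstar / w[:, None]
        xtwx = xstar.T @ xw
        beta = np.linalg.solve(xtwx, xw.T @ ystar)
        r = ystar - xstar @ beta
        rss = float(r @ (r / w))
        sign, logdet_xtwx = np.linalg.slogdet(xtwx)
        if sign <= 0 or rss <= 0:
            return np.inf
        return 0.5 * (
            (n - p) * np.log(rss / (n - p)) + np.log(w).sum() + logdet_xtwx
        )

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(-10.0, 10.0), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def emmax_scan(
    panel: GenotypePanel,
    phenotype,
    k: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    threshold: float = 5.75,
) -> AssocResult:
    """Single-marker mixed-model scan of ``phenotype`` over all SNPs.

    Parameters
    ----------
    panel : GenotypePanel
        Post-QC genotypes aligned to the phenotype vector.
    phenotype : array-like (n,)
        Typically the composite D value (or a per-trait DI column).
    k : (n, n) array, optional
        Relatedness matrix; computed from the panel (VanRaden) if omitted.
    covariates : (n, c) array, optional
        Extra fixed effects; an intercept is always included.
    threshold : float
        Genome-wide significance cut-off on -log10(p) (strict inequality).

    Notes
    -----
    Variance components are estimated once under the null by REML; each
    marker is then tested by GLS on the spectrally rotated data, with a
    two-sided p from the t distribution on n - rank(X) - 1 degrees of
    freedom.  Missing genotypes are mean-imputed per SNP.  p-values are
    carried in log space so -log10(p) does not underflow.
    """
    y = np.asarray(phenotype, dtype=float)
    n = panel.n_accessions
    if y.shape != (n,):
        raise AssociationError(
            f"phenotype length {y.size} does not match {n} accessions"
        )
    if np.ptp(y) == 0:
        raise AssociationError("constant phenotype")
    if k is None:
        k = kinship(panel)
    k = np.asarray(k, dtype=float)
    if k.shape != (n, n) or not np.allclose(k, k.T, atol=1e-8):
        raise AssociationError("K must be a symmetric n x n matrix")

    s, u = np.linalg.eigh(k)
    if s[0] < -1e-6 * max(1.0, s[-1]):
        raise AssociationError("K is not positive semi-definite")
    s = np.clip(s, 0.0, None)

    x = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        x = np.hstack([x, cov])
    p_fixed = np.linalg.matrix_rank(x)

    ystar = u.T @ y
    xstar = u.T @ x
    delta = _reml_delta(s, ystar, xstar)
    w = s + delta
    sqrt_w = np.sqrt(w)

    # null-model variance components
    xw = xstar / w[:, None]
    beta0 = np.linalg.solve(xstar.T @ xw, xw.T @ ystar)
    r0 = ystar - xstar @ beta0
    sigma_g2 = float(r0 @ (r0 / w)) / (n - p_fixed)
    sigma_e2 = delta * sigma_g2

    # rotate + whiten once, then project out fixed effects
    yt = ystar / sqrt_w
    xt = xstar / sqrt_w[:, None]
    q, _ = np.linalg.qr(xt)
    yr = yt - q @ (q.T @ yt)

    g = _imputed_dosage(panel.genotypes)
    gstar = (u.T @ g) / sqrt_w[:, None]
    gr = gstar - q @ (q.T @ gstar)

    gg = np.einsum("ij,ij->j", gr, gr)
    gy = gr.T @ yr
    yy = float(yr @ yr)
    df = n - p_fixed - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(gg > 0, gy / gg, 0.0)
        rss = np.maximum(yy - beta * gy, 0.0)
        se = np.sqrt(rss / df / np.where(gg > 0, gg, np.nan))
        tstat = beta / se
    logp = np.log(2.0) + stats.t.logsf(np.abs(tstat), df)
    neglog10p = np.where(np.isfinite(tstat), -logp / LOG10, 0.0)
    pval = np.where(np.isfinite(tstat), np.exp(np.minimum(logp, 0.0)), 1.0)

    table = panel.sites.copy()
    table["maf"] = panel.maf()
    table["beta"] = np.where(np.isfinite(tstat), beta, 0.0)
    table["se"] = se
    table["p"] = pval
    table["neglog10p"] = neglog10p
    table["significant"] = neglog10p > threshold
    result = AssocResult(
        table=table,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta,
        threshold=threshold,
    )
    result.lambda_gc = genomic_inflation(table["p"].to_numpy())
    return result


def significance_filter(result: AssocResult, threshold: float | None = None) -> pd.DataFrame:
    """SNPs with -log10(p) strictly above the threshold (may be empty)."""
    if len(result.table) == 0:
        raise AssociationError("empty association result")
    thr = result.threshold if threshold is None else threshold
    return result.table[result.table["neglog10p"] > thr].reset_index(drop=True)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def genomic_inflation(pvalues: np.ndarray) -> float:
    """lambda_GC: median observed association chi-square over its null
    median (chi2_1, ~0.4549)."""
    chi2 = stats.chi2.isf(np.clip(pvalues, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.median(df=1))


def diagnostics(result: AssocResult) -> tuple[pd.DataFrame, float]:
    """QQ table (expected vs observed -log10 p quantiles) and lambda_GC."""
    p = result.table["p"].to_numpy()
    if p.size < 10:
        raise AssociationError("need at least 10 SNPs for diagnostics")
    obs = np.sort(result.table["neglog10p"].to_numpy())
    m = p.size
    expected = -np.log10((np.arange(m, 0, -1) - 0.5) / m)
    qq = pd.DataFrame({"expected": np.sort(expected), "observed": obs})
    return qq, genomic_inflation(p)
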