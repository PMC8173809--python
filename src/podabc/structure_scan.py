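"""Population-structure summaries and the selection-outlier scan.

``classical_mds`` embeds an identity-by-state distance matrix by Torgerson
double-centering; ``pca_genotypes`` is a frequency-scaled genotype PCA; and
``pcadapt_scan`` flags SNPs whose association with the leading K principal
components is an outlier: per-SNP z-scores from multiple regression on the
PC scores, a robust Mahalanobis distance across SNPs, rescaling by the
genomic inflation factor, chi-square(K) p-values and Storey q-values.
SNPs below the chosen false-discovery-rate cut-off are reported for removal
so that downstream demographic inference uses putatively neutral loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotype_io import MISSING, GenotypeDataset
from .popgen_stats import DistanceMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# classical (metric) MDS
# ---------------------------------------------------------------------------

def classical_mds(dist, k: int = 2) -> np.ndarray:
    """Torgerson MDS: double-center the squared distances, keep the top-k
    eigenvectors scaled by the square root of their eigenvalues.  Negative
    eigenvalues (non-Euclidean input) are truncated with a logged warning.
    Exact for Euclidean distance matrices of rank <= k."""
    d = dist.matrix if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if (w < -1e-8 * max(1.0, abs(w[0]))).any():
        logger.warning("MDS: truncating negative eigenvalues "
                       "(non-Euclidean distances)")
    lam = np.clip(w[:k], 0.0, None)
    return v[:, :k] * np.sqrt(lam)[None, :]


# ---------------------------------------------------------------------------
# genotype PCA
# ---------------------------------------------------------------------------

def _scaled_genotypes(ds: GenotypeDataset) -> np.ndarray:
    """Center each SNP by 2p and scale by sqrt(p(1-p)); missing genotypes
    are imputed at the column mean (0 after centering); monomorphic SNPs
    become all-zero columns."""
    g = ds.genotypes.astype(float)
    g[ds.genotypes == MISSING] = np.nan
    p = ds.allele_freq()
    x = g - 2.0 * p[None, :]
    sd = np.sqrt(p * (1.0 - p))
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(sd > 0, x / sd[None, :], 0.0)
    return np.nan_to_num(x)


def pca_genotypes(ds: GenotypeDataset, K: int):
    """Truncated PCA of the scaled genotype matrix.

    Returns (scores, loadings, eigenvalues): scores is n_samples x K,
    loadings n_snps x K, eigenvalues the non-increasing variances of the
    components (singular values squared over the SNP count).
    """
    if K >= ds.n_samples:
        raise ValueError("K must be smaller than the number of samples")
    x = _scaled_genotypes(ds)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :K] * s[None, :K]
    loadings = vt[:K].T
    eigenvalues = (s[:K] ** 2) / ds.n_snps
    return scores, loadings, eigenvalues


# ---------------------------------------------------------------------------
# robust covariance (orthogonalized Gnanadesikan-Kettenring)
# ---------------------------------------------------------------------------

def _mad_scale(x: np.ndarray) -> np.ndarray:
    return 1.4826 * np.median(np.abs(x - np.median(x, axis=0)), axis=0)


def ogk_location_cov(z: np.ndarray, reweight: bool = True):
    """Maronna-Zamar orthogonalized Gnanadesikan-Kettenring estimate of
    location and covariance, with one optional hard-rejection reweighting
    step at the chi-square(K) 0.9 quantile."""
    n, k = z.shape
    d = _mad_scale(z)
    d[d == 0] = 1.0
    y = z / d
    u = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            sp = _mad_scale((y[:, a] + y[:, b])[:, None])[0]
            sm = _mad_scale((y[:, a] - y[:, b])[:, None])[0]
            u[a, b] = u[b, a] = 0.25 * (sp ** 2 - sm ** 2)
    _w, e = np.linalg.eigh(u)
    v = y @ e
    gamma = _mad_scale(v) ** 2
    gamma[gamma == 0] = 1e-12
    med = np.median(v, axis=0)
    loc = d * (e @ med)
    cov = (d[:, None] * e) @ np.diag(gamma) @ (e.T * d[None, :])
    if reweight:
        dist = _mahalanobis_sq(z, loc, cov)
        q = stats.chi2.ppf(0.9, k)
        cut = q * np.median(dist) / stats.chi2.ppf(0.5, k)
        keep = dist <= cut
        if keep.sum() > k + 1:
            zi = z[keep]
            loc = zi.mean(axis=0)
            # consistency factor for hard rejection at the 0.9 quantile
            c = stats.chi2.cdf(q, k + 2) / 0.9
            cov = np.cov(zi, rowvar=False) / c
    return loc, cov


def _mahalanobis_sq(z, loc, cov) -> np.ndarray:
    delta = z - loc[None, :]
    sol = np.linalg.solve(cov, delta.T)
    return np.einsum("ij,ji->i", delta, sol)


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_qvalues(pvalues, lambda_: float = 0.5, pi0: float | None = None,
                   smoother: bool = False) -> np.ndarray:
    """Storey q-values with a fixed-lambda pi0 estimate by default.

    ``pi0=1`` reduces to Benjamini-Hochberg adjusted p-values.  The
    optional smoother fits a cubic in lambda over a grid and evaluates it
    at the largest lambda (closer to the qvalue package's default but less
    stable at small SNP counts).
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is None:
        if smoother:
            grid = np.arange(0.05, 0.95, 0.05)
            pi0s = np.array([(p > lam).mean() / (1 - lam) for lam in grid])
            coef = np.polyfit(grid, pi0s, 3)
            pi0 = float(np.polyval(coef, grid[-1]))
        else:
            pi0 = (p > lambda_).mean() / (1.0 - lambda_)
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        val = min(pi0 * m * p[i] / (rank + 1), prev)
        q[i] = val
        prev = val
    return q


# ---------------------------------------------------------------------------
# pcadapt-style outlier scan
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    snp_ids: list
    zscores: np.ndarray          # n_snps x K
    stat: np.ndarray             # Mahalanobis distance squared, GIF-rescaled
    pvalues: np.ndarray
    qvalues: np.ndarray
    gif: float
    removed_snp_ids: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_snp_ids)


def pcadapt_scan(ds: GenotypeDataset, K: int = 5, fdr: float = 0.001,
                 robust: bool = True) -> OutlierReport:
    """Mahalanobis outlier scan on per-SNP principal-component z-scores.

    Each scaled SNP is regressed on the K retained PC score vectors giving K
    z-scores; their squared Mahalanobis distance (robust OGK location and
    covariance by default, classical with ``robust=False``) is divided by
    the genomic inflation factor (median distance over the chi-square(K)
    median), compared to the chi-square(K) upper tail, and converted to
    Storey q-values.  SNPs with q < ``fdr`` are reported as outliers.
    """
    scores, _loadings, _eig = pca_genotypes(ds, K)
    x = _scaled_genotypes(ds)
    n = ds.n_samples
    gtg_inv = np.linalg.inv(scores.T @ scores)
    beta = gtg_inv @ scores.T @ x                    # K x m
    resid = x - scores @ beta
    dof = max(n - K, 1)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(gtg_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, beta / se, 0.0).T       # m x K
    z = np.nan_to_num(z)

    if robust:
        loc, cov = ogk_location_cov(z)
    else:
        loc, cov = z.mean(axis=0), np.cov(z, rowvar=False)
    d2 = _mahalanobis_sq(z, loc, cov)
    gif = float(np.median(d2) / stats.chi2.ppf(0.5, K))
    d2_adj = d2 / gif if gif > 0 else d2
    pvals = stats.chi2.sf(d2_adj, K)
    qvals = storey_qvalues(pvals)
    removed = [ds.snp_ids[j] for j in np.flatnonzero(qvals < fdr)]
    logger.info("pcadapt scan: K=%d GIF=%.3f removed %d of %d SNPs at "
                "FDR %.4g", K, gif, len(removed), ds.n_snps, fdr)
    return OutlierReport(list(ds.snp_ids), z, d2_adj, pvals, qvals, gif,
                         removed)


def remove_outliers(ds: GenotypeDataset, report: OutlierReport
                    ) -> GenotypeDataset:
    from .genotype_io import subset

    drop = set(report.removed_snp_ids)
    return subset(ds, snps=[s for s in ds.snp_ids if s not in drop])


def write_outlier_tsv(report: OutlierReport, path) -> None:
    removed = set(report.removed_snp_ids)
    with open(path, "w") as fh:
        fh.write("snp_id\tstat\tp\tq\tremoved\n")
        for j, sid in enumerate(report.snp_ids):
            fh.write(f"{sid}\t{report.stat[j]:.6g}\t{report.pvalues[j]:.6g}"
                     f"\t{report.qvalues[j]:.6g}\t"
                     f"{int(sid in removed)}\n")
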