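"""Diversity and differentiation statistics.

Per-breed observed/expected heterozygosity and mean MAF (Table-1-style
summaries), an LD-based effective-population-size trajectory (Sved's
relation between expected r² and 4Nc on a linear genetic map), genome-wide
identity-by-state distances, and the population differentiation measures
used as ABC summary statistics: the Reynolds-Weir-Cockerham coancestry
distance, Hudson's FST, Nei's standard distance and the f3 admixture
statistic.

All frequency-based statistics are invariant to swapping which allele is
labelled A1 (codes 0 and 2 exchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeDataset

# ---------------------------------------------------------------------------
# per-breed frequency machinery
# ---------------------------------------------------------------------------


def _freq_counts(geno: np.ndarray):
    """Per-SNP A1 frequency and diploid count over non-missing genotypes."""
    obs = geno != MISSING
    n = obs.sum(axis=0).astype(float)
    tot = np.where(obs, geno, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, tot / (2.0 * n), np.nan)
    return p, n


def _breed_geno(ds: GenotypeDataset, breed: str) -> np.ndarray:
    return ds.genotypes[ds.samples_of_breed(breed)]


def heterozygosity(ds: GenotypeDataset, breed: str, unbiased: bool = False):
    """Observed and expected heterozygosity, mean and SD across SNPs.

    Ho is the fraction of heterozygous non-missing genotypes per SNP; He is
    2p(1-p) from the within-breed A1 frequency.  ``unbiased`` applies the
    2n/(2n-1) small-sample correction to He (off by default, matching the
    plain PLINK report).
    """
    g = _breed_geno(ds, breed)
    obs = g != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, ((g == 1) & obs).sum(axis=0) / n, np.nan)
    p, n = _freq_counts(g)
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        with np.errstate(invalid="ignore", divide="ignore"):
            he = he * 2.0 * n / (2.0 * n - 1.0)
    return (float(np.nanmean(ho)), float(np.nanstd(ho)),
            float(np.nanmean(he)), float(np.nanstd(he)))


def mean_maf(ds: GenotypeDataset, breed: str):
    """Mean and SD across SNPs of the within-breed minor-allele frequency."""
    p, _ = _freq_counts(_breed_geno(ds, breed))
    maf = np.minimum(p, 1.0 - p)
    return float(np.nanmean(maf)), float(np.nanstd(maf))


# ---------------------------------------------------------------------------
# LD-based Ne trajectory
# ---------------------------------------------------------------------------

#: default genetic-distance bin edges in Morgans (0.05 to 5 cM)
DEFAULT_C_BINS = (0.0005, 0.001, 0.0025, 0.005, 0.01, 0.025, 0.05)


@dataclass(frozen=True)
class NeBin:
    generations_ago: float
    ne_hat: float               # NaN where undefined
    n_snp_pairs: int
    mean_r2_adj: float


@dataclass
class NeTrajectory:
    """Ne per genetic-distance bin, ordered by increasing generations ago."""

    bins: list = field(default_factory=list)

    def point_estimate(self) -> float:
        """Most recent bin with a defined Ne (the Table-1-style scalar)."""
        for b in self.bins:
            if np.isfinite(b.ne_hat):
                return b.ne_hat
        return float("nan")


def _pairwise_r2_binned(geno, chrom, pos_bp, c_edges, bp_per_morgan):
    """Sum of r² and pair count per distance bin; complete-data fast path,
    pairwise-complete loop when genotypes are missing."""
    edges_bp = np.asarray(c_edges, dtype=float) * bp_per_morgan
    max_bp = edges_bp[-1]
    n_bins = len(c_edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    complete = not (geno == MISSING).any()
    for c in np.unique(chrom.astype(str)):
        idx = np.flatnonzero(chrom.astype(str) == c)
        idx = idx[np.argsort(pos_bp[idx], kind="stable")]
        if len(idx) < 2:
            continue
        pos = pos_bp[idx].astype(float)
        g = geno[:, idx].astype(float)
        if complete:
            z = g - g.mean(axis=0)
            sd = z.std(axis=0)
            ok = sd > 0
            z[:, ok] /= sd[ok]
            n = g.shape[0]
            block = 512
            for s in range(0, len(idx), block):
                e = min(s + block, len(idx))
                r = (z[:, s:e].T @ z) / n
                for ii in range(s, e):
                    if not ok[ii]:
                        continue
                    jhi = np.searchsorted(pos, pos[ii] + max_bp, side="right")
                    js = np.arange(ii + 1, jhi)
                    js = js[ok[js]]
                    if js.size == 0:
                        continue
                    d = pos[js] - pos[ii]
                    b = np.searchsorted(edges_bp, d, side="left") - 1
                    keep = (b >= 0) & (b < n_bins) & (d > 0)
                    np.add.at(sums, b[keep], r[ii - s, js[keep]] ** 2)
                    np.add.at(counts, b[keep], 1)
        else:
            for ii in range(len(idx)):
                for jj in range(ii + 1, len(idx)):
                    d = pos[jj] - pos[ii]
                    if d > max_bp:
                        break
                    b = int(np.searchsorted(edges_bp, d, side="left")) - 1
                    if b < 0 or b >= n_bins:
                        continue
                    x, y = g[:, ii], g[:, jj]
                    m = (x != MISSING) & (y != MISSING)
                    if m.sum() < 3:
                        continue
                    xv, yv = x[m], y[m]
                    if xv.std() == 0 or yv.std() == 0:
                        continue
                    r = np.corrcoef(xv, yv)[0, 1]
                    sums[b] += r * r
                    counts[b] += 1
    return sums, counts


def ne_trajectory(ds: GenotypeDataset, breed: str, bins=DEFAULT_C_BINS,
                  cm_per_mb: float = 1.0, alpha: float = 1.0,
                  mutation_adjust: bool = False) -> NeTrajectory:
    """LD-based Ne history for one breed.

    Intra-chromosomal SNP pairs are binned by genetic distance
    c = bp * cm_per_mb * 1e-8 Morgans.  Within a bin with midpoint c,
    Ne = (1/(4c)) (1/E[r²_adj] - alpha) with the sample-size correction
    r²_adj = r² - 1/(2n) for phase-unknown genotypes of n diploids, and the
    bin dates to 1/(2c) generations ago.  ``mutation_adjust`` switches alpha
    to 2.2.  Bins with no pairs or a non-positive rate estimate carry
    Ne = NaN rather than a fabricated value.
    """
    if mutation_adjust:
        alpha = 2.2
    idx = ds.samples_of_breed(breed)
    geno = ds.genotypes[idx]
    n = len(idx)
    for c in np.unique(ds.chrom.astype(str)):
        if (ds.chrom.astype(str) == c).sum() >= 2:
            break
    else:
        raise ValueError("need at least 2 SNPs on one chromosome")
    bp_per_morgan = 1e8 / cm_per_mb
    edges = np.asarray(bins, dtype=float)
    sums, counts = _pairwise_r2_binned(geno, ds.chrom, ds.pos_bp, edges,
                                       bp_per_morgan)
    rows = []
    mids = 0.5 * (edges[:-1] + edges[1:])
    for b in range(len(mids) - 1, -1, -1):   # large c first = recent first
        c_mid = mids[b]
        gen = 1.0 / (2.0 * c_mid)
        if counts[b] == 0:
            rows.append(NeBin(gen, float("nan"), 0, float("nan")))
            continue
        mean_r2 = sums[b] / counts[b] - 1.0 / (2.0 * n)
        ne = float("nan")
        if mean_r2 > 0:
            val = (1.0 / mean_r2 - alpha) / (4.0 * c_mid)
            if val > 0:
                ne = val
        rows.append(NeBin(gen, ne, int(counts[b]), float(mean_r2)))
    return NeTrajectory(rows)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.labels),) * 2:
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                fh.write(lab + "\t"
                         + "\t".join(f"{v:.8g}" for v in self.matrix[i])
                         + "\n")

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                fh.write(f"{lab:<10s} "
                         + " ".join(f"{v:.8g}" for v in self.matrix[i])
                         + "\n")


def ibs_distance(ds: GenotypeDataset) -> DistanceMatrix:
    """1 - (mean proportion of alleles shared identical-by-state), over SNPs
    non-missing in both samples of a pair."""
    g = ds.genotypes.astype(np.int16)
    obs = g != MISSING
    n = ds.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        both = obs[i] & obs[i + 1:]
        diff = np.abs(g[i] - g[i + 1:])
        share = np.where(both, 2 - diff, 0).sum(axis=1)
        cnt = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            dij = 1.0 - np.where(cnt > 0, share / (2.0 * cnt), np.nan)
        d[i, i + 1:] = dij
        d[i + 1:, i] = dij
    return DistanceMatrix(list(ds.sample_ids), d)


# ---------------------------------------------------------------------------
# population differentiation
# ---------------------------------------------------------------------------

def _two_pop_freqs(ds, breedA, breedB, by_group=False):
    sel = ds.samples_of_group if by_group else ds.samples_of_breed
    p1, n1 = _freq_counts(ds.genotypes[sel(breedA)])
    p2, n2 = _freq_counts(ds.genotypes[sel(breedB)])
    ok = np.isfinite(p1) & np.isfinite(p2) & (n1 > 1) & (n2 > 1)
    return p1[ok], n1[ok], p2[ok], n2[ok]


def reynolds_distance(ds: GenotypeDataset, breedA: str, breedB: str,
                      unbiased: bool = True, linearized: bool = False,
                      by_group: bool = False) -> float:
    """Reynolds-Weir-Cockerham coancestry distance theta.

    Ratio-of-sums over loci of the least-squares drift estimator; with
    ``unbiased=False`` the sample-size correction is dropped (pure
    frequency input: identical frequency vectors give exactly 0).
    ``linearized`` returns -ln(1 - theta).
    """
    p1, n1, p2, n2 = _two_pop_freqs(ds, breedA, breedB, by_group)
    dsq = (p1 - p2) ** 2
    if unbiased:
        h1 = 2.0 * n1 * 2.0 * p1 * (1 - p1) / (2.0 * n1 - 1.0)
        h2 = 2.0 * n2 * 2.0 * p2 * (1 - p2) / (2.0 * n2 - 1.0)
        hsum = n1 * h1 + n2 * h2
        denom4 = 4.0 * n1 * n2 * (n1 + n2 - 1.0)
        a = dsq - (n1 + n2) * hsum / denom4
        b = (4.0 * n1 * n2 - n1 - n2) * hsum / denom4
    else:
        a = dsq
        b = p1 * (1 - p1) + p2 * (1 - p2)
    tot = np.sum(a) + np.sum(b)
    theta = float(np.sum(a) / tot) if tot != 0 else 0.0
    if linearized:
        theta = float(-np.log(max(1.0 - theta, 1e-300)))
    return theta


def hudson_fst(ds: GenotypeDataset, breedA: str, breedB: str,
               by_group: bool = False) -> float:
    """Hudson's FST estimator, ratio of averages across SNPs."""
    p1, n1, p2, n2 = _two_pop_freqs(ds, breedA, breedB, by_group)
    nh1, nh2 = 2.0 * n1, 2.0 * n2
    num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (nh1 - 1)
           - p2 * (1 - p2) / (nh2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    tot = np.sum(den)
    return float(np.sum(num) / tot) if tot != 0 else 0.0


def nei_distance(ds: GenotypeDataset, breedA: str, breedB: str,
                 by_group: bool = False) -> float:
    """Nei's (1972) standard genetic distance from biallelic frequencies."""
    p1, _n1, p2, _n2 = _two_pop_freqs(ds, breedA, breedB, by_group)
    jx = np.mean(p1 ** 2 + (1 - p1) ** 2)
    jy = np.mean(p2 ** 2 + (1 - p2) ** 2)
    jxy = np.mean(p1 * p2 + (1 - p1) * (1 - p2))
    if jxy <= 0:
        return float("inf")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def f3_statistic(ds: GenotypeDataset, target: str, source1: str,
                 source2: str, by_group: bool = False) -> float:
    """f3(T; A, B): mean over SNPs of (pT-pA)(pT-pB) with the small-sample
    bias correction for the target frequency (raw covariance form, no
    heterozygosity normalization).  Significantly negative values indicate
    that T is a mixture of sources related to A and B."""
    sel = ds.samples_of_group if by_group else ds.samples_of_breed
    pt, nt = _freq_counts(ds.genotypes[sel(target)])
    pa, na = _freq_counts(ds.genotypes[sel(source1)])
    pb, nb = _freq_counts(ds.genotypes[sel(source2)])
    ok = (np.isfinite(pt) & np.isfinite(pa) & np.isfinite(pb)
          & (2 * nt > 1))
    pt, pa, pb, nt = pt[ok], pa[ok], pb[ok], nt[ok]
    corr = pt * (1 - pt) / (2.0 * nt - 1.0)
    return float(np.mean((pt - pa) * (pt - pb) - corr))


# ---------------------------------------------------------------------------
# Table-1-style per-breed summary
# ---------------------------------------------------------------------------

def diversity_summary(ds: GenotypeDataset, breeds=None, with_ne=False,
                      **ne_kwargs):
    """Per-breed Ho/He/MAF means and SDs (and optionally the LD-based Ne
    point estimate) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for breed in (breeds or ds.pop_map.breeds()):
        idx = ds.samples_of_breed(breed)
        ho_m, ho_s, he_m, he_s = heterozygosity(ds, breed)
        maf_m, maf_s = mean_maf(ds, breed)
        row = {"breed": breed, "n": len(idx),
               "Ho_mean": ho_m, "Ho_sd": ho_s,
               "He_mean": he_m, "He_sd": he_s,
               "MAF_mean": maf_m, "MAF_sd": maf_s}
        if with_ne:
            row["Ne"] = ne_trajectory(ds, breed, **ne_kwargs).point_estimate()
        rows.append(row)
    return pd.DataFrame(rows)
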