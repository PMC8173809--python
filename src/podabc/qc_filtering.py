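"""SNP quality-control filters: MAF, call rate, and LD pruning.

The pipeline mirrors the PLINK conventions it emulates: the MAF filter keeps
sites with pooled minor-allele frequency >= the threshold, the call-rate
filter removes sites whose missing fraction exceeds the threshold, and the
two LD pruners slide a fixed-size SNP window along each chromosome removing
sites either pairwise (squared genotype correlation above r2_max) or by
variance-inflation factor.  r² is the squared Pearson correlation of
allele-count vectors over samples non-missing at both SNPs — not the
haplotype-EM r².  All filters are idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeDataset, subset

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    n_input: int
    n_removed_maf: int = 0
    n_removed_geno: int = 0
    n_removed_ld: int = 0
    kept_snp_ids: list = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return len(self.kept_snp_ids)

    def validate(self) -> None:
        total = (self.n_kept + self.n_removed_maf + self.n_removed_geno
                 + self.n_removed_ld)
        if total != self.n_input:
            raise ValueError("filter report counts do not add up")

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "n_removed_maf": self.n_removed_maf,
                "n_removed_geno": self.n_removed_geno,
                "n_removed_ld": self.n_removed_ld, "n_kept": self.n_kept}


def _keep(ds: GenotypeDataset, mask: np.ndarray) -> GenotypeDataset:
    return subset(ds, snps=[ds.snp_ids[j] for j in np.flatnonzero(mask)])


def filter_maf(ds: GenotypeDataset, min_maf: float = 0.05):
    """Remove SNPs whose pooled MAF (over non-missing genotypes) is below
    ``min_maf``; the boundary value is kept."""
    p = ds.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    keep = np.isfinite(maf) & (maf >= min_maf)
    if not keep.any():
        raise ValueError(f"MAF filter at {min_maf} removed every SNP")
    rep = FilterReport(ds.n_snps, n_removed_maf=int((~keep).sum()),
                       kept_snp_ids=list(ds.snp_ids[keep]))
    rep.validate()
    return _keep(ds, keep), rep


def filter_call_rate(ds: GenotypeDataset, max_missing: float = 0.01):
    """Remove SNPs whose missing-genotype fraction exceeds ``max_missing``
    (strict inequality, so the boundary value is kept)."""
    miss = (ds.genotypes == MISSING).mean(axis=0)
    keep = miss <= max_missing
    rep = FilterReport(ds.n_snps, n_removed_geno=int((~keep).sum()),
                       kept_snp_ids=list(ds.snp_ids[keep]))
    rep.validate()
    return _keep(ds, keep), rep


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _sorted_order(ds: GenotypeDataset) -> np.ndarray:
    chrom = ds.chrom.astype(str)
    return np.lexsort((ds.pos_bp, chrom))


def _pairwise_r2(g: np.ndarray) -> np.ndarray:
    """r² matrix over samples non-missing at both SNPs of each pair."""
    if not (g == MISSING).any():
        z = g.astype(float)
        z -= z.mean(axis=0)
        sd = z.std(axis=0)
        sd[sd == 0] = np.inf          # monomorphic: correlation 0 with all
        z /= sd
        r = (z.T @ z) / g.shape[0]
        return r ** 2
    m = g.shape[1]
    r2 = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            mask = (g[:, i] != MISSING) & (g[:, j] != MISSING)
            if mask.sum() < 3:
                continue
            x, y = g[mask, i].astype(float), g[mask, j].astype(float)
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    return r2


def _maf_of(ds: GenotypeDataset) -> np.ndarray:
    p = ds.allele_freq()
    return np.minimum(p, 1.0 - p)


def _prune_loser(i, j, maf, order_rank):
    """Which member of an over-correlated pair to drop: the one with lower
    MAF; on a tie, the later SNP in map order."""
    if maf[i] < maf[j]:
        return i
    if maf[j] < maf[i]:
        return j
    return i if order_rank[i] > order_rank[j] else j


def ld_prune_pairwise(ds: GenotypeDataset, window: int = 50, step: int = 10,
                      r2_max: float = 0.1):
    """Greedy sliding-window pairwise pruning (PLINK --indep-pairwise).

    Within each window of ``window`` currently-kept SNPs, pairs with
    r² > ``r2_max`` lose one member; the window slides by ``step`` SNPs and
    the whole scan repeats until no SNP is removed, so the surviving set has
    no within-window pair above the threshold.
    """
    if window < 2:
        raise ValueError("window must cover at least 2 SNPs")
    order = _sorted_order(ds)
    chrom = ds.chrom.astype(str)
    maf = _maf_of(ds)
    rank = np.empty(ds.n_snps, dtype=int)
    rank[order] = np.arange(ds.n_snps)

    kept = {c: [j for j in order if chrom[j] == c]
            for c in dict.fromkeys(chrom[order])}
    changed = True
    while changed:
        changed = False
        for c, snps in kept.items():
            start = 0
            while start < len(snps):
                win = snps[start:start + window]
                if len(win) >= 2:
                    r2 = _pairwise_r2(ds.genotypes[:, win])
                    alive = set(range(len(win)))
                    removed_local = True
                    while removed_local:
                        removed_local = False
                        for a in sorted(alive):
                            for b in sorted(alive):
                                if b <= a:
                                    continue
                                if r2[a, b] > r2_max:
                                    lose = _prune_loser(win[a], win[b], maf,
                                                        rank)
                                    alive.discard(win.index(lose))
                                    removed_local = True
                                    changed = True
                                    break
                            if removed_local:
                                break
                    if len(alive) < len(win):
                        keep_set = {win[a] for a in alive}
                        kept[c] = [s for s in kept[c]
                                   if s in keep_set or s not in win]
                        snps = kept[c]
                start += step
    kept_idx = sorted(j for snps in kept.values() for j in snps)
    mask = np.zeros(ds.n_snps, dtype=bool)
    mask[kept_idx] = True
    rep = FilterReport(ds.n_snps, n_removed_ld=int((~mask).sum()),
                       kept_snp_ids=list(ds.snp_ids[mask]))
    rep.validate()
    logger.info("indep-pairwise %d %d %.3g: kept %d of %d SNPs",
                window, step, r2_max, rep.n_kept, rep.n_input)
    return _keep(ds, mask), rep


def _window_vifs(g: np.ndarray) -> np.ndarray:
    """VIF of each SNP in a window: 1/(1-R²) from least-squares regression
    of that SNP on all the others (mean-imputed missing genotypes)."""
    x = g.astype(float)
    miss = g == MISSING
    if miss.any():
        x[miss] = np.nan
        col_mean = np.nan_to_num(np.nanmean(x, axis=0))
        rr, cc = np.where(miss)
        x[rr, cc] = col_mean[cc]
    x = x - x.mean(axis=0)
    m = x.shape[1]
    vifs = np.empty(m)
    for j in range(m):
        y = x[:, j]
        sst = float(y @ y)
        if sst == 0:
            vifs[j] = 1.0
            continue
        others = np.delete(x, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        r2 = 1.0 - float(resid @ resid) / sst
        vifs[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return vifs


def ld_prune_vif(ds: GenotypeDataset, window: int = 50, step: int = 5,
                 vif_max: float = 1.2):
    """Sliding-window VIF pruning (PLINK --indep): within each window the
    SNP with the largest variance-inflation factor is removed, worst first,
    until all VIFs are <= ``vif_max``; repeated to a fixed point."""
    if window < 2:
        raise ValueError("window must cover at least 2 SNPs")
    order = _sorted_order(ds)
    chrom = ds.chrom.astype(str)
    kept = {c: [j for j in order if chrom[j] == c]
            for c in dict.fromkeys(chrom[order])}
    changed = True
    while changed:
        changed = False
        for c, snps in kept.items():
            start = 0
            while start < len(snps):
                win = snps[start:start + window]
                while len(win) >= 2:
                    vifs = _window_vifs(ds.genotypes[:, win])
                    worst = int(np.argmax(vifs))
                    if vifs[worst] <= vif_max:
                        break
                    removed = win[worst]
                    win = [s for s in win if s != removed]
                    kept[c] = [s for s in kept[c] if s != removed]
                    snps = kept[c]
                    changed = True
                start += step
    kept_idx = sorted(j for snps in kept.values() for j in snps)
    mask = np.zeros(ds.n_snps, dtype=bool)
    mask[kept_idx] = True
    rep = FilterReport(ds.n_snps, n_removed_ld=int((~mask).sum()),
                       kept_snp_ids=list(ds.snp_ids[mask]))
    rep.validate()
    logger.info("indep (VIF) %d %d %.3g: kept %d of %d SNPs",
                window, step, vif_max, rep.n_kept, rep.n_input)
    return _keep(ds, mask), rep


def qc_pipeline(ds: GenotypeDataset, min_maf: float = 0.05,
                max_missing: float = 0.01, prune=("pairwise", 50, 10, 0.1)):
    """MAF -> call-rate -> LD pruning, in the fixed pipeline order.

    ``prune`` is ``("pairwise", window, step, r2_max)``,
    ``("vif", window, step, vif_max)`` or ``None``.  Returns the filtered
    dataset and one FilterReport accumulating all removals.
    """
    n_input = ds.n_snps
    ds1, rep_maf = filter_maf(ds, min_maf)
    ds2, rep_cr = filter_call_rate(ds1, max_missing)
    if prune is None:
        ds3, n_ld = ds2, 0
    elif prune[0] == "pairwise":
        ds3, rep_ld = ld_prune_pairwise(ds2, *prune[1:])
        n_ld = rep_ld.n_removed_ld
    elif prune[0] == "vif":
        ds3, rep_ld = ld_prune_vif(ds2, *prune[1:])
        n_ld = rep_ld.n_removed_ld
    else:
        raise ValueError(f"unknown pruning mode {prune[0]!r}")
    rep = FilterReport(n_input, n_removed_maf=rep_maf.n_removed_maf,
                       n_removed_geno=rep_cr.n_removed_geno,
                       n_removed_ld=n_ld, kept_snp_ids=list(ds3.snp_ids))
    rep.validate()
    return ds3, rep
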