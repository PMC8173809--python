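"""Genotype data model and PLINK-dialect text I/O.

The central container is :class:`GenotypeDataset`: a samples x SNPs matrix of
A1-allele counts (0/1/2, missing = :data:`MISSING`) with per-SNP metadata
(chromosome, 1-based physical position, allele pair) and a
:class:`PopulationMap` assigning every sample to a breed and every breed to
one of a fixed set of geographic groups.

File formats are the space-delimited PLINK text PED/MAP dialect ("0 0" for a
missing genotype), a simple transposed TSV matrix for small fixtures, and
two-column TSV population maps.  Binary BED/BIM/FAM and VCF are out of scope.

The reader orients every SNP deterministically: A1 is the lexicographically
smaller of the two observed alleles.  Datasets already in this orientation
(everything produced by this package) round-trip through write/read with
bit-identical genotype codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype.  Never 0: 0 means "homozygous A2".
MISSING = -1

#: Fixed vocabulary of geographic group labels.
GROUPS = (
    "indicine",
    "african_taurine",
    "nonpodolian_taurine",
    "italian_podolian",
    "balkan_podolian",
    "se_podolian",
    "other",
)

#: The five groups used by the demographic scenarios, in canonical order.
ABC_GROUPS = (
    "indicine",
    "nonpodolian_taurine",
    "italian_podolian",
    "balkan_podolian",
    "se_podolian",
)


@dataclass
class PopulationMap:
    """sample -> breed -> group assignment.

    ``sample_to_breed`` maps each sample id to a breed code;
    ``breed_to_group`` maps each breed code to a label in :data:`GROUPS`.
    """

    sample_to_breed: dict = field(default_factory=dict)
    breed_to_group: dict = field(default_factory=dict)

    def validate(self, sample_ids) -> None:
        for s in sample_ids:
            if s not in self.sample_to_breed:
                raise ValueError(f"sample {s!r} has no breed assignment")
            b = self.sample_to_breed[s]
            if b not in self.breed_to_group:
                raise ValueError(f"breed {b!r} has no group assignment")
        for b, g in self.breed_to_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r} for breed {b!r}")

    def group_of(self, sample: str) -> str:
        return self.breed_to_group[self.sample_to_breed[sample]]

    def breeds(self):
        return sorted(set(self.sample_to_breed.values()))

    def samples_of_breed(self, breed: str, sample_ids):
        return [s for s in sample_ids if self.sample_to_breed.get(s) == breed]

    def samples_of_group(self, group: str, sample_ids):
        if group not in GROUPS:
            raise ValueError(f"unknown group label {group!r}")
        return [s for s in sample_ids
                if self.group_of(s) == group]

    def subset(self, sample_ids) -> "PopulationMap":
        s2b = {s: self.sample_to_breed[s] for s in sample_ids}
        return PopulationMap(s2b, dict(self.breed_to_group))


@dataclass
class GenotypeDataset:
    """Diploid biallelic genotypes for a panel of samples.

    ``genotypes[i, j]`` counts copies of allele A1 of SNP ``j`` carried by
    sample ``i`` (0, 1, 2, or :data:`MISSING`).
    """

    sample_ids: list
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    genotypes: np.ndarray
    pop_map: PopulationMap

    # -- construction ------------------------------------------------------
    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.a1 = np.asarray(self.a1, dtype=object)
        self.a2 = np.asarray(self.a2, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def alleles(self):
        return list(zip(self.a1, self.a2))

    def validate(self) -> None:
        if len(set(self.sample_ids)) != self.n_samples:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != self.n_snps:
            raise ValueError("duplicate snp ids")
        if self.genotypes.shape != (self.n_samples, self.n_snps):
            raise ValueError("genotype matrix shape does not match ids")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,missing}")
        for c in np.unique(self.chrom.astype(str)):
            pos = self.pos_bp[self.chrom.astype(str) == c]
            pos = np.sort(pos)
            if len(pos) > 1 and (np.diff(pos) <= 0).any():
                raise ValueError(f"duplicate positions on chromosome {c}")
        self.pop_map.validate(self.sample_ids)

    # -- convenience -------------------------------------------------------
    def samples_of_breed(self, breed: str):
        idx = [i for i, s in enumerate(self.sample_ids)
               if self.pop_map.sample_to_breed[s] == breed]
        if not idx:
            raise ValueError(f"no samples for breed {breed!r}")
        return np.asarray(idx)

    def samples_of_group(self, group: str):
        idx = [i for i, s in enumerate(self.sample_ids)
               if self.pop_map.group_of(s) == group]
        if not idx:
            raise ValueError(f"no samples for group {group!r}")
        return np.asarray(idx)

    def allele_freq(self, sample_idx=None) -> np.ndarray:
        """Per-SNP A1 frequency over non-missing genotypes (NaN if none)."""
        g = self.genotypes if sample_idx is None else self.genotypes[sample_idx]
        obs = g != MISSING
        n_obs = obs.sum(axis=0)
        tot = np.where(obs, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, tot / (2.0 * n_obs), np.nan)


def from_arrays(genotypes, breeds, breed_to_group, chrom=None, pos_bp=None,
                snp_ids=None, sample_ids=None, a1=None, a2=None) -> GenotypeDataset:
    """Build a dataset from a genotype matrix and per-sample breed labels."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if sample_ids is None:
        sample_ids = [f"{breeds[i]}_{i:04d}" for i in range(n)]
    if snp_ids is None:
        snp_ids = np.array([f"snp{j:06d}" for j in range(m)], dtype=object)
    if chrom is None:
        # round-robin over the 29 cattle autosomes, positions spaced 100 kb
        chrom = np.array([str(j % 29 + 1) for j in range(m)], dtype=object)
        pos_bp = np.array([(j // 29 + 1) * 100_000 for j in range(m)])
    if a1 is None:
        a1 = np.array(["A"] * m, dtype=object)
        a2 = np.array(["G"] * m, dtype=object)
    pm = PopulationMap({s: b for s, b in zip(sample_ids, breeds)},
                       dict(breed_to_group))
    return GenotypeDataset(list(sample_ids), snp_ids, chrom, pos_bp,
                           np.asarray(a1, dtype=object),
                           np.asarray(a2, dtype=object), genotypes, pm)


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path, pop_map=None) -> GenotypeDataset:
    """Read space-delimited PLINK text PED/MAP files.

    A1 is the lexicographically smaller observed allele; "0 0" is missing.
    Breeds default to the PED family id (column 1) with group ``other``
    unless ``pop_map`` is supplied.
    """
    snp_ids, chroms, pos = [], [], []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise ValueError(f"{map_path}: line {ln}: expected 3 or 4 "
                                 f"columns, got {len(parts)}")
            chroms.append(parts[0])
            snp_ids.append(parts[1])
            pos.append(int(parts[-1]))
    m = len(snp_ids)

    sample_ids, fids, rows = [], [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * m} columns "
                    f"for {m} MAP SNPs, got {len(parts)}")
            fids.append(parts[0])
            sample_ids.append(parts[1])
            rows.append(parts[6:])
    alle = np.array(rows, dtype=object).reshape(len(rows), m, 2)

    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    geno = np.full((len(rows), m), MISSING, dtype=np.int8)
    for j in range(m):
        col = alle[:, j, :]
        obs = col[col != "0"]
        uniq = sorted(set(obs.tolist()))
        if len(uniq) > 2:
            raise ValueError(f"SNP {snp_ids[j]} is not biallelic: "
                             f"alleles {uniq}")
        a1[j] = uniq[0] if uniq else "0"
        a2[j] = uniq[1] if len(uniq) > 1 else "0"
        present = (col[:, 0] != "0") & (col[:, 1] != "0")
        geno[present, j] = ((col[present, 0] == a1[j]).astype(np.int8)
                            + (col[present, 1] == a1[j]).astype(np.int8))

    if pop_map is None:
        pop_map = PopulationMap({s: f for s, f in zip(sample_ids, fids)},
                                {f: "other" for f in fids})
    ds = GenotypeDataset(sample_ids, np.array(snp_ids, dtype=object),
                         np.array(chroms, dtype=object), np.array(pos),
                         a1, a2, geno, pop_map)
    ds.validate()
    return ds


def write_plink_text(ds: GenotypeDataset, ped_path, map_path) -> None:
    """Write PED/MAP text files; ``read_plink_text`` inverts this exactly
    for datasets whose A1 is the lexicographically smaller allele."""
    with open(map_path, "w") as fh:
        for j in range(ds.n_snps):
            fh.write(f"{ds.chrom[j]} {ds.snp_ids[j]} 0 {ds.pos_bp[j]}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(ds.sample_ids):
            breed = ds.pop_map.sample_to_breed.get(s, s)
            cells = []
            for j in range(ds.n_snps):
                g = ds.genotypes[i, j]
                if g == MISSING:
                    cells.append("0 0")
                elif g == 2:
                    cells.append(f"{ds.a1[j]} {ds.a1[j]}")
                elif g == 1:
                    cells.append(f"{ds.a1[j]} {ds.a2[j]}")
                else:
                    cells.append(f"{ds.a2[j]} {ds.a2[j]}")
            fh.write(f"{breed} {s} 0 0 0 -9 " + " ".join(cells) + "\n")


# ---------------------------------------------------------------------------
# simple transposed TSV matrix (small fixtures)
# ---------------------------------------------------------------------------

def write_matrix_tsv(ds: GenotypeDataset, path) -> None:
    """One row per SNP: id, chrom, pos, A1, A2, then one code per sample."""
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\ta1\ta2\t" + "\t".join(ds.sample_ids) + "\n")
        for j in range(ds.n_snps):
            codes = ["NA" if g == MISSING else str(int(g))
                     for g in ds.genotypes[:, j]]
            fh.write(f"{ds.snp_ids[j]}\t{ds.chrom[j]}\t{ds.pos_bp[j]}\t"
                     f"{ds.a1[j]}\t{ds.a2[j]}\t" + "\t".join(codes) + "\n")


def read_matrix_tsv(path, pop_map=None) -> GenotypeDataset:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_ids = list(df.columns[5:])
    geno = df[sample_ids].to_numpy(dtype=float).T
    geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    if pop_map is None:
        pop_map = PopulationMap({s: "POP" for s in sample_ids},
                                {"POP": "other"})
    ds = GenotypeDataset(sample_ids, df["snp_id"].to_numpy(dtype=object),
                         df["chrom"].to_numpy(dtype=object),
                         df["pos"].to_numpy(), df["a1"].to_numpy(dtype=object),
                         df["a2"].to_numpy(dtype=object), geno, pop_map)
    ds.validate()
    return ds


def read_pop_map(samples_tsv, groups_tsv) -> PopulationMap:
    """Two-column TSVs: (sample_id, breed) and (breed, group)."""
    s2b, b2g = {}, {}
    with open(samples_tsv) as fh:
        for line in fh:
            if line.strip():
                s, b = line.split()[:2]
                s2b[s] = b
    with open(groups_tsv) as fh:
        for line in fh:
            if line.strip():
                b, g = line.split()[:2]
                b2g[b] = g
    return PopulationMap(s2b, b2g)


# ---------------------------------------------------------------------------
# merge / subset
# ---------------------------------------------------------------------------

def merge_datasets(a: GenotypeDataset, b: GenotypeDataset) -> GenotypeDataset:
    """Merge two panels on the intersection of their SNP ids.

    Allele pairs are reconciled when they differ only by an A1/A2 swap (codes
    of the second panel are flipped 0<->2); pairs that are not a swap are
    dropped with a logged count.  Strand flips are not resolved.
    """
    dup = set(a.sample_ids) & set(b.sample_ids)
    if dup:
        raise ValueError(f"duplicate sample ids across inputs: {sorted(dup)[:5]}")
    b_index = {s: j for j, s in enumerate(b.snp_ids)}
    keep_a, keep_b, flip = [], [], []
    n_dropped = 0
    for j, sid in enumerate(a.snp_ids):
        if sid not in b_index:
            continue
        k = b_index[sid]
        if (a.a1[j], a.a2[j]) == (b.a1[k], b.a2[k]):
            keep_a.append(j); keep_b.append(k); flip.append(False)
        elif (a.a1[j], a.a2[j]) == (b.a2[k], b.a1[k]):
            keep_a.append(j); keep_b.append(k); flip.append(True)
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning("merge: dropped %d SNPs with irreconcilable allele "
                       "pairs", n_dropped)
    if not keep_a:
        logger.warning("merge: no shared SNPs between the two panels")
    keep_a = np.asarray(keep_a, dtype=int)
    keep_b = np.asarray(keep_b, dtype=int)
    flip = np.asarray(flip, dtype=bool)

    gb = b.genotypes[:, keep_b].copy()
    if flip.any():
        fl = gb[:, flip]
        gb[:, flip] = np.where(fl == MISSING, MISSING, 2 - fl)
    geno = np.vstack([a.genotypes[:, keep_a], gb]) if len(keep_a) else \
        np.zeros((a.n_samples + b.n_samples, 0), dtype=np.int8)

    b2g = dict(a.pop_map.breed_to_group)
    for br, g in b.pop_map.breed_to_group.items():
        if br in b2g and b2g[br] != g:
            raise ValueError(f"breed {br!r} mapped to conflicting groups")
        b2g[br] = g
    pm = PopulationMap({**a.pop_map.sample_to_breed,
                        **b.pop_map.sample_to_breed}, b2g)
    ds = GenotypeDataset(list(a.sample_ids) + list(b.sample_ids),
                         a.snp_ids[keep_a], a.chrom[keep_a],
                         a.pos_bp[keep_a], a.a1[keep_a], a.a2[keep_a],
                         geno, pm)
    ds.validate()
    return ds


def subset(ds: GenotypeDataset, samples=None, snps=None, groups=None
           ) -> GenotypeDataset:
    """Order-preserving selection of samples, groups and/or SNPs."""
    keep = list(range(ds.n_samples))
    if samples is not None:
        wanted = set(samples)
        unknown = wanted - set(ds.sample_ids)
        if unknown:
            raise ValueError(f"unknown sample ids: {sorted(unknown)}")
        keep = [i for i in keep if ds.sample_ids[i] in wanted]
    if groups is not None:
        for g in groups:
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
        gs = set(groups)
        keep = [i for i in keep if ds.pop_map.group_of(ds.sample_ids[i]) in gs]
    cols = np.arange(ds.n_snps)
    if snps is not None:
        wanted = set(snps)
        unknown = wanted - set(ds.snp_ids)
        if unknown:
            raise ValueError(f"unknown snp ids: {sorted(unknown)}")
        cols = np.array([j for j in range(ds.n_snps)
                         if ds.snp_ids[j] in wanted], dtype=int)
    sample_ids = [ds.sample_ids[i] for i in keep]
    out = GenotypeDataset(sample_ids, ds.snp_ids[cols], ds.chrom[cols],
                          ds.pos_bp[cols], ds.a1[cols], ds.a2[cols],
                          ds.genotypes[np.ix_(keep, cols)],
                          ds.pop_map.subset(sample_ids))
    out.validate()
    return out
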