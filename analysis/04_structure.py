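#!/usr/bin/env python
"""Population structure and the selection-outlier scan.

Computes the genome-wide identity-by-state distance matrix and its
classical MDS embedding, pairwise Reynolds distances between populations,
a frequency-scaled genotype PCA, and the principal-component Mahalanobis
outlier scan (K = 5, FDR 0.1%) whose flagged SNPs would be excluded from
demographic inference.  Writes coordinate tables, distance matrices and
the per-SNP outlier report under results/.
"""

import argparse
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from podabc import genotype_io as gio, popgen_stats as ps, structure_scan as sc


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--K", type=int, default=5)
    ap.add_argument("--fdr", type=float, default=0.001)
    args = ap.parse_args()

    pop_map = gio.read_pop_map(args.data / "samples.tsv",
                               args.data / "groups.tsv")
    ds = gio.read_plink_text(args.data / "pod.ped", args.data / "pod.map",
                             pop_map)
    args.out.mkdir(parents=True, exist_ok=True)

    ibs = ps.ibs_distance(ds)
    ibs.write_tsv(args.out / "ibs_distances.tsv")
    coords = sc.classical_mds(ibs, k=2)
    pd.DataFrame({"sample": ds.sample_ids,
                  "breed": [ds.pop_map.sample_to_breed[s]
                            for s in ds.sample_ids],
                  "mds1": coords[:, 0], "mds2": coords[:, 1]}
                 ).to_csv(args.out / "mds.tsv", sep="\t", index=False)

    breeds = ds.pop_map.breeds()
    rey = np.zeros((len(breeds), len(breeds)))
    for (i, a), (j, b) in combinations(enumerate(breeds), 2):
        rey[i, j] = rey[j, i] = ps.reynolds_distance(ds, a, b)
    ps.DistanceMatrix(breeds, rey).write_phylip(
        args.out / "reynolds.phylip.dist")

    scores, _, eig = sc.pca_genotypes(ds, K=args.K)
    pd.DataFrame(scores, index=ds.sample_ids,
                 columns=[f"PC{i+1}" for i in range(args.K)]
                 ).to_csv(args.out / "pca_scores.tsv", sep="\t")

    rep = sc.pcadapt_scan(ds, K=args.K, fdr=args.fdr)
    sc.write_outlier_tsv(rep, args.out / "outlier_scan.tsv")

    centro = {b: coords[ds.samples_of_breed(b), 0].mean() for b in breeds}
    print("MDS axis-1 population centroids:",
          {b: round(v, 3) for b, v in centro.items()})
    print(f"PCA leading eigenvalues: {np.round(eig, 3)}")
    print(f"outlier scan: GIF = {rep.gif:.3f}, removed {rep.n_removed} of "
          f"{ds.n_snps} SNPs at FDR {args.fdr}")


if __name__ == "__main__":
    main()
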