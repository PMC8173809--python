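# Methods

`podabc` re-implements, as a tested library plus a short analysis pipeline,
a demographic-inference workflow for the origins of Podolian (grey-steppe)
cattle: SNP-chip quality control, diversity and structure summaries, and —
at its core — coalescent simulation of six competing colonization scenarios
with approximate Bayesian computation via random forests (ABC-RF) for
scenario choice and parameter estimation.  The genotypes the original
analysis used are not public, so the package ships a first-class synthetic
data path: every stage runs, and is validated, on pseudo-observed datasets
(PODs) simulated under the same scenarios.

## Demographic model

Five sampled populations represent the main geographic groups: Asian
indicine (IND, 30 diploids), non-Podolian European taurine (NPT, 40),
Italian Podolian (ITP, 49), Balkan Podolian (BKP, 48) and South-East
Mediterranean Podolian (SEP, 43).  All scenarios share a backbone, with
times in generations before present and sizes in diploid individuals:

* `t3` — deep split of the indicine and taurine lineages (prior
  Uniform(80,000, 120,000), i.e. roughly 200–300 kY at 2.5 y/generation);
* `tdt`, `tdi` — taurine and indicine domestications, each modelled as a
  bottleneck (size Uniform(50, 2000) for Uniform(2, 50) generations)
  placed on the backward interval [t_dom, t_dom + duration].  `tdt`
  carries the internal calibration prior Uniform(3600, 7800);
* `ta` — a pulse of indicine ancestry into the Podolian ancestor, with
  introgression fraction `ra` ~ Uniform(0.05, 0.5).  The event vocabulary
  requires this proportion even though it is not one of the headline
  parameters; its prior is a package choice;
* `tD` — split of the non-Podolian taurine lineage;
* `t1` — split of BKP and SEP from the Podolian ancestor;
* `ta1` — formation of the Italian Podolian group, by one of three routes:
  a split from SEP with a founder-effect size reduction (Mediterranean), a
  split from BKP (Balkan), or an admixture pulse BKP/SEP with BKP
  proportion `r` ~ Uniform(0.05, 0.95).

The two scenario *sets* differ only in the time ordering: in set 1 (two
colonization waves; scenarios 1–3) `tdt >= tD >= ta >= t1 >= ta1`, so the
non-Podolian taurine lineage branches off before the indicine pulse and
does not carry it; in set 2 (one wave; scenarios 4–6)
`tdt >= ta >= tD >= t1 >= ta1` and it does.  Size parameters map to
populations as N1 = IND, N2 = NPT, N4 = BKP, N4b = ITP, N5 = SEP,
N5b = the Podolian/second-wave ancestor between `t1` and the taurine
domestication, and N3 = the deep taurine ancestor and root; all size
priors default to Uniform(100, 50,000).  This mapping and the prior table
are declared package defaults, overridable from configuration, not a
reproduction of any external prior file.

Prior draws keep the calibration honest: unconstrained parameters
(including `tdt` and `t3`) are drawn once from their uniforms, and only
the four chained times below `tdt` are rejection-sampled until ordered, so
the `tdt` marginal stays exactly Uniform(3600, 7800) (verified by a KS
test).

## Coalescent engine

Loci are unlinked — the data being emulated are LD-pruned chip SNPs — so
there is no recombination machinery.  Each locus is an independent
structured-coalescent genealogy over the scenario's populations:
continuous time, exact exponential waiting times with piecewise-constant
rates k(k−1)/(4N) per population, lineage movement at split/admixture
events, sizes changed at size-change events.  One mutation is placed
uniformly at random on the total branch length; the derived-allele
carriers are the leaves below it.  Haploid lineages are paired
consecutively into diploids (within-population exchangeability makes the
pairing immaterial; a permutation test confirms it).

SNP-chip ascertainment is emulated by conditioning each locus on a pooled
minor-allele frequency of at least 0.05 (matching the MAF filter): a locus
failing the floor is redrawn from scratch — tree and mutation — so that
tree shapes with higher acceptance probability are enriched exactly as
ascertainment enriches them.  The redraw cap (200) is logged and a capped
draw raises an error naming the parameter vector.  The engine is a
numba-compiled kernel; calibration checks: the mean pairwise coalescence
time in a constant population matches E[T2] = 2N within 2% over 20,000
replicates, cross-population coalescence times order with split depths,
and the admixture route with r = 1 is distributionally indistinguishable
from the pure Balkan route.

What the generator does *not* emulate: linkage (so LD-based statistics are
meaningless on simulated panels), real chip ascertainment panels
(discovery in a small taurine panel biases MAF spectra differently from a
pooled-MAF floor), genotyping error, and within-group breed substructure
(each group is one random-mating population).  Passing tests therefore
demonstrate correctness of the inference machinery under the stated model,
not fidelity of any particular parameter estimate to real cattle history.

## Summary statistics and ABC-RF

The summary vector has 37 fixed-order components: per group, expected
heterozygosity, mean MAF and the proportion of polymorphic SNPs (5 × 3);
per group pair, Hudson's FST (ratio of averages) and Nei's standard
distance (10 × 2); and two f3 statistics, f3(ITP; BKP, SEP) and
f3(ITP; NPT, SEP), sensitive to an admixed origin of the Italian
Podolian group.  f3 uses the raw covariance form with the small-sample
correction on the target frequency and no heterozygosity normalization.
Undefined entries (monomorphic groups) are imputed as 0 with a logged
count, because forests need complete rows.  The statistic pool is this
package's declared contract, chosen to expose the contrasts the scenarios
differ by; other ABC implementations use different pools.

Scenario choice trains a random-forest classifier on the summary
statistics augmented with the linear-discriminant axes (k−1 axes for k
classes, fitted on the table only).  Votes are the trees' predictions at
the observed point.  The posterior probability of the selected scenario is
*not* the vote share: it is the prediction, at the observed point, of a
regression forest trained on the out-of-bag indicator "was this reference
row classified correctly" — the standard ABC-RF recipe.  A scenario can
win a modest plurality of trees yet carry a much higher (or lower)
posterior probability; conflating the two is a common misreading.  The
grouped (set-level) choice collapses scenario
labels to set labels before training, including the LDA step.  A prior
compatibility check requires every LDA coordinate of the observed point to
lie within the [0.1%, 99.9%] empirical range of the simulated cloud.

Parameter estimation uses a quantile regression forest: leaf
co-occurrence frequencies of the observed point weight the reference
rows, giving the weighted posterior median and the 0.05/0.95 quantiles.
Generations convert to years before present at 2.5 years per cattle
generation, rounded down (floor): 2593 generations → 6482 YBP,
790 → 1975 YBP.

Desk-scale defaults, chosen once for this package: 500 reference rows per
scenario, 1000 ascertained loci per dataset, 500 trees.  These are
deliberately smaller than a production analysis (thousands of rows per
scenario, 1000 trees, ~8K loci); at this scale, pseudo-observed recovery
is already strong (all six scenarios recovered as the modal choice; set
choice >= 90%; the 90% interval for tD covers the truth in >= 80% of
PODs).

## Upstream statistics

* **MAF / call-rate filters** follow PLINK semantics: MAF keeps sites at
  or above the threshold; call rate removes sites whose missing fraction
  strictly exceeds it.
* **LD pruning**: r² is the squared Pearson correlation of allele-count
  vectors over samples non-missing at both SNPs (not haplotype-EM r²).
  Pairwise pruning slides a window of 50 kept SNPs by 10, removing one
  member of each pair with r² above 0.1 — the lower-MAF member, the later
  one in map order on ties — and rescans to a fixed point, so the output
  provably contains no within-window pair above the threshold.  The VIF
  variant (threshold 1.2, window 50, step 5) removes worst-first by
  variance-inflation factor from a least-squares regression of each SNP on
  the rest of its window (the PLINK `--indep` convention; its threshold is
  a VIF, and 1.2 is this package's default).
* **Heterozygosity**: He = 2p(1−p) without the 2n/(2n−1) correction by
  default (a flag enables it).
* **LD-based Ne**: Sved's relation on a linear map, Ne = (1/(4c))
  (1/E[r²_adj] − α) with c = bp × (1 cM/Mb) × 10⁻⁸ Morgans, α = 1 (2.2
  with mutation adjustment), r²_adj = r² − 1/(2n) for unphased data, bins
  dated 1/(2c) generations ago; the scalar "Ne" is the most recent bin
  with a defined estimate, and empty or non-positive bins are flagged NaN,
  never fabricated.  Validated against coalescent simulations with
  recombination (msprime) to within a factor of two of a known constant N.
* **Reynolds distance**: the least-squares coancestry estimator from
  two-population allele frequencies, ratio of sums over loci, with the
  sample-size correction (a flag disables it for pure frequency input,
  where identical frequencies give exactly 0); optional −ln(1−θ)
  linearization.
* **IBS distance**: 1 − mean shared-allele proportion over jointly
  observed SNPs; embedded by Torgerson classical MDS (negative
  eigenvalues truncated with a warning — IBS matrices are generally
  non-Euclidean).
* **PCA / outlier scan**: genotypes centered by 2p and scaled by
  √(p(1−p)), missing values mean-imputed after scaling, monomorphic
  columns zeroed.  The scan regresses each scaled SNP on the top-K PC
  scores (K = 5 by default, always explicit configuration; a scree table
  is available but there is no automatic elbow), takes the robust
  Mahalanobis distance of the K z-scores — orthogonalized
  Gnanadesikan–Kettenring location/covariance with one hard-rejection
  reweighting step at the χ²_K 0.9 quantile and the standard truncation
  consistency factor; a plain-covariance fallback flag exists — divides by
  the genomic inflation factor (median distance over the χ²_K median),
  and converts to χ²_K upper-tail p-values.  The order robustify → GIF →
  χ² is fixed here as a documented choice.  Storey q-values use a fixed
  λ = 0.5 estimate of π₀ by default (robust at small SNP counts; the
  λ-grid smoother is optional); SNPs with q below the FDR (0.1% by
  default) are reported for removal.
* **Merging** reconciles only A1/A2 swaps; allele pairs that differ
  otherwise (including unresolvable A/T, C/G strand flips) are dropped
  with a logged count — chip panels sharing one manifest rarely need
  more, and the original multi-study merge's strand handling is unknown.

## Numerical and degenerate-input choices

Missing genotypes are a distinct sentinel (−1), never 0.  Frequency
statistics skip loci unobserved in either population; FST/Reynolds/f3
require at least two observed diploids per group per locus.  Monomorphic
SNP columns correlate 0 with everything in LD pruning and contribute VIF 1.
Vote ties in model choice break toward the smaller scenario id
(deterministic).  All randomness flows from a single `numpy` Generator per
run; forests run single-threaded with seeds derived from it, so results
are bit-reproducible for a fixed seed.

## Known limitations

Scenario confusion, when it occurs at desk scale, concentrates within
route variants of the same set, which share most of their event structure.
The posterior-probability regression forest is only as calibrated as the
reference table is dense near the observed point.  The Ne trajectory
applies to linked real data only.  Breed-level diversity tables, SNP
counts surviving each filter and vote counts on a real chip panel all
depend on genotypes this package does not ship; its guarantees are about
the machinery, demonstrated on synthetic data.
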