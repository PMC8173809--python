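# podabc

Coalescent simulation and ABC random-forest inference for the colonization
history of Podolian cattle, with the supporting SNP-chip QC, diversity and
population-structure statistics.

Podolian (grey-steppe) cattle — long-horned, grey-coated breeds scattered
from Anatolia and the Balkans to Italy — are a long-standing puzzle in
livestock genetics: did they reach southern Europe in a second migration
wave along the Mediterranean, over land through the Balkans, or by a
mixture of both routes?  `podabc` is a package for testing such competing
colonization scenarios with SNP-chip genotypes: it simulates genotype data
under explicit demographic models and uses approximate Bayesian
computation with random forests (ABC-RF) to choose among scenarios and
estimate their parameters.  It is written for population geneticists who
want a transparent, fully testable version of this workflow.  Because
breed-panel chip genotypes are rarely public, the package ships a
first-class synthetic-data path that exercises every stage end to end.

## The model in brief

Five sampled populations (Asian indicine IND, non-Podolian taurine NPT,
Italian ITP, Balkan BKP and South-East SEP Podolian; 30/40/49/48/43
diploids) descend from a common ancestor through a deep indicine/taurine
split (t3), domestication bottlenecks (tdt, tdi; tdt calibrated by a
Uniform(3600, 7800)-generation prior), an indicine admixture pulse into
the Podolian ancestor (ta), the non-Podolian taurine split (tD), the
Balkan/South-East split (t1), and the formation of the Italian Podolian
group at ta1 — by a Mediterranean split, a Balkan split, or BKP/SEP
admixture.  Scenarios 1–3 put tD before ta (two colonization waves);
scenarios 4–6 put it after (one wave).

Each locus is an independent structured-coalescent genealogy (rate
k(k−1)/4N per population) carrying a single uniformly placed mutation and
conditioned on pooled MAF ≥ 0.05 to mimic chip ascertainment.  A reference
table of simulated datasets is summarized into 37 statistics (per-group
He/MAF/polymorphism, pairwise Hudson FST and Nei distance, two f3 tests of
an admixed Italian origin); a classification forest over these statistics
plus their LDA axes votes among scenarios, a regression forest on
out-of-bag correctness turns the winner into a posterior probability, and
a quantile regression forest yields posterior medians and 90% intervals
for the demographic times, converted to years at 2.5 years per generation.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
pseudo-observed dataset (POD) simulated under the two-wave admixture
scenario (scenario 3) at mid-prior parameters:

```sh
python analysis/01_simulate_data.py --seed 1     # POD: 210 samples x 2000 SNPs
python analysis/02_qc_filtering.py               # MAF / call-rate / LD pruning
python analysis/03_diversity.py                  # per-group Ho, He, MAF
python analysis/04_structure.py                  # IBS-MDS, PCA, outlier scan
python analysis/05_abc_model_choice.py --seed 2  # reference table + RF choice
python analysis/06_parameter_estimation.py --seed 3
```

Step 05 prints, for a reference table of 150 draws per scenario at 500
loci and 500 trees:

```
prior compatibility: OK (per-axis percentiles [19.6 63.3 48.1 47.  26.3])
set choice (1 = two waves, 2 = one wave): set 1, votes {1: 500, 2: 0}, posterior prob 1.00
scenario choice: scenario 3, votes {1: 136, 2: 36, 3: 326, 4: 0, 5: 0, 6: 2}, posterior prob 0.74
```

Read: the observed summaries sit inside the simulated cloud (the priors
can explain the data); every tree prefers a two-wave history; and the
admixture scenario that actually generated the data wins the full vote,
with the residual confusion concentrated in its same-set route variants —
exactly the behaviour expected of route siblings that share most of their
event structure.  Step 06 then recovers the generating times; e.g. the
non-Podolian taurine split, truth tD = 4562 generations, gets posterior
median 4418 with 90% interval [2650, 6560] (≈ 11,046 [6,624–16,399] YBP).

## Layout

```
src/podabc/          genotype_io, qc_filtering, popgen_stats,
                     structure_scan, scenario_sim (+ numba kernel), abc_rf
analysis/            numbered drivers for the worked example
tests/               pytest suite (unit, property and end-to-end)
docs/methods.md      model, estimators, defaults and their rationale
```
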