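"""ABC random-forest inference: reference tables, scenario choice and
quantile-forest parameter estimation.

The reference table holds, per simulated dataset, the generating scenario,
its parameter draw and a fixed 37-component summary-statistic vector:
per-group expected heterozygosity, mean MAF and proportion of polymorphic
SNPs (5 groups x 3), pairwise Hudson FST and Nei distance (10 pairs x 2),
and two f3 statistics probing an admixed origin of the Italian Podolian
group.  Linear-discriminant axes fitted on the summary statistics are
appended as extra features (the standard ABC-RF augmentation) and used for
a prior-compatibility check of the observed data.

Scenario choice is a classification forest: the votes are the trees'
predictions at the observed point, and the posterior probability of the
selected scenario is estimated by a regression forest trained on the
out-of-bag "was this row classified correctly" indicator — vote share is
not a posterior probability.  Parameter posteriors come from a quantile
regression forest: leaf co-occurrence weights of the observed point yield
weighted posterior quantiles.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from . import popgen_stats
from .genotype_io import GenotypeDataset
from .scenario_sim import (PARAM_NAMES, PriorSpec, ScenarioSpec, SimConfig,
                           draw_params, simulate_dataset)

logger = logging.getLogger(__name__)

_GROUPS = ("IND", "NPT", "ITP", "BKP", "SEP")
_GROUP_LABEL = {
    "IND": "indicine",
    "NPT": "nonpodolian_taurine",
    "ITP": "italian_podolian",
    "BKP": "balkan_podolian",
    "SEP": "se_podolian",
}

SUMMARY_NAMES = tuple(
    [f"{stat}_{g}" for g in _GROUPS for stat in ("he", "maf", "poly")]
    + [f"{stat}_{a}_{b}" for a, b in itertools.combinations(_GROUPS, 2)
       for stat in ("fst", "nei")]
    + ["f3_ITP_BKP_SEP", "f3_ITP_NPT_SEP"]
)


def summarize(ds: GenotypeDataset) -> np.ndarray:
    """The fixed-order 37-statistic summary vector of a five-group dataset.

    Undefined entries (e.g. a distance between monomorphic groups) are
    imputed as 0 with a logged count; the vector is always finite.
    """
    vals = {}
    freqs = {}
    for g in _GROUPS:
        idx = ds.samples_of_group(_GROUP_LABEL[g])
        p, _n = popgen_stats._freq_counts(ds.genotypes[idx])
        freqs[g] = p
        he = 2.0 * p * (1.0 - p)
        maf = np.minimum(p, 1.0 - p)
        vals[f"he_{g}"] = float(np.nanmean(he))
        vals[f"maf_{g}"] = float(np.nanmean(maf))
        with np.errstate(invalid="ignore"):
            vals[f"poly_{g}"] = float(np.nanmean((p > 0) & (p < 1)))
    for a, b in itertools.combinations(_GROUPS, 2):
        vals[f"fst_{a}_{b}"] = popgen_stats.hudson_fst(
            ds, _GROUP_LABEL[a], _GROUP_LABEL[b], by_group=True)
        vals[f"nei_{a}_{b}"] = popgen_stats.nei_distance(
            ds, _GROUP_LABEL[a], _GROUP_LABEL[b], by_group=True)
    vals["f3_ITP_BKP_SEP"] = popgen_stats.f3_statistic(
        ds, _GROUP_LABEL["ITP"], _GROUP_LABEL["BKP"], _GROUP_LABEL["SEP"],
        by_group=True)
    vals["f3_ITP_NPT_SEP"] = popgen_stats.f3_statistic(
        ds, _GROUP_LABEL["ITP"], _GROUP_LABEL["NPT"], _GROUP_LABEL["SEP"],
        by_group=True)
    vec = np.array([vals[k] for k in SUMMARY_NAMES], dtype=float)
    bad = ~np.isfinite(vec)
    if bad.any():
        logger.info("summarize: imputed %d undefined statistics as 0",
                    int(bad.sum()))
        vec[bad] = 0.0
    return vec


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Rows of (scenario id, parameter draw, summary vector)."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def scenario_ids(self) -> np.ndarray:
        return self.df["scenario"].to_numpy(dtype=int)

    def stats_matrix(self) -> np.ndarray:
        return self.df[list(SUMMARY_NAMES)].to_numpy(dtype=float)

    def params(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy(dtype=float)

    def to_tsv(self, path, meta_path=None) -> None:
        self.df.to_csv(path, sep="\t", index=False)
        if meta_path:
            with open(meta_path, "w") as fh:
                json.dump(self.meta, fh, indent=1)

    @staticmethod
    def from_tsv(path, meta_path=None) -> "ReferenceTable":
        df = pd.read_csv(path, sep="\t")
        meta = {}
        if meta_path:
            with open(meta_path) as fh:
                meta = json.load(fh)
        return ReferenceTable(df, meta)


def build_reference_table(scenarios, priors: PriorSpec, n_per_scenario: int,
                          simcfg: SimConfig, rng: np.random.Generator
                          ) -> ReferenceTable:
    """Simulate ``n_per_scenario`` prior draws per scenario and summarize.

    Simulation failures (retry-cap exhaustion under extreme draws) are
    logged and the row skipped; any resulting imbalance is reported in the
    metadata.
    """
    rows = []
    n_failed = 0
    for spec in scenarios:
        for _ in range(n_per_scenario):
            params = draw_params(priors, spec, rng)
            try:
                ds = simulate_dataset(spec, params, simcfg, rng)
            except RuntimeError as exc:
                logger.warning("reference table: %s", exc)
                n_failed += 1
                continue
            row = {"scenario": spec.scenario_id, **params.as_dict()}
            row.update(zip(SUMMARY_NAMES, summarize(ds)))
            rows.append(row)
    df = pd.DataFrame(rows)
    counts = df["scenario"].value_counts().to_dict()
    if n_failed:
        logger.warning("reference table: %d failed simulations; per-scenario "
                       "counts %s", n_failed, counts)
    meta = {"n_per_scenario": n_per_scenario, "n_failed": n_failed,
            "counts": {int(k): int(v) for k, v in counts.items()},
            "n_loci": simcfg.n_loci, "min_maf": simcfg.min_maf,
            "sample_sizes": dict(simcfg.sample_sizes),
            "prior_bounds": {k: list(v) for k, v in priors.bounds.items()}}
    return ReferenceTable(df, meta)


# ---------------------------------------------------------------------------
# LDA augmentation and prior compatibility
# ---------------------------------------------------------------------------

def _fit_lda(stats: np.ndarray, labels: np.ndarray):
    lda = LinearDiscriminantAnalysis()
    lda.fit(stats, labels)
    return lda


def add_lda_axes(table: ReferenceTable, observed_summary: np.ndarray):
    """Append the k-1 linear-discriminant coordinates (fitted on summary
    statistics vs scenario id) to the table and the observed vector."""
    stats = table.stats_matrix()
    labels = table.scenario_ids
    lda = _fit_lda(stats, labels)
    axes = lda.transform(stats)
    obs_axes = lda.transform(observed_summary.reshape(1, -1))[0]
    df = table.df.copy()
    for i in range(axes.shape[1]):
        df[f"LD{i + 1}"] = axes[:, i]
    aug = ReferenceTable(df, dict(table.meta))
    observed_aug = np.concatenate([observed_summary, obs_axes])
    return aug, observed_aug


@dataclass
class CompatibilityReport:
    compatible: bool
    axis_percentiles: np.ndarray    # percentile of the observed point, per axis
    lo: float
    hi: float


def prior_compatibility_check(table: ReferenceTable, observed: np.ndarray,
                              lo: float = 0.1, hi: float = 99.9
                              ) -> CompatibilityReport:
    """Observed data are prior-compatible iff every LDA coordinate lies
    within the [lo, hi] empirical percentile range of the simulated cloud."""
    stats = table.stats_matrix()
    lda = _fit_lda(stats, table.scenario_ids)
    cloud = lda.transform(stats)
    obs = lda.transform(observed[: len(SUMMARY_NAMES)].reshape(1, -1))[0]
    pct = np.array([float(np.mean(cloud[:, a] <= obs[a])) * 100.0
                    for a in range(cloud.shape[1])])
    lo_v = np.percentile(cloud, lo, axis=0)
    hi_v = np.percentile(cloud, hi, axis=0)
    compatible = bool(np.all((obs >= lo_v) & (obs <= hi_v)))
    return CompatibilityReport(compatible, pct, lo, hi)


# ---------------------------------------------------------------------------
# scenario choice
# ---------------------------------------------------------------------------

@dataclass
class ModelChoiceResult:
    votes: dict                     # label -> number of trees
    selected: int
    posterior_prob: float
    n_trees: int

    def validate(self) -> None:
        if sum(self.votes.values()) != self.n_trees:
            raise ValueError("votes must sum to the number of trees")
        if not 0.0 <= self.posterior_prob <= 1.0:
            raise ValueError("posterior probability outside [0, 1]")


def _check_n_trees(n_trees: int) -> None:
    if n_trees < 50:
        raise ValueError("n_trees < 50 gives unstable vote fractions; refuse")


class ScenarioChoiceForest:
    """Classification forest over a reference table, reusable across many
    observed points (trained once, queried per dataset)."""

    def __init__(self, table: ReferenceTable, n_trees: int = 1000,
                 rng: np.random.Generator = None, labels: np.ndarray = None,
                 augment_lda: bool = True):
        _check_n_trees(n_trees)
        rng = rng or np.random.default_rng()
        seed = int(rng.integers(0, 2**31 - 1))
        self.n_trees = n_trees
        self.y = (table.scenario_ids if labels is None
                  else np.asarray(labels))
        self._stats = table.stats_matrix()
        self._lda = None
        x = self._stats
        if augment_lda and len(np.unique(self.y)) > 1:
            self._lda = _fit_lda(self._stats, self.y)
            x = np.hstack([x, self._lda.transform(x)])
        self.clf = RandomForestClassifier(n_estimators=n_trees,
                                          random_state=seed, n_jobs=1,
                                          oob_score=True)
        self.clf.fit(x, self.y)
        oob = self.clf.oob_decision_function_
        have_oob = np.isfinite(oob).all(axis=1) & (oob.sum(axis=1) > 0)
        oob_pred = self.clf.classes_[np.argmax(oob[have_oob], axis=1)]
        correct = (oob_pred == self.y[have_oob]).astype(float)
        self.reg = RandomForestRegressor(n_estimators=n_trees,
                                         random_state=seed + 1, n_jobs=1)
        self.reg.fit(x[have_oob], correct)

    def _augment(self, observed: np.ndarray) -> np.ndarray:
        obs = np.asarray(observed, dtype=float)[: self._stats.shape[1]]
        if self._lda is not None:
            obs = np.concatenate(
                [obs, self._lda.transform(obs.reshape(1, -1))[0]])
        return obs

    def choose(self, observed: np.ndarray) -> ModelChoiceResult:
        obs = self._augment(observed).reshape(1, -1)
        tree_preds = np.array(
            [self.clf.classes_[int(t.predict(obs)[0])]
             for t in self.clf.estimators_])
        votes = {int(c): int((tree_preds == c).sum())
                 for c in self.clf.classes_}
        selected = int(max(votes, key=lambda c: (votes[c], -c)))
        post = float(np.clip(self.reg.predict(obs)[0], 0.0, 1.0))
        res = ModelChoiceResult(votes, selected, post, self.n_trees)
        res.validate()
        return res


def rf_model_choice(table: ReferenceTable, observed: np.ndarray,
                    n_trees: int = 1000, rng: np.random.Generator = None,
                    labels: np.ndarray = None, augment_lda: bool = True
                    ) -> ModelChoiceResult:
    """Classification-forest scenario choice at one observed summary vector.

    Votes are the per-tree predictions at the observed point; the posterior
    probability of the winning scenario is the prediction of a regression
    forest trained on the out-of-bag correctness indicator of the
    classifier over the reference table (the ABC-RF recipe).
    """
    forest = ScenarioChoiceForest(table, n_trees=n_trees, rng=rng,
                                  labels=labels, augment_lda=augment_lda)
    return forest.choose(observed)


def grouped_model_choice(table: ReferenceTable, grouping: dict,
                         observed: np.ndarray, n_trees: int = 1000,
                         rng: np.random.Generator = None,
                         augment_lda: bool = True) -> ModelChoiceResult:
    """Set-level choice: scenario labels are collapsed to group labels
    (e.g. {1: {1,2,3}, 2: {4,5,6}}) before training."""
    ids = set(table.scenario_ids.tolist())
    members = [m for v in grouping.values() for m in v]
    if len(members) != len(set(members)) or set(members) != ids:
        raise ValueError(f"grouping {grouping} must partition the scenario "
                         f"ids {sorted(ids)}")
    lookup = {m: g for g, v in grouping.items() for m in v}
    labels = np.array([lookup[s] for s in table.scenario_ids])
    return rf_model_choice(table, observed, n_trees=n_trees, rng=rng,
                           labels=labels, augment_lda=augment_lda)


# ---------------------------------------------------------------------------
# parameter estimation (quantile regression forest)
# ---------------------------------------------------------------------------

@dataclass
class ParamPosterior:
    param: str
    median: float
    q05: float
    q95: float

    def validate(self) -> None:
        if not self.q05 <= self.median <= self.q95:
            raise ValueError("posterior quantiles must be ordered")

    def to_years(self, gen_time: float = 2.5) -> dict:
        return {k: generations_to_years(getattr(self, k), gen_time)
                for k in ("median", "q05", "q95")}


def _weighted_quantile(values, weights, qs):
    order = np.argsort(values)
    v = np.asarray(values)[order]
    w = np.asarray(weights)[order]
    cum = np.cumsum(w)
    cum /= cum[-1]
    return [float(np.interp(q, cum, v)) for q in qs]


class ParameterForest:
    """Quantile regression forest for one parameter, reusable across many
    observed points.

    The forest maps summary statistics to the parameter; posterior weights
    of the training rows are their leaf co-occurrence frequencies with the
    observed point, giving weighted posterior quantiles.
    """

    def __init__(self, table: ReferenceTable, param: str,
                 n_trees: int = 1000, rng: np.random.Generator = None,
                 augment_lda: bool = True, min_samples_leaf: int = 5):
        _check_n_trees(n_trees)
        rng = rng or np.random.default_rng()
        seed = int(rng.integers(0, 2**31 - 1))
        self.param = param
        self.n_trees = n_trees
        self.y = table.params(param)
        self._stats = table.stats_matrix()
        labels = table.scenario_ids
        self._lda = None
        x = self._stats
        if augment_lda and len(np.unique(labels)) > 1:
            self._lda = _fit_lda(self._stats, labels)
            x = np.hstack([x, self._lda.transform(x)])
        self._constant = np.ptp(self.y) == 0
        if self._constant:
            return
        self.rf = RandomForestRegressor(n_estimators=n_trees,
                                        random_state=seed, n_jobs=1,
                                        min_samples_leaf=min_samples_leaf)
        self.rf.fit(x, self.y)
        self._train_leaves = self.rf.apply(x)       # n x T

    def estimate(self, observed: np.ndarray) -> ParamPosterior:
        if self._constant:
            v = float(self.y[0])
            return ParamPosterior(self.param, v, v, v)
        obs = np.asarray(observed, dtype=float)[: self._stats.shape[1]]
        if self._lda is not None:
            obs = np.concatenate(
                [obs, self._lda.transform(obs.reshape(1, -1))[0]])
        obs_leaves = self.rf.apply(obs.reshape(1, -1))[0]
        weights = np.zeros(len(self.y))
        for t in range(self.n_trees):
            in_leaf = self._train_leaves[:, t] == obs_leaves[t]
            cnt = in_leaf.sum()
            if cnt:
                weights[in_leaf] += 1.0 / cnt
        q05, med, q95 = _weighted_quantile(self.y, weights,
                                           (0.05, 0.5, 0.95))
        res = ParamPosterior(self.param, med, q05, q95)
        res.validate()
        return res


def rf_parameter_estimate(table: ReferenceTable, observed: np.ndarray,
                          param: str, n_trees: int = 1000,
                          rng: np.random.Generator = None,
                          augment_lda: bool = True,
                          min_samples_leaf: int = 5) -> ParamPosterior:
    """Quantile-regression-forest posterior (median and 0.05/0.95 weighted
    quantiles) for one parameter at one observed summary vector."""
    forest = ParameterForest(table, param, n_trees=n_trees, rng=rng,
                             augment_lda=augment_lda,
                             min_samples_leaf=min_samples_leaf)
    return forest.estimate(observed)


def generations_to_years(g: float, gen_time: float = 2.5) -> int:
    """Generations before present to integer years before present,
    rounding down (2593 generations x 2.5 y -> 6482 YBP)."""
    return math.floor(g * gen_time)
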