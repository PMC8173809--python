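"""Summary statistics, reference tables and the random-forest machinery."""

import numpy as np
import pandas as pd
import pytest

from podabc import abc_rf, scenario_sim as ss
from podabc.abc_rf import (SUMMARY_NAMES, ParameterForest, ReferenceTable,
                           ScenarioChoiceForest, add_lda_axes,
                           build_reference_table, generations_to_years,
                           grouped_model_choice, prior_compatibility_check,
                           rf_model_choice, rf_parameter_estimate, summarize)
from podabc.genotype_io import from_arrays


def five_group_dataset(rng, p_fn, n_per=8, m=120):
    """Dataset with the five scenario groups; per-group frequencies from
    ``p_fn(group_index, base_freqs)``."""
    base = rng.uniform(0.1, 0.9, m)
    blocks, breeds = [], []
    for gi, pop in enumerate(ss.POPS[:5]):
        p = np.clip(p_fn(gi, base), 0.0, 1.0)
        blocks.append(rng.binomial(2, np.tile(p, (n_per, 1))))
        breeds += [pop] * n_per
    ids = [f"{b}_{i:03d}" for i, b in enumerate(breeds)]
    return from_arrays(np.vstack(blocks).astype(np.int8), breeds,
                       ss.SIM_GROUPS, sample_ids=ids)


def synthetic_table(rng, n_per=40, informative="he_IND", noise=0.01,
                    noise_features=0.0):
    """Reference table whose scenario label is encoded (almost) noiselessly
    in one summary column; the others are constant (or pure noise when
    ``noise_features`` > 0)."""
    rows = []
    for sid in range(1, 7):
        for _ in range(n_per):
            row = {"scenario": sid}
            row.update({k: rng.normal() for k in ss.PARAM_NAMES})
            row.update({k: rng.normal(scale=noise_features)
                        if noise_features else 0.0 for k in SUMMARY_NAMES})
            row[informative] = sid + rng.normal(scale=noise)
            rows.append(row)
    return ReferenceTable(pd.DataFrame(rows))


def observed_for(sid, table, informative="he_IND"):
    obs = np.zeros(len(SUMMARY_NAMES))
    obs[SUMMARY_NAMES.index(informative)] = sid
    return obs


class TestSummarize:
    def test_vector_shape_and_finiteness(self, rng):
        ds = five_group_dataset(rng, lambda gi, p: p)
        s = summarize(ds)
        assert s.shape == (37,)
        assert len(SUMMARY_NAMES) == 37
        assert np.isfinite(s).all()

    def test_identical_groups_near_zero_fst(self, rng):
        ds = five_group_dataset(rng, lambda gi, p: p, n_per=20)
        s = dict(zip(SUMMARY_NAMES, summarize(ds)))
        assert abs(s["fst_IND_NPT"]) < 0.02
        assert abs(s["fst_BKP_SEP"]) < 0.02

    def test_half_frequency_gives_half_heterozygosity(self, rng):
        ds = five_group_dataset(rng, lambda gi, p: np.full_like(p, 0.5),
                                n_per=40, m=400)
        s = dict(zip(SUMMARY_NAMES, summarize(ds)))
        for g in ("IND", "NPT", "ITP", "BKP", "SEP"):
            assert s[f"he_{g}"] == pytest.approx(0.5, abs=0.02)

    def test_monomorphic_group_imputed_zero(self, rng, caplog):
        ds = five_group_dataset(rng, lambda gi, p: np.zeros_like(p)
                                if gi == 0 else p)
        with caplog.at_level("INFO"):
            s = summarize(ds)
        assert np.isfinite(s).all()


class TestReferenceTable:
    def test_build_counts_and_reproducibility(self):
        specs = ss.build_builtin_scenarios()
        pri = ss.PriorSpec()
        cfg = ss.SimConfig(n_loci=40,
                           sample_sizes={p: 6 for p in ss.POPS[:5]})
        t1 = build_reference_table(specs, pri, 4, cfg,
                                   np.random.default_rng(9))
        t2 = build_reference_table(specs, pri, 4, cfg,
                                   np.random.default_rng(9))
        assert len(t1.df) == 24
        assert (t1.df["scenario"].value_counts() == 4).all()
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_tsv_roundtrip(self, rng, tmp_path):
        t = synthetic_table(rng, n_per=3)
        t.meta = {"n_per_scenario": 3}
        t.to_tsv(tmp_path / "t.tsv", tmp_path / "t.json")
        back = ReferenceTable.from_tsv(tmp_path / "t.tsv",
                                       tmp_path / "t.json")
        pd.testing.assert_frame_equal(back.df, t.df)
        assert back.meta["n_per_scenario"] == 3

    def test_single_wave_contrast_visible_in_npt_statistics(self, rng):
        """The one-wave scenarios nest the non-Podolian taurine inside the
        indicine-introgressed lineage, lowering FST(IND, NPT)."""
        specs = ss.build_builtin_scenarios()
        cfg = ss.SimConfig(n_loci=200,
                           sample_sizes={p: 10 for p in ss.POPS[:5]})
        j = SUMMARY_NAMES.index("fst_IND_NPT")
        a = [summarize(ss.simulate_dataset(specs[0], ss.midprior_params(
            specs[0]), cfg, rng))[j] for _ in range(25)]
        b = [summarize(ss.simulate_dataset(specs[3], ss.midprior_params(
            specs[3]), cfg, rng))[j] for _ in range(25)]
        t = __import__("scipy.stats", fromlist=["ttest_ind"]).ttest_ind(a, b)
        assert np.mean(a) > np.mean(b)
        assert t.pvalue < 1e-3


class TestLdaAndCompatibility:
    def test_axis_count_and_separability(self, rng):
        table = synthetic_table(rng, noise_features=1.0)
        obs = observed_for(2, table)
        aug, obs_aug = add_lda_axes(table, obs)
        assert {f"LD{i}" for i in range(1, 6)} <= set(aug.df.columns)
        assert obs_aug.shape == (37 + 5,)
        # the informative feature makes classes LDA-separable
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        lda = LinearDiscriminantAnalysis().fit(table.stats_matrix(),
                                               table.scenario_ids)
        assert lda.score(table.stats_matrix(), table.scenario_ids) == 1.0

    def test_table_row_is_compatible(self, rng):
        table = synthetic_table(rng)
        row = table.stats_matrix()[10]
        rep = prior_compatibility_check(table, row)
        assert rep.compatible

    def test_far_point_is_incompatible(self, rng):
        table = synthetic_table(rng)
        centroid = table.stats_matrix().mean(axis=0)
        radius = np.abs(table.stats_matrix() - centroid).max()
        rep = prior_compatibility_check(table, centroid + 100 * radius)
        assert not rep.compatible


class TestModelChoice:
    def test_separable_table_votes_for_truth(self, rng):
        table = synthetic_table(rng)
        res = rf_model_choice(table, observed_for(5, table), n_trees=200,
                              rng=np.random.default_rng(0))
        assert res.selected == 5
        assert res.votes[5] >= 0.95 * 200
        assert sum(res.votes.values()) == 200
        assert 0.0 <= res.posterior_prob <= 1.0

    def test_training_row_reassigned_to_its_scenario(self, rng):
        table = synthetic_table(rng)
        row = table.df[table.df.scenario == 2].iloc[3]
        obs = row[list(SUMMARY_NAMES)].to_numpy(dtype=float)
        res = rf_model_choice(table, obs, n_trees=100,
                              rng=np.random.default_rng(1))
        assert res.selected == 2

    def test_noise_columns_do_not_flip_choice(self):
        quiet = synthetic_table(np.random.default_rng(3))
        noisy = synthetic_table(np.random.default_rng(3), noise_features=1.0)
        r1 = rf_model_choice(quiet, observed_for(4, quiet), n_trees=200,
                             rng=np.random.default_rng(2))
        r2 = rf_model_choice(noisy, observed_for(4, noisy), n_trees=200,
                             rng=np.random.default_rng(2))
        assert r1.selected == r2.selected == 4

    def test_reproducible_under_fixed_seed(self, rng):
        table = synthetic_table(rng)
        obs = observed_for(3, table)
        a = rf_model_choice(table, obs, n_trees=100,
                            rng=np.random.default_rng(11))
        b = rf_model_choice(table, obs, n_trees=100,
                            rng=np.random.default_rng(11))
        assert a.votes == b.votes
        assert a.posterior_prob == b.posterior_prob

    def test_too_few_trees_refused(self, rng):
        table = synthetic_table(rng, n_per=5)
        with pytest.raises(ValueError, match="n_trees"):
            rf_model_choice(table, observed_for(1, table), n_trees=10)


class TestGroupedChoice:
    def test_collapsed_labels_vote_for_correct_set(self, rng):
        table = synthetic_table(rng)
        res = grouped_model_choice(table, {1: {1, 2, 3}, 2: {4, 5, 6}},
                                   observed_for(6, table), n_trees=200,
                                   rng=np.random.default_rng(4))
        assert res.selected == 2
        assert res.votes[2] == 200

    def test_grouping_must_partition(self, rng):
        table = synthetic_table(rng, n_per=5)
        with pytest.raises(ValueError, match="partition"):
            grouped_model_choice(table, {1: {1, 2}, 2: {4, 5, 6}},
                                 observed_for(1, table), n_trees=100)
        with pytest.raises(ValueError, match="partition"):
            grouped_model_choice(table, {1: {1, 2, 3}, 2: {3, 4, 5, 6}},
                                 observed_for(1, table), n_trees=100)


class TestParameterEstimate:
    def test_noiseless_linear_relation_recovered(self, rng):
        table = synthetic_table(rng, n_per=100)
        # tD an exact linear function of the informative statistic
        table.df["tD"] = 100.0 * table.df["he_IND"] + 50.0
        obs = observed_for(4, table)
        post = rf_parameter_estimate(table, obs, "tD", n_trees=200,
                                     rng=np.random.default_rng(5),
                                     min_samples_leaf=2)
        truth = 100.0 * 4 + 50.0
        assert post.median == pytest.approx(truth, rel=0.02)
        assert post.q05 <= post.median <= post.q95

    def test_constant_parameter_degenerate(self, rng):
        table = synthetic_table(rng, n_per=10)
        table.df["ta1"] = 123.0
        post = rf_parameter_estimate(table, observed_for(1, table), "ta1",
                                     n_trees=100)
        assert post.median == post.q05 == post.q95 == 123.0

    def test_forest_reusable_across_observations(self, rng):
        table = synthetic_table(rng, n_per=50)
        table.df["tD"] = 10.0 * table.df["he_IND"]
        forest = ParameterForest(table, "tD", n_trees=100,
                                 rng=np.random.default_rng(6),
                                 min_samples_leaf=2)
        for sid in (1, 3, 6):
            post = forest.estimate(observed_for(sid, table))
            assert post.median == pytest.approx(10.0 * sid, rel=0.1)

    def test_years_conversion_helper(self):
        post = abc_rf.ParamPosterior("tD", 2593.0, 913.86, 5439.0)
        yrs = post.to_years()
        assert yrs == {"median": 6482, "q05": 2284, "q95": 13597}


class TestGenerationsToYears:
    @pytest.mark.parametrize("gens,years", [
        (2593, 6482), (790, 1975), (0, 0), (5439, 13597), (1874.90, 4687)])
    def test_floor_conversion(self, gens, years):
        assert generations_to_years(gens) == years

    def test_custom_generation_time(self):
        assert generations_to_years(100, gen_time=3.0) == 300


def test_scenario_choice_forest_batch_consistency(rng):
    table = synthetic_table(rng)
    forest = ScenarioChoiceForest(table, n_trees=100,
                                  rng=np.random.default_rng(8))
    for sid in (1, 2, 6):
        assert forest.choose(observed_for(sid, table)).selected == sid
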