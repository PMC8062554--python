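"""Ensemble classifier: moderated t, OVL, SVM ranks, OAO votes, convergence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossclust.ensemble import (EnsembleConfig, VoteTally, iterate_to_convergence,
                                 moderated_t_qvalues, ovl_coefficient, ovl_scores,
                                 rank_features, run_iteration, run_round,
                                 svm_weight_ranks, vote_from_wins)


def frame(values, columns=None):
    arr = np.asarray(values, dtype=float)
    cols = columns or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


class TestModeratedT:
    def test_equal_groups_give_zero_t(self, rng):
        half = rng.normal(0, 1, (20, 4))
        x = frame(np.hstack([half, half]))
        labels = np.repeat([0, 1], 4)
        _, t = moderated_t_qvalues(x, labels)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_no_shrinkage_reduces_to_ordinary_t(self, rng):
        x = frame(rng.normal(0, 1, (60, 12)))
        labels = np.repeat([0, 1], 6)
        _, t = moderated_t_qvalues(x, labels, d0_override=0)
        t_ref = stats.ttest_ind(x.to_numpy()[:, :6], x.to_numpy()[:, 6:],
                                axis=1).statistic
        np.testing.assert_allclose(t.to_numpy(), t_ref, atol=1e-8)

    def test_infinite_prior_df_pools_all_variances(self, rng):
        x = frame(rng.normal(0, 1, (40, 10)))
        labels = np.repeat([0, 1], 5)
        _, t = moderated_t_qvalues(x, labels, d0_override=np.inf)
        # closed form: common variance s0^2 for every gene
        xv = x.to_numpy()
        dg = 8
        s2 = (xv[:, :5].var(axis=1, ddof=1) * 4 + xv[:, 5:].var(axis=1, ddof=1) * 4) / dg
        from scipy.special import digamma
        e = np.log(s2) - digamma(dg / 2) + np.log(dg / 2)
        s0 = np.exp(e.mean())
        expected = (xv[:, :5].mean(axis=1) - xv[:, 5:].mean(axis=1)) / np.sqrt(
            s0 * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(t.to_numpy(), expected, atol=1e-8)

    def test_shrinkage_between_extremes(self, rng):
        x = frame(rng.normal(0, 1, (200, 8)))
        x.iloc[:10, :4] += 2.0
        labels = np.repeat([0, 1], 4)
        _, t_mod = moderated_t_qvalues(x, labels)
        _, t_raw = moderated_t_qvalues(x, labels, d0_override=0)
        # moderated statistics are damped for genes with tiny sample variance
        assert np.abs(t_mod).max() <= np.abs(t_raw).max() + 1e-9

    def test_small_group_errors(self, rng):
        with pytest.raises(ValueError):
            moderated_t_qvalues(frame(rng.normal(0, 1, (5, 3))), [0, 1, 1])


class TestOvl:
    def test_identical_samples(self, rng):
        x = rng.normal(0, 1, 300)
        assert ovl_coefficient(x, x) == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_samples(self, rng):
        assert ovl_coefficient(rng.normal(0, 0.1, 100),
                               rng.normal(50, 0.1, 100)) < 1e-3

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(0, 1, 500)
        x2 = rng.normal(2, 1, 500)
        expected = 2 * stats.norm.cdf(-1)  # overlap of N(0,1) and N(2,1)
        assert ovl_coefficient(x1, x2) == pytest.approx(expected, abs=0.03)

    def test_constant_samples(self):
        assert ovl_coefficient(np.full(6, 2.0), np.full(6, 2.0)) == 1.0
        assert ovl_coefficient(np.full(6, 2.0), np.full(6, 9.0)) < 0.05

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            ovl_coefficient([1.0, 2.0], [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_scores_rank_separated_gene_first(self, rng):
        x = frame(rng.normal(0, 1, (5, 24)))
        x.iloc[2, :12] += 5.0
        labels = np.repeat([0, 1], 12)
        scores = ovl_scores(x, labels)
        assert scores.idxmin() == x.index[2]


class TestSvmWeightRanks:
    def test_informative_gene_ranks_first(self, rng):
        x = frame(rng.normal(0, 1, (30, 24)))
        x.iloc[7, :12] += 4.0
        labels = np.repeat([0, 1], 12)
        ranks = svm_weight_ranks(x, labels)
        assert ranks.iloc[7] == 1

    def test_rank_list_is_permutation(self, rng):
        x = frame(rng.normal(0, 1, (15, 16)))
        labels = np.repeat([0, 1], 8)
        ranks = svm_weight_ranks(x, labels)
        assert sorted(ranks) == list(range(1, 16))

    def test_duplicated_gene_pair_shares_magnitude(self, rng):
        x = frame(rng.normal(0, 1, (10, 20)))
        x.iloc[3] = x.iloc[4]
        x.iloc[3, :10] += 2.0
        x.iloc[4, :10] += 2.0
        labels = np.repeat([0, 1], 10)
        ranks = svm_weight_ranks(x, labels)
        assert abs(ranks.iloc[3] - ranks.iloc[4]) == 1  # adjacent, stable ties


class TestVoteRule:
    def test_two_classes_every_prediction_votes(self):
        assert vote_from_wins([1, 0], 2) == 0
        assert vote_from_wins([0, 1], 2) == 1

    def test_cyclic_three_class_outcome_casts_no_vote(self):
        # pairwise outcomes A>B, C>A, B>C: every class wins once
        assert vote_from_wins([1, 1, 1], 3) is None

    def test_coherent_winner(self):
        assert vote_from_wins([2, 1, 0], 3) == 0
        assert vote_from_wins([0, 1, 2], 3) == 2


class TestIterationAndRound:
    @pytest.fixture()
    def separable(self, rng):
        x = rng.normal(0, 1, (40, 36))
        x[:8, :18] += 4.0
        m = frame(x)
        labels = pd.Series(["A"] * 18 + ["B"] * 18, index=m.columns)
        return m, labels

    def test_per_expert_votes_bounded(self, separable):
        x, labels = separable
        config = EnsembleConfig(n_iters=1, n_per_class=10,
                                n_feature_grid=(8, 16), seed=0)
        votes, opps = run_iteration(x, labels, config, iter_seed=1)
        n_experts = 3 * 3 * 2
        tested = opps > 0
        assert (votes.sum(axis=1)[tested] <= n_experts).all()
        assert (votes.to_numpy() >= 0).all()

    def test_round_totals(self, separable):
        x, labels = separable
        config = EnsembleConfig(n_iters=2, n_per_class=10,
                                n_feature_grid=(8, 16), seed=0)
        tally = run_round(x, labels, config, round_seed=4)
        assert tally.total_possible == 2 * 3 * 3 * 2
        assert (tally.votes.sum(axis=1) <= tally.opportunities).all()
        shares = tally.shares()
        assert shares.to_numpy().min() >= 0 and shares.to_numpy().max() <= 1

    def test_default_vote_capacity(self):
        assert EnsembleConfig().total_possible == 5400

    def test_minimal_config_capacity(self):
        config = EnsembleConfig(n_iters=1, fs_methods=("modt",),
                                clf_methods=("knn",), n_feature_grid=(8,))
        assert config.total_possible == 1

    def test_round_deterministic(self, separable):
        x, labels = separable
        config = EnsembleConfig(n_iters=2, n_per_class=10,
                                n_feature_grid=(8,), fs_methods=("modt", "wsv"),
                                seed=0)
        a = run_round(x, labels, config, round_seed=11)
        b = run_round(x, labels, config, round_seed=11)
        pd.testing.assert_frame_equal(a.votes, b.votes)

    def test_missing_class_errors(self, separable):
        x, labels = separable
        config = EnsembleConfig()
        with pytest.raises(ValueError):
            run_iteration(x, labels[labels == "A"], config, iter_seed=0)


class TestIterateToConvergence:
    def test_separable_data_all_confident_none_removed(self, rng):
        x = rng.normal(0, 1, (50, 40))
        x[:10, :20] += 4.0
        m = frame(x)
        meta = pd.DataFrame({"platform": "microarray", "batch": "b0",
                             "label": ["A"] * 20 + ["B"] * 20}, index=m.columns)
        config = EnsembleConfig(n_iters=20, n_rounds_max=1, n_per_class=10,
                                n_feature_grid=(8, 16), seed=2)
        out, tallies = iterate_to_convergence(m, meta, config)
        assert out["removed"].sum() == 0
        assert (out["confidence"] > 0.9).all()
        assert (out["final_label"] == meta["label"]).all()

    def test_pure_noise_vote_shares_near_uniform(self, rng):
        x = frame(rng.normal(0, 1, (30, 60)))
        labels = pd.Series(["A"] * 30 + ["B"] * 30, index=x.columns)
        config = EnsembleConfig(n_iters=12, n_per_class=15,
                                n_feature_grid=(8,), clf_methods=("knn", "svm"),
                                fs_methods=("modt", "wsv"), seed=3)
        tally = run_round(x, labels, config, round_seed=9)
        shares = tally.shares()
        eligible = tally.opportunities > 0
        mean_share_a = shares.loc[eligible, "A"].mean()
        assert 0.3 < mean_share_a < 0.7  # binomial band around 0.5

    def test_mislabeled_sample_removed_not_relabeled(self, rng):
        # cleaning judges a sample against the label it carries: a flipped
        # label on separable data is never confirmed, so the sample drops
        x = rng.normal(0, 1, (50, 40))
        x[:10, :20] += 4.0
        m = frame(x)
        labels = ["A"] * 20 + ["B"] * 20
        labels[3] = "B"  # mislabel one clear class-A sample
        meta = pd.DataFrame({"platform": "microarray", "batch": "b0",
                             "label": labels}, index=m.columns)
        config = EnsembleConfig(n_iters=20, n_rounds_max=1, n_per_class=10,
                                n_feature_grid=(8, 16), seed=4)
        out, _ = iterate_to_convergence(m, meta, config)
        assert out.loc[m.columns[3], "removed"]
        assert out["removed"].sum() == 1

    def test_requires_initial_labels(self, rng):
        x = frame(rng.normal(0, 1, (10, 8)))
        meta = pd.DataFrame({"platform": "microarray", "batch": "b0",
                             "label": [np.nan] * 8}, index=x.columns)
        with pytest.raises(ValueError):
            iterate_to_convergence(x, meta, EnsembleConfig())

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            EnsembleConfig(feedback_threshold=0.7, final_threshold=0.8).validate()
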