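import numpy as np
import pytest

from fusemble import (
    ClassRegistry,
    FusionModel,
    GeneratorConfig,
    PredictionSet,
    ProbabilityError,
    StackingConfig,
    StratificationError,
    WeightVector,
    generate,
    hard_vote,
    optimize_weights,
    soft_vote,
    stack,
)


def two_class_ps(prob_rows, truth=None):
    """One-item-per-row helper: prob_rows[j] is classifier j's (N, 2) matrix."""
    prob_rows = np.asarray(prob_rows, dtype=float)
    n = prob_rows.shape[1]
    return PredictionSet(
        classifiers=[f"c{j}" for j in range(len(prob_rows))],
        probs=prob_rows,
        truth=np.zeros(n, dtype=int) if truth is None else truth,
        registry=ClassRegistry(["A", "B"]),
    )


class TestWeightVector:
    def test_normalization_and_validation(self):
        w = WeightVector([2.0, 1.0, 1.0])
        assert w.weights.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            WeightVector([0.0, 0.0])
        with pytest.raises(ValueError):
            WeightVector([-1.0, 2.0])


class TestSoftVote:
    def test_uniform_average(self):
        ps = two_class_ps([[[0.6, 0.4]], [[0.3, 0.7]]])
        res = soft_vote(ps)
        assert np.allclose(res.fused_probs[0], [0.45, 0.55])
        assert res.fused_labels[0] == 1

    def test_weighted_average(self):
        ps = two_class_ps([[[0.6, 0.4]], [[0.2, 0.8]]])
        res = soft_vote(ps, weights=WeightVector([2.0, 1.0]))
        # scores proportional to (1.4, 1.6)
        assert np.allclose(res.fused_probs[0], [1.4 / 3, 1.6 / 3])
        assert res.fused_labels[0] == 1

    def test_single_member_is_identity(self, random_ps_factory):
        ps = random_ps_factory(0, m=1)
        res = soft_vote(ps)
        assert np.array_equal(res.fused_labels, ps.labels("clf0"))

    def test_rejects_label_only_member(self, registry4):
        ps = PredictionSet.from_labels(
            ["h"], np.array([0, 1]), np.array([0, 1]), registry4
        )
        with pytest.raises(ProbabilityError):
            soft_vote(ps)

    def test_fused_rows_sum_to_one_and_labels_are_argmax(self, random_ps_factory):
        ps = random_ps_factory(6, m=5, n=40)
        res = soft_vote(ps, weights=WeightVector([5, 1, 2, 1, 1]))
        assert np.allclose(res.fused_probs.sum(axis=1), 1.0)
        assert np.array_equal(res.fused_labels, res.fused_probs.argmax(axis=1))


class TestHardVote:
    def test_weighted_majority(self):
        # votes A, B, B with weights .5, .3, .3 -> B (0.6 > 0.5)
        ps = two_class_ps([[[1.0, 0.0]], [[0.0, 1.0]], [[0.0, 1.0]]])
        res = hard_vote(ps, weights=WeightVector([0.5, 0.3, 0.3]))
        assert res.fused_labels[0] == 1
        assert res.tie_count == 0

    def test_tie_goes_to_top_ranked_member(self):
        ps = two_class_ps([[[1.0, 0.0]], [[0.0, 1.0]]])
        res = hard_vote(ps, tie_rule="rank")
        assert res.fused_labels[0] == 0  # first member voted A
        assert res.tie_items == (0,)

    def test_tie_lowest_class_rule(self):
        ps = two_class_ps([[[0.0, 1.0]], [[1.0, 0.0]]])
        res = hard_vote(ps, tie_rule="lowest")
        assert res.fused_labels[0] == 0

    def test_unanimous_vote_wins_regardless_of_weights(self, random_ps_factory):
        ps = random_ps_factory(1, m=4, n=30)
        lab = ps.labels("clf0")
        clone = PredictionSet(
            ps.classifiers, np.repeat(ps.probs[:1], 4, axis=0), ps.truth, ps.registry
        )
        res = hard_vote(clone, weights=WeightVector([0.7, 0.1, 0.1, 0.1]))
        assert np.array_equal(res.fused_labels, lab)

    def test_degenerate_weight_vector_reduces_to_single_member(self, random_ps_factory):
        ps = random_ps_factory(2, m=3, n=25)
        res = hard_vote(ps, weights=WeightVector([1.0, 0.0, 0.0]))
        assert np.array_equal(res.fused_labels, ps.labels("clf0"))


class TestVotingInvariances:
    def test_weight_scale_invariance(self, random_ps_factory):
        rng = np.random.default_rng(42)
        for trial in range(20):
            ps = random_ps_factory(trial, m=4, n=30)
            raw = rng.random(4) + 0.05
            for c in (0.1, 3.0, 250.0):
                a = soft_vote(ps, weights=WeightVector(raw))
                b = soft_vote(ps, weights=WeightVector(raw * c))
                assert np.array_equal(a.fused_labels, b.fused_labels)
                ha = hard_vote(ps, weights=WeightVector(raw))
                hb = hard_vote(ps, weights=WeightVector(raw * c))
                assert np.array_equal(ha.fused_labels, hb.fused_labels)

    def test_uniform_weighted_average_equals_soft_vote(self, random_ps_factory):
        for trial in range(10):
            ps = random_ps_factory(100 + trial, m=5, n=40)
            sv = soft_vote(ps)
            wav = soft_vote(ps, weights=WeightVector(np.full(5, 0.2)))
            assert np.array_equal(sv.fused_labels, wav.fused_labels)

    def test_identical_members_equal_single_member(self, random_ps_factory):
        ps = random_ps_factory(7, m=1, n=50)
        clones = PredictionSet(
            ["a", "b", "c"], np.repeat(ps.probs, 3, axis=0), ps.truth, ps.registry
        )
        single = ps.labels("clf0")
        assert np.array_equal(soft_vote(clones).fused_labels, single)
        assert np.array_equal(hard_vote(clones).fused_labels, single)


class TestOptimizeWeights:
    def test_perfect_plus_adversarial_member_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        n, c = 60, 3
        truth = rng.integers(0, c, n)
        perfect = np.full((n, c), 0.05)
        perfect[np.arange(n), truth] = 0.9
        wrong_label = (truth + 1) % c
        adversarial = np.full((n, c), 0.05)
        adversarial[np.arange(n), wrong_label] = 0.9
        ps = PredictionSet(
            ["good", "bad"],
            np.stack([perfect, adversarial]),
            truth,
            ClassRegistry([f"C{i}" for i in range(c)]),
        )
        w = optimize_weights(ps, method="sv", budget=40, seed=0)
        res = soft_vote(ps, weights=w)
        assert np.mean(res.fused_labels == truth) == 1.0

    def test_identical_members_give_member_accuracy(self, random_ps_factory):
        ps = random_ps_factory(3, m=1, n=40)
        clones = PredictionSet(
            ["a", "b"], np.repeat(ps.probs, 2, axis=0), ps.truth, ps.registry
        )
        w = optimize_weights(clones, method="sv", budget=10, seed=1)
        assert w.provenance["objective_value"] == pytest.approx(
            np.mean(ps.labels("clf0") == ps.truth)
        )

    def test_never_below_uniform_baseline(self):
        ps = generate(GeneratorConfig(n_items=300, n_classifiers=5,
                                      skills=[0.7, 0.68, 0.66, 0.64, 0.62], seed=7))
        uniform_acc = np.mean(soft_vote(ps).fused_labels == ps.truth)
        w = optimize_weights(ps, method="sv", budget=25, seed=2)
        tuned_acc = np.mean(soft_vote(ps, weights=w).fused_labels == ps.truth)
        assert tuned_acc >= uniform_acc

    def test_deterministic_under_seed(self, random_ps_factory):
        ps = random_ps_factory(9, m=3, n=50)
        w1 = optimize_weights(ps, method="hv", budget=15, seed=5)
        w2 = optimize_weights(ps, method="hv", budget=15, seed=5)
        assert np.array_equal(w1.weights, w2.weights)

    def test_budget_must_be_positive(self, random_ps_factory):
        with pytest.raises(ValueError):
            optimize_weights(random_ps_factory(0), budget=0)


class TestStacking:
    def test_separable_meta_features_recover_truth(self):
        # one member leaks the truth one-hot (plus jitter): any competent
        # meta-learner should reach near-perfect out-of-fold accuracy
        rng = np.random.default_rng(0)
        n, c = 500, 4
        truth = np.repeat(np.arange(c), n // c)
        rng.shuffle(truth)
        leak = np.full((n, c), 0.1 / (c - 1))
        leak[np.arange(n), truth] = 0.9
        noise = rng.dirichlet(np.ones(c), size=n)
        ps = PredictionSet(
            ["leak", "noise"],
            np.stack([leak, noise]),
            truth,
            ClassRegistry([f"C{i}" for i in range(c)]),
        )
        res = stack(ps, config=StackingConfig(meta_learner="logistic"), seed=0)
        assert np.mean(res.fused_labels == truth) >= 0.95

    def test_single_member_stack_close_to_member(self, synth_default):
        ps = synth_default.subset(["m01"])
        res = stack(ps, config=StackingConfig(meta_learner="logistic"), seed=7)
        member_acc = synth_default.accuracy("m01")
        stacked_acc = np.mean(res.fused_labels == ps.truth)
        assert abs(stacked_acc - member_acc) <= 0.05

    def test_stratification_error_when_folds_exceed_support(self, registry4):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(4), size=(1, 4))
        ps = PredictionSet(["c"], probs, np.arange(4), registry4)
        with pytest.raises(StratificationError, match="fewer folds"):
            stack(ps, config=StackingConfig(folds=2, meta_learner="logistic"))

    def test_gbdt_meta_learner_runs_and_is_seeded(self, random_ps_factory):
        ps = random_ps_factory(4, m=2, n=120, c=3)
        cfg = StackingConfig(meta_learner="gbdt", search_trials=2)
        a = stack(ps, config=cfg, seed=3)
        b = stack(ps, config=cfg, seed=3)
        assert np.array_equal(a.fused_labels, b.fused_labels)
        assert np.allclose(a.fused_probs.sum(axis=1), 1.0)

    def test_rejects_label_only_member(self, registry4):
        ps = PredictionSet.from_labels(
            ["h"], np.tile([0, 1, 2, 3], 10), np.tile([0, 1, 2, 3], 10), registry4
        )
        with pytest.raises(ProbabilityError):
            stack(ps, config=StackingConfig(meta_learner="logistic"))


class TestFusionModel:
    def test_sv_model_matches_function(self, random_ps_factory):
        ps = random_ps_factory(5, m=4, n=60)
        res = FusionModel(ps, "sv").fit()
        assert np.array_equal(res.fused_labels, soft_vote(ps).fused_labels)
        assert 0.0 <= res.accuracy <= 1.0

    def test_wav_fit_optimizes_and_reports_weights(self):
        ps = generate(GeneratorConfig(n_items=200, n_classifiers=4,
                                      skills=[0.7, 0.68, 0.66, 0.64], seed=3))
        res = FusionModel(ps, "wav").fit(seed=3, budget=15)
        assert res.weights is not None
        assert res.weights.provenance["kind"] == "optimized"
        assert "WAV" in res.summary()

    def test_paper_mode_objective_is_full_set(self):
        ps = generate(GeneratorConfig(n_items=200, n_classifiers=4,
                                      skills=[0.7, 0.68, 0.66, 0.64], seed=4))
        res = FusionModel(ps, "whv").fit(seed=1, budget=10, paper_mode=True)
        assert res.weights.provenance["n_objective_items"] == ps.n

    def test_metric_report_and_fused_feedback(self, random_ps_factory):
        ps = random_ps_factory(8, m=3, n=80)
        res = FusionModel(ps, "sv").fit()
        rep = res.metric_report(ci="wilson", with_auc=True)
        assert rep.n == 80
        assert ("overall", "accuracy") in rep.cis
        fused_ps = res.to_prediction_set()
        assert fused_ps.m == 1
        assert np.array_equal(fused_ps.labels(fused_ps.classifiers[0]), res.fused_labels)

    def test_unknown_method_rejected(self, random_ps_factory):
        with pytest.raises(ValueError):
            FusionModel(random_ps_factory(0), "bagging")
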