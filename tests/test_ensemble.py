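"""Boosting mechanics (weights, errors, coefficients), fusion, evaluation."""

import numpy as np
import pytest

import sahpanel.ensemble as ens
from sahpanel.ensemble import (
    BoostedClassifier,
    EnsembleClassifier,
    EvalReport,
    evaluate,
)
from sahpanel.simulate import simulate_benchmark


class StubLearner:
    """Weak learner with scripted predictions, one script per fit call."""

    scripts: list[np.ndarray] = []
    calls: int = 0

    def __init__(self):
        self._script = None

    def fit(self, X, y, sample_weight=None):
        self._script = np.asarray(StubLearner.scripts[StubLearner.calls % len(StubLearner.scripts)])
        StubLearner.calls += 1
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        return self._script[: len(X)]

    def predict_proba(self, X):
        p1 = self._script[: len(X)].astype(float)
        return np.column_stack([1 - p1, p1])

    def get_params(self, deep=True):
        return {}

    def set_params(self, **kw):
        return self


@pytest.fixture
def scripted(monkeypatch):
    def install(scripts):
        StubLearner.scripts = [np.asarray(s) for s in scripts]
        StubLearner.calls = 0
        monkeypatch.setattr(ens, "_make_weak", lambda family, seed: StubLearner())

    return install


class TestBoostFit:
    def test_initial_weights_are_uniform(self, scripted):
        scripted([[0, 0, 1, 1]])
        X = np.zeros((4, 1))
        y = np.array([0, 0, 1, 1])
        model = BoostedClassifier(T=1, keep_weight_history=True).fit(X, y)
        np.testing.assert_allclose(model.sample_weights_history_[0], 0.25)

    def test_hand_computed_round(self, scripted):
        """One miss in four under uniform weights: eps=1/4, alpha=ln(3)/2,
        and the missed sample's weight renormalizes to 1/2."""
        scripted([[0, 0, 1, 0], [0, 0, 1, 1]])  # round 1 misses sample 3
        X = np.zeros((4, 1))
        y = np.array([0, 0, 1, 1])
        model = BoostedClassifier(T=2, keep_weight_history=True).fit(X, y)
        r1 = model.rounds_[0]
        assert r1.epsilon == pytest.approx(0.25)
        assert r1.alpha == pytest.approx(0.5 * np.log(3), abs=1e-12)
        assert r1.alpha == pytest.approx(0.5493, abs=1e-4)
        D2 = model.sample_weights_history_[1]
        assert D2[3] == pytest.approx(0.5)
        np.testing.assert_allclose(D2[:3], 1 / 6)

    def test_weight_conservation_every_round(self, scripted):
        scripted([[0, 0, 1, 0], [0, 1, 1, 1], [0, 0, 1, 1]])
        X = np.zeros((4, 1))
        y = np.array([0, 0, 1, 1])
        model = BoostedClassifier(T=3, keep_weight_history=True).fit(X, y)
        for D in model.sample_weights_history_:
            assert D.sum() == pytest.approx(1.0, abs=1e-12)

    def test_half_error_round_discarded(self, scripted):
        scripted([[0, 0, 1, 1], [1, 1, 1, 1]])  # round 2 has eps = 0.5... stop
        X = np.zeros((4, 1))
        y = np.array([0, 0, 1, 1])
        model = BoostedClassifier(T=5).fit(X, y)
        # first round is perfect -> kept with capped alpha, loop ends there
        assert len(model.rounds_) == 1
        assert model.rounds_[0].epsilon == 0.0
        n = 4
        eps_min = 1 / (2 * n)
        assert model.rounds_[0].alpha == pytest.approx(0.5 * np.log((1 - eps_min) / eps_min))

    def test_no_usable_classifier_raises(self, scripted):
        scripted([[1, 1, 0, 0]])  # always wrong: eps = 1 >= 0.5
        X = np.zeros((4, 1))
        y = np.array([0, 0, 1, 1])
        with pytest.raises(RuntimeError, match="no usable weak classifier"):
            BoostedClassifier(T=3).fit(X, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            BoostedClassifier().fit(np.zeros((3, 1)), np.array([1, 1, 1]))

    def test_training_error_bound_on_seeded_fits(self):
        """AdaBoost bound: training error <= prod_t 2 sqrt(eps_t(1-eps_t))."""
        for seed in range(3):
            X, y = simulate_benchmark(seed=seed, n_samples=80)
            for family in ("logistic", "margin", "naive_prob"):
                model = BoostedClassifier(family=family, T=8).fit(X, y)
                err = float(np.mean(model.predict(X) != y))
                assert err <= model.training_error_bound() + 1e-12


class TestBoostPredict:
    def test_single_certain_round(self, scripted):
        scripted([[0, 0, 1, 1]])
        X = np.zeros((4, 1))
        y = np.array([0, 0, 1, 1])
        model = BoostedClassifier(T=1).fit(X, y)
        assert model.predict(X)[3] == 1
        assert model.predict_proba(X)[3, 1] == pytest.approx(1.0)

    def test_margin_is_weighted_vote_sum(self, scripted):
        scripted([[0, 0, 1, 0], [0, 1, 1, 1]])
        X = np.zeros((4, 1))
        y = np.array([0, 0, 1, 1])
        model = BoostedClassifier(T=2).fit(X, y)
        a1, a2 = (r.alpha for r in model.rounds_)
        h1 = np.where(model.rounds_[0].learner.predict(X) == 1, 1, -1)
        h2 = np.where(model.rounds_[1].learner.predict(X) == 1, 1, -1)
        np.testing.assert_allclose(model.decision_function(X), a1 * h1 + a2 * h2)

    def test_zero_margin_tie_goes_positive(self):
        model = BoostedClassifier()
        model.classes_ = np.array([0, 1])
        model.rounds_ = []
        model.n_features_in_ = 1
        # two synthetic rounds with equal alpha and opposite votes
        class Const:
            def __init__(self, v):
                self.v = v

            def predict(self, X):
                return np.full(len(X), self.v)

        model.rounds_ = [
            ens.BoostRound(Const(1), 0.2, 0.7),
            ens.BoostRound(Const(0), 0.2, 0.7),
        ]
        X = np.zeros((1, 1))
        assert model.decision_function(X)[0] == pytest.approx(0.0)
        assert model.predict(X)[0] == 1

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            BoostedClassifier().predict(np.zeros((1, 2)))


class TestEnsemble:
    def test_three_distinct_members(self):
        X, y = simulate_benchmark(seed=1, n_samples=60)
        model = EnsembleClassifier(T=3).fit(X, y)
        assert set(model.members_) == {"logistic", "margin", "naive_prob"}

    def test_determinism(self):
        X, y = simulate_benchmark(seed=2, n_samples=60)
        m1 = EnsembleClassifier(T=3, random_state=0).fit(X, y)
        m2 = EnsembleClassifier(T=3, random_state=0).fit(X, y)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))
        np.testing.assert_allclose(m1.fused_score(X), m2.fused_score(X))

    def test_separable_data_zero_training_error(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += np.where(y == 1, 3.0, -3.0)
        model = EnsembleClassifier(T=5).fit(X, y)
        for member in model.members_.values():
            assert np.mean(member.predict(X) != y) == 0.0

    @pytest.mark.parametrize(
        "probs,expected",
        [((1.0, 1.0, 1.0), 1), ((0.5, 0.5, 0.5), 1), ((0.9, 0.2, 0.1), 0)],
    )
    def test_mean_fusion_vote(self, probs, expected):
        """E is the mean of member probabilities; the 0.5 boundary votes 1."""
        model = EnsembleClassifier(fusion="mean", threshold=0.5)
        model.classes_ = np.array([0, 1])

        class FixedMember:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, X):
                return np.column_stack([np.full(len(X), 1 - self.p), np.full(len(X), self.p)])

        model.members_ = {f: FixedMember(p) for f, p in zip(ens.FAMILIES, probs)}
        E = model.fused_score(np.zeros((1, 1)))[0]
        assert E == pytest.approx(np.mean(probs))
        assert model.predict(np.zeros((1, 1)))[0] == expected

    def test_sum_fusion_equivalent_to_mean_at_triple_threshold(self):
        rng = np.random.default_rng(4)
        for tau in (0.3, 0.5, 0.7):
            triples = rng.uniform(size=(500, 3))
            mean_vote = triples.mean(axis=1) >= tau
            sum_vote = triples.sum(axis=1) >= 3 * tau
            np.testing.assert_array_equal(mean_vote, sum_vote)

    def test_model_serialization_round_trip(self, tmp_path):
        import json

        X, y = simulate_benchmark(seed=5, n_samples=60)
        model = EnsembleClassifier(T=3).fit(X, y)
        model.save(tmp_path / "model.json")
        doc = json.loads((tmp_path / "model.json").read_text())
        assert doc["version"] == 1
        assert set(doc["families"]) == set(ens.FAMILIES)
        for fam, rounds in doc["families"].items():
            assert all(0 <= r["epsilon"] < 0.5 and r["alpha"] > 0 for r in rounds)


class TestEvaluate:
    def test_confusion_arithmetic(self):
        """(TP,FP,TN,FN)=(8,2,7,3): acc 0.75, prec 0.8, sens 8/11, spec 7/9."""
        y_true = np.array([1] * 8 + [0] * 2 + [0] * 7 + [1] * 3)
        y_pred = np.array([1] * 8 + [1] * 2 + [0] * 7 + [0] * 3)
        scores = y_pred.astype(float)
        rep = EvalReport.from_predictions(y_true, y_pred, scores)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (8, 2, 7, 3)
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.precision == pytest.approx(0.8)
        assert rep.sensitivity == pytest.approx(8 / 11)
        assert rep.specificity == pytest.approx(7 / 9)

    def test_perfect_scorer(self):
        y = np.array([0] * 10 + [1] * 10)
        scores = y.astype(float)
        rep = EvalReport.from_predictions(y, y, scores)
        assert rep.auc == pytest.approx(1.0)
        assert (rep.accuracy, rep.precision, rep.sensitivity, rep.specificity) == (1, 1, 1, 1)

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=500)
        scores = rng.uniform(size=500)
        rep = EvalReport.from_predictions(y, (scores >= 0.5).astype(int), scores)
        assert abs(rep.auc - 0.5) <= 0.05

    def test_roc_points_monotone(self):
        X, y = simulate_benchmark(seed=7, n_samples=60)
        rep = evaluate(X, y, T=3, scheme="k_fold", seed=0)
        diffs = np.diff(rep.roc_points, axis=0)
        assert (diffs >= -1e-12).all()

    def test_leave_one_out_default_for_small_n(self):
        X, y = simulate_benchmark(seed=8, n_samples=24)
        rep = evaluate(X, y, T=2, seed=0)
        total = rep.tp + rep.fp + rep.tn + rep.fn
        assert total == 24  # every sample held out exactly once
        assert set(rep.base_accuracy) == {"logistic", "margin", "naive_prob", "ensemble"}
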