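"""Bayes-rule fusion, majority voting and the naive upper bound."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intentsense.classifiers import ConfusionMatrixSet
from intentsense.fusion import (
    FusionConfig,
    bayes_fuse,
    fuse_trial,
    majority_vote,
    naive_upper_bound,
)


def _random_cms(rng, sensors, n_steps):
    like = {}
    for s in sensors:
        counts = rng.integers(1, 30, size=(n_steps, 3, 3)).astype(float)
        like[s] = (counts + 1.0) / (counts + 1.0).sum(axis=-1, keepdims=True)
    return ConfusionMatrixSet.from_likelihoods(like)


def _enumeration_oracle(votes, cms, prior=None):
    """Exhaustive joint-Bayes: product of per-vote likelihoods per class,
    normalised over classes (written from the definition, linear domain)."""
    prior = np.full(3, 1 / 3) if prior is None else np.asarray(prior)
    lik = np.ones(3)
    for s, vs in votes.items():
        tables = cms.likelihoods(s)
        for tau, v in enumerate(vs):
            for e in range(3):
                lik[e] *= tables[tau, e, v]
    post = lik * prior
    return post / post.sum()


class TestBayesFuse:
    def test_hand_case_single_sensor_diag_09(self):
        """One sensor, one step, L with 0.9 diagonal and 0.05 off-diagonal,
        vote = class 1, uniform prior: posterior of class 1 is
        0.9/(0.9 + 0.05 + 0.05) = 0.9 exactly."""
        L = np.full((3, 3), 0.05)
        np.fill_diagonal(L, 0.9)
        cms = ConfusionMatrixSet.from_likelihoods({"s1": L})
        post = bayes_fuse({"s1": [0]}, cms)
        assert post.probabilities[0] == pytest.approx(0.9, abs=1e-12)
        assert post.decided_class == 0

    def test_uninformative_sensors_give_uniform_posterior(self):
        cms = ConfusionMatrixSet.from_likelihoods(
            {"a": np.full((2, 3, 3), 1 / 3), "b": np.full((2, 3, 3), 1 / 3)}
        )
        post = bayes_fuse({"a": [0, 2], "b": [1, 1]}, cms)
        assert np.allclose(post.probabilities, 1 / 3, atol=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cms = _random_cms(rng, ["a", "b"], 2)
            votes = {"a": rng.integers(0, 3, 2), "b": rng.integers(0, 3, 2)}
            post = bayes_fuse(votes, cms)
            assert np.allclose(post.probabilities, _enumeration_oracle(votes, cms), atol=1e-12)

    def test_log_and_linear_domains_agree(self):
        rng = np.random.default_rng(3)
        cms = _random_cms(rng, ["a", "b", "c"], 3)
        votes = {s: rng.integers(0, 3, 3) for s in "abc"}
        p_log = bayes_fuse(votes, cms, FusionConfig(log_domain=True)).probabilities
        p_lin = bayes_fuse(votes, cms, FusionConfig(log_domain=False)).probabilities
        assert np.allclose(p_log, p_lin, atol=1e-9)

    def test_missing_confusion_matrix_is_configuration_error(self):
        cms = ConfusionMatrixSet.from_likelihoods({"a": np.full((1, 3, 3), 1 / 3)})
        with pytest.raises(KeyError, match="no confusion matrices"):
            bayes_fuse({"b": [0]}, cms)

    def test_step_pooled_method_uses_pooled_tables(self):
        rng = np.random.default_rng(5)
        cms = _random_cms(rng, ["a"], 4)
        votes = {"a": [1, 1]}
        pooled = cms.pooled_likelihood("a")
        expected = pooled[:, 1] * pooled[:, 1]
        expected = expected / expected.sum()
        post = bayes_fuse(votes, cms, FusionConfig(method="bayes_sensor_only"))
        assert np.allclose(post.probabilities, expected, atol=1e-12)

    def test_sensor_subset_needs_no_retraining(self):
        """Modularity: fusing any subset of sensors is well-defined with the
        same per-sensor matrices."""
        rng = np.random.default_rng(8)
        cms = _random_cms(rng, ["a", "b", "c"], 2)
        votes = {s: rng.integers(0, 3, 2) for s in "abc"}
        for subset in (["a"], ["a", "c"], ["b", "c"]):
            sub = {s: votes[s] for s in subset}
            post = bayes_fuse(sub, cms)
            assert np.allclose(post.probabilities, _enumeration_oracle(sub, cms), atol=1e-12)

    def test_adding_supportive_sensor_never_decreases_posterior(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            cms = _random_cms(rng, ["a"], 2)
            votes = {"a": rng.integers(0, 3, 2)}
            target = 1
            before = bayes_fuse(votes, cms).probabilities[target]
            L = np.full((3, 3), 0.1)
            np.fill_diagonal(L, 0.8)  # informative: diagonal > 1/3
            cms2 = ConfusionMatrixSet.from_likelihoods(
                {**{s: cms.likelihoods(s) for s in cms.sensors},
                 "extra": np.stack([L, L])}
            )
            after = bayes_fuse({**votes, "extra": [target, target]}, cms2).probabilities[target]
            assert after >= before - 1e-12


class TestMajorityVote:
    def test_vote_fractions(self):
        post = majority_vote([0, 0, 1])
        assert np.allclose(post.probabilities, [2 / 3, 1 / 3, 0.0])
        assert post.decided_class == 0

    def test_tie_breaks_to_lowest_class(self):
        assert majority_vote([0, 1]).decided_class == 0
        assert majority_vote([2, 1]).decided_class == 1

    def test_unanimous_votes(self):
        votes = {s: np.full(10, 2) for s in "abcdef"}
        post = majority_vote(votes)
        assert post.probabilities[2] == 1.0
        assert post.decided_class == 2

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            majority_vote([])


class TestNaiveBound:
    def test_closed_forms(self):
        assert naive_upper_bound({"s1": 0.9}).p_bound == pytest.approx(0.9)
        assert naive_upper_bound({"s1": 0.9, "s2": 0.8}).p_bound == pytest.approx(0.98)
        assert naive_upper_bound({"s1": 1.0, "s2": 0.37}).p_bound == pytest.approx(1.0)

    def test_bound_dominates_best_sensor(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            accs = {f"s{i}": rng.uniform(0, 1) for i in range(6)}
            nb = naive_upper_bound(accs)
            assert nb.p_bound >= max(accs.values()) - 1e-12
            assert nb.p_bound <= 1.0

    def test_invalid_accuracy_rejected(self):
        with pytest.raises(ValueError):
            naive_upper_bound({"s1": 1.2})


class TestFuseTrial:
    def test_prefix_property_majority(self):
        votes = {"a": np.array([0, 1, 2]), "b": np.array([1, 1, 0])}
        seq = fuse_trial(votes, None, FusionConfig(method="majority_full"))
        single = majority_vote({"a": votes["a"][:1], "b": votes["b"][:1]})
        assert np.allclose(seq[0].probabilities, single.probabilities)

    def test_prefix_property_bayes(self):
        rng = np.random.default_rng(4)
        cms = _random_cms(rng, ["a", "b"], 3)
        votes = {"a": rng.integers(0, 3, 3), "b": rng.integers(0, 3, 3)}
        seq = fuse_trial(votes, cms, FusionConfig())
        for t in (1, 2, 3):
            direct = bayes_fuse({s: v[:t] for s, v in votes.items()}, cms)
            assert np.allclose(seq[t - 1].probabilities, direct.probabilities, atol=1e-12)

    def test_always_correct_votes_stay_correct(self):
        L = np.full((3, 3), 0.05)
        np.fill_diagonal(L, 0.9)
        cms = ConfusionMatrixSet.from_likelihoods(
            {s: np.stack([L] * 5) for s in ("a", "b")}
        )
        votes = {s: np.full(5, 1) for s in ("a", "b")}
        seq = fuse_trial(votes, cms, FusionConfig())
        assert all(p.decided_class == 1 for p in seq)
        probs = np.array([p.probabilities[1] for p in seq])
        assert np.all(np.diff(probs) >= -1e-12)

    def test_recovery_after_adversarial_first_step(self):
        L = np.full((3, 3), 0.05)
        np.fill_diagonal(L, 0.9)
        cms = ConfusionMatrixSet.from_likelihoods({"a": np.stack([L] * 6)})
        votes = {"a": np.array([2, 1, 1, 1, 1, 1])}  # wrong once, then truth=1
        seq = fuse_trial(votes, cms, FusionConfig())
        assert seq[0].decided_class == 2
        assert seq[-1].decided_class == 1
        probs = np.array([p.probabilities[1] for p in seq])
        assert np.all(np.diff(probs[1:]) >= -1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_posteriors_normalised_and_sensor_order_invariant(seed):
    rng = np.random.default_rng(seed)
    cms = _random_cms(rng, ["a", "b", "c"], 2)
    votes = {s: rng.integers(0, 3, 2) for s in "abc"}
    post = bayes_fuse(votes, cms)
    assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(post.probabilities >= 0)
    reordered = bayes_fuse(dict(reversed(list(votes.items()))), cms)
    assert np.allclose(post.probabilities, reordered.probabilities, atol=1e-12)
    maj = majority_vote(votes)
    maj_r = majority_vote(dict(reversed(list(votes.items()))))
    assert np.allclose(maj.probabilities, maj_r.probabilities, atol=1e-12)
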