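"""Probabilistic fusion of per-sensor, per-time-step intent votes.

At every time step each sensor classifier casts a vote (argmax class)
for the window ending at that step.  The fused intent estimate at step t
combines *all* votes from all sensors at all steps up to and including
t:

* **Bayes-rule fusion** weights each vote by the confusion matrix of its
  (sensor, step) — the likelihood table L[e, v] = P(vote v | true e)
  learned on the Confusion-Matrix-Learning subjects.  Assuming
  independence between sensors (and between time steps given the
  intent), the likelihood of the observed vote set V under intent e is
  the product of the per-vote likelihoods, and with prior P(e),

      P(e | V) = P(V | e) P(e) / (P(V | e) P(e) + P(V | e') P(e')),

  where the complement event e' expands as the prior-weighted average of
  the other classes, P(V | e') P(e') = sum_{f != e} P(V | f) P(f).  With
  a uniform prior this reduces to the product likelihoods normalised
  over the three classes.  ``bayes_sensor_time`` uses per-(sensor, step)
  tables; ``bayes_sensor_only`` uses step-pooled per-sensor tables.

* **Majority voting** gives every (sensor, step) vote equal weight; it
  consumes no confusion matrices, so its classifiers may be trained on
  the full training set (``majority_full``) or on half of it
  (``majority_half``, the controlled comparison against the weighted
  methods, which can only ever train on half).

* The **naive model** predicts an upper bound on fused network accuracy
  from per-sensor accuracies under independence:
  P_B = P(S1 u ... u S6) = 1 - prod_i (1 - P(S_i)).

Fusion consumes hard argmax votes by default (that is what
confusion-matrix weighting operationally means); expected-likelihood
fusion of soft class probabilities is available via
``FusionConfig.soft_votes``.  Products are evaluated in the log domain
by default to avoid underflow over many steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .classifiers import N_CLASSES, ConfusionMatrixSet
from .config import ACTIVITIES, FUSION_METHODS

__all__ = [
    "IntentPosterior",
    "FusionConfig",
    "NaiveBound",
    "bayes_fuse",
    "majority_vote",
    "naive_upper_bound",
    "fuse_trial",
]


@dataclass(frozen=True)
class IntentPosterior:
    """Fused probability over the intent classes at one time step."""

    step_index: int
    probabilities: np.ndarray  # (3,), sums to 1
    decided_class: int  # argmax, ties -> lowest class index

    @property
    def decided_label(self) -> str:
        return ACTIVITIES[self.decided_class]


@dataclass
class FusionConfig:
    """Which fusion rule to apply and how."""

    method: str = "bayes_sensor_time"
    prior: np.ndarray = field(default_factory=lambda: np.full(N_CLASSES, 1.0 / N_CLASSES))
    log_domain: bool = True
    soft_votes: bool = False

    def __post_init__(self) -> None:
        if self.method not in FUSION_METHODS:
            raise ValueError(
                f"unknown fusion method {self.method!r}; valid: {list(FUSION_METHODS)}"
            )
        self.prior = np.asarray(self.prior, dtype=float)
        if self.prior.shape != (N_CLASSES,) or not np.isclose(self.prior.sum(), 1.0):
            raise ValueError("prior must be a 3-vector summing to 1")


def _posterior_from_loglik(loglik: np.ndarray, prior: np.ndarray, step: int) -> IntentPosterior:
    logpost = loglik + np.log(prior)
    logpost -= logsumexp(logpost)
    probs = np.exp(logpost)
    probs /= probs.sum()
    return IntentPosterior(
        step_index=step, probabilities=probs, decided_class=int(np.argmax(probs))
    )


def _vote_loglik(
    sensor: str,
    cms: ConfusionMatrixSet,
    votes: np.ndarray,
    config: FusionConfig,
    probs: np.ndarray | None,
) -> np.ndarray:
    """Log-likelihood contributions of one sensor's votes, (t, 3).

    Entry [tau, e] is log P(vote_tau | true class e) under the sensor's
    likelihood table for step tau (or the step-pooled table).
    """
    t = len(votes)
    if config.method == "bayes_sensor_only":
        like = np.broadcast_to(cms.pooled_likelihood(sensor), (t, N_CLASSES, N_CLASSES))
    else:
        like = cms.likelihoods(sensor)[:t]
    if config.soft_votes:
        if probs is None:
            raise ValueError("soft_votes fusion requires per-window class probabilities")
        # expected likelihood of the soft vote: sum_v p(v) L[e, v]
        return np.log(np.einsum("tev,tv->te", like, probs[:t]))
    return np.log(like[np.arange(t), :, np.asarray(votes, dtype=int)])


def bayes_fuse(
    votes: dict[str, np.ndarray],
    cms: ConfusionMatrixSet,
    config: FusionConfig | None = None,
    probs: dict[str, np.ndarray] | None = None,
) -> IntentPosterior:
    """Fuse all votes up to the current step with the Bayes rule.

    ``votes[sensor]`` holds that sensor's voted class indices at steps
    1..t.  Confusion matrices must cover every included sensor.
    """
    config = config or FusionConfig()
    if not votes:
        raise ValueError("no votes to fuse")
    t = max(len(v) for v in votes.values())
    loglik = np.zeros(N_CLASSES)
    for sensor, v in votes.items():
        if sensor not in cms.counts:
            raise KeyError(f"no confusion matrices for sensor {sensor!r}")
        contrib = _vote_loglik(
            sensor, cms, np.asarray(v), config, None if probs is None else probs.get(sensor)
        )
        loglik += contrib.sum(axis=0)
    if not config.log_domain:
        lik = np.exp(loglik) * config.prior
        probs_out = lik / lik.sum()
        return IntentPosterior(
            step_index=t,
            probabilities=probs_out,
            decided_class=int(np.argmax(probs_out)),
        )
    return _posterior_from_loglik(loglik, config.prior, t)


def majority_vote(votes) -> IntentPosterior:
    """Equal-weight fusion: class fractions over all (sensor, step) votes.

    ``votes`` may be a flat vote sequence or a mapping sensor -> votes.
    Modal class decided with ties broken toward the lowest class index.
    """
    if isinstance(votes, dict):
        flat = np.concatenate([np.asarray(v, dtype=int) for v in votes.values()])
        t = max(len(v) for v in votes.values())
    else:
        flat = np.asarray(votes, dtype=int).ravel()
        t = len(flat)
    if flat.size == 0:
        raise ValueError("empty vote set")
    fractions = np.bincount(flat, minlength=N_CLASSES) / flat.size
    return IntentPosterior(
        step_index=t,
        probabilities=fractions,
        decided_class=int(np.argmax(fractions)),
    )


@dataclass(frozen=True)
class NaiveBound:
    """Independence-based upper bound on fused network accuracy."""

    p_bound: float
    sensor_accuracies: dict[str, float]


def naive_upper_bound(sensor_accuracies: dict[str, float]) -> NaiveBound:
    """P_B = 1 - prod_i (1 - P(S_i)): the union of per-sensor successes
    evaluated under independence."""
    acc = np.array(list(sensor_accuracies.values()), dtype=float)
    if np.any(acc < 0) or np.any(acc > 1):
        raise ValueError("sensor accuracies must lie in [0, 1]")
    p_bound = 1.0 - np.prod(1.0 - acc)
    return NaiveBound(p_bound=float(p_bound), sensor_accuracies=dict(sensor_accuracies))


def fuse_trial(
    votes: dict[str, np.ndarray],
    cms: ConfusionMatrixSet | None,
    config: FusionConfig,
    steps: list[int] | None = None,
    probs: dict[str, np.ndarray] | None = None,
) -> list[IntentPosterior]:
    """One fused posterior per evaluation step for a whole trial.

    ``votes[sensor]`` is the full (n_steps,) vote sequence; the posterior
    at step t uses all votes at steps <= t.  Computed cumulatively, so a
    trial costs O(n_sensors * n_steps).
    """
    sensors = list(votes)
    n_steps = len(next(iter(votes.values())))
    steps = steps or list(range(1, n_steps + 1))
    if config.method in ("majority_full", "majority_half"):
        stacked = np.stack([np.asarray(votes[s], dtype=int) for s in sensors])  # (S, T)
        onehot = np.zeros((len(sensors), n_steps, N_CLASSES))
        s_idx, t_idx = np.meshgrid(
            np.arange(len(sensors)), np.arange(n_steps), indexing="ij"
        )
        onehot[s_idx, t_idx, stacked] = 1.0
        cum = onehot.sum(axis=0).cumsum(axis=0)  # (T, 3) cumulative counts
        out = []
        for t in steps:
            counts = cum[t - 1]
            fr = counts / counts.sum()
            out.append(
                IntentPosterior(
                    step_index=t, probabilities=fr, decided_class=int(np.argmax(fr))
                )
            )
        return out
    if cms is None:
        raise ValueError("Bayes fusion requires confusion matrices")
    contrib = np.zeros((n_steps, N_CLASSES))
    for s in sensors:
        contrib += _vote_loglik(
            s,
            cms,
            np.asarray(votes[s], dtype=int),
            config,
            None if probs is None else probs.get(s),
        )
    cumlog = contrib.cumsum(axis=0)
    return [_posterior_from_loglik(cumlog[t - 1], config.prior, t) for t in steps]
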