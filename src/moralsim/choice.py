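"""Logistic random-utility choice model.

An option's social utility is the linear score u(theta) = w . lambda with
lambda the option's feature content; the probability of choosing the
intervention option is the logistic function of the utility difference,

    P(Y = 1 | theta0, theta1) = 1 / (1 + exp(-(u(theta1) - u(theta0)))).

Decisions are simulated either stochastically (a Bernoulli draw at that
probability) or deterministically (the maximum-likelihood decision: 1 iff
the utility difference is positive, with exact ties resolved to the
non-intervention status quo).  The deterministic variant removes the
irreducible randomness of the choice process so that a predictor knowing
the true weights is exactly right on every decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .scenarios import CharacterVocabulary, OptionVector, Scenario, features

__all__ = [
    "TIE_TOLERANCE",
    "DecisionProcess",
    "utility",
    "utility_difference",
    "intervention_probability",
    "decide_deterministic",
    "simulate_decision",
    "sigmoid",
]

#: Utility differences within this of zero count as a tie (decision 0).
TIE_TOLERANCE: float = 1e-12


@dataclass(frozen=True)
class DecisionProcess:
    kind: Literal["stochastic", "deterministic"]

    def __post_init__(self):
        if self.kind not in ("stochastic", "deterministic"):
            raise ValueError(f"unknown decision process {self.kind!r}")


def sigmoid(x):
    """Numerically stable logistic function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.shape else float(out)


def utility(w: np.ndarray, theta: OptionVector,
            vocab: CharacterVocabulary | None = None) -> float:
    """Social utility u(theta) = w . features(theta)."""
    lam = features(theta, vocab)
    w = np.asarray(w, dtype=float)
    if w.shape != lam.shape:
        raise ValueError(f"weight length {w.shape} does not match feature "
                         f"length {lam.shape}")
    return float(w @ lam)


def utility_difference(w: np.ndarray, s: Scenario,
                       vocab: CharacterVocabulary | None = None) -> float:
    """u(theta1) - u(theta0): the log-odds of intervening."""
    return utility(w, s.theta1, vocab) - utility(w, s.theta0, vocab)


def intervention_probability(w: np.ndarray, s: Scenario,
                             vocab: CharacterVocabulary | None = None) -> float:
    """Probability that a participant with weights ``w`` intervenes."""
    return float(sigmoid(utility_difference(w, s, vocab)))


def decide_deterministic(delta_u) -> int:
    """Maximum-likelihood decision with the shared tie rule.

    1 when the intervention utility strictly exceeds the status quo,
    otherwise 0 (ties |delta_u| <= TIE_TOLERANCE go to non-intervention).
    """
    return int(np.asarray(delta_u) > TIE_TOLERANCE)


def simulate_decision(w: np.ndarray, s: Scenario, process: DecisionProcess,
                      rng: np.random.Generator | None = None,
                      vocab: CharacterVocabulary | None = None) -> int:
    """Simulate one decision under the stochastic or deterministic process."""
    du = utility_difference(w, s, vocab)
    if process.kind == "deterministic":
        return decide_deterministic(du)
    if rng is None:
        raise ValueError("stochastic decisions need an rng")
    return int(rng.random() < sigmoid(du))
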