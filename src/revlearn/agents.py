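"""Model-free reinforcement-learning models for the two-choice task.

Two Rescorla-Wagner variants, each usable as a simulator (choice policy for
:func:`revlearn.task.run_session`) and as a likelihood provider for fitting:

* single learning rate: V[k] <- V[k] + alpha * (lambda - V[k])
* dual learning rate: alpha+ applied when the prediction error
  delta = lambda - V[k] is positive, alpha- otherwise (delta = 0 included).

Choices follow a softmax on the expected values with inverse temperature
beta. Outcomes are coded lambda = +1 (win) / -1 (loss); the +/-50 point
magnitude of the task is absorbed into beta. Initial values are 0 for both
options. Missed trials contribute no likelihood term and trigger no update.

For fitting, parameters live in an unconstrained space: learning rates via
the logistic transform, beta via the exponential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from numba import njit

from .task import IMAGES, MISS, Session, TaskState

SINGLE = "single"
DUAL = "dual"


def sigmoid(x):
    from scipy.special import expit

    return expit(np.asarray(x, dtype=float))


def _safe_exp(x: float) -> float:
    # optimisers may probe huge unconstrained betas; keep them finite
    return float(np.exp(min(float(x), 50.0)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


@dataclass(frozen=True)
class SingleRateParams:
    """Single learning-rate model: alpha in [0,1], beta >= 0."""

    alpha: float
    beta: float

    model = SINGLE
    n_params = 2

    def to_unconstrained(self) -> np.ndarray:
        return np.array([float(logit(self.alpha)), np.log(self.beta)])

    @classmethod
    def from_unconstrained(cls, theta: Sequence[float]) -> "SingleRateParams":
        return cls(alpha=float(sigmoid(theta[0])), beta=_safe_exp(theta[1]))


@dataclass(frozen=True)
class DualRateParams:
    """Dual learning-rate model: separate rates for positive and negative
    prediction errors."""

    alpha_pos: float
    alpha_neg: float
    beta: float

    model = DUAL
    n_params = 3

    def to_unconstrained(self) -> np.ndarray:
        return np.array(
            [
                float(logit(self.alpha_pos)),
                float(logit(self.alpha_neg)),
                np.log(self.beta),
            ]
        )

    @classmethod
    def from_unconstrained(cls, theta: Sequence[float]) -> "DualRateParams":
        return cls(
            alpha_pos=float(sigmoid(theta[0])),
            alpha_neg=float(sigmoid(theta[1])),
            beta=_safe_exp(theta[2]),
        )


Params = Union[SingleRateParams, DualRateParams]


def softmax_probs(V: Sequence[float], beta: float) -> np.ndarray:
    """Softmax choice probabilities p_k = exp(beta V_k) / sum_i exp(beta V_i).

    beta = 0 gives uniform choice; beta -> inf approaches a hard argmax.
    Computed with max-subtraction for numerical stability.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("values must be finite")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    z = beta * V
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def update_single(V: Sequence[float], choice: int, lam: float, alpha: float) -> np.ndarray:
    """One Rescorla-Wagner update of the chosen option's value."""
    V = np.array(V, dtype=float)
    V[choice] += alpha * (lam - V[choice])
    return V


def update_dual(V: Sequence[float], choice: int, lam: float, params: DualRateParams) -> np.ndarray:
    """Dual-rate update: alpha+ when delta > 0, alpha- otherwise."""
    V = np.array(V, dtype=float)
    delta = lam - V[choice]
    alpha = params.alpha_pos if delta > 0 else params.alpha_neg
    V[choice] += alpha * delta
    return V


# -- likelihood ---------------------------------------------------------------


@njit(cache=False)
def _nll_kernel(choices, lams, a_pos, a_neg, beta):  # pragma: no cover - jit
    v0 = 0.0
    v1 = 0.0
    nll = 0.0
    for t in range(choices.shape[0]):
        c = choices[t]
        if c < 0:  # miss: no likelihood term, no update
            continue
        vc = v0 if c == 0 else v1
        vo = v1 if c == 0 else v0
        zc = beta * vc
        zo = beta * vo
        m = zc if zc > zo else zo
        nll -= zc - (m + np.log(np.exp(zc - m) + np.exp(zo - m)))
        d = lams[t] - vc
        a = a_pos if d > 0 else a_neg
        vc += a * d
        if c == 0:
            v0 = vc
        else:
            v1 = vc
    return nll


def session_arrays(session: Session) -> tuple[np.ndarray, np.ndarray]:
    """Encode a session for the likelihood kernel.

    choices: int8 (0/1 image index, -1 for a miss); lams: outcome values
    (+1 win / -1 loss, 0 on misses).
    """
    from .task import outcome_value

    choices = np.array(
        [-1 if t.choice is None else IMAGES.index(t.choice) for t in session.trials],
        dtype=np.int8,
    )
    lams = np.array([outcome_value(t.outcome) for t in session.trials])
    return choices, lams


def nll_arrays(choices: np.ndarray, lams: np.ndarray, params: Params) -> float:
    if isinstance(params, SingleRateParams):
        a_pos = a_neg = params.alpha
    else:
        a_pos, a_neg = params.alpha_pos, params.alpha_neg
    return float(_nll_kernel(choices, lams, a_pos, a_neg, params.beta))


def nll(params: Params, session: Session, model: Optional[str] = None) -> float:
    """Negative log likelihood of the observed choices under a model.

    Values are updated trial by trial with the model's rule; missed trials
    are skipped entirely. Raises if the session contains no response.
    """
    if model is not None and model != params.model:
        raise ValueError(f"params are for model {params.model!r}, not {model!r}")
    choices, lams = session_arrays(session)
    if np.all(choices < 0):
        raise ValueError("all trials missed: likelihood undefined")
    return nll_arrays(choices, lams, params)


def nll_python(params: Params, session: Session) -> float:
    """Pure-python reference implementation of :func:`nll` (used to validate
    the compiled kernel)."""
    from .task import outcome_value

    V = np.zeros(2)
    total = 0.0
    for t in session.trials:
        if t.choice is None:
            continue
        k = IMAGES.index(t.choice)
        p = softmax_probs(V, params.beta)
        total -= np.log(p[k])
        lam = outcome_value(t.outcome)
        if isinstance(params, SingleRateParams):
            V = update_single(V, k, lam, params.alpha)
        else:
            V = update_dual(V, k, lam, params)
    return float(total)


# -- simulation ---------------------------------------------------------------


def act(params: Params, V: Sequence[float], rng: np.random.Generator) -> int:
    """Sample a choice index from the softmax over current values."""
    p = softmax_probs(V, params.beta)
    return int(rng.random() < p[1])  # one uniform draw per trial


class RLAgent:
    """Simulator wrapper satisfying the :class:`revlearn.task.Agent` protocol.

    Never reads the task state: choices depend only on the agent's own value
    estimates (V0 = 0 for both images).
    """

    def __init__(self, params: Params):
        self.params = params
        self.V = np.zeros(2)

    def choose(self, state: TaskState, rng: np.random.Generator) -> str:
        return IMAGES[act(self.params, self.V, rng)]

    def observe(self, choice: Optional[str], outcome_value: float) -> None:
        if choice is MISS or choice is None:
            return
        k = IMAGES.index(choice)
        if isinstance(self.params, SingleRateParams):
            self.V = update_single(self.V, k, outcome_value, self.params.alpha)
        else:
            self.V = update_dual(self.V, k, outcome_value, self.params)
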