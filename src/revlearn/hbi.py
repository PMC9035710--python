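"""Hierarchical Bayesian model fitting and random-effects model comparison.

Per-subject fits use the Laplace approximation: parameters are estimated in
unconstrained space by maximum a posteriori under a Gaussian prior
(mean 0, variance 6.25 by default), and the log model evidence is
approximated from the curvature at the mode,

    log p(D) ~ log p(D|theta*) + log p(theta*) + (d/2) log 2*pi
               - 1/2 log det H,

with H the Hessian of the negative log joint at the MAP theta*.

Group-level inference is an empirical-Bayes mean-field scheme over a set of
candidate models. Each iteration performs four steps: (1) responsibility-
weighted summary statistics of the subject-level estimates, (2) update of
the group Gaussian (mean regularised toward 0 by the subject-level
hyperprior), (3) subject-level re-fit under the current group Gaussian as
prior, and (4) update of the per-subject model responsibilities from the
Laplace evidences plus a digamma log-frequency term from the Dirichlet
posterior over model frequencies.

Model comparison reports exceedance probabilities (Monte-Carlo over the
Dirichlet posterior), a Bayes-omnibus-risk-style probability that observed
evidence differences arose by chance, and the protected exceedance
probability PXP_m = EP_m * (1 - p0) + p0 / M.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp

from .agents import DualRateParams, SingleRateParams, nll_arrays, session_arrays
from .task import Session

logger = logging.getLogger(__name__)

PRIOR_VARIANCE = 6.25  # wide Gaussian over unconstrained parameters

__all__ = [
    "PriorSpec",
    "SubjectFit",
    "ModelSpec",
    "SINGLE_MODEL",
    "DUAL_MODEL",
    "map_fit",
    "laplace_evidence",
    "exceedance_probability",
    "protected_xp",
    "HBIModel",
    "HBIResults",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian prior over unconstrained parameters."""

    mean: np.ndarray
    variance: np.ndarray

    @classmethod
    def default(cls, d: int, variance: float = PRIOR_VARIANCE) -> "PriorSpec":
        if variance <= 0:
            raise ValueError("prior variance must be positive")
        return cls(mean=np.zeros(d), variance=np.full(d, float(variance)))

    @property
    def d(self) -> int:
        return len(self.mean)

    def neg_log_pdf(self, theta: np.ndarray) -> float:
        z = (np.asarray(theta) - self.mean) ** 2 / self.variance
        return float(0.5 * np.sum(z + np.log(2 * np.pi * self.variance)))


@dataclass
class SubjectFit:
    """Laplace fit of one model to one subject."""

    model: str
    theta: np.ndarray  # MAP in unconstrained space
    hessian: np.ndarray  # of the negative log joint at the MAP
    neg_log_joint: float
    log_evidence: float
    n_params: int
    ok: bool = True


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: a name, a parameter class with unconstrained
    transforms, and a likelihood over encoded sessions."""

    name: str
    param_cls: type
    n_params: int

    def nll_fn(self, session: Session) -> Callable[[np.ndarray], float]:
        choices, lams = session_arrays(session)

        def fn(theta: np.ndarray) -> float:
            params = self.param_cls.from_unconstrained(theta)
            return nll_arrays(choices, lams, params)

        return fn


SINGLE_MODEL = ModelSpec("single", SingleRateParams, 2)
DUAL_MODEL = ModelSpec("dual", DualRateParams, 3)

_HESS_STEP = 1e-4


def _fd_hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
                step: float = _HESS_STEP) -> np.ndarray:
    """Central finite-difference Hessian with a fixed step."""
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * step**2)
    return H


def _is_pd(H: np.ndarray) -> bool:
    if H.size == 0:
        return True
    try:
        np.linalg.cholesky(H)
        return True
    except np.linalg.LinAlgError:
        return False


def map_fit(
    nll_fn: Callable[[np.ndarray], float],
    prior: PriorSpec,
    n_starts: int = 10,
    rng: Optional[np.random.Generator] = None,
    model: str = "",
    x0: Optional[np.ndarray] = None,
) -> SubjectFit:
    """MAP estimate and Laplace evidence for one subject and one model.

    Minimises ``nll_fn(theta) + neg log prior(theta)`` in unconstrained space
    from ``n_starts`` initial points drawn from the prior (plus an optional
    warm start ``x0``), keeping the best optimum. The Hessian is computed by
    central finite differences; a non-positive-definite Hessian is repaired
    with a small ridge if possible, otherwise the fit is flagged ``ok=False``.
    """
    if rng is None:
        rng = np.random.default_rng()
    d = prior.d

    def objective(theta: np.ndarray) -> float:
        val = nll_fn(theta) + prior.neg_log_pdf(theta)
        return val if np.isfinite(val) else 1e12

    if d == 0:
        theta = np.zeros(0)
        nlj = objective(theta)
        return SubjectFit(model, theta, np.zeros((0, 0)), nlj, -nlj, 0)

    starts = [] if x0 is None else [np.asarray(x0, dtype=float)]
    starts += [
        prior.mean + np.sqrt(prior.variance) * rng.standard_normal(d)
        for _ in range(n_starts)
    ]
    best = None
    for s in starts:
        res = minimize(objective, s, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    theta = np.asarray(best.x, dtype=float)
    H = _fd_hessian(objective, theta)
    H = 0.5 * (H + H.T)
    ok = True
    if not _is_pd(H):
        ridge = 1e-8
        while ridge <= 1e-2 and not _is_pd(H + ridge * np.eye(d)):
            ridge *= 10
        if _is_pd(H + ridge * np.eye(d)):
            H = H + ridge * np.eye(d)
        else:
            ok = False
            logger.warning("non-positive-definite Hessian for model %s", model)
    fit = SubjectFit(model, theta, H, float(best.fun), np.nan, d, ok=ok)
    fit.log_evidence = laplace_evidence(fit) if ok else -np.inf
    return fit


def laplace_evidence(fit: SubjectFit) -> float:
    """Laplace approximation to the log model evidence.

    log p(D|MAP) + log prior(MAP) + (d/2) log 2*pi - 1/2 log det H.
    """
    d = fit.n_params
    if d == 0:
        return -fit.neg_log_joint
    sign, logdet = np.linalg.slogdet(fit.hessian)
    if sign <= 0:
        raise np.linalg.LinAlgError("Hessian is not positive definite")
    return float(-fit.neg_log_joint + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet)


# -- model comparison ---------------------------------------------------------


def exceedance_probability(
    counts: Sequence[float],
    rng: Optional[np.random.Generator] = None,
    n_draws: int = 100_000,
) -> np.ndarray:
    """Exceedance probabilities from a Dirichlet posterior over model
    frequencies, by Monte-Carlo sampling.

    ``counts`` are the Dirichlet concentration parameters (prior counts plus
    summed responsibilities). EP_m is the fraction of sampled frequency
    vectors in which model m is the most frequent; exact ties split equally.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("Dirichlet concentrations must be positive")
    m = len(counts)
    if m == 1:
        return np.array([1.0])
    if rng is None:
        rng = np.random.default_rng()
    draws = rng.dirichlet(counts, size=n_draws)
    maxes = draws.max(axis=1, keepdims=True)
    winners = draws == maxes
    ep = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return ep / ep.sum()


def protected_xp(ep: Sequence[float], null_prob: float) -> np.ndarray:
    """Protected exceedance probability: EP shrunk toward uniform by the
    probability ``null_prob`` that evidence differences arose by chance."""
    ep = np.asarray(ep, dtype=float)
    if not 0.0 <= null_prob <= 1.0:
        raise ValueError("null_prob must be in [0, 1]")
    m = len(ep)
    return ep * (1.0 - null_prob) + null_prob / m


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL(Dir(alpha) || Dir(alpha0))."""
    a_sum = alpha.sum()
    return float(
        gammaln(a_sum)
        - gammaln(alpha).sum()
        - gammaln(alpha0.sum())
        + gammaln(alpha0).sum()
        + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(a_sum)))
    )


def bayes_omnibus_risk(lme: np.ndarray, r: np.ndarray, alpha: np.ndarray,
                       alpha0: np.ndarray) -> float:
    """Probability that differences in model evidence are due to chance.

    Compares the variational free energy of the fitted random-effects
    mixture (frequencies estimated) against the null model in which all
    models are equally frequent; returned as 1 / (1 + exp(F1 - F0)).
    """
    n, m = lme.shape
    e_log_f = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(r > 0, r * np.log(r), 0.0)
    f1 = float(np.sum(r * lme) + np.sum(r * e_log_f) - np.sum(ent)
               - _dirichlet_kl(alpha, alpha0))
    f0 = float(np.sum(logsumexp(lme - np.log(m), axis=1)))
    return float(1.0 / (1.0 + np.exp(f1 - f0)))


# -- hierarchical model -------------------------------------------------------


@dataclass
class HBIResults:
    """Group posterior, responsibilities and model comparison of an
    :class:`HBIModel` fit."""

    model_names: list[str]
    group_means: dict  # unconstrained, per model
    group_variances: dict
    group_params: dict  # back-transformed group means, per model
    subject_params: dict  # per model: list of constrained param objects
    subject_param_means: dict  # mean of back-transformed subject estimates
    responsibilities: np.ndarray  # subjects x models
    frequencies: np.ndarray  # posterior mean model frequencies
    alpha: np.ndarray  # Dirichlet concentrations
    exceedance: np.ndarray
    pxp: np.ndarray
    null_prob: float
    converged: bool
    n_iter: int
    trace: list[float] = field(default_factory=list)

    @property
    def argmax_counts(self) -> np.ndarray:
        """Subjects assigned to each model by argmax responsibility."""
        idx = self.responsibilities.argmax(axis=1)
        return np.bincount(idx, minlength=len(self.model_names))

    def summary(self) -> str:
        lines = [
            "Hierarchical Bayesian model comparison",
            "=" * 54,
            f"subjects: {self.responsibilities.shape[0]}   "
            f"converged: {self.converged} ({self.n_iter} iterations)",
            "",
            f"{'model':>8} {'freq':>7} {'EP':>7} {'PXP':>7} {'N(argmax)':>10}",
        ]
        for j, name in enumerate(self.model_names):
            lines.append(
                f"{name:>8} {self.frequencies[j]:7.3f} {self.exceedance[j]:7.3f} "
                f"{self.pxp[j]:7.3f} {self.argmax_counts[j]:10d}"
            )
        lines.append(f"null probability (chance): {self.null_prob:.3f}")
        for name in self.model_names:
            lines.append("")
            lines.append(f"[{name}] group means (back-transformed): "
                         f"{self.group_params[name]}")
            lines.append(f"[{name}] mean of subject estimates:      "
                         f"{self.subject_param_means[name]}")
        return "\n".join(lines)


class HBIModel:
    """Random-effects hierarchical Bayesian inference over candidate
    reinforcement-learning models, statsmodels-style.

    Parameters
    ----------
    sessions : list of Session
        One behavioural session per subject.
    models : list of ModelSpec
        Candidate models (default: single- and dual-learning-rate).
    prior_variance : float
        Variance of the zero-mean Gaussian hyperprior on unconstrained
        parameters (default 6.25).
    """

    def __init__(
        self,
        sessions: Sequence[Session],
        models: Optional[Sequence[ModelSpec]] = None,
        prior_variance: float = PRIOR_VARIANCE,
    ):
        if len(sessions) < 2:
            raise ValueError("hierarchical inference needs >= 2 subjects")
        self.sessions = list(sessions)
        self.models = list(models) if models is not None else [SINGLE_MODEL, DUAL_MODEL]
        if not self.models:
            raise ValueError("at least one candidate model is required")
        self.prior_variance = float(prior_variance)

    def fit(
        self,
        seed: Optional[int] = None,
        max_iter: int = 50,
        tol: float = 1e-4,
        n_starts: int = 10,
        ep_draws: int = 100_000,
        var_floor: float = 1e-4,
    ) -> HBIResults:
        """Run the four-step mean-field iteration to convergence."""
        rng = np.random.default_rng(seed)
        n, m = len(self.sessions), len(self.models)
        nll_fns = [[spec.nll_fn(s) for spec in self.models] for s in self.sessions]

        # initial non-hierarchical Laplace fits under the wide prior
        fits: list[list[SubjectFit]] = []
        for i in range(n):
            row = []
            for j, spec in enumerate(self.models):
                prior = PriorSpec.default(spec.n_params, self.prior_variance)
                row.append(map_fit(nll_fns[i][j], prior, n_starts, rng, spec.name))
            fits.append(row)

        alpha0 = np.ones(m)
        alpha = alpha0.copy()
        r = self._responsibilities(fits, alpha)
        group_mean = {s.name: np.zeros(s.n_params) for s in self.models}
        group_var = {
            s.name: np.full(s.n_params, self.prior_variance) for s in self.models
        }
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            prev_r = r.copy()
            prev_means = {k: v.copy() for k, v in group_mean.items()}

            # steps 1-2: weighted sufficient statistics -> group posterior
            for j, spec in enumerate(self.models):
                ok = np.array([fits[i][j].ok for i in range(n)])
                w = r[:, j] * ok
                n_eff = w.sum()
                if n_eff < 1e-8:
                    continue
                thetas = np.array([fits[i][j].theta for i in range(n)])
                # subject-level Laplace posterior variances enter the second
                # moment; without them the group variance collapses over
                # iterations instead of reaching a fixed point
                post_var = np.array(
                    [
                        np.diag(np.linalg.inv(fits[i][j].hessian))
                        if fits[i][j].ok
                        else np.zeros(spec.n_params)
                        for i in range(n)
                    ]
                )
                mean_w = (w[:, None] * thetas).sum(axis=0) / n_eff
                var_w = (
                    w[:, None] * ((thetas - mean_w) ** 2 + post_var)
                ).sum(axis=0) / n_eff
                var_w = np.maximum(var_w + var_floor, var_floor)
                # hyperprior N(0, prior_variance) regularises the group mean
                prec = n_eff / var_w + 1.0 / self.prior_variance
                group_mean[spec.name] = (n_eff / var_w * mean_w) / prec
                group_var[spec.name] = var_w

            # step 3: subject-level re-fits under the group Gaussian
            for i in range(n):
                for j, spec in enumerate(self.models):
                    prior = PriorSpec(
                        mean=group_mean[spec.name],
                        variance=group_var[spec.name].copy(),
                    )
                    # warm start from the previous MAP only: deterministic
                    # re-fits let the outer iteration converge
                    fits[i][j] = map_fit(
                        nll_fns[i][j], prior, 0, rng, spec.name,
                        x0=fits[i][j].theta,
                    )

            # step 4: responsibilities and Dirichlet counts
            r = self._responsibilities(fits, alpha)
            alpha = alpha0 + r.sum(axis=0)

            delta = max(
                float(np.max(np.abs(r - prev_r))),
                max(
                    float(np.max(np.abs(group_mean[k] - prev_means[k])))
                    for k in group_mean
                ),
            )
            trace.append(delta)
            if delta < tol:
                converged = True
                break
        if not converged:
            logger.warning("HBI did not converge in %d iterations", max_iter)

        lme = self._lme_matrix(fits)
        ep = exceedance_probability(alpha, rng, ep_draws)
        if m == 1:
            bor = 0.0
        else:
            bor = bayes_omnibus_risk(lme, r, alpha, alpha0)
        pxp = protected_xp(ep, bor)

        subject_params = {
            spec.name: [
                spec.param_cls.from_unconstrained(fits[i][j].theta)
                for i in range(n)
            ]
            for j, spec in enumerate(self.models)
        }
        subject_param_means = {}
        for j, spec in enumerate(self.models):
            arr = np.array(
                [
                    _constrain(spec, fits[i][j].theta)
                    for i in range(n)
                    if fits[i][j].ok
                ]
            )
            subject_param_means[spec.name] = arr.mean(axis=0)
        return HBIResults(
            model_names=[s.name for s in self.models],
            group_means=group_mean,
            group_variances=group_var,
            group_params={
                s.name: _constrain(s, group_mean[s.name]) for s in self.models
            },
            subject_params=subject_params,
            subject_param_means=subject_param_means,
            responsibilities=r,
            frequencies=alpha / alpha.sum(),
            alpha=alpha,
            exceedance=ep,
            pxp=pxp,
            null_prob=bor,
            converged=converged,
            n_iter=it,
            trace=trace,
        )

    def _lme_matrix(self, fits: list[list[SubjectFit]]) -> np.ndarray:
        n, m = len(fits), len(self.models)
        lme = np.full((n, m), -np.inf)
        for i in range(n):
            for j in range(m):
                if fits[i][j].ok:
                    lme[i, j] = fits[i][j].log_evidence
        return lme

    def _responsibilities(
        self, fits: list[list[SubjectFit]], alpha: np.ndarray
    ) -> np.ndarray:
        """r_nm proportional to exp(lme_nm + E[log f_m]), normalised per
        subject; subjects with no valid fit get uniform responsibilities."""
        lme = self._lme_matrix(fits)
        m = lme.shape[1]
        logits = lme + (digamma(alpha) - digamma(alpha.sum()))
        r = np.empty_like(logits)
        for i in range(lme.shape[0]):
            row = logits[i]
            if not np.any(np.isfinite(row)):
                logger.warning("subject %d has no valid fit; uniform r", i)
                r[i] = 1.0 / m
                continue
            row = row - logsumexp(row[np.isfinite(row)])
            r[i] = np.where(np.isfinite(row), np.exp(row), 0.0)
            r[i] /= r[i].sum()
        return r


def _constrain(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    p = spec.param_cls.from_unconstrained(theta)
    if spec.param_cls is SingleRateParams:
        return np.array([p.alpha, p.beta])
    return np.array([p.alpha_pos, p.alpha_neg, p.beta])
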