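"""Synthetic study cohorts: RL parameters, simulated sessions, behavioural
metrics and neurochemistry with a planted statistical structure.

Each subject's dual-learning-rate parameters are drawn from group Gaussians
in unconstrained space (defaults back-transform to the published group means
alpha+ = 0.4605, alpha- = 0.9786, beta = 1.8533) and used to simulate a full
360-trial session. Dorsal-striatal choline (mM) is then generated from the
subject's behaviour as

    choline = base + effect_scale * sum_j w_j * z(predictor_j) + noise,

with standardised planted weights w_j whose default magnitudes and signs
follow the published stage-3 regression (negative for reversals, alpha+,
perseverative and regressive errors; positive for alpha-; zero for beta).
GPC+PC is mixed from standardised choline plus independent noise so the
population correlation equals a configurable target (default -0.912), and
NAA is drawn independently of everything as a control metabolite.
Concentrations are kept positive by redrawing the noise, not by clipping.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agents import DualRateParams, RLAgent, logit, sigmoid
from .metrics import PerformanceSummary, summarize
from .task import Session, TaskConfig, run_session

PREDICTORS = ("reversals", "alpha_pos", "alpha_neg", "beta",
              "perseverative", "regressive")

#: standardised planted weights on choline, sign pattern and magnitudes from
#: the published stage-3 coefficients
DEFAULT_WEIGHTS = {
    "reversals": -0.400,
    "alpha_pos": -0.303,
    "alpha_neg": 0.328,
    "beta": 0.0,
    "perseverative": -0.619,
    "regressive": -0.574,
}


def _default_weights() -> dict:
    return dict(DEFAULT_WEIGHTS)


@dataclass(frozen=True)
class CohortConfig:
    """Stated world of the synthetic cohort.

    Group means are given in unconstrained space (logit for learning rates,
    log for beta); the defaults back-transform to the published group means.
    ``choline_noise_sd`` defaults to 0.04 mM so the planted stage-3 model
    explains ~98% of choline variance, matching the published fit.
    """

    n_subjects: int = 13
    mu_alpha_pos: float = float(logit(0.4605))
    mu_alpha_neg: float = float(logit(0.9786))
    mu_beta: float = float(np.log(1.8533))
    sd_alpha_pos: float = 0.5
    sd_alpha_neg: float = 0.5
    sd_beta: float = 0.5
    choline_mean: float = 0.797  # mM
    choline_effect_scale: float = 0.22  # mM per planted standardised unit
    choline_noise_sd: float = 0.04  # mM, unstructured residual
    gpcpc_mean: float = 0.854  # mM
    gpcpc_sd: float = 0.241  # mM
    target_anticorr: float = -0.912  # choline vs GPC+PC
    naa_mean: float = 8.7  # mM, typical striatal value (not printed upstream)
    naa_sd: float = 1.0
    weights: dict = field(default_factory=_default_weights)
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("sd_alpha_pos", "sd_alpha_neg", "sd_beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not abs(self.target_anticorr) < 1:
            raise ValueError("|target_anticorr| must be < 1")
        unknown = set(self.weights) - set(PREDICTORS)
        if unknown:
            raise ValueError(f"unknown planted-weight predictors: {unknown}")
        if not all(np.isfinite(list(self.weights.values()))):
            raise ValueError("planted weights must be finite")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=str)


@dataclass
class SubjectRecord:
    subject: str
    params: DualRateParams
    session: Session
    summary: PerformanceSummary
    choline: float
    gpc_pc: float
    naa: float


def sample_subject_params(config: CohortConfig, rng: np.random.Generator) -> DualRateParams:
    """Draw one subject's parameters from the group Gaussians and
    back-transform to constrained space."""
    theta = np.array([config.mu_alpha_pos, config.mu_alpha_neg, config.mu_beta])
    sd = np.array([config.sd_alpha_pos, config.sd_alpha_neg, config.sd_beta])
    theta = theta + sd * rng.standard_normal(3)
    return DualRateParams.from_unconstrained(theta)


def simulate_behaviour(
    config: CohortConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[DualRateParams], list[Session], list[PerformanceSummary], pd.DataFrame]:
    """Sample parameters and simulate one session per subject.

    Returns the per-subject parameters, sessions, summaries, and the
    behavioural predictor table used for neurochemistry generation.
    Subjects who never reversed have no post-reversal events; their error
    means are recorded as 0 (no errors were observable).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params_list, sessions, summaries, rows = [], [], [], []
    for i in range(config.n_subjects):
        params = sample_subject_params(config, rng)
        session = run_session(RLAgent(params), config.task, rng, subject=f"S{i + 1:03d}")
        summ = summarize(session)
        params_list.append(params)
        sessions.append(session)
        summaries.append(summ)
        rows.append(
            {
                "subject": summ.subject,
                "alpha_pos": params.alpha_pos,
                "alpha_neg": params.alpha_neg,
                "beta": params.beta,
                "correct": summ.correct,
                "reversals": summ.reversals,
                "mean_trials_to_criterion": summ.mean_trials_to_criterion,
                "perseverative": np.nan_to_num(summ.mean_perseverative),
                "regressive": np.nan_to_num(summ.mean_regressive),
                "misses": summ.misses,
            }
        )
    return params_list, sessions, summaries, pd.DataFrame(rows)


def _zscore(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    if sd == 0:
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def _positive_normal(
    loc: np.ndarray, scale: float, rng: np.random.Generator, max_tries: int = 1000
) -> np.ndarray:
    """loc + scale * eps with eps ~ N(0,1) redrawn until all entries are
    positive (resampling, not clipping, to preserve moments)."""
    if scale == 0:
        if np.any(loc <= 0):
            raise ValueError("non-positive concentration with zero noise")
        return np.array(loc, dtype=float)
    out = loc + scale * rng.standard_normal(len(loc))
    for _ in range(10):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = loc[bad] + scale * rng.standard_normal(int(bad.sum()))
    bad = out <= 0
    if bad.any():
        # deep-tail locations: draw the noise from its exact conditional
        # (truncated-normal) distribution instead of looping forever
        from scipy.stats import truncnorm

        a = (0.0 - loc[bad]) / scale
        out[bad] = truncnorm.rvs(
            a, np.inf, loc=loc[bad], scale=scale, random_state=rng
        )
    return out


def generate_neurochem(
    behaviour: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate choline, GPC+PC and NAA for a cohort's behaviour table.

    Operates on the whole cohort at once: planted weights apply to
    within-cohort z-scored predictors, and the GPC+PC mixing uses the
    cohort-standardised choline so the population anti-correlation matches
    the configured target. NAA is independent of everything by construction.
    """
    n = len(behaviour)
    z = np.column_stack([_zscore(behaviour[p].to_numpy(float)) for p in PREDICTORS])
    w = np.array([config.weights.get(p, 0.0) for p in PREDICTORS])
    loc = config.choline_mean + config.choline_effect_scale * (z @ w)
    choline = _positive_normal(loc, config.choline_noise_sd, rng)

    rho = config.target_anticorr
    sd_ch = choline.std()
    if sd_ch > 0 and n > 1:
        z_ch = (choline - choline.mean()) / sd_ch
        loc_g = config.gpcpc_mean + config.gpcpc_sd * rho * z_ch
        gpcpc = _positive_normal(
            loc_g, config.gpcpc_sd * float(np.sqrt(1 - rho**2)), rng
        )
    else:
        gpcpc = _positive_normal(
            np.full(n, config.gpcpc_mean), config.gpcpc_sd, rng
        )
    naa = _positive_normal(np.full(n, config.naa_mean), config.naa_sd, rng)
    return pd.DataFrame(
        {"choline_mM": choline, "gpcpc_mM": gpcpc, "naa_mM": naa},
        index=behaviour.index,
    )


def generate_cohort(
    config: CohortConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """End-to-end synthetic cohort: parameters -> sessions -> metrics ->
    neurochemistry. Returns the subject records and the cohort table."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params_list, sessions, summaries, behaviour = simulate_behaviour(config, rng)
    chem = generate_neurochem(behaviour, config, rng)
    table = pd.concat([behaviour, chem], axis=1)
    records = [
        SubjectRecord(
            subject=row.subject,
            params=params_list[i],
            session=sessions[i],
            summary=summaries[i],
            choline=float(chem["choline_mM"].iloc[i]),
            gpc_pc=float(chem["gpcpc_mM"].iloc[i]),
            naa=float(chem["naa_mM"].iloc[i]),
        )
        for i, row in enumerate(behaviour.itertuples())
    ]
    return records, table
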