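"""Calibration suites for the regression pipeline.

Two checks:

* type-I calibration — with all planted weights zero, the stage-3 F-change
  p-value must be uniform, so its rejection rate at 0.05 is 0.05. Under the
  null the p-value is uniform *conditional on any fixed design*, so the
  suite simulates one behavioural cohort and redraws only the
  neurochemistry; this is the exact test and keeps runtime low.

* sign recovery — with the default planted Table-style weights and the
  default noise, the stage-3 coefficient signs must reproduce the planted
  signs in nearly all replicate cohorts. Noise lives in the neurochemistry
  stage, so replicates are organised as fresh behavioural cohorts times a
  few neurochemistry redraws each.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CohortConfig, generate_neurochem, simulate_behaviour
from .stats import PAPER_STAGES, HierarchicalOLS


def null_config(config: Optional[CohortConfig] = None, **kw) -> CohortConfig:
    """A copy of ``config`` with every planted weight set to zero."""
    base = config if config is not None else CohortConfig(**kw)
    return dataclasses.replace(base, weights={k: 0.0 for k in base.weights})


def null_fchange_pvalues(
    config: CohortConfig,
    n_redraws: int = 1000,
    seed: int = 0,
    behaviour: Optional[pd.DataFrame] = None,
) -> np.ndarray:
    """Stage-3 F-change p-values under the zero-weight null.

    One behavioural design (simulated from ``config`` unless supplied),
    ``n_redraws`` independent neurochemistry draws.
    """
    cfg = null_config(config)
    rng = np.random.default_rng(seed)
    if behaviour is None:
        _, _, _, behaviour = simulate_behaviour(cfg, rng)
    pvals = np.empty(n_redraws)
    for i in range(n_redraws):
        chem = generate_neurochem(behaviour, cfg, rng)
        data = pd.concat([behaviour, chem], axis=1)
        stages = HierarchicalOLS(data, "choline_mM", PAPER_STAGES).fit(
            correlations=False
        ).stages
        pvals[i] = stages[-1].f_change_p
    return pvals


def planted_signs(config: CohortConfig) -> dict:
    """Predictors with non-zero planted weight and their signs."""
    return {k: np.sign(v) for k, v in config.weights.items() if v != 0.0}


def signs_recovered(data: pd.DataFrame, config: CohortConfig) -> bool:
    """True iff the stage-3 coefficient signs match every planted sign."""
    stages = HierarchicalOLS(data, "choline_mM", PAPER_STAGES).fit(
        correlations=False
    ).stages
    coefs = stages[-1].coefs["b"]
    return all(
        np.sign(coefs[name]) == sign for name, sign in planted_signs(config).items()
    )


def sign_recovery_rate(
    config: CohortConfig,
    replicates: int = 100,
    seed: int = 0,
    redraws_per_design: int = 5,
) -> float:
    """Fraction of replicate cohorts whose stage-3 coefficient signs match
    the planted pattern."""
    rng = np.random.default_rng(seed)
    n_designs = max(1, int(np.ceil(replicates / redraws_per_design)))
    hits = 0
    done = 0
    for _ in range(n_designs):
        _, _, _, behaviour = simulate_behaviour(config, rng)
        for _ in range(redraws_per_design):
            if done >= replicates:
                break
            chem = generate_neurochem(behaviour, config, rng)
            hits += signs_recovered(pd.concat([behaviour, chem], axis=1), config)
            done += 1
    return hits / done
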