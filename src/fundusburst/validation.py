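"""Simulation-based checks of the evaluation statistics.

These routines tie the synthetic session model to the bootstrap: they are
used to verify, by simulation, that the paired cluster bootstrap's percentile
interval attains nominal coverage under a true null difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bootstrap import BootstrapConfig, bootstrap_difference
from .study import select_from_session
from .synthetic import SessionTable, default_quality_model, simulate_session

__all__ = ["sufficient_frame_from_session", "null_coverage_simulation"]


def sufficient_frame_from_session(session: SessionTable | pd.DataFrame) -> pd.DataFrame:
    """Selected, paired, majority-voted analysis frame for the bootstrap.

    Applies the grading-selection rule, restricts to eyes captured on both
    cameras, and reduces the three sufficiency labels to their majority.
    Columns: ``participant_id``, ``camera``, ``sufficient``.
    """
    sel = select_from_session(session)
    maj = (sel[["grader1_sufficient", "grader2_sufficient", "grader3_sufficient"]]
           .sum(axis=1) >= 2)
    key = sel["participant_id"] + "|" + sel["eye"]
    paired = key.map(key.value_counts()).to_numpy() == 2
    out = sel[["participant_id", "camera"]].assign(sufficient=maj.to_numpy())
    return out[paired].reset_index(drop=True)


def null_coverage_simulation(
    n_studies: int = 500,
    n_participants: int = 108,
    B: int = 2000,
    seed: int = 0,
    marginal: float = 0.978,
) -> float:
    """Fraction of simulated null studies whose percentile CI covers 0.

    Each study simulates a paired session with identical marginal
    majority-sufficient proportions on both cameras (true difference 0) and
    bootstraps the difference; returns the CI coverage of 0 over
    ``n_studies`` studies.
    """
    qm = default_quality_model(marginal_investigational=marginal,
                               marginal_reference=marginal)
    covered = 0
    for i in range(n_studies):
        session = simulate_session(n_participants, quality_model=qm, seed=seed + i)
        df = sufficient_frame_from_session(session)
        res = bootstrap_difference(df, BootstrapConfig(B=B, seed=seed + i))
        covered += res.ci_low <= 0.0 <= res.ci_high
    return covered / n_studies
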