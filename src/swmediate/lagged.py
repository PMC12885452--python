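"""Time-lagged mediator analysis.

Tests temporal precedence: the outcome at wave ``t+1`` is predicted from the
mediator at wave ``t``, controlling for the outcome at ``t``, treatment and
time, with random intercepts for participant and cluster:

    outcome_{t+1} ~ mediator_t + outcome_t + treatment + wave
                    + (1 | participant) + (1 | cluster)

A negative mediator coefficient means that higher mediator levels at one
assessment precede lower outcome levels at the next.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lmm
from .lmm import LmmFit

__all__ = ["LaggedResult", "build_lagged_rows", "fit_lagged"]


@dataclass
class LaggedResult:
    """Lagged mediator coefficient with Wald CI/p and the underlying fit."""

    mediator: str
    outcome: str
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_lagged_rows: int
    fit: LmmFit


def build_lagged_rows(
    panel: pd.DataFrame, mediator: str, outcome: str
) -> pd.DataFrame:
    """One row per participant per consecutive wave pair (t, t+1).

    A pair is kept only when the mediator and outcome at ``t`` and the outcome
    at ``t+1`` are all observed.  The returned table carries ``mediator_prev``
    and ``outcome_prev`` (wave ``t``), the outcome at ``t+1``, treatment at
    the predicted wave ``t+1`` and the predicted wave index.  The construction
    is idempotent and invariant to the input row order.
    """
    cols = ["participant_id", "cluster", "sequence", "wave", "treatment", mediator, outcome]
    srt = panel[cols].sort_values(["participant_id", "wave"], kind="stable")
    cur = srt.copy()
    nxt = srt.copy()
    nxt["wave"] = nxt["wave"] - 1  # align wave t+1 onto wave t
    merged = cur.merge(
        nxt[["participant_id", "wave", "treatment", outcome]],
        on=["participant_id", "wave"],
        suffixes=("_prev", ""),
    )
    merged = merged.rename(
        columns={
            mediator: "mediator_prev",
            f"{outcome}_prev": "outcome_prev",
            outcome: "outcome",
        }
    )
    merged["wave"] = merged["wave"] + 1  # index of the predicted wave
    out = merged.dropna(subset=["mediator_prev", "outcome_prev", "outcome"])
    out = out[
        ["participant_id", "cluster", "sequence", "wave", "treatment",
         "mediator_prev", "outcome_prev", "outcome"]
    ].reset_index(drop=True)
    out.attrs["mediator"] = mediator
    out.attrs["outcome_name"] = outcome
    return out


def fit_lagged(
    panel: pd.DataFrame,
    mediator: str,
    outcome: str,
    *,
    random_effects: tuple = ("participant", "cluster"),
    categorical_wave: bool = False,
) -> LaggedResult:
    """Fit the lagged model and return the lagged mediator coefficient.

    ``wave`` enters as a linear term by default (``categorical_wave=True``
    switches to one indicator per wave).  Treatment is taken at the predicted
    wave.
    """
    rows = build_lagged_rows(panel, mediator, outcome)
    if not len(rows):
        raise ValueError("no complete (t, t+1) pairs in the panel")
    terms = ["mediator_prev", "outcome_prev", "treatment", "wave"]
    if categorical_wave:
        rows = rows.copy()
        rows["wave_cat"] = "w" + rows["wave"].astype(str)
        terms = ["mediator_prev", "outcome_prev", "treatment", "wave_cat"]
    fit = lmm.fit_lmm(rows, "outcome", terms, random_effects=random_effects)
    lo, hi = fit.wald_ci("mediator_prev")
    return LaggedResult(
        mediator=mediator,
        outcome=outcome,
        coefficient=fit.coef["mediator_prev"],
        se=fit.se["mediator_prev"],
        ci_low=lo,
        ci_high=hi,
        p=fit.wald_p("mediator_prev"),
        n_lagged_rows=len(rows),
        fit=fit,
    )
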