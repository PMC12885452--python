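"""Simulation studies that characterise the pipeline's operating behaviour.

These routines generate replicate trials under the default stepped-wedge
design, run the full estimation machinery on each, and summarise parameter
recovery, test size (type-I error) and percentile-CI coverage.  They back
both the test suite and the reproduction script, so the numbers reported in
either come from the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .lagged import fit_lagged
from .mediation import bootstrap_mediation, estimate_paths
from .panel import ModelSpec, attach_baseline
from .synthdata import SimulationConfig, generate_trial

__all__ = [
    "RecoveryStudy",
    "recovery_study",
    "rejection_and_coverage",
    "lagged_recovery",
]


@dataclass
class RecoveryStudy:
    """Replicate-mean path estimates with Monte-Carlo standard errors."""

    n_trials: int
    mean: dict[str, float]
    mcse: dict[str, float]
    truth: dict[str, float]

    def z(self, key: str) -> float:
        return (self.mean[key] - self.truth[key]) / self.mcse[key]


def _panel_for(config: SimulationConfig, seed: int):
    cfg = replace(config, seed=seed)
    return attach_baseline(generate_trial(cfg), cfg.outcome), cfg


def recovery_study(
    config: SimulationConfig | None = None, n_trials: int = 50, seed: int = 0
) -> RecoveryStudy:
    """Full-sample path recovery over replicate trials.

    Each replicate simulates a trial, fits the two mediation models and
    records a-hat, b-hat, the direct effect and the indirect product.
    """
    config = config or SimulationConfig()
    spec = ModelSpec.for_outcome(config.outcome, [config.mediator])
    rows = {"a": [], "b": [], "direct": [], "indirect": []}
    for i in range(n_trials):
        panel, cfg = _panel_for(config, seed + i)
        paths = estimate_paths(panel, spec)
        rows["a"].append(paths.a[cfg.mediator])
        rows["b"].append(paths.b[cfg.mediator])
        rows["direct"].append(paths.direct)
        rows["indirect"].append(paths.indirect(cfg.mediator))
    tp = config.true_paths()
    truth = {"a": tp.a, "b": tp.b, "direct": tp.c_prime, "indirect": tp.indirect}
    arrays = {k: np.asarray(v) for k, v in rows.items()}
    return RecoveryStudy(
        n_trials=n_trials,
        mean={k: float(v.mean()) for k, v in arrays.items()},
        mcse={k: float(v.std(ddof=1) / np.sqrt(n_trials)) for k, v in arrays.items()},
        truth=truth,
    )


def rejection_and_coverage(
    config: SimulationConfig | None = None,
    n_trials: int = 200,
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Bootstrap-test rejection rate and percentile-CI coverage of the truth.

    With a null configuration (``a_path=0``) the rejection rate estimates the
    test's type-I error; with a non-null configuration the coverage estimates
    how often the 95% percentile CI contains the true ``a*b``.
    """
    config = config or SimulationConfig()
    truth = config.true_paths().indirect
    reject = 0
    cover = 0
    for i in range(n_trials):
        panel, cfg = _panel_for(config, seed + i)
        res = bootstrap_mediation(
            panel,
            mediator=cfg.mediator,
            outcome=cfg.outcome,
            n_boot=n_boot,
            seed=seed + i,
        )
        reject += res.indirect.p < alpha
        cover += res.indirect.ci_low <= truth <= res.indirect.ci_high
    return {
        "n_trials": n_trials,
        "rejection_rate": reject / n_trials,
        "coverage": cover / n_trials,
        "truth": truth,
    }


def lagged_recovery(
    theta: float = -0.21,
    n_trials: int = 50,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> RecoveryStudy:
    """Recovery of the lagged mediator coefficient over replicate trials."""
    base = config or SimulationConfig()
    coefs = []
    for i in range(n_trials):
        cfg = replace(base, lagged_mediator_effect=theta, seed=seed + i)
        res = fit_lagged(generate_trial(cfg), cfg.mediator, cfg.outcome)
        coefs.append(res.coefficient)
    coefs = np.asarray(coefs)
    return RecoveryStudy(
        n_trials=n_trials,
        mean={"lagged": float(coefs.mean())},
        mcse={"lagged": float(coefs.std(ddof=1) / np.sqrt(n_trials))},
        truth={"lagged": theta},
    )
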