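"""Synthetic stepped-wedge trial generator with a known mediation structure.

The generator emulates the design of a six-cluster stepped-wedge trial of a
web-based stress-reduction program for health-care professionals: three
sequences cross over from control to intervention after 8, 16 and 24 weeks,
and participants are assessed every 8 weeks for 5 waves.  Scores follow
linear random-intercept models.  Wave-1 (baseline) outcomes carry stable
individual differences ``eta_i``; post-baseline waves inherit them through
the observed baseline score, exactly as the analysis models assume when they
adjust for the baseline level of the outcome:

    Y_i1 = mu_Y + eta_i + u_c + gamma' x_i + eps_i1
    M_it = mu_M + a * T_it + kappa * (Y_i1 - mu_Y) + gamma' x_i
           + delta_M * (wave-1) + u_i^M + eps_it
    Y_it = beta0 + c' * T_it + b * M_it + g_bl * (Y_i1 - mu_Y) + gamma' x_i
           + delta_Y * (wave-1) + u_c + u_i^Y + eps'_it        (waves t >= 2)

with all random intercepts and residuals independent Gaussians.  The true
indirect effect of treatment on the outcome through the mediator is exactly
``a * b``, and because the generative model matches the baseline-adjusted
random-intercept analysis models, the product-of-coefficients estimator is
unbiased for it — every inferential stage of the package can be tested
against a known truth without any external data.

Default path coefficients (a = 2.62, b = -0.48, c' = -2.77, on the CD-RISC /
PSS-10 scales) and covariate marginals (85.6 % female, mean age 45.01, ...)
match the published magnitudes for the trial the design emulates; variance
components are free parameters chosen to give realistic baseline score spreads
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .panel import MEDIATORS, OUTCOMES, SCORE_COLUMNS, SCORE_RANGES

__all__ = [
    "SimulationConfig",
    "TruePaths",
    "ConfigError",
    "make_design",
    "generate_trial",
    "apply_dropout",
]


class ConfigError(ValueError):
    """A simulation configuration field is invalid (message names the field)."""


#: Baseline instrument means used as generator intercepts (per instrument).
BASELINE_MEANS: dict[str, float] = {
    "pss": 16.88,
    "phq9": 6.25,
    "gad7": 7.05,
    "bsi_gsi": 12.34,
    "cd_risc": 27.31,
    "ffmq_observe": 2.84,
    "ffmq_describe": 3.54,
    "ffmq_act": 3.26,
    "ffmq_nonjudge": 3.80,
    "ffmq_nonreact": 3.01,
    "socs_other": 61.90,
    "socs_self": 53.53,
    "aaq2": 20.89,
}

#: Baseline instrument standard deviations (total spread across participants).
BASELINE_SDS: dict[str, float] = {
    "pss": 6.33,
    "phq9": 4.36,
    "gad7": 4.23,
    "bsi_gsi": 9.88,
    "cd_risc": 6.79,
    "ffmq_observe": 0.86,
    "ffmq_describe": 0.84,
    "ffmq_act": 0.91,
    "ffmq_nonjudge": 0.87,
    "ffmq_nonreact": 0.85,
    "socs_other": 8.77,
    "socs_self": 10.24,
    "aaq2": 8.33,
}

#: Share of total score variance assigned to the participant intercept for
#: secondary score columns (a typical test-retest correlation for self-report
#: instruments over 8-week intervals).
SECONDARY_ICC = 0.5

#: Allowed keys in ``covariate_effects`` (indicator or numeric covariates).
COVARIATE_EFFECT_KEYS = ("male", "nurse", "other", "temporary", "trainee", "age")

AGE_CENTER = 45.01  # age enters the generator centred here


@dataclass(frozen=True)
class TruePaths:
    """Ground-truth path coefficients of a generated trial."""

    a: float
    b: float
    indirect: float
    c_prime: float
    total: float

    @classmethod
    def from_coefficients(cls, a: float, b: float, c_prime: float) -> "TruePaths":
        return cls(a=a, b=b, indirect=a * b, c_prime=c_prime, total=c_prime + a * b)


@dataclass
class SimulationConfig:
    """Design geometry, true path coefficients and variance components.

    The defaults reproduce the emulated trial: 6 clusters of sizes
    81/48/60/75/57/26, two clusters per sequence, crossovers after 8/16/24
    weeks, 5 waves spaced 8 weeks apart, and path coefficients
    a = 2.62 (treatment -> resilience), b = -0.48 (resilience -> stress),
    c' = -2.77 (direct treatment -> stress), giving a true indirect effect
    a*b = -1.2576.
    """

    cluster_sizes: tuple = (81, 48, 60, 75, 57, 26)
    sequence_of_cluster: dict = field(
        default_factory=lambda: {1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3}
    )
    crossover_week_of_sequence: dict = field(
        default_factory=lambda: {1: 8.0, 2: 16.0, 3: 24.0}
    )
    n_waves: int = 5
    wave_spacing_weeks: float = 8.0

    mediator: str = "cd_risc"
    outcome: str = "pss"
    a_path: float = 2.62
    b_path: float = -0.48
    c_prime: float = -2.77
    #: optional additional mediated paths: column -> (a_k, b_k)
    extra_paths: dict = field(default_factory=dict)

    time_slope_mediator: float = 0.0
    time_slope_outcome: float = 0.0
    covariate_effects: dict = field(default_factory=dict)

    #: carry-over of the (centred) baseline outcome into post-baseline waves
    #: of the outcome (gamma_bl) and of the primary mediator (kappa_bl).
    #: Stable individual differences are transmitted through the baseline
    #: score, matching the analysis models, which adjust for baseline.
    baseline_effect_outcome: float = 0.5
    baseline_effect_mediator: float = -0.15

    sd_participant_mediator: float = 4.8
    sd_participant_outcome: float = 4.48
    sd_resid_mediator: float = 4.8
    sd_resid_outcome: float = 4.48
    sd_cluster_outcome: float = 0.0

    dropout_hazard_per_wave: float = 0.0
    clip_to_range: bool = False
    score_ranges: dict = field(default_factory=lambda: dict(SCORE_RANGES))

    #: "post_crossover": treated from the crossover week onwards (default);
    #: "active_program": treated only while the 8-week program is running.
    exposure_coding: str = "post_crossover"
    program_duration_weeks: float = 8.0

    #: When set, the primary outcome is generated sequentially as an AR(1)
    #: process in which the mediator at wave t enters the outcome at wave t+1
    #: with this coefficient (used to test the lagged analysis).
    lagged_mediator_effect: float | None = None
    outcome_ar: float = 0.3

    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if not self.cluster_sizes or any(
            (int(s) != s or s <= 0) for s in self.cluster_sizes
        ):
            raise ConfigError("cluster_sizes: all entries must be positive integers")
        n_clusters = len(self.cluster_sizes)
        for c in range(1, n_clusters + 1):
            if c not in self.sequence_of_cluster:
                raise ConfigError(f"sequence_of_cluster: no sequence for cluster {c}")
            if self.sequence_of_cluster[c] not in self.crossover_week_of_sequence:
                raise ConfigError(
                    f"sequence_of_cluster: cluster {c} maps to unknown sequence "
                    f"{self.sequence_of_cluster[c]}"
                )
        weeks = [self.crossover_week_of_sequence[s]
                 for s in sorted(self.crossover_week_of_sequence)]
        if any(w2 <= w1 for w1, w2 in zip(weeks, weeks[1:])):
            raise ConfigError(
                "crossover_week_of_sequence: crossover weeks must be strictly "
                "increasing across sequences"
            )
        if self.n_waves < 2:
            raise ConfigError("n_waves: must be >= 2")
        if self.wave_spacing_weeks <= 0:
            raise ConfigError("wave_spacing_weeks: must be positive")
        for name in ("sd_participant_mediator", "sd_participant_outcome",
                     "sd_cluster_outcome"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be non-negative")
        for name in ("sd_resid_mediator", "sd_resid_outcome"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be positive")
        if not (0.0 <= self.dropout_hazard_per_wave < 1.0):
            raise ConfigError("dropout_hazard_per_wave: must lie in [0, 1)")
        if self.mediator not in MEDIATORS:
            raise ConfigError(f"mediator: unknown score column {self.mediator!r}")
        if self.outcome not in OUTCOMES:
            raise ConfigError(f"outcome: unknown score column {self.outcome!r}")
        for k in self.extra_paths:
            if k not in MEDIATORS or k == self.mediator:
                raise ConfigError(f"extra_paths: invalid mediator column {k!r}")
        for k in self.covariate_effects:
            if k not in COVARIATE_EFFECT_KEYS:
                raise ConfigError(
                    f"covariate_effects: unknown key {k!r} "
                    f"(allowed: {COVARIATE_EFFECT_KEYS})"
                )
        if self.exposure_coding not in ("post_crossover", "active_program"):
            raise ConfigError(
                "exposure_coding: must be 'post_crossover' or 'active_program'"
            )

    # ------------------------------------------------------------------
    def true_paths(self) -> TruePaths:
        return TruePaths.from_coefficients(self.a_path, self.b_path, self.c_prime)

    @property
    def n_participants(self) -> int:
        return int(sum(self.cluster_sizes))

    def schedule(self) -> dict:
        """Schedule mapping usable by :func:`swmediate.panel.validate_panel`."""
        d = {int(s): float(w) for s, w in self.crossover_week_of_sequence.items()}
        d["wave_spacing_weeks"] = self.wave_spacing_weeks
        return d

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["cluster_sizes"] = list(self.cluster_sizes)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "cluster_sizes" in payload:
            payload["cluster_sizes"] = tuple(payload["cluster_sizes"])
        for key in ("sequence_of_cluster", "crossover_week_of_sequence"):
            if key in payload:
                payload[key] = {int(k): v for k, v in payload[key].items()}
        cfg = cls(**payload)
        cfg.validate()
        return cfg


# ----------------------------------------------------------------------
def make_design(config: SimulationConfig) -> pd.DataFrame:
    """Expand a configuration into the participant-by-wave design table.

    Returns one row per participant per wave with columns ``participant_id``,
    ``cluster``, ``sequence``, ``wave``, ``time_weeks`` and ``treatment``.
    ``time_weeks = (wave - 1) * wave_spacing_weeks`` and treatment switches on
    at the participant's sequence crossover week (and, under the default
    "post_crossover" coding, stays on thereafter).
    """
    config.validate()
    n = config.n_participants
    cluster_of = np.repeat(
        np.arange(1, len(config.cluster_sizes) + 1),
        np.asarray(config.cluster_sizes, dtype=int),
    )
    pid = np.array([f"p{i:04d}" for i in range(1, n + 1)])
    seq_of = np.array([config.sequence_of_cluster[int(c)] for c in cluster_of])

    waves = np.arange(1, config.n_waves + 1)
    df = pd.DataFrame(
        {
            "participant_id": np.repeat(pid, config.n_waves),
            "cluster": np.repeat(cluster_of, config.n_waves).astype(np.int64),
            "sequence": np.repeat(seq_of, config.n_waves).astype(np.int64),
            "wave": np.tile(waves, n).astype(np.int64),
        }
    )
    df["time_weeks"] = (df["wave"] - 1) * config.wave_spacing_weeks
    cross = np.array(
        [config.crossover_week_of_sequence[int(s)] for s in df["sequence"]],
        dtype=float,
    )
    on = df["time_weeks"].to_numpy() >= cross
    if config.exposure_coding == "active_program":
        on &= df["time_weeks"].to_numpy() < cross + config.program_duration_weeks
    df["treatment"] = on.astype(np.int64)
    return df


def _covariate_matrix(config: SimulationConfig, rng: np.random.Generator, n: int):
    """Draw participant-level covariates; returns (DataFrame, effect-column dict)."""
    gender = np.where(rng.random(n) < 0.856, "female", "male")
    age = rng.normal(45.01, 11.17, size=n)
    # redraw out-of-range ages (truncation to the trial's 18-70 eligibility)
    for _ in range(100):
        bad = (age < 18) | (age > 70)
        if not bad.any():
            break
        age[bad] = rng.normal(45.01, 11.17, size=int(bad.sum()))
    age = np.clip(age, 18.0, 70.0).round(1)
    profession = rng.choice(
        ["physician", "nurse", "other"], size=n, p=[0.424, 0.268, 0.308]
    )
    contract = np.where(rng.random(n) < 0.184, "temporary", "nontemporary")
    trainee = (rng.random(n) < 0.098).astype(np.int64)
    cov = pd.DataFrame(
        {
            "gender": gender,
            "age": age,
            "profession": profession,
            "contract": contract,
            "trainee": trainee,
        }
    )
    indicators = {
        "male": (gender == "male").astype(float),
        "nurse": (profession == "nurse").astype(float),
        "other": (profession == "other").astype(float),
        "temporary": (contract == "temporary").astype(float),
        "trainee": trainee.astype(float),
        "age": age - AGE_CENTER,
    }
    return cov, indicators


def generate_trial(config: SimulationConfig) -> pd.DataFrame:
    """Generate a complete long panel with known ground-truth paths.

    All random draws come from one ``numpy`` generator seeded with
    ``config.seed`` and are made in a fixed canonical order (participants
    sorted by id, score columns in schema order), so an identical seed yields
    a bit-identical panel regardless of how the result is later reordered or
    how many workers consume it.  The true paths are available from
    ``config.true_paths()`` and are stored in ``panel.attrs["true_paths"]``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = make_design(config)
    n = config.n_participants
    n_waves = config.n_waves
    row_pid = np.repeat(np.arange(n), n_waves)  # canonical row -> participant
    wave0 = design["wave"].to_numpy() - 1
    T = design["treatment"].to_numpy().astype(float)
    cluster_idx = design["cluster"].to_numpy() - 1

    cov, indicators = _covariate_matrix(config, rng, n)
    cov_effect_part = np.zeros(n)
    for key, coef in config.covariate_effects.items():
        cov_effect_part += coef * indicators[key]
    cov_effect = cov_effect_part[row_pid]

    u_cluster = rng.normal(0.0, 1.0, size=len(config.cluster_sizes))
    u_cluster *= config.sd_cluster_outcome  # zero SD => exactly zero effect

    scores: dict[str, np.ndarray] = {}
    b_terms: list[tuple[float, str]] = []  # (b_k, mediator column) for outcome
    wave1 = design["wave"].to_numpy() == 1

    def _sd_split(col):
        sd_tot = BASELINE_SDS[col]
        return sd_tot * np.sqrt(SECONDARY_ICC), sd_tot * np.sqrt(1.0 - SECONDARY_ICC)

    # --- baseline (wave-1) outcome values, canonical outcome order ------
    # stable individual differences eta enter later waves only through the
    # observed baseline score, matching the baseline-adjusted analysis models
    y1: dict[str, np.ndarray] = {}
    for col in OUTCOMES:
        if col == config.outcome:
            sd_eta, sd_e1 = config.sd_participant_outcome, config.sd_resid_outcome
        else:
            sd_eta, sd_e1 = _sd_split(col)
        eta = rng.normal(0.0, 1.0, size=n) * sd_eta
        eps1 = rng.normal(0.0, sd_e1, size=n)
        y1[col] = BASELINE_MEANS[col] + eta + cov_effect_part + eps1
        if col == config.outcome:
            y1[col] = y1[col] + u_cluster[cluster_idx[wave1]]
    bl_primary = y1[config.outcome] - BASELINE_MEANS[config.outcome]

    # --- mediators, canonical column order -----------------------------
    for col in MEDIATORS:
        kappa = 0.0
        if col == config.mediator:
            a_k = config.a_path
            sd_u, sd_e = config.sd_participant_mediator, config.sd_resid_mediator
            slope = config.time_slope_mediator
            kappa = config.baseline_effect_mediator
            b_terms.append((config.b_path, col))
        elif col in config.extra_paths:
            a_k, b_k = config.extra_paths[col]
            sd_u, sd_e = _sd_split(col)
            slope = 0.0
            b_terms.append((b_k, col))
        else:
            a_k = 0.0
            sd_u, sd_e = _sd_split(col)
            slope = 0.0
        u_i = rng.normal(0.0, 1.0, size=n) * sd_u
        eps = rng.normal(0.0, sd_e, size=n * n_waves)
        scores[col] = (
            BASELINE_MEANS[col]
            + a_k * T
            + kappa * bl_primary[row_pid]
            + cov_effect
            + slope * wave0
            + u_i[row_pid]
            + eps
        )

    # --- post-baseline outcomes -----------------------------------------
    g_bl = config.baseline_effect_outcome
    for col in OUTCOMES:
        if col == config.outcome:
            c_k = config.c_prime
            sd_u, sd_e = config.sd_participant_outcome, config.sd_resid_outcome
            slope = config.time_slope_outcome
            terms = b_terms
        else:
            # secondary outcomes share the mediation structure, with paths
            # scaled by the ratio of instrument spreads
            r = BASELINE_SDS[col] / BASELINE_SDS[config.outcome]
            c_k = config.c_prime * r
            sd_u, sd_e = _sd_split(col)
            slope = 0.0
            terms = [(b * r, m) for b, m in b_terms]
        u_i = rng.normal(0.0, 1.0, size=n) * sd_u
        eps = rng.normal(0.0, sd_e, size=n * n_waves)
        if col == config.outcome and config.lagged_mediator_effect is not None:
            scores[col] = _generate_lagged_outcome(
                config, y1[col], T, cov_effect,
                u_cluster[cluster_idx], eps, scores[config.mediator], n, n_waves,
            )
            continue
        intercept = BASELINE_MEANS[col] - sum(
            b_k * BASELINE_MEANS[m] for b_k, m in terms
        )
        y = (
            intercept
            + c_k * T
            + g_bl * (y1[col] - BASELINE_MEANS[col])[row_pid]
            + cov_effect
            + slope * wave0
            + u_i[row_pid]
            + eps
        )
        for b_k, m in terms:
            y = y + b_k * scores[m]
        if col == config.outcome:
            y = y + u_cluster[cluster_idx]
        y[wave1] = y1[col]  # observed baseline values
        scores[col] = y

    if config.clip_to_range:
        for col in SCORE_COLUMNS:
            lo, hi = config.score_ranges[col]
            scores[col] = np.clip(scores[col], lo, hi)

    panel = pd.concat(
        [design.reset_index(drop=True), cov.iloc[row_pid].reset_index(drop=True)],
        axis=1,
    )
    for col in SCORE_COLUMNS:
        panel[col] = scores[col]

    if config.dropout_hazard_per_wave > 0:
        panel = apply_dropout(
            panel, config.dropout_hazard_per_wave,
            seed=int(np.random.default_rng(config.seed + 1).integers(2**31)),
        )

    panel.attrs["true_paths"] = config.true_paths()
    panel.attrs["schedule"] = config.schedule()
    return panel


def _generate_lagged_outcome(config, y1, T, cov_effect, u_c, eps,
                             mediator, n, n_waves):
    """AR(1) outcome: Y_{t+1} = kappa + phi Y_t + theta M_t + c' T + ...

    Matches the fitted lagged model exactly (no participant intercept in this
    mode, so the lagged coefficient is recoverable without dynamic-panel bias).
    """
    theta = float(config.lagged_mediator_effect)
    phi = float(config.outcome_ar)
    mean_y = BASELINE_MEANS[config.outcome]
    mean_m = BASELINE_MEANS[config.mediator]
    kappa = mean_y * (1.0 - phi) - theta * mean_m
    M = mediator.reshape(n, n_waves)
    Tm = T.reshape(n, n_waves)
    cove = cov_effect.reshape(n, n_waves)
    ucm = u_c.reshape(n, n_waves)
    em = eps.reshape(n, n_waves)
    Y = np.empty((n, n_waves))
    Y[:, 0] = y1
    for t in range(1, n_waves):
        Y[:, t] = (
            kappa
            + phi * Y[:, t - 1]
            + theta * M[:, t - 1]
            + config.c_prime * Tm[:, t]
            + config.time_slope_outcome * t
            + cove[:, t]
            + ucm[:, t]
            + em[:, t]
        )
    return Y.reshape(-1)


def apply_dropout(panel: pd.DataFrame, hazard: float, seed: int) -> pd.DataFrame:
    """Apply monotone (staircase) dropout to a panel.

    Each participant independently misses wave ``w >= 2`` with the given
    per-wave hazard, and once a wave is missed all later waves are missing
    too; wave 1 is always retained.  Retention of a participant at wave ``w``
    therefore follows a geometric survival curve ``(1 - hazard)**(w - 1)``.
    """
    if not (0.0 <= hazard < 1.0):
        raise ConfigError("dropout hazard: must lie in [0, 1)")
    if hazard == 0.0:
        return panel
    rng = np.random.default_rng(seed)
    pids = panel["participant_id"].drop_duplicates().to_numpy()
    max_wave = int(panel["wave"].max())
    draws = rng.random((len(pids), max_wave - 1))
    # first missed wave per participant (max_wave + 1 => never drops out)
    missed = np.where(
        (draws < hazard).any(axis=1),
        (draws < hazard).argmax(axis=1) + 2,
        max_wave + 1,
    )
    cutoff = pd.Series(missed, index=pids)
    keep = panel["wave"].to_numpy() < cutoff[panel["participant_id"]].to_numpy()
    out = panel[keep].reset_index(drop=True)
    out.attrs = dict(panel.attrs)
    return out
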