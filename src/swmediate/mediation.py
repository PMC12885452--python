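"""Bootstrap product-of-coefficients mediation for stepped-wedge panels.

Two random-intercept linear mixed models are fitted per mediator:

* model A (a-path):   mediator ~ treatment + covariates + baseline outcome
* model B (b-path):   outcome ~ mediator(s) + treatment + covariates + baseline

both with a participant random intercept, on analysis rows (waves >= 2; the
wave-1 outcome enters as the baseline covariate).  The indirect effect is the
product ``a * b``; the direct effect is the treatment coefficient of model B.

Inference for the indirect effect is by nonparametric bootstrap: each
iteration resamples participants — whole trajectories — with replacement,
stratified by cluster so cluster sizes are preserved, refits both models and
records ``a * b``.  The 95% CI is the 2.5th/97.5th percentile of the recorded
draws, and the p-value is the two-sided sign-crossing proportion
``min(1, 2 * min(P(draw <= 0), P(draw >= 0)))``.

Resampled participants are relabelled, so a participant drawn twice
contributes two independent random-intercept groups, preserving the
within-participant correlation structure that row-level resampling would
destroy (row-level resampling is available behind ``resample_unit="row"``
for comparison).
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lmm
from .lmm import FitError, LmmFit
from .panel import DEFAULT_COVARIATES, MEDIATORS, ModelSpec, PanelError

logger = logging.getLogger(__name__)

__all__ = [
    "EffectEstimate",
    "MediationResult",
    "MultivariateMediationResult",
    "SensitivityResult",
    "BootstrapError",
    "estimate_paths",
    "bootstrap_mediation",
    "multivariate_mediation",
    "sensitivity_models",
    "percentile_ci",
    "sign_crossing_p",
    "one_sided_sign_proportion",
    "select_significant",
    "select_per_family",
    "DEFAULT_FAMILIES",
]


class BootstrapError(RuntimeError):
    """The bootstrap could not produce a valid result (too many failures...)."""


#: Default mediator -> construct family assignment used by the second
#: sensitivity model (one factor per psychological construct).
DEFAULT_FAMILIES: dict[str, str] = {
    "cd_risc": "resilience",
    "ffmq_observe": "mindfulness",
    "ffmq_describe": "mindfulness",
    "ffmq_act": "mindfulness",
    "ffmq_nonjudge": "mindfulness",
    "ffmq_nonreact": "mindfulness",
    "socs_self": "compassion",
    "socs_other": "compassion",
    "aaq2": "acceptance",
}


# ----------------------------------------------------------------------
# pure helpers


def percentile_ci(draws, level: float = 0.95, method: str = "linear"):
    """Percentile bootstrap CI from stored draws (linear interpolation by
    default; ``method="lower"`` etc. give nearest-rank variants)."""
    draws = np.asarray(draws, dtype=float)
    alpha = (1.0 - level) / 2.0 * 100.0
    lo, hi = np.percentile(draws, [alpha, 100.0 - alpha], method=method)
    return float(lo), float(hi)


def sign_crossing_p(draws) -> float:
    """Two-sided bootstrap p from the proportion of draws on each side of 0."""
    draws = np.asarray(draws, dtype=float)
    n = len(draws)
    if n == 0:
        return float("nan")
    n_le = int(np.sum(draws <= 0.0))
    n_ge = int(np.sum(draws >= 0.0))
    return min(1.0, 2.0 * min(n_le, n_ge) / n)


def one_sided_sign_proportion(draws) -> float:
    """Literal one-sided crossing proportion (share of draws on the minority
    side of zero); the two-sided :func:`sign_crossing_p` is twice this."""
    draws = np.asarray(draws, dtype=float)
    if len(draws) == 0:
        return float("nan")
    n_le = int(np.sum(draws <= 0.0))
    n_ge = int(np.sum(draws >= 0.0))
    return min(n_le, n_ge) / len(draws)


# ----------------------------------------------------------------------
# result containers


@dataclass
class EffectEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("CI bounds out of order")


@dataclass
class MediationResult:
    """Univariate mediation: paths, bootstrap CI and sign-crossing p."""

    mediator: str
    outcome: str
    a: EffectEstimate
    b: EffectEstimate
    indirect: EffectEstimate
    direct: EffectEstimate
    n_boot_requested: int
    n_boot_used: int
    draws: np.ndarray
    seed: int
    a_fit: LmmFit | None = None
    y_fit: LmmFit | None = None


@dataclass
class MultivariateMediationResult:
    """Joint mediation: one b per mediator from a single outcome model."""

    mediators: list[str]
    outcome: str
    a: dict[str, EffectEstimate]
    b: dict[str, EffectEstimate]
    indirect: dict[str, EffectEstimate]
    direct: EffectEstimate
    n_boot_requested: int
    n_boot_used: int
    draws: dict[str, np.ndarray]
    seed: int
    y_fit: LmmFit | None = None


@dataclass
class SensitivityResult:
    """Results of the two multivariate sensitivity models."""

    s1_selected: list[str]
    s1: MultivariateMediationResult | None
    s1_status: str
    s2_selected: list[str]
    s2: MultivariateMediationResult | None
    s2_status: str


@dataclass
class PathEstimates:
    """Full-sample path fits (no bootstrap)."""

    a_fits: dict[str, LmmFit]
    y_fit: LmmFit
    a: dict[str, float]
    b: dict[str, float]
    direct: float

    def indirect(self, mediator: str) -> float:
        return self.a[mediator] * self.b[mediator]


# ----------------------------------------------------------------------
# full-sample path estimation


def _analysis_rows(panel: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    if spec.baseline_column not in panel.columns:
        raise PanelError(
            f"baseline column {spec.baseline_column!r} missing — call "
            "panel.attach_baseline(panel, outcome) first"
        )
    if "is_analysis" in panel.columns:
        rows = panel[panel["is_analysis"]]
    else:
        rows = panel[panel["wave"] >= 2]
    return rows.sort_values(["participant_id", "wave"], kind="stable").reset_index(drop=True)


def estimate_paths(panel: pd.DataFrame, spec: ModelSpec) -> PathEstimates:
    """Fit the a-path and b-path models on the full sample.

    Returns one model-A fit per mediator and the single model-B fit; ``a`` is
    the treatment coefficient of each model A, ``b`` the mediator
    coefficient(s) of model B, ``direct`` its treatment coefficient.
    """
    rows = _analysis_rows(panel, spec)
    cov_terms = list(spec.covariates) + [spec.baseline_column]
    a_fits: dict[str, LmmFit] = {}
    for m in spec.mediators:
        try:
            a_fits[m] = lmm.fit_lmm(
                rows, m, ["treatment"] + cov_terms, spec.random_effects
            )
        except FitError as err:
            raise FitError(f"a-path model for mediator {m!r}: {err}") from err
    try:
        y_fit = lmm.fit_lmm(
            rows,
            spec.outcome,
            list(spec.mediators) + ["treatment"] + cov_terms,
            spec.random_effects,
        )
    except FitError as err:
        raise FitError(f"outcome model for {spec.outcome!r}: {err}") from err
    a = {m: a_fits[m].coef["treatment"] for m in spec.mediators}
    b = {m: y_fit.coef[m] for m in spec.mediators}
    return PathEstimates(a_fits=a_fits, y_fit=y_fit, a=a, b=b, direct=y_fit.coef["treatment"])


# ----------------------------------------------------------------------
# bootstrap engine


class _Resampler:
    """Precomputed design matrices + fast stratified participant resampling.

    Rows are the analysis rows sorted by participant; the fixed-effect design
    (treatment, covariate dummies, baseline) is built once on the full panel
    so every resample shares one stable column layout.
    """

    def __init__(self, panel: pd.DataFrame, spec: ModelSpec):
        rows = _analysis_rows(panel, spec)
        self.rows = rows
        self.spec = spec
        cov_terms = ["treatment"] + list(spec.covariates) + [spec.baseline_column]
        self.Xc, self.names_c = lmm.build_design(rows, cov_terms)
        self.treat_idx = self.names_c.index("treatment")
        self.med_mat = rows[list(spec.mediators)].to_numpy(dtype=float)
        self.y_out = rows[spec.outcome].to_numpy(dtype=float)
        ok_c = np.isfinite(self.Xc).all(axis=1)
        self.mask_a = {
            m: ok_c & np.isfinite(self.med_mat[:, j])
            for j, m in enumerate(spec.mediators)
        }
        self.mask_b = (
            ok_c & np.isfinite(self.med_mat).all(axis=1) & np.isfinite(self.y_out)
        )

        pid = rows["participant_id"].to_numpy()
        # contiguous participant blocks (rows are sorted by participant)
        change = np.flatnonzero(pid[1:] != pid[:-1]) + 1
        self.block_start = np.concatenate([[0], change])
        block_end = np.concatenate([change, [len(pid)]])
        self.block_len = block_end - self.block_start
        block_cluster = rows["cluster"].to_numpy()[self.block_start]
        self.blocks_by_cluster = {
            c: np.flatnonzero(block_cluster == c) for c in np.unique(block_cluster)
        }
        self.n_blocks = len(self.block_start)

    # -- resampling ----------------------------------------------------
    def sample_blocks(self, rng: np.random.Generator) -> np.ndarray:
        chosen = [
            rng.choice(blocks, size=len(blocks), replace=True)
            for _, blocks in sorted(self.blocks_by_cluster.items())
        ]
        return np.concatenate(chosen)

    def _assemble(self, blocks: np.ndarray):
        lens = self.block_len[blocks]
        total = int(lens.sum())
        out_starts = (np.cumsum(lens) - lens).astype(np.intp)
        # contiguous source ranges expanded without a python loop
        rows_idx = (
            np.arange(total, dtype=np.intp)
            - np.repeat(out_starts, lens)
            + np.repeat(self.block_start[blocks], lens)
        )
        return rows_idx, out_starts

    def _masked_fit(self, y, X, mask, rows_idx, starts, allow_singular=True):
        mm = mask[rows_idx]
        sizes = np.add.reduceat(mm.astype(np.intp), starts)
        sizes = sizes[sizes > 0]
        keep = rows_idx[mm]
        return lmm.profiled_reml(
            y[keep], X[keep], sizes, reml=True, allow_singular=allow_singular
        )

    # -- one bootstrap iteration ---------------------------------------
    def iteration(self, rng: np.random.Generator):
        """Refit all models on one resample; returns (a_vec, b_vec, direct)."""
        blocks = self.sample_blocks(rng)
        rows_idx, starts = self._assemble(blocks)
        a = np.empty(len(self.spec.mediators))
        for j, m in enumerate(self.spec.mediators):
            fit = self._masked_fit(
                self.med_mat[:, j], self.Xc, self.mask_a[m], rows_idx, starts
            )
            a[j] = fit.beta[self.treat_idx]
        XB = np.hstack([self.Xc, self.med_mat])
        fit_b = self._masked_fit(self.y_out, XB, self.mask_b, rows_idx, starts)
        b = fit_b.beta[self.Xc.shape[1]:]
        direct = fit_b.beta[self.treat_idx]
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise FitError("non-finite path estimate in bootstrap iteration")
        return a, b, float(direct)

    def iteration_rows(self, rng: np.random.Generator):
        """Row-level resample (breaks trajectories; comparison only)."""
        idx = np.sort(
            np.concatenate(
                [
                    rng.choice(
                        np.flatnonzero(self.rows["cluster"].to_numpy() == c),
                        size=int((self.rows["cluster"] == c).sum()),
                        replace=True,
                    )
                    for c in sorted(self.rows["cluster"].unique())
                ]
            )
        )
        pid = self.rows["participant_id"].to_numpy()[idx]
        change = np.flatnonzero(pid[1:] != pid[:-1]) + 1
        starts = np.concatenate([[0], change]).astype(np.intp)
        a = np.empty(len(self.spec.mediators))
        for j, m in enumerate(self.spec.mediators):
            mm = self.mask_a[m][idx]
            sizes = np.add.reduceat(mm.astype(np.intp), starts)
            sizes = sizes[sizes > 0]
            fit = lmm.profiled_reml(
                self.med_mat[idx, j][mm], self.Xc[idx][mm], sizes, allow_singular=True
            )
            a[j] = fit.beta[self.treat_idx]
        XB = np.hstack([self.Xc, self.med_mat])
        mm = self.mask_b[idx]
        sizes = np.add.reduceat(mm.astype(np.intp), starts)
        sizes = sizes[sizes > 0]
        fit_b = lmm.profiled_reml(
            self.y_out[idx][mm], XB[idx][mm], sizes, allow_singular=True
        )
        return a, fit_b.beta[self.Xc.shape[1]:], float(fit_b.beta[self.treat_idx])


def _run_bootstrap(
    resampler: _Resampler,
    n_boot: int,
    seed: int,
    n_jobs: int = 1,
    max_retries: int = 3,
    resample_unit: str = "participant",
):
    """Run ``n_boot`` deterministic iterations; returns (a, b, direct) arrays.

    Each iteration ``i`` derives its generator from ``(seed, i, attempt)``, so
    results are bit-identical regardless of execution order or worker count.
    A failed iteration is redrawn up to ``max_retries`` times, then dropped.
    """
    iterate = (
        resampler.iteration if resample_unit == "participant" else resampler.iteration_rows
    )

    def one(i: int):
        for attempt in range(max_retries + 1):
            rng = np.random.default_rng([seed, i, attempt])
            try:
                return iterate(rng)
            except (FitError, np.linalg.LinAlgError):
                continue
        return None

    if n_jobs == 1:
        results = [one(i) for i in range(n_boot)]
    else:
        with ThreadPoolExecutor(max_workers=n_jobs) as pool:
            results = list(pool.map(one, range(n_boot)))
    kept = [r for r in results if r is not None]
    n_failed = n_boot - len(kept)
    if len(kept) < 0.95 * n_boot:
        raise BootstrapError(
            f"{n_failed}/{n_boot} bootstrap iterations failed after retries"
        )
    if n_failed:
        logger.warning("bootstrap: dropped %d/%d failed iterations", n_failed, n_boot)
    a = np.array([r[0] for r in kept])
    b = np.array([r[1] for r in kept])
    direct = np.array([r[2] for r in kept])
    return a, b, direct


def _wald_effect(fit: LmmFit, term: str) -> EffectEstimate:
    lo, hi = fit.wald_ci(term)
    return EffectEstimate(
        estimate=fit.coef[term], ci_low=lo, ci_high=hi, p=fit.wald_p(term), se=fit.se[term]
    )


def bootstrap_mediation(
    panel: pd.DataFrame,
    spec: ModelSpec | None = None,
    *,
    mediator: str | None = None,
    outcome: str | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    n_jobs: int = 1,
    resample_unit: str = "participant",
) -> MediationResult:
    """Univariate bootstrap mediation analysis.

    Either pass a univariate ``spec`` or name ``mediator`` and ``outcome``.
    The a/b/direct path estimates carry Wald (normal-approximation) CIs and
    p-values from the full-sample fits; the indirect effect carries the
    percentile bootstrap CI and the sign-crossing p-value.
    """
    if spec is None:
        if mediator is None or outcome is None:
            raise ValueError("pass either a ModelSpec or mediator= and outcome=")
        spec = ModelSpec.for_outcome(outcome, [mediator])
    if len(spec.mediators) != 1:
        raise ValueError("bootstrap_mediation requires a univariate spec")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    m = spec.mediators[0]

    paths = estimate_paths(panel, spec)
    point = paths.a[m] * paths.b[m]

    resampler = _Resampler(panel, spec)
    a_draws, b_draws, _ = _run_bootstrap(
        resampler, n_boot, seed, n_jobs=n_jobs, resample_unit=resample_unit
    )
    draws = a_draws[:, 0] * b_draws[:, 0]
    ci_lo, ci_hi = percentile_ci(draws)
    # delta-method (Sobel) interval, logged for comparison with the bootstrap
    se_a, se_b = paths.a_fits[m].se["treatment"], paths.y_fit.se[m]
    sobel_se = float(np.hypot(paths.a[m] * se_b, paths.b[m] * se_a))
    logger.info(
        "bootstrap CI [%.4f, %.4f] vs Sobel CI [%.4f, %.4f] for %s -> %s",
        ci_lo, ci_hi, point - 1.96 * sobel_se, point + 1.96 * sobel_se,
        m, spec.outcome,
    )
    return MediationResult(
        mediator=m,
        outcome=spec.outcome,
        a=_wald_effect(paths.a_fits[m], "treatment"),
        b=_wald_effect(paths.y_fit, m),
        indirect=EffectEstimate(
            estimate=point,
            ci_low=ci_lo,
            ci_high=ci_hi,
            p=sign_crossing_p(draws),
            se=float(np.std(draws, ddof=1)),
        ),
        direct=_wald_effect(paths.y_fit, "treatment"),
        n_boot_requested=n_boot,
        n_boot_used=len(draws),
        draws=draws,
        seed=seed,
        a_fit=paths.a_fits[m],
        y_fit=paths.y_fit,
    )


def multivariate_mediation(
    panel: pd.DataFrame,
    mediators: list[str],
    outcome: str,
    *,
    covariates: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    n_jobs: int = 1,
) -> MultivariateMediationResult:
    """Mediation with all mediators entered simultaneously in the outcome model.

    One a-path model per mediator and a single joint outcome model; per
    mediator the indirect effect is ``a_m * b_m``, with bootstrap CI and
    sign-crossing p computed from the same resample in every iteration.
    Analysis rows are restricted to cases complete across all mediators.
    """
    if len(mediators) < 2:
        raise ValueError("multivariate_mediation requires >= 2 mediators")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    spec = ModelSpec.for_outcome(
        outcome,
        list(mediators),
        **({"covariates": list(covariates)} if covariates is not None else {}),
    )
    complete = panel.dropna(subset=list(mediators))
    complete.attrs = dict(panel.attrs)

    dup = _duplicated_mediators(complete, mediators)
    if dup:
        raise FitError(f"collinear mediators: {dup}")

    paths = estimate_paths(complete, spec)
    resampler = _Resampler(complete, spec)
    a_draws, b_draws, _ = _run_bootstrap(resampler, n_boot, seed, n_jobs=n_jobs)

    a_eff, b_eff, ind_eff, draws = {}, {}, {}, {}
    for j, m in enumerate(mediators):
        d = a_draws[:, j] * b_draws[:, j]
        lo, hi = percentile_ci(d)
        draws[m] = d
        a_eff[m] = _wald_effect(paths.a_fits[m], "treatment")
        b_eff[m] = _wald_effect(paths.y_fit, m)
        ind_eff[m] = EffectEstimate(
            estimate=paths.a[m] * paths.b[m],
            ci_low=lo,
            ci_high=hi,
            p=sign_crossing_p(d),
            se=float(np.std(d, ddof=1)),
        )
    return MultivariateMediationResult(
        mediators=list(mediators),
        outcome=outcome,
        a=a_eff,
        b=b_eff,
        indirect=ind_eff,
        direct=_wald_effect(paths.y_fit, "treatment"),
        n_boot_requested=n_boot,
        n_boot_used=len(a_draws),
        draws=draws,
        seed=seed,
        y_fit=paths.y_fit,
    )


def _duplicated_mediators(panel: pd.DataFrame, mediators: list[str]) -> list[str]:
    """Pairs of mediator columns that are exact linear aliases of each other."""
    sub = panel[mediators].dropna()
    if not len(sub):
        return []
    corr = np.corrcoef(sub.to_numpy(dtype=float), rowvar=False)
    out = []
    for i in range(len(mediators)):
        for j in range(i + 1, len(mediators)):
            if abs(corr[i, j]) > 1.0 - 1e-10:
                out.append((mediators[i], mediators[j]))
    return out


# ----------------------------------------------------------------------
# sensitivity models


def select_significant(
    univariate_results: dict[str, MediationResult], alpha: float = 0.05
) -> list[str]:
    """Mediators whose univariate bootstrap indirect p is below ``alpha``."""
    return [m for m, r in univariate_results.items() if r.indirect.p < alpha]


def select_per_family(
    univariate_results: dict[str, MediationResult], family_map: dict[str, str]
) -> list[str]:
    """One mediator per construct family: the smallest univariate p, ties
    broken by larger absolute indirect effect, then lexicographic name."""
    best: dict[str, tuple] = {}
    for m, r in sorted(univariate_results.items()):
        fam = family_map[m]
        key = (r.indirect.p, -abs(r.indirect.estimate), m)
        if fam not in best or key < best[fam][0]:
            best[fam] = (key, m)
    return [best[f][1] for f in sorted(best)]


def sensitivity_models(
    panel: pd.DataFrame,
    univariate_results: dict[str, MediationResult],
    outcome: str,
    *,
    family_map: dict[str, str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    n_jobs: int = 1,
) -> SensitivityResult:
    """The two multivariate sensitivity models.

    S1 re-runs the multivariate analysis with only the mediators significant
    in the univariate analyses (bootstrap p < .05); S2 keeps one mediator per
    construct family (resilience / mindfulness / compassion / acceptance),
    the most significant one.  An empty S1 set yields an informative status,
    not an exception.
    """
    family_map = dict(DEFAULT_FAMILIES if family_map is None else family_map)
    missing = [m for m in univariate_results if m not in family_map]
    if missing:
        raise ValueError(f"family_map lacks entries for {missing}")

    def run(selected: list[str], tag: str):
        if not selected:
            return None, "no mediators passed the selection"
        if len(selected) == 1:
            uni = bootstrap_mediation(
                panel,
                mediator=selected[0],
                outcome=outcome,
                n_boot=n_boot,
                seed=seed,
                n_jobs=n_jobs,
            )
            wrapped = MultivariateMediationResult(
                mediators=selected,
                outcome=outcome,
                a={selected[0]: uni.a},
                b={selected[0]: uni.b},
                indirect={selected[0]: uni.indirect},
                direct=uni.direct,
                n_boot_requested=uni.n_boot_requested,
                n_boot_used=uni.n_boot_used,
                draws={selected[0]: uni.draws},
                seed=seed,
                y_fit=uni.y_fit,
            )
            return wrapped, f"{tag}: single mediator, univariate bootstrap"
        return (
            multivariate_mediation(
                panel, selected, outcome, n_boot=n_boot, seed=seed, n_jobs=n_jobs
            ),
            "ok",
        )

    s1_selected = select_significant(univariate_results)
    s1, s1_status = run(s1_selected, "S1")
    s2_selected = select_per_family(univariate_results, family_map)
    s2, s2_status = run(s2_selected, "S2")
    return SensitivityResult(
        s1_selected=s1_selected,
        s1=s1,
        s1_status=s1_status,
        s2_selected=s2_selected,
        s2=s2,
        s2_status=s2_status,
    )
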