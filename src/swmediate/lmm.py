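"""Random-intercept linear mixed models with a stable, testable contract.

Two fitting paths sit behind :func:`fit_lmm`:

* single random intercept (participant *or* cluster) — an exact profiled-REML
  solver written here.  For ``y = X beta + Z u + e`` with one grouping factor,
  the covariance is compound-symmetric within groups, so the generalized least
  squares problem can be profiled down to a one-dimensional optimization over
  the variance ratio ``lambda = sigma_u^2 / sigma_e^2`` (Woodbury identity per
  group).  This is the same REML criterion lme4 and statsmodels maximise, but
  runs in ~2 ms per fit, which is what makes the bootstrap engine practical.
* participant + cluster random intercepts (nested) — delegated to
  ``statsmodels`` ``MixedLM`` with a variance component for participants
  inside cluster groups.

Fixed-effect terms are given as a list of column names ("term-list grammar"):
numeric columns enter as-is, categorical columns are dummy-expanded against
the fixed reference levels in :data:`swmediate.panel.REFERENCE_LEVELS`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .panel import REFERENCE_LEVELS

logger = logging.getLogger(__name__)

__all__ = ["LmmFit", "FitError", "ConvergenceError", "fit_lmm", "build_design"]


class FitError(RuntimeError):
    """A model could not be fitted (singular design, failed convergence...)."""


class ConvergenceError(FitError):
    """The optimizer did not converge; the fit is not returned."""


# ----------------------------------------------------------------------
# design construction


def _is_categorical(data: pd.DataFrame, col: str) -> bool:
    return (
        col in REFERENCE_LEVELS
        or data[col].dtype == object
        or isinstance(data[col].dtype, pd.CategoricalDtype)
    )


def build_design(
    data: pd.DataFrame, terms: Iterable[str], add_intercept: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Expand a term list into a design matrix with named columns.

    Categorical terms become one indicator column per non-reference level
    (named ``term[level]``); numeric terms enter unchanged.  Levels are taken
    from the *full* data frame passed in, so a design built on the full panel
    and later subset by rows keeps a stable column layout.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        cols.append(np.ones(len(data)))
        names.append("intercept")
    for term in terms:
        if term not in data.columns:
            raise FitError(f"unknown model term {term!r}")
        if _is_categorical(data, term):
            levels = sorted(data[term].dropna().unique().tolist(), key=str)
            ref = REFERENCE_LEVELS.get(term, levels[0] if levels else None)
            if ref not in levels and levels:
                ref = levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((data[term] == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
        else:
            cols.append(data[term].to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return X, names


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns made redundant by collinearity (QR pivot test)."""
    _, r = np.linalg.qr(X)
    d = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (d.max() if d.size else 0.0)
    return [n for n, keep in zip(names, d > tol) if not keep]


# ----------------------------------------------------------------------
# profiled REML core (single random intercept, rows grouped contiguously)


class ProfiledFit(NamedTuple):
    beta: np.ndarray
    cov: np.ndarray
    sigma2_resid: float
    sigma2_group: float
    loglik: float
    lam: float


def profiled_reml(
    y: np.ndarray,
    X: np.ndarray,
    group_sizes: np.ndarray,
    reml: bool = True,
    allow_singular: bool = False,
) -> ProfiledFit:
    """Exact (RE)ML fit of a single-random-intercept model.

    Rows must be ordered so that each group's rows are contiguous with the
    given sizes.  The criterion is profiled over ``beta`` and the residual
    variance, leaving a scalar search over ``log lambda``; the boundary
    ``lambda = 0`` (no group variance, i.e. ordinary least squares) is checked
    explicitly, so a zero variance component reproduces OLS exactly.
    """
    y = np.ascontiguousarray(y, dtype=float)
    X = np.ascontiguousarray(X, dtype=float)
    n, p = X.shape
    sizes = np.asarray(group_sizes, dtype=float)
    starts = np.concatenate([[0], np.cumsum(group_sizes)[:-1]]).astype(np.intp)
    GX = np.add.reduceat(X, starts, axis=0)
    gy = np.add.reduceat(y, starts)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    if allow_singular:
        # fall back to a minimum-norm solution only on an actual singularity
        def solve(A, b):
            try:
                return np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                return np.linalg.pinv(A) @ b
    else:
        solve = np.linalg.solve
    dof = n - p if reml else n

    def evaluate(lam: float):
        c = lam / (1.0 + sizes * lam)
        A = XtX - GX.T @ (c[:, None] * GX)
        bvec = Xty - GX.T @ (c * gy)
        yWy = yty - c @ (gy * gy)
        beta = solve(A, bvec)
        rss = max(yWy - beta @ bvec, 1e-300)
        logdet_w = float(np.sum(np.log1p(sizes * lam)))
        crit = dof * np.log(rss) + logdet_w
        if reml:
            sign, logdet_a = np.linalg.slogdet(A)
            if sign <= 0 or not np.isfinite(logdet_a):
                return 1e300, beta, A, rss, logdet_w, 0.0  # repel singular region
            crit += logdet_a
        else:
            logdet_a = 0.0
        if not np.isfinite(crit):
            crit = 1e300
        return crit, beta, A, rss, logdet_w, logdet_a

    res = minimize_scalar(
        lambda u: evaluate(np.exp(u))[0],
        bounds=(-14.0, 14.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:  # pragma: no cover - bounded Brent essentially always succeeds
        raise ConvergenceError("profiled REML scalar search failed")
    lam = float(np.exp(res.x))
    crit0 = evaluate(0.0)
    critl = evaluate(lam)
    if crit0[0] <= critl[0] + 1e-10:
        lam, (crit, beta, A, rss, logdet_w, logdet_a) = 0.0, crit0
    else:
        crit, beta, A, rss, logdet_w, logdet_a = critl
    s2e = rss / dof
    s2u = lam * s2e
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        if not allow_singular:
            raise
        Ainv = np.linalg.pinv(A)
    cov = s2e * Ainv
    if reml:
        ll = -0.5 * (dof * (np.log(2 * np.pi * s2e) + 1.0) + logdet_w + logdet_a)
    else:
        ll = -0.5 * (n * (np.log(2 * np.pi * s2e) + 1.0) + logdet_w)
    if not (np.all(np.isfinite(beta)) and np.isfinite(ll)):
        raise FitError("non-finite estimates in profiled (RE)ML fit")
    return ProfiledFit(beta, cov, float(s2e), float(s2u), float(ll), lam)


# ----------------------------------------------------------------------
# public fit surface


@dataclass
class LmmFit:
    """Fixed-effect estimates and variance components of one fitted model."""

    coef: dict[str, float]
    se: dict[str, float]
    var_components: dict[str, float]
    resid_var: float
    converged: bool
    n_obs: int
    n_groups: int
    loglik: float
    n_dropped: int = 0
    method: str = "reml"
    terms: list[str] = field(default_factory=list)

    def z(self, term: str) -> float:
        return self.coef[term] / self.se[term]

    def wald_p(self, term: str) -> float:
        """Two-sided p-value from the normal approximation."""
        return float(2.0 * stats.norm.sf(abs(self.z(term))))

    def wald_ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        zcrit = stats.norm.ppf(0.5 + level / 2.0)
        est, se = self.coef[term], self.se[term]
        return est - zcrit * se, est + zcrit * se


def _complete_rows(data: pd.DataFrame, cols: list[str]) -> pd.Series:
    mask = pd.Series(True, index=data.index)
    for c in cols:
        if pd.api.types.is_numeric_dtype(data[c]):
            mask &= data[c].notna()
        else:
            mask &= data[c].notna()
    return mask


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed_terms: Iterable[str],
    random_effects: Iterable[str] = ("participant",),
    reml: bool = True,
) -> LmmFit:
    """Fit ``response ~ fixed_terms`` with random intercepts.

    ``random_effects`` is a subset of ``{"participant", "cluster"}``; the
    grouping columns are ``participant_id`` and ``cluster``.  Rows with a
    missing response or missing fixed-term value are dropped (complete-case)
    and counted in ``LmmFit.n_dropped``.  Raises :class:`FitError` on a
    singular design (naming the aliased terms) and falls back to ordinary
    least squares, with a logged warning, when fewer than two grouping levels
    are present.
    """
    fixed_terms = list(fixed_terms)
    re_set = frozenset(random_effects)
    if not re_set or not re_set <= {"participant", "cluster"}:
        raise ValueError("random_effects must be a non-empty subset of {participant, cluster}")

    cols = [response] + fixed_terms
    mask = _complete_rows(data, cols)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("fit_lmm(%s): dropped %d incomplete rows", response, n_dropped)
    rows = data.loc[mask]
    if not len(rows):
        raise FitError(f"no complete rows for response {response!r}")

    X, names = build_design(rows, fixed_terms)
    aliased = _aliased_columns(X, names)
    if aliased:
        raise FitError(f"singular design: aliased term(s) {aliased}")
    y = rows[response].to_numpy(dtype=float)

    if re_set == {"participant", "cluster"}:
        return _fit_nested(rows, y, X, names, reml, n_dropped, fixed_terms)

    group_col = "participant_id" if "participant" in re_set else "cluster"
    groups = rows[group_col].to_numpy()
    order = np.argsort(groups, kind="stable")
    y_s, X_s, g_s = y[order], X[order], groups[order]
    uniq, counts = np.unique(g_s, return_counts=True)

    if len(uniq) < 2:
        warnings.warn(
            f"fit_lmm: fewer than 2 levels of {group_col!r}; falling back to OLS",
            stacklevel=2,
        )
        beta, res_ss, _, _ = np.linalg.lstsq(X_s, y_s, rcond=None)
        dof = len(y_s) - X_s.shape[1]
        s2 = float(res_ss[0] / dof) if len(res_ss) and dof > 0 else 0.0
        cov = s2 * np.linalg.inv(X_s.T @ X_s)
        ll = -0.5 * len(y_s) * (np.log(2 * np.pi * max(s2, 1e-300)) + 1.0)
        return LmmFit(
            coef=dict(zip(names, beta)),
            se=dict(zip(names, np.sqrt(np.diag(cov)))),
            var_components={},
            resid_var=s2,
            converged=True,
            n_obs=len(y_s),
            n_groups=len(uniq),
            loglik=float(ll),
            n_dropped=n_dropped,
            method="ols",
            terms=names,
        )

    fit = profiled_reml(y_s, X_s, counts, reml=reml)
    re_name = "participant" if group_col == "participant_id" else "cluster"
    return LmmFit(
        coef=dict(zip(names, fit.beta)),
        se=dict(zip(names, np.sqrt(np.diag(fit.cov)))),
        var_components={re_name: fit.sigma2_group},
        resid_var=fit.sigma2_resid,
        converged=True,
        n_obs=len(y_s),
        n_groups=len(uniq),
        loglik=fit.loglik,
        n_dropped=n_dropped,
        method="reml" if reml else "ml",
        terms=names,
    )


def _fit_nested(rows, y, X, names, reml, n_dropped, fixed_terms) -> LmmFit:
    """Participant-within-cluster random intercepts via statsmodels MixedLM."""
    import statsmodels.api as sm

    frame = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    frame["_y"] = y
    frame["_cluster"] = rows["cluster"].to_numpy()
    frame["_pid"] = rows["participant_id"].astype(str).to_numpy()
    rhs = " + ".join(f"x{i}" for i in range(X.shape[1]))
    model = sm.MixedLM.from_formula(
        f"_y ~ 0 + {rhs}",
        groups="_cluster",
        re_formula="1",
        vc_formula={"participant": "0 + C(_pid)"},
        data=frame,
    )
    result = None
    for method in ("lbfgs", "powell", "cg"):  # boundary fits need robust optimizers
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            candidate = model.fit(reml=reml, method=method)
        if candidate.converged:
            result = candidate
            break
    if result is None:
        raise ConvergenceError("MixedLM (participant + cluster) did not converge")
    k = X.shape[1]
    coef = dict(zip(names, np.asarray(result.fe_params)[:k]))
    se = dict(zip(names, np.asarray(result.bse_fe)[:k]))
    var_components = {
        "cluster": float(np.asarray(result.cov_re)[0, 0]),
        "participant": float(result.vcomp[0]),
    }
    return LmmFit(
        coef=coef,
        se=se,
        var_components=var_components,
        resid_var=float(result.scale),
        converged=True,
        n_obs=int(len(y)),
        n_groups=int(rows["participant_id"].nunique()),
        loglik=float(result.llf),
        n_dropped=n_dropped,
        method="reml" if reml else "ml",
        terms=names,
    )
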