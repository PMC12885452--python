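"""Descriptive baseline tables, multiplicity adjustment, result rendering.

* :func:`baseline_table` summarises wave-1 characteristics per cluster with
  Pearson chi-square tests (categorical variables) and one-way ANOVA F tests
  (continuous variables) across clusters, flagging rows that stay significant
  after Benjamini–Hochberg adjustment over the table's test family.
* :func:`bh_adjust` is the standard step-up false-discovery-rate procedure.
* :func:`render_results` turns mediation / lagged results into deterministic
  text, CSV or JSON tables.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lagged import LaggedResult
from .mediation import (
    MediationResult,
    MultivariateMediationResult,
    SensitivityResult,
)
from .panel import MEDIATORS, OUTCOMES

__all__ = ["BaselineTable", "baseline_table", "bh_adjust", "render_results"]

CATEGORICAL_BASELINE_VARS = ("gender", "profession", "contract", "trainee")
CONTINUOUS_BASELINE_VARS = ("age",) + OUTCOMES + MEDIATORS


def bh_adjust(pvalues, q: float = 0.05):
    """Benjamini–Hochberg step-up adjustment.

    Returns ``(adjusted, reject)`` in the input order, where
    ``adjusted[(i)] = min_{j >= i} min(1, m * p_(j) / j)`` over the sorted
    p-values and ``reject`` flags adjusted p <= ``q``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("all p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


@dataclass
class BaselineTable:
    """Per-variable cross-cluster summary with tests and BH flags."""

    table: pd.DataFrame
    n_per_cluster: dict

    def to_csv(self, path=None):
        return self.table.to_csv(path, index=False)


def _fmt_mean_sd(x: pd.Series) -> str:
    x = x.dropna()
    if not len(x):
        return "-"
    return f"{x.mean():.2f} ({x.std(ddof=1):.2f})"


def _fmt_count_pct(x: pd.Series, level) -> str:
    n = int((x == level).sum())
    total = int(x.notna().sum())
    pct = 100.0 * n / total if total else 0.0
    return f"{n} ({pct:.1f})"


def baseline_table(panel: pd.DataFrame) -> BaselineTable:
    """Baseline (wave-1) characteristics by cluster, with cross-cluster tests.

    Categorical variables get a Pearson chi-square without continuity
    correction (df = (levels-1)(clusters-1)); continuous variables a one-way
    F test (df = (clusters-1, N - clusters - missing)).  The BH flag marks
    tests still significant at q = .05 after adjustment over this table.
    """
    base = panel[panel["wave"] == 1]
    clusters = sorted(base["cluster"].unique())
    empty = [c for c in sorted(panel["cluster"].unique()) if c not in clusters]
    if empty:
        import warnings

        warnings.warn(f"clusters without wave-1 rows excluded: {empty}", stacklevel=2)

    records = []
    for var in CATEGORICAL_BASELINE_VARS:
        col = base[var].astype(str)
        contingency = pd.crosstab(col, base["cluster"])
        chi2, p, dof, _ = stats.chi2_contingency(contingency, correction=False)
        levels = sorted(col.dropna().unique())
        display_level = levels[-1] if var == "gender" else levels[0]
        rec = {
            "variable": var,
            "kind": "categorical",
            "overall": _fmt_count_pct(col, display_level),
            "statistic": float(chi2),
            "df": f"({dof})",
            "p": float(p),
        }
        for c in clusters:
            rec[f"cluster_{c}"] = _fmt_count_pct(col[base["cluster"] == c], display_level)
        records.append(rec)
    for var in CONTINUOUS_BASELINE_VARS:
        groups = [
            base.loc[base["cluster"] == c, var].dropna().to_numpy() for c in clusters
        ]
        groups_ok = [g for g in groups if len(g)]
        n_total = int(sum(len(g) for g in groups_ok))
        df1 = len(groups_ok) - 1
        df2 = n_total - len(groups_ok)
        if np.allclose(
            np.concatenate(groups_ok), np.concatenate(groups_ok)[0], atol=0, rtol=0
        ):
            fstat, p = 0.0, 1.0
        else:
            fstat, p = stats.f_oneway(*groups_ok)
        rec = {
            "variable": var,
            "kind": "continuous",
            "overall": _fmt_mean_sd(base[var]),
            "statistic": float(fstat),
            "df": f"({df1}, {df2})",
            "p": float(p),
        }
        for c in clusters:
            rec[f"cluster_{c}"] = _fmt_mean_sd(base.loc[base["cluster"] == c, var])
        records.append(rec)

    table = pd.DataFrame.from_records(records)
    adjusted, reject = bh_adjust(table["p"].to_numpy())
    table["p_bh"] = adjusted
    table["bh_significant"] = reject
    n_per_cluster = {int(c): int((base["cluster"] == c).sum()) for c in clusters}
    return BaselineTable(table=table, n_per_cluster=n_per_cluster)


# ----------------------------------------------------------------------
# rendering


def _fmt_p(p: float, n_boot: int | None = None, digits: int = 3) -> str:
    if n_boot and p < 2.0 / n_boot:
        return f"<{2.0 / n_boot:.{digits}g}"
    if p < 0.001:
        return "<0.001"
    return f"{p:.{digits}g}"


def _effect_row(label, eff, n_boot=None, digits=2):
    return {
        "path": label,
        "estimate": round(eff.estimate, digits),
        "ci_low": round(eff.ci_low, digits),
        "ci_high": round(eff.ci_high, digits),
        "se": round(eff.se, digits) if eff.se is not None else None,
        "p": _fmt_p(eff.p, n_boot),
    }


def _mediation_rows(res: MediationResult, digits=2):
    return [
        _effect_row(f"a (treatment -> {res.mediator})", res.a, digits=digits),
        _effect_row(f"b ({res.mediator} -> {res.outcome})", res.b, digits=digits),
        _effect_row("Indirect effect (a*b)", res.indirect, res.n_boot_used, digits),
        _effect_row(f"Direct effect (treatment -> {res.outcome})", res.direct, digits=digits),
    ]


def _multivariate_rows(res: MultivariateMediationResult, digits=2):
    rows = [
        _effect_row(f"Indirect via {m}", res.indirect[m], res.n_boot_used, digits)
        for m in res.mediators
    ]
    rows.append(
        _effect_row(f"Direct effect (treatment -> {res.outcome})", res.direct, digits=digits)
    )
    return rows


def _result_frame(result, digits=2) -> pd.DataFrame:
    if isinstance(result, MediationResult):
        return pd.DataFrame(_mediation_rows(result, digits))
    if isinstance(result, MultivariateMediationResult):
        return pd.DataFrame(_multivariate_rows(result, digits))
    if isinstance(result, LaggedResult):
        return pd.DataFrame(
            [
                {
                    "path": f"lagged {result.mediator} -> next-wave {result.outcome}",
                    "estimate": round(result.coefficient, digits),
                    "ci_low": round(result.ci_low, digits),
                    "ci_high": round(result.ci_high, digits),
                    "se": round(result.se, digits),
                    "p": _fmt_p(result.p),
                }
            ]
        )
    raise ValueError(f"cannot render object of type {type(result).__name__}")


def render_results(result, format: str = "text", digits: int = 2) -> str:
    """Render a result object as ``"text"``, ``"csv"`` or ``"json"``.

    Rendering is deterministic for fixed inputs; bootstrap p-values smaller
    than the bootstrap resolution ``2 / n_boot`` are shown as a "<" bound.
    """
    if format not in ("text", "csv", "json"):
        raise ValueError(f"unknown format {format!r} (use text, csv or json)")
    if isinstance(result, SensitivityResult):
        parts = []
        for tag, selected, res, status in (
            ("S1 (univariately significant mediators)", result.s1_selected, result.s1, result.s1_status),
            ("S2 (one factor per construct family)", result.s2_selected, result.s2, result.s2_status),
        ):
            if res is None:
                block = {"model": tag, "status": "no mediators passed", "rows": []}
            else:
                block = {
                    "model": tag,
                    "status": status,
                    "mediators": selected,
                    "rows": _result_frame(res, digits).to_dict("records"),
                }
            parts.append(block)
        if format == "json":
            return json.dumps(parts, indent=2)
        chunks = []
        for block in parts:
            chunks.append(block["model"])
            if not block["rows"]:
                chunks.append("  no mediators passed the selection")
            else:
                chunks.append(pd.DataFrame(block["rows"]).to_string(index=False))
            chunks.append("")
        text = "\n".join(chunks)
        return text

    frame = _result_frame(result, digits)
    if format == "csv":
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        return buf.getvalue()
    if format == "json":
        return json.dumps(frame.to_dict("records"), indent=2)
    header = ""
    if isinstance(result, MediationResult):
        header = (
            f"Mediation of treatment -> {result.outcome} through {result.mediator} "
            f"(bootstrap n={result.n_boot_used}/{result.n_boot_requested}, "
            f"seed={result.seed})\n"
        )
    elif isinstance(result, MultivariateMediationResult):
        header = (
            f"Multivariate mediation of treatment -> {result.outcome} "
            f"({len(result.mediators)} mediators, bootstrap n={result.n_boot_used})\n"
        )
    return header + frame.to_string(index=False) + "\n"
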