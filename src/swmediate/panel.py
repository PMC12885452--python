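"""Long-format trial data model: schema, validation, CSV I/O, derived columns.

The canonical in-memory representation of a trial is a tidy ("long") pandas
DataFrame with one row per participant per assessment wave.  Columns fall into
four groups:

* design     — ``participant_id``, ``cluster``, ``sequence``, ``wave``,
               ``time_weeks``, ``treatment``
* covariates — ``gender``, ``age``, ``profession``, ``contract``, ``trainee``
               (constant within participant)
* mediators  — resilience (CD-RISC), five mindfulness facets (FFMQ-15),
               self/other compassion (SOCS), experiential avoidance (AAQ-II)
* outcomes   — perceived stress (PSS-10), depression (PHQ-9), anxiety (GAD-7),
               general symptom severity (BSI-18 GSI)

Any score cell may be missing (``NaN``; empty cell in CSV).  See
``docs/data_dictionary.md`` for the full column reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Mediator score columns, in canonical order.
MEDIATORS: tuple[str, ...] = (
    "cd_risc",
    "ffmq_observe",
    "ffmq_describe",
    "ffmq_act",
    "ffmq_nonjudge",
    "ffmq_nonreact",
    "socs_self",
    "socs_other",
    "aaq2",
)

#: Outcome score columns, in canonical order.
OUTCOMES: tuple[str, ...] = ("pss", "phq9", "gad7", "bsi_gsi")

SCORE_COLUMNS: tuple[str, ...] = MEDIATORS + OUTCOMES

#: Printed score range of each instrument (used for optional clipping and for
#: range checks in validation).
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "pss": (0, 40),
    "phq9": (0, 27),
    "gad7": (0, 21),
    "bsi_gsi": (0, 72),
    "cd_risc": (0, 40),
    "ffmq_observe": (1, 5),
    "ffmq_describe": (1, 5),
    "ffmq_act": (1, 5),
    "ffmq_nonjudge": (1, 5),
    "ffmq_nonreact": (1, 5),
    "socs_self": (20, 100),
    "socs_other": (20, 100),
    "aaq2": (7, 49),
}

DESIGN_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "cluster",
    "sequence",
    "wave",
    "time_weeks",
    "treatment",
)

COVARIATE_COLUMNS: tuple[str, ...] = (
    "gender",
    "age",
    "profession",
    "contract",
    "trainee",
)

REQUIRED_COLUMNS: tuple[str, ...] = DESIGN_COLUMNS + COVARIATE_COLUMNS + SCORE_COLUMNS

#: Reference levels for dummy coding of categorical covariates.  Fixing the
#: references makes coefficient signs reproducible across runs.
REFERENCE_LEVELS: dict[str, object] = {
    "cluster": 1,
    "gender": "female",
    "profession": "physician",
    "contract": "nontemporary",
}

#: Default covariate adjustment set used by the mediation and lagged models
#: (baseline outcome is added separately as a derived column).
DEFAULT_COVARIATES: tuple[str, ...] = (
    "cluster",
    "gender",
    "profession",
    "age",
    "contract",
    "trainee",
)


class PanelError(ValueError):
    """A panel violates the long-format schema or its invariants."""


class PanelParseError(PanelError):
    """A CSV cell could not be parsed (names the offending row/column)."""


@dataclass
class ModelSpec:
    """Specification of one mediation model family.

    Parameters
    ----------
    outcome : str
        Outcome score column.
    mediators : list of str
        One entry for a univariate mediation, several for a multivariate one.
    covariates : list of str
        Adjustment covariates (categorical columns are dummy-expanded at fit
        time with the references in :data:`REFERENCE_LEVELS`).
    baseline_column : str
        Derived column holding the wave-1 value of the outcome; created by
        :func:`attach_baseline`.
    random_effects : frozenset of {"participant", "cluster"}
        Random-intercept grouping(s).
    """

    outcome: str
    mediators: list[str]
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    baseline_column: str = ""
    random_effects: frozenset = frozenset({"participant"})

    def __post_init__(self) -> None:
        if not self.mediators:
            raise ValueError("ModelSpec.mediators must contain at least one column")
        if len(set(self.mediators)) != len(self.mediators):
            raise ValueError("ModelSpec.mediators must be distinct")
        if self.outcome in self.mediators:
            raise ValueError("ModelSpec.outcome must not appear among mediators")
        if not self.random_effects:
            raise ValueError("ModelSpec.random_effects must be non-empty")
        if not set(self.random_effects) <= {"participant", "cluster"}:
            raise ValueError("random_effects must be a subset of {participant, cluster}")
        if not self.baseline_column:
            self.baseline_column = f"{self.outcome}_baseline"

    @classmethod
    def for_outcome(cls, outcome: str, mediators: list[str] | str, **kwargs) -> "ModelSpec":
        if isinstance(mediators, str):
            mediators = [mediators]
        return cls(outcome=outcome, mediators=list(mediators), **kwargs)

    def to_yaml(self, path) -> None:
        payload = {
            "outcome": self.outcome,
            "mediators": list(self.mediators),
            "covariates": list(self.covariates),
            "baseline_column": self.baseline_column,
            "random_effects": sorted(self.random_effects),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["random_effects"] = frozenset(payload.get("random_effects", ["participant"]))
        return cls(**payload)


def validate_panel(panel: pd.DataFrame, schedule: dict | None = None) -> None:
    """Check the long-panel invariants, raising :class:`PanelError` on failure.

    Checks: mandatory columns, unique (participant, wave) keys, integer waves
    in 1..max, per-participant constancy of design and covariate columns,
    non-decreasing treatment within participant, and — when a crossover
    ``schedule`` is supplied (mapping sequence -> crossover week, plus key
    ``"wave_spacing_weeks"``) — agreement of the treatment indicator with the
    stepped-wedge schedule.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelError(f"panel is missing mandatory column(s): {missing}")

    dup = panel.duplicated(subset=["participant_id", "wave"])
    if dup.any():
        keys = panel.loc[dup, ["participant_id", "wave"]].iloc[0].tolist()
        raise PanelError(f"duplicate (participant_id, wave) key: {keys}")

    waves = panel["wave"].to_numpy()
    if not np.all((waves >= 1) & (waves == np.round(waves))):
        raise PanelError("wave must be an integer >= 1")

    constant_cols = ["cluster", "sequence", "gender", "age", "profession", "contract", "trainee"]
    nun = panel.groupby("participant_id", sort=False)[constant_cols].nunique(dropna=False)
    bad = nun[(nun > 1).any(axis=1)]
    if len(bad):
        pid = bad.index[0]
        cols = list(bad.columns[(bad.iloc[0] > 1).to_numpy()])
        raise PanelError(f"participant {pid!r} has non-constant column(s) {cols}")

    srt = panel.sort_values(["participant_id", "wave"])
    tr = srt.groupby("participant_id", sort=False)["treatment"]
    if (tr.diff().fillna(0) < 0).any():
        raise PanelError("treatment indicator decreases within a participant")

    if schedule is not None:
        spacing = schedule.get("wave_spacing_weeks", 8.0)
        cross = np.array([schedule[int(s)] for s in panel["sequence"]], dtype=float)
        expected = ((panel["wave"].to_numpy() - 1) * spacing >= cross).astype(int)
        mism = panel["treatment"].to_numpy() != expected
        if mism.any():
            row = panel.index[mism][0]
            raise PanelError(
                f"treatment inconsistent with crossover schedule at row {row} "
                f"(participant {panel.loc[row, 'participant_id']!r}, wave {panel.loc[row, 'wave']})"
            )


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write a long panel to CSV (missing score cells become empty cells)."""
    panel.to_csv(path, index=False)


def read_panel(path, validate: bool = True) -> pd.DataFrame:
    """Read a long panel from CSV, coercing types and validating the schema.

    Non-numeric text in a score cell (anything other than an empty cell) is a
    parse error naming the row and column.  Extra columns are preserved.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"panel file is missing mandatory column(s): {missing}")

    numeric_cols = list(SCORE_COLUMNS) + ["age", "time_weeks"] + [
        c for c in df.columns if c.endswith("_baseline")
    ]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PanelParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        df[col] = coerced
    for col in ("cluster", "sequence", "wave", "treatment", "trainee"):
        df[col] = df[col].astype(np.int64)
    df["participant_id"] = df["participant_id"].astype(str)
    if validate:
        validate_panel(df)
    return df


def attach_baseline(panel: pd.DataFrame, score_column: str) -> pd.DataFrame:
    """Attach the wave-1 value of ``score_column`` as ``<score>_baseline``.

    Every row of a participant carries that participant's wave-1 score; rows
    with wave >= 2 are flagged ``is_analysis`` (baseline enters the models only
    as a covariate, so wave-1 rows are never analysis rows).  Participants
    without a wave-1 row are excluded; the count is logged and recorded in
    ``result.attrs["n_excluded_no_baseline"]``.
    """
    if score_column not in panel.columns:
        raise PanelError(f"score column {score_column!r} not present in panel")
    wave1 = panel.loc[panel["wave"] == 1, ["participant_id", score_column]]
    wave1 = wave1.rename(columns={score_column: f"{score_column}_baseline"})
    has_baseline = set(wave1["participant_id"])
    excluded = [p for p in panel["participant_id"].unique() if p not in has_baseline]
    if excluded:
        logger.warning(
            "attach_baseline: excluding %d participant(s) without a wave-1 row", len(excluded)
        )
    out = panel[panel["participant_id"].isin(has_baseline)].merge(
        wave1, on="participant_id", how="left"
    )
    out["is_analysis"] = out["wave"] >= 2
    out.attrs = dict(panel.attrs)
    out.attrs["n_excluded_no_baseline"] = len(excluded)
    return out
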