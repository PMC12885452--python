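"""Generator: design expansion, treatment coding, reproducibility, dropout."""

import numpy as np
import pandas as pd
import pytest

from swmediate.panel import SCORE_COLUMNS, SCORE_RANGES
from swmediate.synthdata import (
    ConfigError,
    SimulationConfig,
    TruePaths,
    apply_dropout,
    generate_trial,
    make_design,
)


class TestMakeDesign:
    def test_default_dimensions(self):
        design = make_design(SimulationConfig())
        assert len(design) == 347 * 5
        assert design["participant_id"].nunique() == 347
        assert (design.loc[design["wave"] == 1, "treatment"] == 0).all()
        assert design["time_weeks"].tolist()[:5] == [0.0, 8.0, 16.0, 24.0, 32.0]

    @pytest.mark.parametrize(
        "sequence, expected",
        [(1, [0, 1, 1, 1, 1]), (2, [0, 0, 1, 1, 1]), (3, [0, 0, 0, 1, 1])],
    )
    def test_crossover_vectors(self, sequence, expected):
        design = make_design(SimulationConfig())
        one = design[design["sequence"] == sequence]
        pid = one["participant_id"].iloc[0]
        assert one.loc[one["participant_id"] == pid, "treatment"].tolist() == expected

    def test_treatment_monotone_within_participant(self, small_config):
        design = make_design(small_config)
        diffs = design.sort_values(["participant_id", "wave"]).groupby(
            "participant_id"
        )["treatment"].diff()
        assert (diffs.dropna() >= 0).all()

    def test_active_program_coding_switches_off(self):
        cfg = SimulationConfig(exposure_coding="active_program")
        design = make_design(cfg)
        seq1 = design[design["sequence"] == 1]
        pid = seq1["participant_id"].iloc[0]
        # program runs weeks 8-16 for sequence 1: only the wave at week 8 is active
        assert seq1.loc[seq1["participant_id"] == pid, "treatment"].tolist() == [0, 1, 0, 0, 0]

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"cluster_sizes": (10, -3)}, "cluster_sizes"),
            ({"n_waves": 1}, "n_waves"),
            ({"dropout_hazard_per_wave": 1.0}, "dropout_hazard"),
            ({"sd_resid_outcome": 0.0}, "sd_resid_outcome"),
            ({"crossover_week_of_sequence": {1: 8, 2: 8, 3: 24}}, "crossover_week"),
            ({"mediator": "nope"}, "mediator"),
            ({"covariate_effects": {"height": 1.0}}, "covariate_effects"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            make_design(SimulationConfig(**kwargs))


class TestTruePaths:
    def test_product_and_total(self):
        tp = SimulationConfig(a_path=2.62, b_path=-0.48, c_prime=-2.77).true_paths()
        assert tp.indirect == pytest.approx(-1.2576, abs=1e-12)
        assert tp.total == tp.c_prime + tp.indirect

    @pytest.mark.parametrize("a, b", [(0.0, -0.48), (2.62, 0.0)])
    def test_zero_factor_zero_indirect(self, a, b):
        assert TruePaths.from_coefficients(a, b, -1.0).indirect == 0.0


class TestGenerateTrial:
    def test_seed_reproducibility(self, small_config):
        p1 = generate_trial(small_config)
        p2 = generate_trial(small_config)
        pd.testing.assert_frame_equal(p1, p2)
        p3 = generate_trial(SimulationConfig(cluster_sizes=small_config.cluster_sizes, seed=999))
        assert not p1["pss"].equals(p3["pss"])

    def test_schema_complete(self, small_panel, small_config):
        assert len(small_panel) == small_config.n_participants * 5
        for col in SCORE_COLUMNS:
            assert small_panel[col].notna().all()

    def test_covariates_constant_within_participant(self, small_panel):
        nun = small_panel.groupby("participant_id")[["gender", "age", "profession"]].nunique()
        assert (nun == 1).all().all()

    def test_treated_minus_control_mean_recovers_a(self):
        """With noise switched off the group contrast equals the a-path."""
        cfg = SimulationConfig(
            cluster_sizes=(400, 400, 400),
            sequence_of_cluster={1: 1, 2: 2, 3: 3},
            sd_participant_mediator=0.0,
            sd_participant_outcome=0.0,
            sd_resid_mediator=0.01,
            sd_resid_outcome=0.01,
            baseline_effect_mediator=0.0,
            seed=7,
        )
        panel = generate_trial(cfg)
        wave3 = panel[panel["wave"] == 3]
        contrast = (
            wave3.loc[wave3["treatment"] == 1, "cd_risc"].mean()
            - wave3.loc[wave3["treatment"] == 0, "cd_risc"].mean()
        )
        assert contrast == pytest.approx(cfg.a_path, abs=0.005)

    def test_participant_mean_variance_decomposition(self):
        """Var of participant-level mean scores ~ sd_u^2 + sd_e^2 / n_waves."""
        cfg = SimulationConfig(
            cluster_sizes=(1000, 1000),
            sequence_of_cluster={1: 1, 2: 2},
            crossover_week_of_sequence={1: 8.0, 2: 16.0},
            a_path=0.0,
            baseline_effect_mediator=0.0,
            seed=11,
        )
        panel = generate_trial(cfg)
        means = panel.groupby("participant_id")["cd_risc"].mean()
        expected = cfg.sd_participant_mediator**2 + cfg.sd_resid_mediator**2 / cfg.n_waves
        assert means.var(ddof=1) == pytest.approx(expected, rel=0.08)

    def test_clip_to_range(self):
        cfg = SimulationConfig(
            cluster_sizes=(50,), sequence_of_cluster={1: 1}, clip_to_range=True, seed=3
        )
        panel = generate_trial(cfg)
        for col, (lo, hi) in SCORE_RANGES.items():
            assert panel[col].between(lo, hi).all()


class TestDropout:
    def test_zero_hazard_identity(self, small_panel):
        assert apply_dropout(small_panel, 0.0, seed=1) is small_panel

    def test_monotone_missingness(self, small_panel):
        out = apply_dropout(small_panel, 0.3, seed=5)
        observed = out.groupby("participant_id")["wave"].apply(list)
        for waves in observed:
            assert waves == list(range(1, len(waves) + 1))  # no gaps, wave 1 kept

    def test_geometric_retention_rate(self):
        cfg = SimulationConfig(
            cluster_sizes=(500, 500),
            sequence_of_cluster={1: 1, 2: 2},
            crossover_week_of_sequence={1: 8.0, 2: 16.0},
            seed=21,
        )
        panel = generate_trial(cfg)
        out = apply_dropout(panel, 0.2, seed=77)
        retained = (out["wave"] == 5).sum() / 1000
        # geometric survival 0.8^4 = 0.4096; 4 sigma binomial band
        assert abs(retained - 0.8**4) < 4 * np.sqrt(0.4096 * 0.5904 / 1000)

    def test_invalid_hazard(self, small_panel):
        with pytest.raises(ConfigError):
            apply_dropout(small_panel, 1.2, seed=0)
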