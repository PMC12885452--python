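"""Mediation engine: identities, determinism, equivariance, selection logic."""

import numpy as np
import pandas as pd
import pytest

from swmediate.lmm import FitError
from swmediate.mediation import (
    DEFAULT_FAMILIES,
    EffectEstimate,
    MediationResult,
    bootstrap_mediation,
    estimate_paths,
    multivariate_mediation,
    percentile_ci,
    select_per_family,
    select_significant,
    sensitivity_models,
    sign_crossing_p,
)
from swmediate.panel import ModelSpec, attach_baseline
from swmediate.synthdata import SimulationConfig, generate_trial

N_BOOT = 100  # smallest allowed; plenty for structural tests


class TestPureHelpers:
    def test_percentile_ci_matches_sorted_quantile_oracle(self, rng):
        draws = rng.normal(size=473)
        lo, hi = percentile_ci(draws)
        srt = np.sort(draws)

        def quantile(q):  # linear interpolation between order statistics
            h = q * (len(srt) - 1)
            f = int(np.floor(h))
            return srt[f] + (h - f) * (srt[min(f + 1, len(srt) - 1)] - srt[f])

        assert lo == pytest.approx(quantile(0.025), abs=1e-12)
        assert hi == pytest.approx(quantile(0.975), abs=1e-12)

    def test_nearest_rank_option(self, rng):
        draws = rng.normal(size=100)
        lo, hi = percentile_ci(draws, method="lower")
        assert lo in draws and hi in draws

    @pytest.mark.parametrize(
        "draws, expected",
        [
            (-np.arange(1.0, 101.0), 0.0),              # all strictly negative
            (np.concatenate([-np.arange(1, 51), np.arange(1, 51)]), 1.0),  # symmetric
            (np.concatenate([-np.ones(5), np.ones(95)]), 0.1),
        ],
    )
    def test_sign_crossing_p(self, draws, expected):
        assert sign_crossing_p(draws) == pytest.approx(expected)

    def test_one_sided_proportion_is_half_two_sided(self, rng):
        from swmediate.mediation import one_sided_sign_proportion

        draws = rng.normal(loc=-0.8, size=200)
        assert sign_crossing_p(draws) == pytest.approx(
            min(1.0, 2 * one_sided_sign_proportion(draws))
        )


class TestEstimatePaths:
    def test_sign_flip_equivariance(self, small_panel):
        """Negating mediator and outcome flips a and the indirect effect but
        leaves b unchanged (linear-model equivariance)."""
        spec = ModelSpec.for_outcome("pss", ["cd_risc"])
        base = estimate_paths(attach_baseline(small_panel, "pss"), spec)
        flipped = small_panel.copy()
        flipped["cd_risc"] = -flipped["cd_risc"]
        flipped["pss"] = -flipped["pss"]
        alt = estimate_paths(attach_baseline(flipped, "pss"), spec)
        assert alt.a["cd_risc"] == pytest.approx(-base.a["cd_risc"], rel=1e-8)
        assert alt.b["cd_risc"] == pytest.approx(base.b["cd_risc"], rel=1e-8)
        assert alt.indirect("cd_risc") == pytest.approx(-base.indirect("cd_risc"), rel=1e-8)

    def test_null_a_path_centred_on_zero(self):
        est = []
        for s in range(12):
            cfg = SimulationConfig(
                cluster_sizes=(30, 25, 30, 25, 20, 20), a_path=0.0, seed=300 + s
            )
            dfb = attach_baseline(generate_trial(cfg), "pss")
            est.append(estimate_paths(dfb, ModelSpec.for_outcome("pss", ["cd_risc"])).a["cd_risc"])
        est = np.array(est)
        assert abs(est.mean()) < 3 * est.std(ddof=1) / np.sqrt(len(est))

    def test_missing_baseline_column_raises(self, small_panel):
        with pytest.raises(Exception, match="baseline"):
            estimate_paths(small_panel, ModelSpec.for_outcome("pss", ["cd_risc"]))


class TestBootstrap:
    def test_point_estimate_identity(self, small_panel_baseline, pss_spec):
        res = bootstrap_mediation(small_panel_baseline, pss_spec, n_boot=N_BOOT, seed=5)
        paths = estimate_paths(small_panel_baseline, pss_spec)
        assert res.indirect.estimate == paths.a["cd_risc"] * paths.b["cd_risc"]

    def test_seed_determinism_across_workers(self, small_panel_baseline, pss_spec):
        r1 = bootstrap_mediation(small_panel_baseline, pss_spec, n_boot=N_BOOT, seed=9)
        r2 = bootstrap_mediation(small_panel_baseline, pss_spec, n_boot=N_BOOT, seed=9)
        r3 = bootstrap_mediation(
            small_panel_baseline, pss_spec, n_boot=N_BOOT, seed=9, n_jobs=2
        )
        np.testing.assert_array_equal(r1.draws, r2.draws)
        np.testing.assert_array_equal(r1.draws, r3.draws)
        assert (r1.indirect.ci_low, r1.indirect.p) == (r3.indirect.ci_low, r3.indirect.p)
        r4 = bootstrap_mediation(small_panel_baseline, pss_spec, n_boot=N_BOOT, seed=10)
        assert not np.array_equal(r1.draws, r4.draws)

    def test_ci_from_stored_draws(self, small_panel_baseline, pss_spec):
        res = bootstrap_mediation(small_panel_baseline, pss_spec, n_boot=N_BOOT, seed=5)
        assert (res.indirect.ci_low, res.indirect.ci_high) == percentile_ci(res.draws)
        assert res.indirect.p == sign_crossing_p(res.draws)
        assert res.n_boot_used <= res.n_boot_requested

    def test_cluster_sizes_preserved_in_resample(self, small_panel_baseline, pss_spec):
        from swmediate.mediation import _Resampler

        rs = _Resampler(small_panel_baseline, pss_spec)
        blocks = rs.sample_blocks(np.random.default_rng(0))
        assert len(blocks) == rs.n_blocks  # one trajectory drawn per original one

    def test_point_identity_survives_dropout(self, pss_spec):
        """Unequal trajectory lengths (attrition) leave the identity intact."""
        cfg = SimulationConfig(
            cluster_sizes=(40, 30, 35, 40, 30, 25),
            dropout_hazard_per_wave=0.15,
            seed=99,
        )
        dfb = attach_baseline(generate_trial(cfg), "pss")
        res = bootstrap_mediation(dfb, pss_spec, n_boot=N_BOOT, seed=1)
        paths = estimate_paths(dfb, pss_spec)
        assert res.indirect.estimate == paths.a["cd_risc"] * paths.b["cd_risc"]
        assert res.n_boot_used == N_BOOT

    def test_n_boot_floor(self, small_panel_baseline, pss_spec):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_mediation(small_panel_baseline, pss_spec, n_boot=50, seed=1)


@pytest.fixture(scope="module")
def two_mediator_panel():
    cfg = SimulationConfig(
        cluster_sizes=(40, 30, 35, 40, 30, 25),
        extra_paths={"ffmq_observe": (0.0, -1.64)},  # second mediator: null a
        seed=777,
    )
    return attach_baseline(generate_trial(cfg), "pss")


class TestMultivariate:
    def test_null_second_mediator_centred(self, two_mediator_panel):
        res = multivariate_mediation(
            two_mediator_panel, ["cd_risc", "ffmq_observe"], "pss", n_boot=N_BOOT, seed=4
        )
        assert len(res.indirect) == 2
        null = res.indirect["ffmq_observe"]
        assert null.ci_low <= 0.0 <= null.ci_high
        active = res.indirect["cd_risc"]
        assert active.estimate < 0

    def test_indirect_additivity_over_replicates(self):
        """Independent mediated paths add: sum of fitted indirect effects
        approaches a1*b1 + a2*b2."""
        total = []
        for s in range(10):
            cfg = SimulationConfig(
                cluster_sizes=(40, 30, 35, 40, 30, 25),
                extra_paths={"ffmq_observe": (0.30, -1.64)},
                seed=880 + s,
            )
            dfb = attach_baseline(generate_trial(cfg), "pss")
            paths = estimate_paths(
                dfb, ModelSpec.for_outcome("pss", ["cd_risc", "ffmq_observe"])
            )
            total.append(sum(paths.indirect(m) for m in ("cd_risc", "ffmq_observe")))
        total = np.array(total)
        truth = 2.62 * -0.48 + 0.30 * -1.64
        assert abs(total.mean() - truth) < 3 * total.std(ddof=1) / np.sqrt(len(total))

    def test_duplicated_mediator_detected(self, two_mediator_panel):
        panel = two_mediator_panel.copy()
        panel["ffmq_observe"] = panel["cd_risc"]
        with pytest.raises(FitError, match="cd_risc.*ffmq_observe"):
            multivariate_mediation(panel, ["cd_risc", "ffmq_observe"], "pss", n_boot=N_BOOT, seed=1)

    def test_requires_two_mediators(self, two_mediator_panel):
        with pytest.raises(ValueError, match="2 mediators"):
            multivariate_mediation(two_mediator_panel, ["cd_risc"], "pss", n_boot=N_BOOT, seed=1)


def _fake_result(mediator, p, indirect=-0.5):
    eff = EffectEstimate(estimate=indirect, ci_low=indirect - 1, ci_high=indirect + 1, p=p)
    other = EffectEstimate(estimate=0.0, ci_low=-1, ci_high=1, p=0.5)
    return MediationResult(
        mediator=mediator, outcome="pss", a=other, b=other, indirect=eff, direct=other,
        n_boot_requested=100, n_boot_used=100, draws=np.zeros(100), seed=0,
    )


class TestSensitivitySelection:
    #: univariate indirect-effect p-value pattern used for the selection tests
    PATTERN = {
        "cd_risc": 0.02,
        "ffmq_observe": 0.04,
        "ffmq_describe": 0.02,
        "ffmq_nonreact": 0.01,
        "ffmq_act": 0.96,
        "ffmq_nonjudge": 0.85,
        "socs_other": 0.82,
        "socs_self": 0.23,
        "aaq2": 0.70,
    }

    def test_s1_selects_significant_set(self):
        results = {m: _fake_result(m, p) for m, p in self.PATTERN.items()}
        assert set(select_significant(results)) == {
            "cd_risc", "ffmq_observe", "ffmq_describe", "ffmq_nonreact",
        }

    def test_s2_one_per_family(self):
        results = {m: _fake_result(m, p) for m, p in self.PATTERN.items()}
        chosen = select_per_family(results, DEFAULT_FAMILIES)
        assert sorted(chosen) == ["aaq2", "cd_risc", "ffmq_nonreact", "socs_self"]

    def test_s2_tie_broken_by_magnitude_then_name(self):
        results = {
            "ffmq_observe": _fake_result("ffmq_observe", 0.03, indirect=-0.2),
            "ffmq_describe": _fake_result("ffmq_describe", 0.03, indirect=-0.9),
        }
        fam = {"ffmq_observe": "mindfulness", "ffmq_describe": "mindfulness"}
        assert select_per_family(results, fam) == ["ffmq_describe"]
        results["ffmq_observe"] = _fake_result("ffmq_observe", 0.03, indirect=-0.9)
        assert select_per_family(results, fam) == ["ffmq_describe"]  # lexicographic

    def test_empty_s1_is_status_not_error(self, small_panel_baseline):
        results = {m: _fake_result(m, 0.5) for m in self.PATTERN}
        out = sensitivity_models(
            small_panel_baseline, results, "pss", n_boot=N_BOOT, seed=2
        )
        assert out.s1 is None
        assert "no mediators" in out.s1_status
        assert len(out.s2_selected) == 4  # one per family regardless

    def test_single_member_family_always_selected(self):
        results = {"cd_risc": _fake_result("cd_risc", 0.9)}
        assert select_per_family(results, {"cd_risc": "resilience"}) == ["cd_risc"]
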