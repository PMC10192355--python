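"""Coupled simulation engine and ensembles."""

import numpy as np
import pytest

from evacsim.attitudes import CommunicationParams
from evacsim.engine import (
    EVACUATED,
    EVACUATING,
    IDLE,
    SimulationConfig,
    completion_ratio,
    paired_relative_difference,
    relative_difference,
    run_ensemble,
    run_simulation,
    summarise,
    unpaired_relative_difference,
)


def frozen_comm(**kw):
    """Communication parameters with attitudes frozen (mu = 0)."""
    return CommunicationParams(mu=0.0, **kw)


class TestDecoupledLimits:
    def test_all_positive_attitudes_complete(self, small_city, small_nav):
        cfg = SimulationConfig(
            urban=small_city,
            n_agents=60,
            comm=frozen_comm(),
            horizon=600.0,
            seed=2,
            initial_attitudes=np.ones(60),
        )
        res = run_simulation(cfg, nav=small_nav)
        assert completion_ratio(res) == 1.0
        assert np.nanmax(res.arrival_times) <= cfg.horizon

    def test_all_negative_attitudes_stay(self, small_city, small_nav):
        cfg = SimulationConfig(
            urban=small_city,
            n_agents=40,
            comm=frozen_comm(),
            horizon=200.0,
            seed=2,
            initial_attitudes=-np.ones(40),
        )
        res = run_simulation(cfg, nav=small_nav)
        assert completion_ratio(res) == 0.0
        assert (res.final_states == IDLE).all()

    def test_frozen_attitudes_completion_equals_high_fraction(self, small_city, small_nav):
        """With mu = 0 exactly the A >= 0.5 agents evacuate."""
        cfg = SimulationConfig(
            urban=small_city, n_agents=300, comm=frozen_comm(), horizon=600.0, seed=5
        )
        res = run_simulation(cfg, nav=small_nav)
        high = res.initial_attitudes >= 0.5
        # every evacuee had a high attitude; nearly every high-attitude
        # agent gets out (a standing neighbour can pin an agent indoors)
        assert (res.initial_attitudes[res.final_states == 2] >= 0.5).all()
        assert completion_ratio(res) == pytest.approx(high.mean(), abs=0.01)


class TestRunSemantics:
    def test_state_transitions_and_monotone_completion(self, small_city, small_nav):
        cfg = SimulationConfig(urban=small_city, n_agents=150, horizon=400.0, seed=8)
        res = run_simulation(cfg, nav=small_nav)
        ts = res.completion_timeseries()
        assert (np.diff(ts) >= 0).all()
        # evacuated is absorbing
        ever = np.zeros(res.n_agents, dtype=bool)
        for s in range(len(res.times)):
            now = res.states[s] == EVACUATED
            assert not (ever & ~now).any()
            ever |= now
        assert np.isin(res.states, [IDLE, EVACUATING, EVACUATED]).all()

    def test_run_reproducible_bitwise(self, small_city, small_nav):
        cfg = SimulationConfig(urban=small_city, n_agents=100, horizon=200.0, seed=13)
        a = run_simulation(cfg, nav=small_nav)
        b = run_simulation(cfg, nav=small_nav)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.attitudes, b.attitudes)
        assert np.array_equal(a.final_states, b.final_states)

    def test_leaders_always_evacuating_and_fixed(self, small_city, small_nav):
        cfg = SimulationConfig(
            urban=small_city, n_agents=80, leader_fraction=0.1, horizon=120.0, seed=4
        )
        res = run_simulation(cfg, nav=small_nav)
        assert len(res.leader_indices) == 8
        for s in range(len(res.times)):
            lead_states = res.states[s][res.leader_indices]
            done = lead_states == EVACUATED
            assert (lead_states[~done] == EVACUATING).all()
            assert np.allclose(res.attitudes[s][res.leader_indices][~done], 0.7)


class TestEnsembles:
    def test_ensemble_reproducible(self, small_city, small_nav):
        cfg = SimulationConfig(urban=small_city, n_agents=60, horizon=100.0, seed=21)
        a = run_ensemble(cfg, 3, nav=small_nav)
        b = run_ensemble(cfg, 3, nav=small_nav)
        assert np.array_equal(a.completions, b.completions)
        assert a.run_seeds == b.run_seeds

    def test_attitude_mode_resamples_attitudes(self, small_city, small_nav):
        cfg = SimulationConfig(urban=small_city, n_agents=60, horizon=60.0, seed=22)
        ens = run_ensemble(cfg, 3, nav=small_nav)
        assert not np.allclose(ens.initial_attitudes[0], ens.initial_attitudes[1])

    def test_leader_mode_fixes_attitudes_and_counts(self, small_city, small_nav):
        fixed = np.linspace(-1, 1, 60)
        cfg = SimulationConfig(
            urban=small_city, n_agents=60, leader_fraction=0.1, horizon=60.0, seed=23
        )
        ens = run_ensemble(cfg, 4, mode="leaders", attitudes=fixed, nav=small_nav)
        assert (ens.metrics.n_leaders == 6).all()
        # non-leader initial attitudes equal the fixed vector in every run
        for r, res_A in enumerate(ens.initial_attitudes):
            same = np.isclose(res_A, fixed.astype(np.float32))
            assert same.sum() >= 60 - 6 - 2  # leaders overwritten to 0.7

    def test_leader_mode_requires_attitudes(self, small_city, small_nav):
        cfg = SimulationConfig(urban=small_city, n_agents=10, horizon=10.0, seed=1)
        with pytest.raises(ValueError, match="leader mode"):
            run_ensemble(cfg, 2, mode="leaders", nav=small_nav)

    def test_median_case_lower_median(self, small_city, small_nav):
        cfg = SimulationConfig(urban=small_city, n_agents=40, horizon=60.0, seed=30)
        ens = run_ensemble(cfg, 4, nav=small_nav)
        idx, att = ens.median_case()
        order = np.sort(ens.completions)
        assert ens.completions[idx] == order[1]  # lower median of 4
        assert np.allclose(att, ens.initial_attitudes[idx])

    def test_single_run_summary_degenerate(self, small_city, small_nav):
        cfg = SimulationConfig(urban=small_city, n_agents=30, horizon=30.0, seed=31)
        ens = run_ensemble(cfg, 1, nav=small_nav)
        s = ens.summary
        assert s["median"] == s["q1"] == s["q3"] == ens.completions[0]


class TestMetrics:
    def test_completion_ratio_arithmetic(self, small_city, small_nav):
        cfg = SimulationConfig(
            urban=small_city,
            n_agents=10,
            comm=frozen_comm(),
            horizon=400.0,
            seed=2,
            initial_attitudes=np.array([1.0] * 4 + [-1.0] * 6),
        )
        res = run_simulation(cfg, nav=small_nav)
        assert completion_ratio(res) == pytest.approx(0.4)

    @pytest.mark.parametrize(
        "a,b,expected", [(0.4, 0.4, 0.0), (0.3, 0.1, 200.0), (0.43, 0.1, 330.0)]
    )
    def test_relative_difference(self, a, b, expected):
        assert relative_difference(a, b) == pytest.approx(expected)

    def test_relative_difference_zero_reference(self):
        with pytest.raises(ValueError):
            relative_difference(0.3, 0.0)

    def test_pairing_conventions(self):
        a = np.array([0.3, 0.4])
        b = np.array([0.1, 0.2])
        # mean of per-pair differences vs difference of means
        assert paired_relative_difference(a, b) == pytest.approx((200 + 100) / 2)
        assert unpaired_relative_difference(a, b) == pytest.approx(
            (0.35 - 0.15) / 0.15 * 100
        )

    def test_summarise_box_convention(self):
        v = np.arange(1, 121, dtype=float)
        s = summarise(v)
        assert s["median"] == np.percentile(v, 50)
        assert s["q1"] == np.percentile(v, 25, method="linear")
        assert s["q3"] == np.percentile(v, 75, method="linear")
        assert s["whisker_low"] >= s["q1"] - 1.5 * s["iqr"]
        assert s["whisker_high"] <= s["q3"] + 1.5 * s["iqr"]
        assert s["fliers"] == []
        with_flier = summarise(np.append(v, 1e3))
        assert 1e3 in with_flier["fliers"]


class TestConfigValidation:
    def test_bad_config_rejected(self, small_city):
        with pytest.raises(ValueError):
            SimulationConfig(urban=small_city, horizon=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(urban=small_city, leader_fraction=1.5)

    def test_restriction_defaults_by_style(self, small_city, root_city):
        assert SimulationConfig(urban=small_city).resolve_restriction() is True
        assert SimulationConfig(urban=root_city).resolve_restriction() is False
        cfg = SimulationConfig(urban=small_city, restrict_to_inundation=False)
        assert cfg.resolve_restriction() is False
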