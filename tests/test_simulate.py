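"""Integration, outcome classification and trajectory-summary tests."""

import numpy as np
import pytest

from senoliv import (
    InitialCondition,
    ModelParameters,
    SolverConfig,
    check_convergence,
    classify_outcome,
    clearance_time,
    peak_summary,
    simulate,
)
from senoliv.model import STATE_VARS
from senoliv.simulate import HorizonTooShortError

LN10 = np.log(10.0)


class TestSimulate:
    def test_zero_dose_stays_at_homeostasis(self, params_ones):
        traj = simulate(params_ones, InitialCondition(T_in=0.0))
        assert traj.outcome == "resolved"
        assert np.max(np.abs(traj.y)) == 0.0

    def test_medium_dose_resolves_with_interior_maxima(self, params_ones):
        traj = simulate(params_ones, InitialCondition(T_in=1.4), SolverConfig(t_end=100))
        assert np.all(np.abs(traj.y[-1]) < 1e-3)
        for name in ("M1", "M2", "E", "C", "F"):
            v = traj.component(name)
            i = int(np.argmax(v))
            assert 0 < i < v.size - 1, f"{name} has no interior maximum"
            assert v[i] > 0

    def test_decoupled_senescence_decays_exponentially(self):
        p = ModelParameters(K_T=0.0)
        traj = simulate(p, InitialCondition(T_in=5.0), SolverConfig(t_end=10))
        np.testing.assert_allclose(
            traj.component("T"), 5.0 * np.exp(-traj.t), rtol=1e-6, atol=1e-8
        )

    def test_supercritical_dose_hits_blowup_bound(self, params_ones):
        traj = simulate(params_ones, InitialCondition(T_in=2.7))
        assert traj.outcome == "unresolved"
        assert traj.blowup_hit
        assert traj.t[-1] < traj.config.t_end

    def test_first_state_equals_initial_condition(self, medium_traj):
        np.testing.assert_array_equal(medium_traj.y[0], [1.4, 0, 0, 0, 0, 0])
        assert medium_traj.t[0] == 0.0
        assert np.all(np.diff(medium_traj.t) > 0)

    def test_tidy_export_shape(self, medium_traj):
        df = medium_traj.to_frame()
        assert list(df.columns) == ["time", "variable", "value"]
        assert len(df) == 6 * medium_traj.t.size
        assert set(df["variable"]) == set(STATE_VARS)


class TestTrajectoryInvariants:
    @pytest.mark.parametrize("tin", [0.6, 1.4, 2.2])
    def test_senescence_strictly_decreasing(self, params_ones, tin):
        traj = simulate(params_ones, InitialCondition(T_in=tin))
        T = traj.component("T")
        tol = 10 * traj.config.atol
        assert np.all(np.diff(T) < tol)

    @pytest.mark.parametrize("tin", [0.6, 2.2])
    def test_exponential_dominance_bound(self, params_ones, tin):
        traj = simulate(params_ones, InitialCondition(T_in=tin))
        bound = tin * np.exp(-params_ones.D * traj.t) + 10 * traj.config.atol
        assert np.all(traj.component("T") <= bound)

    @pytest.mark.parametrize("tin", [0.6, 1.4, 2.2, 2.7])
    def test_componentwise_nonnegativity(self, params_ones, tin):
        traj = simulate(params_ones, InitialCondition(T_in=tin))
        assert np.min(traj.y) >= -10 * traj.config.atol

    @pytest.mark.parametrize("tin, expected", [(1.4, "resolved"), (2.7, "unresolved")])
    def test_classification_stable_under_tolerance_halving(self, params_ones, tin, expected):
        for cfg in (SolverConfig(), SolverConfig(rtol=5e-9, atol=5e-11)):
            assert simulate(params_ones, InitialCondition(T_in=tin), cfg).outcome == expected

    def test_resolved_runs_have_single_interior_maximum(self, params_ones):
        """Rise-then-fall shape: after its peak, each responder population
        never climbs back above the resolution band."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            tin = rng.uniform(0.2, 2.0)
            traj = simulate(params_ones, InitialCondition(T_in=tin))
            assert traj.outcome == "resolved"
            eps = traj.config.eps_res
            for name in ("M1", "M2", "E", "C", "F"):
                v = traj.component(name)
                after = v[int(np.argmax(v)):]
                assert np.all(np.diff(after) <= eps)


class TestClassifyOutcome:
    def test_examples(self, params_ones):
        cfg = SolverConfig(t_end=200)
        assert simulate(params_ones, InitialCondition(1.4), cfg).outcome == "resolved"
        assert simulate(params_ones, InitialCondition(0.0), cfg).outcome == "resolved"
        assert simulate(params_ones, InitialCondition(2.7), cfg).outcome == "unresolved"

    def test_short_horizon_is_undetermined_not_misclassified(self, params_ones):
        traj = simulate(params_ones, InitialCondition(T_in=1.4), SolverConfig(t_end=5))
        assert classify_outcome(traj) == "undetermined"


class TestClearanceTime:
    @pytest.mark.parametrize("D, tin", [(1.0, 0.5), (1.0, 1.5), (2.0, 1.0)])
    def test_closed_form_limit_without_macrophage_clearance(self, D, tin):
        p = ModelParameters(K_T=0.0, D=D)
        traj = simulate(p, InitialCondition(T_in=tin), SolverConfig(t_end=50))
        assert clearance_time(traj) == pytest.approx(LN10 / D, abs=1e-3)

    def test_macrophage_clearance_only_accelerates(self, params_ones, medium_traj):
        # comparison against the K_T = 0 closed form: M2-mediated removal
        # can only shorten the clearance time
        assert clearance_time(medium_traj) < LN10

    def test_horizon_too_short_raises(self, params_ones):
        traj = simulate(params_ones, InitialCondition(T_in=1.4), SolverConfig(t_end=0.5))
        with pytest.raises(HorizonTooShortError):
            clearance_time(traj)

    def test_requires_positive_dose(self, params_ones):
        traj = simulate(params_ones, InitialCondition(T_in=0.0))
        with pytest.raises(ValueError):
            clearance_time(traj)


class TestPeakSummary:
    def test_zero_dose_all_peaks_zero(self, params_ones):
        peaks = simulate(params_ones, InitialCondition(0.0))
        df = peak_summary(peaks)
        assert np.all(df["peak"] == 0.0) and np.all(df["peak_time"] == 0.0)

    def test_senescence_peak_is_the_dose_at_time_zero(self, medium_traj):
        row = peak_summary(medium_traj).set_index("variable").loc["T"]
        assert row["peak"] == 1.4 and row["peak_time"] == 0.0

    def test_macrophage_peaks_increase_with_dose(self, params_ones):
        peaks = []
        for tin in (0.6, 1.4, 2.2):
            traj = simulate(params_ones, InitialCondition(tin))
            df = peak_summary(traj).set_index("variable")
            peaks.append(df.loc["M1", "peak"])
        assert peaks[0] < peaks[1] < peaks[2]


class TestConvergence:
    def test_tolerance_refinement_gap_is_small(self, params_ones):
        gap = check_convergence(params_ones, InitialCondition(1.4), SolverConfig(t_end=50))
        assert gap < 1e-5

    def test_zero_dose_gap_is_exactly_zero(self, params_ones):
        assert check_convergence(params_ones, InitialCondition(0.0)) == 0.0
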