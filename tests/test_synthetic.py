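"""Synthetic cohort generator: calibration, structure, noise and summaries."""

import numpy as np
import pandas as pd
import pytest

from senoliv import (
    DesignConfig,
    ModelParameters,
    SolverConfig,
    calibrate_marker_map,
    calibrate_time_scale,
    generate_dataset,
    summarize,
)
from senoliv.synthetic import DEFAULT_GROUPS


@pytest.fixture(scope="module")
def noiseless():
    """CV = 0 dataset: observations equal the model curves exactly."""
    design = DesignConfig(cv={"p21": 0.0}, default_cv=0.0, seed=1)
    return generate_dataset(design=design)


@pytest.fixture(scope="module")
def noisy():
    return generate_dataset(design=DesignConfig(seed=11, default_cv=0.2, cv={"p21": 0.2}))


class TestCalibration:
    def test_time_scale_resolves_severe_dose_by_final_day(self):
        s = calibrate_time_scale()
        assert s > 0
        # the severe-trajectory magnitude at day 14 sits an order of
        # magnitude inside the resolution band
        from senoliv import InitialCondition, simulate

        traj = simulate(ModelParameters(), InitialCondition(T_in=2.2))
        assert np.max(np.abs(traj.at(14.0 / s))) <= SolverConfig().eps_res / 10 * 1.01

    def test_p21_anchor_reproduced_exactly_without_noise(self, noiseless):
        d = noiseless.data
        val = d[(d.group == "moderate") & (d.day == 7) & (d.marker == "p21")]["fold_change"]
        assert np.allclose(val, 114.6)

    def test_cd80_anchor_and_dose_pattern(self, noiseless):
        d = noiseless.data
        cd80 = {
            g: d[(d.group == g) & (d.day == 3) & (d.marker == "CD80")]["fold_change"].iloc[0]
            for g in ("mild", "moderate", "severe")
        }
        assert cd80["moderate"] == pytest.approx(30.0, rel=1e-9)
        # the calibrated generator reproduces the ~10/30/100-fold tiering
        assert 5 < cd80["mild"] < 15
        assert 80 < cd80["severe"] < 160

    def test_every_model_variable_carries_a_marker(self):
        mm = calibrate_marker_map()
        assert {mm.variable(m) for m in mm.names} == {"T", "M1", "M2", "E", "C", "F"}
        assert all(mm.gain(m) > 0 for m in mm.names)


class TestGenerateDataset:
    def test_record_count_and_schema(self, noisy):
        design, mm = noisy.design, noisy.marker_map
        expected = len(design.groups) * len(design.days) * design.n_animals * len(mm.names)
        assert len(noisy.data) == expected
        assert list(noisy.data.columns) == ["group", "day", "animal", "marker", "fold_change"]

    def test_all_fold_changes_positive(self, noisy):
        assert (noisy.data["fold_change"] > 0).all()

    def test_control_group_is_exactly_baseline_without_noise(self, noiseless):
        ctrl = noiseless.data[noiseless.data.group == "control"]
        assert np.allclose(ctrl["fold_change"], 1.0)

    def test_same_seed_identical_different_seed_not(self):
        design = DesignConfig(seed=5)
        a = generate_dataset(design=design).data
        b = generate_dataset(design=design).data
        c = generate_dataset(design=DesignConfig(seed=6)).data
        pd.testing.assert_frame_equal(a, b)
        assert not a["fold_change"].equals(c["fold_change"])

    def test_supercritical_group_rejected(self):
        design = DesignConfig(groups={"lethal": 3.0})
        with pytest.raises(ValueError, match="supercritical"):
            generate_dataset(design=design)

    def test_day_beyond_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            generate_dataset(
                design=DesignConfig(time_scale=0.4),
                cfg=SolverConfig(t_end=10.0),
            )

    def test_group_means_concentrate_on_noiseless_values(self):
        """Monte-Carlo contract of the log-normal noise model: across
        replicate cohorts the group mean stays within 3 SEM-scale bands of
        the noiseless value (allowing the log-normal mean-median offset)."""
        design_base = DesignConfig(
            groups={"moderate": 1.4}, days=(3,), n_animals=4, default_cv=0.3,
            cv={}, time_scale=0.4,
        )
        mm = calibrate_marker_map(design=DesignConfig(time_scale=0.4))
        first = generate_dataset(design=design_base, marker_map=mm)
        trajs = first.trajectories
        curves = first.curves.set_index("marker")["value"]
        cv, n = 0.3, 4
        # lognormal(median=v): E = v*sqrt(1+cv^2); include it in the center
        center = curves * np.sqrt(1 + cv**2)
        sem = cv * curves / np.sqrt(n)
        hits = []
        for seed in range(200):
            ds = generate_dataset(
                design=DesignConfig(**{**design_base.__dict__, "seed": seed}),
                marker_map=mm,
                trajectories=trajs,
            )
            means = ds.data.groupby("marker")["fold_change"].mean().reindex(center.index)
            hits.append((np.abs(means - center) <= 3 * sem).all())
        assert np.mean(hits) > 0.9


class TestStructure:
    def test_responder_curves_rise_and_resolve(self, noiseless):
        curves = noiseless.curves
        for (g, m), grp in curves[curves.marker != "p21"].groupby(["group", "marker"]):
            if g == "control":
                continue
            by_day = grp.set_index("day")["value"]
            assert by_day.max() > 1.0
            assert by_day.loc[14] < 1.05, (g, m)

    def test_senescence_curve_monotone_decreasing(self, noiseless):
        curves = noiseless.curves
        for g in ("mild", "moderate", "severe"):
            p21 = curves[(curves.group == g) & (curves.marker == "p21")]
            v = p21.sort_values("day")["value"].to_numpy()
            assert np.all(np.diff(v) < 0), g

    def test_noiseless_dose_ordering_at_peak_day(self, noiseless):
        curves = noiseless.curves
        for m in noiseless.marker_map.names:
            if noiseless.marker_map.variable(m) == "T":
                continue  # senescent pool ordering is clearance-dominated
            sub = curves[curves.marker == m]
            peak_day = sub[sub.group == "severe"].sort_values("value").iloc[-1]["day"]
            at_peak = sub[sub.day == peak_day].set_index("group")["value"]
            assert at_peak["severe"] > at_peak["moderate"] > at_peak["mild"], m


class TestSummarize:
    def test_hand_computed_sem(self):
        df = pd.DataFrame(
            {
                "group": "g", "day": 3, "animal": ["a", "b", "c"],
                "marker": "m", "fold_change": [1.0, 2.0, 3.0],
            }
        )
        out = summarize(df)
        assert out["mean"].iloc[0] == pytest.approx(2.0)
        assert out["sem"].iloc[0] == pytest.approx(1.0 / np.sqrt(3))
        assert out["n"].iloc[0] == 3

    def test_identical_values_give_zero_sem(self):
        df = pd.DataFrame(
            {"group": "g", "day": 3, "animal": ["a", "b"], "marker": "m",
             "fold_change": [4.2, 4.2]}
        )
        assert summarize(df)["sem"].iloc[0] == 0.0

    def test_single_animal_flagged(self):
        df = pd.DataFrame(
            {"group": "g", "day": 3, "animal": ["a"], "marker": "m", "fold_change": [1.5]}
        )
        out = summarize(df)
        assert not out["sem_defined"].iloc[0]

    def test_deterministic_in_seed(self, noisy):
        a = summarize(noisy)
        b = summarize(generate_dataset(design=noisy.design))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=["group", "day", "marker", "fold_change"]))
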