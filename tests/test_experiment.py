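"""Closed-loop orchestration: seeding, determinism, volume bookkeeping,
effluent assays and fixtures."""

import numpy as np
import pytest

from morbidosim import (
    ControllerConfig,
    ExperimentConfig,
    GrowthModel,
    PumpKind,
    StrainPhenotype,
    assay_mixture,
    detect_growth_phases,
    fit_hill,
    generate_fixtures,
    resistance_trajectory,
    run_experiment,
    write_logs,
)


def short_config(seed=0, duration=6.0, **kwargs):
    return ExperimentConfig(
        n_units=1, duration_h=duration, seed=seed,
        growth=GrowthModel(mode="stochastic", seed=seed), **kwargs
    )


class TestRunExperiment:
    def test_duration_shorter_than_cycle_logs_single_reading(self):
        config = short_config(duration=0.1)  # cycle is 12 min = 0.2 h
        result = run_experiment(config)
        assert len(result.unit_logs[0]) == 1
        assert result.events.empty

    def test_volume_constant_after_every_cycle(self):
        result = run_experiment(short_config(duration=4.0))
        np.testing.assert_allclose(result.unit_logs[0]["volume_ml"], 12.0)

    def test_od_never_exceeds_carrying_capacity(self):
        result = run_experiment(short_config(duration=12.0))
        assert result.unit_logs[0]["od_total"].max() <= 1.0 + 1e-9

    def test_same_seed_reproduces_logs(self):
        a = run_experiment(short_config(seed=3))
        b = run_experiment(short_config(seed=3))
        assert a.unit_logs[0].equals(b.unit_logs[0])
        assert a.events.equals(b.events)

    def test_unit_trajectory_independent_of_unit_count(self):
        solo = run_experiment(ExperimentConfig(n_units=1, duration_h=3.0, seed=5))
        trio = run_experiment(ExperimentConfig(n_units=3, duration_h=3.0, seed=5))
        assert solo.unit_logs[0].equals(trio.unit_logs[0])

    def test_replicate_units_differ_but_resemble(self):
        result = run_experiment(ExperimentConfig(n_units=3, duration_h=6.0, seed=2))
        finals = [log["od_total"].iloc[-1] for log in result.unit_logs.values()]
        assert len({round(f, 12) for f in finals}) == 3  # distinct trajectories
        assert np.std(finals) / np.mean(finals) < 0.5  # statistically similar

    def test_selective_fires_soon_after_threshold_crossing(self):
        result = run_experiment(short_config(seed=1, duration=12.0))
        events = result.events
        log = result.unit_logs[0]
        theta = ControllerConfig().od_threshold
        crossing = log[(log["od_est"] > theta)]
        sel = events[events["decision"] == "selective"]
        assert not sel.empty
        # first drug addition within 2 cycles of the first rising crossing
        first_cross = crossing["time_h"].iloc[0]
        assert sel["time_h"].iloc[0] <= first_cross + 2 * 0.2 + 1e-9

    def test_selective_only_when_rule_satisfied(self):
        result = run_experiment(short_config(seed=4, duration=20.0))
        sel = result.events[result.events["decision"] == "selective"]
        theta = ControllerConfig().od_threshold
        assert (sel["od_at_decision"] > theta).all()
        assert (sel["growth_rate_per_h"] > 0).all()

    def test_susceptible_only_culture_gets_knocked_down(self):
        # large kill rate, no mutation: drug pressure rises, growth stops,
        # drug additions cease while the density declines
        config = short_config(seed=0, duration=24.0)
        config.growth = GrowthModel(mode="deterministic", mutation_rate=0.0,
                                    kill_rate=1.0)
        result = run_experiment(config)
        log = result.unit_logs[0]
        events = result.events
        sel_times = events[events["decision"] == "selective"]["time_h"]
        assert not sel_times.empty
        assert log["drug_ugml"].max() > 2.0
        # in the hour after peak drug pressure no drug is added (growth has
        # stopped) and the density is falling
        t_peak = log.loc[log["drug_ugml"].idxmax(), "time_h"]
        window = log[(log["time_h"] >= t_peak) & (log["time_h"] <= t_peak + 1.0)]
        sel_in_window = sel_times[(sel_times > t_peak) & (sel_times <= t_peak + 1.0)]
        assert sel_in_window.empty
        assert window["od_total"].iloc[-1] < window["od_total"].iloc[0]


class TestSampling:
    def test_samples_taken_on_schedule(self):
        config = short_config(duration=25.0)
        config.sampling_interval_h = 12.0
        result = run_experiment(config)
        times = [t for t, _ in result.samples[0]]
        assert times == pytest.approx([0.0, 12.0, 24.0], abs=1e-6)

    def test_ancestral_sample_composition(self, ancestor):
        result = run_experiment(short_config(duration=1.0))
        t0, comp = result.samples[0][0]
        assert t0 == 0.0
        assert list(comp) == [ancestor]


class TestAssay:
    def test_endpoint_ic50_orders_phenotypes(self, model):
        fits = []
        for ic50 in (4.0, 8.0, 16.0):
            plate = assay_mixture({StrainPhenotype(1.0, ic50, 2.0): 1.0}, model)
            fits.append(fit_hill(plate))
        assert fits[0].ic50 < fits[1].ic50 < fits[2].ic50
        # ancestral endpoint IC50 lands near the strain's pharmacodynamic IC50
        assert 2.0 < fits[0].ic50 < 8.0

    def test_mixture_shifts_toward_resistant(self, model):
        sens = StrainPhenotype(1.0, 4.0, 2.0)
        res = StrainPhenotype(1.0, 16.0, 2.0)
        pure = fit_hill(assay_mixture({sens: 1.0}, model))
        mixed = fit_hill(assay_mixture({sens: 0.9, res: 0.1}, model))
        assert mixed.ic50 > pure.ic50

    def test_empty_sample_rejected(self, model):
        with pytest.raises(ValueError):
            assay_mixture({}, model)

    def test_trajectory_assembly(self):
        config = short_config(seed=1, duration=25.0)
        result = run_experiment(config)
        table, fits = resistance_trajectory(result, 0)
        assert list(table.columns) == ["time_h", "ic50_ugml", "ic50_var", "converged"]
        assert len(table) == 3
        assert table["converged"].all()


class TestPhaseDetection:
    def test_pure_logistic_has_no_decline(self):
        t = np.linspace(0, 20, 200)
        od = 1.0 * 0.01 * np.exp(t) / (1.0 + 0.01 * (np.exp(t) - 1.0))
        phases = detect_growth_phases(t, od)
        assert phases["expanded"] and not phases["declined"]

    def test_knockdown_with_recovery_detected(self):
        t = np.linspace(0, 30, 300)
        od = np.where(t < 10, 0.02 * np.exp(0.5 * t),
                      np.where(t < 20, 0.02 * np.exp(5) * np.exp(-0.3 * (t - 10)),
                               0.02 * np.exp(5) * np.exp(-3) * np.exp(0.4 * (t - 20))))
        phases = detect_growth_phases(t, od)
        assert phases == {"expanded": True, "declined": True, "rebounded": True}


class TestConfigAndFixtures:
    def test_yaml_round_trip(self, tmp_path):
        config = ExperimentConfig(n_units=2, duration_h=10.0, seed=9)
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        again = ExperimentConfig.from_yaml(path)
        assert again == config

    def test_fixtures_byte_identical_for_same_seed(self, tmp_path):
        for kind in ("calibration", "plate"):
            a = generate_fixtures(kind, 7, tmp_path / "a")
            b = generate_fixtures(kind, 7, tmp_path / "b")
            for pa, pb in zip(a, b):
                assert pa.read_bytes() == pb.read_bytes()
            c = generate_fixtures(kind, 8, tmp_path / "c")
            assert c[0].read_bytes() != a[0].read_bytes()

    def test_calibration_fixture_linear_fit_quality(self, tmp_path):
        from morbidosim.sensor import fit_calibration, read_calibration_csv

        (path,) = generate_fixtures("calibration", 0, tmp_path)
        volts, od = read_calibration_csv(path)
        mask = od <= 0.3
        curve = fit_calibration(od[mask], volts[mask], 1)
        assert curve.r_squared > 0.95

    def test_plate_fixture_recovers_truth(self, tmp_path):
        from morbidosim.doseresponse import read_plate_csv

        (path,) = generate_fixtures("plate", 0, tmp_path)
        fit = fit_hill(read_plate_csv(path))
        assert fit.ic50 == pytest.approx(4.0, rel=0.25)

    def test_write_logs_complete(self, tmp_path):
        result = run_experiment(short_config(duration=2.0))
        paths = write_logs(result, tmp_path)
        names = {p.name for p in paths}
        assert "unit0.csv" in names and "events.csv" in names
        assert "calibration_unit0.json" in names
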