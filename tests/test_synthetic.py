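import numpy as np
import pytest

from pbpkddi.engine import DosingRegimen, one_compartment_system, simulate
from pbpkddi.network import TrialSpec
from pbpkddi.synthetic import (FitModel, NoiseModel, fit_parameters,
                               generate_noncompliance_caffeine,
                               generate_observed, synthetic_observed_ratios,
                               trial_fit_model)
from pbpkddi.metrics import DDIRatios


@pytest.fixture(scope="module")
def onecomp_sim():
    sys = one_compartment_system(10.0, 0.1, [(0.0, 100.0)])
    return simulate(sys, 1440.0, np.linspace(0, 1440, 481))


SCHEDULE = [10.0, 30.0, 60.0, 120.0, 240.0, 480.0, 720.0, 1080.0]


class TestGenerateObserved:
    def test_zero_noise_single_subject_matches_model(self, onecomp_sim):
        noise = NoiseModel(proportional_cv=0.0, seed=1)
        ds = generate_observed(onecomp_sim, SCHEDULE, noise, 1)
        expected = np.interp(SCHEDULE, onecomp_sim.time,
                             onecomp_sim.plasma("drug"))
        assert np.allclose(ds.data.concentration, expected)
        assert not ds.data.blq.any()

    def test_empirical_cv_matches_nominal(self, onecomp_sim):
        noise = NoiseModel(proportional_cv=0.2, seed=11)
        ds = generate_observed(onecomp_sim, SCHEDULE, noise, 1000)
        for t, group in ds.data.groupby("time"):
            cv = group.concentration.std() / group.concentration.mean()
            assert 0.18 < cv < 0.22

    def test_lloq_above_cmax_flags_everything(self, onecomp_sim):
        noise = NoiseModel(proportional_cv=0.1, lloq=1e6, seed=2)
        ds = generate_observed(onecomp_sim, SCHEDULE, noise, 3)
        assert ds.data.blq.all()
        assert (ds.data.concentration == 1e6).all()

    def test_lloq_censoring_never_negative(self, onecomp_sim):
        noise = NoiseModel(proportional_cv=0.5, lloq=0.05, seed=3)
        ds = generate_observed(onecomp_sim, SCHEDULE, noise, 50)
        assert (ds.data.concentration >= 0.05).all()

    def test_same_seed_identical_bytes(self, onecomp_sim):
        noise = NoiseModel(proportional_cv=0.2, seed=5)
        a = generate_observed(onecomp_sim, SCHEDULE, noise, 10).csv_bytes()
        b = generate_observed(onecomp_sim, SCHEDULE, noise, 10).csv_bytes()
        assert a == b
        c = generate_observed(
            onecomp_sim, SCHEDULE,
            noise.model_copy(update={"seed": 6}), 10).csv_bytes()
        assert a != c

    def test_schedule_outside_span_rejected(self, onecomp_sim):
        noise = NoiseModel(seed=1)
        with pytest.raises(ValueError, match="span"):
            generate_observed(onecomp_sim, [10.0, 2000.0], noise, 1)

    def test_iiv_scaling_approximation_spreads_subjects(self, onecomp_sim):
        noise = NoiseModel(proportional_cv=0.0, seed=4,
                           iiv_cvs={"CL": 0.3})
        ds = generate_observed(onecomp_sim, SCHEDULE, noise, 200)
        first = ds.data[ds.data.time == SCHEDULE[0]].concentration
        assert first.std() / first.mean() > 0.2

    def test_truth_sidecar_written(self, onecomp_sim, tmp_path):
        noise = NoiseModel(seed=1)
        ds = generate_observed(onecomp_sim, SCHEDULE, noise, 1,
                               true_parameters={"CL": 0.1})
        out = tmp_path / "obs.csv"
        ds.to_csv(out)
        assert out.exists()
        assert (tmp_path / "obs.csv.truth.json").exists()


class TestSyntheticRatios:
    def test_seeded_lognormal_perturbation(self):
        pred = {"a": DDIRatios(auc_ratio=2.0, cmax_ratio=1.5)}
        obs1 = synthetic_observed_ratios(pred, 0.2, 7)
        obs2 = synthetic_observed_ratios(pred, 0.2, 7)
        assert obs1 == obs2
        assert obs1["a"][0] != 2.0  # noise applied
        assert 0.5 < obs1["a"][0] / 2.0 < 2.0


class TestNoncompliance:
    def spec(self):
        return TrialSpec(
            name="caffeine-noncompliance",
            victim=[DosingRegimen(drug="caffeine", route="oral",
                                  dose="150 mg", times=[720.0])],
            t_end=1440.0, n_grid=481)

    def test_zero_background_gives_zero_predose(self, library):
        noise = NoiseModel(proportional_cv=0.0, seed=1)
        ds = generate_noncompliance_caffeine(
            self.spec(), library, 0.0, [600.0, 700.0, 780.0, 900.0], noise)
        predose = ds.data[ds.data.time < 720.0].concentration
        assert (predose == 0.0).all()

    def test_positive_background_gives_positive_trough(self, library):
        noise = NoiseModel(proportional_cv=0.0, seed=1)
        ds = generate_noncompliance_caffeine(
            self.spec(), library, 0.05, [600.0, 700.0, 780.0, 900.0], noise)
        predose = ds.data[ds.data.time < 720.0].concentration
        assert (predose > 0.0).all()
        assert ds.true_parameters["background_rate_umol_min"] == 0.05

    def test_non_dietary_victim_rejected(self, library):
        spec = TrialSpec(name="x", victim=[DosingRegimen(
            drug="tizanidine", route="oral", dose="4 mg", times=[0.0])],
            t_end=720.0)
        with pytest.raises(ValueError, match="dietary"):
            generate_noncompliance_caffeine(spec, library, 0.1, [60.0],
                                            NoiseModel(seed=1))

    def test_background_rate_recovered(self, library):
        # hypothesis-testing use case: estimate the hidden dietary intake
        truth = 0.05
        noise = NoiseModel(proportional_cv=0.1, seed=9)
        schedule = [480.0, 600.0, 700.0, 760.0, 840.0, 960.0, 1140.0, 1380.0]
        ds = generate_noncompliance_caffeine(self.spec(), library, truth,
                                             schedule, noise, n_subjects=8)
        model = trial_fit_model(
            self.spec(), library, ds,
            {"background_rate": (0.005, 0.5)}, arm="alone",
            background_rate_handle="background_rate")
        fit = fit_parameters(ds, model)
        assert fit.estimates["background_rate"] == pytest.approx(truth,
                                                                 rel=0.15)


def analytic_onecomp_model(times, dose=100.0, volume=10.0,
                           bounds=None) -> FitModel:
    """Closed-form one-compartment prediction; CL is the free parameter."""
    times = np.asarray(times, dtype=float)

    def predict(params):
        cl = params["CL"]
        return dose / volume * np.exp(-cl / volume * times)

    return FitModel(predict=predict, bounds=bounds or {"CL": (0.01, 1.0)})


class TestFitParameters:
    def test_zero_noise_recovers_truth_exactly(self, onecomp_sim):
        noise = NoiseModel(proportional_cv=0.0, seed=1)
        ds = generate_observed(onecomp_sim, SCHEDULE, noise, 1)
        times = ds.data.time.to_numpy()
        fit = fit_parameters(ds, analytic_onecomp_model(times))
        assert fit.estimates["CL"] == pytest.approx(0.1, rel=1e-4)
        assert fit.success and not fit.non_identifiable

    def test_bias_shrinks_with_noise_and_sample_size(self, onecomp_sim):
        def err(cv, n, seed=21):
            noise = NoiseModel(proportional_cv=cv, seed=seed)
            ds = generate_observed(onecomp_sim, SCHEDULE, noise, n)
            times = ds.data.time.to_numpy()
            fit = fit_parameters(ds, analytic_onecomp_model(times))
            return abs(np.log(fit.estimates["CL"] / 0.1))
        assert err(0.05, 12) < err(0.4, 12)
        assert err(0.4, 96) < err(0.4, 3)

    def test_confounded_parameters_flagged(self, onecomp_sim):
        # dose and volume only enter through their ratio: unidentifiable
        noise = NoiseModel(proportional_cv=0.05, seed=13)
        ds = generate_observed(onecomp_sim, SCHEDULE, noise, 4)
        times = ds.data.time.to_numpy()

        def predict(params):
            return (params["Dose"] / 10.0 * params["Scale"]
                    * np.exp(-0.01 * times))

        model = FitModel(predict=predict, bounds={"Dose": (10.0, 1000.0),
                                                  "Scale": (0.1, 10.0)})
        fit = fit_parameters(ds, model)
        assert fit.non_identifiable
        corr = abs(fit.correlation.loc["Dose", "Scale"])
        assert np.isnan(corr) or corr > 0.99

    def test_blq_rows_excluded(self, onecomp_sim):
        noise = NoiseModel(proportional_cv=0.0, lloq=0.5, seed=1)
        ds = generate_observed(onecomp_sim, SCHEDULE, noise, 1)
        assert ds.data.blq.any() and not ds.data.blq.all()
        times = ds.data.time.to_numpy()
        fit = fit_parameters(ds, analytic_onecomp_model(times))
        assert fit.n_obs == int((~ds.data.blq).sum())
        assert fit.estimates["CL"] == pytest.approx(0.1, rel=1e-3)

    def test_infinite_bounds_rejected(self, onecomp_sim):
        noise = NoiseModel(proportional_cv=0.0, seed=1)
        ds = generate_observed(onecomp_sim, SCHEDULE, noise, 1)
        model = analytic_onecomp_model(ds.data.time.to_numpy(),
                                       bounds={"CL": (0.0, np.inf)})
        with pytest.raises(ValueError, match="finite"):
            fit_parameters(ds, model)
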