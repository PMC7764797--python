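import numpy as np
import pytest

from pbpkddi.drugs import Inhibition, ki_for_pair
from pbpkddi.engine import DosingRegimen
from pbpkddi.network import (DrugLibrary, TrialSpec, compare_mechanisms,
                             default_qualification_network, load_trial_spec,
                             qualify_network, run_trial,
                             trial_sensitivity_task)
from pbpkddi.sensitivity import sensitivity_coefficient


def oral(drug, dose, times):
    return DosingRegimen(drug=drug, route="oral", dose=dose, times=times)


def small_spec(perp_dose="50 mg", phenotypes=None, **kw):
    """Compact fluvoxamine→esomeprazole trial (perpetrator to steady state,
    single victim dose, 12 h victim window)."""
    defaults = dict(
        name="fluvoxamine-esomeprazole",
        victim=[oral("esomeprazole", "20 mg", [1440.0])],
        perpetrator=[oral("fluvoxamine", perp_dose, [0.0, 720.0, 1440.0])],
        phenotypes=phenotypes or {},
        t_end=2160.0, n_grid=721, endpoint_interval=(1440.0, 2160.0),
        victim_substrate="omeprazole")
    defaults.update(kw)
    return TrialSpec(**defaults)


class TestRunTrial:
    def test_em_interaction_raises_exposure(self, library):
        res = run_trial(small_spec(), library)
        assert res.ratios.auc_ratio > 1.5
        assert res.ratios.cmax_ratio > 1.0
        assert res.alone.mass_balance_rel_error < 1e-3
        assert res.combo.mass_balance_rel_error < 1e-3

    def test_poor_metabolizer_sees_no_interaction(self, library):
        # no CYP2C19 activity: a pure CYP2C19 inhibitor cannot change
        # exposure; the CYP3A4 pathway is untouched
        lib = DrugLibrary([library.get(n) for n in library.names()])
        pure = library.get("fluvoxamine").with_inhibitions(
            ki_for_pair("fluvoxamine", "omeprazole"))
        lib.add(pure)
        res = run_trial(small_spec(phenotypes={"CYP2C19": 0.0},
                                   use_pair_ki=False), lib)
        assert res.ratios.auc_ratio == pytest.approx(1.0, abs=5e-3)
        assert res.ratios.cmax_ratio == pytest.approx(1.0, abs=5e-3)

    def test_zero_perpetrator_dose_gives_unity_ratios(self, library):
        res = run_trial(small_spec(perp_dose=0.0), library)
        assert res.ratios.auc_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.ratios.cmax_ratio == pytest.approx(1.0, abs=1e-6)

    def test_removing_inhibitions_forces_unity(self, library):
        # no hidden coupling besides the declared inhibition entries
        lib = DrugLibrary([library.get(n) for n in library.names()])
        lib.add(library.get("fluvoxamine").with_inhibitions([]))
        spec = small_spec(use_pair_ki=False)
        with pytest.warns(RuntimeWarning, match="inhibits none"):
            res = run_trial(spec, lib)
        assert res.ratios.auc_ratio == pytest.approx(1.0, abs=1e-6)

    def test_pair_ki_override_applies_table_constant(self, library):
        on = run_trial(small_spec(), library)
        off = run_trial(small_spec(use_pair_ki=False), library)
        # drug-file default and pair constant coincide for this pair
        assert on.ratios.auc_ratio == pytest.approx(off.ratios.auc_ratio,
                                                    rel=1e-6)

    def test_deterministic_and_unaliased(self, library):
        a = run_trial(small_spec(), library)
        b = run_trial(small_spec(), library)
        assert a.ratios == b.ratios
        assert np.array_equal(a.combo.states, b.combo.states)


class TestQualificationNetwork:
    def test_eleven_pairs_with_category_counts(self):
        specs = default_qualification_network()
        assert len(specs) == 11
        cats = [s.category for s in specs]
        assert cats.count("strong CYP2C19") == 2
        assert cats.count("strong CYP1A2") == 3
        assert cats.count("moderate CYP2C19") == 2
        assert cats.count("moderate CYP1A2") == 4

    def test_report_structure_and_prediction_only_status(self, library):
        specs = default_qualification_network()[:2]
        report = qualify_network(specs, observed={specs[0].name: (2.0, 1.2)},
                                 library=library)
        assert list(report.frame["pair"]) == [s.name for s in specs]
        assert report.frame.status.tolist() == ["compared",
                                                "prediction-only"]

    def test_synthetic_observed_equal_to_predicted_passes(self, library):
        specs = default_qualification_network()[:1]
        pred = qualify_network(specs, library=library)
        obs = {name: (r.ratios.auc_ratio, r.ratios.cmax_ratio)
               for name, r in pred.results.items()}
        report = qualify_network(specs, observed=obs, library=library)
        assert report.overall_pass
        assert np.allclose(report.frame.pred_obs_auc, 1.0)

    def test_byte_identical_reports(self, library):
        specs = default_qualification_network()[:1]
        a = qualify_network(specs, library=library).frame.to_csv()
        b = qualify_network(specs, library=library).frame.to_csv()
        assert a.encode() == b.encode()


class TestCompareMechanisms:
    def test_identical_variants_tie_in_input_order(self, library):
        inhs = ki_for_pair("fluvoxamine", "omeprazole")
        spec = small_spec(use_pair_ki=False)
        df = compare_mechanisms(spec, [("first", inhs), ("second", inhs)],
                                observed_auc_r=2.0, library=library)
        assert df.variant.tolist() == ["first", "second"]
        assert df.fit_metric.iloc[0] == df.fit_metric.iloc[1]

    def test_needs_two_variants(self, library):
        with pytest.raises(ValueError, match="2 mechanism"):
            compare_mechanisms(small_spec(), [("only", [])],
                               observed_auc_r=1.0, library=library)


class TestSensitivityBridge:
    def test_dose_proportionality_through_trial_task(self, library):
        spec = TrialSpec(name="caffeine-alone",
                         victim=[oral("caffeine", "150 mg", [0.0])],
                         t_end=1440.0, n_grid=481)
        task = trial_sensitivity_task(
            spec, library, parameters=["regimen:caffeine/dose"])
        s, _ = sensitivity_coefficient(task, "regimen:caffeine/dose", "AUC",
                                       deltas=(-0.1, 0.1))
        assert s == pytest.approx(1.0, abs=1e-3)


class TestSpecIO:
    def test_yaml_round_trip(self, tmp_path, library):
        path = tmp_path / "trial.yaml"
        path.write_text(
            "name: example\n"
            "victim:\n"
            "  - {drug: caffeine, route: oral, dose: 150 mg, times: [1440]}\n"
            "perpetrator:\n"
            "  - {drug: fluvoxamine, route: oral, dose: 50 mg,\n"
            "     times: [0, 720, 1440]}\n"
            "phenotypes: {}\n"
            "t_end: 2880\n"
            "endpoint_interval: [1440, 2880]\n"
            "victim_substrate: caffeine\n")
        spec = load_trial_spec(path)
        assert spec.victim[0].drug == "caffeine"
        assert spec.endpoint_interval == (1440.0, 2880.0)

    def test_sampling_must_cover_endpoint_and_doses(self):
        with pytest.raises(ValueError, match="sampled span"):
            small_spec(t_end=1000.0)
        with pytest.raises(ValueError, match="cover all dose events"):
            small_spec(t_end=1200.0, endpoint_interval=(720.0, 1200.0))
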