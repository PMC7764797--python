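import numpy as np
import pytest

from pbpkddi.drugs import Absorption, Inhibition, Pathway
from pbpkddi.engine import (DosingRegimen, SolverSettings, assemble,
                            enzyme_turnover_rate, metabolic_rate,
                            one_compartment_system, simulate)
from pbpkddi.metrics import compute_metrics
from pbpkddi.physiology import scale_gut_expression

from conftest import iv, make_probe, oral, run


class TestMetabolicRate:
    def test_linear_definition(self):
        pw = Pathway(enzyme="CYP1A2", kinetics="linear", cl_int=0.5)
        assert metabolic_rate(pw, 1.0, 1.0) == pytest.approx(0.5)

    def test_competitive_inhibitor_at_ki_halves_linear_rate(self):
        pw = Pathway(enzyme="CYP1A2", kinetics="linear", cl_int=0.5)
        assert metabolic_rate(pw, 1.0, 1.0, [(2.0, 2.0)]) == pytest.approx(
            0.25)

    def test_saturable_limit_is_vmax_independent_of_inhibitor(self):
        pw = Pathway(enzyme="CYP2D6", kinetics="saturable", vmax=2.0, km=0.1)
        rate = metabolic_rate(pw, 1e6, 3.0, [(10.0, 1.0)])
        assert rate == pytest.approx(6.0, rel=1e-4)

    def test_unspecific_insensitive_to_inhibitors(self):
        pw = Pathway(enzyme="UNSPECIFIC", kinetics="unspecific_hepatic",
                     cl_apparent=0.2)
        assert metabolic_rate(pw, 2.0, 0.0, [(100.0, 1.0)]) == pytest.approx(
            0.4)

    def test_negative_concentration_rejected(self):
        pw = Pathway(enzyme="CYP1A2", kinetics="linear", cl_int=0.5)
        with pytest.raises(ValueError):
            metabolic_rate(pw, -1.0, 1.0)


class TestEnzymeTurnover:
    def test_baseline_steady_state(self):
        assert enzyme_turnover_rate(2.0, 2.0, 1e-3) == 0.0

    def test_integrator_converges_to_closed_form(self, individual):
        # clamped inhibitor: E_ss = E0·kdeg/(kdeg + kinact·I/(KI+I))
        kdeg, kinact, k_i, i_u = 4.4e-4, 0.02, 0.5, 0.25
        victim = make_probe(enzyme="CYP2C19", cl_int=0.01)
        sys = assemble(individual, [victim], [iv("probe", 1.0)],
                       constant_tdi={"CYP2C19": [(i_u, kinact, k_i)]})
        res = simulate(sys, 40000.0, np.linspace(0, 40000, 401))
        e_end = res.enzyme_fraction("CYP2C19", "liver")[-1]
        e_ss = kdeg / (kdeg + kinact * i_u / (k_i + i_u))
        assert e_end == pytest.approx(e_ss, rel=1e-3)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            enzyme_turnover_rate(-1.0, 1.0, 1e-3)


class TestAssemblyLayout:
    def test_no_tdi_no_enzyme_states(self, individual, probe):
        sys = assemble(individual, [probe], [iv("probe", 10.0)])
        assert sys.meta["enzyme_states"] == []
        assert not any(lbl.startswith("enzyme:")
                       for lbl in sys.state_labels)

    def test_tdi_targets_get_states_in_expressing_organs(self, individual):
        some = make_probe(name="s_ome", enzyme="CYP2C19", cl_int=1.0,
                          inhibitions=[Inhibition(
                              target_enzyme="CYP2C19", mechanism="tdi",
                              k_i_tdi=0.3, k_inact=0.05)])
        sys = assemble(individual, [some], [iv("s_ome", 10.0)])
        assert set(sys.meta["enzyme_states"]) == {("CYP2C19", "gut"),
                                                  ("CYP2C19", "liver")}

    def test_codosed_state_count_shares_enzyme_states(self, individual):
        a = make_probe(name="a", enzyme="CYP2C19",
                       inhibitions=[Inhibition(target_enzyme="CYP2C19",
                                               mechanism="tdi", k_i_tdi=1.0,
                                               k_inact=0.01)])
        b = make_probe(name="b", enzyme="CYP2C19",
                       inhibitions=[Inhibition(target_enzyme="CYP2C19",
                                               mechanism="tdi", k_i_tdi=2.0,
                                               k_inact=0.01)])
        na = assemble(individual, [a], [iv("a", 1.0)]).n_states
        nb = assemble(individual, [b], [iv("b", 1.0)]).n_states
        nab = assemble(individual, [a, b],
                       [iv("a", 1.0), iv("b", 1.0)]).n_states
        n_enz = 2  # CYP2C19 in liver and gut, counted once when co-dosed
        assert nab == na + nb - n_enz

    def test_regimen_for_unknown_drug(self, individual, probe):
        with pytest.raises(ValueError, match="unknown drug"):
            assemble(individual, [probe], [iv("ghost", 1.0)])

    def test_missing_kp_for_organ(self, individual, probe):
        bad = probe.model_copy(update={"kp_map": {"liver": 1.0}})
        with pytest.raises(ValueError, match="no Kp"):
            assemble(individual, [bad], [iv("probe", 1.0)])

    def test_oral_regimen_requires_absorption_block(self, individual, probe):
        bare = probe.model_copy(update={"absorption": {}})
        with pytest.raises(ValueError, match="absorption"):
            assemble(individual, [bare], [oral("probe", 1.0)])


class TestSimulate:
    def test_closed_system_conserves_amount(self, individual):
        inert = make_probe(cl_int=1e-12)  # effectively no clearance
        res = run(individual, [inert], [iv("probe", 100.0)], 1440.0, n=145)
        totals = [res.system.balances["probe"][0](y) for y in res.states]
        assert np.allclose(totals, 100.0, rtol=1e-6)

    def test_one_compartment_closed_form(self):
        v, cl, dose = 10.0, 0.1, 100.0
        sys = one_compartment_system(v, cl, [(0.0, dose)])
        res = simulate(sys, 2000.0, np.linspace(0, 2000, 501))
        exact = dose / v * np.exp(-cl / v * res.time)
        assert np.max(np.abs(res.plasma("drug") - exact) / exact) < 1e-3
        m = compute_metrics(res.time, res.plasma("drug"), extrapolate=True)
        assert m.auc == pytest.approx(dose / cl, rel=1e-3)

    def test_infusion_mass_balance(self):
        sys = one_compartment_system(
            10.0, 0.1, doses=[], infusions=[(1.0, 0.0, 120.0)])
        res = simulate(sys, 600.0, np.linspace(0, 600, 121))
        assert res.mass_balance_rel_error < 1e-6
        assert res.plasma("drug")[0] == 0.0
        assert res.plasma("drug")[24] > 0  # during infusion

    def test_dose_linearity_for_linear_pathways(self, individual, probe):
        def auc(dose):
            res = run(individual, [probe], [iv("probe", dose)], 3000.0)
            return compute_metrics(res.time, res.plasma("probe"),
                                   extrapolate=True).auc
        assert auc(100.0) / auc(50.0) == pytest.approx(2.0, rel=1e-3)

    def test_saturable_pathway_auc_per_dose_nondecreasing(self, individual):
        sat = make_probe(name="sat").model_copy(update={"pathways": [
            Pathway(enzyme="CYP2D6", kinetics="saturable", vmax=0.6, km=1.0)]})
        def auc_per_dose(dose):
            res = run(individual, [sat], [iv("sat", dose)], 6000.0)
            return compute_metrics(res.time, res.plasma("sat"),
                                   extrapolate=True).auc / dose
        vals = [auc_per_dose(d) for d in (10.0, 50.0, 250.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_steady_state_superposition_linear(self, individual, probe):
        single = run(individual, [probe], [iv("probe", 100.0)], 3000.0)
        auc_inf = compute_metrics(single.time, single.plasma("probe"),
                                  extrapolate=True).auc
        times = [float(t) for t in range(0, 7200, 720)]
        multi = run(individual, [probe], [iv("probe", 100.0, times)],
                    7200.0, n=2401)
        auc_ss = compute_metrics(multi.time, multi.plasma("probe"),
                                 interval=(6480.0, 7200.0)).auc
        assert auc_ss == pytest.approx(auc_inf, rel=0.01)

    def test_tdi_autoinhibition_exceeds_linear_superposition(
            self, individual, autoinhibitor):
        times = [float(t) for t in range(0, 10080, 720)]
        def accumulation(drug):
            single = run(individual, [drug], [iv("auto", 50.0)], 4000.0)
            auc_inf = compute_metrics(single.time, single.plasma("auto"),
                                      extrapolate=True).auc
            multi = run(individual, [drug], [iv("auto", 50.0, times)],
                        10080.0, n=3361)
            auc_ss = compute_metrics(multi.time, multi.plasma("auto"),
                                     interval=(9360.0, 10080.0)).auc
            return auc_ss / auc_inf
        assert accumulation(autoinhibitor.with_inhibitions([])) == \
            pytest.approx(1.0, abs=0.01)
        assert accumulation(autoinhibitor) > 1.05

    def test_mass_balance_with_absorption_and_metabolism(self, individual):
        d = make_probe(f_abs=0.8)
        res = run(individual, [d], [oral("probe", 100.0, [0.0, 720.0])],
                  2880.0)
        assert res.mass_balance_rel_error < 1e-3
        unabsorbed = res.states[-1, res.system.state_labels.index(
            "probe:unabsorbed")]
        assert unabsorbed == pytest.approx(0.2 * 200.0, rel=1e-3)

    def test_fast_ka_approaches_bolus_into_gut_limit(self, individual):
        def auc(ka):
            d = make_probe(ka=ka)
            res = run(individual, [d], [oral("probe", 100.0)], 4000.0)
            return compute_metrics(res.time, res.plasma("probe"),
                                   extrapolate=True).auc
        assert auc(10.0) == pytest.approx(auc(200.0), rel=0.01)

    def test_weibull_shape_one_reduces_to_first_order(self, individual):
        # shape=1 Weibull release followed by fast ka ~ first-order ka=1/scale
        wb = make_probe(name="wb").model_copy(update={"absorption": {
            "oral": Absorption(ka=5.0, f_abs=1.0, weibull_scale=1 / 0.03,
                               weibull_shape=1.0)}})
        fo = make_probe(name="wb", ka=0.03)
        res_wb = run(individual, [wb], [oral("wb", 100.0)], 2880.0)
        res_fo = run(individual, [fo], [oral("wb", 100.0)], 2880.0)
        auc = lambda r: compute_metrics(r.time, r.plasma("wb"),
                                        extrapolate=True).auc
        assert auc(res_wb) == pytest.approx(auc(res_fo), rel=0.01)

    def test_gut_expression_scaling_raises_oral_bioavailability(
            self, individual):
        d = make_probe(name="gsub", enzyme="CYP2C19", cl_int=8.0,
                       fu=0.05, kp=0.4, bp=0.6)
        aucs = []
        for f in (1.0, 0.5, 0.0):
            ind = scale_gut_expression(individual, "CYP2C19", f)
            res = run(ind, [d], [oral("gsub", 60.0)], 1440.0, n=721)
            aucs.append(compute_metrics(res.time, res.plasma("gsub"),
                                        extrapolate=True).auc)
        assert aucs[0] < aucs[1] < aucs[2]

    def test_grid_convergence(self, individual, probe):
        def metrics(n):
            res = run(individual, [probe], [oral("probe", 100.0)], 2880.0,
                      n=n)
            return compute_metrics(res.time, res.plasma("probe"),
                                   interval=(0.0, 2880.0))
        coarse, fine = metrics(721), metrics(1441)
        assert fine.auc == pytest.approx(coarse.auc, rel=1e-3)
        assert fine.cmax == pytest.approx(coarse.cmax, rel=1e-3)

    def test_event_after_t_end_rejected(self, individual, probe):
        sys = assemble(individual, [probe], [iv("probe", 1.0, [100.0])])
        with pytest.raises(ValueError, match="after t_end"):
            simulate(sys, 50.0)

    def test_decreasing_grid_rejected(self, individual, probe):
        sys = assemble(individual, [probe], [iv("probe", 1.0)])
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate(sys, 100.0, [0.0, 50.0, 50.0])

    def test_reproducible_from_same_inputs(self, individual, probe):
        a = run(individual, [probe], [oral("probe", 100.0)], 1440.0, n=145)
        b = run(individual, [probe], [oral("probe", 100.0)], 1440.0, n=145)
        assert np.array_equal(a.states, b.states)

    def test_tidy_export(self, individual, probe):
        res = run(individual, [probe], [iv("probe", 10.0)], 100.0, n=11)
        frame = res.to_frame()
        assert {"time", "output", "value"} == set(frame.columns)
        assert f"plasma:probe" in set(frame.output)


class TestSolverSettings:
    def test_defaults(self):
        s = SolverSettings()
        assert s.rtol == 1e-8 and s.atol == 1e-10

    def test_infusion_regimen_validation(self):
        with pytest.raises(ValueError, match="infusion_duration"):
            DosingRegimen(drug="x", route="iv_infusion", dose=1.0)
        with pytest.raises(ValueError, match="sorted"):
            DosingRegimen(drug="x", route="iv_bolus", dose=1.0,
                          times=[10.0, 5.0])
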