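"""Dwell extraction, censored exponential-mixture MLE, binding curves,
heterogeneity and correlation diagnostics."""

import numpy as np
import pandas as pd
import pytest

from zmwbind import table1_preset
from zmwbind.dwells import (
    BindingCurveFit,
    analysis_view,
    bound_probability,
    dwell_correlations,
    extract_dwells,
    first_step_tetramer_analysis,
    fit_exp_mixture,
    lr_component_test,
    per_molecule_heterogeneity,
    select_components,
)
from zmwbind.process import IdealizedTrace
from zmwbind.simulate import (
    simulate_binary_cohort,
    simulate_mixed_binary_cohort,
    simulate_multisite,
    static_two_population_models,
)

from conftest import ideals_from_binary


def _ideal(states, mol="m0", conc=1e-6):
    return IdealizedTrace(mol, np.asarray(states, np.int8), 1.0, 5.0, None, 1,
                          True, "", conc, 0.1)


class TestExtractDwells:
    def test_run_length_and_edge_rule(self):
        dw = extract_dwells([_ideal([0, 0, 0, 1, 1, 1, 1, 0, 0])])
        assert dw.duration_s.tolist() == pytest.approx([0.3, 0.4, 0.2])
        assert dw.edge_flag.tolist() == [True, False, True]
        av = analysis_view(dw)
        assert av.duration_s.tolist() == [pytest.approx(0.4)]
        assert av.state_class.tolist() == ["bound"]

    def test_all_bound_trace_has_no_analysis_events(self):
        dw = extract_dwells([_ideal(np.ones(50))])
        assert len(analysis_view(dw)) == 0

    def test_subthreshold_flagged_not_dropped(self):
        dw = extract_dwells([_ideal([0, 0, 1, 0, 0, 1, 1, 1, 0, 0])])
        assert dw.subthreshold_flag.tolist() == [False, True, False, False, False]
        assert len(analysis_view(dw)) == 2

    def test_total_time_conservation(self, m4_ideals):
        dw = extract_dwells(m4_ideals[:50])
        for it in m4_ideals[:50]:
            tot = dw.loc[dw.molecule_id == it.molecule_id, "duration_s"].sum()
            assert tot == pytest.approx(len(it.states) * 0.1)

    def test_unbound_shortens_with_concentration_bound_does_not(self, model2):
        means = {}
        for conc in (0.3e-6, 3e-6):
            coh = simulate_binary_cohort(model2, [conc], 150, 60.0, seed=3)
            av = analysis_view(extract_dwells(ideals_from_binary(coh)))
            means[conc] = av.groupby("state_class").duration_s.mean()
        assert means[3e-6]["unbound"] < 0.6 * means[0.3e-6]["unbound"]
        assert means[3e-6]["bound"] == pytest.approx(means[0.3e-6]["bound"], rel=0.15)


class TestExpMixture:
    def test_shifted_exponential_closed_form(self):
        # k=1 MLE with left truncation d: tau_hat = mean(t - d)
        fit = fit_exp_mixture([0.3, 0.5, 1.0] * 4, 1, dead_time=0.2)
        assert fit.taus[0] == pytest.approx(0.4)
        assert fit.amplitudes[0] == 1.0

    def test_untruncated_equals_standard_mle(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2.0, 400)
        fit = fit_exp_mixture(t, 1, dead_time=0.0)
        assert fit.taus[0] == pytest.approx(t.mean(), rel=1e-9)

    def test_biexponential_recovery(self):
        rng = np.random.default_rng(1)
        n = 5000
        fast = rng.random(n) < 0.7
        t = np.where(fast, rng.exponential(0.5, n), rng.exponential(3.0, n)) + 0.2
        fit = fit_exp_mixture(t, 2, dead_time=0.2, seed=0, compute_ci=True)
        lo1, hi1 = fit.ci["tau1"]
        lo2, hi2 = fit.ci["tau2"]
        assert lo1 < 0.5 < hi1
        assert lo2 < 3.0 < hi2
        assert fit.amplitudes.sum() == pytest.approx(1.0)
        assert np.all(np.diff(fit.taus) > 0)

    def test_amplitudes_normalized_after_every_fit(self, m4_ideals):
        av = analysis_view(extract_dwells(m4_ideals))
        for cls in ("bound", "unbound"):
            d = av.loc[av.state_class == cls, "duration_s"]
            for k in (1, 2, 3):
                f = fit_exp_mixture(d, k, seed=1)
                assert f.amplitudes.sum() == pytest.approx(1.0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_exp_mixture([0.5] * 5, 1)
        with pytest.raises(ValueError):
            fit_exp_mixture([0.1] * 20, 1, dead_time=0.2)
        with pytest.raises(ValueError):
            fit_exp_mixture([0.5] * 12, 3)


class TestComponentSelection:
    def test_lr_p_value_chi2_2df(self):
        a = fit_exp_mixture([0.3, 0.5, 1.0] * 4, 1, 0.2)
        b = fit_exp_mixture([0.3, 0.5, 1.0] * 4, 2, 0.2, seed=0)
        # identical data: p from chi2(2df) on 2*dLL
        from scipy.stats import chi2

        d = 2 * (b.log_likelihood - a.log_likelihood)
        assert lr_component_test(a, b) == pytest.approx(chi2.sf(d, 2))

    def test_quantile_anchor(self):
        # 2*dLL = 13.82 corresponds to p ~ 0.001 (the selection threshold)
        from scipy.stats import chi2

        assert chi2.sf(13.82, 2) == pytest.approx(0.001, rel=0.01)

    def test_identical_fits_give_p_one(self):
        a = fit_exp_mixture([0.3, 0.5, 1.0] * 4, 1, 0.2)
        b = fit_exp_mixture([0.3, 0.5, 1.0] * 4, 1, 0.2)
        b.k = 2  # same likelihood, nominally larger model
        assert lr_component_test(a, b) == pytest.approx(1.0)

    def test_null_rejection_rate_conservative(self):
        # monoexponential truth: LR at p<0.001 rejects far less than 1%
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 120
        for _ in range(reps):
            t = rng.exponential(1.0, 400) + 0.2
            f1 = fit_exp_mixture(t, 1, 0.2)
            f2 = fit_exp_mixture(t, 2, 0.2, seed=0, n_starts=4)
            rejections += int(lr_component_test(f1, f2) < 0.001)
        assert rejections / reps < 0.01 + 1e-9

    def test_model4_bound_dwells_select_two_components(self, m4_ideals):
        av = analysis_view(extract_dwells(m4_ideals))
        bound = av.loc[av.state_class == "bound", "duration_s"]
        k, fits = select_components(bound, seed=0)
        assert k == 2
        assert lr_component_test(fits[1], fits[2]) < 0.001
        # the third component adds nothing significant
        assert lr_component_test(fits[2], fits[3]) > 0.001


class TestBindingCurve:
    def test_half_saturation_point(self):
        fit = BindingCurveFit(0.75, 1.5e-6, np.array([]), np.array([]))
        assert fit.predict(1.5e-6) == pytest.approx(0.375)

    def test_kd_recovery_on_model1(self, model1):
        coh = simulate_binary_cohort(
            model1, [0.1e-6, 0.3e-6, 1e-6, 3e-6, 10e-6], 80, 120.0, seed=5)
        curve = bound_probability(ideals_from_binary(coh), fix_bmax=True)
        # two-state scheme saturates at 1 with Kd = koff/kon ~ 2.6 uM
        assert curve.kd == pytest.approx(0.34 / 1.3e5, rel=0.15)

    def test_zero_bound_frames_is_an_error(self):
        ideals = [_ideal(np.zeros(50), f"m{i}", c)
                  for i, c in enumerate([1e-7, 1e-6, 1e-5])]
        with pytest.raises(ValueError, match="zero bound"):
            bound_probability(ideals)

    def test_needs_three_concentrations(self):
        ideals = [_ideal([0, 1, 1, 0], "m0", 1e-6)]
        with pytest.raises(ValueError, match="3 concentrations"):
            bound_probability(ideals)


class TestHeterogeneity:
    def test_single_molecule_mean(self):
        it = _ideal([0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0])
        dw = extract_dwells([it], dead_time=0.0)
        het = per_molecule_heterogeneity(dw)
        assert het.per_molecule.mean_bound_s.iloc[0] == pytest.approx(0.1)
        assert het.modality == "undetermined"  # too few molecules to classify

    def test_dynamic_heterogeneity_is_unimodal(self, m4_ideals):
        dw = extract_dwells(m4_ideals)
        het = per_molecule_heterogeneity(dw)
        assert het.modality == "unimodal"
        assert het.delta_bic < 0

    def test_static_two_population_is_bimodal(self):
        coh = simulate_mixed_binary_cohort(
            static_two_population_models(), 1e-6, 150, 120.0, seed=9)
        dw = extract_dwells(ideals_from_binary(coh))
        het = per_molecule_heterogeneity(dw)
        assert het.modality == "bimodal"
        assert het.delta_bic > 0


class TestCorrelations:
    def test_sequential_model_has_no_correlations(self, m4_ideals):
        dw = extract_dwells(m4_ideals)
        c1 = dwell_correlations(dw, 1, seed=0)
        c2 = dwell_correlations(dw, 2, seed=0)
        for res in list(c1.values()) + list(c2.values()):
            assert res["n_pairs"] >= 2000
            assert abs(res["r"]) < 0.05

    def test_static_populations_induce_correlation(self):
        coh = simulate_mixed_binary_cohort(
            static_two_population_models(), 1e-6, 150, 120.0, seed=9)
        dw = extract_dwells(ideals_from_binary(coh))
        res = dwell_correlations(dw, 2, seed=0)["U_i,U_i+2"]
        assert res["r"] > 0.3

    def test_shuffled_events_decorrelate(self, m4_cohort):
        rng = np.random.default_rng(3)
        shuffled = []
        for i, tr in enumerate(m4_cohort.traces[:150]):
            dw_runs = np.diff(np.r_[0, np.flatnonzero(np.diff(tr)) + 1, len(tr)])
            cls0 = tr[0]
            perm_u = rng.permutation(dw_runs[int(cls0 == 1)::2])
            perm_b = rng.permutation(dw_runs[int(cls0 == 0)::2])
            out = []
            iu = ib = 0
            c = cls0
            for _ in dw_runs:
                if c == 0:
                    out += [0] * perm_u[iu % len(perm_u)]
                    iu += 1
                else:
                    out += [1] * perm_b[ib % len(perm_b)]
                    ib += 1
                c = 1 - c
            shuffled.append(
                IdealizedTrace(f"s{i}", np.array(out, np.int8), 1.0, 5.0,
                               None, 1, True, "", 1e-6, 0.1))
        dw = extract_dwells(shuffled)
        for res in dwell_correlations(dw, 2, seed=1).values():
            assert abs(res["r"]) < 0.06


class TestTetramerFirstStep:
    def test_single_site_reduces_to_monomer_pipeline(self, model4):
        occ = simulate_multisite(model4, 1, 300e-9, 2000.0, seed=2)
        dw, f1, f2 = first_step_tetramer_analysis([occ])
        mono = extract_dwells([_ideal(occ.astype(np.int8), "tet0", 0.0)])
        assert len(dw) == len(mono)
        assert np.allclose(dw.duration_s.values, mono.duration_s.values)

    def test_tetramer_bound_lifetimes_biexponential(self, model4):
        occs = [simulate_multisite(model4, 4, 300e-9, 1500.0, seed=s)
                for s in range(40)]
        dw, f1, f2 = first_step_tetramer_analysis(occs, seed=0)
        assert lr_component_test(f1, f2) < 0.001

    def test_frequent_multiple_occupancy_rejected(self, model4):
        occs = [simulate_multisite(model4, 4, 10e-6, 500.0, seed=s)
                for s in range(5)]
        with pytest.raises(ValueError, match="lower ligand concentration"):
            first_step_tetramer_analysis(occs)

    def test_level0_dwell_superposition(self, model4):
        # empty-tetramer dwells are ~4x shorter than monomer unbound dwells
        occs = [simulate_multisite(model4, 4, 300e-9, 2000.0, seed=100 + s)
                for s in range(20)]
        dw, _, _ = first_step_tetramer_analysis(occs, seed=0)
        av = analysis_view(dw)
        tet_unbound = av.loc[av.state_class == "unbound", "duration_s"].mean()
        mono = simulate_binary_cohort(model4, [300e-9], 20, 2000.0, seed=3)
        mav = analysis_view(extract_dwells(ideals_from_binary(mono)))
        mono_unbound = mav.loc[mav.state_class == "unbound", "duration_s"].mean()
        assert mono_unbound / tet_unbound == pytest.approx(4.0, rel=0.3)
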