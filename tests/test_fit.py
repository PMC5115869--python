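"""Global likelihood, optimization, AIC ranking and resimulation checks."""

import numpy as np
import pytest
from scipy.linalg import expm

from zmwbind import table1_preset
from zmwbind.models import build_generator
from zmwbind.fit import (
    ModelFit,
    alternating_renewal_log_likelihood,
    encode_cohort,
    fit_model_global,
    global_log_likelihood,
    majority_emission_kernels,
    missed_event_option,
    naive_forward_log_likelihood,
    rank_models,
    resimulate_and_compare,
    _class_vector,
)
from zmwbind.simulate import BinaryCohort, simulate_binary_cohort


def _cohort(traces, concs, dt=0.1):
    return BinaryCohort([np.asarray(t, np.int8) for t in traces],
                        np.asarray(concs), dt)


class TestLikelihood:
    def test_two_frame_trace_hand_computed(self, model1):
        # single trace U,U: logL = log pi(U|U) + log T_UU = log T_UU
        Q = build_generator(model1, 1e-6).Q
        T = expm(Q * 0.1)
        ll = global_log_likelihood(model1, _cohort([[0, 0]], [1e-6]))
        assert ll == pytest.approx(np.log(T[0, 0]), rel=1e-12)

    def test_matches_naive_forward_pass(self, model4):
        rng = np.random.default_rng(0)
        traces = [rng.integers(0, 2, rng.integers(20, 80)).astype(np.int8)
                  for _ in range(6)]
        coh = _cohort(traces, [1e-6] * 6)
        fast = global_log_likelihood(model4, coh)
        naive = sum(naive_forward_log_likelihood(model4, t, 1e-6) for t in traces)
        assert fast == pytest.approx(naive, rel=1e-10)

    def test_invariant_to_molecule_order(self, model2):
        coh = simulate_binary_cohort(model2, [0.3e-6, 3e-6], 10, 30.0, seed=1)
        ll = global_log_likelihood(model2, coh)
        rev = BinaryCohort(coh.traces[::-1], coh.concentrations[::-1],
                           coh.frame_period)
        assert global_log_likelihood(model2, rev) == pytest.approx(ll, rel=1e-12)

    def test_true_rates_beat_perturbed_rates(self, model2):
        wins = 0
        for rep in range(10):
            coh = simulate_binary_cohort(model2, [1e-6], 80, 60.0, seed=100 + rep)
            ll_true = global_log_likelihood(model2, coh,
                                            observation_model="majority")
            doubled = model2.with_rates(
                {k: 2 * v for k, v in model2.rate_values.items()})
            ll_bad = global_log_likelihood(doubled, coh,
                                           observation_model="majority")
            wins += int(ll_true > ll_bad)
        assert wins >= 9

    def test_agrees_with_alternating_renewal_closed_form(self, model1):
        # two-state scheme, dwells >> frame period: within 1%
        coh = simulate_binary_cohort(model1, [1e-6], 20, 120.0, seed=4)
        ll_hmm = global_log_likelihood(model1, coh)
        ll_ren = sum(alternating_renewal_log_likelihood(model1, t, 1e-6)
                     for t in coh.traces)
        assert abs(ll_hmm - ll_ren) / abs(ll_ren) < 0.01


class TestMajorityKernels:
    def test_marginal_is_matrix_exponential(self, model4):
        Q = build_generator(model4, 3e-6).Q
        Mu, Mb = majority_emission_kernels(Q, _class_vector(model4), 0.1)
        assert np.allclose(Mu + Mb, expm(Q * 0.1), atol=1e-12)
        assert np.all(Mu >= -1e-15) and np.all(Mb >= -1e-15)

    def test_slow_rates_split_single_transition_frames_evenly(self, model1):
        # rare transitions: a transition frame gets the new label only when
        # the jump lands in the first half, so off-diagonals are T[i,j]/2
        slow = model1.with_rates({"U1->B1": 1.3e3, "B1->U1": 0.0034})
        Q = build_generator(slow, 1e-6).Q
        Mu, Mb = majority_emission_kernels(Q, _class_vector(slow), 0.1)
        T = expm(Q * 0.1)
        assert Mb[1, 1] == pytest.approx(T[1, 1], abs=1e-7)
        assert Mu[0, 0] == pytest.approx(T[0, 0], abs=1e-7)
        assert Mb[0, 1] == pytest.approx(T[0, 1] / 2, rel=1e-3)
        assert Mu[1, 0] == pytest.approx(T[1, 0] / 2, rel=1e-3)

    def test_monte_carlo_bridge(self, model2):
        # brute-force occupancy-bridge simulation vs the closed form
        rng = np.random.default_rng(0)
        Q = build_generator(model2, 3e-6).Q * 20.0  # make jumps frequent
        cls = _class_vector(model2)
        Mu, Mb = majority_emission_kernels(Q, cls, 0.1)
        S, dt, n = 3, 0.1, 8000
        emp = np.zeros((S, S))
        for i in range(S):
            for _ in range(n):
                t, s, occ = 0.0, i, 0.0
                while True:
                    ex = -Q[s, s]
                    h = rng.exponential(1 / ex) if ex > 0 else np.inf
                    seg = min(h, dt - t)
                    occ += seg * cls[s]
                    t += seg
                    if t >= dt - 1e-15:
                        break
                    p = Q[s].copy()
                    p[s] = 0
                    s = rng.choice(S, p=p / p.sum())
                if occ / dt >= 0.5:
                    emp[i, s] += 1
        emp /= n
        assert np.abs(emp - Mb).max() < 4 / np.sqrt(n)


class TestMissedEventOption:
    def test_slow_kinetics_limit_is_identity(self, model2):
        slow = model2.with_rates(
            {k: v * 1e-2 for k, v in model2.rate_values.items()})
        base = expm(build_generator(slow, 1e-6).Q * 0.1)
        corr = missed_event_option(slow, 1e-6, dead_time=0.1, frame_period=0.1)
        assert np.abs(corr - base).max() < 0.01

    def test_rows_stochastic(self, model4):
        corr = missed_event_option(model4, 3e-6, dead_time=0.2)
        assert np.allclose(corr.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(corr >= -1e-12)

    def test_dead_time_below_frame_rejected(self, model1):
        with pytest.raises(ValueError):
            missed_event_option(model1, 1e-6, dead_time=0.05, frame_period=0.1)

    def test_correction_reduces_flicker_bias(self, model2):
        # fast bound-state flicker: corrected likelihood prefers the truth
        fast = model2.with_rates({"U1->B1": 1.4e5, "B1->U1": 0.91,
                                  "B1->B2": 5.0, "B2->B1": 5.0})
        coh = simulate_binary_cohort(fast, [1e-6], 120, 60.0, seed=6)
        biased = fast.with_rates({"U1->B1": 1.4e5, "B1->U1": 0.91,
                                  "B1->B2": 2.5, "B2->B1": 2.5})
        raw_pref = (global_log_likelihood(fast, coh)
                    - global_log_likelihood(biased, coh))
        cor_pref = (global_log_likelihood(fast, coh, dead_time=0.2,
                                          missed_event_correction=True)
                    - global_log_likelihood(biased, coh, dead_time=0.2,
                                            missed_event_correction=True))
        assert cor_pref > raw_pref


class TestFitAndRank:
    def test_fit_determinism(self, model1):
        coh = simulate_binary_cohort(model1, [1e-6, 3e-6], 25, 40.0, seed=2)
        enc = encode_cohort(coh)
        a = fit_model_global(model1, enc, n_starts=3, seed=9)
        b = fit_model_global(model1, enc, n_starts=3, seed=9)
        assert a.rate_values == b.rate_values
        assert a.log_likelihood == b.log_likelihood

    def test_model1_rate_recovery_small(self, model1):
        coh = simulate_binary_cohort(
            model1, [0.3e-6, 1e-6, 3e-6], 120, 60.0, seed=3)
        fit = fit_model_global(model1, coh, n_starts=4, seed=1)
        assert fit.rate_values["U1->B1"] == pytest.approx(1.3e5, rel=0.10)
        assert fit.rate_values["B1->U1"] == pytest.approx(0.34, rel=0.10)

    def test_aic_identity_and_ranking(self):
        f1 = ModelFit(1, {}, {}, -1000.0, 4, 2 * 4 + 2000.0, 0, "h")
        f2 = ModelFit(2, {}, {}, -990.0, 8, 2 * 8 + 1980.0, 0, "h")
        ranked = rank_models([f1, f2])
        assert ranked[0].model_id == 2
        assert ranked[1].delta_aic == pytest.approx(12.0)
        assert ranked[0].delta_aic == 0.0

    def test_rank_rejects_mismatched_data(self):
        f1 = ModelFit(1, {}, {}, -10.0, 2, 24.0, 0, "aaa")
        f2 = ModelFit(2, {}, {}, -10.0, 2, 24.0, 0, "bbb")
        with pytest.raises(ValueError, match="hash"):
            rank_models([f1, f2])

    def test_aic_tie_breaks_to_fewer_parameters(self):
        f1 = ModelFit(1, {}, {}, -10.0, 2, 24.0, 0, "h")
        f2 = ModelFit(2, {}, {}, -8.0, 4, 24.0, 0, "h")
        assert rank_models([f2, f1])[0].model_id == 1


class TestResimulation:
    def test_self_consistency(self, model2):
        coh = simulate_binary_cohort(model2, [1e-6], 150, 60.0, seed=5)
        fit = ModelFit(2, dict(model2.rate_values), {}, 0.0, 4, 8.0, 0,
                       encode_cohort(coh).data_hash, model=model2)
        out = resimulate_and_compare(fit, coh, seed=1)
        assert len(out["per_group"]) == 2
        for res in out["per_group"].values():
            assert res["p"] > 0.01

    def test_misfit_detected(self, model2, model1):
        # data with biexponential bound dwells vs a single-step model
        coh = simulate_binary_cohort(model2, [1e-6], 150, 60.0, seed=5)
        wrong = model1.with_rates({"U1->B1": 1.4e5, "B1->U1": 1.0 / 2.94})
        fit = ModelFit(1, dict(wrong.rate_values), {}, 0.0, 2, 4.0, 0,
                       encode_cohort(coh).data_hash, model=wrong)
        out = resimulate_and_compare(fit, coh, seed=1)
        assert out["per_group"]["1e-06|bound"]["p"] < 0.001

    def test_empty_data_flagged(self, model1):
        coh = _cohort([np.zeros(30, np.int8)], [1e-6])
        fit = ModelFit(1, dict(model1.rate_values), {}, 0.0, 2, 4.0, 0,
                       encode_cohort(coh).data_hash, model=model1)
        out = resimulate_and_compare(fit, coh, seed=0)
        assert out.get("empty", False) or out["per_group"] == {}
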