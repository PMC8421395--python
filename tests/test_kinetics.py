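"""Full-tail state calling, dwell events, residence times, free energies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nuctail import (
    GAS_CONSTANT_KCAL,
    binding_free_energy,
    compare_residence_times,
    competitive_binding_model,
    extract_binding_events,
    full_tail_states,
    residence_times,
)
from nuctail.kinetics import bound_fraction, residue_residence_times
from nuctail import synthetic as syn


class TestFullTailStates:
    def test_ten_percent_rule_on_36_residue_tail(self):
        """3/36 residues in contact (8.3%) -> unbound; 4/36 (11.1%) -> bound."""
        rb = np.zeros((2, 36), dtype=bool)
        rb[0, :3] = True
        rb[1, :4] = True
        states = full_tail_states(rb, fraction_threshold=0.10)
        assert not states[0]
        assert states[1]

    def test_zero_threshold_means_any_contact(self):
        rb = np.array([[False, False], [True, False]])
        states = full_tail_states(rb, fraction_threshold=0.0)
        assert list(states) == [False, True]

    def test_empty_tail_errors(self):
        with pytest.raises(ValueError):
            full_tail_states(np.zeros((5, 0), dtype=bool))

    def test_bound_fraction_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        rb = rng.random((500, 20)) < 0.3
        fracs = [full_tail_states(rb, th).mean() for th in (0.0, 0.1, 0.3, 0.5)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestEventExtraction:
    def test_short_dwell_excluded(self):
        # U B(8 ns) U  B(50 ns) ... U   on a 1 ns grid
        states = np.array([0] + [1] * 8 + [0] * 3 + [1] * 50 + [0] * 5, dtype=bool)
        events, n_unb = extract_binding_events(states, np.arange(len(states), dtype=float), 10.0)
        assert len(events) == 1
        assert events["duration"].iloc[0] == 50.0
        assert n_unb == 1

    def test_all_bound_series_is_one_censored_event(self):
        states = np.ones(100, dtype=bool)
        events, n_unb = extract_binding_events(states, np.arange(100.0), 10.0)
        assert len(events) == 1
        assert events["censored"].iloc[0]
        assert n_unb == 0

    def test_planted_dwells_recovered(self):
        """Generator ground truth minus sub-10 ns dwells equals the calls."""
        spec = syn.TwoStateKineticsSpec(
            n_residues=1, k_on=0.02, k_off=0.02, total_time=5000.0, dt=1.0, seed=8
        )
        sim = syn.simulate_two_state_series(spec)
        events, _ = extract_binding_events(sim.states[:, 0], sim.times, min_dwell=10.0)
        completed = events[~events["censored"]]
        truth = sim.true_bound_intervals[0]
        interior = truth[(truth[:, 0] > 0) & (truth[:, 1] < spec.total_time)]
        # grid-discretised dwells differ from continuous truth by < 2 frames
        long_true = interior[(interior[:, 1] - interior[:, 0]) >= 12.0]
        assert len(completed) >= len(long_true)
        for a, b in long_true:
            assert ((completed["start"] >= a - 2) & (completed["end"] <= b + 2)).any()

    def test_event_count_parity(self):
        """#binding events == #unbinding events ± 1 in any single series."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            states = rng.random(200) < 0.5
            events, n_unb = extract_binding_events(states, np.arange(200.0), min_dwell=0.0)
            n_bind = len(events)
            assert abs(n_bind - n_unb) <= 1

    def test_n_events_non_increasing_in_min_dwell(self):
        rng = np.random.default_rng(12)
        states = rng.random(1000) < 0.4
        times = np.arange(1000.0)
        counts = [len(extract_binding_events(states, times, d)[0]) for d in (0, 2, 5, 10, 20)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestResidenceTimes:
    def test_mean_and_koff_arithmetic(self):
        out = residence_times({"H3": np.array([50.0, 150.0])}, min_dwell=10.0)
        assert out["tau_mean"].iloc[0] == pytest.approx(100.0)
        assert out["k_off"].iloc[0] == pytest.approx(0.01)

    def test_single_event(self):
        out = residence_times({"H4": np.array([500.0])}, min_dwell=10.0)
        assert out["tau_mean"].iloc[0] == 500.0

    def test_zero_events_flagged(self):
        with pytest.warns(UserWarning, match="no completed events"):
            out = residence_times({"H2A_N": np.array([])}, min_dwell=10.0)
        assert np.isnan(out["tau_mean"].iloc[0])

    def test_parameter_recovery_two_state(self):
        """20 × 5 µs series at τ = 500 ns recover τ̂ within 20%."""
        durations = []
        for seed in range(20):
            spec = syn.TwoStateKineticsSpec(
                n_residues=1, k_on=0.002, k_off=0.002,
                total_time=5000.0, dt=1.0, seed=seed,
            )
            sim = syn.simulate_two_state_series(spec)
            ev, _ = extract_binding_events(sim.states[:, 0], sim.times, min_dwell=10.0)
            durations.extend(ev.loc[~ev["censored"], "duration"])
        tau_hat = np.mean(durations)
        assert abs(tau_hat - 500.0) / 500.0 < 0.20

    def test_residue_level_no_filter_by_default(self):
        rb = np.zeros((20, 1), dtype=bool)
        rb[2:5, 0] = True  # 3 ns dwell, would be killed by the 10 ns filter
        tau = residue_residence_times(rb, np.arange(20.0))
        assert tau[0] == pytest.approx(3.0)


class TestFreeEnergy:
    def test_half_occupancy_zero_energy(self):
        assert binding_free_energy(0.5, 10).delta_g == pytest.approx(0.0)

    def test_closed_form_at_nine_to_one(self):
        fe = binding_free_energy(0.9, 10, temperature=310.0)
        assert fe.delta_g == pytest.approx(-GAS_CONSTANT_KCAL * 310.0 * np.log(9.0), abs=1e-9)

    def test_few_events_invalid_but_reported(self):
        fe = binding_free_energy(0.8, 4)
        assert not fe.valid
        assert np.isfinite(fe.delta_g)

    def test_extreme_fractions_flagged_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            fe = binding_free_energy(1.0, 10)
        assert fe.delta_g == -np.inf and not fe.valid

    @settings(deadline=None, max_examples=50)
    @given(f=st.floats(0.01, 0.99))
    def test_antisymmetry_and_monotonicity(self, f):
        """ΔG(f) = −ΔG(1−f) and ΔG strictly decreasing in f."""
        a = binding_free_energy(f, 10).delta_g
        b = binding_free_energy(1.0 - f, 10).delta_g
        assert a == pytest.approx(-b, abs=1e-9)
        if f < 0.98:
            assert binding_free_energy(f + 0.01, 10).delta_g < a


class TestAnovaTukey:
    def test_identical_groups_not_significant(self):
        x = np.array([100.0, 110.0, 90.0, 105.0, 95.0])
        anova, tukey = compare_residence_times({"a": x, "b": x.copy()})
        assert anova["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert not tukey["reject"].any()

    def test_order_of_magnitude_separation_detected(self):
        """exp(τ=100) vs exp(τ=1000), n=30: significant in ≥90% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = rng.exponential(100.0, size=30)
            b = rng.exponential(1000.0, size=30)
            anova, tukey = compare_residence_times({"short": a, "long": b})
            hits += bool(tukey["reject"].iloc[0])
        assert hits >= 0.9 * n_seeds

    def test_degenerate_groups_error(self):
        with pytest.raises(ValueError):
            compare_residence_times({"a": np.array([1.0, 2.0]), "b": np.array([])})


class TestCompetitionModel:
    def test_no_competition_limit(self):
        out = competitive_binding_model(1e8, 1.0, 0.0)
        assert out.k_effective == pytest.approx(1e8)
        assert out.delta_delta_g == pytest.approx(0.0)

    def test_tenfold_reduction_closed_form(self):
        out = competitive_binding_model(1e8, 9.0, 1.0, temperature=310.0)
        assert out.k_effective == pytest.approx(1e7)
        assert out.delta_delta_g == pytest.approx(GAS_CONSTANT_KCAL * 310.0 * np.log(10.0))

    def test_three_orders_of_magnitude(self):
        """Strong tail occupancy cuts partner affinity ~1000-fold."""
        out = competitive_binding_model(1e8, 999.0, 1.0)
        assert out.k_effective == pytest.approx(1e5)
        assert out.fold_reduction == pytest.approx(1000.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            competitive_binding_model(-1.0, 1.0, 1.0)


class TestConvergence:
    def test_fbound_and_tau_converge_with_simulated_time(self):
        """f̂ → k_on/(k_on+k_off), τ̂ → 1/k_off as total time grows."""
        k_on, k_off = 0.004, 0.002
        f_true = k_on / (k_on + k_off)
        tau_true = 1.0 / k_off
        err_f, err_tau = [], []
        for total in (20000.0, 80000.0, 320000.0):
            spec = syn.TwoStateKineticsSpec(
                n_residues=4, k_on=k_on, k_off=k_off, total_time=total, dt=1.0, seed=99
            )
            sim = syn.simulate_two_state_series(spec)
            f_hat = bound_fraction([sim.states])
            durations = []
            for r in range(4):
                ev, _ = extract_binding_events(sim.states[:, r], sim.times, min_dwell=0.0)
                durations.extend(ev.loc[~ev["censored"], "duration"])
            err_f.append(abs(f_hat - f_true))
            err_tau.append(abs(np.mean(durations) - tau_true) / tau_true)
        assert err_f[-1] < 0.03
        assert err_tau[-1] < 0.10
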