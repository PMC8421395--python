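"""Contact engine and contact-profile statistics."""

import numpy as np
import pytest

from nuctail import (
    atomic_contacts,
    compute_contacts,
    copy_symmetry_correlation,
    per_bp_contact_profile,
    preferred_binding_regions,
    compare_contact_profiles,
)
from nuctail.contacts import copy_profile, per_bp_profile_by_tail
from nuctail import synthetic as syn

from oracles import brute_force_contacts


class TestContactEngine:
    def test_cutoff_is_inclusive(self):
        a = np.array([[0.0, 0.0, 0.0]])
        assert len(atomic_contacts(a, np.array([[3.99, 0, 0]]), 4.0)) == 1
        assert len(atomic_contacts(a, np.array([[4.0, 0, 0]]), 4.0)) == 1
        assert len(atomic_contacts(a, np.array([[4.01, 0, 0]]), 4.0)) == 0

    def test_empty_group_is_empty_set(self):
        assert atomic_contacts(np.empty((0, 3)), np.ones((5, 3)), 4.0).shape == (0, 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 30, size=(150, 3))
        b = rng.uniform(0, 30, size=(150, 3))
        pairs = {(int(i), int(j)) for i, j in atomic_contacts(a, b, 4.0)}
        assert pairs == brute_force_contacts(a, b, 4.0)


class TestResidueStates:
    def test_planted_states_recovered_exactly(self, toy):
        """Contact analysis inverts the generator's placements bit-for-bit."""
        rng = np.random.default_rng(5)
        n_res = len(toy.tail_atom_indices)
        states = rng.random((30, n_res)) < 0.4
        run = syn.generate_toy_trajectory(toy, states)
        series = compute_contacts(run, toy.topology)
        np.testing.assert_array_equal(series.residue_bound, states)

    def test_bound_iff_any_contact(self, toy):
        states = np.zeros((4, len(toy.tail_atom_indices)), dtype=bool)
        states[2, 17] = True
        run = syn.generate_toy_trajectory(toy, states)
        series = compute_contacts(run, toy.topology)
        assert series.residue_bound[2, 17]
        assert series.residue_ncontacts[2, 17] >= 1
        assert series.residue_bound.sum() == 1


class TestPerBpProfile:
    def test_constant_occupancy_mean_and_single_unit_sem(self, toy):
        """Every frame bound -> mean equals atoms-per-visit; SEM null at n=1."""
        n_res = len(toy.tail_atom_indices)
        states = np.zeros((10, n_res), dtype=bool)
        # bind all residues of H3 copy 1 (first tail) in every frame
        n_h3 = toy.topology.tails[0].n_residues
        states[:, :n_h3] = True
        run = syn.generate_toy_trajectory(toy, states)
        series = compute_contacts(run, toy.topology)
        prof = per_bp_contact_profile([series], mirror_copy2=False)
        assert prof["n"].iloc[0] == 2  # two copies are separate units
        occupied = prof[prof["mean"] > 0]
        assert len(occupied) == n_h3  # one bead per target bp, every frame
        assert occupied["mean"].max() == pytest.approx(0.5)  # copy 2 never binds
        assert copy_profile([series], copy=1).max() == pytest.approx(1.0)
        # a single statistical unit has no SEM: reported as null
        from nuctail.contacts import _profile_frame

        single = _profile_frame(np.ones((1, 5)), np.arange(5))
        assert single["sem"].isna().all()

    def test_dyad_mirroring_yields_symmetric_pooled_profile(self):
        """Identical copy footprints pooled through the dyad map are even."""
        spec = syn.ToyNucleosomeSpec(mirror_copy2_targets=False)
        toy2 = syn.build_toy_nucleosome(spec)
        n_res = len(toy2.tail_atom_indices)
        rng = np.random.default_rng(9)
        # copy 2 repeats copy 1's binding pattern on the same physical bps
        states = np.zeros((40, n_res), dtype=bool)
        col = 0
        saved = {}
        for tail in toy2.topology.tails:
            if tail.copy == 1:
                saved[tail.tail_id] = rng.random((40, tail.n_residues)) < 0.5
            states[:, col : col + tail.n_residues] = saved[tail.tail_id]
            col += tail.n_residues
        run = syn.generate_toy_trajectory(toy2, states)
        series = compute_contacts(run, toy2.topology)
        prof = per_bp_contact_profile([series], mirror_copy2=True)
        m = prof["mean"].to_numpy()
        np.testing.assert_allclose(m, m[::-1], atol=1e-12)

    def test_occupancy_expectation(self, toy):
        """Mean per-bp contacts ≈ planted occupancy × atoms per visit."""
        lam = 0.65
        n_res = len(toy.tail_atom_indices)
        rng = np.random.default_rng(2)
        states = rng.random((400, n_res)) < lam
        run = syn.generate_toy_trajectory(toy, states)
        series = compute_contacts(run, toy.topology)
        # H3 copy 1 occupies one bp per residue: occupancy per target bp = lam
        counts = series.bp_counts(copy=1, tail_id="H3").mean(axis=0)
        hit = counts[counts > 0]
        assert np.all(np.abs(hit - lam) < 3 * np.sqrt(lam * (1 - lam) / 400))

    def test_zero_frames_error(self, toy):
        states = np.zeros((1, len(toy.tail_atom_indices)), dtype=bool)
        run = syn.generate_toy_trajectory(toy, states)
        series = compute_contacts(run, toy.topology)
        series.residue_ncontacts = series.residue_ncontacts[:0]
        series.bp_tail_counts = series.bp_tail_counts[:0]
        series.times = series.times[:0]
        with pytest.raises(ValueError, match="zero frames"):
            per_bp_contact_profile([series])


class TestPreferredRegions:
    def test_strict_threshold(self):
        import pandas as pd

        prof = pd.DataFrame({"bp_offset": [-1, 0, 1], "mean": [5.0, 5.1, 0.0]})
        regions = preferred_binding_regions(prof, threshold=5.0)
        assert regions == {0}

    def test_all_zero_profile_empty(self):
        import pandas as pd

        prof = pd.DataFrame({"bp_offset": range(5), "mean": np.zeros(5)})
        assert preferred_binding_regions(prof) == set()


class TestCopySymmetry:
    def test_identical_profiles_r_one(self):
        x = np.random.default_rng(0).random(187)
        r, p = copy_symmetry_correlation(x, x[::-1])  # mirroring undoes the flip
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_anticorrelated_profiles(self):
        x = np.linspace(0, 1, 187)
        r, _ = copy_symmetry_correlation(x, (1 - x)[::-1], mirror=True)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r, p = copy_symmetry_correlation(np.ones(10), np.arange(10.0))
        assert np.isnan(r)

    def test_white_noise_profiles_uncorrelated(self):
        """|r| small and p roughly uniform over independent noise pairs."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            r, p = copy_symmetry_correlation(rng.random(187), rng.random(187))
            pvals.append(p)
        pvals = np.asarray(pvals)
        # uniformity: roughly 5% below 0.05 (binomial 99% CI), KS not needed
        assert 1 <= (pvals < 0.05).sum() <= 25
        assert abs(np.mean(pvals) - 0.5) < 0.1

    def test_mirrored_generator_copies_correlate(self, toy):
        rng = np.random.default_rng(21)
        n_res = len(toy.tail_atom_indices)
        states = np.zeros((60, n_res), dtype=bool)
        col = 0
        saved = {}
        for tail in toy.topology.tails:
            if tail.copy == 1:
                saved[tail.tail_id] = rng.random((60, tail.n_residues)) < 0.5
            states[:, col : col + tail.n_residues] = saved[tail.tail_id]
            col += tail.n_residues
        run = syn.generate_toy_trajectory(toy, states)
        series = compute_contacts(run, toy.topology)
        p1 = copy_profile([series], copy=1)
        p2 = copy_profile([series], copy=2)
        r, _ = copy_symmetry_correlation(p1, p2)
        assert r > 0.99


class TestEnsembleComparison:
    @staticmethod
    def _kinetic_series(toy, n_runs, k_on, seed):
        ens, _ = syn.toy_kinetic_ensemble(
            toy, n_runs=n_runs, total_time=300.0, k_on=k_on, k_off=0.05,
            seed=seed, coupling=None,
        )
        return [compute_contacts(r, toy.topology) for r in ens.runs]

    def test_identical_ensembles_zero_delta(self, toy):
        a = self._kinetic_series(toy, 2, 0.05, seed=42)
        b = self._kinetic_series(toy, 2, 0.05, seed=42)
        out = compare_contact_profiles(a, b, level="full_tail")
        assert np.allclose(out["delta"], 0.0)

    def test_halved_occupancy_detected(self, toy):
        """5 runs: halving k_on drops contacts; BH flags affected tails."""
        a = self._kinetic_series(toy, 5, 0.10, seed=1)
        b = self._kinetic_series(toy, 5, 0.02, seed=100)
        out = compare_contact_profiles(a, b, level="full_tail")
        assert (out["delta"] < 0).all()
        assert out["significant"].all()

    def test_single_run_skips_test_with_warning(self, toy):
        a = self._kinetic_series(toy, 1, 0.05, seed=7)
        b = self._kinetic_series(toy, 1, 0.05, seed=8)
        with pytest.warns(UserWarning, match="skipped"):
            out = compare_contact_profiles(a, b, level="residue")
        assert out["p"].isna().all()

    def test_type_one_error_near_nominal(self, toy):
        """Same-parameter ensembles reject at ≈ the nominal 5% rate."""
        rng = np.random.default_rng(0)
        rejections = 0
        trials = 120
        for t in range(trials):
            # run-level mean contacts emulated by binomial occupancy means,
            # the same sampling model the run-level Welch test sees
            a = rng.binomial(300, 0.5, size=5) / 300
            b = rng.binomial(300, 0.5, size=5) / 300
            from scipy import stats

            p = stats.ttest_ind(a, b, equal_var=False).pvalue
            rejections += p < 0.05
        # binomial 99.7% envelope around 0.05 for 120 trials
        assert rejections <= 16

    def test_bp_atom_count_accounting(self, toy):
        """Σ_bp distinct-atom counts ≥ distinct contacting atoms per frame."""
        rng = np.random.default_rng(4)
        n_res = len(toy.tail_atom_indices)
        states = rng.random((20, n_res)) < 0.5
        run = syn.generate_toy_trajectory(toy, states)
        series = compute_contacts(run, toy.topology)
        per_frame_sum = series.bp_tail_counts.sum(axis=(1, 2))
        distinct_atoms = series.residue_bound.sum(axis=1)  # one bead per residue
        assert np.all(per_frame_sum >= distinct_atoms)
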