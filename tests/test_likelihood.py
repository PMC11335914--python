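"""Race/mixture likelihoods: composition, conservation, oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from rdex.design import AccumulatorRole, DesignCell, build_map
from rdex.distributions import (
    GoRunnerParams,
    StopRunnerParams,
    wald_density,
    wald_survival,
)
from rdex.likelihood import (
    CompiledTrials,
    Trial,
    dataset_loglik,
    go_omission_probability,
    go_response_density,
    inhibition_probability,
    respond_probability,
    signal_respond_density,
)
from rdex.simulate import simulate_stop_outcomes

WINNER = GoRunnerParams(v=3.0, B=1.0, t0=0.3)
LOSER = GoRunnerParams(v=1.5, B=1.0, t0=0.3)
STOP = StopRunnerParams(mu=0.2, sigma=0.05, tau=0.08)


class TestGoTrial:
    def test_composition_of_kernels(self):
        got = go_response_density(0.8, WINNER, LOSER, pgf=0.0)
        expected = wald_density(0.5, 3.0, 1.0) * wald_survival(0.5, 1.5, 1.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_certain_go_failure_kills_response_density(self):
        for rt in (0.3, 0.8, 1.5):
            assert go_response_density(rt, WINNER, LOSER, pgf=1.0) == 0.0

    def test_zero_before_nondecision_time(self):
        assert go_response_density(0.29, WINNER, LOSER, pgf=0.0) == 0.0
        assert go_response_density(0.3, WINNER, LOSER, pgf=0.0) == 0.0

    def test_loser_survival_is_one_before_its_t0(self):
        early_loser = GoRunnerParams(v=1.5, B=1.0, t0=0.9)
        got = go_response_density(0.8, WINNER, early_loser, pgf=0.0)
        assert got == pytest.approx(wald_density(0.5, 3.0, 1.0), rel=1e-12)

    @pytest.mark.parametrize("pgf", [0.0, 0.07, 1.0])
    def test_omission_probability_identity(self, pgf):
        assert go_omission_probability(pgf) == pgf

    @pytest.mark.parametrize("pgf", [0.0, 0.05, 0.3])
    def test_outcome_probabilities_conserve(self, pgf):
        """pgf + both responses' defective densities integrate to 1."""
        total = pgf
        for winner, loser in ((WINNER, LOSER), (LOSER, WINNER)):
            mass, _ = quad(
                go_response_density, 0.3, 20, args=(winner, loser, pgf), limit=200
            )
            total += mass
        assert total == pytest.approx(1.0, abs=1e-5)

    def test_matches_race_simulation(self, rng):
        """Defective response density integrates to the simulated win rate."""
        n = 200_000
        t_w = 0.3 + rng.wald(1.0 / 3.0, 1.0, size=n)
        t_l = 0.3 + rng.wald(1.0 / 1.5, 1.0, size=n)
        p_win_sim = np.mean(t_w < t_l)
        p_win, _ = quad(go_response_density, 0.3, 30, args=(WINNER, LOSER, 0.0), limit=200)
        assert p_win == pytest.approx(p_win_sim, abs=3 * np.sqrt(0.25 / n) + 1e-4)


class TestStopTrial:
    def test_certain_trigger_failure_collapses_to_go_density(self):
        for rt in (0.5, 0.8, 1.2):
            got = signal_respond_density(rt, 0.2, WINNER, LOSER, STOP, 0.05, 1.0)
            expected = 0.95 * wald_density(rt - 0.3, 3.0, 1.0) * wald_survival(
                rt - 0.3, 1.5, 1.0
            )
            assert got == pytest.approx(expected, rel=1e-12)

    def test_stop_survival_one_inside_truncation_bound(self):
        # rt - ssd below the 0.05 s support bound: stop cannot have finished
        rt, ssd = 0.64, 0.6
        got = signal_respond_density(rt, ssd, WINNER, LOSER, STOP, 0.0, 0.0)
        expected = wald_density(rt - 0.3, 3.0, 1.0) * wald_survival(rt - 0.3, 1.5, 1.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_inhibition_edge_cases(self):
        assert inhibition_probability(0.2, WINNER, LOSER, STOP, 1.0, 0.3) == 1.0
        assert inhibition_probability(0.2, WINNER, LOSER, STOP, 0.0, 1.0) == 0.0

    def test_instant_stop_always_wins(self):
        fast_stop = StopRunnerParams(mu=0.1, sigma=0.01, tau=0.01)
        p = inhibition_probability(0.0, WINNER, LOSER, fast_stop, 0.0, 0.0)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_respond_probability_complements(self):
        p_i = inhibition_probability(0.25, WINNER, LOSER, STOP, 0.02, 0.07)
        assert respond_probability(0.25, WINNER, LOSER, STOP, 0.02, 0.07) == pytest.approx(
            1 - p_i, abs=1e-12
        )

    @pytest.mark.parametrize("pgf,ptf", [(0.0, 0.0), (0.05, 0.1)])
    def test_stop_outcome_probabilities_conserve(self, pgf, ptf):
        total = inhibition_probability(0.2, WINNER, LOSER, STOP, pgf, ptf)
        for winner, loser in ((WINNER, LOSER), (LOSER, WINNER)):
            mass, _ = quad(
                signal_respond_density, 0.3, 20,
                args=(0.2, winner, loser, STOP, pgf, ptf), limit=200,
            )
            total += mass
        assert total == pytest.approx(1.0, abs=1e-5)

    def test_inhibition_matches_simulation(self, rng):
        n = 300_000
        for ssd in (0.1, 0.3, 0.5):
            responded, _ = simulate_stop_outcomes(
                n, WINNER, LOSER, STOP, 0.02, 0.07, ssd, rng
            )
            p_sim = 1 - responded.mean()
            p = inhibition_probability(ssd, WINNER, LOSER, STOP, 0.02, 0.07)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(p - p_sim) < 3 * se + 1e-4

    def test_signal_respond_density_matches_histogram(self, rng):
        n = 400_000
        ssd = 0.2
        responded, rt = simulate_stop_outcomes(n, WINNER, LOSER, STOP, 0.0, 0.1, ssd, rng)
        # density of the winner's responses only
        t_l = 0.3 + rng.wald(1.0 / 1.5, 1.0, size=n)
        edges = np.array([0.5, 0.6, 0.7, 0.8, 1.0])
        for lo, hi in zip(edges[:-1], edges[1:]):
            mass, _ = quad(
                signal_respond_density, lo, hi,
                args=(ssd, WINNER, LOSER, STOP, 0.0, 0.1), limit=200,
            )
            mass += quad(
                signal_respond_density, lo, hi,
                args=(ssd, LOSER, WINNER, STOP, 0.0, 0.1), limit=200,
            )[0]
            sim = np.mean(responded & (rt >= lo) & (rt < hi))
            se = np.sqrt(sim * (1 - sim) / n)
            assert abs(mass - sim) < 3 * se + 2e-4

    def test_monotone_in_ssd(self):
        grid = np.arange(0.0, 0.8, 0.1)
        vals = [respond_probability(s, WINNER, LOSER, STOP, 0.02, 0.07) for s in grid]
        assert np.all(np.diff(vals) >= -1e-9)

    def test_ssd_limits(self):
        late = respond_probability(25.0, WINNER, LOSER, STOP, 0.02, 0.07)
        assert late == pytest.approx(1 - 0.02, abs=1e-6)
        fast_stop = StopRunnerParams(mu=0.06, sigma=0.001, tau=0.001)
        early = respond_probability(0.0, WINNER, LOSER, fast_stop, 0.0, 0.07)
        assert early == pytest.approx(0.07, abs=1e-4)


class TestDatasetLoglik:
    def test_empty_dataset_is_zero(self, pmap, base_truth):
        assert dataset_loglik([], base_truth, pmap) == 0.0

    def test_single_go_trial_reduces_to_response_density(self, pmap, base_truth):
        cell = DesignCell("block", "blue", "easy", "blue")
        trial = Trial(cell=cell, response="blue", rt=0.7)
        winner = pmap.go_params(base_truth, cell, AccumulatorRole("blue"))
        loser = pmap.go_params(base_truth, cell, AccumulatorRole("orange"))
        mix = pmap.mixture_params(base_truth, cell)
        expected = np.log(go_response_density(0.7, winner, loser, mix.pgf))
        assert dataset_loglik([trial], base_truth, pmap) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_independent_per_trial_loop(self, pmap, base_truth, small_trials):
        """The dataset log-likelihood equals an explicitly written loop over
        per-trial scalar operations."""
        subset = small_trials[:50]
        expected = 0.0
        for tr in subset:
            cell = tr.cell
            mix = pmap.mixture_params(base_truth, cell)
            stop = pmap.stop_params(base_truth, cell)
            if tr.response is not None:
                other = "orange" if tr.response == "blue" else "blue"
                w = pmap.go_params(base_truth, cell, AccumulatorRole(tr.response))
                l = pmap.go_params(base_truth, cell, AccumulatorRole(other))
                if tr.is_stop:
                    lik = signal_respond_density(tr.rt, tr.ssd, w, l, stop, mix.pgf, mix.ptf)
                else:
                    lik = go_response_density(tr.rt, w, l, mix.pgf)
            elif tr.is_stop:
                gi = pmap.go_params(base_truth, cell, AccumulatorRole("blue"))
                gj = pmap.go_params(base_truth, cell, AccumulatorRole("orange"))
                lik = inhibition_probability(tr.ssd, gi, gj, stop, mix.pgf, mix.ptf)
            else:
                lik = mix.pgf
            expected += np.log(lik)
        assert dataset_loglik(subset, base_truth, pmap) == pytest.approx(
            expected, abs=1e-10
        )

    def test_trial_invariants(self):
        cell = DesignCell("block", "blue", "easy", "blue")
        with pytest.raises(ValueError):
            Trial(cell=cell, is_stop=False, ssd=0.2)
        with pytest.raises(ValueError):
            Trial(cell=cell, is_stop=True)
        with pytest.raises(ValueError):
            Trial(cell=cell, response="blue", rt=-0.1)
        with pytest.raises(ValueError):
            Trial(cell=cell, response=None, rt=0.5)


class TestCompiledTrials:
    def test_matches_reference_loglik(self, pmap, base_truth, small_trials):
        compiled = CompiledTrials(small_trials, pmap)
        ref = dataset_loglik(small_trials, base_truth, pmap)
        assert compiled.loglik(base_truth) == pytest.approx(ref, abs=2e-4)

    def test_numba_and_numpy_paths_agree(self, pmap, base_truth, small_trials, rng):
        fast = CompiledTrials(small_trials, pmap, use_numba=True)
        plain = CompiledTrials(small_trials, pmap, use_numba=False)
        thetas = base_truth[None, :] + 0.01 * rng.standard_normal((16, pmap.n_params))
        a = fast.loglik_many(thetas)
        b = plain.loglik_many(thetas)
        finite = np.isfinite(a) | np.isfinite(b)
        np.testing.assert_allclose(a[finite], b[finite], rtol=1e-9, atol=1e-8)

    def test_scale_floor_rejects_degenerate_stop_runner(self, pmap, base_truth, small_trials):
        compiled = CompiledTrials(small_trials, pmap)
        degenerate = base_truth.copy()
        degenerate[pmap.labels().index("tau")] = 1e-6
        assert compiled.loglik(degenerate) == -np.inf
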