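"""Posterior predictive summaries, bimodality diagnostics, recovery report."""

import numpy as np
import pandas as pd
import pytest

from rdex.assess import (
    RecoveryReport,
    bimodality_flag,
    defective_cdf_percentiles,
    inhibition_function,
    posterior_predict,
    srrt_by_ssd,
)
from rdex.design import build_map
from rdex.inference import PosteriorSamples
from rdex.likelihood import respond_probability
from rdex.simulate import BASE_TRUTH, make_schedule, simulate_dataset
from rdex.design import AccumulatorRole, DesignCell


class TestDefectiveCDF:
    def test_percentile_rule_on_uniform_grid(self):
        rts = np.arange(1, 101) / 100.0
        responses = np.array(["blue"] * 100, dtype=object)
        table = defective_cdf_percentiles(rts, responses)
        row = table.iloc[0]
        assert row["p10"] == pytest.approx(0.10, abs=1e-12)
        assert row["p50"] == pytest.approx(0.50, abs=1e-12)
        assert row["p90"] == pytest.approx(0.90, abs=1e-12)
        assert row["proportion"] == 1.0

    def test_asymptotes_split_by_response(self):
        rts = np.concatenate([np.linspace(0.4, 1, 60), np.linspace(0.5, 1.2, 40)])
        responses = np.array(["blue"] * 60 + ["orange"] * 40, dtype=object)
        table = defective_cdf_percentiles(rts, responses).set_index("response")
        assert table.loc["blue", "proportion"] == pytest.approx(0.6)
        assert table.loc["orange", "proportion"] == pytest.approx(0.4)

    def test_omissions_reduce_asymptote_sum(self):
        rts = np.array([0.5, 0.6, np.nan, np.nan])
        responses = np.array(["blue", "blue", "none", "none"], dtype=object)
        table = defective_cdf_percentiles(rts, responses)
        assert table["proportion"].sum() == pytest.approx(0.5)

    def test_percentiles_nondecreasing(self, small_dataset):
        table = defective_cdf_percentiles(
            small_dataset.rt.to_numpy(), small_dataset.response.to_numpy()
        )
        cols = ["p10", "p30", "p50", "p70", "p90"]
        for _, row in table.iterrows():
            assert np.all(np.diff(row[cols].to_numpy(dtype=float)) >= 0)


class TestInhibitionFunction:
    def test_flat_at_one_when_all_respond(self):
        ssd = np.linspace(0.1, 0.5, 40)
        table = inhibition_function(ssd, np.ones(40, dtype=bool), n_bins=4)
        assert (table.p_respond == 1.0).all()

    def test_equal_count_bins(self):
        ssd = np.arange(23) * 0.01
        table = inhibition_function(ssd, np.zeros(23, dtype=bool), n_bins=5)
        assert table.n.max() - table.n.min() <= 1
        assert table.n.sum() == 23

    def test_bin_reduction_warns(self):
        with pytest.warns(UserWarning):
            inhibition_function(np.array([0.1, 0.2]), np.array([True, False]), n_bins=5)

    def test_matches_respond_probability_oracle(self, rng):
        """Binned response rates on simulated stop trials match the model's
        inhibition function at the bin-mean SSDs."""
        from rdex.distributions import GoRunnerParams, StopRunnerParams
        from rdex.simulate import simulate_stop_outcomes

        go_i = GoRunnerParams(v=3.0, B=1.8, t0=0.25)
        go_j = GoRunnerParams(v=1.2, B=1.9, t0=0.25)
        stop = StopRunnerParams(mu=0.2, sigma=0.04, tau=0.08)
        ssds = np.repeat([0.1, 0.2, 0.3, 0.4, 0.5], 20_000)
        responded = np.empty(ssds.size, dtype=bool)
        for s in np.unique(ssds):
            mask = ssds == s
            responded[mask], _ = simulate_stop_outcomes(
                int(mask.sum()), go_i, go_j, stop, 0.02, 0.07, s, rng
            )
        table = inhibition_function(ssds, responded, n_bins=5)
        for _, row in table.iterrows():
            p = respond_probability(row.mean_ssd, go_i, go_j, stop, 0.02, 0.07)
            se = np.sqrt(p * (1 - p) / row.n)
            assert abs(row.p_respond - p) < 3 * se + 1e-3


class TestSRRT:
    def test_medians_increase_with_ssd_without_trigger_failures(self, rng):
        """Signal-respond RT rises with SSD when every stop runner fires."""
        from rdex.distributions import GoRunnerParams, StopRunnerParams
        from rdex.simulate import simulate_stop_outcomes

        go_i = GoRunnerParams(v=3.0, B=1.8, t0=0.25)
        go_j = GoRunnerParams(v=1.2, B=1.9, t0=0.25)
        stop = StopRunnerParams(mu=0.2, sigma=0.04, tau=0.08)
        levels = np.array([0.15, 0.3, 0.45, 0.6])
        ssds = np.repeat(levels, 20_000)
        rts = np.empty(ssds.size)
        for s in levels:
            mask = ssds == s
            _, rts[mask] = simulate_stop_outcomes(
                int(mask.sum()), go_i, go_j, stop, 0.0, 0.0, s, rng
            )
        table = srrt_by_ssd(ssds, rts, n_bins=4)
        assert len(table) == 4
        assert np.all(np.diff(table.median_srrt) > 0)

    def test_single_trial_bin_and_empty_bins(self):
        ssd = np.array([0.1, 0.3, 0.5])
        rt = np.array([0.62, np.nan, np.nan])
        table = srrt_by_ssd(ssd, rt, n_bins=3)
        assert len(table) == 1
        assert table.iloc[0].median_srrt == pytest.approx(0.62)


class TestBimodalityFlag:
    def test_unimodal_not_flagged(self, rng):
        flag = bimodality_flag(rng.normal(0.3, 0.05, 500))
        assert not flag.bimodal and flag.n_modes == 1

    def test_separated_mixture_flagged(self, rng):
        draws = np.concatenate([rng.normal(0.15, 0.01, 250), rng.normal(0.4, 0.01, 250)])
        flag = bimodality_flag(draws)
        assert flag.bimodal and flag.n_modes == 2
        locs = sorted(flag.mode_locations)
        assert locs[0] == pytest.approx(0.15, abs=0.03)
        assert locs[1] == pytest.approx(0.4, abs=0.03)

    def test_small_secondary_mass_ignored(self, rng):
        draws = np.concatenate([rng.normal(0.0, 0.01, 970), rng.normal(1.0, 0.01, 30)])
        assert not bimodality_flag(draws, min_mass=0.10).bimodal

    def test_boundary_pileup_detected(self, rng):
        draws = np.concatenate([
            np.full(200, 0.1) + rng.uniform(0, 0.004, 200),
            rng.normal(0.3, 0.05, 300),
        ])
        flag = bimodality_flag(draws, bounds=(0.1, 1.0))
        assert flag.boundary_pileup

    def test_constant_draws_degenerate(self):
        flag = bimodality_flag(np.full(50, 0.2))
        assert not flag.bimodal and flag.n_modes == 1


class TestRecoveryReport:
    def _perfect_report(self, pmap, n_sets=4, n_reps=3):
        rng = np.random.default_rng(0)
        truths = BASE_TRUTH(pmap)[None, :] + 0.3 * rng.standard_normal(
            (n_sets, pmap.n_params)
        )
        means = np.repeat(truths[:, None, :], n_reps, axis=1)
        return RecoveryReport(
            truths=truths,
            means=means,
            ci_low=means - 1.0,
            ci_high=means + 1.0,
            labels=pmap.labels(),
        )

    def test_perfect_estimates_give_unit_scores(self, pmap):
        report = self._perfect_report(pmap)
        corr = report.correlation_by_type()
        assert all(c == pytest.approx(1.0, abs=1e-12) for c in corr.values())
        assert np.all(report.coverage() == 1.0)
        assert np.all(np.abs(report.bias()) < 1e-12)

    def test_failed_fits_recorded_not_fatal(self, pmap):
        report = self._perfect_report(pmap)
        report.means[0, 0, :] = np.nan
        cov = report.coverage()
        assert np.all(np.isfinite(cov))
        assert np.isfinite(report.averaged_means).all()


class TestPosteriorPredict:
    @pytest.fixture(scope="class")
    def point_samples(self, pmap, base_truth):
        draws = np.tile(base_truth, (4, 25, 1))
        return PosteriorSamples(draws, pmap.labels(), 1, 0, True)

    def test_counts_and_ssds_preserved(self, small_dataset, point_samples, pmap):
        reps = posterior_predict(small_dataset, point_samples, pmap, n_draws=3, seed=1)
        assert len(reps) == 3
        obs_counts = small_dataset.groupby(
            ["block_type", "bias", "difficulty", "stimulus", "trial_type"]
        ).size()
        for rep in reps:
            counts = rep.groupby(
                ["block_type", "bias", "difficulty", "stimulus", "trial_type"]
            ).size()
            pd.testing.assert_series_equal(counts, obs_counts)
            np.testing.assert_array_equal(
                rep.loc[rep.trial_type == "stop", "ssd"].to_numpy(),
                small_dataset.loc[small_dataset.trial_type == "stop", "ssd"].to_numpy(),
            )

    def test_point_posterior_reproduces_simulator(self, small_dataset, point_samples, pmap, base_truth):
        """With a point posterior the predictive draw equals a direct
        simulator call under the same rng."""
        rep = posterior_predict(
            small_dataset, point_samples, pmap, n_draws=1, seed=9
        )[0]
        rng = np.random.default_rng(9)
        rng.integers(4, size=1)
        rng.integers(25, size=1)
        schedule = small_dataset[
            ["session", "block", "trial", "block_type", "bias", "difficulty", "stimulus"]
        ].copy()
        schedule["is_stop"] = (small_dataset.trial_type == "stop").to_numpy()
        ssd = small_dataset.loc[small_dataset.trial_type == "stop", "ssd"].to_numpy()
        direct = simulate_dataset(
            schedule, base_truth, pmap, rng=rng, fixed_ssd=ssd
        )
        pd.testing.assert_frame_equal(rep, direct)

    def test_insufficient_draws_rejected(self, small_dataset, point_samples, pmap):
        with pytest.raises(ValueError):
            posterior_predict(small_dataset, point_samples, pmap, n_draws=1000)


class TestPredictiveSelfConsistency:
    def test_observed_statistics_inside_predictive_intervals(self, pmap, base_truth):
        """Datasets simulated at known parameters fall inside the 95%
        predictive intervals of a point posterior at those parameters at
        close to the nominal rate."""
        rng = np.random.default_rng(17)
        schedule = make_schedule(rng=rng)

        def stats(tab):
            go = tab[tab.trial_type == "go"]
            stop = tab[tab.trial_type == "stop"]
            return (
                go.rt.median(),
                (go.response != "none").mean(),
                (stop.response != "none").mean(),
            )

        n_pred, n_obs = 150, 120
        pred = np.array([
            stats(simulate_dataset(schedule, base_truth, pmap, rng=rng))
            for _ in range(n_pred)
        ])
        lo, hi = np.percentile(pred, [2.5, 97.5], axis=0)
        obs = np.array([
            stats(simulate_dataset(schedule, base_truth, pmap, rng=rng))
            for _ in range(n_obs)
        ])
        inside = ((obs >= lo) & (obs <= hi)).mean()
        assert 0.88 <= inside <= 1.0


class TestPlots:
    def test_figures_render(self, small_dataset, pmap, base_truth):
        import matplotlib
        matplotlib.use("Agg")
        from rdex.plots import plot_defective_cdfs, plot_inhibition_function, plot_recovery

        ax = plot_defective_cdfs(small_dataset)
        assert ax.get_xlabel() == "RT (s)"
        stop = small_dataset[small_dataset.trial_type == "stop"]
        obs = inhibition_function(
            stop.ssd.to_numpy(), (stop.response != "none").to_numpy()
        )
        ax = plot_inhibition_function(obs)
        assert ax.get_ylabel() == "p(respond)"
        rng = np.random.default_rng(0)
        truths = BASE_TRUTH(pmap)[None, :] + 0.2 * rng.standard_normal((3, 22))
        means = truths[:, None, :] + 0.01 * rng.standard_normal((3, 2, 22))
        report = RecoveryReport(truths, means, means - 1, means + 1, pmap.labels())
        axes = plot_recovery(report)
        assert len(np.atleast_1d(axes)) == 3
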