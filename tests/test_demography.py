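"""Size-change inference: summaries, PSRF, reporting, posterior contracts."""

import numpy as np
import pandas as pd
import pytest

from streamscape import demography as dem
from streamscape import synthetic

from conftest import make_dataset


class TestSummaryStatistics:
    def test_monomorphic_locus_vector(self):
        calls = np.full((5, 2, 2), 100)
        data = make_dataset(["P"] * 5, calls)
        stats = dem.summary_statistics(data)
        assert np.allclose(stats, [0.0, 1.0, 0.0, 0.0, 1.0])

    def test_hand_variance_and_m_ratio(self):
        # one locus, gene copies (100, 100, 100, 102)
        calls = np.array([[[100, 100], [100, 100]],
                          [[100, 102], [100, 100]]])
        data = make_dataset(["P"] * 2, calls)
        stats = dem.summary_statistics(data)
        # locus 1: genes (100,100,100,102): var=1.0, k=2, range=2, M=2/3
        # locus 2: monomorphic
        assert stats[2] == pytest.approx((1.0 + 0.0) / 2)
        assert stats[1] == pytest.approx(1.5)
        assert stats[4] == pytest.approx((2 / 3 + 1.0) / 2)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(20, 30, size=(10, 3, 2))
        a = dem.summary_statistics(make_dataset(["P"] * 10, calls))
        b = dem.summary_statistics(make_dataset(["P"] * 10, calls + 10))
        assert np.allclose(a, b)


class TestDiscardAndThin:
    def test_arithmetic(self):
        assert len(dem.discard_and_thin(np.arange(100), 0.1, 1)) == 90
        assert len(dem.discard_and_thin(np.arange(100), 0.1, 10)) == 9
        assert np.array_equal(dem.discard_and_thin(np.arange(10), 0.0, 1),
                              np.arange(10))

    def test_bad_thin_rejected(self):
        with pytest.raises(ValueError):
            dem.discard_and_thin(np.arange(10), 0.1, 0)


class TestPsrf:
    def test_identical_replicates_formula(self):
        out = dem.psrf({"x": [np.tile([1.0, 2, 3], 4),
                              np.tile([1.0, 2, 3], 4)]})
        n = 12
        assert out.psrf.iloc[0] == pytest.approx(np.sqrt((n - 1) / n))

    def test_hand_three_point_chains(self):
        chains = [np.array([1.0, 2, 3] * 4), np.array([1.0, 2, 3] * 4)]
        # B = 0 so R_hat = sqrt((n-1)/n); with n=12 -> sqrt(11/12)
        out = dem.psrf({"x": chains})
        assert out.psrf.iloc[0] == pytest.approx(np.sqrt(11 / 12))

    def test_separated_chains_fail(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 100)
        b = rng.normal(10, 1, 100)
        out = dem.psrf({"x": [a, b]})
        assert out.psrf.iloc[0] > 1.2
        assert not out.converged.iloc[0]

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            dem.psrf({"x": [np.arange(20.0)]})


def degenerate_posterior(log_n0, log_n1, log_ta, reps=2, n=40):
    frames = []
    for rep in range(reps):
        frames.append(pd.DataFrame({
            "log10_N0": np.full(n, log_n0),
            "log10_N1": np.full(n, log_n1),
            "log10_Ta": np.full(n, log_ta),
            "log10_mu": np.full(n, -3.5),
            "replicate": rep,
        }))
    return dem.DemographicPosterior(pd.concat(frames, ignore_index=True),
                                    1000, 0.05)


class TestSizeChangeSummary:
    def test_equal_sizes_stable(self):
        post = degenerate_posterior(3.0, 3.0, 2.0)
        s = dem.size_change_summary(post)
        assert s.classification == "stable"
        assert np.allclose(s.r_samples, 1.0)

    def test_tenfold_larger_n0_expansion(self):
        post = degenerate_posterior(4.0, 3.0, 2.0)
        assert dem.size_change_summary(post).classification == "expansion"

    def test_constructed_interval_covers_one(self):
        samples = pd.DataFrame({
            "log10_N0": np.log10([0.5, 0.8, 1.0, 1.2]),
            "log10_N1": np.zeros(4),
            "log10_Ta": np.full(4, 2.0),
            "log10_mu": np.full(4, -3.5),
            "replicate": 0,
        })
        post = dem.DemographicPosterior(samples, 1000, 0.05)
        s = dem.size_change_summary(post)
        assert s.r_samples.mean() == pytest.approx(0.875)
        assert s.classification == "stable"

    def test_pointwise_ratio_differs_from_ratio_of_means(self):
        # skewed joint draws: mean(N0/N1) != mean(N0)/mean(N1)
        samples = pd.DataFrame({
            "log10_N0": np.log10([100.0, 1000.0, 100.0, 1000.0]),
            "log10_N1": np.log10([1000.0, 100.0, 1000.0, 100.0]),
            "log10_Ta": np.full(4, 2.0),
            "log10_mu": np.full(4, -3.5),
            "replicate": 0,
        })
        post = dem.DemographicPosterior(samples, 1000, 0.05)
        s = dem.size_change_summary(post)
        ratio_of_means = (10.0 ** samples.log10_N0).mean() / \
            (10.0 ** samples.log10_N1).mean()
        assert s.r_samples.mean() != pytest.approx(ratio_of_means)


class TestReportTable:
    def test_generation_time_conversion(self):
        post = degenerate_posterior(3.63, 4.544, np.log10(67920))
        report = dem.report_table(post, generation_time_years=12.5)
        t_row = report[report.parameter == "T"].iloc[0]
        assert t_row.converted == pytest.approx(67920, rel=1e-9)
        assert t_row.years == pytest.approx(849000, rel=1e-9)

    def test_degenerate_log_n0_converts_exactly(self):
        post = degenerate_posterior(3.0, 3.0, 2.0)
        report = dem.report_table(post)
        assert report[report.parameter == "N0"].converted.iloc[0] == \
            pytest.approx(1000.0)

    def test_quantile_bounds_ordered(self):
        rng = np.random.default_rng(2)
        samples = pd.DataFrame({
            "log10_N0": rng.normal(3, 0.3, 200),
            "log10_N1": rng.normal(4, 0.3, 200),
            "log10_Ta": rng.normal(3, 0.5, 200),
            "log10_mu": np.full(200, -3.5),
            "replicate": np.repeat([0, 1], 100),
        })
        post = dem.DemographicPosterior(samples, 1000, 0.05)
        report = dem.report_table(post)
        assert (report["lower_0.025"] <= report["upper_0.975"]).all()


class TestReportingHelpers:
    def test_percent_smaller_rounding(self):
        assert dem.percent_smaller(2138, 34995) == 94

    def test_proportion_truncation(self):
        assert dem.proportion_pct(5, 13) == 38.4
        assert dem.proportion_pct(2, 20) == 10.0
        assert dem.proportion_pct(2, 6) == 33.3

    def test_years_since_change(self):
        assert dem.years_since_change(67920, 12.5) == 849000.0


class TestInferPosterior:
    def test_point_mass_prior_returns_prior_point(self):
        data = synthetic.simulate_size_change_sample(
            200, 200, 50, 1e-3, 15, 6, seed=4
        )
        priors = dem.PriorSpec({
            "log10_N0": (2.3, 2.3), "log10_N1": (2.3, 2.3),
            "log10_Ta": (1.7, 1.7), "log10_mu": (-3.0, -3.0),
        })
        post = dem.infer_posterior(data, priors, n_sims=1000,
                                   accept_fraction=0.05, n_replicates=2,
                                   seed=1, adjust=False)
        assert np.allclose(post.samples.log10_N0, 2.3)
        assert np.allclose(post.samples.log10_mu, -3.0)

    def test_accepted_count_bookkeeping(self):
        data = synthetic.simulate_size_change_sample(
            200, 200, 50, 1e-3, 15, 6, seed=5
        )
        post = dem.infer_posterior(data, n_sims=1000, accept_fraction=0.02,
                                   n_replicates=3, seed=2)
        per_rep = post.samples.groupby("replicate").size()
        expected = round(0.02 * 1000)
        assert (per_rep == expected - int(0.10 * expected)).all()

    def test_seed_determinism(self):
        data = synthetic.simulate_size_change_sample(
            300, 300, 50, 1e-3, 12, 5, seed=6
        )
        a = dem.infer_posterior(data, n_sims=1000, accept_fraction=0.05,
                                n_replicates=2, seed=3)
        b = dem.infer_posterior(data, n_sims=1000, accept_fraction=0.05,
                                n_replicates=2, seed=3)
        pd.testing.assert_frame_equal(a.samples, b.samples)
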