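"""Subsampling, expansion estimation, the two CI constructions and the
effort experiment."""

import numpy as np
import pytest

from cliffcensus.errors import InsufficientDataError, ValidationError
from cliffcensus.grid_io import total_count
from cliffcensus.minimum_effort import (
    EffortRecord,
    SubsampleDesign,
    ci_maximum_likelihood,
    ci_simple_bootstrap,
    draw_subsample,
    estimate_total,
    records_to_frame,
    render_effort_plots,
    run_effort_analysis,
    subsample_size,
    summarize_effort,
)

from conftest import make_census


class TestDesign:
    def test_default_fractions_span_90_down_to_5(self):
        d = SubsampleDesign()
        assert len(d.fractions) == 18
        assert d.fractions[0] == 0.90 and d.fractions[-1] == 0.05
        assert d.repetitions == 25 and d.bootstrap_B == 10_000

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValidationError):
            SubsampleDesign(fractions=(0.5, 0.9))  # not decreasing
        with pytest.raises(ValidationError):
            SubsampleDesign(fractions=(1.5,))
        with pytest.raises(ValidationError):
            SubsampleDesign(bootstrap_B=10)
        with pytest.raises(ValidationError):
            SubsampleDesign(repetitions=0)


class TestDrawSubsample:
    def test_55_percent_of_100_cells(self):
        census = make_census(np.arange(100))
        sample = draw_subsample(census, 0.55, np.random.default_rng(0))
        assert sample.size == 55

    def test_full_fraction_takes_every_included_cell(self):
        census = make_census([1, 2, 3, 4], included=[True, True, False, True])
        sample = draw_subsample(census, 1.0, np.random.default_rng(0))
        assert sorted(sample) == [1, 2, 4]

    def test_deterministic_given_seed(self, poisson_census):
        a = draw_subsample(poisson_census, 0.4, np.random.default_rng(42))
        b = draw_subsample(poisson_census, 0.4, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_without_replacement(self, poisson_census):
        # sampled cells are distinct plots: size never exceeds population
        sample = draw_subsample(poisson_census, 1.0, np.random.default_rng(1))
        assert sample.size == poisson_census.n_included

    def test_rounding_half_up_with_floor(self):
        assert subsample_size(0.05, 147) == 7  # 7.35 -> 7
        assert subsample_size(0.05, 10) == 1   # 0.5 -> 1 (floor at one cell)
        assert subsample_size(0.55, 100) == 55

    def test_no_included_cells(self):
        census = make_census([1, 2], included=[False, False])
        with pytest.raises(InsufficientDataError):
            draw_subsample(census, 0.5, np.random.default_rng(0))


class TestEstimateTotal:
    def test_expansion_arithmetic(self):
        # subsample mean 4.2 expanded to 147 cells
        sample = [3, 4, 5, 4, 5]  # mean 4.2
        assert estimate_total(sample, 147, "poisson") == pytest.approx(617.4)

    @pytest.mark.parametrize("family", ["poisson", "geometric", "negative_binomial"])
    def test_full_sample_identity(self, poisson_census, family):
        counts = poisson_census.included_counts
        est = estimate_total(counts, counts.size, family)
        assert est == pytest.approx(total_count(poisson_census), rel=1e-9)

    def test_all_zero_subsample_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert estimate_total([0, 0, 0], 147, "geometric") == 0.0

    def test_unbiasedness_on_synthetic_grid(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(6, 200)
        census = make_census(counts)
        ests = []
        for rep in range(1000):
            sample = draw_subsample(census, 0.5, np.random.default_rng([10, rep]))
            ests.append(estimate_total(sample, 200, "poisson"))
        assert np.mean(ests) == pytest.approx(counts.sum(), rel=0.01)


class TestMLInterval:
    def test_identical_counts_zero_width(self):
        low, high = ci_maximum_likelihood([4, 4, 4, 4], 100, "poisson")
        assert low == high == 400.0

    def test_log_symmetry_and_z(self):
        rng = np.random.default_rng(12)
        x = rng.poisson(6, 80)
        t_hat = estimate_total(x, 147, "poisson")
        low, high = ci_maximum_likelihood(x, 147, "poisson", alpha=0.05)
        assert low < t_hat < high
        assert high / t_hat == pytest.approx(t_hat / low, rel=1e-9)
        # interval endpoints follow the 1.96-sigma log-normal construction
        s = np.sqrt(x.mean() / x.size) / x.mean()
        from scipy.stats import norm

        z = norm.ppf(0.975)
        assert high == pytest.approx(t_hat * np.exp(z * s), rel=1e-9)

    def test_zero_estimate_degenerate(self):
        with pytest.warns(UserWarning):
            assert ci_maximum_likelihood([0, 0, 0], 100, "poisson") == (0.0, 0.0)


class TestSBInterval:
    def test_constant_counts_zero_width(self):
        low, high = ci_simple_bootstrap([5, 5, 5], 100, rng=np.random.default_rng(0))
        assert low == high == 500.0

    def test_deterministic_given_rng(self):
        x = np.random.default_rng(13).poisson(5, 60)
        a = ci_simple_bootstrap(x, 147, B=1000, rng=np.random.default_rng(7))
        b = ci_simple_bootstrap(x, 147, B=1000, rng=np.random.default_rng(7))
        assert a == b

    def test_contains_point_estimate(self):
        x = np.random.default_rng(14).poisson(5, 60)
        t_hat = estimate_total(x, 147, "poisson")
        low, high = ci_simple_bootstrap(x, 147, B=2000, rng=np.random.default_rng(1))
        assert low <= t_hat <= high

    def test_stabilises_at_large_B(self):
        # two independent resampling streams at B=10,000 agree within 2%
        x = np.random.default_rng(15).poisson(5, 70)
        a = ci_simple_bootstrap(x, 147, B=10_000, rng=np.random.default_rng(100))
        b = ci_simple_bootstrap(x, 147, B=10_000, rng=np.random.default_rng(200))
        assert abs(a[0] - b[0]) / b[0] < 0.02
        assert abs(a[1] - b[1]) / b[1] < 0.02

    def test_small_B_rejected(self):
        with pytest.raises(ValidationError):
            ci_simple_bootstrap([1, 2, 3], 10, B=50)


class TestRunEffortAnalysis:
    def test_record_count_and_reproducibility(self, poisson_census):
        design = SubsampleDesign(fractions=(0.8, 0.4, 0.1), repetitions=4,
                                 bootstrap_B=300, seed=5)
        a = run_effort_analysis(poisson_census, design)
        b = run_effort_analysis(poisson_census, design)
        assert len(a) == 12
        assert records_to_frame(a).to_csv() == records_to_frame(b).to_csv()

    def test_degenerate_design_recovers_census_total(self, poisson_census):
        design = SubsampleDesign(fractions=(1.0,), repetitions=1, bootstrap_B=200, seed=1)
        rec = run_effort_analysis(poisson_census, design)[0]
        assert rec.estimated_total == pytest.approx(total_count(poisson_census))

    def test_intervals_bracket_estimates(self, poisson_census):
        design = SubsampleDesign(fractions=(0.6, 0.2), repetitions=5, bootstrap_B=500, seed=2)
        for rec in run_effort_analysis(poisson_census, design):
            assert rec.ci_ml[0] <= rec.estimated_total <= rec.ci_ml[1]
            # percentile interval: allow resampling discreteness
            w = rec.ci_sb[1] - rec.ci_sb[0]
            assert rec.ci_sb[0] - 0.05 * w <= rec.estimated_total <= rec.ci_sb[1] + 0.05 * w


class TestSummarize:
    def test_constant_records_reproduced_exactly(self):
        records = [
            EffortRecord(0.5, rep, 50, 600.0, (550.0, 650.0), (560.0, 640.0))
            for rep in range(5)
        ]
        s = summarize_effort(records, census_total=600.0)
        row = s.table.iloc[0]
        assert row["ml_mean_low"] == 550.0 and row["ml_mean_high"] == 650.0
        assert row["sb_mean_width"] == 80.0
        assert row["ml_coverage"] == 1.0

    def test_method_choice_follows_smaller_width(self):
        narrow_ml = [EffortRecord(0.55, r, 55, 600.0, (590.0, 610.0), (500.0, 700.0))
                     for r in range(3)]
        assert summarize_effort(narrow_ml, 600.0).recommended_method == "ML"
        narrow_sb = [EffortRecord(0.55, r, 55, 600.0, (500.0, 700.0), (590.0, 610.0))
                     for r in range(3)]
        assert summarize_effort(narrow_sb, 600.0).recommended_method == "SB"

    def test_recommended_fraction_is_smallest_qualifying(self):
        def rec(frac, half):
            return EffortRecord(frac, 0, 10, 600.0,
                                (600.0 - half, 600.0 + half), (600.0 - half, 600.0 + half))

        # half-widths: 30% at fraction .2, 10% at .5, 5% at .8
        records = [rec(0.2, 180.0), rec(0.5, 60.0), rec(0.8, 30.0)]
        s = summarize_effort(records, 600.0, rel_halfwidth_tol=0.15, coverage_floor=0.9)
        assert s.recommended_fraction == 0.5

    def test_no_fraction_qualifies(self):
        records = [EffortRecord(0.5, 0, 10, 600.0, (0.0, 1200.0), (0.0, 1200.0))]
        s = summarize_effort(records, 600.0, rel_halfwidth_tol=0.15)
        assert s.recommended_fraction is None

    def test_empty_records_rejected(self):
        with pytest.raises(ValidationError):
            summarize_effort([], 600.0)


class TestRenderEffortPlots:
    def test_writes_three_figures(self, tmp_path, poisson_census):
        design = SubsampleDesign(fractions=(0.6, 0.3), repetitions=3, bootstrap_B=200, seed=3)
        records = run_effort_analysis(poisson_census, design)
        summary = summarize_effort(records, total_count(poisson_census))
        paths = render_effort_plots(records, summary, tmp_path)
        assert len(paths) == 3
        assert all(p.exists() and p.stat().st_size > 0 for p in paths)

    def test_empty_records_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            render_effort_plots([], None, tmp_path)
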