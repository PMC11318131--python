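"""Scale construction and the variance from outcome categorisation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from noisy_measures import (
    categorisation_variance,
    constrained_normal_distribution,
    make_scale,
    sample_discretised_normal,
    table1,
    uniform_distribution,
)


class TestMakeScale:
    @pytest.mark.parametrize(
        "M, midpoints",
        [
            (1, [49.5]),
            (2, [24.75, 74.5]),
            (3, [16.5, 49.5, 82.5]),
            (5, [9.5, 29.5, 49.5, 69.5, 89.5]),
            (10, [4.5, 14.5, 24.5, 34.5, 44.5, 54.5, 64.5, 74.5, 84.5, 94.5]),
        ],
    )
    def test_published_midpoints_on_canonical_scale(self, M, midpoints):
        scale = make_scale(M)
        assert scale.midpoints == pytest.approx(midpoints)

    def test_identity_categorisation(self):
        scale = make_scale(100)
        assert scale.M == 100
        assert scale.midpoints == pytest.approx(np.arange(100))

    def test_mean_convention_dichotomy_is_symmetric(self):
        scale = make_scale(2, convention="mean")
        assert scale.midpoints == pytest.approx([24.5, 74.5])

    @pytest.mark.parametrize("M", [0, -1, 101])
    def test_invalid_category_counts_rejected(self, M):
        with pytest.raises(ValueError):
            make_scale(M, 0, 99)

    @given(
        lo=st.integers(-50, 50),
        width=st.integers(1, 200),
        M=st.integers(1, 30),
        convention=st.sampled_from(["published", "mean"]),
    )
    def test_partition_invariants(self, lo, width, M, convention):
        """Categories are disjoint, exhaustive and carry in-range midpoints."""
        hi = lo + width
        if M > hi - lo + 1:
            with pytest.raises(ValueError):
                make_scale(M, lo, hi, convention)
            return
        scale = make_scale(M, lo, hi, convention)
        support = np.arange(lo, hi + 1)
        cats = scale.category_of(support)
        # every integer in exactly one category, categories contiguous 0..M-1
        assert cats.min() == 0 and cats.max() == M - 1
        assert np.all(np.diff(cats) >= 0)
        assert len(np.unique(cats)) == M
        assert np.all(np.diff(scale.midpoints) > 0)
        # each midpoint inside its own category's span
        for m in range(M):
            block = support[cats == m]
            assert block.min() - 0.5 <= scale.midpoints[m] <= block.max() + 0.5


class TestDistributions:
    def test_uniform_mass_and_variance(self):
        d = uniform_distribution(0, 99)
        assert d.pmf == pytest.approx(np.full(100, 0.01))
        assert d.variance(about=49.5) == pytest.approx(833.25)

    def test_uniform_binary_spread(self):
        assert uniform_distribution(0, 1).variance() == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "sigma, expected",
        [(5.0, 25.08), (10.0, 100.11), (15.0, 222.51), (20.0, 362.63), (25.0, 479.07)],
    )
    def test_constrained_normal_nonmeasurement_variance(self, sigma, expected):
        """Truncate-at-endpoints binning reproduces the published variances."""
        d = constrained_normal_distribution(49.5, sigma)
        assert d.variance(about=49.5) == pytest.approx(expected, rel=5e-3)

    def test_narrow_normal_concentrates_on_four_points(self):
        d = constrained_normal_distribution(49.5, 0.5)
        mass = d.pmf[(d.support >= 48) & (d.support <= 51)].sum()
        assert mass > 0.999

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            constrained_normal_distribution(49.5, 0.0)

    @given(
        mu=st.floats(2, 97),
        sigma=st.floats(0.3, 60),
    )
    def test_pmf_normalised(self, mu, sigma):
        d = constrained_normal_distribution(mu, sigma)
        assert abs(d.pmf.sum() - 1.0) <= 1e-12
        assert np.all(d.pmf >= 0)

    def test_sample_discretisation_close_to_analytic(self):
        analytic = constrained_normal_distribution(49.5, 10.0)
        sampled = sample_discretised_normal(49.5, 10.0, n=400_000, seed=7)
        assert sampled.variance() == pytest.approx(analytic.variance(), rel=0.01)


class TestCategorisationVariance:
    @pytest.mark.parametrize(
        "M, expected_var, expected_pct",
        [
            (2, 208.28, 75.0),
            (3, 92.73, 88.8),
            (5, 33.25, 96.0),
            (10, 8.25, 99.0),
        ],
    )
    def test_uniform_cells(self, M, expected_var, expected_pct):
        res = categorisation_variance(uniform_distribution(), make_scale(M))
        assert res.sigma_c_sq == pytest.approx(expected_var, abs=5e-3)
        assert res.pct_reduction == pytest.approx(expected_pct, abs=0.15)

    def test_perfect_measurement_for_any_distribution(self):
        scale = make_scale(100)
        for dist in (uniform_distribution(), constrained_normal_distribution(49.5, 8)):
            assert categorisation_variance(dist, scale).sigma_c_sq == 0.0

    def test_miscalibrated_scale_can_be_worse_than_no_measurement(self):
        """A dichotomy on a tight distribution inflates error: negative reduction."""
        dist = constrained_normal_distribution(49.5, 5.0)
        res2 = categorisation_variance(dist, make_scale(2))
        res3 = categorisation_variance(dist, make_scale(3))
        assert res2.sigma_c_sq == pytest.approx(444.73, abs=0.01)
        assert res2.pct_reduction < 0
        assert res3.pct_reduction > 0

    def test_support_must_fit_scale(self):
        with pytest.raises(ValueError):
            categorisation_variance(uniform_distribution(0, 120), make_scale(5, 0, 99))

    def test_uniform_variance_nonincreasing_in_category_count(self):
        values = [
            categorisation_variance(uniform_distribution(), make_scale(M)).sigma_c_sq
            for M in (1, 2, 3, 5, 8, 10, 15, 100)
        ]
        assert np.all(np.diff(values) <= 0)

    @pytest.mark.parametrize("M", [4, 10, 20, 25, 50])
    def test_uniform_closed_form_for_divisible_counts(self, M):
        """Equal blocks of b points give sigma_c^2 = (b^2 - 1) / 12."""
        b = 100 // M
        res = categorisation_variance(uniform_distribution(), make_scale(M, convention="mean"))
        assert res.sigma_c_sq == pytest.approx((b**2 - 1) / 12)

    @pytest.mark.parametrize(
        "dist_builder, M",
        [
            (uniform_distribution, 3),
            (lambda: constrained_normal_distribution(49.5, 10.0), 5),
        ],
    )
    def test_monte_carlo_oracle(self, dist_builder, M):
        """Analytic sigma_c^2 agrees with simulated squared assignment error."""
        dist = dist_builder()
        scale = make_scale(M)
        analytic = categorisation_variance(dist, scale).sigma_c_sq
        rng = np.random.default_rng(20260922)
        draws = dist.sample(1_000_000, rng)
        sq_err = (draws - scale.assign(draws)) ** 2
        se = sq_err.std() / np.sqrt(len(sq_err))
        assert abs(sq_err.mean() - analytic) < 3 * se


class TestTable1Driver:
    def test_uniform_column_layout(self):
        df = table1(category_counts=(1, 2, 3, 5, 8, 10, 15, 100), sds=())
        assert set(df.columns) == {"M", "family", "sd", "sigma_c_sq", "pct_reduction"}
        assert (df.family == "uniform").all()
        got = df.set_index("M").sigma_c_sq
        assert got.loc[1] == pytest.approx(833.25)
        assert got.loc[8] == pytest.approx(13.06, abs=5e-3)
        assert got.loc[100] == 0.0

    def test_single_cell(self):
        df = table1(category_counts=(1,), sds=(10.0,), include_uniform=False)
        assert len(df) == 1
        assert df.sigma_c_sq.iloc[0] == pytest.approx(100.11, rel=5e-3)

    def test_grid_cardinality(self):
        df = table1(category_counts=(2, 5), sds=(5.0, 25.0))
        assert len(df) == 2 * 3  # two normals + uniform per M
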