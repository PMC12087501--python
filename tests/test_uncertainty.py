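"""Bootstrap-within-imputation, subsampling and E-value behaviour."""

import numpy as np
import pandas as pd
import pytest

import ptbmediation as pm
from ptbmediation.uncertainty import percentile_bounds


def _bernoulli_df(n, p, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({"y": (rng.random(n) < p).astype(float)})


def mean_stat(df):
    return float(df["y"].to_numpy().mean())


class TestPercentileRanks:
    def test_literal_rank_convention(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=10_000)
        lo, hi = percentile_bounds(values)
        s = np.sort(values)
        assert lo == s[249]
        assert hi == s[9749]

    def test_pooled_count_m10_b1000(self):
        datasets = [_bernoulli_df(60, 0.4, seed=i) for i in range(10)]
        est = pm.bootstrap_mi_ci(mean_stat, datasets, b_per_imputation=1000, seed=5)
        assert est.n_resamples == 10_000
        assert est.method == "percentile_bootstrap_mi"
        assert est.lower <= est.upper

    def test_determinism(self):
        datasets = [_bernoulli_df(200, 0.3, seed=1)]
        a = pm.bootstrap_mi_ci(mean_stat, datasets, b_per_imputation=200, seed=9)
        b = pm.bootstrap_mi_ci(mean_stat, datasets, b_per_imputation=200, seed=9)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_constant_statistic_zero_width(self):
        datasets = [_bernoulli_df(100, 0.5, seed=2)]
        est = pm.bootstrap_mi_ci(lambda d: 3.14, datasets, b_per_imputation=100, seed=1)
        assert est.lower == est.upper == est.point == 3.14

    def test_binomial_ci_agreement(self):
        """Percentile bootstrap CI width for a Bernoulli mean is close to the
        exact (Clopper-Pearson-free, normal-approx) binomial interval."""
        n, p = 10_000, 0.3
        df = _bernoulli_df(n, p, seed=3)
        est = pm.bootstrap_mi_ci(mean_stat, [df], b_per_imputation=1000, seed=4)
        phat = mean_stat(df)
        se = np.sqrt(phat * (1 - phat) / n)
        exact_width = 2 * 1.959963984540054 * se
        boot_width = est.upper - est.lower
        assert abs(boot_width - exact_width) / exact_width < 0.10

    def test_failure_tolerance(self):
        datasets = [_bernoulli_df(50, 0.5, seed=6)]

        def flaky(d):
            raise RuntimeError("always fails")

        with pytest.raises(RuntimeError, match="resamples failed"):
            pm.bootstrap_mi_ci(flaky, datasets, b_per_imputation=20, seed=0)


class TestSubsampling:
    def test_subsample_size_arithmetic(self):
        assert pm.subsample_size(10_000) == 631
        assert pm.subsample_size(100, 0.7) == round(100**0.7)

    def test_constant_statistic_zero_width(self):
        datasets = [_bernoulli_df(500, 0.5, seed=7)]
        est = pm.subsampling_ci(lambda d: 1.0, datasets, n_subsamples=50, seed=1)
        assert est.lower == est.upper == 1.0
        assert est.method == "subsampling"

    def test_subsamples_are_without_replacement(self):
        df = pd.DataFrame({"y": np.arange(3000, dtype=float)})
        m = pm.subsample_size(3000)

        def unique_count(d):
            if len(d) < 3000:  # subsample draws (the point estimate sees the full data)
                assert d["y"].nunique() == m == len(d)
            return float(d["y"].mean())

        pm.subsampling_ci(unique_count, [df], n_subsamples=10, seed=2)

    def test_allocation_across_datasets(self):
        datasets = [_bernoulli_df(500, 0.5, seed=i) for i in range(3)]
        est = pm.subsampling_ci(mean_stat, datasets, n_subsamples=100, seed=3)
        assert est.n_resamples == 100

    def test_rate_corrected_narrower_for_mean(self):
        df = _bernoulli_df(5000, 0.4, seed=8)
        raw = pm.subsampling_ci(mean_stat, [df], n_subsamples=300, seed=4)
        corrected = pm.subsampling_ci(mean_stat, [df], n_subsamples=300, seed=4, rate_corrected=True)
        assert (corrected.upper - corrected.lower) < (raw.upper - raw.lower)

    def test_too_small_subsample_errors(self):
        df = _bernoulli_df(40, 0.5, seed=9)
        with pytest.raises(ValueError, match="too small"):
            pm.subsampling_ci(mean_stat, [df], n_subsamples=10, seed=0)


class TestEvalue:
    def test_null_is_one(self):
        assert pm.evalue(1.0).evalue_point == 1.0

    def test_closed_form_point(self):
        res = pm.evalue(1.26)
        assert res.evalue_point == pytest.approx(1.26 + np.sqrt(1.26 * 0.26), abs=1e-9)

    def test_inversion_symmetry(self):
        assert pm.evalue(0.5).evalue_point == pytest.approx(pm.evalue(2.0).evalue_point)

    def test_monotone_in_log_or(self):
        ors = [1.05, 1.2, 1.5, 2.0, 3.0]
        evs = [pm.evalue(o).evalue_point for o in ors]
        assert all(a < b for a, b in zip(evs, evs[1:]))

    def test_ci_crossing_null_gives_one(self):
        assert pm.evalue(1.26, 0.98).evalue_ci_limit == 1.0
        assert pm.evalue(1.26, 1.10).evalue_ci_limit > 1.0

    def test_sqrt_or_approximation(self):
        res = pm.evalue(1.44, approximation="sqrt_or")
        rr = 1.2
        assert res.evalue_point == pytest.approx(rr + np.sqrt(rr * 0.2))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pm.evalue(-1.0)
        with pytest.raises(ValueError):
            pm.evalue(1.2, approximation="bogus")
        with pytest.raises(ValueError):
            pm.evalue(1.2, ci_limit_nearest_null=0.0)

    def test_evalue_at_least_one(self):
        for o in (0.2, 0.9, 1.0, 1.1, 4.0):
            assert pm.evalue(o).evalue_point >= 1.0
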