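import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ndoikit import (EntropyWeightNDOI, MonthlyCaseTable, SHANGHAI_WEIGHTS,
                     annual_ndoi_means, compute_ndoi, entropy_weights,
                     minmax_normalize, monthly_components)
from ndoikit.index import DegenerateSeriesWarning, StratumError, WeightError


class TestMinMaxNormalize:
    @pytest.mark.parametrize("series,expected", [
        ([2, 4, 6], [0.0, 0.5, 1.0]),
        ([10, 30, 20, 50], [0.0, 0.5, 0.25, 1.0]),
    ])
    def test_examples(self, series, expected):
        assert minmax_normalize(series).values == pytest.approx(expected)

    def test_constant_series_degenerate(self):
        with pytest.warns(DegenerateSeriesWarning):
            out = minmax_normalize([5, 5, 5])
        assert out.degenerate and out.values.tolist() == [0, 0, 0]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=20).filter(lambda xs: max(xs) > min(xs)),
           st.floats(0.01, 100), st.floats(-1e3, 1e3))
    def test_affine_invariance(self, xs, a, b):
        base = minmax_normalize(xs).values
        scaled = minmax_normalize([a * x + b for x in xs]).values
        assert scaled == pytest.approx(base, abs=1e-6)


class TestMonthlyComponents:
    def test_counts_and_types(self, tiny_table):
        comps = monthly_components(tiny_table, "all")
        assert comps["n"].tolist() == [1, 3, 8, 6]
        assert comps["t"].tolist() == [1, 1, 3, 2]

    def test_stratum_restriction(self, tiny_table):
        comps = monthly_components(tiny_table, "airborne")
        assert comps["n"].tolist() == [0, 3, 5, 2]

    def test_route_additivity(self, four_year_table):
        total = monthly_components(four_year_table, "all")["n"]
        parts = sum(monthly_components(four_year_table, r)["n"]
                    for r in ("airborne", "water-food", "vector-borne"))
        assert (total == parts).all()

    def test_unknown_stratum(self, tiny_table):
        with pytest.raises(StratumError):
            monthly_components(tiny_table, "fomite")


class TestEntropyWeights:
    def test_identical_indicators_give_half_half(self):
        comps = pd.DataFrame({"n": [1, 5, 3, 9], "t": [1, 5, 3, 9]})
        w = entropy_weights(comps)
        assert (w.alpha, w.beta) == pytest.approx((0.5, 0.5))

    def test_hand_oracle_toy(self):
        # n=(2,4,6) -> N=(0,.5,1); t=(1,2,1) -> T=(0,1,0); entropies worked
        # through by hand: d_N=0.42066, d_T=1 -> w=(0.29608, 0.70392)
        comps = pd.DataFrame({"n": [2, 4, 6], "t": [1, 2, 1]})
        w = entropy_weights(comps)
        assert w.alpha == pytest.approx(0.2960819109658653, abs=1e-12)
        assert w.beta == pytest.approx(0.7039180890341347, abs=1e-12)

    def test_weights_sum_to_one_on_random_components(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            comps = pd.DataFrame({"n": rng.integers(0, 100, 12),
                                  "t": rng.integers(1, 10, 12)})
            if comps["n"].nunique() == 1 or comps["t"].nunique() == 1:
                continue
            w = entropy_weights(comps)
            assert w.alpha + w.beta == pytest.approx(1.0, abs=1e-12)
            assert 0 <= w.alpha <= 1

    def test_constant_indicator_rejected(self):
        with pytest.warns(DegenerateSeriesWarning):
            with pytest.raises(WeightError, match="entropy undefined"):
                entropy_weights(pd.DataFrame({"n": [1, 2, 3], "t": [4, 4, 4]}))


class TestComputeNDOI:
    def test_extreme_months(self, four_year_table):
        series = compute_ndoi(four_year_table, weights=SHANGHAI_WEIGHTS)
        f = series.frame
        assert ((f.ndoi >= 0) & (f.ndoi <= 1)).all()
        both_max = (f["N"] == 1) & (f["T"] == 1)
        if both_max.any():
            assert f.ndoi[both_max].iloc[0] == pytest.approx(1.0)
        # identity NDOI = alpha*N + beta*T holds every month
        assert f.ndoi.to_numpy() == pytest.approx(
            0.51 * f["N"].to_numpy() + 0.49 * f["T"].to_numpy(), abs=1e-12)

    def test_fixed_weight_arithmetic(self, tiny_catalog):
        # one month attains (max n, min t) -> N=1, T=0 -> ndoi = alpha
        df = pd.DataFrame({"flu": [0, 9, 1], "cholera": [1, 0, 2], "dengue": [1, 0, 3]},
                          index=["2020-01", "2020-02", "2020-03"])
        series = compute_ndoi(MonthlyCaseTable(df, tiny_catalog), weights=(0.51, 0.49))
        f = series.frame
        month2 = f.loc["2020-02"]
        assert (month2["N"], month2["T"]) == (1.0, 0.0)
        assert month2["ndoi"] == pytest.approx(0.51)

    def test_scale_invariance(self, four_year_table):
        series = compute_ndoi(four_year_table, weights=SHANGHAI_WEIGHTS)
        scaled = MonthlyCaseTable(four_year_table.counts * 7, four_year_table.catalog)
        series7 = compute_ndoi(scaled, weights=SHANGHAI_WEIGHTS)
        assert series7.frame.N.to_numpy() == pytest.approx(series.frame.N.to_numpy())
        assert series7.frame.ndoi.to_numpy() == pytest.approx(series.frame.ndoi.to_numpy())

    def test_monotonicity_in_one_month(self, four_year_table):
        # bump one non-extreme month's counts; its NDOI must not decrease
        base = compute_ndoi(four_year_table, weights=SHANGHAI_WEIGHTS)
        counts = four_year_table.counts.copy()
        month = counts.index[5]
        counts.loc[month, "flu"] += 10
        bumped = compute_ndoi(MonthlyCaseTable(counts, four_year_table.catalog),
                              weights=SHANGHAI_WEIGHTS)
        assert bumped.frame.loc[month, "ndoi"] >= base.frame.loc[month, "ndoi"] - 1e-12

    def test_transform_reuses_fitted_window(self, four_year_table):
        est = EntropyWeightNDOI(weights=SHANGHAI_WEIGHTS).fit(four_year_table)
        sub = MonthlyCaseTable(four_year_table.counts.iloc[:12], four_year_table.catalog)
        scored = est.transform(sub)
        full = est.transform(four_year_table)
        assert scored.frame.ndoi.to_numpy() == pytest.approx(
            full.frame.ndoi.to_numpy()[:12])


class TestAnnualMeans:
    def test_constant_series(self, four_year_table):
        series = compute_ndoi(four_year_table, weights=SHANGHAI_WEIGHTS)
        means = annual_ndoi_means(series)
        assert list(means.index) == [2017, 2018, 2019, 2020]
        grouped = series.ndoi.groupby(series.months.year).mean()
        assert means.to_numpy() == pytest.approx(grouped.to_numpy())

    def test_partial_year_rejected(self, tiny_table):
        series = compute_ndoi(tiny_table, weights=(0.5, 0.5))
        with pytest.raises(ValueError, match="partial"):
            annual_ndoi_means(series)
        assert annual_ndoi_means(series, allow_partial=True).index.tolist() == [2020]
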