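"""Mortality-rate arithmetic, bootstrap aggregation and regional comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from canopyhazard.rates import (
    IntervalRate,
    bootstrap_weighted_mean,
    compare_regions,
    compact_letter_display,
    interval_mortality_rate,
    mode_specific_rates,
    plot_interval_rates,
    plot_mortality_rate,
    plot_rates_table,
)
from conftest import make_dataset, make_obs, make_plot_frame


class TestIntervalRate:
    @pytest.mark.parametrize(
        "n0,n1,T,expect",
        [(100, 100, 2.0, 0.0), (100, 50, 1.0, 50.0), (100, 81, 2.0, 10.0)],
    )
    def test_closed_forms(self, n0, n1, T, expect):
        assert interval_mortality_rate(n0, n1, T) == pytest.approx(expect)

    def test_errors(self):
        with pytest.raises(ValueError, match="N_t0"):
            interval_mortality_rate(0, 0, 1.0)
        with pytest.raises(ValueError):
            interval_mortality_rate(10, 11, 1.0)
        with pytest.raises(ValueError):
            interval_mortality_rate(10, 5, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(
        n0=st.integers(10, 10_000),
        surv=st.floats(0.01, 1.0),
        t1=st.floats(0.2, 10.0),
        t2=st.floats(0.2, 10.0),
    )
    def test_interval_splitting_invariance(self, n0, surv, t1, t2):
        """Compounding two sub-interval survival fractions reproduces the
        full-interval annualised rate."""
        m_full = (1.0 - surv ** (1.0 / (t1 + t2))) * 100.0
        # split the survival arbitrarily between the sub-intervals
        s1 = surv ** (t1 / (t1 + t2))
        s2 = surv / s1
        m1 = (1.0 - s1 ** (1.0 / t1)) * 100.0
        m2 = (1.0 - s2 ** (1.0 / t2)) * 100.0
        compound = (1.0 - (s1 * s2) ** (1.0 / (t1 + t2))) * 100.0
        assert compound == pytest.approx(m_full, abs=1e-9)
        # the weighted-mean plot rate of two equal-rate sub-intervals is that rate
        if abs(m1 - m2) < 1e-9:
            iv = [
                IntervalRate("P", 0.0, t1, n0, n0, m1),
                IntervalRate("P", t1, t1 + t2, n0, n0, m2),
            ]
            assert plot_mortality_rate(iv).m_plot == pytest.approx(m1)


class TestPlotRate:
    def test_weighted_mean(self):
        iv = [
            IntervalRate("P", 0, 1, 100, 98, 2.0),
            IntervalRate("P", 1, 4, 100, 88, 4.0),
        ]
        assert plot_mortality_rate(iv).m_plot == pytest.approx(3.5)

    def test_single_interval_identity(self):
        iv = [IntervalRate("P", 0, 2, 50, 45, 5.1)]
        assert plot_mortality_rate(iv).m_plot == pytest.approx(5.1)

    def test_equal_lengths_arithmetic_mean(self):
        iv = [IntervalRate("P", i, i + 2, 100, 95, m) for i, m in zip((0, 2, 4), (1.0, 2.0, 6.0))]
        assert plot_mortality_rate(iv).m_plot == pytest.approx(3.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            plot_mortality_rate([])


def _plot_with_deaths(n_alive=100, standing=5, broken=5, unassessed=0):
    dates = (2000.0, 2001.0)
    plots = make_plot_frame(dates=dates)
    rows = []
    k = 0
    for mode, count in (("standing", standing), ("broken_uprooted", broken),
                        ("unassessed", unassessed)):
        for _ in range(count):
            rows += make_obs("P1", f"T{k}", [
                (0, 2000.0, 200.0, "alive", "not_applicable"),
                (1, 2001.0, np.nan, "dead", mode),
            ])
            k += 1
    survivors = n_alive - standing - broken - unassessed
    for _ in range(survivors):
        rows += make_obs("P1", f"T{k}", [
            (0, 2000.0, 200.0, "alive", "not_applicable"),
            (1, 2001.0, 203.0, "alive", "not_applicable"),
        ])
        k += 1
    return make_dataset(plots, rows)


class TestModeSpecificRates:
    def test_partition_of_modes(self):
        ds = _plot_with_deaths(100, 5, 5)
        st_rate = mode_specific_rates(ds, "P1", "standing").m_plot
        br_rate = mode_specific_rates(ds, "P1", "broken_uprooted").m_plot
        # direct evaluation of the rate formula with N_t1 in {95, 90}
        assert st_rate == pytest.approx(interval_mortality_rate(100, 95, 1.0))
        assert br_rate == pytest.approx(interval_mortality_rate(100, 95, 1.0))
        total = plot_mortality_rate(plot_interval_rates(ds, "P1")).m_plot
        assert total == pytest.approx(10.0)
        # survival fractions partition exactly by death counts
        assert (1 - st_rate / 100) * 100 == pytest.approx(95.0)

    def test_zero_deaths_of_a_mode(self):
        ds = _plot_with_deaths(100, 8, 0)
        assert mode_specific_rates(ds, "P1", "broken_uprooted").m_plot == 0.0
        st_rate = mode_specific_rates(ds, "P1", "standing").m_plot
        assert st_rate == pytest.approx(interval_mortality_rate(100, 92, 1.0))

    def test_ineligible_plot_raises(self):
        ds = _plot_with_deaths(100, 2, 2)
        with pytest.raises(ValueError, match="ineligible"):
            mode_specific_rates(ds, "P1", "standing")

    def test_lost_trees_censored_out(self):
        """A tree lost without a death record leaves both N_t0 and N_t1."""
        plots = make_plot_frame(dates=(2000.0, 2001.0, 2002.0))
        rows = []
        for i in range(10):
            rows += make_obs("P1", f"S{i}", [
                (0, 2000.0, 200.0, "alive", "not_applicable"),
                (1, 2001.0, 202.0, "alive", "not_applicable"),
                (2, 2002.0, 204.0, "alive", "not_applicable"),
            ])
        rows += make_obs("P1", "L1", [
            (0, 2000.0, 200.0, "alive", "not_applicable"),
            (1, 2001.0, np.nan, "lost", "not_applicable"),
        ])
        ds = make_dataset(plots, rows)
        ivs = plot_interval_rates(ds, "P1")
        assert [iv.n_t0 for iv in ivs] == [10, 10]
        assert all(iv.m == 0.0 for iv in ivs)


class TestBootstrap:
    def test_degenerate_equal_values(self):
        s = bootstrap_weighted_mean([2.0] * 8, [1.0] * 8, B=500, seed=1)
        assert s.mean == pytest.approx(2.0)
        assert s.ci_low == pytest.approx(2.0) and s.ci_high == pytest.approx(2.0)

    def test_two_plot_enumeration_oracle(self):
        """values {1,3}, weights {1,3}: the four equiprobable resamples have
        weighted means {1, 2.5, 2.5, 3}, so the replicate mean converges to
        2.25 and the CI spans [1, 3]."""
        B = 40_000
        s = bootstrap_weighted_mean([1.0, 3.0], [1.0, 3.0], B=B, seed=2)
        vals = np.array([1.0, 2.5, 2.5, 3.0])
        mu, sd = vals.mean(), vals.std()
        assert abs(s.mean - mu) < 4 * sd / np.sqrt(B)
        assert s.ci_low == pytest.approx(1.0) and s.ci_high == pytest.approx(3.0)

    def test_deterministic_given_seed(self):
        a = bootstrap_weighted_mean([1.0, 2.0, 4.0], [1.0, 1.0, 2.0], B=200, seed=9)
        b = bootstrap_weighted_mean([1.0, 2.0, 4.0], [1.0, 1.0, 2.0], B=200, seed=9)
        assert a == b

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_weighted_mean([1.0], [1.0], B=0)
        with pytest.raises(ValueError):
            bootstrap_weighted_mean([1.0, 2.0], [1.0, -1.0])


class TestCompareRegions:
    def _rates(self, means, sd, n, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, mu in enumerate(means):
            for v in rng.normal(mu, sd, n):
                rows.append({"plot_id": f"R{i}P{len(rows)}", "region": f"R{i}", "m_plot": v})
        return pd.DataFrame(rows)

    def test_identical_groups(self):
        df = self._rates([2.0, 2.0], sd=0.3, n=15, seed=1)
        df.loc[df["region"] == "R1", "m_plot"] = df.loc[df["region"] == "R0", "m_plot"].values
        out = compare_regions(df)
        assert out["p_adj"].iloc[0] > 0.99
        letters = out.attrs["letters"]
        assert letters["R0"] == letters["R1"]

    def test_strong_separation(self):
        df = self._rates([0.0, 10.0], sd=0.1, n=20, seed=2)
        out = compare_regions(df)
        assert out["p_adj"].iloc[0] < 1e-6

    def test_outlier_group_gets_unique_letter(self):
        df = self._rates([2.0, 2.05, 8.0], sd=0.2, n=15, seed=3)
        out = compare_regions(df)
        letters = out.attrs["letters"]
        assert letters["R0"] == letters["R1"]
        assert letters["R2"] not in (letters["R0"], letters["R1"])

    def test_singleton_region_excluded(self):
        df = self._rates([2.0, 3.0], sd=0.2, n=10, seed=4)
        df = pd.concat([df, pd.DataFrame([{"plot_id": "X", "region": "R9", "m_plot": 5.0}])])
        out = compare_regions(df)
        assert out.attrs["excluded"] == ["R9"]

    def test_tukey_matches_permutation_direction(self):
        """The studentized-range p-value agrees with a permutation oracle on
        which side of 0.05 a moderate contrast falls."""
        df = self._rates([2.0, 2.6], sd=0.5, n=12, seed=5)
        out = compare_regions(df)
        a = df[df["region"] == "R0"]["m_plot"].values
        b = df[df["region"] == "R1"]["m_plot"].values
        obs = abs(a.mean() - b.mean())
        rng = np.random.default_rng(0)
        pool = np.concatenate([a, b])
        perm = [
            abs(pool[p[: len(a)]].mean() - pool[p[len(a):]].mean())
            for p in (rng.permutation(len(pool)) for _ in range(4000))
        ]
        p_perm = float(np.mean(np.array(perm) >= obs))
        assert (out["p_adj"].iloc[0] < 0.05) == (p_perm < 0.05)


class TestCLD:
    def test_absorption(self):
        sig = {("A", "C"): True}
        letters = compact_letter_display(["A", "B", "C"], sig)
        assert letters["A"] != letters["C"]
        assert set(letters["B"]) & set(letters["A"])
        assert set(letters["B"]) & set(letters["C"])


class TestPlotRatesTable(object):
    def test_on_simulation(self, small_sim):
        _, ds, _ = small_sim
        pr = plot_rates_table(ds)
        assert len(pr) == len(ds.plots)
        assert (pr["m_plot"] >= 0).all() and (pr["m_plot"] < 100).all()
        skipped = pr.attrs["skipped"]
        assert skipped.empty
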