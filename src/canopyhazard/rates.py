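"""Mortality-rate estimation from repeated censuses.

The per-interval annualised mortality rate is

    m = (1 - (N_t1 / N_t0)^(1/T)) * 100   [% yr⁻¹]

with ``N_t0`` individuals alive at the start of the interval, ``N_t1`` of
them surviving to its end, and ``T`` the interval length in years.  Plot
rates are the census-interval-length-weighted mean of interval rates;
regional and basin-wide summaries are area-weighted bootstrap means with
percentile confidence intervals; regions are compared with Tukey's HSD on
plot-level rates.

Convention for incomplete histories: a tree enters ``N_t0`` only from its
first alive census; a tree lost without a death record is censored out of
both ``N_t0`` and ``N_t1`` for every interval after its last observation
(it must be observed at the end of an interval, alive or dead, to count).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .census import CensusDataset, mode_assessment_eligibility

__all__ = [
    "IntervalRate",
    "PlotRate",
    "RateSummary",
    "interval_mortality_rate",
    "plot_interval_rates",
    "plot_mortality_rate",
    "plot_rates_table",
    "mode_specific_rates",
    "bootstrap_weighted_mean",
    "compare_regions",
    "compact_letter_display",
]


@dataclass(frozen=True)
class IntervalRate:
    plot_id: str
    t0: float
    t1: float
    n_t0: int
    n_t1: int
    m: float  # % yr-1

    @property
    def T(self) -> float:
        return self.t1 - self.t0


@dataclass(frozen=True)
class PlotRate:
    plot_id: str
    m_plot: float  # % yr-1
    span_yr: float
    area_ha: float


@dataclass(frozen=True)
class RateSummary:
    scope: str
    mean: float
    ci_low: float
    ci_high: float
    B: int
    seed: int
    n_plots: int


def interval_mortality_rate(n_t0: int, n_t1: int, T: float) -> float:
    """Annualised mortality rate in % yr⁻¹ for one census interval."""
    if n_t0 < 1:
        raise ValueError("undefined mortality rate: no individuals at risk (N_t0 = 0)")
    if not 0 <= n_t1 <= n_t0:
        raise ValueError("require 0 <= N_t1 <= N_t0")
    if T <= 0:
        raise ValueError("census interval length must be positive")
    return (1.0 - (n_t1 / n_t0) ** (1.0 / T)) * 100.0


def _interval_counts(
    plot_trees: pd.DataFrame, dates: Sequence[float], mode: str | None = None
) -> list[tuple[int, int, int]]:
    """Per-interval (census j, N_t0, N_t1) counts for one plot.

    With ``mode`` given, only deaths of that recorded mode count as deaths
    (deaths by any other mode — or unassessed — count as survivors), per the
    mode-specific reading of the rate formula.
    """
    K = len(dates)
    st = plot_trees.pivot(index="tree_id", columns="census_index", values="status")
    st = st.reindex(columns=range(K))
    alive = (st == "alive").values
    dead = (st == "dead").values
    if mode is not None:
        md = plot_trees.pivot(
            index="tree_id", columns="census_index", values="mode_of_death"
        ).reindex(columns=range(K))
        md_vals = md.values
    has_alive = alive.any(axis=1)
    first_alive = alive.argmax(axis=1)
    out = []
    for j in range(K - 1):
        at_risk = has_alive & (first_alive <= j) & alive[:, j]
        # must be observed at the interval's end (alive or dead) to count
        counted = at_risk & (alive[:, j + 1] | dead[:, j + 1])
        n0 = int(counted.sum())
        surv = counted & alive[:, j + 1]
        if mode is None:
            n1 = int(surv.sum())
        else:
            died_other = counted & dead[:, j + 1] & (md_vals[:, j + 1] != mode)
            n1 = int(surv.sum() + died_other.sum())
        out.append((j, n0, n1))
    return out


def plot_interval_rates(
    ds: CensusDataset, plot_id: str, mode: str | None = None
) -> list[IntervalRate]:
    dates = ds.plots.at[plot_id, "census_dates"]
    sub = ds.trees[ds.trees["plot_id"] == plot_id]
    rates = []
    for j, n0, n1 in _interval_counts(sub, dates, mode=mode):
        if n0 < 1:
            continue
        rates.append(
            IntervalRate(
                plot_id=plot_id,
                t0=dates[j],
                t1=dates[j + 1],
                n_t0=n0,
                n_t1=n1,
                m=interval_mortality_rate(n0, n1, dates[j + 1] - dates[j]),
            )
        )
    return rates


def plot_mortality_rate(intervals: Sequence[IntervalRate], area_ha: float = np.nan) -> PlotRate:
    """Interval-length-weighted mean rate across a plot's censuses."""
    if not intervals:
        raise ValueError("no census intervals supplied")
    T = np.array([iv.T for iv in intervals])
    m = np.array([iv.m for iv in intervals])
    return PlotRate(
        plot_id=intervals[0].plot_id,
        m_plot=float((m * T).sum() / T.sum()),
        span_yr=float(T.sum()),
        area_ha=area_ha,
    )


def plot_rates_table(ds: CensusDataset, mode: str | None = None) -> pd.DataFrame:
    """Plot-level weighted mortality rates for every plot (optionally per mode).

    For mode-specific rates, plots failing the mode-assessment eligibility
    rule (>=50 % of deaths assessed and >=5 assessed) are skipped and listed
    in the ``skipped`` attribute of the returned frame.
    """
    rows, skipped = [], []
    for pid in ds.plots.index:
        if mode is not None:
            elig = mode_assessment_eligibility(ds.trees[ds.trees["plot_id"] == pid])
            if not elig.eligible:
                skipped.append({"plot_id": pid, "reason": elig.reason})
                continue
        intervals = plot_interval_rates(ds, pid, mode=mode)
        if not intervals:
            skipped.append({"plot_id": pid, "reason": "no usable census interval"})
            continue
        pr = plot_mortality_rate(intervals, area_ha=float(ds.plots.at[pid, "area_ha"]))
        rows.append(
            {
                "plot_id": pid,
                "region": ds.plots.at[pid, "region"],
                "m_plot": pr.m_plot,
                "span_yr": pr.span_yr,
                "area_ha": pr.area_ha,
            }
        )
    out = pd.DataFrame(rows, columns=["plot_id", "region", "m_plot", "span_yr", "area_ha"])
    out.attrs["skipped"] = pd.DataFrame(skipped, columns=["plot_id", "reason"])
    return out


def mode_specific_rates(ds: CensusDataset, plot_id: str, mode: str) -> PlotRate:
    """Plot rate counting only deaths of one recorded mode as deaths."""
    if mode not in ("standing", "broken_uprooted"):
        raise ValueError("mode must be 'standing' or 'broken_uprooted'")
    elig = mode_assessment_eligibility(ds.trees[ds.trees["plot_id"] == plot_id])
    if not elig.eligible:
        raise ValueError(f"plot {plot_id} ineligible for mode-specific rates: {elig.reason}")
    return plot_mortality_rate(
        plot_interval_rates(ds, plot_id, mode=mode),
        area_ha=float(ds.plots.at[plot_id, "area_ha"]),
    )


def bootstrap_weighted_mean(
    values: Sequence[float],
    weights: Sequence[float],
    B: int = 10_000,
    seed: int = 0,
    scope: str = "basin",
) -> RateSummary:
    """Area-weighted bootstrap mean and percentile 95 % CI of plot rates.

    Plots are resampled uniformly with replacement; the weights enter each
    replicate's weighted mean (they are not sampling probabilities).
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1 or len(v) < 1:
        raise ValueError("values and weights must be 1-D of equal length >= 1")
    if (w <= 0).any():
        raise ValueError("weights must be > 0")
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    n = len(v)
    idx = rng.integers(0, n, size=(B, n))
    reps = (v[idx] * w[idx]).sum(axis=1) / w[idx].sum(axis=1)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return RateSummary(
        scope=scope,
        mean=float(reps.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        B=B,
        seed=seed,
        n_plots=n,
    )


def compare_regions(plot_rates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD on plot-level rates grouped by region, plus letter display.

    Returns the pairwise table; the compact letter display is attached as
    ``result.attrs['letters']`` (regions sharing a letter do not differ at
    ``alpha``).  Regions with fewer than 2 plots are excluded with a warning
    entry in ``result.attrs['excluded']``.
    """
    groups = {}
    excluded = []
    for region, sub in plot_rates.groupby("region"):
        if len(sub) < 2:
            excluded.append(region)
        else:
            groups[region] = sub["m_plot"].values
    if len(groups) < 2:
        raise ValueError("need at least two regions with >= 2 plots each")
    names = sorted(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    ns = np.array([len(groups[g]) for g in names])
    k, N = len(names), len(all_vals)
    df = N - k
    means = {g: groups[g].mean() for g in names}
    sse = sum(((groups[g] - means[g]) ** 2).sum() for g in names)
    mse = sse / df
    rows = []
    for a, b in combinations(names, 2):
        diff = means[a] - means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(studentized_range.sf(q, k, df)) if np.isfinite(q) else 0.0
        rows.append({"region_a": a, "region_b": b, "diff": diff, "se": se, "q": q, "p_adj": min(1.0, p)})
    out = pd.DataFrame(rows)
    out.attrs["letters"] = compact_letter_display(
        names, {(r["region_a"], r["region_b"]): r["p_adj"] < alpha for _, r in out.iterrows()}
    )
    out.attrs["excluded"] = excluded
    out.attrs["means"] = means
    return out


def compact_letter_display(
    groups: Sequence[str], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display from pairwise significance."""

    letters: list[set[str]] = [set(groups)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        for s in list(letters):
            if a in s and b in s:  # split the offending set
                letters.remove(s)
                letters.extend([s - {a}, s - {b}])
        # absorb sets contained in another
        letters = [
            s for i, s in enumerate(letters)
            if s and not any(
                (s < t) or (s == t and i > j)
                for j, t in enumerate(letters) if i != j
            )
        ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for lab, s in zip(alphabet, letters):
        for g in sorted(s):
            out[g] += lab
    return out
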