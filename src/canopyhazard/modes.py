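"""Mode-of-death proportions and the census-interval-length bias correction.

Standing dead trees break with time, so a plot revisited after a long
census interval records more broken/uprooted stems than one revisited
quickly.  The correction regresses the plot-level proportion of a mode
(``Pmod``) on the plot's mean census-interval length (``CIL``), centred to
mean zero across the plots entering the fit:

    Pmod = b0 + b1 * (CIL - mean CIL) + e

so the intercept ``b0`` is the corrected proportion at the network's mean
interval length.  The regional model adds a region factor and reports each
region's adjusted proportion (the fitted value at centred CIL = 0) with
t-based 95 % confidence intervals, plus Tukey-adjusted pairwise region
contrasts.

Proportions are modelled on the identity scale by ordinary least squares;
fitted values outside [0, 1] are flagged with a warning, never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import studentized_range

from .census import CensusDataset, mode_assessment_eligibility

__all__ = [
    "ModeProportion",
    "CorrectionFit",
    "RegionalModeEstimate",
    "plot_mode_proportions",
    "fit_cil_correction",
    "fit_regional_mode_model",
]

ASSESSED_MODES = ("standing", "broken_uprooted")


@dataclass(frozen=True)
class ModeProportion:
    plot_id: str
    mode: str
    p_mod: float
    n_assessed: int
    cil_bar: float
    region: str = ""


@dataclass(frozen=True)
class CorrectionFit:
    mode: str
    beta0: float  # corrected proportion at the mean CIL
    beta1: float  # change in proportion per yr of CIL
    r_squared: float
    p_value: float  # two-sided, for beta1
    df_resid: int
    beta0_ci: tuple[float, float]
    beta1_ci: tuple[float, float]


@dataclass(frozen=True)
class RegionalModeEstimate:
    region: str
    mode: str
    proportion: float
    ci_low: float
    ci_high: float


def plot_mode_proportions(ds: CensusDataset) -> pd.DataFrame:
    """Per-plot proportions of assessed deaths in each mode.

    Only plots passing the assessment-eligibility rule (>=50 % of deaths
    assessed, >=5 assessed) are returned; unassessed deaths are excluded
    from numerator and denominator.  ``cil_bar`` is the mean of the plot's
    census-interval lengths.  Skipped plots are listed in
    ``result.attrs['skipped']``.
    """
    rows, skipped = [], []
    for pid in ds.plots.index:
        sub = ds.trees[ds.trees["plot_id"] == pid]
        elig = mode_assessment_eligibility(sub)
        if not elig.eligible:
            skipped.append({"plot_id": pid, "reason": elig.reason})
            continue
        dates = ds.plots.at[pid, "census_dates"]
        cil_bar = float(np.mean(np.diff(dates)))
        dead = sub[sub["status"] == "dead"]
        assessed = dead[dead["mode_of_death"].isin(ASSESSED_MODES)]
        n = len(assessed)
        for mode in ASSESSED_MODES:
            rows.append(
                {
                    "plot_id": pid,
                    "region": ds.plots.at[pid, "region"],
                    "mode": mode,
                    "p_mod": float((assessed["mode_of_death"] == mode).sum() / n),
                    "n_assessed": n,
                    "cil_bar": cil_bar,
                }
            )
    out = pd.DataFrame(
        rows, columns=["plot_id", "region", "mode", "p_mod", "n_assessed", "cil_bar"]
    )
    out.attrs["skipped"] = pd.DataFrame(skipped, columns=["plot_id", "reason"])
    return out


def _one_mode(props: pd.DataFrame, mode: str | None) -> pd.DataFrame:
    if mode is not None:
        props = props[props["mode"] == mode]
    if props["plot_id"].duplicated().any():
        raise ValueError(
            "proportions for several modes supplied; pass mode=... to select one"
        )
    return props


def fit_cil_correction(
    props: pd.DataFrame, mode: str | None = None, alpha: float = 0.05
) -> CorrectionFit:
    """OLS of a mode's plot proportions on centred mean census-interval length."""
    props = _one_mode(props, mode)
    if len(props) < 3:
        raise ValueError("need at least 3 plots to fit the CIL correction")
    cil = props["cil_bar"].values.astype(float)
    if np.ptp(cil) == 0 or np.allclose(cil, cil[0]):
        raise ValueError("correction unidentifiable: zero variance in mean CIL")
    x = sm.add_constant(cil - cil.mean())
    fit = sm.OLS(props["p_mod"].values.astype(float), x).fit()
    beta0, beta1 = fit.params
    ci = fit.conf_int(alpha)
    if not 0.0 <= beta0 <= 1.0:
        warnings.warn(
            f"corrected proportion {beta0:.3f} outside [0, 1]; reported as-is",
            stacklevel=2,
        )
    mode_label = mode or props["mode"].iloc[0]
    return CorrectionFit(
        mode=mode_label,
        beta0=float(beta0),
        beta1=float(beta1),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        df_resid=int(fit.df_resid),
        beta0_ci=(float(ci[0, 0]), float(ci[0, 1])),
        beta1_ci=(float(ci[1, 0]), float(ci[1, 1])),
    )


def fit_regional_mode_model(
    props: pd.DataFrame, mode: str | None = None, alpha: float = 0.05
) -> tuple[list[RegionalModeEstimate], pd.DataFrame]:
    """Regional adjusted proportions controlling for census-interval length.

    Fits ``Pmod ~ centred CIL + region`` by OLS and returns, per region, the
    adjusted proportion (fitted value at centred CIL = 0) with a t-based
    95 % CI, together with all pairwise region contrasts carrying
    Tukey-adjusted (studentized-range) p-values.  Regions contributing a
    single plot are dropped with a warning.
    """
    props = _one_mode(props, mode).copy()
    counts = props.groupby("region")["plot_id"].count()
    singletons = counts.index[counts < 2].tolist()
    if singletons:
        warnings.warn(f"dropping region(s) with a single plot: {singletons}", stacklevel=2)
        props = props[~props["region"].isin(singletons)]
    regions = sorted(props["region"].unique())
    if len(regions) < 2:
        raise ValueError("need at least two regions with >= 2 plots each")

    cil = props["cil_bar"].values.astype(float)
    cil_c = cil - cil.mean()
    dummies = pd.get_dummies(props["region"], dtype=float)[regions]
    # cell-means coding: one column per region, no global intercept
    X = np.column_stack([cil_c, dummies.values])
    names = ["cil_c"] + regions
    fit = sm.OLS(props["p_mod"].values.astype(float), X).fit()
    cov = fit.cov_params()
    from scipy.stats import t as t_dist

    tcrit = t_dist.ppf(1 - alpha / 2, fit.df_resid)
    mode_label = mode or props["mode"].iloc[0]
    estimates = []
    for i, region in enumerate(regions, start=1):
        est = float(fit.params[i])
        se = float(np.sqrt(cov[i, i]))
        if not 0.0 <= est <= 1.0:
            warnings.warn(
                f"adjusted proportion {est:.3f} for {region} outside [0, 1]",
                stacklevel=2,
            )
        estimates.append(
            RegionalModeEstimate(
                region=region,
                mode=mode_label,
                proportion=est,
                ci_low=est - tcrit * se,
                ci_high=est + tcrit * se,
            )
        )

    k, df = len(regions), int(fit.df_resid)
    rows = []
    for (i, a), (j, b) in combinations(enumerate(regions, start=1), 2):
        diff = float(fit.params[i] - fit.params[j])
        se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
        q = abs(diff) / (se / np.sqrt(2.0)) if se > 0 else np.inf
        p = float(studentized_range.sf(q, k, df)) if np.isfinite(q) else 0.0
        rows.append(
            {"region_a": a, "region_b": b, "diff": diff, "se": se, "p_adj": min(1.0, p)}
        )
    contrasts = pd.DataFrame(rows)
    contrasts.attrs["coef_names"] = names
    return estimates, contrasts
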