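"""Synthetic forest-census generator with known ground truth.

The generator emulates a network of long-term tropical-forest inventory
plots: four geological regions, 0.5–2 ha plots, irregular censuses averaging
2.8 years, stems measured from the 100 mm recruitment threshold upward, and
species-level trait variation (wood density, maximum size, mean growth,
water-deficit affiliation).

Tree death times are drawn *exactly* from a proportional-hazards model

    h(t) = h0 * exp((x(t) - x_ref)' beta + b_plot)

with covariates held piecewise-constant between censuses, so each census
interval has a flat hazard and the death time is obtained by inversion of
the cumulative hazard (no discretisation error).  Covariates are centred at
a configurable reference tree so that ``h0`` is interpretable as the hazard
of an average tree — centring only rescales the baseline and leaves the
coefficients untouched.  The plot random effect ``b_plot`` is normal with
variance ``frailty_variance`` and mean ``-frailty_variance/2``, giving the
multiplier ``exp(b)`` mean 1 on the hazard scale.

Whether a dying tree truly dies standing or broken/uprooted follows a
logistic function of its relative growth rate at death (slow growers die
standing more often).  After death, a standing stem may break before the
census at which it is found: :func:`degrade_mode_of_death` flips standing
records to broken/uprooted with probability ``1 - exp(-r * tau)`` where
``tau`` is the time from true death to discovery — the measurement bias the
census-interval-length correction is designed to remove.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .census import CensusDataset, REGIONS, RECRUIT_DIAMETER_MM, validate_dataset

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_dataset",
    "degrade_mode_of_death",
    "mask_traits",
    "HAZARD_TERMS",
]

#: model terms of the generating hazard, in design order
HAZARD_TERMS = ("D", "D2", "rel_growth", "max_d", "mean_growth", "wood_density", "wda")

#: rough lat/lon anchors for the four-region scheme (generator only)
REGION_ANCHORS = {
    "Northern": (2.5, -59.0),
    "EastCentral": (-3.0, -54.0),
    "Western": (-5.0, -72.0),
    "Southern": (-12.5, -61.5),
}


def _default_beta() -> dict:
    # magnitudes comparable to the fitted pan-scale risk model, on the
    # package's covariate scales (D in m, rel growth % yr-1, max_d mm,
    # mean growth mm yr-1, WD g cm-3, WDA mm)
    return {
        "D": -2.0,
        "D2": 1.5,
        "rel_growth": -0.08,
        "max_d": -0.002,
        "mean_growth": 0.2,
        "wood_density": -0.7,
        "wda": -1e-4,
    }


def _default_reference() -> dict:
    return {
        "D": 0.22,
        "D2": 0.22**2,
        "rel_growth": 0.8,
        "max_d": 420.0,
        "mean_growth": 1.4,
        "wood_density": 0.65,
        "wda": -150.0,
    }


@dataclass
class SimulationConfig:
    """Generating truth for a synthetic census dataset.

    Defaults describe a realistic Amazon-like monitoring network: ~550
    stems >=10 cm per hectare, census intervals of 2.8 +/- 0.7 yr, a 25-yr
    monitoring horizon, baseline hazard 2 % yr⁻¹ for the reference tree,
    moderate plot-level frailty, post-mortem breakage at 4 % yr⁻¹ and
    trait missingness at the 14/6/3 % species/genus/family regime.
    """

    n_plots_per_region: int = 5
    regions: Sequence[str] = REGIONS
    plot_area_ha: tuple[float, float] = (0.5, 2.0)
    stem_density_ha: float = 550.0
    recruit_pool_frac: float = 0.25
    n_species: int = 200

    # species trait distributions
    wood_density_mean: float = 0.65
    wood_density_sd: float = 0.15
    max_d_log_mean: float = float(np.log(420.0))
    max_d_log_sd: float = 0.35
    mean_growth_log_mean: float = float(np.log(1.2))
    mean_growth_log_sd: float = 0.55
    wda_mean: float = -150.0
    wda_sd: float = 100.0

    # hazard
    beta: dict = field(default_factory=_default_beta)
    covariate_reference: dict = field(default_factory=_default_reference)
    h0: float = 0.02
    frailty_variance: float = 0.25

    # monitoring design
    mean_census_interval_yr: float = 2.8
    census_interval_jitter_yr: float = 0.7
    horizon_yr: float = 25.0
    start_year: float = 1985.0

    # growth and measurement
    growth_multiplier_log_sd: float = 0.5
    initial_diameter_scale_mm: float = 120.0
    measurement_sd_mm: float = 1.5
    burnin_yr: float = 0.0

    # mode of death
    standing_logit_intercept: float = 0.5
    standing_logit_slope_per_pct: float = -0.6
    mode_assessed_prob: float = 0.85
    breakage_rate_yr: float = 0.04

    # trait missingness (species / genus / family shares)
    trait_missing_rates: tuple[float, float, float] = (0.14, 0.06, 0.03)

    lost_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_plots_per_region < 1 or len(self.regions) < 1:
            raise ValueError("need at least one plot in at least one region")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        for name in ("h0", "breakage_rate_yr", "stem_density_ha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frailty_variance < 0:
            raise ValueError("frailty_variance must be >= 0")
        for p in (self.mode_assessed_prob, self.lost_prob, *self.trait_missing_rates):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.horizon_yr <= 2 * self.mean_census_interval_yr:
            raise ValueError("horizon must exceed twice the mean census interval")
        unknown = set(self.beta) - set(HAZARD_TERMS)
        if unknown:
            raise ValueError(f"unknown hazard terms: {sorted(unknown)}")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TruthTable:
    """Ground truth for one simulated dataset.

    ``trees``: one row per simulated (recruited) tree with its true death
    time (NaN if censored alive), true mode at death, growth rate and the
    date at which it was found dead.  ``plot_frailty``: the realised
    log-frailty per plot.  ``species_traits``: the complete trait table
    before any missingness masking.
    """

    trees: pd.DataFrame
    plot_frailty: pd.DataFrame
    species_traits: pd.DataFrame

    @property
    def n_deaths(self) -> int:
        return int(self.trees["death_time"].notna().sum())


def _make_species_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_species
    n_gen = max(1, n // 3)
    n_fam = max(1, n_gen // 3)
    fam_of_gen = rng.integers(0, n_fam, n_gen)
    gen_of_sp = rng.integers(0, n_gen, n)
    genus = np.array([f"Genus{g:03d}" for g in gen_of_sp])
    family = np.array([f"Family{fam_of_gen[g]:02d}" for g in gen_of_sp])
    species = np.array([f"{genus[i]} sp{i:04d}" for i in range(n)])
    wd = np.clip(
        rng.normal(cfg.wood_density_mean, cfg.wood_density_sd, n), 0.2, 1.1
    )
    max_d = np.maximum(150.0, rng.lognormal(cfg.max_d_log_mean, cfg.max_d_log_sd, n))
    growth = rng.lognormal(cfg.mean_growth_log_mean, cfg.mean_growth_log_sd, n)
    wda = np.minimum(50.0, rng.normal(cfg.wda_mean, cfg.wda_sd, n))
    # lognormal rank-abundance
    abundance = rng.lognormal(0.0, 1.2, n)
    return pd.DataFrame(
        {
            "species": species,
            "genus": genus,
            "family": family,
            "wd_g_cm3": wd,
            "max_d_mm": max_d,
            "mean_growth_mm_yr": growth,
            "wda_mm": wda,
            "abundance": abundance / abundance.sum(),
        }
    )


def _census_schedule(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    t0 = cfg.start_year + rng.uniform(0.0, 3.0)
    dates = [t0]
    while dates[-1] - t0 < cfg.horizon_yr:
        gap = rng.normal(cfg.mean_census_interval_yr, cfg.census_interval_jitter_yr)
        dates.append(dates[-1] + max(0.5, gap))
    return np.round(np.array(dates), 3)


def simulate_dataset(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[CensusDataset, TruthTable]:
    """Simulate a census dataset plus its ground truth; deterministic given seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    species_table = _make_species_table(cfg, rng)
    beta = np.array([cfg.beta.get(t, 0.0) for t in HAZARD_TERMS])
    ref = np.array([cfg.covariate_reference.get(t, 0.0) for t in HAZARD_TERMS])

    plot_rows = []
    tree_rows = []
    truth_rows = []
    frailty_rows = []

    for region in cfg.regions:
        lat0, lon0 = REGION_ANCHORS.get(region, (0.0, -60.0))
        for p in range(cfg.n_plots_per_region):
            plot_id = f"{region[:2].upper()}-{p:03d}"
            area = rng.uniform(*cfg.plot_area_ha)
            lat = lat0 + rng.normal(0.0, 1.2)
            lon = lon0 + rng.normal(0.0, 1.2)
            elev = rng.uniform(50.0, 400.0)
            dates = _census_schedule(cfg, rng)
            b_plot = (
                rng.normal(-cfg.frailty_variance / 2.0, np.sqrt(cfg.frailty_variance))
                if cfg.frailty_variance > 0
                else 0.0
            )
            frailty_rows.append({"plot_id": plot_id, "log_frailty": b_plot})
            plot_rows.append(
                {
                    "plot_id": plot_id,
                    "region": region,
                    "area_ha": round(area, 3),
                    "lat": round(lat, 4),
                    "lon": round(lon, 4),
                    "elev_m": round(elev, 1),
                    "census_dates": tuple(dates),
                }
            )
            _simulate_plot(
                cfg, rng, plot_id, area, dates, b_plot, species_table, beta, ref,
                tree_rows, truth_rows,
            )

    plots = pd.DataFrame(plot_rows).set_index("plot_id")
    trees = pd.DataFrame(
        tree_rows,
        columns=[
            "plot_id", "tree_id", "species", "family", "is_palm",
            "census_date", "d_mm", "status", "mode_of_death", "census_index",
        ],
    )
    trees["genus"] = trees["species"].str.split().str[0]
    truth_trees = pd.DataFrame(
        truth_rows,
        columns=[
            "plot_id", "tree_id", "species", "death_time", "found_date",
            "true_mode", "growth_mm_yr", "d0_mm", "recruit_date",
        ],
    )
    truth = TruthTable(
        trees=truth_trees,
        plot_frailty=pd.DataFrame(frailty_rows),
        species_traits=species_table.drop(columns="abundance"),
    )

    traits = species_table.drop(columns="abundance").copy()
    if any(r > 0 for r in cfg.trait_missing_rates):
        traits, _ = mask_traits(
            traits, cfg.trait_missing_rates, seed=int(rng.integers(0, 2**31 - 1))
        )
    ds = CensusDataset(plots=plots, trees=trees, traits=traits)

    if cfg.breakage_rate_yr > 0:
        ds = degrade_mode_of_death(
            ds, truth, cfg.breakage_rate_yr, seed=int(rng.integers(0, 2**31 - 1))
        )
    validate_dataset(ds)
    return ds, truth


def _simulate_plot(
    cfg, rng, plot_id, area, dates, b_plot, species_table, beta, ref,
    tree_rows, truth_rows,
):
    n_init = rng.poisson(area * cfg.stem_density_ha)
    n_pool = rng.poisson(area * cfg.stem_density_ha * cfg.recruit_pool_frac)
    n = n_init + n_pool
    if n == 0:
        return
    sp_idx = rng.choice(len(species_table), size=n, p=species_table["abundance"].values)
    sp = species_table.iloc[sp_idx]
    growth = sp["mean_growth_mm_yr"].values * rng.lognormal(
        -cfg.growth_multiplier_log_sd**2 / 2.0, cfg.growth_multiplier_log_sd, n
    )
    d_start = np.concatenate(
        [
            RECRUIT_DIAMETER_MM + rng.exponential(cfg.initial_diameter_scale_mm, n_init),
            rng.uniform(55.0, RECRUIT_DIAMETER_MM, n_pool),
        ]
    )
    if cfg.burnin_yr > 0:
        # crude quasi-equilibrium: grow the initial cohort forward, letting
        # baseline-hazard deaths be replaced by fresh recruits at threshold
        aged = d_start + growth * cfg.burnin_yr
        died = rng.random(n) < 1.0 - np.exp(-cfg.h0 * cfg.burnin_yr)
        aged[died] = RECRUIT_DIAMETER_MM + rng.exponential(
            cfg.initial_diameter_scale_mm / 4.0, int(died.sum())
        )
        d_start = aged

    K = len(dates)
    t_rel = dates - dates[0]
    # true diameters at each census: (K, n)
    D_true = d_start[None, :] + growth[None, :] * t_rel[:, None]
    D_meas = D_true + rng.normal(0.0, cfg.measurement_sd_mm, D_true.shape)
    recruited = D_meas >= RECRUIT_DIAMETER_MM
    # recruitment is permanent: first census with measured >= threshold
    first_rec = np.where(
        recruited.any(axis=0), recruited.argmax(axis=0), K
    )

    # per-interval hazards for every tree (interval j spans dates[j]..dates[j+1]);
    # the growth risk factor is the *observable* one: diameter growth over the
    # preceding census interval relative to its starting diameter
    T = np.diff(dates)  # (K-1,)
    lag = np.maximum(np.arange(K - 1) - 1, 0)
    relg_true = 100.0 * growth[None, :] / D_true[lag, :]  # % yr-1, lagged
    x = np.empty((len(HAZARD_TERMS), K - 1, n))
    Dm = D_true[:-1, :] / 1000.0
    x[0] = Dm
    x[1] = Dm**2
    x[2] = relg_true
    x[3] = sp["max_d_mm"].values[None, :]
    x[4] = sp["mean_growth_mm_yr"].values[None, :]
    x[5] = sp["wd_g_cm3"].values[None, :]
    x[6] = sp["wda_mm"].values[None, :]
    eta = np.tensordot(beta, x - ref[:, None, None], axes=(0, 0)) + b_plot
    lam = cfg.h0 * np.exp(eta)  # (K-1, n)

    E = rng.exponential(1.0, n)
    lost_at = np.full(n, K + 1)
    if cfg.lost_prob > 0:
        lost_draws = rng.random((K, n)) < cfg.lost_prob
        lost_any = lost_draws.any(axis=0)
        lost_at[lost_any] = lost_draws.argmax(axis=0)[lost_any]

    u_mode = rng.random(n)
    u_assessed = rng.random(n)

    for i in range(n):
        a = first_rec[i]
        if a >= K:
            continue  # never recruited within the monitoring window
        tree_id = f"{plot_id}-t{i:05d}"
        cum = 0.0
        death_time = np.nan
        death_census = -1
        for j in range(a, K - 1):
            seg = lam[j, i] * T[j]
            if E[i] < cum + seg:
                death_time = dates[j] + (E[i] - cum) / lam[j, i]
                death_census = j + 1
                break
            cum += seg
        last_alive = (death_census - 1) if death_census >= 0 else K - 1
        last_alive = min(last_alive, lost_at[i] - 1)
        if last_alive < a:
            continue  # lost before ever being recorded — drop entirely
        lost = lost_at[i] <= (death_census if death_census >= 0 else K - 1)

        sp_name = sp["species"].iloc[i]
        fam = sp["family"].iloc[i]
        for j in range(a, last_alive + 1):
            tree_rows.append(
                {
                    "plot_id": plot_id,
                    "tree_id": tree_id,
                    "species": sp_name,
                    "family": fam,
                    "is_palm": False,
                    "census_date": dates[j],
                    "d_mm": round(max(D_meas[j, i], RECRUIT_DIAMETER_MM) if j == a else D_meas[j, i], 1),
                    "status": "alive",
                    "mode_of_death": "not_applicable",
                    "census_index": j,
                }
            )
        true_mode = ""
        found_date = np.nan
        if death_census >= 0 and not lost:
            relg_death = 100.0 * growth[i] / (d_start[i] + growth[i] * (death_time - dates[0]))
            p_standing = expit(
                cfg.standing_logit_intercept
                + cfg.standing_logit_slope_per_pct * relg_death
            )
            true_mode = "standing" if u_mode[i] < p_standing else "broken_uprooted"
            recorded = true_mode if u_assessed[i] < cfg.mode_assessed_prob else "unassessed"
            found_date = dates[death_census]
            tree_rows.append(
                {
                    "plot_id": plot_id,
                    "tree_id": tree_id,
                    "species": sp_name,
                    "family": fam,
                    "is_palm": False,
                    "census_date": dates[death_census],
                    "d_mm": np.nan,
                    "status": "dead",
                    "mode_of_death": recorded,
                    "census_index": death_census,
                }
            )
        elif lost and lost_at[i] <= K - 1:
            tree_rows.append(
                {
                    "plot_id": plot_id,
                    "tree_id": tree_id,
                    "species": sp_name,
                    "family": fam,
                    "is_palm": False,
                    "census_date": dates[min(lost_at[i], K - 1)],
                    "d_mm": np.nan,
                    "status": "lost",
                    "mode_of_death": "not_applicable",
                    "census_index": int(min(lost_at[i], K - 1)),
                }
            )
        truth_rows.append(
            {
                "plot_id": plot_id,
                "tree_id": tree_id,
                "species": sp_name,
                "death_time": death_time if (death_census >= 0 and not lost) else np.nan,
                "found_date": found_date,
                "true_mode": true_mode,
                "growth_mm_yr": growth[i],
                "d0_mm": d_start[i],
                "recruit_date": dates[a],
            }
        )


def degrade_mode_of_death(
    ds: CensusDataset, truth: TruthTable, r: float, seed: int = 0
) -> CensusDataset:
    """Flip recorded standing deaths to broken/uprooted by post-mortem breakage.

    Each tree that truly died standing and whose recorded mode is still
    ``standing`` is re-recorded ``broken_uprooted`` with probability
    ``1 - exp(-r * tau)``, where ``tau`` is the time between the true death
    and the census at which the tree was found dead.  Truly broken trees are
    never relabelled standing.
    """
    if r < 0:
        raise ValueError("breakage rate must be >= 0")
    out = ds.copy()
    if r == 0:
        return out
    rng = np.random.default_rng(seed)
    t = truth.trees
    standing = t[t["true_mode"] == "standing"]
    tau = (standing["found_date"] - standing["death_time"]).clip(lower=0.0)
    flip = rng.random(len(standing)) < 1.0 - np.exp(-r * tau.values)
    flip_keys = set(
        zip(standing.loc[flip.tolist(), "plot_id"], standing.loc[flip.tolist(), "tree_id"])
    )
    trees = out.trees
    is_dead_standing = (trees["status"] == "dead") & (trees["mode_of_death"] == "standing")
    keys = list(zip(trees["plot_id"], trees["tree_id"]))
    mask = is_dead_standing.values & np.array([k in flip_keys for k in keys])
    trees.loc[mask, "mode_of_death"] = "broken_uprooted"
    return out


def mask_traits(
    traits: pd.DataFrame,
    rates: Sequence[float],
    seed: int = 0,
    columns: Sequence[str] = ("wd_g_cm3", "max_d_mm", "mean_growth_mm_yr", "wda_mm"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply hierarchical trait missingness; returns (masked table, report).

    ``rates = (p_species, p_genus, p_family)``: each species independently
    loses its own value with probability ``p_species`` (imputable from its
    genus); each genus loses *all* member species' values with probability
    ``p_genus`` (falls through to the family mean); each family likewise
    with probability ``p_family`` (falls through to the plot mean).  All
    three mechanisms are applied independently per trait column, so the
    imputation cascade exercises every branch.
    """
    p_sp, p_gen, p_fam = rates
    for p in rates:
        if not 0.0 <= p <= 1.0:
            raise ValueError("missingness rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = traits.copy()
    genera = np.sort(traits["genus"].unique())
    families = np.sort(traits["family"].unique())
    report_rows = []
    for col in columns:
        sp_mask = rng.random(len(out)) < p_sp
        gen_masked = set(genera[rng.random(len(genera)) < p_gen])
        fam_masked = set(families[rng.random(len(families)) < p_fam])
        full_mask = (
            sp_mask
            | out["genus"].isin(gen_masked).values
            | out["family"].isin(fam_masked).values
        )
        out.loc[full_mask, col] = np.nan
        report_rows.append(
            {
                "trait": col,
                "n_species_masked": int(sp_mask.sum()),
                "n_genera_masked": len(gen_masked),
                "n_families_masked": len(fam_masked),
                "n_missing_total": int(full_mask.sum()),
            }
        )
    return out, pd.DataFrame(report_rows)
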