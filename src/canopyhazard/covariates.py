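"""Analysis-ready survival records: growth, size terms and trait attachment.

Each tree entering the risk model contributes one record (or, optionally, a
counting-process set of per-interval records).  Tree-level covariates follow
the census-data convention: stem diameter ``D`` is taken at the penultimate
census in which the tree was recorded, and the relative growth rate

    rel_growth = 100 * ((D_t1 - D_t0) / T) / D_t0   [% yr⁻¹]

is computed between the antepenultimate (t0) and penultimate (t1) censuses.
Palms are excluded (no secondary growth), as are records with relative
growth below −5 % yr⁻¹ (biologically impossible shrinkage, i.e. measurement
error).

Species traits (wood density g cm⁻³, maximum diameter mm, species mean
growth mm yr⁻¹, water-deficit affiliation mm) attach through a hierarchical
imputation cascade: species value → genus mean → family mean → plot mean
over individuals; the level used is recorded per trait.

Units on the model scale: D in metres (so size coefficients are O(1–10)),
rel_growth in % yr⁻¹, max_d in mm, mean_growth in mm yr⁻¹, wood density in
g cm⁻³, WDA in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census import CensusDataset

__all__ = [
    "relative_growth",
    "size_terms",
    "TraitImputer",
    "impute_trait",
    "assemble_survival_records",
    "TRAITS",
    "RECORD_TERMS",
]

TRAITS = ("wd_g_cm3", "max_d_mm", "mean_growth_mm_yr", "wda_mm")
#: trait column -> survival-record column
TRAIT_RENAME = {
    "wd_g_cm3": "wood_density",
    "max_d_mm": "max_d",
    "mean_growth_mm_yr": "mean_growth",
    "wda_mm": "wda",
}
RECORD_TERMS = ("D", "D2", "rel_growth", "max_d", "mean_growth", "wood_density", "wda")
GROWTH_FLOOR = -5.0  # % yr-1


def relative_growth(d_t0: float, d_t1: float, T: float) -> float:
    """Relative diameter growth in % yr⁻¹ over the interval t0 → t1."""
    if d_t0 <= 0:
        raise ValueError("initial diameter must be positive")
    if T <= 0:
        raise ValueError("time span must be positive")
    return 100.0 * ((d_t1 - d_t0) / T) / d_t0


def size_terms(d_m: float, quadratic: bool = True):
    """Linear (and optionally quadratic) design terms for diameter in metres."""
    if np.any(np.asarray(d_m) <= 0):
        raise ValueError("diameter must be positive")
    return (d_m, d_m**2) if quadratic else (d_m,)


class TraitImputer:
    """Hierarchical species → genus → family → plot trait imputation.

    Genus and family means are computed across the *species* present in the
    trait table (each species counted once); the plot fallback is the mean
    across the plot's individual trees of their species-level values, so
    abundant species weigh more.  Deterministic and order-invariant.
    """

    def __init__(self, traits: pd.DataFrame, plot_individuals: pd.DataFrame | None = None):
        if traits is None or traits.empty:
            raise ValueError("empty trait table")
        self.traits = traits.drop_duplicates(subset="species").set_index("species")
        self.genus_means = traits.groupby("genus")[list(TRAITS)].mean()
        self.family_means = traits.groupby("family")[list(TRAITS)].mean()
        self.plot_means = None
        if plot_individuals is not None:
            # one row per individual tree: plot_id, species
            joined = plot_individuals.merge(
                traits[["species", *TRAITS]], on="species", how="left"
            )
            self.plot_means = joined.groupby("plot_id")[list(TRAITS)].mean()

    def impute(self, species: str, trait: str, plot_id: str | None = None):
        """Return ``(value, level)`` for one species/trait pair."""
        if trait not in TRAITS:
            raise KeyError(trait)
        if species in self.traits.index:
            v = self.traits.at[species, trait]
            if pd.notna(v):
                return float(v), "species"
        genus = species.split()[0] if species else ""
        row = self.traits.loc[species] if species in self.traits.index else None
        if row is not None and pd.notna(row.get("genus")):
            genus = row["genus"]
        if genus in self.genus_means.index:
            v = self.genus_means.at[genus, trait]
            if pd.notna(v):
                return float(v), "genus"
        family = row["family"] if row is not None and pd.notna(row.get("family")) else None
        if family in self.family_means.index:
            v = self.family_means.at[family, trait]
            if pd.notna(v):
                return float(v), "family"
        if self.plot_means is not None and plot_id in self.plot_means.index:
            v = self.plot_means.at[plot_id, trait]
            if pd.notna(v):
                return float(v), "plot"
        raise ValueError(
            f"trait {trait!r} unresolvable for species {species!r} (empty cascade)"
        )


def impute_trait(
    species: str,
    trait: str,
    traits: pd.DataFrame,
    plot_individuals: pd.DataFrame | None = None,
    plot_id: str | None = None,
):
    """Functional wrapper around :class:`TraitImputer` for a single lookup."""
    return TraitImputer(traits, plot_individuals).impute(species, trait, plot_id)


def _attach_traits(records: pd.DataFrame, ds: CensusDataset) -> pd.DataFrame:
    """Vectorised cascade over the assembled record set."""
    traits = ds.traits
    if traits is None:
        raise ValueError("dataset has no trait table")
    sp = traits.drop_duplicates(subset="species").set_index("species")
    genus_means = traits.groupby("genus")[list(TRAITS)].mean()
    family_means = traits.groupby("family")[list(TRAITS)].mean()
    # plot fallback: individual-weighted over trees present in the plot
    individuals = (
        ds.trees.groupby(["plot_id", "tree_id"], sort=False)
        .agg(species=("species", "first"))
        .reset_index()
    )
    plot_means = (
        individuals.merge(traits[["species", *TRAITS]], on="species", how="left")
        .groupby("plot_id")[list(TRAITS)]
        .mean()
    )
    out = records.copy()
    genus = out["species"].str.split().str[0]
    family = out["species"].map(sp["family"]) if "family" in sp else None
    for trait in TRAITS:
        v_sp = out["species"].map(sp[trait])
        v_gen = genus.map(genus_means[trait])
        v_fam = family.map(family_means[trait]) if family is not None else pd.Series(np.nan, index=out.index)
        v_plot = out["plot_id"].map(plot_means[trait])
        value = v_sp.copy()
        level = np.where(v_sp.notna(), "species", "")
        use = value.isna() & v_gen.notna()
        value[use] = v_gen[use]
        level = np.where(use, "genus", level)
        use = value.isna() & v_fam.notna()
        value[use] = v_fam[use]
        level = np.where(use, "family", level)
        use = value.isna() & v_plot.notna()
        value[use] = v_plot[use]
        level = np.where(use, "plot", level)
        if value.isna().any():
            bad = out.loc[value.isna(), "species"].unique()[:5]
            raise ValueError(f"trait {trait!r} unresolvable for species: {list(bad)}")
        out[TRAIT_RENAME[trait]] = value.astype(float)
        out[f"imput_{TRAIT_RENAME[trait]}"] = level
    return out


@dataclass
class ExclusionReport:
    excluded: pd.DataFrame  # tree_id, plot_id, reason
    counts: dict

    def count(self, reason: str) -> int:
        return int(self.counts.get(reason, 0))


def assemble_survival_records(
    ds: CensusDataset,
    entry: str = "first",
    death_time: str = "census",
    counting_process: bool = False,
    min_censuses: int = 3,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Build one survival record per eligible tree (plus an exclusion report).

    Default timing convention: the tree's clock starts at its first observed
    census (``entry='first'``; ``entry='penultimate'`` restricts risk time to
    the growth-measurement interval onward), and ends at the census where it
    was found dead (``death_time='census'``; ``'midpoint'`` places the death
    halfway into the final interval) or at its last census if censored.
    Trees observed fewer than three times, palms, records with missing
    diameters and relative growth below −5 % yr⁻¹ are excluded and counted.

    With ``counting_process=True``, each tree instead contributes one row per
    census interval from its second observed interval onward (``start`` and
    ``time`` on the plot-calendar clock, covariates updated per interval,
    delayed entry once a growth history exists) — the time-varying
    representation for sensitivity checks.
    """
    if entry not in ("first", "penultimate"):
        raise ValueError("entry must be 'first' or 'penultimate'")
    if death_time not in ("census", "midpoint"):
        raise ValueError("death_time must be 'census' or 'midpoint'")

    plots_ok = [p for p in ds.plots.index if len(ds.plots.at[p, "census_dates"]) >= min_censuses]
    excl_rows = []
    for p in set(ds.plots.index) - set(plots_ok):
        excl_rows.append({"tree_id": "*", "plot_id": p, "reason": f"plot has < {min_censuses} censuses"})

    rec_frames = []
    for pid in plots_ok:
        sub = ds.trees[ds.trees["plot_id"] == pid]
        dates = np.asarray(ds.plots.at[pid, "census_dates"], dtype=float)
        frame = _plot_records(sub, dates, pid, entry, death_time, counting_process, excl_rows)
        if frame is not None:
            rec_frames.append(frame)
    if rec_frames:
        records = pd.concat(rec_frames, ignore_index=True)
    else:
        records = pd.DataFrame(
            columns=["tree_id", "plot_id", "species", "start", "time", "event", "death_mode",
                     "D", "D2", "rel_growth"]
        )

    # growth-outlier exclusion happens on the assembled covariates
    bad = records["rel_growth"] < GROWTH_FLOOR
    if bad.any():
        for r in records.loc[bad, ["tree_id", "plot_id"]].drop_duplicates().itertuples():
            excl_rows.append({"tree_id": r.tree_id, "plot_id": r.plot_id,
                              "reason": "relative growth < -5 % yr-1"})
        bad_trees = set(zip(records.loc[bad, "plot_id"], records.loc[bad, "tree_id"]))
        keep = [k not in bad_trees for k in zip(records["plot_id"], records["tree_id"])]
        records = records[np.asarray(keep)]

    if not records.empty and ds.traits is not None:
        records = _attach_traits(records, ds)

    excluded = pd.DataFrame(excl_rows, columns=["tree_id", "plot_id", "reason"])
    counts = excluded["reason"].value_counts().to_dict()
    return records.reset_index(drop=True), ExclusionReport(excluded=excluded, counts=counts)


def _plot_records(sub, dates, pid, entry, death_time, counting_process, excl_rows):
    K = len(dates)
    st = sub.pivot(index="tree_id", columns="census_index", values="status").reindex(columns=range(K))
    dm = sub.pivot(index="tree_id", columns="census_index", values="d_mm").reindex(columns=range(K))
    meta = sub.groupby("tree_id").agg(species=("species", "first"), is_palm=("is_palm", "first"))
    md = (
        sub[sub["status"] == "dead"].set_index("tree_id")["mode_of_death"]
        if (sub["status"] == "dead").any()
        else pd.Series(dtype=object)
    )
    status = st.values
    diam = dm.values.astype(float)
    observed = pd.notna(st).values
    alive = status == "alive"
    trees = st.index.to_numpy()

    palm = meta.loc[st.index, "is_palm"].values.astype(bool)
    for t in trees[palm]:
        excl_rows.append({"tree_id": t, "plot_id": pid, "reason": "palm"})

    n_obs = observed.sum(axis=1)
    first_obs = observed.argmax(axis=1)
    last_obs = K - 1 - observed[:, ::-1].argmax(axis=1)
    too_few = (~palm) & (n_obs < 3)
    for t in trees[too_few]:
        excl_rows.append({"tree_id": t, "plot_id": pid, "reason": "fewer than 2 pre-final observations"})

    cand = ~(palm | too_few)
    rows = []
    idx_all = np.arange(len(trees))
    for i in idx_all[cand]:
        j_last = last_obs[i]
        j_pen, j_ante = j_last - 1, j_last - 2
        final_status = status[i, j_last]
        if final_status == "lost":
            # exit at the last alive census; the measurement pair shifts back
            j_exit = j_last - 1
            j_pen, j_ante = j_last - 2, j_last - 3
            event = 0
            if j_ante < first_obs[i]:
                excl_rows.append({"tree_id": trees[i], "plot_id": pid,
                                  "reason": "fewer than 2 pre-final observations"})
                continue
        else:
            j_exit = j_last
            event = int(final_status == "dead")
        d_pen, d_ante = diam[i, j_pen], diam[i, j_ante]
        if not (np.isfinite(d_pen) and np.isfinite(d_ante)):
            excl_rows.append({"tree_id": trees[i], "plot_id": pid, "reason": "missing diameter"})
            continue
        T = dates[j_pen] - dates[j_ante]
        relg = relative_growth(d_ante, d_pen, T)
        entry_j = first_obs[i] if entry == "first" else j_pen
        t_entry = dates[entry_j]
        t_exit = dates[j_exit]
        if event and death_time == "midpoint":
            t_exit = 0.5 * (dates[j_exit - 1] + dates[j_exit])
        D_m = d_pen / 1000.0
        mode = md.get(trees[i], "not_applicable") if event else "not_applicable"
        if not counting_process:
            rows.append(
                {
                    "tree_id": trees[i], "plot_id": pid, "species": meta.at[trees[i], "species"],
                    "start": 0.0, "time": t_exit - t_entry, "event": event,
                    "death_mode": mode, "D": D_m, "D2": D_m**2, "rel_growth": relg,
                }
            )
        else:
            # one row per at-risk interval from the second observed interval on,
            # on the plot-calendar clock (delayed entry at the first interval
            # with a measurable growth history)
            t0 = dates[0]
            for j in range(first_obs[i] + 1, j_exit):
                if not alive[i, j]:
                    break
                d_j, d_prev = diam[i, j], diam[i, j - 1]
                if not (np.isfinite(d_j) and np.isfinite(d_prev)):
                    continue
                relg_j = relative_growth(d_prev, d_j, dates[j] - dates[j - 1])
                stop = dates[j + 1] if (j + 1 < j_exit or not event or death_time == "census") else t_exit
                stop = min(stop, t_exit)
                is_final = (j + 1 == j_exit) or (stop == t_exit)
                Dj = d_j / 1000.0
                rows.append(
                    {
                        "tree_id": trees[i], "plot_id": pid,
                        "species": meta.at[trees[i], "species"],
                        "start": dates[j] - t0, "time": stop - t0,
                        "event": event if is_final else 0,
                        "death_mode": mode if is_final and event else "not_applicable",
                        "D": Dj, "D2": Dj**2, "rel_growth": relg_j,
                    }
                )
                if is_final:
                    break
    if not rows:
        return None
    return pd.DataFrame(rows)
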