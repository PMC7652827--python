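"""Census-table domain model, I/O, validation and plot eligibility filters.

The canonical interchange format is a pair of UTF-8 CSV files:

* census table — one row per tree per census:
  ``plot_id, tree_id, species, family, is_palm, census_date, d_mm, status,
  mode_of_death``
* plot table — one row per plot:
  ``plot_id, region, area_ha, lat, lon, elev_m``

Dates are decimal years throughout; diameters are millimetres at 1.3 m (or
above buttresses).  Trees enter the record when they first reach the 100 mm
recruitment threshold; because diameters are measured with tape error, a
tree's *first* alive observation must be >= 100 mm but later observations may
dip marginally below it (a warning, not an error).

Statuses: ``alive``, ``dead``, ``not_yet_recruited``, ``lost``.  A dead row
carries a mode of death (``standing``, ``broken_uprooted`` or ``unassessed``);
live rows carry ``not_applicable``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlotRecord",
    "TreeObservation",
    "TreeSeries",
    "CensusDataset",
    "CensusFormatError",
    "CensusValidationError",
    "read_census_table",
    "write_census_table",
    "filter_plots",
    "merge_nearby_plots",
    "mode_assessment_eligibility",
    "EligibilityResult",
    "haversine_km",
]

REGIONS = ("Northern", "EastCentral", "Western", "Southern")
STATUSES = ("alive", "dead", "not_yet_recruited", "lost")
MODES = ("standing", "broken_uprooted", "unassessed", "not_applicable")
RECRUIT_DIAMETER_MM = 100.0

CENSUS_COLUMNS = [
    "plot_id",
    "tree_id",
    "species",
    "family",
    "is_palm",
    "census_date",
    "d_mm",
    "status",
    "mode_of_death",
]
PLOT_COLUMNS = ["plot_id", "region", "area_ha", "lat", "lon", "elev_m"]


class CensusFormatError(ValueError):
    """Raised when an input file does not match the documented column contract."""


class CensusValidationError(ValueError):
    """Raised when a structurally well-formed dataset violates an invariant."""


@dataclass(frozen=True)
class PlotRecord:
    plot_id: str
    region: str
    area_ha: float
    latitude: float
    longitude: float
    elevation_m: float
    census_dates: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise CensusValidationError(f"plot {self.plot_id}: area_ha must be > 0")
        if any(b <= a for a, b in zip(self.census_dates, self.census_dates[1:])):
            raise CensusValidationError(
                f"plot {self.plot_id}: census dates not strictly increasing"
            )

    @property
    def n_censuses(self) -> int:
        return len(self.census_dates)

    @property
    def max_census_gap_yr(self) -> float:
        if self.n_censuses < 2:
            return 0.0
        return max(b - a for a, b in zip(self.census_dates, self.census_dates[1:]))


@dataclass(frozen=True)
class TreeObservation:
    tree_id: str
    plot_id: str
    census_index: int
    date: float
    diameter_mm: float | None
    status: str
    mode_of_death: str = "not_applicable"


@dataclass(frozen=True)
class TreeSeries:
    tree_id: str
    plot_id: str
    species_name: str
    genus: str
    family: str
    is_palm: bool
    observations: tuple[TreeObservation, ...]

    @property
    def is_dead(self) -> bool:
        return any(o.status == "dead" for o in self.observations)

    @property
    def mode_of_death(self) -> str:
        for o in self.observations:
            if o.status == "dead":
                return o.mode_of_death
        return "not_applicable"


@dataclass
class CensusDataset:
    """Validated plot + tree tables (long format) with optional species traits.

    ``plots`` is indexed by ``plot_id`` with columns region, area_ha, lat,
    lon, elev_m and census_dates (tuple of decimal years).  ``trees`` is the
    long observation table with one row per tree per census, carrying a
    ``census_index`` into the owning plot's census_dates.
    """

    plots: pd.DataFrame
    trees: pd.DataFrame
    traits: pd.DataFrame | None = None

    def plot_record(self, plot_id: str) -> PlotRecord:
        row = self.plots.loc[plot_id]
        return PlotRecord(
            plot_id=plot_id,
            region=row["region"],
            area_ha=float(row["area_ha"]),
            latitude=float(row["lat"]),
            longitude=float(row["lon"]),
            elevation_m=float(row["elev_m"]),
            census_dates=tuple(row["census_dates"]),
        )

    def tree_series(self, plot_id: str, tree_id: str) -> TreeSeries:
        sub = self.trees[
            (self.trees["plot_id"] == plot_id) & (self.trees["tree_id"] == tree_id)
        ].sort_values("census_index")
        if sub.empty:
            raise KeyError((plot_id, tree_id))
        first = sub.iloc[0]
        obs = tuple(
            TreeObservation(
                tree_id=tree_id,
                plot_id=plot_id,
                census_index=int(r.census_index),
                date=float(r.census_date),
                diameter_mm=None if pd.isna(r.d_mm) else float(r.d_mm),
                status=r.status,
                mode_of_death=r.mode_of_death,
            )
            for r in sub.itertuples()
        )
        return TreeSeries(
            tree_id=tree_id,
            plot_id=plot_id,
            species_name=first["species"],
            genus=first["genus"],
            family=first["family"],
            is_palm=bool(first["is_palm"]),
            observations=obs,
        )

    @property
    def n_trees(self) -> int:
        return self.trees.groupby(["plot_id", "tree_id"], sort=False).ngroups

    def copy(self) -> "CensusDataset":
        return CensusDataset(
            plots=self.plots.copy(),
            trees=self.trees.copy(),
            traits=None if self.traits is None else self.traits.copy(),
        )

    def validate(self) -> "CensusDataset":
        validate_dataset(self)
        return self


def _genus_from_species(species: pd.Series) -> pd.Series:
    return species.fillna("").str.split().str[0].fillna("")


def read_census_table(
    census_path,
    plots_path,
    traits_path=None,
    column_map: Mapping[str, str] | None = None,
) -> CensusDataset:
    """Read the canonical census + plot CSV pair into a validated dataset.

    ``column_map`` maps canonical column names to the names used in a
    non-canonical dialect, e.g. ``{"d_mm": "dbh_mm"}``.
    """
    census = pd.read_csv(census_path)
    if column_map:
        census = census.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in CENSUS_COLUMNS if c not in census.columns]
    if missing:
        raise CensusFormatError(
            f"census table missing required column(s): {', '.join(missing)}"
        )
    plots = pd.read_csv(plots_path)
    missing = [c for c in PLOT_COLUMNS if c not in plots.columns]
    if missing:
        raise CensusFormatError(
            f"plot table missing required column(s): {', '.join(missing)}"
        )

    census = census.copy()
    census["plot_id"] = census["plot_id"].astype(str)
    census["tree_id"] = census["tree_id"].astype(str)
    census["census_date"] = census["census_date"].astype(float)
    census["d_mm"] = pd.to_numeric(census["d_mm"], errors="coerce")
    census["is_palm"] = census["is_palm"].astype(bool)
    census["mode_of_death"] = census["mode_of_death"].fillna("not_applicable")
    census["genus"] = _genus_from_species(census["species"])

    plots = plots.copy()
    plots["plot_id"] = plots["plot_id"].astype(str)
    plots = plots.set_index("plot_id")

    # census_index: position of the row's date within the plot's date set
    dates = (
        census.groupby("plot_id")["census_date"].agg(lambda s: tuple(sorted(s.unique())))
    )
    plots["census_dates"] = dates.reindex(plots.index).apply(
        lambda v: v if isinstance(v, tuple) else ()
    )
    idx = np.empty(len(census), dtype=int)
    for pid, sub in census.groupby("plot_id"):
        lookup = {d: i for i, d in enumerate(plots.at[pid, "census_dates"])}
        idx[sub.index] = [lookup[d] for d in sub["census_date"]]
    census["census_index"] = idx

    traits = None
    if traits_path is not None:
        traits = read_traits_table(traits_path)

    ds = CensusDataset(plots=plots, trees=census, traits=traits)
    validate_dataset(ds)
    return ds


TRAIT_COLUMNS = [
    "species",
    "genus",
    "family",
    "wd_g_cm3",
    "max_d_mm",
    "mean_growth_mm_yr",
    "wda_mm",
]


def read_traits_table(path) -> pd.DataFrame:
    traits = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing:
        raise CensusFormatError(
            f"traits table missing required column(s): {', '.join(missing)}"
        )
    return traits


def write_census_table(ds: CensusDataset, census_path, plots_path, traits_path=None) -> None:
    """Inverse of :func:`read_census_table` (canonical dialect)."""
    out = ds.trees[CENSUS_COLUMNS].copy()
    out.to_csv(census_path, index=False)
    plots = ds.plots.reset_index()[PLOT_COLUMNS]
    plots.to_csv(plots_path, index=False)
    if traits_path is not None and ds.traits is not None:
        ds.traits[TRAIT_COLUMNS].to_csv(traits_path, index=False)


def validate_dataset(ds: CensusDataset) -> None:
    trees, plots = ds.trees, ds.plots
    bad_status = set(trees["status"]) - set(STATUSES)
    if bad_status:
        raise CensusValidationError(f"unknown status value(s): {sorted(bad_status)}")
    bad_mode = set(trees["mode_of_death"]) - set(MODES)
    if bad_mode:
        raise CensusValidationError(f"unknown mode_of_death value(s): {sorted(bad_mode)}")

    unknown_plots = set(trees["plot_id"]) - set(plots.index)
    if unknown_plots:
        raise CensusValidationError(
            f"tree rows reference unknown plot(s): {sorted(unknown_plots)}"
        )
    if (plots["area_ha"] <= 0).any():
        bad = plots.index[plots["area_ha"] <= 0].tolist()
        raise CensusValidationError(f"non-positive plot area for plot(s): {bad}")
    for pid, dates in plots["census_dates"].items():
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise CensusValidationError(
                f"census dates not strictly increasing for plot {pid}"
            )

    dup = trees.duplicated(subset=["plot_id", "tree_id", "census_date"], keep=False)
    if dup.any():
        key = trees.loc[dup, ["plot_id", "tree_id", "census_date"]].iloc[0]
        raise CensusValidationError(
            "duplicated (plot, tree, census) row: "
            f"({key.plot_id}, {key.tree_id}, {key.census_date})"
        )

    # mode only meaningful on dead rows
    bad = (trees["status"] != "dead") & (trees["mode_of_death"] != "not_applicable")
    if bad.any():
        r = trees.loc[bad].iloc[0]
        raise CensusValidationError(
            f"mode_of_death set on non-dead row: ({r.plot_id}, {r.tree_id})"
        )
    bad = (trees["status"] == "dead") & (trees["mode_of_death"] == "not_applicable")
    if bad.any():
        r = trees.loc[bad].iloc[0]
        raise CensusValidationError(
            f"dead row without mode_of_death (use 'unassessed'): ({r.plot_id}, {r.tree_id})"
        )

    # per-tree sequencing: a terminal (dead/lost) record must be the tree's
    # last observation
    order = trees.sort_values(["plot_id", "tree_id", "census_index"])
    pid_a = order["plot_id"].to_numpy()
    tid_a = order["tree_id"].to_numpy()
    same_tree_as_next = np.zeros(len(order), dtype=bool)
    if len(order) > 1:
        same_tree_as_next[:-1] = (pid_a[:-1] == pid_a[1:]) & (tid_a[:-1] == tid_a[1:])
    terminal = order["status"].isin(["dead", "lost"]).to_numpy()
    bad = terminal & same_tree_as_next
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        raise CensusValidationError(
            f"observation after dead/lost record for tree ({pid_a[k]}, {tid_a[k]})"
        )

    alive_rows = order["status"].to_numpy() == "alive"
    same_tree_as_prev = np.zeros(len(order), dtype=bool)
    same_tree_as_prev[1:] = same_tree_as_next[:-1]
    # first alive observation of a tree: alive and no earlier alive row
    grp_start = ~same_tree_as_prev
    alive_int = alive_rows.astype(int)
    cs = np.cumsum(alive_int)
    base = np.where(grp_start, cs - alive_int, np.nan)
    base = pd.Series(base).ffill().to_numpy()
    n_alive_before = cs - alive_int - base
    first_alive_row = alive_rows & (n_alive_before == 0)
    small = first_alive_row & (order["d_mm"].to_numpy() < RECRUIT_DIAMETER_MM)
    if small.any():
        k = int(np.flatnonzero(small)[0])
        raise CensusValidationError(
            f"first alive observation below {RECRUIT_DIAMETER_MM:g} mm recruitment "
            f"threshold for tree ({pid_a[k]}, {tid_a[k]})"
        )
    later_small = (order["status"] == "alive") & (order["d_mm"] < RECRUIT_DIAMETER_MM)
    if later_small.any():
        warnings.warn(
            f"{int(later_small.sum())} alive observation(s) below the recruitment "
            "threshold after recruitment (tape error tolerated)",
            stacklevel=2,
        )


# ---------------------------------------------------------------------------
# eligibility filters


def filter_plots(
    ds: CensusDataset,
    max_census_gap_yr: float = 10.0,
    min_area_ha: float = 0.5,
    max_elevation_m: float = 1000.0,
    min_censuses: int = 2,
) -> tuple[CensusDataset, pd.DataFrame]:
    """Drop plots violating the monitoring-eligibility rules.

    Returns the filtered dataset and an exclusion report with one row per
    (plot, rule) pair.  With ``min_censuses=3`` this reproduces the
    survival-analysis subset rule (plots monitored three or more times).
    """
    rows = []
    keep = []
    for pid, row in ds.plots.iterrows():
        dates = row["census_dates"]
        reasons = []
        if row["elev_m"] >= max_elevation_m:
            reasons.append(f"elevation >= {max_elevation_m:g} m")
        if row["area_ha"] < min_area_ha:
            reasons.append(f"area < {min_area_ha:g} ha")
        if len(dates) < min_censuses:
            reasons.append(f"fewer than {min_censuses} censuses")
        gaps = [b - a for a, b in zip(dates, dates[1:])]
        if gaps and max(gaps) > max_census_gap_yr:
            reasons.append(f"census gap > {max_census_gap_yr:g} yr")
        if reasons:
            rows.extend({"plot_id": pid, "rule": r} for r in reasons)
        else:
            keep.append(pid)
    report = pd.DataFrame(rows, columns=["plot_id", "rule"])
    if not keep:
        warnings.warn("all plots excluded by the eligibility filters", stacklevel=2)
    out = CensusDataset(
        plots=ds.plots.loc[keep],
        trees=ds.trees[ds.trees["plot_id"].isin(keep)].copy(),
        traits=ds.traits,
    )
    return out, report


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (mean Earth radius 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = p2 - p1, math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * 6371.0 * math.asin(math.sqrt(a))


def _schedules_compatible(d1: Sequence[float], d2: Sequence[float], tol: float) -> bool:
    return len(d1) == len(d2) and all(abs(a - b) <= tol for a, b in zip(d1, d2))


def merge_nearby_plots(
    ds: CensusDataset,
    max_distance_km: float = 1.0,
    schedule_tol_yr: float = 0.5,
) -> tuple[CensusDataset, pd.DataFrame]:
    """Join plots closer than ``max_distance_km`` into single analysis units.

    Merging is transitive within a connected component of the distance graph,
    but only among plots whose census schedules align within
    ``schedule_tol_yr`` per census after index alignment; incompatible plots
    are left unmerged and reported.  Merged plots must share a region — mixed
    regions within a merge candidate raise loudly rather than guessing.
    Area is summed; the merged census dates are the per-index mean.
    """
    pids = list(ds.plots.index)
    parent = {p: p for p in pids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(pids):
        ra = ds.plots.loc[a]
        for b in pids[i + 1 :]:
            rb = ds.plots.loc[b]
            if haversine_km(ra["lat"], ra["lon"], rb["lat"], rb["lon"]) < max_distance_km:
                parent[find(a)] = find(b)

    report_rows = []
    new_plots = []
    tree_frames = []
    for root in sorted({find(p) for p in pids}):
        members = sorted(p for p in pids if find(p) == root)
        if len(members) == 1:
            pid = members[0]
            new_plots.append(ds.plots.loc[[pid]])
            tree_frames.append(ds.trees[ds.trees["plot_id"] == pid])
            continue
        # greedy schedule-compatible clustering inside the component
        clusters: list[list[str]] = []
        for pid in members:
            dates = ds.plots.at[pid, "census_dates"]
            for cl in clusters:
                if _schedules_compatible(
                    ds.plots.at[cl[0], "census_dates"], dates, schedule_tol_yr
                ):
                    cl.append(pid)
                    break
            else:
                clusters.append([pid])
        for cl in clusters:
            if len(cl) == 1:
                pid = cl[0]
                report_rows.append(
                    {"plot_id": pid, "note": "within merge distance but census schedule incompatible"}
                )
                new_plots.append(ds.plots.loc[[pid]])
                tree_frames.append(ds.trees[ds.trees["plot_id"] == pid])
                continue
            sub = ds.plots.loc[cl]
            regions = set(sub["region"])
            if len(regions) > 1:
                raise CensusValidationError(
                    f"cannot merge plots {cl}: regions differ ({sorted(regions)})"
                )
            area = sub["area_ha"].sum()
            w = sub["area_ha"] / area
            dates = tuple(
                float(np.mean([ds.plots.at[p, "census_dates"][i] for p in cl]))
                for i in range(len(ds.plots.at[cl[0], "census_dates"]))
            )
            merged_id = "+".join(cl)
            new_plots.append(
                pd.DataFrame(
                    {
                        "region": [sub["region"].iloc[0]],
                        "area_ha": [area],
                        "lat": [float((sub["lat"] * w).sum())],
                        "lon": [float((sub["lon"] * w).sum())],
                        "elev_m": [float((sub["elev_m"] * w).sum())],
                        "census_dates": [dates],
                    },
                    index=pd.Index([merged_id], name="plot_id"),
                )
            )
            t = ds.trees[ds.trees["plot_id"].isin(cl)].copy()
            t["tree_id"] = t["plot_id"] + ":" + t["tree_id"]  # avoid tag collisions
            t["plot_id"] = merged_id
            tree_frames.append(t)

    out = CensusDataset(
        plots=pd.concat(new_plots),
        trees=pd.concat(tree_frames, ignore_index=True),
        traits=ds.traits,
    )
    report = pd.DataFrame(report_rows, columns=["plot_id", "note"])
    return out, report


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    n_dead: int
    n_assessed: int
    reason: str = ""


def mode_assessment_eligibility(
    plot_trees: pd.DataFrame,
    min_fraction: float = 0.5,
    min_assessed: int = 5,
) -> EligibilityResult:
    """Mode-of-death eligibility: >=50 % of dead trees assessed and >=5 assessed.

    ``plot_trees`` is the long observation table restricted to one plot.
    Counts alone decide; tree order is irrelevant.
    """
    dead = plot_trees[plot_trees["status"] == "dead"]
    n_dead = len(dead)
    n_assessed = int((dead["mode_of_death"] != "unassessed").sum())
    if n_dead == 0:
        return EligibilityResult(False, 0, 0, "no deaths")
    if n_assessed < min_assessed:
        return EligibilityResult(
            False, n_dead, n_assessed, f"fewer than {min_assessed} assessed deaths"
        )
    if n_assessed / n_dead < min_fraction:
        return EligibilityResult(
            False, n_dead, n_assessed, f"less than {min_fraction:.0%} of deaths assessed"
        )
    return EligibilityResult(True, n_dead, n_assessed)
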