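"""Stem- and species-level biomass and woody-productivity accounting.

Stem abundance and biomass are taken from the first census of each plot.
Woody productivity uses multi-census plots only (at least two censuses
spanning two or more years): each stem's productivity is the mean of its
per-interval biomass changes,

    P_stem = (1 / N) * sum_i P_i,      P_i = (B(D_end) - B(D_start)) / dt_i,

over the N census intervals in which the stem was present, with recruits
assumed to cross the 10-cm threshold at the start of their recruitment
interval.  Shrinkage (negative P_i) is retained.  Diameter series that
changed point of measurement are standardized first.

Monocots (palms) lack radial growth, so their productivity is estimated by
the necromass-equilibrium method: for every stem of a (stem-hyperdominant)
palm species that died,

    P_stem = (B_final - B_10cm) / (C_dead - C_1),

where B_final is palm biomass at the last recorded diameter, B_10cm the palm
biomass at 10 cm, C_1 the initial plot census date and C_dead the census at
which the stem was recorded dead; species productivity is the sum over its
dead stems.  Stems of palm species too rare for this estimator are excluded
from both the productivity numerator and denominator.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .allometry import AllometryConfig, agb_palm, stem_biomass_kg
from .census import Dataset, first_census_view, plot_census_dates
from .dominance import hyperdominants

__all__ = [
    "standardize_pom",
    "standardize_dataset_pom",
    "interval_productivity_table",
    "stem_productivity_table",
    "palm_mortality_records",
    "productivity_subset",
    "SpeciesAggregates",
    "species_table",
    "aggregate_species",
]

RECRUIT_D_CM = 10.0
POM_TOL_M = 1e-6


# ---------------------------------------------------------------------------
# POM standardization

def standardize_pom(dates, d_cm, pom_m):
    """Return a diameter series standardized across POM changes.

    The series is split into constant-POM segments.  The newest segment is
    kept verbatim; each earlier segment is shifted additively so that the
    growth imputed across the join equals the tree's mean within-segment
    growth rate times the join interval (zero if the tree has no
    within-segment increment).  This preserves every post-change diameter
    and all increments measured at a single POM.  A constant-POM series is
    returned unchanged.
    """
    dates = np.asarray(dates, dtype=float)
    d = np.asarray(d_cm, dtype=float).copy()
    pom = np.asarray(pom_m, dtype=float)
    if len(d) < 2:
        return d
    change = np.abs(np.diff(pom)) > POM_TOL_M
    if not change.any():
        return d
    joins = np.flatnonzero(change)  # join between index j and j+1
    # mean within-segment growth rate
    seg_id = np.concatenate([[0], np.cumsum(change)])
    incr = 0.0
    span = 0.0
    for s in np.unique(seg_id):
        idx = np.flatnonzero(seg_id == s)
        if len(idx) >= 2:
            incr += d[idx[-1]] - d[idx[0]]
            span += dates[idx[-1]] - dates[idx[0]]
    rate = incr / span if span > 0 else 0.0
    if span == 0:
        warnings.warn(
            "POM change with no within-segment increments; splicing with "
            "zero imputed growth across the join",
            stacklevel=2,
        )
    for j in joins[::-1]:  # newest join first; shift everything before it
        g = rate * (dates[j + 1] - dates[j])
        offset = (d[j + 1] - g) - d[j]
        d[: j + 1] += offset
    return d


def standardize_dataset_pom(ds: Dataset) -> pd.DataFrame:
    """Alive observations with a ``d_std_cm`` column (POM-standardized)."""
    alive = ds.obs[ds.obs["alive"]].sort_values(["tree_id", "census_index"])
    out = alive.copy()
    out["d_std_cm"] = out["d_cm"]
    changed = (
        alive.groupby("tree_id")["pom_m"]
        .transform(lambda s: (s.diff().abs() > POM_TOL_M).any())
    )
    for tree_id, grp in alive[changed].groupby("tree_id", sort=False):
        out.loc[grp.index, "d_std_cm"] = standardize_pom(
            grp["date"].values, grp["d_cm"].values, grp["pom_m"].values
        )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# productivity dataset

def productivity_subset(ds: Dataset, min_span_yr: float = 2.0) -> Dataset:
    """Restrict to plots with >= 2 censuses spanning >= ``min_span_yr`` years."""
    sched = plot_census_dates(ds)
    span = sched.groupby("plot_id")["date"].agg(["min", "max", "count"])
    ok = span[(span["count"] >= 2) & (span["max"] - span["min"] >= min_span_yr)]
    out = ds.copy()
    out.plots = out.plots[out.plots["plot_id"].isin(ok.index)].reset_index(drop=True)
    out.trees = out.trees[out.trees["plot_id"].isin(ok.index)].reset_index(drop=True)
    out.obs = out.obs[out.obs["tree_id"].isin(out.trees["tree_id"])].reset_index(
        drop=True
    )
    if out.attributes is not None:
        out.attributes = out.attributes[
            out.attributes["tree_id"].isin(out.trees["tree_id"])
        ].reset_index(drop=True)
    return out


def _stem_frame(ds: Dataset) -> pd.DataFrame:
    """Per-tree static attributes: plot, taxon, rho, region, monocot flag."""
    if ds.attributes is None or "rho" not in ds.attributes:
        raise ValueError("wood density not assigned; run assign_wood_density first")
    if "region" not in ds.attributes:
        raise ValueError("regions not assigned; run assign_regions first")
    taxa = ds.taxa.set_index("taxon_id")
    t = ds.trees.merge(ds.attributes, on="tree_id", how="left")
    t["is_monocot"] = t["taxon_id"].map(taxa["is_monocot"]).astype(bool)
    t["id_level"] = t["taxon_id"].map(taxa["id_level"])
    return t


def interval_productivity_table(ds: Dataset, config: AllometryConfig) -> pd.DataFrame:
    """Per-interval stem productivity P_i (Mg yr^-1) for non-monocot stems.

    Includes the recruitment interval (start clamped to a 10-cm diameter at
    the previous plot census).  Columns: tree_id, interval, t0, t1, d0, d1,
    p_mg_yr, is_recruit_interval.
    """
    stems = _stem_frame(ds)
    sched = plot_census_dates(ds)
    obs = standardize_dataset_pom(ds)
    obs = obs.merge(
        stems[["tree_id", "plot_id", "rho", "region", "is_monocot"]],
        on="tree_id", how="left",
    )
    obs = obs[~obs["is_monocot"]].sort_values(["tree_id", "census_index"])
    if len(obs) == 0:
        return pd.DataFrame(
            columns=["tree_id", "interval", "t0", "t1", "d0", "d1",
                     "p_mg_yr", "is_recruit_interval"],
        )
    obs = obs.copy()
    obs["b_Mg"] = stem_biomass_kg(
        obs["d_std_cm"].values, obs["rho"].values, obs["region"].values,
        np.zeros(len(obs), dtype=bool), config,
    ) / 1000.0

    g = obs.groupby("tree_id", sort=False)
    dt = g["date"].diff()
    if (dt.dropna() <= 0).any():
        bad = obs.loc[dt[dt <= 0].index[0], "tree_id"]
        raise ValueError(f"zero-length census interval for tree {bad!r}")
    within = pd.DataFrame(
        {
            "tree_id": obs["tree_id"],
            "t0": g["date"].shift(1),
            "t1": obs["date"],
            "d0": g["d_std_cm"].shift(1),
            "d1": obs["d_std_cm"],
            "p_mg_yr": g["b_Mg"].diff() / dt,
            "is_recruit_interval": False,
        }
    ).dropna(subset=["p_mg_yr"])

    # recruits: first alive observation after the plot's first census gains
    # an interval from the preceding plot census with a 10-cm start diameter
    first = g.first().reset_index()  # first alive obs per tree
    first_plot_census = sched.groupby("plot_id")["census_index"].min()
    rec = first[
        first["census_index"] > first["plot_id"].map(first_plot_census)
    ].copy()
    if len(rec):
        # date of the plot census immediately preceding first detection
        sched_sorted = sched.sort_values(["plot_id", "census_index"])
        prev_date = {}
        for pid, grp in sched_sorted.groupby("plot_id"):
            idxs = grp["census_index"].values
            dates = grp["date"].values
            for i in range(1, len(idxs)):
                prev_date[(pid, idxs[i])] = dates[i - 1]
        rec["t0"] = [
            prev_date.get((p, c))
            for p, c in zip(rec["plot_id"], rec["census_index"])
        ]
        rec = rec[pd.notna(rec["t0"])]
        below = rec["d_std_cm"] < RECRUIT_D_CM
        if below.any():
            warnings.warn(
                f"{int(below.sum())} recruit(s) first measured below 10 cm; "
                "start clamped at 10 cm",
                stacklevel=2,
            )
        b10 = stem_biomass_kg(
            np.full(len(rec), RECRUIT_D_CM), rec["rho"].values,
            rec["region"].values, np.zeros(len(rec), dtype=bool), config,
        ) / 1000.0
        recruit_iv = pd.DataFrame(
            {
                "tree_id": rec["tree_id"],
                "t0": rec["t0"].astype(float),
                "t1": rec["date"],
                "d0": RECRUIT_D_CM,
                "d1": rec["d_std_cm"],
                "p_mg_yr": (rec["b_Mg"].values - b10)
                / (rec["date"].values - rec["t0"].values.astype(float)),
                "is_recruit_interval": True,
            }
        )
        within = pd.concat([recruit_iv, within], ignore_index=True)

    within = within.sort_values(["tree_id", "t0"]).reset_index(drop=True)
    within["interval"] = within.groupby("tree_id").cumcount()
    return within[
        ["tree_id", "interval", "t0", "t1", "d0", "d1", "p_mg_yr",
         "is_recruit_interval"]
    ]


def stem_productivity_table(ds: Dataset, config: AllometryConfig) -> pd.DataFrame:
    """P_stem per non-monocot stem: mean of its interval productivities.

    Stems with no census interval (e.g. dead before the second census) carry
    no productivity and are absent from the result.
    Columns: tree_id, p_stem_mg_yr, n_intervals.
    """
    iv = interval_productivity_table(ds, config)
    if len(iv) == 0:
        return pd.DataFrame(columns=["tree_id", "p_stem_mg_yr", "n_intervals"])
    out = iv.groupby("tree_id", as_index=False).agg(
        p_stem_mg_yr=("p_mg_yr", "mean"), n_intervals=("p_mg_yr", "size")
    )
    return out


# ---------------------------------------------------------------------------
# palm necromass-equilibrium productivity

def palm_mortality_records(
    ds: Dataset, config: AllometryConfig, taxa_ids=None
) -> pd.DataFrame:
    """Necromass records for dead monocot stems.

    One row per monocot stem with an alive observation followed by a dead
    record: B_final (Mg, palm allometry at last recorded D), B_10cm (Mg),
    C_1 (initial plot census date), C_dead (census date recorded dead), and
    p_stem = (B_final - B_10cm) / (C_dead - C_1).  ``taxa_ids`` optionally
    restricts to given species.
    """
    stems = _stem_frame(ds)
    palms = stems[stems["is_monocot"]]
    if taxa_ids is not None:
        palms = palms[palms["taxon_id"].isin(set(taxa_ids))]
    sched = plot_census_dates(ds)
    c1 = sched.groupby("plot_id")["date"].min()
    b10 = agb_palm(RECRUIT_D_CM, config) / 1000.0

    obs = ds.obs[ds.obs["tree_id"].isin(palms["tree_id"])].sort_values(
        ["tree_id", "census_index"]
    )
    rows = []
    pinfo = palms.set_index("tree_id")
    for tree_id, grp in obs.groupby("tree_id", sort=False):
        alive = grp[grp["alive"]]
        dead = grp[~grp["alive"]]
        if len(alive) == 0 or len(dead) == 0:
            continue
        last_alive = alive.iloc[-1]
        first_dead = dead[dead["census_index"] > last_alive["census_index"]]
        if len(first_dead) == 0:
            continue
        c_dead = first_dead.iloc[0]["date"]
        c_1 = c1[pinfo.loc[tree_id, "plot_id"]]
        if c_dead <= c_1:
            continue
        b_final = agb_palm(last_alive["d_cm"], config) / 1000.0
        rows.append(
            (tree_id, pinfo.loc[tree_id, "taxon_id"], b_final, b10, c_1,
             c_dead, (b_final - b10) / (c_dead - c_1))
        )
    return pd.DataFrame(
        rows,
        columns=["tree_id", "taxon_id", "B_final_Mg", "B_10cm_Mg", "C_1",
                 "C_dead", "p_stem_mg_yr"],
    )


def palm_species_productivity(
    ds: Dataset, config: AllometryConfig, taxon_id
) -> float:
    """Necromass-equilibrium productivity (Mg yr^-1) of one palm species."""
    rec = palm_mortality_records(ds, config, taxa_ids=[taxon_id])
    if len(rec) == 0:
        warnings.warn(
            f"no recorded deaths for palm taxon {taxon_id!r}; productivity 0",
            stacklevel=2,
        )
        return 0.0
    return float(rec["p_stem_mg_yr"].sum())


# ---------------------------------------------------------------------------
# species aggregation

@dataclasses.dataclass
class SpeciesAggregates:
    """Per-species totals and contributions, plus dataset-level metadata.

    ``table`` has one row per species-level taxon: n_stems, biomass_Mg,
    productivity_Mg_yr (NaN where no stem survived to a second census, or
    where the metric is unavailable), and pct_* columns whose denominators
    include unidentified stems.  ``meta`` carries the totals those
    denominators used and the bookkeeping counts.
    """

    table: pd.DataFrame
    meta: dict


def species_table(
    ds: Dataset,
    config: AllometryConfig,
    include_productivity: bool = True,
    min_span_yr: float = 2.0,
) -> SpeciesAggregates:
    """Aggregate stems, biomass and (optionally) productivity per species.

    Stems and biomass use the first census of each plot.  Productivity uses
    the multi-census subset of ``ds`` (callers comparing full-set and
    productivity-set contributions pass the appropriate subset explicitly).
    Unidentified stems enter only the denominators.
    """
    stems = _stem_frame(ds)
    taxa = ds.taxa.set_index("taxon_id")

    # --- stems & biomass at the first census of each plot
    sched = plot_census_dates(ds)
    first_idx = sched.groupby("plot_id")["census_index"].min()
    obs1 = ds.obs[ds.obs["alive"]].merge(
        stems[["tree_id", "plot_id", "taxon_id", "rho", "region",
               "is_monocot", "id_level"]],
        on="tree_id",
    )
    obs1 = obs1[obs1["census_index"] == obs1["plot_id"].map(first_idx)]
    obs1 = obs1.copy()
    obs1["biomass_Mg"] = stem_biomass_kg(
        obs1["d_cm"].values, obs1["rho"].values,
        obs1["region"].values, obs1["is_monocot"].values, config,
    ) / 1000.0

    identified = obs1["id_level"] == "species"
    total_stems = int(len(obs1))
    total_biomass = float(obs1["biomass_Mg"].sum())

    by_sp = obs1[identified].groupby("taxon_id").agg(
        n_stems=("tree_id", "size"), biomass_Mg=("biomass_Mg", "sum")
    )

    meta = {
        "total_stems": total_stems,
        "total_biomass_Mg": total_biomass,
        "identified_stem_fraction": float(identified.mean()) if total_stems else np.nan,
        "n_species": int(by_sp.shape[0]),
        "allometry": config.to_dict(),
    }

    table = by_sp.reset_index()
    table["pct_stems"] = 100.0 * table["n_stems"] / total_stems
    table["pct_biomass"] = 100.0 * table["biomass_Mg"] / total_biomass

    if include_productivity:
        prod_ds = productivity_subset(ds, min_span_yr=min_span_yr)
        if len(prod_ds.plots) == 0:
            raise ValueError(
                "productivity requested but no plot has >= 2 censuses "
                f"spanning >= {min_span_yr} years"
            )
        p = _species_productivity(prod_ds, config)
        # outer merge keeps species observed only as recruits (0 first-census
        # stems) so the productivity table stays conservative
        table = table.merge(p["per_species"], on="taxon_id", how="outer")
        table["n_stems"] = table["n_stems"].fillna(0).astype(int)
        table["biomass_Mg"] = table["biomass_Mg"].fillna(0.0)
        table["pct_stems"] = 100.0 * table["n_stems"] / total_stems
        table["pct_biomass"] = 100.0 * table["biomass_Mg"] / total_biomass
        # species-level taxa observed only outside the productivity subset
        # or whose stems all died before a re-census keep NaN productivity
        table["pct_productivity"] = (
            100.0 * table["productivity_Mg_yr"] / p["total_productivity_Mg_yr"]
        )
        meta.update(
            total_productivity_Mg_yr=p["total_productivity_Mg_yr"],
            n_stems_productivity=p["n_stems_productivity"],
            n_rare_palm_stems_excluded=p["n_rare_palm_stems_excluded"],
            n_species_no_productivity=int(table["productivity_Mg_yr"].isna().sum()),
            palm_hyperdominant_taxa=p["palm_hyperdominant_taxa"],
        )
    else:
        table["productivity_Mg_yr"] = np.nan
        table["pct_productivity"] = np.nan

    table = table.merge(
        taxa[["family", "genus", "species"]], left_on="taxon_id",
        right_index=True, how="left",
    )
    cols = ["taxon_id", "family", "genus", "species", "n_stems", "biomass_Mg",
            "productivity_Mg_yr", "pct_stems", "pct_biomass", "pct_productivity"]
    table = table[cols].sort_values("taxon_id").reset_index(drop=True)
    meta["n_species"] = int(len(table))
    return SpeciesAggregates(table=table, meta=meta)


def _species_productivity(prod_ds: Dataset, config: AllometryConfig) -> dict:
    """Species productivity over a multi-census dataset (already subset).

    Dicot route: sum of P_stem over stems alive at the first plot census or
    recruited later.  Monocot route: necromass estimator for palm species
    that are stem hyperdominants of this dataset; other monocot stems are
    excluded from numerator and denominator.
    """
    stems = _stem_frame(prod_ds)
    taxa_level = stems.set_index("tree_id")["id_level"]

    # stem hyperdominants of this dataset decide palm eligibility
    sched = plot_census_dates(prod_ds)
    first_idx = sched.groupby("plot_id")["census_index"].min()
    obs1 = prod_ds.obs[prod_ds.obs["alive"]].merge(
        stems[["tree_id", "plot_id", "taxon_id", "id_level", "is_monocot"]],
        on="tree_id",
    )
    obs1 = obs1[obs1["census_index"] == obs1["plot_id"].map(first_idx)]
    sp_stems = (
        obs1[obs1["id_level"] == "species"].groupby("taxon_id").size()
        .rename("n_stems").reset_index()
    )
    sp_stems["pct_stems"] = 100.0 * sp_stems["n_stems"] / len(obs1)
    hd = hyperdominants(sp_stems, metric="stems")
    stem_hd = set(hd.ordered_taxa[: hd.n_hyperdominant])

    monocot_taxa = set(stems.loc[stems["is_monocot"], "taxon_id"].unique())
    palm_hd = sorted(t for t in monocot_taxa if t in stem_hd)

    # dicot (growth) route
    ps = stem_productivity_table(prod_ds, config)
    ps = ps.merge(stems[["tree_id", "taxon_id", "id_level"]], on="tree_id")
    ident = ps[ps["id_level"] == "species"]
    per_species = ident.groupby("taxon_id", as_index=False).agg(
        productivity_Mg_yr=("p_stem_mg_yr", "sum")
    )
    unid_productivity = float(ps.loc[ps["id_level"] != "species",
                                     "p_stem_mg_yr"].sum())

    # species present (alive, census 1) whose every stem died before any
    # interval: give them an explicit 0-interval marker by NOT appearing in
    # `per_species` — callers see NaN after the merge.

    # palm (necromass) route
    palm_rows = []
    for t in palm_hd:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            palm_rows.append(
                (t, palm_species_productivity(prod_ds, config, t))
            )
    if palm_rows:
        palm_df = pd.DataFrame(palm_rows,
                               columns=["taxon_id", "productivity_Mg_yr"])
        per_species = pd.concat(
            [per_species[~per_species["taxon_id"].isin(palm_hd)], palm_df],
            ignore_index=True,
        )
    n_rare_palm = int(
        stems["is_monocot"].sum()
        - stems["taxon_id"].isin(palm_hd).sum()
    )
    if n_rare_palm:
        warnings.warn(
            f"{n_rare_palm} stem(s) of non-hyperdominant palm species excluded "
            "from productivity numerator and denominator",
            stacklevel=2,
        )

    total = float(per_species["productivity_Mg_yr"].sum()) + unid_productivity
    return {
        "per_species": per_species,
        "total_productivity_Mg_yr": total,
        "n_stems_productivity": int(len(ps)),
        "n_rare_palm_stems_excluded": n_rare_palm,
        "palm_hyperdominant_taxa": palm_hd,
    }


def aggregate_species(
    ds: Dataset, config: AllometryConfig, mode: str = "all",
    min_span_yr: float = 2.0,
) -> SpeciesAggregates:
    """Spec-level entry point.

    ``mode`` selects which metrics are populated: ``stems`` / ``biomass``
    (first-census accounting only), ``productivity`` (requires a multi-census
    dataset) or ``all``.
    """
    if mode not in ("stems", "biomass", "productivity", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    include_p = mode in ("productivity", "all")
    return species_table(ds, config, include_productivity=include_p,
                         min_span_yr=min_span_yr)
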