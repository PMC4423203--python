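"""Census data model: containers, delimited-table I/O, filtering, wood density, regions.

The unit of observation is a single stem (tree) measured repeatedly across
plot censuses: diameter ``d_cm`` at a point of measurement ``pom_m`` (1.3 m or
above buttresses), an ``alive`` flag, and a decimal-year census date.  A
:class:`Dataset` bundles the per-tree table, the long observation table, plot
metadata, the taxonomy, and a wood-density lookup, plus (once assigned)
per-stem attributes: wood density with its provenance and the plot's region.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "CensusSchemaError",
    "LinkError",
    "MONOCOT_FAMILIES",
    "REGIONS",
    "read_census_tables",
    "write_census_tables",
    "filter_dataset",
    "assign_wood_density",
    "assign_regions",
    "assign_region",
    "first_census_view",
    "plot_census_dates",
]

#: Families treated as monocots (no radial growth; palm allometry route).
MONOCOT_FAMILIES = frozenset({"Arecaceae", "Strelitziaceae"})

#: Region codes: Guiana Shield, Brazilian Shield, East-Central,
#: Northwestern and Southwestern Amazonia.
REGIONS = ("GS", "BS", "EC", "NW", "SW")

_REGION_ALIASES = {
    "GS": "GS", "GUIANA SHIELD": "GS", "GUIANA": "GS",
    "BS": "BS", "BRAZILIAN SHIELD": "BS", "BRAZIL SHIELD": "BS",
    "EC": "EC", "EAST-CENTRAL": "EC", "EAST CENTRAL": "EC",
    "NW": "NW", "NORTHWESTERN": "NW",
    "SW": "SW", "SOUTHWESTERN": "SW",
    "W": "W", "WEST": "W", "WESTERN": "W",
}

#: Latitude (degrees) splitting Western Amazonia into NW (>= -8) and SW (< -8).
WEST_SPLIT_LATITUDE = -8.0

# Crude rectangular fallback delineation (lon_min, lon_max, lat_min, lat_max),
# used only for plots carrying no region label.  Real analyses should supply
# per-plot labels or their own boundary table.
DEFAULT_REGION_BOUNDS = [
    ("GS", (-62.0, -50.0, 0.0, 10.0)),
    ("EC", (-62.0, -44.0, -10.0, 0.0)),
    ("BS", (-64.0, -44.0, -20.0, -10.0)),
    ("W", (-80.0, -62.0, -20.0, 2.0)),
]

ID_LEVELS = ("species", "genus", "family", "none")


class CensusSchemaError(ValueError):
    """A table is missing mandatory columns or violates a row-level invariant."""


class LinkError(ValueError):
    """A record references an unknown plot or taxon."""


@dataclasses.dataclass
class Dataset:
    """Linked census tables.

    Attributes
    ----------
    trees : per-tree table (tree_id, plot_id, taxon_id, recruit_census).
    obs : long observation table
        (tree_id, census_index, date, d_cm, pom_m, alive).
    plots : plot metadata
        (plot_id, area_ha, lat, lon, elev_m, old_growth, terra_firme,
        cerrado, region_label).
    taxa : taxonomy (taxon_id, family, genus, species, id_level, is_monocot).
    wood_density : lookup (level, name, rho_g_cm3).
    attributes : per-stem derived attributes, filled by
        :func:`assign_wood_density` / :func:`assign_regions`
        (tree_id, rho, rho_provenance, region); ``None`` until assigned.
    """

    trees: pd.DataFrame
    obs: pd.DataFrame
    plots: pd.DataFrame
    taxa: pd.DataFrame
    wood_density: pd.DataFrame
    attributes: pd.DataFrame | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def copy(self) -> "Dataset":
        return Dataset(
            trees=self.trees.copy(),
            obs=self.obs.copy(),
            plots=self.plots.copy(),
            taxa=self.taxa.copy(),
            wood_density=self.wood_density.copy(),
            attributes=None if self.attributes is None else self.attributes.copy(),
        )

    def validate(self) -> None:
        """Raise on any structural invariant violation."""
        _validate_obs(self.obs)
        _validate_links(self)
        bad_rho = self.wood_density[
            ~self.wood_density["rho_g_cm3"].between(0.05, 1.5, inclusive="neither")
        ]
        if len(bad_rho):
            raise CensusSchemaError(
                f"wood density outside (0.05, 1.5) g cm^-3: "
                f"{bad_rho['name'].tolist()[:5]}"
            )


# ---------------------------------------------------------------------------
# parsing helpers

def to_decimal_year(value) -> float:
    """Parse a census date to decimal years.

    Accepts a decimal year (``2004.54``) or an ISO date string
    (``"2004-07-15"``).
    """
    if isinstance(value, (int, float, np.floating, np.integer)):
        return float(value)
    s = str(value).strip()
    try:
        return float(s)
    except ValueError:
        pass
    d = _dt.date.fromisoformat(s)
    start = _dt.date(d.year, 1, 1)
    length = (_dt.date(d.year + 1, 1, 1) - start).days
    return d.year + (d - start).days / length


_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _to_bool(series: pd.Series, col: str) -> pd.Series:
    if series.dtype == bool:
        return series
    def conv(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, (int, float, np.integer, np.floating)) and not pd.isna(v):
            return bool(int(v))
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE or pd.isna(v):
            return False
        raise CensusSchemaError(f"cannot parse boolean {v!r} in column {col!r}")
    return series.map(conv)


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CensusSchemaError(f"{table}: missing mandatory column(s) {missing}")


def _validate_obs(obs: pd.DataFrame) -> None:
    dup = obs.duplicated(subset=["tree_id", "census_index"], keep=False)
    if dup.any():
        first = obs.loc[dup, ["tree_id", "census_index"]].iloc[0]
        rows = obs.index[dup].tolist()[:5]
        raise CensusSchemaError(
            f"duplicate observation for tree {first['tree_id']!r} at census "
            f"{int(first['census_index'])} (rows {rows})"
        )
    alive = obs[obs["alive"]]
    bad_d = alive[~(alive["d_cm"] > 0)]
    if len(bad_d):
        raise CensusSchemaError(
            f"non-positive diameter on live stems, rows {bad_d.index.tolist()[:5]}"
        )
    srt0 = obs.sort_values(["tree_id", "census_index"])
    ddiff = srt0.groupby("tree_id", sort=False)["date"].diff()
    nonmono = ddiff.notna() & (ddiff <= 0)
    if nonmono.any():
        tree = srt0.loc[nonmono[nonmono].index[0], "tree_id"]
        raise CensusSchemaError(
            f"census dates not strictly increasing for tree {tree!r}"
        )
    # once dead, never alive again: scan each tree's series in census order
    srt = obs.sort_values(["tree_id", "census_index"])
    dead_seen = (~srt["alive"].astype(bool)).groupby(
        srt["tree_id"].values, sort=False
    ).cummax()
    dead_before = dead_seen.groupby(srt["tree_id"].values, sort=False).shift(
        1, fill_value=False
    )
    bad = srt["alive"].astype(bool).values & dead_before.astype(bool).values
    if bad.any():
        tree = srt.loc[srt.index[np.flatnonzero(bad)[0]], "tree_id"]
        raise CensusSchemaError(f"tree {tree!r} recorded alive after being dead")


def _validate_links(ds: Dataset) -> None:
    unknown_plot = ~ds.trees["plot_id"].isin(ds.plots["plot_id"])
    if unknown_plot.any():
        bad = ds.trees.loc[unknown_plot, ["tree_id", "plot_id"]].iloc[0]
        raise LinkError(
            f"tree {bad['tree_id']!r} references unknown plot {bad['plot_id']!r}"
        )
    unknown_taxon = ~ds.trees["taxon_id"].isin(ds.taxa["taxon_id"])
    if unknown_taxon.any():
        bad = ds.trees.loc[unknown_taxon, ["tree_id", "taxon_id"]].iloc[0]
        raise LinkError(
            f"tree {bad['tree_id']!r} references unknown taxon {bad['taxon_id']!r}"
        )
    unknown_obs = ~ds.obs["tree_id"].isin(ds.trees["tree_id"])
    if unknown_obs.any():
        raise LinkError(
            f"observations for unknown tree "
            f"{ds.obs.loc[unknown_obs, 'tree_id'].iloc[0]!r}"
        )


# ---------------------------------------------------------------------------
# I/O

def read_census_tables(trees_path, plots_path, taxa_path, wd_path) -> Dataset:
    """Read the four delimited tables into a validated, linked :class:`Dataset`.

    ``trees.csv`` is long format (one row per observation) with the tree-level
    columns repeated; it is normalized into ``trees`` + ``obs`` here.
    """
    raw = pd.read_csv(trees_path)
    _require_columns(
        raw,
        ["tree_id", "plot_id", "taxon_id", "census_index", "date", "d_cm",
         "pom_m", "alive"],
        "trees.csv",
    )
    if "recruit_census" not in raw.columns:
        raw["recruit_census"] = pd.NA
    raw["date"] = raw["date"].map(to_decimal_year)
    raw["alive"] = _to_bool(raw["alive"], "alive")
    raw["census_index"] = raw["census_index"].astype(int)
    raw["d_cm"] = pd.to_numeric(raw["d_cm"], errors="coerce")
    raw["pom_m"] = pd.to_numeric(raw["pom_m"], errors="coerce")

    trees = (
        raw[["tree_id", "plot_id", "taxon_id", "recruit_census"]]
        .drop_duplicates(subset="tree_id")
        .reset_index(drop=True)
    )
    trees["recruit_census"] = pd.to_numeric(
        trees["recruit_census"], errors="coerce"
    ).astype("Int64")
    conflicting = raw.groupby("tree_id")[["plot_id", "taxon_id"]].nunique()
    bad = conflicting[(conflicting > 1).any(axis=1)]
    if len(bad):
        raise CensusSchemaError(
            f"tree(s) with conflicting plot/taxon across rows: "
            f"{bad.index.tolist()[:5]}"
        )
    obs = raw[["tree_id", "census_index", "date", "d_cm", "pom_m", "alive"]].copy()
    obs = obs.sort_values(["tree_id", "census_index"]).reset_index(drop=True)

    plots = pd.read_csv(plots_path)
    _require_columns(
        plots,
        ["plot_id", "area_ha", "lat", "lon", "elev_m", "old_growth",
         "terra_firme", "cerrado"],
        "plots.csv",
    )
    for c in ("old_growth", "terra_firme", "cerrado"):
        plots[c] = _to_bool(plots[c], c)
    if "region_label" not in plots.columns:
        plots["region_label"] = pd.NA
    if not (plots["area_ha"] > 0).all():
        raise CensusSchemaError("plots.csv: non-positive area_ha")

    taxa = pd.read_csv(taxa_path)
    _require_columns(taxa, ["taxon_id", "family", "genus", "species", "id_level"],
                     "taxa.csv")
    bad_level = ~taxa["id_level"].isin(ID_LEVELS)
    if bad_level.any():
        raise CensusSchemaError(
            f"taxa.csv: unknown id_level "
            f"{taxa.loc[bad_level, 'id_level'].unique().tolist()}"
        )
    taxa = taxa.copy()
    taxa["is_monocot"] = taxa["family"].isin(MONOCOT_FAMILIES)

    wd = pd.read_csv(wd_path)
    _require_columns(wd, ["level", "name", "rho_g_cm3"], "wood_density.csv")

    ds = Dataset(trees=trees, obs=obs, plots=plots, taxa=taxa, wood_density=wd)
    ds.validate()
    return ds


def write_census_tables(ds: Dataset, outdir) -> dict[str, Path]:
    """Write the dataset back to the four-table CSV layout; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long = ds.obs.merge(ds.trees, on="tree_id", how="left")
    long = long[
        ["tree_id", "plot_id", "taxon_id", "recruit_census", "census_index",
         "date", "d_cm", "pom_m", "alive"]
    ]
    paths = {
        "trees": outdir / "trees.csv",
        "plots": outdir / "plots.csv",
        "taxa": outdir / "taxa.csv",
        "wood_density": outdir / "wood_density.csv",
    }
    long.to_csv(paths["trees"], index=False)
    ds.plots.to_csv(paths["plots"], index=False)
    ds.taxa.drop(columns=["is_monocot"], errors="ignore").to_csv(
        paths["taxa"], index=False
    )
    ds.wood_density.to_csv(paths["wood_density"], index=False)
    return paths


# ---------------------------------------------------------------------------
# derived views

def first_census_view(ds: Dataset) -> pd.DataFrame:
    """One row per tree at its first *alive* observation (d_cm, date, census)."""
    alive = ds.obs[ds.obs["alive"]]
    first = alive.sort_values(["tree_id", "census_index"]).groupby(
        "tree_id", as_index=False
    ).first()
    return first.merge(ds.trees, on="tree_id", how="left")


def plot_census_dates(ds: Dataset) -> pd.DataFrame:
    """Per-plot census schedule derived from observations.

    Returns (plot_id, census_index, date) with the median observation date per
    plot census — robust to a handful of date-entry slips within a campaign.
    """
    j = ds.obs.merge(ds.trees[["tree_id", "plot_id"]], on="tree_id")
    out = (
        j.groupby(["plot_id", "census_index"], as_index=False)["date"]
        .median()
        .sort_values(["plot_id", "census_index"])
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# filtering

def filter_dataset(
    ds: Dataset,
    max_elev_m: float = 500.0,
    require_old_growth: bool = True,
    require_terra_firme: bool = True,
    exclude_cerrado: bool = True,
    min_identified_fraction: float | None = None,
    min_first_d_cm: float = 10.0,
) -> Dataset:
    """Apply the plot- and stem-level inclusion protocol.

    Retains plots below ``max_elev_m`` that are old-growth terra firme (and
    not cerrado); drops stems whose first alive diameter is below the census
    protocol threshold (10 cm).  ``min_identified_fraction`` optionally keeps
    only plots where at least that fraction of stems is identified to species
    (0.80 reproduces the identification-sensitivity subset).
    """
    keep = ds.plots["elev_m"] < max_elev_m
    if require_old_growth:
        keep &= ds.plots["old_growth"]
    if require_terra_firme:
        keep &= ds.plots["terra_firme"]
    if exclude_cerrado:
        keep &= ~ds.plots["cerrado"]
    plots = ds.plots[keep].reset_index(drop=True)

    trees = ds.trees[ds.trees["plot_id"].isin(plots["plot_id"])]

    if min_identified_fraction is not None:
        id_species = ds.taxa.set_index("taxon_id")["id_level"] == "species"
        ident = trees["taxon_id"].map(id_species)
        frac = ident.groupby(trees["plot_id"]).mean()
        ok_plots = frac[frac >= min_identified_fraction].index
        plots = plots[plots["plot_id"].isin(ok_plots)].reset_index(drop=True)
        trees = trees[trees["plot_id"].isin(ok_plots)]

    first = first_census_view(ds)
    small = set(first.loc[first["d_cm"] < min_first_d_cm, "tree_id"])
    # trees with no alive observation at all carry no information either
    never_alive = set(trees["tree_id"]) - set(first["tree_id"])
    trees = trees[~trees["tree_id"].isin(small | never_alive)].reset_index(drop=True)
    obs = ds.obs[ds.obs["tree_id"].isin(trees["tree_id"])].reset_index(drop=True)

    if len(trees) == 0:
        warnings.warn("filter_dataset produced an empty dataset", stacklevel=2)

    attrs = None
    if ds.attributes is not None:
        attrs = ds.attributes[
            ds.attributes["tree_id"].isin(trees["tree_id"])
        ].reset_index(drop=True)
    return Dataset(trees=trees, obs=obs, plots=plots, taxa=ds.taxa.copy(),
                   wood_density=ds.wood_density.copy(), attributes=attrs)


# ---------------------------------------------------------------------------
# wood density

def assign_wood_density(ds: Dataset) -> Dataset:
    """Attach a wood density (g cm^-3) to every stem.

    Lookup order: species name -> genus -> family -> stem-weighted plot mean
    over the already-resolved stems of that plot; a plot with no resolvable
    stem falls back to the dataset mean (with a warning).  Provenance of the
    matched level is recorded per stem.
    """
    wd = ds.wood_density
    maps = {
        lvl: wd[wd["level"] == lvl].drop_duplicates("name").set_index("name")[
            "rho_g_cm3"
        ]
        for lvl in ("species", "genus", "family")
    }
    taxa = ds.taxa.set_index("taxon_id")
    t = ds.trees.merge(
        taxa[["family", "genus", "species", "id_level"]],
        left_on="taxon_id", right_index=True, how="left",
    )

    rho = pd.Series(np.nan, index=t.index)
    prov = pd.Series("plot_mean", index=t.index, dtype=object)

    lvl = t["id_level"]
    for level, key in (("species", "species"), ("genus", "genus"),
                       ("family", "family")):
        allowed = {
            "species": lvl == "species",
            "genus": lvl.isin(["species", "genus"]),
            "family": lvl.isin(["species", "genus", "family"]),
        }[level]
        cand = t[key].map(maps[level])
        use = rho.isna() & allowed & cand.notna()
        rho[use] = cand[use]
        prov[use] = level

    unresolved = rho.isna()
    if unresolved.any():
        resolved_mean = rho.groupby(t["plot_id"]).mean()  # stem-weighted
        fill = t.loc[unresolved, "plot_id"].map(resolved_mean)
        still = fill.isna()
        if still.any():
            warnings.warn(
                f"{int(still.sum())} stem(s) in plot(s) with no resolvable wood "
                "density; using dataset mean",
                stacklevel=2,
            )
            fill[still] = rho.mean()
            prov[unresolved[unresolved].index[still]] = "dataset_mean"
        rho[unresolved] = fill

    attrs = pd.DataFrame(
        {"tree_id": t["tree_id"], "rho": rho, "rho_provenance": prov}
    )
    out = ds.copy()
    if ds.attributes is not None and "region" in ds.attributes:
        attrs = attrs.merge(
            ds.attributes[["tree_id", "region"]], on="tree_id", how="left"
        )
    out.attributes = attrs.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# regions

def assign_region(
    lat: float,
    lon: float,
    region_label=None,
    bounds=None,
) -> str:
    """Resolve a plot to one of the five region codes.

    An explicit label wins; the label ``W`` (Western Amazonia) is split at
    -8 degrees latitude into SW (strictly south) and NW.  Unlabelled plots
    fall through to the rectangular ``bounds`` table.
    """
    label = None
    if region_label is not None and not pd.isna(region_label):
        key = str(region_label).strip().upper()
        if key not in _REGION_ALIASES:
            raise ValueError(f"unknown region label {region_label!r}")
        label = _REGION_ALIASES[key]
    else:
        for code, (x0, x1, y0, y1) in (bounds or DEFAULT_REGION_BOUNDS):
            if x0 <= lon <= x1 and y0 <= lat <= y1:
                label = code
                break
        if label is None:
            raise ValueError(
                f"coordinates ({lat}, {lon}) outside configured region bounds"
            )
    if label == "W":
        return "SW" if lat < WEST_SPLIT_LATITUDE else "NW"
    return label


def assign_regions(ds: Dataset, bounds=None) -> Dataset:
    """Attach a region code to every plot (``plots['region']``) and stem."""
    out = ds.copy()
    regions = [
        assign_region(r.lat, r.lon, r.region_label, bounds)
        for r in ds.plots.itertuples()
    ]
    out.plots["region"] = regions
    by_plot = out.plots.set_index("plot_id")["region"]
    stem_region = out.trees["plot_id"].map(by_plot)
    if out.attributes is None:
        out.attributes = pd.DataFrame(
            {"tree_id": out.trees["tree_id"], "region": stem_region.values}
        )
    else:
        attrs = out.attributes.drop(columns=["region"], errors="ignore")
        reg = pd.DataFrame(
            {"tree_id": out.trees["tree_id"], "region": stem_region.values}
        )
        out.attributes = attrs.merge(reg, on="tree_id", how="outer")
    return out
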