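"""Dominance statistics: hyperdominant sets, size/wood-density trait curves,
contribution regressions, regional tallies, and the ratio-scaling estimate.

A *hyperdominant* set for a metric (stems, biomass or productivity) is the
minimal set of species, taken in descending order of contribution, whose
summed contributions reach 50% of the dataset total (unidentified stems
included in the denominator).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "HyperdominanceResult",
    "RegressionSummary",
    "hyperdominants",
    "species_max_diameter",
    "species_traits",
    "cumulative_trait_curve",
    "contribution_regression",
    "residual_trait_regression",
    "regional_analysis",
    "scale_estimate",
]

METRICS = ("stems", "biomass", "productivity")


@dataclasses.dataclass
class HyperdominanceResult:
    metric: str
    ordered_taxa: list
    contributions_pct: np.ndarray
    cumulative_pct: np.ndarray
    n_hyperdominant: int
    pct_of_species: float
    threshold: float = 50.0

    @property
    def hyperdominant_taxa(self) -> list:
        return self.ordered_taxa[: self.n_hyperdominant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon_id": self.ordered_taxa,
                "pct": self.contributions_pct,
                "cumulative_pct": self.cumulative_pct,
                "hyperdominant": np.arange(len(self.ordered_taxa))
                < self.n_hyperdominant,
            }
        )


@dataclasses.dataclass
class RegressionSummary:
    """OLS summary on log-transformed quantities (natural log)."""

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: int
    p_value: float
    n: int
    transform: str
    log_base: str = "e"
    residuals: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("slope", "intercept", "r_squared", "f_stat", "df",
                      "p_value", "n", "transform", "log_base")
        }


def _pct_column(table: pd.DataFrame, metric: str) -> pd.Series:
    col = f"pct_{metric}"
    if col not in table.columns:
        raise KeyError(f"aggregate table has no column {col!r}")
    return table[col]


def hyperdominants(
    aggregates, metric: str = "stems", threshold: float = 50.0
) -> HyperdominanceResult:
    """Minimal descending-ordered species set reaching ``threshold`` percent.

    ``aggregates`` is a per-species table (or SpeciesAggregates) with
    ``taxon_id`` and ``pct_<metric>`` columns; rows with missing percentage
    (species without the metric) are excluded from both the ordering and the
    species denominator.  Ties are broken by taxon_id for determinism.
    """
    table = getattr(aggregates, "table", aggregates)
    pct = _pct_column(table, metric)
    sub = table.loc[pct.notna(), ["taxon_id"]].copy()
    sub["pct"] = pct[pct.notna()].values
    if len(sub) == 0:
        raise ValueError("no species with a defined contribution")
    sub = sub.sort_values(["pct", "taxon_id"],
                          ascending=[False, True], kind="mergesort")
    cum = sub["pct"].cumsum().values
    if cum[-1] < threshold:
        raise ValueError(
            f"identified species reach only {cum[-1]:.2f}% of {metric}; "
            f"cannot attain the {threshold}% threshold"
        )
    n = int(np.searchsorted(cum, threshold) + 1)
    # guard for exact floating boundaries
    while n > 1 and cum[n - 2] >= threshold:
        n -= 1
    return HyperdominanceResult(
        metric=metric,
        ordered_taxa=sub["taxon_id"].tolist(),
        contributions_pct=sub["pct"].values,
        cumulative_pct=cum,
        n_hyperdominant=n,
        pct_of_species=100.0 * n / len(sub),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# species traits

def species_max_diameter(
    ds, min_stems: int = 20, percentile: float = 95.0
) -> pd.DataFrame:
    """Species maximum D: the given percentile of per-stem maximum diameters.

    Uses every recorded (raw) alive diameter from any census, keeping only
    the maximum per individual stem; species with fewer than ``min_stems``
    individuals get no value.  Percentile uses linear interpolation between
    order statistics.  Columns: taxon_id, max_d_cm, n_stems_for_trait.
    """
    taxa = ds.taxa.set_index("taxon_id")
    alive = ds.obs[ds.obs["alive"]]
    per_stem = alive.groupby("tree_id")["d_cm"].max().reset_index()
    per_stem = per_stem.merge(ds.trees[["tree_id", "taxon_id"]], on="tree_id")
    per_stem["id_level"] = per_stem["taxon_id"].map(taxa["id_level"])
    per_stem = per_stem[per_stem["id_level"] == "species"]

    def q(x):
        return float(np.percentile(x, percentile, method="linear"))

    g = per_stem.groupby("taxon_id")["d_cm"]
    out = g.agg(n_stems_for_trait="size").reset_index()
    vals = g.apply(q)
    out["max_d_cm"] = out["taxon_id"].map(vals)
    out.loc[out["n_stems_for_trait"] < min_stems, "max_d_cm"] = np.nan
    return out[["taxon_id", "max_d_cm", "n_stems_for_trait"]]


def species_traits(ds, min_stems: int = 20, percentile: float = 95.0) -> pd.DataFrame:
    """Trait table: maximum D plus *species-level* wood density.

    The wood-density trait requires a species-specific entry in the lookup
    table (taxonomic fallback values are not species traits).
    """
    out = species_max_diameter(ds, min_stems=min_stems, percentile=percentile)
    wd = ds.wood_density
    sp_rho = wd[wd["level"] == "species"].drop_duplicates("name").set_index(
        "name"
    )["rho_g_cm3"]
    taxa = ds.taxa.set_index("taxon_id")
    all_sp = taxa[taxa["id_level"] == "species"]
    out = out.merge(
        all_sp[["species"]].reset_index(), on="taxon_id", how="outer"
    )
    out["rho"] = out["species"].map(sp_rho)
    out["n_stems_for_trait"] = out["n_stems_for_trait"].fillna(0).astype(int)
    return out[["taxon_id", "max_d_cm", "rho", "n_stems_for_trait"]]


def cumulative_trait_curve(
    aggregates, traits: pd.DataFrame, trait: str = "max_d_cm"
) -> dict:
    """Cumulative contribution curves ordered from highest to lowest trait.

    Restricted to species carrying the trait; the % axes are normalized
    within that subset, so the top-50%-of-species shares are directly
    comparable across metrics.  Returns ``{"curve": DataFrame,
    "top50_share": {metric: pct}, "trait_at_50": {metric: value}}``.
    """
    table = getattr(aggregates, "table", aggregates)
    if trait not in traits.columns:
        raise KeyError(f"trait table has no column {trait!r}")
    j = table.merge(traits[["taxon_id", trait]], on="taxon_id", how="left")
    j = j[j[trait].notna()]
    if len(j) == 0:
        raise ValueError(f"no species carry trait {trait!r}")
    j = j.sort_values([trait, "taxon_id"], ascending=[False, True],
                      kind="mergesort").reset_index(drop=True)

    curve = pd.DataFrame({"trait_value": j[trait]})
    curve["cum_pct_species"] = 100.0 * (np.arange(len(j)) + 1) / len(j)
    metric_cols = {"stems": "n_stems", "biomass": "biomass_Mg",
                   "productivity": "productivity_Mg_yr"}
    for metric, col in metric_cols.items():
        v = j[col].fillna(0.0).values.astype(float)
        tot = v.sum()
        curve[f"cum_pct_{metric}"] = (
            100.0 * np.cumsum(v) / tot if tot > 0 else np.nan
        )

    top50, at50 = {}, {}
    xs = curve["cum_pct_species"].values
    for metric in ("species", *metric_cols):
        ys = curve[f"cum_pct_{metric}"].values
        if np.all(np.isnan(ys)):
            continue
        top50[metric] = float(np.interp(50.0, xs, ys))
        tv = j[trait].values
        # first crossing of 50% of the metric, trait value linearly interpolated
        idx = np.searchsorted(ys, 50.0)
        if idx == 0:
            at50[metric] = float(tv[0])
        elif idx >= len(ys):
            at50[metric] = float(tv[-1])
        else:
            y0, y1 = ys[idx - 1], ys[idx]
            w = (50.0 - y0) / (y1 - y0) if y1 > y0 else 1.0
            at50[metric] = float(tv[idx - 1] + w * (tv[idx] - tv[idx - 1]))
    return {"curve": curve, "top50_share": top50, "trait_at_50": at50}


# ---------------------------------------------------------------------------
# regressions

def _ols(y: np.ndarray, x: np.ndarray, transform: str,
         index=None) -> RegressionSummary:
    if len(y) < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.allclose(np.var(y), 0.0):
        # degenerate: constant response carries no slope information
        return RegressionSummary(
            slope=0.0, intercept=float(np.mean(y)), r_squared=0.0,
            f_stat=0.0, df=len(y) - 2, p_value=1.0, n=len(y),
            transform=transform,
            residuals=pd.Series(np.zeros(len(y)), index=index),
        )
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    resid = pd.Series(fit.resid, index=index)
    return RegressionSummary(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        df=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        n=int(fit.nobs),
        transform=transform,
        residuals=resid,
    )


def contribution_regression(
    aggregates, y_metric: str, x_metric: str = "stems"
) -> RegressionSummary:
    """OLS of ln(% contribution to *y_metric*) on ln(% contribution to
    *x_metric*), over species with strictly positive contributions to both
    (species with zero or negative productivity are thereby excluded)."""
    table = getattr(aggregates, "table", aggregates)
    y = _pct_column(table, y_metric)
    x = _pct_column(table, x_metric)
    ok = y.notna() & x.notna() & (y > 0) & (x > 0)
    sub = table[ok]
    return _ols(
        np.log(y[ok].values), np.log(x[ok].values),
        transform=f"ln(pct_{y_metric}) ~ ln(pct_{x_metric})",
        index=pd.Index(sub["taxon_id"], name="taxon_id"),
    )


def residual_trait_regression(
    aggregates, traits: pd.DataFrame, y_metric: str, trait: str = "max_d_cm",
    base: RegressionSummary | None = None,
) -> RegressionSummary:
    """Regress the abundance-regression residuals on ln(trait value).

    Measures whether the trait predicts a species' contribution to
    ``y_metric`` after its stem abundance has been accounted for.
    """
    if base is None:
        base = contribution_regression(aggregates, y_metric)
    if base.residuals is None:
        raise ValueError("base regression carries no residuals")
    tr = traits.set_index("taxon_id")[trait]
    tvals = base.residuals.index.map(tr)
    ok = pd.notna(tvals) & (np.asarray(tvals, dtype=float) > 0)
    if not ok.any():
        raise ValueError(f"trait {trait!r} missing for every regression species")
    y = base.residuals.values[np.asarray(ok)]
    x = np.log(np.asarray(tvals, dtype=float)[np.asarray(ok)])
    return _ols(
        y, x,
        transform=f"resid[{base.transform}] ~ ln({trait})",
        index=base.residuals.index[np.asarray(ok)],
    )


# ---------------------------------------------------------------------------
# regional analysis & scaling

def regional_analysis(
    ds, config, metrics=METRICS, threshold: float = 50.0,
    min_span_yr: float = 2.0,
) -> dict:
    """Run the species aggregation and hyperdominance per region.

    Returns ``{"regions": {code: {"aggregates": SpeciesAggregates,
    "hyperdominance": {metric: HyperdominanceResult}}},
    "cross_region": {metric: DataFrame(taxon_id, n_regions_dominant)}}``.
    The cross-region tally counts, for each whole-dataset hyperdominant, the
    regions (0-5) where it is also regionally dominant.
    """
    from .productivity import productivity_subset, species_table

    if ds.attributes is None or "region" not in ds.attributes:
        raise ValueError("regions not assigned; run assign_regions first")
    regions = ds.plots["region"].dropna().unique()

    global_agg = species_table(ds, config, include_productivity="productivity"
                               in metrics, min_span_yr=min_span_yr)
    global_hd = {m: hyperdominants(global_agg, m, threshold) for m in metrics}

    per_region = {}
    for code in sorted(regions):
        sub = ds.copy()
        sub.plots = sub.plots[sub.plots["region"] == code].reset_index(drop=True)
        sub.trees = sub.trees[
            sub.trees["plot_id"].isin(sub.plots["plot_id"])
        ].reset_index(drop=True)
        sub.obs = sub.obs[sub.obs["tree_id"].isin(sub.trees["tree_id"])].reset_index(
            drop=True
        )
        if sub.attributes is not None:
            sub.attributes = sub.attributes[
                sub.attributes["tree_id"].isin(sub.trees["tree_id"])
            ].reset_index(drop=True)
        if len(sub.plots) == 0:
            warnings.warn(f"region {code}: no plots; skipped", stacklevel=2)
            continue
        want_p = "productivity" in metrics and len(
            productivity_subset(sub, min_span_yr).plots
        ) > 0
        agg = species_table(sub, config, include_productivity=want_p,
                            min_span_yr=min_span_yr)
        hds = {}
        for m in metrics:
            if m == "productivity" and not want_p:
                continue
            try:
                hds[m] = hyperdominants(agg, m, threshold)
            except ValueError as e:
                warnings.warn(f"region {code}, metric {m}: {e}", stacklevel=2)
        per_region[code] = {"aggregates": agg, "hyperdominance": hds}

    cross = {}
    for m in metrics:
        counts = []
        for taxon in global_hd[m].hyperdominant_taxa:
            k = sum(
                1
                for r in per_region.values()
                if m in r["hyperdominance"]
                and taxon in set(r["hyperdominance"][m].hyperdominant_taxa)
            )
            counts.append((taxon, k))
        cross[m] = pd.DataFrame(counts, columns=["taxon_id", "n_regions_dominant"])
    return {"regions": per_region, "global": global_hd, "cross_region": cross}


def scale_estimate(n_reference_stem_hd: int, n_stem_hd: int,
                   n_metric_hd: int) -> int:
    """Scale a hyperdominant count to a reference flora by the stem ratio.

    ``round(n_reference_stem_hd * n_metric_hd / n_stem_hd)`` — e.g. carrying
    a dataset's biomass/stem hyperdominant ratio over to an independent,
    Amazon-wide stem-hyperdominant count.
    """
    if n_stem_hd <= 0:
        raise ValueError("stem hyperdominant count must be positive")
    if n_reference_stem_hd <= 0 or n_metric_hd <= 0:
        raise ValueError("counts must be positive")
    return int(round(n_reference_stem_hd * n_metric_hd / n_stem_hd))
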