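"""End-to-end pipeline orchestration and report rendering.

``run_pipeline`` executes load (or simulate) -> filter -> regions -> wood
density -> species aggregation (full and productivity datasets) ->
hyperdominance -> traits -> regressions -> regional tallies, writing CSV/JSON
reports plus a run manifest (config snapshot, input hashes, package version,
seed, timestamps) so a results directory is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import load_allometry_config
from .census import (
    Dataset,
    assign_regions,
    assign_wood_density,
    filter_dataset,
    read_census_tables,
    write_census_tables,
)
from .dominance import (
    contribution_regression,
    cumulative_trait_curve,
    hyperdominants,
    regional_analysis,
    residual_trait_regression,
    species_traits,
)
from .productivity import productivity_subset, species_table
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("hyperdom")

__all__ = [
    "prepare_dataset",
    "analyze_dataset",
    "run_pipeline",
    "render_tables",
    "load_species_package",
    "hyperdominance_from_species_package",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name):
    logger.info("stage: %s", name)


def prepare_dataset(config: dict) -> tuple[Dataset, dict]:
    """Load or simulate, then filter and assign regions + wood density."""
    hashes = {}
    if "simulate" in config:
        _stage("simulate")
        sim_kwargs = dict(config["simulate"])
        sim_kwargs.setdefault("seed", config.get("seed", 0))
        ds, _truth = simulate_dataset(SimulationConfig(**sim_kwargs))
    else:
        _stage("load")
        inp = config["inputs"]
        ds = read_census_tables(inp["trees"], inp["plots"], inp["taxa"],
                                inp["wood_density"])
        hashes = {k: _sha256(v) for k, v in inp.items()}
    logger.info("loaded %d trees in %d plots", ds.n_trees, len(ds.plots))

    _stage("filter")
    f = config.get("filters", {})
    ds = filter_dataset(
        ds,
        max_elev_m=f.get("max_elev_m", 500.0),
        min_identified_fraction=f.get("min_identified_fraction"),
    )
    logger.info("after filtering: %d trees in %d plots", ds.n_trees,
                len(ds.plots))
    _stage("regions")
    ds = assign_regions(ds)
    _stage("wood density")
    ds = assign_wood_density(ds)
    return ds, hashes


def analyze_dataset(
    ds: Dataset,
    allometry=None,
    metrics=("stems", "biomass", "productivity"),
    regional: bool = True,
    traits: bool = True,
    threshold: float = 50.0,
) -> dict:
    """All dominance statistics for a prepared dataset.

    Stem and biomass contributions are computed twice — on the full dataset
    and on the multi-census productivity dataset — because cross-metric
    comparisons must use consistent denominators.
    """
    allom = allometry if allometry is not None else load_allometry_config()
    want_p = "productivity" in metrics

    _stage("aggregate (full data set)")
    agg_full = species_table(ds, allom, include_productivity=False)
    prod_ds = productivity_subset(ds) if want_p else None
    agg_prod = None
    if want_p:
        if len(prod_ds.plots) == 0:
            raise ValueError("no multi-census plots for productivity")
        _stage("aggregate (productivity data set)")
        agg_prod = species_table(prod_ds, allom, include_productivity=True)

    _stage("hyperdominance")
    hd = {}
    for m in metrics:
        if m == "productivity":
            hd[m] = hyperdominants(agg_prod, m, threshold)
        else:
            hd[m] = hyperdominants(agg_full, m, threshold)
    hd_prod = {}
    if want_p:
        for m in ("stems", "biomass"):
            if m in metrics:
                hd_prod[m] = hyperdominants(agg_prod, m, threshold)

    results = {
        "dataset": ds,
        "allometry": allom,
        "aggregates_full": agg_full,
        "aggregates_productivity": agg_prod,
        "hyperdominance": hd,
        "hyperdominance_productivity_set": hd_prod,
    }

    if traits:
        _stage("traits")
        tr = species_traits(ds)
        results["traits"] = tr
        # trait curves on the productivity data set where available
        curve_agg = agg_prod if agg_prod is not None else agg_full
        results["trait_curves"] = {
            t: cumulative_trait_curve(curve_agg, tr, t)
            for t in ("max_d_cm", "rho")
        }
        _stage("regressions")
        regs = {}
        regs["biomass_vs_stems"] = contribution_regression(agg_full, "biomass")
        if agg_prod is not None:
            regs["productivity_vs_stems"] = contribution_regression(
                agg_prod, "productivity"
            )
        for y, agg in (("biomass", agg_full),
                       ("productivity", agg_prod)):
            if agg is None:
                continue
            base = regs[f"{y}_vs_stems"]
            for t in ("max_d_cm", "rho"):
                try:
                    regs[f"{y}_residuals_vs_{t}"] = residual_trait_regression(
                        agg, tr, y, t, base=base
                    )
                except ValueError as e:
                    logger.warning("residual regression %s ~ %s: %s", y, t, e)
        results["regressions"] = regs

    if regional:
        _stage("regional analysis")
        results["regional"] = regional_analysis(ds, allom, metrics=metrics,
                                                threshold=threshold)
    return results


# ---------------------------------------------------------------------------
# report rendering

def render_tables(results: dict, top_k: int = 20) -> dict[str, pd.DataFrame]:
    """Paper-style tables: top-k per metric with cross-metric ranks,
    per-region hyperdominant counts, and trait-share summaries.

    Percentages print to 1 decimal and biomass to whole Mg; a species absent
    from the productivity set shows a blank cross-rank, not 0.
    """
    out = {}
    agg_full = results["aggregates_full"].table
    agg_prod = (
        results["aggregates_productivity"].table
        if results.get("aggregates_productivity") is not None
        else None
    )

    def ranks(table, metric):
        col = f"pct_{metric}"
        s = table.dropna(subset=[col]).sort_values(
            [col, "taxon_id"], ascending=[False, True]
        )
        return {t: i + 1 for i, t in enumerate(s["taxon_id"])}

    rank_stems = ranks(agg_full, "stems")
    rank_prod = ranks(agg_prod, "productivity") if agg_prod is not None else {}

    for metric, res in results["hyperdominance"].items():
        table = agg_prod if metric == "productivity" else agg_full
        value_col = {"stems": "n_stems", "biomass": "biomass_Mg",
                     "productivity": "productivity_Mg_yr"}[metric]
        k = min(top_k, len(res.ordered_taxa))
        top = pd.DataFrame({"taxon_id": res.ordered_taxa[:k]})
        info = table.set_index("taxon_id")
        top["family"] = top["taxon_id"].map(info["family"])
        top["species"] = top["taxon_id"].map(info["species"])
        v = top["taxon_id"].map(info[value_col])
        top["value"] = v.round(0) if metric == "biomass" else v
        top["pct"] = np.round(res.contributions_pct[:k], 2)
        top["cumulative_pct"] = np.round(res.cumulative_pct[:k], 2)
        top["rank_by_stems"] = top["taxon_id"].map(rank_stems)
        top["rank_by_productivity"] = top["taxon_id"].map(
            lambda t: rank_prod.get(t, pd.NA)
        )
        out[f"top_{metric}"] = top

    if "regional" in results:
        rows = []
        for code, r in results["regional"]["regions"].items():
            meta = r["aggregates"].meta
            row = {"region": code, "n_species": meta["n_species"]}
            for m, res in r["hyperdominance"].items():
                row[f"n_hyperdominant_{m}"] = res.n_hyperdominant
                row[f"pct_of_species_{m}"] = round(res.pct_of_species, 1)
            rows.append(row)
        out["regional"] = pd.DataFrame(rows)

    if "trait_curves" in results:
        rows = []
        for trait, tc in results["trait_curves"].items():
            for metric, share in tc["top50_share"].items():
                rows.append(
                    {
                        "trait": trait,
                        "metric": metric,
                        "pct_contribution_top50_species": round(share, 1),
                        "trait_value_at_50pct": round(
                            tc["trait_at_50"].get(metric, np.nan), 2
                        ),
                    }
                )
        out["trait_shares"] = pd.DataFrame(rows)
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the full analysis described by ``config``; returns out_dir.

    Deterministic given (inputs, config, seed): two runs with equal manifests
    produce identical report files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    t_start = time.time()
    try:
        ds, hashes = prepare_dataset(config)
        allom = load_allometry_config(config.get("allometry"))
        metrics = tuple(config.get("metrics",
                                   ("stems", "biomass", "productivity")))
        results = analyze_dataset(
            ds, allom, metrics=metrics,
            regional=config.get("regional", True),
            traits=config.get("traits", True),
        )
        _stage("write reports")
        _write_reports(results, out, config, hashes, t_start)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
    return out


def _write_reports(results, out: Path, config, hashes, t_start) -> None:
    agg_full = results["aggregates_full"]
    agg_full.table.to_csv(out / "species_aggregates.csv", index=False)
    if results.get("aggregates_productivity") is not None:
        results["aggregates_productivity"].table.to_csv(
            out / "species_aggregates_productivity.csv", index=False
        )

    hd_json = {}
    for scope, hds in (("full", results["hyperdominance"]),
                       ("productivity_set",
                        results.get("hyperdominance_productivity_set", {}))):
        hd_json[scope] = {
            m: {
                "n_hyperdominant": r.n_hyperdominant,
                "pct_of_species": round(r.pct_of_species, 2),
                "n_species": len(r.ordered_taxa),
                "threshold": r.threshold,
            }
            for m, r in hds.items()
        }
    (out / "hyperdominance_report.json").write_text(
        json.dumps(hd_json, indent=2, default=_jsonable)
    )

    tables = render_tables(results)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)

    if "trait_curves" in results:
        for trait, tc in results["trait_curves"].items():
            tc["curve"].to_csv(out / f"trait_curve_{trait}.csv", index=False)

    if "regressions" in results:
        (out / "regressions.json").write_text(
            json.dumps(
                {k: v.to_dict() for k, v in results["regressions"].items()},
                indent=2, default=_jsonable,
            )
        )

    if "regional" in results:
        for m, df in results["regional"]["cross_region"].items():
            df.to_csv(out / f"cross_region_{m}.csv", index=False)

    manifest = {
        "package": "hyperdom",
        "version": __version__,
        "seed": config.get("seed"),
        "config": _scrub(config),
        "input_hashes": hashes,
        "allometry": results["allometry"].to_dict(),
        "started_unix": round(t_start, 3),
        "elapsed_s": round(time.time() - t_start, 3),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_jsonable)
    )


def _scrub(config):
    def conv(v):
        if dataclasses.is_dataclass(v):
            return dataclasses.asdict(v)
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        return v
    return conv(config)


def load_run_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


# ---------------------------------------------------------------------------
# archived species-level package validation path

def load_species_package(path) -> pd.DataFrame:
    """Load a species-level aggregate table (the pipeline's own
    species_aggregates.csv layout, also used by archived data packages).

    Percentage columns are used as-is when present; otherwise they are
    derived from the value columns (a denominator that then excludes
    unidentified stems, which is noted in the returned frame's attrs).
    """
    df = pd.read_csv(path)
    if "taxon_id" not in df.columns:
        if {"genus", "species"} <= set(df.columns):
            df["taxon_id"] = (
                df["genus"].astype(str) + "_" + df["species"].astype(str)
            )
        else:
            raise ValueError("species package needs taxon_id or genus+species")
    pairs = {"stems": "n_stems", "biomass": "biomass_Mg",
             "productivity": "productivity_Mg_yr"}
    for metric, col in pairs.items():
        pct = f"pct_{metric}"
        if pct not in df.columns:
            if col not in df.columns:
                continue
            df[pct] = 100.0 * df[col] / df[col].sum()
            df.attrs[f"{pct}_derived"] = True
    return df


def hyperdominance_from_species_package(path, metrics=("stems", "biomass",
                                                       "productivity"),
                                        threshold: float = 50.0) -> dict:
    """Hyperdominance statistics straight from a species-level package."""
    df = load_species_package(path)
    out = {}
    for m in metrics:
        col = f"pct_{m}"
        if col not in df.columns or df[col].notna().sum() == 0:
            continue
        out[m] = hyperdominants(df, m, threshold)
    return out
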