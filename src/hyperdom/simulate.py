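"""Synthetic multi-census forest datasets with exact ground truth.

The generator emulates the statistical structure a plot-network census
analysis assumes: a log-series species-abundance distribution (Fisher's
alpha parameterization), diameter distributions truncated at the 10-cm
census threshold with species-specific maximum sizes, species-level wood
density and growth rates, multi-census growth / mortality / recruitment,
occasional point-of-measurement (POM) changes that shift the recorded
diameter, a monocot (palm) subset, and a configurable fraction of stems
stripped of their species identity.

Ground truth (:class:`SyntheticTruth`) is recorded from the noise-free
bookkeeping — true diameters, true taxon of every stem — before POM
artifacts and identity stripping are applied, so recovery tests can compare
pipeline output against exact per-species contributions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .allometry import AllometryConfig, agb_palm, default_allometry_config, \
    stem_biomass_kg
from .census import Dataset, MONOCOT_FAMILIES, REGIONS

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_community",
    "simulate_censuses",
    "simulate_dataset",
    "steady_state_palm_population",
]

_FAMILY_POOL = [
    "Fabaceae", "Lecythidaceae", "Sapotaceae", "Moraceae", "Burseraceae",
    "Chrysobalanaceae", "Lauraceae", "Annonaceae", "Euphorbiaceae",
    "Myristicaceae", "Meliaceae", "Vochysiaceae", "Apocynaceae",
    "Malvaceae", "Urticaceae",
]


@dataclasses.dataclass
class SimulationConfig:
    """Desk-scale defaults: ~25 plots, ~5,000 stems, ~300 species,
    3 censuses at 5-year intervals (a few-percent-scale replica of a large
    plot-network campaign)."""

    seed: int = 0
    fisher_alpha: float = 70.0
    n_species: int | None = None          # derived from alpha if None
    n_plots: int = 25
    plot_area_ha: float = 1.0
    stems_per_ha: float = 200.0
    region_mix: dict = dataclasses.field(
        default_factory=lambda: {
            "NW": 0.25, "SW": 0.30, "GS": 0.20, "EC": 0.15, "BS": 0.10}
    )
    monocot_fraction: float = 0.03        # fraction of species that are palms
    unidentified_fraction: float = 0.21   # fraction of stems stripped of species
    n_censuses: int = 3
    census_interval_yr: float = 5.0
    # traits
    rho_mean: float = 0.63
    rho_sd: float = 0.15
    rho_bounds: tuple = (0.2, 1.1)
    d95_ln_mean: float = np.log(40.0)     # species maximum-size parameter (cm)
    d95_ln_sd: float = 0.4
    wd_missing_species_fraction: float = 0.10
    # dynamics
    growth_ln_mean: float = np.log(0.20)  # species mean increment, cm yr^-1
    growth_ln_sd: float = 0.5
    growth_noise_sd: float = 0.08         # stem-level noise, cm yr^-0.5
    annual_mortality: float = 0.02
    recruitment_per_mortality: float = 1.0
    pom_change_prob: float = 0.02         # per stem per later census
    pom_change_ratio: float = 0.90        # recorded D shrinks at the new POM
    allometry: AllometryConfig | None = None

    def __post_init__(self):
        for name in ("monocot_fraction", "unidentified_fraction",
                     "annual_mortality", "pom_change_prob",
                     "wd_missing_species_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_censuses < 1:
            raise ValueError("n_censuses must be >= 1")
        if self.fisher_alpha <= 0:
            raise ValueError("fisher_alpha must be positive")
        if abs(sum(self.region_mix.values()) - 1.0) > 1e-9:
            raise ValueError("region_mix must sum to 1")
        if not set(self.region_mix) <= set(REGIONS):
            raise ValueError(f"region_mix keys must be among {REGIONS}")

    @property
    def target_stems(self) -> float:
        return self.n_plots * self.plot_area_ha * self.stems_per_ha

    def get_allometry(self) -> AllometryConfig:
        return self.allometry or default_allometry_config()


@dataclasses.dataclass
class SyntheticTruth:
    """Generator-side ground truth.

    ``species``: per-species true n_stems (first census), biomass (Mg),
    productivity (Mg yr^-1, growth accounting on true diameters) and the
    corresponding percentage contributions of dataset totals.
    ``stem_diameters``: true per-stem diameter series (tree_id,
    census_index, d_true_cm).
    """

    species: pd.DataFrame
    stem_diameters: pd.DataFrame
    totals: dict


def simulate_community(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Draw the species pool: log-series abundance weights plus traits.

    The number of species defaults to Fisher's expectation
    ``S = alpha * ln(1 + N / alpha)`` for the target stem count ``N``; each
    species' abundance weight is an independent log-series draw with
    ``x = N / (N + alpha)``, so the realized pool recovers the target alpha.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N = config.target_stems
    alpha = config.fisher_alpha
    x = N / (N + alpha)
    S = config.n_species or max(1, int(round(alpha * np.log(1 + N / alpha))))

    from scipy import stats

    weights = stats.logser.rvs(x, size=S, random_state=rng).astype(float)

    rho = np.clip(
        rng.normal(config.rho_mean, config.rho_sd, size=S), *config.rho_bounds
    )
    d95 = np.clip(
        np.exp(rng.normal(config.d95_ln_mean, config.d95_ln_sd, size=S)),
        15.0, 180.0,
    )
    growth = np.exp(rng.normal(config.growth_ln_mean, config.growth_ln_sd,
                               size=S))

    # monocots: drawn half from the most abundant decile (the large arborescent
    # palms are among the commonest Amazonian trees), half uniformly
    n_mono = int(round(config.monocot_fraction * S))
    mono = np.zeros(S, dtype=bool)
    if n_mono and S > 1:
        order = np.argsort(weights)[::-1]
        top = order[: max(1, S // 10)]
        k_top = min(len(top), (n_mono + 1) // 2)
        chosen = list(rng.choice(top, size=k_top, replace=False))
        rest = [i for i in range(S) if i not in set(chosen)]
        chosen += list(rng.choice(rest, size=n_mono - k_top, replace=False))
        mono[chosen] = True

    n_genera = max(1, S // 3)
    genus_of = rng.integers(0, n_genera, size=S)
    family_of_genus = rng.integers(0, len(_FAMILY_POOL), size=n_genera)

    sp = pd.DataFrame(
        {
            "taxon_id": [f"sp{i:04d}" for i in range(S)],
            "species": [f"Species specimen{i:04d}" for i in range(S)],
            "genus": [f"Genus{genus_of[i]:03d}" for i in range(S)],
            "family": [
                "Arecaceae" if mono[i] else _FAMILY_POOL[family_of_genus[genus_of[i]]]
                for i in range(S)
            ],
            "is_monocot": mono,
            "abundance_weight": weights,
            "rho_true": rho,
            "d95_cm": d95,
            "growth_cm_yr": growth,
        }
    )
    # palms live in palm genera
    sp.loc[mono, "genus"] = [
        f"Palmus{g:03d}" for g in genus_of[mono]
    ]
    return sp


def _diameter_scales(d95: np.ndarray) -> np.ndarray:
    """Exponential scales so each species' 95th percentile targets its d95."""
    return np.maximum(d95 - 10.0, 1.0) / 3.0


def simulate_censuses(
    community: pd.DataFrame, config: SimulationConfig, rng=None
) -> tuple[Dataset, SyntheticTruth]:
    """Simulate the plot network through its censuses.

    Census 1 draws stems per plot (Poisson plot totals, multinomial species);
    later censuses apply growth (species increment + stem noise), Bernoulli
    mortality, recruitment entering just above 10 cm, and POM changes that
    shift the recorded diameter by a fixed ratio.  Identity stripping
    replaces the taxon of a random stem fraction by genus-, family- or
    fully-unidentified morphotaxa.  Truth is recorded before stripping and
    before POM artifacts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    allom = config.get_allometry()
    S = len(community)
    probs = community["abundance_weight"].values / community[
        "abundance_weight"
    ].values.sum()

    region_codes = list(config.region_mix)
    region_p = np.array([config.region_mix[r] for r in region_codes])
    plot_regions = rng.choice(region_codes, size=config.n_plots, p=region_p)
    plot_ids = [f"P{i:03d}" for i in range(config.n_plots)]
    base_dates = 2000.0 + rng.uniform(0, 0.5, size=config.n_plots)

    sp_idx_of = {t: i for i, t in enumerate(community["taxon_id"])}
    growth = community["growth_cm_yr"].values
    d95 = community["d95_cm"].values

    # state arrays per stem
    tree_plot, tree_sp, tree_recruit = [], [], []
    rows = []  # obs rows: tree, census, date, d_true, pom, alive, pom_ratio
    next_tree = 0

    scales = _diameter_scales(d95)
    for p in range(config.n_plots):
        n0 = rng.poisson(config.plot_area_ha * config.stems_per_ha)
        cur_sp = rng.choice(S, size=n0, p=probs)
        cur_d = 10.0 + rng.exponential(scales[cur_sp])
        cur_ids = np.arange(next_tree, next_tree + n0)
        next_tree += n0
        tree_plot += [p] * n0
        tree_sp += list(cur_sp)
        tree_recruit += [pd.NA] * n0

        alive = np.ones(n0, dtype=bool)
        died_at = np.zeros(n0, dtype=int)  # census index of the dead record
        pom_ratio = np.ones(n0)
        pom = np.full(n0, 1.3)
        for c in range(1, config.n_censuses + 1):
            date = base_dates[p] + (c - 1) * config.census_interval_yr
            for i in np.flatnonzero(alive):
                rows.append((cur_ids[i], c, date, cur_d[i], pom[i], True,
                             pom_ratio[i]))
            for i in np.flatnonzero(died_at == c):
                rows.append((cur_ids[i], c, date, np.nan, pom[i], False,
                             pom_ratio[i]))
            if c == config.n_censuses:
                break
            dt = config.census_interval_yr
            surv_p = (1.0 - config.annual_mortality) ** dt
            dies = alive & (rng.random(len(cur_ids)) > surv_p)
            died_at[dies] = c + 1
            # growth for survivors
            inc = growth[cur_sp] * dt + rng.normal(
                0, config.growth_noise_sd * np.sqrt(dt), size=len(cur_ids)
            )
            survives = alive & ~dies
            cur_d = np.where(survives, np.maximum(cur_d + inc, 1.0), cur_d)
            alive = survives
            # POM changes on survivors
            pchg = alive & (rng.random(len(cur_ids)) < config.pom_change_prob)
            pom = np.where(pchg, pom + 0.5, pom)
            pom_ratio = np.where(pchg, pom_ratio * config.pom_change_ratio,
                                 pom_ratio)
            # recruitment replaces expected deaths
            exp_deaths = dies.sum() * config.recruitment_per_mortality
            n_rec = rng.poisson(exp_deaths) if exp_deaths > 0 else 0
            if n_rec:
                rsp = rng.choice(S, size=n_rec, p=probs)
                rd = 10.0 + rng.exponential(0.5, size=n_rec)
                rid = np.arange(next_tree, next_tree + n_rec)
                next_tree += n_rec
                tree_plot += [p] * n_rec
                tree_sp += list(rsp)
                tree_recruit += [c + 1] * n_rec
                cur_ids = np.concatenate([cur_ids, rid])
                cur_sp = np.concatenate([cur_sp, rsp])
                cur_d = np.concatenate([cur_d, rd])
                alive = np.concatenate([alive, np.ones(n_rec, dtype=bool)])
                died_at = np.concatenate([died_at, np.zeros(n_rec, dtype=int)])
                pom = np.concatenate([pom, np.full(n_rec, 1.3)])
                pom_ratio = np.concatenate([pom_ratio, np.ones(n_rec)])

    obs = pd.DataFrame(
        rows,
        columns=["tree_i", "census_index", "date", "d_true_cm", "pom_m",
                 "alive", "pom_ratio"],
    )
    obs["tree_id"] = obs["tree_i"].map(lambda i: f"T{i:06d}")
    obs["d_cm"] = obs["d_true_cm"] * obs["pom_ratio"]

    trees = pd.DataFrame(
        {
            "tree_id": [f"T{i:06d}" for i in range(next_tree)],
            "plot_id": [plot_ids[p] for p in tree_plot],
            "taxon_true": [community["taxon_id"].iloc[s] for s in tree_sp],
            "recruit_census": pd.array(tree_recruit, dtype="Int64"),
        }
    )

    plots = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "area_ha": config.plot_area_ha,
            "lat": rng.uniform(-12, 2, size=config.n_plots).round(3),
            "lon": rng.uniform(-75, -50, size=config.n_plots).round(3),
            "elev_m": rng.uniform(50, 400, size=config.n_plots).round(0),
            "old_growth": True,
            "terra_firme": True,
            "cerrado": False,
            "region_label": plot_regions,
        }
    )

    taxa, wood_density, stripped_taxon = _taxonomy_tables(
        community, trees, config, rng
    )
    trees["taxon_id"] = stripped_taxon

    truth = _compute_truth(community, trees, obs, plots, config, allom)

    obs_out = obs[["tree_id", "census_index", "date", "d_cm", "pom_m",
                   "alive"]].sort_values(["tree_id", "census_index"]).reset_index(
        drop=True
    )
    ds = Dataset(
        trees=trees[["tree_id", "plot_id", "taxon_id", "recruit_census"]],
        obs=obs_out,
        plots=plots,
        taxa=taxa,
        wood_density=wood_density,
    )
    ds.validate()
    return ds, truth


def _taxonomy_tables(community, trees, config, rng):
    """Build taxa.csv / wood_density.csv content and strip stem identities."""
    sp_taxa = community[["taxon_id", "family", "genus", "species"]].copy()
    sp_taxa["id_level"] = "species"

    genera = community.groupby("genus").agg(
        family=("family", "first"), rho=("rho_true", "mean")
    )
    families = community.groupby("family")["rho_true"].mean()

    indet_rows = []
    for g, r in genera.iterrows():
        indet_rows.append((f"indet_g_{g}", r["family"], g, "", "genus"))
    for f in families.index:
        indet_rows.append((f"indet_f_{f}", f, "", "", "family"))
    indet_rows.append(("indet_none", "", "", "", "none"))
    indet = pd.DataFrame(
        indet_rows, columns=["taxon_id", "family", "genus", "species",
                             "id_level"]
    )
    taxa = pd.concat([sp_taxa, indet], ignore_index=True)
    taxa["is_monocot"] = taxa["family"].isin(MONOCOT_FAMILIES)

    # wood-density table: species entries for most species, genus/family means
    S = len(community)
    missing = rng.random(S) < config.wd_missing_species_fraction
    wd_rows = [
        ("species", community["species"].iloc[i],
         float(community["rho_true"].iloc[i]))
        for i in range(S) if not missing[i]
    ]
    wd_rows += [("genus", g, float(r["rho"])) for g, r in genera.iterrows()]
    wd_rows += [("family", f, float(v)) for f, v in families.items()]
    wood_density = pd.DataFrame(wd_rows, columns=["level", "name", "rho_g_cm3"])

    # strip identities
    sp_info = community.set_index("taxon_id")
    strip = rng.random(len(trees)) < config.unidentified_fraction
    u = rng.random(len(trees))
    out = trees["taxon_true"].copy()
    for i in np.flatnonzero(strip):
        true = trees["taxon_true"].iloc[i]
        if u[i] < 0.5:
            out.iloc[i] = f"indet_g_{sp_info.loc[true, 'genus']}"
        elif u[i] < 0.75:
            out.iloc[i] = f"indet_f_{sp_info.loc[true, 'family']}"
        else:
            out.iloc[i] = "indet_none"
    return taxa, wood_density, out


def _compute_truth(community, trees, obs, plots, config, allom):
    """Exact per-species accounting on true diameters and true identities."""
    sp = community.set_index("taxon_id")
    tr = trees.set_index("tree_id")
    plot_region = plots.set_index("plot_id")["region_label"]

    alive = obs[obs["alive"]].copy()
    alive["taxon_true"] = alive["tree_id"].map(tr["taxon_true"])
    alive["plot_id"] = alive["tree_id"].map(tr["plot_id"])
    alive["region"] = alive["plot_id"].map(plot_region)
    alive["rho"] = alive["taxon_true"].map(sp["rho_true"])
    alive["is_monocot"] = alive["taxon_true"].map(sp["is_monocot"]).astype(bool)

    # first census of each plot
    first_idx = alive.groupby("plot_id")["census_index"].min()
    at1 = alive[alive["census_index"] == alive["plot_id"].map(first_idx)].copy()
    at1["b_Mg"] = stem_biomass_kg(
        at1["d_true_cm"].values, at1["rho"].values, at1["region"].values,
        at1["is_monocot"].values, allom,
    ) / 1000.0
    per_sp = at1.groupby("taxon_true").agg(
        n_stems=("tree_id", "size"), biomass_Mg=("b_Mg", "sum")
    )

    # productivity on true diameters: mean per-interval rate per stem,
    # recruits from a 10-cm start at the previous plot census
    alive = alive.sort_values(["tree_id", "census_index"])
    alive["b_Mg"] = stem_biomass_kg(
        alive["d_true_cm"].values, alive["rho"].values,
        alive["region"].values, alive["is_monocot"].values, allom,
    ) / 1000.0
    g = alive.groupby("tree_id", sort=False)
    p_i = (g["b_Mg"].diff() / g["date"].diff()).rename("p")
    iv = pd.DataFrame({"tree_id": alive["tree_id"], "p": p_i}).dropna()

    first_obs = g.first().reset_index()
    sched = alive.groupby(["plot_id", "census_index"])["date"].median()
    rec = first_obs[
        first_obs["census_index"] > first_obs["plot_id"].map(first_idx)
    ].copy()
    if len(rec):
        prev_dates = []
        for pid, c in zip(rec["plot_id"], rec["census_index"]):
            s = sched.loc[pid]
            before = s[s.index < c]
            prev_dates.append(before.iloc[-1] if len(before) else np.nan)
        rec["t0"] = prev_dates
        rec = rec[pd.notna(rec["t0"])]
        b10 = stem_biomass_kg(
            np.full(len(rec), 10.0), rec["rho"].values, rec["region"].values,
            rec["is_monocot"].values, allom,
        ) / 1000.0
        iv = pd.concat(
            [iv, pd.DataFrame({
                "tree_id": rec["tree_id"],
                "p": (rec["b_Mg"].values - b10)
                / (rec["date"].values - rec["t0"].values.astype(float)),
            })],
            ignore_index=True,
        )
    p_stem = iv.groupby("tree_id")["p"].mean().rename("p_stem")
    pstem_df = p_stem.reset_index()
    pstem_df["taxon_true"] = pstem_df["tree_id"].map(tr["taxon_true"])
    per_sp_p = pstem_df.groupby("taxon_true")["p_stem"].sum()
    per_sp = per_sp.join(per_sp_p.rename("productivity_Mg_yr"), how="outer")
    per_sp["n_stems"] = per_sp["n_stems"].fillna(0).astype(int)
    per_sp["biomass_Mg"] = per_sp["biomass_Mg"].fillna(0.0)
    per_sp.index.name = "taxon_true"
    totals = {
        "total_stems": int(len(at1)),
        "total_biomass_Mg": float(at1["b_Mg"].sum()),
        "total_productivity_Mg_yr": float(p_stem.sum()),
    }
    per_sp = per_sp.reset_index().rename(columns={"taxon_true": "taxon_id"})
    per_sp["pct_stems"] = 100.0 * per_sp["n_stems"] / totals["total_stems"]
    per_sp["pct_biomass"] = (
        100.0 * per_sp["biomass_Mg"] / totals["total_biomass_Mg"]
    )
    per_sp["pct_productivity"] = (
        100.0 * per_sp["productivity_Mg_yr"]
        / totals["total_productivity_Mg_yr"]
    )
    stem_d = obs[["tree_id", "census_index", "d_true_cm"]].copy()
    return SyntheticTruth(species=per_sp, stem_diameters=stem_d, totals=totals)


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, SyntheticTruth]:
    """Community + censuses under one seed (the one-call entry point)."""
    rng = np.random.default_rng(config.seed)
    community = simulate_community(config, rng)
    return simulate_censuses(community, config, rng)


# ---------------------------------------------------------------------------
# steady-state palm population

def steady_state_palm_population(
    n_palms: int = 2000,
    annual_mortality: float = 0.02,
    growth_cm_yr: float = 0.5,
    max_d_cm: float = 35.0,
    interval_yr: float = 5.0,
    seed: int = 0,
    burn_in_yr: int = 60,
    drift_tol: float = 0.02,
    allometry: AllometryConfig | None = None,
) -> tuple[Dataset, dict]:
    """A demographically stationary palm population observed by two censuses.

    Annual steps: every palm grows by ``growth_cm_yr`` up to its determinate
    adult diameter ``max_d_cm`` (arborescent palms stop thickening once
    mature), then dies with probability ``annual_mortality``; each death is
    matched by recruitment at 10 cm, so mortality equals recruitment and
    (after burn-in from a geometric age structure) the size structure is
    stationary.  Returns the two-census dataset plus a truth dict with the
    realized mean biomass production rate over the observation window
    (Mg yr^-1), for checking the necromass-equilibrium estimator.
    """
    if annual_mortality <= 0:
        raise ValueError(
            "zero mortality cannot equilibrate a closed population"
        )
    rng = np.random.default_rng(seed)
    allom = allometry or default_allometry_config()
    m = annual_mortality
    g = growth_cm_yr

    ages = rng.geometric(m, size=n_palms) - 1  # stationary start
    d = np.minimum(10.0 + g * ages.astype(float), max_d_cm)

    def total_b(dd):
        return agb_palm(dd, allom).sum() / 1000.0

    # burn-in with drift check
    totals = [total_b(d)]
    for _ in range(burn_in_yr):
        d = np.minimum(d + g, max_d_cm)
        dies = rng.random(n_palms) < m
        d[dies] = 10.0
        totals.append(total_b(d))
    half = np.array(totals[burn_in_yr // 2:])
    drift = abs(half[-1] - half[0]) / max(len(half) - 1, 1)
    if drift > drift_tol * np.mean(half):
        raise RuntimeError(
            f"palm population failed to stabilize: per-year biomass drift "
            f"{drift:.3g} Mg exceeds tolerance"
        )

    # observation window: census at t0, annual dynamics, census at t0 + T
    t0 = 2000.0
    d_c1 = d.copy()
    alive_at_c1 = np.ones(n_palms, dtype=bool)
    died = np.zeros(n_palms, dtype=bool)
    production = 0.0
    years = int(round(interval_yr))
    for _ in range(years):
        live = ~died
        d_next = np.minimum(d[live] + g, max_d_cm)
        production += (agb_palm(d_next, allom).sum()
                       - agb_palm(d[live], allom).sum()) / 1000.0
        d[live] = d_next
        dies = live & (rng.random(n_palms) < m)
        died |= dies
        # replacements recruit but are omitted from the emitted tables:
        # they cannot be measured alive before the closing census anyway
    production_rate = production / years

    taxon = "palm0001"
    rows = []
    for i in range(n_palms):
        tid = f"PL{i:05d}"
        rows.append((tid, 1, t0, d_c1[i], 1.3, True))
        if died[i]:
            rows.append((tid, 2, t0 + interval_yr, np.nan, 1.3, False))
        else:
            rows.append((tid, 2, t0 + interval_yr, d[i], 1.3, True))
    obs = pd.DataFrame(
        rows, columns=["tree_id", "census_index", "date", "d_cm", "pom_m",
                       "alive"],
    )
    trees = pd.DataFrame(
        {
            "tree_id": [f"PL{i:05d}" for i in range(n_palms)],
            "plot_id": "PALM0",
            "taxon_id": taxon,
            "recruit_census": pd.array([pd.NA] * n_palms, dtype="Int64"),
        }
    )
    plots = pd.DataFrame(
        {
            "plot_id": ["PALM0"], "area_ha": [10.0], "lat": [-3.0],
            "lon": [-60.0], "elev_m": [100.0], "old_growth": [True],
            "terra_firme": [True], "cerrado": [False], "region_label": ["EC"],
        }
    )
    taxa = pd.DataFrame(
        {
            "taxon_id": [taxon], "family": ["Arecaceae"],
            "genus": ["Palmus"], "species": ["Palmus sturdyi"],
            "id_level": ["species"], "is_monocot": [True],
        }
    )
    wd = pd.DataFrame(
        {"level": ["species"], "name": ["Palmus sturdyi"], "rho_g_cm3": [0.45]}
    )
    ds = Dataset(trees=trees, obs=obs, plots=plots, taxa=taxa,
                 wood_density=wd)
    ds.validate()
    truth = {
        "true_production_Mg_yr": float(production_rate),
        "n_deaths": int(died.sum()),
        "n_palms": n_palms,
    }
    return ds, truth
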