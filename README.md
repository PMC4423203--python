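# hyperdom

Which tree species dominate a forest's carbon storage and cycling?

Tropical forests concentrate their stems in remarkably few "hyperdominant"
species, and the question this package answers is whether the *functions* —
aboveground woody biomass and woody productivity — are concentrated even more
strongly, and in which species. `hyperdom` is a tested, reusable pipeline for
multi-census forest-plot networks (tree-by-tree diameter records across
repeated censuses), written for forest ecologists and carbon-cycle modellers
working with RAINFOR/ForestPlots-style census tables.

## What it computes

For every stem with diameter *D* (cm, measured at the POM — 1.3 m or above
buttresses), wood density *ρ* (g cm⁻³, with species → genus → family →
plot-mean fallback) and modeled height *H* from a per-region Weibull fit
*H = a*(1 − e^(−*bD^c*)), aboveground biomass is

    AGB = 0.0509 · ρ · D² · H            (dicots, kg)
    ln AGB = c₀ + c₁ · ln D              (palms: Arecaceae, Strelitziaceae)

Woody productivity of a stem is the mean of its per-census-interval biomass
changes, *P*_stem = (1/*N*) Σᵢ *P*ᵢ with *P*ᵢ = [*B*(*D*_end) −
*B*(*D*_start)]/Δ*t*ᵢ, recruits entering at *D* = 10 cm, and diameter series
standardized across point-of-measurement changes. Palms, which lack radial
growth, get the necromass-equilibrium estimator *P*_stem = (*B*_final −
*B*_10cm)/(*C*_dead − *C*₁) summed over dead stems.

From the per-species aggregates the package derives **hyperdominance
statistics**: the minimal set of species accounting for 50% of total stems,
biomass or productivity (unidentified stems count in the denominators),
cumulative dominance curves ordered by species maximum diameter or wood
density, log–log regressions of functional contribution on stem abundance
(and of their residuals on traits), per-region tallies, and the ratio-scaling
estimate that carries hyperdominant counts to a reference flora.

A synthetic census generator (log-series species abundances, truncated
diameter distributions, growth/mortality/recruitment dynamics, POM changes,
palms, unidentified stems) provides exact ground truth for every statistic.

## Worked example

```python
from hyperdom import (SimulationConfig, simulate_dataset, assign_regions,
                      assign_wood_density, default_allometry_config,
                      species_table, hyperdominants)

ds, truth = simulate_dataset(SimulationConfig(seed=1))
ds = assign_wood_density(assign_regions(ds))
agg = species_table(ds, default_allometry_config())

print(f"stems: {agg.meta['total_stems']},",
      f"biomass: {agg.meta['total_biomass_Mg']:.0f} Mg,",
      f"productivity: {agg.meta['total_productivity_Mg_yr']:.1f} Mg/yr")
print(f"identified to species: {100*agg.meta['identified_stem_fraction']:.1f}%")
for metric in ("stems", "biomass", "productivity"):
    r = hyperdominants(agg, metric)
    print(f"{metric:>12}: {r.n_hyperdominant} hyperdominants "
          f"({r.pct_of_species:.1f}% of {len(r.ordered_taxa)} species)")
```

prints

```
stems: 4915, biomass: 2485 Mg, productivity: 36.8 Mg/yr
identified to species: 79.0%
       stems: 38 hyperdominants (13.9% of 273 species)
     biomass: 20 hyperdominants (7.3% of 273 species)
productivity: 26 hyperdominants (10.0% of 259 species)
```

Half the simulated biomass sits in 20 of 273 species (7.3%) — fewer than the
38 species (13.9%) needed to hold half the stems: carbon function is more
concentrated than abundance, and the desk-scale synthetic community shows the
same ordering (biomass < productivity < stems) as real Amazonian plot
networks.

The same analysis runs from the shell:

```
hyperdom simulate --out data/              # or bring your own CSV tables
hyperdom analyze data/ --out report/
hyperdom run --config run.yaml             # fully configured pipeline
hyperdom validate --species-package species_aggregates.csv
```

Input formats (UTF-8, comma-delimited, header row): `trees.csv` (long,
one row per stem per census: tree_id, plot_id, taxon_id, recruit_census,
census_index, date, d_cm, pom_m, alive), `plots.csv` (area, coordinates,
elevation, forest-type flags, optional region label), `taxa.csv`
(taxonomy + identification level) and `wood_density.csv` (level, name, ρ).

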