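"""POM standardization, interval/stem productivity, palm necromass
accounting, and species aggregation with the unidentified-denominator rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from hyperdom.census import Dataset, assign_regions, assign_wood_density
from hyperdom.allometry import agb_palm, stem_biomass_kg
from hyperdom.productivity import (
    aggregate_species,
    interval_productivity_table,
    palm_mortality_records,
    productivity_subset,
    species_table,
    standardize_pom,
    stem_productivity_table,
)


def build_dataset(obs_rows, taxa_rows=None, rho=0.6, region="EC",
                  n_plots=1, area_ha=1.0):
    """Dataset from (tree, taxon, census, date, d, pom, alive) tuples."""
    obs = pd.DataFrame(
        obs_rows,
        columns=["tree_id", "taxon_id", "census_index", "date", "d_cm",
                 "pom_m", "alive"],
    )
    trees = obs[["tree_id", "taxon_id"]].drop_duplicates("tree_id").copy()
    trees["plot_id"] = "p1"
    trees["recruit_census"] = pd.array([pd.NA] * len(trees), dtype="Int64")
    plots = pd.DataFrame(
        [["p1", area_ha, -3.0, -60.0, 100.0, True, True, False, region]],
        columns=["plot_id", "area_ha", "lat", "lon", "elev_m", "old_growth",
                 "terra_firme", "cerrado", "region_label"],
    )
    if taxa_rows is None:
        taxa_rows = [["spA", "Fabaceae", "GenA", "GenA alpha", "species"]]
    taxa = pd.DataFrame(
        taxa_rows,
        columns=["taxon_id", "family", "genus", "species", "id_level"],
    )
    taxa["is_monocot"] = taxa["family"].isin(["Arecaceae", "Strelitziaceae"])
    wd = pd.DataFrame(
        [["species", r[3], rho] for r in taxa_rows if r[4] == "species"],
        columns=["level", "name", "rho_g_cm3"],
    )
    ds = Dataset(
        trees=trees[["tree_id", "plot_id", "taxon_id", "recruit_census"]],
        obs=obs[["tree_id", "census_index", "date", "d_cm", "pom_m",
                 "alive"]],
        plots=plots, taxa=taxa, wood_density=wd,
    )
    ds.validate()
    return assign_wood_density(assign_regions(ds))


def B(d, cfg, rho=0.6, region="EC"):
    return stem_biomass_kg(d, rho, region, False, cfg) / 1000.0


class TestStandardizePOM:
    def test_constant_pom_identity(self):
        d = np.array([30.0, 31.0, 32.5])
        out = standardize_pom([2000.0, 2005.0, 2010.0], d, [1.3, 1.3, 1.3])
        np.testing.assert_array_equal(out, d)

    def test_single_change_preserves_increments(self):
        # measured 30 -> 31 at old POM, then 28, 29 at a raised POM
        dates = [2000.0, 2005.0, 2010.0, 2015.0]
        d = [30.0, 31.0, 28.0, 29.0]
        pom = [1.3, 1.3, 1.8, 1.8]
        out = standardize_pom(dates, d, pom)
        assert out[2] == 28.0 and out[3] == 29.0  # post-change kept verbatim
        assert out[1] - out[0] == pytest.approx(1.0)  # old increment kept
        assert out[3] - out[2] == pytest.approx(1.0)

    def test_join_growth_imputed_from_mean_rate(self):
        dates = [2000.0, 2005.0, 2010.0, 2015.0]
        out = standardize_pom(dates, [30.0, 31.0, 28.0, 29.0],
                              [1.3, 1.3, 1.8, 1.8])
        # both segments grow 1.0 per 5 yr -> join interval imputes 1.0
        assert out[2] - out[1] == pytest.approx(1.0)
        np.testing.assert_allclose(out, [26.0, 27.0, 28.0, 29.0])

    def test_two_changes_preserve_all_within_segment_increments(self):
        dates = [2000.0, 2005.0, 2010.0, 2015.0, 2020.0, 2025.0]
        d = [40.0, 42.0, 37.0, 39.0, 33.0, 35.0]
        pom = [1.3, 1.3, 2.0, 2.0, 2.6, 2.6]
        out = standardize_pom(dates, d, pom)
        np.testing.assert_allclose(np.diff(out)[[0, 2, 4]], [2.0, 2.0, 2.0])
        np.testing.assert_allclose(out[-2:], [33.0, 35.0])

    @given(st.lists(st.floats(min_value=-0.5, max_value=2.0),
                    min_size=2, max_size=6),
           st.integers(min_value=1, max_value=4))
    @settings(max_examples=60, deadline=None)
    def test_property_post_change_and_increment_preservation(
        self, increments, change_at
    ):
        n = len(increments) + 1
        change_at = min(change_at, n - 1)
        d = 30.0 + np.concatenate([[0.0], np.cumsum(increments)])
        pom = np.where(np.arange(n) >= change_at, 1.9, 1.3)
        recorded = np.where(np.arange(n) >= change_at, d * 0.9, d)
        dates = 2000.0 + 5.0 * np.arange(n)
        out = standardize_pom(dates, recorded, pom)
        # post-change diameters preserved exactly
        np.testing.assert_allclose(out[change_at:], recorded[change_at:])
        # increments within each constant-POM segment preserved
        for seg in (slice(0, change_at), slice(change_at, n)):
            np.testing.assert_allclose(np.diff(out[seg]),
                                       np.diff(recorded[seg]), atol=1e-9)

    def test_no_overlap_warns_when_rate_unknown(self):
        with pytest.warns(UserWarning, match="splicing"):
            out = standardize_pom([2000.0, 2005.0], [30.0, 27.0], [1.3, 1.8])
        # zero imputed growth: old diameter shifted onto the new series
        np.testing.assert_allclose(out, [27.0, 27.0])


class TestIntervalProductivity:
    def test_growth_interval_matches_allometry(self, pinned_allometry):
        ds = build_dataset([
            ("t1", "spA", 1, 2000.0, 10.0, 1.3, True),
            ("t1", "spA", 2, 2002.0, 12.0, 1.3, True),
        ])
        iv = interval_productivity_table(ds, pinned_allometry)
        expected = (B(12.0, pinned_allometry) - B(10.0, pinned_allometry)) / 2.0
        assert iv["p_mg_yr"].item() == pytest.approx(expected, rel=1e-12)

    def test_no_growth_zero(self, pinned_allometry):
        ds = build_dataset([
            ("t1", "spA", 1, 2000.0, 15.0, 1.3, True),
            ("t1", "spA", 2, 2004.0, 15.0, 1.3, True),
        ])
        iv = interval_productivity_table(ds, pinned_allometry)
        assert iv["p_mg_yr"].item() == 0.0

    def test_shrinkage_negative_retained(self, pinned_allometry):
        ds = build_dataset([
            ("t1", "spA", 1, 2000.0, 15.0, 1.3, True),
            ("t1", "spA", 2, 2004.0, 14.0, 1.3, True),
        ])
        iv = interval_productivity_table(ds, pinned_allometry)
        assert iv["p_mg_yr"].item() < 0

    def test_recruit_equals_formula_with_10cm_start(self, pinned_allometry):
        ds = build_dataset([
            ("t0", "spA", 1, 2000.0, 20.0, 1.3, True),
            ("t0", "spA", 2, 2002.0, 20.5, 1.3, True),
            ("t1", "spA", 2, 2002.0, 12.0, 1.3, True),  # recruit
        ])
        iv = interval_productivity_table(ds, pinned_allometry)
        rec = iv[iv["tree_id"] == "t1"]
        assert rec["is_recruit_interval"].item()
        expected = (B(12.0, pinned_allometry) - B(10.0, pinned_allometry)) / 2.0
        assert rec["p_mg_yr"].item() == pytest.approx(expected, rel=1e-12)

    def test_recruit_at_exactly_10_zero(self, pinned_allometry):
        ds = build_dataset([
            ("t0", "spA", 1, 2000.0, 20.0, 1.3, True),
            ("t0", "spA", 2, 2002.0, 20.5, 1.3, True),
            ("t1", "spA", 2, 2002.0, 10.0, 1.3, True),
        ])
        iv = interval_productivity_table(ds, pinned_allometry)
        assert iv.loc[iv["tree_id"] == "t1", "p_mg_yr"].item() == 0.0

    def test_undersized_recruit_clamped_with_warning(self, pinned_allometry):
        ds = build_dataset([
            ("t0", "spA", 1, 2000.0, 20.0, 1.3, True),
            ("t0", "spA", 2, 2002.0, 20.5, 1.3, True),
            ("t1", "spA", 2, 2002.0, 9.5, 1.3, True),
        ])
        with pytest.warns(UserWarning, match="clamped"):
            iv = interval_productivity_table(ds, pinned_allometry)
        assert iv.loc[iv["tree_id"] == "t1", "p_mg_yr"].item() < 0


class TestStemProductivity:
    def test_single_interval(self, pinned_allometry):
        ds = build_dataset([
            ("t1", "spA", 1, 2000.0, 10.0, 1.3, True),
            ("t1", "spA", 2, 2002.0, 12.0, 1.3, True),
        ])
        ps = stem_productivity_table(ds, pinned_allometry)
        iv = interval_productivity_table(ds, pinned_allometry)
        assert ps["p_stem_mg_yr"].item() == iv["p_mg_yr"].item()
        assert ps["n_intervals"].item() == 1

    def test_mean_over_intervals(self, pinned_allometry):
        ds = build_dataset([
            ("t1", "spA", 1, 2000.0, 10.0, 1.3, True),
            ("t1", "spA", 2, 2005.0, 14.0, 1.3, True),
            ("t1", "spA", 3, 2010.0, 16.0, 1.3, True),
        ])
        iv = interval_productivity_table(ds, pinned_allometry)
        ps = stem_productivity_table(ds, pinned_allometry)
        assert ps["p_stem_mg_yr"].item() == pytest.approx(
            iv["p_mg_yr"].mean()
        )
        assert ps["n_intervals"].item() == 2

    def test_dead_before_second_census_absent(self, pinned_allometry):
        ds = build_dataset([
            ("t1", "spA", 1, 2000.0, 10.0, 1.3, True),
            ("t1", "spA", 2, 2005.0, np.nan, 1.3, False),
            ("t2", "spA", 1, 2000.0, 12.0, 1.3, True),
            ("t2", "spA", 2, 2005.0, 13.0, 1.3, True),
        ])
        ps = stem_productivity_table(ds, pinned_allometry)
        assert set(ps["tree_id"]) == {"t2"}

    def test_interval_split_invariance_linear_in_biomass(
        self, pinned_allometry
    ):
        """Splitting one interval at an interpolated diameter chosen so the
        biomass path is linear in time leaves P_stem unchanged."""
        d0, d1 = 10.0, 14.0
        b_mid = (B(d0, pinned_allometry) + B(d1, pinned_allometry)) / 2.0
        d_mid = brentq(lambda d: B(d, pinned_allometry) - b_mid, d0, d1)
        one = build_dataset([
            ("t1", "spA", 1, 2000.0, d0, 1.3, True),
            ("t1", "spA", 2, 2010.0, d1, 1.3, True),
        ])
        two = build_dataset([
            ("t1", "spA", 1, 2000.0, d0, 1.3, True),
            ("t1", "spA", 2, 2005.0, d_mid, 1.3, True),
            ("t1", "spA", 3, 2010.0, d1, 1.3, True),
        ])
        p1 = stem_productivity_table(one, pinned_allometry)["p_stem_mg_yr"].item()
        p2 = stem_productivity_table(two, pinned_allometry)["p_stem_mg_yr"].item()
        assert p2 == pytest.approx(p1, rel=1e-9)


class TestPalmNecromass:
    palm_taxa = [["palmA", "Arecaceae", "PalmG", "PalmG alta", "species"]]

    def test_record_formula(self, pinned_allometry):
        ds = build_dataset(
            [
                ("t1", "palmA", 1, 2000.0, 18.0, 1.3, True),
                ("t1", "palmA", 2, 2005.0, np.nan, 1.3, False),
            ],
            taxa_rows=self.palm_taxa,
        )
        rec = palm_mortality_records(ds, pinned_allometry)
        b_final = agb_palm(18.0, pinned_allometry) / 1000.0
        b10 = agb_palm(10.0, pinned_allometry) / 1000.0
        assert rec["p_stem_mg_yr"].item() == pytest.approx(
            (b_final - b10) / 5.0
        )
        assert rec["C_1"].item() == 2000.0
        assert rec["C_dead"].item() == 2005.0

    def test_death_at_10cm_contributes_zero(self, pinned_allometry):
        ds = build_dataset(
            [
                ("t1", "palmA", 1, 2000.0, 10.0, 1.3, True),
                ("t1", "palmA", 2, 2005.0, np.nan, 1.3, False),
            ],
            taxa_rows=self.palm_taxa,
        )
        rec = palm_mortality_records(ds, pinned_allometry)
        assert rec["p_stem_mg_yr"].item() == 0.0

    def test_hand_arithmetic_quadruple(self):
        # (B_final - B_10cm) / (C_dead - C_1) = (0.30 - 0.05) / 5 = 0.05
        assert (0.30 - 0.05) / (2005.0 - 2000.0) == pytest.approx(0.05)

    def test_survivors_produce_no_record(self, pinned_allometry):
        ds = build_dataset(
            [
                ("t1", "palmA", 1, 2000.0, 18.0, 1.3, True),
                ("t1", "palmA", 2, 2005.0, 18.0, 1.3, True),
            ],
            taxa_rows=self.palm_taxa,
        )
        assert len(palm_mortality_records(ds, pinned_allometry)) == 0


class TestAggregation:
    def test_toy_denominator_rule(self, pinned_allometry):
        # species A: 2 stems, B: 1 stem, 1 unidentified -> A=50%, B=25%
        taxa = [
            ["spA", "Fabaceae", "GenA", "GenA alpha", "species"],
            ["spB", "Moraceae", "GenB", "GenB beta", "species"],
            ["unid", "", "", "", "none"],
        ]
        ds = build_dataset(
            [
                ("t1", "spA", 1, 2000.0, 12.0, 1.3, True),
                ("t2", "spA", 1, 2000.0, 14.0, 1.3, True),
                ("t3", "spB", 1, 2000.0, 20.0, 1.3, True),
                ("t4", "unid", 1, 2000.0, 25.0, 1.3, True),
            ],
            taxa_rows=taxa,
        )
        agg = species_table(ds, pinned_allometry, include_productivity=False)
        t = agg.table.set_index("taxon_id")
        assert t.loc["spA", "pct_stems"] == 50.0
        assert t.loc["spB", "pct_stems"] == 25.0
        assert agg.meta["total_stems"] == 4
        assert "unid" not in t.index

    def test_conservation_stems_biomass(self, desk_sim, pinned_allometry):
        ds, _ = desk_sim
        agg = species_table(ds, pinned_allometry, include_productivity=False)
        # independent stem-level totals
        from hyperdom.census import plot_census_dates
        sched = plot_census_dates(ds)
        first_idx = sched.groupby("plot_id")["census_index"].min()
        obs1 = ds.obs[ds.obs["alive"]].merge(ds.trees, on="tree_id")
        obs1 = obs1[obs1["census_index"] == obs1["plot_id"].map(first_idx)]
        assert agg.meta["total_stems"] == len(obs1)
        # identified + unidentified biomass == total
        id_level = ds.taxa.set_index("taxon_id")["id_level"]
        ident = obs1["taxon_id"].map(id_level) == "species"
        assert agg.table["n_stems"].sum() == int(ident.sum())
        attrs = ds.attributes.set_index("tree_id")
        taxa = ds.taxa.set_index("taxon_id")
        b = stem_biomass_kg(
            obs1["d_cm"].values,
            obs1["tree_id"].map(attrs["rho"]).values,
            obs1["tree_id"].map(attrs["region"]).values,
            obs1["taxon_id"].map(taxa["is_monocot"]).values.astype(bool),
            pinned_allometry,
        ) / 1000.0
        assert agg.meta["total_biomass_Mg"] == pytest.approx(b.sum(),
                                                             rel=1e-9)
        assert agg.table["biomass_Mg"].sum() == pytest.approx(
            b[ident.values].sum(), rel=1e-9
        )

    def test_truth_contributions_recovered_exactly(self, clean_sim):
        ds, truth = clean_sim
        # truth was recorded under the generator's allometry (the default
        # config), so the pipeline must run under the same one
        from hyperdom.allometry import default_allometry_config
        agg = species_table(ds, default_allometry_config())
        t = agg.table.set_index("taxon_id")
        s = truth.species.set_index("taxon_id")
        j = t.join(s, rsuffix="_true", how="outer")
        assert (j["n_stems"] == j["n_stems_true"]).all()
        np.testing.assert_allclose(j["pct_stems"], j["pct_stems_true"],
                                   rtol=1e-9)
        np.testing.assert_allclose(j["pct_biomass"], j["pct_biomass_true"],
                                   rtol=1e-9)
        both = j[j["productivity_Mg_yr"].notna()
                 & j["productivity_Mg_yr_true"].notna()]
        np.testing.assert_allclose(both["pct_productivity"],
                                   both["pct_productivity_true"], rtol=1e-9)

    def test_productivity_requires_multicensus(self, pinned_allometry):
        ds = build_dataset([("t1", "spA", 1, 2000.0, 12.0, 1.3, True)])
        with pytest.raises(ValueError, match="censuses"):
            aggregate_species(ds, pinned_allometry, mode="productivity")

    def test_productivity_subset_span_rule(self, pinned_allometry):
        ds = build_dataset([
            ("t1", "spA", 1, 2000.0, 12.0, 1.3, True),
            ("t1", "spA", 2, 2001.0, 12.5, 1.3, True),  # 1-yr span only
        ])
        assert len(productivity_subset(ds, min_span_yr=2.0).plots) == 0
        assert len(productivity_subset(ds, min_span_yr=0.5).plots) == 1
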