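"""Tree allometry, coarse-woody-debris and understory biomass estimators."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from firewebs import plant_biomass as pb


@pytest.fixture
def params() -> pb.AllometryParams:
    return pb.AllometryParams(
        agb={"Pinaceae": (-2.5356, 2.4349)},
        tissue={
            "Pinaceae": {
                "foliage": (-2.0, 10.0),
                "coarse_roots": (-1.5, 0.0),
                "stem_bark": (-2.1, -1.1),
                "stem_wood": (-0.37, -1.8),
            }
        },
        height={"Pinaceae": (1.0, 0.5, 0.1, 0.0)},
    )


class TestTreeAllometry:
    @pytest.mark.parametrize(
        "b0,b1,dbh,expected",
        [
            (0.0, 0.0, 17.3, 1.0),
            (0.0, 1.0, math.e, math.e),
            (-2.5356, 2.4349, 30.0, math.exp(-2.5356 + 2.4349 * math.log(30.0))),
        ],
    )
    def test_agb_closed_form(self, b0, b1, dbh, expected):
        p = pb.AllometryParams(agb={"Pinaceae": (b0, b1)}, tissue={}, height={})
        assert pb.tree_agb(dbh, p, "Pinaceae") == pytest.approx(expected, rel=1e-12)

    def test_tissue_ratio_closed_form(self, params):
        # b0=-2, b1=10, dbh=20 -> exp(-2 + 10/20) = exp(-1.5)
        assert pb.tissue_ratio(20.0, "foliage", params, "Pinaceae") == pytest.approx(
            math.exp(-1.5)
        )
        # b1 = 0 -> DBH-independent exp(b0)
        assert pb.tissue_ratio(7.0, "coarse_roots", params, "Pinaceae") == pytest.approx(
            math.exp(-1.5)
        )
        # DBH -> infinity limit equals exp(b0)
        assert pb.tissue_ratio(1e9, "foliage", params, "Pinaceae") == pytest.approx(
            math.exp(-2.0), rel=1e-6
        )

    def test_tissue_ratio_rejects_unknown_tissue(self, params):
        with pytest.raises(ValueError, match="tissue"):
            pb.tissue_ratio(20.0, "twigs", params, "Pinaceae")

    def test_full_height_closed_form(self):
        p = pb.AllometryParams(agb={}, tissue={}, height={"Pinaceae": (1.0, 0.5, 0.1, 0.0)})
        # dbh = e: ln d = 1 -> exp(1 + 0.5 + 0.1) = exp(1.6)
        assert pb.tree_full_height(math.e, p, "Pinaceae") == pytest.approx(math.exp(1.6))
        p0 = pb.AllometryParams(agb={}, tissue={}, height={"Pinaceae": (0, 0, 0, 0)})
        assert pb.tree_full_height(5.0, p0, "Pinaceae") == pytest.approx(1.0)
        p1 = pb.AllometryParams(agb={}, tissue={}, height={"Pinaceae": (0, 1, 0, 0)})
        assert pb.tree_full_height(10.0, p1, "Pinaceae") == pytest.approx(10.0)

    def test_pinaceae_fallback_for_unidentified(self, params):
        # unidentified trees use the Pinaceae parameters
        assert pb.tree_agb(30.0, params, "Unknown_sp") == pb.tree_agb(30.0, params, "Pinaceae")
        empty = pb.AllometryParams(agb={}, tissue={}, height={})
        with pytest.raises(KeyError):
            pb.tree_agb(30.0, empty, "Unknown_sp")


class TestTreeCategories:
    def test_intact_alive_is_agb_plus_roots(self, params):
        tree = pb.TreeRecord("s1", "Pinaceae", 30.0, "healthy")
        agb = pb.tree_agb(30.0, params, "Pinaceae")
        roots = pb.tissue_ratio(30.0, "coarse_roots", params, "Pinaceae")
        mass, cat = pb.tree_biomass(tree, params)
        assert cat == "intact_alive"
        assert mass == pytest.approx(agb * (1 + roots))

    def test_intact_dead_drops_foliage(self, params):
        tree = pb.TreeRecord("s1", "Pinaceae", 30.0, "dead")
        agb = pb.tree_agb(30.0, params, "Pinaceae")
        r_f = pb.tissue_ratio(30.0, "foliage", params, "Pinaceae")
        r_r = pb.tissue_ratio(30.0, "coarse_roots", params, "Pinaceae")
        mass, cat = pb.tree_biomass(tree, params)
        assert cat == "intact_dead"
        assert mass == pytest.approx(agb * (1 - r_f + r_r))

    def test_damaged_alive_scales_tissue_sum_by_height_fraction(self):
        # equal tissue ratios r: damaged at 50% height = half the 4-tissue sum
        r = 0.1
        p = pb.AllometryParams(
            agb={"Pinaceae": (0.0, 1.0)},
            tissue={"Pinaceae": {t: (math.log(r), 0.0) for t in pb.TISSUES}},
            height={"Pinaceae": (math.log(20.0), 0.0, 0.0, 0.0)},  # full height 20 m
        )
        tree = pb.TreeRecord("s1", "Pinaceae", 10.0, "healthy", damaged=True,
                             measured_height_m=10.0)
        mass, cat = pb.tree_biomass(tree, p)
        agb = 10.0  # exp(0 + 1*ln 10)
        assert cat == "damaged_alive"
        assert mass == pytest.approx(0.5 * agb * 4 * r)

    def test_damaged_needs_height_and_tall_trees_become_intact(self, params):
        with pytest.raises(ValueError, match="height"):
            pb.tree_biomass(
                pb.TreeRecord("s1", "Pinaceae", 30.0, "healthy", damaged=True), params
            )
        tall = pb.TreeRecord("s1", "Pinaceae", 30.0, "healthy", damaged=True,
                             measured_height_m=1e4)
        _, cat = pb.tree_biomass(tall, params)
        assert cat == "intact_alive"

    @given(dbh=st.floats(5.0, 150.0), frac=st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_damaged_never_exceeds_intact(self, dbh, frac):
        p = pb.AllometryParams(
            agb={"Pinaceae": (-2.5, 2.4)},
            tissue={
                "Pinaceae": {
                    "foliage": (-2.9, 4.5),
                    "coarse_roots": (-1.5, 0.6),
                    "stem_bark": (-2.1, -1.1),
                    "stem_wood": (-0.4, -1.8),
                }
            },
            height={"Pinaceae": (1.0, 0.5, 0.05, 0.0)},
        )
        full = pb.tree_full_height(dbh, p, "Pinaceae")
        damaged = pb.TreeRecord("s", "Pinaceae", dbh, "healthy", damaged=True,
                                measured_height_m=frac * full)
        intact = pb.TreeRecord("s", "Pinaceae", dbh, "healthy")
        m_damaged, _ = pb.tree_biomass(damaged, p)
        m_intact, _ = pb.tree_biomass(intact, p)
        assert 0 <= m_damaged <= m_intact * (1 + 1e-9)


class TestCoarseWoodyDebris:
    def test_weighted_specific_gravity_printed_components(self):
        # pine 0.372 at 94.7% plus oak 0.566 at 5.3%
        assert pb.weighted_specific_gravity(
            [(0.372, 0.947), (0.566, 0.053)]
        ) == pytest.approx(0.382, abs=5e-4)

    def test_weighted_specific_gravity_identity_and_symmetry(self):
        assert pb.weighted_specific_gravity([(0.44, 1.0)]) == pytest.approx(0.44)
        assert pb.weighted_specific_gravity([(0.4, 0.5), (0.6, 0.5)]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            pb.weighted_specific_gravity([(0.4, 0.0), (0.6, 0.0)])

    def test_frustum_reduces_to_cylinder_when_ends_equal(self):
        piece = pb.CwdPiece("s", 20.0, 20.0, 1.0, 1)
        cylinder = math.pi * 0.10**2 * 1.0
        assert pb.cwd_piece_volume(piece) == pytest.approx(cylinder, rel=1e-12)

    def test_frustum_hand_value_and_linearity(self):
        piece = pb.CwdPiece("s", 15.0, 20.0, 2.0, 1)
        assert pb.cwd_piece_volume(piece) == pytest.approx(
            (math.pi / 8) * (225 + 400) * 2 / 1e4
        )
        double = pb.CwdPiece("s", 15.0, 20.0, 4.0, 1)
        assert pb.cwd_piece_volume(double) == pytest.approx(2 * pb.cwd_piece_volume(piece))

    def test_volume_density_hand_value(self):
        consts = pb.CwdConstants()
        vd = pb.cwd_volume_density(0.031416, 1.0, consts)
        assert vd == pytest.approx(4.9348, abs=1e-3)
        assert pb.cwd_volume_density(0.0, 1.0, consts) == 0.0
        halved = pb.CwdConstants(transect_length_m=50.0)
        assert pb.cwd_volume_density(0.031416, 1.0, halved) == pytest.approx(2 * vd)

    def test_mass_density_hand_value(self):
        assert pb.cwd_mass_density(4.9348, 0.382, 1.0) == pytest.approx(1885.1, abs=0.5)
        assert pb.cwd_mass_density(4.9348, 0.382, 0.0) == 0.0
        assert pb.cwd_mass_density(4.9348, 0.2, 1.0) == pytest.approx(
            0.5 * pb.cwd_mass_density(4.9348, 0.4, 1.0)
        )

    def test_piece_inclusion_rules(self):
        with pytest.raises(ValueError):
            pb.CwdPiece("s", 20.0, 15.0, 2.0, 1)  # D_S > D_L
        with pytest.raises(ValueError):
            pb.CwdPiece("s", 15.0, 20.0, 0.5, 1)  # shorter than 1 m


class TestMassToVolumePooling:
    def _brute_force(self, df: pd.DataFrame, species: str, tissue: str):
        """Direct re-derivation of the species->genus->family->all pooling."""
        sub = df[df["tissue_type"] == tissue].copy()
        sub["ratio"] = sub["mass_kg"] / sub["volume_m3"]
        own = sub[sub["species_id"] == species]
        if len(own) >= 3:
            return own["ratio"].mean(), "species"
        genus = own["genus"].iloc[0]
        family = own["family"].iloc[0]
        g = sub[sub["genus"] == genus]
        f = sub[sub["family"] == family]
        if pd.notna(genus) and len(g) >= 3:
            return g["ratio"].mean(), "genus"
        if pd.notna(family) and len(f) >= 3:
            return f["ratio"].mean(), "family"
        if pd.notna(genus) and len(g) > len(own):
            return g["ratio"].mean(), "genus"
        if pd.notna(family) and len(f) > len(own):
            return f["ratio"].mean(), "family"
        return sub["ratio"].mean(), "all"

    def test_species_level_mean(self):
        df = pd.DataFrame(
            {
                "species_id": ["A"] * 3, "genus": ["G"] * 3, "family": ["F"] * 3,
                "tissue_type": ["leaf"] * 3,
                "mass_kg": [1.0, 2.0, 3.0], "volume_m3": [1.0, 1.0, 1.0],
            }
        )
        (ratio,) = pb.mass_to_volume_ratios(df)
        assert ratio.ratio_kg_per_m3 == pytest.approx(2.0)
        assert ratio.pooling_level == "species"

    def test_congener_pooling(self):
        # species A n=1 (ratio 2) and congener B n=2 (4, 6) both report
        # the genus-pooled mean 4
        df = pd.DataFrame(
            {
                "species_id": ["A", "B", "B"],
                "genus": ["G"] * 3, "family": ["F"] * 3, "tissue_type": ["leaf"] * 3,
                "mass_kg": [2.0, 4.0, 6.0], "volume_m3": [1.0] * 3,
            }
        )
        ratios = {r.taxon_id: r for r in pb.mass_to_volume_ratios(df)}
        assert ratios["A"].ratio_kg_per_m3 == pytest.approx(4.0)
        assert ratios["B"].ratio_kg_per_m3 == pytest.approx(4.0)
        assert ratios["A"].pooling_level == "genus"

    def test_singleton_pools_to_global_mean(self):
        df = pd.DataFrame(
            {
                "species_id": ["A", "B", "C"],
                "genus": ["G1", "G2", "G3"], "family": ["F1", "F2", "F3"],
                "tissue_type": ["leaf"] * 3,
                "mass_kg": [2.0, 4.0, 6.0], "volume_m3": [1.0] * 3,
            }
        )
        ratios = {r.taxon_id: r for r in pb.mass_to_volume_ratios(df)}
        assert ratios["A"].pooling_level == "all"
        assert ratios["A"].ratio_kg_per_m3 == pytest.approx(4.0)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(3, 20)
            df = pd.DataFrame(
                {
                    "species_id": rng.choice(["A", "B", "C", "D"], n),
                    "genus": None, "family": None, "tissue_type": "leaf",
                    "mass_kg": rng.uniform(0.5, 5.0, n),
                    "volume_m3": rng.uniform(0.01, 0.5, n),
                }
            )
            df["genus"] = df["species_id"].map({"A": "G1", "B": "G1", "C": "G2", "D": "G2"})
            df["family"] = "F"
            out = {r.taxon_id: r for r in pb.mass_to_volume_ratios(df)}
            for species in df["species_id"].unique():
                expect_ratio, expect_level = self._brute_force(df, species, "leaf")
                assert out[species].ratio_kg_per_m3 == pytest.approx(expect_ratio)
                assert out[species].pooling_level == expect_level


class TestUnderstoryBiomass:
    def test_hand_chain(self):
        # 50% cover x 0.2 m over 20 m^2 sampled, ratio 10 kg/m^3 -> 500 kg/ha
        cover = pd.DataFrame(
            [{"site": "s1", "species_id": "A", "tissue_type": "leaf",
              "cover_fraction": 0.5, "height_m": 0.2, "quadrat_area_m2": 1.0}]
        )
        ratios = [pb.MassVolumeRatio("A", "leaf", 10.0, 3, "species")]
        out = pb.understory_biomass(cover, ratios, sampled_area_m2=20.0)
        assert out["biomass_kg_ha"].iloc[0] == pytest.approx(500.0)

    def test_zero_cover_and_ratio_scaling(self):
        cover = pd.DataFrame(
            [{"site": "s1", "species_id": "A", "tissue_type": "leaf",
              "cover_fraction": 0.0, "height_m": 0.2, "quadrat_area_m2": 1.0}]
        )
        out = pb.understory_biomass(cover, [pb.MassVolumeRatio("A", "leaf", 10.0, 3, "species")])
        assert (out["biomass_kg_ha"] == 0).all()

        cover2 = cover.assign(cover_fraction=0.3)
        one = pb.understory_biomass(cover2, [pb.MassVolumeRatio("A", "leaf", 10.0, 3, "species")])
        two = pb.understory_biomass(cover2, [pb.MassVolumeRatio("A", "leaf", 20.0, 3, "species")])
        assert two["biomass_kg_ha"].iloc[0] == pytest.approx(2 * one["biomass_kg_ha"].iloc[0])

    def test_missing_ratio_is_reported(self):
        cover = pd.DataFrame(
            [{"site": "s1", "species_id": "Zz", "tissue_type": "leaf",
              "cover_fraction": 0.5, "height_m": 0.2, "quadrat_area_m2": 1.0}]
        )
        with pytest.raises(ValueError, match="Zz"):
            pb.understory_biomass(cover, [])


class TestProxyBootstrap:
    def test_degenerate_single_species(self):
        out = pb.assign_proxy_species(
            {"Arctostaphylos": 5},
            {"u1": {"Arctostaphylos": {"A. patula": 7}}},
            reps=50, seed=1,
        )
        assert out["mean_count"].iloc[0] == pytest.approx(5.0)
        assert out["bootstrap_se"].iloc[0] == pytest.approx(0.0)

    def test_multinomial_expectation(self):
        # one proxy site {A:3, B:1}, 4 unidentified: expect means near 3 and 1
        out = pb.assign_proxy_species(
            {"tax": 4}, {"u1": {"tax": {"A": 3, "B": 1}}}, reps=9_999, seed=2
        )
        means = dict(zip(out["species_id"], out["mean_count"]))
        ses = dict(zip(out["species_id"], out["bootstrap_se"]))
        n = 9_999
        for sp, expected in (("A", 3.0), ("B", 1.0)):
            assert abs(means[sp] - expected) < 3 * ses[sp] / math.sqrt(n)

    def test_deterministic_and_absent_taxon_errors(self):
        kwargs = dict(
            focal_unidentified={"tax": 6},
            proxy_sites={"u1": {"tax": {"A": 2, "B": 5}}, "u2": {"tax": {"A": 1}}},
            reps=99,
        )
        a = pb.assign_proxy_species(seed=3, **kwargs)
        b = pb.assign_proxy_species(seed=3, **kwargs)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError, match="absent"):
            pb.assign_proxy_species({"other": 1}, {"u1": {"tax": {"A": 1}}}, reps=9, seed=0)


def test_treatment_aggregation_is_mean_and_sem_over_sites():
    per_site = pd.DataFrame(
        {"site": ["u1", "u2", "u3", "h1"], "kg_ha": [10.0, 12.0, 14.0, 3.0]}
    )
    out = pb.treatment_mean_se(
        per_site, "kg_ha", {"u1": "unburned", "u2": "unburned", "u3": "unburned", "h1": "high"}
    )
    row = out[out["treatment"] == "unburned"].iloc[0]
    assert row["kg_ha"] == pytest.approx(12.0)
    assert row["se"] == pytest.approx(np.std([10, 12, 14], ddof=1) / math.sqrt(3))
    assert row["n_sites"] == 3
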