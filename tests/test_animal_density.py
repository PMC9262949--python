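"""Method-specific animal density conversions and partitioning rules."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from firewebs import animal_density as ad
from firewebs.registry import NodeRegistry, TaxonStage, Taxonomy


class TestGeometries:
    """Printed per-site sample areas re-derive from the stated geometry."""

    @pytest.mark.parametrize(
        "method,expected,abs_tol",
        [
            ("soil_cores", 0.0471, 5e-4),         # six 10-cm-diameter cores
            ("hard_substrate", 58.9, 0.05),       # three 5-m-diameter cylinders
            ("sweep_net", 58.9, 0.05),
            ("ground_cover", 20.0, 0),            # twenty 1-m^2 quadrats
            ("box_quadrat", 0.75, 0),             # three 0.25-m^2 boxes
            ("small_mammal_grid", 8100.0, 0),     # 90 x 90 m grid
            ("reptile_grid", 8100.0, 0),
            ("tree_transect", 1500.0, 0),         # 2 x 50 m x 15 m bands
            ("shrub_transect", 500.0, 0),         # 2 x 50 m x 5 m bands
            ("bird_point_count", 15708.0, 0),     # protocol's printed area
        ],
    )
    def test_default_areas(self, method, expected, abs_tol):
        assert ad.DEFAULT_GEOMETRIES[method].sampled_area_m2 == pytest.approx(
            expected, abs=abs_tol or None
        )

    def test_positive_area_enforced(self):
        with pytest.raises(ValueError):
            ad.MethodGeometry("bad", 0.0)


class TestAreaDensity:
    def test_quotient_of_count_and_area(self):
        geom = ad.DEFAULT_GEOMETRIES["hard_substrate"]
        assert ad.area_density(0, geom) == 0.0
        assert ad.area_density(5, geom) == pytest.approx(5 / 58.9, abs=1e-4)
        assert ad.area_density(10, geom) == pytest.approx(2 * ad.area_density(5, geom))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ad.area_density(-1, ad.DEFAULT_GEOMETRIES["sweep_net"])


class TestBerlese:
    def test_hand_chain(self):
        # 10 arthropods in 1 of 2 kg, box volume 0.1 m^3, plant volume
        # density 0.05 m^3/m^2 -> 200/m^3 x 0.05 = 10/m^2
        assert ad.berlese_density(10, 1.0, 2.0, 0.1, 0.05) == pytest.approx(10.0)

    def test_full_subsample_no_rescaling(self):
        assert ad.berlese_density(6, 2.0, 2.0, 0.1, 0.05) == pytest.approx(
            6 / 0.1 * 0.05
        )

    def test_zero_transect_volume_and_errors(self):
        assert ad.berlese_density(10, 1.0, 2.0, 0.1, 0.0) == 0.0
        with pytest.raises(ValueError):
            ad.berlese_density(1, 0.0, 2.0, 0.1, 0.05)
        with pytest.raises(ValueError):
            ad.berlese_density(1, 3.0, 2.0, 0.1, 0.05)  # subsample > sample


class TestFogging:
    def test_hand_value(self):
        # 9 on 4.5 m^2 tarp, 1000 m^2 live-tree cover -> 2000 per site
        assert ad.fogging_density(9, 4.5, "live_tree", {"live_tree": 1000.0}) == pytest.approx(2000.0)

    def test_zero_cover_and_pooled_tarps(self):
        assert ad.fogging_density(9, 4.5, "live_tree", {"live_tree": 0.0}) == 0.0
        one = ad.fogging_density(4, 2.25, "shrub", {"shrub": 500.0})
        pooled = ad.fogging_density(8, 4.5, "shrub", {"shrub": 500.0})
        assert pooled == pytest.approx(one)

    def test_unknown_habitat_errors(self):
        with pytest.raises(KeyError):
            ad.fogging_density(1, 4.5, "dead_tree", {"live_tree": 10.0})


def _node(nid, order="Lepidoptera", mass=1.0):
    sp, stage = nid.rsplit(".", 1)
    return TaxonStage(
        node_id=nid, species_id=sp, stage=stage, node_class="consumer_stage",
        taxonomy=Taxonomy(kingdom="Animalia", order=order), body_mass_g=mass,
        habitat=frozenset({"aerial"}),
    )


class TestBlacklightAnalog:
    def _setup(self, counts):
        registry = NodeRegistry(
            [_node("t.adult", mass=1.0), _node("a.adult", mass=1.2),
             _node("far.adult", order="Coleoptera", mass=1.0)]
        )
        bl = pd.DataFrame(counts)
        dens = pd.DataFrame([
            {"node_id": "a.adult", "density": 1.0},
            {"node_id": "far.adult", "density": 9.0},
        ])
        return registry, bl, dens

    def test_ratio_arithmetic(self):
        registry, bl, dens = self._setup(
            [{"node_id": "t.adult", "site": s, "count": 5} for s in "xy"]
            + [{"node_id": "a.adult", "site": s, "count": 10} for s in "xy"]
        )
        d, analog = ad.blacklight_analog_density(
            "t.adult", [registry["a.adult"], registry["far.adult"]], bl, dens, registry
        )
        assert analog == "a.adult"  # same order beats same size
        assert d == pytest.approx(0.5)

    def test_identical_counts_give_analog_density(self):
        registry, bl, dens = self._setup(
            [{"node_id": "t.adult", "site": "x", "count": 7},
             {"node_id": "a.adult", "site": "x", "count": 7}]
        )
        d, _ = ad.blacklight_analog_density(
            "t.adult", [registry["a.adult"]], bl, dens, registry
        )
        assert d == pytest.approx(1.0)

    def test_mean_ratio_over_sites(self):
        registry, bl, dens = self._setup(
            [{"node_id": "t.adult", "site": "x", "count": 1},
             {"node_id": "a.adult", "site": "x", "count": 2},
             {"node_id": "t.adult", "site": "y", "count": 3},
             {"node_id": "a.adult", "site": "y", "count": 2}]
        )
        d, _ = ad.blacklight_analog_density(
            "t.adult", [registry["a.adult"]], bl, dens, registry
        )
        assert d == pytest.approx(1.0)  # mean of 0.5 and 1.5

    def test_no_candidate_flags_no_density(self):
        registry, bl, dens = self._setup(
            [{"node_id": "t.adult", "site": "x", "count": 5}]
        )
        d, analog = ad.blacklight_analog_density("t.adult", [], bl, dens, registry)
        assert d is None and analog is None


class TestLarvalPartitioning:
    def test_proportional_split(self):
        adults = pd.DataFrame(
            [{"species_id": "m1", "taxon_bin": "Lepidoptera", "density": 2.0},
             {"species_id": "m2", "taxon_bin": "Lepidoptera", "density": 1.0}]
        )
        out = ad.partition_larvae(12.0, "Lepidoptera", adults)
        split = dict(zip(out["species_id"], out["larval_density"]))
        assert split == pytest.approx({"m1": 8.0, "m2": 4.0})

    def test_single_adult_and_eligibility(self):
        adults = pd.DataFrame(
            [{"species_id": "m1", "taxon_bin": "Lepidoptera", "density": 2.0},
             {"species_id": "m2", "taxon_bin": "Lepidoptera", "density": 1.0}]
        )
        out = ad.partition_larvae(
            6.0, "Lepidoptera", adults, observed_larval_species=["m2"]
        )
        assert out["species_id"].tolist() == ["m1"]
        assert out["larval_density"].iloc[0] == pytest.approx(6.0)

    def test_no_eligible_adults_flagged(self):
        out = ad.partition_larvae(5.0, "Coleoptera", pd.DataFrame(
            columns=["species_id", "taxon_bin", "density"]))
        assert out["flag"].iloc[0] == "unassigned"
        assert out["larval_density"].iloc[0] == pytest.approx(5.0)

    @given(
        pooled=st.floats(0.0, 100.0),
        densities=st.lists(st.floats(0.01, 50.0), min_size=1, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation(self, pooled, densities):
        adults = pd.DataFrame(
            [{"species_id": f"s{i}", "taxon_bin": "b", "density": d}
             for i, d in enumerate(densities)]
        )
        out = ad.partition_larvae(pooled, "b", adults)
        assert out["larval_density"].sum() == pytest.approx(pooled, rel=1e-9, abs=1e-12)


class TestAbundanceConversions:
    def test_home_range_and_grid_division(self):
        assert ad.abundance_to_density(3.0, home_range_ha=1.5) == pytest.approx(2.0)
        # 8.1 individuals on the 8,100 m^2 grid = 10 per ha
        assert ad.abundance_to_density(8.1, area_m2=8100.0) == pytest.approx(10.0)
        assert ad.abundance_to_density(0.0, area_m2=8100.0) == 0.0

    def test_exactly_one_divisor(self):
        with pytest.raises(ValueError):
            ad.abundance_to_density(1.0)
        with pytest.raises(ValueError):
            ad.abundance_to_density(1.0, area_m2=1.0, home_range_ha=1.0)

    def test_seasonal_correction(self):
        annual = ad.HomeRange("puma", 300.0, "annual")
        assert ad.seasonal_home_range(annual).area_ha == pytest.approx(300.0 * 0.67)
        seasonal = ad.HomeRange("puma", 200.0, "seasonal")
        assert ad.seasonal_home_range(seasonal) is seasonal

    def test_weighted_mean(self):
        assert ad.weighted_mean([2.0, 4.0], [1.0, 1.0]) == pytest.approx(3.0)
        assert ad.weighted_mean([2.0, 4.0], [3.0, 1.0]) == pytest.approx(2.5)
        assert ad.weighted_mean([7.0]) == pytest.approx(7.0)
        assert ad.weighted_mean([2.0, 4.0], [None, None]) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            ad.weighted_mean([])

    def test_mean_home_range_applies_correction_then_weights(self):
        ranges = [
            ad.HomeRange("x", 100.0, "annual", weight=1.0),   # -> 67 ha
            ad.HomeRange("x", 50.0, "seasonal", weight=3.0),
        ]
        assert ad.mean_home_range(ranges) == pytest.approx((67.0 + 150.0) / 4.0)


class TestGroupPartitioning:
    def test_proportional_and_conserving(self):
        out = ad.partition_group_density(10.0, {"A": 0.5, "B": 0.5})
        assert out == pytest.approx({"A": 5.0, "B": 5.0})
        assert ad.partition_group_density(7.0, {"A": 1.0}) == pytest.approx({"A": 7.0})

    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=6),
           st.floats(0.0, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_random_conservation(self, raw, total_density):
        total = sum(raw)
        props = {f"s{i}": v / total for i, v in enumerate(raw)}
        out = ad.partition_group_density(total_density, props)
        assert sum(out.values()) == pytest.approx(total_density, rel=1e-9, abs=1e-12)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            ad.partition_group_density(1.0, {"A": 0.7, "B": 0.7})


class TestFixedZeros:
    def _table(self):
        return pd.DataFrame(
            [{"node_id": "woodrat.adult", "treatment": "high", "density": 2.0, "se": 0.5},
             {"node_id": "woodrat.adult", "treatment": "unburned", "density": 3.0, "se": 0.4}]
        )

    def test_override_and_idempotence(self):
        out = ad.fixed_zero_densities(self._table(), [("woodrat.adult", "high")])
        row = out[out["treatment"] == "high"].iloc[0]
        assert row["density"] == 0.0 and row["provenance"] == "fixed_zero"
        assert out[out["treatment"] == "unburned"]["density"].iloc[0] == 3.0
        again = ad.fixed_zero_densities(out, [("woodrat.adult", "high")])
        pd.testing.assert_frame_equal(out, again)

    def test_no_rules_is_noop_and_unknown_errors(self):
        out = ad.fixed_zero_densities(self._table(), [])
        assert (out["density"] == self._table()["density"]).all()
        with pytest.raises(KeyError):
            ad.fixed_zero_densities(self._table(), [("ghost.adult", "high")])


def test_unit_mixing_raises():
    a = pd.DataFrame([{"density": 1.0, "unit": "ind/m2"}])
    b = pd.DataFrame([{"density": 1.0, "unit": "ind/ha"}])
    with pytest.raises(ad.UnitMismatchError):
        ad.check_units([a, b])
    assert ad.check_units([a, a]) == "ind/m2"
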