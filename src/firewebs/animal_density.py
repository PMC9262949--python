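"""Convert method-specific animal survey tables into per-node densities.

Every estimator here is a deterministic post-processing conversion: counts
over a known sampled area, Berlese subsample scaling, canopy-fog tarp
scaling, black-light analog ratios, larval partitioning among adults,
abundance-to-density division by grid area or home range, proportional
group partitioning, and weighted literature means.  Hierarchical abundance
models (spatial capture-recapture, N-mixture, Royle-Nichols, removal) run
upstream; their outputs arrive as abundance tables.

Densities carry explicit unit tags (``ind/m2`` for invertebrates,
``ind/ha`` for vertebrates); mixing tags raises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import NodeRegistry, TaxonStage

M2_PER_HA = 10_000.0

#: sampled areas per site (m^2) printed protocol geometry
DEFAULT_GEOMETRIES: dict[str, "MethodGeometry"] = {}


@dataclass(frozen=True)
class MethodGeometry:
    method: str
    sampled_area_m2: float
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.sampled_area_m2 <= 0:
            raise ValueError(f"{self.method}: sampled area must be positive")


for _name, _area, _reps in (
    # six 10-cm cores: 6 * pi * 0.05^2 = 0.0471 m^2
    ("soil_cores", 6 * math.pi * 0.05**2, 6),
    # three 5-m-diameter cylinders: 3 * pi * 2.5^2 = 58.9 m^2
    ("hard_substrate", 3 * math.pi * 2.5**2, 3),
    ("sweep_net", 3 * math.pi * 2.5**2, 3),
    # twenty 1-m^2 ground-cover quadrats
    ("ground_cover", 20.0, 20),
    # three 1 x 0.5 m box quadrats, 0.25 m^2 footprint each
    ("box_quadrat", 0.75, 3),
    # 90 x 90 m live-trapping / reptile-search grid
    ("small_mammal_grid", 8_100.0, 1),
    ("reptile_grid", 8_100.0, 1),
    # two point-count stations; the protocol's printed area
    ("bird_point_count", 15_708.0, 2),
    # two parallel 50-m transects, 15-m band (trees) / 5-m band (shrubs)
    ("tree_transect", 1_500.0, 2),
    ("shrub_transect", 500.0, 2),
):
    DEFAULT_GEOMETRIES[_name] = MethodGeometry(_name, _area, _reps)


@dataclass(frozen=True)
class HomeRange:
    species_id: str
    area_ha: float
    period: str  # seasonal | annual
    source: str = ""
    weight: float | None = None  # study sample size for weighted averaging

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError("home range must be positive")
        if self.period not in ("seasonal", "annual"):
            raise ValueError(f"unknown period {self.period!r}")


class UnitMismatchError(ValueError):
    """Raised when densities with different unit tags are combined."""


def check_units(frames: Iterable[pd.DataFrame]) -> str:
    units: set[str] = set()
    for frame in frames:
        if "unit" in frame.columns and len(frame):
            units.update(frame["unit"].unique())
    if len(units) > 1:
        raise UnitMismatchError(f"mixed density units: {sorted(units)}")
    return units.pop() if units else ""


# ----------------------------------------------------------- core estimators


def area_density(count: float, geometry: MethodGeometry) -> float:
    """Density (individuals/m^2) as the quotient of counts and sampled area."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / geometry.sampled_area_m2


def berlese_density(
    count: float,
    subsample_mass_kg: float,
    box_plant_mass_kg: float,
    box_plant_volume_m3: float,
    transect_volume_density_m3_per_m2: float,
) -> float:
    """Arthropods per m^2 from Berlese extractions of box-quadrat plants.

    Counts from the processed subsample are scaled to the full box plant
    sample by mass, divided by the box plant volume to an
    arthropods-per-m^3-of-plant ratio, then multiplied by the plant volume
    per unit ground area estimated from transects.
    """
    if subsample_mass_kg > box_plant_mass_kg + 1e-12:
        raise ValueError("subsample mass exceeds the full box sample")
    if subsample_mass_kg <= 0:
        if count > 0:
            raise ValueError("non-zero count with zero subsample mass")
        return 0.0
    if box_plant_volume_m3 <= 0:
        raise ValueError("box plant volume must be positive")
    per_m3 = count * (box_plant_mass_kg / subsample_mass_kg) / box_plant_volume_m3
    return per_m3 * transect_volume_density_m3_per_m2


def fogging_density(
    tarp_count: float,
    tarp_area_m2: float,
    habitat_type: str,
    habitat_cover_m2: Mapping[str, float],
) -> float:
    """Individuals per site from canopy-fog tarp counts.

    Per-tarp density (count / tarp area) scaled by the total area the
    fogged habitat type (live tree, dead tree, shrub) covers at the site.
    """
    if tarp_area_m2 <= 0:
        raise ValueError("tarp area must be positive")
    if habitat_type not in habitat_cover_m2:
        raise KeyError(f"habitat type {habitat_type!r} absent from cover table")
    return tarp_count / tarp_area_m2 * habitat_cover_m2[habitat_type]


def blacklight_analog_density(
    target_id: str,
    candidates: Sequence[TaxonStage],
    blacklight_counts: pd.DataFrame,
    absolute_densities: pd.DataFrame,
    registry: NodeRegistry,
) -> tuple[float | None, str | None]:
    """Absolute density for a black-light-only node via an ecological analog.

    Candidates must share sites with the target in the black-light table and
    have an absolute density.  The analog is the candidate with the deepest
    shared taxonomy, ties broken by smallest |log body-mass difference|,
    then lexicographic node id.  Density = analog absolute density x mean
    over co-occurring sites of (target count / analog count).  Returns
    (None, None) when no candidate qualifies — the node keeps its place in
    the web without biomass.
    """
    target = registry[target_id]
    bl = blacklight_counts
    target_sites = set(bl.loc[bl["node_id"] == target_id, "site"])
    dens_map = dict(zip(absolute_densities["node_id"], absolute_densities["density"]))

    def sort_key(c: TaxonStage):
        depth = target.taxonomy.shared_rank_depth(c.taxonomy)
        if target.body_mass_g and c.body_mass_g:
            size_gap = abs(math.log(c.body_mass_g) - math.log(target.body_mass_g))
        else:
            size_gap = math.inf
        return (-depth, size_gap, c.node_id)

    for cand in sorted(candidates, key=sort_key):
        if cand.node_id == target_id or cand.node_id not in dens_map:
            continue
        cand_rows = bl[bl["node_id"] == cand.node_id]
        shared = target_sites & set(cand_rows["site"])
        ratios = []
        for site in sorted(shared):
            t = float(bl.loc[(bl["node_id"] == target_id) & (bl["site"] == site), "count"].sum())
            a = float(cand_rows.loc[cand_rows["site"] == site, "count"].sum())
            if a > 0:
                ratios.append(t / a)
        if ratios:
            return dens_map[cand.node_id] * float(np.mean(ratios)), cand.node_id
    return None, None


def partition_larvae(
    pooled_density: float,
    larval_bin: str,
    adults: pd.DataFrame,
    *,
    observed_larval_species: Iterable[str] = (),
    resources_present: bool = True,
) -> pd.DataFrame:
    """Split a pooled larval density among eligible adults by relative abundance.

    Adults are eligible if they belong to the larval bin's taxonomic rank,
    have no observed larval stage of their own, and larval resources are
    present in the treatment.  The split conserves the pooled total; when no
    adult qualifies the density is retained on a flagged unassigned node.

    ``adults`` columns: species_id, taxon_bin, density.
    """
    if pooled_density < 0:
        raise ValueError("pooled density must be non-negative")
    observed = set(observed_larval_species)
    eligible = adults[
        (adults["taxon_bin"] == larval_bin)
        & (~adults["species_id"].isin(observed))
        & (adults["density"] > 0)
    ]
    if not resources_present or eligible.empty:
        return pd.DataFrame(
            [{"species_id": f"unassigned_{larval_bin}", "larval_density": pooled_density,
              "flag": "unassigned"}]
        )
    total = float(eligible["density"].sum())
    rows = [
        {"species_id": r["species_id"],
         "larval_density": pooled_density * float(r["density"]) / total,
         "flag": ""}
        for _, r in eligible.iterrows()
    ]
    return pd.DataFrame(rows, columns=["species_id", "larval_density", "flag"])


def abundance_to_density(
    abundance: float,
    *,
    area_m2: float | None = None,
    home_range_ha: float | None = None,
) -> float:
    """Abundance to density on a per-hectare basis.

    Grid-based estimates divide by the sampled area; camera/acoustic
    estimates divide by the species' average home range.
    """
    if abundance < 0:
        raise ValueError("abundance must be non-negative")
    if (area_m2 is None) == (home_range_ha is None):
        raise ValueError("provide exactly one of area_m2 or home_range_ha")
    if area_m2 is not None:
        if area_m2 <= 0:
            raise ValueError("area must be positive")
        return abundance / area_m2 * M2_PER_HA
    if home_range_ha <= 0:
        raise ValueError("home range must be positive")
    return abundance / home_range_ha


def partition_group_density(
    group_density: float,
    proportions: Mapping[str, float],
    tolerance: float = 1e-6,
) -> dict[str, float]:
    """Split a shared-model group density by individual proportions.

    Used for chipmunks trapped as one pooled species and for snakes per
    burn category: species density = group density x its share of captured
    individuals.  Proportions must sum to 1 within tolerance.
    """
    if any(p < 0 for p in proportions.values()):
        raise ValueError("negative proportion")
    total = sum(proportions.values())
    if not (1 - tolerance) <= total <= (1 + tolerance):
        raise ValueError(f"proportions sum to {total}, expected 1")
    return {sp: group_density * p / total for sp, p in proportions.items()}


ANNUAL_TO_SEASONAL = 0.67


def seasonal_home_range(home_range: HomeRange) -> HomeRange:
    """Approximate a summer/fall home range from an annual one (x 0.67)."""
    if home_range.period == "seasonal":
        return home_range
    return HomeRange(
        species_id=home_range.species_id,
        area_ha=home_range.area_ha * ANNUAL_TO_SEASONAL,
        period="seasonal",
        source=home_range.source,
        weight=home_range.weight,
    )


def weighted_mean(values: Sequence[float], weights: Sequence[float | None] | None = None) -> float:
    """Sample-size-weighted mean across studies; equal weights when missing."""
    if not len(values):
        raise ValueError("no values")
    if weights is None or all(w is None for w in weights):
        w = np.ones(len(values))
    else:
        w = np.array([1.0 if x is None else float(x) for x in weights])
    if (w < 0).any():
        raise ValueError("negative weight")
    if w.sum() == 0:
        raise ValueError("all-zero weights")
    return float(np.average(np.asarray(values, dtype=float), weights=w))


def mean_home_range(ranges: Sequence[HomeRange]) -> float:
    """Weighted mean seasonal home range (ha) across literature studies."""
    seasonal = [seasonal_home_range(r) for r in ranges]
    return weighted_mean([r.area_ha for r in seasonal], [r.weight for r in seasonal])


def fixed_zero_densities(
    densities: pd.DataFrame, rules: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Force species x treatment densities to exact zero (never-caught rule).

    ``rules`` lists (node_id, treatment) pairs; each must reference a node
    present in the table.  Overridden rows get provenance ``fixed_zero``;
    the override is idempotent.
    """
    out = densities.copy()
    if "provenance" not in out.columns:
        out["provenance"] = ""
    known = set(out["node_id"])
    for node_id, treatment in rules:
        if node_id not in known:
            raise KeyError(f"fixed-zero rule references unknown node {node_id!r}")
        mask = (out["node_id"] == node_id) & (out["treatment"] == treatment)
        out.loc[mask, "density"] = 0.0
        out.loc[mask, "se"] = 0.0 if "se" in out.columns else None
        out.loc[mask, "provenance"] = "fixed_zero"
    return out


# ----------------------------------------------------- survey-table pipeline


def estimate_method_densities(
    surveys: Mapping[str, pd.DataFrame],
    geometries: Mapping[str, MethodGeometry] | None = None,
    detection_scaling: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-node, per-site densities from raw count tables of area-based methods.

    Handles every method whose estimator is count / sampled area (soil
    cores, hard substrate, sweep net, transect counts).  Tables need
    columns node_id, site, treatment, count.  Detection scalings (known
    from calibration, default 1) divide out of the counts.  Returns
    node_id, site, treatment, density, unit, method.
    """
    geometries = dict(DEFAULT_GEOMETRIES if geometries is None else geometries)
    detection_scaling = detection_scaling or {}
    frames = []
    for method, table in sorted(surveys.items()):
        if method not in geometries:
            raise KeyError(f"no geometry for method {method!r}")
        geom = geometries[method]
        det = detection_scaling.get(method, 1.0)
        if not 0 < det <= 1:
            raise ValueError(f"{method}: detection scaling must be in (0, 1]")
        df = table.copy()
        df["density"] = df["count"] / (geom.sampled_area_m2 * det)
        df["unit"] = "ind/m2"
        df["method"] = method
        frames.append(df[["node_id", "site", "treatment", "density", "unit", "method"]])
    if not frames:
        return pd.DataFrame(columns=["node_id", "site", "treatment", "density", "unit", "method"])
    return pd.concat(frames, ignore_index=True)


def treatment_density_summary(per_site: pd.DataFrame) -> pd.DataFrame:
    """Mean density and SE across replicate sites within each treatment."""
    check_units([per_site])
    agg = (
        per_site.groupby(["node_id", "treatment", "unit", "method"], sort=True)["density"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "density", "sem": "se", "count": "n_sites"})
    )
    agg["se"] = agg["se"].fillna(0.0)
    return agg
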