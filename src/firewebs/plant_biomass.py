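"""Plant biomass-density estimation (kg/ha) from transect and quadrat tables.

Covers four estimators:

* tree allometry — above-ground biomass from DBH, tissue-type ratios,
  predicted full height, and the four health/damage categories
  (intact alive, intact dead, damaged alive, damaged dead);
* coarse woody debris — line-intercept frustum volumes converted to
  volume density and then dry-mass density with a weighted specific
  gravity and decay-class correction;
* understory plants — cover x height volumes multiplied by
  mass-to-volume ratios with taxonomic pooling (species -> genus ->
  family -> all) whenever a species has fewer than three measurements;
* proxy-site bootstrap — assigns species identities to individuals
  identified only to a higher rank by resampling the species-abundance
  distribution of randomly drawn unburned proxy sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AREA_PER_HA_M2 = 10_000.0

TISSUES = ("foliage", "coarse_roots", "stem_bark", "stem_wood")

TREE_CATEGORIES = ("intact_alive", "intact_dead", "damaged_alive", "damaged_dead")


# --------------------------------------------------------------------- types


@dataclass(frozen=True)
class TreeRecord:
    site: str
    species_group: str  # allometry key, e.g. "Pinaceae"; family fallback
    dbh_cm: float
    health: str  # healthy | unhealthy | dead
    damaged: bool = False
    measured_height_m: float | None = None

    def __post_init__(self) -> None:
        if self.dbh_cm <= 0:
            raise ValueError("DBH must be positive")
        if self.health not in ("healthy", "unhealthy", "dead"):
            raise ValueError(f"unknown health category {self.health!r}")


@dataclass(frozen=True)
class AllometryParams:
    """Per species group: total-AGB, tissue-ratio and height coefficients.

    ``agb``: (b0, b1) for AGB = exp(b0 + b1 ln DBH), DBH in cm, AGB in kg.
    ``tissue``: tissue -> (b0, b1) for ratio = exp(b0 + b1/DBH).
    ``height``: (b0, b1, b2, b3) for full height (m) as a cubic in ln DBH.
    """

    agb: Mapping[str, tuple[float, float]]
    tissue: Mapping[str, Mapping[str, tuple[float, float]]]
    height: Mapping[str, tuple[float, float, float, float]]
    fallback_group: str = "Pinaceae"

    def _lookup(self, table: Mapping, group: str):
        if group in table:
            return table[group]
        if self.fallback_group in table:
            return table[self.fallback_group]
        raise KeyError(
            f"no allometry parameters for {group!r} and no "
            f"{self.fallback_group!r} fallback"
        )


@dataclass(frozen=True)
class CwdPiece:
    site: str
    small_diameter_cm: float
    large_diameter_cm: float
    length_m: float
    decay_class: int

    def __post_init__(self) -> None:
        if self.length_m < 1.0:
            raise ValueError("pieces shorter than 1 m are excluded by protocol")
        if self.small_diameter_cm > self.large_diameter_cm:
            raise ValueError("small-end diameter exceeds large-end diameter")
        if not 1 <= self.decay_class <= 5:
            raise ValueError("decay class must be 1..5")


@dataclass(frozen=True)
class CwdConstants:
    transect_length_m: float = 100.0
    area_conversion: float = AREA_PER_HA_M2
    specific_gravity: float = 0.382
    # decay-class density corrections; a documented default table, overridable
    decay_correction: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 1.0, 3: 0.85, 4: 0.55, 5: 0.35}
    )

    def __post_init__(self) -> None:
        if self.transect_length_m <= 0:
            raise ValueError("combined transect length must be positive")
        if not 0 < self.specific_gravity <= 1.5:
            raise ValueError("specific gravity outside plausible range")
        if any(not 0 < d <= 1 for d in self.decay_correction.values()):
            raise ValueError("decay corrections must lie in (0, 1]")


@dataclass(frozen=True)
class MassVolumeRatio:
    taxon_id: str
    tissue_type: str
    ratio_kg_per_m3: float
    n_measurements: int
    pooling_level: str  # species | genus | family | all


# ------------------------------------------------------------- tree allometry


def tree_agb(dbh_cm: float, params: AllometryParams, group: str) -> float:
    """Total above-ground biomass (kg): exp(b0 + b1 ln DBH)."""
    if dbh_cm <= 0:
        raise ValueError("DBH must be positive")
    b0, b1 = params._lookup(params.agb, group)
    return math.exp(b0 + b1 * math.log(dbh_cm))


def tissue_ratio(dbh_cm: float, tissue: str, params: AllometryParams, group: str) -> float:
    """Ratio of one tissue's biomass to total AGB: exp(b0 + b1/DBH)."""
    if dbh_cm <= 0:
        raise ValueError("DBH must be positive")
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    b0, b1 = params._lookup(params.tissue, group)[tissue]
    return math.exp(b0 + b1 / dbh_cm)


def tree_full_height(dbh_cm: float, params: AllometryParams, group: str) -> float:
    """Predicted undamaged height (m): exp of a cubic polynomial in ln DBH."""
    if dbh_cm <= 0:
        raise ValueError("DBH must be positive")
    b0, b1, b2, b3 = params._lookup(params.height, group)
    x = math.log(dbh_cm)
    return math.exp(b0 + b1 * x + b2 * x**2 + b3 * x**3)


def tree_category(tree: TreeRecord) -> str:
    alive = tree.health != "dead"
    if tree.damaged:
        return "damaged_alive" if alive else "damaged_dead"
    return "intact_alive" if alive else "intact_dead"


def tree_biomass(tree: TreeRecord, params: AllometryParams) -> tuple[float, str]:
    """Individual-tree biomass (kg) and its health/damage category.

    Intact alive: AGB + roots.  Intact dead: AGB - foliage + roots.
    Damaged: each tissue biomass scaled by the proportion of the tree
    remaining (measured height / predicted full height, clipped to [0, 1]),
    summed; foliage dropped if dead.  Trees measured taller than their
    predicted height are treated as intact.
    """
    agb = tree_agb(tree.dbh_cm, params, tree.species_group)
    ratios = {
        t: tissue_ratio(tree.dbh_cm, t, params, tree.species_group) for t in TISSUES
    }
    category = tree_category(tree)
    if category.startswith("damaged"):
        if tree.measured_height_m is None:
            raise ValueError(f"damaged tree at {tree.site} has no measured height")
        full = tree_full_height(tree.dbh_cm, params, tree.species_group)
        remaining = min(max(tree.measured_height_m / full, 0.0), 1.0)
        if remaining >= 1.0:
            category = "intact_alive" if tree.health != "dead" else "intact_dead"
    if category == "intact_alive":
        return agb * (1.0 + ratios["coarse_roots"]), "intact_alive"
    if category == "intact_dead":
        return agb * (1.0 - ratios["foliage"] + ratios["coarse_roots"]), "intact_dead"
    tissues = list(TISSUES)
    if category == "damaged_dead":
        tissues.remove("foliage")
    total = sum(agb * ratios[t] * remaining for t in tissues)
    return total, category


def tree_stand_density(
    trees: Iterable[TreeRecord],
    params: AllometryParams,
    sampled_area_m2: float = 1500.0,
) -> pd.DataFrame:
    """Per-site tree biomass density (kg/ha) summed over individuals."""
    if sampled_area_m2 <= 0:
        raise ValueError("sampled area must be positive")
    totals: dict[str, float] = {}
    for tree in trees:
        mass, _ = tree_biomass(tree, params)
        totals[tree.site] = totals.get(tree.site, 0.0) + mass
    rows = [
        {"site": site, "biomass_kg_ha": total / sampled_area_m2 * AREA_PER_HA_M2}
        for site, total in sorted(totals.items())
    ]
    return pd.DataFrame(rows, columns=["site", "biomass_kg_ha"])


# --------------------------------------------------------- coarse woody debris


def weighted_specific_gravity(components: Sequence[tuple[float, float]]) -> float:
    """Community specific gravity: sum of SpG_i x relative abundance_i."""
    if not components:
        raise ValueError("no components")
    weights = [w for _, w in components]
    if any(w < 0 for w in weights):
        raise ValueError("negative weight")
    if sum(weights) == 0:
        raise ValueError("all-zero weights")
    if sum(weights) > 1 + 1e-6:
        raise ValueError("relative abundances exceed 1")
    return sum(spg * w for spg, w in components)


def cwd_piece_volume(piece: CwdPiece) -> float:
    """Frustum volume (m^3): (pi/8)(D_S^2 + D_L^2) l / 10,000, diameters in cm."""
    if piece.length_m <= 0:
        raise ValueError("length must be positive")
    return (
        (math.pi / 8.0)
        * (piece.small_diameter_cm**2 + piece.large_diameter_cm**2)
        * piece.length_m
        / 10_000.0
    )


def cwd_volume_density(volume_m3: float, piece_length_m: float, consts: CwdConstants) -> float:
    """Line-intercept volume density (m^3/ha) for one piece."""
    if piece_length_m <= 0:
        raise ValueError("piece length must be positive")
    if consts.transect_length_m <= 0:
        raise ValueError("transect length must be positive")
    return (
        (math.pi / (2.0 * consts.transect_length_m))
        * (volume_m3 / piece_length_m)
        * consts.area_conversion
    )


def cwd_mass_density(vol_density_m3_ha: float, specific_gravity: float, decay: float) -> float:
    """Dry-weight biomass density (kg/ha): m^3/ha x 1000 kg/m^3 x SpG x D."""
    if vol_density_m3_ha < 0 or specific_gravity < 0 or decay < 0:
        raise ValueError("inputs must be non-negative")
    return vol_density_m3_ha * 1000.0 * specific_gravity * decay


def cwd_site_mass_density(pieces: Iterable[CwdPiece], consts: CwdConstants) -> pd.DataFrame:
    """Per-site CWD dry-mass density (kg/ha), summed over intersected pieces."""
    totals: dict[str, float] = {}
    for piece in pieces:
        if piece.decay_class not in consts.decay_correction:
            raise KeyError(f"no decay correction for class {piece.decay_class}")
        vd = cwd_volume_density(cwd_piece_volume(piece), piece.length_m, consts)
        md = cwd_mass_density(vd, consts.specific_gravity, consts.decay_correction[piece.decay_class])
        totals[piece.site] = totals.get(piece.site, 0.0) + md
    rows = [{"site": s, "cwd_kg_ha": v} for s, v in sorted(totals.items())]
    return pd.DataFrame(rows, columns=["site", "cwd_kg_ha"])


# ----------------------------------------------------------- understory plants


def mass_to_volume_ratios(box_samples: pd.DataFrame) -> list[MassVolumeRatio]:
    """Taxon mass-to-volume ratios with upward pooling for sparse species.

    ``box_samples`` columns: species_id, genus, family, tissue_type,
    mass_kg, volume_m3.  A species with at least three measurements keeps
    its own mean ratio; otherwise measurements are pooled over all members
    of the next rank up (genus, then family, then the whole table) and the
    pooling level recorded.
    """
    if box_samples.empty:
        return []
    df = box_samples.copy()
    if (df["mass_kg"] <= 0).any() or (df["volume_m3"] <= 0).any():
        raise ValueError("box samples need positive mass and volume")
    df["ratio"] = df["mass_kg"] / df["volume_m3"]

    out: list[MassVolumeRatio] = []
    for (species, tissue), grp in df.groupby(["species_id", "tissue_type"], sort=True):
        same_tissue = df[df["tissue_type"] == tissue]
        if len(grp) >= 3:
            pool, level = grp, "species"
        else:
            genus, family = grp["genus"].iloc[0], grp["family"].iloc[0]
            genus_pool = same_tissue[same_tissue["genus"] == genus]
            family_pool = same_tissue[same_tissue["family"] == family]
            if pd.notna(genus) and len(genus_pool) >= 3:
                pool, level = genus_pool, "genus"
            elif pd.notna(family) and len(family_pool) >= 3:
                pool, level = family_pool, "family"
            elif pd.notna(genus) and len(genus_pool) > len(grp):
                pool, level = genus_pool, "genus"
            elif pd.notna(family) and len(family_pool) > len(grp):
                pool, level = family_pool, "family"
            else:
                pool, level = same_tissue, "all"
        out.append(
            MassVolumeRatio(
                taxon_id=species,
                tissue_type=tissue,
                ratio_kg_per_m3=float(pool["ratio"].mean()),
                n_measurements=int(len(pool)),
                pooling_level=level,
            )
        )
    return out


def understory_biomass(
    cover_transects: pd.DataFrame,
    ratios: Iterable[MassVolumeRatio],
    sampled_area_m2: float = 20.0,
) -> pd.DataFrame:
    """Understory biomass (kg/ha) per taxon per site from cover x height volumes.

    ``cover_transects`` columns: site, species_id, tissue_type, cover_fraction,
    height_m, quadrat_area_m2.  Volume per quadrat = cover x height x quadrat
    area; summed per site, divided by the pooled sampled area and scaled by
    the taxon's mass-to-volume ratio to kg/ha.
    """
    if sampled_area_m2 <= 0:
        raise ValueError("sampled area must be positive")
    bad = cover_transects[
        (cover_transects["cover_fraction"] < 0) | (cover_transects["cover_fraction"] > 1)
    ]
    if len(bad):
        raise ValueError("cover fractions must lie in [0, 1]")
    if (cover_transects["height_m"] < 0).any():
        raise ValueError("heights must be non-negative")

    ratio_map = {(r.taxon_id, r.tissue_type): r.ratio_kg_per_m3 for r in ratios}
    df = cover_transects.copy()
    df["volume_m3"] = df["cover_fraction"] * df["height_m"] * df["quadrat_area_m2"]
    grouped = df.groupby(["site", "species_id", "tissue_type"], sort=True)["volume_m3"].sum()

    missing = sorted(
        {key[1:] for key in grouped.index if key[1:] not in ratio_map and grouped[key] > 0}
    )
    if missing:
        raise ValueError(f"taxa with no mass-to-volume ratio after pooling: {missing}")

    rows = []
    for (site, species, tissue), volume in grouped.items():
        ratio = ratio_map.get((species, tissue), 0.0)
        kg_per_m2 = volume / sampled_area_m2 * ratio
        rows.append(
            {
                "site": site,
                "species_id": species,
                "tissue_type": tissue,
                "biomass_kg_ha": kg_per_m2 * AREA_PER_HA_M2,
            }
        )
    return pd.DataFrame(rows, columns=["site", "species_id", "tissue_type", "biomass_kg_ha"])


# ------------------------------------------------------- proxy-site bootstrap


def assign_proxy_species(
    focal_unidentified: Mapping[str, int],
    proxy_sites: Mapping[str, Mapping[str, Mapping[str, int]]],
    reps: int = 999,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Bootstrap species identities for higher-rank-only plant records.

    ``focal_unidentified`` maps higher taxon -> number of unidentified
    individuals.  ``proxy_sites`` maps unburned site -> higher taxon ->
    {species: abundance}.  Each rep draws one proxy site uniformly, then
    assigns identities multinomially from that site's abundance distribution
    of the focal taxon.  Returns per-species mean counts and bootstrap SE.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    site_ids = sorted(proxy_sites)
    rows = []
    for taxon, n_unidentified in sorted(focal_unidentified.items()):
        eligible = [
            s for s in site_ids if sum(proxy_sites[s].get(taxon, {}).values()) > 0
        ]
        if not eligible:
            raise ValueError(f"focal taxon {taxon!r} absent from all proxy sites")
        species_union = sorted(
            {sp for s in eligible for sp in proxy_sites[s].get(taxon, {})}
        )
        draws = np.zeros((reps, len(species_union)))
        for i in range(reps):
            site = eligible[rng.integers(len(eligible))]
            dist = proxy_sites[site].get(taxon, {})
            labels = sorted(dist)
            probs = np.array([dist[sp] for sp in labels], dtype=float)
            probs /= probs.sum()
            counts = rng.multinomial(n_unidentified, probs)
            for label, count in zip(labels, counts):
                draws[i, species_union.index(label)] = count
        means = draws.mean(axis=0)
        ses = draws.std(axis=0, ddof=1) if reps > 1 else np.zeros(len(species_union))
        for sp, mean, se in zip(species_union, means, ses):
            rows.append(
                {"higher_taxon": taxon, "species_id": sp, "mean_count": float(mean),
                 "bootstrap_se": float(se)}
            )
    return pd.DataFrame(rows, columns=["higher_taxon", "species_id", "mean_count", "bootstrap_se"])


# --------------------------------------------------------- treatment summary


def treatment_mean_se(per_site: pd.DataFrame, value_col: str, site_treatments: Mapping[str, str]) -> pd.DataFrame:
    """Mean and SE of a per-site quantity across the replicate sites per treatment."""
    df = per_site.copy()
    df["treatment"] = df["site"].map(site_treatments)
    if df["treatment"].isna().any():
        unknown = sorted(df.loc[df["treatment"].isna(), "site"].unique())
        raise KeyError(f"sites with no treatment assignment: {unknown}")
    group_cols = [c for c in ("species_id", "tissue_type") if c in df.columns]
    agg = (
        df.groupby(["treatment", *group_cols], sort=True)[value_col]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": value_col, "sem": "se", "count": "n_sites"})
    )
    return agg
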