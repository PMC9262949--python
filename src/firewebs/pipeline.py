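"""End-to-end orchestration: simulate -> biomass/density -> registry ->
links -> webs -> validation, as staged functions with file contracts.

Each stage reads its inputs from (and writes its outputs to) a run
directory, so stages can be toggled or rerun independently; the CLI in
:mod:`firewebs.cli` is a thin wrapper over these functions.  A manifest
records the seed, package version and SHA-256 digests of every artifact,
so a rerun with the same seed is verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import animal_density as ad
from . import plant_biomass as pb
from .diversity import grouped_validation
from .links import assign_links, build_encounter_groups, rules_from_yaml, rules_to_yaml
from .registry import NodeRegistry, attach_biomass, node_id_for
from .synthetic import (
    SITE_AREA_M2,
    SimConfig,
    SurveyBundle,
    gen_community,
    gen_rules,
    gen_surveys,
)
from .webs import assemble_web, export_web, web_summary

SURVEY_DIR = "surveys"

VERT_GUILDS = ("small_mammal", "insectivorous_bird", "bat", "reptile", "large_mammal")


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    sim: SimConfig | None = None
    stages: tuple[str, ...] = (
        "simulate", "biomass", "density", "registry", "links", "assemble", "validate"
    )

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)


def validate_config(config: RunConfig) -> list[str]:
    """Schema/referential checks; returns a list of failures (empty = valid)."""
    failures: list[str] = []
    known = ("simulate", "biomass", "density", "registry", "links", "assemble", "validate")
    for stage in config.stages:
        if stage not in known:
            failures.append(f"unknown stage {stage!r}")
    try:
        SimConfig(**{**config.sim.__dict__}) if config.sim else None
    except ValueError as exc:
        failures.append(f"simulation config invalid: {exc}")
    if "simulate" not in config.stages:
        for artifact in ("registry.csv", "rules.yaml", f"{SURVEY_DIR}"):
            if not (config.out_dir / artifact).exists():
                failures.append(f"stage inputs missing: {artifact}")
    return failures


# ------------------------------------------------------------------ stages


def stage_simulate(config: RunConfig) -> SurveyBundle:
    out = config.out_dir
    (out / SURVEY_DIR).mkdir(parents=True, exist_ok=True)
    registry, truth = gen_community(config.sim)
    bundle = gen_surveys(registry, truth, config.sim)
    rules = gen_rules(registry, config.sim)

    registry.to_csv(out / "registry.csv")
    (out / "rules.yaml").write_text(rules_to_yaml(rules))
    for method, table in sorted(bundle.tables.items()):
        table.to_csv(out / SURVEY_DIR / f"{method}.csv", index=False)
    bundle.habitat_cover.to_csv(out / "habitat_cover.csv", index=False)
    pd.DataFrame(
        [{"site": s, "treatment": t} for s, t in bundle.site_treatments.items()]
    ).to_csv(out / "sites.csv", index=False)
    # ground truth, for transparency and downstream recovery checks
    truth_rows = [
        {"node_id": nid, "treatment": t, "density": d, "unit": truth.unit[nid]}
        for nid, per_t in sorted(truth.density.items())
        for t, d in per_t.items()
    ]
    pd.DataFrame(truth_rows).to_csv(out / "truth_densities.csv", index=False)
    return bundle


def _load_surveys(out: Path) -> dict[str, pd.DataFrame]:
    return {
        p.stem: pd.read_csv(p) for p in sorted((out / SURVEY_DIR).glob("*.csv"))
    }


def _site_treatments(out: Path) -> dict[str, str]:
    df = pd.read_csv(out / "sites.csv")
    return dict(zip(df["site"], df["treatment"]))


def stage_biomass(config: RunConfig) -> pd.DataFrame:
    """Plant biomass densities (kg/ha): trees, CWD, understory."""
    out = config.out_dir
    surveys = _load_surveys(out)
    sites = _site_treatments(out)
    frames = []

    trees = surveys["tree_transect"]
    records = [
        pb.TreeRecord(
            site=r["site"], species_group=r["species_group"], dbh_cm=r["dbh_cm"],
            health=r["health"], damaged=bool(r["damaged"]),
            measured_height_m=None if pd.isna(r["measured_height_m"]) else r["measured_height_m"],
        )
        for _, r in trees.iterrows()
    ]
    per_site = pb.tree_stand_density(records, default_allometry())
    per_site["component"] = "trees"
    frames.append(per_site.rename(columns={"biomass_kg_ha": "kg_ha"}))

    cwd = surveys["cwd_transect"]
    pieces = [
        pb.CwdPiece(
            site=r["site"], small_diameter_cm=r["small_diameter_cm"],
            large_diameter_cm=r["large_diameter_cm"], length_m=r["length_m"],
            decay_class=int(r["decay_class"]),
        )
        for _, r in cwd.iterrows()
    ]
    per_site = pb.cwd_site_mass_density(pieces, pb.CwdConstants())
    per_site["component"] = "coarse_woody_debris"
    frames.append(per_site.rename(columns={"cwd_kg_ha": "kg_ha"}))

    ratios = pb.mass_to_volume_ratios(surveys["box_quadrat"])
    under = pb.understory_biomass(surveys["ground_cover"], ratios)
    under = under.groupby("site", as_index=False)["biomass_kg_ha"].sum()
    under["component"] = "understory"
    frames.append(under.rename(columns={"biomass_kg_ha": "kg_ha"}))

    per_site = pd.concat(frames, ignore_index=True)
    per_site["treatment"] = per_site["site"].map(sites)
    per_site.to_csv(out / "plant_biomass_site.csv", index=False)
    summary = (
        per_site.groupby(["component", "treatment"])["kg_ha"]
        .agg(["mean", "sem", "count"]).reset_index()
        .rename(columns={"mean": "kg_ha", "sem": "se", "count": "n_sites"})
    )
    summary.to_csv(out / "plant_biomass_treatment.csv", index=False)
    return summary


def estimate_densities(
    surveys: dict[str, pd.DataFrame],
    registry: NodeRegistry,
    habitat_cover: pd.DataFrame,
    detection_scaling: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-node treatment densities from every survey method.

    Returns columns node_id, treatment, density, se, n_sites, unit, method.
    Invertebrate estimates are ind/m^2, vertebrates ind/ha.
    """
    det = detection_scaling or {}
    area_methods = {
        m: surveys[m][["node_id", "site", "treatment", "count"]]
        for m in ("soil_cores", "hard_substrate", "sweep_net", "vegetation_transect")
        if m in surveys
    }
    geoms = dict(ad.DEFAULT_GEOMETRIES)
    geoms["vegetation_transect"] = ad.MethodGeometry(
        "vegetation_transect", geoms["shrub_transect"].sampled_area_m2, 2
    )
    per_site = ad.estimate_method_densities(area_methods, geoms, det)

    extra_frames = [per_site]
    if "berlese" in surveys:
        b = surveys["berlese"].copy()
        scale = det.get("berlese", 1.0)
        b["density"] = [
            ad.berlese_density(
                r["count"] / scale, r["subsample_mass_kg"], r["box_mass_kg"],
                r["box_volume_m3"], r["transect_volume_density"],
            )
            for _, r in b.iterrows()
        ]
        b["unit"], b["method"] = "ind/m2", "berlese"
        extra_frames.append(b[["node_id", "site", "treatment", "density", "unit", "method"]])

    if "fogging" in surveys and len(surveys["fogging"]):
        f = surveys["fogging"].copy()
        cover = {
            (r["site"], r["habitat_type"]): r["cover_m2"]
            for _, r in habitat_cover.iterrows()
        }
        scale = det.get("fogging", 1.0)
        f["per_site"] = [
            ad.fogging_density(
                r["count"] / scale, r["tarp_area_m2"], r["habitat_type"],
                {r["habitat_type"]: cover[(r["site"], r["habitat_type"])]},
            )
            for _, r in f.iterrows()
        ]
        f["density"] = f["per_site"] / SITE_AREA_M2
        f["unit"], f["method"] = "ind/m2", "fogging"
        extra_frames.append(f[["node_id", "site", "treatment", "density", "unit", "method"]])

    invert_site = pd.concat(extra_frames, ignore_index=True)
    invert_summary = ad.treatment_density_summary(invert_site)

    frames = [invert_summary]

    # vertebrate model-output abundances -> per-ha densities
    if "vertebrate_abundance" in surveys:
        v = surveys["vertebrate_abundance"].copy()
        v["density"] = [
            ad.abundance_to_density(
                r["abundance"],
                area_m2=None if r["basis"] == "home_range" else r["area_m2"],
                home_range_ha=r["home_range_ha"] if r["basis"] == "home_range" else None,
            )
            for _, r in v.iterrows()
        ]
        v["unit"], v["method"] = "ind/ha", "vertebrate_models"
        vert_summary = ad.treatment_density_summary(
            v[["node_id", "site", "treatment", "density", "unit", "method"]]
        )
        frames.append(vert_summary)

    # black-light-only nodes: analog-ratio densities at treatment level
    if "blacklight" in surveys and len(surveys["blacklight"]):
        bl = surveys["blacklight"]
        absolute = invert_summary
        with_abs = set(absolute.loc[absolute["density"] > 0, "node_id"])
        bl_nodes = set(bl.loc[bl["count"] > 0, "node_id"])
        targets = sorted(bl_nodes - with_abs)
        candidates = [registry[nid] for nid in sorted(bl_nodes & with_abs)]
        rows = []
        for treatment, abs_t in absolute.groupby("treatment"):
            bl_t = bl[bl["treatment"] == treatment]
            for target in targets:
                if target not in set(bl_t["node_id"]):
                    continue
                density, analog = ad.blacklight_analog_density(
                    target, candidates, bl_t, abs_t, registry
                )
                if density is not None:
                    se = float(
                        abs_t.loc[abs_t["node_id"] == analog, "se"].iloc[0]
                    ) * (density / max(float(abs_t.loc[abs_t["node_id"] == analog, "density"].iloc[0]), 1e-12))
                    rows.append(
                        {"node_id": target, "treatment": treatment, "unit": "ind/m2",
                         "method": "blacklight_analog", "density": density,
                         "se": se, "n_sites": int(bl_t.loc[bl_t["node_id"] == target, "site"].nunique())}
                    )
        if rows:
            frames.append(pd.DataFrame(rows))

    summary = pd.concat(frames, ignore_index=True)

    # a node measured by several methods keeps the method with the greatest
    # ability to detect it (largest mean density)
    summary = (
        summary.sort_values(["node_id", "treatment", "density"], ascending=[True, True, False])
        .drop_duplicates(["node_id", "treatment"], keep="first")
        .reset_index(drop=True)
    )
    return summary


def partition_pooled_larvae(
    larval_bins: pd.DataFrame, densities: pd.DataFrame, registry: NodeRegistry
) -> pd.DataFrame:
    """Allocate pooled unidentifiable larval densities to species larval nodes."""
    rows = []
    for _, bin_row in larval_bins.iterrows():
        treatment, taxon_bin = bin_row["treatment"], bin_row["taxon_bin"]
        adults = []
        for node in registry:
            if (node.stage == "adult" and node.taxonomy.rank("order") == taxon_bin):
                larva = registry.get(node_id_for(node.species_id, "larva"))
                d = densities[
                    (densities["node_id"] == node.node_id)
                    & (densities["treatment"] == treatment)
                ]
                adults.append(
                    {"species_id": node.species_id, "taxon_bin": taxon_bin,
                     "density": float(d["density"].iloc[0]) if len(d) else 0.0}
                )
        observed_larvae = [
            n.species_id for n in registry if n.stage == "larva" and n.observed
        ]
        split = ad.partition_larvae(
            float(bin_row["pooled_density"]), taxon_bin, pd.DataFrame(adults),
            observed_larval_species=observed_larvae,
        )
        for _, r in split.iterrows():
            if r["flag"] == "unassigned":
                continue
            rows.append(
                {"node_id": node_id_for(r["species_id"], "larva"),
                 "treatment": treatment, "density": float(r["larval_density"]),
                 "se": 0.0, "n_sites": 0, "unit": bin_row.get("unit", "ind/m2"),
                 "method": "larval_partition"}
            )
    return pd.DataFrame(
        rows, columns=["node_id", "treatment", "density", "se", "n_sites", "unit", "method"]
    )


def stage_density(config: RunConfig) -> pd.DataFrame:
    out = config.out_dir
    surveys = _load_surveys(out)
    registry = NodeRegistry.from_csv(out / "registry.csv")
    habitat_cover = pd.read_csv(out / "habitat_cover.csv")
    det = dict(config.sim.detection_scaling) if config.sim else {}
    summary = estimate_densities(surveys, registry, habitat_cover, det)
    if "larval_bins" in surveys:
        partitioned = partition_pooled_larvae(surveys["larval_bins"], summary, registry)
        if len(partitioned):
            summary = pd.concat([summary, partitioned], ignore_index=True)
    # broadcast producer species densities (estimated on the leaf node) to
    # every part node of the species
    extra = []
    for _, r in summary[summary["method"] == "vegetation_transect"].iterrows():
        species = registry[r["node_id"]].species_id
        for node in registry:
            if node.species_id == species and node.node_id != r["node_id"]:
                extra.append({**r.to_dict(), "node_id": node.node_id})
    if extra:
        summary = pd.concat([summary, pd.DataFrame(extra)], ignore_index=True)
        summary = summary.drop_duplicates(["node_id", "treatment"], keep="first")
    summary.to_csv(out / "densities_treatment.csv", index=False)
    return summary


def stage_registry(config: RunConfig) -> pd.DataFrame:
    """Attach biomass densities (mass x density) to observed nodes."""
    out = config.out_dir
    registry = NodeRegistry.from_csv(out / "registry.csv")
    densities = pd.read_csv(out / "densities_treatment.csv")
    # nodes whose density came from pooled-larvae partitioning were
    # physically collected (just unidentifiable) — flag them observed
    partitioned = set(densities.loc[densities["method"] == "larval_partition", "node_id"])
    for nid in partitioned:
        registry.replace_node(replace(registry[nid], observed=True))
    # vertebrates to the common per-m^2 basis at the registry boundary
    densities = densities.copy()
    per_ha = densities["unit"] == "ind/ha"
    densities.loc[per_ha, "density"] = densities.loc[per_ha, "density"] / 1e4
    densities.loc[per_ha, "unit"] = "ind/m2"
    biomass = attach_biomass(registry, densities)
    biomass.to_csv(out / "biomass_treatment.csv", index=False)
    registry.to_csv(out / "registry_final.csv")
    return biomass


def stage_links(config: RunConfig) -> pd.DataFrame:
    out = config.out_dir
    registry = NodeRegistry.from_csv(
        out / ("registry_final.csv" if (out / "registry_final.csv").exists() else "registry.csv")
    )
    rules = rules_from_yaml((out / "rules.yaml").read_text())
    groups = build_encounter_groups(registry, rules.groups)
    links = assign_links(registry, groups, rules.rules)
    edges = pd.DataFrame(
        [{"consumer_id": l.consumer_id, "resource_id": l.resource_id,
          "rule_id": l.rule_id} for l in links]
    )
    edges.to_csv(out / "links.csv", index=False)
    pd.DataFrame(
        [{"consumer_id": l.consumer_id, "resource_id": l.resource_id,
          "rule_id": l.rule_id, "trace": "|".join(l.trace)} for l in links]
    ).to_csv(out / "link_provenance.csv", index=False)
    return edges


def stage_assemble(config: RunConfig) -> list[dict]:
    out = config.out_dir
    registry = NodeRegistry.from_csv(
        out / ("registry_final.csv" if (out / "registry_final.csv").exists() else "registry.csv")
    )
    densities = pd.read_csv(out / "densities_treatment.csv")
    biomass_path = out / "biomass_treatment.csv"
    biomass = pd.read_csv(biomass_path) if biomass_path.exists() else None
    edges = pd.read_csv(out / "links.csv")
    from .links import LinkRecord

    links = [
        LinkRecord(r["consumer_id"], r["resource_id"], r["rule_id"], ("replay",))
        for _, r in edges.iterrows()
    ]
    summaries = []
    for treatment in sorted(densities["treatment"].unique()):
        web = assemble_web(registry, links, densities, treatment, biomass)
        export_web(
            web,
            out / f"web_{treatment}_edges.csv",
            out / f"web_{treatment}.graphml",
        )
        summaries.append(web_summary(web))
    (out / "web_metrics.json").write_text(json.dumps(summaries, indent=2))
    return summaries


def stage_validate(config: RunConfig) -> pd.DataFrame:
    out = config.out_dir
    surveys = _load_surveys(out)
    count_methods = {
        m: t for m, t in surveys.items()
        if {"node_id", "treatment", "count"} <= set(t.columns)
    }
    method_groups = {
        "plants": ["vegetation_transect"],
        "invertebrates": ["soil_cores", "hard_substrate", "sweep_net", "berlese",
                          "fogging", "blacklight"],
    }
    if "vertebrate_abundance" in surveys:
        v = surveys["vertebrate_abundance"].copy()
        v["count"] = v["abundance"].round().astype(int)
        count_methods["vertebrate_abundance"] = v
        method_groups["vertebrates"] = ["vertebrate_abundance"]
    table = grouped_validation(count_methods, method_groups, seed=config.seed)
    table.to_csv(out / "validation_table.csv", index=False)
    return table


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "biomass": stage_biomass,
    "density": stage_density,
    "registry": stage_registry,
    "links": stage_links,
    "assemble": stage_assemble,
    "validate": stage_validate,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write a reproducibility manifest."""
    failures = validate_config(config)
    if failures:
        raise ValueError("invalid run config: " + "; ".join(failures))
    config.out_dir.mkdir(parents=True, exist_ok=True)
    for stage in config.stages:
        _STAGE_FUNCS[stage](config)
    artifacts = sorted(
        p for p in config.out_dir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "artifacts": {
            str(p.relative_to(config.out_dir)): _sha256(p) for p in artifacts
        },
    }
    (config.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def recovery_table(
    surveys_bundle,
    registry: NodeRegistry,
    truth,
    detection_scaling: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Estimator recovery diagnostics against synthetic ground truth.

    Runs the full density-estimation path on a survey bundle and joins the
    treatment-mean estimates to the generator's true densities, reporting
    a z-score (estimate - truth) / SE per node x treatment x method.  Rows
    with zero SE and an exact hit get z = 0; zero SE with a miss gets inf.
    """
    est = estimate_densities(
        surveys_bundle.tables, registry, surveys_bundle.habitat_cover,
        detection_scaling,
    )
    rows = []
    for _, r in est.iterrows():
        per_t = truth.density.get(r["node_id"])
        if per_t is None or r["treatment"] not in per_t:
            continue
        true_d = per_t[r["treatment"]]
        if truth.unit[r["node_id"]] != r["unit"]:
            continue
        se = float(r["se"])
        err = float(r["density"]) - true_d
        z = 0.0 if (se == 0 and err == 0) else (np.inf if se == 0 else err / se)
        rows.append(
            {"node_id": r["node_id"], "treatment": r["treatment"],
             "method": r["method"], "estimate": float(r["density"]),
             "se": se, "truth": true_d, "z": z}
        )
    return pd.DataFrame(rows)


def default_allometry() -> pb.AllometryParams:
    """Documented default allometric coefficient table.

    The total-AGB coefficients are the national-scale softwood (pine) and
    hardwood (oak) groupings; tissue-ratio and height coefficients are
    representative published values for those groups.
    """
    return pb.AllometryParams(
        agb={"Pinaceae": (-2.5356, 2.4349), "Quercus": (-2.0127, 2.4342)},
        tissue={
            "Pinaceae": {
                "foliage": (-2.9584, 4.4766),
                "coarse_roots": (-1.5619, 0.6614),
                "stem_bark": (-2.0980, -1.1432),
                "stem_wood": (-0.3737, -1.8055),
            },
            "Quercus": {
                "foliage": (-4.0813, 5.8816),
                "coarse_roots": (-1.6911, 0.8160),
                "stem_bark": (-2.0129, -1.6805),
                "stem_wood": (-0.3065, -5.4240),
            },
        },
        height={"Pinaceae": (1.0, 0.5, 0.05, 0.0), "Quercus": (0.9, 0.5, 0.05, 0.0)},
    )
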