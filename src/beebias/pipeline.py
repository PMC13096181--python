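"""End-to-end orchestration of the synthetic study.

:func:`run_pipeline` executes the stages in order — simulate, count,
networks, traits, bias — writing each stage's outputs before the next
starts and recording row counts, applied filters and warnings in a
:class:`RunManifest`. All randomness flows from per-stage generators
derived deterministically from the master seed, so identical configs give
byte-identical numeric outputs and an identical manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .corpus import InvertedIndex, count_genus_mentions, match_cross_source, dedup_within_source, validate_counts
from .networks import (
    aggregate_region_balanced,
    filter_small_networks,
    network_metric_rows,
    spearman,
)
from .stats import classify_quadrants, nb_glm, richness_effort_scaling, era_share_change
from .synth import (
    CorpusSpec,
    CountsSpec,
    NetworkSpec,
    TraitSpec,
    default_genus_table,
    gen_corpus,
    gen_counts,
    gen_networks,
    gen_traits,
)
from .traits import (
    centroid_distance,
    kde2d,
    overlap_and_unique,
    residualize_on_genus_pcs,
)


@dataclass
class RunConfig:
    """Configuration for a full synthetic run."""

    out_dir: str = "beebias_run"
    seed: int = 0
    n_docs: int = 400
    n_genera: int = 12
    n_networks: int = 12
    sim_threshold: float = 0.9
    count_mode: str = "full"
    isopleth_level: float = 0.95
    grid_size: int = 120
    effort_threshold: float | None = None
    centrality_threshold: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are; exclude it so
        # the same study written to two directories hashes identically.
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
            "warnings": self.warnings,
        }


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run simulate -> count -> networks -> traits -> bias, writing outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.config_hash(), config.seed)

    # --- simulate ---------------------------------------------------------
    corpus = gen_corpus(CorpusSpec(n_genera=config.n_genera, n_docs=config.n_docs,
                                   seed=_stage_seed(config.seed, "corpus")))
    networks, attract = gen_networks(NetworkSpec(n_networks=config.n_networks,
                                                 seed=_stage_seed(config.seed, "networks")))
    trait_table, _ = gen_traits(TraitSpec(seed=_stage_seed(config.seed, "traits")))
    effort_table, counts_truth = gen_counts(CountsSpec(seed=_stage_seed(config.seed, "counts")))
    bio.write_records_csv(corpus.wos, out / "wos_records.csv")
    bio.write_records_csv(corpus.scopus, out / "scopus_records.csv")
    trait_table.to_csv(out / "traits.csv", index=False)
    effort_table.to_csv(out / "effort_table.csv", index=False)
    manifest.stages["simulate"] = {
        "wos_records": len(corpus.wos),
        "scopus_records": len(corpus.scopus),
        "networks": len(networks),
        "trait_species": len(trait_table),
        "effort_rows": len(effort_table),
    }

    # --- count ------------------------------------------------------------
    wos = dedup_within_source(corpus.wos)
    scopus = dedup_within_source(corpus.scopus)
    linkage = match_cross_source(wos, scopus, sim_threshold=config.sim_threshold)
    index = InvertedIndex.build(linkage.documents)
    counts = count_genus_mentions(index, corpus.library, mode=config.count_mode)
    bio.write_counts_csv(counts, out / "genus_year_counts.csv")
    bio.write_cooccurrence_csv(counts, out / "genus_cooccurrence.csv")
    truth_totals: dict[str, int] = {}
    for (g, _), c in corpus.true_counts(config.count_mode).items():
        truth_totals[g] = truth_totals.get(g, 0) + c
    auto_totals = counts.totals()
    shared = set(truth_totals) & set(auto_totals)
    validation = None
    if len(shared) >= 3:
        validation = validate_counts(auto_totals, truth_totals)
        bio.write_json(validation.to_dict(), out / "count_validation.json")
    manifest.stages["count"] = {
        "union_documents": linkage.union_size,
        "intersection": len(linkage.intersection),
        "wos_only": len(linkage.wos_only),
        "scopus_only": len(linkage.scopus_only),
        "genera_detected": len(auto_totals),
    }

    # --- networks ---------------------------------------------------------
    rows, dropped = network_metric_rows(networks)
    rows, dropped_small = filter_small_networks(rows)
    centrality = aggregate_region_balanced(rows)
    rows.to_csv(out / "network_metrics.csv", index=False)
    centrality.to_csv(out / "genus_centrality.csv", index=False)
    manifest.stages["networks"] = {
        "networks_in": len(networks),
        "networks_dropped_lt3": len(dropped) + len(dropped_small),
        "metric_rows": len(rows),
        "genera": len(centrality),
    }

    # --- traits -----------------------------------------------------------
    coords = residualize_on_genus_pcs(trait_table)
    coords["managed"] = trait_table["managed"].to_numpy()
    coords.to_csv(out / "residualized_traits.csv", index=False)
    pts = coords[["x", "y"]].to_numpy()
    managed_mask = coords["managed"].to_numpy(dtype=bool)
    grid_all = kde2d(pts, grid_size=(config.grid_size, config.grid_size))
    extent = (grid_all.x[0], grid_all.x[-1], grid_all.y[0], grid_all.y[-1])
    g_managed = kde2d(pts[managed_mask], grid_size=(config.grid_size, config.grid_size), extent=extent)
    g_wild = kde2d(pts[~managed_mask], grid_size=(config.grid_size, config.grid_size), extent=extent)
    overlap = overlap_and_unique(g_managed, g_wild, level=config.isopleth_level)
    trait_summary = {
        "overlap_mass": overlap.overlap_mass,
        "unique_mass_managed": overlap.unique_mass_a,
        "unique_mass_wild": overlap.unique_mass_b,
        "centroid_distance": centroid_distance(pts[managed_mask], pts[~managed_mask]),
        "isopleth_level": config.isopleth_level,
    }
    bio.write_json(trait_summary, out / "trait_space_summary.json")
    manifest.stages["traits"] = {"species": len(coords), "managed": int(managed_mask.sum())}

    # --- bias -------------------------------------------------------------
    totals = effort_table.groupby("genus")["papers"].sum()
    effort = totals.to_dict()
    centrality_map = dict(zip(centrality["genus"], centrality["mean_z_strength"]))
    attrs = default_genus_table().set_index("genus")
    managed_map = attrs["managed"].to_dict()

    shared_genera = sorted(set(effort) & set(centrality_map))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, rho_p = spearman(
            [centrality_map[g] for g in shared_genera],
            [effort[g] for g in shared_genera],
        )
    quadrants = classify_quadrants(
        {g: effort[g] for g in shared_genera},
        {g: centrality_map[g] for g in shared_genera},
        effort_threshold=config.effort_threshold,
        centrality_threshold=config.centrality_threshold,
        managed=managed_map,
    )
    quadrants.assignments.to_csv(out / "quadrant_assignments.csv", index=False)

    richness = attrs["species_richness"].to_dict()
    scaling = richness_effort_scaling(
        {g: float(v) for g, v in effort.items()},
        {g: float(richness[g]) for g in effort},
    ) if len(effort) >= 10 else None

    noab = effort_table[~effort_table["genus"].isin(["Apis", "Bombus"])]
    X = pd.DataFrame(
        {
            "managed": noab["managed"].astype(float).to_numpy(),
            "managed_x_year": (noab["managed"].astype(float) * noab["year_z"]).to_numpy(),
            "log_richness_z": noab["log_richness_z"].to_numpy(),
        }
    )
    nb = nb_glm(noab["papers"].to_numpy(), X, offset=np.log(noab["total_year"].to_numpy()),
                offset_description="log total bee-genus papers per year")

    managed_counts = (
        effort_table.assign(category=np.where(effort_table["managed"], "managed", "wild"))
        .groupby(["year", "category"], as_index=False)["papers"].sum()
        .rename(columns={"papers": "count"})
    )
    years = sorted(effort_table["year"].unique())
    era = era_share_change(
        managed_counts,
        early_window=(years[0], years[0] + 4),
        recent_window=(years[-1] - 4, years[-1]),
    )

    bias_summary = {
        "centrality_effort_spearman_rho": rho,
        "centrality_effort_spearman_p": rho_p,
        "quadrant_sizes": quadrants.group_sizes,
        "quadrant_thresholds": {
            "effort": quadrants.effort_threshold,
            "centrality": quadrants.centrality_threshold,
        },
        "managed_share_by_group": quadrants.managed_share,
        "scaling_slope": None if scaling is None else scaling.slope,
        "scaling_ci": None if scaling is None else list(scaling.ci),
        "nb_managed_irr": float(nb.irr["managed"]),
        "nb_managed_irr_ci": [float(nb.ci_low["managed"]), float(nb.ci_high["managed"])],
        "nb_theta": nb.theta if math.isfinite(nb.theta) else None,
        "true_managed_irr": math.exp(counts_truth["beta_managed"]),
        "managed_share_change_points": float(
            era.loc[era["category"] == "managed", "change_points"].iloc[0]
        ),
    }
    bio.write_json(bias_summary, out / "bias_summary.json")
    manifest.stages["bias"] = {
        "genera_in_scatter": len(shared_genera),
        "nb_rows": len(noab),
    }

    bio.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
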