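"""End-to-end orchestration: world in, conservation report out.

One call, :func:`run_pipeline`, chains every stage: occurrence cleaning,
model validation with the buffer fallback, gap scoring and priority
banding, gap/hotspot/richness rasters, pairwise niche and range overlap
with cohort summaries, PCA + Ward clustering in environment space, and
phylogenetic statistics (Blomberg's K per variable, Mantel tests between
the environmental, geographic, and cophenetic distance matrices).

The pipeline is a pure function of (inputs, config, seed): rerunning with
the same arguments reproduces every tabular output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geodata import BinaryRange, circular_buffer_range, write_ascii_grid, richness_map
from .occurrences import coords_of, deduplicate, partition_counts, taxa_of
from .sdm_eval import kfold_split, realized_range, validate_model
from .gap_analysis import (
    collecting_gap_map,
    ers,
    fps_classify,
    grs,
    hotspot_map,
    priority_table,
    srs,
)
from .niche_overlap import asymmetry_stat, overlap_summary, pairwise_driver
from .eco_phylo import (
    blomberg_k_table,
    build_trait_table,
    cophenetic_distances,
    conservatism_fraction,
    geographic_distances,
    hcpc_clusters,
    mahalanobis_distances,
    mantel,
    pca,
    sister_pairs,
    taxon_centroids,
)
from .synthetic_data import SyntheticWorld

log = logging.getLogger("gapkit")


@dataclass
class RunConfig:
    """Analysis constants for one pipeline run; unknown keys are rejected
    by construction and every value is checked against its domain."""

    buffer_radius_km: float = 50.0
    k_folds: int = 5
    background_n: int = 10_000
    atauc_min: float = 0.7
    stauc_max: float = 0.15
    asd_cut: float = 0.15
    asd_frac: float = 0.10
    pcs: int = 3
    clusters: int = 3
    n_perm: int = 1000
    seed: int = 0

    def validate(self) -> None:
        checks = {
            "buffer_radius_km": self.buffer_radius_km > 0,
            "k_folds": self.k_folds >= 2,
            "background_n": self.background_n >= 1,
            "atauc_min": 0 <= self.atauc_min <= 1,
            "stauc_max": self.stauc_max > 0,
            "asd_cut": self.asd_cut > 0,
            "asd_frac": 0 <= self.asd_frac <= 1,
            "pcs": self.pcs >= 1,
            "clusters": self.clusters >= 1,
            "n_perm": self.n_perm >= 0,
            "seed": self.seed >= 0,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"config value(s) out of domain: {bad}")

    @classmethod
    def from_mapping(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _background_scores(surface, rng, n):
    cells = np.argwhere(surface.valid_mask)
    idx = rng.choice(cells.shape[0], size=n, replace=True)
    return surface.values[cells[idx, 0], cells[idx, 1]]


def run_pipeline(world: SyntheticWorld, config: RunConfig, out_dir: str | Path) -> Path:
    """Run every analysis stage on a world and write the report directory.

    Outputs: scores.csv, overlap.csv, summary.csv, clusters.csv,
    ksignal.csv, rasters/ (.asc), run.log, run.json.  Stage failures
    abort with the stage and taxon named.
    """
    config.validate()
    out = Path(out_dir)
    (out / "rasters").mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(world, config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(world: SyntheticWorld, config: RunConfig, out: Path) -> Path:
    rng = np.random.default_rng(config.seed)
    log.info("gapkit %s seed=%d config=%s", __version__, config.seed, dataclasses.asdict(config))

    records = deduplicate(world.records)
    log.info("records: %d after deduplication (from %d)", len(records), len(world.records))
    taxa = taxa_of(records)
    template = world.template
    surfaces = {t.taxon: t.true_suitability for t in world.taxa}

    # --- distribution validation and realized ranges -----------------
    stage = "sdm_eval"
    ranges: dict[str, BinaryRange] = {}
    model_surfaces = {}
    provenance = {}
    for taxon in taxa:
        try:
            pts = coords_of(records, taxon)
            surf = surfaces.get(taxon)
            metrics = None
            bg = None
            if surf is not None and len(pts) >= config.k_folds:
                folds = kfold_split(pts, config.k_folds, seed=int(rng.integers(2**31)))
                bg = _background_scores(surf, rng, config.background_n)
                metrics = validate_model(
                    [surf] * config.k_folds,
                    folds,
                    bg,
                    atauc_min=config.atauc_min,
                    stauc_max=config.stauc_max,
                    asd_cut=config.asd_cut,
                    asd_frac=config.asd_frac,
                )
            rr = realized_range(
                surface=surf if metrics is not None else None,
                metrics=metrics,
                points=pts,
                bg_scores=bg,
                template=template,
                exclusion_mask=world.exclusion_mask,
                buffer_radius_km=config.buffer_radius_km,
            )
            ranges[taxon] = rr.range
            provenance[taxon] = rr.provenance
            if rr.provenance == "model":
                model_surfaces[taxon] = surf
            log.info("range %s: %s (%d cells)", taxon, rr.provenance, rr.range.cell_count)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed for taxon {taxon}: {exc}") from exc

    # --- gap scores ---------------------------------------------------
    stage = "gap_analysis"
    scores, gap_maps = [], {}
    for taxon in taxa:
        try:
            n_g, n_h, _, _ = partition_counts(records, taxon)
            g_pts = coords_of(records, taxon, "G")
            buffers = (
                circular_buffer_range(g_pts, config.buffer_radius_km, template)
                if g_pts
                else None
            )
            s = srs(n_g, n_h)
            g = grs(buffers, ranges[taxon])
            e = ers(world.ecoregions, ranges[taxon], buffers)
            gs = fps_classify(taxon, s, g, e)
            scores.append(gs)
            gap_maps[taxon] = collecting_gap_map(ranges[taxon], buffers)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed for taxon {taxon}: {exc}") from exc
    table = priority_table(scores)
    table.to_csv(out / "scores.csv", index=False)
    hps = [s.taxon for s in scores if s.category == "HPS"]
    if hps:
        write_ascii_grid(hotspot_map([gap_maps[t] for t in hps]), out / "rasters" / "hotspots.asc")
    else:
        log.warning("no high-priority taxa: hotspot map skipped")
    write_ascii_grid(richness_map(list(ranges.values())), out / "rasters" / "richness.asc")

    # --- pairwise overlap --------------------------------------------
    stage = "niche_overlap"
    results = pairwise_driver(ranges, model_surfaces)
    df = pd.DataFrame(
        {
            "taxon_a": r.taxon_a, "taxon_b": r.taxon_b, "D": r.d, "I": r.i,
            "shared_cells": r.shared_cells, "sorensen": r.sorensen,
            "frac_larger": r.frac_larger, "frac_smaller": r.frac_smaller,
            "sympatric": r.sympatric,
        }
        for r in results
    )
    df.to_csv(out / "overlap.csv", index=False)
    sisters = {tuple(sorted(p)) for p in sister_pairs(world.tree)}
    cohorts = {}
    for r in results:
        labels = ["sympatric" if r.sympatric else "allopatric"]
        if (r.taxon_a, r.taxon_b) in sisters:
            labels.append("sister")
        cohorts[(r.taxon_a, r.taxon_b)] = labels
    summary = overlap_summary(results, cohorts)
    summary.to_csv(out / "summary.csv", index=False)
    asym = asymmetry_stat(results)
    log.info("pairwise overlap: %d pairs, asymmetry %.2f pp", len(results), asym)

    # --- clustering ---------------------------------------------------
    stage = "eco_phylo/clustering"
    traits, excluded = build_trait_table(records, world.env_layers)
    point_rows, point_taxa = [], []
    from .eco_phylo import extract_env

    for taxon in traits.index:
        mat, _ = extract_env(coords_of(records, taxon), world.env_layers)
        point_rows.append(mat)
        point_taxa.extend([taxon] * len(mat))
    points_env = pd.concat(point_rows, ignore_index=True)
    pca_res = pca(points_env)
    pc_var = float(pca_res.variance_fractions[: config.pcs].sum())
    clusters = hcpc_clusters(
        pca_res.scores.to_numpy(), point_taxa, k=config.clusters, n_pcs=config.pcs
    )
    pd.DataFrame(
        {"taxon": list(clusters.assignments), "cluster": list(clusters.assignments.values())}
    ).to_csv(out / "clusters.csv", index=False)
    log.info("clustering: first %d PCs explain %.1f%% of variance", config.pcs, 100 * pc_var)

    # --- phylogenetic signal -----------------------------------------
    stage = "eco_phylo/signal"
    tree_tips = {leaf.taxon.label for leaf in world.tree.leaf_node_iter()}
    shared = sorted(tree_tips & set(traits.index))
    ktable = pd.DataFrame()
    conservatism = float("nan")
    if len(shared) >= 4:
        pruned = world.tree.clone(depth=1)
        pruned.retain_taxa_with_labels(shared)
        kres = blomberg_k_table(
            pruned, traits.loc[shared], n_perm=config.n_perm, seed=config.seed
        )
        ktable = pd.DataFrame(
            {"variable": r.variable, "K": r.k, "p": r.p_value, "n_perm": r.n_perm}
            for r in kres
        )
        from statsmodels.stats.multitest import multipletests

        ktable["p_bh"] = multipletests(ktable["p"], method="fdr_bh")[1]
        conservatism = conservatism_fraction(kres)
    ktable.to_csv(out / "ksignal.csv", index=False)

    env_dist = mahalanobis_distances(traits.loc[shared] if shared else traits)
    cents = taxon_centroids(records)
    geo_dist = geographic_distances({t: cents[t] for t in env_dist.index})
    m_env_geo = mantel(env_dist, geo_dist, n_perm=config.n_perm, seed=config.seed)
    mantel_results = {"env_vs_geo": {"r": m_env_geo.r, "p": m_env_geo.p_value}}
    if len(shared) >= 4:
        coph = cophenetic_distances(pruned)
        m_geo_phy = mantel(
            geo_dist.loc[shared, shared], coph, n_perm=config.n_perm, seed=config.seed + 1
        )
        mantel_results["geo_vs_phylo"] = {"r": m_geo_phy.r, "p": m_geo_phy.p_value}

    # --- machine-readable sidecar ------------------------------------
    sidecar = {
        "gapkit_version": __version__,
        "config": dataclasses.asdict(config),
        "n_records": len(records),
        "n_taxa": len(taxa),
        "range_provenance": provenance,
        "n_pairwise": len(results),
        "asymmetry_pp": asym,
        "pc_variance_fraction": pc_var,
        "excluded_taxa": excluded,
        "conservatism_fraction": conservatism,
        "mantel": mantel_results,
        "category_counts": {
            c: sum(1 for s in scores if s.category == c) for c in ("HPS", "MPS", "LPS", "NFCR")
        },
    }
    (out / "run.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", out)
    return out
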