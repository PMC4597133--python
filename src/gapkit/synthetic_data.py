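"""Synthetic study worlds with known truth.

Stands in for the field inputs of a real gap analysis — gridded climate
and soil layers, an ecoregion map, genebank/herbarium occurrence records,
and a phylogeny — so every downstream stage can be exercised end-to-end
offline.  The world emulates, at desk scale, the structure of a
continental crop-wild-relative study: 36 taxa, 26 spatially
autocorrelated environmental variables on a 60 x 60 grid of 0.25-degree
cells, Gaussian niche responses, presence sampling proportional to
suitability, a germplasm/reference record split with a coordinate-free
remainder, Voronoi-patch ecoregions, and Brownian-motion trait evolution
on a random coalescent tree.

Everything is a deterministic function of the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .geodata import BinaryRange, GridLayer, write_ascii_grid
from .occurrences import OccurrenceRecord, save_occurrences
from .eco_phylo import read_newick


@dataclass
class WorldConfig:
    """Generator settings; defaults give the standard desk-scale world."""

    seed: int = 0
    n_taxa: int = 36
    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 0.25
    origin_lon: float = -110.0
    origin_lat: float = 45.0
    n_env_layers: int = 26
    correlation_length: int = 7
    env_collinearity: float = 0.7
    n_ecoregion_classes: int = 10
    exclusion_fraction: float = 0.05
    n_niche_axes: int = 3
    niche_breadth_range: tuple[float, float] = (0.6, 1.5)
    n_occurrences: int = 40        # coordinate-bearing records per taxon
    n_coordless: int = 68          # coordinate-free records per taxon
    germplasm_fraction_range: tuple[float, float] = (0.0, 0.7)
    bm_rate: float = 1.0

    def validate(self) -> None:
        checks = {
            "n_taxa": self.n_taxa >= 2,
            "n_rows": self.n_rows >= 4,
            "n_cols": self.n_cols >= 4,
            "cell_size": self.cell_size > 0,
            "n_env_layers": self.n_env_layers >= 1,
            "correlation_length": self.correlation_length >= 1,
            "env_collinearity": 0.0 <= self.env_collinearity < 1.0,
            "n_ecoregion_classes": 1 <= self.n_ecoregion_classes <= self.n_rows * self.n_cols,
            "exclusion_fraction": 0.0 <= self.exclusion_fraction < 1.0,
            "n_niche_axes": 1 <= self.n_niche_axes <= self.n_env_layers,
            "niche_breadth_range": 0 < self.niche_breadth_range[0] <= self.niche_breadth_range[1],
            "n_occurrences": self.n_occurrences >= 1,
            "n_coordless": self.n_coordless >= 0,
            "germplasm_fraction_range": (
                0.0 <= self.germplasm_fraction_range[0]
                <= self.germplasm_fraction_range[1] <= 1.0
            ),
            "bm_rate": self.bm_rate > 0,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid config field(s): {bad}")


@dataclass
class TaxonTruth:
    taxon: str
    niche_center: dict[str, float]
    niche_breadth: dict[str, float]
    true_suitability: GridLayer
    n_occurrences: int
    germplasm_fraction: float


@dataclass
class SyntheticWorld:
    config: WorldConfig
    env_layers: dict[str, GridLayer]
    ecoregions: GridLayer
    exclusion_mask: BinaryRange
    taxa: list[TaxonTruth]
    records: list[OccurrenceRecord]
    tree: dendropy.Tree
    tree_newick: str

    @property
    def template(self) -> GridLayer:
        return next(iter(self.env_layers.values()))


# ---------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------

def _template(cfg: WorldConfig) -> GridLayer:
    return GridLayer(
        np.zeros((cfg.n_rows, cfg.n_cols)), cfg.origin_lon, cfg.origin_lat, cfg.cell_size
    )


def make_env_layers(
    n_layers: int,
    template: GridLayer,
    correlation_length: int = 7,
    seed: int = 0,
    collinearity: float = 0.0,
    n_latent: int = 3,
) -> dict[str, GridLayer]:
    """Smoothed-white-noise environmental fields, standardized per layer.

    White noise is moving-average filtered with a square window of side
    ``correlation_length`` cells (reflecting edges), producing spatial
    autocorrelation on roughly that scale, then rescaled to mean 0 and
    SD 1 over valid cells.  With ``collinearity`` c > 0, each layer mixes
    a shared latent field (cycled over ``n_latent`` of them) with weight c
    against its own noise, emulating the strong pairwise correlations of
    real bioclimatic variable sets.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if correlation_length < 1:
        raise ValueError("correlation_length must be >= 1 cell")
    if not 0.0 <= collinearity < 1.0:
        raise ValueError("collinearity must be in [0, 1)")
    rng = np.random.default_rng(seed)

    def smooth_field() -> np.ndarray:
        noise = rng.standard_normal(template.shape)
        if correlation_length > 1:
            noise = uniform_filter(noise, size=correlation_length, mode="reflect")
        return (noise - noise.mean()) / noise.std()

    latents = [smooth_field() for _ in range(n_latent)] if collinearity > 0 else []
    out = {}
    for i in range(n_layers):
        field_vals = smooth_field()
        if latents:
            c = collinearity
            field_vals = c * latents[i % n_latent] + np.sqrt(1 - c * c) * field_vals
            field_vals = (field_vals - field_vals.mean()) / field_vals.std()
        out[f"env_{i + 1:02d}"] = template.copy_with(field_vals)
    return out


def make_ecoregions(template: GridLayer, n_classes: int, seed: int = 0) -> GridLayer:
    """Voronoi-in-grid categorical patches, classes 1..n_classes.

    Class seeds are distinct random cells; every cell takes the class of
    its nearest seed in grid-index space, so all classes are non-empty
    and patches are contiguous-ish.
    """
    n_cells = template.n_rows * template.n_cols
    if not 1 <= n_classes <= n_cells:
        raise ValueError("n_classes must be in [1, n_cells]")
    rng = np.random.default_rng(seed)
    seeds = rng.choice(n_cells, size=n_classes, replace=False)
    sr, sc = np.divmod(seeds, template.n_cols)
    rr, cc = np.indices(template.shape)
    d2 = (rr[..., None] - sr) ** 2 + (cc[..., None] - sc) ** 2
    classes = np.argmin(d2, axis=-1) + 1.0
    return template.copy_with(classes)


def make_exclusion_mask(
    template: GridLayer, fraction: float, seed: int = 0, correlation_length: int = 5
) -> BinaryRange:
    """Clumped exclusion mask (urban/water/bare stand-in) covering about
    ``fraction`` of cells: the top quantile of a smoothed noise field."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    noise = uniform_filter(rng.standard_normal(template.shape), size=correlation_length)
    if fraction == 0.0:
        vals = np.zeros(template.shape)
    else:
        cut = np.quantile(noise, 1.0 - fraction)
        vals = (noise >= cut).astype(float)
    return BinaryRange.from_layer(template, vals)


def make_taxon(
    name: str,
    env_layers: Mapping[str, GridLayer],
    niche_center: Mapping[str, float],
    niche_breadth: Mapping[str, float],
    n_occurrences: int,
    germplasm_fraction: float,
    seed: int = 0,
    exclusion_mask: BinaryRange | None = None,
    n_coordless: int = 0,
) -> tuple[TaxonTruth, list[OccurrenceRecord]]:
    """One taxon: Gaussian-niche suitability plus sampled records.

    Suitability is exp(-0.5 * sum(((env - center) / breadth)^2)) over the
    niche axes, rescaled to max 1.  Coordinate-bearing occurrences are
    cells sampled without replacement with probability proportional to
    suitability (excluded cells removed first), jittered uniformly within
    the cell; ``germplasm_fraction`` of records (rounded) are flagged G.
    Coordinate-free records carry no position but count toward SRS.
    """
    for var in niche_center:
        if var not in env_layers:
            raise ValueError(f"niche variable {var!r} has no layer")
        if not niche_breadth[var] > 0:
            raise ValueError("niche breadths must be positive")
    template = next(iter(env_layers.values()))
    z2 = np.zeros(template.shape)
    for var, center in niche_center.items():
        z2 += ((env_layers[var].values - center) / niche_breadth[var]) ** 2
    suit = np.exp(-0.5 * z2)
    if exclusion_mask is not None:
        suit[exclusion_mask.values == 1.0] = np.nan
    peak = np.nanmax(suit)
    if not peak > 0:
        raise ValueError(f"taxon {name}: suitability is zero everywhere")
    suit = suit / peak
    surface = template.copy_with(suit)

    rng = np.random.default_rng(seed)
    flat = suit.ravel()
    valid = np.flatnonzero(~np.isnan(flat) & (flat > 0))
    if n_occurrences > valid.size:
        raise ValueError(f"taxon {name}: more occurrences than habitable cells")
    p = flat[valid] / flat[valid].sum()
    cells = rng.choice(valid, size=n_occurrences, replace=False, p=p)
    jitter = rng.uniform(-0.49, 0.49, size=(n_occurrences, 2))

    n_total = n_occurrences + n_coordless
    n_g = int(round(germplasm_fraction * n_total))
    type_flags = np.array(["G"] * n_g + ["H"] * (n_total - n_g))
    rng.shuffle(type_flags)

    records = []
    for i, cell in enumerate(cells):
        r, c = divmod(int(cell), template.n_cols)
        lon, lat = template.cell_center(r, c)
        records.append(
            OccurrenceRecord(
                record_id=f"{name}-{i:04d}",
                taxon=name,
                record_type=str(type_flags[i]),
                lon=lon + jitter[i, 0] * template.cell_size,
                lat=lat + jitter[i, 1] * template.cell_size,
                source="synthetic",
            )
        )
    for i in range(n_coordless):
        records.append(
            OccurrenceRecord(
                record_id=f"{name}-x{i:04d}",
                taxon=name,
                record_type=str(type_flags[n_occurrences + i]),
                source="synthetic-nocoord",
            )
        )
    truth = TaxonTruth(
        taxon=name,
        niche_center=dict(niche_center),
        niche_breadth=dict(niche_breadth),
        true_suitability=surface,
        n_occurrences=n_occurrences,
        germplasm_fraction=germplasm_fraction,
    )
    return truth, records


# ---------------------------------------------------------------------
# trees and traits
# ---------------------------------------------------------------------

def _coalescent_newick(labels: Sequence[str], rng: np.random.Generator) -> str:
    """Kingman-style random ultrametric tree over the given tip labels."""
    nodes = [(lbl, 0.0) for lbl in labels]  # (newick fragment, height)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (sa, ha) = nodes[i]
        (sb, hb) = nodes.pop(j)
        nodes[i] = (f"({sa}:{t - ha:.10f},{sb}:{t - hb:.10f})", t)
    return nodes[0][0] + ";"


def make_tree_and_traits(
    n_tips: int,
    seed: int = 0,
    mode: str = "BM",
    n_traits: int = 1,
    rate: float = 1.0,
    labels: Sequence[str] | None = None,
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Random ultrametric tree plus tip traits.

    mode "BM": traits evolve by Brownian motion along branches with
    variance ``rate`` per unit branch length (root value 0), so across
    replicates the tip variance is rate * tip depth.  mode "white_noise":
    exchangeable iid standard-normal tip values, carrying no signal.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if mode not in ("BM", "white_noise"):
        raise ValueError("mode must be 'BM' or 'white_noise'")
    if labels is None:
        labels = [f"t{i + 1:03d}" for i in range(n_tips)]
    elif len(labels) != n_tips:
        raise ValueError("one label per tip required")
    rng = np.random.default_rng(seed)
    newick = _coalescent_newick(list(labels), rng)
    tree = read_newick(newick)
    cols = {}
    for j in range(n_traits):
        if mode == "white_noise":
            vals = dict(zip(labels, rng.standard_normal(n_tips)))
        else:
            vals = {}
            node_val = {tree.seed_node: 0.0}
            for node in tree.preorder_node_iter():
                if node is tree.seed_node:
                    continue
                parent = node_val[node.parent_node]
                step = rng.standard_normal() * np.sqrt(rate * node.edge.length)
                node_val[node] = parent + step
                if node.is_leaf():
                    vals[node.taxon.label] = node_val[node]
        cols[f"trait_{j + 1}"] = pd.Series(vals)
    traits = pd.DataFrame(cols).loc[list(labels)]
    return tree, traits


# ---------------------------------------------------------------------
# world assembly
# ---------------------------------------------------------------------

def make_world(config: WorldConfig | None = None, **overrides) -> SyntheticWorld:
    """Compose all generators into one coherent study world.

    The phylogeny is drawn first and each niche axis's centers evolve by
    Brownian motion along it (standardized across taxa), so related taxa
    genuinely share environmental preferences — downstream K and Mantel
    statistics measure a real signal, not an artifact.  Per-taxon
    germplasm fractions are uniform over ``germplasm_fraction_range``,
    spreading taxa across the collecting-priority bands the way uneven
    genebank holdings do.
    """
    cfg = config if config is not None else WorldConfig()
    if overrides:
        cfg = WorldConfig(**{**asdict_flat(cfg), **overrides})
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    s_env, s_eco, s_mask, s_niche, s_tree, s_taxa = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)
    ]
    template = _template(cfg)
    env = make_env_layers(
        cfg.n_env_layers, template, cfg.correlation_length, s_env,
        collinearity=cfg.env_collinearity,
    )
    eco = make_ecoregions(template, cfg.n_ecoregion_classes, s_eco)
    mask = make_exclusion_mask(template, cfg.exclusion_fraction, s_mask)

    names = [f"taxon_{i + 1:02d}" for i in range(cfg.n_taxa)]
    axis_names = list(env)[: cfg.n_niche_axes]
    tree, centers_bm = make_tree_and_traits(
        cfg.n_taxa, seed=s_tree, mode="BM", rate=cfg.bm_rate,
        n_traits=cfg.n_niche_axes, labels=names,
    )
    # standardize each BM axis across taxa so centers live on the env scale
    centers_bm = (centers_bm - centers_bm.mean()) / centers_bm.std(ddof=0)
    newick = tree.as_string(schema="newick", unquoted_underscores=True).strip()

    niche_rng = np.random.default_rng(s_niche)
    taxon_rng = np.random.default_rng(s_taxa)
    lo, hi = cfg.niche_breadth_range
    glo, ghi = cfg.germplasm_fraction_range
    taxa, records = [], []
    for i, name in enumerate(names):
        center = {v: float(centers_bm.iloc[i, j]) for j, v in enumerate(axis_names)}
        breadth = {v: float(niche_rng.uniform(lo, hi)) for v in axis_names}
        gfrac = float(niche_rng.uniform(glo, ghi))
        truth, recs = make_taxon(
            name,
            env,
            center,
            breadth,
            cfg.n_occurrences,
            gfrac,
            seed=int(taxon_rng.integers(2**31)),
            exclusion_mask=mask,
            n_coordless=cfg.n_coordless,
        )
        taxa.append(truth)
        records.extend(recs)
    return SyntheticWorld(cfg, env, eco, mask, taxa, records, tree, newick)


def asdict_flat(cfg: WorldConfig) -> dict:
    d = asdict(cfg)
    d["niche_breadth_range"] = tuple(d["niche_breadth_range"])
    return d


def write_world(world: SyntheticWorld, out_dir: str | Path) -> Path:
    """Write a world as the on-disk inputs the CLI consumes.

    Layout: occ.csv, layers/*.asc, eco.asc, exclusion.asc, tree.nwk,
    suitability/*.asc (the truth-derived surrogate surfaces), truth.json
    with every generator parameter and per-taxon niche truth.
    """
    out = Path(out_dir)
    (out / "layers").mkdir(parents=True, exist_ok=True)
    (out / "suitability").mkdir(exist_ok=True)
    save_occurrences(world.records, out / "occ.csv")
    for name, layer in world.env_layers.items():
        write_ascii_grid(layer, out / "layers" / f"{name}.asc")
    write_ascii_grid(world.ecoregions, out / "eco.asc")
    write_ascii_grid(world.exclusion_mask, out / "exclusion.asc")
    for t in world.taxa:
        write_ascii_grid(t.true_suitability, out / "suitability" / f"{t.taxon}.asc")
    (out / "tree.nwk").write_text(world.tree_newick + "\n")
    truth = {
        "config": asdict_flat(world.config),
        "taxa": [
            {
                "taxon": t.taxon,
                "niche_center": t.niche_center,
                "niche_breadth": t.niche_breadth,
                "n_occurrences": t.n_occurrences,
                "germplasm_fraction": t.germplasm_fraction,
            }
            for t in world.taxa
        ],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return out
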