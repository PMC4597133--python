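"""Environment-space ordination, clustering, and phylogenetic statistics.

Occurrence points are projected into environment space (one value per
environmental layer), summarised per taxon, ordinated by PCA, and
clustered by Ward agglomeration on the leading principal components
(HCPC).  Phylogenetic signal of each ecogeographic variable is measured
with Blomberg's K:

    K = [ (x-a)'(x-a) / (x-a)' C^-1 (x-a) ]
        / [ (tr C - n / sum(C^-1)) / (n-1) ]

where C is the matrix of shared branch lengths implied by the tree and
``a`` the generalized-least-squares phylogenetic mean.  K is about 1 for
traits evolving by Brownian motion on the tree, below 1 when relatives
resemble each other less than the tree predicts.  Significance comes from
permuting tip labels and ranking the observed rate-scaled fit (1/MSE)
among the permutations.  The Mantel test correlates two taxon-by-taxon
distance matrices (environmental Mahalanobis, geographic great-circle, or
cophenetic) with a row/column co-permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .geodata import GridLayer, haversine_km
from .occurrences import OccurrenceRecord

#: number of leading principal components fed to clustering
DEFAULT_N_PCS = 3
#: number of clusters cut from the Ward tree
DEFAULT_N_CLUSTERS = 3
#: permutations for K and Mantel tests
DEFAULT_N_PERM = 1000
#: taxa with fewer occurrence points than this are excluded from
#: clustering and trait summaries
MIN_POINTS_PER_TAXON = 3
#: ridge added to a singular trait covariance before inversion
MAHALANOBIS_RIDGE = 1e-8


# ---------------------------------------------------------------------
# environment extraction and trait tables
# ---------------------------------------------------------------------

def extract_env(
    points: Sequence[tuple[float, float]],
    layers: Mapping[str, GridLayer],
) -> tuple[pd.DataFrame, int]:
    """Per-point environmental values by nearest (containing) cell.

    Returns (matrix, n_dropped): rows are the retained points, columns the
    layer names; points outside the grid or on nodata in any layer are
    dropped and counted.
    """
    names = list(layers)
    if not names:
        raise ValueError("no layers supplied")
    base = layers[names[0]]
    for nm in names[1:]:
        base.require_aligned(layers[nm], "environmental layers")
    rows, dropped = [], 0
    for lon, lat in points:
        cell = base.cell_of(lon, lat)
        if cell is None:
            dropped += 1
            continue
        vals = [layers[nm].values[cell] for nm in names]
        if any(np.isnan(v) for v in vals):
            dropped += 1
            continue
        rows.append(vals)
    if not rows:
        raise ValueError("every point fell outside the grid or on nodata")
    return pd.DataFrame(rows, columns=names), dropped


def build_trait_table(
    records: Sequence[OccurrenceRecord],
    layers: Mapping[str, GridLayer],
    stat: str = "median",
    min_points: int = MIN_POINTS_PER_TAXON,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-taxon trait summary (default median) of point extractions.

    Returns (table, excluded): rows are taxa with at least ``min_points``
    usable points; the rest are listed in ``excluded`` with a warning.
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    by_taxon: dict[str, list[tuple[float, float]]] = {}
    for r in records:
        if r.has_coords:
            by_taxon.setdefault(r.taxon, []).append((r.lon, r.lat))
    rows, excluded = {}, []
    for taxon in sorted(by_taxon):
        try:
            mat, _ = extract_env(by_taxon[taxon], layers)
        except ValueError:
            excluded.append(taxon)
            continue
        if len(mat) < min_points:
            excluded.append(taxon)
            continue
        rows[taxon] = mat.median() if stat == "median" else mat.mean()
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} taxa with < {min_points} usable points: "
            + ", ".join(excluded)
        )
    if not rows:
        raise ValueError("no taxon has enough usable occurrence points")
    return pd.DataFrame(rows).T, excluded


# ---------------------------------------------------------------------
# ordination and clustering
# ---------------------------------------------------------------------

@dataclass
class PcaResult:
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame    # observations x components
    variance_fractions: np.ndarray


def pca(matrix: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """Full PCA with a deterministic sign convention.

    Columns are standardized (mean 0, SD 1) by default; a zero-variance
    column under standardization is an error naming the column.  Each
    component is flipped so its largest-magnitude loading is positive.
    Variance fractions sort descending and sum to 1.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("pca needs at least 2 rows and 2 columns")
    mu = X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            names = [str(matrix.columns[i]) for i in dead] if hasattr(matrix, "columns") else list(dead)
            raise ValueError(f"zero-variance column(s) under standardization: {names}")
        Xs = (X - mu) / sd
    else:
        Xs = X - mu
    model = PCA(n_components=min(Xs.shape))
    scores = model.fit_transform(Xs)
    load = model.components_.T  # variables x components
    for j in range(load.shape[1]):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(load.shape[1])]
    var_names = list(matrix.columns) if hasattr(matrix, "columns") else list(range(X.shape[1]))
    idx = list(matrix.index) if hasattr(matrix, "index") else list(range(X.shape[0]))
    return PcaResult(
        loadings=pd.DataFrame(load, index=var_names, columns=comp_names),
        scores=pd.DataFrame(scores, index=idx, columns=comp_names),
        variance_fractions=model.explained_variance_ratio_.copy(),
    )


@dataclass
class ClusterAssignment:
    assignments: dict[str, int]          # taxon -> cluster id in 1..k
    point_clusters: np.ndarray           # cluster id per occurrence point
    cluster_means: pd.DataFrame          # cluster x PC mean scores


def hcpc_clusters(
    point_scores: np.ndarray,
    point_taxa: Sequence[str],
    k: int = DEFAULT_N_CLUSTERS,
    n_pcs: int = DEFAULT_N_PCS,
) -> ClusterAssignment:
    """Ward clustering of occurrence points on leading PC scores (HCPC).

    Points cluster by Ward-linkage agglomeration on their first ``n_pcs``
    principal-component scores, cut into ``k`` groups; each taxon is
    assigned the cluster holding the majority of its points (ties to the
    smaller cluster id).  Deterministic for a given input.
    """
    S = np.asarray(point_scores, dtype=float)
    if S.ndim != 2:
        raise ValueError("point_scores must be 2-D")
    if k > S.shape[0]:
        raise ValueError(f"k={k} exceeds the number of points ({S.shape[0]})")
    if len(point_taxa) != S.shape[0]:
        raise ValueError("one taxon label per point required")
    S = S[:, : min(n_pcs, S.shape[1])]
    Z = linkage(S, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    assignments: dict[str, int] = {}
    for taxon in sorted(set(point_taxa)):
        mask = np.asarray([t == taxon for t in point_taxa])
        counts = np.bincount(labels[mask], minlength=k + 1)
        assignments[taxon] = int(np.argmax(counts))  # argmax takes smallest id on ties
    means = pd.DataFrame(
        [S[labels == c].mean(axis=0) for c in range(1, k + 1)],
        index=pd.Index(range(1, k + 1), name="cluster"),
        columns=[f"PC{j + 1}" for j in range(S.shape[1])],
    )
    return ClusterAssignment(assignments, labels, means)


# ---------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------

def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick tree (string or file path); unit branch lengths are
    imputed with a warning when absent."""
    import os

    if os.path.exists(source):
        tree = dendropy.Tree.get(path=source, schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(data=source, schema="newick", preserve_underscores=True)
    missing = [e for e in tree.edges() if e.length is None and e.head_node.parent_node is not None]
    if missing:
        warnings.warn("tree has edges without branch lengths; imputing unit lengths")
        for e in missing:
            e.length = 1.0
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def sister_pairs(tree: dendropy.Tree) -> list[tuple[str, str]]:
    """All cherries: internal nodes whose two children are both tips."""
    pairs = []
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(c.is_leaf() for c in children):
            a, b = sorted(c.taxon.label for c in children)
            pairs.append((a, b))
    return sorted(pairs)


def phylo_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Shared-branch-length matrix C: C[i,j] = depth of the MRCA of i and j.

    Diagonal entries are tip depths (root-to-tip path lengths).
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    labels = [nd.taxon.label for nd in leaves]
    if len(labels) != len(set(labels)):
        raise ValueError("tip labels are not unique")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    C = np.zeros((n, n))
    for i, li in enumerate(leaves):
        C[i, i] = li.root_distance
        for j in range(i + 1, n):
            lj = leaves[j]
            d = pdm.patristic_distance(li.taxon, lj.taxon)
            C[i, j] = C[j, i] = 0.5 * (li.root_distance + lj.root_distance - d)
    return pd.DataFrame(C, index=labels, columns=labels)


# ---------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------

@dataclass
class KResult:
    variable: str
    k: float
    p_value: float
    n_perm: int


def blomberg_k(
    tree: dendropy.Tree,
    traits: Mapping[str, float] | pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    variable: str = "trait",
    C: pd.DataFrame | None = None,
) -> KResult:
    """Blomberg's K with a tip-label permutation test.

    The observed statistic ranks 1/MSE (with MSE the GLS mean-squared
    error under the tree's covariance) against ``n_perm`` random
    reassignments of trait values to tips; ``p = (1 + #(perm >= obs)) /
    (n_perm + 1)``.  Pass ``n_perm=0`` to skip the test (p reported as 1).
    ``C`` short-circuits the covariance computation when the caller has
    it already (e.g. across the columns of a trait table).
    """
    if C is None:
        C = phylo_covariance(tree)
    labels = list(C.index)
    traits = pd.Series(traits)
    missing = sorted(set(labels) ^ set(traits.index))
    if missing:
        raise ValueError(f"tips and trait names differ: {missing}")
    if len(labels) < 4:
        raise ValueError("blomberg_k needs at least 4 tips")
    x = traits.loc[labels].to_numpy(dtype=float)
    Cm = C.to_numpy()
    Ci = np.linalg.inv(Cm)
    n = len(x)
    ones = np.ones(n)
    ci1 = Ci @ ones
    s = float(ones @ ci1)
    expected = (np.trace(Cm) - n / Ci.sum()) / (n - 1)

    def ratios(v: np.ndarray) -> tuple[float, float]:
        a = float(v @ ci1) / s
        r = v - a
        num = float(r @ r)
        den = float(r @ Ci @ r)
        return num, den

    num, den = ratios(x)
    k = (num / den) / expected
    if n_perm <= 0:
        return KResult(variable, float(k), 1.0, 0)
    rng = np.random.default_rng(seed)
    obs_stat = (n - 1) / den  # 1 / MSE
    hits = 0
    for _ in range(n_perm):
        xp = x[rng.permutation(n)]
        _, dp = ratios(xp)
        if (n - 1) / dp >= obs_stat:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return KResult(variable, float(k), float(p), n_perm)


def blomberg_k_table(
    tree: dendropy.Tree,
    trait_table: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> list[KResult]:
    """K and permutation p for each trait-table column (variable)."""
    C = phylo_covariance(tree)
    out = []
    for j, col in enumerate(trait_table.columns):
        out.append(
            blomberg_k(
                tree, trait_table[col], n_perm=n_perm, seed=seed + j,
                variable=str(col), C=C,
            )
        )
    return out


def conservatism_fraction(kresults: Sequence[KResult], rule: str = "p") -> float:
    """Fraction of variables showing phylogenetic niche conservatism.

    rule "p": p < 0.05; rule "k_and_p": additionally K > 1.
    """
    if not kresults:
        raise ValueError("no K results")
    if rule == "p":
        hits = sum(r.p_value < 0.05 for r in kresults)
    elif rule == "k_and_p":
        hits = sum(r.p_value < 0.05 and r.k > 1.0 for r in kresults)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return hits / len(kresults)


# ---------------------------------------------------------------------
# Mantel test and distance builders
# ---------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int


def _check_dist(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=1e-10):
        raise ValueError(f"{name} must have a zero diagonal")
    return m


def mantel(
    dist_a: np.ndarray | pd.DataFrame,
    dist_b: np.ndarray | pd.DataFrame,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlation of two distance matrices, one-sided upper test.

    r is the Pearson correlation of the off-diagonal entries; the null
    co-permutes rows and columns of the second matrix, and
    ``p = (1 + #(perm r >= observed)) / (n_perm + 1)``.
    """
    if isinstance(dist_a, pd.DataFrame) and isinstance(dist_b, pd.DataFrame):
        if list(dist_a.index) != list(dist_b.index):
            dist_b = dist_b.loc[dist_a.index, dist_a.index]
    A = _check_dist(np.asarray(dist_a, dtype=float), "dist_a")
    B = _check_dist(np.asarray(dist_b, dtype=float), "dist_b")
    if A.shape != B.shape:
        raise ValueError("distance matrices must match in size")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a = A[iu]

    def corr(bm: np.ndarray) -> float:
        b = bm[iu]
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr(B)
    if n_perm <= 0:
        return MantelResult(r_obs, 1.0, 0)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(B[np.ix_(perm, perm)]) >= r_obs:
            hits += 1
    return MantelResult(r_obs, (1 + hits) / (n_perm + 1), n_perm)


def mahalanobis_distances(
    trait_table: pd.DataFrame, ridge: float | None = MAHALANOBIS_RIDGE
) -> pd.DataFrame:
    """Pairwise Mahalanobis distance between taxa in trait space.

    Uses the pooled covariance of the trait table; a singular covariance
    gets a ridge (ridge * mean diagonal * I) before inversion, or raises
    if ridge is None.
    """
    X = trait_table.to_numpy(dtype=float)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        VI = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        if ridge is None:
            raise ValueError("singular trait covariance and no ridge allowed")
        VI = np.linalg.inv(cov + ridge * np.mean(np.diag(cov)) * np.eye(cov.shape[0]))
    diff = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,kl,ijl->ij", diff, VI, diff)
    D = np.sqrt(np.clip(d2, 0.0, None))
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=trait_table.index, columns=trait_table.index)


def geographic_distances(
    centroids: Mapping[str, tuple[float, float]]
) -> pd.DataFrame:
    """Great-circle distance (km) between taxon occurrence centroids."""
    names = sorted(centroids)
    n = len(names)
    D = np.zeros((n, n))
    for i, a in enumerate(names):
        for j in range(i + 1, n):
            b = names[j]
            d = haversine_km(centroids[a][0], centroids[a][1], centroids[b][0], centroids[b][1])
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=names, columns=names)


def taxon_centroids(
    records: Sequence[OccurrenceRecord],
) -> dict[str, tuple[float, float]]:
    """Mean (lon, lat) of coordinate-bearing records per taxon."""
    sums: dict[str, list[float]] = {}
    for r in records:
        if r.has_coords:
            acc = sums.setdefault(r.taxon, [0.0, 0.0, 0.0])
            acc[0] += r.lon
            acc[1] += r.lat
            acc[2] += 1.0
    return {t: (a[0] / a[2], a[1] / a[2]) for t, a in sums.items()}


def cophenetic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic (path-length) distance between all tip pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    labels = [nd.taxon.label for nd in leaves]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
    return pd.DataFrame(D, index=labels, columns=labels)
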