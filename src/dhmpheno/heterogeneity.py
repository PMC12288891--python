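"""UMAP embedding, density contours, dendrograms and the tumor
heterogeneity score.

The heterogeneity score quantifies intra-sample phenotypic dispersion: all
cells of one comparison are embedded jointly into 2D with UMAP, the
centroid c of each sample's cells is taken in that embedding, and each
cell contributes d_i = ||x_i - c||^2, the squared Euclidean distance to
its own sample's centroid.  The per-sample score is the arithmetic mean of
its d_i.  UMAP coordinates carry arbitrary scale, so scores are comparable
only within one fitted embedding; cross-embedding comparisons are refused.

Group comparisons of per-cell scores use the Mann-Whitney U test for two
groups and Kruskal-Wallis with Dunn's post-hoc (Bonferroni-adjusted) for
more, all two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist
from skimage import measure

__all__ = [
    "EmbeddingResult",
    "HeterogeneityResult",
    "DendrogramResult",
    "embed_umap",
    "density_contours",
    "select_top_features",
    "sample_dendrogram",
    "heterogeneity_score",
    "compare_heterogeneity",
    "dunn_posthoc",
]


@dataclass
class EmbeddingResult:
    coords: np.ndarray                 # (n, 2)
    sample_of: np.ndarray              # (n,) sample labels
    umap_params: dict = field(default_factory=dict)
    fitted_on: np.ndarray | None = None  # cell ids
    embedding_id: str = ""


@dataclass
class HeterogeneityResult:
    per_cell_d: np.ndarray
    sample_of: np.ndarray
    per_sample_mean: dict[str, float]
    centroid_per_sample: dict[str, np.ndarray]
    space: str = "embedding-2d"
    embedding_id: str = ""


@dataclass
class DendrogramResult:
    linkage_tree: np.ndarray           # scipy linkage matrix
    leaf_labels: list[str]
    feature_subset: list[str]
    representatives: np.ndarray        # per-sample median vectors

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_tree[:, 2]

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_tree)

        def walk(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.leaf_labels[node.id]}:{length:.6g}"
            return (f"({walk(node.left, node.dist)},"
                    f"{walk(node.right, node.dist)}):{length:.6g}")

        return walk(tree, tree.dist) + ";"


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def embed_umap(X: np.ndarray, sample_labels, n_neighbors: int = 15,
               min_dist: float = 0.1, seed: int = 0) -> EmbeddingResult:
    """Joint 2D UMAP of all cells in one comparison (z-scored features).

    Deterministic for a fixed seed (single-threaded fit).
    """
    import umap  # deferred: numba jit on first import

    X = np.asarray(X, dtype=float)
    sample_labels = np.asarray(sample_labels)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 cells to embed")
    bad = ~np.all(np.isfinite(X), axis=1)
    if bad.any():
        raise ValueError(f"non-finite features for cells {np.nonzero(bad)[0].tolist()}")
    Z = _zscore(X)
    # identical feature rows must map to identical coordinates: fit on the
    # unique rows and broadcast back (the stochastic layout would otherwise
    # jitter exact duplicates apart)
    uniq, inverse = np.unique(Z, axis=0, return_inverse=True)
    reducer = umap.UMAP(n_components=2,
                        n_neighbors=min(n_neighbors, max(2, uniq.shape[0] - 1)),
                        min_dist=min_dist, random_state=seed)
    coords = np.asarray(reducer.fit_transform(uniq), dtype=float)[inverse]
    params = {"n_neighbors": n_neighbors, "min_dist": min_dist, "seed": seed}
    return EmbeddingResult(coords=coords, sample_of=sample_labels,
                           umap_params=params,
                           embedding_id=f"umap-{seed}-{X.shape[0]}")


def density_contours(coords: np.ndarray, group_labels,
                     mass_levels: tuple[float, ...] = (0.25, 0.5, 0.75),
                     grid_size: int = 128, pad_frac: float = 0.2):
    """Per-group bivariate Gaussian KDE contours on a shared regular grid.

    Contour levels are highest-density levels enclosing the given
    probability masses.  Returns a dict:
    group -> {"levels": ..., "polylines": [(k,2) arrays in data coords],
    "integral": grid integral of the KDE}.  All-coincident groups are
    skipped with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    group_labels = np.asarray(group_labels)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    lo = lo - pad_frac * span
    hi = hi + pad_frac * span
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    mx, my = np.meshgrid(gx, gy, indexing="ij")
    grid_pts = np.vstack([mx.ravel(), my.ravel()])
    dx, dy = gx[1] - gx[0], gy[1] - gy[0]

    out: dict = {}
    for g in np.unique(group_labels):
        pts = coords[group_labels == g]
        if pts.shape[0] < 5:
            warnings.warn(f"group {g!r}: fewer than 5 points, skipped")
            continue
        if np.allclose(pts.std(axis=0), 0):
            warnings.warn(f"group {g!r}: all points coincident, skipped")
            continue
        kde = stats.gaussian_kde(pts.T)
        dens = kde(grid_pts).reshape(grid_size, grid_size)
        integral = float(dens.sum() * dx * dy)
        # highest-density levels enclosing each mass fraction
        order = np.argsort(dens.ravel())[::-1]
        cmass = np.cumsum(dens.ravel()[order]) * dx * dy
        levels = []
        for m in mass_levels:
            k = np.searchsorted(cmass, m * integral)
            k = min(k, order.size - 1)
            levels.append(float(dens.ravel()[order[k]]))
        polylines = []
        for lev in levels:
            for c in measure.find_contours(dens, lev):
                xy = np.column_stack([np.interp(c[:, 0], np.arange(grid_size), gx),
                                      np.interp(c[:, 1], np.arange(grid_size), gy)])
                polylines.append(xy)
        out[g] = {"levels": levels, "polylines": polylines,
                  "integral": integral}
    return out


def select_top_features(X: np.ndarray, labels, feature_names,
                        k: int = 26, seed: int = 0) -> list[str]:
    """Top-k features by random-forest impurity importance.

    Descending importance; ties broken by feature name for stability.
    """
    from sklearn.ensemble import RandomForestClassifier

    X = np.asarray(X, dtype=float)
    names = list(feature_names)
    if k > len(names):
        raise ValueError(f"k={k} exceeds the {len(names)} available features")
    rf = RandomForestClassifier(n_estimators=100, random_state=seed)
    rf.fit(X, np.asarray(labels))
    imp = rf.feature_importances_
    order = sorted(range(len(names)), key=lambda i: (-imp[i], names[i]))
    return [names[i] for i in order[:k]]


def sample_dendrogram(X: np.ndarray, sample_labels, feature_names,
                      top_features: list[str]) -> DendrogramResult:
    """Single-linkage dendrogram over per-sample representatives.

    Each sample is represented by the median vector of its cells over the
    selected features after z-scoring across all cells; samples are
    agglomerated by single linkage on Euclidean distances.  Leaf order is
    the sorted sample names, so merges are deterministic.
    """
    X = np.asarray(X, dtype=float)
    sample_labels = np.asarray(sample_labels)
    names = list(feature_names)
    cols = [names.index(f) for f in top_features]
    samples = sorted(map(str, np.unique(sample_labels)))
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    Z = _zscore(X[:, cols])
    reps = []
    for s in samples:
        rows = Z[sample_labels.astype(str) == s]
        if rows.shape[0] == 0:
            raise ValueError(f"sample {s!r} has no cells")
        reps.append(np.median(rows, axis=0))
    reps = np.asarray(reps)
    link = linkage(pdist(reps, metric="euclidean"), method="single")
    return DendrogramResult(linkage_tree=link, leaf_labels=samples,
                            feature_subset=list(top_features),
                            representatives=reps)


def heterogeneity_score(embedding: EmbeddingResult) -> HeterogeneityResult:
    """Per-cell squared distance to the cell's own sample centroid.

    c is the mean 2D coordinate of the sample's cells; d_i = ||x_i - c||^2.
    The per-sample score is mean(d_i).  Samples of size 1 get d = 0 with a
    warning (the score is undefined dispersion-wise).
    """
    coords = np.asarray(embedding.coords, dtype=float)
    labels = np.asarray(embedding.sample_of)
    d = np.empty(coords.shape[0])
    means: dict[str, float] = {}
    cents: dict[str, np.ndarray] = {}
    for s in np.unique(labels):
        idx = labels == s
        c = coords[idx].mean(axis=0)
        di = np.sum((coords[idx] - c) ** 2, axis=1)
        if idx.sum() == 1:
            warnings.warn(f"sample {s!r} has a single cell; score degenerate")
        d[idx] = di
        means[str(s)] = float(di.mean())
        cents[str(s)] = c
    return HeterogeneityResult(per_cell_d=d, sample_of=labels,
                               per_sample_mean=means, centroid_per_sample=cents,
                               embedding_id=embedding.embedding_id)


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests with tie correction and
    Bonferroni adjustment across all pairs (two-sided)."""
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    all_v = np.concatenate(values)
    n_tot = all_v.size
    ranks = stats.rankdata(all_v)
    mean_rank = {}
    i = 0
    for g, v in zip(names, values):
        mean_rank[g] = ranks[i:i + v.size].mean()
        i += v.size
    _, tie_counts = np.unique(all_v, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_tot - 1))
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            na, nb = values[a].size, values[b].size
            se = np.sqrt((n_tot * (n_tot + 1) / 12.0 - tie_term)
                         * (1.0 / na + 1.0 / nb))
            z = (mean_rank[names[a]] - mean_rank[names[b]]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": names[a], "group_b": names[b],
                         "z": float(z), "p_raw": float(p),
                         "p_adj": float(min(1.0, p * m))})
    return pd.DataFrame(rows)


def compare_heterogeneity(result: HeterogeneityResult | dict[str, np.ndarray],
                          same_embedding: bool = True) -> dict:
    """Two-sided group comparison of per-cell heterogeneity scores.

    Mann-Whitney U for 2 groups; Kruskal-Wallis plus Dunn's Bonferroni
    post-hoc for more.  Refuses scores from different embeddings
    (``same_embedding=False``), since UMAP scales are not comparable.
    """
    if not same_embedding:
        raise ValueError("heterogeneity scores from different embeddings are "
                         "not comparable; fit one joint embedding")
    if isinstance(result, HeterogeneityResult):
        groups = {str(s): result.per_cell_d[result.sample_of == s]
                  for s in np.unique(result.sample_of)}
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in result.items()}
    for g, v in groups.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
    out: dict = {"groups": {g: {"n": int(v.size), "mean": float(v.mean())}
                            for g, v in groups.items()}}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if len(groups) == 2:
        (ga, va), (gb, vb) = groups.items()
        u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        out["test"] = "mann-whitney"
        out["statistic"] = float(u)
        out["p_value"] = float(p)
    else:
        h, p = stats.kruskal(*groups.values())
        out["test"] = "kruskal-wallis"
        out["statistic"] = float(h)
        out["p_value"] = float(p)
        out["dunn_bonferroni"] = dunn_posthoc(groups).to_dict(orient="records")
    return out
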