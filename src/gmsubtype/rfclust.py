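"""Unsupervised random-forest subtype clustering.

The clustering core works in five steps:

1. :func:`rf_proximity` — a two-class random forest separates the
   observed subjects from an equal-sized synthetic contrast set (each
   synthetic row permutes every feature column independently, which
   preserves the marginals but destroys the dependence structure).
   The fraction of trees in which two observed subjects share a
   terminal node is their proximity.
2. :func:`proximity_to_dissimilarity` — d = sqrt(1 - proximity).
3. :func:`average_linkage` — UPGMA-style group-average agglomeration.
4. :func:`select_k` — cut the tree at each K and pick the K with the
   highest Calinski-Harabasz index, computed in the residual ROI space.
5. :func:`gini_importance` / :func:`supervised_discrimination` — rank
   ROIs by mean decrease in Gini impurity from a supervised forest on
   the cluster labels, then refit on the top ROIs to measure
   out-of-bag discrimination and per-ROI separation direction.

:func:`stability_assessment` repeats step 1 with fresh seeds and
reports the elementwise difference from the main proximity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import calinski_harabasz_score

from .preprocess import ResidualMatrix

DEFAULT_N_TREES = 2000
DEFAULT_FOREST_REPEATS = 5
DEFAULT_K_RANGE = tuple(range(2, 11))


def _as_matrix(residuals) -> tuple[np.ndarray, list[str]]:
    """Accept a ResidualMatrix, DataFrame or ndarray; return array + names."""
    if isinstance(residuals, ResidualMatrix):
        return residuals.values.to_numpy(dtype=float), residuals.roi_names
    if isinstance(residuals, pd.DataFrame):
        return residuals.to_numpy(dtype=float), list(residuals.columns)
    arr = np.asarray(residuals, dtype=float)
    return arr, [f"f{j}" for j in range(arr.shape[1])]


# ---------------------------------------------------------------------------
# proximity

@dataclass
class ProximityMatrix:
    """Symmetric n x n co-assignment similarity in [0, 1]."""

    values: np.ndarray
    n_trees: int
    seed: int
    forest_repeats: int = 1
    scheme: str = "columnwise-permutation"

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("proximity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("proximity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("proximity matrix must have unit diagonal")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("proximity entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _synthetic_contrast(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each column independently: marginals kept, dependence broken."""
    synth = np.empty_like(X)
    for j in range(X.shape[1]):
        synth[:, j] = rng.permutation(X[:, j])
    return synth


def _tree_coassignment(leaves: np.ndarray) -> np.ndarray:
    """Mean co-occupancy of terminal nodes over trees; leaves is n x T."""
    n, n_trees = leaves.shape
    prox = np.zeros((n, n), dtype=float)
    for t in range(n_trees):
        col = leaves[:, t]
        prox += col[:, None] == col[None, :]
    return prox / n_trees


def rf_proximity(residuals,
                 n_trees: int = DEFAULT_N_TREES,
                 seed: int = 0,
                 forest_repeats: int = DEFAULT_FOREST_REPEATS) -> ProximityMatrix:
    """Random-forest proximity of observed subjects.

    Builds ``forest_repeats`` two-class forests (observed vs synthetic
    contrast, class balance 1:1), each with its own synthetic draw, and
    averages their proximities to damp Monte-Carlo noise.  Deterministic
    given ``seed``.
    """
    X, _ = _as_matrix(residuals)
    n = X.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 subjects, got {n}")
    if np.isnan(X).any():
        raise ValueError("residuals contain missing values")
    if n_trees < 100:
        raise ValueError("n_trees must be at least 100")
    if forest_repeats < 1:
        raise ValueError("forest_repeats must be at least 1")
    if np.all(np.ptp(X, axis=0) == 0):
        raise ValueError("degenerate input: all features are constant")

    root = np.random.default_rng(seed)
    prox = np.zeros((n, n), dtype=float)
    for _ in range(forest_repeats):
        contrast_rng = np.random.default_rng(root.integers(2 ** 31))
        forest_seed = int(root.integers(2 ** 31))
        synth = _synthetic_contrast(X, contrast_rng)
        X_all = np.vstack([X, synth])
        y = np.repeat([0, 1], n)
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=forest_seed,
            n_jobs=1, min_samples_leaf=1)
        forest.fit(X_all, y)
        leaves = forest.apply(X)
        prox += _tree_coassignment(leaves)
    prox /= forest_repeats
    np.fill_diagonal(prox, 1.0)
    prox = (prox + prox.T) / 2.0
    return ProximityMatrix(values=prox, n_trees=n_trees, seed=seed,
                           forest_repeats=forest_repeats)


def proximity_to_dissimilarity(prox: ProximityMatrix | np.ndarray,
                               transform: str = "sqrt") -> np.ndarray:
    """d = sqrt(1 - proximity) (default) or d = 1 - proximity."""
    values = prox.values if isinstance(prox, ProximityMatrix) else np.asarray(prox)
    if transform == "sqrt":
        d = np.sqrt(np.clip(1.0 - values, 0.0, None))
    elif transform == "linear":
        d = np.clip(1.0 - values, 0.0, None)
    else:
        raise ValueError(f"unknown transform: {transform!r}")
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# agglomeration

@dataclass
class LinkageTree:
    """Average-linkage merge tree over n leaves (scipy linkage encoding)."""

    merges: np.ndarray  # (n-1) x 4 scipy linkage matrix
    method: str = "average"

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def cut(self, k: int) -> np.ndarray:
        """Labels 1..k, numbered by order of first appearance."""
        raw = hierarchy.cut_tree(self.merges, n_clusters=k).ravel()
        _, first = np.unique(raw, return_index=True)
        order = {raw[i]: rank + 1 for rank, i in enumerate(np.sort(first))}
        return np.array([order[r] for r in raw])

    def cophenetic(self) -> np.ndarray:
        return squareform(hierarchy.cophenet(self.merges))

    def to_newick(self, leaf_names=None) -> str:
        """Newick string with branch lengths derived from merge heights."""
        root = hierarchy.to_tree(self.merges)
        if leaf_names is None:
            leaf_names = [f"L{i}" for i in range(self.n_leaves)]

        def render(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{leaf_names[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.10g}"

        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"


def average_linkage(dissimilarity: np.ndarray) -> LinkageTree:
    """Unweighted group-average (UPGMA-style) agglomeration.

    Requires a symmetric, zero-diagonal, non-negative dissimilarity.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(D, D.T):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("dissimilarity must have zero diagonal")
    if D.min() < 0:
        raise ValueError("dissimilarity must be non-negative")
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return LinkageTree(merges=Z)


# ---------------------------------------------------------------------------
# model selection

@dataclass
class ClusterSolution:
    """Tree cuts for each K, their CH indices, and the selected K."""

    labels_by_k: dict[int, np.ndarray]
    ch_by_k: dict[int, float]
    chosen_k: int
    degenerate_k: tuple[int, ...] = ()
    provenance: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        """Labels at the chosen K (1-based)."""
        return self.labels_by_k[self.chosen_k]

    def ch_table(self) -> pd.DataFrame:
        ks = sorted(self.ch_by_k)
        return pd.DataFrame({"k": ks, "ch_index": [self.ch_by_k[k] for k in ks],
                             "chosen": [k == self.chosen_k for k in ks]})


def select_k(tree: LinkageTree, residuals,
             k_range=DEFAULT_K_RANGE) -> ClusterSolution:
    """Choose the number of clusters by the Calinski-Harabasz index.

    Cuts the tree at each K in ``k_range`` and evaluates CH(K) in the
    residual feature space; the chosen K maximizes CH (lowest K wins
    ties).  A cut with zero within-cluster dispersion gets CH = +inf
    and is flagged as degenerate.
    """
    X, _ = _as_matrix(residuals)
    k_range = sorted(k_range)
    if k_range[0] < 2:
        raise ValueError("k_range must start at 2 or above")
    if X.shape[0] <= k_range[-1]:
        raise ValueError(f"n={X.shape[0]} must exceed max(k_range)={k_range[-1]}")
    labels_by_k: dict[int, np.ndarray] = {}
    ch_by_k: dict[int, float] = {}
    degenerate: list[int] = []
    for k in k_range:
        labels = tree.cut(k)
        labels_by_k[k] = labels
        with np.errstate(divide="ignore", invalid="ignore"):
            ch = calinski_harabasz_score(X, labels)
        if not np.isfinite(ch):
            ch = float("inf")
            degenerate.append(k)
            warnings.warn(f"K={k}: zero within-cluster dispersion, CH set to +inf")
        ch_by_k[k] = float(ch)
    chosen = max(k_range, key=lambda k: (ch_by_k[k], -k))
    return ClusterSolution(labels_by_k=labels_by_k, ch_by_k=ch_by_k,
                           chosen_k=chosen, degenerate_k=tuple(degenerate))


# ---------------------------------------------------------------------------
# importance & discrimination

@dataclass
class ImportanceRanking:
    """Per-ROI mean decrease in Gini impurity, ranked."""

    scores: pd.Series      # index: ROI name, in input order
    top_k: int = 10

    @property
    def ranking(self) -> list[str]:
        """ROI names from most to least important (ties: input order)."""
        order = np.argsort(-self.scores.to_numpy(), kind="stable")
        return [self.scores.index[i] for i in order]

    @property
    def top(self) -> list[str]:
        return self.ranking[: self.top_k]

    def to_frame(self) -> pd.DataFrame:
        ranked = self.ranking
        rank = {name: i + 1 for i, name in enumerate(ranked)}
        return pd.DataFrame({
            "roi": self.scores.index,
            "gini_importance": self.scores.to_numpy(),
            "rank": [rank[r] for r in self.scores.index],
        })


def _canonical_row_order(X: np.ndarray) -> np.ndarray:
    """Lexicographic row order, making forest fits row-order invariant."""
    return np.lexsort(X.T[::-1])


def gini_importance(residuals, labels,
                    n_trees: int = DEFAULT_N_TREES,
                    seed: int = 0,
                    top_k: int = 10) -> ImportanceRanking:
    """Rank ROIs by mean decrease in Gini from a supervised forest.

    The forest predicts the cluster labels from all ROI residuals; the
    rows are internally sorted into a canonical order before fitting so
    the ranking does not depend on subject ordering.
    """
    X, names = _as_matrix(residuals)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 clusters to rank importances")
    order = _canonical_row_order(X)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
    forest.fit(X[order], labels[order])
    scores = pd.Series(forest.feature_importances_, index=names,
                       name="gini_importance")
    return ImportanceRanking(scores=scores, top_k=top_k)


@dataclass
class DiscriminationSummary:
    """Out-of-bag performance of the reduced (top-ROI) supervised forest."""

    oob_accuracy: float
    confusion: pd.DataFrame          # rows: true cluster, cols: OOB predicted
    importances: pd.Series           # within the reduced model
    cluster_means: pd.DataFrame      # clusters x ROIs mean residuals
    separations: dict[str, tuple[tuple[int, ...], tuple[int, ...]]]
    # per ROI: (low-mean cluster group, high-mean cluster group)

    def separation_table(self) -> pd.DataFrame:
        rows = []
        for roi, (low, high) in self.separations.items():
            rows.append({"roi": roi,
                         "low_clusters": "+".join(map(str, low)),
                         "high_clusters": "+".join(map(str, high))})
        return pd.DataFrame(rows)


def _gap_split(means: pd.Series) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Split clusters at the largest gap in their sorted ROI means."""
    ordered = means.sort_values()
    gaps = np.diff(ordered.to_numpy())
    cut = int(np.argmax(gaps)) + 1
    low = tuple(sorted(int(c) for c in ordered.index[:cut]))
    high = tuple(sorted(int(c) for c in ordered.index[cut:]))
    return low, high


def supervised_discrimination(residuals, labels,
                              n_trees: int = DEFAULT_N_TREES,
                              seed: int = 0) -> DiscriminationSummary:
    """Fit a supervised forest on the top-ROI residuals and summarize it.

    ``residuals`` must already be restricted to the predictor ROIs
    (typically the Gini top 10).  Reports the out-of-bag confusion
    matrix, within-model importances, and for each ROI which cluster
    groups it separates (largest gap between sorted cluster means).
    """
    X, names = _as_matrix(residuals)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("need at least 2 clusters")
    order = _canonical_row_order(X)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    oob_score=True, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-n rows may never be OOB
        forest.fit(X[order], labels[order])
    oob = forest.oob_decision_function_
    valid = ~np.isnan(oob).any(axis=1)
    pred = forest.classes_[np.argmax(oob[valid], axis=1)]
    true = labels[order][valid]
    confusion = pd.crosstab(pd.Series(true, name="true"),
                            pd.Series(pred, name="oob_predicted"))
    confusion = confusion.reindex(index=clusters, columns=clusters, fill_value=0)
    accuracy = float((pred == true).mean())
    importances = pd.Series(forest.feature_importances_, index=names,
                            name="gini_importance")
    cmeans = pd.DataFrame(
        {name: {int(c): X[labels == c, j].mean() for c in clusters}
         for j, name in enumerate(names)})
    cmeans.index.name = "cluster"
    separations = {name: _gap_split(cmeans[name]) for name in names}
    return DiscriminationSummary(oob_accuracy=accuracy, confusion=confusion,
                                 importances=importances, cluster_means=cmeans,
                                 separations=separations)


# ---------------------------------------------------------------------------
# stability

@dataclass
class StabilityReport:
    """Proximity-matrix differences over repeated forest builds."""

    differences: np.ndarray       # mean |diff| over the upper triangle, per repeat
    max_differences: np.ndarray   # max |diff|, per repeat
    metric: str = "mean-abs-upper-triangle"

    @property
    def mean(self) -> float:
        return float(self.differences.mean())

    @property
    def max(self) -> float:
        return float(self.max_differences.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "repeat": np.arange(1, len(self.differences) + 1),
            "mean_abs_difference": self.differences,
            "max_abs_difference": self.max_differences,
        })


def stability_assessment(residuals, main_prox: ProximityMatrix,
                         n_repeats: int = 100,
                         base_seed: int = 0,
                         n_trees: int | None = None,
                         forest_repeats: int | None = None) -> StabilityReport:
    """Rebuild the proximity matrix ``n_repeats`` times with fresh seeds.

    Each repeat r uses seed ``base_seed + r``; the difference from the
    main matrix is the mean absolute elementwise deviation over the
    upper triangle (the max deviation is reported alongside).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    X, _ = _as_matrix(residuals)
    if X.shape[0] != main_prox.n:
        raise ValueError("main proximity matrix does not match residuals")
    n_trees = n_trees if n_trees is not None else main_prox.n_trees
    forest_repeats = (forest_repeats if forest_repeats is not None
                      else main_prox.forest_repeats)
    iu = np.triu_indices(main_prox.n, k=1)
    main_vals = main_prox.values[iu]
    mean_diffs = np.empty(n_repeats)
    max_diffs = np.empty(n_repeats)
    for r in range(1, n_repeats + 1):
        rep = rf_proximity(X, n_trees=n_trees, seed=base_seed + r,
                           forest_repeats=forest_repeats)
        diff = np.abs(rep.values[iu] - main_vals)
        mean_diffs[r - 1] = diff.mean()
        max_diffs[r - 1] = diff.max()
    return StabilityReport(differences=mean_diffs, max_differences=max_diffs)
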